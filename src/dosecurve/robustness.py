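"""Model-robustness diagnostics.

Three families of summary statistics:

* ``qq_normality_rho`` — the Pearson correlation of a normal Q-Q plot
  (rho_N), a scalar diagnostic of how normal a residual sample looks.
* inter-batch statistics — for one perturbation condition measured in two
  batches, the Pearson correlation (rho_inter) of the two model-derived
  log2 fold-change vectors over genes, and the per-gene between-batch SD
  (|a - b| / sqrt(2) for two batches).
* intra-batch statistics — correlations between *different* conditions in
  the same batch (rho_intra), expected near zero when perturbation signal,
  not batch identity, drives the fold changes.

``batch_comparison_report`` runs all three per model family over a tidy
log2FC table, so that the robust fits (spline GAM, Huber ANOVA) can be
compared against the OLS baseline.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "qq_normality_rho",
    "pairwise_log2fc_stats",
    "log2fc_table_from_experiments",
    "batch_comparison_report",
]


def log2fc_table_from_experiments(experiments, model_kinds=("GAM", "RLM", "LM")
                                  ) -> pd.DataFrame:
    """Fit each requested model family per gene and tabulate log2 fold changes.

    Produces the tidy input of :func:`batch_comparison_report`: one row per
    (model_kind, batch, compound, cell line, time, dose, gene).
    """
    from .diffexpr import contrast_vs_vehicle
    from .models import fit_gam, fit_lm, fit_rlm

    fitters = {"GAM": fit_gam, "RLM": fit_rlm, "LM": fit_lm}
    rows = []
    for exp in experiments:
        design = exp.design()
        for kind in model_kinds:
            for gene_id in exp.gene_ids:
                try:
                    est = fitters[kind](design, exp.y(gene_id))
                except Exception:
                    continue
                for t in design.time_levels:
                    for dose in design.dose_levels:
                        fc, _ = contrast_vs_vehicle(est, float(np.log10(dose)), t)
                        rows.append({
                            "model_kind": kind, "batch": exp.group_id,
                            "pert_id": exp.pert_id, "cell_id": exp.cell_id,
                            "time": t, "dose": float(dose),
                            "gene_id": gene_id, "log2fc": fc,
                        })
    return pd.DataFrame(rows)


def qq_normality_rho(residuals) -> float:
    """Pearson correlation between sorted residuals and normal plotting quantiles.

    Uses Blom plotting positions (i - 3/8) / (n + 1/4). Values near 1
    indicate agreement with normality; heavy tails pull the statistic down.
    """
    r = np.asarray(residuals, dtype=float).ravel()
    if r.size < 3:
        raise ValueError("need at least 3 residuals for a Q-Q correlation")
    if np.std(r) == 0:
        return float("nan")
    order = np.sort(r)
    pos = (np.arange(1, r.size + 1) - 0.375) / (r.size + 0.25)
    q = stats.norm.ppf(pos)
    return float(stats.pearsonr(order, q)[0])


def pairwise_log2fc_stats(a, b) -> tuple[float, np.ndarray]:
    """Correlation and per-gene SD of two aligned log2FC vectors.

    Returns ``(rho, sd)`` where ``sd[g] = |a[g] - b[g]| / sqrt(2)``, the
    sample SD of the two batch values for gene g.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("log2FC vectors must be aligned")
    if a.size < 3:
        raise ValueError("need at least 3 shared genes")
    sd = np.abs(a - b) / np.sqrt(2.0)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), sd
    return float(stats.pearsonr(a, b)[0]), sd


def _condition_vectors(table: pd.DataFrame):
    """Map (condition, batch) -> log2FC Series indexed by gene."""
    out = {}
    cond_cols = ["pert_id", "cell_id", "time", "dose"]
    for (batch, *cond), grp in table.groupby(["batch"] + cond_cols, sort=True):
        out[(tuple(cond), batch)] = grp.set_index("gene_id")["log2fc"]
    return out


def batch_comparison_report(log2fc_table: pd.DataFrame,
                            model_kinds=("GAM", "RLM", "LM")) -> pd.DataFrame:
    """Inter-/intra-batch correlation and SD summaries per model family.

    Parameters
    ----------
    log2fc_table : DataFrame
        Tidy table with columns ``model_kind, batch, pert_id, cell_id, time,
        dose, gene_id, log2fc`` (one row per gene and condition).

    Returns
    -------
    Tidy DataFrame with columns ``model_kind, statistic, median, n`` where
    statistic is one of ``rho_inter``, ``rho_intra``, ``sd_inter``; plus the
    raw per-pair values in the attribute ``.attrs['pairs']``.
    """
    required = {"model_kind", "batch", "pert_id", "cell_id", "time",
                "dose", "gene_id", "log2fc"}
    missing = required - set(log2fc_table.columns)
    if missing:
        raise ValueError(f"log2fc table missing columns: {sorted(missing)}")

    rows = []
    raw = {}
    for kind in model_kinds:
        sub = log2fc_table[log2fc_table["model_kind"] == kind]
        vectors = _condition_vectors(sub)
        rho_inter, sds, rho_intra = [], [], []

        by_cond: dict = {}
        for (cond, batch), vec in vectors.items():
            by_cond.setdefault(cond, {})[batch] = vec
        # inter-batch: same condition, all unordered batch pairs
        for cond, per_batch in by_cond.items():
            for b1, b2 in itertools.combinations(sorted(per_batch), 2):
                v1, v2 = per_batch[b1].align(per_batch[b2], join="inner")
                if v1.size < 3:
                    continue
                rho, sd = pairwise_log2fc_stats(v1.to_numpy(), v2.to_numpy())
                rho_inter.append(rho)
                sds.extend(sd.tolist())
        # intra-batch: same batch, different conditions
        by_batch: dict = {}
        for (cond, batch), vec in vectors.items():
            by_batch.setdefault(batch, {})[cond] = vec
        for batch, per_cond in by_batch.items():
            for c1, c2 in itertools.combinations(sorted(per_cond), 2):
                if c1[:2] == c2[:2]:
                    continue  # same compound/cell pair is not an unrelated condition
                v1, v2 = per_cond[c1].align(per_cond[c2], join="inner")
                if v1.size < 3:
                    continue
                rho, _ = pairwise_log2fc_stats(v1.to_numpy(), v2.to_numpy())
                rho_intra.append(rho)

        raw[kind] = {"rho_inter": rho_inter, "rho_intra": rho_intra,
                     "sd_inter": sds}
        for stat, values in raw[kind].items():
            values = [v for v in values if np.isfinite(v)]
            rows.append({
                "model_kind": kind,
                "statistic": stat,
                "median": float(np.median(values)) if values else float("nan"),
                "n": len(values),
            })

    if not any(raw[k]["rho_inter"] for k in raw):
        logger.warning("no matched conditions across batches: inter-batch "
                       "section is empty")
    report = pd.DataFrame(rows)
    report.attrs["pairs"] = raw
    return report
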