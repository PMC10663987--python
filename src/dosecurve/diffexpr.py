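"""Differential expression: each nonzero concentration against the vehicle baseline.

For a spline (GAM) fit the contrast at log10 dose ``x*`` is the linear
functional ``(b(x*) - b(cp)) beta`` with standard error from the coefficient
covariance; the t-statistic is referred to a t distribution whose degrees of
freedom are the model's residual (effective) degrees of freedom, which need
not be an integer. For cell-means models the contrast is the difference of
the treated and baseline cell means.

P-values are adjusted by Benjamini-Hochberg step-up within each
(experiment, dose, time) stratum; the stratum choice is recorded in the
output metadata so users can re-adjust under a different family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import PenalizedSplineGAM

logger = logging.getLogger(__name__)

__all__ = [
    "contrast_vs_vehicle",
    "t_test",
    "bh_adjust",
    "run_differential_expression",
    "ALPHA",
]

ALPHA = 0.05


def contrast_vs_vehicle(fit, x_star: float, time_level=0) -> tuple[float, float]:
    """log2 fold change of the fit at ``x_star`` versus the vehicle baseline, with SE.

    The baseline is the pseudo-concentration ``cp`` for spline fits and the
    zero-dose cell for cell-means fits.
    """
    if isinstance(fit, PenalizedSplineGAM):
        cp = getattr(fit, "cp_", fit.x_min_)
        fit._check_range(np.array([x_star]))
        c = fit.basis_row(x_star, time_level) - fit.basis_row(cp, time_level)
        log2fc = float(c @ fit.coef_)
        se = float(np.sqrt(max(c @ fit.cov_ @ c, 0.0)))
    else:
        cp = getattr(fit, "cp_", None)
        if cp is None:
            cp = float(np.min(fit.cells_[:, 0]))
        i = fit._cell_index(x_star, time_level)
        j = fit._cell_index(cp, time_level)
        if i == j:
            return 0.0, 0.0
        log2fc = float(fit.coef_[i] - fit.coef_[j])
        var = fit.cov_[i, i] + fit.cov_[j, j] - 2.0 * fit.cov_[i, j]
        se = float(np.sqrt(max(var, 0.0)))
    return log2fc, se


def t_test(log2fc: float, se: float, d: float) -> float:
    """Two-sided p-value of the contrast t-statistic with ``d`` degrees of freedom.

    ``d`` may be non-integer (effective degrees of freedom of a penalized
    fit). A zero standard error gives an undefined (NaN) p-value rather
    than false certainty.
    """
    if d <= 0:
        raise ValueError("degrees of freedom must be positive")
    if not np.isfinite(se) or se <= 0:
        # degenerate fit: the contrast of a condition against itself is the
        # only zero-variance case that is exactly null
        return 1.0 if log2fc == 0 and se == 0 else float("nan")
    t = log2fc / se
    return float(2.0 * stats.t.sf(abs(t), d))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs propagate and do not count in m."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.sum() == 0:
        return out
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def run_differential_expression(experiment, fits: dict, alpha: float = ALPHA) -> pd.DataFrame:
    """Test every (gene, nonzero dose, time) contrast of one experiment.

    Parameters
    ----------
    experiment : PerturbationExperiment
        Provides the dose design (doses, times, cp).
    fits : dict
        Mapping gene_id -> fitted model (spline or cell-means estimator).

    Returns
    -------
    DataFrame with one row per (gene, dose, time): columns gene_id, dose, x,
    time, log2fc, se, t, df, p, padj, significant. ``padj`` is BH-adjusted
    across genes within each (dose, time) stratum.
    """
    design = experiment.design()
    rows = []
    skipped = 0
    for gene_id in experiment.gene_ids:
        fit = fits.get(gene_id)
        if fit is None or not getattr(fit, "converged_", False):
            skipped += 1
            continue
        d = fit.df_resid_
        for time_level in design.time_levels:
            for dose in design.dose_levels:
                x_star = float(np.log10(dose))
                log2fc, se = contrast_vs_vehicle(fit, x_star, time_level)
                p = t_test(log2fc, se, d)
                rows.append({
                    "gene_id": gene_id,
                    "dose": float(dose),
                    "x": x_star,
                    "time": time_level,
                    "log2fc": log2fc,
                    "se": se,
                    "t": log2fc / se if se > 0 else np.nan,
                    "df": d,
                    "p": p,
                })
    if skipped:
        logger.info("differential expression: skipped %d gene(s) without a "
                    "converged fit", skipped)
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["padj"] = np.nan
    for _, idx in table.groupby(["dose", "time"]).groups.items():
        table.loc[idx, "padj"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    table["significant"] = table["padj"] < alpha
    table.attrs["bh_family"] = "per (experiment, dose, time) stratum"
    table.attrs["alpha"] = alpha
    return table
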