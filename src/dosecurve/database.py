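"""Four-table results layout: combination, model, test, interaction.

* ``combination`` — one row per (pert_id, group_id, cell_id) tuple with an
  integer surrogate key ``combo_id``. The same compound measured in two
  batches yields two combination rows, so a compound record is identified
  by the (pert_id, group_id) pair.
* ``model`` — which family (spline GAM vs robust ANOVA) was fitted for each
  (combo, gene) and whether it converged.
* ``test`` — the differential-expression contrasts (log2FC, SE, df, p, padj)
  for every nonzero concentration and time.
* ``interaction`` — efficacy/potency estimates with standard errors; rows
  exist only for spline-fitted genes, since cell-means fits define no curve.

Serialized to SQLite (primary) or a TSV set (secondary); both round-trip
losslessly through :func:`read_database`.

The exact field list of the published artifact is not reproducible from
prose alone; this schema is a documented reconstruction carrying every
named quantity (fold changes, SEs, degrees of freedom, potency/efficacy
estimates and their SEs, the pseudo-concentration).
"""

from __future__ import annotations

import sqlite3
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TABLE_NAMES",
    "IntegrityError",
    "build_tables",
    "validate_tables",
    "write_database",
    "read_database",
    "export_efficacy_matrix",
]

TABLE_NAMES = ("combination", "model", "test", "interaction")


class IntegrityError(ValueError):
    """Raised when foreign keys across the four tables do not resolve."""


def build_tables(experiments, fits_by_experiment, test_tables,
                 interaction_tables) -> dict[str, pd.DataFrame]:
    """Assemble the four-table layout from per-experiment results.

    Parameters
    ----------
    experiments : sequence of PerturbationExperiment
    fits_by_experiment : sequence of dict
        Per experiment, mapping gene_id -> fitted estimator (aligned with
        ``experiments``).
    test_tables, interaction_tables : sequence of DataFrame
        Per-experiment outputs of ``run_differential_expression`` and
        ``run_potency`` (aligned with ``experiments``).
    """
    combos, model_rows, test_parts, inter_parts = [], [], [], []
    combo_ids: dict[tuple, int] = {}
    for exp, fits, test_df, inter_df in zip(
            experiments, fits_by_experiment, test_tables,
            interaction_tables):
        key = (exp.pert_id, exp.group_id, exp.cell_id)
        if key in combo_ids:           # duplicate tuples collapse to one row
            combo_id = combo_ids[key]
        else:
            combo_id = combo_ids[key] = len(combo_ids) + 1
            combos.append({
                "combo_id": combo_id,
                "pert_id": exp.pert_id,
                "group_id": exp.group_id,
                "cell_id": exp.cell_id,
            })
        for gene_id, fit in fits.items():
            model_rows.append({
                "combo_id": combo_id,
                "gene_id": gene_id,
                "model_kind": fit.kind,
                "converged": bool(getattr(fit, "converged_", False)),
                "edf": float(getattr(fit, "edf_", np.nan)),
                "n": int(getattr(fit, "n_samples_", 0)),
            })
        if test_df is not None and not test_df.empty:
            t = test_df.copy()
            t.insert(0, "combo_id", combo_id)
            test_parts.append(t)
        if inter_df is not None and not inter_df.empty:
            t = inter_df.copy()
            t.insert(0, "combo_id", combo_id)
            inter_parts.append(t)

    combination = pd.DataFrame(combos,
                               columns=["combo_id", "pert_id", "group_id",
                                        "cell_id"])
    tables = {
        "combination": combination,
        "model": pd.DataFrame(model_rows, columns=[
            "combo_id", "gene_id", "model_kind", "converged", "edf",
            "n"]).drop_duplicates(["combo_id", "gene_id"],
                                  ignore_index=True),
        "test": (pd.concat(test_parts, ignore_index=True)
                 if test_parts else pd.DataFrame(columns=[
                     "combo_id", "gene_id", "dose", "x", "time", "log2fc",
                     "se", "t", "df", "p", "padj", "significant"])),
        "interaction": (pd.concat(inter_parts, ignore_index=True)
                        if inter_parts else pd.DataFrame(columns=[
                            "combo_id", "gene_id", "time", "direction",
                            "log2_max_effect", "se_max_effect", "log10_xc50",
                            "se_xc50", "cp", "y0", "y_ext", "x_ext",
                            "flags"])),
    }
    validate_tables(tables)
    return tables


def validate_tables(tables: dict[str, pd.DataFrame]) -> None:
    """Check referential integrity of the four-table layout."""
    for name in TABLE_NAMES:
        if name not in tables:
            raise IntegrityError(f"missing table {name!r}")
    known = set(tables["combination"]["combo_id"])
    offenders = {}
    for name in ("model", "test", "interaction"):
        dangling = set(tables[name]["combo_id"]) - known
        if dangling:
            offenders[name] = sorted(dangling)
    if offenders:
        raise IntegrityError(f"dangling combo_id keys: {offenders}")
    # interaction rows only for spline-fitted genes
    model = tables["model"]
    gam_pairs = set(map(tuple, model.loc[model["model_kind"] == "GAM",
                                         ["combo_id", "gene_id"]].itertuples(
                                             index=False)))
    if not model.empty and not tables["interaction"].empty:
        inter_pairs = set(map(tuple, tables["interaction"][
            ["combo_id", "gene_id"]].itertuples(index=False)))
        bad = inter_pairs - gam_pairs
        if bad:
            raise IntegrityError(
                f"interaction rows for non-GAM fits: {sorted(bad)[:5]}")


def write_database(tables: dict[str, pd.DataFrame], path,
                   fmt: str = "sqlite", provenance: dict | None = None) -> None:
    """Serialize the four tables to SQLite or a TSV set (directory)."""
    validate_tables(tables)
    path = Path(path)
    if fmt == "sqlite":
        with sqlite3.connect(path) as con:
            for name in TABLE_NAMES:
                tables[name].to_sql(name, con, index=False,
                                    if_exists="replace")
            if provenance:
                pd.DataFrame([provenance]).to_sql("provenance", con,
                                                  index=False,
                                                  if_exists="replace")
    elif fmt == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        for name in TABLE_NAMES:
            tables[name].to_csv(path / f"{name}.tsv", sep="\t", index=False)
        if provenance:
            pd.DataFrame([provenance]).to_csv(path / "provenance.tsv",
                                              sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'sqlite' or 'tsv')")


def read_database(path, fmt: str = "sqlite") -> dict[str, pd.DataFrame]:
    """Read back a serialized four-table set."""
    path = Path(path)
    tables = {}
    if fmt == "sqlite":
        with sqlite3.connect(path) as con:
            for name in TABLE_NAMES:
                tables[name] = pd.read_sql(f"SELECT * FROM {name}", con)
            tables["test"]["significant"] = \
                tables["test"]["significant"].astype(bool)
            tables["model"]["converged"] = \
                tables["model"]["converged"].astype(bool)
    elif fmt == "tsv":
        for name in TABLE_NAMES:
            tables[name] = pd.read_csv(path / f"{name}.tsv", sep="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return tables


def export_efficacy_matrix(interaction: pd.DataFrame,
                           combination: pd.DataFrame,
                           cell_id: str | None = None) -> pd.DataFrame:
    """Genes x compounds matrix of log2 maximum effect, for clustering.

    Columns are labelled ``pert_id@group_id``; pairs without a spline fit
    are NaN. Only compounds with at least one potency row appear.
    """
    combo = combination
    if cell_id is not None:
        combo = combo[combo["cell_id"] == cell_id]
    merged = interaction.merge(combo, on="combo_id", how="inner")
    if merged.empty:
        return pd.DataFrame()
    merged = merged.assign(
        compound=merged["pert_id"].astype(str) + "@"
        + merged["group_id"].astype(str))
    return merged.pivot_table(index="gene_id", columns="compound",
                              values="log2_max_effect", aggfunc="first")
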