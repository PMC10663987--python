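"""Reading L1000-style expression data and assembling per-compound experiments.

Supports the GCT v1.3 text format and the conventional GCTX (HDF5) layout
(``/0/DATA/0/matrix`` with row/column id datasets), plus a TSV instance-
metadata table with a configurable column mapping. Treatment wells are
grouped into one :class:`PerturbationExperiment` per (pert_id, group_id,
cell_id) tuple together with the vehicle-control (DMSO) wells of the plates
those treatments sit on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .design import DoseDesign, round_doses, transform_doses

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PerturbationExperiment",
    "GCTFormatError",
    "read_gct",
    "write_gct",
    "read_gctx",
    "write_gctx",
    "read_instance_metadata",
    "assemble_experiments",
    "DEFAULT_COLUMN_MAP",
]

DEFAULT_COLUMN_MAP = {
    "sample_id": "inst_id",
    "pert_id": "pert_id",
    "dose": "pert_dose",
    "dose_unit": "pert_dose_unit",
    "time": "pert_time",
    "cell_id": "cell_id",
    "plate_id": "rna_plate",
    "well": "rna_well",
    "pert_type": "pert_type",
    "group_id": "group_id",
}

VEHICLE_TYPES = {"vehicle_control", "ctl_vehicle"}
TREATMENT_TYPES = {"treatment", "trt_cp"}


class GCTFormatError(ValueError):
    """Raised for malformed GCT/GCTX containers."""


@dataclass
class ExpressionMatrix:
    """Dense log2 expression, genes x samples, with opaque annotations."""

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    row_meta: pd.DataFrame | None = None
    col_meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise GCTFormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise GCTFormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GCTFormatError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise GCTFormatError("non-finite expression values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)


def read_gct(path) -> ExpressionMatrix:
    """Read a GCT v1.3 text file."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.3":
            raise GCTFormatError(f"unsupported GCT version line: {version!r}")
        dims = fh.readline().split()
        if len(dims) != 4:
            raise GCTFormatError("GCT dimension line must have 4 fields")
        try:
            n_rows, n_cols, n_rmeta, n_cmeta = map(int, dims)
        except ValueError as exc:
            raise GCTFormatError("non-integer GCT dimensions") from exc

        header = fh.readline().rstrip("\n").split("\t")
        expected_width = 1 + n_rmeta + n_cols
        if len(header) != expected_width:
            raise GCTFormatError(
                f"header width {len(header)} != declared {expected_width}")
        rmeta_names = header[1:1 + n_rmeta]
        sample_ids = header[1 + n_rmeta:]

        col_meta_rows = []
        for _ in range(n_cmeta):
            fields = fh.readline().rstrip("\n").split("\t")
            if len(fields) != expected_width:
                raise GCTFormatError("column-annotation row width mismatch")
            col_meta_rows.append(fields)

        gene_ids, rmeta_vals, data = [], [], []
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != expected_width:
                raise GCTFormatError("data row width mismatch")
            gene_ids.append(fields[0])
            rmeta_vals.append(fields[1:1 + n_rmeta])
            try:
                data.append([float(v) for v in fields[1 + n_rmeta:]])
            except ValueError as exc:
                raise GCTFormatError("non-numeric expression value") from exc

    if len(gene_ids) != n_rows:
        raise GCTFormatError(
            f"declared {n_rows} rows but body has {len(gene_ids)}")
    values = np.asarray(data, dtype=float).reshape(n_rows, n_cols)

    row_meta = pd.DataFrame(rmeta_vals, index=gene_ids, columns=rmeta_names,
                            dtype=str) if n_rmeta else None
    col_meta = None
    if n_cmeta:
        col_meta = pd.DataFrame(
            {row[0]: row[1 + n_rmeta:] for row in col_meta_rows},
            index=sample_ids, dtype=str)
    return ExpressionMatrix(gene_ids, sample_ids, values, row_meta, col_meta)


def write_gct(matrix: ExpressionMatrix, path) -> None:
    """Write a GCT v1.3 text file."""
    rmeta = matrix.row_meta if matrix.row_meta is not None else pd.DataFrame(
        index=matrix.gene_ids)
    cmeta = matrix.col_meta if matrix.col_meta is not None else pd.DataFrame(
        index=matrix.sample_ids)
    n_rmeta, n_cmeta = rmeta.shape[1], cmeta.shape[1]
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{len(matrix.gene_ids)}\t{len(matrix.sample_ids)}"
                 f"\t{n_rmeta}\t{n_cmeta}\n")
        fh.write("\t".join(["id", *rmeta.columns.astype(str),
                            *map(str, matrix.sample_ids)]) + "\n")
        for name in cmeta.columns:
            fh.write("\t".join([str(name)] + ["na"] * n_rmeta
                               + [str(v) for v in cmeta[name]]) + "\n")
        for i, gid in enumerate(matrix.gene_ids):
            fields = [str(gid)] + [str(v) for v in rmeta.iloc[i]] \
                + [repr(float(v)) for v in matrix.values[i]]
            fh.write("\t".join(fields) + "\n")


def read_gctx(path) -> ExpressionMatrix:
    """Read a GCTX (HDF5) container with the conventional /0/DATA/0/matrix layout.

    The matrix dataset is stored samples x genes and transposed on read.
    """
    with h5py.File(path, "r") as f:
        try:
            mat = f["/0/DATA/0/matrix"][...]
            rids = [_as_str(v) for v in f["/0/META/ROW/id"][...]]
            cids = [_as_str(v) for v in f["/0/META/COL/id"][...]]
        except KeyError as exc:
            raise GCTFormatError(f"missing GCTX dataset: {exc}") from exc
    if mat.shape == (len(cids), len(rids)):
        mat = mat.T
    elif mat.shape != (len(rids), len(cids)):
        raise GCTFormatError(f"GCTX matrix shape {mat.shape} inconsistent "
                             f"with {len(rids)} rows / {len(cids)} cols")
    return ExpressionMatrix(rids, cids, np.asarray(mat, dtype=float))


def write_gctx(matrix: ExpressionMatrix, path) -> None:
    """Write the conventional GCTX layout (matrix stored samples x genes)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("/0/DATA/0/matrix",
                         data=matrix.values.T.astype("f8"))
        str_dt = h5py.string_dtype()
        f.create_dataset("/0/META/ROW/id",
                         data=[str(g) for g in matrix.gene_ids], dtype=str_dt)
        f.create_dataset("/0/META/COL/id",
                         data=[str(s) for s in matrix.sample_ids], dtype=str_dt)


def _as_str(v) -> str:
    return v.decode() if isinstance(v, bytes) else str(v)


def read_instance_metadata(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read instance (per-well) metadata from TSV into the canonical schema.

    Canonical columns: sample_id, pert_id, group_id, cell_id, dose,
    dose_unit, time, plate_id, well, pert_type. When no group_id column is
    present the batch is derived as the plate-name prefix before the first
    ``_X`` replicate marker (e.g. ``LJP005_MCF7_24H_X1_B19`` -> ``LJP005``).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    meta = pd.DataFrame(index=raw.index)
    for canon, source in cmap.items():
        if source in raw.columns:
            meta[canon] = raw[source]
        elif canon in ("dose_unit", "well", "group_id"):
            meta[canon] = None
        else:
            raise GCTFormatError(f"metadata missing required column "
                                 f"{source!r} (for {canon})")
    meta["dose"] = pd.to_numeric(meta["dose"], errors="coerce")
    if meta["group_id"].isna().all():
        meta["group_id"] = meta["plate_id"].str.split("_").str[0]
    if meta["sample_id"].duplicated().any():
        raise GCTFormatError("duplicate sample ids in metadata")
    return meta


def _canon_pert_type(t: str) -> str:
    t = str(t).lower()
    if t in VEHICLE_TYPES:
        return "vehicle_control"
    if t in TREATMENT_TYPES:
        return "treatment"
    return "other"


@dataclass
class PerturbationExperiment:
    """One (compound, batch, cell line) dilution series plus matched vehicle wells."""

    pert_id: str
    group_id: str
    cell_id: str
    expression: pd.DataFrame          # genes x samples (treatment + vehicle)
    meta: pd.DataFrame                # per-sample: dose, time, plate_id, pert_type
    dilution_factor: float | None = None

    @property
    def gene_ids(self) -> list:
        return list(self.expression.index)

    @property
    def sample_ids(self) -> list:
        return list(self.expression.columns)

    @property
    def dose_levels(self) -> np.ndarray:
        doses = round_doses(self.meta["dose"].to_numpy(dtype=float))
        return np.sort(np.unique(doses[doses > 0]))

    @property
    def time_levels(self) -> np.ndarray:
        return np.sort(self.meta["time"].unique())

    @property
    def C(self) -> int:
        return int(self.dose_levels.size)

    @property
    def K(self) -> int:
        return int(self.time_levels.size)

    def design(self) -> DoseDesign:
        return transform_doses(
            self.meta["dose"].to_numpy(dtype=float),
            time_labels=self.meta["time"].to_numpy(),
            dilution_factor=self.dilution_factor,
        )

    def y(self, gene_id) -> np.ndarray:
        """Expression of one gene aligned to the design rows."""
        return self.expression.loc[gene_id].to_numpy(dtype=float)

    def validate(self) -> None:
        doses = self.meta["dose"].to_numpy(dtype=float)
        types = self.meta["pert_type"].to_numpy()
        if not np.all((doses == 0) == (types == "vehicle_control")):
            raise ValueError("dose is 0 iff the well is a vehicle control")
        if self.C < 1:
            raise ValueError("experiment has no nonzero dose")


def assemble_experiments(matrix: ExpressionMatrix,
                         meta: pd.DataFrame) -> list[PerturbationExperiment]:
    """Group treatment wells into experiments with their same-plate vehicle wells.

    One experiment per (pert_id, group_id, cell_id) with >= 1 treatment
    sample; its vehicle wells are exactly the vehicle_control samples on the
    plates of its treatment wells (shared across compounds on a plate).
    Experiments whose plates carry no vehicle well are excluded with a
    logged reason; wells that are neither treatment nor vehicle are dropped.
    """
    meta = meta.copy()
    missing = set(meta["sample_id"]) - set(map(str, matrix.sample_ids))
    if missing:
        raise ValueError(f"{len(missing)} metadata samples absent from the "
                         f"matrix, e.g. {sorted(missing)[:3]}")
    meta["pert_type"] = meta["pert_type"].map(_canon_pert_type)
    n_other = int((meta["pert_type"] == "other").sum())
    if n_other:
        logger.info("dropping %d well(s) with pert_type other than "
                    "treatment/vehicle_control", n_other)
    meta = meta[meta["pert_type"] != "other"]
    meta["dose"] = round_doses(meta["dose"].fillna(0.0).to_numpy(dtype=float))
    meta.loc[meta["pert_type"] == "vehicle_control", "dose"] = 0.0

    frame = matrix.to_frame()
    frame.columns = frame.columns.map(str)
    vehicles = meta[meta["pert_type"] == "vehicle_control"]
    treatments = meta[(meta["pert_type"] == "treatment") & (meta["dose"] > 0)]
    n_bad = int(((meta["pert_type"] == "treatment") & (meta["dose"] <= 0)).sum())
    if n_bad:
        logger.warning("dropping %d treatment well(s) with nonpositive dose",
                       n_bad)

    experiments = []
    for (pert_id, group_id, cell_id), trt in treatments.groupby(
            ["pert_id", "group_id", "cell_id"], sort=True):
        plates = set(trt["plate_id"])
        veh = vehicles[vehicles["plate_id"].isin(plates)]
        if veh.empty:
            logger.warning("excluding %s/%s/%s: no vehicle well on plate(s) %s",
                           pert_id, group_id, cell_id, sorted(plates))
            continue
        sub = pd.concat([trt, veh]).drop_duplicates("sample_id")
        sub = sub.set_index("sample_id")
        exp = PerturbationExperiment(
            pert_id=pert_id, group_id=group_id, cell_id=cell_id,
            expression=frame[sub.index.tolist()],
            meta=sub,
        )
        exp.validate()
        experiments.append(exp)
    return experiments
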