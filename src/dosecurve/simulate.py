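"""Synthetic L1000-like experiments with known ground truth.

The generator emulates the structure of a compound-perturbation plate:
DMSO vehicle wells at dose zero, a geometric dilution series, one or more
time points, replicate wells, and approximately normal log2-expression
noise with an optional fraction of gross outliers. True per-gene curves
come in three families:

* ``null`` — flat at the baseline;
* ``hill`` — the standard sigmoid
  ``y0 + Emax / (1 + 10**(slope * (log10EC50 - x)))``;
* ``hook`` — a rise-then-fall (or fall-then-rise) product of two sigmoids,
  the non-monotone shape that defeats parametric sigmoid fits.

The truth table records, per gene, the generating parameters together with
the *operational* truth used for recovery benchmarking: the extremum effect
and midpoint-crossing concentration of the noiseless curve restricted to
the tested range (matching the estimator's definitions, since a curve whose
asymptote lies beyond the top dose never attains its full Emax on-plate).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize

from .design import transform_doses
from .l1000io import ExpressionMatrix, PerturbationExperiment

__all__ = [
    "SimulationSpec",
    "SimulatedExperiment",
    "hill_curve",
    "hook_curve",
    "true_curve",
    "simulate_experiment",
    "simulate_replicated_batches",
]


def hill_curve(x, y0: float, emax: float, log10_ec50: float, slope: float):
    """Sigmoid log2 expression: ``y0 + emax / (1 + 10**(slope*(log10_ec50 - x)))``."""
    if slope <= 0:
        raise ValueError("hill slope must be positive")
    x = np.asarray(x, dtype=float)
    return y0 + emax / (1.0 + 10.0 ** (slope * (log10_ec50 - x)))


def hook_curve(x, y0: float, emax: float, log10_ec50: float, slope: float,
               descent_offset: float = 1.5, descent_slope: float = 2.0):
    """Rise-then-fall curve: a sigmoid multiplied by a descending sigmoid.

    The effect rises with midpoint ``log10_ec50`` and collapses again with
    midpoint ``log10_ec50 + descent_offset``.
    """
    if slope <= 0 or descent_slope <= 0:
        raise ValueError("slopes must be positive")
    x = np.asarray(x, dtype=float)
    rise = 1.0 / (1.0 + 10.0 ** (slope * (log10_ec50 - x)))
    fall = 1.0 / (1.0 + 10.0 ** (descent_slope * (x - log10_ec50 - descent_offset)))
    return y0 + emax * rise * fall


@dataclass
class SimulationSpec:
    """Design and ground-truth parameters of one simulated experiment.

    Defaults emulate a typical compound dilution plate: 8 half-log doses
    from 10 uM down, 3 replicate treatment wells per dose, 6 DMSO vehicle
    wells, one 24 h time point, and log2 noise SD 0.1.
    """

    n_genes: int = 50
    top_dose: float = 10.0            # in dose units (uM)
    dilution_factor: float = 10.0 ** 0.5
    n_doses: int = 8
    replicates: int = 3
    n_vehicle: int = 6
    time_levels: tuple = (24,)
    noise_sd: float = 0.1
    outlier_frac: float = 0.0
    outlier_scale: float = 4.0        # offset magnitude in units of noise_sd
    frac_null: float = 0.2
    frac_hook: float = 0.1            # remainder of non-null genes are hill
    effect_range: tuple = (0.5, 3.0)  # |max effect| in log2 units
    baseline_range: tuple = (4.0, 12.0)
    slope_range: tuple = (0.75, 2.0)
    activator_frac: float = 0.5
    n_batches: int = 1
    batch_sd: float = 0.0
    seed: int | None = None
    pert_id: str = "CPD-001"
    cell_id: str = "CELL-A"

    def dose_series(self) -> np.ndarray:
        return self.top_dose / self.dilution_factor ** np.arange(self.n_doses)[::-1]

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible simulation")
        if self.n_doses < 1 or self.noise_sd <= 0:
            raise ValueError("need at least one dose and positive noise SD")
        if not 0 <= self.outlier_frac <= 0.5:
            raise ValueError("outlier fraction must lie in [0, 0.5]")


class SimulatedExperiment(NamedTuple):
    experiment: PerturbationExperiment
    truth: pd.DataFrame               # per-gene generating + operational truth
    truth_fc: pd.DataFrame            # per (gene, dose): true log2FC vs baseline


def _draw_truth(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_genes
    families = rng.choice(
        ["null", "hook", "hill"], size=n,
        p=[spec.frac_null, spec.frac_hook,
           1.0 - spec.frac_null - spec.frac_hook])
    doses = spec.dose_series()
    lx = np.log10(doses)
    rows = []
    for g in range(n):
        fam = families[g]
        y0 = rng.uniform(*spec.baseline_range)
        sign = 1.0 if rng.random() < spec.activator_frac else -1.0
        emax = sign * rng.uniform(*spec.effect_range)
        # midpoint inside the tested range so potency is identifiable
        ec50 = rng.uniform(lx[1], lx[-2]) if spec.n_doses >= 3 else lx[0]
        slope = rng.uniform(*spec.slope_range)
        rows.append({
            "gene_id": f"G{g:04d}", "family": fam, "y0": y0,
            "emax": 0.0 if fam == "null" else emax,
            "log10_ec50": np.nan if fam == "null" else ec50,
            "slope": slope,
            "descent_offset": 1.5, "descent_slope": 2.0,
        })
    return pd.DataFrame(rows).set_index("gene_id", drop=False)


def true_curve(row: pd.Series):
    """Noiseless log2-expression curve of one truth row, as a callable of x."""
    fam = row["family"]
    if fam == "null":
        return lambda x: np.full_like(np.asarray(x, dtype=float), row["y0"])
    if fam == "hill":
        return lambda x: hill_curve(x, row["y0"], row["emax"],
                                    row["log10_ec50"], row["slope"])
    if fam == "hook":
        return lambda x: hook_curve(x, row["y0"], row["emax"],
                                    row["log10_ec50"], row["slope"],
                                    row["descent_offset"], row["descent_slope"])
    raise ValueError(f"unknown curve family {fam!r}")


def _operational_truth(curve, cp: float, x_max: float,
                       grid_n: int = 1024) -> tuple[float, float]:
    """Extremum effect and midpoint crossing of the curve on [cp, x_max]."""
    grid = np.linspace(cp, x_max, grid_n)
    fx = curve(grid)
    y0 = float(fx[0])
    i_min, i_max = int(np.argmin(fx)), int(np.argmax(fx))
    rise, drop = fx[i_max] - y0, y0 - fx[i_min]
    i_ext = i_max if rise > drop else i_min
    y_ext = float(fx[i_ext])
    effect = y_ext - y0
    if effect == 0.0:
        return 0.0, float("nan")
    target = 0.5 * (y0 + y_ext)
    h = fx[:i_ext + 1] - target
    cross = np.flatnonzero(np.sign(h[:-1]) * np.sign(h[1:]) <= 0)
    x50 = float("nan")
    for i in cross:
        if i == 0 and h[0] == 0:
            continue
        try:
            x50 = float(optimize.brentq(
                lambda x: float(curve(np.atleast_1d(x))[0]) - target,
                float(grid[i]), float(grid[i + 1]), xtol=1e-10))
            break
        except ValueError:
            continue
    return effect, x50


def simulate_experiment(spec: SimulationSpec,
                        truth: pd.DataFrame | None = None,
                        group_id: str = "BATCH01",
                        batch_shift: float = 0.0) -> SimulatedExperiment:
    """Generate one experiment (expression + metadata + truth tables)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if truth is None:
        truth = _draw_truth(spec, rng)

    doses = spec.dose_series()
    sample_doses, sample_times, plates = [], [], []
    for t in spec.time_levels:
        sample_doses.extend([0.0] * spec.n_vehicle)
        sample_times.extend([t] * spec.n_vehicle)
        for d in doses:
            sample_doses.extend([d] * spec.replicates)
            sample_times.extend([t] * spec.replicates)
    sample_doses = np.asarray(sample_doses)
    sample_times = np.asarray(sample_times)
    n_samples = sample_doses.size
    plate = f"{group_id}_{spec.cell_id}"

    design = transform_doses(sample_doses, sample_times,
                             dilution_factor=spec.dilution_factor)
    x = design.x

    values = np.empty((spec.n_genes, n_samples))
    fc_rows = []
    op_effect, op_x50 = [], []
    for g, (gid, row) in enumerate(truth.iterrows()):
        curve = true_curve(row)
        mu = curve(x)
        eps = rng.normal(0.0, spec.noise_sd, n_samples)
        if spec.outlier_frac > 0:
            hit = rng.random(n_samples) < spec.outlier_frac
            eps[hit] += (rng.choice([-1.0, 1.0], hit.sum())
                         * spec.outlier_scale * spec.noise_sd)
        values[g] = mu + eps + batch_shift
        baseline = float(curve(np.atleast_1d(design.cp))[0])
        for d in doses:
            fc_rows.append({
                "gene_id": gid, "dose": float(d),
                "true_log2fc": float(curve(np.atleast_1d(np.log10(d)))[0]
                                     - baseline),
            })
        eff, x50 = _operational_truth(curve, design.cp, float(np.max(x)))
        op_effect.append(eff)
        op_x50.append(x50)

    truth = truth.copy()
    truth["cp"] = design.cp
    truth["true_max_effect"] = op_effect
    truth["true_log10_xc50"] = op_x50

    sample_ids = [f"{group_id}:{plate}:W{i:03d}" for i in range(n_samples)]
    matrix = ExpressionMatrix(truth["gene_id"].tolist(), sample_ids, values)
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "pert_id": np.where(sample_doses > 0, spec.pert_id, "DMSO"),
        "group_id": group_id,
        "cell_id": spec.cell_id,
        "dose": sample_doses,
        "dose_unit": "uM",
        "time": sample_times,
        "plate_id": plate,
        "well": [f"W{i:03d}" for i in range(n_samples)],
        "pert_type": np.where(sample_doses > 0, "treatment",
                              "vehicle_control"),
    }).set_index("sample_id", drop=False)

    experiment = PerturbationExperiment(
        pert_id=spec.pert_id, group_id=group_id, cell_id=spec.cell_id,
        expression=matrix.to_frame(),
        meta=meta.drop(columns="sample_id"),
        dilution_factor=spec.dilution_factor,
    )
    return SimulatedExperiment(experiment, truth, pd.DataFrame(fc_rows))


def simulate_replicated_batches(spec: SimulationSpec) -> list[SimulatedExperiment]:
    """The same true curves measured in ``spec.n_batches`` batches.

    Each batch receives an additive shift drawn from N(0, batch_sd^2)
    applied to all of its wells, plus independent well noise.
    """
    spec.validate()
    if spec.n_batches < 2:
        raise ValueError("need at least 2 batches for replication")
    rng = np.random.default_rng(spec.seed)
    truth = _draw_truth(spec, rng)
    shifts = rng.normal(0.0, spec.batch_sd, spec.n_batches) \
        if spec.batch_sd > 0 else np.zeros(spec.n_batches)
    out = []
    for b in range(spec.n_batches):
        sub = replace(spec, seed=int(rng.integers(0, 2 ** 31 - 1)))
        out.append(simulate_experiment(sub, truth=truth,
                                       group_id=f"BATCH{b + 1:02d}",
                                       batch_shift=float(shifts[b])))
    return out
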