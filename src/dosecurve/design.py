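"""Dose design: log10 transform of concentrations and the pseudo-concentration baseline.

Gene expression is modelled against log10 concentration. Vehicle-control wells
carry dose 0, which has no log transform; they are placed on the log axis at a
pseudo-concentration ``cp`` one dilution step below the smallest tested dose:

    cp = log10(d_min) - log10(F)

where ``F`` is the dilution factor of the series (inferred from the dose
ladder when possible, otherwise 10). ``cp`` is carried through all downstream
outputs so linear-scale potencies can be recovered as ``10**(log10_xc50 - cp)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DoseDesign", "transform_doses", "infer_dilution_factor", "round_doses"]


class InvalidDesignError(ValueError):
    """Raised when a dose/time layout cannot support model fitting."""


def round_doses(doses: np.ndarray, sig: int = 4) -> np.ndarray:
    """Round doses to ``sig`` significant figures to merge float-jittered replicates."""
    doses = np.asarray(doses, dtype=float)
    out = np.zeros_like(doses)
    nz = doses != 0
    mag = np.floor(np.log10(np.abs(doses[nz])))
    factor = 10.0 ** (sig - 1 - mag)
    out[nz] = np.round(doses[nz] * factor) / factor
    return out


def infer_dilution_factor(dose_levels: np.ndarray, rtol: float = 0.15) -> float | None:
    """Infer the dilution factor from successive ratios of the sorted dose ladder.

    Returns the median ratio if all successive ratios agree within ``rtol``
    (a geometric series), else None.
    """
    levels = np.sort(np.unique(np.asarray(dose_levels, dtype=float)))
    levels = levels[levels > 0]
    if levels.size < 2:
        return None
    ratios = levels[1:] / levels[:-1]
    med = float(np.median(ratios))
    if med <= 1:
        return None
    if np.all(np.abs(ratios / med - 1) <= rtol):
        return med
    return None


@dataclass
class DoseDesign:
    """Per-sample design points for one experiment.

    Attributes
    ----------
    x : ndarray
        Per-sample log10 concentration; vehicle samples sit at ``cp``.
    time_labels : ndarray
        Per-sample categorical time level.
    cp : float
        Pseudo-concentration (log10) assigned to the zero-dose baseline.
    dose_levels : ndarray
        Sorted unique nonzero doses on the linear scale.
    time_levels : ndarray
        Sorted unique time levels.
    """

    x: np.ndarray
    time_labels: np.ndarray
    cp: float
    dose_levels: np.ndarray
    time_levels: np.ndarray
    dilution_factor: float = 10.0

    @property
    def C(self) -> int:
        return int(self.dose_levels.size)

    @property
    def K(self) -> int:
        return int(self.time_levels.size)

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def x_max(self) -> float:
        return float(np.max(self.x))

    def time_index(self) -> np.ndarray:
        """Integer code of each sample's time level (order of ``time_levels``)."""
        lookup = {t: k for k, t in enumerate(self.time_levels.tolist())}
        return np.array([lookup[t] for t in self.time_labels.tolist()], dtype=int)

    def design_matrix_input(self) -> np.ndarray:
        """(n, 2) array of [x, time_code] accepted by the estimators."""
        return np.column_stack([self.x, self.time_index().astype(float)])


def transform_doses(
    doses,
    time_labels=None,
    dilution_factor: float | None = None,
) -> DoseDesign:
    """Build a :class:`DoseDesign` from per-sample linear-scale doses.

    Nonzero doses map to log10(dose); zero doses (vehicle) map to
    ``cp = log10(d_min) - log10(F)``. ``F`` is ``dilution_factor`` when
    supplied, else inferred from the dose ladder, else 10.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0 or np.any(doses < 0) or not np.all(np.isfinite(doses)):
        raise InvalidDesignError("doses must be finite and nonnegative")
    doses = round_doses(doses)
    nonzero = np.sort(np.unique(doses[doses > 0]))
    if nonzero.size == 0:
        raise InvalidDesignError("all doses are zero: no treatment condition to model")

    if dilution_factor is None:
        dilution_factor = infer_dilution_factor(nonzero)
        if dilution_factor is None:
            dilution_factor = 10.0
    if dilution_factor <= 1:
        raise InvalidDesignError("dilution factor must exceed 1")

    cp = float(np.log10(nonzero[0]) - np.log10(dilution_factor))
    x = np.where(doses > 0, np.log10(np.where(doses > 0, doses, 1.0)), cp)

    if time_labels is None:
        time_labels = np.zeros(doses.size, dtype=int)
    time_labels = np.asarray(time_labels)
    if time_labels.size != doses.size:
        raise InvalidDesignError("time_labels length must match doses")
    time_levels = np.sort(np.unique(time_labels))

    return DoseDesign(
        x=x,
        time_labels=time_labels,
        cp=cp,
        dose_levels=nonzero,
        time_levels=time_levels,
        dilution_factor=float(dilution_factor),
    )
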