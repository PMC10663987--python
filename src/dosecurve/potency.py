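"""Potency and efficacy of compound-gene pairs from fitted spline curves.

A compound is classified per gene as an activator or inhibitor by comparing
the fitted curve's maximum rise and maximum drop relative to the fitted
vehicle baseline ``y0 = f(cp)``. Efficacy is the log2 maximum effect

    log2Emax = ymax - y0   (activator)      log2Imax = ymin - y0   (inhibitor)

over the tested concentration range, and potency is the smallest log10
concentration at which the curve reaches the midpoint between baseline and
extremum:

    f(x50) = (y0 + y_ext) / 2 ,   x50 in (cp, x_ext].

Standard errors: efficacy by the linear contrast c = b(x_ext) - b(cp);
potency by the delta method, with the gradient of x50 with respect to the
spline coefficients obtained in closed form by implicit differentiation of
the midpoint-crossing condition:

    dx50/dbeta = [ (b(cp) + b(x_ext))/2 - b(x50) ] / f'(x50)

(x_ext held fixed: at an interior extremum f'(x_ext) = 0 so its first-order
contribution vanishes; at a boundary extremum it is exactly fixed). The
closed form is validated against finite differences and case-resampling
bootstrap in the test-suite.

These quantities are defined only for spline (GAM) fits; cell-means models
carry no continuous curve to interrogate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .design import DoseDesign
from .models import PenalizedSplineGAM, fit_gam

logger = logging.getLogger(__name__)

__all__ = [
    "PotencyEstimate",
    "fitted_extrema",
    "classify_direction",
    "max_effect_with_se",
    "xc50",
    "delta_se_xc50",
    "bootstrap_se_xc50",
    "percent_max_inhibition",
    "xc50_linear",
    "estimate_potency",
    "run_potency",
]

GRID_N = 512
DERIV_TOL = 1e-8
ROOT_XTOL = 1e-8
FLAT_DERIV_FLOOR = 1e-10


@dataclass
class PotencyEstimate:
    """Efficacy and potency of one compound-gene pair at one time level."""

    gene_id: object
    time_level: object
    direction: str                      # "activator" | "inhibitor"
    log2_max_effect: float              # >= 0 activator, <= 0 inhibitor
    se_max_effect: float
    log10_xc50: float                   # on the cp-shifted log10 axis; NaN if flat
    se_xc50: float
    cp: float
    y0: float
    y_ext: float
    x_ext: float
    flags: list = field(default_factory=list)

    @property
    def xc50_linear(self) -> float:
        return xc50_linear(self.log10_xc50, self.cp)


def _require_gam(fit) -> None:
    if not isinstance(fit, PenalizedSplineGAM):
        raise TypeError(
            "potency/efficacy is defined only for spline (GAM) fits; "
            f"got a {getattr(fit, 'kind', type(fit).__name__)} fit")


def _refine_extremum(f, fprime, x_lo: float, x_hi: float, x0: float) -> float:
    """Refine a grid extremum by locating the stationary point in its bracket."""
    if x_lo >= x_hi:
        return x0
    try:
        g_lo, g_hi = fprime(x_lo), fprime(x_hi)
        if np.sign(g_lo) * np.sign(g_hi) < 0:
            return float(optimize.brentq(fprime, x_lo, x_hi, xtol=DERIV_TOL))
    except ValueError:
        pass
    return x0


def fitted_extrema(fit, time_level=0, grid_n: int = GRID_N,
                   cp: float | None = None):
    """Locate the baseline value and the extrema of one fitted curve.

    Scans a dense grid over [cp, x_max] and refines interior candidates to a
    stationary point. Returns ``(y0, ymin, ymax, x_at_min, x_at_max)``.
    """
    _require_gam(fit)
    if cp is None:
        cp = getattr(fit, "cp_", fit.x_min_)
    x_hi = fit.x_max_
    grid = np.linspace(cp, x_hi, grid_n)
    f = lambda x: float(fit.curve(np.atleast_1d(x), time_level,
                                  check_range=False)[0])
    fp = lambda x: float(fit.curve_deriv(np.atleast_1d(x), time_level)[0])
    fx = fit.curve(grid, time_level, check_range=False)
    y0 = float(fx[0])
    step = grid[1] - grid[0] if grid_n > 1 else 0.0

    def locate(idx: int) -> float:
        x0 = float(grid[idx])
        if idx in (0, grid_n - 1):
            return x0
        return _refine_extremum(f, fp, x0 - step, x0 + step, x0)

    x_at_min = locate(int(np.argmin(fx)))
    x_at_max = locate(int(np.argmax(fx)))
    ymin = min(f(x_at_min), float(np.min(fx)))
    ymax = max(f(x_at_max), float(np.max(fx)))
    return y0, ymin, ymax, x_at_min, x_at_max


def classify_direction(y0: float, ymin: float, ymax: float) -> str:
    """Activator iff the rise above baseline exceeds the drop below it; ties → inhibitor."""
    rise = ymax - y0
    drop = y0 - ymin
    return "activator" if rise > drop else "inhibitor"


def max_effect_with_se(fit, x_ext: float, time_level=0,
                       cp: float | None = None) -> tuple[float, float]:
    """Maximum log2 effect ``f(x_ext) - f(cp)`` and its contrast SE."""
    _require_gam(fit)
    if cp is None:
        cp = getattr(fit, "cp_", fit.x_min_)
    c = fit.basis_row(x_ext, time_level) - fit.basis_row(cp, time_level)
    est = float(c @ fit.coef_)
    se = float(np.sqrt(max(c @ fit.cov_ @ c, 0.0)))
    return est, se


def xc50(fit, x_ext: float, time_level=0, cp: float | None = None,
         grid_n: int = GRID_N) -> float:
    """Smallest x in (cp, x_ext] where the curve crosses the baseline-extremum midpoint.

    Returns NaN when the curve is numerically flat (no crossing).
    """
    _require_gam(fit)
    if cp is None:
        cp = getattr(fit, "cp_", fit.x_min_)
    y0 = float(fit.curve(np.atleast_1d(cp), time_level, check_range=False)[0])
    y_ext = float(fit.curve(np.atleast_1d(x_ext), time_level,
                            check_range=False)[0])
    if y_ext == y0:
        return float("nan")
    target = 0.5 * (y0 + y_ext)
    grid = np.linspace(cp, x_ext, grid_n)
    h = fit.curve(grid, time_level, check_range=False) - target
    crossings = np.flatnonzero(np.sign(h[:-1]) * np.sign(h[1:]) <= 0)
    g = lambda x: float(fit.curve(np.atleast_1d(x), time_level,
                                  check_range=False)[0]) - target
    for i in crossings:
        a, b = float(grid[i]), float(grid[i + 1])
        if h[i] == 0.0 and i == 0:
            continue  # the left endpoint is the baseline, not a crossing
        try:
            return float(optimize.brentq(g, a, b, xtol=ROOT_XTOL))
        except ValueError:
            continue
    return float("nan")


def delta_se_xc50(fit, log10_xc50: float, x_ext: float, time_level=0,
                  cp: float | None = None) -> float:
    """Delta-method SE of x50 via implicit differentiation of the midpoint condition."""
    _require_gam(fit)
    if not np.isfinite(log10_xc50):
        return float("nan")
    if cp is None:
        cp = getattr(fit, "cp_", fit.x_min_)
    fprime = float(fit.curve_deriv(np.atleast_1d(log10_xc50), time_level)[0])
    if abs(fprime) < FLAT_DERIV_FLOOR:
        return float("nan")
    g = (0.5 * (fit.basis_row(cp, time_level) + fit.basis_row(x_ext, time_level))
         - fit.basis_row(log10_xc50, time_level)) / fprime
    return float(np.sqrt(max(g @ fit.cov_ @ g, 0.0)))


def estimate_potency(fit, gene_id=None, time_level=0, cp: float | None = None,
                     grid_n: int = GRID_N) -> PotencyEstimate:
    """Full efficacy/potency characterization of one fitted spline curve."""
    _require_gam(fit)
    if cp is None:
        cp = getattr(fit, "cp_", fit.x_min_)
    y0, ymin, ymax, x_at_min, x_at_max = fitted_extrema(
        fit, time_level, grid_n=grid_n, cp=cp)
    direction = classify_direction(y0, ymin, ymax)
    flags = []
    if (ymax - y0) == (y0 - ymin):
        flags.append("direction_tie")
    if direction == "activator":
        y_ext, x_ext = ymax, x_at_max
    else:
        y_ext, x_ext = ymin, x_at_min
    eff, se_eff = max_effect_with_se(fit, x_ext, time_level, cp=cp)
    x50 = xc50(fit, x_ext, time_level, cp=cp, grid_n=grid_n)
    if not np.isfinite(x50):
        flags.append("flat_curve_no_xc50")
        se_x50 = float("nan")
    else:
        se_x50 = delta_se_xc50(fit, x50, x_ext, time_level, cp=cp)
        if not np.isfinite(se_x50):
            flags.append("se_xc50_unstable")
    return PotencyEstimate(
        gene_id=gene_id, time_level=time_level, direction=direction,
        log2_max_effect=eff, se_max_effect=se_eff,
        log10_xc50=x50, se_xc50=se_x50, cp=cp,
        y0=y0, y_ext=y_ext, x_ext=x_ext, flags=flags)


def bootstrap_se_xc50(design: DoseDesign, y, R: int = 1000, seed: int = 0,
                      time_level=0, basis_dim: int = 4,
                      max_fail_frac: float = 0.2) -> tuple[float, int]:
    """Case-resampling bootstrap SE of x50 for one gene.

    Resamples replicates with replacement within each (dose, time) cell,
    refits the spline with GCV, and recomputes x50. Resampled deviations
    from the cell mean are inflated by sqrt(n_c / (n_c - 1)): with the few
    replicates per cell typical of dilution plates, the plain case bootstrap
    deflates within-cell variance by (n_c - 1)/n_c and would systematically
    understate the SE. Returns ``(se, n_failed)``; the SE is NaN-flagged as
    unreliable when more than ``max_fail_frac`` of the resamples fail
    (non-convergence or a flat refitted curve).
    """
    if R < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    X = design.design_matrix_input()
    # within-cell index pools: all rows of X in one cell share the same x,
    # so only y changes across resamples
    cells = {}
    for i, key in enumerate(map(tuple, X)):
        cells.setdefault(key, []).append(i)
    pools = [np.asarray(v) for v in cells.values()]

    means = [float(np.mean(y[pool])) for pool in pools]
    factors = [np.sqrt(pool.size / (pool.size - 1.0)) if pool.size > 1 else 1.0
               for pool in pools]
    draws = []
    n_failed = 0
    y_b = np.empty_like(y)
    for _ in range(R):
        # resampling within a cell leaves the design rows unchanged (all
        # rows of a cell share one x), so only the responses are redrawn
        for pool, m, cf in zip(pools, means, factors):
            drawn = y[pool[rng.integers(0, pool.size, pool.size)]]
            y_b[pool] = m + cf * (drawn - m)
        try:
            fit_b = fit_gam(design, y_b, basis_dim=basis_dim)
        except Exception:
            n_failed += 1
            continue
        est = estimate_potency(fit_b, time_level=time_level, cp=design.cp)
        if np.isfinite(est.log10_xc50):
            draws.append(est.log10_xc50)
        else:
            n_failed += 1
    if n_failed > max_fail_frac * R or len(draws) < 2:
        logger.warning("bootstrap SE unreliable: %d/%d resamples failed",
                       n_failed, R)
        return float("nan"), n_failed
    return float(np.std(draws, ddof=1)), n_failed


def percent_max_inhibition(log2_imax: float) -> float:
    """Fractional maximum inhibition ``1 - 2**log2Imax`` (log2Imax <= 0)."""
    if log2_imax > 0:
        raise ValueError("log2Imax must be <= 0 for an inhibitor")
    return float(1.0 - 2.0 ** log2_imax)


def xc50_linear(log10_xc50: float, cp: float) -> float:
    """Linear-scale XC50 in the experiment's dose unit: ``10**(log10_xc50 - cp)``."""
    return float(10.0 ** (log10_xc50 - cp))


def run_potency(experiment, fits: dict, grid_n: int = GRID_N) -> pd.DataFrame:
    """Potency/efficacy table ("interaction") for every spline-fitted gene."""
    design = experiment.design()
    rows = []
    for gene_id in experiment.gene_ids:
        fit = fits.get(gene_id)
        if fit is None or not isinstance(fit, PenalizedSplineGAM):
            continue
        if not getattr(fit, "converged_", False):
            continue
        for time_level in design.time_levels:
            try:
                est = estimate_potency(fit, gene_id=gene_id,
                                       time_level=time_level,
                                       cp=design.cp, grid_n=grid_n)
            except Exception as exc:  # per-gene isolation
                logger.warning("potency failed for gene %s: %s", gene_id, exc)
                continue
            rows.append({
                "gene_id": gene_id,
                "time": time_level,
                "direction": est.direction,
                "log2_max_effect": est.log2_max_effect,
                "se_max_effect": est.se_max_effect,
                "log10_xc50": est.log10_xc50,
                "se_xc50": est.se_xc50,
                "cp": est.cp,
                "y0": est.y0,
                "y_ext": est.y_ext,
                "x_ext": est.x_ext,
                "flags": ";".join(est.flags),
            })
    return pd.DataFrame(rows)
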