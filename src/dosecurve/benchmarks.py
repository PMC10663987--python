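"""Simulation benchmarks validating the estimator stack end to end.

Each function generates its own synthetic data (seeded), runs the package's
estimators, and returns summary statistics: the delta-method SE against the
bootstrap oracle, the implicit-differentiation gradient against finite
differences, potency/efficacy parameter recovery, null-path type-I error,
and the robustness ordering of the three model families under outlier
contamination. They are used by the test-suite and by the reproduction
script; sizes are arguments so both can pick their scale.
"""

from __future__ import annotations

import time

import numpy as np
from scipy import optimize

from .diffexpr import bh_adjust, contrast_vs_vehicle, t_test
from .models import fit_gam, fit_rlm
from .potency import bootstrap_se_xc50, delta_se_xc50, estimate_potency
from .robustness import batch_comparison_report, log2fc_table_from_experiments
from .simulate import SimulationSpec, simulate_experiment, \
    simulate_replicated_batches

__all__ = [
    "well_conditioned_sigmoid_spec",
    "delta_vs_bootstrap_benchmark",
    "xc50_gradient_check",
    "recovery_benchmark",
    "type1_error_benchmark",
    "robustness_ordering_benchmark",
    "bh_stepup_reference",
    "bh_agreement_check",
]


def well_conditioned_sigmoid_spec(seed: int, **overrides) -> SimulationSpec:
    """One-gene sigmoid experiment the rank-4 spline can represent well.

    Canonical Hill slope near 1 (U(0.75, 1.25)), a clear effect
    (|Emax| in [1.0, 2.5] log2 units), midpoint inside the tested range;
    8 half-log doses x 3 replicates, noise SD 0.1.
    """
    base = dict(n_genes=1, seed=seed, frac_null=0.0, frac_hook=0.0,
                slope_range=(0.75, 1.25), effect_range=(1.0, 2.5))
    base.update(overrides)
    return SimulationSpec(**base)


def delta_vs_bootstrap_benchmark(n_experiments: int = 100, R: int = 1000,
                                 seed: int = 0) -> dict:
    """Median delta/bootstrap SE ratio and the wall-clock speed advantage."""
    ratios = []
    t_delta = 0.0
    t_boot = 0.0
    for i in range(n_experiments):
        sim = simulate_experiment(well_conditioned_sigmoid_spec(seed * 100003
                                                                + i))
        design = sim.experiment.design()
        y = sim.experiment.y(sim.experiment.gene_ids[0])
        fit = fit_gam(design, y)
        est = estimate_potency(fit, cp=design.cp)
        if not np.isfinite(est.log10_xc50):
            continue
        t0 = time.perf_counter()
        dse = delta_se_xc50(fit, est.log10_xc50, est.x_ext, cp=design.cp)
        t_delta += time.perf_counter() - t0
        t0 = time.perf_counter()
        bse, _ = bootstrap_se_xc50(design, y, R=R, seed=seed + i)
        t_boot += time.perf_counter() - t0
        if np.isfinite(dse) and np.isfinite(bse) and bse > 0:
            ratios.append(dse / bse)
    return {
        "median_ratio": float(np.median(ratios)),
        "speedup": float(t_boot / max(t_delta, 1e-12)),
        "n": len(ratios),
    }


def _fd_gradient(fit, x50: float, x_ext: float, cp: float,
                 h: float = 1e-6) -> np.ndarray:
    """Central finite differences of x50(beta), x_ext held fixed."""
    J = fit.basis_.J
    b = fit.basis_.evaluate
    base = fit.coef_.copy()

    def solve(coef):
        beta = coef[:J]
        target = 0.5 * (float(b(cp)[0] @ beta) + float(b(x_ext)[0] @ beta))
        g = lambda x: float(b(x)[0] @ beta) - target
        return optimize.brentq(g, max(cp + 1e-9, x50 - 0.25),
                               min(x_ext, x50 + 0.25), xtol=1e-12)

    grad = np.zeros_like(base)
    for j in range(base.size):
        hi, lo = base.copy(), base.copy()
        hi[j] += h
        lo[j] -= h
        grad[j] = (solve(hi) - solve(lo)) / (2 * h)
    return grad


def xc50_gradient_check(n_fits: int = 50, seed: int = 0) -> dict:
    """Analytic dx50/dbeta versus central finite differences."""
    worst = 0.0
    n_done = 0
    i = 0
    while n_done < n_fits:
        sim = simulate_experiment(well_conditioned_sigmoid_spec(seed * 7919
                                                                + i))
        i += 1
        design = sim.experiment.design()
        fit = fit_gam(design, sim.experiment.y(sim.experiment.gene_ids[0]))
        est = estimate_potency(fit, cp=design.cp)
        if not (np.isfinite(est.log10_xc50) and np.isfinite(est.se_xc50)):
            continue
        fprime = float(fit.curve_deriv(np.array([est.log10_xc50]))[0])
        analytic = (0.5 * (fit.basis_row(design.cp)
                           + fit.basis_row(est.x_ext))
                    - fit.basis_row(est.log10_xc50)) / fprime
        fd = _fd_gradient(fit, est.log10_xc50, est.x_ext, design.cp)
        # near-zero coordinates are judged relative to the gradient's
        # magnitude (pointwise relative error is ill-posed at 0)
        scale = np.maximum(np.abs(fd), 1e-4 * np.max(np.abs(fd)))
        worst = max(worst, float(np.max(np.abs(analytic - fd) / scale)))
        n_done += 1
    return {"max_rel_error": worst, "n": n_done}


def recovery_benchmark(n_sims: int = 200, seed: int = 0) -> dict:
    """Potency/efficacy recovery and 95% CI coverage over simulated sigmoids."""
    x50_err, eff_err = [], []
    covered = 0
    n_ci = 0
    midpoint_resid = 0.0
    for i in range(n_sims):
        sim = simulate_experiment(well_conditioned_sigmoid_spec(seed * 31337
                                                                + i))
        design = sim.experiment.design()
        fit = fit_gam(design, sim.experiment.y(sim.experiment.gene_ids[0]))
        est = estimate_potency(fit, cp=design.cp)
        truth = sim.truth.iloc[0]
        eff_err.append(abs(est.log2_max_effect - truth.true_max_effect))
        if np.isfinite(est.log10_xc50):
            x50_err.append(abs(est.log10_xc50 - truth.true_log10_xc50))
            f_at = float(fit.curve(np.array([est.log10_xc50]),
                                   check_range=False)[0])
            midpoint_resid = max(midpoint_resid,
                                 abs(f_at - 0.5 * (est.y0 + est.y_ext)))
            if np.isfinite(est.se_xc50):
                n_ci += 1
                covered += (abs(est.log10_xc50 - truth.true_log10_xc50)
                            <= 1.96 * est.se_xc50)
    return {
        "median_x50_abs_error": float(np.median(x50_err)),
        "median_effect_abs_error": float(np.median(eff_err)),
        "coverage": covered / n_ci if n_ci else float("nan"),
        "max_midpoint_residual": midpoint_resid,
        "n": n_sims,
    }


def type1_error_benchmark(n_genes: int = 1000, path: str = "gam",
                          seed: int = 0) -> dict:
    """Raw-p rejection rate at alpha=0.05 on all-null genes."""
    n_doses = 8 if path == "gam" else 3
    spec = SimulationSpec(n_genes=n_genes, seed=seed + 17, frac_null=1.0,
                          frac_hook=0.0, n_doses=n_doses)
    sim = simulate_experiment(spec)
    design = sim.experiment.design()
    fitter = fit_gam if path == "gam" else fit_rlm
    rej = 0
    tot = 0
    for g in sim.experiment.gene_ids:
        fit = fitter(design, sim.experiment.y(g))
        for dose in design.dose_levels:
            fc, se = contrast_vs_vehicle(fit, float(np.log10(dose)),
                                         design.time_levels[0])
            tot += 1
            rej += t_test(fc, se, fit.df_resid_) < 0.05
    return {"rejection_rate": rej / tot, "n": tot}


def robustness_ordering_benchmark(n_genes: int = 100,
                                  outlier_frac: float = 0.08,
                                  seed: int = 0) -> dict:
    """Median inter-batch correlation and SD per model family, contaminated data."""
    spec = SimulationSpec(n_genes=n_genes, seed=seed + 23,
                          outlier_frac=outlier_frac, outlier_scale=4.0,
                          n_batches=2, batch_sd=0.1, frac_null=0.3,
                          frac_hook=0.1)
    sims = simulate_replicated_batches(spec)
    table = log2fc_table_from_experiments([s.experiment for s in sims])
    report = batch_comparison_report(table)
    med = report.set_index(["model_kind", "statistic"])["median"]
    return {
        "median_rho_inter": {k: float(med[k, "rho_inter"])
                             for k in ("GAM", "RLM", "LM")},
        "median_sd": {k: float(med[k, "sd_inter"])
                      for k in ("GAM", "RLM", "LM")},
        "n_pairs": int(report.set_index(["model_kind", "statistic"])["n"][
            "GAM", "rho_inter"]),
    }


def bh_stepup_reference(p) -> np.ndarray:
    """Brute-force Benjamini-Hochberg step-up (independent of the implementation)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return np.minimum(adj, 1.0)


def bh_agreement_check(n_vectors: int = 1000, seed: int = 0) -> dict:
    """Max |implementation - brute force| over random p-vector families."""
    rng = np.random.default_rng(seed + 5)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.random(rng.integers(1, 60))
        worst = max(worst, float(np.max(np.abs(bh_adjust(p)
                                               - bh_stepup_reference(p)))))
    return {"max_abs_diff": worst, "n": n_vectors}
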