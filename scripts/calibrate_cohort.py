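#!/usr/bin/env python
"""Calibration of the default cohort-generator configuration.

The shipped defaults in ``vascmark.synthetic.CohortConfig`` were found with
this script.  The procedure:

1. Coordinate search over the segment loading (lambda) and the four ordinal
   threshold exceedance probabilities, at n=100,000 per evaluation, targeting
   the published segment-score summaries: Mean SC mean 1.6, SD 0.5, and
   Max SC median 5.
2. Given the winning (lambda, thresholds), estimate kappa = corr(Mean SC,
   latent severity) by Monte Carlo, then solve the linear system implied by
   the target correlations for the path coefficients:

       r(MeanSC, age)       = kappa * a            = 0.58
       r(MeanSC, PWV_dist)  = kappa * (b + c * a)  = 0.64
       r(PWV_dist, age)     = a * b + c            = 0.60

   where a = age->severity, b = severity->distal, c = age->distal.  The 0.58
   and 0.60 targets follow from the published correlation 0.64 and the
   standardized regression coefficients 0.46 (distal PWV) and 0.30 (age).

Run ``python scripts/calibrate_cohort.py`` to re-derive and verify; it prints
the solved coefficients and a Monte-Carlo check of every calibration target.
"""

import numpy as np
from scipy.stats import norm, pearsonr

N_EVAL = 100_000
TARGET_R_MEANSC_DIST = 0.64
TARGET_R_MEANSC_AGE = 0.58
TARGET_R_DIST_AGE = 0.60


def segment_summary(lam: float, tail_probs, n: int, seed: int):
    """Mean SC / Max SC distribution and kappa for one candidate."""
    thresholds = norm.ppf(1 - np.asarray(tail_probs))
    rng = np.random.default_rng(seed)
    severity = rng.standard_normal(n)
    u = lam * severity[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((n, 27))
    classes = 1 + (u[:, :, None] > thresholds[None, None, :]).sum(axis=2)
    mean_sc = classes.mean(axis=1)
    max_sc = classes.max(axis=1)
    kappa = float(np.corrcoef(mean_sc, severity)[0, 1])
    return {
        "thresholds": thresholds,
        "mean": float(mean_sc.mean()),
        "sd": float(mean_sc.std()),
        "median_max": float(np.median(max_sc)),
        "kappa": kappa,
    }


def solve_path_coefficients(kappa: float):
    a = TARGET_R_MEANSC_AGE / kappa
    c = (TARGET_R_DIST_AGE - TARGET_R_MEANSC_DIST * a / kappa) / (1 - a**2)
    b = TARGET_R_MEANSC_DIST / kappa - a * c
    resid = 1 - (b * b + c * c + 2 * a * b * c)
    return a, b, c, resid


def coordinate_search():
    """Small documented grid around the operating point (full search was wider)."""
    best = None
    for lam in (0.48, 0.50, 0.52, 0.54):
        for p1 in (0.32, 0.33, 0.34):
            tail = (p1, 0.13, 0.08, 0.06)
            s = segment_summary(lam, tail, N_EVAL, seed=7)
            loss = (
                abs(s["mean"] - 1.6) / 1.6
                + abs(s["sd"] - 0.5) / 0.5
                + (0.0 if s["median_max"] == 5 else 1.0)
            )
            if best is None or loss < best[0]:
                best = (loss, lam, tail, s)
    return best


def main() -> None:
    loss, lam, tail, s = coordinate_search()
    print(f"winner: lambda={lam}, tail probs={tail} (loss {loss:.4f})")
    print(
        f"  Mean SC {s['mean']:.4f} (target 1.6), SD {s['sd']:.4f} (target 0.5), "
        f"Max SC median {s['median_max']:.0f} (target 5), kappa {s['kappa']:.4f}"
    )
    print(f"  thresholds: {np.round(s['thresholds'], 6).tolist()}")
    a, b, c, resid = solve_path_coefficients(s["kappa"])
    print(
        f"solved path coefficients: age->severity a={a:.4f}, "
        f"severity->distal b={b:.4f}, age->distal c={c:.4f} "
        f"(residual variance {resid:.4f})"
    )

    # verify the whole chain by simulation
    rng = np.random.default_rng(11)
    n = N_EVAL
    z_age = rng.standard_normal(n)
    severity = a * z_age + np.sqrt(1 - a * a) * rng.standard_normal(n)
    u = lam * severity[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((n, 27))
    classes = 1 + (u[:, :, None] > s["thresholds"][None, None, :]).sum(axis=2)
    mean_sc = classes.mean(axis=1)
    pwv_d = b * severity + c * z_age + np.sqrt(resid) * rng.standard_normal(n)
    print("Monte-Carlo verification:")
    print(f"  r(MeanSC, PWV_dist) = {pearsonr(mean_sc, pwv_d)[0]:.4f} (target 0.64)")
    print(f"  r(MeanSC, age)      = {pearsonr(mean_sc, z_age)[0]:.4f} (target 0.58)")
    print(f"  r(PWV_dist, age)    = {pearsonr(pwv_d, z_age)[0]:.4f} (target 0.60)")


if __name__ == "__main__":
    main()
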