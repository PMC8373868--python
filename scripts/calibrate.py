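"""Calibration checks for the shipped default parameter set.

The default constants in ``invasim.ModelParameters`` are a calibrated set
chosen to satisfy four qualitative conditions of the study design:

  (a) warmup carrying capacity of order 1e2 cells, matching the mean-field
      balance N* = k_0 (p/d_c - 1) when immune pressure on unmutated cells
      is off;
  (b) a non-degenerate distribution of times to invasion inside the
      2000-cycle censoring horizon (neither ~0% nor ~100% censoring);
  (c) cohort restricted mean invasion-free survival decreasing in
      mesenchymal immune evasion (delta_mie 0.2 -> 0.5 -> 0.8);
  (d) an interior optimum of survival in mesenchymal growth arrest
      (delta_mga) on [0, 0.4] under the cycling inflammation scheme.

Running this script re-evaluates all four conditions for the current
defaults and prints a PASS/FAIL line per condition.  Cohort sizes are kept
moderate so the whole check runs in a few minutes.

Usage:  python scripts/calibrate.py [--n-patients N] [--seed S]
"""

import argparse
import sys

import numpy as np

from invasim import (
    InflammationScheme,
    ModelParameters,
    SurvivalData,
    km_estimate,
    restricted_mean,
    run_warmup,
    simulate_cohort,
)


def cohort_rmst(params, n_patients, master_seed):
    scheme = InflammationScheme.from_params(params)
    cohort = simulate_cohort(params, scheme, n_patients, master_seed)
    curve = km_estimate(SurvivalData(cohort.times(), cohort.events()))
    return restricted_mean(curve, params.max_cycles), cohort


def main(argv=None):
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-patients", type=int, default=100)
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args(argv)
    n, seed = args.n_patients, args.seed
    params = ModelParameters()
    failures = 0

    # (a) warmup carrying capacity
    target = params.k_0 * (params.p / params.d_c - 1.0)
    means = []
    for i in range(3):
        _, sizes = run_warmup(
            params, np.random.default_rng(seed + i), return_sizes=True
        )
        means.append(np.mean(sizes[-100:]))
    mean_size = float(np.mean(means))
    ok = abs(mean_size / target - 1.0) < 0.2 and 50 <= target <= 1000
    failures += not ok
    print(f"[{'PASS' if ok else 'FAIL'}] (a) warmup capacity "
          f"{mean_size:.0f} vs mean-field {target:.0f} cells")

    # (b) non-degenerate censoring
    rmst, cohort = cohort_rmst(params, n, seed)
    cens = cohort.censoring_fraction()
    ok = 0.02 <= cens <= 0.8
    failures += not ok
    print(f"[{'PASS' if ok else 'FAIL'}] (b) default cohort: censoring "
          f"{cens:.2f}, RMST {rmst:.0f} cycles "
          f"(median {np.median(cohort.times()):.0f})")

    # (c) survival decreasing in mesenchymal immune evasion
    mie_rmst = [
        cohort_rmst(params.replace(delta_mie=v), n, seed)[0]
        for v in (0.2, 0.5, 0.8)
    ]
    ok = mie_rmst[0] > mie_rmst[1] > mie_rmst[2]
    failures += not ok
    print(f"[{'PASS' if ok else 'FAIL'}] (c) RMST vs delta_mie "
          f"{[round(v) for v in mie_rmst]} (want strictly decreasing)")

    # (d) interior optimum in mesenchymal growth arrest
    mga_rmst = [
        cohort_rmst(params.replace(delta_mga=v), n, seed)[0]
        for v in (0.0, 0.2, 0.4)
    ]
    ok = mga_rmst[1] > mga_rmst[0] and mga_rmst[1] > mga_rmst[2]
    failures += not ok
    print(f"[{'PASS' if ok else 'FAIL'}] (d) RMST vs delta_mga "
          f"{[round(v) for v in mga_rmst]} (want interior maximum at 0.2)")

    return failures


if __name__ == "__main__":
    sys.exit(main())
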