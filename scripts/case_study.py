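#!/usr/bin/env python
"""External-validation case study: risk model vs a standard-of-care test.

Given a validation CSV with columns ``outcome`` (0/1 ovarian-cancer-style
diagnosis) and ``model`` (predicted risk in [0, 1]) — for example, the
publicly available adnexal-mass validation data — this script:

1. simulates a hypothetical standard-of-care (SoC) binary test with 81%
   sensitivity and 88% specificity against the observed outcomes,
2. runs the conjugate Bayesian decision curve analysis over thresholds
   0.00-0.50,
3. prints the headline interrogation quantities: the net-benefit gain of the
   model over Treat-all at t = 0.06, the model-vs-SoC comparison at t = 0.41,
   P(SoC best) at t = 0.50, and the maximum EVPI.

Usage:  python scripts/case_study.py --data validation.csv [--seed 1]
"""

from __future__ import annotations

import argparse

import numpy as np

from bdca import (
    BinaryValidationData,
    dca_binary,
    evpi_curve,
    make_threshold_grid,
    p_best,
    pairwise_superiority,
    read_validation_csv,
    simulate_binary_test,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", required=True, help="CSV with outcome,model columns")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--draws", type=int, default=8000)
    args = parser.parse_args()

    base = read_validation_csv(args.data, schema="binary", strategies=["model"])
    soc = simulate_binary_test(base.outcome, 0.81, 0.88, seed=args.seed)
    data = BinaryValidationData(
        outcome=base.outcome,
        predictions={"model": base.predictions["model"], "soc": soc.astype(float)},
    )
    print(f"N = {data.n}, events = {data.n_events}")

    grid = make_threshold_grid(start=0.0, stop=0.5, step=0.01)
    curves = dca_binary(data, grid, m=args.draws, seed=args.seed)

    _, d6 = pairwise_superiority(curves, "model", "treat_all", 0.06)
    lo, hi = np.percentile(d6, [2.5, 97.5])
    print(f"NB(model) - NB(treat all) at t=0.06: {d6.mean():.3f} (95% CrI {lo:.3f}-{hi:.3f})")

    p41, d41 = pairwise_superiority(curves, "model", "soc", 0.41)
    lo, hi = np.percentile(d41, [2.5, 97.5])
    print(f"NB(model) - NB(SoC) at t=0.41: {d41.mean():.3f} (95% CrI {lo:.3f}-{hi:.3f})")
    print(f"P(model > SoC) at t=0.41: {p41:.1%}")
    print(f"P(SoC best) at t=0.50: {p_best(curves, 'soc', 0.50):.1%}")

    ev = evpi_curve(curves)
    print(f"max EVPI over thresholds: {ev.evpi.max():.4f} "
          f"(at t={float(ev.threshold[ev.evpi.idxmax()]):.2f})")


if __name__ == "__main__":
    main()
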