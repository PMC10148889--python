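#!/usr/bin/env python
"""Defeat-cohort study: avoidance scores, classification, entry-locked dF/F.

Runs the end-to-end open-field social-interaction workflow on a synthetic
chronic-defeat cohort (10 resilient / 10 susceptible / 10 control, with
group-dependent entry-locked transient amplitudes), then reports:

* zone occupancies and the composite social-avoidance score per stressed
  animal, with susceptible/resilient labels checked against ground truth,
* entry-locked dF/F amplitudes (sliding-median normalization, 3 s
  refractory rule) compared across groups with a mouse-level mixed model,
* how close the resilient-vs-control contrast comes to the injected
  amplitude difference after kernel-window scaling.

Tables land under --out (default results/ofsi).
"""

import argparse
import warnings

from socialcircuit.pipeline_io import RunConfig, run_ofsi_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/ofsi")
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    cfg = RunConfig(seed=args.seed, out_dir=args.out)
    res = run_ofsi_pipeline(cfg)
    s = res["summary"]

    c = s["classification"]
    print(f"Cohort of {s['n_animals']} animals; scored {c['n_scored']} "
          f"stressed animals, {c['n_correct']} labeled correctly.")
    scores = res["scores"]
    for grp, df in scores.groupby("truth_group"):
        print(f"  {grp}: composite avoidance score "
              f"{df.composite.mean():+.2f} +/- {df.composite.std():.2f} "
              f"(n = {len(df)})")

    expected = s["expected_amp_scale"] * 0.05
    l = s["lmm_resilient_vs_control"]
    print(f"Entry-locked dF/F, resilient vs control: LMM contrast "
          f"{l['estimate']:.4f} (t({l['df']:.0f}) = {l['t']:.2f}, "
          f"p = {l['p']:.2g}).")
    print(f"  Injected difference after [0,4] s kernel-window scaling: "
          f"{expected:.4f}; recovery error "
          f"{100 * abs(l['estimate'] - expected) / expected:.1f}%.")
    l2 = s["lmm_resilient_vs_susceptible"]
    print(f"Resilient vs susceptible: contrast {l2['estimate']:.4f} "
          f"(p = {l2['p']:.2g}).")
    print(f"Tables written under {args.out}/.")


if __name__ == "__main__":
    main()
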