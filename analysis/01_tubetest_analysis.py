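#!/usr/bin/env python
"""Tube-test study: ethograms, behavior rates, hierarchy, push-locked dF/F.

Runs the end-to-end tube-test workflow on a synthetic round-robin study
(2 cages x 4 mice x 5 days; scripted bouts with known ground truth), then
reports what the analysis chain finds:

* how completely the rule-based classifier recovers the scripted events,
* whether dominant mice push more and subordinates retreat more (Welch t on
  per-bout rates),
* when each cage's hierarchy stabilizes (four identical days of ranks),
* whether push-locked photometry amplitude is higher when a subordinate
  pushes a dominant partner (mixed model with mouse as random effect).

Tables land under --out (default results/tubetest).
"""

import argparse
import warnings

from socialcircuit.pipeline_io import RunConfig, run_tubetest_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/tubetest")
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    cfg = RunConfig(seed=args.seed, out_dir=args.out)
    res = run_tubetest_pipeline(cfg)
    s = res["summary"]

    rec = s["recovery"]
    print(f"Scored {s['n_bouts']} bouts "
          f"({len(res['events'])} behavior events classified).")
    print(f"Event recovery vs ground truth: body_push precision "
          f"{rec['body_push']['precision']:.3f} / recall "
          f"{rec['body_push']['recall']:.3f}; retreat "
          f"{rec['retreat']['precision']:.3f} / {rec['retreat']['recall']:.3f}.")

    wp, wr = s["welch_push"], s["welch_retreat"]
    print(f"Dominants push more: Welch t({wp['df']:.1f}) = {wp['t']:.2f}, "
          f"p = {wp['p']:.2g}.")
    print(f"Subordinates retreat more: Welch t({wr['df']:.1f}) = "
          f"{wr['t']:.2f}, p = {wr['p']:.2g}.")
    for cage, day in s["stability"].items():
        print(f"Cage {cage}: ranks stable from day {day}.")

    l = s["lmm_push_sub_vs_dom"]
    if l:
        print(f"Push-locked dF/F, subordinate-vs-dominant pusher: "
              f"LMM contrast {l['estimate']:.4f} dF/F "
              f"(t({l['df']:.0f}) = {l['t']:.2f}, p = {l['p']:.2g}; "
              f"{l['n_obs']} events from {l['n_groups_random']} mice).")
    print(f"Tables written under {args.out}/ (manifest.json records "
          f"exclusions and checksums).")


if __name__ == "__main__":
    main()
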