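#!/usr/bin/env python
"""Measure how fast the two arms zip up after the loader is re-induced.

For each time point of the simulated re-induction course: balanced log map,
per-arm band-marginal profiles, and the half-rise alignment extent.  An OLS
fit of extent against time over the 10-25 min window estimates the per-arm
alignment rates, which should recover the configured translocation speeds
(19 and 16 kb/min for the left and right arm).  Writes
results/timecourse_rates.tsv.
"""

import sys
from pathlib import Path

from armalign import io, presets
from armalign.armstats import alignment_extent, alignment_rate, arm_marginal
from armalign.hic import bin_pairs, iterative_correction, log_map

ROOT = Path(__file__).resolve().parent.parent / "results"
TIMES = [0, 5, 10, 15, 25, 30]


def main() -> int:
    genome = presets.caulobacter()
    cfg = presets.scenario("timecourse")
    extents = {"left": [], "right": []}
    for t in TIMES:
        pairs = io.read_pairs(ROOT / "datasets" / f"timecourse_t{t:g}_pairs.tsv")
        lg = log_map(iterative_correction(bin_pairs(pairs, genome)))
        row = [f"t={t:>2} min:"]
        for arm in ("left", "right"):
            est = alignment_extent(arm_marginal(lg, genome, arm=arm))
            extents[arm].append((float(t), est.extent_kb))
            row.append(f"{arm} {est.extent_kb:4.0f} kb")
        print("  ".join(row))

    report = {}
    for arm, v in (("left", cfg.v_left), ("right", cfg.v_right)):
        fit = alignment_rate(extents[arm], window_min=(10, 25))
        report[f"rate_{arm}_kb_per_min"] = fit.slope_kb_per_min
        report[f"rate_{arm}_configured"] = v
        print(f"{arm} arm: {fit.slope_kb_per_min:.1f} kb/min "
              f"(configured {v} kb/min)")
        with open(ROOT / f"extents_{arm}.tsv", "w") as fh:
            fh.write("# time_min\textent_kb\n")
            for t, e in extents[arm]:
                fh.write(f"{t:g}\t{e:g}\n")
    io.write_report(report, ROOT / "timecourse_rates.tsv")
    return 0


if __name__ == "__main__":
    sys.exit(main())
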