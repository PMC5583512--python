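#!/usr/bin/env python
"""Generate the scenario datasets every later analysis step consumes.

Simulates labelled Hi-C pair collections for the steady-state scenarios
(wild type, SMC deletion, the stall-barrier inversion strain and its
transcription-inhibited variant) plus the loader re-induction time course,
and writes them with the shared restriction-fragment map under
results/datasets/.  400k pairs per steady-state scenario and 100k per time
point keep this quick-look run light; the test suite and acceptance script
re-simulate at full depth.
"""

import sys
from pathlib import Path

from armalign import io, presets, simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "datasets"
SEED = 1
SCENARIOS = ["wt", "dsmc", "flip25", "rif"]
TIMES = [0, 5, 10, 15, 25, 30]


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = presets.caulobacter()
    frag = simulate.synthetic_fragment_map(genome, seed=SEED)
    io.write_fragments_bed(frag, OUT / "fragments.bed")
    print(f"fragment map: {frag.n_fragments} fragments "
          f"(mean {genome.length_bp / frag.n_fragments / 1000:.1f} kb)")

    for name in SCENARIOS:
        cfg = presets.scenario(name, n_pairs=400_000, seed=SEED)
        pairs = simulate.sample_pairs(cfg, frag)
        io.write_pairs(pairs, OUT / f"{name}_pairs.tsv")
        frac = pairs["label"].value_counts(normalize=True).round(3).to_dict()
        print(f"{name}: {len(pairs)} pairs, class fractions {frac}")

    cfg = presets.scenario("timecourse", n_pairs=100_000, seed=SEED)
    for t, pairs in simulate.simulate_timecourse(cfg, TIMES, frag):
        io.write_pairs(pairs, OUT / f"timecourse_t{t:g}_pairs.tsv")
    print(f"time course: {len(TIMES)} points at t={TIMES} min")
    return 0


if __name__ == "__main__":
    sys.exit(main())
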