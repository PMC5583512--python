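# armalign

Hi-C and ChIP-seq analysis of SMC-mediated chromosomal arm alignment on a
circular bacterial chromosome, built around the *Caulobacter crescentus*
system: the SMC condensin complex is loaded at the centromeric *parS* site
next to the replication origin (*ori*), tethers the two chromosomal arms
together and progressively "zips" them toward the terminus (*ter*) — until
head-on transcription gets in its way.

The package is for people who want to quantify arm alignment from contact
maps — or to test such estimators against exact ground truth. It provides:

* **Hi-C core** — in-silico restriction digestion of a circular genome,
  read-pair classification (valid / self-ligation / non-ligation by
  fragment and orientation), 10-kb binning, iterative-correction balancing,
  natural-log maps (`armalign.genome`, `armalign.hic`);
* **arm statistics** — secondary-diagonal and per-arm band profiles, the
  half-rise alignment extent, OLS alignment rates over a time course,
  vertical-streak ridge geometry, paired-t and Pearson comparisons
  (`armalign.armstats`);
* **ChIP-seq** — RPKPM tracks, tagged/untagged enrichment ratios, per-gene
  RNA-polymerase occupancy, head-on vs co-directional orientation calls and
  inversion-strain remapping (`armalign.chipseq`);
* **a generative simulator** of *parS*-loaded SMC translocation — logistic
  processivity front with half-maximum at the processivity λ, per-arm
  speeds v_L/v_R, Gaussian arm co-progression, stall/unload transcription
  barriers — that emits labelled read pairs, expected matrices and ChIP
  tracks for every stage (`armalign.simulate`, `armalign.presets`).

The central statistic is the score along the **secondary diagonal** of an
ori-centred log contact map, m[(b−k) mod n, (b+k) mod n]: elevated values
mean loci k bins either side of *ori*/*parS* — equidistant points on
opposite arms — touch each other. Its half-rise **extent**
(background + ½(peak − background), first down-crossing) measures how far
alignment reaches; the slope of extent vs time over 10–25 min after loader
re-induction gives the per-arm **alignment rate** in kb/min; the principal
axis of the above-threshold inter-arm score cloud gives the band's
**deviation from 45°**, with a flag for the vertical-streak geometry a
stalled arm produces.

## Worked example

The numbered drivers under `analysis/` run the full study on simulated
data (about two minutes end to end):

```sh
python analysis/01_simulate_scenarios.py   # labelled pairs per scenario
python analysis/02_contact_maps.py         # balanced log maps (+ PNGs)
python analysis/03_arm_alignment.py        # profiles and extents
python analysis/04_timecourse_rates.py     # per-arm alignment rates
python analysis/05_transcription_conflicts.py
python analysis/06_chip_hic_coupling.py
```

Step 03 prints, for 2.8×10⁵ valid pairs per scenario:

```
wt: extent 600 kb (background 0.89, peak 3.38)
dsmc: extent 90 kb (background 0.96, peak 2.52)
flip25: extent 140 kb (background 0.86, peak 3.24)
rif: extent 420 kb (background 0.91, peak 3.48)
dsmc - wt secondary-diagonal scores: mean diff -0.51, t = -5.0, one-sided p = 5.30e-07
```

Read: the wild-type arms are aligned out to ~600 kb from *parS* (the
configured processivity); deleting SMC (`dsmc`) leaves only the ~90-kb
intra-arm decay shoulder, and the paired t test confirms the loss; the
stall-barrier strain (`flip25`, a highly expressed cluster reoriented
head-on at 70 kb on the left arm) truncates the symmetric band at ~140 kb,
and switching transcription off (`rif`) restores long-range alignment.

Step 04 recovers the establishment dynamics from six time points:

```
t=25 min:  left  490 kb  right  380 kb
t=30 min:  left  570 kb  right  450 kb
left arm: 19.3 kb/min (configured 19.0 kb/min)
right arm: 15.4 kb/min (configured 16.0 kb/min)
```

Step 05 quantifies the stall geometry — `flip25: ridge deviation 44.2 deg
from the diagonal, streak=yes` against `rif: 0.4 deg, streak=no` — and
step 06 ties the simulated SMC ChIP enrichment ratio (peak 4.7-fold at the
*parS* bin) to the Hi-C band: `Pearson r = 0.82` across secondary-diagonal
offsets.

A thin CLI wraps the same library for shell use
(`armalign simulate|digest|classify|bin|balance|armscore|extent|rate|ridge|chip|occupancy|timecourse`),
writing a JSON manifest next to every output; see `armalign --help`.

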