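# Methods

`armalign` re-implements, as a tested pipeline over synthetic ground truth,
the genome-wide analyses used to characterise SMC-mediated alignment of the
two chromosomal arms in *Caulobacter crescentus*: Hi-C contact-map
construction from restriction-fragment read pairs, arm-alignment statistics
on those maps, ChIP-seq enrichment tracks, inversion-strain coordinate
remapping, and a generative model of *parS*-loaded SMC translocation with
head-on transcription barriers that supplies labelled inputs for every
stage.

## Coordinate conventions

All coordinates are 0-based base pairs on a circle; intervals are half-open;
kilobases appear only in reports. The default chromosome preset uses the
NA1000 geometry: length 4,042,929 bp with the replication origin (*ori*) at
coordinate 0, the centromeric *parS* site 8 kb counter-clockwise of *ori*
(i.e. at the start of the left arm), and the terminus (*ter*) at the
antipode of *ori*. Positions ascending from *ori* toward *ter* form the
right arm (positive ori-offsets), positions descending from the top
coordinate toward *ter* the left arm (negative offsets). SMC translocates
from *parS* toward *ter* on each arm, so a gene transcribing toward *parS*
on its arm is *head-on*, otherwise *co-directional*.

Inversions are specified on linearised coordinates not spanning the origin;
a point x inside [a, b) maps to a + b − 1 − x (an involution; contained
genes flip strand, and inverted sequence segments are reverse-complemented).
The four printed inversion endpoints ship as presets (1 = 4,038 kb,
2 = 4,030 kb, 4 = 3,788 kb, 5 = 3,611 kb); endpoint "3" is not printed in
any source we rely on and is deliberately absent, so the 3–4 inversion
cannot be constructed from presets.

## Hi-C core

**Digestion.** In-silico BglII digestion scans one strand for AGATCT
(its own reverse complement — asserted, not re-scanned), including matches
wrapping the coordinate origin, and cuts one base into the site (A^GATCT).
On a circle, n cuts give n fragments whose lengths always sum to the genome
length.

**Classification.** Each mate is assigned to its fragment by binary search.
Mates on different fragments form a valid Hi-C product. Mates on the same
fragment pointing toward each other (by within-fragment order and strand)
are non-ligation (dangling-end) products; pointing away from each other,
self-ligation (circularised) products. The same-fragment/same-strand corner
case, which the simulator never generates, is kept as valid and documented
here. The simulator constructs its three classes by exactly this geometry,
so classification against simulator labels must be exact — the
corresponding check is a closure test of the rule, not a benchmark against
biology.

**Binning.** Valid pairs are accumulated into a dense symmetric matrix
(10-kb bins by default; 405 bins for the preset genome, the last bin
short). Each off-diagonal pair increments (i, j) and (j, i) once each, each
within-bin pair increments (i, i) once, so the upper triangle plus diagonal
conserves the valid-pair count. Duplicate pairs are not removed (no
deduplication flag is set by the simulator either).

**Balancing.** Iterative correction divides the matrix by the outer product
of its relative row sums until the coefficient of variation (CV) of row
sums falls below 1e-6 (at most 500 iterations; non-convergence sets a flag
and warns). Bins with zero coverage, plus bins more than 0.1% below the
bottom-1% coverage quantile, are masked to NaN first; the 0.1% slack makes
the masking rule idempotent, so re-balancing a balanced matrix changes
nothing (within tolerance) instead of shaving another 1% of bins each pass.
Total unmasked mass is preserved by a final global rescale. The log stage is
m_ij = ln(f_ij + pseudocount), pseudocount defaulting to half the smallest
positive balanced frequency; masked bins propagate NaN.

## Arm-alignment statistics

**Secondary diagonal.** With the anchor (default *ori*) at bin b, the
profile is score(d) = m[(b−k) mod n, (b+k) mod n], d = k·bin. Offsets
within 30 kb of the anchor or of its antipode are flagged excluded: on a
circle those cells are dominated by intra-arm contacts. The profile is
invariant under ori-centring rotation of the matrix.

**Arm marginals.** The strict anti-diagonal misses alignment bands that run
off 45° (unequal arm speeds during establishment, stalled arms). The
per-arm marginal takes, for each offset on one arm, the maximum
median-filtered (3×3) inter-arm score over the opposite arm. Its
down-crossing measures how far alignment has progressed along *that* arm;
the median filter keeps single noisy bins from inflating the maximum.

**Alignment extent.** Background = median score over a distal window
(default 1,200–1,800 kb — beyond the wild-type ~600 kb alignment but clear
of the *ter* exclusion); peak = maximum of the 3-bin moving-median-smoothed
profile; threshold = background + 0.5·(peak − background); extent = the
largest offset below the first down-crossing of the smoothed profile. The
rule is deterministic and scale-free; all three knobs (window, fraction,
smoothing) are exposed. A profile whose peak does not exceed background
reports extent 0 with a no-signal flag. Note that even with no tether term
the secondary diagonal is not flat near the anchor — at offset d it samples
loci 2d apart, so an intra-arm decay shoulder of ~60–110 kb survives; "no
alignment" therefore reads as a small extent, not zero.

**Alignment rate.** Ordinary least squares of extent (kb) against time
(min) over an inclusive window, default 10–25 min.

**Ridge asymmetry.** The inter-arm quadrant (left offset × right offset
from the anchor, default 30–500 kb each) is 3×3 median filtered; cells above
the half-rise threshold form the signal cloud. The band angle is the
principal axis of that cloud — 45° for symmetric alignment, → 90° for a
vertical streak — reported as the deviation from 45°. The streak flag is
set when the interquartile spread of left offsets in the cloud is less than
a quarter of that of right offsets. A per-left-offset argmax curve and its
least-absolute-deviation slope are retained for inspection, but the angle
is *not* derived from them: for a truly vertical streak the argmax stays on
the diagonal wherever the free band survives and a y-on-x regression cannot
represent a near-infinite slope, so the principal axis is the robust
formulation of the same statistic.

**Statistics.** The paired Student's t test (differences of two profiles on
shared unmasked offsets; t = mean(d)/(sd(d)/√n), df = n−1) and the sample
Pearson correlation with its t-transform p-value are implemented directly
and cross-checked in the tests against scipy's independent implementations
to 1e-10. No multiple-testing correction is applied anywhere; single tests
are reported singly. For ChIP-vs-Hi-C coupling, a track is aggregated to
profile offsets by the mean of the two arm positions at each offset (10-kb
windows).

## ChIP-seq

Coverage is reported as RPKPM — reads per kb per million mapped reads —
value(bin) = count/bin_kb/(total/1e6), 1-kb bins by default, the final
partial bin normalised by its true length; reads are assigned by 5′
position. SMC enrichment is the per-bin ratio of tagged to untagged RPKPM
(1.0 = no enrichment; optional pseudocount). RNA polymerase abundance per
gene is the length-weighted mean RPKPM over the gene's bins × gene length
in kb; genes flagged unreliable (e.g. rRNA clusters, where short multi-copy
reads cannot be assigned) are reported as NaN. Genes spanning *ori* or
*ter* are rejected rather than split (none exist in the synthetic
annotation). The orientation-bias summary reports the co-directional :
head-on ratio of summed expression weight (and of counts) overall and per
arm.

## The generative model

One SMC tether loaded at *parS* occupies a point (dL, dR) of
left-arm × right-arm progress. Population occupancy is

    O(dL, dR) = F(p̄; λ, w) · exp(−Δ²/2σ²) · barrier terms · time fronts

* **Processivity front** F(x; λ, w) = 1/(1 + exp((x − λ)/w)) evaluated at
  the mean progress p̄ of the two arms: tether density plateaus near *parS*
  and levels out around the processivity λ, whose value is by construction
  the half-maximum extent of the band. λ defaults to 600 kb (the wild-type
  alignment extent), front width w = 6 kb. A logistic front rather than an
  exponential tail was chosen so that the half-rise extent estimator reads
  back exactly λ for any λ — an exponential exp(−x/λ) would put the
  half-maximum near λ·ln 2 and make "configured processivity" and "measured
  extent" two different numbers. Mean rather than maximum progress keeps the
  front centred on the nominal offset when the two bins of a profile cell
  straddle it (max-progress shifts the front inward by half a bin).
* **Co-progression kernel** (width σ = 30 kb): at steady state (t = ∞) the
  arms are equally threaded and the kernel acts on Δ = dL − dR, placing the
  band on the 45° diagonal; during establishment (finite t) each arm
  progresses at its own speed (defaults 19 and 16 kb/min for left and
  right) and the kernel acts on the speed-scaled progress difference
  Δ = (dL/v_L − dR/v_R)·v̄, so the band climbs along the line dR =
  (v_R/v_L)·dL and genuinely reaches both per-arm fronts v_L·t and v_R·t
  (smoothly truncated, 5-kb edge). Treating the steady state as symmetric
  while establishment is speed-skewed is a deliberate simplification: the
  steady-state maps in question are all symmetric-band observations, and
  per-arm speeds are only identifiable from the time course.
* **Barriers** at offset g on one arm with strength β ∈ [0, 1]: in
  *unload* mode occupancy beyond g on that arm is multiplied by (1 − β)
  (the complex dissociates); in *stall* mode a fraction β is additionally
  pinned at g (Gaussian ridge of width σ) while the other arm continues
  under its own processivity — this produces the vertical-streak geometry
  in which a ~2σ window on one arm contacts hundreds of kb of the other.
  Both modes exist because the underlying mechanism (impeding vs
  dissociating) is an open question; presets use stall.
* **t = 0** has no tethers (amplitude forced to 0): re-induction starts
  from the unaligned state.

The expected contact map adds A·O over *parS*-inter-arm bin pairs to an
intra-chromosomal background (s + s₀)^(−α) + ε (arc distance s in kb,
α = 1, s₀ = 10 kb, random-ligation floor ε = 3e-3), symmetrises and
normalises the upper triangle to 1.

**Amplitude calibration.** ε and the tether amplitude A are not constrained
by any reported number, so they were fixed once, at design time, by two
requirements evaluated on the noiseless expected map and a seed sweep:
(i) the half-rise extent of the expected profile equals λ across
λ ∈ {150, 300, 600} kb, and (ii) at the benchmark depth (10⁶ pairs over a
405-bin map) the ln-scale gap between the band plateau and the half-rise
threshold is several Poisson standard deviations, so a single noisy bin
cannot trigger a premature down-crossing. A = 0.04 and ε = 3e-3 satisfy
both with a band contrast of ≈ 2 natural-log units over background —
stronger than a typical real map, which is the price of making a 10⁶-pair
benchmark decisive.

**Sampling.** Class counts follow the configured fractions (defaults 0.70
valid, 0.15 self-ligation, 0.15 non-ligation) by largest-remainder
rounding. Valid pairs draw bin pairs from the multinomial over expected
upper-triangle probabilities, then uniform within-bin positions, re-drawn
until the mates land on different fragments (cells whose whole span lies
inside one fragment are re-drawn as cells); strands are uniform.
Same-fragment products are placed on length-weighted non-wrapping fragments
with inward (non-ligation) or outward (self-ligation) orientation and
random mate order. All draws come from seed-derived substreams of one
configured seed, so identical configurations reproduce byte-identical
outputs. Because valid pairs respect fragment geometry while the expected
matrix is smooth, sampled maps match the model cell-by-cell only on cells
whose span crosses at least one restriction cut; the goodness-of-fit test
conditions on that.

**ChIP tracks.** Tagged-SMC intensity = 1 + loading peak at *parS*
(Gaussian, 10 kb) + per-arm occupancy marginal + "hyper-ChIPable" artifact
peaks at configured highly expressed loci; the untagged control carries the
same artifact peaks scaled by a shared fraction (default 0.5), so artifacts
cancel only partially in the ratio — they are simulated as caveats, not
corrected. Read counts are Poisson at the configured depth (default 2×10⁶
per track) and normalised to RPKPM.

**Synthetic annotation.** A deterministic gene table (60 genes, log-normal
expression weights, 75% co-directional strand bias, two rRNA-like
co-directional clusters on the left arm) stands in for a real annotation;
it is synthetic and emulates only position, strand and weight. Scenario
presets (`wt`, `dsmc`, `flip15`, `flip25`, `flip24`, `flip45`, `rif`,
`ectopic_parS`, `timecourse`) live in a YAML catalogue; the stall-barrier
presets place explicit barriers (e.g. flip25: stall at 70 kb on the left
arm, β = 0.9, λ reduced to 420 kb), and `barriers_from_genes` derives
equivalent barriers from remapped head-on genes for the analysis scripts.

## What the synthetic benchmark does and does not show

Passing tests demonstrate that the pipeline's estimators recover the
generative model's ground truth (processivity, per-arm speeds, barrier
geometry, classification labels) under realistic binning, depth and
sampling noise, and that all bookkeeping (circular coordinates, fragment
geometry, balancing, rotation) is exact. They do not validate the
biological model itself: the simulator contains no polymer physics, no
explicit RNA polymerase dynamics, no replication, and cannot distinguish a
single ring embracing both arms from handcuffed rings — the occupancy
formulation is agnostic to that. Real-data idiosyncrasies (mappability,
copy-number structure, restriction-site density bias beyond what the
fragment map induces, distance-dependent ligation efficiency) are absent,
so thresholds tuned here (e.g. the background window) may need adjustment
on real libraries.

Two genome-level checks — 700 BglII fragments and a 4,043-kb chromosome —
run against the public NA1000 assembly (GenBank CP001340), which is too
large to redistribute here; place the FASTA at `data/CP001340.fasta` to
enable them. Without it those two tests fail with a pointer to this note.

## Problem sizes

Default analysis runs use 4×10⁵ pairs per steady-state scenario and 10⁵ per
time point (quick look); the verification suite and the acceptance script
use 10⁶ pairs for steady-state recoveries, 5×10⁵ per time point for rate
recovery and 10⁵ labelled pairs for classification — sizes at which the
estimators' noise floors, quantified during calibration, are comfortably
inside the stated tolerances.
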