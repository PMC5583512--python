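"""Binned ChIP-seq coverage tracks, enrichment ratios and per-gene RNA
polymerase occupancy.

Coverage is reported as RPKPM — reads per kb per million mapped reads — in
fixed bins (1 kb default).  SMC enrichment is the ratio of a FLAG-tagged
ChIP track to an untagged control; 1.0 is the no-enrichment reference.  Gene
occupancy (RPKPM x gene length) summarises RNA polymerase abundance per
gene, and each gene's transcription direction is classified relative to SMC
translocation away from *parS* (head-on vs co-directional), the quantity
that matters for transcription/SMC conflicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec, ori_offset

__all__ = [
    "Track",
    "make_gene_table",
    "rpkpm_track",
    "track_from_counts",
    "enrichment_ratio",
    "gene_occupancy",
    "classify_orientation",
    "orientation_bias",
    "aggregate_to_offsets",
]

GENE_COLUMNS = ["gene_id", "start", "end", "strand", "weight"]


@dataclass
class Track:
    """Per-bin coverage values on a fixed grid over the circular genome."""

    values: np.ndarray
    bin_size: int
    genome: GenomeSpec
    total_reads: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = -(-self.genome.length_bp // self.bin_size)
        if self.values.shape != (n,):
            raise ValueError(f"expected {n} bins, got {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("track values must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.size

    def bin_lengths_bp(self) -> np.ndarray:
        lengths = np.full(self.n_bins, self.bin_size, dtype=np.int64)
        rem = self.genome.length_bp - (self.n_bins - 1) * self.bin_size
        lengths[-1] = rem
        return lengths

    def same_grid(self, other: "Track") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.n_bins == other.n_bins
            and self.genome.length_bp == other.genome.length_bp
        )


def make_gene_table(records) -> pd.DataFrame:
    """Validated gene table from (gene_id, start, end, strand, weight) rows."""
    df = pd.DataFrame(list(records), columns=GENE_COLUMNS)
    if (df["start"] >= df["end"]).any():
        raise ValueError("gene start must be < end")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    if (df["weight"] < 0).any():
        raise ValueError("expression weight must be >= 0")
    return df.reset_index(drop=True)


def rpkpm_track(
    read_positions,
    genome: GenomeSpec,
    bin_size: int = 1000,
    label: str = "",
) -> Track:
    """RPKPM coverage from 5'-end read positions.

    value(bin) = count(bin) / bin_length_kb / (total_reads / 1e6); the final
    partial bin is normalised by its true length.
    """
    pos = np.asarray(read_positions, dtype=np.int64)
    if pos.size == 0:
        raise ValueError("zero mapped reads")
    if np.any((pos < 0) | (pos >= genome.length_bp)):
        raise ValueError("read position outside genome")
    n = -(-genome.length_bp // bin_size)
    counts = np.bincount(np.minimum(pos // bin_size, n - 1), minlength=n).astype(float)
    return track_from_counts(counts, genome, bin_size, label=label)


def track_from_counts(counts, genome: GenomeSpec, bin_size: int, label: str = "") -> Track:
    """RPKPM normalisation of pre-binned read counts."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero mapped reads")
    t = Track(values=counts, bin_size=bin_size, genome=genome,
              total_reads=int(round(total)), label=label)
    kb = t.bin_lengths_bp() / 1000.0
    values = counts / kb / (total / 1e6)
    return Track(values=values, bin_size=bin_size, genome=genome,
                 total_reads=int(round(total)), label=label)


def enrichment_ratio(tagged: Track, untagged: Track, pseudocount: float = 0.0) -> Track:
    """Per-bin (tagged + pc) / (untagged + pc) enrichment; 1.0 = no enrichment."""
    if not tagged.same_grid(untagged):
        raise ValueError("tracks are on different bin grids")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    denom = untagged.values + pseudocount
    if pseudocount == 0 and np.any(denom == 0):
        raise ValueError("zero untagged bins; use a positive pseudocount")
    vals = (tagged.values + pseudocount) / denom
    return Track(values=vals, bin_size=tagged.bin_size, genome=tagged.genome,
                 total_reads=tagged.total_reads, label=f"{tagged.label}/{untagged.label}")


def gene_occupancy(
    track: Track,
    genes: pd.DataFrame,
    exclude_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Per-gene occupancy = length-weighted mean track value over the gene's
    bins x gene length in kb (i.e. RPKPM x gene length).

    ``exclude_ids`` marks genes (e.g. rRNA clusters, where short reads cannot
    be assigned reliably) whose occupancy is reported as NaN with
    reliable=False.
    """
    exclude_ids = exclude_ids or set()
    L = track.genome.length_bp
    bs = track.bin_size
    rows = []
    for rec in genes.itertuples(index=False):
        if rec.end > L or rec.start < 0:
            raise ValueError(f"gene {rec.gene_id} outside genome")
        if rec.gene_id in exclude_ids:
            occ = np.nan
        else:
            first, last = rec.start // bs, (rec.end - 1) // bs
            acc = 0.0
            for b in range(first, last + 1):
                lo = max(rec.start, b * bs)
                hi = min(rec.end, min((b + 1) * bs, L))
                acc += track.values[b] * (hi - lo)
            mean_val = acc / (rec.end - rec.start)
            occ = mean_val * (rec.end - rec.start) / 1000.0
        direction = classify_orientation(rec, track.genome)
        rows.append((rec.gene_id, occ, direction, rec.gene_id not in exclude_ids))
    return pd.DataFrame(rows, columns=["gene_id", "occupancy", "orientation", "reliable"])


def classify_orientation(gene, genome: GenomeSpec) -> str:
    """Classify a gene as co_directional or head_on relative to SMC
    translocation away from *parS* on the gene's arm.

    SMC moves from *parS* toward *ter* on each arm: toward ascending
    coordinates on the right arm and toward descending coordinates on the
    left arm.  A '+'-strand gene transcribes toward ascending coordinates, so
    it is co-directional on the right arm and head-on on the left arm.
    Genes spanning *ori* or *ter* have no unambiguous arm and are rejected.
    """
    start, end, strand = int(gene.start), int(gene.end), str(gene.strand)
    _, arm_start = ori_offset(start % genome.length_bp, genome)
    _, arm_end = ori_offset((end - 1) % genome.length_bp, genome)
    if arm_start != arm_end or arm_start == "ori":
        raise ValueError(
            f"gene {getattr(gene, 'gene_id', '?')} spans ori or ter (ambiguous arm)"
        )
    if arm_start == "right":
        return "co_directional" if strand == "+" else "head_on"
    return "co_directional" if strand == "-" else "head_on"


def orientation_bias(genes: pd.DataFrame, genome: GenomeSpec) -> dict:
    """Expression-weighted co-directional : head-on bias ratio.

    Returns the overall weight ratio and per-arm breakdowns, plus the
    count-based ratio.  An empty head-on class yields an infinite ratio with
    the ``infinite`` flag set.
    """
    if len(genes) == 0:
        raise ValueError("empty gene table")
    orient = np.array([classify_orientation(g, genome) for g in genes.itertuples(index=False)])
    arm = np.array([ori_offset(int(g.start), genome)[1] for g in genes.itertuples(index=False)])
    w = genes["weight"].to_numpy(dtype=float)

    def ratio(mask):
        co = w[mask & (orient == "co_directional")].sum()
        ho = w[mask & (orient == "head_on")].sum()
        n_co = int((mask & (orient == "co_directional")).sum())
        n_ho = int((mask & (orient == "head_on")).sum())
        return {
            "weight_co": float(co), "weight_head_on": float(ho),
            "weight_ratio": float(co / ho) if ho > 0 else float("inf"),
            "count_ratio": float(n_co / n_ho) if n_ho > 0 else float("inf"),
            "n_co": n_co, "n_head_on": n_ho,
            "infinite": ho == 0,
        }

    all_mask = np.ones(len(genes), dtype=bool)
    return {
        "overall": ratio(all_mask),
        "left_arm": ratio(arm == "left"),
        "right_arm": ratio(arm == "right"),
    }


def aggregate_to_offsets(
    track: Track,
    genome: GenomeSpec,
    anchor_bp: int,
    offsets_kb,
    window_kb: float = 10.0,
) -> np.ndarray:
    """Aggregate a track to anchor-offset coordinates: at each offset d the
    mean of the track over ``window_kb`` windows centred at anchor-d and
    anchor+d (both-arm mean), matching score-profile offsets."""
    offsets_kb = np.asarray(offsets_kb, dtype=float)
    L = genome.length_bp
    bs = track.bin_size
    half = int(round(window_kb * 1000 / 2))
    out = np.empty(offsets_kb.size)
    for i, d in enumerate(offsets_kb):
        vals = []
        for sign in (-1, +1):
            centre = (anchor_bp + sign * int(round(d * 1000))) % L
            lo, hi = centre - half, centre + half
            bins = np.arange(lo // bs, (hi - 1) // bs + 1) % track.n_bins
            vals.append(track.values[bins].mean())
        out[i] = float(np.mean(vals))
    return out
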