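"""Circular-genome coordinate arithmetic, in-silico restriction digestion and
inversion-strain remapping.

Coordinates are 0-based base pairs on a circle of size ``length_bp``;
intervals are half-open.  Kilobases appear only at reporting boundaries.
The default preset describes the *Caulobacter crescentus* NA1000 chromosome:
the replication origin (*ori*) defines coordinate zero, the centromeric
*parS* site sits ~8 kb counter-clockwise of *ori* (i.e. on the left arm),
and the terminus (*ter*) is at the antipode of *ori* unless configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GenomeSpec",
    "FragmentMap",
    "InversionSpec",
    "digest",
    "arc_distance",
    "ori_offset",
    "apply_inversion",
    "invert_genes",
    "invert_sequence",
    "BGLII_SITE",
]

#: BglII recognition site; the enzyme cleaves A^GATCT, one base after the
#: motif start.  The site is its own reverse complement.
BGLII_SITE = "AGATCT"


@dataclass(frozen=True)
class GenomeSpec:
    """Geometry of a single circular chromosome."""

    name: str
    length_bp: int
    ori_bp: int = 0
    parS_bp: int | None = None
    ter_bp: int | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        # ter defaults to the antipode of ori; parS to ori itself.
        if self.ter_bp is None:
            object.__setattr__(
                self, "ter_bp", (self.ori_bp + self.length_bp // 2) % self.length_bp
            )
        if self.parS_bp is None:
            object.__setattr__(self, "parS_bp", self.ori_bp)
        for label in ("ori_bp", "parS_bp", "ter_bp"):
            v = getattr(self, label)
            if not 0 <= v < self.length_bp:
                raise ValueError(f"{label}={v} outside [0, {self.length_bp})")

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


@dataclass(frozen=True)
class FragmentMap:
    """Ordered restriction cut coordinates and the fragments they induce.

    ``cuts`` are strictly increasing positions in ``[0, length_bp)``.  On a
    circle, n cuts induce n fragments; fragment ``i`` spans
    ``[cuts[i], cuts[i+1])`` with the last fragment wrapping around the
    origin of the coordinate system.  With no cuts there is a single
    fragment covering the whole circle.
    """

    cuts: np.ndarray
    genome: GenomeSpec

    def __post_init__(self) -> None:
        cuts = np.asarray(self.cuts, dtype=np.int64)
        object.__setattr__(self, "cuts", cuts)
        if cuts.size:
            if np.any(np.diff(cuts) <= 0):
                raise ValueError("cuts must be strictly increasing")
            if cuts[0] < 0 or cuts[-1] >= self.genome.length_bp:
                raise ValueError("cuts outside genome")

    @property
    def n_fragments(self) -> int:
        return max(int(self.cuts.size), 1)

    def fragment_lengths(self) -> np.ndarray:
        """Lengths of all fragments in circular order; sums to length_bp."""
        if self.cuts.size == 0:
            return np.array([self.genome.length_bp], dtype=np.int64)
        ends = np.roll(self.cuts, -1)
        return (ends - self.cuts) % self.genome.length_bp if self.cuts.size > 1 else np.array(
            [self.genome.length_bp], dtype=np.int64
        )

    def fragment_bounds(self, index: int) -> tuple[int, int]:
        """(start, end) of fragment ``index``; end may be < start for the
        wrap-around fragment (end is taken modulo the genome length)."""
        n = self.n_fragments
        if not 0 <= index < n:
            raise IndexError(index)
        if self.cuts.size == 0:
            return 0, self.genome.length_bp
        start = int(self.cuts[index])
        end = int(self.cuts[(index + 1) % self.cuts.size])
        return start, end


@dataclass(frozen=True)
class InversionSpec:
    """A chromosomal inversion of the linearized segment [start_bp, end_bp)."""

    label: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_bp < self.end_bp:
            raise ValueError("need 0 <= start_bp < end_bp")


def digest(sequence: str, site: str = BGLII_SITE, genome_name: str = "genome") -> FragmentMap:
    """In-silico restriction digestion of a circular sequence.

    The motif is searched on the given strand only, including matches that
    wrap around the coordinate origin of the circle.  Each match at 0-based
    position ``p`` yields a cut at ``(p + 1) mod L`` (cleavage one base into
    the site, as for BglII A^GATCT).  BglII's site is palindromic, so a
    single-strand scan finds every cut.

    Returns a :class:`FragmentMap`; with no match the whole circle is one
    fragment.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    motif = site.upper()
    L = len(seq)
    if len(motif) > L:
        raise ValueError("motif longer than sequence")
    # append a motif-length-1 prefix so wrap-around matches are found once
    extended = seq + seq[: len(motif) - 1]
    cuts = []
    start = extended.find(motif)
    while start != -1 and start < L:
        cuts.append((start + 1) % L)
        start = extended.find(motif, start + 1)
    genome = GenomeSpec(name=genome_name, length_bp=L)
    return FragmentMap(cuts=np.sort(np.asarray(cuts, dtype=np.int64)), genome=genome)


def arc_distance(x: int, y: int, genome: GenomeSpec) -> int:
    """Shortest distance between two positions along the circle (bp)."""
    L = genome.length_bp
    for v in (x, y):
        if not 0 <= v < L:
            raise ValueError(f"position {v} outside [0, {L})")
    d = abs(int(x) - int(y))
    return min(d, L - d)


def ori_offset(x: int, genome: GenomeSpec) -> tuple[float, str]:
    """Signed kb offset of a position from *ori* and the arm it lies on.

    Convention: positions ascending from *ori* toward *ter* form the right
    arm (positive offsets); positions descending from ``length_bp`` toward
    *ter* form the left arm (negative offsets).  *ter* splits the circle and
    is reported on the right arm; *ori* itself has offset 0 and arm "ori".
    """
    L = genome.length_bp
    if not 0 <= x < L:
        raise ValueError(f"position {x} outside [0, {L})")
    d_cw = (int(x) - genome.ori_bp) % L  # ascending (clockwise) distance
    if d_cw == 0:
        return 0.0, "ori"
    ter_cw = (genome.ter_bp - genome.ori_bp) % L
    if d_cw <= ter_cw:
        return d_cw / 1000.0, "right"
    return -(L - d_cw) / 1000.0, "left"


def apply_inversion(x: int, inv: InversionSpec, genome: GenomeSpec) -> int:
    """Remap a point through an inversion; an involution on [0, length)."""
    L = genome.length_bp
    if inv.end_bp > L:
        raise ValueError("inversion outside genome")
    if not 0 <= x < L:
        raise ValueError(f"position {x} outside [0, {L})")
    if inv.start_bp <= x < inv.end_bp:
        # reflection within the segment: offset o maps to (len-1-o)
        return inv.start_bp + inv.end_bp - 1 - int(x)
    return int(x)


def invert_genes(genes, inv: InversionSpec, genome: GenomeSpec):
    """Remap a gene table (pandas DataFrame with start/end/strand columns)
    through an inversion, reversing the strand of contained genes.

    Genes straddling an inversion boundary are rejected.
    """
    import pandas as pd  # local import keeps genome module light

    out = genes.copy()
    inside = (genes["start"] >= inv.start_bp) & (genes["end"] <= inv.end_bp)
    straddle = (
        ((genes["start"] < inv.start_bp) & (genes["end"] > inv.start_bp))
        | ((genes["start"] < inv.end_bp) & (genes["end"] > inv.end_bp))
    )
    if straddle.any():
        bad = genes.loc[straddle, "gene_id"].tolist()
        raise ValueError(f"genes straddle inversion boundary: {bad}")
    a, b = inv.start_bp, inv.end_bp
    new_start = a + b - genes.loc[inside, "end"]
    new_end = a + b - genes.loc[inside, "start"]
    out.loc[inside, "start"] = new_start
    out.loc[inside, "end"] = new_end
    out.loc[inside, "strand"] = genes.loc[inside, "strand"].map({"+": "-", "-": "+"})
    return out.sort_values("start", ignore_index=True) if isinstance(out, pd.DataFrame) else out


def invert_sequence(sequence: str, inv: InversionSpec) -> str:
    """Reverse-complement the inverted segment of a sequence (the biological
    consequence of a chromosomal inversion)."""
    if inv.end_bp > len(sequence):
        raise ValueError("inversion outside sequence")
    comp = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
    seg = sequence[inv.start_bp : inv.end_bp]
    return sequence[: inv.start_bp] + seg.translate(comp)[::-1] + sequence[inv.end_bp :]
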