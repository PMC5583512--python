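"""From mapped Hi-C read pairs to balanced, natural-log contact matrices.

The pipeline follows the classic chromosome-conformation-capture bookkeeping
for a single circular chromosome: each mate of a read pair is assigned to its
restriction fragment; pairs are classified as valid Hi-C products,
self-ligation (circularised fragment, mates pointing away from each other on
one fragment) or non-ligation (unligated/dangling ends, mates pointing toward
each other on one fragment); valid products are binned (10-kb default) into a
symmetric count matrix; the matrix is balanced by iterative row/column
scaling (Sinkhorn-style) and finally mapped to natural-log scale, the form in
which arm-alignment statistics are scored.

A pair collection is a pandas DataFrame with columns
``read_id, pos1, strand1, pos2, strand2`` and optionally ``label`` (ground
truth when simulated).  :class:`ReadPair` is the scalar record form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import FragmentMap, GenomeSpec

__all__ = [
    "ReadPair",
    "ContactMatrix",
    "assign_fragment",
    "assign_fragments",
    "classify_pair",
    "classify_pairs",
    "bin_pairs",
    "iterative_correction",
    "log_map",
    "ori_center",
    "VALID",
    "SELF_LIGATION",
    "NON_LIGATION",
]

VALID = "valid"
SELF_LIGATION = "self_ligation"
NON_LIGATION = "non_ligation"

PAIR_COLUMNS = ["read_id", "pos1", "strand1", "pos2", "strand2"]


@dataclass(frozen=True)
class ReadPair:
    pos1: int
    strand1: str
    pos2: int
    strand2: str
    label: str | None = None


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts/frequencies for a circular genome.

    stage: "raw" (integer counts), "balanced" (iteratively corrected
    frequencies), "log" (natural log of balanced frequencies) or
    "probability" (model-expected frequencies summing to 1).  Masked bins are
    NaN in balanced/log stages.
    """

    values: np.ndarray
    bin_size: int
    stage: str
    genome: GenomeSpec
    mask: np.ndarray = field(default=None)  # boolean, True = excluded bin
    converged: bool = True
    bin_shift: int = 0  # whole-bin circular rotation applied to indices

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("contact matrix must be square")
        n = expected_n_bins(self.genome, self.bin_size)
        if v.shape[0] != n:
            raise ValueError(f"expected {n} bins for {self.genome.length_bp} bp "
                             f"at {self.bin_size} bp bins, got {v.shape[0]}")
        self.values = v
        if self.mask is None:
            self.mask = np.zeros(v.shape[0], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def bin_of(self, pos: int) -> int:
        """Bin index of a genomic position under the current rotation."""
        if not 0 <= pos < self.genome.length_bp:
            raise ValueError(f"position {pos} outside genome")
        base = min(int(pos) // self.bin_size, self.n_bins - 1)
        return (base + self.bin_shift) % self.n_bins

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            values=self.values.copy(), bin_size=self.bin_size, stage=self.stage,
            genome=self.genome, mask=self.mask.copy(), converged=self.converged,
            bin_shift=self.bin_shift,
        )


def expected_n_bins(genome: GenomeSpec, bin_size: int) -> int:
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    return math.ceil(genome.length_bp / bin_size)


# ---------------------------------------------------------------------------
# fragment assignment and pair classification


def assign_fragments(pos, frag: FragmentMap) -> np.ndarray:
    """Vectorised fragment index for positions on the circle.

    Fragment i spans [cuts[i], cuts[i+1]); positions before the first cut or
    at/after the last cut belong to the wrap-around fragment (index n-1).
    """
    if frag.n_fragments == 0:
        raise ValueError("empty fragment map")
    pos = np.asarray(pos, dtype=np.int64)
    L = frag.genome.length_bp
    if np.any((pos < 0) | (pos >= L)):
        raise ValueError("position outside genome")
    if frag.cuts.size == 0:
        return np.zeros(pos.shape, dtype=np.int64)
    idx = np.searchsorted(frag.cuts, pos, side="right") - 1
    idx[idx < 0] = frag.cuts.size - 1
    return idx


def assign_fragment(pos: int, frag: FragmentMap) -> int:
    """Fragment index of a single position (binary-search contract)."""
    return int(assign_fragments(np.asarray([pos]), frag)[0])


def _check_strands(strands: np.ndarray) -> None:
    bad = ~np.isin(strands, ["+", "-"])
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(f"malformed strand {strands[i]!r} at record {i}")


def classify_pairs(pairs: pd.DataFrame, frag: FragmentMap) -> pd.Series:
    """Classify read pairs as valid / self_ligation / non_ligation.

    Rule (standard 3C geometry): mates on the same restriction fragment and
    oriented toward each other (inward) are non-ligation (dangling-end)
    products; mates on the same fragment oriented away from each other
    (outward) are self-ligation (circularised) products; mates on different
    fragments are valid Hi-C products.  "Inward" is judged from the mates'
    order along the fragment (wrap-around fragments use the within-fragment
    offset) and their strands; same-fragment pairs on the same strand are
    kept as valid.
    """
    s1 = pairs["strand1"].to_numpy(dtype=object)
    s2 = pairs["strand2"].to_numpy(dtype=object)
    _check_strands(s1)
    _check_strands(s2)
    p1 = pairs["pos1"].to_numpy(dtype=np.int64)
    p2 = pairs["pos2"].to_numpy(dtype=np.int64)
    f1 = assign_fragments(p1, frag)
    f2 = assign_fragments(p2, frag)

    L = frag.genome.length_bp
    if frag.cuts.size:
        start = frag.cuts[np.minimum(f1, frag.cuts.size - 1)]
    else:
        start = np.zeros_like(p1)
    off1 = (p1 - start) % L
    off2 = (p2 - start) % L  # same fragment => same start
    first_is_1 = off1 <= off2
    left = np.where(first_is_1, s1, s2)
    right = np.where(first_is_1, s2, s1)

    labels = np.full(len(pairs), VALID, dtype=object)
    same = f1 == f2
    labels[same & (left == "+") & (right == "-")] = NON_LIGATION
    labels[same & (left == "-") & (right == "+")] = SELF_LIGATION
    return pd.Series(labels, index=pairs.index, name="label")


def classify_pair(pair: ReadPair, frag: FragmentMap) -> str:
    df = pd.DataFrame(
        [[0, pair.pos1, pair.strand1, pair.pos2, pair.strand2]], columns=PAIR_COLUMNS
    )
    return str(classify_pairs(df, frag).iloc[0])


# ---------------------------------------------------------------------------
# binning


def bin_pairs(
    pairs: pd.DataFrame,
    genome: GenomeSpec,
    bin_size: int = 10_000,
    labels: pd.Series | None = None,
) -> ContactMatrix:
    """Bin valid pairs into a raw symmetric count matrix.

    Each valid pair increments (i, j) and (j, i) once each for i != j and
    (i, i) once, so the upper triangle plus diagonal conserves the valid-pair
    count while the full matrix double-counts off-diagonal mass symmetrically.
    Pairs without a label column (and no ``labels`` argument) are all treated
    as valid.
    """
    n = expected_n_bins(genome, bin_size)
    counts = np.zeros((n, n), dtype=float)
    if labels is None and "label" in pairs.columns:
        labels = pairs["label"]
    if labels is not None:
        pairs = pairs.loc[np.asarray(labels) == VALID]
    if len(pairs):
        i = np.minimum(pairs["pos1"].to_numpy(np.int64) // bin_size, n - 1)
        j = np.minimum(pairs["pos2"].to_numpy(np.int64) // bin_size, n - 1)
        np.add.at(counts, (i, j), 1.0)
        np.add.at(counts, (j, i), 1.0)
        # diagonal was incremented twice per i==j pair; count it once
        diag_twice = np.zeros(n)
        np.add.at(diag_twice, i[i == j], 1.0)
        counts[np.diag_indices(n)] -= diag_twice
    return ContactMatrix(values=counts, bin_size=bin_size, stage="raw", genome=genome)


# ---------------------------------------------------------------------------
# iterative correction (matrix balancing)


def iterative_correction(
    m: ContactMatrix,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_coverage_quantile: float = 0.01,
) -> ContactMatrix:
    """Balance a raw contact matrix by alternating row/column scaling.

    Bins with zero coverage, plus bins below the ``min_coverage_quantile`` of
    coverage (strict inequality, so an already-uniform matrix masks nothing),
    are masked before scaling.  Iteration stops when the coefficient of
    variation of unmasked row sums drops below ``tol``; total unmasked mass
    is preserved by a final global rescale.  Non-convergence sets
    ``converged=False`` and warns rather than failing silently.
    """
    if m.stage not in ("raw", "balanced", "probability"):
        raise ValueError(f"cannot balance a {m.stage}-stage matrix")
    W = np.array(m.values, dtype=float)
    if not np.allclose(W, W.T, equal_nan=True):
        raise ValueError("matrix must be symmetric")
    mask = m.mask.copy()
    mask |= np.isnan(W).all(axis=1)  # rows masked upstream are all-NaN
    coverage = np.nansum(np.where(np.isnan(W), 0.0, W), axis=1)
    mask |= coverage <= 0
    if (~mask).sum() > 0 and min_coverage_quantile > 0:
        thr = np.quantile(coverage[~mask], min_coverage_quantile, method="lower")
        # only bins materially below the quantile: near-uniform coverage
        # (e.g. an already-balanced matrix) masks nothing, so the operation
        # is idempotent
        mask |= coverage < thr * (1.0 - 1e-3)
    live = ~mask
    if live.sum() == 0:
        raise ValueError("all bins masked; nothing to balance")

    sub = W[np.ix_(live, live)].astype(float)
    total = sub.sum()
    converged = False
    for _ in range(max_iter):
        s = sub.sum(axis=1)
        mean_s = s.mean()
        cv = s.std() / mean_s if mean_s > 0 else 0.0
        if cv < tol:
            converged = True
            break
        b = s / mean_s
        b[b == 0] = 1.0
        sub /= np.outer(b, b)
    else:
        s = sub.sum(axis=1)
        cv = s.std() / s.mean() if s.mean() > 0 else 0.0
        converged = cv < tol
    if not converged:
        warnings.warn(
            f"iterative correction did not reach CV<{tol} in {max_iter} iterations",
            RuntimeWarning,
        )
    # preserve total mass
    cur = sub.sum()
    if cur > 0:
        sub *= total / cur

    out = np.full_like(W, np.nan)
    out[np.ix_(live, live)] = (sub + sub.T) / 2.0  # enforce exact symmetry
    return ContactMatrix(
        values=out, bin_size=m.bin_size, stage="balanced", genome=m.genome,
        mask=mask, converged=converged, bin_shift=m.bin_shift,
    )


def log_map(m: ContactMatrix, pseudocount: float | None = None) -> ContactMatrix:
    """Natural-log transform of a balanced matrix: m_ij = ln(f_ij + pc).

    The default pseudocount is half the smallest positive balanced frequency;
    masked bins stay NaN.
    """
    if m.stage != "balanced":
        raise ValueError("log_map expects a balanced-stage matrix")
    vals = m.values
    if pseudocount is None:
        positive = vals[np.isfinite(vals) & (vals > 0)]
        pseudocount = 0.5 * positive.min() if positive.size else 1.0
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    out = np.where(np.isfinite(vals), np.log(np.nan_to_num(vals) + pseudocount), np.nan)
    return ContactMatrix(
        values=out, bin_size=m.bin_size, stage="log", genome=m.genome,
        mask=m.mask.copy(), converged=m.converged, bin_shift=m.bin_shift,
    )


def ori_center(m: ContactMatrix, genome: GenomeSpec | None = None) -> ContactMatrix:
    """Rotate bin indices so the *ori* bin sits at the matrix centre.

    A pure circular relabelling: values are unchanged, only the genomic start
    of bin 0 moves.
    """
    genome = genome or m.genome
    n = m.n_bins
    ori_bin = m.bin_of(genome.ori_bp)
    shift = n // 2 - ori_bin
    vals = np.roll(np.roll(m.values, shift, axis=0), shift, axis=1)
    mask = np.roll(m.mask, shift)
    return ContactMatrix(
        values=vals, bin_size=m.bin_size, stage=m.stage, genome=m.genome,
        mask=mask, converged=m.converged, bin_shift=(m.bin_shift + shift) % n,
    )
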