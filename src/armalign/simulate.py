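"""Generative model of *parS*-loaded SMC translocation and the synthetic
datasets derived from it.

The model: SMC complexes load at *parS* and tether the two chromosomal arms,
threading DNA so that the tether's anchor points progress away from *parS*
along both arms.  A tether's occupancy over (left-offset dL, right-offset
dR) from *parS* is

    O(dL, dR) = front(mean progress; lambda) * kernel(co-progression; sigma)
                * barrier survival * time-front truncation

* ``front`` is a logistic processivity front ``1 / (1 + exp((x - lambda)/w))``
  whose half-maximum sits at the processivity ``lambda`` — tether density
  plateaus near *parS* and levels out to background beyond ``lambda``.
* ``kernel`` couples the two arms' progress (Gaussian, width ``sigma``):
  at steady state (t = inf) arms are equally threaded and the kernel acts on
  dL - dR, putting the interaction band on the 45-degree diagonal; during
  establishment (finite t) arms progress at per-arm speeds v_left/v_right
  and the kernel acts on the speed-scaled progress difference, so the band
  reaches the per-arm fronts v_left*t and v_right*t.
* barriers model head-on transcription conflicts at an offset g on one arm:
  ``unload`` multiplies occupancy beyond g by (1 - beta); ``stall`` pins a
  fraction beta of complexes at g on that arm while the other arm continues,
  adding the near-vertical ridge ("streak") seen for reoriented highly
  expressed genes.

Expected contact maps add this tether term to a power-law intra-chromosomal
distance decay plus a uniform random-ligation floor; labelled read pairs,
time courses and SMC/RNAP ChIP tracks are sampled from the same model so
every pipeline stage has exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chipseq import Track, track_from_counts
from .genome import FragmentMap, GenomeSpec
from .hic import (NON_LIGATION, PAIR_COLUMNS, SELF_LIGATION, VALID,
                  ContactMatrix, expected_n_bins)

__all__ = [
    "Barrier",
    "SimConfig",
    "OccupancySurface",
    "occupancy",
    "expected_matrix",
    "sample_pairs",
    "simulate_timecourse",
    "simulate_chip",
    "synthetic_fragment_map",
    "random_sequence",
    "barriers_from_genes",
]


@dataclass(frozen=True)
class Barrier:
    """A transcription barrier at ``offset_kb`` from *parS* on one arm."""

    arm: str  # "left" | "right"
    offset_kb: float
    strength: float  # beta in [0, 1]
    mode: str = "stall"  # "stall" | "unload"

    def __post_init__(self) -> None:
        if self.arm not in ("left", "right"):
            raise ValueError("barrier arm must be 'left' or 'right'")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("barrier strength must be in [0, 1]")
        if self.mode not in ("stall", "unload"):
            raise ValueError("barrier mode must be 'stall' or 'unload'")


@dataclass(frozen=True)
class SimConfig:
    """All generative parameters.

    Distance-decay exponent ``alpha`` and offset ``s0_kb`` shape intra-arm
    contacts; ``epsilon`` is the uniform random-ligation floor; ``amplitude``
    scales the inter-arm tether term; ``lam_kb`` is the processivity
    (half-maximal tether extent), ``front_width_kb`` the sharpness of its
    front; ``sigma_kb`` the arm co-progression width; speeds are in kb/min;
    ``t_min`` = inf means steady state.  Class fractions order:
    (valid, self_ligation, non_ligation).
    """

    genome: GenomeSpec
    alpha: float = 1.0
    s0_kb: float = 10.0
    epsilon: float = 3e-3
    amplitude: float = 0.04
    sigma_kb: float = 30.0
    lam_kb: float = 600.0
    front_width_kb: float = 6.0
    v_left: float = 19.0
    v_right: float = 16.0
    barriers: tuple[Barrier, ...] = ()
    t_min: float = math.inf
    n_pairs: int = 1_000_000
    class_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    bin_size: int = 10_000
    chip_bin_size: int = 1_000
    chip_reads: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.lam_kb <= 0 or self.sigma_kb <= 0:
            raise ValueError("alpha, lam_kb and sigma_kb must be positive")
        if self.v_left < 0 or self.v_right < 0:
            raise ValueError("speeds must be >= 0")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if self.amplitude < 0 or self.epsilon < 0:
            raise ValueError("amplitude and epsilon must be >= 0")
        if not isinstance(self.barriers, tuple):
            object.__setattr__(self, "barriers", tuple(self.barriers))


@dataclass
class OccupancySurface:
    """Tether occupancy O(dL, dR) on a kb grid, with per-arm marginals."""

    dL_kb: np.ndarray
    dR_kb: np.ndarray
    values: np.ndarray  # shape (len(dL), len(dR))
    marginal_left: np.ndarray
    marginal_right: np.ndarray


def _logistic_front(x_kb: np.ndarray, lam_kb: float, width_kb: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.clip((x_kb - lam_kb) / width_kb, -60, 60)))


def _arm_barriers(cfg: SimConfig, arm: str):
    bs = sorted((b for b in cfg.barriers if b.arm == arm), key=lambda b: b.offset_kb)
    return bs


def _passage(offsets_kb: np.ndarray, barriers) -> np.ndarray:
    """Fraction of complexes whose arm progressed past all barriers up to
    each offset (both modes remove a fraction beta at the barrier)."""
    out = np.ones_like(offsets_kb, dtype=float)
    for b in barriers:
        out = out * np.where(offsets_kb > b.offset_kb, 1.0 - b.strength, 1.0)
    return out


def _pinned_masses(barriers) -> list[tuple[float, float]]:
    """(offset, mass) of complexes stalled at each stall barrier, accounting
    for losses at upstream barriers."""
    out = []
    surv = 1.0
    for b in barriers:
        if b.mode == "stall":
            out.append((b.offset_kb, surv * b.strength))
        surv *= 1.0 - b.strength
    return out


def occupancy_at(cfg: SimConfig, dL_kb: np.ndarray, dR_kb: np.ndarray) -> np.ndarray:
    """Evaluate O on the outer grid dL x dR (kb offsets from *parS*)."""
    dL = np.asarray(dL_kb, dtype=float)[:, None]
    dR = np.asarray(dR_kb, dtype=float)[None, :]
    finite_t = np.isfinite(cfg.t_min)
    vbar = 0.5 * (cfg.v_left + cfg.v_right)
    if finite_t and (cfg.v_left > 0 and cfg.v_right > 0):
        progress = 0.5 * (dL / cfg.v_left + dR / cfg.v_right) * vbar
        delta = (dL / cfg.v_left - dR / cfg.v_right) * vbar
    else:
        progress = 0.5 * (dL + dR)
        delta = dL - dR
    free = _logistic_front(progress, cfg.lam_kb, cfg.front_width_kb)
    free = free * np.exp(-(delta**2) / (2.0 * cfg.sigma_kb**2))

    left_b = _arm_barriers(cfg, "left")
    right_b = _arm_barriers(cfg, "right")
    free = free * _passage(dL[:, 0], left_b)[:, None]
    free = free * _passage(dR[0, :], right_b)[None, :]

    out = free
    # stalled components: one arm pinned at the barrier, the other continues
    for g, mass in _pinned_masses(left_b):
        ridge = mass * np.exp(-((dL[:, 0] - g) ** 2) / (2.0 * cfg.sigma_kb**2))[:, None]
        cont = (
            _logistic_front(dR[0, :], cfg.lam_kb, cfg.front_width_kb)
            * _passage(dR[0, :], right_b)
            * (dR[0, :] >= g)
        )[None, :]
        out = out + ridge * cont
    for g, mass in _pinned_masses(right_b):
        ridge = mass * np.exp(-((dR[0, :] - g) ** 2) / (2.0 * cfg.sigma_kb**2))[None, :]
        cont = (
            _logistic_front(dL[:, 0], cfg.lam_kb, cfg.front_width_kb)
            * _passage(dL[:, 0], left_b)
            * (dL[:, 0] >= g)
        )[:, None]
        out = out + ridge * cont

    if finite_t:
        front_w = 5.0  # kb; sharp establishment front
        out = out * _logistic_front(dL[:, 0], cfg.v_left * cfg.t_min, front_w)[:, None]
        out = out * _logistic_front(dR[0, :], cfg.v_right * cfg.t_min, front_w)[None, :]
    return out


def occupancy(cfg: SimConfig, grid_kb: float = 5.0) -> OccupancySurface:
    """Tether occupancy surface over both arms on a regular kb grid."""
    half = cfg.genome.length_bp / 2000.0
    d = np.arange(0.0, half + grid_kb, grid_kb)
    O = occupancy_at(cfg, d, d)
    return OccupancySurface(
        dL_kb=d, dR_kb=d, values=O,
        marginal_left=O.sum(axis=1) * grid_kb,
        marginal_right=O.sum(axis=0) * grid_kb,
    )


# ---------------------------------------------------------------------------
# expected contact matrix


def _bin_centres_bp(genome: GenomeSpec, bin_size: int) -> np.ndarray:
    n = expected_n_bins(genome, bin_size)
    starts = np.arange(n, dtype=float) * bin_size
    ends = np.minimum(starts + bin_size, genome.length_bp)
    return (starts + ends) / 2.0


def parS_offsets(genome: GenomeSpec, positions_bp: np.ndarray):
    """(arm, offset-kb-from-parS) for positions: each position is assigned to
    the arm along which it is nearer to *parS* (the circle is split at *parS*
    and its antipode)."""
    x = np.asarray(positions_bp, dtype=float)
    L = genome.length_bp
    d_right = (x - genome.parS_bp) % L / 1000.0  # ascending from parS
    d_left = (genome.parS_bp - x) % L / 1000.0  # descending from parS
    is_left = d_left < d_right
    return is_left, np.where(is_left, d_left, d_right)


def expected_matrix(cfg: SimConfig) -> ContactMatrix:
    """Model-expected contact probabilities (upper triangle sums to 1).

    P(i, j) is proportional to (s_ij + s0)^(-alpha) + epsilon for every bin
    pair (s_ij = arc distance between bin centres, kb) plus
    amplitude * O(dL_i, dR_j) for *parS*-inter-arm pairs.  At t = 0 or with
    amplitude 0 there are no tethers and the map is pure distance decay.
    """
    genome = cfg.genome
    n = expected_n_bins(genome, cfg.bin_size)
    centres = _bin_centres_bp(genome, cfg.bin_size)
    L = genome.length_bp
    diff = np.abs(centres[:, None] - centres[None, :])
    s_kb = np.minimum(diff, L - diff) / 1000.0
    P = (s_kb + cfg.s0_kb) ** (-cfg.alpha) + cfg.epsilon

    tether_on = cfg.amplitude > 0 and not (np.isfinite(cfg.t_min) and cfg.t_min <= 0)
    if tether_on:
        is_left, d = parS_offsets(genome, centres)
        li = np.nonzero(is_left)[0]
        ri = np.nonzero(~is_left)[0]
        O = occupancy_at(cfg, d[li], d[ri])
        T = np.zeros_like(P)
        T[np.ix_(li, ri)] = cfg.amplitude * O
        P = P + T + T.T
    P = (P + P.T) / 2.0
    upper_mass = (P.sum() + np.trace(P)) / 2.0
    P /= upper_mass
    return ContactMatrix(values=P, bin_size=cfg.bin_size, stage="probability",
                         genome=genome)


# ---------------------------------------------------------------------------
# read-pair sampling


def _class_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    raw = [f * n for f in fractions]
    base = [int(math.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainder first
    for k in range(short):
        base[order[k]] += 1
    return tuple(base)


def _uniform_in_bin(rng, bins: np.ndarray, bin_size: int, L: int) -> np.ndarray:
    lo = bins.astype(np.int64) * bin_size
    hi = np.minimum(lo + bin_size, L)
    return lo + rng.integers(0, hi - lo)


def sample_pairs(cfg: SimConfig, frag: FragmentMap, rng=None) -> pd.DataFrame:
    """Sample exactly ``cfg.n_pairs`` labelled read pairs.

    Valid pairs are drawn from the expected-matrix bin probabilities, with
    uniform within-bin positions re-drawn until the two mates fall on
    different restriction fragments, and uniform random strands.
    Self-ligation / non-ligation pairs are placed on a single (non-wrapping,
    length >= 2) fragment with outward / inward mate orientation.  Output is
    reproducible for a given config (seed included).
    """
    if cfg.n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 101])
    genome = cfg.genome
    L = genome.length_bp
    n_valid, n_self, n_non = _class_counts(cfg.n_pairs, cfg.class_fractions)

    em = expected_matrix(cfg)
    n = em.n_bins
    iu, ju = np.triu_indices(n)
    p = em.values[iu, ju]
    p = p / p.sum()

    # --- valid pairs
    rows1 = np.empty(0, np.int64)
    if n_valid:
        cell_counts = rng.multinomial(n_valid, p)
        sel = np.nonzero(cell_counts)[0]
        bi = np.repeat(iu[sel], cell_counts[sel])
        bj = np.repeat(ju[sel], cell_counts[sel])
        pos1 = _uniform_in_bin(rng, bi, cfg.bin_size, L)
        pos2 = _uniform_in_bin(rng, bj, cfg.bin_size, L)
        from .hic import assign_fragments

        for attempt in range(200):
            f1 = assign_fragments(pos1, frag)
            f2 = assign_fragments(pos2, frag)
            clash = f1 == f2
            if not clash.any():
                break
            if attempt and attempt % 20 == 0:
                # bin pair may sit inside one fragment: redraw those cells
                k = int(clash.sum())
                cells = rng.choice(p.size, size=k, p=p)
                bi[clash], bj[clash] = iu[cells], ju[cells]
            pos1[clash] = _uniform_in_bin(rng, bi[clash], cfg.bin_size, L)
            pos2[clash] = _uniform_in_bin(rng, bj[clash], cfg.bin_size, L)
        else:
            raise RuntimeError("could not place valid pairs on distinct fragments")
        s1 = rng.choice(np.array(["+", "-"], dtype=object), size=n_valid)
        s2 = rng.choice(np.array(["+", "-"], dtype=object), size=n_valid)
        valid_block = (pos1, s1, pos2, s2)

    # --- same-fragment products
    lengths = frag.fragment_lengths()
    eligible = np.nonzero(lengths >= 2)[0]
    if frag.cuts.size > 1:
        # exclude the wrap-around fragment for simplicity of placement
        eligible = eligible[eligible != frag.cuts.size - 1]
    if (n_self or n_non) and eligible.size == 0:
        raise ValueError("no fragment long enough for same-fragment products")

    def same_fragment_block(k: int, inward: bool):
        if k == 0:
            return None
        w = (lengths[eligible] - 1).astype(float)
        fsel = rng.choice(eligible, size=k, p=w / w.sum())
        starts = frag.cuts[fsel]
        ends = starts + lengths[fsel]
        a = starts + rng.integers(0, lengths[fsel] - 1)
        b = a + 1 + rng.integers(0, ends - a - 1)
        if inward:  # mates point toward each other: non-ligation geometry
            sa, sb = "+", "-"
        else:  # outward: self-ligation (circularised) geometry
            sa, sb = "-", "+"
        swap = rng.random(k) < 0.5
        pos1 = np.where(swap, b, a)
        pos2 = np.where(swap, a, b)
        s1 = np.where(swap, sb, sa).astype(object)
        s2 = np.where(swap, sa, sb).astype(object)
        return pos1, s1, pos2, s2

    blocks, labels = [], []
    if n_valid:
        blocks.append(valid_block)
        labels.append(np.full(n_valid, VALID, dtype=object))
    sb = same_fragment_block(n_self, inward=False)
    if sb is not None:
        blocks.append(sb)
        labels.append(np.full(n_self, SELF_LIGATION, dtype=object))
    nb = same_fragment_block(n_non, inward=True)
    if nb is not None:
        blocks.append(nb)
        labels.append(np.full(n_non, NON_LIGATION, dtype=object))

    pos1 = np.concatenate([b[0] for b in blocks])
    s1 = np.concatenate([b[1] for b in blocks])
    pos2 = np.concatenate([b[2] for b in blocks])
    s2 = np.concatenate([b[3] for b in blocks])
    label = np.concatenate(labels)
    order = rng.permutation(pos1.size)
    df = pd.DataFrame(
        {
            "read_id": [f"r{i:08d}" for i in range(pos1.size)],
            "pos1": pos1[order],
            "strand1": s1[order],
            "pos2": pos2[order],
            "strand2": s2[order],
            "label": label[order],
        }
    )
    return df


def simulate_timecourse(cfg: SimConfig, times_min, frag: FragmentMap):
    """One labelled pair collection per time point after re-induction of the
    loader: occupancy truncated at the per-arm fronts v*t; t = 0 has no
    tethers yet (amplitude forced to 0)."""
    out = []
    streams = np.random.SeedSequence([cfg.seed, 301]).spawn(len(list(times_min)))
    for t, ss in zip(times_min, streams):
        if t < 0:
            raise ValueError("times must be >= 0")
        cfg_t = replace(cfg, t_min=float(t), amplitude=0.0 if t == 0 else cfg.amplitude)
        rng = np.random.default_rng(ss)
        out.append((float(t), sample_pairs(cfg_t, frag, rng=rng)))
    return out


# ---------------------------------------------------------------------------
# ChIP-seq simulation


def simulate_chip(
    cfg: SimConfig,
    artifact_positions_bp=(),
    artifact_height: float = 4.0,
    artifact_shared: float = 0.5,
    load_height: float = 6.0,
    load_width_kb: float = 10.0,
    occ_height: float = 3.0,
    artifact_width_kb: float = 2.0,
) -> tuple[Track, Track]:
    """Simulate tagged-SMC and untagged-control ChIP tracks (RPKPM).

    tagged intensity = 1 + loading peak at *parS* + per-arm tether-occupancy
    marginal + "hyper-ChIPable" artifact peaks at highly expressed loci;
    untagged = 1 + the same artifact peaks scaled by ``artifact_shared`` (so
    artifacts cancel only partially in the enrichment ratio).  Read counts
    are Poisson at the configured depth; both tracks share the seed-derived
    stream so a config reproduces byte-identical tracks.
    """
    genome = cfg.genome
    rng = np.random.default_rng([cfg.seed, 202])
    bs = cfg.chip_bin_size
    centres = _bin_centres_bp(genome, bs)
    L = genome.length_bp
    darc = np.abs(centres - genome.parS_bp)
    darc = np.minimum(darc, L - darc) / 1000.0

    is_left, d = parS_offsets(genome, centres)
    # per-arm tether marginal at each locus: occupancy of that arm coordinate
    grid = occupancy(cfg, grid_kb=5.0)
    margL = grid.marginal_left / max(grid.marginal_left.max(), 1e-12)
    margR = grid.marginal_right / max(grid.marginal_right.max(), 1e-12)
    occ_m = np.where(
        is_left,
        np.interp(d, grid.dL_kb, margL),
        np.interp(d, grid.dR_kb, margR),
    )

    art = np.zeros_like(centres)
    for gpos in artifact_positions_bp:
        da = np.abs(centres - gpos)
        da = np.minimum(da, L - da) / 1000.0
        art += artifact_height * np.exp(-(da**2) / (2 * artifact_width_kb**2))

    tagged_int = 1.0 + load_height * np.exp(-(darc**2) / (2 * load_width_kb**2))
    if cfg.amplitude > 0:
        tagged_int = tagged_int + occ_height * occ_m
    tagged_int = tagged_int + art
    untag_int = 1.0 + artifact_shared * art

    def sample_track(intensity, label):
        lam = cfg.chip_reads * intensity / intensity.sum()
        counts = rng.poisson(lam)
        return track_from_counts(counts, genome, bs, label=label)

    return sample_track(tagged_int, "tagged"), sample_track(untag_int, "untagged")


# ---------------------------------------------------------------------------
# synthetic inputs


def random_sequence(length_bp: int, seed: int = 0, gc: float = 0.67) -> str:
    """Random circular genome sequence with the given GC content (the
    *Caulobacter* chromosome is GC-rich, ~67%)."""
    rng = np.random.default_rng([seed, 7])
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ATGC")), size=length_bp, p=p))


def synthetic_fragment_map(
    genome: GenomeSpec, mean_fragment_bp: int = 5800, seed: int = 0
) -> FragmentMap:
    """Restriction-like cut map with exponential fragment spacing (what a
    6-bp cutter produces on a random genome)."""
    rng = np.random.default_rng([seed, 11])
    n_exp = max(int(genome.length_bp / mean_fragment_bp), 1)
    cuts = np.sort(rng.choice(genome.length_bp, size=n_exp, replace=False))
    return FragmentMap(cuts=cuts.astype(np.int64), genome=genome)


def barriers_from_genes(
    genes: pd.DataFrame,
    genome: GenomeSpec,
    min_weight: float,
    strength: float = 0.6,
    mode: str = "stall",
) -> tuple[Barrier, ...]:
    """Derive SMC barriers from highly expressed head-on genes: each gene
    with weight >= min_weight transcribing toward *parS* on its arm becomes a
    barrier at its *parS* offset."""
    from .chipseq import classify_orientation

    out = []
    for g in genes.itertuples(index=False):
        if g.weight < min_weight:
            continue
        if classify_orientation(g, genome) != "head_on":
            continue
        mid = (g.start + g.end) // 2
        is_left, d = parS_offsets(genome, np.array([mid]))
        out.append(Barrier("left" if is_left[0] else "right", float(d[0]),
                           min(strength, 0.95), mode))
    return tuple(sorted(out, key=lambda b: b.offset_kb))
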