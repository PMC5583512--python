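"""Preset genomes, inversion strains, simulation scenarios and the synthetic
gene annotation, loaded from the shipped ``presets.yaml`` catalogue."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .chipseq import make_gene_table
from .genome import GenomeSpec, InversionSpec
from .simulate import Barrier, SimConfig

__all__ = [
    "caulobacter",
    "genome_preset",
    "inversion_preset",
    "scenario",
    "scenario_names",
    "synthetic_gene_table",
]


@lru_cache(maxsize=1)
def _catalogue() -> dict:
    with resources.files("armalign").joinpath("presets.yaml").open() as fh:
        return yaml.safe_load(fh)


def genome_preset(name: str = "caulobacter") -> GenomeSpec:
    try:
        g = _catalogue()["genomes"][name]
    except KeyError:
        raise KeyError(f"unknown genome preset {name!r}") from None
    return GenomeSpec(name=name, **g)


def caulobacter() -> GenomeSpec:
    return genome_preset("caulobacter")


def inversion_preset(name: str) -> InversionSpec:
    cat = _catalogue()
    try:
        spec = cat["inversions"][name]
    except KeyError:
        raise KeyError(f"unknown inversion preset {name!r}") from None
    ends = cat["inversion_endpoints_bp"]
    return InversionSpec(
        label=name, start_bp=int(ends[spec["start"]]), end_bp=int(ends[spec["end"]])
    )


def scenario_names() -> list[str]:
    return sorted(_catalogue()["scenarios"])


def scenario(name: str, **overrides) -> SimConfig:
    """SimConfig for a named scenario; keyword overrides win (e.g. n_pairs,
    seed, lam_kb)."""
    try:
        params = dict(_catalogue()["scenarios"][name])
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; one of {scenario_names()}") from None
    genome = caulobacter()
    if "parS_bp" in params:
        genome = GenomeSpec(
            name=f"caulobacter_{name}", length_bp=genome.length_bp,
            ori_bp=genome.ori_bp, parS_bp=int(params.pop("parS_bp")),
            ter_bp=genome.ter_bp,
        )
    barriers = tuple(Barrier(**b) for b in params.pop("barriers", []))
    params.update(overrides)
    params.setdefault("genome", genome)
    params.setdefault("barriers", barriers)
    return SimConfig(**params)


def synthetic_gene_table(
    genome: GenomeSpec | None = None,
    n_genes: int = 60,
    co_directional_bias: float = 0.75,
    seed: int = 0,
):
    """Deterministic synthetic annotation of highly/moderately expressed
    genes: positions spread over both arms (avoiding ori/ter), strands drawn
    with the genome-wide ori->ter transcription bias, log-normal expression
    weights, plus two co-directional rRNA-like clusters on the left arm.

    This is a synthetic stand-in for a real annotation; it emulates only the
    features the analyses use (position, strand, expression weight).
    """
    from .genome import ori_offset

    genome = genome or caulobacter()
    rng = np.random.default_rng([seed, 23])
    L = genome.length_bp
    recs = []
    margin = 50_000  # keep clear of ori and ter so arms are unambiguous
    while len(recs) < n_genes:
        start = int(rng.integers(0, L - 5000))
        length = int(rng.integers(1000, 5000))
        end = start + length
        if end >= L:
            continue
        _, arm_s = ori_offset(start, genome)
        _, arm_e = ori_offset(end - 1, genome)
        if arm_s != arm_e or arm_s == "ori":
            continue
        dist_ori = min(start, L - start)
        dist_ter = abs(start - genome.ter_bp)
        if dist_ori < margin or dist_ter < margin:
            continue
        co = rng.random() < co_directional_bias
        if arm_s == "right":
            strand = "+" if co else "-"
        else:
            strand = "-" if co else "+"
        weight = float(rng.lognormal(mean=3.0, sigma=1.0))
        recs.append((f"gene{len(recs):03d}", start, end, strand, weight))
    # rRNA-like clusters: very highly expressed, ori->ter on the left arm
    recs.append(("rrnA", 3_700_000, 3_705_000, "-", 2000.0))
    recs.append(("rrnB", 3_950_000, 3_955_000, "-", 2000.0))
    return make_gene_table(recs)
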