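"""Text formats used across the pipeline.

All genomic interval formats are 0-based half-open (BED/bedGraph
convention); kb appears only in report files.  Floats are written with 12
significant digits so every writer/reader round-trips to <= 1e-9 relative.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .armstats import ScoreProfile
from .chipseq import GENE_COLUMNS, Track, make_gene_table
from .genome import FragmentMap, GenomeSpec
from .hic import PAIR_COLUMNS, ContactMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_pairs",
    "write_pairs",
    "read_matrix",
    "write_matrix",
    "read_bedgraph",
    "write_bedgraph",
    "write_fragments_bed",
    "read_genes_bed",
    "write_genes_bed",
    "read_profile",
    "write_profile",
    "read_report",
    "write_report",
    "write_manifest",
]

FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> tuple[str, str]:
    """Single circular record -> (name, sequence); multi-record input errors."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"{path}: no FASTA records")
    if len(records) > 1:
        raise ValueError(f"{path}: expected a single circular record, got {len(records)}")
    rec = records[0]
    return rec.id, str(rec.seq)


def write_fasta(path, name: str, sequence: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Hi-C pairs


def write_pairs(pairs: pd.DataFrame, path) -> None:
    cols = PAIR_COLUMNS + (["label"] if "label" in pairs.columns else [])
    with open(path, "w") as fh:
        fh.write("# armalign pairs v1: " + "\t".join(cols) + "\n")
        pairs[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(
        str(path), sep="\t", comment="#", header=None,
        names=PAIR_COLUMNS + ["label"],
        dtype={"read_id": str, "pos1": np.int64, "strand1": str,
               "pos2": np.int64, "strand2": str, "label": str},
    )
    if df["label"].isna().all():
        df = df.drop(columns=["label"])
    bad = ~(df["strand1"].isin(["+", "-"]) & df["strand2"].isin(["+", "-"]))
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        # +2: one for the header comment line, one for 1-based numbering
        raise ValueError(f"{path}: malformed strand field at line {i + 2}")
    return df


# ---------------------------------------------------------------------------
# contact matrices (dense TSV with a structured '#' header)


def write_matrix(m: ContactMatrix, path) -> None:
    header = {
        "stage": m.stage,
        "bin_size": m.bin_size,
        "genome_name": m.genome.name,
        "genome_length": m.genome.length_bp,
        "ori_bp": m.genome.ori_bp,
        "parS_bp": m.genome.parS_bp,
        "ter_bp": m.genome.ter_bp,
        "bin_shift": m.bin_shift,
        "converged": int(m.converged),
        "mask": ",".join(map(str, np.nonzero(m.mask)[0])),
    }
    with open(path, "w") as fh:
        fh.write("# armalign matrix v1 " + json.dumps(header) + "\n")
        starts = np.arange(m.n_bins) * m.bin_size
        fh.write("bin_start\t" + "\t".join(map(str, starts)) + "\n")
        for i, start in enumerate(starts):
            row = "\t".join(FLOAT_FMT % v for v in m.values[i])
            fh.write(f"{start}\t{row}\n")


def read_matrix(path) -> ContactMatrix:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# armalign matrix"):
            raise ValueError(f"{path}: not an armalign matrix file")
        header = json.loads(first.split("v1 ", 1)[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    genome = GenomeSpec(
        name=header["genome_name"], length_bp=int(header["genome_length"]),
        ori_bp=int(header["ori_bp"]), parS_bp=int(header["parS_bp"]),
        ter_bp=int(header["ter_bp"]),
    )
    values = df.to_numpy(dtype=float)
    mask = np.zeros(values.shape[0], dtype=bool)
    if header["mask"]:
        mask[[int(i) for i in header["mask"].split(",")]] = True
    return ContactMatrix(
        values=values, bin_size=int(header["bin_size"]), stage=header["stage"],
        genome=genome, mask=mask, converged=bool(header["converged"]),
        bin_shift=int(header.get("bin_shift", 0)),
    )


# ---------------------------------------------------------------------------
# tracks (bedGraph), fragments and genes (BED)


def write_bedgraph(track: Track, path, chrom: str | None = None) -> None:
    chrom = chrom or track.genome.name
    starts = np.arange(track.n_bins, dtype=np.int64) * track.bin_size
    ends = np.minimum(starts + track.bin_size, track.genome.length_bp)
    with open(path, "w") as fh:
        fh.write(f"# armalign track label={track.label} total_reads={track.total_reads}\n")
        for s, e, v in zip(starts, ends, track.values):
            fh.write(f"{chrom}\t{s}\t{e}\t{FLOAT_FMT % v}\n")


def read_bedgraph(path, genome: GenomeSpec) -> Track:
    label, total = "", 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# armalign track"):
            for tok in first.split()[3:]:
                k, _, v = tok.partition("=")
                if k == "label":
                    label = v
                elif k == "total_reads":
                    total = int(v)
            body = fh
        else:
            fh.seek(0)
            body = fh
        df = pd.read_csv(body, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
    widths = (df["end"] - df["start"]).to_numpy()
    bin_size = int(widths[0])
    if not np.all(widths[:-1] == bin_size):
        raise ValueError(f"{path}: bedGraph bins must be uniform (last may be short)")
    return Track(values=df["value"].to_numpy(float), bin_size=bin_size,
                 genome=genome, total_reads=total, label=label)


def write_fragments_bed(frag: FragmentMap, path, chrom: str | None = None) -> None:
    """FragmentMap as BED3 (wrap-around fragment split at the origin)."""
    chrom = chrom or frag.genome.name
    L = frag.genome.length_bp
    with open(path, "w") as fh:
        if frag.cuts.size == 0:
            fh.write(f"{chrom}\t0\t{L}\n")
            return
        for i in range(frag.cuts.size):
            start, end = frag.fragment_bounds(i)
            if end > start:
                fh.write(f"{chrom}\t{start}\t{end}\n")
            else:  # wraps the origin: emit two intervals
                fh.write(f"{chrom}\t{start}\t{L}\n")
                if end > 0:
                    fh.write(f"{chrom}\t0\t{end}\n")


def write_genes_bed(genes: pd.DataFrame, path, chrom: str = "genome") -> None:
    """BED6 with the score column carrying the expression weight (float)."""
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            fh.write(f"{chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t"
                     f"{FLOAT_FMT % g.weight}\t{g.strand}\n")


def read_genes_bed(path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "gene_id", "weight", "strand"])
    return make_gene_table(df[GENE_COLUMNS].itertuples(index=False, name=None))


# ---------------------------------------------------------------------------
# profiles and reports


def write_profile(p: ScoreProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# armalign profile label={p.label} anchor_bp={p.anchor_bp}\n")
        fh.write("# offset_kb\tscore\texcluded\n")
        for o, s, e in zip(p.offsets_kb, p.scores, p.excluded):
            fh.write(f"{FLOAT_FMT % o}\t{FLOAT_FMT % s}\t{int(e)}\n")


def read_profile(path) -> ScoreProfile:
    label, anchor = "", 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# armalign profile"):
            for tok in first.split()[3:]:
                k, _, v = tok.partition("=")
                if k == "label":
                    label = v
                elif k == "anchor_bp":
                    anchor = int(v)
        df = pd.read_csv(fh, sep="\t", header=None, comment="#",
                         names=["offset_kb", "score", "excluded"])
    return ScoreProfile(df["offset_kb"].to_numpy(float), df["score"].to_numpy(float),
                        df["excluded"].to_numpy(bool), anchor_bp=anchor, label=label)


def write_report(values: dict, path) -> None:
    """Flat key-value report (str keys; numbers at 9 significant digits)."""
    with open(path, "w") as fh:
        for k, v in values.items():
            if isinstance(v, float):
                v = FLOAT_FMT % v
            fh.write(f"{k}\t{v}\n")


def read_report(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            k, _, v = line.rstrip("\n").partition("\t")
            try:
                out[k] = int(v)
            except ValueError:
                try:
                    out[k] = float(v)
                except ValueError:
                    out[k] = v
    return out


def write_manifest(out_dir, command: str, params: dict, inputs: list) -> Path:
    """Run manifest: command, parameters, input digests, versions, seed."""
    import armalign

    digests = {}
    for p in inputs:
        p = Path(p)
        if p.is_file():
            digests[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = {
        "command": command,
        "params": {k: (v if not isinstance(v, Path) else str(v)) for k, v in params.items()},
        "inputs_sha256": digests,
        "versions": {
            "armalign": armalign.__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    out = Path(out_dir) / f"manifest_{command}.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
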