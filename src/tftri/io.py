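"""Readers and writers for the plain-text exchange formats.

bedGraph carries binned signal (4 columns, track lines tolerated and
skipped), narrowPeak (BED6+4) carries peak calls, and plain TSVs carry
annotation, counts, motif hits and result tables. All genomic files are
0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from tftri.containers import ANNOTATION_COLUMNS, SignalTrack, validate_annotation

FLOAT_FMT = "%.6g"

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
]

MOTIF_COLUMNS = ["motif_id", "family_id", "chrom", "start", "end", "strand", "score"]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    return validate_annotation(ann[ANNOTATION_COLUMNS])


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    write_table(validate_annotation(ann), path)


def read_counts(counts_path: str | Path, samples_path: str | Path):
    """Read a counts TSV (gene_id + one column per sample) and its sample sheet.

    The sample sheet has columns sample_id, group and optionally pair.
    Returns (counts DataFrame indexed by gene_id, groups Series, pairs
    Series or None).
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    groups = samples["group"]
    pairs = samples["pair"] if "pair" in samples.columns else None
    return counts, groups, pairs


def write_counts(cm, counts_path: str | Path, samples_path: str | Path) -> None:
    write_table(cm.counts, counts_path, index=True)
    samples = pd.DataFrame({"group": cm.groups.loc[list(cm.counts.columns)]})
    if cm.pairs is not None:
        samples["pair"] = cm.pairs.loc[list(cm.counts.columns)]
    samples.index.name = "sample_id"
    write_table(samples, samples_path, index=True)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    bs = track.bin_size
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={track.sample_id}_{track.mark}\n")
        for contig in sorted(track.data):
            v = track.data[contig]
            starts = np.arange(len(v)) * bs
            for s, x in zip(starts, v):
                fh.write(f"{contig}\t{s}\t{s + bs}\t{FLOAT_FMT % x}\n")


def read_bedgraph(path: str | Path, bin_size: int, sample_id: str = "", mark: str = "") -> SignalTrack:
    """Read a bedGraph into fixed-width bins.

    Intervals wider than one bin are expanded; values landing in the same
    bin overwrite (the file is expected to be bin-aligned).
    """
    data: dict[str, list] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser", "#")) or not line.strip():
                continue
            chrom, s, e, v = line.split("\t")
            rows.append((chrom, int(s), int(e), float(v)))
    sizes: dict[str, int] = {}
    for chrom, s, e, v in rows:
        sizes[chrom] = max(sizes.get(chrom, 0), e)
    arrays = {c: np.zeros(int(np.ceil(n / bin_size))) for c, n in sizes.items()}
    for chrom, s, e, v in rows:
        arrays[chrom][s // bin_size : (e + bin_size - 1) // bin_size] = v
    return SignalTrack(arrays, bin_size, sample_id, mark)


def write_narrowpeak(peaks: pd.DataFrame, path: str | Path) -> None:
    """Write a BED6+4 narrowPeak table (``peak`` is the summit offset from start)."""
    df = peaks[NARROWPEAK_COLUMNS].copy()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, header=False, float_format=FLOAT_FMT)


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLUMNS, comment="#")
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: peak with start >= end")
    summit = df["start"] + df["peak"]
    if ((summit < df["start"]) | (summit >= df["end"])).any():
        raise ValueError(f"{path}: summit outside [start, end)")
    return df


def read_motifs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTIF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motif table missing columns: {missing}")
    if (df["start"] >= df["end"]).any():
        raise ValueError("motif hit with start >= end")
    fam = df.groupby("motif_id")["family_id"].nunique()
    if (fam > 1).any():
        raise ValueError("a motif_id maps to more than one family_id")
    return df[MOTIF_COLUMNS]


def write_motifs(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df[MOTIF_COLUMNS], path)
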