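"""In-memory containers shared across the pipeline stages.

Coordinates are 0-based half-open throughout; BED-family files are
written natively in that convention and 1-based inputs must be converted
by their readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss"]


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check a gene-annotation table (gene_id, chrom, start, end, strand, tss).

    TSS convention: ``start`` for + genes, ``end - 1`` for - genes
    (last covered base in 0-based terms).
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if (ann["end"] <= ann["start"]).any():
        raise ValueError("annotation has genes with end <= start")
    if not ann["strand"].isin(["+", "-"]).all():
        raise ValueError("annotation strand must be '+' or '-'")
    plus = ann["strand"] == "+"
    bad = (ann.loc[plus, "tss"] != ann.loc[plus, "start"]).any() or (
        ann.loc[~plus, "tss"] != ann.loc[~plus, "end"] - 1
    ).any()
    if bad:
        raise ValueError("tss inconsistent with strand convention")
    return ann


@dataclass
class CountMatrix:
    """Integer count matrix (genes x samples) with sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene_id with one column per sample.
    groups
        Series mapping sample_id -> group label.
    pairs
        Optional Series mapping sample_id -> pair label for a paired
        (control/treated) design; every pair must contain exactly two
        samples.
    lib_size
        Per-sample library sizes; defaults to column sums.
    """

    counts: pd.DataFrame
    groups: pd.Series
    pairs: pd.Series | None = None
    lib_size: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if not np.isfinite(c).all() or (c < 0).any():
            raise ValueError("counts must be finite and non-negative")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        if self.pairs is not None:
            sizes = self.pairs.loc[list(self.counts.columns)].value_counts()
            if (sizes != 2).any():
                raise ValueError("every pair must contain exactly two samples")
        if self.lib_size is None:
            self.lib_size = self.counts.sum(axis=0).astype(float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def cpm(self) -> pd.DataFrame:
        """Counts per million: count / lib_size * 1e6."""
        lib = self.lib_size.loc[list(self.counts.columns)]
        if (lib <= 0).any():
            zero = list(lib.index[lib <= 0])
            raise ValueError(f"zero/negative library size for samples: {zero}")
        return self.counts / lib * 1e6

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[gene_ids].copy(),
            self.groups,
            self.pairs,
            self.lib_size,
        )


@dataclass
class SignalTrack:
    """Binned signal over one or more contigs for a single sample.

    ``data`` maps contig -> vector of per-bin values; bin i covers
    [i*bin_size, (i+1)*bin_size).
    """

    data: dict[str, np.ndarray]
    bin_size: int
    sample_id: str
    mark: str

    def __post_init__(self) -> None:
        for contig, v in self.data.items():
            v = np.asarray(v, dtype=float)
            if not np.isfinite(v).all():
                raise ValueError(f"non-finite values on contig {contig}")
            self.data[contig] = v

    def flat(self) -> np.ndarray:
        """All bins concatenated in sorted-contig order."""
        return np.concatenate([self.data[c] for c in sorted(self.data)])

    def same_binning(self, other: "SignalTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and sorted(self.data) == sorted(other.data)
            and all(len(self.data[c]) == len(other.data[c]) for c in self.data)
        )
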