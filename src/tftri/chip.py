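"""Promoter ChIP-signal analyses.

Input normalisation of binned tracks via signal extraction scaling
(SES), TSS-window maximum scoring, robust group scaling of scores,
binding-tier assignment, cross-sample consensus peak ranking and peak
genomic annotation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from tftri.containers import SignalTrack

log = logging.getLogger(__name__)


def ses_scale_factor(chip: SignalTrack, input_: SignalTrack) -> float:
    """Signal-extraction-scaling factor for chip relative to input.

    Bins are sorted by increasing chip value; at the index where the
    cumulative chip fraction and cumulative input fraction differ the
    most, the ratio of input mass to chip mass over the background bins
    up to that index defines the factor. Multiplying the chip track by
    it equalises the background portions of the two libraries.
    """
    if not chip.same_binning(input_):
        raise ValueError("chip and input tracks must share binning")
    c = chip.flat()
    i = input_.flat()
    nonempty = (c > 0) | (i > 0)
    if nonempty.sum() < 10:
        raise ValueError("need >= 10 non-empty bins for SES")
    if c.sum() <= 0:
        raise ValueError(f"degenerate chip track {chip.sample_id}/{chip.mark}: zero mass")
    if i.sum() <= 0:
        raise ValueError(f"degenerate input track {input_.sample_id}: zero mass")
    order = np.argsort(c, kind="stable")
    cc = np.cumsum(c[order]) / c.sum()
    ci = np.cumsum(i[order]) / i.sum()
    k = int(np.argmax(np.abs(cc - ci)))
    chip_mass = float(np.sum(c[order][: k + 1]))
    input_mass = float(np.sum(i[order][: k + 1]))
    if chip_mass <= 0:
        raise ValueError(
            f"degenerate chip track {chip.sample_id}/{chip.mark}: zero background mass"
        )
    return input_mass / chip_mass


def normalize_track(
    chip: SignalTrack,
    input_: SignalTrack,
    factor: float,
    mode: str = "log2ratio",
    pseudocount: float = 1.0,
) -> SignalTrack:
    """Input-normalised track: log2((chip*factor + e) / (input + e)) per bin,
    or the linear ratio in ``mode="ratio"``."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if not chip.same_binning(input_):
        raise ValueError("chip and input tracks must share binning")
    data = {}
    for contig in chip.data:
        ratio = (chip.data[contig] * factor + pseudocount) / (input_.data[contig] + pseudocount)
        data[contig] = np.log2(ratio) if mode == "log2ratio" else ratio
    if mode not in ("log2ratio", "ratio"):
        raise ValueError(f"unknown mode {mode!r}")
    return SignalTrack(data, chip.bin_size, chip.sample_id, chip.mark)


def tss_score(track: SignalTrack, ann: pd.DataFrame, half_window: int = 2000) -> pd.Series:
    """Per-gene maximum bin value over the TSS +-half_window window (inclusive
    at both ends, clipped at contig edges). Genes on unknown contigs get NaN."""
    bs = track.bin_size
    scores = np.full(len(ann), np.nan)
    for j, (contig, tss) in enumerate(zip(ann["chrom"], ann["tss"])):
        v = track.data.get(contig)
        if v is None:
            log.warning("gene on unknown contig %s; score set to missing", contig)
            continue
        lo = max(0, (int(tss) - half_window) // bs)
        hi = min(len(v) - 1, (int(tss) + half_window) // bs)
        if hi >= lo:
            scores[j] = v[lo : hi + 1].max()
    return pd.Series(scores, index=ann["gene_id"], name=f"{track.mark}_{track.sample_id}")


def group_scale_scores(
    scores: pd.DataFrame,
    groups: pd.Series,
    reference_group: str,
    target_group: str,
) -> tuple[pd.DataFrame, float]:
    """Rescale the target group's scores to remove global bias.

    The factor is exp(median over genes of ln(mean_ref / mean_target)),
    computed on genes with positive means in both groups, and multiplies
    every target-group sample column. Returns (scaled scores, factor).
    """
    ref_cols = [s for s in scores.columns if groups[s] == reference_group]
    tgt_cols = [s for s in scores.columns if groups[s] == target_group]
    if not ref_cols or not tgt_cols:
        raise ValueError("both groups must be non-empty")
    mr = scores[ref_cols].mean(axis=1)
    mt = scores[tgt_cols].mean(axis=1)
    ok = (mr > 0) & (mt > 0)
    if not ok.any():
        raise ValueError("no gene with positive mean scores in both groups")
    f = float(np.exp(np.median(np.log(mr[ok]) - np.log(mt[ok]))))
    out = scores.copy()
    out[tgt_cols] = out[tgt_cols] * f
    return out, f


def assign_tier(overall_mean: float, bounds: tuple[float, float] = (2.0, 4.0)) -> str:
    """Binding tier: low (< lower), moderate (lower <= s <= upper), high (> upper)."""
    lo, hi = bounds
    if not np.isfinite(overall_mean):
        raise ValueError("score must be finite")
    if overall_mean < lo:
        return "low"
    if overall_mean <= hi:
        return "moderate"
    return "high"


def promoter_score_table(
    scores: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    tier_bounds: tuple[float, float] = (2.0, 4.0),
    scale_target_group: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Assemble the per-gene promoter score table for one mark.

    Per-sample scores are raw; the target (group B) columns are then
    rescaled by the median-log-ratio factor, group means and the overall
    mean are taken over the scaled scores, and the tier is assigned on
    the overall mean. Returns (table, scale factor).
    """
    factor = 1.0
    scaled = scores
    if scale_target_group:
        scaled, factor = group_scale_scores(scores, groups, group_a, group_b)
    cols_a = [s for s in scaled.columns if groups[s] == group_a]
    cols_b = [s for s in scaled.columns if groups[s] == group_b]
    out = scaled.copy()
    out["group_mean_A"] = scaled[cols_a].mean(axis=1)
    out["group_mean_B"] = scaled[cols_b].mean(axis=1)
    out["overall_mean"] = scaled[cols_a + cols_b].mean(axis=1)
    out["tier"] = [assign_tier(v, tier_bounds) for v in out["overall_mean"]]
    return out, factor


def _merge_intervals(peaks: pd.DataFrame) -> list[tuple]:
    """Single-linkage merge (>= 1 bp overlap) of (chrom, start, end, sample) records."""
    merged = []
    for contig, sub in peaks.groupby("chrom"):
        sub = sub.sort_values(["start", "end"]).to_dict("records")
        cur = None
        for r in sub:
            if cur is None or r["start"] >= cur["end"]:
                if cur is not None:
                    merged.append(cur)
                cur = {"chrom": contig, "start": r["start"], "end": r["end"],
                       "samples": {r["sample"]}}
            else:
                cur["end"] = max(cur["end"], r["end"])
                cur["samples"].add(r["sample"])
        if cur is not None:
            merged.append(cur)
    return merged


def consensus_peaks(
    peaksets: dict[str, pd.DataFrame],
    intensity: SignalTrack,
    min_support: int = 2,
    top_n: int = 500,
) -> pd.DataFrame:
    """Cross-sample consensus peaks ranked by normalised intensity.

    Peaks from all samples are merged by single-linkage overlap; merged
    regions supported by fewer than ``min_support`` distinct samples are
    dropped; survivors are scored by the maximum intensity-track value
    inside the region and the ``top_n`` highest are returned (ties broken
    by genomic coordinate).
    """
    if len(peaksets) < min_support:
        raise ValueError("need at least min_support peak sets")
    frames = []
    for sample in sorted(peaksets):
        df = peaksets[sample][["chrom", "start", "end"]].copy()
        df["sample"] = sample
        frames.append(df)
    merged = _merge_intervals(pd.concat(frames, ignore_index=True))
    rows = []
    bs = intensity.bin_size
    for m in merged:
        if len(m["samples"]) < min_support:
            continue
        v = intensity.data.get(m["chrom"])
        if v is None:
            score = np.nan
        else:
            lo = max(0, m["start"] // bs)
            hi = min(len(v), (m["end"] + bs - 1) // bs)
            score = float(v[lo:hi].max()) if hi > lo else np.nan
        rows.append((m["chrom"], m["start"], m["end"], len(m["samples"]), score))
    if not rows:
        log.warning("no consensus peaks survive the support filter")
        return pd.DataFrame(columns=["chrom", "start", "end", "n_samples", "intensity"])
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_samples", "intensity"])
    out = out.sort_values(
        ["intensity", "chrom", "start"], ascending=[False, True, True]
    ).head(top_n)
    return out.reset_index(drop=True)


def annotate_peaks(
    peaks: pd.DataFrame, ann: pd.DataFrame, promoter_half_window: int = 2000
) -> pd.DataFrame:
    """Genomic category and nearest-TSS distance per peak.

    Category: promoter if the summit lies within +-promoter_half_window
    of any TSS, else gene body if inside a gene span, else intergenic.
    Distance is the signed summit-TSS offset to the nearest TSS in
    transcription direction (negative = upstream).
    """
    if len(ann) == 0:
        raise ValueError("annotation is empty")
    if "peak" in peaks.columns:
        summits = peaks["start"] + peaks["peak"]
    else:
        summits = (peaks["start"] + peaks["end"]) // 2
    cats, dists = [], []
    by_contig = {c: sub.reset_index(drop=True) for c, sub in ann.groupby("chrom")}
    for contig, summit in zip(peaks["chrom"], summits):
        sub = by_contig.get(contig)
        if sub is None:
            cats.append("intergenic")
            dists.append(np.nan)
            continue
        tss = sub["tss"].to_numpy()
        j = int(np.argmin(np.abs(tss - summit)))
        strand = sub.loc[j, "strand"]
        signed = summit - tss[j] if strand == "+" else tss[j] - summit
        dists.append(int(signed))
        if abs(summit - tss[j]) <= promoter_half_window:
            cats.append("promoter")
        elif ((sub["start"] <= summit) & (summit < sub["end"])).any():
            cats.append("gene_body")
        else:
            cats.append("intergenic")
    out = peaks.copy()
    out["summit"] = summits
    out["category"] = cats
    out["tss_distance"] = dists
    return out
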