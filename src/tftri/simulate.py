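"""Synthetic study generator with planted ground truth.

Emulates the full input set of the triangulation analysis: a basal
3-vs-3 count matrix with planted differentially expressed genes (DEGs),
a paired control/knockdown count matrix in which a planted subset of
group-A-upregulated genes responds to the knockdown, binned ChIP and
input signal tracks with promoter-centred bumps whose amplitude encodes
a planted binding tier, per-sample peak calls at the planted bumps, and
motif hits placed in the promoters of planted target genes.

Every output family (annotation, truth/counts, tracks, motifs) draws
from its own child stream of the master seed, so regenerating one
artifact never shifts another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tftri.config import SimConfig
from tftri.containers import CountMatrix, SignalTrack, validate_annotation
from tftri import io as tio

_STREAMS = {"annotation": 0, "truth": 1, "counts": 2, "tracks": 3, "motifs": 4}

BUMP_HALF_WIDTH = 500  # bp; triangular bump, maximum at the summit
_GENE_PAD = 2500  # flank kept free on each side of a gene within its slot

TIERS = ("low", "moderate", "high")

E2F_FAMILY = "E2F"
E2F_MOTIFS = ("E2F_m1", "E2F_m2", "E2F_m3")
BACKGROUND_FAMILIES = {"NULLA": ("NULLA_m1", "NULLA_m2", "NULLA_m3"),
                       "NULLB": ("NULLB_m1", "NULLB_m2")}
MOTIF_LENGTH = 12


def _rng(cfg: SimConfig, family: str) -> np.random.Generator:
    children = np.random.SeedSequence(cfg.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[family]])


def _layout(cfg: SimConfig):
    """Slot layout of genes over two contigs; returns (slot, contig sizes, per-gene contig/offset)."""
    slot = cfg.genome_size // cfg.n_genes
    if slot < cfg.gene_length + 2 * _GENE_PAD:
        raise ValueError(
            f"genome too small: need >= {cfg.n_genes * (cfg.gene_length + 2 * _GENE_PAD)} bp "
            f"for {cfg.n_genes} genes, got {cfg.genome_size}"
        )
    slot -= slot % cfg.bin_size  # keep bins aligned to slots
    n1 = (cfg.n_genes + 1) // 2
    sizes = {"chr1": n1 * slot, "chr2": (cfg.n_genes - n1) * slot}
    sizes = {c: n for c, n in sizes.items() if n > 0}
    return slot, sizes, n1


def simulate_annotation(cfg: SimConfig) -> pd.DataFrame:
    """Place non-overlapping fixed-length genes on two contigs, random strand."""
    rng = _rng(cfg, "annotation")
    slot, sizes, n1 = _layout(cfg)
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    rows = []
    for i in range(cfg.n_genes):
        contig = "chr1" if i < n1 else "chr2"
        local = i if i < n1 else i - n1
        start = local * slot + _GENE_PAD
        end = start + cfg.gene_length
        tss = start if strands[i] == "+" else end - 1
        rows.append((f"g{i:05d}", contig, start, end, strands[i], tss))
    ann = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"])
    return validate_annotation(ann)


def _make_truth(cfg: SimConfig, gene_ids: pd.Index) -> pd.DataFrame:
    rng = _rng(cfg, "truth")
    n = len(gene_ids)
    n_deg = int(round(cfg.frac_deg * n))
    deg = rng.choice(n, size=n_deg, replace=False)
    n_up = n_deg - n_deg // 2
    up, down = deg[:n_up], deg[n_up:]
    n_target = int(round(cfg.frac_e2f1_target * n_up))
    targets = rng.choice(up, size=n_target, replace=False) if n_target else np.array([], int)

    tier = np.full(n, "low", dtype=object)
    if n_target:
        high = rng.choice(targets, size=n_target // 2, replace=False)
        tier[targets] = "moderate"
        tier[high] = "high"

    has_motif = np.zeros(n, bool)
    has_motif[targets] = True
    others = np.setdiff1d(np.arange(n), targets)
    n_bg = int(round(cfg.frac_motif_background * len(others)))
    if n_bg:
        has_motif[rng.choice(others, size=n_bg, replace=False)] = True

    is_mito = np.zeros(n, bool)
    n_mito = int(round(cfg.frac_mito * n))
    if n_mito:
        is_mito[rng.choice(n, size=n_mito, replace=False)] = True

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_deg_up_groupA": np.isin(np.arange(n), up),
            "is_deg_down_groupA": np.isin(np.arange(n), down),
            "is_e2f1_target": np.isin(np.arange(n), targets),
            "planted_tier": tier,
            "has_motif": has_motif,
            "is_mito": is_mito,
        }
    )
    assert not (truth["is_deg_up_groupA"] & truth["is_deg_down_groupA"]).any()
    return truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson when dispersion ~ 0)."""
    mean = np.asarray(mean, float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(cfg: SimConfig, ann: pd.DataFrame):
    """Basal and paired-knockdown count matrices plus the planted truth table.

    Basal: group A gets planted up-DEGs scaled by ``deg_fold`` and
    down-DEGs by ``1/deg_fold`` relative to group B. Knockdown: every
    line contributes a control/treated pair; planted target genes are
    scaled by ``1/kd_fold`` in the treated member.
    """
    truth = _make_truth(cfg, ann["gene_id"])
    rng = _rng(cfg, "counts")
    n = len(ann)

    weights = rng.lognormal(mean=0.0, sigma=cfg.lognormal_sigma, size=n)
    base_mean = cfg.lib_size_mean * weights / weights.sum()

    fold_a = np.ones(n)
    fold_a[truth["is_deg_up_groupA"].to_numpy()] = cfg.deg_fold
    fold_a[truth["is_deg_down_groupA"].to_numpy()] = 1.0 / cfg.deg_fold

    lines_a = [f"A{i + 1}" for i in range(cfg.n_per_group)]
    lines_b = [f"B{i + 1}" for i in range(cfg.n_per_group)]

    basal_cols, basal_counts = [], []
    for line in lines_a + lines_b:
        mean = base_mean * (fold_a if line in lines_a else 1.0)
        basal_counts.append(_nb_draw(rng, mean, cfg.nb_dispersion))
        basal_cols.append(line)
    basal = CountMatrix(
        pd.DataFrame(np.column_stack(basal_counts), index=ann["gene_id"], columns=basal_cols),
        groups=pd.Series({**{s: "A" for s in lines_a}, **{s: "B" for s in lines_b}}),
    )

    kd_scale = np.where(truth["is_e2f1_target"], 1.0 / cfg.kd_fold, 1.0)
    kd_cols, kd_counts, kd_groups, kd_pairs = [], [], {}, {}
    for line in lines_a + lines_b:
        ctrl_mean = base_mean * (fold_a if line in lines_a else 1.0)
        for role, mean in (("ctrl", ctrl_mean), ("kd", ctrl_mean * kd_scale)):
            sid = f"{line}_{role}"
            kd_counts.append(_nb_draw(rng, mean, cfg.nb_dispersion))
            kd_cols.append(sid)
            kd_groups[sid] = "control" if role == "ctrl" else "knockdown"
            kd_pairs[sid] = line
    knockdown = CountMatrix(
        pd.DataFrame(np.column_stack(kd_counts), index=ann["gene_id"], columns=kd_cols),
        groups=pd.Series(kd_groups),
        pairs=pd.Series(kd_pairs),
    )
    return basal, knockdown, truth


def _bump_profile(lam: np.ndarray, tss: int, amp: float, bin_size: int) -> None:
    """Add a triangular bump (in place) centred at ``tss`` to a per-bin rate vector."""
    if amp <= 0:
        return
    lo = max(0, (tss - BUMP_HALF_WIDTH) // bin_size)
    hi = min(len(lam) - 1, (tss + BUMP_HALF_WIDTH) // bin_size)
    centres = (np.arange(lo, hi + 1) + 0.5) * bin_size
    lam[lo : hi + 1] += amp * np.clip(1.0 - np.abs(centres - tss) / BUMP_HALF_WIDTH, 0.0, None)


def simulate_tracks_and_peaks(cfg: SimConfig, ann: pd.DataFrame, truth: pd.DataFrame):
    """Per-sample ChIP/input tracks, peak calls at planted bumps, and motif hits.

    Returns (tracks, peaks, motifs): ``tracks`` maps (mark, sample) ->
    SignalTrack with mark "input" holding each sample's genomic input;
    ``peaks`` maps (mark, sample) -> narrowPeak-style DataFrame.
    """
    rng = _rng(cfg, "tracks")
    _, sizes, _ = _layout(cfg)
    nbins = {c: int(np.ceil(s / cfg.bin_size)) for c, s in sizes.items()}
    lines = [f"A{i + 1}" for i in range(cfg.n_per_group)] + [
        f"B{i + 1}" for i in range(cfg.n_per_group)
    ]

    amp = truth["planted_tier"].map(cfg.peak_amp_by_tier).to_numpy(float)
    flagged = (truth["is_deg_up_groupA"] & truth["is_e2f1_target"]).to_numpy()

    tracks: dict[tuple, SignalTrack] = {}
    peaks: dict[tuple, pd.DataFrame] = {}
    for sample in lines:
        data = {
            c: rng.poisson(cfg.background_rate, nb).astype(float) for c, nb in sorted(nbins.items())
        }
        tracks[("input", sample)] = SignalTrack(data, cfg.bin_size, sample, "input")

    for mark in cfg.marks:
        histone = mark != "E2F1"
        for sample in lines:
            in_group_a = sample.startswith("A")
            gene_amp = amp.copy()
            if histone and in_group_a:
                gene_amp[flagged] *= cfg.histone_boost
            lam = {c: np.full(nb, cfg.background_rate) for c, nb in sorted(nbins.items())}
            for tss, contig, a in zip(ann["tss"], ann["chrom"], gene_amp):
                _bump_profile(lam[contig], int(tss), a, cfg.bin_size)
            data = {c: rng.poisson(v).astype(float) for c, v in lam.items()}
            tracks[(mark, sample)] = SignalTrack(data, cfg.bin_size, sample, mark)

            rows = []
            bumps = truth["planted_tier"] != "low"
            for gid, contig, tss, a in zip(
                ann.loc[bumps.to_numpy(), "gene_id"],
                ann.loc[bumps.to_numpy(), "chrom"],
                ann.loc[bumps.to_numpy(), "tss"],
                gene_amp[bumps.to_numpy()],
            ):
                start = max(0, int(tss) - BUMP_HALF_WIDTH)
                rows.append(
                    (contig, start, int(tss) + BUMP_HALF_WIDTH, f"{gid}_{sample}",
                     int(min(1000, a)), ".", a, -1.0, -1.0, int(tss) - start)
                )
            for j in range(cfg.noise_peaks_per_sample):
                contig = sorted(sizes)[int(rng.integers(len(sizes)))]
                pos = int(rng.integers(0, sizes[contig] - 400))
                rows.append(
                    (contig, pos, pos + 400, f"noise_{sample}_{j}",
                     50, ".", float(cfg.background_rate), -1.0, -1.0, 200)
                )
            peaks[(mark, sample)] = pd.DataFrame(rows, columns=tio.NARROWPEAK_COLUMNS)

    motifs = _simulate_motifs(cfg, ann, truth)
    return tracks, peaks, motifs


def _simulate_motifs(cfg: SimConfig, ann: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    rng = _rng(cfg, "motifs")
    rows = []
    half = 2000 - MOTIF_LENGTH
    for gid, contig, tss, hit in zip(
        ann["gene_id"], ann["chrom"], ann["tss"], truth["has_motif"]
    ):
        if hit:
            motif = E2F_MOTIFS[int(rng.integers(len(E2F_MOTIFS)))]
            start = int(tss) + int(rng.integers(-half, half))
            rows.append(
                (motif, E2F_FAMILY, contig, max(0, start), max(0, start) + MOTIF_LENGTH,
                 "+" if rng.random() < 0.5 else "-", float(np.round(8 + 4 * rng.random(), 3)))
            )
        # background families: hits independent of the planted truth
        for family, motif_ids in BACKGROUND_FAMILIES.items():
            for motif in motif_ids:
                if rng.random() < 0.15:
                    start = int(tss) + int(rng.integers(-half, half))
                    rows.append(
                        (motif, family, contig, max(0, start), max(0, start) + MOTIF_LENGTH,
                         "+" if rng.random() < 0.5 else "-",
                         float(np.round(5 + 4 * rng.random(), 3)))
                    )
    return pd.DataFrame(rows, columns=tio.MOTIF_COLUMNS)


@dataclass
class SimBundle:
    """All synthetic artifacts of one seeded study."""

    cfg: SimConfig
    annotation: pd.DataFrame
    basal: CountMatrix
    knockdown: CountMatrix
    truth: pd.DataFrame
    tracks: dict
    peaks: dict
    motifs: pd.DataFrame


def simulate_all(cfg: SimConfig, with_tracks: bool = True) -> SimBundle:
    ann = simulate_annotation(cfg)
    basal, kd, truth = simulate_counts(cfg, ann)
    if with_tracks:
        tracks, peaks, motifs = simulate_tracks_and_peaks(cfg, ann, truth)
    else:
        tracks, peaks, motifs = {}, {}, _simulate_motifs(cfg, ann, truth)
    return SimBundle(cfg, ann, basal, kd, truth, tracks, peaks, motifs)


def write_simulation(bundle: SimBundle, outdir) -> None:
    """Write every artifact as plain text (TSV / bedGraph / narrowPeak)."""
    from pathlib import Path

    out = Path(outdir)
    tio.write_annotation(bundle.annotation, out / "annotation.tsv")
    tio.write_counts(bundle.basal, out / "counts_basal.tsv", out / "samples_basal.tsv")
    tio.write_counts(bundle.knockdown, out / "counts_knockdown.tsv", out / "samples_knockdown.tsv")
    tio.write_table(bundle.truth, out / "truth.tsv")
    tio.write_motifs(bundle.motifs, out / "motifs.tsv")
    for (mark, sample), track in sorted(bundle.tracks.items()):
        tio.write_bedgraph(track, out / "tracks" / f"{mark}_{sample}.bedgraph")
    for (mark, sample), pk in sorted(bundle.peaks.items()):
        tio.write_narrowpeak(pk, out / "peaks" / f"{mark}_{sample}.narrowPeak")
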