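"""Configuration objects for simulation and pipeline runs.

Both configs round-trip through YAML unchanged so a run log can echo the
exact configuration it was produced from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    The defaults emulate the study design this package targets: a 3-vs-3
    basal contrast between two neonatal groups (A = growth-restricted,
    B = control), a paired control/knockdown design over the same six
    cell lines, promoter-centred binding signal in three amplitude tiers
    and motif hits planted at target promoters.
    """

    n_genes: int = 2000
    n_per_group: int = 3
    genome_size: int = 20_000_000
    bin_size: int = 50
    gene_length: int = 2000
    lib_size_mean: float = 1_000_000.0
    lognormal_sigma: float = 1.0
    nb_dispersion: float = 0.05
    frac_deg: float = 0.10
    deg_fold: float = 4.0
    frac_e2f1_target: float = 0.5  # fraction of group-A-up DEGs planted as targets
    kd_fold: float = 4.0
    # amplitudes are extra counts per bin at the bump summit, on top of background
    peak_amp_by_tier: dict = field(
        default_factory=lambda: {"low": 0.0, "moderate": 140.0, "high": 620.0}
    )
    background_rate: float = 20.0  # expected counts per bin away from bumps
    histone_boost: float = 2.0  # group-A amplitude multiplier at flagged genes
    frac_motif_background: float = 0.10
    frac_mito: float = 0.05
    noise_peaks_per_sample: int = 20
    marks: tuple = ("E2F1", "H3K27ac")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_deg", "frac_e2f1_target", "frac_motif_background", "frac_mito"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("deg_fold", "kd_fold"):
            if getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be > 1")
        if self.genome_size % self.bin_size != 0:
            raise ValueError("bin_size must divide genome_size")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        self.marks = tuple(self.marks)
        bad = set(self.peak_amp_by_tier) - {"low", "moderate", "high"}
        if bad:
            raise ValueError(f"unknown tiers in peak_amp_by_tier: {sorted(bad)}")


@dataclass
class Thresholds:
    """Statistical thresholds; the defaults are the printed study values."""

    fc_cutoff: float = 1.3
    alpha: float = 0.05
    basal_criterion: str = "p"
    kd_criterion: str = "fdr"
    tier_bounds: tuple = (2.0, 4.0)
    half_window: int = 2000
    min_support: int = 2
    top_n: int = 500
    pseudocount: float = 0.5
    track_pseudocount: float = 1.0
    track_mode: str = "log2ratio"

    def __post_init__(self) -> None:
        if self.fc_cutoff <= 1 or self.alpha <= 0 or self.half_window <= 0:
            raise ValueError("thresholds must be positive (fc_cutoff > 1)")
        if self.basal_criterion not in ("p", "fdr") or self.kd_criterion not in ("p", "fdr"):
            raise ValueError("criterion must be 'p' or 'fdr'")
        self.tier_bounds = tuple(float(x) for x in self.tier_bounds)


@dataclass
class RunConfig:
    """Full pipeline configuration: a simulation (or input paths) plus thresholds."""

    outdir: str
    seed: int = 0
    simulate: SimConfig | None = None
    inputs: dict | None = None  # paths: annotation, counts_basal, counts_kd, ...
    thresholds: Thresholds = field(default_factory=Thresholds)
    group_a: str = "SGA"
    group_b: str = "AGA"
    write_tracks: bool = False

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("group labels must be distinct")
        if self.simulate is None and not self.inputs:
            raise ValueError("need either a simulate block or input paths")

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        if d["simulate"] is not None:
            d["simulate"]["marks"] = list(d["simulate"]["marks"])
        d["thresholds"]["tier_bounds"] = list(d["thresholds"]["tier_bounds"])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = yaml.safe_load(text)
        if d.get("simulate") is not None:
            d["simulate"] = SimConfig(**d["simulate"])
        if d.get("thresholds") is not None:
            d["thresholds"] = Thresholds(**d["thresholds"])
        return cls(**d)
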