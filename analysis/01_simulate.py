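"""Generate the synthetic study.

Simulates the default design this analysis targets — 2000 genes, a
3-vs-3 basal contrast (group A = growth-restricted SGA lines, group B =
AGA controls), a paired E2F1-knockdown arm over the same six lines,
planted DEGs (10%, 4-fold), planted E2F1 targets (half of the up-DEGs)
and promoter motif hits — and writes the count tables, annotation,
motif hits, peak calls and planted truth under results/01_study/.

Signal tracks are not written here (hundreds of MB as text); later
steps regenerate them in memory from the same seed, which is safe
because each output family draws from its own RNG stream.
"""

from pathlib import Path

from tftri.config import SimConfig
from tftri import io as tio, simulate as sim

OUT = Path("results/01_study")
SEED = 1


def main() -> None:
    cfg = SimConfig(seed=SEED)
    bundle = sim.simulate_all(cfg, with_tracks=True)
    tio.write_annotation(bundle.annotation, OUT / "annotation.tsv")
    tio.write_counts(bundle.basal, OUT / "counts_basal.tsv", OUT / "samples_basal.tsv")
    tio.write_counts(
        bundle.knockdown, OUT / "counts_knockdown.tsv", OUT / "samples_knockdown.tsv"
    )
    tio.write_table(bundle.truth, OUT / "truth.tsv")
    tio.write_motifs(bundle.motifs, OUT / "motifs.tsv")
    for (mark, sample), pk in sorted(bundle.peaks.items()):
        tio.write_narrowpeak(pk, OUT / "peaks" / f"{mark}_{sample}.narrowPeak")

    t = bundle.truth
    print(f"simulated {cfg.n_genes} genes on a {cfg.genome_size/1e6:.0f} Mb genome (seed {SEED})")
    print(f"planted DEGs: {int(t['is_deg_up_groupA'].sum())} up, "
          f"{int(t['is_deg_down_groupA'].sum())} down in group A")
    print(f"planted E2F1 targets: {int(t['is_e2f1_target'].sum())} "
          f"(tiers: {t['planted_tier'].value_counts().to_dict()})")
    print(f"promoters with an E2F-family motif: {int(t['has_motif'].sum())}")
    print(f"wrote study inputs to {OUT}/")


if __name__ == "__main__":
    main()
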