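"""Integration: does the factor's binding explain the differential transcriptome?

Joins the expression tables (02) with the promoter signal tables (03)
and asks the study's headline questions on the synthetic data:
binding-vs-DEG-direction association (Fisher), motif-family enrichment
between up- and down-DEG promoters (per-motif Fisher, within-family
Bonferroni-or-median correction, BH across families), the binding-tier
cross-tab of expression categories, and group comparisons of promoter
signal at up-DEGs (paired Wilcoxon and two-tailed binomial sign test).
Tables go to results/04_integration/.
"""

from pathlib import Path

import pandas as pd

from tftri import enrich, io as tio

STUDY = Path("results/01_study")
EXPR = Path("results/02_expression")
CHIP = Path("results/03_chip")
OUT = Path("results/04_integration")


def main() -> None:
    ann = tio.read_annotation(STUDY / "annotation.tsv")
    motifs = tio.read_motifs(STUDY / "motifs.tsv")
    de_basal = pd.read_csv(EXPR / "de_basal.tsv", sep="\t")
    de_kd = pd.read_csv(EXPR / "de_knockdown.tsv", sep="\t")
    scores = pd.read_csv(CHIP / "promoter_scores_E2F1.tsv", sep="\t", index_col=0)
    peaks = pd.read_csv(CHIP / "consensus_peaks.tsv", sep="\t")

    up = set(de_basal.loc[de_basal["direction"] == "up", "gene_id"])
    down = set(de_basal.loc[de_basal["direction"] == "down", "gene_id"])
    universe = set(de_basal["gene_id"])

    hits = peaks[["chrom", "start", "end"]].copy()
    hits["key"] = "peak"
    bound = enrich.genes_with_promoter_hit(
        hits, ann[ann["gene_id"].isin(universe)], by="key"
    ).get("peak", set())
    assoc = enrich.binding_vs_deg_association(bound, up, down)
    tio.write_table(
        pd.DataFrame([{k: v for k, v in assoc.items() if k != "table"}]),
        OUT / "binding_association.tsv",
    )
    print(f"promoter-bound genes: {len(bound)} of {len(universe)} expressed")
    print(f"bound fraction among up-DEGs {assoc['prop_up_bound']:.2f} vs "
          f"down-DEGs {assoc['prop_down_bound']:.2f}; Fisher p = {assoc['p']:.3g}")

    fam = enrich.motif_family_enrichment(motifs, up, down, ann)
    tio.write_table(fam, OUT / "motif_family_enrichment.tsv")
    top = fam.iloc[0]
    print(f"top motif family: {top['family_id']} "
          f"(corrected p = {top['corrected_p']:.3g}, FDR = {top['fdr']:.3g}, {top['direction']})")

    # tier cross-tab over the full annotation (unexpressed genes form "UN")
    basal_cat = pd.Series("UN", index=ann["gene_id"], dtype=object)
    basal_cat.loc[list(universe)] = "S=A"
    basal_cat.loc[list(up)] = "S>A"
    basal_cat.loc[list(down)] = "S<A"
    kd_cat = pd.Series("none", index=ann["gene_id"], dtype=object)
    dk = de_kd.set_index("gene_id")
    kd_cat.loc[dk.index[dk["direction"] == "down"]] = "down"
    kd_cat.loc[dk.index[dk["direction"] == "up"]] = "up"
    tier = scores["tier"].reindex(ann["gene_id"]).fillna("low")
    ct = enrich.category_crosstab(basal_cat, kd_cat, tier)
    flat = ct["props"].copy()
    flat.columns = [f"{b}|{k}" for b, k in flat.columns]
    tio.write_table(flat, OUT / "crosstab_props.tsv", index=True)
    modhigh = 100 * (1 - ct["props"].loc["low"])
    by_basal = ct["counts"].T.groupby(level=0).sum()
    frac = 100 * (by_basal[["moderate", "high"]].sum(axis=1) / by_basal.sum(axis=1))
    print("moderate-or-high binding by basal category: "
          + ", ".join(f"{k} {v:.0f}%" for k, v in frac.items()))
    print(f"tier-collapse Fisher (S>A vs S<A): p = {ct['fisher']['p']:.3g}")
    _ = modhigh

    # group comparison of promoter signal at up-DEGs: the study's key
    # contrast is that the factor's own binding does not differ between
    # groups while the active histone mark does
    rows = []
    for mark in ("E2F1", "H3K27ac"):
        table = pd.read_csv(CHIP / f"promoter_scores_{mark}.tsv", sep="\t", index_col=0)
        sub = table.loc[table.index.isin(up)]
        w = enrich.wilcoxon_group_compare(sub["group_mean_A"], sub["group_mean_B"], paired=True)
        above = int((sub["group_mean_A"] > sub["group_mean_B"]).sum())
        below = int((sub["group_mean_A"] < sub["group_mean_B"]).sum())
        b = enrich.binomial_sign_test(above, below)
        rows.append({"mark": mark, "n": len(sub), "wilcoxon_p": w,
                     "n_above": above, "n_below": below, "binomial_p": b})
        print(f"{mark} signal at up-DEG promoters, group A vs B: Wilcoxon p = {w:.3g}, "
              f"binomial sign p = {b:.3g} ({above} above / {below} below)")
    tio.write_table(pd.DataFrame(rows), OUT / "mark_group_tests.tsv")


if __name__ == "__main__":
    main()
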