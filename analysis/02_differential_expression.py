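"""Differential expression: basal contrast and paired knockdown.

Reads the study written by 01_simulate.py, removes low-count genes
(> 1 CPM in at least 3 of 6 samples), runs the basal two-group test
(FC 1.3, p < 0.05) and the paired knockdown test (FC 1.3, BH FDR
< 0.05), summarises the overlap of the two DEG sets, and classifies
every gene into a (basal, knockdown) fold-change quadrant with a
per-quadrant Fisher enrichment test. Tables go to results/02_expression/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tftri.containers import CountMatrix
from tftri import expression as expr, io as tio

IN = Path("results/01_study")
OUT = Path("results/02_expression")


def main() -> None:
    counts, groups, _ = tio.read_counts(IN / "counts_basal.tsv", IN / "samples_basal.tsv")
    basal = CountMatrix(counts, groups)
    counts, groups, pairs = tio.read_counts(
        IN / "counts_knockdown.tsv", IN / "samples_knockdown.tsv"
    )
    kd = CountMatrix(counts, groups, pairs)

    expressed = expr.cpm_filter(basal)
    print(f"expressed genes: {len(expressed.gene_ids)} of {len(basal.gene_ids)}")

    de_basal = expr.de_test(expressed, "two_group", group_a="A", group_b="B", criterion="p")
    de_kd = expr.de_test(
        kd.subset_genes(list(expressed.gene_ids)), "paired", criterion="fdr"
    )
    tio.write_table(de_basal, OUT / "de_basal.tsv")
    tio.write_table(de_kd, OUT / "de_knockdown.tsv")
    n_up = (de_basal["direction"] == "up").sum()
    n_down = (de_basal["direction"] == "down").sum()
    print(f"basal DEGs (FC>=1.3, p<0.05): {n_up} up, {n_down} down in group A")
    print(f"knockdown-responsive genes (FC>=1.3, FDR<0.05): "
          f"{(de_kd['direction'] == 'down').sum()} down, {(de_kd['direction'] == 'up').sum()} up")

    basal_up = set(de_basal.loc[de_basal["direction"] == "up", "gene_id"])
    kd_down = set(de_kd.loc[de_kd["direction"] == "down", "gene_id"])
    v = expr.venn_summarize(basal_up, kd_down)
    tio.write_table(pd.DataFrame([v]), OUT / "venn_basal_up_vs_kd_down.tsv")
    print(f"basal-up vs knockdown-repressed: {v['n_common']} common, "
          f"{v['n_exclusive_A']} basal-up only ({v['pct_exclusive_A']}%)")

    quad = expr.quadrant_classify(
        de_basal, de_kd, tau=np.log2(1.3), basal_criterion="p", kd_criterion="fdr"
    )
    qe = expr.quadrant_enrichment(quad)
    tio.write_table(quad, OUT / "quadrants.tsv")
    tio.write_table(qe, OUT / "quadrant_enrichment.tsv")
    for _, r in qe.iterrows():
        print(f"quadrant {r['quadrant']}: n={r['n_in']} Fisher p={r['p']:.3g}")


if __name__ == "__main__":
    main()
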