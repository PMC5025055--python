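# tftri — transcription-factor target triangulation

`tftri` is an analysis pipeline for a recurring question in regulatory
genomics: *does one transcription factor drive the up-regulated half of
a differential transcriptome?* It implements the integrative strategy
used in studies of E2F1 in Wharton's-jelly mesenchymal stem cells from
growth-restricted (SGA) versus normally grown (AGA) newborns, where
three independent genome-scale readouts are triangulated:

1. **Basal contrast** — 3-vs-3 RNA-seq between groups; DEGs at
   fold-change ≥ 1.3 and p < 0.05.
2. **Knockdown response** — paired control/siRNA RNA-seq over the same
   cell lines; responsive genes at fold-change ≥ 1.3 and BH FDR < 0.05.
   Genes that are up in the affected group *and* down upon knockdown
   (the "up–down" quadrant at |log2FC| ≥ log2 1.3 ≈ 0.38 on both axes)
   are candidate direct targets.
3. **Promoter occupancy** — per-sample ChIP tracks are normalised to
   genomic input by signal extraction scaling (SES), each gene scored
   by the highest track point within ±2 kb of the TSS, group-rescaled
   by a median-log-ratio factor, and tiered
   (low < 2 ≤ moderate ≤ 4 < high); plus motif-family enrichment
   between up- and down-DEG promoters with the two-stage correction
   min(best-p × #motifs, median-p) then BH across families.

Because the original sequencing data live in a repository archive, the
package ships a first-class synthetic-study generator with planted
ground truth (planted DEGs, planted targets, planted binding tiers,
planted motifs), so every stage is benchmarked by recovery of known
effects rather than by eyeballing. See `docs/methods.md` for the model
and every statistical choice.

## Worked example

The numbered drivers under `analysis/` run the whole study; each prints
what it found and writes its tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_promoter_signal.py
python analysis/04_integration_enrichment.py
python analysis/05_report.py
```

Selected output of a run with the default seed:

```
planted DEGs: 100 up, 100 down in group A
planted E2F1 targets: 50 (tiers: {'low': 1950, 'high': 25, 'moderate': 25})
...
basal DEGs (FC>=1.3, p<0.05): 148 up, 148 down in group A
knockdown-responsive genes (FC>=1.3, FDR<0.05): 52 down, 1 up
quadrant up-down: n=50 Fisher p=2.9e-29
...
E2F1 tier recovery vs planted truth: 100.0%
bound fraction among up-DEGs 0.34 vs down-DEGs 0.00; Fisher p = 1.19e-17
top motif family: E2F (corrected p = 0.00149, FDR = 0.00447, positive_set)
E2F1 signal at up-DEG promoters, group A vs B: Wilcoxon p = 0.387 ...
H3K27ac signal at up-DEG promoters, group A vs B: Wilcoxon p = 7.77e-09 ...
```

Reading it: all 50 planted targets land in the up–down quadrant and the
quadrant is massively over-populated (Fisher p ≈ 1e-29); promoter
binding concentrates on up-DEGs (34% vs 0% bound, p ≈ 1e-17); the
planted motif family tops the enrichment ranking; and — mirroring the
motivating study's key observation — the factor's own binding does not
differ between groups (Wilcoxon p = 0.39) while the active histone mark
does (p ≈ 8e-9). The basal arm also shows the cost of the printed
raw-p criterion: 148 calls for 100 planted up-DEGs.

Everything is also available as a library (`tftri.expression`,
`tftri.chip`, `tftri.enrich`, `tftri.simulate`, `tftri.pipeline`) and
as a CLI:

```sh
tftri simulate --config sim.yaml --outdir study/
tftri run --config run.yaml
tftri report --bundle results/05_bundle
```

Identical config and seed reproduce every bundle byte for byte.

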