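"""End-to-end orchestration: simulate/load -> filter -> DE -> score ->
integrate -> enrich -> report.

A run writes a machine-readable bundle of TSV tables plus a plain-text
run log; identical config and seed produce byte-identical bundles (the
log carries no timestamps). The gene universe for all association tests
is the set of genes surviving the CPM filter; unexpressed genes are kept
only for the binding-tier cross-tab, where they form the "UN" column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from tftri import chip, enrich, expression as expr, io as tio, simulate as sim
from tftri.config import RunConfig
from tftri.containers import CountMatrix


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _load_inputs(cfg: RunConfig) -> sim.SimBundle:
    paths = cfg.inputs
    ann = tio.read_annotation(paths["annotation"])
    counts, groups, _ = tio.read_counts(paths["counts_basal"], paths["samples_basal"])
    basal = CountMatrix(counts, groups)
    counts, groups, pairs = tio.read_counts(paths["counts_knockdown"], paths["samples_knockdown"])
    kd = CountMatrix(counts, groups, pairs)
    motifs = tio.read_motifs(paths["motifs"])
    tracks, peaks = {}, {}
    bin_size = int(paths.get("bin_size", 50))
    for key, p in paths.get("tracks", {}).items():
        mark, sample = key.split(":")
        tracks[(mark, sample)] = tio.read_bedgraph(p, bin_size, sample, mark)
    for key, p in paths.get("peaks", {}).items():
        mark, sample = key.split(":")
        peaks[(mark, sample)] = tio.read_narrowpeak(p)
    truth = pd.read_csv(paths["truth"], sep="\t") if "truth" in paths else None
    scfg = sim.SimConfig(seed=cfg.seed)
    bundle = sim.SimBundle(scfg, ann, basal, kd, truth, tracks, peaks, motifs)
    return bundle


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the results bundle into ``cfg.outdir``.

    Returns a dict of the in-memory results keyed by stage.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    th = cfg.thresholds
    logbuf: list[str] = []

    def stage(name):
        logbuf.append(f"[stage] {name}")

    # -- inputs -----------------------------------------------------------
    try:
        if cfg.simulate is not None:
            stage("simulate")
            data = sim.simulate_all(cfg.simulate)
            tio.write_annotation(data.annotation, out / "annotation.tsv")
            tio.write_table(data.truth, out / "truth.tsv")
            tio.write_motifs(data.motifs, out / "motifs.tsv")
            if cfg.write_tracks:
                sim.write_simulation(data, out / "inputs")
        else:
            stage("load_inputs")
            data = _load_inputs(cfg)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("inputs", str(e)) from e

    results: dict = {"data": data}
    group_a_samples = [s for s in data.basal.sample_ids if data.basal.groups[s] == "A"]
    line_group = {s: ("A" if s.startswith("A") else "B") for s in data.basal.sample_ids}

    # -- expression -------------------------------------------------------
    try:
        stage("cpm_filter")
        expressed = expr.cpm_filter(data.basal, min_cpm=1.0, min_samples=3)
        universe = list(expressed.gene_ids)
        logbuf.append(f"expressed genes: {len(universe)} of {len(data.basal.gene_ids)}")

        stage("de_basal")
        de_basal = expr.de_test(
            expressed, "two_group", group_a="A", group_b="B",
            fc_cutoff=th.fc_cutoff, alpha=th.alpha, criterion=th.basal_criterion,
        )
        tio.write_table(de_basal, out / "de_basal.tsv")

        stage("de_knockdown")
        kd_expressed = data.knockdown.subset_genes(universe)
        de_kd = expr.de_test(
            kd_expressed, "paired",
            fc_cutoff=th.fc_cutoff, alpha=th.alpha, criterion=th.kd_criterion,
        )
        tio.write_table(de_kd, out / "de_knockdown.tsv")

        stage("venn")
        basal_up = set(de_basal.loc[de_basal["direction"] == "up", "gene_id"])
        basal_down = set(de_basal.loc[de_basal["direction"] == "down", "gene_id"])
        kd_down = set(de_kd.loc[de_kd["direction"] == "down", "gene_id"])
        kd_up = set(de_kd.loc[de_kd["direction"] == "up", "gene_id"])
        venns = pd.DataFrame(
            [
                {"comparison": "basal_up_vs_kd_down", **expr.venn_summarize(basal_up, kd_down)},
                {"comparison": "basal_down_vs_kd_up", **expr.venn_summarize(basal_down, kd_up)},
            ]
        )
        tio.write_table(venns, out / "venn.tsv")

        stage("quadrants")
        quad = expr.quadrant_classify(
            de_basal, de_kd, tau=np.log2(th.fc_cutoff),
            basal_criterion=th.basal_criterion, kd_criterion=th.kd_criterion, alpha=th.alpha,
        )
        quad_enr = expr.quadrant_enrichment(quad)
        tio.write_table(quad, out / "quadrants.tsv")
        tio.write_table(quad_enr, out / "quadrant_enrichment.tsv")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("expression", str(e)) from e

    results.update(
        de_basal=de_basal, de_kd=de_kd, venns=venns, quadrants=quad, quadrant_enrichment=quad_enr
    )

    # -- chip signal ------------------------------------------------------
    score_tables: dict[str, pd.DataFrame] = {}
    norm_tracks: dict[tuple, object] = {}
    try:
        marks = sorted({mark for (mark, _s) in data.tracks if mark != "input"})
        for mark in marks:
            stage(f"score_{mark}")
            cols = {}
            for (m, sample) in sorted(data.tracks):
                if m != mark:
                    continue
                f = chip.ses_scale_factor(data.tracks[(m, sample)], data.tracks[("input", sample)])
                logbuf.append(f"SES factor {mark}/{sample}: {f:.6g}")
                nt = chip.normalize_track(
                    data.tracks[(m, sample)], data.tracks[("input", sample)], f,
                    mode=th.track_mode, pseudocount=th.track_pseudocount,
                )
                norm_tracks[(mark, sample)] = nt
                cols[sample] = chip.tss_score(nt, data.annotation, th.half_window)
            scores = pd.DataFrame(cols)
            table, gf = chip.promoter_score_table(
                scores, pd.Series(line_group), "A", "B", tier_bounds=th.tier_bounds
            )
            logbuf.append(f"group scale factor {mark} (B->A): {gf:.6g}")
            score_tables[mark] = table
            tio.write_table(table, out / f"promoter_scores_{mark}.tsv", index=True)

        consensus = pd.DataFrame()
        peak_ann = pd.DataFrame()
        if any(m == "E2F1" for (m, _s) in data.peaks):
            stage("consensus_peaks")
            e2f1_sets = {s: pk for (m, s), pk in data.peaks.items() if m == "E2F1"}
            mean_track = _mean_track([norm_tracks[("E2F1", s)] for s in sorted(e2f1_sets)])
            consensus = chip.consensus_peaks(
                e2f1_sets, mean_track, min_support=th.min_support, top_n=th.top_n
            )
            tio.write_table(consensus, out / "consensus_peaks.tsv")
            stage("annotate_peaks")
            peak_ann = chip.annotate_peaks(consensus, data.annotation, th.half_window)
            tio.write_table(peak_ann, out / "peak_annotation.tsv")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("chip_signal", str(e)) from e

    results.update(score_tables=score_tables, consensus=consensus, peak_annotation=peak_ann)

    # -- integration + enrichment ----------------------------------------
    try:
        stage("bound_set")
        bound: set = set()
        if len(consensus):
            ann_u = data.annotation[data.annotation["gene_id"].isin(universe)]
            hits = consensus.rename(columns={"chrom": "chrom"})[["chrom", "start", "end"]].copy()
            hits["key"] = "peak"
            gmap = enrich.genes_with_promoter_hit(hits, ann_u, th.half_window, by="key")
            bound = gmap.get("peak", set())
        logbuf.append(f"bound genes (promoter peak): {len(bound)}")

        stage("binding_association")
        assoc = None
        if basal_up and basal_down:
            assoc = enrich.binding_vs_deg_association(bound, basal_up, basal_down)
            tio.write_table(
                pd.DataFrame(
                    [
                        {
                            "n_up_bound": assoc["table"][0][0],
                            "n_up_unbound": assoc["table"][0][1],
                            "n_down_bound": assoc["table"][1][0],
                            "n_down_unbound": assoc["table"][1][1],
                            "p": assoc["p"],
                            "odds_ratio": assoc["odds_ratio"],
                            "prop_up_bound": assoc["prop_up_bound"],
                            "prop_down_bound": assoc["prop_down_bound"],
                        }
                    ]
                ),
                out / "binding_association.tsv",
            )

        stage("motif_enrichment")
        fam = enrich.motif_family_enrichment(
            data.motifs, basal_up, basal_down, data.annotation, th.half_window
        ) if (basal_up and basal_down and len(data.motifs)) else pd.DataFrame()
        tio.write_table(fam, out / "motif_family_enrichment.tsv")

        stage("crosstab")
        crosstab = None
        if "E2F1" in score_tables:
            basal_cat = pd.Series("UN", index=data.annotation["gene_id"], dtype=object)
            basal_cat.loc[universe] = "S=A"
            basal_cat.loc[list(basal_up)] = "S>A"
            basal_cat.loc[list(basal_down)] = "S<A"
            kd_cat = pd.Series("none", index=data.annotation["gene_id"], dtype=object)
            de_kd_idx = de_kd.set_index("gene_id")
            kd_cat.loc[de_kd_idx.index[de_kd_idx["direction"] == "down"]] = "down"
            kd_cat.loc[de_kd_idx.index[de_kd_idx["direction"] == "up"]] = "up"
            tier = score_tables["E2F1"]["tier"].reindex(basal_cat.index).fillna("low")
            crosstab = enrich.category_crosstab(basal_cat, kd_cat, tier)
            flat = crosstab["counts"].copy()
            flat.columns = [f"{b}|{k}" for b, k in flat.columns]
            tio.write_table(flat, out / "crosstab_counts.tsv", index=True)
            flatp = crosstab["props"].copy()
            flatp.columns = [f"{b}|{k}" for b, k in flatp.columns]
            tio.write_table(flatp, out / "crosstab_props.tsv", index=True)
            (a, b_), (c, d) = crosstab["fisher"]["table"]
            tio.write_table(
                pd.DataFrame(
                    [{"a": a, "b": b_, "c": c, "d": d,
                      "p": crosstab["fisher"]["p"],
                      "odds_ratio": crosstab["fisher"]["odds_ratio"]}]
                ),
                out / "crosstab_fisher.tsv",
            )

        stage("mark_group_tests")
        mark_tests = []
        for mark, table in sorted(score_tables.items()):
            sub = table.loc[table.index.isin(basal_up)]
            if len(sub) >= 3:
                w = enrich.wilcoxon_group_compare(
                    sub["group_mean_A"].to_numpy(), sub["group_mean_B"].to_numpy(), paired=True
                )
                above = int((sub["group_mean_A"] > sub["group_mean_B"]).sum())
                below = int((sub["group_mean_A"] < sub["group_mean_B"]).sum())
                ties = len(sub) - above - below
                bino = enrich.binomial_sign_test(above, below) if above + below else 1.0
                mark_tests.append(
                    {"mark": mark, "gene_set": "basal_up", "n": len(sub),
                     "wilcoxon_p": w, "n_above": above, "n_below": below,
                     "n_ties": ties, "binomial_p": bino}
                )
        mark_tests = pd.DataFrame(mark_tests)
        tio.write_table(mark_tests, out / "mark_group_tests.tsv")

        stage("integration")
        integration = _integration_table(
            data, universe, de_basal, de_kd, quad, score_tables, bound, th.half_window
        )
        tio.write_table(integration, out / "integration.tsv")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("integration", str(e)) from e

    results.update(
        bound=bound, association=assoc, motif_families=fam, crosstab=crosstab,
        mark_tests=mark_tests, integration=integration,
    )

    # -- bundle metadata --------------------------------------------------
    stage("write_bundle")
    cfg.to_yaml(out / "config_echo.yaml")
    (out / "run_log.txt").write_text("\n".join(logbuf) + "\n")
    summary = {
        "n_genes": int(len(data.basal.gene_ids)),
        "n_expressed": len(universe),
        "n_basal_up": len(basal_up),
        "n_basal_down": len(basal_down),
        "n_kd_down": len(kd_down),
        "n_kd_up": len(kd_up),
        "n_bound": len(bound),
        "association_p": None if assoc is None else assoc["p"],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    results["summary"] = summary
    return results


def _mean_track(tracks):
    data = {
        c: np.mean([t.data[c] for t in tracks], axis=0) for c in tracks[0].data
    }
    return type(tracks[0])(data, tracks[0].bin_size, "mean", tracks[0].mark)


def _integration_table(data, universe, de_basal, de_kd, quad, score_tables, bound, half_window):
    idx = pd.Index(universe, name="gene_id")
    t = pd.DataFrame(index=idx)
    b = de_basal.set_index("gene_id")
    k = de_kd.set_index("gene_id")
    for col in ("log2fc", "p", "fdr", "direction"):
        t[f"basal_{col}"] = b[col].reindex(idx)
        t[f"kd_{col}"] = k[col].reindex(idx)
    t["quadrant"] = quad.set_index("gene_id")["quadrant"].reindex(idx)
    for mark, table in sorted(score_tables.items()):
        t[f"{mark}_score"] = table["overall_mean"].reindex(idx)
        t[f"{mark}_tier"] = table["tier"].reindex(idx)
    if len(data.motifs):
        gmap = enrich.genes_with_promoter_hit(data.motifs, data.annotation, half_window, by="family_id")
        with_motif = gmap.get(sim.E2F_FAMILY, set())
    else:
        with_motif = set()
    t["has_motif"] = t.index.isin(with_motif)
    t["bound"] = t.index.isin(bound)
    if data.truth is not None:
        tr = data.truth.set_index("gene_id")
        for col in tr.columns:
            t[f"truth_{col}"] = tr[col].reindex(idx)
    return t.reset_index()


def report(bundle_dir) -> str:
    """Human-readable summary built only from the bundle files."""
    out = Path(bundle_dir)
    lines = ["triangulation run report", "=" * 24]

    def section(title):
        lines.append("")
        lines.append(title)
        lines.append("-" * len(title))

    summary_path = out / "summary.json"
    if summary_path.exists():
        s = json.loads(summary_path.read_text())
        section("overview")
        for key in sorted(s):
            lines.append(f"{key}: {s[key]}")

    section("DEG Venn summaries")
    vp = out / "venn.tsv"
    if vp.exists():
        v = pd.read_csv(vp, sep="\t")
        for _, r in v.iterrows():
            lines.append(
                f"{r['comparison']}: |A|={r['n_total_A']} |B|={r['n_total_B']} "
                f"common={r['n_common']} exclusive_A={r['n_exclusive_A']} "
                f"({r['pct_exclusive_A']}%) exclusive_B={r['n_exclusive_B']} "
                f"({r['pct_exclusive_B']}%)"
            )
    else:
        lines.append("missing: venn.tsv")

    section("quadrant counts and Fisher p")
    qp = out / "quadrant_enrichment.tsv"
    if qp.exists():
        q = pd.read_csv(qp, sep="\t")
        for _, r in q.iterrows():
            lines.append(f"{r['quadrant']}: n={r['n_in']} p={r['p']:.3g}")
    else:
        lines.append("missing: quadrant_enrichment.tsv")

    section("binding tiers by expression category")
    cp = out / "crosstab_props.tsv"
    if cp.exists():
        lines.append(Path(cp).read_text().rstrip())
    else:
        lines.append("missing: crosstab_props.tsv")

    section("top motif families")
    mp = out / "motif_family_enrichment.tsv"
    if mp.exists() and mp.stat().st_size > 0:
        fam = pd.read_csv(mp, sep="\t")
        if len(fam):
            for _, r in fam.head(5).iterrows():
                lines.append(
                    f"{r['family_id']}: corrected_p={r['corrected_p']:.3g} "
                    f"fdr={r['fdr']:.3g} ({r['direction']})"
                )
        else:
            lines.append("no families tested")
    else:
        lines.append("no families tested")

    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text
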