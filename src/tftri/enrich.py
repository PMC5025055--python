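"""Association statistics.

Exact tests (Fisher 2x2, two-tailed binomial sign test, Wilcoxon),
Benjamini-Hochberg adjustment, promoter motif-family enrichment with a
two-stage correction (within-family Bonferroni-or-median, then BH across
families), binding-vs-expression association and the binding-tier
cross-tab.

Two-sided p-values follow the minimum-likelihood convention: the sum of
outcome probabilities no larger than that of the observed outcome.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def fisher_exact_2x2(table, sided: str = "two") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table of counts.

    Returns (p, odds_ratio) with odds_ratio = ad/bc (may be inf or nan
    on zero margins).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or not np.isfinite(t).all() or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative finite counts")
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sided]
    res = stats.fisher_exact(t.astype(int), alternative=alternative)
    (a, b), (c, d) = t
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (a * d) / (b * c) if b * c > 0 else (np.inf if a * d > 0 else np.nan)
    return float(res.pvalue), float(odds)


def binomial_sign_test(n_above: int, n_below: int, p0: float = 0.5) -> float:
    """Two-tailed exact binomial test on above/below counts (ties dropped by the caller)."""
    n = n_above + n_below
    if n < 1:
        raise ValueError("need at least one untied observation")
    return float(stats.binomtest(n_above, n, p0, alternative="two-sided").pvalue)


def wilcoxon_group_compare(scores_a, scores_b, paired: bool = True) -> float:
    """Wilcoxon comparison of two score vectors.

    Paired mode is the signed-rank test on per-gene differences (zero
    differences dropped); unpaired mode is the rank-sum test. The exact
    null distribution is used for small samples without ties, the normal
    approximation with tie correction otherwise. Returns p = 1 when all
    paired differences are zero.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired mode needs equal-length vectors")
        d = a - b
        d = d[d != 0]
        if len(d) == 0:
            return 1.0
        n = len(d)
        exact = n <= 25 and len(np.unique(np.abs(d))) == n
        res = stats.wilcoxon(
            d, alternative="two-sided", method="exact" if exact else "approx"
        )
        return float(res.pvalue)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def genes_with_promoter_hit(
    hits: pd.DataFrame, ann: pd.DataFrame, half_window: int = 2000, by: str = "motif_id"
):
    """Map each hit-source (motif, or any grouping column) to the set of genes
    whose TSS +-half_window window overlaps at least one of its hits."""
    out: dict[str, set] = {}
    for contig, sub in ann.groupby("chrom"):
        order = np.argsort(sub["tss"].to_numpy())
        tss = sub["tss"].to_numpy()[order]
        gids = sub["gene_id"].to_numpy()[order]
        h = hits[hits["chrom"] == contig]
        lo = np.searchsorted(tss, h["start"].to_numpy() - half_window - 0, side="left")
        hi = np.searchsorted(tss, h["end"].to_numpy() - 1 + half_window, side="right")
        for key, i0, i1 in zip(h[by], lo, hi):
            if i1 > i0:
                out.setdefault(key, set()).update(gids[i0:i1])
    return out


def motif_family_enrichment(
    hits: pd.DataFrame,
    set_pos,
    set_neg,
    ann: pd.DataFrame,
    half_window: int = 2000,
) -> pd.DataFrame:
    """Motif-family enrichment between two promoter gene sets.

    Per motif: Fisher on [pos with a promoter hit, pos without; neg
    with, neg without]. Per family: corrected_p = min(best_p * n_motifs,
    median_p), capped at 1, then BH across families. ``direction``
    reports which set the best motif is enriched in.
    """
    pos, neg = set(set_pos), set(set_neg)
    if pos & neg:
        raise ValueError("positive and negative sets must be disjoint")
    motif_genes = genes_with_promoter_hit(hits, ann, half_window, by="motif_id")
    fam_of = hits.drop_duplicates("motif_id").set_index("motif_id")["family_id"]

    rows = []
    for motif in sorted(fam_of.index):
        g = motif_genes.get(motif, set())
        a, b = len(pos & g), len(pos - g)
        c, d = len(neg & g), len(neg - g)
        p, odds = fisher_exact_2x2(((a, b), (c, d)))
        rows.append((fam_of[motif], motif, p, odds))
    per_motif = pd.DataFrame(rows, columns=["family_id", "motif_id", "p", "odds_ratio"])

    fams = []
    for family, sub in per_motif.groupby("family_id"):
        if len(sub) == 0:
            warnings.warn(f"family {family} has no motifs; skipped")
            continue
        best = sub["p"].min()
        med = float(np.median(sub["p"]))
        corrected = min(best * len(sub), med, 1.0)
        best_row = sub.loc[sub["p"].idxmin()]
        direction = "positive_set" if best_row["odds_ratio"] > 1 else "negative_set"
        fams.append((family, len(sub), best, med, corrected, direction))
    out = pd.DataFrame(
        fams, columns=["family_id", "n_motifs", "best_p", "median_p", "corrected_p", "direction"]
    )
    out["fdr"] = bh_adjust(out["corrected_p"].to_numpy()) if len(out) else []
    return out.sort_values(["fdr", "corrected_p", "family_id"]).reset_index(drop=True)


def binding_vs_deg_association(bound, deg_up, deg_down) -> dict:
    """Fisher association between promoter binding and DEG direction.

    2x2 = [[up & bound, up & unbound], [down & bound, down & unbound]].
    Also reports the bound proportion of each DEG set.
    """
    bound, up, down = set(bound), set(deg_up), set(deg_down)
    if not up or not down:
        raise ValueError("both DEG sets must be non-empty")
    a, b = len(up & bound), len(up - bound)
    c, d = len(down & bound), len(down - bound)
    p, odds = fisher_exact_2x2(((a, b), (c, d)))
    return {
        "table": ((a, b), (c, d)),
        "p": p,
        "odds_ratio": odds,
        "prop_up_bound": a / len(up),
        "prop_down_bound": c / len(down),
    }


BASAL_CATEGORIES = ("S>A", "S<A", "S=A", "UN")
KD_CATEGORIES = ("down", "up", "none")
TIER_CATEGORIES = ("low", "moderate", "high")


def category_crosstab(
    basal_direction: pd.Series,
    kd_response: pd.Series,
    tier: pd.Series,
    compare=({"basal": "S>A"}, {"basal": "S<A"}),
) -> dict:
    """Binding-tier composition of expression categories.

    Columns are (basal category x knockdown category) combinations, rows
    are binding tiers; ``props`` holds within-column proportions. The
    headline Fisher test collapses tiers to {low} vs {moderate, high}
    and contrasts the two ``compare`` selectors (each a dict over
    "basal"/"kd" keys; omitted keys are marginalised over).
    """
    df = pd.DataFrame({"basal": basal_direction, "kd": kd_response, "tier": tier})
    for col, vocab in (("basal", BASAL_CATEGORIES), ("kd", KD_CATEGORIES), ("tier", TIER_CATEGORIES)):
        bad = set(df[col].unique()) - set(vocab)
        if bad:
            raise ValueError(f"unknown {col} categories: {sorted(bad)}")
    counts = (
        df.groupby(["tier", "basal", "kd"], observed=False)
        .size()
        .unstack(["basal", "kd"], fill_value=0)
        .reindex(TIER_CATEGORIES, fill_value=0)
    )
    col_tot = counts.sum(axis=0)
    props = counts.div(col_tot.where(col_tot > 0), axis=1)

    def _select(sel: dict):
        mask = np.ones(len(df), bool)
        for key, value in sel.items():
            mask &= (df[key] == value).to_numpy()
        sub = df[mask]
        hi = int(sub["tier"].isin(["moderate", "high"]).sum())
        return hi, len(sub) - hi

    a, b = _select(compare[0])
    c, d = _select(compare[1])
    p, odds = fisher_exact_2x2(((a, b), (c, d))) if (a + b) and (c + d) else (1.0, np.nan)
    return {
        "counts": counts,
        "props": props,
        "fisher": {
            "table": ((a, b), (c, d)),
            "p": p,
            "odds_ratio": odds,
            "compare": compare,
        },
    }
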