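"""Expression-side analyses.

CPM filtering of low-count genes, basal two-group and paired-knockdown
differential expression on log2-CPM, Venn summaries of DEG sets,
quadrant triangulation of the basal contrast against the knockdown
response, and gene-list intersection.

The differential test is a location test on log2(CPM + 0.5). With three
samples per group a per-gene variance estimate carries ~4 degrees of
freedom and is far too noisy to rank genes reliably, so the default
variance model borrows strength across genes: each gene's variance
follows the negative-binomial mean-variance relation
Var(log2 x) ~ (1/mu + phi) / ln(2)^2 with a single moment-estimated
dispersion phi common to all genes, and a normal (z) reference
distribution. Per-gene Welch / paired-t behaviour is available with
``var_model="per_gene"``. The fold-change gate and the p/FDR gate are
applied jointly, mirroring the study's cutoffs (FC 1.3, alpha 0.05; BH
FDR for the paired knockdown arm).
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from tftri.containers import CountMatrix
from tftri.enrich import bh_adjust, fisher_exact_2x2

PSEUDOCOUNT = 0.5


def cpm_filter(cm: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3) -> CountMatrix:
    """Keep genes with CPM strictly above ``min_cpm`` in at least ``min_samples`` samples."""
    cpm = cm.cpm()
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    return cm.subset_genes(cm.gene_ids[keep])


def _log2cpm(cm: CountMatrix, pseudocount: float) -> pd.DataFrame:
    return np.log2(cm.cpm() + pseudocount)


def _z_pvalue(effect: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Two-sided normal p for effect/se; degenerate (zero or non-finite)
    standard errors carry no evidence and give p = 1."""
    se = np.broadcast_to(np.asarray(se, float), np.shape(effect))
    ok = np.isfinite(se) & (se > 0)
    z = np.zeros_like(np.asarray(effect, float))
    z[ok] = np.abs(np.asarray(effect)[ok]) / se[ok]
    p = 2.0 * stats.norm.sf(z)
    p[~ok] = 1.0
    return p


_LN2_SQ = np.log(2.0) ** 2


def _common_dispersion(log2x: np.ndarray, mean_counts: np.ndarray) -> float:
    """Moment estimate of the NB dispersion shared across genes.

    Uses Var(log2 x) ~ (1/mu + phi) / ln(2)^2 per gene and averages the
    implied phi over genes (clipped at zero).
    """
    s2 = log2x.var(axis=1, ddof=1) * _LN2_SQ
    phi = s2 - 1.0 / np.maximum(mean_counts, 0.5)
    return float(max(0.0, np.mean(phi[np.isfinite(phi)])))


def de_test(
    cm: CountMatrix,
    design: str,
    group_a: str | None = None,
    group_b: str | None = None,
    treated: str = "knockdown",
    control: str = "control",
    fc_cutoff: float = 1.3,
    alpha: float = 0.05,
    criterion: str = "p",
    var_model: str = "common_dispersion",
    center_log2fc: bool = True,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene differential expression table.

    Parameters
    ----------
    design
        ``"two_group"`` (log2FC is A over B) or ``"paired"`` (treated
        over control within each pair).
    criterion
        Which value is gated against ``alpha``: raw ``"p"`` or BH ``"fdr"``.
    var_model
        ``"common_dispersion"`` (default) gives each gene a variance
        from the NB mean-variance relation with one dispersion shared
        across genes and a normal reference; ``"per_gene"`` uses Welch /
        per-gene paired t.
    center_log2fc
        Subtract the across-gene median log2FC before testing (default).
        This removes library composition bias: when differential mass is
        asymmetric between conditions, per-library CPM scaling shifts
        every unchanged gene, which robust normalisation (e.g. TMM in
        the edgeR route) otherwise absorbs.

    Returns a DataFrame with columns gene_id, log2fc, p, fdr, passes,
    direction. Degenerate (constant) genes get p = 1.
    """
    if criterion not in ("p", "fdr"):
        raise ValueError("criterion must be 'p' or 'fdr'")
    if var_model not in ("common_dispersion", "per_gene"):
        raise ValueError("var_model must be 'common_dispersion' or 'per_gene'")
    lc = _log2cpm(cm, pseudocount)

    if design == "two_group":
        labels = sorted(cm.groups.loc[list(cm.counts.columns)].unique())
        if group_a is None or group_b is None:
            if len(labels) != 2:
                raise ValueError("two_group design needs exactly two groups")
            group_a, group_b = labels[0], labels[1]
        sa = [s for s in cm.counts.columns if cm.groups[s] == group_a]
        sb = [s for s in cm.counts.columns if cm.groups[s] == group_b]
        if len(sa) < 2 or len(sb) < 2:
            raise ValueError("need >= 2 samples per group")
        xa, xb = lc[sa].to_numpy(), lc[sb].to_numpy()
        log2fc = xa.mean(axis=1) - xb.mean(axis=1)
        shift = float(np.median(log2fc)) if center_log2fc and len(log2fc) else 0.0
        log2fc = log2fc - shift
        if var_model == "per_gene":
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p = stats.ttest_ind(xa - shift, xb, axis=1, equal_var=False)
        else:
            ma = cm.counts[sa].to_numpy(float).mean(axis=1)
            mb = cm.counts[sb].to_numpy(float).mean(axis=1)
            phi = 0.5 * (_common_dispersion(xa, ma) + _common_dispersion(xb, mb))
            na, nb = len(sa), len(sb)
            var = (
                (1.0 / np.maximum(ma, 0.5) + phi) / na
                + (1.0 / np.maximum(mb, 0.5) + phi) / nb
            ) / _LN2_SQ
            p = _z_pvalue(log2fc, np.sqrt(var))
    elif design == "paired":
        if cm.pairs is None:
            raise ValueError("paired design needs pair labels")
        diffs, t_samples, c_samples = [], [], []
        for pair in sorted(cm.pairs.loc[list(cm.counts.columns)].unique()):
            members = [s for s in cm.counts.columns if cm.pairs[s] == pair]
            t = [s for s in members if cm.groups[s] == treated]
            c = [s for s in members if cm.groups[s] == control]
            if len(t) != 1 or len(c) != 1:
                raise ValueError(f"pair {pair} is not one control + one treated sample")
            diffs.append(lc[t[0]] - lc[c[0]])
            t_samples.append(t[0])
            c_samples.append(c[0])
        d = np.column_stack(diffs)
        if d.shape[1] < 2:
            raise ValueError("need >= 2 pairs")
        log2fc = d.mean(axis=1)
        shift = float(np.median(log2fc)) if center_log2fc and len(log2fc) else 0.0
        log2fc = log2fc - shift
        if var_model == "per_gene":
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p = stats.ttest_1samp(d, shift, axis=1)
        else:
            npair = d.shape[1]
            mc = cm.counts[c_samples].to_numpy(float).mean(axis=1)
            mt = cm.counts[t_samples].to_numpy(float).mean(axis=1)
            base = 1.0 / np.maximum(mc, 0.5) + 1.0 / np.maximum(mt, 0.5)
            s2 = d.var(axis=1, ddof=1) * _LN2_SQ
            ok = np.isfinite(s2)
            phi = max(0.0, float(np.mean((s2[ok] - base[ok]) / 2.0)))
            var = (base + 2.0 * phi) / (_LN2_SQ * npair)
            p = _z_pvalue(log2fc, np.sqrt(var))
    else:
        raise ValueError(f"unknown design {design!r}")

    p = np.where(np.isfinite(p), p, 1.0)
    fdr = bh_adjust(p)
    chosen = p if criterion == "p" else fdr
    tau = np.log2(fc_cutoff)
    passes = (np.abs(log2fc) >= tau) & (chosen < alpha)
    direction = np.where(~passes, "none", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "passes": passes,
            "direction": direction,
        }
    ).reset_index(drop=True)


def _pct(numer: int, denom: int):
    """Percentage to one decimal, half-up, or None for an empty denominator."""
    if denom == 0:
        return None
    q = Decimal(numer) * 100 / Decimal(denom)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def venn_from_counts(n_total_a: int, n_total_b: int, n_common: int) -> dict:
    """Two-set Venn summary from set sizes and overlap size."""
    if n_common > min(n_total_a, n_total_b):
        raise ValueError("overlap larger than a set")
    ea, eb = n_total_a - n_common, n_total_b - n_common
    return {
        "n_total_A": n_total_a,
        "n_total_B": n_total_b,
        "n_common": n_common,
        "n_exclusive_A": ea,
        "n_exclusive_B": eb,
        "pct_exclusive_A": _pct(ea, n_total_a),
        "pct_exclusive_B": _pct(eb, n_total_b),
    }


def venn_summarize(set_a, set_b) -> dict:
    """Exact two-set Venn summary with exclusive percentages (1 decimal, half-up)."""
    sa, sb = set(set_a), set(set_b)
    return venn_from_counts(len(sa), len(sb), len(sa & sb))


QUADRANTS = ("up-up", "up-down", "down-up", "down-down")
_SECTOR = {"up-up": (1, 1), "up-down": (1, -1), "down-up": (-1, 1), "down-down": (-1, -1)}


def quadrant_classify(
    basal: pd.DataFrame,
    kd: pd.DataFrame,
    tau: float = np.log2(1.3),
    basal_criterion: str = "p",
    kd_criterion: str = "fdr",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Joint (basal log2FC, knockdown log2FC) quadrant assignment.

    A gene is assigned iff both fold changes reach ``tau`` in magnitude
    (inclusive) and both tests meet their significance criterion; all
    other genes, including genes missing from either table, are
    ``unassigned``.
    """
    m = basal.set_index("gene_id")[["log2fc", "p", "fdr"]].join(
        kd.set_index("gene_id")[["log2fc", "p", "fdr"]], how="outer", lsuffix="_basal", rsuffix="_kd"
    )
    bfc = m["log2fc_basal"].to_numpy()
    kfc = m["log2fc_kd"].to_numpy()
    bsig = (m[f"{basal_criterion}_basal"] < alpha).to_numpy() & np.isfinite(bfc)
    ksig = (m[f"{kd_criterion}_kd"] < alpha).to_numpy() & np.isfinite(kfc)
    assigned = bsig & ksig & (np.abs(bfc) >= tau) & (np.abs(kfc) >= tau)
    bdir = np.where(bfc >= 0, "up", "down")
    kdir = np.where(kfc >= 0, "up", "down")
    quad = np.where(assigned, np.char.add(np.char.add(bdir, "-"), kdir), "unassigned")
    return pd.DataFrame(
        {
            "gene_id": m.index,
            "basal_log2fc": bfc,
            "kd_log2fc": kfc,
            "basal_sig": bsig,
            "kd_sig": ksig,
            "quadrant": quad,
        }
    ).reset_index(drop=True)


def quadrant_enrichment(qt: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Fisher test per quadrant.

    The 2x2 contrasts quadrant membership among assigned genes against
    sign-sector membership among unassigned genes:
    [[assigned in quadrant, assigned elsewhere],
     [unassigned in the quadrant's sign sector, unassigned elsewhere]].
    """
    if (qt["quadrant"] != "unassigned").sum() < 1:
        raise ValueError("no assigned genes")
    assigned = qt["quadrant"] != "unassigned"
    bfc = qt["basal_log2fc"].to_numpy()
    kfc = qt["kd_log2fc"].to_numpy()
    rows = []
    for quad in QUADRANTS:
        sx, sy = _SECTOR[quad]
        in_sector = (
            np.isfinite(bfc) & np.isfinite(kfc)
            & ((bfc >= 0) == (sx > 0)) & ((kfc >= 0) == (sy > 0))
        )
        a = int((assigned & (qt["quadrant"] == quad)).sum())
        b = int(assigned.sum() - a)
        c = int((~assigned & in_sector).sum())
        d = int((~assigned).sum() - c)
        if min(a + b, c + d, a + c, b + d) == 0:
            p, orr = 1.0, np.nan
        else:
            p, orr = fisher_exact_2x2(((a, b), (c, d)))
        rows.append((quad, a, b, c, d, p, orr))
    return pd.DataFrame(
        rows, columns=["quadrant", "n_in", "n_out", "n_bg_in", "n_bg_out", "p", "odds_ratio"]
    )


def intersect_gene_list(genes, reference) -> list:
    """Order-preserving intersection of ``genes`` with ``reference``."""
    ref = set(reference)
    return [g for g in genes if g in ref]
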