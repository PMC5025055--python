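"""SES normalisation, TSS scoring, tiers, consensus peaks, peak annotation."""

import numpy as np
import pandas as pd
import pytest

from tftri.containers import SignalTrack
from tftri import chip


def _track(values, bin_size=50, sample="s", mark="E2F1", contig="chr1"):
    return SignalTrack({contig: np.asarray(values, float)}, bin_size, sample, mark)


def _ses_bruteforce(c, i):
    """Exhaustive scan over every candidate background cut-off k."""
    order = np.argsort(c, kind="stable")
    cs, isrt = c[order], i[order]
    best_gap, best_k = -1.0, 0
    for k in range(len(c)):
        gap = abs(cs[: k + 1].sum() / cs.sum() - isrt[: k + 1].sum() / isrt.sum())
        if gap > best_gap:
            best_gap, best_k = gap, k
    return isrt[: best_k + 1].sum() / cs[: best_k + 1].sum()


class TestSes:
    def test_identical_tracks_factor_one(self, rng):
        v = rng.poisson(10, 200).astype(float) + 1
        assert chip.ses_scale_factor(_track(v), _track(v)) == pytest.approx(1.0)

    def test_uniform_double_factor_half(self, rng):
        v = rng.poisson(10, 200).astype(float) + 1
        assert chip.ses_scale_factor(_track(2 * v), _track(v)) == pytest.approx(0.5)

    def test_matches_bruteforce_on_spiked_tracks(self, rng):
        for _ in range(50):
            c = rng.poisson(5, 100).astype(float)
            i = rng.poisson(5, 100).astype(float)
            c[rng.integers(100)] += rng.integers(50, 500)
            if c.sum() == 0 or i.sum() == 0:
                continue
            got = chip.ses_scale_factor(_track(c), _track(i))
            assert got == pytest.approx(_ses_bruteforce(c, i))

    def test_degenerate_track_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            chip.ses_scale_factor(_track(np.zeros(20)), _track(np.ones(20)))

    def test_mismatched_binning_raises(self):
        with pytest.raises(ValueError):
            chip.ses_scale_factor(_track(np.ones(20)), _track(np.ones(30)))


class TestNormalize:
    def test_identical_tracks_log2_zero(self):
        v = np.full(50, 7.0)
        out = chip.normalize_track(_track(v), _track(v), 1.0)
        assert np.allclose(out.data["chr1"], 0.0)

    def test_sixteen_fold_bin_is_four(self):
        c = np.full(20, 16.0)
        i = np.full(20, 1.0)
        out = chip.normalize_track(_track(c), _track(i), 1.0, pseudocount=1e-9)
        assert out.data["chr1"][0] == pytest.approx(4.0, abs=1e-6)

    def test_ratio_mode(self):
        c = np.full(20, 16.0)
        i = np.full(20, 1.0)
        out = chip.normalize_track(_track(c), _track(i), 1.0, mode="ratio", pseudocount=1e-9)
        assert out.data["chr1"][0] == pytest.approx(16.0, abs=1e-5)

    def test_nonpositive_factor_raises(self):
        with pytest.raises(ValueError):
            chip.normalize_track(_track(np.ones(5)), _track(np.ones(5)), 0.0)


class TestTssScore:
    ann = pd.DataFrame(
        [("g1", "chr1", 10_000, 12_000, "+", 10_000)],
        columns=["gene_id", "chrom", "start", "end", "strand", "tss"],
    )

    def test_flat_track_returns_constant(self):
        track = _track(np.full(400, 3.0))
        assert chip.tss_score(track, self.ann).iloc[0] == 3.0

    def test_spike_inside_window_found(self):
        v = np.full(400, 1.0)
        v[(10_000 + 1500) // 50] = 9.0
        assert chip.tss_score(_track(v), self.ann).iloc[0] == 9.0

    def test_spike_outside_window_ignored(self):
        v = np.full(400, 1.0)
        v[(10_000 + 2500) // 50] = 9.0
        assert chip.tss_score(_track(v), self.ann).iloc[0] == 1.0

    def test_boundary_bin_inclusive(self):
        v = np.full(400, 1.0)
        v[(10_000 + 2000) // 50] = 9.0  # bin containing tss + 2000
        assert chip.tss_score(_track(v), self.ann).iloc[0] == 9.0

    def test_unknown_contig_missing(self):
        ann = self.ann.assign(chrom="chrX")
        assert np.isnan(chip.tss_score(_track(np.ones(400)), ann).iloc[0])

    def test_invariant_to_out_of_window_edits(self, rng):
        v = rng.normal(1, 0.1, 400)
        s1 = chip.tss_score(_track(v.copy()), self.ann).iloc[0]
        v2 = v.copy()
        v2[300:] += 100  # beyond tss + 2 kb
        v2[:100] -= 50
        assert chip.tss_score(_track(v2), self.ann).iloc[0] == s1


class TestGroupScaling:
    def _scores(self, rng, factor=1.0):
        base = rng.lognormal(1, 0.5, 200)
        noise = lambda: rng.lognormal(0, 0.05, 200)  # noqa: E731
        return pd.DataFrame(
            {
                "a1": base * noise(),
                "a2": base * noise(),
                "b1": factor * base * noise(),
                "b2": factor * base * noise(),
            }
        )

    groups = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})

    def test_identical_groups_factor_one(self):
        s = pd.DataFrame({"a1": [1.0, 2], "a2": [1.0, 2], "b1": [1.0, 2], "b2": [1.0, 2]})
        _, f = chip.group_scale_scores(s, self.groups, "A", "B")
        assert f == pytest.approx(1.0)

    def test_double_target_factor_half(self, rng):
        s = self._scores(rng)
        s[["b1", "b2"]] = 2 * s[["a1", "a2"]].to_numpy()
        _, f = chip.group_scale_scores(s, self.groups, "A", "B")
        assert f == pytest.approx(0.5)

    def test_median_ratio_after_scaling_is_one(self, rng):
        s = self._scores(rng, factor=3.7)
        scaled, _ = chip.group_scale_scores(s, self.groups, "A", "B")
        ratio = scaled[["a1", "a2"]].mean(axis=1) / scaled[["b1", "b2"]].mean(axis=1)
        assert np.median(np.log(ratio)) == pytest.approx(0.0, abs=1e-9)

    def test_swap_groups_reciprocal_and_idempotent(self, rng):
        s = self._scores(rng, factor=2.5)
        scaled, f_ab = chip.group_scale_scores(s, self.groups, "A", "B")
        _, f_ba = chip.group_scale_scores(s, self.groups, "B", "A")
        # the two directions are exact reciprocals (median log-ratio is odd)
        assert f_ab * f_ba == pytest.approx(1.0, abs=1e-9)
        # once scaled, swapping the roles finds nothing left to correct
        back, f2 = chip.group_scale_scores(scaled, self.groups, "B", "A")
        assert f2 == pytest.approx(1.0, abs=1e-9)
        pd.testing.assert_frame_equal(back[["a1", "a2"]], s[["a1", "a2"]])

    def test_no_positive_genes_raises(self):
        s = pd.DataFrame({"a1": [-1.0], "a2": [-1.0], "b1": [1.0], "b2": [1.0]})
        with pytest.raises(ValueError):
            chip.group_scale_scores(s, self.groups, "A", "B")


class TestTiers:
    @pytest.mark.parametrize(
        "score,tier",
        [(1.99, "low"), (2.0, "moderate"), (4.0, "moderate"), (4.01, "high"),
         (0.0, "low"), (-3.0, "low"), (100.0, "high")],
    )
    def test_printed_partition(self, score, tier):
        assert chip.assign_tier(score) == tier

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            chip.assign_tier(float("nan"))


def _peak(chrom, start, end):
    return {"chrom": chrom, "start": start, "end": end}


class TestConsensusPeaks:
    intensity = SignalTrack({"chr1": np.arange(100.0)}, 50, "mean", "E2F1")

    def test_singleton_peak_dropped_and_pair_kept(self):
        sets = {
            "s1": pd.DataFrame([_peak("chr1", 100, 200), _peak("chr1", 1000, 1100)]),
            "s2": pd.DataFrame([_peak("chr1", 150, 250)]),
        }
        out = chip.consensus_peaks(sets, self.intensity, min_support=2, top_n=10)
        assert len(out) == 1
        assert out.iloc[0]["start"] == 100 and out.iloc[0]["end"] == 250

    def test_top_n_by_intensity(self):
        sets = {
            "s1": pd.DataFrame(
                [_peak("chr1", 0, 100), _peak("chr1", 2000, 2100), _peak("chr1", 4000, 4100)]
            ),
            "s2": pd.DataFrame(
                [_peak("chr1", 50, 150), _peak("chr1", 2050, 2150), _peak("chr1", 4050, 4150)]
            ),
        }
        out = chip.consensus_peaks(sets, self.intensity, min_support=2, top_n=2)
        # intensity track rises with coordinate, so the two right-most survive
        assert list(out["start"]) == [4000, 2000]

    def test_sample_order_invariance(self, rng):
        peaks = [
            pd.DataFrame([_peak("chr1", int(s), int(s) + 120) for s in rng.integers(0, 4000, 8)])
            for _ in range(4)
        ]
        sets1 = {f"s{i}": p for i, p in enumerate(peaks)}
        sets2 = {f"s{i}": peaks[len(peaks) - 1 - i] for i in range(len(peaks))}
        o1 = chip.consensus_peaks(sets1, self.intensity)
        o2 = chip.consensus_peaks(sets2, self.intensity)
        pd.testing.assert_frame_equal(o1, o2)

    def test_support_counts_distinct_samples(self):
        # two records from the same sample do not make a consensus
        sets = {
            "s1": pd.DataFrame([_peak("chr1", 100, 200), _peak("chr1", 150, 260)]),
            "s2": pd.DataFrame([_peak("chr1", 5000, 5100)]),
        }
        out = chip.consensus_peaks(sets, self.intensity, min_support=2, top_n=10)
        assert len(out) == 0


class TestAnnotatePeaks:
    def test_categories(self, tiny_annotation):
        peaks = pd.DataFrame(
            [
                _peak("chr1", 10_050, 10_250),   # summit 10150: promoter of gA
                _peak("chr1", 30_000, 30_200),   # intergenic
                _peak("chr2", 10_900, 11_100),   # summit 11000 inside gC body, 1000 from TSS
                _peak("chr2", 95_000, 95_200),   # intergenic
            ]
        )
        out = chip.annotate_peaks(peaks, tiny_annotation)
        assert list(out["category"]) == ["promoter", "intergenic", "promoter", "intergenic"]

    def test_gene_body_beyond_promoter_window(self):
        ann = pd.DataFrame(
            [("g", "chr1", 10_000, 40_000, "+", 10_000)],
            columns=["gene_id", "chrom", "start", "end", "strand", "tss"],
        )
        peaks = pd.DataFrame([_peak("chr1", 19_900, 20_100)])  # 10 kb into the gene
        out = chip.annotate_peaks(peaks, ann)
        assert out["category"].iloc[0] == "gene_body"
        assert out["tss_distance"].iloc[0] == 10_000

    def test_upstream_distance_negative_in_transcription_direction(self, tiny_annotation):
        # gB is minus-strand with TSS at 51_999; a summit at 52_499 is upstream
        peaks = pd.DataFrame([_peak("chr1", 52_399, 52_599)])
        out = chip.annotate_peaks(peaks, tiny_annotation)
        assert out["tss_distance"].iloc[0] == -500
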