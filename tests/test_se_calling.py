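"""Super-enhancer calling: stitching, ranking, the inflection cutoff, the
top-N override, consensus building and differential activity."""

import numpy as np
import pandas as pd
import pytest

import episenet as ep
from episenet.intervals import Gene, GenomeAnnotation, GenomicInterval
from episenet.se_calling import SECallingParams, StitchedEnhancer


@pytest.fixture
def genome():
    genes = [
        Gene("gA", "chr1", 50_000, "+", GenomicInterval("chr1", 50_000, 55_000)),
        Gene("gB", "chr1", 200_000, "-", GenomicInterval("chr1", 195_000, 200_001)),
    ]
    return GenomeAnnotation({"chr1": 1_000_000}, genes)


def brute_force_stitch(peaks, genome, params):
    """Oracle: explicit promoter filter then pairwise transitive merge."""
    windows = [
        (g.chrom, t - params.tss_exclusion, t + params.tss_exclusion)
        for g in genome.genes
        for t in g.all_tss
    ]
    kept = [
        p
        for p in peaks
        if not any(
            c == p.chrom and lo <= p.start and p.end <= hi for c, lo, hi in windows
        )
    ]
    items = [(p.chrom, p.start, p.end) for p in kept]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                ci, si, ei = items[i]
                cj, sj, ej = items[j]
                if ci == cj and max(si, sj) - min(ei, ej) <= params.stitch_distance:
                    items[i] = (ci, min(si, sj), max(ei, ej))
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(GenomicInterval(*t) for t in items)


class TestStitchEnhancers:
    def test_peaks_within_stitch_distance_merge(self, genome):
        peaks = [
            GenomicInterval("chr1", 300_000, 301_000),
            GenomicInterval("chr1", 313_400, 314_000),  # 12 400 bp gap
        ]
        out = ep.stitch_enhancers(peaks, genome)
        assert len(out) == 1
        assert out[0].constituent_peak_count == 2

    def test_promoter_contained_peak_excluded(self, genome):
        peaks = [
            GenomicInterval("chr1", 49_000, 51_000),  # inside gA TSS +/- 2500
            GenomicInterval("chr1", 300_000, 301_000),
        ]
        out = ep.stitch_enhancers(peaks, genome)
        assert [se.interval.start for se in out] == [300_000]

    def test_peak_straddling_promoter_window_kept(self, genome):
        # not fully contained -> kept
        peaks = [GenomicInterval("chr1", 46_000, 51_000)]
        assert len(ep.stitch_enhancers(peaks, genome)) == 1

    def test_empty_peak_set(self, genome):
        assert ep.stitch_enhancers([], genome) == []

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_filter_plus_merge_oracle(self, genome, seed):
        rng = np.random.default_rng(seed)
        params = SECallingParams()
        peaks = []
        for _ in range(int(rng.integers(1, 50))):
            s = int(rng.integers(0, 900_000))
            peaks.append(GenomicInterval("chr1", s, s + int(rng.integers(200, 3000))))
        expected = brute_force_stitch(peaks, genome, params)
        got = [se.interval for se in ep.stitch_enhancers(peaks, genome, params)]
        assert got == expected


class TestRankEnhancers:
    def make_stitched(self, signals):
        stitched, rows = [], []
        for i, (ip, inp) in enumerate(signals):
            start = i * 50_000
            stitched.append(
                StitchedEnhancer(GenomicInterval("chr1", start, start + 1000), 1)
            )
            rows.append(("chr1", start, start + 1000, ip, inp))
        signal = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "ip", "input"]
        )
        return stitched, signal

    def test_rank_order_example(self):
        stitched, signal = self.make_stitched([(5, 0), (9, 0), (1, 0)])
        ranked = ep.rank_enhancers(stitched, signal)
        by_pos = {se.interval.start // 50_000: se.rank for se in ranked}
        assert by_pos == {0: 2, 1: 1, 2: 3}

    def test_corrected_signal_floored_and_ties_by_position(self):
        stitched, signal = self.make_stitched([(1, 10), (2, 30), (0, 5)])
        ranked = ep.rank_enhancers(stitched, signal)
        assert all(se.corrected_signal == 0 for se in ranked)
        assert [se.interval.start for se in ranked] == [0, 50_000, 100_000]

    def test_input_order_invariance(self):
        stitched, signal = self.make_stitched([(7, 1), (3, 1), (9, 2), (5, 5)])
        a = ep.rank_enhancers(stitched, signal)
        b = ep.rank_enhancers(stitched[::-1], signal)
        assert [(s.interval.start, s.rank) for s in a] == [
            (s.interval.start, s.rank) for s in b
        ]

    def test_missing_signal_names_region(self):
        stitched, signal = self.make_stitched([(5, 0)])
        orphan = [StitchedEnhancer(GenomicInterval("chr2", 0, 1000), 1)]
        with pytest.raises(ValueError, match="chr2"):
            ep.rank_enhancers(orphan, signal)


def tangent_oracle(signals):
    """Exhaustive diagonal-tangent search: the cutoff point maximises the
    depth below the unit-slope diagonal of the scaled ranked curve."""
    y = np.sort(np.asarray(signals, float))
    x = np.linspace(0, 1, len(y))
    ys = (y - y[0]) / (y[-1] - y[0])
    i = int(np.argmin(ys - x))
    return len(y) - i


class TestRoseCutoff:
    def test_flat_curve_has_no_inflection(self):
        assert ep.rose_cutoff(np.full(100, 7.0)) == 0

    def test_linear_curve_has_no_inflection(self):
        assert ep.rose_cutoff(np.linspace(0, 10, 200)) == 0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            ep.rose_cutoff(np.array([1.0, 2.0]))

    @pytest.mark.parametrize("n,seed", [(50, 0), (500, 1), (5000, 2), (300, 3)])
    def test_hockey_stick_matches_tangent_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        base = np.linspace(0, 1, n - 50)
        tail = np.exp(np.linspace(0, 6, 50))
        signals = rng.permutation(np.concatenate([base, 1 + tail]))
        got = ep.rose_cutoff(signals)
        expected = tangent_oracle(signals)
        assert abs(got - expected) <= 2


class TestCallSuperenhancers:
    def make_ranked(self, signals):
        stitched = []
        for i, s in enumerate(np.sort(signals)[::-1]):
            se = StitchedEnhancer(
                GenomicInterval("chr1", i * 1000 + 1, i * 1000 + 999),
                1,
                ip_signal=float(s),
                input_signal=0.0,
            )
            se.rank = i + 1
            stitched.append(se)
        return stitched

    def test_top_n_contract(self):
        rng = np.random.default_rng(0)
        ranked = self.make_ranked(rng.gamma(2, 10, 1500))
        called, _ = ep.call_superenhancers(ranked)
        assert sum(se.is_SE for se in called) == 1000

    def test_fewer_than_top_n_all_called(self):
        ranked = self.make_ranked(np.arange(1, 801))
        called, _ = ep.call_superenhancers(ranked)
        assert sum(se.is_SE for se in called) == 800

    def test_amplification_shrinks_inflection_count_not_top_n(self):
        rng = np.random.default_rng(1)
        base = np.concatenate(
            [rng.gamma(2, 10, 1450), 200 + np.exp(np.linspace(0, 5, 50))]
        )
        amplified = base.copy()
        amplified[-1] *= 100
        called_a, cut_a = ep.call_superenhancers(self.make_ranked(base))
        called_b, cut_b = ep.call_superenhancers(self.make_ranked(amplified))
        assert sum(se.is_SE for se in called_a) == 1000
        assert sum(se.is_SE for se in called_b) == 1000
        assert cut_b < cut_a


def toy_se(chrom, start, end, signal=100.0, is_se=True):
    se = StitchedEnhancer(
        GenomicInterval(chrom, start, end), 1, ip_signal=signal, input_signal=0.0
    )
    se.is_SE = is_se
    return se


class TestBuildConsensus:
    def make_sets(self):
        # five regions with occupancies {3, 2, 2, 1, 1} across three samples
        r = [(0, 1000), (5000, 6000), (10_000, 11_000), (15_000, 16_000),
             (20_000, 21_000)]
        return {
            "s1": [toy_se("chr1", *r[0]), toy_se("chr1", *r[1]),
                   toy_se("chr1", *r[3])],
            "s2": [toy_se("chr1", *r[0]), toy_se("chr1", *r[1]),
                   toy_se("chr1", *r[2])],
            "s3": [toy_se("chr1", *r[0]), toy_se("chr1", *r[2]),
                   toy_se("chr1", *r[4])],
        }

    def test_min_samples_two_keeps_three_regions(self):
        rep = ep.build_consensus(self.make_sets(), SECallingParams(min_samples=2))
        assert len(rep.consensus_regions) == 3
        assert (rep.occupancy.sum(axis=1) >= 2).all()

    def test_min_samples_one_keeps_all_five(self):
        rep = ep.build_consensus(self.make_sets(), SECallingParams(min_samples=1))
        assert len(rep.consensus_regions) == 5

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ep.build_consensus({"s1": [toy_se("chr1", 0, 1000)]})

    def test_activity_is_log2_signal_per_kb(self):
        rep = ep.build_consensus(self.make_sets(), SECallingParams(min_samples=1))
        # signal 100 over a 1 kb region -> log2(1 + 100)
        assert rep.activity.loc["chr1:0-1000", "s1"] == pytest.approx(
            np.log2(101)
        )


class TestDifferentialSE:
    def make_repertoire(self, rng, n_regions=40, effect_regions=(), effect=1.5):
        samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        act = rng.normal(5, 0.5, size=(n_regions, 8))
        for r in effect_regions:
            act[r, :4] += effect
        activity = pd.DataFrame(
            act,
            index=[f"chr1:{i * 1000}-{i * 1000 + 500}" for i in range(n_regions)],
            columns=samples,
        )
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=samples)
        rep = ep.SERepertoire(
            consensus_regions=[], occupancy=activity > 0, activity=activity
        )
        return rep, groups

    def test_identical_groups_zero_log2fc(self, rng):
        rep, groups = self.make_repertoire(rng)
        rep.activity.iloc[0, 4:] = rep.activity.iloc[0, :4].to_numpy()
        out = ep.differential_se(rep, groups, "A", "B")
        assert out.loc[0, "log2FC"] == pytest.approx(0.0)

    def test_antisymmetric_under_group_swap(self, rng):
        rep, groups = self.make_repertoire(rng, effect_regions=(1, 2))
        ab = ep.differential_se(rep, groups, "A", "B")
        ba = ep.differential_se(rep, groups, "B", "A")
        np.testing.assert_allclose(ab["log2FC"], -ba["log2FC"])
        np.testing.assert_allclose(ab["p"], ba["p"])

    def test_small_group_rejected(self, rng):
        rep, groups = self.make_repertoire(rng)
        groups.iloc[:1] = "C"
        with pytest.raises(ValueError):
            ep.differential_se(rep, groups, "C", "B")

    def test_planted_effects_detected(self, rng):
        rep, groups = self.make_repertoire(rng, effect_regions=(0, 5, 9),
                                           effect=3.0)
        out = ep.differential_se(rep, groups, "A", "B")
        assert out.loc[[0, 5, 9], "significant"].all()
        assert (out.loc[[0, 5, 9], "direction"] == "gained in A").all()


class TestRepertoirePCAProperty:
    def test_consensus_activity_separates_planted_groups(self, small_cohort):
        from sklearn.decomposition import PCA
        from sklearn.metrics import silhouette_score

        from conftest import call_sample_ses

        rep = ep.build_consensus(call_sample_ses(small_cohort))
        coords = PCA(n_components=2).fit_transform(rep.activity.T.to_numpy())
        score = silhouette_score(coords, small_cohort.sample_groups.to_numpy())
        assert score > 0
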