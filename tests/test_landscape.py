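"""Chromatin-state landscape: signed transform, entropy selection, MCA,
MDS+MNN, loadings, score differences and segment eQTL."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import episenet as ep
from episenet.intervals import Gene, GenomeAnnotation, GenomicInterval
from episenet.landscape import STATE_SCORES, StateMatrix, state_numeric_transform


def random_state_matrix(rng, n_regions, n_samples):
    states = np.array(["E1", "E2", "E3", "E4", "E5", "E6"])
    cat = pd.DataFrame(
        rng.choice(states, size=(n_regions, n_samples)),
        index=[f"r{i}" for i in range(n_regions)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    regions = [GenomicInterval("chr1", i * 100, i * 100 + 100)
               for i in range(n_regions)]
    return StateMatrix(regions=regions, categorical=cat)


class TestNumericTransform:
    @pytest.mark.parametrize(
        "state,score",
        [("E2", 3), ("E3", 2), ("E1", 1), ("E5", -1), ("E6", -2), ("E4", -3)],
    )
    def test_fixed_mapping(self, state, score):
        assert state_numeric_transform(state) == score

    def test_bijection_onto_signed_scores(self):
        values = [state_numeric_transform(s) for s in STATE_SCORES]
        assert sorted(values) == [-3, -2, -1, 1, 2, 3]

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            state_numeric_transform("E7")


class TestEntropyAndSelection:
    def test_constant_region_zero_entropy(self, rng):
        m = random_state_matrix(rng, 5, 24)
        m.categorical.iloc[0] = "E4"
        assert m.region_entropy.iloc[0] == 0.0

    def test_uniform_region_max_entropy(self, rng):
        m = random_state_matrix(rng, 1, 24)
        m.categorical.iloc[0] = np.repeat(
            ["E1", "E2", "E3", "E4", "E5", "E6"], 4
        )
        assert m.region_entropy.iloc[0] == pytest.approx(np.log2(6))

    def test_entropy_bounds_and_zero_iff_constant(self, rng):
        m = random_state_matrix(rng, 200, 10)
        ent = m.region_entropy
        assert ((ent >= 0) & (ent <= np.log2(6) + 1e-12)).all()
        constant = m.categorical.nunique(axis=1) == 1
        assert ((ent == 0) == constant).all()

    def test_all_e1_regions_never_selected(self, rng):
        m = random_state_matrix(rng, 50, 8)
        m.categorical.iloc[:5] = "E1"
        sel = ep.select_features(m, ep.LandscapeParams(0.5, 0.5))
        assert not set(m.categorical.index[:5]) & set(sel.categorical.index)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_state_matrix(rng, 2000, 24)
        params = ep.LandscapeParams(0.05, 0.02)
        sel = ep.select_features(m, params)
        # oracle: independent sequential sort with inclusive boundaries
        keep = ~(m.categorical == "E1").all(axis=1)
        ent = m.region_entropy[keep]
        n_e = int(np.ceil(0.05 * keep.sum()))
        cut_e = ent.sort_values(ascending=False).iloc[n_e - 1]
        stage1 = ent.index[ent >= cut_e]
        var = m.region_variance[stage1]
        n_v = int(np.ceil(0.02 * keep.sum()))
        cut_v = var.sort_values(ascending=False).iloc[min(n_v, len(var)) - 1]
        expected = set(var.index[var >= cut_v])
        assert set(sel.categorical.index) == expected

    def test_invariant_to_sample_and_region_order(self, rng):
        m = random_state_matrix(rng, 300, 12)
        params = ep.LandscapeParams(0.1, 0.05)
        sel = ep.select_features(m, params)
        perm = rng.permutation(300)
        m2 = StateMatrix(
            regions=[m.regions[i] for i in perm],
            categorical=m.categorical.iloc[perm, ::-1],
        )
        sel2 = ep.select_features(m2, params)
        assert set(sel.categorical.index) == set(sel2.categorical.index)


def ca_oracle_coords(cat):
    """Independent CA route: eigendecomposition of the weighted cross-product
    (not the SVD used by the implementation)."""
    obs = cat.T
    Z = pd.get_dummies(obs, prefix_sep="=").astype(float).to_numpy()
    P = Z / Z.sum()
    r, c = P.sum(1), P.sum(0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    M = S @ S.T
    w, V = np.linalg.eigh(M)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    keep = w > 1e-12
    coords = V[:, keep] * np.sqrt(w[keep]) / np.sqrt(r)[:, None]
    return coords, w[keep]


class TestMCA:
    def test_two_block_matrix_separates_on_dim1(self):
        cat = pd.DataFrame(
            [["E2"] * 5 + ["E4"] * 5] * 10,
            index=[f"r{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(10)],
        )
        coords, _, _ = ep.mca(cat, n_components=2)
        d1 = coords["Dim1"]
        gap = abs(d1[:5].mean() - d1[5:].mean())
        assert d1[:5].std() < 1e-6 * gap
        assert d1[5:].std() < 1e-6 * gap

    def test_total_inertia_formula(self, rng):
        cat = random_state_matrix(rng, 30, 12).categorical
        model = ep.MCA(n_components=5).fit(cat)
        J = int(cat.nunique(axis=1).sum())  # total levels over all regions
        Q = cat.shape[0]
        assert model.all_eigenvalues_.sum() == pytest.approx(J / Q - 1)
        assert model.total_inertia_ == pytest.approx(J / Q - 1)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_independent_ca_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cat = random_state_matrix(rng, 50, 8).categorical
        model = ep.MCA(n_components=4).fit(cat)
        oracle_coords, oracle_eigs = ca_oracle_coords(cat)
        np.testing.assert_allclose(
            model.eigenvalues_, oracle_eigs[:4], rtol=1e-8
        )
        # coordinates match up to sign within non-degenerate dimensions
        eigs = oracle_eigs[:4]
        for d in range(4):
            degenerate = np.any(
                np.isclose(eigs[d], np.delete(eigs[:4], d), rtol=1e-6)
            )
            if degenerate:
                continue
            got = model.sample_coordinates_.iloc[:, d].to_numpy()
            exp = oracle_coords[:, d]
            assert np.allclose(got, exp, atol=1e-8) or np.allclose(
                got, -exp, atol=1e-8
            )

    def test_weighted_mean_zero_and_eigenvalues_sorted(self, rng):
        cat = random_state_matrix(rng, 40, 10).categorical
        model = ep.MCA(n_components=5).fit(cat)
        w = model.row_weights_
        for d in model.sample_coordinates_:
            assert np.average(
                model.sample_coordinates_[d], weights=w
            ) == pytest.approx(0, abs=1e-10)
        assert (np.diff(model.eigenvalues_) <= 1e-12).all()

    def test_constant_matrix_rejected(self):
        cat = pd.DataFrame([["E2"] * 6] * 4)
        with pytest.raises(ValueError):
            ep.MCA().fit(cat)

    def test_loading_orientation_tracks_numeric_scores(self):
        # samples 1-5 active (E2), samples 6-10 repressed (E4): the signed
        # loading of each region must share one orientation with Dim1
        cat = pd.DataFrame(
            [["E2"] * 5 + ["E4"] * 5] * 8,
            index=[f"r{i}" for i in range(8)],
            columns=[f"s{j}" for j in range(10)],
        )
        model = ep.MCA(n_components=2).fit(cat)
        assert (model.loading_p_["Dim1"] < 0.05).all()
        signs = np.sign(model.loading_["Dim1"])
        assert len(set(signs)) == 1


class TestMDSMNN:
    def test_identical_batches_negligible_correction(self, rng):
        X = pd.DataFrame(
            rng.normal(size=(30, 8)),
            columns=[f"t{i}" for i in range(4)] + [f"c{i}" for i in range(4)],
        )
        X.iloc[:, 4:] = X.iloc[:, :4].to_numpy()  # duplicated, relabelled
        batch = pd.Series(["tumour"] * 4 + ["cell_line"] * 4, index=X.columns)
        pre = ep.classical_mds(X, 2)
        post = ep.mnn_correct(pre, batch)
        disp = np.abs(post.to_numpy() - pre.to_numpy()).max()
        assert disp < 1e-8

    def test_offset_batch_silhouette_decreases_group_preserved(self, rng):
        from sklearn.metrics import silhouette_score

        groups = ["A"] * 6 + ["B"] * 6
        base = np.vstack(
            [rng.normal(0, 1, (6, 20)), rng.normal(4, 1, (6, 20))]
        )
        tum = base + rng.normal(0, 0.2, base.shape)
        cell = base + 8.0 + rng.normal(0, 0.2, base.shape)  # constant offset
        X = pd.DataFrame(
            np.vstack([tum, cell]).T,
            columns=[f"t{i}" for i in range(12)] + [f"c{i}" for i in range(12)],
        )
        batch = pd.Series(["tumour"] * 12 + ["cell_line"] * 12, index=X.columns)
        glab = np.array(groups + groups)
        pre = ep.classical_mds(X, 2)
        post = ep.mnn_correct(pre, batch)
        assert silhouette_score(post, batch) < silhouette_score(pre, batch)
        assert silhouette_score(post, glab) >= 0.9 * silhouette_score(pre, glab)

    def test_small_batch_reduces_k_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 5)),
                         columns=list("abcde"))
        batch = pd.Series(["t", "t", "t", "c", "c"], index=X.columns)
        pre = ep.classical_mds(X, 2)
        with pytest.warns(UserWarning, match="reducing"):
            ep.mnn_correct(pre, batch, k=4)


class TestRankGenesByLoading:
    def test_p_filter_and_max_magnitude_rule(self):
        loadings = pd.Series({"r1": 0.9, "r2": -0.2, "r3": 0.5})
        pvals = pd.Series({"r1": 0.01, "r2": 0.01, "r3": 0.2})
        gene_map = {"r1": ["gA"], "r2": ["gA"], "r3": ["gB"]}
        ranked = ep.rank_genes_by_loading(loadings, pvals, gene_map)
        assert ranked.to_dict() == {"gA": 0.9}   # r3 filtered, max-|.| wins

    def test_empty_after_filter_warns(self):
        loadings = pd.Series({"r1": 0.9})
        pvals = pd.Series({"r1": 0.5})
        with pytest.warns(UserWarning):
            out = ep.rank_genes_by_loading(loadings, pvals, {"r1": ["g"]})
        assert out.empty


class TestStateScoreDifference:
    def test_extreme_case_is_plus_six(self):
        num = pd.DataFrame(
            [[3, 3, -3, -3]], columns=["b1", "b2", "n1", "n2"]
        )
        groups = pd.Series(
            {"b1": "Basal", "b2": "Basal", "n1": "Luminal", "n2": "Luminal"}
        )
        delta = ep.state_score_difference(num, groups, group_a="Basal")
        assert delta.iloc[0] == pytest.approx(6.0)

    def test_identical_groups_zero_and_antisymmetry(self, rng):
        num = pd.DataFrame(rng.integers(-3, 4, size=(5, 6)).astype(float),
                           columns=list("abcdef"))
        groups = pd.Series(dict(zip("abcdef", ["X"] * 3 + ["Y"] * 3)))
        num.iloc[:, 3:] = num.iloc[:, :3].to_numpy()
        assert np.allclose(ep.state_score_difference(num, groups, "X"), 0)
        num2 = pd.DataFrame(rng.normal(size=(5, 6)), columns=list("abcdef"))
        dx = ep.state_score_difference(num2, groups, "X")
        dy = ep.state_score_difference(num2, groups, "Y")
        np.testing.assert_allclose(dx, -dy)


class TestSegmentEqtl:
    def test_noise_free_coupling_retained(self, rng):
        score = rng.normal(size=20)
        num = pd.DataFrame([score], index=["r1"],
                           columns=[f"s{i}" for i in range(20)])
        expr = pd.DataFrame([2 * score + 1, -score],
                            index=["gPos", "gNeg"], columns=num.columns)
        out = ep.segment_eqtl(num, expr, [("r1", "gPos"), ("r1", "gNeg")])
        assert len(out) == 2
        assert out.set_index("gene").loc["gPos", "r"] == pytest.approx(1.0)
        assert out.set_index("gene").loc["gNeg", "r"] == pytest.approx(-1.0)

    def test_constant_pair_skipped_with_count(self, rng):
        num = pd.DataFrame([[1.0] * 10], index=["r1"],
                           columns=[f"s{i}" for i in range(10)])
        expr = pd.DataFrame([rng.normal(size=10)], index=["g"],
                            columns=num.columns)
        out = ep.segment_eqtl(num, expr, [("r1", "g")])
        assert out.empty and out.attrs["n_skipped"] == 1

    def test_null_retention_near_nominal(self):
        rng = np.random.default_rng(42)
        n_pairs, n_samples = 1000, 24
        num = pd.DataFrame(rng.normal(size=(n_pairs, n_samples)),
                           index=[f"r{i}" for i in range(n_pairs)],
                           columns=[f"s{i}" for i in range(n_samples)])
        expr = pd.DataFrame(rng.normal(size=(n_pairs, n_samples)),
                            index=[f"g{i}" for i in range(n_pairs)],
                            columns=num.columns)
        pairs = [(f"r{i}", f"g{i}") for i in range(n_pairs)]
        out = ep.segment_eqtl(num, expr, pairs)
        lo, hi = stats.binom.interval(0.99, n_pairs, 0.05)
        assert lo <= len(out) <= hi


class TestTssStateSummary:
    def test_expression_ordering_by_tss_state(self, small_cohort):
        out = ep.tss_state_summary(
            small_cohort.segmentations,
            small_cohort.genome,
            small_cohort.bulk_expression,
        )
        wide = out.pivot(index="sample", columns="state",
                         values="median_expression")
        assert (wide["E2"] > wide["E4"]).mean() > 0.9

    def test_multi_tss_frequency_dominance(self):
        genes = [
            Gene("g1", "chr1", 500, "+", GenomicInterval("chr1", 500, 1500),
                 alt_tss=(1100, 2500)),
        ]
        genome = GenomeAnnotation({"chr1": 10_000}, genes)
        segs = {
            "s1": [
                (GenomicInterval("chr1", 0, 2000), "E2"),     # TSSs 500, 1100
                (GenomicInterval("chr1", 2000, 10_000), "E4"),  # TSS 2500
            ]
        }
        expr = pd.DataFrame({"s1": [7.0]}, index=["g1"])
        out = ep.tss_state_summary(segs, genome, expr)
        assert out.loc[out["sample"] == "s1", "state"].tolist() == ["E2"]
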