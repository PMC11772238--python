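import itertools

import numpy as np
import pandas as pd
import pytest

from ucoseq import celldeconv, normtmm, simdata, trendscan
from ucoseq.celldeconv import (
    RankProfile,
    _u_statistic,
    aggregate,
    compare_pre_post,
    convergence_report,
    deconvolve,
    mixed_model_check,
    permutation_null,
    rank_samples,
    resolve_markers,
)
from ucoseq.core_io import MarkerTable, SampleTable


def pair_count_u(pre, post):
    """Exhaustive oracle: number of (pre, post) pairs with pre > post,
    counting ties as one half."""
    u = 0.0
    for a in pre:
        for b in post:
            if a > b:
                u += 1
            elif a == b:
                u += 0.5
    return u


def _profile_samples(n_pre=3, n_post=3, values=None):
    ids = [f"p{i}" for i in range(n_pre)] + [f"q{i}" for i in range(n_post)]
    rows = []
    for i, s in enumerate(ids):
        pre = i < n_pre
        rows.append(
            {"sample_id": s, "animal_id": s, "timepoint_h": -1.0 if pre else 6.0,
             "treatment": "vehicle", "phase": "pre" if pre else "post",
             "injury_class": "unknown"}
        )
    samples = SampleTable(pd.DataFrame(rows))
    if values is None:
        values = np.arange(1, n_pre + n_post + 1, dtype=float)
    profile = RankProfile(
        profile=pd.DataFrame({"CT": values}, index=ids),
        n_markers_used=pd.Series({"CT": 1}),
        dropped_types=[],
    )
    return profile, samples


class TestResolveMarkers:
    def test_identity_map_all_present_unchanged(self):
        mt = MarkerTable(pd.DataFrame({"marker_gene_id": ["a", "b"],
                                       "cell_type": ["T", "B"]}))
        omap = pd.DataFrame({"marker_gene_id": ["a", "b"], "ortholog_id": ["a", "b"]})
        resolved, ledger = resolve_markers(mt, omap, {"a", "b"})
        assert resolved.data["marker_gene_id"].tolist() == ["a", "b"]
        assert (ledger["n_after"] == 1).all()

    def test_type_losing_all_markers_ledgered(self):
        mt = MarkerTable(pd.DataFrame({"marker_gene_id": ["a", "b"],
                                       "cell_type": ["T", "B"]}))
        resolved, ledger = resolve_markers(mt, None, {"a"})
        assert ledger.set_index("cell_type").loc["B", "n_after"] == 0
        assert "B" not in set(resolved.data["cell_type"])

    def test_all_markers_dropped_hard_error(self):
        mt = MarkerTable(pd.DataFrame({"marker_gene_id": ["a"], "cell_type": ["T"]}))
        with pytest.raises(ValueError, match="every marker"):
            resolve_markers(mt, None, {"zzz"})

    def test_paper_scale_attrition_leaves_about_165(self):
        rng = np.random.default_rng(8)
        genes = [f"m{i}" for i in range(547)]
        mt = MarkerTable(pd.DataFrame({
            "marker_gene_id": genes,
            "cell_type": [f"CT{i % 22}" for i in range(547)],
        }))
        omap = simdata.simulate_ortholog_map(mt, 0.7, seed=8)
        resolved, _ = resolve_markers(mt, omap, set(omap["ortholog_id"]))
        assert 120 <= len(resolved) <= 210


class TestRanking:
    def test_simple_ranks(self):
        expr = pd.DataFrame([[5.0, 1.0, 3.0]], index=["m"], columns=list("abc"))
        mt = MarkerTable(pd.DataFrame({"marker_gene_id": ["m"], "cell_type": ["T"]}))
        r = rank_samples(expr, mt)
        assert r.loc["m"].tolist() == [3.0, 1.0, 2.0]

    def test_average_ties(self):
        expr = pd.DataFrame([[2.0, 2.0, 7.0]], index=["m"], columns=list("abc"))
        mt = MarkerTable(pd.DataFrame({"marker_gene_id": ["m"], "cell_type": ["T"]}))
        r = rank_samples(expr, mt)
        assert r.loc["m"].tolist() == [1.5, 1.5, 3.0]

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.lognormal(2, 1, size=(4, 8)),
                            index=list("wxyz"), columns=[f"s{i}" for i in range(8)])
        mt = MarkerTable(pd.DataFrame({"marker_gene_id": list("wxyz"),
                                       "cell_type": ["T", "T", "B", "B"]}))
        r1 = rank_samples(expr, mt)
        r2 = rank_samples(np.log2(expr + 3.7), mt)
        pd.testing.assert_frame_equal(r1, r2)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(2, 6)), index=["m1", "m2"],
                            columns=[f"s{i}" for i in range(6)])
        mt = MarkerTable(pd.DataFrame({"marker_gene_id": ["m1", "m2"],
                                       "cell_type": ["T", "T"]}))
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        r1 = rank_samples(expr, mt)
        r2 = rank_samples(expr[perm], mt)
        pd.testing.assert_frame_equal(r1[perm], r2)


class TestAggregate:
    def test_single_marker_type_passthrough(self):
        ranks = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"], columns=list("abc"))
        mt = MarkerTable(pd.DataFrame({"marker_gene_id": ["m"], "cell_type": ["T"]}))
        prof = aggregate(ranks, mt)
        assert prof.profile["T"].tolist() == [1.0, 2.0, 3.0]

    def test_odd_and_even_median_conventions(self):
        ranks = pd.DataFrame(
            [[2.0], [5.0], [8.0], [9.0]],
            index=["m1", "m2", "m3", "m4"], columns=["s"],
        )
        mt3 = MarkerTable(pd.DataFrame({"marker_gene_id": ["m1", "m2", "m3"],
                                        "cell_type": ["T"] * 3}))
        assert aggregate(ranks.iloc[:3], mt3).profile.loc["s", "T"] == 5.0
        mt4 = MarkerTable(pd.DataFrame({"marker_gene_id": ["m1", "m2", "m3", "m4"],
                                        "cell_type": ["T"] * 4}))
        assert aggregate(ranks, mt4).profile.loc["s", "T"] == 6.5


class TestUStatistic:
    def test_fully_separated_groups(self):
        profile, samples = _profile_samples(values=np.array([1, 2, 3, 4, 5, 6.0]))
        out = compare_pre_post(profile, samples)
        assert out["U"].iloc[0] == 0.0
        assert out["wilcoxon_p"].iloc[0] == pytest.approx(0.1)

    def test_interleaved_pair_example(self):
        profile, samples = _profile_samples(2, 2, np.array([1.0, 3.0, 2.0, 4.0]))
        out = compare_pre_post(profile, samples)
        assert out["U"].iloc[0] == 1.0

    def test_identical_groups_p_one(self):
        profile, samples = _profile_samples(3, 3, np.array([5.0] * 6))
        out = compare_pre_post(profile, samples)
        assert out["wilcoxon_p"].iloc[0] == pytest.approx(1.0)

    def test_matches_pair_count_oracle_small_groups(self):
        rng = np.random.default_rng(5)
        for n1, n2 in itertools.product(range(1, 6), range(1, 6)):
            for tied in (False, True):
                x = rng.integers(0, 4, n1 + n2).astype(float) if tied else \
                    rng.normal(size=n1 + n2)
                assert _u_statistic(x[:n1], x[n1:]) == pytest.approx(
                    pair_count_u(x[:n1], x[n1:])
                )


class TestPermutationNull:
    def test_maximal_separation_count_zero(self):
        # study-scale groups: no random relabelling reproduces the extremity
        profile, samples = _profile_samples(10, 28, np.arange(1.0, 39.0))
        out = permutation_null(profile, samples, n_perm=500, seed=1)
        assert out["count_lower"].iloc[0] == 0
        assert out["empirical_p"].iloc[0] == pytest.approx(1 / 501)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(3)
        profile, samples = _profile_samples(4, 6, rng.normal(size=10))
        a = permutation_null(profile, samples, n_perm=200, seed=7)
        b = permutation_null(profile, samples, n_perm=200, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_empirical_p_tracks_wilcoxon(self):
        rng = np.random.default_rng(4)
        profile, samples = _profile_samples(5, 8, rng.normal(size=13))
        wil = compare_pre_post(profile, samples)
        perm = permutation_null(profile, samples, n_perm=2000, seed=2)
        p_w, p_e = wil["wilcoxon_p"].iloc[0], perm["empirical_p"].iloc[0]
        se = np.sqrt(p_e * (1 - p_e) / 2000)
        assert abs(p_e - p_w) < 4 * max(se, 0.005)


class TestMixedModel:
    def test_zero_between_animal_variance_tracks_ols(self):
        """Repeated measures with no true animal effect: the phase p agrees
        with ordinary regression to within small-sample df differences."""
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        ids, rows = [], []
        for i in range(8):
            for tp in (-1.0, 6.0, 24.0):
                s = f"A{i}_{tp:g}"
                ids.append(s)
                rows.append(
                    {"sample_id": s, "animal_id": f"A{i}", "timepoint_h": tp,
                     "treatment": "vehicle", "phase": "pre" if tp < 0 else "post",
                     "injury_class": "unknown"}
                )
        samples = SampleTable(pd.DataFrame(rows))
        vals = rng.uniform(1, 24, 24)
        profile = RankProfile(
            profile=pd.DataFrame({"CT": vals}, index=ids),
            n_markers_used=pd.Series({"CT": 1}),
            dropped_types=[],
        )
        out = mixed_model_check(profile, samples)
        meta = samples.data
        y = np.log(vals)
        post = (meta["phase"] == "post").astype(float).to_numpy()
        tps = meta["timepoint_h"].to_numpy()
        z = (tps - tps.mean()) / tps.std()
        X = np.column_stack([np.ones(24), post, z])
        ols = sm.OLS(y, X).fit()
        assert out["lmm_p"].iloc[0] == pytest.approx(ols.pvalues[1], rel=0.5, abs=0.05)

    def test_planted_shift_sign_matches(self, small_experiment):
        sub_s = trendscan.vehicle_trend_subset(small_experiment.samples)
        sub = small_experiment.counts.subset_samples(sub_s.sample_ids)
        factors = normtmm.tmm_factors(sub)
        prof = deconvolve(sub, factors, small_experiment.markers)
        out = mixed_model_check(prof, sub_s).set_index("cell_type")
        for _, row in small_experiment.truth.shifted_cell_types.iterrows():
            fc = out.loc[row.cell_type, "fold_change"]
            assert (fc > 1) == (row.sign > 0)


class TestConvergenceReport:
    def test_empty_profile_empty_report(self):
        assert convergence_report(pd.DataFrame(), pd.DataFrame(), pd.DataFrame()).empty

    def test_strong_effect_full_convergence(self, small_experiment):
        sub_s = trendscan.vehicle_trend_subset(small_experiment.samples)
        sub = small_experiment.counts.subset_samples(sub_s.sample_ids)
        factors = normtmm.tmm_factors(sub)
        prof = deconvolve(sub, factors, small_experiment.markers)
        wil = compare_pre_post(prof, sub_s)
        perm = permutation_null(prof, sub_s, n_perm=500, seed=3)
        mixed = mixed_model_check(prof, sub_s)
        rep = convergence_report(wil, perm, mixed)
        assert rep["sign_agreement"].iloc[0] == 1.0
        assert rep["spearman_p_wilcoxon_perm"].iloc[0] > 0.9
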