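import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import omnidiet as od
from omnidiet.community import DissimilarityMatrix
from omnidiet.occurrence import OccurrenceMatrix


def _occ(presence):
    presence = np.asarray(presence)
    return OccurrenceMatrix(
        presence=pd.DataFrame(
            presence,
            index=[f"s{i}" for i in range(presence.shape[0])],
            columns=[f"t{j}" for j in range(presence.shape[1])],
        ),
        zero_total_samples=[],
    )


def _euclid_dm(X):
    X = np.asarray(X, dtype=float)
    D = squareform(pdist(X))
    return DissimilarityMatrix(ids=[f"s{i}" for i in range(len(X))], D=D)


class TestSorensen:
    def test_hand_enumeration(self):
        occ = _occ([[1, 1, 0], [1, 0, 1]])
        dm = od.sorensen_matrix(occ)
        assert dm.D[0, 1] == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        occ = _occ([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]])
        dm = od.sorensen_matrix(occ)
        assert dm.D[0, 1] == 0.0
        assert dm.D[0, 2] == 1.0

    def test_scipy_dice_oracle(self):
        rng = np.random.default_rng(1)
        presence = (rng.uniform(size=(12, 8)) < 0.5).astype(int)
        presence[presence.sum(axis=1) == 0, 0] = 1  # avoid empty rows here
        dm = od.sorensen_matrix(_occ(presence))
        expected = squareform(pdist(presence.astype(bool), metric="dice"))
        np.testing.assert_allclose(dm.D, expected, atol=1e-12)

    def test_all_absent_pair_flagged_zero(self):
        occ = _occ([[0, 0], [0, 0], [1, 0]])
        dm = od.sorensen_matrix(occ)
        assert dm.D[0, 1] == 0.0
        assert ("s0", "s1") in dm.flagged_pairs


class TestPcoa:
    def test_three_equidistant_points(self):
        """Unit simplex: two equal positive eigenvalues, one zero."""
        D = np.ones((3, 3)) - np.eye(3)
        res = od.pcoa(DissimilarityMatrix(ids=list("abc"), D=D))
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        assert res.eigenvalues[0] > 0
        assert res.eigenvalues[2] == pytest.approx(0.0, abs=1e-10)

    def test_euclidean_embedding_reproduces_distances(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 2))
        dm = _euclid_dm(X)
        res = od.pcoa(dm)
        pos = res.eigenvalues > 1e-10
        recon = squareform(pdist(res.coordinates[:, pos]))
        np.testing.assert_allclose(recon, dm.D, atol=1e-8)

    def test_duplicate_samples_coincide(self):
        occ = _occ([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        res = od.pcoa(od.sorensen_matrix(occ))
        np.testing.assert_allclose(
            res.coordinates[0], res.coordinates[1], atol=1e-10
        )

    def test_skbio_oracle_on_positive_axes(self):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(3)
        presence = (rng.uniform(size=(9, 6)) < 0.5).astype(int)
        presence[presence.sum(axis=1) == 0, 0] = 1
        dm = od.sorensen_matrix(_occ(presence))
        res = od.pcoa(dm)
        ref = skbio_ordination.pcoa(dm.D)
        # skbio clamps negative eigenvalues to zero; compare positive spectra
        ref_eigs = ref.eigvals.to_numpy()
        ref_pos = np.sort(ref_eigs[ref_eigs > 1e-8])[::-1]
        ours_pos = np.sort(res.eigenvalues[res.eigenvalues > 1e-8])[::-1]
        np.testing.assert_allclose(ours_pos, ref_pos, atol=1e-8)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(od.ValidationError):
            DissimilarityMatrix(ids=["a", "b"], D=D)


def _oneway_F_bruteforce(D, codes):
    """Anderson's group-sum formula: an independent pseudo-F path."""
    n = len(codes)
    a = len(set(codes))
    d2 = D**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in set(codes):
        idx = np.nonzero(codes == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_study_design_degrees_of_freedom(self):
        """4 habitats x 7 sessions: df 3 / 6 / 18, residual n - 28."""
        from omnidiet.simulate import _study_metadata

        n = 56
        meta = _study_metadata(n, 4, 7)
        rng = np.random.default_rng(4)
        presence = (rng.uniform(size=(n, 10)) < 0.5).astype(int)
        occ = OccurrenceMatrix(
            presence=pd.DataFrame(presence, index=meta.index,
                                  columns=[f"t{j}" for j in range(10)]),
            zero_total_samples=[],
        )
        res = od.permanova_two_way(od.sorensen_matrix(occ), meta,
                                   ("habitat", "session"), n_perm=19, seed=0)
        t = res.table
        assert t.loc["habitat", "df"] == 3
        assert t.loc["session", "df"] == 6
        assert t.loc["habitat x session", "df"] == 18
        assert t.loc["Residual", "df"] == n - 28
        assert t.loc["Total", "df"] == n - 1

    def test_one_way_equals_classical_anova(self):
        """On univariate Euclidean data the pseudo-F is the ANOVA F."""
        rng = np.random.default_rng(5)
        y = np.concatenate([rng.normal(0, 1, 8), rng.normal(1.0, 1, 8),
                            rng.normal(0.5, 1, 8)])
        codes = np.repeat([0, 1, 2], 8)
        dm = _euclid_dm(y[:, None])
        meta = pd.DataFrame({"group": codes}, index=dm.ids)
        res = od.permanova(dm, meta, ("group",), n_perm=9, seed=1)
        F_classic = stats.f_oneway(y[:8], y[8:16], y[16:]).statistic
        assert res.table.loc["group", "pseudo_F"] == pytest.approx(F_classic,
                                                                   abs=1e-8)

    def test_group_sum_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        presence = (rng.uniform(size=(14, 9)) < 0.5).astype(int)
        presence[presence.sum(axis=1) == 0, 0] = 1
        codes = np.repeat([0, 1], 7)
        dm = od.sorensen_matrix(_occ(presence))
        meta = pd.DataFrame({"group": codes}, index=dm.ids)
        res = od.permanova(dm, meta, ("group",), n_perm=9, seed=1)
        assert res.table.loc["group", "pseudo_F"] == pytest.approx(
            _oneway_F_bruteforce(dm.D, codes), abs=1e-8
        )

    def test_full_enumeration_oracle(self):
        """Sampled permutation p matches exhaustive enumeration for n = 6."""
        rng = np.random.default_rng(7)
        y = rng.normal(size=6)
        y[3:] += 1.5
        codes = np.array([0, 0, 0, 1, 1, 1])
        dm = _euclid_dm(y[:, None])
        meta = pd.DataFrame({"group": codes}, index=dm.ids)
        res = od.permanova(dm, meta, ("group",), n_perm=9999, seed=2)
        F_obs = res.table.loc["group", "pseudo_F"]
        count = 0
        total = 0
        for perm in itertools.permutations(range(6)):
            F_p = _oneway_F_bruteforce(dm.D, codes[list(perm)])
            total += 1
            if F_p >= F_obs - 1e-12:
                count += 1
        p_exact = count / total
        assert res.table.loc["group", "p_perm"] == pytest.approx(p_exact, abs=0.02)

    def test_ss_additivity_balanced_design(self):
        rng = np.random.default_rng(8)
        n = 24  # 2 habitats x 3 sessions x 4 replicates: balanced
        meta = pd.DataFrame(
            {
                "habitat": np.tile(np.repeat(["forest", "shrub"], 12), 1),
                "session": np.tile(np.repeat([1, 2, 3], 4), 2),
            },
            index=[f"s{i}" for i in range(n)],
        )
        X = rng.normal(size=(n, 3))
        dm = _euclid_dm(X)
        dm.ids = list(meta.index)
        res = od.permanova_two_way(dm, meta, ("habitat", "session"), n_perm=9,
                                   seed=3)
        t = res.table
        terms_ss = t.loc[["habitat", "session", "habitat x session", "Residual"],
                         "SS"].sum()
        assert terms_ss == pytest.approx(t.loc["Total", "SS"], rel=1e-8)
        assert (t["pseudo_F"].dropna() > 0).all()

    def test_empty_cell_raises(self):
        meta = pd.DataFrame(
            {
                "habitat": ["forest"] * 4 + ["shrub"] * 4,
                "session": [1, 1, 2, 2, 1, 1, 1, 1],  # shrub x session 2 empty
            },
            index=[f"s{i}" for i in range(8)],
        )
        dm = _euclid_dm(np.arange(8)[:, None])
        dm.ids = list(meta.index)
        with pytest.raises(od.ValidationError, match="empty design cell"):
            od.permanova_two_way(dm, meta, ("habitat", "session"), n_perm=9)

    def test_reorder_invariance(self):
        rng = np.random.default_rng(9)
        presence = (rng.uniform(size=(16, 6)) < 0.5).astype(int)
        presence[presence.sum(axis=1) == 0, 0] = 1
        codes = np.repeat([0, 1], 8)
        occ = _occ(presence)
        dm = od.sorensen_matrix(occ)
        meta = pd.DataFrame({"group": codes}, index=dm.ids)
        res1 = od.permanova(dm, meta, ("group",), n_perm=199, seed=5)
        order = rng.permutation(16)
        dm2 = DissimilarityMatrix(
            ids=[dm.ids[i] for i in order], D=dm.D[np.ix_(order, order)]
        )
        res2 = od.permanova(dm2, meta, ("group",), n_perm=199, seed=5)
        assert res1.table.loc["group", "p_perm"] == res2.table.loc["group", "p_perm"]

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 stays near nominal."""
        rng = np.random.default_rng(10)
        n, reps, n_perm = 20, 200, 99
        codes = np.repeat([0, 1, 2, 3], 5)
        rejections = 0
        for _ in range(reps):
            presence = (rng.uniform(size=(n, 10)) < 0.4).astype(int)
            presence[presence.sum(axis=1) == 0, 0] = 1
            dm = od.sorensen_matrix(_occ(presence))
            meta = pd.DataFrame({"group": codes}, index=dm.ids)
            res = od.permanova(dm, meta, ("group",), n_perm=n_perm,
                               seed=int(rng.integers(2**31)))
            if res.table.loc["group", "p_perm"] <= 0.05:
                rejections += 1
        rate = rejections / reps
        assert 0.02 <= rate <= 0.09  # 200-rep screen; acceptance runs 500


class TestPermdisp:
    def test_equal_dispersion_mirror_groups(self):
        X = np.array([[0, 0], [1, 0], [0, 1], [10, 10], [11, 10], [10, 11]],
                     dtype=float)
        dm = _euclid_dm(X)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=dm.ids)
        res = od.permdisp(dm, groups, n_perm=199, seed=1)
        assert res.F == pytest.approx(0.0, abs=1e-10)
        assert res.p_perm > 0.5

    def test_detects_dispersion_difference(self):
        rng = np.random.default_rng(11)
        tight = rng.normal(0, 0.2, size=(20, 2))
        diffuse = rng.normal(0, 3.0, size=(20, 2))
        dm = _euclid_dm(np.vstack([tight, diffuse]))
        groups = pd.Series(["t"] * 20 + ["d"] * 20, index=dm.ids)
        res = od.permdisp(dm, groups, n_perm=499, seed=2)
        assert res.p_perm < 0.05
        assert res.group_means["d"] > res.group_means["t"]

    def test_identical_points_zero_distance(self):
        X = np.array([[1.0, 1.0]] * 3 + [[0.0, 0.0], [2.0, 2.0]])
        dm = _euclid_dm(X)
        groups = pd.Series(["a"] * 3 + ["b"] * 2, index=dm.ids)
        res = od.permdisp(dm, groups, n_perm=99, seed=3)
        assert res.group_means["a"] == pytest.approx(0.0, abs=1e-10)

    def test_euclidean_matches_direct_levene_distances(self):
        """On metric data, z equals distance-to-centroid in coordinate space."""
        rng = np.random.default_rng(12)
        X = rng.normal(size=(18, 3))
        dm = _euclid_dm(X)
        groups = pd.Series(np.repeat(["a", "b", "c"], 6), index=dm.ids)
        res = od.permdisp(dm, groups, n_perm=99, seed=4)
        z_direct = np.empty(18)
        for g in ("a", "b", "c"):
            idx = np.nonzero((groups == g).to_numpy())[0]
            cen = X[idx].mean(axis=0)
            z_direct[idx] = np.linalg.norm(X[idx] - cen, axis=1)
        np.testing.assert_allclose(res.distances.to_numpy(), z_direct, atol=1e-8)
        F_direct = stats.f_oneway(
            *[z_direct[groups.to_numpy() == g] for g in ("a", "b", "c")]
        ).statistic
        assert res.F == pytest.approx(F_direct, abs=1e-8)

    def test_df_and_group_size_guards(self):
        X = np.arange(10, dtype=float)[:, None]
        dm = _euclid_dm(X)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=dm.ids)
        res = od.permdisp(dm, groups, n_perm=49, seed=5)
        assert (res.df1, res.df2) == (1, 8)
        bad = pd.Series(["a"] * 9 + ["b"], index=dm.ids)
        with pytest.raises(od.ValidationError, match="fewer than 2"):
            od.permdisp(dm, bad, n_perm=49, seed=5)


class TestPairwise:
    def test_t_is_sqrt_F_and_matches_oneway(self):
        rng = np.random.default_rng(13)
        presence = (rng.uniform(size=(18, 7)) < 0.5).astype(int)
        presence[presence.sum(axis=1) == 0, 0] = 1
        groups = pd.Series(np.repeat(["a", "b", "c"], 6),
                           index=[f"s{i}" for i in range(18)])
        dm = od.sorensen_matrix(_occ(presence))
        pw = od.pairwise_permanova(dm, groups, n_perm=99, seed=6)
        assert len(pw) == 3
        keep = np.nonzero(groups.isin(["a", "b"]).to_numpy())[0]
        sub = DissimilarityMatrix(ids=[dm.ids[i] for i in keep],
                                  D=dm.D[np.ix_(keep, keep)])
        res = od.permanova(sub, pd.DataFrame({"group": groups}),
                           ("group",), n_perm=99, seed=6)
        row = pw[(pw.group_1 == "a") & (pw.group_2 == "b")].iloc[0]
        assert row["t"] == pytest.approx(
            np.sqrt(res.table.loc["group", "pseudo_F"])
        )
        assert row["p_perm"] == res.table.loc["group", "p_perm"]

    def test_complete_separation_minimal_p(self):
        presence = np.zeros((10, 4), dtype=int)
        presence[:5, :2] = 1
        presence[5:, 2:] = 1
        groups = pd.Series(["a"] * 5 + ["b"] * 5,
                           index=[f"s{i}" for i in range(10)])
        dm = od.sorensen_matrix(_occ(presence))
        pw = od.pairwise_permanova(dm, groups, n_perm=199, seed=7)
        # complete separation: observed F is only beaten by label-preserving
        # permutations, p near the attainable minimum
        assert pw["p_perm"].iloc[0] < 0.05
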