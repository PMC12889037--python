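import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from wmkdiv.geometry import kabsch_superpose
from wmkdiv.structcomp import (
    PairRecord, core_find, group_summary, joint_pca, msa_correspondence, outlier_rank,
    pairwise_matrix, progressive_removal, tm_d0, tm_score_at, tm_score_fixed, tm_score_msa,
)
from wmkdiv.structio import HomologRecord, HomologSet, MSA, Structure
from wmkdiv.synthdata import _rotate_tail, _swing_axis, make_hinge_ensemble, make_two_domain_fold


def struct(coords, sid="s"):
    coords = np.asarray(coords, float)
    n = len(coords)
    return Structure(sid, tuple(range(1, n + 1)), "A" * n, coords)


def brute_force_tm(A, B, L, n_restarts=60, seed=0):
    """Oracle: multi-start 6-dof maximization of the TM sum."""
    d0 = tm_d0(L)
    rng = np.random.default_rng(seed)
    XA, XB = A.coords, B.coords

    def neg_tm(params):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        return -tm_score_at(XA, XB, R, params[3:], d0, L)

    best = -np.inf
    for _ in range(n_restarts):
        q = rng.normal(size=4)
        rot = Rotation.from_quat(q / np.linalg.norm(q))
        t0 = XB.mean(0) - rot.as_matrix() @ XA.mean(0) + rng.normal(scale=1.0, size=3)
        x0 = np.concatenate([rot.as_rotvec(), t0])
        res = minimize(neg_tm, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        best = max(best, -res.fun)
    return best


class TestTMScore:
    def test_self_comparison_is_one(self):
        rng = np.random.default_rng(0)
        A = struct(rng.normal(scale=8, size=(20, 3)))
        corr = [(i, i) for i in range(1, 21)]
        res = tm_score_fixed(A, A, corr, 20)
        assert res.score == pytest.approx(1.0, abs=1e-9)
        assert res.n_pairs == 20

    def test_analytic_one_displaced_atom(self):
        # 29 pairs at distance 0 and one at exactly d0: formula gives 29.5/30
        rng = np.random.default_rng(1)
        L = 30
        d0 = tm_d0(L)
        XA = rng.normal(scale=9, size=(L, 3))
        XB = XA.copy()
        XB[-1] += np.array([d0, 0.0, 0.0])
        val = tm_score_at(XA, XB, np.eye(3), np.zeros(3), d0, L)
        assert val == pytest.approx(29.5 / 30)
        res = tm_score_fixed(struct(XA), struct(XB), [(i, i) for i in range(1, L + 1)], L)
        assert res.score >= val - 1e-9  # optimizer can only improve

    def test_d0_formula_and_floor(self):
        assert tm_d0(30) == pytest.approx(1.24 * 15 ** (1 / 3) - 1.8)
        assert tm_d0(21) == 0.5
        assert tm_d0(5) == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_on_small_structures(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        A = struct(np.cumsum(rng.normal(scale=2.0, size=(n, 3)), axis=0), "a")
        B = struct(np.cumsum(rng.normal(scale=2.0, size=(n, 3)), axis=0), "b")
        corr = [(i, i) for i in range(1, n + 1)]
        ours = tm_score_fixed(A, B, corr, n).score
        oracle = brute_force_tm(A, B, n, seed=seed)
        assert ours == pytest.approx(oracle, abs=5e-3)

    def test_symmetry_with_fixed_normalization(self):
        rng = np.random.default_rng(5)
        A = struct(rng.normal(scale=8, size=(15, 3)), "a")
        B = struct(rng.normal(scale=8, size=(15, 3)), "b")
        corr = [(i, i) for i in range(1, 16)]
        ab = tm_score_fixed(A, B, corr, 15).score
        ba = tm_score_fixed(B, A, [(j, i) for i, j in corr], 15).score
        assert ab == pytest.approx(ba, abs=1e-8)

    def test_at_least_plain_least_squares_score(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            A = struct(rng.normal(scale=6, size=(12, 3)), "a")
            B = struct(rng.normal(scale=6, size=(12, 3)), "b")
            corr = [(i, i) for i in range(1, 13)]
            res = tm_score_fixed(A, B, corr, 12)
            sup = kabsch_superpose(A.coords, B.coords)
            ls = tm_score_at(A.coords, B.coords, sup.rotation, sup.translation, res.d0, 12)
            assert res.score >= ls - 1e-9

    def test_empty_correspondence_rejected(self):
        A = struct(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            tm_score_fixed(A, A, [], 3)


class TestMSAGuidedTM:
    def test_identical_sequences_and_structures(self):
        rng = np.random.default_rng(7)
        A = struct(rng.normal(scale=8, size=(10, 3)), "a")
        B = A.with_coords(A.coords.copy(), id="b")
        msa = MSA(("a", "b"), ("ACDEFGHIKL", "ACDEFGHIKL"))
        assert tm_score_msa(A, B, msa).score == pytest.approx(1.0, abs=1e-9)

    def test_gapped_block_shrinks_correspondence(self):
        msa = MSA(("a", "b"), ("ACDEFGHIKL", "ACD---HIKL"))
        pairs = msa_correspondence(msa, "a", "b")
        assert len(pairs) == 7
        assert pairs[3] == (7, 4)  # H aligns after the 3-column gap

    def test_score_decreases_with_hinge_angle(self):
        st, ann = make_two_domain_fold(seed=4)
        msa = MSA(("a", "b"), (st.residue_codes, st.residue_codes))
        base = struct(st.coords, "a")
        axis = _swing_axis(st.coords, 106)
        scores = []
        for ang in [0.0, 15.0, 30.0, 60.0]:
            moved = struct(_rotate_tail(st.coords, 106, axis, ang), "b")
            scores.append(tm_score_msa(base, moved, msa).score)
        assert scores[0] == pytest.approx(1.0, abs=1e-6)
        assert scores == sorted(scores, reverse=True)


def two_homolog_set(n_frames=8, seed=0):
    rng = np.random.default_rng(seed)
    n = 12
    seq = "ACDEFGHIKLMN"
    msa = MSA(("a", "b"), (seq, seq))
    records = []
    for sid in ("a", "b"):
        base = rng.normal(scale=6, size=(n, 3))
        frames = [
            Structure(sid, tuple(range(1, n + 1)), seq,
                      base + rng.normal(scale=0.2, size=(n, 3)))
            for _ in range(n_frames)
        ]
        from wmkdiv.structio import Ensemble

        records.append(
            HomologRecord(sid, seq, "type-I", Ensemble(sid, frames, np.arange(float(n_frames))))
        )
    return HomologSet(records, msa, "a")


class TestPairwiseMatrix:
    def test_within_homolog_combinatorics(self):
        rows = pairwise_matrix(two_homolog_set(), "within_homolog")
        assert len(rows) == 2 * 28  # 2 homologs x C(8,2)
        assert all(r.comparison_class == "within_homolog" for r in rows)

    def test_between_homolog_combinatorics(self):
        rows = pairwise_matrix(two_homolog_set(), "between_homolog")
        assert len(rows) == 64
        assert all(r.comparison_class == "within_group" for r in rows)

    def test_family_separation(self, family, sampled_conformations):
        hs = family.homolog_set
        from wmkdiv.ensemble_stats import sample_frames

        sampled = HomologSet(
            [HomologRecord(r.id, r.sequence, r.group, sample_frames(r.ensemble)) for r in hs],
            hs.msa, "ref",
        )
        within = pairwise_matrix(sampled, "within_homolog")
        between = pairwise_matrix(sampled, "between_homolog")
        summary = group_summary(within + between)
        assert summary["within_homolog"]["median"] > summary["between_group"]["median"]
        assert summary["within_group"]["median"] > summary["between_group"]["median"]


class TestGroupSummary:
    def test_single_row(self):
        rows = [PairRecord("a", 0, "b", 0, 0.5, "between_group")]
        s = group_summary(rows)["between_group"]
        assert s["median"] == s["min"] == s["max"] == 0.5

    def test_matches_sorted_oracle(self):
        scores = [0.2, 0.9, 0.4, 0.6, 0.5]
        rows = [PairRecord("a", i, "b", i, v, "within_group") for i, v in enumerate(scores)]
        s = group_summary(rows)["within_group"]
        srt = sorted(scores)
        assert s["median"] == srt[2] and s["min"] == srt[0] and s["max"] == srt[-1]


class TestCoreFind:
    def test_identical_structures_keep_everything(self):
        rng = np.random.default_rng(8)
        base = rng.normal(scale=6, size=(10, 3))
        seq = "ACDEFGHIKL"
        msa = MSA(("a", "b"), (seq, seq))
        confs = [Structure(s, tuple(range(1, 11)), seq, base.copy()) for s in ("a", "b", "a")]
        cf = core_find(confs, ["a", "b", "a"], msa)
        assert set(cf.core_positions) == set(range(1, 11))

    def test_graded_noise_gives_monotone_trace_and_correct_core(self):
        # per-position noise scales increase with position: the trace of
        # removed max-variances must be non-increasing and the low-noise
        # positions must survive
        rng = np.random.default_rng(9)
        n, n_conf = 12, 20
        base = rng.normal(scale=8, size=(n, 3))
        scales = np.concatenate([np.full(6, 0.01), np.linspace(1.0, 4.0, 6)])
        seq = "ACDEFGHIKLMN"
        msa = MSA(("a",), (seq,))
        confs = [
            Structure("a", tuple(range(1, n + 1)), seq,
                      base + rng.normal(size=(n, 3)) * scales[:, None])
            for _ in range(n_conf)
        ]
        cf = core_find(confs, ["a"] * n_conf, msa, stop="count", target_count=6)
        assert set(cf.core_positions) == set(range(1, 7))
        vmax = [v for _, v in cf.trace]
        assert all(b <= a * 1.5 for a, b in zip(vmax, vmax[1:]))  # near-monotone greedy

    def test_count_stop_and_validation(self, family, sampled_conformations):
        confs, cids = sampled_conformations
        msa = family.homolog_set.msa
        cf = core_find(confs, cids, msa, stop="count", target_count=40)
        assert len(cf.core_positions) == 40
        with pytest.raises(ValueError):
            core_find(confs, cids, msa, stop="count")
        with pytest.raises(ValueError):
            core_find(confs[:1], cids[:1], msa)

    def test_family_core_in_stable_domain(self, family, sampled_conformations):
        confs, cids = sampled_conformations
        cf = core_find(confs, cids, family.homolog_set.msa)
        lo, hi = family.truth["stable_domain"]
        stable = set(range(lo, hi + 1))
        frac = len(set(cf.core_positions) & stable) / len(cf.core_positions)
        assert frac >= 0.9


class TestJointPCAOutliers:
    def test_identical_conformations_zero_eigenvalues(self):
        rng = np.random.default_rng(10)
        base = rng.normal(scale=6, size=(8, 3))
        seq = "ACDEFGHI"
        msa = MSA(("a", "b", "c"), (seq, seq, seq))
        confs = [Structure(s, tuple(range(1, 9)), seq, base.copy()) for s in "abcabc"]
        jp = joint_pca(confs, list("abcabc"), msa, range(1, 9))
        np.testing.assert_allclose(jp.eigenvalues, 0.0, atol=1e-16)
        rows = outlier_rank(jp)
        assert all(r["centroid_distance"] == 0.0 for r in rows)
        assert [r["homolog_id"] for r in rows] == ["a", "b", "c"]  # id tie-break

    def test_family_groups_separate(self, family, sampled_conformations):
        confs, cids = sampled_conformations
        msa = family.homolog_set.msa
        cf = core_find(confs, cids, msa)
        jp = joint_pca(confs, cids, msa, cf.core_positions)
        assert jp.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        groups = family.truth["groups"]
        proj = jp.projections[:, :2]
        labels = ["distant" if groups[l] == "distant" else "type-I" for l in jp.labels]
        from sklearn.metrics import silhouette_score

        assert silhouette_score(proj, labels) > 0

    def test_planted_outlier_ranked_first(self, family, sampled_conformations):
        confs, cids = sampled_conformations
        msa = family.homolog_set.msa
        cf = core_find(confs, cids, msa)
        hp = family.truth["hinge_positions"]["t3"]
        planted = []
        for c, i in zip(confs, cids):
            if i == "t3":
                axis = _swing_axis(c.coords, hp - 1)
                c = c.with_coords(_rotate_tail(c.coords, hp - 1, axis, 120.0))
            planted.append(c)
        jp = joint_pca(planted, cids, msa, cf.core_positions)
        assert outlier_rank(jp)[0]["homolog_id"] == "t3"


def constructed_pair_table():
    """4 homologs; 'd' scores low against everyone."""
    scores = {
        ("a", "b"): 0.8, ("a", "c"): 0.7, ("b", "c"): 0.75,
        ("a", "d"): 0.2, ("b", "d"): 0.25, ("c", "d"): 0.3,
    }
    return [
        PairRecord(x, 0, y, 0, v, "within_group") for (x, y), v in scores.items()
    ]


class TestProgressiveRemoval:
    def test_zero_removals_baseline_only(self):
        table = constructed_pair_table()
        res = progressive_removal(table, 0)
        assert res["removal_order"] == []
        assert res["medians"] == [pytest.approx(np.median([0.8, 0.7, 0.75, 0.2, 0.25, 0.3]))]

    def test_greedy_matches_exhaustive_subsets(self):
        table = constructed_pair_table()
        res = progressive_removal(table, 2)
        homologs = ["a", "b", "c", "d"]

        def med(removed):
            s = [r.score for r in table if r.id_a not in removed and r.id_b not in removed]
            return np.median(s)

        best2 = max(itertools.combinations(homologs, 2), key=lambda c: med(set(c)))
        assert set(res["removal_order"]) == set(best2)
        assert res["medians"][-1] == pytest.approx(med(set(best2)))

    def test_family_with_outlier_monotone_medians(self, family):
        from wmkdiv.ensemble_stats import sample_frames

        hs = family.homolog_set
        sampled = HomologSet(
            [HomologRecord(r.id, r.sequence, r.group, sample_frames(r.ensemble)) for r in hs],
            hs.msa, "ref",
        )
        between = pairwise_matrix(sampled, "between_homolog")
        res = progressive_removal(between, 2)
        meds = res["medians"]
        assert all(b >= a - 1e-12 for a, b in zip(meds, meds[1:]))

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            progressive_removal(constructed_pair_table(), 3)
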