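"""GRM construction, mixed-model solve vs a variance-matrix oracle,
validation splits, accuracy metrics and GRM PCA."""

import numpy as np
import pandas as pd
import pytest

from smallherd.gblup_prediction import (
    TraitRecords,
    accuracy,
    bootstrap_accuracy,
    build_grm,
    debv_reliability_filter,
    forward_split,
    parent_average,
    parent_average_correlation,
    pca_grm,
    solve_gblup,
)

from conftest import make_genotypes


def records_of(ids, values, reliability=0.6, kind="ebv"):
    rel = np.broadcast_to(np.asarray(reliability, float), (len(ids),))
    return TraitRecords(
        table=pd.DataFrame(
            {"sample_id": ids, "trait": "t", "pseudo_phenotype": values,
             "reliability": rel, "kind": kind}
        )
    )


class TestGRM:
    def test_hand_arithmetic_two_individuals(self):
        g = make_genotypes(np.array([[0, 2], [2, 0]], dtype=np.int8))
        grm = build_grm(g)
        # p = 0.5 at both markers: denominator 2 * (0.25 + 0.25) = 1
        assert np.allclose(grm.values, [[2, -2], [-2, 2]])

    def test_identical_individuals_equal_rows(self, rng):
        row = rng.integers(0, 3, 30).astype(np.int8)
        other = rng.integers(0, 3, 30).astype(np.int8)
        g = make_genotypes(np.vstack([row, row, other]))
        grm = build_grm(g)
        assert np.allclose(grm.values[0], grm.values[1])
        assert grm.values[0, 1] == pytest.approx(grm.values[0, 0])

    def test_symmetric_and_marker_order_invariant(self, rng):
        calls = rng.integers(-1, 3, size=(12, 50)).astype(np.int8)
        g = make_genotypes(calls)
        grm = build_grm(g)
        assert np.abs(grm.values - grm.values.T).max() == 0.0
        perm = rng.permutation(50)
        g2 = make_genotypes(calls[:, perm])
        assert np.allclose(grm.values, build_grm(g2).values)

    def test_all_monomorphic_rejected(self):
        g = make_genotypes(np.full((4, 6), 2, dtype=np.int8))
        with pytest.raises(ValueError):
            build_grm(g)


def gblup_oracle(gmat, y, z_idx, lam, r_diag):
    """Variance-matrix route: V = Z G Z' + lam R, mu = GLS mean,
    g_hat = G Z' V^-1 (y - mu).  Independent of the MME solve."""
    n_g = gmat.shape[0]
    z = np.zeros((len(y), n_g))
    z[np.arange(len(y)), z_idx] = 1.0
    v = z @ gmat @ z.T + lam * np.diag(r_diag)
    vi = np.linalg.inv(v)
    ones = np.ones(len(y))
    mu = (ones @ vi @ y) / (ones @ vi @ ones)
    ghat = gmat @ z.T @ vi @ (y - mu * ones)
    return mu, ghat


class TestSolveGblup:
    def make_grm(self, gmat, ids):
        from smallherd.gblup_prediction import GRM

        return GRM(values=np.asarray(gmat, float), sample_ids=list(ids),
                   allele_frequencies=np.array([]))

    def test_identity_grm_known_solution(self):
        ids = ["a", "b", "c"]
        grm = self.make_grm(np.eye(3), ids)
        recs = records_of(ids, [1.0, 2.0, 3.0], reliability=0.5)
        res = solve_gblup(grm, recs, ids, variance_ratio=1.0,
                          use_weights=False, jitter=0.0)
        assert res.mu_hat == pytest.approx(2.0)
        assert np.allclose(res.gebv.to_numpy(), [-0.5, 0.0, 0.5])

    def test_infinite_shrinkage_limit(self):
        ids = ["a", "b", "c"]
        grm = self.make_grm(np.eye(3), ids)
        recs = records_of(ids, [1.0, 2.0, 3.0])
        res = solve_gblup(grm, recs, ids, variance_ratio=1e9,
                          use_weights=False, jitter=0.0)
        assert np.abs(res.gebv.to_numpy()).max() < 1e-6
        assert res.mu_hat == pytest.approx(2.0, abs=1e-6)

    def test_constant_y_gives_zero_gebv(self, rng):
        ids = [f"s{i}" for i in range(5)]
        a = rng.normal(size=(5, 8))
        grm = self.make_grm(a @ a.T / 8 + np.eye(5), ids)
        recs = records_of(ids, [3.0] * 5)
        res = solve_gblup(grm, recs, ids, variance_ratio=2.0, jitter=0.0)
        assert np.abs(res.gebv.to_numpy()).max() < 1e-10

    @pytest.mark.parametrize("weights", ["standard", "as_printed"])
    def test_matches_variance_matrix_oracle(self, rng, weights):
        for n in (5, 20, 50):
            a = rng.normal(size=(n, 2 * n))
            gmat = a @ a.T / (2 * n) + 0.5 * np.eye(n)
            ids = [f"s{i}" for i in range(n)]
            grm = self.make_grm(gmat, ids)
            ref = ids[: max(3, n - 5)]
            rel = rng.uniform(0.2, 0.9, len(ref))
            y = rng.normal(size=len(ref))
            recs = records_of(ref, y, reliability=rel)
            lam = 1.7
            res = solve_gblup(grm, recs, ref, lam, weights=weights, jitter=0.0)
            r_diag = (1 - rel) / rel if weights == "standard" else rel / (1 - rel)
            mu, ghat = gblup_oracle(gmat, y, np.arange(len(ref)), lam, r_diag)
            assert res.mu_hat == pytest.approx(mu, abs=1e-8)
            assert np.abs(res.gebv.to_numpy() - ghat).max() < 1e-8

    def test_validation_animals_predicted_through_grm(self):
        # validation animal's GEBV follows its near-twin in the reference
        gmat = np.array(
            [
                [1.0, 0.0, 0.9, 0.0],
                [0.0, 1.0, 0.0, 0.0],
                [0.9, 0.0, 1.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        ids = ["ref1", "ref2", "val_twin", "val_stranger"]
        grm = self.make_grm(gmat, ids)
        recs = records_of(["ref1", "ref2"], [2.0, -2.0])
        res = solve_gblup(grm, recs, ["ref1", "ref2"], 1.0, use_weights=False, jitter=0.0)
        assert res.gebv["val_twin"] > 0.5 * res.gebv["ref1"] > 0
        assert res.gebv["val_stranger"] == pytest.approx(0.0, abs=1e-10)


class TestForwardSplit:
    def samples(self):
        return pd.DataFrame(
            {
                "sample_id": ["t1", "t2", "t3", "t4", "b1", "f1"],
                "birth_year": [2000, 2002, 2004, 2006, 2001, 2005],
                "breed": ["TG", "TG", "TG", "TG", "BS", "FV"],
                "sire_id": "0", "dam_id": "0", "sex": "M",
            }
        )

    def test_single_breed_split(self):
        ref, val = forward_split(self.samples(), 2003, "single", "TG")
        assert ref == ["t1", "t2"] and val == ["t3", "t4"]

    def test_across_breed_all_focal_validated(self):
        ref, val = forward_split(self.samples(), 2003, "across", "TG", ("BS", "FV"))
        assert set(val) == {"t1", "t2", "t3", "t4"}
        assert set(ref) == {"b1", "f1"}

    def test_multi_breed_reference_union(self):
        ref, val = forward_split(self.samples(), 2003, "multi", "TG", ("BS", "FV"))
        assert set(ref) == {"t1", "t2", "b1", "f1"} and val == ["t3", "t4"]

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            forward_split(self.samples(), 1990, "single", "TG")


class TestReliabilityFilter:
    def test_debv_boundaries(self):
        recs = records_of(["a", "b", "c"], [1, 2, 3],
                          reliability=[0.29, 0.30, 0.8], kind="debv")
        out = debv_reliability_filter(recs)
        assert list(out.table["sample_id"]) == ["b", "c"]

    def test_ebv_untouched(self):
        recs = records_of(["a", "b"], [1, 2], reliability=[0.05, 0.1], kind="ebv")
        assert len(debv_reliability_filter(recs).table) == 2


class TestAccuracy:
    def test_perfect_and_inverted(self):
        ids = ["a", "b", "c", "d"]
        recs = records_of(ids, [1.0, 2.0, 3.0, 4.0])
        gebv = pd.Series([1.0, 2.0, 3.0, 4.0], index=ids)
        assert accuracy(gebv, recs, ids) == pytest.approx(1.0)
        assert accuracy(-gebv, recs, ids) == pytest.approx(-1.0)

    def test_hand_vectors(self):
        ids = list("abcde")
        obs = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        pred = np.array([2.0, 2.5, 1.0, 4.0, 4.5])
        recs = records_of(ids, obs)
        gebv = pd.Series(pred, index=ids)
        assert accuracy(gebv, recs, ids) == pytest.approx(np.corrcoef(pred, obs)[0, 1])

    def test_invariance_to_affine_positive_rescale(self, rng):
        ids = [f"s{i}" for i in range(8)]
        obs = rng.normal(size=8)
        pred = rng.normal(size=8)
        gebv = pd.Series(pred, index=ids)
        base = accuracy(gebv, records_of(ids, obs), ids)
        shifted = accuracy(gebv, records_of(ids, 3.5 * obs + 11.0), ids)
        assert shifted == pytest.approx(base)

    def test_constant_vector_nan(self):
        ids = ["a", "b", "c"]
        recs = records_of(ids, [1.0, 1.0, 1.0])
        gebv = pd.Series([1.0, 2.0, 3.0], index=ids)
        assert np.isnan(accuracy(gebv, recs, ids))


def bootstrap_oracle(x, y, reps, seed):
    """Plain-loop reimplementation used as the independent resampling oracle."""
    rng = np.random.default_rng(seed)
    out = []
    n = len(x)
    while len(out) < reps:
        idx = rng.integers(0, n, n)
        xs, ys = x[idx], y[idx]
        if xs.std() == 0 or ys.std() == 0:
            continue
        out.append(np.corrcoef(xs, ys)[0, 1])
    return np.array(out)


class TestBootstrapAccuracy:
    def test_perfect_correlation_zero_se(self):
        x = np.arange(6, dtype=float)
        mean, se, lo, hi, _ = bootstrap_accuracy(x, 2 * x + 1, reps=200, seed=1)
        assert mean == pytest.approx(1.0) and se == pytest.approx(0.0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_single_rep_ci_collapses(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        mean, se, lo, hi, _ = bootstrap_accuracy(x, y, reps=1, seed=2)
        assert lo == pytest.approx(mean) and hi == pytest.approx(mean)

    def test_matches_independent_oracle(self, rng):
        x = rng.normal(size=10)
        y = 0.6 * x + rng.normal(scale=0.8, size=10)
        mean, se, lo, hi, _ = bootstrap_accuracy(x, y, reps=20_000, seed=3)
        oracle = bootstrap_oracle(x, y, 20_000, seed=99)
        assert abs(mean - oracle.mean()) < 0.01
        assert abs(se - oracle.std(ddof=1)) < 0.01


class TestParentAverage:
    def ped(self):
        return pd.DataFrame(
            {
                "sample_id": ["s", "d", "x", "y"],
                "sire_id": ["0", "0", "s", "s"],
                "dam_id": ["0", "0", "d", "0"],
                "birth_year": [1990, 1990, 2000, 2000],
                "breed": "TG", "sex": "U",
            }
        )

    def test_direct_formula(self):
        recs = records_of(["s", "d"], [10.0, 6.0])
        pa = parent_average(recs, self.ped(), ["x"])
        assert pa["x"] == pytest.approx(8.0)

    def test_unknown_dam_excluded(self):
        recs = records_of(["s", "d"], [10.0, 6.0])
        pa = parent_average(recs, self.ped(), ["x", "y"])
        assert list(pa.index) == ["x"]

    def test_gebv_equal_to_pa_gives_unit_correlation(self):
        ped = pd.DataFrame(
            {
                "sample_id": ["s1", "d1", "s2", "d2", "a", "b", "c"],
                "sire_id": ["0", "0", "0", "0", "s1", "s2", "s1"],
                "dam_id": ["0", "0", "0", "0", "d1", "d2", "d2"],
                "birth_year": [1990] * 4 + [2000] * 3,
                "breed": "TG", "sex": "U",
            }
        )
        recs = records_of(["s1", "d1", "s2", "d2"], [1.0, 3.0, -2.0, 4.0])
        pa = parent_average(recs, ped, ["a", "b", "c"])
        gebv = pd.Series(pa.to_numpy(), index=pa.index)
        assert parent_average_correlation(recs, ped, gebv, ["a", "b", "c"]) == pytest.approx(1.0)


class TestPcaGrm:
    def make_grm(self, gmat, n):
        from smallherd.gblup_prediction import GRM

        return GRM(values=gmat, sample_ids=[f"s{i}" for i in range(n)],
                   allele_frequencies=np.array([]))

    def test_identity_equal_explained_variance(self):
        coords, explained = pca_grm(self.make_grm(np.eye(5), 5), 2)
        assert np.allclose(explained, [0.2, 0.2])

    def test_two_block_structure_separated_by_pc1(self):
        block = np.ones((3, 3))
        gmat = np.block([[block, np.zeros((3, 3))], [np.zeros((3, 3)), block]])
        coords, explained = pca_grm(self.make_grm(gmat, 6), 2)
        pc1 = coords["pc1"].to_numpy()
        assert len({np.sign(v) for v in pc1[:3]}) == 1
        assert np.sign(pc1[0]) != np.sign(pc1[3])

    def test_components_orthogonal(self, rng):
        a = rng.normal(size=(10, 30))
        gmat = a @ a.T / 30
        coords, _ = pca_grm(self.make_grm(gmat, 10), 2)
        dot = coords["pc1"] @ coords["pc2"]
        assert abs(dot) < 1e-8
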