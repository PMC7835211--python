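import numpy as np
import pandas as pd
import pytest
from _oracles import bh_stepup_bruteforce, manova_pillai_p_reference
from conftest import random_de_table

from rankset import (
    GeneSetCollection,
    ValidationError,
    density_grid,
    enrich2d_all,
    join_contrasts,
    manova_rank_test,
    set_scores_2d,
)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(20)


@pytest.fixture(scope="module")
def joint_random(rng):
    de1 = random_de_table(rng, 400)
    de2 = random_de_table(rng, 400)
    return join_contrasts(de1, de2)


class TestJoinContrasts:
    def test_identity_diagonal(self, rng):
        de = random_de_table(rng, 50)
        joint = join_contrasts(de, de.copy())
        assert np.allclose(joint["r1"], joint["r2"])

    def test_negated_anti_diagonal(self, rng):
        de = random_de_table(rng, 51)
        flipped = de.assign(log2fc=-de["log2fc"])
        joint = join_contrasts(de, flipped)
        assert np.allclose(joint["r1"], -joint["r2"])

    def test_disjoint_universes_error(self, rng):
        de1 = random_de_table(rng, 30, prefix="A")
        de2 = random_de_table(rng, 30, prefix="B")
        with pytest.raises(ValidationError, match="universe"):
            join_contrasts(de1, de2)

    def test_swap_symmetry(self, rng):
        de1 = random_de_table(rng, 80)
        de2 = random_de_table(rng, 80)
        ab = join_contrasts(de1, de2).set_index("gene_id")
        ba = join_contrasts(de2, de1).set_index("gene_id")
        assert np.allclose(ab["r1"], ba.loc[ab.index, "r2"])
        assert np.allclose(ab["r2"], ba.loc[ab.index, "r1"])

    def test_duplicate_resolved_by_smallest_p(self, rng):
        de1 = random_de_table(rng, 30)
        dup = de1.iloc[[0]].assign(p=1e-9, log2fc=3.0)
        de1_dup = pd.concat([de1, dup], ignore_index=True)
        de2 = random_de_table(rng, 30)
        joint = join_contrasts(de1_dup, de2)
        assert len(joint) == 30
        top = joint.set_index("gene_id").loc[de1["gene_id"].iloc[0]]
        assert top["s1"] == joint["s1"].max()  # kept the p=1e-9 row

    def test_ranks_recomputed_within_universe(self, rng):
        de1 = random_de_table(rng, 100)
        de2 = random_de_table(rng, 100).iloc[:60].reset_index(drop=True)
        joint = join_contrasts(de1, de2)
        assert len(joint) == 60
        assert joint["r1"].sum() == pytest.approx(0.0, abs=1e-12)
        assert joint["r2"].sum() == pytest.approx(0.0, abs=1e-12)


class TestSetScores:
    def test_top_k_closed_form(self):
        # members occupy the top k ranks of dimension 1 (N=10, k=2) -> s1 = 0.8
        joint = pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(10)],
                "s1": np.arange(10, dtype=float),
                "s2": np.zeros(10),
                "r1": (np.arange(1, 11) - 5.5) / 10,
                "r2": np.zeros(10),
            }
        )
        s1, _, _ = set_scores_2d(joint, {"G8", "G9"})
        assert s1 == pytest.approx((10 - 2) / 10)

    def test_uniform_members_near_zero(self, joint_random, rng):
        members = rng.choice(joint_random["gene_id"], 100, replace=False)
        s1, s2, dist = set_scores_2d(joint_random, members)
        assert abs(s1) < 0.2 and abs(s2) < 0.2
        assert dist == pytest.approx(np.hypot(s1, s2))

    def test_bound(self, joint_random, rng):
        n = len(joint_random)
        for k in (5, 50):
            members = rng.choice(joint_random["gene_id"], k, replace=False)
            s1, s2, _ = set_scores_2d(joint_random, members)
            assert abs(s1) <= (n - k) / n + 1e-12
            assert abs(s2) <= (n - k) / n + 1e-12

    def test_too_few_members(self, joint_random):
        with pytest.raises(ValidationError):
            set_scores_2d(joint_random, [joint_random["gene_id"].iloc[0]])


class TestManovaRankTest:
    def test_equal_mean_vectors_gives_p_one(self):
        # antipodal member pair: member and rest mean rank vectors coincide
        r1 = np.array([-0.3, 0.3, -0.2, 0.2, -0.1, 0.1])
        r2 = np.array([-0.1, 0.1, 0.2, -0.2, -0.3, 0.3])
        joint = pd.DataFrame(
            {
                "gene_id": list("ABCDEF"),
                "s1": r1, "s2": r2, "r1": r1, "r2": r2,
            }
        )
        members = {"A", "B"}
        pillai, f_stat, dfs, p = manova_rank_test(joint, members)
        assert f_stat == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)
        assert pillai == pytest.approx(0.0, abs=1e-20)

    def test_uniform_membership_p_uniform(self, joint_random, rng):
        from scipy.stats import kstest

        ps = [
            manova_rank_test(
                joint_random, rng.choice(joint_random["gene_id"], 25, replace=False)
            )[3]
            for _ in range(500)
        ]
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_matches_reference_implementation(self, rng):
        # oracle comparison on small fixed tables, 6 significant figures
        for trial in range(30):
            de1 = random_de_table(rng, 30)
            de2 = random_de_table(rng, 30)
            joint = join_contrasts(de1, de2)
            k = int(rng.integers(3, 8))
            members = rng.choice(joint["gene_id"], k, replace=False)
            _, _, _, p = manova_rank_test(joint, members)
            p_ref = manova_pillai_p_reference(joint, members)
            assert p == pytest.approx(p_ref, rel=1e-6)

    def test_displaced_corner_set_significant(self, rng):
        de1 = random_de_table(rng, 30)
        de2 = random_de_table(rng, 30)
        joint = join_contrasts(de1, de2)
        corner = joint.sort_values("r1").tail(5)["gene_id"]
        _, _, _, p = manova_rank_test(joint, corner)
        assert p < 0.05

    def test_singular_covariance_names_dimension(self):
        n = 20
        joint = pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(n)],
                "s1": np.arange(n, dtype=float),
                "s2": np.zeros(n),
                "r1": (np.arange(1, n + 1) - (n + 1) / 2) / n,
                "r2": np.zeros(n),
            }
        )
        with pytest.raises(ValidationError, match="r2"):
            manova_rank_test(joint, {"G0", "G1", "G2"})

    def test_invariant_to_monotone_score_transform(self, rng):
        de1 = random_de_table(rng, 60)
        de2 = random_de_table(rng, 60)
        joint_a = join_contrasts(de1, de2)
        # squash p toward 1 monotonically: order, hence ranks, unchanged
        de1_t = de1.assign(p=de1["p"] ** 0.5)
        de2_t = de2.assign(p=de2["p"] ** 0.25)
        joint_b = join_contrasts(de1_t, de2_t)
        members = rng.choice(joint_a["gene_id"], 12, replace=False)
        assert manova_rank_test(joint_a, members)[3] == pytest.approx(
            manova_rank_test(joint_b, members)[3]
        )


class TestEnrich2dAll:
    def test_single_set_fdr_equals_p(self, joint_random, rng):
        members = rng.choice(joint_random["gene_id"], 30, replace=False)
        sets = GeneSetCollection.from_dict({"ONLY": members})
        result = enrich2d_all(joint_random, sets)
        assert len(result) == 1
        assert result["fdr"].iloc[0] == result["p"].iloc[0]

    def test_fdr_matches_bh_oracle(self, joint_random, rng):
        sets = GeneSetCollection.from_dict(
            {
                f"S{i}": rng.choice(joint_random["gene_id"], 20, replace=False)
                for i in range(40)
            }
        )
        result = enrich2d_all(joint_random, sets)
        assert np.allclose(result["fdr"], bh_stepup_bruteforce(result["p"].to_numpy()))

    def test_small_sets_skipped(self, joint_random, rng):
        sets = GeneSetCollection.from_dict(
            {
                "BIG": rng.choice(joint_random["gene_id"], 30, replace=False),
                "SMALL": rng.choice(joint_random["gene_id"], 4, replace=False),
            }
        )
        result = enrich2d_all(joint_random, sets, min_size=10)
        assert result["set_name"].tolist() == ["BIG"]

    def test_no_set_passes_raises(self, joint_random):
        sets = GeneSetCollection.from_dict({"TINY": joint_random["gene_id"].iloc[:3]})
        with pytest.raises(ValidationError):
            enrich2d_all(joint_random, sets, min_size=10)

    def test_sorted_by_p(self, joint_random, rng):
        sets = GeneSetCollection.from_dict(
            {
                f"S{i}": rng.choice(joint_random["gene_id"], 15, replace=False)
                for i in range(10)
            }
        )
        result = enrich2d_all(joint_random, sets)
        assert result["p"].is_monotonic_increasing

    def test_planted_geometry(self, planted_de_pair, planted_experiment):
        # glucose-up / drug-reversed sets: upper-left displacement, tiny fdr
        de1, de2 = planted_de_pair
        _, sets, truth = planted_experiment
        joint = join_contrasts(de1, de2)
        result = enrich2d_all(joint, sets).set_index("set_name")
        planted = truth.set_info.loc[~truth.set_info["is_null"], "set_name"]
        for name in planted:
            assert result.loc[name, "fdr"] <= 0.05
            assert result.loc[name, "s1"] > 0
            assert result.loc[name, "s2"] < 0


class TestDensityGrid:
    def test_single_cell_conservation(self, joint_random):
        grid = density_grid(joint_random, bins=1)
        assert grid.to_numpy().sum() == len(joint_random)
        assert grid.shape == (1, 1)

    def test_identity_contrasts_diagonal(self, rng):
        de = random_de_table(rng, 40)
        joint = join_contrasts(de, de.copy())
        grid = density_grid(joint, bins=2).to_numpy()
        assert grid[0, 1] == 0 and grid[1, 0] == 0
        assert grid.sum() == 40

    def test_conservation_any_bins(self, joint_random):
        for bins in (2, 7, 33):
            assert density_grid(joint_random, bins=bins).to_numpy().sum() == len(joint_random)

    def test_uniform_fill(self, rng):
        de1 = random_de_table(rng, 5000)
        de2 = random_de_table(rng, 5000)
        joint = join_contrasts(de1, de2)
        grid = density_grid(joint, bins=10).to_numpy()
        expected = len(joint) / 100
        # multinomial sd ~ sqrt(np(1-p)) ~ 7; allow 5 sd
        assert np.abs(grid - expected).max() < 5 * np.sqrt(expected)

    def test_swap_transposes(self, rng):
        de1 = random_de_table(rng, 200)
        de2 = random_de_table(rng, 200)
        g12 = density_grid(join_contrasts(de1, de2), bins=8).to_numpy()
        g21 = density_grid(join_contrasts(de2, de1), bins=8).to_numpy()
        assert np.array_equal(g12, g21.T)

    def test_bad_bins(self, joint_random):
        with pytest.raises(ValidationError):
            density_grid(joint_random, bins=0)
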