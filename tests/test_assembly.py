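import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from ecoassembly.assembly import (NullModelConfig, beta_mntd,
                                  beta_mntd_matrix, bnti, classify_pair,
                                  rc_bray, raup_crick_score,
                                  sample_null_communities,
                                  summarize_processes)
from ecoassembly.io import CommunityTable, Phylogeny
from ecoassembly.preprocess import to_relative


def rel_table(rows, taxa, samples=None):
    rows = np.asarray(rows, dtype=float)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    rows = rows / rows.sum(axis=1, keepdims=True)
    return CommunityTable(pd.DataFrame(rows, index=samples, columns=taxa),
                          kind="relative")


def brute_force_bmntd(x, y, dist, weighted=True):
    """Independent double-loop betaMNTD oracle."""
    def side(a, b):
        idx_a = np.flatnonzero(a > 0)
        idx_b = np.flatnonzero(b > 0)
        if weighted:
            w = a[idx_a] / a[idx_a].sum()
        else:
            w = np.full(idx_a.size, 1.0 / idx_a.size)
        total = 0.0
        for wi, i in zip(w, idx_a):
            total += wi * min(dist[i, j] for j in idx_b)
        return total
    return 0.5 * (side(x, y) + side(y, x))


class TestBetaMntd:
    def test_identical_communities_zero(self, five_taxon_tree):
        t = rel_table([[1, 2, 0, 3, 0], [1, 2, 0, 3, 0]], list("ABCDE"))
        assert beta_mntd(t, five_taxon_tree, ("s0", "s1")) == pytest.approx(0.0)

    def test_single_taxon_pair_is_patristic_distance(self, small_tree):
        t = rel_table([[1, 0, 0], [0, 1, 0]], list("ABC"))
        assert beta_mntd(t, small_tree, ("s0", "s1")) == pytest.approx(2.0)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_oracle(self, five_taxon_tree, weighted):
        rng = np.random.default_rng(8)
        dist = five_taxon_tree.patristic(list("ABCDE")).to_numpy()
        for _ in range(25):
            rows = rng.integers(0, 9, size=(2, 5)).astype(float)
            rows[rows.sum(axis=1) == 0, 0] = 1
            t = rel_table(rows, list("ABCDE"))
            got = beta_mntd(t, five_taxon_tree, ("s0", "s1"), weighted)
            want = brute_force_bmntd(t.matrix[0], t.matrix[1], dist, weighted)
            assert got == pytest.approx(want, abs=1e-12)

    def test_matches_picante_comdistnt(self, tmp_path):
        """Cross-check against the reference R implementation."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the picante cross-check")
        nwk = "((A:0.3,B:0.4):0.5,(C:0.2,(D:0.6,E:0.1):0.3):0.4);"
        (tmp_path / "t.nwk").write_text(nwk)
        rng = np.random.default_rng(5)
        mat = rng.integers(0, 20, size=(4, 5)).astype(float)
        mat[mat < 3] = 0
        mat[mat.sum(axis=1) == 0, 0] = 5
        df = pd.DataFrame(mat, index=[f"s{i}" for i in range(4)],
                          columns=list("ABCDE"))
        df.to_csv(tmp_path / "comm.csv")
        table = rel_table(mat, list("ABCDE"))
        ours = beta_mntd_matrix(table, Phylogeny(TreeNode.read([nwk])))
        script = f"""
        suppressMessages(library(picante))
        comm <- as.matrix(read.csv('{tmp_path}/comm.csv', row.names=1))
        tree <- read.tree('{tmp_path}/t.nwk')
        d <- comdistnt(comm, cophenetic(tree), abundance.weighted=TRUE)
        write.csv(as.matrix(d), '{tmp_path}/out.csv')
        """
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        theirs = pd.read_csv(tmp_path / "out.csv", index_col=0)
        assert np.allclose(ours.to_numpy(), theirs.to_numpy(), atol=1e-9)


class TestBnti:
    def test_star_tree_null_sd_zero_flagged(self):
        star = Phylogeny(TreeNode.read(["(A:1,B:1,C:1,D:1);"]))
        t = rel_table([[1, 1, 0, 0], [0, 0, 1, 1]], list("ABCD"))
        res = bnti(t, star, NullModelConfig(n_null=20, rng_seed=0))
        assert res.n_undefined_pairs == 1
        assert np.isnan(res.bnti.iloc[0, 1])

    def test_exhaustive_enumeration_matches_oracle(self, five_taxon_tree):
        """betaNTI z-score computed from all 5! tip relabelings equals an
        independently coded exhaustive enumeration to 1e-9."""
        taxa = list("ABCDE")
        t = rel_table([[3, 1, 0, 2, 0], [0, 2, 4, 0, 1]], taxa)
        dist = five_taxon_tree.patristic(taxa).to_numpy()
        perms = [np.array(p) for p in itertools.permutations(range(5))]
        res = bnti(t, five_taxon_tree, NullModelConfig(rng_seed=0),
                   permutations=perms)
        nulls = [brute_force_bmntd(t.matrix[0], t.matrix[1],
                                   dist[np.ix_(p, p)]) for p in perms]
        obs = brute_force_bmntd(t.matrix[0], t.matrix[1], dist)
        z_oracle = (obs - np.mean(nulls)) / np.std(nulls, ddof=1)
        assert res.bnti.iloc[0, 1] == pytest.approx(z_oracle, abs=1e-9)

    def test_invariant_to_joint_taxon_relabeling(self, five_taxon_tree):
        taxa = list("ABCDE")
        t = rel_table([[3, 1, 0, 2, 0], [0, 2, 4, 0, 1]], taxa)
        res1 = bnti(t, five_taxon_tree, NullModelConfig(n_null=50, rng_seed=4))
        # apply the same renaming to table columns and tree tips
        mapping = dict(zip(taxa, ["X1", "X2", "X3", "X4", "X5"]))
        renamed = CommunityTable(t.data.rename(columns=mapping),
                                 kind="relative")
        tree2 = Phylogeny(TreeNode.read([
            "((X1:0.3,X2:0.4):0.5,(X3:0.2,(X4:0.6,X5:0.1):0.3):0.4);"]))
        res2 = bnti(renamed, tree2, NullModelConfig(n_null=50, rng_seed=4))
        assert res1.beta_mntd_obs.iloc[0, 1] == pytest.approx(
            res2.beta_mntd_obs.iloc[0, 1], abs=1e-12)

    def test_doubling_counts_leaves_bmntd_unchanged(self, five_taxon_tree):
        rows = np.array([[3, 1, 0, 2, 0], [0, 2, 4, 0, 1]], dtype=float)
        a = beta_mntd(rel_table(rows, list("ABCDE")), five_taxon_tree,
                      ("s0", "s1"))
        b = beta_mntd(rel_table(2 * rows, list("ABCDE")), five_taxon_tree,
                      ("s0", "s1"))
        assert a == pytest.approx(b, abs=1e-12)


class TestRaupCrick:
    def test_obs_above_all_nulls_is_plus_one(self):
        assert raup_crick_score(0.9, np.full(99, 0.5)) == 1.0

    def test_obs_at_median_is_zero(self):
        nulls = np.concatenate([np.full(50, 0.2), np.full(50, 0.8)])
        assert raup_crick_score(0.5, nulls) == 0.0

    def test_ties_split(self):
        nulls = np.array([0.5] * 10)
        assert raup_crick_score(0.5, nulls) == 0.0

    def test_identical_samples_strongly_negative(self):
        """Two identical samples drawn from a diverse pool sit below any
        non-degenerate null draw."""
        rng = np.random.default_rng(0)
        pool = rng.dirichlet(np.ones(60) * 0.5)
        counts = rng.multinomial(1500, pool, size=10)
        counts[1] = counts[0]
        counts[counts.sum(axis=1) == 0, 0] = 1
        table = CommunityTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(10)],
                         columns=[f"t{j}" for j in range(60)]), kind="counts")
        rc = rc_bray(table, ("s0", "s1"),
                     NullModelConfig(n_null=999, rng_seed=1))
        assert rc < -0.95

    def test_rarefied_scale_invariance(self):
        """Scaling both samples' counts jointly leaves RCBray unchanged at a
        fixed seed in expectation terms: richness and relative structure are
        preserved."""
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 30, size=(6, 25))
        counts[counts.sum(axis=1) == 0, 0] = 1
        t1 = CommunityTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(6)],
                         columns=[f"t{j}" for j in range(25)]), kind="counts")
        t2 = CommunityTable(t1.data * 2, kind="counts")
        cfg = NullModelConfig(n_null=499, rng_seed=3)
        rc1 = rc_bray(t1, ("s0", "s1"), cfg)
        rc2 = rc_bray(t2, ("s0", "s1"), cfg)
        assert abs(rc1 - rc2) < 0.15

    def test_richness_exceeding_pool_is_error(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            sample_null_communities(rng, 5, richness=10, total=50,
                                    occ_weights=np.array([1.0, 1.0, 0.0]),
                                    ab_weights=np.array([0.5, 0.5, 0.0]))


class TestClassifyPair:
    @pytest.mark.parametrize("z,rc,expected", [
        (-2.5, None, "homogeneous_selection"),
        (2.5, None, "heterogeneous_selection"),
        (1.0, 0.2, "undominated"),
        (0.0, 0.96, "dispersal_limitation"),
        (0.0, -0.96, "homogenizing_dispersal"),
        # boundary values fall through to the weaker call
        (-2.0, 0.0, "undominated"),
        (2.0, 0.0, "undominated"),
        (0.0, 0.95, "undominated"),
        (0.0, -0.95, "undominated"),
    ])
    def test_threshold_rules(self, z, rc, expected):
        assert classify_pair(z, rc) == expected

    def test_rc_required_inside_selection_band(self):
        with pytest.raises(ValueError):
            classify_pair(1.0, None)

    def test_outputs_partition_the_plane(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            z = rng.uniform(-4, 4)
            rc = rng.uniform(-1, 1)
            label = classify_pair(z, rc)
            assert label in {"homogeneous_selection",
                             "heterogeneous_selection",
                             "dispersal_limitation",
                             "homogenizing_dispersal", "undominated"}


class TestSummarize:
    def make_pairs(self, labels):
        return pd.DataFrame({
            "sample_i": [f"a{i}" for i in range(len(labels))],
            "sample_j": [f"b{i}" for i in range(len(labels))],
            "beta_mntd_obs": 0.0, "bnti": 0.0, "rc_bray": 0.0,
            "process": labels,
        })

    def test_single_process_is_hundred_percent(self):
        s = summarize_processes(self.make_pairs(["homogeneous_selection"] * 4))
        assert s.iloc[0]["homogeneous_selection"] == 100.0
        assert s.iloc[0]["undominated"] == 0.0

    def test_two_one_split(self):
        s = summarize_processes(self.make_pairs(
            ["undominated", "undominated", "dispersal_limitation"]))
        assert s.iloc[0]["undominated"] == pytest.approx(66.6667, abs=0.01)
        assert s.iloc[0]["dispersal_limitation"] == pytest.approx(33.3333,
                                                                  abs=0.01)

    def test_undefined_excluded_from_denominator(self):
        s = summarize_processes(self.make_pairs(
            ["undominated", "undefined", "undefined"]))
        assert s.iloc[0]["undominated"] == 100.0
        assert s.iloc[0]["n_undefined"] == 2
        assert s.iloc[0]["n_pairs"] == 1

    def test_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(1)
        from ecoassembly.assembly import PROCESSES
        labels = rng.choice(PROCESSES, size=40).tolist()
        s = summarize_processes(self.make_pairs(labels))
        total = sum(s.iloc[0][p] for p in PROCESSES)
        assert total == pytest.approx(100.0, abs=0.01)
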