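import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova

from ecoassembly.multivariate import (bh_adjust, distance_decay,
                                      distlm_forward, mantel, permanova,
                                      procrustes_test)


def dm_from_points(pts, ids=None):
    ids = ids or [str(i) for i in range(len(pts))]
    return DistanceMatrix(squareform(pdist(pts)), ids=ids)


class TestPermanova:
    def test_separated_clusters_maximal_r2(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 1e-6, (5, 2)),
                         rng.normal(100, 1e-6, (5, 2))])
        dm = dm_from_points(pts)
        meta = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5}, index=dm.ids)
        res = permanova(dm, meta, ["g"], n_perm=199, seed=1)
        row = res[res.term == "g"].iloc[0]
        assert row.R2 > 0.999
        # permutations reproducing the exact split tie with F_obs, so the
        # p-value floor is the number of equivalent relabelings over m+1
        assert row.p <= 0.02

    def test_r2_decomposition_sums_to_one(self):
        rng = np.random.default_rng(1)
        dm = dm_from_points(rng.normal(size=(12, 4)))
        meta = pd.DataFrame({
            "g": list("aabbcc") * 2,
            "h": ["x"] * 6 + ["y"] * 6,
        }, index=dm.ids)
        res = permanova(dm, meta, ["h", "g"], n_perm=99, seed=2)
        assert res.R2[:-1].sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_exhaustive_split_enumeration(self):
        """n=6, two groups of 3: p equals the exact proportion over all 20
        distinct splits, F computed by an independent group-sum formula."""
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 3))
        dm = dm_from_points(pts)
        meta = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3}, index=dm.ids)
        res = permanova(dm, meta, ["g"], exhaustive=True)

        d2 = dm.data ** 2
        ss_tot = d2.sum() / (2 * 6)

        def f_stat(labels):
            ssw = sum(d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
                      for idx in (
                          [i for i, l in enumerate(labels) if l == "a"],
                          [i for i, l in enumerate(labels) if l == "b"]))
            return (ss_tot - ssw) / (ssw / 4)

        obs = f_stat("aaabbb")
        fs = [f_stat(["a" if i in c else "b" for i in range(6)])
              for c in itertools.combinations(range(6), 3)]
        p_oracle = np.mean([f >= obs - 1e-12 for f in fs])
        row = res[res.term == "g"].iloc[0]
        assert row.F == pytest.approx(obs, abs=1e-9)
        assert row.p == pytest.approx(p_oracle, abs=1e-12)

    def test_one_way_f_matches_skbio(self):
        rng = np.random.default_rng(4)
        dm = dm_from_points(rng.normal(size=(10, 3)))
        meta = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5}, index=dm.ids)
        ours = permanova(dm, meta, ["g"], n_perm=99, seed=0)
        theirs = skbio_permanova(dm, meta, column="g", permutations=99)
        assert ours[ours.term == "g"].F.iloc[0] == pytest.approx(
            theirs["test statistic"], abs=1e-9)

    def test_joint_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 3))
        labels = ["a", "b"] * 4
        dm = dm_from_points(pts)
        meta = pd.DataFrame({"g": labels}, index=dm.ids)
        res1 = permanova(dm, meta, ["g"], n_perm=49, seed=1)
        perm = rng.permutation(8)
        dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)],
                             ids=[dm.ids[i] for i in perm])
        res2 = permanova(dm2, meta, ["g"], n_perm=49, seed=1)
        assert res1[res1.term == "g"].F.iloc[0] == pytest.approx(
            res2[res2.term == "g"].F.iloc[0], abs=1e-9)

    def test_single_level_term_rejected(self):
        rng = np.random.default_rng(6)
        dm = dm_from_points(rng.normal(size=(4, 2)))
        meta = pd.DataFrame({"g": ["a"] * 4}, index=dm.ids)
        with pytest.raises(ValueError):
            permanova(dm, meta, ["g"])


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        dm = dm_from_points(rng.normal(size=(8, 2)))
        assert mantel(dm, dm, n_perm=49, seed=0).r == pytest.approx(1.0)

    def test_affine_transform_r_one(self):
        rng = np.random.default_rng(1)
        a = squareform(pdist(rng.normal(size=(8, 2))))
        b = 3.0 * a + 0.5
        np.fill_diagonal(b, 0.0)
        ids = [str(i) for i in range(8)]
        res = mantel(DistanceMatrix(a, ids=ids), DistanceMatrix(b, ids=ids),
                     n_perm=49, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        """n=5: permutation p equals exact enumeration over all 120
        relabelings of the second matrix."""
        rng = np.random.default_rng(2)
        a = squareform(pdist(rng.normal(size=(5, 2))))
        b = squareform(pdist(rng.normal(size=(5, 2))))
        ids = list("abcde")
        res = mantel(DistanceMatrix(a, ids=ids), DistanceMatrix(b, ids=ids),
                     exhaustive=True)
        va = squareform(a, checks=False)
        r_obs = np.corrcoef(va, squareform(b, checks=False))[0, 1]
        rs = [np.corrcoef(va, squareform(b[np.ix_(p, p)], checks=False))[0, 1]
              for p in itertools.permutations(range(5))]
        p_oracle = np.mean([r >= r_obs - 1e-12 for r in rs])
        assert res.r == pytest.approx(r_obs, abs=1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_r_matches_skbio(self):
        rng = np.random.default_rng(3)
        a = dm_from_points(rng.normal(size=(9, 2)))
        b = dm_from_points(rng.normal(size=(9, 2)))
        ours = mantel(a, b, n_perm=99, seed=0)
        r_skbio, _, _ = skbio_mantel(a, b, permutations=99,
                                     alternative="greater")
        assert ours.r == pytest.approx(r_skbio, abs=1e-12)

    def test_constant_matrix_rejected(self):
        ids = list("abc")
        const = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]],
                                        dtype=float), ids=ids)
        other = dm_from_points(np.random.default_rng(0).normal(size=(3, 2)),
                               ids=ids)
        with pytest.raises(ValueError):
            mantel(const, other)


class TestDistanceDecay:
    def test_perfect_linear_decay_r_minus_one(self):
        x = np.arange(6, dtype=float)[:, None]
        geo = dm_from_points(x)
        # dissimilarity grows linearly with distance -> similarity decays
        diss = DistanceMatrix(geo.data / geo.data.max(), ids=geo.ids)
        res = distance_decay(diss, geo, n_perm=99, seed=0)
        assert res.r == pytest.approx(-1.0)
        assert res.slope < 0

    def test_shuffled_distances_not_significant(self):
        rng = np.random.default_rng(1)
        sim_pts = rng.normal(size=(12, 5))
        geo_pts = rng.normal(size=(12, 2))
        res = distance_decay(dm_from_points(sim_pts),
                             dm_from_points(geo_pts), n_perm=199, seed=2)
        assert abs(res.r) < 0.5

    def test_dispersal_limited_communities_decay(self):
        """The dispersal-limitation scenario shows a significant negative
        distance-decay of similarity."""
        from ecoassembly.diversity import bray_curtis, euclidean
        from ecoassembly.io import align_inputs
        from ecoassembly.preprocess import css_normalize, filter_low_depth
        from ecoassembly.simulate import ScenarioConfig, assemble_communities

        ds = assemble_communities(ScenarioConfig(
            scenario="dispersal_limitation", n_taxa=400, rng_seed=11))
        tab, _, frame = align_inputs(ds.table, None, ds.frame)
        css = css_normalize(filter_low_depth(tab, 1000))
        bc = bray_curtis(css)
        geo = euclidean(frame.data.loc[css.sample_ids, ["x", "y"]])
        res = distance_decay(bc, geo, n_perm=999, seed=3)
        assert res.slope < 0
        assert res.p < 0.01


class TestProcrustes:
    def test_rotation_and_reflection_perfect_fit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        y = (x @ rot) * 3.0 + 5.0
        y[:, 0] *= -1  # reflection
        res = procrustes_test(x, y, n_perm=99, seed=1)
        assert res.m12_squared == pytest.approx(0.0, abs=1e-12)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_independent_configurations_weak(self):
        rng = np.random.default_rng(1)
        res = procrustes_test(rng.normal(size=(20, 2)),
                              rng.normal(size=(20, 2)), n_perm=199, seed=2)
        assert res.r < 0.6
        assert res.p > 0.01

    def test_matches_rotation_grid_oracle(self):
        """2-D residual matches brute-force minimization over rotation
        angles (with optimal scaling) to 1e-6."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 2))
        y = rng.normal(size=(4, 2))
        res = procrustes_test(x, y, n_perm=19, seed=0)

        def center_norm(a):
            a = a - a.mean(axis=0)
            return a / np.linalg.norm(a)

        xc, yc = center_norm(x), center_norm(y)
        best = np.inf
        for theta in np.linspace(0, 2 * np.pi, 200001):
            for refl in (1, -1):
                rot = np.array([
                    [np.cos(theta), -np.sin(theta) * refl],
                    [np.sin(theta), np.cos(theta) * refl]])
                yr = yc @ rot
                scale = np.sum(xc * yr)  # optimal scaling for unit-norm configs
                best = min(best, np.sum((xc - scale * yr) ** 2))
        assert res.m12_squared == pytest.approx(best, abs=1e-6)


class TestDistlm:
    def test_axis_aligned_variable_selected_first(self):
        from ecoassembly.diversity import pcoa
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 3)) * np.array([4.0, 1.0, 0.5])
        dm = dm_from_points(pts)
        ord_ = pcoa(dm)
        chem = pd.DataFrame({
            "axis1_like": ord_.samples["PC1"],
            "noise": rng.normal(size=20),
        }, index=list(dm.ids))
        res = distlm_forward(dm, chem, n_perm=199, seed=1)
        assert res.selected.iloc[0].variable == "axis1_like"
        share = ord_.proportion_explained[0]
        assert res.selected.iloc[0].added_R2 == pytest.approx(share, abs=0.1)
        assert res.marginal.set_index("variable").R2["axis1_like"] > \
            res.marginal.set_index("variable").R2["noise"]

    def test_pure_noise_rarely_selected(self):
        rng = np.random.default_rng(1)
        picks = 0
        for rep in range(20):
            dm = dm_from_points(rng.normal(size=(15, 4)))
            chem = pd.DataFrame(rng.normal(size=(15, 3)),
                                index=list(dm.ids), columns=list("abc"))
            res = distlm_forward(dm, chem, n_perm=99, alpha=0.05, seed=rep)
            picks += len(res.selected) > 0
        assert picks <= 5  # ~alpha-level selection under the null

    def test_no_variables_is_error(self):
        rng = np.random.default_rng(2)
        dm = dm_from_points(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            distlm_forward(dm, pd.DataFrame(index=list(dm.ids)))


def test_bh_adjustment_monotone():
    ps = np.array([0.001, 0.01, 0.02, 0.8])
    adj = bh_adjust(ps)
    assert (np.diff(adj) >= -1e-12).all()
    assert (adj >= ps - 1e-12).all()
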