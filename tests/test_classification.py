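import itertools

import numpy as np
import pandas as pd
import pytest

import stresskit as sk
from stresskit.data_model import INDEX_COLUMNS


def _index_table_from_matrix(values: dict[str, list[float]], genotypes) -> sk.IndexTable:
    """Hand-built IndexTable; unspecified columns filled with a ramp so
    standardization never sees a constant column."""
    n = len(genotypes)
    df = pd.DataFrame({"genotype": genotypes})
    for col in INDEX_COLUMNS:
        df[col] = values.get(col, np.linspace(1.0, 2.0, n))
    return sk.IndexTable(df, si=0.5)


class TestStandardize:
    def test_zscores_definitional(self, heat_indices):
        z = sk.standardize(heat_indices)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_two_observations_closed_form(self):
        """With n = 2 and the n−1 denominator every column standardizes to
        ±√2/2."""
        z = sk.standardize(pd.DataFrame({"a": [1.0, 3.0], "b": [10.0, -2.0]}))
        np.testing.assert_allclose(np.abs(z.to_numpy()), np.sqrt(2) / 2, atol=1e-12)

    def test_constant_column_error_names_column(self):
        with pytest.raises(sk.ValidationError, match="b"):
            sk.standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]}))


class TestPCA:
    def test_rank_one_limit(self):
        """Two perfectly correlated columns: eigenvalues (2, 0), variance
        split (100%, 0%)."""
        x = np.array([1.0, 2.0, 3.0, 5.0])
        z = sk.standardize(pd.DataFrame({"u": x, "v": 3.0 * x + 1.0}))
        pca = sk.pca_indices(z)
        np.testing.assert_allclose(pca.eigenvalues, [2.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(pca.variance_explained, [100.0, 0.0], atol=1e-10)

    def test_contributions_sum_to_100_eigenvalues_to_p(self, heat_indices):
        pca = sk.pca_indices(sk.standardize(heat_indices))
        np.testing.assert_allclose(pca.contributions.sum(axis=0), 100.0, atol=1e-6)
        assert pca.eigenvalues.sum() == pytest.approx(9.0, abs=1e-9)

    def test_characteristic_polynomial_oracle(self):
        """Eigenvalues of a 3-variable correlation matrix match the roots of
        its hand-expanded characteristic polynomial to 1e-9."""
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        df["b"] += 0.6 * df["a"]
        df["c"] -= 0.3 * df["a"]
        z = sk.standardize(df)
        pca = sk.pca_indices(z)
        C = np.corrcoef(z.to_numpy(), rowvar=False)
        # det(C − λI) = −λ³ + tr(C)λ² − M₂λ + det(C), M₂ = sum of 2x2 principal minors
        m2 = sum(
            C[i, i] * C[j, j] - C[i, j] * C[j, i]
            for i, j in itertools.combinations(range(3), 2)
        )
        roots = np.roots([-1.0, np.trace(C), -m2, np.linalg.det(C)])
        np.testing.assert_allclose(np.sort(roots.real)[::-1], pca.eigenvalues, atol=1e-9)

    def test_sign_convention_first_column_nonneg(self, heat_indices):
        pca = sk.pca_indices(sk.standardize(heat_indices))
        assert (pca.loadings.loc["Ys"] >= 0).all()

    def test_nonfinite_rejected(self):
        z = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(sk.ValidationError):
            sk.pca_indices(z)


def _brute_force_ward(points: np.ndarray):
    """Exhaustive minimum-variance agglomeration on raw points.

    At each step merge the pair whose union minimizes the increase in
    total within-cluster sum of squares; report heights on the same
    scale as the linkage matrix (√(2·ΔSS)) plus the partition sequence.
    """
    clusters = [[i] for i in range(len(points))]
    heights, partitions = [], []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = points[clusters[a]], points[clusters[b]]
            na, nb = len(ca), len(cb)
            delta = (na * nb / (na + nb)) * np.sum((ca.mean(0) - cb.mean(0)) ** 2)
            if best is None or delta < best[0] - 1e-12:
                best = (delta, a, b)
        delta, a, b = best
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
        heights.append(np.sqrt(2.0 * delta))
        partitions.append(frozenset(frozenset(c) for c in clusters))
    return heights, partitions


def _linkage_partitions(linkage: np.ndarray, n: int):
    """Partition sequence implied by a linkage matrix."""
    clusters = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, _, _) in enumerate(linkage):
        clusters[n + step] = clusters.pop(int(a)) | clusters.pop(int(b))
        out.append(frozenset(clusters.values()))
    return out


class TestWardCluster:
    def test_zero_noise_blobs_recover_planted_partition(self):
        cfg = sk.ClusterSimConfig(
            group_sizes=(4, 3, 5, 2),
            mean_ysi=(0.6, 0.8, 0.3, 0.1),
            mean_yp=(250.0, 150.0, 320.0, 200.0),
            sd_yp_within=0.0, sd_ysi_within=0.0, seed=0,
        )
        pairs = sk.simulate_yield_pairs(cfg)
        # zero-noise duplicates make index columns piecewise constant but
        # non-degenerate across groups
        z = sk.standardize(sk.compute_indices(pairs))
        result = sk.ward_cluster(z, k=4)
        truth = pairs.data.set_index("genotype")["true_group"]
        mapping = pd.crosstab(truth[result.assignment.index], result.assignment)
        assert (mapping.gt(0).sum(axis=1) == 1).all()

    def test_five_point_exhaustive_oracle(self):
        """Merge history on 5 points equals exhaustive minimum-variance
        agglomeration: same partitions, same heights."""
        rng = np.random.default_rng(23)
        pts = rng.normal(size=(5, 3))
        z = pd.DataFrame(pts, index=[f"g{i}" for i in range(5)])
        result = sk.ward_cluster(z, k=2)
        heights, partitions = _brute_force_ward(pts)
        np.testing.assert_allclose(result.merge_history[:, 2], heights, rtol=1e-9)
        assert _linkage_partitions(result.merge_history, 5) == partitions

    def test_duplicating_points_preserves_structure(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(8, 2)) * 3
        z1 = pd.DataFrame(base, index=[f"g{i}" for i in range(8)])
        dup = np.repeat(base, 2, axis=0)
        z2 = pd.DataFrame(dup, index=[f"g{i}_{j}" for i in range(8) for j in (0, 1)])
        c1 = sk.ward_cluster(z1, k=3)
        c2 = sk.ward_cluster(z2, k=3)
        # duplicated twins always land together, and the induced partition
        # of originals matches
        for i in range(8):
            assert c2.assignment[f"g{i}_0"] == c2.assignment[f"g{i}_1"]
        induced = pd.Series({f"g{i}": c2.assignment[f"g{i}_0"] for i in range(8)})
        assert (pd.crosstab(c1.assignment, induced).gt(0).sum(axis=1) == 1).all()
        assert sorted(c2.cluster_sizes) == sorted(2 * n for n in c1.cluster_sizes)

    def test_merge_heights_nondecreasing(self, heat_indices):
        z = sk.standardize(heat_indices)
        h = sk.ward_cluster(z, k=4).merge_history[:, 2]
        assert (np.diff(h) >= -1e-12).all()

    def test_bad_k_rejected(self, heat_indices):
        z = sk.standardize(heat_indices)
        with pytest.raises(sk.ValidationError):
            sk.ward_cluster(z, k=0)
        with pytest.raises(sk.ValidationError):
            sk.ward_cluster(z, k=len(z))

    def test_newick_export_contains_all_leaves(self, heat_indices):
        z = sk.standardize(heat_indices)
        nwk = sk.dendrogram_newick(sk.ward_cluster(z, k=4))
        assert nwk.endswith(";")
        for g in z.index:
            assert g in nwk


class TestLabelClusters:
    def _clusters(self, assignment: dict[str, int]) -> sk.ClusterResult:
        return sk.ClusterResult(
            assignment=pd.Series(assignment), merge_history=np.empty((0, 4))
        )

    def test_rule_on_constructed_extremes(self):
        """Clusters built to order as (GMP: A max; SSI: B max; YSI: C > D)
        get labels (A tolerant, B susceptible, C moderately tolerant,
        D moderately susceptible)."""
        genotypes = list("abcdefgh")
        assignment = {g: i // 2 + 1 for i, g in enumerate(genotypes)}  # A=1..D=4
        idx = _index_table_from_matrix(
            {
                "GMP": [200, 201, 120, 119, 150, 151, 149, 150],
                "SSI": [0.3, 0.31, 1.8, 1.81, 0.9, 0.91, 1.2, 1.19],
                "YSI": [0.8, 0.79, 0.1, 0.11, 0.55, 0.54, 0.35, 0.36],
            },
            genotypes,
        )
        labelled = sk.label_clusters(self._clusters(assignment), idx)
        assert labelled.labels == {
            1: "tolerant",
            2: "susceptible",
            3: "moderately_tolerant",
            4: "moderately_susceptible",
        }

    def test_tie_in_ranking_statistic_rejected(self):
        genotypes = list("abcdefgh")
        assignment = {g: i // 2 + 1 for i, g in enumerate(genotypes)}
        idx = _index_table_from_matrix(
            {"GMP": [100, 102, 100, 102, 50, 51, 40, 41]}, genotypes
        )
        with pytest.raises(sk.ValidationError, match="tie"):
            sk.label_clusters(self._clusters(assignment), idx)

    def test_wrong_k_rejected(self, heat_indices):
        z = sk.standardize(heat_indices)
        three = sk.ward_cluster(z, k=3)
        with pytest.raises(sk.ValidationError, match="4"):
            sk.label_clusters(three, heat_indices)

    @pytest.mark.parametrize(
        "preset,expected_tolerant",
        [("paper_heat_clusters", 11), ("paper_sni_clusters", 22)],
    )
    def test_planted_tolerant_group_recovered(self, preset, expected_tolerant):
        pairs = sk.simulate_preset(preset, seed=7)
        idx = sk.compute_indices(pairs)
        labelled = sk.label_clusters(sk.ward_cluster(sk.standardize(idx), 4), idx)
        tolerant = [c for c, l in labelled.labels.items() if l == "tolerant"][0]
        assert int((labelled.assignment == tolerant).sum()) == expected_tolerant


class TestClusterProfile:
    def _labelled_from_preset(self, seed=7):
        pairs = sk.simulate_preset("paper_heat_clusters", seed=seed)
        idx = sk.compute_indices(pairs)
        return pairs, sk.label_clusters(sk.ward_cluster(sk.standardize(idx), 4), idx)

    def _trial_for(self, genotypes, value_fn, trait="PH", env="SI"):
        rows = [
            {"genotype": g, "environment": env, "replicate": r, "trait": trait,
             "value": value_fn(g, r)}
            for g in genotypes for r in (1, 2)
        ]
        return sk.TrialTable(pd.DataFrame(rows))

    def test_constant_trait_single_letter(self):
        pairs, labelled = self._labelled_from_preset()
        trial = self._trial_for(pairs.data["genotype"], lambda g, r: 30.0)
        profile = sk.cluster_profile(labelled, trial, ["PH"], "SI")
        assert (profile.means["PH"] == 30.0).all()
        assert set(profile.letters["PH"]) == {"a"}

    def test_zero_noise_planted_means_exact(self):
        pairs, labelled = self._labelled_from_preset()
        truth = pairs.data.set_index("genotype")["true_group"]
        trial = self._trial_for(pairs.data["genotype"], lambda g, r: 10.0 * truth[g])
        profile = sk.cluster_profile(labelled, trial, ["PH"], "SI")
        # recovered clusters coincide with planted groups at this seed, so
        # cluster means are exactly the planted 10·group values
        label_of_group = {}
        for g in truth.index:
            label_of_group.setdefault(truth[g], labelled.label_of(g))
        for grp, label in label_of_group.items():
            assert profile.means.loc[label, "PH"] == pytest.approx(10.0 * grp, abs=1e-12)

    def test_hand_built_means_match_direct_averaging(self):
        genotypes = [f"g{i}" for i in range(8)]
        assignment = pd.Series({g: i // 2 + 1 for i, g in enumerate(genotypes)})
        labelled = sk.ClusterResult(
            assignment=assignment,
            merge_history=np.empty((0, 4)),
            labels={1: "tolerant", 2: "moderately_tolerant",
                    3: "moderately_susceptible", 4: "susceptible"},
        )
        rng = np.random.default_rng(3)
        vals = {(g, r): rng.uniform(20, 40) for g in genotypes for r in (1, 2)}
        trial = self._trial_for(genotypes, lambda g, r: vals[(g, r)])
        profile = sk.cluster_profile(labelled, trial, ["PH"], "SI")
        geno_means = {g: (vals[(g, 1)] + vals[(g, 2)]) / 2 for g in genotypes}
        for cid, label in labelled.labels.items():
            members = [g for g in genotypes if assignment[g] == cid]
            expected = np.mean([geno_means[g] for g in members])
            assert profile.means.loc[label, "PH"] == pytest.approx(expected, rel=1e-12)

    def test_missing_trait_lists_available(self):
        pairs, labelled = self._labelled_from_preset()
        trial = self._trial_for(pairs.data["genotype"], lambda g, r: 1.0)
        with pytest.raises(sk.ValidationError, match="PH"):
            sk.cluster_profile(labelled, trial, ["GY"], "SI")
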