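import numpy as np
import pandas as pd
import pytest

from phagetx.community_metrics import (alpha_diversity, alpha_model, bin_by_annotation,
                                       bray_curtis, dispersion_distances, jaccard_distance,
                                       pcoa, permanova, permdisp)
from phagetx.core_io import CountMatrix, DistanceMatrix, ValidationError, to_presence


def _cm(arr, prefix="f"):
    arr = np.asarray(arr)
    return CountMatrix([f"{prefix}{i}" for i in range(arr.shape[0])],
                       [f"s{j}" for j in range(arr.shape[1])], arr)


class TestAlphaDiversity:
    @pytest.mark.parametrize("column, richness, shannon", [
        ([10, 10, 10, 10], 4, np.log(4)),
        ([100], 1, 0.0),
        ([1, 2, 3, 4], 3, 1.2799),   # counts below min_reads still enter Shannon
    ])
    def test_hand_computed_values(self, column, richness, shannon):
        cm = _cm(np.array(column)[:, None])
        rec = alpha_diversity(cm, min_reads=2).iloc[0]
        assert rec["richness"] == richness
        assert rec["shannon"] == pytest.approx(shannon, abs=1e-4)

    def test_zero_total_sample_flagged_not_fatal(self):
        cm = _cm([[0, 5], [0, 5]])
        with pytest.warns(UserWarning, match="zero-total"):
            out = alpha_diversity(cm, 1)
        assert out.iloc[0]["richness"] == 0 and out.iloc[0]["shannon"] == 0

    def test_shannon_bounded_by_log_richness(self, small_study):
        div = alpha_diversity(small_study["phage_counts"], min_reads=1)
        ok = div["richness"] > 0
        assert (div.loc[ok, "shannon"] <= np.log(div.loc[ok, "richness"]) + 1e-9).all()


class TestDissimilarities:
    def test_bray_curtis_hand_case(self):
        cm = _cm([[2, 1], [2, 1], [0, 2]])
        d = bray_curtis(cm)
        assert d.values[0, 1] == pytest.approx(0.5)
        assert d.metric == "bray_curtis"

    def test_bray_curtis_identical_and_disjoint(self):
        ident = bray_curtis(_cm([[3, 6], [5, 10]]))
        assert ident.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        disjoint = bray_curtis(_cm([[4, 0], [0, 7]]))
        assert disjoint.values[0, 1] == pytest.approx(1.0)

    def test_jaccard_hand_case(self):
        pres = to_presence(_cm([[1, 0], [1, 1], [1, 1], [0, 1]]), 1)
        d = jaccard_distance(pres)
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_jaccard_matches_set_oracle(self, small_study):
        pres = to_presence(small_study["phage_counts"], 2)
        d = jaccard_distance(pres)
        rng = np.random.default_rng(0)
        n = len(pres.sample_ids)
        for i, j in zip(rng.integers(0, n, 50), rng.integers(0, n, 50)):
            a = {f for f, p in zip(pres.feature_ids, pres.present[:, i]) if p}
            b = {f for f, p in zip(pres.feature_ids, pres.present[:, j]) if p}
            expect = 0.0 if not (a | b) else 1 - len(a & b) / len(a | b)
            assert d.values[i, j] == pytest.approx(expect, abs=1e-12)

    def test_distance_invariants_on_synthetic(self, small_study):
        ph = small_study["phage_counts"]
        for d in (bray_curtis(ph), jaccard_distance(to_presence(ph, 2))):
            assert np.allclose(d.values, d.values.T)
            assert np.all(np.diag(d.values) == 0)
            assert d.values.min() >= 0 and d.values.max() <= 1


class TestBinByAnnotation:
    def test_bins_sum_and_conserve_totals(self, toy_counts):
        binned = bin_by_annotation(toy_counts, "host_family")
        assert set(binned.feature_ids) == {"Lachnospiraceae", "unassigned"}
        np.testing.assert_array_equal(binned.counts.sum(axis=0),
                                      toy_counts.counts.sum(axis=0))
        lach = toy_counts.counts[::2].sum(axis=0)   # annotated rows alternate
        np.testing.assert_array_equal(
            binned.counts[binned.feature_ids.index("Lachnospiraceae")], lach)

    def test_requires_annotations(self):
        with pytest.raises(ValidationError):
            bin_by_annotation(_cm([[1]]), "host_family")


class TestPCoA:
    def test_reconstructs_euclidean_configuration(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 2))
        from scipy.spatial.distance import pdist, squareform
        dmat = squareform(pdist(pts))
        d = DistanceMatrix([f"s{i}" for i in range(12)], dmat / dmat.max(), "bray_curtis")
        res = pcoa(d)
        rec = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(rec, d.values, atol=1e-8)

    def test_one_dimensional_input_yields_one_axis(self):
        x = np.array([0.0, 0.3, 0.7, 1.0])
        dmat = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(list("abcd"), dmat, "bray_curtis"))
        assert res.coordinates.shape[1] == 1
        assert (res.all_eigenvalues > 1e-10).sum() == 1

    def test_duplicated_sample_coincides(self):
        dmat = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        res = pcoa(DistanceMatrix(list("abc"), dmat, "bray_curtis"))
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_matches_reference_implementation(self, small_study):
        skbio = pytest.importorskip("skbio")
        d = bray_curtis(small_study["phage_counts"])
        mine = pcoa(d)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.values, d.sample_ids))
        n = mine.coordinates.shape[1]
        np.testing.assert_allclose(mine.eigenvalues,
                                   ref.eigvals.to_numpy()[:n], rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(np.abs(mine.coordinates[:, :3]),
                                   np.abs(ref.samples.to_numpy()[:, :3]), atol=1e-6)

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            pcoa(DistanceMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0]]), "jaccard"))


class TestPermanova:
    def test_matches_reference_statistic(self, small_study):
        skbio = pytest.importorskip("skbio")
        d = bray_curtis(small_study["phage_counts"])
        meta = small_study["metadata"]
        labels = np.where(meta.samples["group"] == "wild_donor", "wild", "captive")
        mine = permanova(d, labels, n_perm=99, seed=1)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, d.sample_ids), labels, permutations=0)
        assert mine.statistic == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_r2_identity(self, small_study):
        d = bray_curtis(small_study["phage_counts"])
        labels = np.array((["a", "b"] * len(d.sample_ids))[:len(d.sample_ids)])
        res = permanova(d, labels, n_perm=49, seed=0)
        n, g = len(labels), 2
        # R2 = SS_A/SS_T and F = (SS_A/(g-1))/(SS_W/(n-g)) must cohere
        f_from_r2 = (res.R2 / (g - 1)) / ((1 - res.R2) / (n - g))
        assert f_from_r2 == pytest.approx(res.statistic, rel=1e-10)

    def test_maximal_separation(self):
        # two tight clusters at distance 1; groups large enough that no
        # permutation reproduces the split (checked for this seed)
        half = 10
        n = 2 * half
        vals = np.ones((n, n)) - np.eye(n)
        vals[:half, :half] = 0.01 * (1 - np.eye(half))
        vals[half:, half:] = 0.01 * (1 - np.eye(half))
        np.fill_diagonal(vals, 0)
        d = DistanceMatrix([f"s{i}" for i in range(n)], vals, "jaccard")
        res = permanova(d, ["a"] * half + ["b"] * half, n_perm=999, seed=0)
        assert res.statistic > 100
        # p attains the permutation floor up to chance re-creations of the split
        assert res.p <= 2 / (999 + 1)

    def test_relabeling_invariance(self, small_study):
        d = bray_curtis(small_study["phage_counts"])
        labels = np.array((["x", "y"] * len(d.sample_ids))[:len(d.sample_ids)])
        a = permanova(d, labels, n_perm=99, seed=5)
        swapped = np.where(labels == "x", "y", "x")
        b = permanova(d, swapped, n_perm=99, seed=5)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p == b.p

    def test_single_member_group_rejected(self, small_study):
        d = bray_curtis(small_study["phage_counts"])
        labels = ["solo"] + ["rest"] * (len(d.sample_ids) - 1)
        with pytest.raises(ValidationError, match="size 1"):
            permanova(d, labels, n_perm=9, seed=0)


class TestPermdisp:
    def test_identical_groups_of_identical_points_give_zero_f(self):
        vals = np.zeros((6, 6))
        vals[:3, 3:] = 1.0
        vals[3:, :3] = 1.0
        d = DistanceMatrix([f"s{i}" for i in range(6)], vals, "jaccard")
        res = permdisp(d, ["a", "a", "a", "b", "b", "b"], n_perm=49, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_detects_dispersion_difference(self, small_study):
        # wild samples are more dispersed than same-strain captive samples
        ph, meta = small_study["phage_counts"], small_study["metadata"]
        ids = meta.select(group="wild_donor") + meta.select(strain="BULS", day="D-1")
        labels = ["wild"] * len(meta.select(group="wild_donor")) + \
                 ["BULS"] * len(meta.select(strain="BULS", day="D-1"))
        d = bray_curtis(ph.subset_samples(ids))
        res = permdisp(d, labels, n_perm=199, seed=0)
        z = dispersion_distances(d, np.array(labels))
        assert z[np.array(labels) == "wild"].mean() > z[np.array(labels) == "BULS"].mean()

    def test_matches_reference_statistic(self, small_study, tmp_path):
        """Independent oracle: the R reference implementation of multivariate
        dispersion (centroid variant, signed negative PCoA axes)."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        d = bray_curtis(small_study["phage_counts"])
        meta = small_study["metadata"]
        labels = np.where(meta.samples["group"] == "wild_donor", "wild", "captive")
        mine = permdisp(d, labels, n_perm=49, seed=1)
        np.savetxt(tmp_path / "d.tsv", d.values, delimiter="\t")
        (tmp_path / "g.txt").write_text("\n".join(labels) + "\n")
        script = (
            'suppressMessages(library(vegan));'
            f'd <- as.dist(as.matrix(read.table("{tmp_path}/d.tsv")));'
            f'g <- factor(readLines("{tmp_path}/g.txt"));'
            'b <- betadisper(d, g, type="centroid");'
            'cat(sprintf("%.10f", anova(b)$`F value`[1]))'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                             check=True)
        assert mine.statistic == pytest.approx(float(out.stdout), rel=1e-6)


class TestAlphaModel:
    def test_single_timepoint_equals_anova(self, small_study):
        ph, meta = small_study["phage_counts"], small_study["metadata"]
        pre = meta.select(day=("D-1", "D0"))
        div = alpha_diversity(ph.subset_samples(pre), 2)
        res = alpha_model(div, meta, response="shannon", formula="group",
                         reduced_formula="1")
        import statsmodels.formula.api as smf
        data = div.merge(meta.samples, on="sample_id")
        ols = smf.ols("shannon ~ group", data).fit()
        np.testing.assert_allclose(res["fit"].beta.to_numpy(), ols.params.to_numpy(),
                                   atol=1e-6)

    def test_group_effect_detected(self, small_study):
        ph, meta = small_study["phage_counts"], small_study["metadata"]
        div = alpha_diversity(ph, 2)
        res = alpha_model(div, meta, response="shannon", formula="group",
                         random_intercepts=("mouse_id",), reduced_formula="1")
        (test,) = res["tests"].values()
        assert test.p < 0.05
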