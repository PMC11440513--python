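import numpy as np
import pandas as pd
import pytest

from phagetx.core_io import ValidationError
from phagetx.pool_fst import (SyncTable, binarize_fst, call_snps, compute_fst_records,
                              fst_divergence_test, fst_from_counts, high_fst_proportions,
                              pairwise_fst, pool_groups, read_sync, write_sync)


def oracle_fst(a1, a2, b1, b2):
    """Textbook pi-based pooled Fst, written independently step by step."""
    na, nb = a1 + a2, b1 + b2
    pa, pb = a1 / na, b1 / nb
    pi_a = (na / (na - 1)) * 2 * pa * (1 - pa)
    pi_b = (nb / (nb - 1)) * 2 * pb * (1 - pb)
    pi_w = (pi_a + pi_b) / 2
    nt = na + nb
    pt = (a1 + b1) / nt
    pi_t = (nt / (nt - 1)) * 2 * pt * (1 - pt)
    if pi_t <= 0:
        return float("nan")
    return min(1.0, max(0.0, (pi_t - pi_w) / pi_t))


def two_pool_sync(counts_by_pos, pools=("p1", "p2")):
    n = len(counts_by_pos)
    counts = np.zeros((n, 2, 6), dtype=int)
    for i, (a, b) in enumerate(counts_by_pos):
        counts[i, 0, :len(a)] = a
        counts[i, 1, :len(b)] = b
    return SyncTable(np.array([f"ctg{i}" for i in range(n)], dtype=object),
                     np.arange(1, n + 1), np.array(["A"] * n, dtype=object),
                     list(pools), counts)


class TestFstEstimator:
    def test_identical_pools_clip_to_zero(self):
        # both (5A,5T): pi_within exceeds pi_total via the n/(n-1) correction
        assert pairwise_fst((5, 5), (5, 5)) == 0.0

    def test_reciprocal_fixation_is_one(self):
        assert pairwise_fst((10, 0), (0, 10)) == 1.0

    def test_hand_case_8_2_vs_2_8(self):
        assert pairwise_fst((8, 2), (2, 8)) == pytest.approx(
            oracle_fst(8, 2, 2, 8), abs=1e-12)

    def test_matches_oracle_on_random_sites(self):
        rng = np.random.default_rng(12)
        n = 10_000
        cov_a = rng.integers(4, 80, n)
        cov_b = rng.integers(4, 80, n)
        a1 = rng.binomial(cov_a, rng.uniform(0, 1, n))
        b1 = rng.binomial(cov_b, rng.uniform(0, 1, n))
        mine = fst_from_counts(a1, cov_a - a1, b1, cov_b - b1)
        ref = np.array([oracle_fst(*args) for args in zip(a1, cov_a - a1, b1, cov_b - b1)])
        both = np.isfinite(mine) & np.isfinite(ref)
        assert (np.isfinite(mine) == np.isfinite(ref)).all()
        np.testing.assert_allclose(mine[both], ref[both], atol=1e-12)

    def test_symmetry_and_allele_relabeling(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            a1, a2, b1, b2 = rng.integers(1, 40, 4)
            f = fst_from_counts(a1, a2, b1, b2)
            assert f == pytest.approx(fst_from_counts(b1, b2, a1, a2), abs=1e-14)
            assert f == pytest.approx(fst_from_counts(a2, a1, b2, b1), abs=1e-14)

    def test_low_coverage_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_fst((1, 0), (5, 5))


class TestSyncHandling:
    def test_round_trip(self, tmp_path, small_study):
        sync = small_study["sync"]
        p = tmp_path / "sync.tsv"
        write_sync(sync, p)
        back = read_sync(p)
        np.testing.assert_array_equal(back.counts, sync.counts)
        assert back.pool_ids == sync.pool_ids

    def test_pool_groups_additivity_and_conservation(self, small_study):
        sync, meta = small_study["sync"], small_study["metadata"]
        grouped = pool_groups(sync, meta)
        assert "donors" in grouped.pool_ids
        np.testing.assert_array_equal(grouped.counts.sum(axis=1), sync.counts.sum(axis=1))
        donor_samples = meta.select(group="wild_donor")
        idx = [sync.pool_ids.index(s) for s in donor_samples]
        j = grouped.pool_ids.index("donors")
        np.testing.assert_array_equal(grouped.counts[:, j, :],
                                      sync.counts[:, idx, :].sum(axis=1))

    def test_unknown_sample_errors(self, small_study):
        sync, meta = small_study["sync"], small_study["metadata"]
        bad = SyncTable(sync.contigs, sync.positions, sync.ref,
                        ["nope"] + sync.pool_ids[1:], sync.counts)
        with pytest.raises(ValidationError, match="nope"):
            pool_groups(bad, meta)


class TestSnpCalling:
    def test_fixed_difference_kept_monomorphic_dropped(self):
        sync = two_pool_sync([((10, 0), (0, 10)),     # fixed difference -> keep
                              ((10, 0), (10, 0))])    # monomorphic -> drop
        calls = call_snps(sync, min_cov=10, min_minor_count=2)
        assert list(calls.contigs) == ["ctg0"]
        np.testing.assert_array_equal(calls.counts[0], [[10, 0], [0, 10]])

    def test_triallelic_low_third_flagged(self):
        sync = two_pool_sync([((6, 5, 1), (5, 6, 0))])
        calls = call_snps(sync, min_cov=10, min_minor_count=2)
        assert len(calls.contigs) == 1
        assert calls.discarded_flag[0]
        assert set(calls.allele_bases[0]) == {"A", "T"}

    def test_coverage_filter(self):
        sync = two_pool_sync([((5, 4), (20, 20))])
        assert len(call_snps(sync, min_cov=10).contigs) == 0
        assert len(call_snps(sync, min_cov=9).contigs) == 1

    def test_requires_two_pools_and_sane_thresholds(self, small_study):
        with pytest.raises(ValidationError, match="2 pools"):
            call_snps(small_study["sync"])
        sync = two_pool_sync([((10, 0), (0, 10))])
        with pytest.raises(ValidationError):
            call_snps(sync, min_cov=2)


class TestBinarization:
    def test_median_rule_with_ties_to_low(self):
        rec = pd.DataFrame({"fst": [0.1, 0.2, 0.3, 0.4]})
        out = binarize_fst(rec)
        assert list(out["fst_class"]) == ["low", "low", "high", "high"]
        assert out.attrs["fst_median"] == pytest.approx(0.25)

    def test_all_equal_warns_all_low(self):
        rec = pd.DataFrame({"fst": [0.3] * 5})
        with pytest.warns(UserWarning, match="equal"):
            out = binarize_fst(rec)
        assert (out["fst_class"] == "low").all()

    def test_high_fraction_never_exceeds_half(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            rec = pd.DataFrame({"fst": rng.uniform(0, 1, rng.integers(2, 60))})
            out = binarize_fst(rec)
            assert (out["fst_class"] == "high").mean() <= 0.5


class TestDivergenceAnalysis:
    def test_planted_strainwise_convergence_recovered(self, default_study):
        """BULS drifts toward donors (convergence_rate 0.7), BUSNA does not."""
        rec = compute_fst_records(default_study["sync"], default_study["metadata"])
        rec = binarize_fst(rec)
        props = high_fst_proportions(rec).set_index(["strain", "treatment", "day"])
        # BULS recipients lose high-Fst SNPs by D7; controls stay put
        assert props.loc[("BULS", "recipient", "D7"), "prop_high"] < \
            props.loc[("BULS", "recipient", "D-1"), "prop_high"] - 0.2
        assert abs(props.loc[("BULS", "control", "D7"), "prop_high"]
                   - props.loc[("BULS", "control", "D-1"), "prop_high"]) < 0.15
        res = fst_divergence_test(rec, by_strain=True)
        assert res["tests"]["strain:treatment:day"].p < 0.001
        assert res["tests"]["BULS:treatment:day"].p < 0.001
        assert res["tests"]["BUSNA:treatment:day"].p > 0.05

    def test_split_half_donor_fst_below_wild_captive_fst(self, default_study):
        """Planted divergence ordering: donors-vs-captive exceeds donors-vs-donors."""
        sync, meta = default_study["sync"], default_study["metadata"]
        donors = meta.select(group="wild_donor")
        half_a, half_b = donors[:5], donors[5:]
        captive_pre = meta.select(group="recipient", day="D-1")

        def pooled(sample_ids):
            idx = [sync.pool_ids.index(s) for s in sample_ids]
            return sync.counts[:, idx, :].sum(axis=1)

        a, b, c = pooled(half_a), pooled(half_b), pooled(captive_pre)
        f_split = np.nanmean(fst_from_counts(a[:, 0], a[:, 1], b[:, 0], b[:, 1]))
        f_wc = np.nanmean(fst_from_counts((a + b)[:, 0], (a + b)[:, 1], c[:, 0], c[:, 1]))
        assert f_wc > f_split + 0.1

    def test_single_snp_rejected(self):
        rec = pd.DataFrame({"snp_id": ["s1"] * 4, "strain": ["BULS"] * 4,
                            "treatment": ["recipient", "recipient", "control", "control"],
                            "day": ["D-1", "D7", "D-1", "D7"],
                            "fst": [0.1, 0.2, 0.3, 0.4]})
        with pytest.raises(ValidationError, match="SNP"):
            fst_divergence_test(binarize_fst(rec))
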