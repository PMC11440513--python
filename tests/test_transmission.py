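import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phagetx.core_io import PresenceMatrix, ValidationError, to_presence
from phagetx.transmission import (candidate_contigs, exclusive_contigs,
                                  matched_cooccurrence, pearson_chi2, permutation_null,
                                  temperate_enrichment)


def brute_force_filter(presence, metadata):
    """Direct per-contig re-statement of the filter, sample by sample."""
    samples = metadata.samples
    out = set()
    pos = {s: i for i, s in enumerate(presence.sample_ids)}
    for i, contig in enumerate(presence.feature_ids):
        def present(sel):
            return any(presence.present[i, pos[s]] for s in sel)
        in_donor = present(metadata.select(group="wild_donor"))
        in_pre = present(metadata.select(group="recipient", day="D-1"))
        in_ctrl = present(metadata.select(group="control"))
        in_post = present(metadata.select(group="recipient", day=("D2", "D7")))
        if in_donor and not in_pre and not in_ctrl and in_post:
            out.add(contig)
    return out


def toy_presence(toy_metadata, patterns):
    """patterns: contig -> set of sample ids where present."""
    ids = toy_metadata.sample_ids
    feats = sorted(patterns)
    mat = np.zeros((len(feats), len(ids)), dtype=bool)
    for i, f in enumerate(feats):
        for s in patterns[f]:
            mat[i, ids.index(s)] = True
    return PresenceMatrix(feats, ids, mat, 2)


class TestCandidateFilter:
    def test_rule_applications(self, toy_metadata):
        pres = toy_presence(toy_metadata, {
            "good": {"W01_D0", "BULS_R01_D2"},                   # textbook candidate
            "in_control": {"W01_D0", "BULS_R01_D2", "BUSNA_C01_D7"},
            "in_pre": {"W01_D0", "BULS_R01_D-1", "BULS_R01_D2"},
            "no_donor": {"BULS_R01_D2"},
            "donor_only": {"W02_D0"},
        })
        assert candidate_contigs(pres, toy_metadata) == {"good"}

    def test_matches_brute_force_on_random_toy(self, toy_metadata):
        rng = np.random.default_rng(21)
        ids = toy_metadata.sample_ids
        mat = rng.random((50, len(ids))) < 0.25
        pres = PresenceMatrix([f"c{i}" for i in range(50)], ids, mat, 2)
        assert candidate_contigs(pres, toy_metadata) == \
            brute_force_filter(pres, toy_metadata)

    def test_missing_day_errors(self, toy_metadata, small_study):
        pres = to_presence(small_study["phage_counts"], 2)
        keep = [s for s in pres.sample_ids if s != "BULS_R01_D2"]
        sub = PresenceMatrix(pres.feature_ids, keep,
                             pres.present[:, [pres.sample_ids.index(s) for s in keep]], 2)
        with pytest.raises(ValidationError, match="BULS_R01"):
            candidate_contigs(sub, small_study["metadata"])


class TestMatchedAndExclusive:
    def test_matching_requires_own_recipient(self, toy_metadata):
        pres = toy_presence(toy_metadata, {
            "own_pair": {"W01_D0", "BUSNA_R01_D7"},      # W01's own recipient
            "cross_pair": {"W01_D0", "BULS_R02_D2"},     # W02's recipient only
        })
        cands = candidate_contigs(pres, toy_metadata)
        assert cands == {"own_pair", "cross_pair"}
        assert matched_cooccurrence(cands, pres, toy_metadata) == {"own_pair"}

    def test_exclusivity_rules(self, toy_metadata):
        pres = toy_presence(toy_metadata, {
            "exclusive": {"W01_D0", "BULS_R01_D2", "BUSNA_R01_D7"},
            "leaky": {"W01_D0", "BULS_R01_D2", "BULS_R02_D7"},   # also in W02's recipient
            "two_donors": {"W01_D0", "W02_D0", "BULS_R01_D2"},
        })
        cands = candidate_contigs(pres, toy_metadata)
        matched = matched_cooccurrence(cands, pres, toy_metadata)
        assert matched == {"exclusive", "leaky", "two_donors"}
        assert exclusive_contigs(matched, pres, toy_metadata) == {"exclusive"}

    def test_brute_force_exclusive_on_random_toy(self, toy_metadata):
        rng = np.random.default_rng(22)
        ids = toy_metadata.sample_ids
        mat = rng.random((60, len(ids))) < 0.2
        pres = PresenceMatrix([f"c{i}" for i in range(60)], ids, mat, 2)
        cands = candidate_contigs(pres, toy_metadata)
        matched = matched_cooccurrence(cands, pres, toy_metadata)
        expect = set()
        for c in matched:
            i = pres.feature_ids.index(c)
            donors_with = [d for d in toy_metadata.donors
                           if pres.present[i, ids.index(f"{d}_D0")]]
            if len(donors_with) != 1:
                continue
            own_post = {s for m in toy_metadata.recipients_of(donors_with[0])
                        for s in toy_metadata.select(mouse_id=m, day=("D2", "D7"))}
            captive = set(toy_metadata.select(group=("recipient", "control")))
            hits = {s for s in captive if pres.present[i, ids.index(s)]}
            if hits and hits <= own_post:
                expect.add(c)
        assert exclusive_contigs(matched, pres, toy_metadata) == expect


class TestPermutationNull:
    def test_planted_transmission_strongly_significant(self, default_study):
        ph, meta = default_study["phage_counts"], default_study["metadata"]
        pres = to_presence(ph, 2)
        cands = candidate_contigs(pres, meta)
        res = permutation_null(cands, pres, meta, n_perm=199, seed=3)
        assert res.perm_p < 0.05
        assert res.wilcoxon_p < 0.01
        assert res.exclusive <= res.matched <= res.candidates
        assert res.observed_fraction == pytest.approx(len(res.matched) / len(res.candidates))

    def test_reproducible_and_presence_conserving(self, default_study):
        ph, meta = default_study["phage_counts"], default_study["metadata"]
        pres = to_presence(ph, 2)
        cands = candidate_contigs(pres, meta)
        a = permutation_null(cands, pres, meta, n_perm=120, seed=9)
        b = permutation_null(cands, pres, meta, n_perm=120, seed=9)
        np.testing.assert_array_equal(a.null_fractions, b.null_fractions)
        assert a.perm_p == b.perm_p

    def test_sample_order_invariance(self, default_study):
        ph, meta = default_study["phage_counts"], default_study["metadata"]
        pres = to_presence(ph, 2)
        order = np.random.default_rng(0).permutation(len(pres.sample_ids))
        shuffled = PresenceMatrix(pres.feature_ids,
                                  [pres.sample_ids[i] for i in order],
                                  pres.present[:, order], 2)
        assert candidate_contigs(pres, meta) == candidate_contigs(shuffled, meta)

    def test_zero_candidates_flagged(self, toy_metadata):
        pres = toy_presence(toy_metadata, {"nothing": set()})
        with pytest.warns(UserWarning, match="vacuous"):
            res = permutation_null(set(), pres, toy_metadata, n_perm=100, seed=0)
        assert res.perm_p == 1.0 and res.flagged

    def test_single_donor_is_degenerate(self, toy_metadata):
        # restrict to contigs present in one donor: permutation of a length-2
        # vector with one present donor can move it, so use a design truly
        # degenerate: both donor samples present for every candidate
        pres = toy_presence(toy_metadata, {
            "c1": {"W01_D0", "W02_D0", "BULS_R01_D2"},
            "c2": {"W01_D0", "W02_D0", "BUSNA_R02_D7"},
        })
        cands = candidate_contigs(pres, toy_metadata)
        res = permutation_null(cands, pres, toy_metadata, n_perm=100, seed=1)
        assert (res.null_fractions == res.observed_fraction).all()
        assert res.perm_p == 1.0

    def test_n_perm_floor(self, toy_metadata):
        pres = toy_presence(toy_metadata, {"c": {"W01_D0"}})
        with pytest.raises(ValidationError):
            permutation_null(set(), pres, toy_metadata, n_perm=50, seed=0)


class TestTemperateEnrichment:
    def _annotations(self, n_temp, n_other):
        ids = [f"c{i}" for i in range(n_temp + n_other)]
        return pd.DataFrame({
            "lifestyle": ["temperate"] * n_temp + ["virulent"] * n_other,
            "family": "x", "host_family": None, "length_bp": 1000,
        }, index=pd.Index(ids, name="feature_id"))

    def test_background_composition_gives_null(self):
        ann = self._annotations(40, 60)
        group = set(ann.index[:20]) | set(ann.index[40:70])   # 20 temp + 30 vir = 40%
        res = temperate_enrichment(group, ann)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-10)
        assert res["odds_ratio"] == pytest.approx(1.0, abs=1e-10)

    def test_haldane_correction_on_zero_cell(self):
        ann = self._annotations(10, 10)
        group = set(ann.index[:10])          # all 10 temperate
        res = temperate_enrichment(group, ann)
        np.testing.assert_array_equal(res["table"], [[10, 0], [0, 10]])
        assert res["odds_ratio"] == pytest.approx(441.0)

    def test_chi2_matches_scipy_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            t = rng.integers(1, 50, size=(2, 2))
            chi2, p = pearson_chi2(t)
            ref = stats.chi2_contingency(t, correction=False)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_study_scale_fractions(self):
        """Printed-count arithmetic: 296 matched of 622 candidates; 108/296
        temperate among transmitted vs 6292/13458 among the rest."""
        n_all, n_matched = 13754, 296
        ann = self._annotations(108 + 6292, n_all - (108 + 6292))
        temp_ids = list(ann.index[:108 + 6292])
        vir_ids = list(ann.index[108 + 6292:])
        group = set(temp_ids[:108]) | set(vir_ids[:296 - 108])
        res = temperate_enrichment(group, ann)
        assert res["prop_temperate_group"] == pytest.approx(0.365, abs=1e-3)
        assert res["prop_temperate_rest"] == pytest.approx(0.467, abs=1e-3)
        assert 296 / 622 == pytest.approx(0.4759, abs=1e-4)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            temperate_enrichment(set(), self._annotations(5, 5))
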