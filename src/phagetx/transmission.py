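"""Detection of putatively transmitted phage contigs.

A contig is a transmission *candidate* when its presence pattern is exactly
what engraftment would produce: present in at least one wild donor,
appearing in at least one recipient only after the transplant (D2 or D7),
absent from every recipient before it (D-1), and never seen in any
non-transplanted control.  A candidate is *matched* when at least one
donor that carries it is the donor of a recipient that shows it
post-transplant — simultaneous occurrence in a true donor-recipient pair.

Whether matching exceeds chance is tested by reshuffling each candidate's
presence vector across the donor samples (recipient data fixed) and
recomputing the matched fraction, with the usual ``(1+exceed)/(1+n_perm)``
permutation p-value; a per-contig Wilcoxon signed-rank test of the observed
matched indicator against its permutation mean is reported alongside.
Matched contigs seen in exactly one donor and in no captive mouse other
than that donor's own recipients are *exclusive* — the strongest
transmission evidence.  Lifestyle composition of a contig group versus the
remaining contigs is compared with a Pearson chi-squared test on the 2x2
table (undetermined lifestyles count as non-temperate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import PresenceMatrix, StudyMetadata, ValidationError


def _design_indices(presence: PresenceMatrix, metadata: StudyMetadata):
    """Sample-index bookkeeping for the presence filter."""
    pos = {s: i for i, s in enumerate(presence.sample_ids)}
    samples = metadata.samples
    missing = [s for s in samples["sample_id"] if s not in pos]
    if missing:
        raise ValidationError(f"presence matrix lacks sample(s): {missing[:5]}")
    for mouse in metadata.mice(group="recipient") + metadata.mice(group="control"):
        days = set(samples.loc[samples["mouse_id"] == mouse, "day"])
        if days != {"D-1", "D2", "D7"}:
            raise ValidationError(f"captive mouse {mouse!r} missing day(s): "
                                  f"{sorted({'D-1', 'D2', 'D7'} - days)}")
    donors = metadata.donors
    donor_cols = [pos[metadata.sample_of(d, "D0")] for d in donors]
    recip_pre = [pos[s] for s in metadata.select(group="recipient", day="D-1")]
    recip_post = [pos[s] for s in metadata.select(group="recipient", day=("D2", "D7"))]
    control_all = [pos[s] for s in metadata.select(group="control")]
    # post-transplant columns of each donor's own recipients
    own_post = {}
    for d in donors:
        cols = []
        for m in metadata.recipients_of(d):
            cols += [pos[s] for s in metadata.select(mouse_id=m, day=("D2", "D7"))]
        own_post[d] = cols
    return donors, donor_cols, recip_pre, recip_post, control_all, own_post, pos


def candidate_contigs(presence: PresenceMatrix, metadata: StudyMetadata) -> set:
    """Contigs matching the transmission presence filter (see module docs)."""
    donors, donor_cols, recip_pre, recip_post, control_all, _, _ = \
        _design_indices(presence, metadata)
    x = presence.present
    keep = (x[:, donor_cols].any(axis=1)
            & ~x[:, recip_pre].any(axis=1)
            & ~x[:, control_all].any(axis=1)
            & x[:, recip_post].any(axis=1))
    return {presence.feature_ids[i] for i in np.flatnonzero(keep)}


def matched_cooccurrence(candidates: set, presence: PresenceMatrix,
                         metadata: StudyMetadata) -> set:
    """Candidates present in >= 1 donor together with that donor's own recipients."""
    donors, donor_cols, _, _, _, own_post, _ = _design_indices(presence, metadata)
    idx = {f: i for i, f in enumerate(presence.feature_ids)}
    x = presence.present
    matched = set()
    for c in candidates:
        i = idx[c]
        for d, dcol in zip(donors, donor_cols):
            if x[i, dcol] and x[i, own_post[d]].any():
                matched.add(c)
                break
    return matched


def exclusive_contigs(matched: set, presence: PresenceMatrix,
                      metadata: StudyMetadata) -> set:
    """Matched contigs confined to one donor and that donor's own recipients."""
    donors, donor_cols, _, _, _, own_post, pos = _design_indices(presence, metadata)
    idx = {f: i for i, f in enumerate(presence.feature_ids)}
    captive_all = [pos[s] for s in metadata.select(group=("recipient", "control"))]
    x = presence.present
    out = set()
    for c in matched:
        i = idx[c]
        donor_hits = [d for d, col in zip(donors, donor_cols) if x[i, col]]
        if len(donor_hits) != 1:
            continue
        allowed = set(own_post[donor_hits[0]])
        captive_hits = {j for j in captive_all if x[i, j]}
        if captive_hits and captive_hits <= allowed:
            out.add(c)
    return out


@dataclass
class TransmissionResult:
    candidates: set
    matched: set
    exclusive: set
    observed_fraction: float
    null_fractions: np.ndarray
    perm_p: float
    wilcoxon_p: float
    n_perm: int
    seed: int
    flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "n_candidates": len(self.candidates),
            "n_matched": len(self.matched),
            "n_exclusive": len(self.exclusive),
            "observed_fraction": self.observed_fraction,
            "null_mean_fraction": float(np.mean(self.null_fractions))
            if len(self.null_fractions) else None,
            "perm_p": self.perm_p,
            "wilcoxon_p": self.wilcoxon_p,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def permutation_null(candidates: set, presence: PresenceMatrix, metadata: StudyMetadata,
                     n_perm: int = 1000, seed: int = 0) -> TransmissionResult:
    """Donor-reshuffling permutation test of matched co-occurrence.

    Each candidate's donor presence vector is independently permuted across
    the donor samples per replicate (presence totals conserved; recipient
    data fixed) and the matched fraction recomputed.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    donors, donor_cols, _, _, _, own_post, _ = _design_indices(presence, metadata)
    if not candidates:
        warnings.warn("no candidate contigs; transmission test is vacuous")
        return TransmissionResult(set(), set(), set(), 0.0, np.empty(0), 1.0, 1.0,
                                  n_perm, seed, flagged=True)
    cand = sorted(candidates)
    idx = {f: i for i, f in enumerate(presence.feature_ids)}
    rows = np.array([idx[c] for c in cand])
    x = presence.present
    donor_pres = x[np.ix_(rows, donor_cols)]                      # candidates x donors
    recip_post = np.array([[x[i, own_post[d]].any() for d in donors] for i in rows])

    obs_ind = (donor_pres & recip_post).any(axis=1)
    observed = float(obs_ind.mean())

    rng = np.random.default_rng(seed)
    n_c, n_d = donor_pres.shape
    null_fracs = np.empty(n_perm)
    null_ind_sum = np.zeros(n_c)
    for p in range(n_perm):
        # independent permutation of each candidate's donor-presence vector
        keys = rng.random((n_c, n_d))
        order = np.argsort(keys, axis=1)
        shuffled = np.take_along_axis(donor_pres, order, axis=1)
        ind = (shuffled & recip_post).any(axis=1)
        null_fracs[p] = ind.mean()
        null_ind_sum += ind
    exceed = int((null_fracs >= observed - 1e-12).sum())
    perm_p = (1 + exceed) / (1 + n_perm)

    null_mean_ind = null_ind_sum / n_perm
    diff = obs_ind.astype(float) - null_mean_ind
    if np.allclose(diff, 0.0):
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(stats.wilcoxon(obs_ind.astype(float), null_mean_ind,
                                          zero_method="wilcox").pvalue)

    matched = {c for c, m in zip(cand, obs_ind) if m}
    exclusive = exclusive_contigs(matched, presence, metadata)
    return TransmissionResult(set(cand), matched, exclusive, observed,
                              null_fracs, float(perm_p), wilcoxon_p, n_perm, seed)


def temperate_enrichment(group: set, annotations: pd.DataFrame,
                         background: set | None = None) -> dict:
    """Lifestyle 2x2 test: group vs remaining contigs, temperate vs not.

    Pearson chi-squared without continuity correction (df=1); odds ratio
    with the Haldane-Anscombe +0.5 correction when a zero cell exists.
    Undetermined lifestyles count as non-temperate.
    """
    if not group:
        raise ValidationError("empty contig group")
    all_ids = set(annotations.index)
    if background is None:
        background = all_ids
    unknown = group - all_ids
    if unknown:
        raise ValidationError(f"group contig(s) missing from annotations: {sorted(unknown)[:5]}")
    rest = background - group
    is_temp = annotations["lifestyle"] == "temperate"
    a = int(is_temp.reindex(sorted(group)).sum())          # in-group temperate
    b = len(group) - a
    c = int(is_temp.reindex(sorted(rest)).sum())
    d = len(rest) - c
    table = np.array([[a, b], [c, d]], dtype=float)
    chi2, p = pearson_chi2(table)
    if (table == 0).any():
        t = table + 0.5
    else:
        t = table
    odds_ratio = float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
    return {"table": table.astype(int), "chi2": chi2, "df": 1, "p": p,
            "odds_ratio": odds_ratio,
            "prop_temperate_group": a / len(group),
            "prop_temperate_rest": c / len(rest) if rest else float("nan")}


def pearson_chi2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) for a 2x2 table."""
    table = np.asarray(table, float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    n = table.sum()
    expected = row @ col / n
    if (expected == 0).any():
        return 0.0, 1.0
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, 1))
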