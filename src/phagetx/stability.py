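"""Temporal stability of captive communities across experiment phases.

How much does an individual's community change between consecutive sampling
days, compared to how different two *different* individuals are across the
same days?  ``delta = mean(other) - mean(self)`` over a phase pair
(D-1 vs D2, or D2 vs D7), where self-dissimilarities pair each mouse with
itself across the two days and other-dissimilarities pair it with every
other same-strain mouse (cross-strain pairs are excluded, since strain
differences would inflate the contrast).  A positive delta with a bootstrap
confidence interval excluding zero indicates individual signatures that
persist through the phase.

The bootstrap resamples *mice* with replacement, stratified by strain, so
the dependence among the many pairs sharing a mouse cannot shrink the
interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import DistanceMatrix, StudyMetadata, ValidationError

PHASE_PAIRS = {"D-1:D2": ("D-1", "D2"), "D2:D7": ("D2", "D7")}


@dataclass
class StabilityResult:
    phase_pair: str
    strain: str                 # a strain name, or "pooled"
    mean_self: float
    mean_other: float
    delta: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {"phase_pair": self.phase_pair, "strain": self.strain,
                "mean_self": self.mean_self, "mean_other": self.mean_other,
                "delta": self.delta, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "n_boot": self.n_boot, "seed": self.seed}


def _phase_blocks(d: DistanceMatrix, metadata: StudyMetadata, phase_pair: str):
    """Per-strain cross-day dissimilarity blocks (mice at t1 x mice at t2)."""
    if phase_pair not in PHASE_PAIRS:
        raise ValidationError(f"phase_pair must be one of {sorted(PHASE_PAIRS)}")
    t1, t2 = PHASE_PAIRS[phase_pair]
    pos = {s: i for i, s in enumerate(d.sample_ids)}
    blocks = {}
    for strain in metadata.strains:
        mice = metadata.mice(strain=strain)
        if len(mice) < 3:
            raise ValidationError(f"strain {strain!r} has < 3 mice; bootstrap degenerate")
        rows = []
        for m in mice:
            s1 = metadata.sample_of(m, t1)
            s2 = metadata.sample_of(m, t2)
            if s1 not in pos or s2 not in pos:
                raise ValidationError(f"distance matrix lacks samples of mouse {m!r}")
            rows.append((pos[s1], pos[s2]))
        i1 = np.array([r[0] for r in rows])
        i2 = np.array([r[1] for r in rows])
        blocks[strain] = d.values[np.ix_(i1, i2)]
    return blocks


def _means_from_blocks(blocks: dict, index_map: dict | None = None):
    """(mean_self, mean_other) pooling strains, optionally on resampled mice.

    Under resampling, two draws of the same original mouse are still the
    same individual: their cross-day pair is a self-dissimilarity and is
    excluded from the between-individual pool (keeping it would bias every
    bootstrap replicate toward smaller contrasts).
    """
    self_vals, other_vals = [], []
    for strain, block in blocks.items():
        idx = index_map[strain] if index_map is not None else np.arange(block.shape[0])
        sub = block[np.ix_(idx, idx)]
        distinct = idx[:, None] != idx[None, :]
        self_vals.append(np.diag(sub))
        other_vals.append(sub[distinct])
    self_all = np.concatenate(self_vals)
    other_all = np.concatenate(other_vals)
    if len(other_all) == 0:
        raise ValidationError("no between-individual pairs (degenerate resample)")
    return float(self_all.mean()), float(other_all.mean())


def stability_contrast(d: DistanceMatrix, metadata: StudyMetadata, phase_pair: str,
                       n_boot: int = 2000, seed: int = 0,
                       per_strain: bool = False) -> list[StabilityResult]:
    """Bootstrap contrast of between- vs within-individual phase dissimilarity.

    Returns the pooled-across-strains result, plus per-strain results when
    ``per_strain`` is set.  The percentile 95% CI resamples mice with
    replacement within strain.
    """
    blocks = _phase_blocks(d, metadata, phase_pair)
    rng = np.random.default_rng(seed)
    results = []

    def run(tag: str, use: dict) -> StabilityResult:
        mean_self, mean_other = _means_from_blocks(use)
        deltas = np.empty(n_boot)
        sizes = {s: b.shape[0] for s, b in use.items()}
        for i in range(n_boot):
            while True:
                idx_map = {s: rng.integers(0, n, size=n) for s, n in sizes.items()}
                # a resample with no two distinct mice anywhere has no
                # between-individual pairs; redraw (rare, tiny cohorts only)
                if any(len(np.unique(ix)) > 1 for ix in idx_map.values()):
                    break
            ms, mo = _means_from_blocks(use, idx_map)
            deltas[i] = mo - ms
        lo, hi = np.percentile(deltas, [2.5, 97.5])
        return StabilityResult(phase_pair, tag, mean_self, mean_other,
                               mean_other - mean_self, float(lo), float(hi),
                               n_boot, seed)

    results.append(run("pooled", blocks))
    if per_strain:
        for strain in sorted(blocks):
            results.append(run(strain, {strain: blocks[strain]}))
    return results
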