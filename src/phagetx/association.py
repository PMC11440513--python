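"""Phageome-bacteriome association.

Two complementary views of the coupling between the viral and bacterial
components of the same gut communities:

* **Procrustes superimposition** of the two ordinations.  Both
  configurations are centered and scaled to unit sum-of-squares; the
  optimal rotation comes from the SVD of the cross-product matrix, and the
  fit statistic is ``m2 = 1 - (sum of singular values)^2`` with correlation
  ``sqrt(1 - m2)``.  Significance is assessed by permuting the sample rows
  of one configuration (the PROTEST procedure).
* **Per-pair co-occurrence GLMMs**: for a chosen feature subset, each phage
  contig's counts are modelled as negative binomial with the paired ASV's
  ``log1p`` relative abundance as predictor, log total phage reads as
  offset, and a mouse random intercept.  Wald p-values are
  Benjamini-Hochberg adjusted across all tested pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community_metrics import OrdinationResult
from .core_io import CountMatrix, StudyMetadata, ValidationError, relative_abundance
from .glmm import GLMMSpec, fit_glmm


@dataclass
class ProcrustesResult:
    m2: float
    correlation: float
    p: float
    n_perm: int
    seed: int
    n_axes: int


def _configuration(ord_res: OrdinationResult, n_axes: int) -> np.ndarray:
    if n_axes > ord_res.coordinates.shape[1]:
        raise ValidationError(
            f"requested {n_axes} axes but only {ord_res.coordinates.shape[1]} available")
    x = ord_res.coordinates[:, :n_axes].astype(float)
    x = x - x.mean(axis=0, keepdims=True)
    ss = (x ** 2).sum()
    if ss <= 0:
        raise ValidationError("degenerate configuration (zero spread)")
    return x / np.sqrt(ss)


def _m2(xa: np.ndarray, xb: np.ndarray) -> float:
    s = np.linalg.svd(xa.T @ xb, compute_uv=False)
    return float(max(0.0, 1.0 - s.sum() ** 2))


def procrustes_test(coords_a: OrdinationResult, coords_b: OrdinationResult,
                    n_axes: int | None = None, n_perm: int = 999,
                    seed: int = 0) -> ProcrustesResult:
    """Symmetric Procrustes m2 between two ordinations + permutation test."""
    if coords_a.sample_ids != coords_b.sample_ids:
        only_a = set(coords_a.sample_ids) - set(coords_b.sample_ids)
        only_b = set(coords_b.sample_ids) - set(coords_a.sample_ids)
        if only_a or only_b:
            raise ValidationError(
                f"sample mismatch; only in first: {sorted(only_a)[:5]}, "
                f"only in second: {sorted(only_b)[:5]}")
        # same set, different order: align b to a's order
        order = [coords_b.sample_ids.index(s) for s in coords_a.sample_ids]
        coords_b = OrdinationResult(list(coords_a.sample_ids),
                                    coords_b.coordinates[order],
                                    coords_b.eigenvalues,
                                    coords_b.proportion_explained,
                                    coords_b.all_eigenvalues,
                                    coords_b.all_vectors[order])
    if n_axes is None:
        n_axes = min(coords_a.coordinates.shape[1], coords_b.coordinates.shape[1])
    xa = _configuration(coords_a, n_axes)
    xb = _configuration(coords_b, n_axes)
    m2_obs = _m2(xa, xb)
    rng = np.random.default_rng(seed)
    exceed = 0
    n = xa.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _m2(xa[perm], xb) <= m2_obs + 1e-15:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return ProcrustesResult(m2_obs, float(np.sqrt(max(0.0, 1.0 - m2_obs))),
                            float(p), n_perm, seed, n_axes)


# ---------------------------------------------------------------------------
# feature selection and per-pair co-occurrence models
# ---------------------------------------------------------------------------

def select_features(counts: CountMatrix, k: int, method: str = "variance",
                    user_list: list | None = None) -> list[str]:
    """Deterministic top-k features by variance or mean relative abundance.

    ``method="user_list"`` validates and passes through an explicit list,
    standing in for an upstream sparse-regression feature selection.
    """
    if method == "user_list":
        if user_list is None:
            raise ValidationError("user_list method requires a feature list")
        unknown = set(user_list) - set(counts.feature_ids)
        if unknown:
            raise ValidationError(f"unknown feature(s) in user_list: {sorted(unknown)[:5]}")
        return list(user_list)
    if k > len(counts.feature_ids):
        raise ValidationError(f"k={k} exceeds {len(counts.feature_ids)} features")
    rel = relative_abundance(counts)
    if method == "variance":
        score = rel.var(axis=1)
    elif method == "abundance":
        score = rel.mean(axis=1)
    else:
        raise ValidationError(f"unknown selection method {method!r}")
    # stable tie-break on feature id
    order = np.lexsort((np.array(counts.feature_ids, dtype=object), -score))
    return [counts.feature_ids[i] for i in order[:k]]


@dataclass
class CooccurrenceLink:
    contig_id: str
    asv_id: str
    coefficient: float
    p_raw: float
    p_adj: float
    sign: str


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        prev = min(prev, p[idx] * m / (rank + 1))
        adj[idx] = prev
    return adj


def cooccurrence_glmm(phage_counts: CountMatrix, asv_counts: CountMatrix,
                      pairs: list, metadata: StudyMetadata) -> list[CooccurrenceLink]:
    """Negative-binomial GLMM per (contig, ASV) pair.

    Response: contig read counts; predictor: ``log1p`` of the ASV's relative
    abundance; offset: log total phage reads per sample; random intercept:
    mouse.  Pairs whose contig has all-zero counts are dropped with a
    warning.  BH adjustment across all tested pairs.
    """
    common = [s for s in phage_counts.sample_ids if s in set(asv_counts.sample_ids)]
    if not common:
        raise ValidationError("no shared samples between phage and ASV matrices")
    ph = phage_counts.subset_samples(common)
    av = asv_counts.subset_samples(common)
    meta = metadata.samples.set_index("sample_id").reindex(common)
    if meta["mouse_id"].isna().any():
        raise ValidationError("shared sample(s) missing from metadata")
    asv_rel = relative_abundance(av)
    totals = ph.counts.sum(axis=0)
    pidx = {f: i for i, f in enumerate(ph.feature_ids)}
    aidx = {f: i for i, f in enumerate(av.feature_ids)}
    rows = []
    fits = []
    for contig, asv in pairs:
        if contig not in pidx or asv not in aidx:
            raise ValidationError(f"pair ({contig!r}, {asv!r}) references unknown feature")
        y = ph.counts[pidx[contig]]
        if (y == 0).all():
            warnings.warn(f"contig {contig!r} has all-zero counts; pair dropped")
            continue
        data = pd.DataFrame({
            "y": y,
            "x": np.log1p(asv_rel[aidx[asv]]),
            "log_total": np.log(totals.astype(float)),
            "mouse_id": meta["mouse_id"].to_numpy(),
        })
        fit = fit_glmm(GLMMSpec("x", "y", "negbin", random_intercepts=("mouse_id",),
                                offset="log_total"), data)
        coef = float(fit.beta["x"])
        se = float(fit.se_beta["x"]) if fit.se_beta is not None else np.nan
        z = coef / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else 1.0
        rows.append((contig, asv, coef, float(p)))
        fits.append(fit)
    if not rows:
        return []
    p_adj = bh_adjust(np.array([r[3] for r in rows]))
    return [CooccurrenceLink(c, a, coef, p, float(pa),
                             "positive" if coef >= 0 else "negative")
            for (c, a, coef, p), pa in zip(rows, p_adj)]
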