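"""Alpha diversity, beta-diversity matrices, ordination and permutation tests.

The ordination-and-testing layer: Shannon/richness per sample, Bray-Curtis
(on total-sum-scaled proportions) and Jaccard (on thresholded
presence/absence) dissimilarities, principal coordinates analysis by Gower
double-centering, PERMANOVA (Anderson's direct-from-distance pseudo-F) and
PERMDISP (one-way ANOVA on distances to group centroids in full signed PCoA
space).  Permutation p-values follow the ``(1 + exceedances) / (1 + n_perm)``
convention throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_io import (CountMatrix, DistanceMatrix, PresenceMatrix, StudyMetadata,
                      ValidationError, relative_abundance)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(counts: CountMatrix, min_reads: int = 2) -> pd.DataFrame:
    """Per-sample richness (features with >= min_reads) and Shannon index.

    Shannon uses natural log over the proportions of all nonzero counts
    (richness thresholding does not change the Shannon denominator).
    Zero-total samples get richness 0 / shannon 0 and a warning.
    """
    c = counts.counts
    totals = c.sum(axis=0)
    if (totals == 0).any():
        warnings.warn(f"zero-total sample(s): "
                      f"{[counts.sample_ids[i] for i in np.flatnonzero(totals == 0)]}")
    richness = (c >= min_reads).sum(axis=0)
    shannon = np.zeros(len(counts.sample_ids))
    for j in range(c.shape[1]):
        if totals[j] == 0:
            richness[j] = 0
            continue
        p = c[:, j][c[:, j] > 0] / totals[j]
        shannon[j] = float(-(p * np.log(p)).sum())
    return pd.DataFrame({"sample_id": counts.sample_ids,
                         "richness": richness.astype(int), "shannon": shannon})


def alpha_model(diversity: pd.DataFrame, metadata: StudyMetadata,
                response: str = "shannon", formula: str = "group",
                random_intercepts: tuple = (), reduced_formula: str | None = None) -> dict:
    """Gaussian (mixed) model of an alpha-diversity index on design terms.

    With repeated measures, pass ``random_intercepts=("mouse_id",)``.  When a
    ``reduced_formula`` is given, the likelihood-ratio test of the dropped
    terms is included.
    """
    from .glmm import GLMMSpec, fit_glmm, lr_test

    data = diversity.merge(metadata.samples, on="sample_id", how="inner")
    if len(data) != len(diversity):
        raise ValidationError("diversity records not all present in metadata")
    fit = fit_glmm(GLMMSpec(formula, response, "gaussian",
                            random_intercepts=tuple(random_intercepts)), data)
    out = {"fit": fit, "tests": {}}
    if reduced_formula is not None:
        red = fit_glmm(GLMMSpec(reduced_formula, response, "gaussian",
                                random_intercepts=tuple(random_intercepts)), data)
        out["tests"][f"{formula} vs {reduced_formula}"] = lr_test(fit, red)
    return out


# ---------------------------------------------------------------------------
# Dissimilarities
# ---------------------------------------------------------------------------

def bray_curtis(counts: CountMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on total-sum-scaled proportions."""
    p = relative_abundance(counts)
    d = squareform(pdist(p.T, metric="braycurtis"))
    return DistanceMatrix(list(counts.sample_ids), d, "bray_curtis")


def jaccard_distance(presence: PresenceMatrix) -> DistanceMatrix:
    """Jaccard distance ``1 - |A n B| / |A u B|`` on presence sets.

    Two samples with no present features at all get distance 0 (flagged via
    warning), matching the empty-set convention.
    """
    x = presence.present
    inter = (x[:, :, None] & x[:, None, :]).sum(axis=0)
    union = (x[:, :, None] | x[:, None, :]).sum(axis=0)
    both_empty = union == 0
    if both_empty.any() and len(presence.sample_ids) > 1:
        off_diag = both_empty & ~np.eye(len(presence.sample_ids), dtype=bool)
        if off_diag.any():
            warnings.warn("sample pair(s) with empty feature sets; distance set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[both_empty] = 0.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(presence.sample_ids), d, "jaccard")


def bin_by_annotation(counts: CountMatrix, key: str = "host_family") -> CountMatrix:
    """Sum features within an annotation level (null -> bin "unassigned")."""
    if counts.annotations is None:
        raise ValidationError("bin_by_annotation requires feature annotations")
    if key not in ("host_family", "family"):
        raise ValidationError(f"unsupported binning key {key!r}")
    labels = counts.annotations.reindex(counts.feature_ids)[key]
    labels = labels.fillna("unassigned").replace({"": "unassigned"}).to_numpy()
    frame = pd.DataFrame(counts.counts, index=labels)
    binned = frame.groupby(level=0, sort=True).sum()
    return CountMatrix(binned.index.tolist(), list(counts.sample_ids), binned.to_numpy())


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray          # samples x retained axes
    eigenvalues: np.ndarray          # retained (positive) eigenvalues
    proportion_explained: np.ndarray
    all_eigenvalues: np.ndarray      # full signed spectrum, for PERMDISP
    all_vectors: np.ndarray          # eigenvectors matching all_eigenvalues


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates by Gower double-centering of ``-0.5 d^2``.

    Axes with eigenvalue > 1e-10 are retained for the ordination output and
    scaled by sqrt(eigenvalue); the full signed spectrum is kept for
    dispersion analysis.  Axis signs are fixed so the largest-magnitude
    loading on each axis is positive.
    """
    n = len(d.sample_ids)
    if n < 3:
        raise ValidationError("PCoA requires >= 3 samples")
    a = -0.5 * d.values ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    g = (g + g.T) / 2.0
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > 1e-10
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])[None, :]
    for ax in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, ax]))
        if coords[i, ax] < 0:
            coords[:, ax] = -coords[:, ax]
            eigvec[:, np.flatnonzero(keep)[ax]] *= -1
    total = eigval[eigval > 0].sum()
    prop = eigval[keep] / total if total > 0 else np.zeros(keep.sum())
    return OrdinationResult(list(d.sample_ids), coords, eigval[keep], prop, eigval, eigvec)


# ---------------------------------------------------------------------------
# PERMANOVA / PERMDISP
# ---------------------------------------------------------------------------

@dataclass
class PermTestResult:
    statistic: float
    R2: float | None
    p: float
    n_perm: int
    seed: int


def _check_groups(labels: np.ndarray) -> list[np.ndarray]:
    levels, codes = np.unique(labels, return_inverse=True)
    if len(levels) < 2:
        raise ValidationError("need >= 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(levels[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValidationError(f"group(s) of size 1: {small}")
    return codes, len(levels), sizes


def _permanova_f(d2: np.ndarray, codes: np.ndarray, g: int, sizes: np.ndarray):
    n = d2.shape[0]
    ss_t = d2[np.triu_indices(n, 1)].sum() / n
    ss_w = 0.0
    for k in range(g):
        idx = np.flatnonzero(codes == k)
        ss_w += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / sizes[k]
    ss_a = ss_t - ss_w
    f = (ss_a / (g - 1)) / (ss_w / (n - g))
    return f, ss_a / ss_t


def permanova(d: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0,
              strata=None) -> PermTestResult:
    """Anderson's distance-based PERMANOVA with free label permutation.

    ``strata``, if given, restricts permutations to within each stratum
    (e.g. within strain when repeated measures exist).
    """
    labels = np.asarray(labels)
    if len(labels) != len(d.sample_ids):
        raise ValidationError("labels length != number of samples")
    codes, g, sizes = _check_groups(labels)
    d2 = d.values ** 2
    f_obs, r2 = _permanova_f(d2, codes, g, sizes)
    rng = np.random.default_rng(seed)
    n = len(codes)
    strata_groups = None
    if strata is not None:
        strata = np.asarray(strata)
        strata_groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    exceed = 0
    perm = codes.copy()
    for _ in range(n_perm):
        if strata_groups is None:
            perm = rng.permutation(codes)
        else:
            perm = codes.copy()
            for idx in strata_groups:
                perm[idx] = perm[idx[rng.permutation(len(idx))]]
        sizes_p = np.bincount(perm, minlength=g)
        f_p, _ = _permanova_f(d2, perm, g, sizes_p)
        if f_p >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermTestResult(float(f_obs), float(r2), float(p), n_perm, seed)


def dispersion_distances(d: DistanceMatrix, labels) -> np.ndarray:
    """Per-sample distance to its group centroid in full signed PCoA space.

    Axes with negative eigenvalues contribute negatively to the squared
    distance, following the published dispersion method; small negative
    squared distances are truncated at zero.
    """
    labels = np.asarray(labels)
    ord_res = pcoa(d)
    ev, vec = ord_res.all_eigenvalues, ord_res.all_vectors
    nonzero = np.abs(ev) > 1e-10
    ev, vec = ev[nonzero], vec[:, nonzero]
    coords = vec * np.sqrt(np.abs(ev))[None, :]
    signs = np.sign(ev)
    z = np.empty(len(labels))
    for lev in np.unique(labels):
        idx = np.flatnonzero(labels == lev)
        centroid = coords[idx].mean(axis=0)
        diff2 = (coords[idx] - centroid[None, :]) ** 2
        z2 = (diff2 * signs[None, :]).sum(axis=1)
        z[idx] = np.sqrt(np.maximum(z2, 0.0))
    return z


def _anova_f(z: np.ndarray, codes: np.ndarray, g: int) -> float:
    n = len(z)
    grand = z.mean()
    ss_a = 0.0
    ss_w = 0.0
    for k in range(g):
        zk = z[codes == k]
        ss_a += len(zk) * (zk.mean() - grand) ** 2
        ss_w += ((zk - zk.mean()) ** 2).sum()
    scale = max((z ** 2).sum(), 1.0)
    if ss_a <= 1e-14 * scale and ss_w <= 1e-14 * scale:
        return 0.0
    if ss_w == 0:
        return np.inf
    return (ss_a / (g - 1)) / (ss_w / (n - g))


def permdisp(d: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0) -> PermTestResult:
    """Homogeneity-of-dispersions test (centroid variant).

    One-way ANOVA F on the distances to group centroids, with the
    permutation distribution obtained by permuting group labels of those
    distance values.
    """
    labels = np.asarray(labels)
    if len(labels) != len(d.sample_ids):
        raise ValidationError("labels length != number of samples")
    codes, g, _ = _check_groups(labels)
    z = dispersion_distances(d, labels)
    f_obs = _anova_f(z, codes, g)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_p = _anova_f(z, rng.permutation(codes), g)
        if f_p >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermTestResult(float(f_obs), None, float(p), n_perm, seed)
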