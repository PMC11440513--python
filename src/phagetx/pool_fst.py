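"""Subcontig divergence from pooled allele counts.

Pooled (Pool-seq) sequencing of phage contigs yields, per contig position, a
table of nucleotide read counts per sample pool (the ``sync`` interchange
format: colon-separated ``A:T:C:G:N:del`` columns).  This module aggregates
sample pools into comparison groups (all wild donors vs each
strain x treatment x day captive group), calls biallelic SNPs, computes the
classical pi-based per-SNP Fst between pools, splits SNPs into low/high-Fst
at the global median, and models the binary class with a binomial GLMM
(random intercept per SNP) to test whether divergence from the donor pool
changes over the experiment.

Fst here is the proportional reduction of nucleotide diversity within pools
relative to the pooled total::

    pi_pool  = n/(n-1) * 2 p (1-p)        (n = read count, p = allele freq)
    pi_w     = (pi_a + pi_b) / 2
    pi_t     = pi over the two pools' summed counts
    Fst      = (pi_t - pi_w) / pi_t       (clipped to [0, 1])

Read counts stand in for pool sizes, the usual Pool-seq convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import StudyMetadata, ValidationError

BASES = ("A", "T", "C", "G")
SYNC_FIELDS = ("A", "T", "C", "G", "N", "del")

DONOR_POOL = "donors"


@dataclass
class SyncTable:
    """Per contig-position pooled nucleotide counts.

    ``counts`` has shape (n_records, n_pools, 6) with the base order
    ``A, T, C, G, N, del``.
    """

    contigs: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    pool_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.contigs = np.asarray(self.contigs, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.contigs)
        if counts.shape != (n, len(self.pool_ids), 6):
            raise ValidationError(f"sync counts shape {counts.shape}, expected ({n}, {len(self.pool_ids)}, 6)")
        if (counts < 0).any():
            raise ValidationError("negative count in sync table")
        key = pd.MultiIndex.from_arrays([self.contigs, self.positions])
        if key.has_duplicates:
            raise ValidationError("duplicate (contig, position) records in sync table")
        self.counts = counts

    def __len__(self) -> int:
        return len(self.contigs)

    def select_pools(self, pool_ids: list[str]) -> "SyncTable":
        pos = {p: i for i, p in enumerate(self.pool_ids)}
        idx = [pos[p] for p in pool_ids]
        return SyncTable(self.contigs, self.positions, self.ref, list(pool_ids),
                         self.counts[:, idx, :])


def read_sync(path) -> SyncTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    pool_ids = list(df.columns[3:])
    n = len(df)
    counts = np.zeros((n, len(pool_ids), 6), dtype=np.int64)
    for j, p in enumerate(pool_ids):
        split = df[p].str.split(":", expand=True).to_numpy()
        if split.shape[1] != 6:
            raise ValidationError(f"pool {p!r}: expected 6 colon-separated counts")
        counts[:, j, :] = split.astype(np.int64)
    return SyncTable(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].astype(int).to_numpy(),
                     df.iloc[:, 2].to_numpy(), pool_ids, counts)


def write_sync(sync: SyncTable, path) -> None:
    cols = {"contig": sync.contigs, "position": sync.positions, "ref": sync.ref}
    for j, p in enumerate(sync.pool_ids):
        cols[p] = [":".join(map(str, row)) for row in sync.counts[:, j, :]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Grouping and SNP calling
# ---------------------------------------------------------------------------

def pool_groups(sync: SyncTable, metadata: StudyMetadata) -> SyncTable:
    """Sum per-sample pools into one donor pool + one pool per captive group.

    Captive pools are named ``{strain}|{treatment}|{day}`` with treatment in
    {recipient, control}; the donor pool sums all wild donor samples.
    """
    meta = metadata.samples.set_index("sample_id")
    unknown = [p for p in sync.pool_ids if p not in meta.index]
    if unknown:
        raise ValidationError(f"sync pool(s) not in metadata: {unknown[:5]}")
    group_of = {}
    for p in sync.pool_ids:
        row = meta.loc[p]
        if row["group"] == "wild_donor":
            group_of[p] = DONOR_POOL
        else:
            group_of[p] = f"{row['strain']}|{row['group']}|{row['day']}"
    groups = sorted(set(group_of.values()), key=lambda g: (g != DONOR_POOL, g))
    out = np.zeros((len(sync), len(groups), 6), dtype=np.int64)
    gidx = {g: i for i, g in enumerate(groups)}
    for j, p in enumerate(sync.pool_ids):
        out[:, gidx[group_of[p]], :] += sync.counts[:, j, :]
    empty = [g for g in groups if out[:, gidx[g], :].sum() == 0]
    if empty:
        raise ValidationError(f"empty pooled group(s): {empty}")
    return SyncTable(sync.contigs, sync.positions, sync.ref, groups, out)


@dataclass
class SnpCalls:
    """Biallelic SNPs between exactly two pools.

    ``counts`` has shape (n_snps, 2 pools, 2 alleles); ``allele_bases`` names
    the two retained alleles; ``discarded_flag`` marks positions where a
    low-count third allele was dropped.
    """

    contigs: np.ndarray
    positions: np.ndarray
    pool_ids: list[str]
    counts: np.ndarray
    allele_bases: np.ndarray
    discarded_flag: np.ndarray


def call_snps(sync: SyncTable, min_cov: int = 10, min_minor_count: int = 2) -> SnpCalls:
    """Filter a two-pool sync table to biallelic polymorphic positions.

    A position is kept when both pools reach ``min_cov`` coverage over
    A/C/G/T and exactly two alleles reach ``min_minor_count`` in the two
    pools combined.  Counts of further (sub-threshold) alleles are discarded
    with a per-position flag.
    """
    if len(sync.pool_ids) != 2:
        raise ValidationError(f"call_snps expects exactly 2 pools, got {len(sync.pool_ids)}")
    if min_cov < 4 or min_minor_count < 2:
        raise ValidationError("require min_cov >= 4 and min_minor_count >= 2")
    acgt = sync.counts[:, :, :4]
    cov = acgt.sum(axis=2)
    covered = (cov >= min_cov).all(axis=1)
    combined = acgt.sum(axis=1)
    qualifying = combined >= min_minor_count
    biallelic = qualifying.sum(axis=1) == 2
    keep = covered & biallelic
    idx = np.flatnonzero(keep)
    # two highest-count alleles per kept position
    order = np.argsort(-combined[idx], axis=1, kind="stable")[:, :2]
    counts = np.take_along_axis(acgt[idx], order[:, None, :], axis=2)
    bases = np.array(BASES, dtype=object)[order]
    n_alleles_present = (combined[idx] > 0).sum(axis=1)
    discarded = n_alleles_present > 2
    return SnpCalls(sync.contigs[idx], sync.positions[idx], list(sync.pool_ids),
                    counts, bases, discarded)


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

def fst_from_counts(a1, a2, b1, b2):
    """Vectorized pi-based Fst from biallelic counts of two pools.

    Returns NaN where the pooled total diversity is zero (monomorphic
    overall) or a pool has coverage < 2.
    """
    a1 = np.asarray(a1, float); a2 = np.asarray(a2, float)
    b1 = np.asarray(b1, float); b2 = np.asarray(b2, float)
    na, nb = a1 + a2, b1 + b2
    nt = na + nb
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_a = na / (na - 1) * 2 * (a1 / na) * (a2 / na)
        pi_b = nb / (nb - 1) * 2 * (b1 / nb) * (b2 / nb)
        pi_w = (pi_a + pi_b) / 2.0
        pt = (a1 + b1) / nt
        pi_t = nt / (nt - 1) * 2 * pt * (1 - pt)
        fst = (pi_t - pi_w) / pi_t
    fst = np.clip(fst, 0.0, 1.0)
    fst = np.where((na < 2) | (nb < 2) | (pi_t <= 0), np.nan, fst)
    return fst


def pairwise_fst(counts_a, counts_b) -> float:
    """Per-SNP Fst between two pools given biallelic counts ``(n1, n2)``."""
    a1, a2 = counts_a
    b1, b2 = counts_b
    if a1 + a2 < 2 or b1 + b2 < 2:
        raise ValidationError("pool coverage < 2")
    return float(fst_from_counts(a1, a2, b1, b2))


def compute_fst_records(sync: SyncTable, metadata: StudyMetadata,
                        min_cov: int = 10, min_minor_count: int = 2) -> pd.DataFrame:
    """Per-SNP Fst of every captive group pool against the donor pool.

    Returns a tidy frame with columns ``contig, position, snp_id, strain,
    treatment, day, fst, coverage_a, coverage_b`` (a = donors).  Positions
    whose pooled diversity is zero are dropped.
    """
    grouped = pool_groups(sync, metadata)
    captive = [g for g in grouped.pool_ids if g != DONOR_POOL]
    if DONOR_POOL not in grouped.pool_ids:
        raise ValidationError("no wild donor samples in sync table")
    frames = []
    for g in captive:
        pair = grouped.select_pools([DONOR_POOL, g])
        calls = call_snps(pair, min_cov=min_cov, min_minor_count=min_minor_count)
        if len(calls.contigs) == 0:
            continue
        fst = fst_from_counts(calls.counts[:, 0, 0], calls.counts[:, 0, 1],
                              calls.counts[:, 1, 0], calls.counts[:, 1, 1])
        strain, treatment, day = g.split("|")
        df = pd.DataFrame({
            "contig": calls.contigs, "position": calls.positions,
            "strain": strain, "treatment": treatment, "day": day,
            "fst": fst,
            "coverage_a": calls.counts[:, 0, :].sum(axis=1),
            "coverage_b": calls.counts[:, 1, :].sum(axis=1),
        })
        frames.append(df[np.isfinite(df["fst"])])
    if not frames:
        raise ValidationError("no SNPs passed filtering in any comparison")
    rec = pd.concat(frames, ignore_index=True)
    rec.insert(2, "snp_id", rec["contig"].astype(str) + ":" + rec["position"].astype(str))
    return rec


def binarize_fst(records: pd.DataFrame) -> pd.DataFrame:
    """Split Fst values at the global median: ``fst > median`` -> high.

    The median is taken across the full comparison set so classes are
    comparable across strains and days; ties go to low.  The threshold is
    stored in ``records.attrs['fst_median']``.
    """
    if len(records) < 2:
        raise ValidationError("need >= 2 Fst records to binarize")
    med = float(np.median(records["fst"]))
    out = records.copy()
    out["fst_class"] = np.where(out["fst"] > med, "high", "low")
    if (out["fst_class"] == "low").all() and out["fst"].nunique() == 1:
        warnings.warn("all Fst values equal; every SNP classed low")
    out.attrs["fst_median"] = med
    return out


def fst_divergence_test(records: pd.DataFrame, by_strain: bool = True) -> dict:
    """Binomial GLMM on the high/low-Fst class.

    Fixed effects ``strain * treatment * day`` (captive pools vs donors),
    random intercept per SNP.  Likelihood-ratio tests report the three-way
    interaction and, per strain, the ``treatment x day`` interaction.
    """
    from .glmm import GLMMSpec, fit_glmm, lr_test

    if "fst_class" not in records.columns:
        records = binarize_fst(records)
    data = records.copy()
    data["high"] = (data["fst_class"] == "high").astype(int)
    if data["snp_id"].nunique() < 2:
        raise ValidationError("need >= 2 SNPs for a per-SNP random intercept")
    out: dict = {"fits": {}, "tests": {}, "median": records.attrs.get("fst_median")}
    multi_strain = data["strain"].nunique() > 1
    if multi_strain:
        full = fit_glmm(GLMMSpec("strain * treatment * day", "high", "binomial",
                                 random_intercepts=("snp_id",)), data, compute_se=False)
        red = fit_glmm(GLMMSpec("strain * treatment * day - strain:treatment:day", "high",
                                "binomial", random_intercepts=("snp_id",)), data, compute_se=False)
        out["fits"]["combined"] = full
        out["tests"]["strain:treatment:day"] = lr_test(full, red)
    if by_strain:
        for strain, sub in data.groupby("strain"):
            if sub["treatment"].nunique() < 2 or sub["day"].nunique() < 2:
                continue
            full = fit_glmm(GLMMSpec("treatment * day", "high", "binomial",
                                     random_intercepts=("snp_id",)), sub, compute_se=False)
            red = fit_glmm(GLMMSpec("treatment + day", "high", "binomial",
                                    random_intercepts=("snp_id",)), sub, compute_se=False)
            out["fits"][strain] = full
            out["tests"][f"{strain}:treatment:day"] = lr_test(full, red)
    return out


def high_fst_proportions(records: pd.DataFrame) -> pd.DataFrame:
    """Proportion of high-Fst SNPs per strain x treatment x day pool."""
    if "fst_class" not in records.columns:
        records = binarize_fst(records)
    grp = records.groupby(["strain", "treatment", "day"], as_index=False).agg(
        n_snps=("fst", "size"), prop_high=("fst_class", lambda s: float((s == "high").mean())))
    return grp
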