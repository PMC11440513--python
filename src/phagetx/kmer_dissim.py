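"""Exact k-mer set dissimilarities between per-sample sequence collections.

Sequence-content dissimilarities complement mapping-based community
distances: they compare what was assembled in two samples, independent of a
shared reference.  At desk scale the k-mer sets are small enough to count
exactly, so the sketch-based estimators (weighted Jaccard ``probWJ``, set
Jaccard ``Jexact``, and the asymmetric containment index) are computed here
from exact canonical k-mer multisets rather than approximated.

K-mers are canonicalized to the lexicographic minimum of the k-mer and its
reverse complement, and windows containing non-ACGT symbols are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .core_io import DistanceMatrix, ValidationError

_COMP = str.maketrans("ACGT", "TGCA")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class KmerProfile:
    """Canonical k-mer -> multiplicity map for one sample.

    Stored as sorted uint64 codes (2 bits/base) with parallel counts, which
    keeps pairwise set operations vectorized.
    """

    sample_id: str
    k: int
    codes: np.ndarray
    counts: np.ndarray

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def kmers(self) -> dict:
        """Decoded canonical k-mer strings -> multiplicity."""
        out = {}
        for code, cnt in zip(self.codes.tolist(), self.counts.tolist()):
            bases = []
            for _ in range(self.k):
                bases.append("ACGT"[code & 3])
                code >>= 2
            out["".join(reversed(bases))] = int(cnt)
        return out


def _encode_kmers(seq: str, k: int) -> np.ndarray:
    """uint64 codes of the canonical k-mers of one sequence (N windows skipped)."""
    seq = seq.upper()
    vals = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(len(vals), 255, dtype=np.uint8)
    for b, v in _CODE.items():
        code[vals == ord(b)] = v
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    windows = np.lib.stride_tricks.sliding_window_view(code, k)
    valid = (windows != 255).all(axis=1)
    windows = windows[valid].astype(np.uint64)
    mult = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd = windows @ mult
    rc_windows = (np.uint64(3) - windows)[:, ::-1]
    rev = rc_windows @ mult
    return np.minimum(fwd, rev)


def kmer_profile(sequences, k: int = 31, sample_id: str = "") -> KmerProfile:
    """Exact canonical k-mer multiset of a sequence collection.

    ``sequences`` may be an iterable of strings, Bio.SeqRecord objects, or a
    FASTA path.  ``k`` must be odd (so no k-mer is its own reverse
    complement) and between 3 and 31.
    """
    if k % 2 == 0 or not 3 <= k <= 31:
        raise ValidationError(f"k must be odd and in [3, 31], got {k}")
    if isinstance(sequences, (str, Path)) and Path(str(sequences)).exists():
        sequences = [str(rec.seq) for rec in SeqIO.parse(str(sequences), "fasta")]
    seqs = [str(getattr(s, "seq", s)) for s in sequences]
    parts = [_encode_kmers(s, k) for s in seqs if len(s) >= k]
    if not parts or sum(len(p) for p in parts) == 0:
        warnings.warn(f"empty k-mer profile for sample {sample_id!r}")
        return KmerProfile(sample_id, k, np.empty(0, dtype=np.uint64),
                           np.empty(0, dtype=np.int64))
    allk = np.concatenate(parts)
    codes, counts = np.unique(allk, return_counts=True)
    return KmerProfile(sample_id, k, codes, counts.astype(np.int64))


def _check_pair(a: KmerProfile, b: KmerProfile) -> None:
    if a.k != b.k:
        raise ValidationError(f"k mismatch: {a.k} vs {b.k}")


def jexact_distance(a: KmerProfile, b: KmerProfile) -> float:
    """Set-Jaccard distance on the canonical k-mer key sets."""
    _check_pair(a, b)
    if len(a) == 0 and len(b) == 0:
        warnings.warn("both profiles empty; Jexact distance set to 0")
        return 0.0
    inter = len(np.intersect1d(a.codes, b.codes, assume_unique=True))
    union = len(a) + len(b) - inter
    return 1.0 - inter / union


def probwj_distance(a: KmerProfile, b: KmerProfile) -> float:
    """Weighted Jaccard distance ``1 - sum min(w) / sum max(w)`` over the key union."""
    _check_pair(a, b)
    if len(a) == 0 and len(b) == 0:
        warnings.warn("both profiles empty; probWJ distance set to 0")
        return 0.0
    common, ia, ib = np.intersect1d(a.codes, b.codes, assume_unique=True,
                                    return_indices=True)
    wa, wb = a.counts[ia], b.counts[ib]
    s_min = np.minimum(wa, wb).sum()
    s_max = np.maximum(wa, wb).sum() + (a.counts.sum() - wa.sum()) + (b.counts.sum() - wb.sum())
    return 1.0 - s_min / s_max


def containment_index(a: KmerProfile, b: KmerProfile) -> float:
    """Fraction of a's k-mer keys found in b (asymmetric)."""
    _check_pair(a, b)
    if len(a) == 0:
        raise ValidationError("containment undefined for empty first profile")
    inter = len(np.intersect1d(a.codes, b.codes, assume_unique=True))
    return inter / len(a)


def kmer_distance_matrix(profiles: list[KmerProfile], metric: str = "jexact") -> DistanceMatrix:
    """Square dissimilarity matrix over samples for ``jexact`` or ``probWJ``."""
    fn = {"jexact": jexact_distance, "probWJ": probwj_distance}.get(metric)
    if fn is None:
        raise ValidationError(f"unknown kmer metric {metric!r}")
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(profiles[i], profiles[j])
    return DistanceMatrix([p.sample_id for p in profiles], d, metric)


def containment_matrix(profiles_a: list[KmerProfile], profiles_b: list[KmerProfile]) -> np.ndarray:
    """Rectangular containment of each profile in ``profiles_a`` within each in ``profiles_b``."""
    return np.array([[containment_index(a, b) for b in profiles_b] for a in profiles_a])
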