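"""Domain types and tabular I/O shared by every analysis stage.

The experiment this package analyses follows a fixed design: wild donor mice
(sampled once, at day ``D0``) provide fecal virome filtrates that are
transplanted into captive recipient mice from one or more inbred strains;
additional captive mice serve as non-transplanted controls.  Captive mice are
sampled one day before transplantation (``D-1``) and two and seven days after
(``D2``, ``D7``).  :class:`StudyMetadata` encodes that design skeleton and is
consumed by all downstream stages.

All tabular formats are plain TSV (UTF-8, samples as columns, feature or
sample identifiers as opaque strings).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("wild_donor", "recipient", "control")
WILD_STRAIN = "wild"
DAY_DONOR = "D0"
DAYS_CAPTIVE = ("D-1", "D2", "D7")
DAYS = ("D-1", "D0", "D2", "D7")
METRICS = ("bray_curtis", "jaccard", "probWJ", "jexact")

METADATA_COLUMNS = ("sample_id", "mouse_id", "group", "strain", "locality", "day", "donor_id")

ANNOTATION_COLUMNS = ("lifestyle", "family", "host_family", "length_bp")
LIFESTYLES = ("temperate", "virulent", "undetermined")


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


# ---------------------------------------------------------------------------
# StudyMetadata
# ---------------------------------------------------------------------------

@dataclass
class StudyMetadata:
    """Sample -> mouse/group/strain/day/donor map for one study.

    Parameters
    ----------
    samples
        One row per sample with columns ``sample_id, mouse_id, group, strain,
        locality, day, donor_id``.  ``locality`` is only meaningful for wild
        donors, ``donor_id`` only for recipients (it names the wild *mouse*
        the recipient received its transplant from).
    """

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.samples.copy()
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if len(df) == 0:
            raise ValidationError("no samples in metadata")
        df = df[list(METADATA_COLUMNS)].reset_index(drop=True)
        for col in ("locality", "donor_id"):
            df[col] = df[col].replace({"": None, np.nan: None})
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown group level(s): {sorted(bad_group)}")
        bad_day = set(df["day"]) - set(DAYS)
        if bad_day:
            raise ValidationError(f"unknown day level(s): {sorted(bad_day)}")

        wild = df["group"] == "wild_donor"
        if (df.loc[wild, "strain"] != WILD_STRAIN).any():
            raise ValidationError("wild donors must have strain='wild'")
        if (df.loc[~wild, "strain"] == WILD_STRAIN).any():
            raise ValidationError("captive mice cannot have strain='wild'")
        if (df.loc[wild, "day"] != DAY_DONOR).any():
            raise ValidationError(f"wild donor samples must carry day={DAY_DONOR}")
        if (~df.loc[~wild, "day"].isin(DAYS_CAPTIVE)).any():
            raise ValidationError(f"captive samples must carry day in {DAYS_CAPTIVE}")

        donors = set(df.loc[wild, "mouse_id"])
        is_recip = df["group"] == "recipient"
        recip_mice = df.loc[is_recip, ["mouse_id", "donor_id"]]
        if recip_mice["donor_id"].isna().any():
            bad = recip_mice.loc[recip_mice["donor_id"].isna(), "mouse_id"].tolist()
            raise ValidationError(f"recipient(s) without donor_id: {sorted(set(bad))}")
        unknown = set(recip_mice["donor_id"]) - donors
        if unknown:
            raise ValidationError(f"donor_id not among wild donors: {sorted(unknown)}")
        per_mouse = recip_mice.groupby("mouse_id")["donor_id"].nunique()
        if (per_mouse > 1).any():
            raise ValidationError(
                f"recipient(s) paired with more than one donor: {per_mouse[per_mouse > 1].index.tolist()}")
        if df.loc[~is_recip, "donor_id"].notna().any():
            bad = df.loc[~is_recip & df["donor_id"].notna(), "mouse_id"].tolist()
            raise ValidationError(f"controls and wild donors must have empty donor_id: {sorted(set(bad))}")
        object.__setattr__(self, "samples", df)

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    @property
    def donors(self) -> list[str]:
        """Wild donor mouse ids, in order of first appearance."""
        wild = self.samples[self.samples["group"] == "wild_donor"]
        return wild["mouse_id"].drop_duplicates().tolist()

    @property
    def strains(self) -> list[str]:
        cap = self.samples[self.samples["group"] != "wild_donor"]
        return sorted(cap["strain"].unique())

    def mice(self, group: str | None = None, strain: str | None = None) -> list[str]:
        df = self.samples
        if group is not None:
            df = df[df["group"] == group]
        if strain is not None:
            df = df[df["strain"] == strain]
        return df["mouse_id"].drop_duplicates().tolist()

    def recipients_of(self, donor_id: str) -> list[str]:
        df = self.samples
        sel = (df["group"] == "recipient") & (df["donor_id"] == donor_id)
        return df.loc[sel, "mouse_id"].drop_duplicates().tolist()

    def donor_of(self, mouse_id: str) -> str | None:
        df = self.samples
        vals = df.loc[df["mouse_id"] == mouse_id, "donor_id"].dropna().unique()
        return vals[0] if len(vals) else None

    def select(self, **criteria) -> list[str]:
        """Sample ids matching equality criteria on metadata columns.

        ``day`` / ``group`` / ``strain`` may be a single level or a list.
        """
        df = self.samples
        for col, val in criteria.items():
            if col not in METADATA_COLUMNS:
                raise KeyError(col)
            if isinstance(val, (list, tuple, set)):
                df = df[df[col].isin(list(val))]
            else:
                df = df[df[col] == val]
        return df["sample_id"].tolist()

    def sample_of(self, mouse_id: str, day: str) -> str:
        hits = self.select(mouse_id=mouse_id, day=day)
        if len(hits) != 1:
            raise KeyError(f"expected one sample for mouse {mouse_id} at {day}, found {hits}")
        return hits[0]

    def row(self, sample_id: str) -> pd.Series:
        df = self.samples
        hit = df[df["sample_id"] == sample_id]
        if len(hit) != 1:
            raise KeyError(sample_id)
        return hit.iloc[0]


def read_metadata(path) -> StudyMetadata:
    """Read a study-design TSV (columns as in :data:`METADATA_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if len(df) == 0:
        raise ValidationError(f"no samples in metadata file {path}")
    return StudyMetadata(df)


def write_metadata(meta: StudyMetadata, path) -> None:
    out = meta.samples.copy()
    for col in ("locality", "donor_id"):
        out[col] = out[col].fillna("")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CountMatrix / PresenceMatrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Features x samples non-negative integer read counts.

    ``annotations`` (optional, phage contigs only) is indexed by feature id
    with columns ``lifestyle`` (temperate / virulent / undetermined),
    ``family``, ``host_family`` (may be null) and ``length_bp``.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.feature_ids = list(map(str, self.feature_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            f, s = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at feature {self.feature_ids[f]!r}, sample {self.sample_ids[s]!r}")
        seen = pd.Index(self.feature_ids)
        if seen.has_duplicates:
            raise ValidationError(f"duplicate feature ids: {seen[seen.duplicated()].unique().tolist()}")
        if pd.Index(self.sample_ids).has_duplicates:
            raise ValidationError("duplicate sample ids in count matrix")
        if self.annotations is not None:
            extra = self.annotations.index.difference(seen)
            if len(extra):
                raise ValidationError(f"annotation for unknown feature(s): {extra.tolist()[:5]}")
        self.counts = counts

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.feature_ids, name="feature_id"),
                            columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return CountMatrix(self.feature_ids, list(sample_ids), self.counts[:, idx], self.annotations)

    def lifestyle_of(self, feature_id: str) -> str:
        if self.annotations is None or feature_id not in self.annotations.index:
            return "undetermined"
        return self.annotations.loc[feature_id, "lifestyle"]


@dataclass
class PresenceMatrix:
    """Boolean feature presence derived from counts at a read threshold."""

    feature_ids: list[str]
    sample_ids: list[str]
    present: np.ndarray
    min_reads: int

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError("presence matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.present, index=pd.Index(self.feature_ids, name="feature_id"),
                            columns=self.sample_ids)


def to_presence(counts: CountMatrix, min_reads: int = 2) -> PresenceMatrix:
    """Threshold counts into presence/absence (``count >= min_reads``)."""
    if min_reads < 1:
        raise ValidationError(f"min_reads must be >= 1, got {min_reads}")
    return PresenceMatrix(counts.feature_ids, counts.sample_ids,
                          counts.counts >= min_reads, int(min_reads))


def relative_abundance(counts: CountMatrix) -> np.ndarray:
    """Total-sum-scaled proportions; columns sum to one."""
    totals = counts.counts.sum(axis=0)
    if (totals == 0).any():
        bad = [counts.sample_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValidationError(f"zero-total sample(s): {bad}")
    return counts.counts / totals[None, :].astype(float)


def read_count_matrix(path, annotation_path=None) -> CountMatrix:
    """Read a feature x sample TSV of integer counts (+ optional annotations).

    The first column holds feature ids; the header row holds sample ids.
    Features absent from the annotation table get ``lifestyle=undetermined``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature ids in {path}: {dups}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.all(np.equal(np.mod(arr, 1), 0)):
        bad = np.argwhere(~np.equal(np.mod(arr.astype(float), 1), 0))
        f, s = bad[0] if len(bad) else (0, 0)
        raise ValidationError(
            f"non-integer count in {path} at feature {df.index[f]!r}, sample {df.columns[s]!r}")
    annotations = None
    if annotation_path is not None:
        annotations = read_annotations(annotation_path, feature_ids=df.index)
    return CountMatrix(df.index.tolist(), df.columns.tolist(), arr.astype(np.int64), annotations)


def read_annotations(path, feature_ids=None) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    ann.index = ann.index.astype(str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValidationError(f"annotation table missing columns: {missing}")
    ann["host_family"] = ann["host_family"].replace({"": None})
    bad = set(ann["lifestyle"]) - set(LIFESTYLES)
    if bad:
        raise ValidationError(f"unknown lifestyle level(s): {sorted(bad)}")
    if feature_ids is not None:
        idx = pd.Index([str(f) for f in feature_ids])
        extra = ann.index.difference(idx)
        if len(extra):
            raise ValidationError(f"annotation for unknown feature(s): {extra.tolist()[:5]}")
        # unannotated features default to undetermined lifestyle
        ann = ann.reindex(idx)
        ann["lifestyle"] = ann["lifestyle"].fillna("undetermined")
        ann["family"] = ann["family"].fillna("unclassified")
        ann["host_family"] = ann["host_family"].where(ann["host_family"].notna(), None)
    return ann


def write_count_matrix(counts: CountMatrix, path, annotation_path=None) -> None:
    counts.to_frame().to_csv(path, sep="\t")
    if annotation_path is not None and counts.annotations is not None:
        ann = counts.annotations.copy()
        ann["host_family"] = ann["host_family"].fillna("")
        ann.index.name = "feature_id"
        ann.to_csv(annotation_path, sep="\t")


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric sample x sample dissimilarities in [0, 1]."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} for {n} samples")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric within 1e-12")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix diagonal not zero")
        if v.min(initial=0.0) < -1e-12 or v.max(initial=0.0) > 1 + 1e-12:
            raise ValidationError("distance values outside [0, 1]")
        v = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(v, 0.0)
        self.values = v

    def get(self, a: str, b: str) -> float:
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.values[i, j])

    def subset(self, sample_ids: list[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids])
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)], self.metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def read_distance_matrix(path, metric: str = "bray_curtis") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError("distance matrix row/column headers differ")
    return DistanceMatrix(df.index.astype(str).tolist(), df.to_numpy(float), metric)


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    d.to_frame().to_csv(path, sep="\t")
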