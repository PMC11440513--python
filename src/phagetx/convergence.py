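"""Donor-recipient convergence models on community dissimilarities.

The central question of the transplantation analysis: do recipient
communities move *toward* their own donor's community after the transplant,
relative to non-transplanted controls?  The unit of analysis is a
donor-captive dissimilarity: each recipient is paired with its own donor at
each captive sampling day (D-1, D2, D7), while each control is paired with
every donor.  Dissimilarities are modelled with a Gamma/log GLMM (they are
positive and effects plausibly multiplicative) with crossed random
intercepts for the captive mouse and the wild donor.  A significant
``day x treatment`` interaction means the dissimilarity trajectories of
recipients and controls diverged over the experiment; its modulation by
strain is captured by the three-way interaction.

The same machinery fits the temperate-fraction time course: per-sample
(temperate reads, lifestyle-assigned reads) modelled as binomial with an
observation-level random intercept for overdispersion plus a mouse random
intercept.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .core_io import CountMatrix, DistanceMatrix, StudyMetadata, ValidationError
from .glmm import GLMMSpec, fit_glmm, lr_test, pairwise_contrasts


def build_donor_distance_table(d: DistanceMatrix, metadata: StudyMetadata) -> pd.DataFrame:
    """Tidy donor-captive dissimilarity rows.

    Recipients contribute one row per captive day against their matched
    donor's D0 sample; controls contribute one row per day per donor.  Zero
    dissimilarities (identical samples) are replaced by half the smallest
    positive value so the Gamma family's support is respected; such rows are
    flagged in the ``zero_replaced`` column and a warning is emitted.
    """
    samples = metadata.samples
    donor_sample = {}
    for donor in metadata.donors:
        hits = metadata.select(mouse_id=donor, day="D0")
        if len(hits) != 1:
            raise ValidationError(f"expected one D0 sample for donor {donor}, found {hits}")
        donor_sample[donor] = hits[0]
    have = set(d.sample_ids)
    missing = [s for s in donor_sample.values() if s not in have]
    if missing:
        raise ValidationError(f"distance matrix lacks donor sample(s): {missing}")

    rows = []
    captive = samples[samples["group"].isin(["recipient", "control"])]
    for _, r in captive.iterrows():
        if r["sample_id"] not in have:
            raise ValidationError(f"distance matrix lacks captive sample {r['sample_id']!r}")
        if r["group"] == "recipient":
            donor = r["donor_id"]
            if donor_sample.get(donor) is None:
                raise ValidationError(
                    f"recipient {r['mouse_id']!r} paired with absent donor {donor!r}")
            pair_donors = [donor]
        else:
            pair_donors = metadata.donors
        for donor in pair_donors:
            rows.append({
                "captive_mouse_id": r["mouse_id"],
                "donor_id": donor,
                "day": r["day"],
                "treatment": r["group"],
                "strain": r["strain"],
                "dissimilarity": d.get(r["sample_id"], donor_sample[donor]),
            })
    tab = pd.DataFrame(rows)
    zero = tab["dissimilarity"] <= 0.0
    tab["zero_replaced"] = zero
    if zero.any():
        pos = tab.loc[~zero, "dissimilarity"]
        if len(pos) == 0:
            raise ValidationError("all dissimilarities are zero; Gamma model undefined")
        repl = 0.5 * float(pos.min())
        tab.loc[zero, "dissimilarity"] = repl
        warnings.warn(f"{int(zero.sum())} zero dissimilarities replaced by {repl:.3g}")
    return tab


def convergence_test(rows: pd.DataFrame, by_strain: bool = True,
                     contrast_alpha: float = 0.05) -> dict:
    """Gamma-GLMM ladder on donor-captive dissimilarities.

    Combined model: ``day * treatment * strain`` with random intercepts for
    captive mouse and donor; LR tests of the three-way and the two-way
    ``day:treatment`` interactions.  With ``by_strain``, per-strain
    ``day * treatment`` models and, per treatment arm, day-only models with
    Holm-adjusted pairwise day contrasts (compact letter display).
    """
    req = {"captive_mouse_id", "donor_id", "day", "treatment", "strain", "dissimilarity"}
    if not req <= set(rows.columns):
        raise ValidationError(f"rows missing columns: {sorted(req - set(rows.columns))}")
    for col in ("treatment", "day"):
        if rows[col].nunique() < 2:
            raise ValidationError(f"need >= 2 levels of {col!r} for the convergence model")
    ri = ("captive_mouse_id", "donor_id")
    out: dict = {"fits": {}, "tests": {}, "contrasts": {}}

    multi_strain = rows["strain"].nunique() > 1
    if multi_strain:
        full = fit_glmm(GLMMSpec("day * treatment * strain", "dissimilarity", "gamma",
                                 random_intercepts=ri), rows, compute_se=False)
        red3 = fit_glmm(GLMMSpec("day * treatment * strain - day:treatment:strain",
                                 "dissimilarity", "gamma", random_intercepts=ri),
                        rows, compute_se=False)
        out["fits"]["combined"] = full
        out["tests"]["day:treatment:strain"] = lr_test(full, red3)
        dt_full = fit_glmm(GLMMSpec("day * treatment + strain", "dissimilarity", "gamma",
                                    random_intercepts=ri), rows, compute_se=False)
        dt_red = fit_glmm(GLMMSpec("day + treatment + strain", "dissimilarity", "gamma",
                                   random_intercepts=ri), rows, compute_se=False)
        out["tests"]["day:treatment"] = lr_test(dt_full, dt_red)
    else:
        dt_full = fit_glmm(GLMMSpec("day * treatment", "dissimilarity", "gamma",
                                    random_intercepts=ri), rows, compute_se=False)
        dt_red = fit_glmm(GLMMSpec("day + treatment", "dissimilarity", "gamma",
                                   random_intercepts=ri), rows, compute_se=False)
        out["fits"]["combined"] = dt_full
        out["tests"]["day:treatment"] = lr_test(dt_full, dt_red)

    if by_strain:
        strains = sorted(rows["strain"].unique())
        for strain in strains:
            sub = rows[rows["strain"] == strain]
            if len(sub) == 0:
                raise ValidationError(f"no rows for strain {strain!r}")
            full = fit_glmm(GLMMSpec("day * treatment", "dissimilarity", "gamma",
                                     random_intercepts=ri), sub, compute_se=False)
            red = fit_glmm(GLMMSpec("day + treatment", "dissimilarity", "gamma",
                                    random_intercepts=ri), sub, compute_se=False)
            out["fits"][strain] = full
            out["tests"][f"{strain}:day:treatment"] = lr_test(full, red)
            for treatment, tsub in sub.groupby("treatment"):
                label = f"{strain}:{treatment}"
                ri_t = ri if tsub["donor_id"].nunique() > 1 else ("captive_mouse_id",)
                day_fit = fit_glmm(GLMMSpec("day", "dissimilarity", "gamma",
                                            random_intercepts=ri_t), tsub)
                day_red = fit_glmm(GLMMSpec("1", "dissimilarity", "gamma",
                                            random_intercepts=ri_t), tsub, compute_se=False)
                out["fits"][label] = day_fit
                out["tests"][f"{label}:day"] = lr_test(day_fit, day_red)
                out["contrasts"][label] = pairwise_contrasts(day_fit, "day",
                                                             alpha=contrast_alpha)
    return out


def temperate_proportion_table(counts: CountMatrix, metadata: StudyMetadata,
                               include_undetermined: bool = False) -> pd.DataFrame:
    """Per-captive-sample temperate read counts out of lifestyle-assigned reads.

    Undetermined-lifestyle contigs are excluded from numerator and
    denominator unless ``include_undetermined`` (then they count as
    non-temperate denominator reads).
    """
    if counts.annotations is None:
        raise ValidationError("temperate proportions require lifestyle annotations")
    lifestyles = counts.annotations.reindex(counts.feature_ids)["lifestyle"].to_numpy()
    if not (lifestyles == "temperate").any():
        raise ValidationError("no temperate contigs in annotations")
    temperate = counts.counts[lifestyles == "temperate"].sum(axis=0)
    if include_undetermined:
        total = counts.counts.sum(axis=0)
    else:
        total = counts.counts[lifestyles != "undetermined"].sum(axis=0)
    tab = pd.DataFrame({"sample_id": counts.sample_ids,
                        "temperate": temperate, "assigned": total})
    tab = tab.merge(metadata.samples, on="sample_id", how="inner")
    cap = tab[tab["group"].isin(["recipient", "control"])].reset_index(drop=True)
    cap = cap.rename(columns={"group": "treatment"})
    cap["obs_id"] = [f"obs{i}" for i in range(len(cap))]
    if (cap["assigned"] == 0).any():
        raise ValidationError("sample(s) with zero lifestyle-assigned reads")
    return cap


def temperate_proportion_test(counts: CountMatrix, metadata: StudyMetadata,
                              include_undetermined: bool = False) -> dict:
    """Binomial GLMM time course of the temperate fraction in captive mice.

    Observation-level random intercept absorbs extra-binomial noise; mouse
    random intercept handles repeated measures.  Reports LR tests of
    ``day:treatment`` and ``day:treatment:strain``.
    """
    cap = temperate_proportion_table(counts, metadata, include_undetermined)
    props = cap["temperate"] / cap["assigned"]
    if props.nunique() == 1:
        warnings.warn("temperate proportion constant across samples; model degenerate")
    ri = ("mouse_id", "obs_id")
    out: dict = {"fits": {}, "tests": {}, "table": cap}
    multi_strain = cap["strain"].nunique() > 1
    if multi_strain:
        full = fit_glmm(GLMMSpec("day * treatment * strain", ("temperate", "assigned"),
                                 "binomial", random_intercepts=ri), cap, compute_se=False)
        red3 = fit_glmm(GLMMSpec("day * treatment * strain - day:treatment:strain",
                                 ("temperate", "assigned"), "binomial",
                                 random_intercepts=ri), cap, compute_se=False)
        out["fits"]["combined"] = full
        out["tests"]["day:treatment:strain"] = lr_test(full, red3)
        dt_full = fit_glmm(GLMMSpec("day * treatment + strain", ("temperate", "assigned"),
                                    "binomial", random_intercepts=ri), cap, compute_se=False)
        dt_red = fit_glmm(GLMMSpec("day + treatment + strain", ("temperate", "assigned"),
                                   "binomial", random_intercepts=ri), cap, compute_se=False)
        out["tests"]["day:treatment"] = lr_test(dt_full, dt_red)
    else:
        dt_full = fit_glmm(GLMMSpec("day * treatment", ("temperate", "assigned"),
                                    "binomial", random_intercepts=ri), cap, compute_se=False)
        dt_red = fit_glmm(GLMMSpec("day + treatment", ("temperate", "assigned"),
                                   "binomial", random_intercepts=ri), cap, compute_se=False)
        out["fits"]["combined"] = dt_full
        out["tests"]["day:treatment"] = lr_test(dt_full, dt_red)
    return out
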