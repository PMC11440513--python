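"""Synthetic phageome-transplantation studies with known ground truth.

The generator emulates the design of a wild-to-captive fecal virome
transplantation experiment: wild donor mice trapped at a few localities are
each paired with one recipient per captive strain; recipients and
non-transplanted controls are sampled before (D-1) and after (D2, D7) the
transplant, donors once (D0).

Community model
---------------
Each mouse carries a subset of contigs ("carriers") drawn from five contig
classes: a shared core (broader occupancy in the wild — wild communities
are richer), wild-associated and captive-associated sets (abundance bonus
``wild_captive_effect`` in their matching group, trace-level presence in
the other), *patchy* wild contigs sparse across donors (the source of
chance donor-recipient co-occurrence), and wild individual-specific contigs
private to a single donor (the pool from which transmission events are
planted; abundant in their carrier).  A few captive-core contigs get a
dominance bonus in captive mice, reproducing the low evenness of
conventional-facility communities.  Log-latent abundances add contig
baselines, strain and locality loadings, per-mouse individual effects
(larger in the wild, reproducing the higher interindividual variation of
wild communities), small per-day noise, mouse-level latent factors shared
with the bacterial (ASV) community at ``coupling_strength``, and planted
per-pair contig-ASV couplings.  Reads are multinomial draws at
Poisson-distributed depth, so low-abundance contigs flicker around any
presence threshold exactly as mapping counts do.

Randomness is split into a community-template stream (contig/ASV-level
parameters, seeded by ``seed``) and a cohort stream (everything indexed by
mouse or sample; ``mouse_seed`` when given, otherwise derived from
``seed``), so replicate cohorts of the same community can be generated.

Transmission is planted by moving a ``transmission_rate`` fraction of each
donor's private contigs into its own recipients' post-transplant (D2/D7)
latent communities at ``transmitted_abundance_factor`` times the donor
relative abundance.  Controls and pre-transplant samples can never carry
them, which the generator guarantees by construction.

Allele-frequency (sync) tables plant a wild-vs-captive frequency gap
``snp_divergence`` at SNP sites of a subset of shared contigs; recipient
pools drift toward donor frequencies after transplantation at a per-strain
``convergence_rate`` (0.6 of the full drift by D2, all of it by D7).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (CountMatrix, StudyMetadata, ValidationError, write_count_matrix,
                      write_metadata)
from .pool_fst import SyncTable, write_sync

_DEFAULT_LOCALITIES = ("Jed", "Nlc", "Vpol")

# contig class fractions: shared core, wild-associated, captive-associated,
# patchy wild (sparse across donors, trace-level in captive mice), wild
# individual-specific
_CLASS_FRACTIONS = {"shared": 0.25, "wild": 0.20, "captive": 0.10,
                    "patchy": 0.15, "wild_specific": 0.30}
_OCCUPANCY = {
    # (prob wild carrier, prob captive carrier) — ASV communities
    "shared": (0.9, 0.9),
    "wild": (0.8, 0.05),
    "captive": (0.05, 0.8),
}


@dataclass
class SimulationConfig:
    """Study-design and effect-size knobs of the generator.

    Defaults mirror the transplantation design (10 donors from 3 localities,
    10 recipients + 3 controls per strain, two captive strains) at a
    sequencing depth and effect sizes chosen to make every downstream
    statistical property decidable at desk scale.
    """

    seed: int
    n_donors: int = 10
    n_localities: int = 3
    strains: tuple = ("BULS", "BUSNA")
    n_recipients_per_strain: int = 10
    n_controls_per_strain: int = 3
    n_contigs: int = 1000
    n_asvs: int = 150
    depth_mean: int = 30000
    asv_depth_mean: int = 20000
    prop_temperate: float = 0.465
    prop_undetermined: float = 0.173
    transmission_rate: float = 0.5
    transmitted_abundance_factor: float = 0.1
    wild_captive_effect: float = 1.0
    strain_effect: float = 0.8
    locality_effect: float = 0.5
    individual_sd_wild: float = 0.9
    individual_sd_captive: float = 0.6
    day_sd: float = 0.3
    coupling_strength: float = 0.6
    n_coupled_pairs: int = 8
    coupling_sd: float = 1.5
    snp_contigs: int = 30
    snp_sites_per_contig: int = 20
    snp_divergence: float = 0.6
    snp_coverage_mean: float = 30.0
    specific_abundance_bonus: float = 2.5
    trace_occupancy: float = 0.3
    trace_abundance_penalty: float = 4.25
    n_dominant_captive: int = 5
    captive_dominance: float = 3.0
    convergence_rate: dict = field(default_factory=lambda: {"BULS": 0.7, "BUSNA": 0.0})
    contig_seq_length: int = 300
    # optional: regenerate the cohort (mice, read draws) while keeping the
    # community template (contig/ASV parameters) fixed by `seed`
    mouse_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("transmission_rate", "prop_temperate", "prop_undetermined",
                     "coupling_strength", "snp_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("wild_captive_effect", "strain_effect", "locality_effect"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for s, r in self.convergence_rate.items():
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"convergence_rate[{s}] must be in [0, 1]")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        self.strains = tuple(self.strains)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery/calibration tests."""

    transmitted_contigs: set          # {(contig_id, donor_mouse_id)}
    temperate_labels: dict            # contig_id -> lifestyle
    true_fixed_effects: dict          # effect name -> value
    coupled_pairs: set                # {(contig_id, asv_id, sign)}
    donor_private_contigs: dict       # donor mouse id -> [contig_id]


def _localities(n: int) -> list[str]:
    if n <= len(_DEFAULT_LOCALITIES):
        return list(_DEFAULT_LOCALITIES[:n])
    return list(_DEFAULT_LOCALITIES) + [f"Loc{i}" for i in range(4, n + 1)]


def design_metadata(cfg: SimulationConfig) -> StudyMetadata:
    """Build the study design skeleton (no randomness involved)."""
    locs = _localities(cfg.n_localities)
    rows = []
    donors = [f"W{i + 1:02d}" for i in range(cfg.n_donors)]
    for i, d in enumerate(donors):
        rows.append((f"{d}_D0", d, "wild_donor", "wild", locs[i % len(locs)], "D0", None))
    for strain in cfg.strains:
        for i in range(cfg.n_recipients_per_strain):
            mouse = f"{strain}_R{i + 1:02d}"
            donor = donors[i % cfg.n_donors]
            for day in ("D-1", "D2", "D7"):
                rows.append((f"{mouse}_{day}", mouse, "recipient", strain, None, day, donor))
        for i in range(cfg.n_controls_per_strain):
            mouse = f"{strain}_C{i + 1:02d}"
            for day in ("D-1", "D2", "D7"):
                rows.append((f"{mouse}_{day}", mouse, "control", strain, None, day, None))
    df = pd.DataFrame(rows, columns=["sample_id", "mouse_id", "group", "strain",
                                     "locality", "day", "donor_id"])
    return StudyMetadata(df)


def _contig_classes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_contigs
    names = ["shared", "wild", "captive", "patchy"]
    bounds = np.cumsum([_CLASS_FRACTIONS[k] for k in names])
    cuts = (bounds * n).astype(int)
    classes = np.empty(n, dtype=object)
    prev = 0
    for name, cut in zip(names, cuts):
        classes[prev:cut] = name
        prev = cut
    classes[prev:] = "wild_specific"
    return classes


def simulate_study(cfg: SimulationConfig) -> dict:
    """Generate one complete synthetic study.

    Returns a dict with ``metadata`` (:class:`StudyMetadata`),
    ``phage_counts`` and ``asv_counts`` (:class:`CountMatrix`), ``sync``
    (:class:`SyncTable`), ``truth`` (:class:`GroundTruth`) and
    ``contig_sequences`` (contig id -> random reference sequence usable as
    per-sample kmer sources).
    """
    ss = np.random.SeedSequence(cfg.seed)
    (s_param, s_mouse_default, s_seq, s_annot) = ss.spawn(4)
    # community-template draws (contig/ASV-level parameters) are separated
    # from cohort draws (everything indexed by mouse or sample) so that a
    # mouse_seed override yields a fresh cohort of the same community
    if cfg.mouse_seed is None:
        s_mouse, s_sync_mouse = s_mouse_default.spawn(2)
    else:
        s_mouse, s_sync_mouse = np.random.SeedSequence(cfg.mouse_seed).spawn(2)
    rng = np.random.default_rng(s_param)          # template stream
    rng_m = np.random.default_rng(s_mouse)        # cohort stream

    meta = design_metadata(cfg)
    samples = meta.samples
    mouse_tbl = samples.drop_duplicates("mouse_id").set_index("mouse_id")
    mice = mouse_tbl.index.tolist()
    n_mice = len(mice)
    donors = meta.donors
    contig_ids = [f"ctg{i + 1:04d}" for i in range(cfg.n_contigs)]

    classes = _contig_classes(cfg, rng)
    owner = np.full(cfg.n_contigs, -1)                      # donor index for wild_specific
    spec_idx = np.flatnonzero(classes == "wild_specific")
    owner[spec_idx] = rng.integers(0, cfg.n_donors, size=len(spec_idx))

    is_wild_mouse = (mouse_tbl["group"] == "wild_donor").to_numpy()
    strain_of = mouse_tbl["strain"].to_numpy()
    loc_of = mouse_tbl["locality"].to_numpy()

    # carrier matrix (contigs x mice); group-mismatched carriers of the
    # wild-/captive-associated classes occur at trace_occupancy and will get
    # a trace-level abundance penalty below, so their detection flickers
    # around the presence threshold like real low-level mapping counts
    # wild communities are richer: broader occupancy of the shared core
    occupancy = {"shared": (0.95, 0.70),
                 "wild": (0.8, cfg.trace_occupancy),
                 "captive": (cfg.trace_occupancy, 0.8),
                 "patchy": (0.25, cfg.trace_occupancy)}
    carriers = np.zeros((cfg.n_contigs, n_mice), dtype=bool)
    u = rng_m.random((cfg.n_contigs, n_mice))
    for cls, (pw, pc) in occupancy.items():
        sel = classes == cls
        carriers[np.ix_(sel, is_wild_mouse)] = u[np.ix_(sel, is_wild_mouse)] < pw
        carriers[np.ix_(sel, ~is_wild_mouse)] = u[np.ix_(sel, ~is_wild_mouse)] < pc
    donor_pos = {d: mice.index(d) for d in donors}
    for c, o in zip(spec_idx, owner[spec_idx]):
        carriers[c, donor_pos[donors[o]]] = True

    # latent log-abundance pieces
    base = rng.normal(0.0, 1.0, size=cfg.n_contigs)
    lam = cfg.wild_captive_effect
    strain_load = rng.normal(0.0, 1.0, size=cfg.n_contigs)
    loc_levels = _localities(cfg.n_localities)
    loc_load = rng.normal(0.0, 1.0, size=(cfg.n_contigs, len(loc_levels)))
    K = 2
    factor_load = rng.normal(0.0, 0.5, size=(cfg.n_contigs, K))
    z_mouse = rng_m.normal(0.0, 1.0, size=(n_mice, K))
    ind_sd = np.where(is_wild_mouse, cfg.individual_sd_wild, cfg.individual_sd_captive)
    indiv = rng_m.normal(0.0, 1.0, size=(cfg.n_contigs, n_mice)) * ind_sd[None, :]

    latent_mouse = np.zeros((cfg.n_contigs, n_mice))
    latent_mouse += base[:, None]
    latent_mouse[np.ix_(classes == "wild", is_wild_mouse)] += lam
    latent_mouse[np.ix_(classes == "captive", ~is_wild_mouse)] += lam
    # group-mismatched carriers persist only at trace abundance
    wildish = (classes == "wild") | (classes == "patchy")
    latent_mouse[np.ix_(wildish, ~is_wild_mouse)] -= cfg.trace_abundance_penalty
    latent_mouse[np.ix_(classes == "captive", is_wild_mouse)] -= cfg.trace_abundance_penalty
    # captive communities are dominated by a few high-abundance phages,
    # giving them the lower evenness seen in conventional facilities
    captive_idx = np.flatnonzero(classes == "captive")
    dom = captive_idx[:min(cfg.n_dominant_captive, len(captive_idx))]
    latent_mouse[np.ix_(dom, ~is_wild_mouse)] += cfg.captive_dominance
    # individual-signature contigs are abundant in their own mouse
    for c, o in zip(spec_idx, owner[spec_idx]):
        latent_mouse[c, donor_pos[donors[o]]] += cfg.specific_abundance_bonus
    strain_sign = np.where(pd.Series(strain_of).isin([cfg.strains[0]]), 0.5,
                           np.where(pd.Series(strain_of).isin(cfg.strains[1:]), -0.5, 0.0))
    latent_mouse += cfg.strain_effect * strain_load[:, None] * strain_sign[None, :]
    for li, loc in enumerate(loc_levels):
        sel = loc_of == loc
        latent_mouse[:, sel] += cfg.locality_effect * loc_load[:, [li]]
    latent_mouse += factor_load @ z_mouse.T
    latent_mouse += indiv

    # planted contig-ASV couplings share a per-(mouse, day) effect
    shared_idx = np.flatnonzero(classes == "shared")
    n_pairs = min(cfg.n_coupled_pairs, len(shared_idx), cfg.n_asvs)
    pair_contigs = rng.choice(shared_idx, size=n_pairs, replace=False)
    pair_asvs = rng.choice(cfg.n_asvs, size=n_pairs, replace=False)
    pair_signs = np.where(rng.random(n_pairs) < 0.75, 1, -1)
    n_samp = len(samples)
    pair_effects = rng_m.normal(0.0, cfg.coupling_sd, size=(n_pairs, n_samp))

    # per-sample latent: mouse latent + day noise (+ transmission below)
    mouse_idx_of_sample = np.array([mice.index(m) for m in samples["mouse_id"]])
    day_noise = rng_m.normal(0.0, cfg.day_sd, size=(cfg.n_contigs, n_samp))
    latent = latent_mouse[:, mouse_idx_of_sample] + day_noise
    weights = np.where(carriers[:, mouse_idx_of_sample], np.exp(latent), 0.0)
    for k in range(n_pairs):
        weights[pair_contigs[k]] *= np.exp(pair_effects[k])

    # plant transmission
    private = {}
    for o, d in enumerate(donors):
        own = spec_idx[owner[spec_idx] == o]
        # private = carried by this donor only and by no captive mouse (true
        # by construction for wild-specific contigs)
        private[d] = [contig_ids[c] for c in own]
    transmitted = set()
    if cfg.transmission_rate > 0:
        plantable = sum(int(round(cfg.transmission_rate * len(v))) for v in private.values())
        if plantable == 0:
            raise ValidationError(
                "transmission_rate > 0 but no plantable donor-private contigs; "
                "increase n_contigs")
        donor_sample_pos = {d: samples.index[samples["sample_id"] == f"{d}_D0"][0] for d in donors}
        donor_rel = weights[:, [donor_sample_pos[d] for d in donors]]
        donor_rel = donor_rel / donor_rel.sum(axis=0, keepdims=True)
        post = samples["day"].isin(["D2", "D7"]).to_numpy()
        for o, d in enumerate(donors):
            own = spec_idx[owner[spec_idx] == o]
            k = int(round(cfg.transmission_rate * len(own)))
            if k == 0:
                continue
            chosen = rng.choice(own, size=k, replace=False)
            recips = meta.recipients_of(d)
            for r in recips:
                sel = (samples["mouse_id"] == r).to_numpy() & post
                cols = np.flatnonzero(sel)
                tot = weights[:, cols].sum(axis=0)
                add = cfg.transmitted_abundance_factor * donor_rel[chosen, o]
                weights[np.ix_(chosen, cols)] += add[:, None] * tot[None, :]
            transmitted.update((contig_ids[c], d) for c in chosen)

    # read sampling
    totals = rng_m.poisson(cfg.depth_mean, size=n_samp)
    colsums = weights.sum(axis=0)
    if (colsums == 0).any():
        raise ValidationError(
            "sample(s) with no carried contigs; increase n_contigs or occupancy")
    probs = weights / colsums[None, :]
    phage = np.zeros((cfg.n_contigs, n_samp), dtype=np.int64)
    for j in range(n_samp):
        phage[:, j] = rng_m.multinomial(totals[j], probs[:, j])

    # annotations
    rng_annot = np.random.default_rng(s_annot)
    r = rng_annot.random(cfg.n_contigs)
    lifestyle = np.where(r < cfg.prop_temperate, "temperate",
                         np.where(r < cfg.prop_temperate + cfg.prop_undetermined,
                                  "undetermined", "virulent"))
    families = rng_annot.choice(
        ["Salasmaviridae", "Caudoviricetes_unclassified", "Suoliviridae",
         "Schitoviridae", "Microviridae"], p=[0.30, 0.45, 0.10, 0.08, 0.07],
        size=cfg.n_contigs)
    hosts = rng_annot.choice(
        ["Lachnospiraceae", "Oscillospiraceae", "Bacteroidaceae", "Muribaculaceae", ""],
        p=[0.2, 0.15, 0.1, 0.05, 0.5], size=cfg.n_contigs)
    lengths = np.maximum(500, rng_annot.lognormal(9.0, 0.8, cfg.n_contigs).astype(int))
    annotations = pd.DataFrame({
        "lifestyle": lifestyle, "family": families,
        "host_family": [h if h else None for h in hosts], "length_bp": lengths,
    }, index=pd.Index(contig_ids, name="feature_id"))
    phage_counts = CountMatrix(contig_ids, samples["sample_id"].tolist(), phage, annotations)

    # ASV community sharing latent factors at coupling_strength
    asv_ids = [f"asv{i + 1:04d}" for i in range(cfg.n_asvs)]
    a_classes = np.empty(cfg.n_asvs, dtype=object)
    cuts = (np.cumsum([0.6, 0.2]) * cfg.n_asvs).astype(int)
    a_classes[:cuts[0]] = "shared"; a_classes[cuts[0]:cuts[1]] = "wild"; a_classes[cuts[1]:] = "captive"
    a_base = rng.normal(0.0, 1.0, cfg.n_asvs)
    a_strain = rng.normal(0.0, 1.0, cfg.n_asvs)
    a_loc = rng.normal(0.0, 1.0, (cfg.n_asvs, len(loc_levels)))
    a_factor = rng.normal(0.0, 0.5, (cfg.n_asvs, K))
    a_carriers = np.zeros((cfg.n_asvs, n_mice), dtype=bool)
    ua = rng_m.random((cfg.n_asvs, n_mice))
    for cls, (pw, pc) in _OCCUPANCY.items():
        sel = a_classes == cls
        a_carriers[np.ix_(sel, is_wild_mouse)] = ua[np.ix_(sel, is_wild_mouse)] < pw
        a_carriers[np.ix_(sel, ~is_wild_mouse)] = ua[np.ix_(sel, ~is_wild_mouse)] < pc
    rho = cfg.coupling_strength
    z_indep = rng_m.normal(0.0, 1.0, size=(n_mice, K))
    z_asv = rho * z_mouse + np.sqrt(1 - rho ** 2) * z_indep
    a_ind = rng_m.normal(0.0, 1.0, (cfg.n_asvs, n_mice)) * ind_sd[None, :]
    a_latent = a_base[:, None] + np.zeros((cfg.n_asvs, n_mice))
    a_latent[np.ix_(a_classes == "wild", is_wild_mouse)] += lam
    a_latent[np.ix_(a_classes == "captive", ~is_wild_mouse)] += lam
    a_latent += cfg.strain_effect * a_strain[:, None] * strain_sign[None, :]
    for li, loc in enumerate(loc_levels):
        a_latent[:, loc_of == loc] += cfg.locality_effect * a_loc[:, [li]]
    a_latent += a_factor @ z_asv.T
    a_latent += a_ind
    a_day = rng_m.normal(0.0, cfg.day_sd, size=(cfg.n_asvs, n_samp))
    a_sample = a_latent[:, mouse_idx_of_sample] + a_day
    a_weights = np.where(a_carriers[:, mouse_idx_of_sample], np.exp(a_sample), 0.0)
    for k in range(n_pairs):
        a_weights[pair_asvs[k]] *= np.exp(pair_signs[k] * pair_effects[k])
    a_totals = rng_m.poisson(cfg.asv_depth_mean, size=n_samp)
    a_probs = a_weights / a_weights.sum(axis=0, keepdims=True)
    asv = np.zeros((cfg.n_asvs, n_samp), dtype=np.int64)
    for j in range(n_samp):
        asv[:, j] = rng_m.multinomial(a_totals[j], a_probs[:, j])
    asv_counts = CountMatrix(asv_ids, samples["sample_id"].tolist(), asv)

    sync = _simulate_sync(cfg, meta, contig_ids, rng,
                          np.random.default_rng(s_sync_mouse))

    rng_seq = np.random.default_rng(s_seq)
    contig_sequences = {c: "".join(rng_seq.choice(list("ACGT"), size=cfg.contig_seq_length))
                        for c in contig_ids}

    truth = GroundTruth(
        transmitted_contigs=transmitted,
        temperate_labels=dict(zip(contig_ids, lifestyle)),
        true_fixed_effects={
            "wild_captive_effect": cfg.wild_captive_effect,
            "strain_effect": cfg.strain_effect,
            "locality_effect": cfg.locality_effect,
            "coupling_strength": cfg.coupling_strength,
            "transmission_rate": cfg.transmission_rate,
            **{f"convergence_rate[{s}]": r for s, r in cfg.convergence_rate.items()},
        },
        coupled_pairs={(contig_ids[c], asv_ids[a], "positive" if s > 0 else "negative")
                       for c, a, s in zip(pair_contigs, pair_asvs, pair_signs)},
        donor_private_contigs=private,
    )
    return {"metadata": meta, "phage_counts": phage_counts, "asv_counts": asv_counts,
            "sync": sync, "truth": truth, "contig_sequences": contig_sequences}


def _simulate_sync(cfg: SimulationConfig, meta: StudyMetadata, contig_ids: list[str],
                   rng: np.random.Generator, rng_m: np.random.Generator) -> SyncTable:
    """Biallelic A/T sites with a planted wild/captive frequency gap.

    Site frequencies come from the template stream; coverages, read draws
    and per-sample jitter from the cohort stream.
    """
    n_ctg = min(cfg.snp_contigs, len(contig_ids))
    sites = cfg.snp_sites_per_contig
    n_rec = n_ctg * sites
    samples = meta.samples
    n_samp = len(samples)

    p_cap = rng.uniform(0.1, 0.9, size=n_rec)
    direction = np.where(p_cap + cfg.snp_divergence <= 0.98, 1.0, -1.0)
    p_wild = np.clip(p_cap + direction * cfg.snp_divergence, 0.02, 0.98)

    drift_frac = {"D-1": 0.0, "D2": 0.6, "D7": 1.0}
    p_sample = np.empty((n_rec, n_samp))
    for j in range(n_samp):
        row = samples.iloc[j]
        if row["group"] == "wild_donor":
            p = p_wild
        elif row["group"] == "recipient":
            rate = cfg.convergence_rate.get(row["strain"], 0.0)
            p = p_cap + rate * drift_frac[row["day"]] * (p_wild - p_cap)
        else:
            p = p_cap
        p_sample[:, j] = np.clip(p + rng_m.normal(0.0, 0.02, size=n_rec), 0.005, 0.995)

    cov = rng_m.poisson(cfg.snp_coverage_mean, size=(n_rec, n_samp))
    a_counts = rng_m.binomial(cov, p_sample)
    counts = np.zeros((n_rec, n_samp, 6), dtype=np.int64)
    counts[:, :, 0] = a_counts
    counts[:, :, 1] = cov - a_counts
    contigs = np.repeat(np.array(contig_ids[:n_ctg], dtype=object), sites)
    positions = np.tile(np.arange(1, sites + 1) * 10, n_ctg)
    ref = np.full(n_rec, "A", dtype=object)
    return SyncTable(contigs, positions, ref, samples["sample_id"].tolist(), counts)


# ---------------------------------------------------------------------------
# GLMM fixture datasets
# ---------------------------------------------------------------------------

def simulate_glmm_dataset(family: str, n_groups: int, n_per_group: int, beta,
                          sigma_b: float, seed: int, shape: float = 5.0,
                          theta: float = 5.0, sigma_e: float = 1.0,
                          trials: int = 1) -> pd.DataFrame:
    """Random-intercept GLM(M) data with known coefficients.

    The design is an intercept plus ``len(beta) - 1`` standard-normal
    covariates named ``x1, x2, ...``; links are the family-canonical ones
    used throughout (log for gamma and negbin, logit for binomial, identity
    for gaussian).
    """
    if sigma_b < 0:
        raise ValidationError("sigma_b must be >= 0")
    if family not in ("gamma", "binomial", "negbin", "gaussian"):
        raise ValidationError(f"unknown family {family!r}")
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    n = n_groups * n_per_group
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(len(beta) - 1)])
    group = np.repeat(np.arange(n_groups), n_per_group)
    b = rng.normal(0.0, sigma_b, size=n_groups)
    eta = X @ beta + b[group]
    if family == "gaussian":
        y = eta + rng.normal(0.0, sigma_e, size=n)
    elif family == "gamma":
        mu = np.exp(eta)
        y = rng.gamma(shape, mu / shape)
    elif family == "binomial":
        p = 1.0 / (1.0 + np.exp(-eta))
        y = rng.binomial(trials, p)
    else:
        mu = np.exp(eta)
        y = rng.negative_binomial(theta, theta / (theta + mu))
    out = pd.DataFrame({"y": y, "group": [f"g{g:03d}" for g in group]})
    for j in range(1, len(beta)):
        out[f"x{j}"] = X[:, j]
    if family == "binomial":
        out["trials"] = trials
    return out


# ---------------------------------------------------------------------------
# Artifact writing
# ---------------------------------------------------------------------------

def write_sample_fastas(study: dict, out_dir, min_reads: int = 2) -> list[Path]:
    """Write one FASTA of detected contig sequences per sample.

    A contig's reference sequence is included in a sample's FASTA when the
    sample has at least ``min_reads`` mapped reads for it — a desk-scale
    stand-in for per-sample assemblies.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: CountMatrix = study["phage_counts"]
    seqs = study["contig_sequences"]
    paths = []
    for j, s in enumerate(counts.sample_ids):
        path = out_dir / f"{s}.fasta"
        with open(path, "w") as fh:
            for i, c in enumerate(counts.feature_ids):
                if counts.counts[i, j] >= min_reads:
                    fh.write(f">{c}\n{seqs[c]}\n")
        paths.append(path)
    return paths


def write_study(study: dict, out_dir) -> dict:
    """Write all study artifacts as TSV/JSON; returns a path manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": out_dir / "metadata.tsv",
        "phage_counts": out_dir / "phage_counts.tsv",
        "phage_annotations": out_dir / "phage_annotations.tsv",
        "asv_counts": out_dir / "asv_counts.tsv",
        "sync": out_dir / "sync.tsv",
        "truth": out_dir / "truth.json",
    }
    write_metadata(study["metadata"], paths["metadata"])
    write_count_matrix(study["phage_counts"], paths["phage_counts"], paths["phage_annotations"])
    write_count_matrix(study["asv_counts"], paths["asv_counts"])
    write_sync(study["sync"], paths["sync"])
    truth: GroundTruth = study["truth"]
    with open(paths["truth"], "w") as fh:
        json.dump({
            "transmitted_contigs": sorted(map(list, truth.transmitted_contigs)),
            "temperate_labels": truth.temperate_labels,
            "true_fixed_effects": truth.true_fixed_effects,
            "coupled_pairs": sorted(map(list, truth.coupled_pairs)),
            "donor_private_contigs": truth.donor_private_contigs,
        }, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
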