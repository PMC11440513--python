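"""End-to-end orchestration: simulate -> dissimilarities -> tests -> summary.

Stages communicate through files in the run directory so any stage can be
re-run or inspected in isolation; a manifest records every artifact path
and a hash of the effective configuration.  All stochastic stages draw
their seeds deterministically from the single run seed, so rerunning the
same configuration reproduces the summary byte for byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, community_metrics, convergence, kmer_dissim, pool_fst, \
    stability, synthetic, transmission
from .core_io import (DistanceMatrix, ValidationError, read_count_matrix,
                      read_metadata, to_presence, write_distance_matrix)

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "min_reads": 2,
    "n_perm": 999,
    "transmission_n_perm": 1000,
    "n_boot": 2000,
    "kmer_k": 31,
    "metrics": ["bray_curtis", "jaccard", "probWJ", "jexact"],
    "simulate": {"enabled": True},
    "inputs": {},
    "fst": {"min_cov": 10, "min_minor_count": 2},
    "association": {"n_contigs": 5, "n_asvs": 4, "method": "variance"},
    "stages": {"dissim": True, "ordinate": True, "permanova": True, "permdisp": True,
               "convergence": True, "fst": True, "transmission": True,
               "stability": True, "associate": True},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _tests_to_dict(res: dict) -> dict:
    out = {"tests": {k: t.to_dict() for k, t in res.get("tests", {}).items()}}
    if res.get("contrasts"):
        out["contrasts"] = {k: {"emmeans": c.emmeans.round(6).to_dict(),
                                "letters": c.letters}
                            for k, c in res["contrasts"].items()}
    if "median" in res and res["median"] is not None:
        out["fst_median"] = round(float(res["median"]), 6)
    return out


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Run all enabled stages; returns the manifest (incl. summary path)."""
    config = _merge(DEFAULT_CONFIG, config or {})
    if out_dir is None:
        out_dir = config.get("out_dir", "phagetx_run")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = config["stages"]
    manifest = {"config_hash": _config_hash(config), "artifacts": {}, "failed_stage": None}
    summary: dict = {"seed": seed, "config_hash": manifest["config_hash"]}

    def record(name, path):
        manifest["artifacts"][name] = str(path)

    current = "inputs"
    try:
        # ---- inputs ---------------------------------------------------------
        contig_sequences = None
        if config["simulate"]["enabled"]:
            current = "simulate"
            sim_over = {k: v for k, v in config["simulate"].items() if k != "enabled"}
            cfg = synthetic.SimulationConfig(seed=_stage_seed(seed, "simulate"), **sim_over)
            study = synthetic.simulate_study(cfg)
            paths = synthetic.write_study(study, out_dir / "inputs")
            for k, v in paths.items():
                record(k, v)
            meta = study["metadata"]
            phage = study["phage_counts"]
            asv = study["asv_counts"]
            sync = study["sync"]
            contig_sequences = study["contig_sequences"]
        else:
            inp = config["inputs"]
            meta = read_metadata(inp["metadata"])
            phage = read_count_matrix(inp["phage_counts"], inp.get("phage_annotations"))
            asv = read_count_matrix(inp["asv_counts"]) if inp.get("asv_counts") else None
            sync = pool_fst.read_sync(inp["sync"]) if inp.get("sync") else None
            if stages.get("fst") and sync is None:
                raise ValidationError("fst stage enabled but no sync input provided")

        min_reads = int(config["min_reads"])
        presence = to_presence(phage, min_reads)

        # ---- dissimilarities ------------------------------------------------
        current = "dissim"
        dmats: dict[str, DistanceMatrix] = {}
        if stages.get("dissim"):
            dmats["bray_curtis"] = community_metrics.bray_curtis(phage)
            dmats["jaccard"] = community_metrics.jaccard_distance(presence)
            kmetrics = [m for m in config["metrics"] if m in ("probWJ", "jexact")]
            if kmetrics and contig_sequences is not None:
                profiles = _presence_profiles(phage, contig_sequences, min_reads,
                                              int(config["kmer_k"]))
                for m in kmetrics:
                    dmats[m] = kmer_dissim.kmer_distance_matrix(profiles, m)
            dmats = {m: dmats[m] for m in config["metrics"] if m in dmats}
            for m, d in dmats.items():
                p = out_dir / f"dist_{m}.tsv"
                write_distance_matrix(d, p)
                record(f"dist_{m}", p)

        labels = np.where(meta.samples["group"] == "wild_donor", "wild",
                          meta.samples["strain"])

        if stages.get("ordinate"):
            current = "ordinate"
            summary["ordination"] = {}
            for m, d in dmats.items():
                ordn = community_metrics.pcoa(d)
                coords = pd.DataFrame(ordn.coordinates[:, :2], index=d.sample_ids,
                                      columns=["PCo1", "PCo2"])
                p = out_dir / f"pcoa_{m}.tsv"
                coords.to_csv(p, sep="\t")
                record(f"pcoa_{m}", p)
                summary["ordination"][m] = {
                    "prop_explained_axis1": round(float(ordn.proportion_explained[0]), 6)}

        for test_name, fn in (("permanova", community_metrics.permanova),
                              ("permdisp", community_metrics.permdisp)):
            if stages.get(test_name):
                current = test_name
                summary[test_name] = {}
                for m, d in dmats.items():
                    res = fn(d, labels, n_perm=int(config["n_perm"]),
                             seed=_stage_seed(seed, f"{test_name}:{m}"))
                    summary[test_name][m] = {"statistic": round(res.statistic, 6),
                                             "R2": None if res.R2 is None else round(res.R2, 6),
                                             "p": res.p}

        if stages.get("convergence"):
            current = "convergence"
            summary["convergence"] = {}
            for m, d in dmats.items():
                rows = convergence.build_donor_distance_table(d, meta)
                p = out_dir / f"donor_distances_{m}.tsv"
                rows.to_csv(p, sep="\t", index=False)
                record(f"donor_distances_{m}", p)
                res = convergence.convergence_test(rows, by_strain=True)
                summary["convergence"][m] = _tests_to_dict(res)
            tp = convergence.temperate_proportion_test(phage, meta)
            summary["temperate_proportion"] = _tests_to_dict(tp)

        if stages.get("fst"):
            current = "fst"
            rec = pool_fst.compute_fst_records(sync, meta, **config["fst"])
            rec = pool_fst.binarize_fst(rec)
            p = out_dir / "fst_records.tsv"
            rec.to_csv(p, sep="\t", index=False)
            record("fst_records", p)
            res = pool_fst.fst_divergence_test(rec, by_strain=True)
            summary["fst"] = _tests_to_dict(res)
            summary["fst"]["prop_high"] = {
                f"{r.strain}|{r.treatment}|{r.day}": round(r.prop_high, 6)
                for r in pool_fst.high_fst_proportions(rec).itertuples()}

        if stages.get("transmission"):
            current = "transmission"
            cands = transmission.candidate_contigs(presence, meta)
            res = transmission.permutation_null(
                cands, presence, meta, n_perm=int(config["transmission_n_perm"]),
                seed=_stage_seed(seed, "transmission"))
            for name, ids in (("candidates", res.candidates), ("matched", res.matched),
                              ("exclusive", res.exclusive)):
                p = out_dir / f"transmission_{name}.tsv"
                pd.Series(sorted(ids), name="contig_id").to_csv(p, sep="\t", index=False)
                record(f"transmission_{name}", p)
            p = out_dir / "transmission_null.tsv"
            pd.Series(res.null_fractions, name="null_fraction").to_csv(p, sep="\t", index=False)
            record("transmission_null", p)
            summary["transmission"] = res.to_dict()
            if res.candidates and phage.annotations is not None and res.matched:
                enr = transmission.temperate_enrichment(res.matched, phage.annotations)
                summary["transmission"]["temperate_enrichment"] = {
                    "table": enr["table"].tolist(), "chi2": round(enr["chi2"], 6),
                    "p": enr["p"], "odds_ratio": round(enr["odds_ratio"], 6)}

        if stages.get("stability"):
            current = "stability"
            summary["stability"] = {}
            d = dmats.get("bray_curtis")
            for phase in ("D-1:D2", "D2:D7"):
                res = stability.stability_contrast(
                    d, meta, phase, n_boot=int(config["n_boot"]),
                    seed=_stage_seed(seed, f"stability:{phase}"))
                summary["stability"][phase] = [r.to_dict() for r in res]

        if stages.get("associate") and asv is not None:
            current = "associate"
            d_ph = dmats.get("bray_curtis")
            d_asv = community_metrics.bray_curtis(asv)
            ord_ph = community_metrics.pcoa(d_ph)
            ord_asv = community_metrics.pcoa(d_asv)
            pro = association.procrustes_test(
                ord_ph, ord_asv, n_perm=int(config["n_perm"]),
                seed=_stage_seed(seed, "procrustes"))
            summary["procrustes"] = {"m2": round(pro.m2, 6),
                                     "correlation": round(pro.correlation, 6),
                                     "p": pro.p, "n_axes": pro.n_axes}
            acfg = config["association"]
            top_c = association.select_features(phage, int(acfg["n_contigs"]), acfg["method"])
            top_a = association.select_features(asv, int(acfg["n_asvs"]), acfg["method"])
            pairs = [(c, a) for c in top_c for a in top_a]
            links = association.cooccurrence_glmm(phage, asv, pairs, meta)
            summary["cooccurrence"] = [
                {"contig_id": l.contig_id, "asv_id": l.asv_id,
                 "coefficient": round(l.coefficient, 6), "p_raw": l.p_raw,
                 "p_adj": l.p_adj, "sign": l.sign}
                for l in links]
    except Exception as exc:
        manifest["failed_stage"] = current
        summary_path = out_dir / "summary.json"
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc

    summary_path = out_dir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    record("summary", summary_path)
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _presence_profiles(phage, contig_sequences, min_reads, k):
    """Per-sample kmer profiles of the contig sequences detected in each sample."""
    profiles = []
    pres = to_presence(phage, min_reads)
    for j, s in enumerate(phage.sample_ids):
        seqs = [contig_sequences[f] for i, f in enumerate(phage.feature_ids)
                if pres.present[i, j]]
        profiles.append(kmer_dissim.kmer_profile(seqs, k=k, sample_id=s))
    return profiles
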