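"""End-to-end orchestration: simulate -> detect -> features -> similarity ->
models -> convergence, with per-stage seeds, itemized config validation and
a reproducible run manifest.

Configuration is a YAML mapping (see ``default_config``); every stochastic
stage receives a sub-seed derived by hashing the global seed with the stage
name, and the manifest records inputs, seeds and SHA-256 hashes of every
output file so identical configs yield byte-identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from . import synth, detect, features, similarity, mm, convergence

STAGES = ("simulate", "detect", "features", "similarity", "models", "convergence")


def default_config() -> dict:
    return {
        "seed": 0,
        "output_dir": "callsim_run",
        "stages": {s: True for s in STAGES},
        "population": {
            "n_bats": 12,
            "n_sites": 2,
            "n_calls_per_bat": 200,
            "median_calls": 2500,
            "rate": 250_000,
            "delta_cohouse": 0.4,
            "delta_bond": 0.2,
        },
        "detection": {
            "noise_k": 5.0,
            "spectral_min_fraction": 0.7,
            "merge_gap_ms": 2.0,
        },
        "filters": {
            "min_duration_ms": 3.0,
            "max_duration_ms": 50.0,
            "min_peak_khz": 10.0,
            "clip_threshold": 0.99,
            "min_calls_per_bat": 100,
        },
        "similarity": {"floor": 0.001},
        "models": {"chains": 4, "draws": 6000, "warmup": 2000},
        "mantel": {"n_perm": 1000},
        "pdfa": {"n_perm": 100},
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    _deep_update(cfg, user)
    return cfg


def _deep_update(base: dict, other: dict):
    for k, v in other.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def validate_config(cfg: dict) -> dict:
    """Schema and range checks; returns {'valid': bool, 'errors': [...]}."""
    errors = []

    def check(cond, msg):
        if not cond:
            errors.append(msg)

    pop = cfg.get("population", {})
    check(isinstance(cfg.get("seed"), int), "seed must be an integer")
    check(pop.get("n_bats", 0) >= 2, "population.n_bats must be >= 2")
    check(pop.get("n_sites", 0) >= 1, "population.n_sites must be >= 1")
    check(pop.get("rate") in synth.SUPPORTED_RATES,
          f"population.rate must be one of {synth.SUPPORTED_RATES}")
    check(0 <= pop.get("delta_cohouse", 0) <= 1, "delta_cohouse must be in [0,1]")
    check(
        pop.get("delta_cohouse", 0) + pop.get("delta_bond", 0) <= 1,
        "delta_cohouse + delta_bond must be <= 1",
    )
    filt = cfg.get("filters", {})
    check(filt.get("min_duration_ms", 3.0) > 0, "min duration must be positive")
    check(
        filt.get("min_duration_ms", 3.0) < filt.get("max_duration_ms", 50.0),
        "duration bounds must be ordered",
    )
    check(filt.get("min_calls_per_bat", 100) >= 2, "min_calls_per_bat must be >= 2")
    check(0 < cfg.get("similarity", {}).get("floor", 0.001) < 1,
          "similarity.floor must be in (0,1)")
    for key in ("mantel", "pdfa"):
        check(cfg.get(key, {}).get("n_perm", 1) >= 1, f"{key}.n_perm must be >= 1")
    m = cfg.get("models", {})
    check(m.get("warmup", 0) < m.get("draws", 1), "models.warmup must be < draws")
    for stage, on in cfg.get("stages", {}).items():
        check(stage in STAGES, f"unknown stage {stage!r}")
        check(isinstance(on, bool), f"stage toggle {stage!r} must be boolean")
    return {"valid": not errors, "errors": errors}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: dict, progress: bool = False) -> dict:
    """Execute the toggled stages and return the run manifest."""
    report = validate_config(cfg)
    if not report["valid"]:
        raise ValueError("invalid config: " + "; ".join(report["errors"]))

    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": cfg, "stages": {}, "outputs": {}}
    stages = cfg["stages"]
    pop_cfg = cfg["population"]
    rate = pop_cfg["rate"]

    def log(msg):
        if progress:
            print(msg)

    def record(stage, **info):
        manifest["stages"][stage] = {"seed": stage_seed(cfg["seed"], stage), **info}

    def save_df(df, name):
        p = out / name
        df.to_csv(p, index=False)
        manifest["outputs"][name] = _sha256(p)
        return p

    # --- simulate -----------------------------------------------------------
    if stages.get("simulate", True):
        seed = stage_seed(cfg["seed"], "simulate")
        conv = synth.ConvergenceSpec(
            pop_cfg["delta_cohouse"], pop_cfg["delta_bond"], seed
        )
        profiles, social = synth.make_population(
            pop_cfg["n_bats"], pop_cfg["n_sites"], conv, seed,
            median_calls=pop_cfg["median_calls"],
        )
        profiles = synth.apply_convergence(profiles, social, conv)
        bats = pd.DataFrame(
            [
                {
                    "bat_id": p.bat_id, "site": p.site, "sex": p.sex,
                    "age_class": p.age_class, **p.contour_params,
                }
                for p in profiles
            ]
        )
        save_df(bats, "bats.csv")
        truth_rows = []
        for k, prof in enumerate(profiles):
            wav, truth = synth.generate_recording_session(
                prof, pop_cfg["n_calls_per_bat"], rate, seed + 1 + k
            )
            pcm = np.clip(wav, -1, 1)
            wavfile.write(out / f"{prof.bat_id}.wav", rate,
                          (pcm * 32767).astype(np.int16))
            truth["bat_id"] = prof.bat_id
            truth_rows.append(truth)
        save_df(pd.concat(truth_rows, ignore_index=True), "ground_truth_segments.csv")
        _save_social(social, out, manifest)
        record("simulate", n_bats=len(profiles))
        log(f"simulate: {len(profiles)} bats")
    else:
        bats = pd.read_csv(out / "bats.csv")
        social = _load_social(out)

    # --- detect -------------------------------------------------------------
    filt = cfg["filters"]
    if stages.get("detect", True):
        det_cfg = detect.DetectionConfig(
            noise_k=cfg["detection"]["noise_k"],
            spectral_min_fraction=cfg["detection"]["spectral_min_fraction"],
            merge_gap_s=cfg["detection"]["merge_gap_ms"] * 1e-3,
        )
        seg_rows = []
        all_segments = {}
        for bat_id in bats["bat_id"]:
            sr, pcm = wavfile.read(out / f"{bat_id}.wav")
            w = detect.Waveform(pcm.astype(float) / 32768.0, sr)
            if w.rate != detect.TARGET_RATE:
                w = detect.resample_to_250k(w)
            segs = detect.detect_calls(w, det_cfg, source=bat_id)
            n_det = len(segs)
            peaks = [detect.peak_frequency_hz(s) for s in segs]
            segs = detect.filter_calls(
                segs, peaks,
                min_duration_ms=filt["min_duration_ms"],
                max_duration_ms=filt["max_duration_ms"],
                min_peak_hz=filt["min_peak_khz"] * 1e3,
            )
            n_filtered = len(segs)
            segs = detect.remove_clipped(segs, filt["clip_threshold"])
            all_segments[bat_id] = segs
            log(
                f"detect {bat_id}: {n_det} detected, "
                f"{n_det - n_filtered} removed by duration/frequency, "
                f"{n_filtered - len(segs)} clipped"
            )
            for s in segs:
                seg_rows.append(
                    {
                        "source": s.source, "onset_s": s.onset_s,
                        "offset_s": s.offset_s, "duration_ms": s.duration_ms,
                    }
                )
        save_df(pd.DataFrame(seg_rows), "segments.csv")
        record("detect", n_segments=len(seg_rows))
    else:
        all_segments = None

    # --- features -----------------------------------------------------------
    if stages.get("features", True):
        if all_segments is None:
            raise ValueError("features stage requires the detect stage outputs")
        tables = []
        for bat_id, segs in all_segments.items():
            if not segs:
                continue
            tab = features.extract_table(segs, bat_ids=[bat_id] * len(segs))
            tables.append(tab)
        feat = pd.concat(tables, ignore_index=True)
        save_df(feat, "features.csv")
        record("features", n_calls=len(feat))
        log(f"features: {len(feat)} calls x {len(features.FEATURE_NAMES)}")
    elif (out / "features.csv").exists():
        feat = pd.read_csv(out / "features.csv")
    else:
        feat = None

    # --- similarity ---------------------------------------------------------
    if stages.get("similarity", True):
        if feat is None:
            raise ValueError("similarity stage requires a feature table")
        kept = similarity.filter_bats_min_calls(feat, filt["min_calls_per_bat"])
        log(
            f"similarity: {feat['bat_id'].nunique() - kept['bat_id'].nunique()} "
            "bats removed by min-call rule"
        )
        sim = similarity.similarity_from_table(
            kept, floor=cfg["similarity"]["floor"]
        )
        sim.S.to_csv(out / "similarity.csv")
        sim.D.to_csv(out / "distances.csv")
        manifest["outputs"]["similarity.csv"] = _sha256(out / "similarity.csv")
        manifest["outputs"]["distances.csv"] = _sha256(out / "distances.csv")
        loocv = similarity.classify_loocv(kept)
        (out / "dfa_summary.json").write_text(
            json.dumps(
                {
                    "overall_loocv_accuracy": loocv["overall"],
                    "n_bats": int(kept["bat_id"].nunique()),
                    "n_calls": int(len(kept)),
                    "max_distance": sim.max_d,
                },
                indent=2,
            )
        )
        manifest["outputs"]["dfa_summary.json"] = _sha256(out / "dfa_summary.json")
        record("similarity", loocv_accuracy=loocv["overall"])
    else:
        sim = None
        kept = None

    # --- models -------------------------------------------------------------
    if stages.get("models", True):
        if sim is None:
            raise ValueError("models stage requires the similarity stage")
        bats_idx = bats.set_index("bat_id")
        records = mm.build_dyad_table(sim, social, bats_idx)
        save_df(records, "dyads.csv")
        seed = stage_seed(cfg["seed"], "models")
        battery = mm.run_model_battery(records, seed=seed, **cfg["models"])
        save_df(battery["coefficients"], "model_coefficients.csv")
        summaries = {
            str(mid): res.summary.to_dict(orient="index")
            for mid, res in battery["results"].items()
        }
        (out / "model_summaries.json").write_text(json.dumps(summaries, indent=2))
        manifest["outputs"]["model_summaries.json"] = _sha256(
            out / "model_summaries.json"
        )
        record("models", n_models=len(battery["results"]))
    else:
        manifest["stages"]["models"] = {"skipped": True}

    # --- convergence --------------------------------------------------------
    if stages.get("convergence", True) and kept is not None:
        seed = stage_seed(cfg["seed"], "convergence")
        site_of = bats.set_index("bat_id")["site"].to_dict()
        tab = kept.copy()
        tab["site"] = tab["bat_id"].map(site_of)
        try:
            pdfa = convergence.pdfa_site(
                tab, n_perm=cfg["pdfa"]["n_perm"], seed=seed
            )
            (out / "pdfa.json").write_text(
                json.dumps(
                    {
                        "observed_accuracy": pdfa.observed_accuracy,
                        "n_perm": pdfa.n_perm,
                        "p_value": pdfa.p_value,
                        "seed": seed,
                    },
                    indent=2,
                )
            )
            manifest["outputs"]["pdfa.json"] = _sha256(out / "pdfa.json")
            record("convergence", pdfa_accuracy=pdfa.observed_accuracy)
        except ValueError as e:
            record("convergence", skipped=str(e))
    elif not stages.get("convergence", True):
        manifest["stages"]["convergence"] = {"skipped": True}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _save_social(social: synth.SocialStructure, out: Path, manifest: dict):
    for name in ("kinship", "cohoused", "groom_seconds", "share_seconds",
                 "sampling_seconds", "familiarity_class"):
        m = getattr(social, name)
        df = pd.DataFrame(m, index=social.bat_ids, columns=social.bat_ids)
        p = out / f"social_{name}.csv"
        df.to_csv(p)
        manifest["outputs"][p.name] = _sha256(p)


def _load_social(out: Path) -> synth.SocialStructure:
    def read(name, dtype=float):
        df = pd.read_csv(out / f"social_{name}.csv", index_col=0)
        return df.to_numpy(dtype=dtype), list(df.index)

    kinship, ids = read("kinship")
    cohoused, _ = read("cohoused", bool)
    groom, _ = read("groom_seconds")
    share, _ = read("share_seconds")
    sampling, _ = read("sampling_seconds")
    fam = pd.read_csv(out / "social_familiarity_class.csv", index_col=0).fillna("")
    return synth.SocialStructure(
        ids, kinship, cohoused, groom, share, sampling,
        fam.to_numpy(dtype=object),
    )
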