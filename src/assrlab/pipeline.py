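"""Study orchestration: simulate -> preprocess -> fit -> ASSR -> stats.

Two entry points:

* :func:`run_study` drives the full sensor-level chain per participant —
  block simulation, motion screening, ocular and cardiac cleanup, sub-
  average dipole fitting, source projection, and the complex 40-Hz
  statistic — then the group statistics.
* :func:`run_source_level_study` skips the sensor stage and computes the
  40-Hz statistic directly on simulated source waveforms. This is the
  fast path for validating the statistical layer and for large cohorts,
  where the forward-inverse round trip (validated separately) is not the
  question being asked.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assr as assr_mod
from . import stats as stats_mod
from .cohort import EffectConfig, ParticipantSpec, generate_cohort, cohort_table
from .forward import HeadModel, SensorArray
from .preprocess import remove_cardiac, remove_ocular, screen_head_motion
from .simulate import (ArtifactConfig, simulate_participant,
                       trial_source_waveforms)
from .sourcefit import (build_subaverages, consolidate_dipole_model,
                        fit_dipole_pair, project_sources)
from .stimulus import StimulusSpec

__all__ = ["RunConfig", "run_study", "run_source_level_study",
           "participant_assr_rows", "build_measures_table",
           "compute_group_stats"]

CONDITIONS = ("quiet", "noise")
HEMISPHERES = ("left", "right")


@dataclass
class RunConfig:
    """Serializable description of a complete run."""

    seed: int = 0
    n_young: int = 19
    n_older: int = 19
    blocks_per_condition: int = 4
    trials_per_block: int = 75
    n_bootstrap: int = 1000
    max_subaverages_fit: int | None = None  # cap dipole fits per condition
    out_dir: str | None = None
    run_preprocess: bool = True
    run_sourcefit: bool = True
    run_stats: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:10]


def participant_assr_rows(p: ParticipantSpec,
                          source_trials: dict[str, dict[str, np.ndarray]],
                          fs: float, n_bootstrap: int = 1000,
                          seed: int = 0) -> list[dict]:
    """Per hemisphere x condition ASSR estimates for one participant.

    ``source_trials[condition][hemisphere]`` is (n_trials, n_samples).
    """
    rows = []
    for ci, (cond, by_hemi) in enumerate(sorted(source_trials.items())):
        for hi, (hemi, trials) in enumerate(sorted(by_hemi.items())):
            prepared = assr_mod.prepare_average(trials, fs)
            est = assr_mod.compute_assr(prepared, fs,
                                        n_trials=trials.shape[0])
            boot = assr_mod.bootstrap_significance(
                trials, fs, n_resamples=n_bootstrap,
                seed=seed + 10 * ci + hi)
            rows.append({
                "id": p.id, "group": p.group, "condition": cond,
                "hemisphere": hemi, "amplitude_nAm": est.amplitude,
                "phase_rad": est.phase,
                "phase_delay_rad": est.phase_delay,
                "hilbert_phase_delay_rad": est.hilbert_phase_delay,
                "p_boot": boot.p_value, "n_trials": trials.shape[0],
            })
    return rows


def build_measures_table(cohort: list[ParticipantSpec],
                         assr_rows: list[dict]) -> pd.DataFrame:
    """One row per participant: covariates plus ASSR outcomes.

    Hemisphere-averaged amplitudes are (L + R)/2; the per-condition phase
    is the angle of the mean unit phasor of the two hemispheres on the
    delay scale.
    """
    long = pd.DataFrame(assr_rows)
    cov = cohort_table(cohort)
    rows = []
    for p in cohort:
        sub = long[long["id"] == p.id]
        row = {"id": p.id}
        for cond in CONDITIONS:
            sc = sub[sub["condition"] == cond]
            if sc.empty:
                continue
            amps = sc.set_index("hemisphere")["amplitude_nAm"]
            row[f"amp_left_{cond}"] = amps.get("left", np.nan)
            row[f"amp_right_{cond}"] = amps.get("right", np.nan)
            row[f"amp_{cond}"] = amps.mean()
            phasors = np.exp(1j * sc["phase_delay_rad"].to_numpy())
            row[f"phase_delay_{cond}"] = float(np.angle(phasors.mean()))
            row[f"p_boot_{cond}"] = sc["p_boot"].max()
        rows.append(row)
    return cov.merge(pd.DataFrame(rows), on="id")


def _amplitude_long(measures: pd.DataFrame) -> pd.DataFrame:
    recs = []
    for _, r in measures.iterrows():
        for cond in CONDITIONS:
            for hemi in HEMISPHERES:
                col = f"amp_{hemi}_{cond}"
                if col in r and np.isfinite(r[col]):
                    recs.append({"id": r["id"], "group": r["group"],
                                 "condition": cond, "hemisphere": hemi,
                                 "amplitude": r[col]})
    return pd.DataFrame(recs)


def _group_latency_ms(measures: pd.DataFrame, col_a: str, col_b: str
                      ) -> float:
    """Mean latency difference (ms) between two phase-delay columns."""
    pa = np.exp(1j * measures[col_a].dropna().to_numpy())
    pb = np.exp(1j * measures[col_b].dropna().to_numpy())
    return assr_mod.latency_contrast(float(np.angle(pa.mean())),
                                     float(np.angle(pb.mean()))).delta_ms


def compute_group_stats(measures: pd.DataFrame, n_boot: int = 1000,
                        seed: int = 0) -> dict:
    """The study's group-level analyses on a measures table.

    Analyses whose sample-size requirements the table cannot meet (e.g.
    contrasts on a single participant per group) are skipped rather than
    failing the whole run.
    """
    out: dict = {}

    def _try(key: str, fn) -> None:
        try:
            out[key] = fn()
        except ValueError:
            out[key] = None

    long = _amplitude_long(measures)
    _try("anova_amplitude", lambda: stats_mod.mixed_anova(
        long, dv="amplitude", subject="id",
        within=["hemisphere", "condition"], between="group").table)

    young = measures[measures["group"] == "young"]
    older = measures[measures["group"] == "older"]
    out["grand_mean_amp"] = {c: float(measures[f"amp_{c}"].mean())
                             for c in CONDITIONS}
    out["group_mean_amp"] = {
        g: {c: float(t[f"amp_{c}"].mean()) for c in CONDITIONS}
        for g, t in (("young", young), ("older", older))}
    _try("condition_contrast", lambda: stats_mod.paired_contrast(
        measures["amp_quiet"], measures["amp_noise"]))
    _try("age_contrast_noise", lambda: stats_mod.group_contrast(
        older["amp_noise"], young["amp_noise"]))

    # laterality and attenuation
    out["laterality"] = {}
    for cond in CONDITIONS:
        li = [(assr_mod.laterality_index(r[f"amp_right_{cond}"],
                                         r[f"amp_left_{cond}"]).li)
              for _, r in measures.iterrows()]
        li = np.asarray(li)
        se = li.std(ddof=1) / np.sqrt(len(li))
        out["laterality"][cond] = {"mean": float(li.mean()),
                                   "ci95_half": float(1.96 * se)}
    att = {g: np.array([assr_mod.attenuation_ratio(r["amp_quiet"],
                                                   r["amp_noise"])
                        for _, r in t.iterrows()])
           for g, t in (("young", young), ("older", older))}
    out["attenuation_pct"] = {g: float(v.mean()) for g, v in att.items()}

    # latency contrasts (delay-scale phases)
    lat = []
    for cond in CONDITIONS:
        py = np.exp(1j * young[f"phase_delay_{cond}"].dropna().to_numpy())
        po = np.exp(1j * older[f"phase_delay_{cond}"].dropna().to_numpy())
        lat.append(assr_mod.latency_contrast(
            float(np.angle(py.mean())), float(np.angle(po.mean()))).delta_ms)
    out["latency_older_minus_young_ms"] = float(np.mean(lat))
    out["latency_noise_minus_quiet_ms"] = _group_latency_ms(
        measures, "phase_delay_quiet", "phase_delay_noise")

    # linear models within the older group
    lm = {}
    pairs = [("amp_quiet_vs_age", "age", "amp_quiet"),
             ("amp_noise_vs_age", "age", "amp_noise"),
             ("amp_noise_vs_pta", "pta_db", "amp_noise"),
             ("amp_noise_vs_sin", "sin_loss_db", "amp_noise"),
             ("amp_quiet_vs_gaba_gm_left", "gaba_gm_left", "amp_quiet"),
             ("amp_noise_vs_gaba_total_right", "gaba_total_right",
              "amp_noise")]
    for name, xcol, ycol in pairs:
        sub = older[[xcol, ycol]].dropna()
        if len(sub) >= 3:
            lm[name] = stats_mod.fit_linear(sub[xcol], sub[ycol])
    out["linear_models"] = lm

    # mediation chains within the older group
    med = {}
    chains = [("age_gaba_sin", "age", "gaba_total_right", "sin_loss_db"),
              ("age_gamma_sin", "age", "amp_noise", "sin_loss_db"),
              ("gamma_gaba_sin", "amp_noise", "gaba_total_right",
               "sin_loss_db")]
    for name, x, m, y in chains:
        sub = older[[x, m, y]].dropna()
        if len(sub) >= 10:
            med[name] = stats_mod.mediate(sub[x], sub[m], sub[y],
                                          n_boot=n_boot, seed=seed)
    out["mediation"] = med
    return out


def run_source_level_study(config: RunConfig,
                           effects: EffectConfig | None = None,
                           stim: StimulusSpec | None = None,
                           trials_per_condition: int = 40,
                           background_rms_nAm: float = 8.0) -> dict:
    """Cohort statistics from source-level simulation (no sensor stage)."""
    stim = stim or StimulusSpec()
    cohort = generate_cohort(config.n_young, config.n_older, effects,
                             seed=config.seed)
    rows: list[dict] = []
    rng = np.random.default_rng(config.seed + 1)
    for p in cohort:
        source_trials = {}
        for cond in CONDITIONS:
            by_hemi: dict[str, list] = {h: [] for h in HEMISPHERES}
            for _ in range(trials_per_condition):
                w = trial_source_waveforms(
                    p, cond, stim, seed=int(rng.integers(2**31)),
                    background_rms_nAm=background_rms_nAm)
                for h in HEMISPHERES:
                    by_hemi[h].append(w[h])
            source_trials[cond] = {h: np.array(v) for h, v in by_hemi.items()}
        rows += participant_assr_rows(p, source_trials, fs=1250.0,
                                      n_bootstrap=config.n_bootstrap,
                                      seed=config.seed)
    measures = build_measures_table(cohort, rows)
    result = {"cohort": cohort, "assr_rows": rows, "measures": measures}
    if config.run_stats:
        result["stats"] = compute_group_stats(measures,
                                              n_boot=config.n_bootstrap,
                                              seed=config.seed)
    return result


def run_study(config: RunConfig, effects: EffectConfig | None = None,
              stim: StimulusSpec | None = None,
              artifacts: ArtifactConfig | None = None) -> dict:
    """Full sensor-level pipeline over a simulated cohort.

    Returns the results bundle in memory; if ``config.out_dir`` is set the
    bundle (cohort CSV, dipole JSON, ASSR TSV, stats JSON, run log) is also
    written there.
    """
    stim = stim or StimulusSpec()
    head = HeadModel()
    array = SensorArray.ctf_like()
    cohort = generate_cohort(config.n_young, config.n_older, effects,
                             seed=config.seed)
    rows: list[dict] = []
    dipole_models: dict[str, dict] = {}
    motion_log: list[dict] = []
    for p in cohort:
        blocks = simulate_participant(
            p, stim, head, array,
            blocks_per_condition=config.blocks_per_condition,
            trials_per_block=config.trials_per_block, seed=config.seed,
            artifacts=artifacts)
        kept = []
        for rec in blocks:
            report = screen_head_motion(rec)
            motion_log.append({"id": p.id, "block": rec.block_id,
                               "condition": rec.condition,
                               "max_mm": report.max_displacement_mm,
                               "keep": report.keep})
            if not report.keep:
                continue
            if config.run_preprocess:
                rec, _ = remove_ocular(rec)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rec, _ = remove_cardiac(rec)
            kept.append(rec)

        source_trials: dict[str, dict[str, np.ndarray]] = {}
        dipole_models[p.id] = {}
        for cond in CONDITIONS:
            cond_blocks = [r for r in kept if r.condition == cond]
            subs = build_subaverages(cond_blocks)
            if config.max_subaverages_fit:
                subs = subs[: config.max_subaverages_fit]
            fits = [fit_dipole_pair(s, head, array) for s in subs]
            model = consolidate_dipole_model(fits)
            dipole_models[p.id][cond] = model.to_json_dict()
            trials = {h: [] for h in HEMISPHERES}
            for rec in cond_blocks:
                proj = project_sources(rec, model)
                for h in HEMISPHERES:
                    trials[h].append(proj[h])
            source_trials[cond] = {h: np.vstack(v)
                                   for h, v in trials.items()}
        rows += participant_assr_rows(p, source_trials, fs=1250.0,
                                      n_bootstrap=config.n_bootstrap,
                                      seed=config.seed)

    measures = build_measures_table(cohort, rows)
    result = {"cohort": cohort, "assr_rows": rows, "measures": measures,
              "dipole_models": dipole_models, "motion_log": motion_log}
    if config.run_stats:
        result["stats"] = compute_group_stats(measures,
                                              n_boot=config.n_bootstrap,
                                              seed=config.seed)
    if config.out_dir:
        _write_bundle(Path(config.out_dir), config, result)
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_bundle(out: Path, config: RunConfig, result: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    tag = f"{config.config_hash()}_seed{config.seed}"
    cohort_table(result["cohort"]).to_csv(out / f"cohort_{tag}.csv",
                                          index=False)
    pd.DataFrame(result["assr_rows"]).to_csv(
        out / f"assr_{tag}.tsv", sep="\t", index=False)
    result["measures"].to_csv(out / f"measures_{tag}.csv", index=False)
    if "dipole_models" in result:
        (out / f"dipoles_{tag}.json").write_text(
            json.dumps(result["dipole_models"], indent=2))
    if "stats" in result:
        (out / f"stats_{tag}.json").write_text(
            json.dumps(_jsonable(result["stats"]), indent=2))
    (out / f"runlog_{tag}.json").write_text(json.dumps(
        {"config": asdict(config), "config_hash": config.config_hash()},
        indent=2))
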