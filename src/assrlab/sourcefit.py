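"""Bilateral equivalent-current-dipole fitting and source projection.

The 40-Hz response is modeled as one dipole per auditory cortex. Onset-
locked 500-ms epochs (stimulus onset and the onsets after the four gaps)
are averaged into sub-averages — all C(5,3) = 10 combinations of three of
the five epoch types per block — giving repeated field distributions for
repeated dipole estimation. Each sub-average is fitted with a spatiotemporal
bilateral dipole pair (positions and orientations fixed over the epoch,
moment amplitudes free per sample), fits are filtered by goodness of fit
and spatial consistency, and the consolidated model projects the raw trials
onto left/right source waveforms in nAm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import minimize

from .forward import HeadModel, SensorArray, forward_field, leadfield_xyz
from .simulate import SensorRecording, TRIAL_PRE_MS, TRIAL_POST_MS

__all__ = ["EpochSet", "SubAverage", "DipoleFitResult", "DipoleModel",
           "parse_epochs", "build_subaverages", "fit_dipole_pair",
           "consolidate_dipole_model", "project_sources"]

EPOCH_MS = 500.0
#: epoch-type onsets relative to the AM onset (ms): stimulus onset and the
#: onsets following each of the four 12.5-ms gaps
EPOCH_ONSETS_MS = (0.0, 412.5, 825.0, 1237.5, 1650.0)

INIT_POSITIONS_MM = {"left": np.array([-50.0, -20.0, 10.0]),
                     "right": np.array([50.0, -20.0, 10.0])}


@dataclass
class EpochSet:
    """Per-type averaged epochs for one block: 5 x channels x samples."""

    data: np.ndarray
    block_id: int
    n_trials: int


@dataclass
class SubAverage:
    data: np.ndarray            # channels x samples (500 ms)
    members: tuple[int, ...]    # which 3 of the 5 epoch types
    block_id: int


@dataclass
class DipoleFitResult:
    positions_mm: dict[str, np.ndarray]
    orientations: dict[str, np.ndarray]
    amplitudes_nAm: dict[str, float]    # RMS moment over the epoch
    gof: float                          # variance explained, in [0, 1]
    converged: bool


@dataclass
class DipoleModel:
    positions_mm: dict[str, np.ndarray]
    orientations: dict[str, np.ndarray]
    n_accepted: int
    n_total: int
    accepted: list[bool] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "positions_mm": {k: v.tolist() for k, v in self.positions_mm.items()},
            "orientations": {k: v.tolist() for k, v in self.orientations.items()},
            "n_accepted": self.n_accepted,
            "n_total": self.n_total,
        }


def parse_epochs(recording: SensorRecording) -> EpochSet:
    """Average 500-ms onset-locked epochs per epoch type for one block."""
    onsets = recording.trial_onsets
    if not onsets:
        raise ValueError("recording has no stimulus onset events")
    fs = recording.fs
    n_ep = int(round(EPOCH_MS / 1000.0 * fs))
    types = []
    for rel_ms in EPOCH_ONSETS_MS:
        segs = []
        for onset in onsets:
            i0 = onset + int(round(rel_ms / 1000.0 * fs))
            if i0 + n_ep <= recording.n_samples:
                segs.append(recording.data[:, i0 : i0 + n_ep])
        types.append(np.mean(segs, axis=0))
    return EpochSet(data=np.stack(types), block_id=recording.block_id,
                    n_trials=len(onsets))


def build_subaverages(recordings: list[SensorRecording],
                      bandpass: bool = True) -> list[SubAverage]:
    """All 3-of-5 epoch-type combinations for every usable block.

    Four blocks per condition give 40 sub-averages; a single block gives
    10. An empty input produces an empty list with a warning. With
    ``bandpass`` (default) the sensor data are restricted to the 28-56 Hz
    band before epoching, since the dipoles are estimated from the 40-Hz
    activity; the zero-phase filter leaves field topographies untouched.
    """
    if not recordings:
        warnings.warn("no usable blocks: returning no sub-averages",
                      stacklevel=2)
        return []
    out = []
    for rec in recordings:
        if bandpass:
            from .assr import _bandpass
            from .filters import apply_zero_phase
            rec = SensorRecording(
                data=apply_zero_phase(rec.data, _bandpass(rec.fs), axis=-1),
                fs=rec.fs, events=rec.events, headpos_pre=rec.headpos_pre,
                headpos_post=rec.headpos_post, condition=rec.condition,
                block_id=rec.block_id, array=rec.array, head=rec.head,
                truth=rec.truth)
        ep = parse_epochs(rec)
        for members in combinations(range(len(EPOCH_ONSETS_MS)), 3):
            out.append(SubAverage(
                data=ep.data[list(members)].mean(axis=0),
                members=members, block_id=rec.block_id))
    return out


def _pair_residual(data: np.ndarray, lf: np.ndarray) -> float:
    """Residual power of the free-moment (6-column) spatiotemporal fit."""
    m, *_ = np.linalg.lstsq(lf, data, rcond=None)
    resid = data - lf @ m
    return float(np.sum(resid**2))


def fit_dipole_pair(sub: SubAverage, head: HeadModel, array: SensorArray,
                    init: dict[str, np.ndarray] | None = None,
                    tol_mm: float = 0.1, max_alternations: int = 50
                    ) -> DipoleFitResult:
    """Spatiotemporal bilateral dipole fit to one sub-average.

    Starting from mirror-symmetric temporal-lobe positions, the position of
    one hemisphere's dipole is optimized while the other is held fixed,
    alternating until neither moves by more than ``tol_mm``. During the
    position search the moment vectors are free per sample; the final model
    fixes one orientation per dipole (dominant direction of its moment
    course) and reports variance explained of that fixed-orientation model.
    """
    data = sub.data
    pos = {h: np.array((init or INIT_POSITIONS_MM)[h], float)
           for h in ("left", "right")}
    bound = head.radius_mm * 0.95
    total_power = float(np.sum(data**2))

    def cost_factory(fixed_lf: np.ndarray):
        def cost(p: np.ndarray) -> float:
            r = np.linalg.norm(p - np.asarray(head.center_mm))
            if r >= bound:
                return total_power * (1.0 + (r - bound) / bound)
            lf = np.hstack([leadfield_xyz(p, head, array), fixed_lf])
            return _pair_residual(data, lf)
        return cost

    converged = False
    for _ in range(max_alternations):
        moved = 0.0
        for h, other in (("left", "right"), ("right", "left")):
            fixed_lf = leadfield_xyz(pos[other], head, array)
            res = minimize(cost_factory(fixed_lf), pos[h],
                           method="Nelder-Mead",
                           options={"xatol": tol_mm / 4, "fatol": 1e-12
                                    * max(total_power, 1e-30),
                                    "maxiter": 200})
            moved = max(moved, float(np.linalg.norm(res.x - pos[h])))
            pos[h] = res.x
        if moved < tol_mm:
            converged = True
            break

    lf_l = leadfield_xyz(pos["left"], head, array)
    lf_r = leadfield_xyz(pos["right"], head, array)
    m, *_ = np.linalg.lstsq(np.hstack([lf_l, lf_r]), data, rcond=None)
    oris, amps, patterns = {}, {}, []
    for i, h in enumerate(("left", "right")):
        block = m[3 * i : 3 * i + 3]
        u, s, vt = np.linalg.svd(block, full_matrices=False)
        ori = u[:, 0]
        if ori[1] < 0:  # orient anteriorly for reportability
            ori = -ori
        oris[h] = ori
        patterns.append((lf_l if h == "left" else lf_r) @ ori)
    G = np.column_stack(patterns)
    a, *_ = np.linalg.lstsq(G, data, rcond=None)
    for i, h in enumerate(("left", "right")):
        amps[h] = float(np.sqrt(np.mean(a[i] ** 2)))
    resid = data - G @ a
    gof = 1.0 - float(np.sum(resid**2)) / total_power if total_power > 0 else 0.0
    return DipoleFitResult(positions_mm=pos, orientations=oris,
                           amplitudes_nAm=amps, gof=max(0.0, min(1.0, gof)),
                           converged=converged)


def consolidate_dipole_model(fits: list[DipoleFitResult],
                             min_gof: float = 0.90,
                             sd_factor: float = 2.0) -> DipoleModel:
    """Two-stage acceptance and averaging of repeated dipole fits.

    Stage 1 keeps fits explaining at least 90% of the field variance;
    stage 2 drops fits whose position lies more than two standard
    deviations from the stage-1 mean (per hemisphere, Euclidean distance,
    applied once). The model is the mean of the surviving dipoles.
    """
    if not fits:
        raise ValueError("no fits to consolidate")
    stage1 = [f.gof >= min_gof for f in fits]
    if not any(stage1):
        raise ValueError("no fit reached the goodness-of-fit criterion; "
                         "inspect the data or the head model")
    accepted = list(stage1)
    for h in ("left", "right"):
        pts = np.array([f.positions_mm[h] for f, ok in zip(fits, stage1) if ok])
        mean = pts.mean(axis=0)
        d = np.linalg.norm(pts - mean, axis=1)
        # positional standard deviation = RMS distance from the mean
        sd = float(np.sqrt(np.mean(d**2)))
        keep = d <= sd_factor * sd + 1e-9
        it = iter(keep)
        accepted = [ok and (next(it) if s1 else False)
                    for ok, s1 in zip(accepted, stage1)]
    if not any(accepted):
        raise ValueError("no fit survived the spatial-consistency filter; "
                         "inspect the data or the head model")
    positions, orientations = {}, {}
    for h in ("left", "right"):
        pts = np.array([f.positions_mm[h] for f, ok in zip(fits, accepted) if ok])
        oris = np.array([f.orientations[h] for f, ok in zip(fits, accepted) if ok])
        positions[h] = pts.mean(axis=0)
        o = oris.mean(axis=0)
        orientations[h] = o / np.linalg.norm(o)
    return DipoleModel(positions_mm=positions, orientations=orientations,
                       n_accepted=int(np.sum(accepted)), n_total=len(fits),
                       accepted=accepted)


def project_sources(recording: SensorRecording, model: DipoleModel
                    ) -> dict[str, np.ndarray]:
    """Least-squares projection of trials onto the two dipole patterns.

    Returns per-hemisphere arrays of shape (n_trials, n_samples) in nAm,
    each trial spanning -500 to +2500 ms around the AM onset.
    """
    G = np.column_stack([
        forward_field(model.positions_mm[h], model.orientations[h],
                      recording.head, recording.array)
        for h in ("left", "right")])
    if np.linalg.cond(G) > 1e6:
        raise ValueError("dipole field patterns are (near-)collinear; "
                         "projection is singular")
    pinv = np.linalg.pinv(G)
    fs = recording.fs
    pre = int(round(TRIAL_PRE_MS / 1000.0 * fs))
    post = int(round(TRIAL_POST_MS / 1000.0 * fs))
    trials_l, trials_r = [], []
    for onset in recording.trial_onsets:
        if onset - pre < 0 or onset + post > recording.n_samples:
            continue
        seg = recording.data[:, onset - pre : onset + post]
        s = pinv @ seg
        trials_l.append(s[0])
        trials_r.append(s[1])
    return {"left": np.array(trials_l), "right": np.array(trials_r)}
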