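"""Synthetic sessions with known ground truth.

Every downstream stage (preprocessing, curation, tracking, tuning, coupling,
BMI metrics) is exercised against data generated here, so each analysis has a
parameter-recovery test with an analytically known answer.

Generative models:

* orientation tuning — homogeneous Poisson within each trial with a von Mises
  profile on the doubled angle, ``lambda(theta) = b + a * exp(kappa * (cos 2(theta - theta_p) - 1))``;
* direction tuning — rectified cosine, ``lambda(d) = b + m * max(0, cos(d - d_p))``
  inside the 0-300 ms post-movement epoch and baseline ``b`` elsewhere;
* functional coupling — binomial thinning of the leader train: each leader
  spike triggers one extra follower spike with probability ``p`` at lag
  ``L + N(0, sigma_j^2)``, so the expected excess coincidence count is
  ``p * n_leader_spikes``;
* raw traces — spatially decaying biphasic templates summed at spike times
  plus white Gaussian noise and optional rectangular high-voltage artifacts;
* waveform drift — a fixed template scaled by ``(1 + k * drift)`` in session
  ``k`` with per-spike Gaussian noise;
* center-out cursor trials — constant-speed steps toward the target with
  von-Mises-free Gaussian heading noise.

All generators are pure functions of (parameters, seed).  Each unit draws
from its own substream seeded by (seed, unit index), so adding units never
perturbs the spike trains of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import (
    ChannelInfo,
    CursorTrial,
    RecordingSession,
    SortedUnit,
    snippet_length,
)

__all__ = [
    "GroundTruth",
    "biphasic_template",
    "gen_orientation_session",
    "gen_direction_session",
    "gen_coupled_pair",
    "gen_coupled_network",
    "gen_raw_trace",
    "gen_multisession_drift",
    "gen_cursor_trials",
    "poisson_train",
]

#: recording-site pitch along a shank in synthetic fixtures, micrometre
SITE_PITCH_UM = 30.0


@dataclass
class GroundTruth:
    """What the generator actually injected, for parameter-recovery tests."""

    units: dict[str, dict] = field(default_factory=dict)
    coupled_pairs: list[dict] = field(default_factory=list)
    spike_samples: dict[str, np.ndarray] = field(default_factory=dict)
    artifacts: list[tuple[float, float]] = field(default_factory=list)
    rng_seed: int = 0


def _unit_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(index)])


def poisson_train(rate_hz: float, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson spike train on [0, duration): sorted times in seconds."""
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def _dedupe(times: np.ndarray, min_gap: float = 1e-6) -> np.ndarray:
    """Enforce strictly increasing spike times (collapse coincidences)."""
    times = np.sort(np.asarray(times, dtype=np.float64))
    if times.size < 2:
        return times
    keep = np.concatenate([[True], np.diff(times) > min_gap])
    return times[keep]


def biphasic_template(
    sampling_rate: float, amplitude_uv: float = -90.0, width_ms: float = 0.25
) -> np.ndarray:
    """Spatially localized biphasic spike template on the snippet grid.

    Negative-leading extracellular shape: a narrow trough followed by a
    broader, smaller rebound.  Peak (trough) sits 0.4 ms into the snippet so
    extraction windows line up with detection alignment.
    """
    n = snippet_length(sampling_rate)
    t = (np.arange(n) / sampling_rate) * 1e3  # ms
    t0 = 0.4
    w = width_ms
    trough = np.exp(-0.5 * ((t - t0) / (w / 2.355)) ** 2)
    rebound = -0.35 * np.exp(-0.5 * ((t - t0 - 2.2 * w) / (w * 1.8 / 2.355)) ** 2)
    shape = trough + rebound
    return (amplitude_uv * shape / np.max(np.abs(shape))).astype(np.float64)


def _default_channels(n_channels: int) -> list[ChannelInfo]:
    return [
        ChannelInfo(
            channel_id=i,
            shank_id="A",
            depth_um=100.0 + SITE_PITCH_UM * i,
            position_um=(0.0, SITE_PITCH_UM * i),
        )
        for i in range(n_channels)
    ]


def _make_unit(unit_id, times, channel, sampling_rate, rng, amplitude_uv=-90.0, noise_sd=2.0):
    """Attach noisy template snippets to a spike train."""
    template = biphasic_template(sampling_rate, amplitude_uv=amplitude_uv)
    wf = template[None, :] + rng.normal(0.0, noise_sd, size=(times.size, template.size))
    return SortedUnit(
        unit_id=unit_id,
        spike_times=times,
        primary_channel=channel,
        waveforms=wf.astype(np.float32).reshape(times.size, template.size),
    )


def _von_mises_rate(theta_deg, b, a, kappa, pref_deg):
    d = np.deg2rad(2.0 * (np.asarray(theta_deg, dtype=float) - pref_deg))
    return b + a * np.exp(kappa * (np.cos(d) - 1.0))


def gen_orientation_session(
    n_units: int = 8,
    orientations: tuple[float, ...] = (0, 22.5, 45, 67.5, 90, 112.5, 135, 157.5),
    n_trials_per_orientation: int = 20,
    trial_dur: float = 1.0,
    tuning_params: dict | None = None,
    seed: int = 0,
    sampling_rate: float = 20_000.0,
    inter_trial_gap: float = 0.5,
) -> tuple[RecordingSession, GroundTruth]:
    """Grating-response session: Poisson units with von Mises orientation tuning.

    ``tuning_params`` may fix ``baseline_hz``, ``amplitude_hz``, ``kappa`` or
    per-unit ``pref_deg`` (list); unset preferred orientations are drawn
    uniformly from [0, 180).
    """
    if not orientations:
        raise ValueError("orientations must be non-empty")
    if trial_dur <= 0:
        raise ValueError("trial_dur must be positive")
    params = {"baseline_hz": 2.0, "amplitude_hz": 18.0, "kappa": 2.0}
    params.update(tuning_params or {})

    root = np.random.default_rng([int(seed), 0xB0])
    conditions = np.repeat(np.asarray(orientations, float), n_trials_per_orientation)
    root.shuffle(conditions)
    onsets = inter_trial_gap + np.arange(conditions.size) * (trial_dur + inter_trial_gap)
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(conditions.size, dtype=int),
            "onset_s": onsets,
            "offset_s": onsets + trial_dur,
            "orientation_deg": conditions,
        }
    )
    duration = float(onsets[-1] + trial_dur + inter_trial_gap)

    truth = GroundTruth(rng_seed=seed)
    units = []
    prefs = params.get("pref_deg")
    for i in range(n_units):
        rng = _unit_rng(seed, i + 1)
        pref = float(prefs[i]) if prefs is not None else float(rng.uniform(0, 180))
        rates = _von_mises_rate(conditions, params["baseline_hz"], params["amplitude_hz"], params["kappa"], pref)
        spikes = []
        for onset, lam in zip(onsets, rates):
            k = rng.poisson(lam * trial_dur)
            spikes.append(onset + np.sort(rng.uniform(0, trial_dur, k)))
        times = _dedupe(np.concatenate(spikes))
        units.append(_make_unit(f"u{i:03d}", times, i % 8, sampling_rate, rng))
        truth.units[f"u{i:03d}"] = {
            "pref_orientation_deg": pref,
            "baseline_hz": params["baseline_hz"],
            "amplitude_hz": params["amplitude_hz"],
            "kappa": params["kappa"],
        }

    session = RecordingSession(
        session_id=f"ori-{seed}",
        sampling_rate=sampling_rate,
        duration_s=duration,
        channels=_default_channels(8),
        trials=trials,
        units=units,
    )
    session.validate()
    return session, truth


def gen_direction_session(
    n_units: int = 8,
    n_trials_per_direction: int = 20,
    params: dict | None = None,
    seed: int = 0,
    sampling_rate: float = 30_000.0,
    epoch_s: float = 0.3,
) -> tuple[RecordingSession, GroundTruth]:
    """Center-out session: rectified-cosine direction tuning in the 0-300 ms epoch."""
    p = {"baseline_hz": 4.0, "modulation_hz": 16.0}
    p.update(params or {})
    directions = np.arange(8) * 45.0

    root = np.random.default_rng([int(seed), 0xD1])
    conditions = np.repeat(directions, n_trials_per_direction)
    root.shuffle(conditions)
    trial_len = 1.2
    onsets = 0.5 + np.arange(conditions.size) * (trial_len + 0.5)
    movement_onsets = onsets + 0.3
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(conditions.size, dtype=int),
            "onset_s": onsets,
            "offset_s": onsets + trial_len,
            "direction_deg": conditions,
            "movement_onset_s": movement_onsets,
        }
    )
    duration = float(onsets[-1] + trial_len + 0.5)

    truth = GroundTruth(rng_seed=seed)
    units = []
    prefs = p.get("pref_deg")
    for i in range(n_units):
        rng = _unit_rng(seed, i + 1)
        pref = float(prefs[i]) if prefs is not None else float(rng.uniform(0, 360))
        spikes = []
        for onset, move, d in zip(onsets, movement_onsets, conditions):
            lam_epoch = p["baseline_hz"] + p["modulation_hz"] * max(
                0.0, np.cos(np.deg2rad(d - pref))
            )
            # baseline spiking outside the response epoch, tuned inside it
            pre = rng.poisson(p["baseline_hz"] * (move - onset))
            spikes.append(onset + np.sort(rng.uniform(0, move - onset, pre)))
            k = rng.poisson(lam_epoch * epoch_s)
            spikes.append(move + np.sort(rng.uniform(0, epoch_s, k)))
            tail = trial_len - (move - onset) - epoch_s
            if tail > 0:
                k2 = rng.poisson(p["baseline_hz"] * tail)
                spikes.append(move + epoch_s + np.sort(rng.uniform(0, tail, k2)))
        times = _dedupe(np.concatenate(spikes))
        units.append(_make_unit(f"m{i:03d}", times, i % 8, sampling_rate, rng))
        truth.units[f"m{i:03d}"] = {
            "pref_direction_deg": pref,
            "baseline_hz": p["baseline_hz"],
            "modulation_hz": p["modulation_hz"],
        }

    session = RecordingSession(
        session_id=f"dir-{seed}",
        sampling_rate=sampling_rate,
        duration_s=duration,
        channels=_default_channels(8),
        trials=trials,
        units=units,
    )
    session.validate()
    return session, truth


def gen_coupled_pair(
    rate_leader: float = 10.0,
    rate_follower_base: float = 10.0,
    p: float = 0.3,
    lag_ms: float = 2.0,
    jitter_ms: float = 0.5,
    duration: float = 600.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Leader/follower trains with injected excess synchrony.

    The follower is an independent Poisson train plus, for each leader spike
    with probability ``p``, one extra spike at ``+lag_ms + N(0, jitter_ms^2)``.
    Expected excess coincidences at the injected lag = ``p * len(leader)``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng([int(seed), 0xCC])
    leader = poisson_train(rate_leader, duration, rng)
    follower = poisson_train(rate_follower_base, duration, rng)
    triggered = leader[rng.uniform(size=leader.size) < p]
    injected = triggered + lag_ms * 1e-3 + rng.normal(0.0, jitter_ms * 1e-3, triggered.size)
    injected = injected[(injected >= 0) & (injected < duration)]
    return leader, _dedupe(np.concatenate([follower, injected]))


def gen_coupled_network(
    n_units: int = 6,
    coupled_pairs: list[tuple[int, int]] | None = None,
    rate_hz: float = 10.0,
    p: float = 0.3,
    lag_ms: float = 2.0,
    jitter_ms: float = 0.5,
    duration: float = 600.0,
    seed: int = 0,
    sampling_rate: float = 20_000.0,
) -> tuple[RecordingSession, GroundTruth]:
    """A population of Poisson units with directed excess-synchrony pairs.

    Each entry of ``coupled_pairs`` is (leader index, follower index); the
    follower receives one extra spike per leader spike with probability ``p``
    at ``+lag_ms`` (jittered).  Units also carry a random preferred
    orientation so coupling-vs-tuning analyses have ground truth.
    """
    coupled_pairs = coupled_pairs or []
    base: list[np.ndarray] = []
    prefs: list[float] = []
    for i in range(n_units):
        rng = _unit_rng(seed, i + 1)
        base.append(poisson_train(rate_hz, duration, rng))
        prefs.append(float(rng.uniform(0, 180)))
    extra: dict[int, list[np.ndarray]] = {}
    truth = GroundTruth(rng_seed=seed)
    for k, (li, fi) in enumerate(coupled_pairs):
        rng = np.random.default_rng([int(seed), 0xEE, k])
        leader = base[li]
        triggered = leader[rng.uniform(size=leader.size) < p]
        inj = triggered + lag_ms * 1e-3 + rng.normal(0.0, jitter_ms * 1e-3, triggered.size)
        extra.setdefault(fi, []).append(inj[(inj >= 0) & (inj < duration)])
        truth.coupled_pairs.append(
            {"leader": f"u{li:03d}", "follower": f"u{fi:03d}", "p": p,
             "lag_ms": lag_ms, "jitter_ms": jitter_ms}
        )
    units = []
    for i in range(n_units):
        rng = _unit_rng(seed, 1000 + i)
        times = _dedupe(np.concatenate([base[i], *extra.get(i, [])]))
        units.append(_make_unit(f"u{i:03d}", times, i % 8, sampling_rate, rng))
        truth.units[f"u{i:03d}"] = {"rate_hz": rate_hz, "pref_orientation_deg": prefs[i]}
    session = RecordingSession(
        session_id=f"net-{seed}",
        sampling_rate=sampling_rate,
        duration_s=duration,
        channels=_default_channels(8),
        units=units,
    )
    session.validate()
    return session, truth


def gen_raw_trace(
    spike_times_per_unit: list[np.ndarray],
    templates: list[np.ndarray],
    primary_channels: list[int],
    n_channels: int,
    duration: float,
    sampling_rate: float = 20_000.0,
    noise_sd: float = 5.0,
    space_constant_um: float = 40.0,
    channel_pitch_um: float = SITE_PITCH_UM,
    artifact_spec: list[tuple[float, float, float]] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Broadband trace matrix from templates + noise + optional artifacts.

    Template amplitude decays as ``exp(-distance / space_constant_um)`` across
    channels; overlapping insertions sum linearly.  ``artifact_spec`` entries
    are ``(t_start_s, dur_s, amplitude_uv)`` rectangular pulses on all channels.
    """
    n_samples = int(round(duration * sampling_rate))
    rng = np.random.default_rng([int(seed), 0xAA])
    trace = (
        rng.normal(0.0, noise_sd, size=(n_channels, n_samples))
        if noise_sd > 0
        else np.zeros((n_channels, n_samples))
    )
    truth = GroundTruth(rng_seed=seed)
    pre = int(round(0.4e-3 * sampling_rate))
    for k, (times, tmpl, prim) in enumerate(zip(spike_times_per_unit, templates, primary_channels)):
        if tmpl.size >= n_samples:
            raise ValueError("template longer than trace")
        samples = np.round(np.asarray(times) * sampling_rate).astype(int)
        keep = (samples - pre >= 0) & (samples - pre + tmpl.size <= n_samples)
        samples = samples[keep]
        truth.spike_samples[f"u{k:03d}"] = samples
        for ch in range(n_channels):
            gain = np.exp(-abs(ch - prim) * channel_pitch_um / space_constant_um)
            if gain < 1e-3:
                continue
            for s in samples:
                trace[ch, s - pre : s - pre + tmpl.size] += gain * tmpl
    for (t0, dur, amp) in artifact_spec or []:
        i0 = int(round(t0 * sampling_rate))
        i1 = min(n_samples, i0 + int(round(dur * sampling_rate)))
        trace[:, i0:i1] += amp
        truth.artifacts.append((t0, t0 + dur))
    return trace, truth


def gen_multisession_drift(
    template: np.ndarray,
    n_sessions: int,
    amplitude_drift_per_session: float = 0.0,
    noise_sd: float = 3.0,
    n_spikes: int = 200,
    seed: int = 0,
) -> list[np.ndarray]:
    """Waveform snippet sets across sessions with multiplicative amplitude drift.

    Session ``k`` uses the template scaled by ``(1 + k * drift)`` plus
    independent per-spike Gaussian noise.
    """
    if amplitude_drift_per_session < 0:
        raise ValueError("drift must be >= 0")
    out = []
    for k in range(n_sessions):
        rng = np.random.default_rng([int(seed), 0xDF, k])
        scaled = template * (1.0 + k * amplitude_drift_per_session)
        out.append(scaled[None, :] + rng.normal(0.0, noise_sd, size=(n_spikes, template.size)))
    return out


def gen_cursor_trials(
    n_trials: int = 80,
    mode: str = "hand",
    noise_level: float = 0.0,
    seed: int = 0,
    speed_cm_s: float = 8.0,
    dt_s: float = 0.05,
    target_distance_cm: float = 7.5,
    target_radius_cm: float = 1.85,
    timeout_s: float = 10.0,
) -> list[CursorTrial]:
    """Center-out trials: 8 targets at 45 deg spacing, 7.5 cm from center.

    The cursor moves at constant speed; at each 50 ms step its heading points
    at the target plus Gaussian noise of SD ``noise_level`` radians.  A trial
    succeeds when the cursor center enters the target disk before timeout.
    """
    trials = []
    for i in range(n_trials):
        rng = np.random.default_rng([int(seed), 0xCE, i])
        direction = 45.0 * (i % 8)
        target = target_distance_cm * np.array(
            [np.cos(np.deg2rad(direction)), np.sin(np.deg2rad(direction))]
        )
        pos = np.zeros(2)
        times = [0.0]
        path = [pos.copy()]
        success = False
        t = 0.0
        while t < timeout_s:
            delta = target - pos
            if np.hypot(*delta) <= target_radius_cm:
                success = True
                break
            heading = np.arctan2(delta[1], delta[0])
            if noise_level > 0:
                heading += rng.normal(0.0, noise_level)
            pos = pos + speed_cm_s * dt_s * np.array([np.cos(heading), np.sin(heading)])
            t += dt_s
            times.append(t)
            path.append(pos.copy())
        trials.append(
            CursorTrial(
                times=np.asarray(times),
                positions=np.asarray(path),
                target_direction_deg=direction,
                target_distance_cm=target_distance_cm,
                target_radius_cm=target_radius_cm,
                mode=mode,
                success=success,
                timeout_s=timeout_s,
            )
        )
    return trials
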