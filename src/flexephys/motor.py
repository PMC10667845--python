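"""Preferred movement direction and preference strength of motor-cortical units.

Each unit's mean firing rate FR_i in the 0-300 ms epoch after movement onset
is collected for the eight center-out directions theta_i = 0, 45, ..., 315
degrees, and projected onto the plane after normalization by the most active
direction:

    FRx = sum_i (FR_i / max_j FR_j) * cos theta_i
    FRy = sum_i (FR_i / max_j FR_j) * sin theta_i

The preferred direction is the angle of [FRx, FRy] and the preference
strength its length.  The max normalization makes both quantities invariant
to rescaling all rates; a uniform profile gives a zero vector (undefined
direction, strength 0) because sines and cosines over eight equispaced
angles cancel exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DirectionTuning", "epoch_rates", "preferred_direction"]

DIRECTIONS_DEG = np.arange(8) * 45.0
EPOCH_S = 0.3  # response window after movement onset


@dataclass
class DirectionTuning:
    directions_deg: np.ndarray
    rates_hz: np.ndarray
    frx: float
    fry: float
    preferred_direction_deg: float  # NaN when the rate vector is uniform/zero
    strength: float


def epoch_rates(
    spike_times: np.ndarray, trials: pd.DataFrame, epoch_s: float = EPOCH_S
) -> tuple[np.ndarray, np.ndarray]:
    """Mean rate in [movement onset, movement onset + 300 ms] per direction.

    Returns ``(directions_deg, rates_hz)``; a direction with no trials is an
    error naming the direction.
    """
    if "movement_onset_s" not in trials.columns:
        raise ValueError("trial table lacks movement_onset_s")
    t = np.asarray(spike_times, dtype=float)
    rates = np.empty(DIRECTIONS_DEG.size)
    for i, d in enumerate(DIRECTIONS_DEG):
        sel = trials[trials["direction_deg"] == d]
        if len(sel) == 0:
            raise ValueError(f"no trials for direction {d} deg")
        per_trial = []
        for row in sel.itertuples(index=False):
            t0 = row.movement_onset_s
            n = np.searchsorted(t, t0 + epoch_s, side="left") - np.searchsorted(t, t0, side="left")
            per_trial.append(n / epoch_s)
        rates[i] = float(np.mean(per_trial))
    return DIRECTIONS_DEG.copy(), rates


def preferred_direction(rates_hz: np.ndarray, directions_deg: np.ndarray | None = None) -> DirectionTuning:
    """Vector-sum preferred direction and strength from eight per-direction rates."""
    fr = np.asarray(rates_hz, dtype=float)
    theta = DIRECTIONS_DEG if directions_deg is None else np.asarray(directions_deg, float)
    if fr.size != 8 or theta.size != 8:
        raise ValueError("expected rates for exactly 8 directions")
    if np.any(fr < 0):
        raise ValueError("rates must be non-negative")
    peak = fr.max()
    if peak == 0:
        return DirectionTuning(theta.copy(), fr, 0.0, 0.0, float("nan"), 0.0)
    w = fr / peak
    rad = np.deg2rad(theta)
    frx = float(np.sum(w * np.cos(rad)))
    fry = float(np.sum(w * np.sin(rad)))
    strength = float(np.hypot(frx, fry))
    if strength < 1e-12:
        return DirectionTuning(theta.copy(), fr, frx, fry, float("nan"), 0.0)
    pref = float(np.mod(np.rad2deg(np.arctan2(fry, frx)), 360.0))
    if pref >= 360.0:  # float wrap of tiny negative angles
        pref = 0.0
    return DirectionTuning(theta.copy(), fr, frx, fry, pref, strength)
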