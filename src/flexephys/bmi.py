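"""Center-out task metrics, hand-vs-brain comparison statistics, and a
plumbing linear decoder with a closed-loop simulator.

Task geometry: eight targets (3.7 cm diameter) at 45 degree spacing, 7.5 cm
from the center; a trial succeeds when the cursor center enters the target
disk before timeout.  Metrics per trial:

* accuracy — successes / attempts per target direction;
* time cost — time from trial start to target acquisition (successes only);
* path efficiency — straight-line distance from start to the acquisition
  point over the actual path length traveled up to it (<= 1 by the triangle
  inequality).

Hand vs brain control is compared per direction: accuracy by a two-tailed
bootstrap of the success-proportion difference (2000 resamples), time cost
and path efficiency by Mann-Whitney U; all p-value families are adjusted by
Benjamini-Hochberg FDR.

The velocity decoder is a deliberately simple ridge regression from binned
population counts to 2D cursor velocity — plumbing to exercise the metrics
in closed loop, not a model of any published decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session import CursorTrial

__all__ = [
    "TaskMetrics",
    "path_efficiency",
    "time_cost",
    "accuracy",
    "bh_fdr",
    "compare_modes",
    "train_velocity_decoder",
    "simulate_closed_loop",
]


@dataclass
class TaskMetrics:
    mode: str
    accuracy_by_direction: dict[float, float]
    time_cost_s: np.ndarray
    path_efficiency: np.ndarray


def _acquisition_index(trial: CursorTrial) -> int:
    """Index of the first cursor sample inside the target disk."""
    d = np.linalg.norm(trial.positions - trial.target_center, axis=1)
    inside = np.flatnonzero(d <= trial.target_radius_cm)
    if inside.size == 0:
        raise ValueError("trial never reaches the target")
    return int(inside[0])


def path_efficiency(trial: CursorTrial) -> float:
    """Shortest-path over traveled distance, up to the acquisition sample."""
    if trial.positions.shape[0] < 2:
        raise ValueError("need >= 2 cursor samples")
    k = _acquisition_index(trial)
    seg = np.diff(trial.positions[: k + 1], axis=0)
    traveled = float(np.sum(np.linalg.norm(seg, axis=1)))
    if traveled == 0.0:
        return float("nan")
    straight = float(np.linalg.norm(trial.positions[k] - trial.positions[0]))
    return straight / traveled


def time_cost(trial: CursorTrial) -> float:
    """Time from trial start to the acquisition sample, seconds."""
    k = _acquisition_index(trial)
    return float(trial.times[k] - trial.times[0])


def accuracy(trials: list[CursorTrial]) -> dict[float, float]:
    """Successes / attempts per target direction."""
    by_dir: dict[float, list[bool]] = {}
    for t in trials:
        by_dir.setdefault(float(t.target_direction_deg), []).append(bool(t.success))
    return {d: float(np.mean(v)) for d, v in sorted(by_dir.items())}


def task_metrics(trials: list[CursorTrial]) -> TaskMetrics:
    """All three per-mode metrics; time cost and efficiency over successes only."""
    succ = [t for t in trials if t.success]
    return TaskMetrics(
        mode=trials[0].mode if trials else "hand",
        accuracy_by_direction=accuracy(trials),
        time_cost_s=np.array([time_cost(t) for t in succ]),
        path_efficiency=np.array([path_efficiency(t) for t in succ]),
    )


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _bootstrap_proportion_test(
    x: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> float:
    """Two-tailed bootstrap p for a difference in success proportions.

    Trials are resampled with replacement within each mode; the two-tailed p
    comes from where zero falls in the resampled difference distribution
    (add-one corrected).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    both = np.r_[x, y]
    if np.all(both == both[0]):  # degenerate: no variation at all
        return 1.0
    bx = rng.integers(0, x.size, size=(n_boot, x.size))
    by = rng.integers(0, y.size, size=(n_boot, y.size))
    diff = x[bx].mean(axis=1) - y[by].mean(axis=1)
    p_le = (1 + np.sum(diff <= 0)) / (n_boot + 1)
    p_ge = (1 + np.sum(diff >= 0)) / (n_boot + 1)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def compare_modes(
    hand_trials: list[CursorTrial],
    brain_trials: list[CursorTrial],
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-direction hand-vs-brain statistics with BH-FDR adjustment.

    Accuracy: two-tailed bootstrap (``n_boot`` resamples) of the
    success-proportion difference.  Time cost / path efficiency (successful
    trials): two-sided Mann-Whitney U.  Each metric's p-value family is
    adjusted separately; rows are directions, columns
    ``{metric}_p`` and ``{metric}_p_adj``.
    """
    rng = np.random.default_rng(seed)
    dirs = sorted(
        {float(t.target_direction_deg) for t in hand_trials}
        & {float(t.target_direction_deg) for t in brain_trials}
    )
    rows = {}
    for d in dirs:
        h = [t for t in hand_trials if float(t.target_direction_deg) == d]
        b = [t for t in brain_trials if float(t.target_direction_deg) == d]
        hs = np.array([t.success for t in h], dtype=float)
        bs = np.array([t.success for t in b], dtype=float)
        row = {"accuracy_hand": hs.mean(), "accuracy_brain": bs.mean()}
        row["accuracy_p"] = _bootstrap_proportion_test(hs, bs, n_boot, rng)
        for name, fn in (("time_cost", time_cost), ("path_efficiency", path_efficiency)):
            xv = np.array([fn(t) for t in h if t.success])
            yv = np.array([fn(t) for t in b if t.success])
            if xv.size == 0 or yv.size == 0:
                row[f"{name}_p"] = np.nan
            elif np.all(np.r_[xv, yv] == xv[0]):  # degenerate: identical constants
                row[f"{name}_p"] = 1.0
            else:
                row[f"{name}_p"] = float(
                    stats.mannwhitneyu(xv, yv, alternative="two-sided").pvalue
                )
        rows[d] = row
    df = pd.DataFrame(rows).T
    df.index.name = "direction_deg"
    for metric in ("accuracy", "time_cost", "path_efficiency"):
        p = df[f"{metric}_p"].to_numpy()
        ok = ~np.isnan(p)
        adj = np.full(p.size, np.nan)
        if ok.any():
            adj[ok] = bh_fdr(p[ok])
        df[f"{metric}_p_adj"] = adj
    return df


def save_cursor_trials(trials: list[CursorTrial], path) -> None:
    """Write cursor trials as a flat CSV, one row per cursor sample."""
    rows = []
    for i, t in enumerate(trials):
        for j in range(t.times.size):
            rows.append(
                {
                    "trial_id": i,
                    "time_s": t.times[j],
                    "x_cm": t.positions[j, 0],
                    "y_cm": t.positions[j, 1],
                    "target_direction_deg": t.target_direction_deg,
                    "target_distance_cm": t.target_distance_cm,
                    "target_radius_cm": t.target_radius_cm,
                    "mode": t.mode,
                    "success": int(t.success),
                    "timeout_s": t.timeout_s,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_cursor_trials(path) -> list[CursorTrial]:
    """Read a flat per-sample cursor CSV back into trials."""
    df = pd.read_csv(path)
    trials = []
    for _, g in df.groupby("trial_id", sort=True):
        trials.append(
            CursorTrial(
                times=g["time_s"].to_numpy(),
                positions=g[["x_cm", "y_cm"]].to_numpy(),
                target_direction_deg=float(g["target_direction_deg"].iloc[0]),
                target_distance_cm=float(g["target_distance_cm"].iloc[0]),
                target_radius_cm=float(g["target_radius_cm"].iloc[0]),
                mode=str(g["mode"].iloc[0]),
                success=bool(g["success"].iloc[0]),
                timeout_s=float(g["timeout_s"].iloc[0]),
            )
        )
    return trials


def train_velocity_decoder(
    counts: np.ndarray, velocities: np.ndarray, ridge_lambda: float = 1e-6
) -> np.ndarray:
    """Ridge regression from binned counts (n x u) to 2D velocity (n x 2).

    Returns an (u + 1) x 2 weight matrix whose last row is the intercept.
    """
    X = np.asarray(counts, dtype=float)
    Y = np.asarray(velocities, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("counts and velocities must align")
    Xa = np.hstack([X, np.ones((X.shape[0], 1))])
    reg = ridge_lambda * np.eye(Xa.shape[1])
    reg[-1, -1] = 0.0  # intercept not penalized
    W = np.linalg.solve(Xa.T @ Xa + reg, Xa.T @ Y)
    return W


def decode_velocity(weights: np.ndarray, counts: np.ndarray) -> np.ndarray:
    c = np.atleast_2d(np.asarray(counts, dtype=float))
    return np.hstack([c, np.ones((c.shape[0], 1))]) @ weights


def simulate_closed_loop(
    weights: np.ndarray,
    preferred_directions_deg: np.ndarray,
    baseline_hz: float = 10.0,
    modulation_hz: float = 15.0,
    n_trials: int = 40,
    dt_s: float = 0.05,
    target_distance_cm: float = 7.5,
    target_radius_cm: float = 1.85,
    timeout_s: float = 10.0,
    noise: bool = True,
    seed: int = 0,
) -> list[CursorTrial]:
    """Closed-loop brain-control simulation over the eight center-out targets.

    At each 50 ms step the cosine-tuned population fires toward the current
    cursor-to-target direction (Poisson counts when ``noise``, expected
    counts otherwise), the decoder maps counts to velocity, and the cursor
    integrates it.  Success per the target-disk rule.
    """
    pd_rad = np.deg2rad(np.asarray(preferred_directions_deg, dtype=float))
    trials = []
    for i in range(n_trials):
        rng = np.random.default_rng([int(seed), 0xB1, i])
        direction = 45.0 * (i % 8)
        target = target_distance_cm * np.array(
            [np.cos(np.deg2rad(direction)), np.sin(np.deg2rad(direction))]
        )
        pos = np.zeros(2)
        times, path = [0.0], [pos.copy()]
        success = False
        t = 0.0
        while t < timeout_s:
            delta = target - pos
            if np.hypot(*delta) <= target_radius_cm:
                success = True
                break
            heading = np.arctan2(delta[1], delta[0])
            lam = (baseline_hz + modulation_hz * np.cos(heading - pd_rad)).clip(min=0.0) * dt_s
            cnt = rng.poisson(lam) if noise else lam
            vel = decode_velocity(weights, cnt)[0]
            pos = pos + vel * dt_s
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
                mode="brain",
                success=success,
                timeout_s=timeout_s,
            )
        )
    return trials


def training_data_for_decoder(
    preferred_directions_deg: np.ndarray,
    baseline_hz: float = 10.0,
    modulation_hz: float = 15.0,
    speed_cm_s: float = 8.0,
    n_samples: int = 2000,
    dt_s: float = 0.05,
    noise: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Open-loop (counts, velocity) pairs from the same cosine-tuned population.

    Headings are drawn uniformly; velocity targets are ``speed * (cos, sin)``
    of the heading — the analogue of hand-control calibration data.
    """
    rng = np.random.default_rng([int(seed), 0xB2])
    pd_rad = np.deg2rad(np.asarray(preferred_directions_deg, dtype=float))
    heading = rng.uniform(0, 2 * np.pi, n_samples)
    lam = (baseline_hz + modulation_hz * np.cos(heading[:, None] - pd_rad[None, :])).clip(min=0.0) * dt_s
    counts = rng.poisson(lam) if noise else lam
    vel = speed_cm_s * np.stack([np.cos(heading), np.sin(heading)], axis=1)
    return counts.astype(float), vel
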