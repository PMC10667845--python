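"""Post-sorting unit quality metrics and accept/reject rules.

A sorted cluster is accepted as a single unit when it clears, jointly:
firing rate > 0.05 Hz, peak SNR > 1.5, refractory (1.6 ms) ISI-violation
fraction <= 2%, and — when the external sorter supplies them — isolation
> 0.95 and noise overlap < 0.03.  Outlier snippets are removed beforehand
with a generalized extreme studentized deviate (GESD) test on each
snippet's L2 distance from the mean waveform.

The ISI-violation denominator is the number of spikes ("fraction of spikes
with short inter-spike intervals"); set ``denominator="isis"`` for the
per-interval reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .session import SortedUnit

__all__ = [
    "CurationCriteria",
    "QualityReport",
    "firing_rate",
    "isi_violation_fraction",
    "peak_to_trough",
    "snr",
    "gesd_outliers",
    "curate",
    "merge_duplicate_units",
]

#: SNR reported when the residual SD is exactly zero (noise-free snippets)
SNR_CAP = np.inf


@dataclass
class CurationCriteria:
    """Acceptance gates; the defaults are the standard chronic-recording set."""

    min_firing_rate_hz: float = 0.05
    min_snr: float = 1.5
    max_isi_violation: float = 0.02
    refractory_ms: float = 1.6
    min_isolation: float = 0.95
    max_noise_overlap: float = 0.03
    gesd_alpha: float = 0.05
    gesd_max_fraction: float = 0.1


@dataclass
class QualityReport:
    unit_id: str
    firing_rate_hz: float
    isi_violation_fraction: float
    peak_to_trough_uv: float
    snr: float
    n_outliers_removed: int
    accepted: bool
    reasons: list[str] = field(default_factory=list)


def firing_rate(spike_times: np.ndarray, duration_s: float) -> float:
    """Mean rate = n_spikes / duration."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    return np.asarray(spike_times).size / duration_s


def isi_violation_fraction(
    spike_times: np.ndarray, refractory_ms: float = 1.6, denominator: str = "spikes"
) -> float:
    """Fraction of refractory-period violations in a sorted train.

    numerator = #ISIs shorter than ``refractory_ms``; denominator = #spikes
    (default) or #ISIs.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        return 0.0
    n_viol = int(np.sum(np.diff(t) < refractory_ms * 1e-3))
    denom = t.size if denominator == "spikes" else t.size - 1
    return n_viol / denom


def peak_to_trough(mean_waveform: np.ndarray) -> float:
    """Peak-to-trough amplitude (max - min) of the mean waveform, microvolt."""
    w = np.asarray(mean_waveform, dtype=float)
    if w.size == 0:
        raise ValueError("empty waveform")
    return float(w.max() - w.min())


def snr(waveforms: np.ndarray) -> float:
    """Peak SNR: p2t of the mean waveform over twice the residual SD.

    Residuals are the per-sample deviations of each snippet from the mean.
    With template amplitude A and additive noise SD s this converges to
    A / (2 s); noise-free snippets report the +inf sentinel.
    """
    w = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if w.shape[0] < 2:
        raise ValueError("snr needs >= 2 snippets")
    mean = w.mean(axis=0)
    resid_sd = float((w - mean).std())
    p2t = peak_to_trough(mean)
    if resid_sd <= 1e-10 * max(1.0, p2t):  # numerically noise-free snippets
        return SNR_CAP
    return p2t / (2.0 * resid_sd)


def _gesd_scalar(x: np.ndarray, alpha: float, max_outliers: int) -> list[int]:
    """Rosner's GESD on a scalar sample; returns indices of declared outliers.

    Iteratively removes the point furthest from the current mean; outlier
    count = the largest i whose studentized extreme R_i exceeds the critical
    value lambda_i from the t distribution.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    idx = np.arange(n)
    removed: list[int] = []
    R: list[float] = []
    work = x.copy()
    for _ in range(max_outliers):
        m, s = work.mean(), work.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(work - m)
        j = int(np.argmax(dev))
        R.append(dev[j] / s)
        removed.append(int(idx[j]))
        work = np.delete(work, j)
        idx = np.delete(idx, j)
    n_out = 0
    for i in range(1, len(R) + 1):
        ni = n - i + 1  # sample size before the i-th removal
        p = 1.0 - alpha / (2.0 * ni)
        tcrit = stats.t.ppf(p, ni - 2)
        lam = (ni - 1) * tcrit / np.sqrt((ni - 2 + tcrit**2) * ni)
        if R[i - 1] > lam:
            n_out = i
    return removed[:n_out]


def gesd_outliers(
    waveforms: np.ndarray, alpha: float = 0.05, max_fraction: float = 0.1
) -> np.ndarray:
    """Indices of outlier snippets by GESD on L2 distance from the mean waveform.

    Fewer than 10 snippets: the test is skipped with a warning (empty result).
    """
    w = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if w.shape[0] < 10:
        warnings.warn("gesd_outliers: fewer than 10 snippets, skipping outlier test")
        return np.array([], dtype=int)
    dist = np.linalg.norm(w - w.mean(axis=0), axis=1)
    max_outliers = max(1, int(np.floor(max_fraction * w.shape[0])))
    return np.asarray(sorted(_gesd_scalar(dist, alpha, max_outliers)), dtype=int)


def curate(
    units: list[SortedUnit],
    duration_s: float,
    criteria: CurationCriteria | None = None,
    isi_denominator: str = "spikes",
) -> list[QualityReport]:
    """Score every unit against the acceptance gates.

    GESD outlier snippets are removed before waveform metrics; each failed
    gate is named in ``reasons``.  Isolation / noise-overlap gates apply only
    to units whose sorter supplied those fields.
    """
    c = criteria or CurationCriteria()
    reports = []
    for u in units:
        fr = firing_rate(u.spike_times, duration_s)
        isi = isi_violation_fraction(u.spike_times, c.refractory_ms, isi_denominator)
        if u.waveforms.shape[0] >= 10:
            out = gesd_outliers(u.waveforms, c.gesd_alpha, c.gesd_max_fraction)
            wf = np.delete(u.waveforms, out, axis=0)
        else:
            out = np.array([], dtype=int)
            wf = u.waveforms
        if wf.shape[0] >= 2:
            p2t = peak_to_trough(wf.mean(axis=0))
            u_snr = snr(wf)
        elif wf.shape[0] == 1:
            p2t, u_snr = peak_to_trough(wf[0]), 0.0
        else:
            p2t, u_snr = 0.0, 0.0

        reasons = []
        if not fr > c.min_firing_rate_hz:
            reasons.append("firing_rate")
        if not u_snr > c.min_snr:
            reasons.append("snr")
        if not isi <= c.max_isi_violation:
            reasons.append("isi_violation")
        if u.isolation is not None and not u.isolation > c.min_isolation:
            reasons.append("isolation")
        if u.noise_overlap is not None and not u.noise_overlap < c.max_noise_overlap:
            reasons.append("noise_overlap")
        reports.append(
            QualityReport(
                unit_id=u.unit_id,
                firing_rate_hz=fr,
                isi_violation_fraction=isi,
                peak_to_trough_uv=p2t,
                snr=u_snr,
                n_outliers_removed=int(out.size),
                accepted=not reasons,
                reasons=reasons,
            )
        )
    return reports


def _coincidence_fraction(a: np.ndarray, b: np.ndarray, window_s: float) -> float:
    """Fraction of the smaller train's spikes with a partner within +-window."""
    small, big = (a, b) if a.size <= b.size else (b, a)
    if small.size == 0:
        return 0.0
    lo = np.searchsorted(big, small - window_s, side="left")
    hi = np.searchsorted(big, small + window_s, side="right")
    return float(np.mean(hi > lo))


def merge_duplicate_units(
    units: list[SortedUnit],
    channel_positions: dict[int, tuple[float, float]],
    adjacency_radius_um: float = 100.0,
    coincidence_window_ms: float = 0.5,
    min_overlap_fraction: float = 0.5,
) -> list[SortedUnit]:
    """Merge near-duplicate clusters split across adjacent channels.

    Pairs whose primary channels lie within the adjacency radius and whose
    spike-time coincidence (within the window) exceeds ``min_overlap_fraction``
    of the smaller train are merged: spikes unioned, duplicates within the
    window collapsed, waveforms concatenated, identity of the lower unit_id
    kept.  Chance coincidence for independent trains is about
    ``2 * rate * window`` and never approaches the 0.5 default.
    """
    window_s = coincidence_window_ms * 1e-3
    pos = {k: np.asarray(v, dtype=float) for k, v in channel_positions.items()}

    parent = {u.unit_id: u.unit_id for u in units}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_id = {u.unit_id: u for u in units}
    ids = sorted(by_id)
    for i, ua in enumerate(ids):
        for ub in ids[i + 1 :]:
            a, b = by_id[ua], by_id[ub]
            d = np.linalg.norm(pos[a.primary_channel] - pos[b.primary_channel])
            if d > adjacency_radius_um:
                continue
            if _coincidence_fraction(a.spike_times, b.spike_times, window_s) > min_overlap_fraction:
                ra, rb = find(ua), find(ub)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[SortedUnit]] = {}
    for u in units:
        groups.setdefault(find(u.unit_id), []).append(u)

    merged = []
    for root, members in sorted(groups.items()):
        if len(members) == 1:
            merged.append(members[0])
            continue
        times = np.sort(np.concatenate([m.spike_times for m in members]))
        keep = np.concatenate([[True], np.diff(times) > window_s])
        lead = min(members, key=lambda m: m.unit_id)
        merged.append(
            SortedUnit(
                unit_id=lead.unit_id,
                spike_times=times[keep],
                primary_channel=lead.primary_channel,
                waveforms=np.concatenate([m.waveforms for m in members], axis=0),
                isolation=lead.isolation,
                noise_overlap=lead.noise_overlap,
            )
        )
    return merged
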