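"""Cross-session unit tracking by waveform PCA distance.

Two units recorded on corresponding channels in consecutive sessions are
declared the same putative neuron when the distance between their waveform
PC-score cluster centers is below ``sigma_multiple`` (default 2) times the
spread of the earlier session's score cloud.  The spread sigma is the RMS
per-component SD of the earlier cloud; a per-component Mahalanobis variant
is available via ``sigma_mode="mahalanobis"``.

The PCA basis is fit on the pooled snippets of the session pair by default
(``basis="pooled"``); ``basis="earlier"`` fits on the earlier session only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .session import SortedUnit

__all__ = ["TrackMatch", "waveform_pc_scores", "match_units", "chain_tracks"]


@dataclass
class TrackMatch:
    session_pair: tuple[str, str]
    unit_pair: tuple[str, str]
    center_distance_sigma: float
    matched: bool


def waveform_pc_scores(
    waveforms_a: np.ndarray,
    waveforms_b: np.ndarray,
    n_components: int = 2,
    basis: str = "pooled",
) -> tuple[np.ndarray, np.ndarray, PCA]:
    """Project two snippet sets onto a shared PC basis.

    Returns ``(scores_a, scores_b, fitted_pca)``.  The basis is fit on the
    pooled snippets (default) or on set A alone (``basis="earlier"``).
    """
    wa = np.atleast_2d(np.asarray(waveforms_a, dtype=float))
    wb = np.atleast_2d(np.asarray(waveforms_b, dtype=float))
    if wa.shape[1] != wb.shape[1]:
        raise ValueError(f"snippet length mismatch: {wa.shape[1]} vs {wb.shape[1]}")
    pca = PCA(n_components=n_components)
    if basis == "pooled":
        pca.fit(np.vstack([wa, wb]))
    elif basis == "earlier":
        pca.fit(wa)
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return pca.transform(wa), pca.transform(wb), pca


def _cloud_sigma(scores: np.ndarray, mode: str) -> float | np.ndarray:
    if mode == "rms":
        return float(np.sqrt(np.mean(scores.var(axis=0, ddof=1))))
    if mode == "mahalanobis":
        return scores.std(axis=0, ddof=1)
    raise ValueError(f"unknown sigma_mode {mode!r}")


def match_units(
    units_a: list[SortedUnit],
    units_b: list[SortedUnit],
    session_ids: tuple[str, str] = ("A", "B"),
    channel_positions: dict[int, tuple[float, float]] | None = None,
    adjacency_radius_um: float = 100.0,
    n_components: int = 2,
    sigma_multiple: float = 2.0,
    basis: str = "pooled",
    sigma_mode: str = "rms",
) -> list[TrackMatch]:
    """One-to-one matching of units across a session pair.

    Candidate pairs share a primary channel, or lie within the adjacency
    radius when channel positions are given.  For each candidate the PC
    cluster-center distance is expressed in units of the earlier session's
    cloud sigma; pairs under ``sigma_multiple`` are match candidates, and a
    greedy one-to-one assignment keeps the smallest distances first (ties
    broken by lower unit_id).
    """
    candidates: list[TrackMatch] = []
    for ua in units_a:
        if ua.waveforms.shape[0] < 2:
            warnings.warn(f"unit {ua.unit_id}: too few waveforms, skipped in matching")
            continue
        for ub in units_b:
            if ub.waveforms.shape[0] < 2:
                continue
            if channel_positions is not None:
                pa = np.asarray(channel_positions[ua.primary_channel], dtype=float)
                pb = np.asarray(channel_positions[ub.primary_channel], dtype=float)
                if np.linalg.norm(pa - pb) > adjacency_radius_um:
                    continue
            elif ua.primary_channel != ub.primary_channel:
                continue
            sa, sb, _ = waveform_pc_scores(ua.waveforms, ub.waveforms, n_components, basis)
            delta = sa.mean(axis=0) - sb.mean(axis=0)
            sig = _cloud_sigma(sa, sigma_mode)
            if sigma_mode == "mahalanobis":
                with np.errstate(divide="ignore", invalid="ignore"):
                    dist = float(np.sqrt(np.nansum((delta / sig) ** 2)))
            else:
                dist = float(np.linalg.norm(delta) / sig) if sig > 0 else np.inf
                if np.linalg.norm(delta) == 0.0:
                    dist = 0.0
            candidates.append(
                TrackMatch(
                    session_pair=session_ids,
                    unit_pair=(ua.unit_id, ub.unit_id),
                    center_distance_sigma=dist,
                    matched=False,
                )
            )

    # greedy one-to-one by smallest distance; ties by lower unit ids
    order = sorted(candidates, key=lambda m: (m.center_distance_sigma, m.unit_pair))
    taken_a: set[str] = set()
    taken_b: set[str] = set()
    for m in order:
        a, b = m.unit_pair
        if m.center_distance_sigma < sigma_multiple and a not in taken_a and b not in taken_b:
            m.matched = True
            taken_a.add(a)
            taken_b.add(b)
    return candidates


def chain_tracks(
    pair_matches: list[list[TrackMatch]],
    day_post_implant: list[int] | None = None,
) -> list[dict]:
    """Transitively chain adjacent-pair matches into per-neuron track chains.

    ``pair_matches[k]`` holds the matches between session k and k+1.  Returns
    a list of chains ``{"units": [(session_index, unit_id), ...], "span_days": int}``.
    Chains never branch because upstream matching is one-to-one.
    """
    chains: list[list[tuple[int, str]]] = []
    open_ends: dict[tuple[int, str], int] = {}
    for k, matches in enumerate(pair_matches):
        for m in matches:
            if not m.matched:
                continue
            a, b = m.unit_pair
            key = (k, a)
            if key in open_ends:
                ci = open_ends.pop(key)
                chains[ci].append((k + 1, b))
                open_ends[(k + 1, b)] = ci
            else:
                chains.append([(k, a), (k + 1, b)])
                open_ends[(k + 1, b)] = len(chains) - 1
    out = []
    for ch in chains:
        span = 0
        if day_post_implant is not None:
            span = day_post_implant[ch[-1][0]] - day_post_implant[ch[0][0]]
        out.append({"units": ch, "span_days": span})
    return out
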