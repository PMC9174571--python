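"""Morphological coherence screening of segmented beats.

Within one pacing setting all beats of a signal kind are resampled to
the modal beat length, every beat pair is compared by maximum
normalized cross-correlation over a small lag window, and the largest
mutually coherent group is kept.  A beat survives only if it is
coherent in ECG, acceleration and pressure simultaneously, so each
beat's electrical and mechanical responses are required to conform.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .acquisition import Beat

__all__ = [
    "CoherenceReport",
    "resample_beats_to_modal_length",
    "pairwise_max_xcorr",
    "coherence_group",
    "cross_confirm",
    "EmptyIntersectionError",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.95
DEFAULT_LAG_FRAC = 0.05
EXACT_SEARCH_MAX = 15


class EmptyIntersectionError(RuntimeError):
    """No beat is coherent in all signal kinds; setting unusable."""


@dataclass
class CoherenceReport:
    setting: str
    signal_kind: str
    kept: list[int]
    rejected: list[int]
    correlation: np.ndarray
    threshold: float
    beat_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.correlation.shape[0]
        if sorted(self.kept + self.rejected) != list(range(n)):
            raise ValueError("kept and rejected must partition the beats")

    def to_json(self) -> str:
        return json.dumps({
            "setting": self.setting,
            "signal_kind": self.signal_kind,
            "kept": self.kept,
            "rejected": self.rejected,
            "threshold": self.threshold,
            "beat_indices": self.beat_indices,
            "correlation": np.round(self.correlation, 6).tolist(),
        }, sort_keys=True)


def resample_beats_to_modal_length(beats: list[Beat]) -> list[Beat]:
    """Linearly resample every beat to the modal sample count.

    The most frequent length wins; ties go to the smaller length.
    Anchor times are rescaled proportionally.
    """
    if len(beats) < 2:
        raise ValueError("need at least 2 beats")
    lengths = np.array([len(b.samples) for b in beats])
    vals, counts = np.unique(lengths, return_counts=True)
    modal = int(vals[np.flatnonzero(counts == counts.max())[0]])
    out = []
    for b in beats:
        n = len(b.samples)
        if n == modal:
            out.append(b)
            continue
        ratio = modal / n
        x_old = np.arange(n)
        x_new = np.linspace(0, n - 1, modal)
        out.append(Beat(
            signal_kind=b.signal_kind,
            samples=np.interp(x_new, x_old, b.samples),
            fs=b.fs * ratio,
            a_spike_time=b.a_spike_time,
            v_spike_time=b.v_spike_time,
            beat_index=b.beat_index,
            pacing=b.pacing,
            t_start=b.t_start,
            channel=b.channel,
        ))
    return out


def pairwise_max_xcorr(
    Y: np.ndarray, max_lag: int
) -> np.ndarray:
    """Max normalized cross-correlation over lags in [-max_lag, max_lag].

    Rows of ``Y`` are zero-meaned and unit-normalized as whole beats;
    the correlation at lag L is the dot product of the overlapping
    segments.  Symmetric with unit diagonal.
    """
    Y = np.asarray(Y, float)
    Y = Y - Y.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Y, axis=1)
    norms[norms == 0] = 1.0
    Y = Y / norms[:, None]
    n, L = Y.shape
    C = Y @ Y.T
    for lag in range(1, max_lag + 1):
        if lag >= L:
            break
        S = Y[:, lag:] @ Y[:, :-lag].T     # row shifted left by lag vs col
        C = np.maximum(C, S)
        C = np.maximum(C, S.T)
    np.fill_diagonal(C, 1.0)
    return C


def _greedy_group(adj: np.ndarray) -> list[int]:
    """Quasi-clique grown from the highest-degree node (deterministic)."""
    n = adj.shape[0]
    degree = adj.sum(axis=1)
    seed = int(np.argmax(degree))           # first max -> lowest index
    group = [seed]
    order = sorted(range(n), key=lambda i: (-degree[i], i))
    changed = True
    while changed:
        changed = False
        for i in order:
            if i in group:
                continue
            if all(adj[i, j] for j in group):
                group.append(i)
                changed = True
    return sorted(group)


def _exact_group(adj: np.ndarray) -> list[int]:
    """Largest clique by exhaustive search (n <= 15 only).

    Ties between equal-size cliques break toward the lexicographically
    smallest member set.
    """
    n = adj.shape[0]
    best: tuple[int, list[int]] = (1, [0])
    nodes = list(range(n))
    for size in range(n, 0, -1):
        found = None
        for combo in itertools.combinations(nodes, size):
            ok = all(adj[i, j] for i, j in itertools.combinations(combo, 2))
            if ok:
                found = list(combo)
                break
        if found is not None:
            best = (size, found)
            break
    return sorted(best[1])


def coherence_group(
    beats: list[Beat],
    threshold: float = DEFAULT_THRESHOLD,
    *,
    lag_frac: float = DEFAULT_LAG_FRAC,
    setting: str = "",
    signal_kind: str = "",
) -> tuple[list[int], CoherenceReport]:
    """Largest mutually coherent beat group for one signal kind.

    Beats must be equal length (see ``resample_beats_to_modal_length``).
    An edge joins beats whose max cross-correlation within the lag
    window reaches ``threshold``; the kept set is the exact maximum
    clique for <=15 beats, otherwise a deterministic greedy quasi-clique
    seeded at the highest-degree beat.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    n = len(beats)
    if n < 2:
        log.warning("coherence_group: <2 beats, keeping all")
        C = np.ones((n, n))
        report = CoherenceReport(setting, signal_kind, list(range(n)), [],
                                 C, threshold,
                                 [b.beat_index for b in beats])
        return list(range(n)), report
    lengths = {len(b.samples) for b in beats}
    if len(lengths) != 1:
        raise ValueError("beats must share a length; resample first")
    L = lengths.pop()
    Y = np.stack([b.samples for b in beats])
    C = pairwise_max_xcorr(Y, max(1, int(lag_frac * L)))
    adj = C >= threshold
    np.fill_diagonal(adj, True)
    kept = _exact_group(adj) if n <= EXACT_SEARCH_MAX else _greedy_group(adj)
    rejected = sorted(set(range(n)) - set(kept))
    report = CoherenceReport(setting, signal_kind, kept, rejected, C,
                             threshold, [b.beat_index for b in beats])
    return kept, report


def cross_confirm(
    kept_ecg: set[int] | list[int],
    kept_accel: set[int] | list[int],
    kept_pressure: set[int] | list[int],
) -> list[int]:
    """Beats coherent in all three signal kinds (set intersection).

    Index sets refer to the shared beat universe (cycle indices).
    Raises :class:`EmptyIntersectionError` when nothing survives.
    """
    final = set(kept_ecg) & set(kept_accel) & set(kept_pressure)
    if not final:
        raise EmptyIntersectionError(
            "no beat is coherent in ECG, acceleration and pressure"
        )
    return sorted(final)
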