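"""Load-spectrum processing: turning points, peak simplification, rainflow counting.

A *load spectrum* is the stress-vs-time history at one leaflet integration
point over one (or more) cardiac cycles.  This module reduces such a history
to a set of counted stress sub-cycles suitable for damage accumulation:

1. :func:`extract_turning_points` keeps only the local extrema of the signal,
2. :func:`simplify_peaks` averages groups of near-equal same-kind peaks,
3. :func:`rainflow_count` decomposes the alternating sequence into closed
   cycles (count 1.0) and residual half-cycles (count 0.5) with the
   four-point rainflow rule,
4. :func:`count_spectrum` composes the three and normalises counts to a
   per-cardiac-cycle spectrum.

Stresses are signed (compression negative) so the amplitude/mean definitions
``s_a = (s_max - s_min)/2`` and ``s_m = (s_max + s_min)/2`` apply unchanged
to tensile and compressive phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StressHistory",
    "SubCycle",
    "cycle_stats",
    "extract_turning_points",
    "simplify_peaks",
    "rainflow_count",
    "count_spectrum",
    "read_history_csv",
    "write_history_csv",
    "subcycles_to_frame",
]

#: Absolute stress tolerance (MPa) below which two sub-cycle extremes are
#: considered identical and their counts merged.
DEFAULT_MERGE_TOL = 1e-6

#: Default relative tolerance for peak simplification: peaks of the same kind
#: within 5 % of the global absolute maximum of each other are averaged.
DEFAULT_REL_TOLERANCE = 0.05


@dataclass(frozen=True)
class StressHistory:
    """A sampled stress signal at one leaflet integration point.

    Parameters
    ----------
    time : array-like
        Sample times in seconds, strictly increasing.
    stress : array-like
        Signed stress in MPa (compression negative), same length as ``time``.
    label : str
        Free-text identifier (patient / surface / integration point).
    period : float, optional
        Seconds per cardiac cycle.  When set, :attr:`n_cycles` estimates how
        many cardiac cycles the history spans, which :func:`count_spectrum`
        uses to normalise counts.
    """

    time: np.ndarray
    stress: np.ndarray
    label: str = ""
    period: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.stress, dtype=float)
        if t.ndim != 1 or s.ndim != 1 or t.shape != s.shape:
            raise ValueError("time and stress must be 1-D arrays of equal length")
        if t.size < 3:
            raise ValueError("a stress history needs at least 3 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if self.period is not None and self.period <= 0:
            raise ValueError("period must be positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "stress", s)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def n_cycles(self) -> int:
        """Number of cardiac cycles spanned (1 if no period is set)."""
        if self.period is None:
            return 1
        return max(1, int(round(self.duration / self.period)))


def cycle_stats(s_max: float, s_min: float) -> tuple[float, float]:
    """Alternating stress and mean stress of a cycle segment.

    Returns ``(s_a, s_m)`` with ``s_a = (s_max - s_min)/2`` and
    ``s_m = (s_max + s_min)/2``.  Raises if the arguments are swapped.
    """
    if s_max < s_min:
        raise ValueError(f"s_max ({s_max}) must be >= s_min ({s_min})")
    return (s_max - s_min) / 2.0, (s_max + s_min) / 2.0


@dataclass(frozen=True)
class SubCycle:
    """One rainflow-extracted stress cycle with a fractional occurrence count.

    ``count`` is 1.0 for a closed (full) cycle and 0.5 for a residual
    half-cycle; merged and per-cardiac-cycle normalised spectra may carry any
    positive count.
    """

    s_max: float
    s_min: float
    count: float
    s_a: float = field(init=False)
    s_m: float = field(init=False)

    def __post_init__(self) -> None:
        s_a, s_m = cycle_stats(self.s_max, self.s_min)
        if self.count <= 0:
            raise ValueError("count must be positive")
        object.__setattr__(self, "s_a", s_a)
        object.__setattr__(self, "s_m", s_m)

    def scaled(self, factor: float) -> "SubCycle":
        return SubCycle(self.s_max, self.s_min, self.count * factor)


def _values(points: Sequence) -> list[float]:
    """Accept either a sequence of floats or of (time, stress) pairs."""
    out = []
    for p in points:
        if np.isscalar(p):
            out.append(float(p))
        else:
            out.append(float(p[1]))
    return out


def extract_turning_points(history: StressHistory) -> list[tuple[float, float]]:
    """Local extrema of the stress signal, endpoints retained.

    Plateaus (runs of equal values) are collapsed to their first sample.  A
    constant signal yields a single point, which downstream counting treats
    as an empty cycle set.
    """
    t, s = history.time, history.stress
    # collapse plateaus, keeping the first sample of each run
    keep = np.concatenate(([True], np.diff(s) != 0))
    t, s = t[keep], s[keep]
    if s.size == 1:
        return [(float(t[0]), float(s[0]))]
    d = np.diff(s)
    interior = np.where(d[:-1] * d[1:] < 0)[0] + 1
    idx = np.concatenate(([0], interior, [s.size - 1]))
    return [(float(t[i]), float(s[i])) for i in idx]


def _classify_kinds(values: Sequence[float]) -> list[bool]:
    """True for maxima, False for minima, for an alternating sequence."""
    n = len(values)
    kinds = []
    for i in range(n):
        if i + 1 < n:
            kinds.append(values[i] > values[i + 1])
        else:
            kinds.append(values[i] > values[i - 1])
    return kinds


def simplify_peaks(
    extrema: Sequence[tuple[float, float]],
    rel_tolerance: float = DEFAULT_REL_TOLERANCE,
) -> list[tuple[float, float]]:
    """Average groups of near-equal same-kind peaks.

    Peaks of the same kind (all maxima or all minima) whose values differ
    pairwise by at most ``rel_tolerance * max|stress|`` are replaced by their
    arithmetic mean.  ``rel_tolerance = 0`` is the identity.  Ordering is
    preserved; if averaging degenerates an adjacent max/min pair the sequence
    is re-reduced to strict alternation.
    """
    if rel_tolerance < 0:
        raise ValueError("rel_tolerance must be >= 0")
    if len(extrema) < 2 or rel_tolerance == 0:
        return list(extrema)
    times = [p[0] for p in extrema]
    vals = _values(extrema)
    tol = rel_tolerance * max(abs(v) for v in vals)
    kinds = _classify_kinds(vals)
    new_vals = list(vals)
    for kind in (True, False):
        members = sorted(
            (i for i in range(len(vals)) if kinds[i] == kind),
            key=lambda i: vals[i],
        )
        cluster: list[int] = []
        for i in members + [None]:  # sentinel flushes the last cluster
            if cluster and (i is None or vals[i] - vals[cluster[0]] > tol):
                mean = sum(vals[j] for j in cluster) / len(cluster)
                for j in cluster:
                    new_vals[j] = mean
                cluster = []
            if i is not None:
                cluster.append(i)
    simplified = list(zip(times, new_vals))
    # restore strict alternation in case averaging flattened a pair
    hist_like = _as_history(simplified)
    return extract_turning_points(hist_like) if hist_like is not None else simplified


def _as_history(points: list[tuple[float, float]]) -> StressHistory | None:
    if len(points) < 3:
        return None
    t = np.array([p[0] for p in points])
    s = np.array([p[1] for p in points])
    return StressHistory(time=t, stress=s)


def _merge(
    raw: Iterable[tuple[float, float, float]], merge_tol: float
) -> list[SubCycle]:
    """Merge (s_max, s_min, count) triples whose extremes agree within tol."""
    merged: list[list[float]] = []
    for s_max, s_min, count in raw:
        for m in merged:
            if abs(m[0] - s_max) <= merge_tol and abs(m[1] - s_min) <= merge_tol:
                m[2] += count
                break
        else:
            merged.append([s_max, s_min, count])
    return [SubCycle(m[0], m[1], m[2]) for m in merged]


def rainflow_count(
    extrema: Sequence, merge_tol: float = DEFAULT_MERGE_TOL
) -> list[SubCycle]:
    """Four-point rainflow decomposition of an alternating extrema sequence.

    Whenever four consecutive turning points enclose an inner range not
    larger than either neighbouring range, the inner pair is extracted as a
    closed cycle (count 1.0).  The unclosed residual contributes one
    half-cycle (count 0.5) per adjacent pair.  Identical (s_max, s_min)
    pairs are merged by summing counts, so twice the total count always
    equals the number of half-cycle ranges in the input.
    """
    vals = _values(extrema)
    if len(vals) < 2:
        return []
    stack: list[float] = []
    raw: list[tuple[float, float, float]] = []
    for v in vals:
        stack.append(v)
        while len(stack) >= 4:
            s1, s2, s3, s4 = stack[-4:]
            inner = abs(s3 - s2)
            if inner <= abs(s2 - s1) and inner <= abs(s4 - s3):
                raw.append((max(s2, s3), min(s2, s3), 1.0))
                del stack[-3:-1]
            else:
                break
    for x, y in zip(stack, stack[1:]):
        raw.append((max(x, y), min(x, y), 0.5))
    # zero-range pairs (possible after plateau-adjacent degeneracies) carry
    # no damage information and are dropped
    raw = [r for r in raw if r[0] > r[1]]
    return _merge(raw, merge_tol)


def count_spectrum(
    history: StressHistory,
    rel_tolerance: float = DEFAULT_REL_TOLERANCE,
    n_cycles: int | None = None,
    merge_tol: float = DEFAULT_MERGE_TOL,
) -> list[SubCycle]:
    """Counted per-cardiac-cycle sub-cycle spectrum of a stress history.

    Counting is performed on the full signal and counts are divided by the
    number of cardiac cycles spanned (stationary-spectrum assumption), so the
    result is the spectrum of one representative cardiac cycle.
    """
    k = n_cycles if n_cycles is not None else history.n_cycles
    if k < 1:
        raise ValueError("n_cycles must be >= 1")
    tp = extract_turning_points(history)
    tp = simplify_peaks(tp, rel_tolerance)
    cycles = rainflow_count(tp, merge_tol)
    if k == 1:
        return cycles
    return [c.scaled(1.0 / k) for c in cycles]


# ---------------------------------------------------------------------------
# CSV interfaces


def read_history_csv(
    path, label: str = "", period: float | None = None
) -> StressHistory:
    """Read a history CSV with required header columns ``time_s, stress_MPa``."""
    df = pd.read_csv(path)
    missing = {"time_s", "stress_MPa"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            "expected header 'time_s,stress_MPa'"
        )
    return StressHistory(
        time=df["time_s"].to_numpy(float),
        stress=df["stress_MPa"].to_numpy(float),
        label=label or str(path),
        period=period,
    )


def write_history_csv(history: StressHistory, path) -> None:
    pd.DataFrame({"time_s": history.time, "stress_MPa": history.stress}).to_csv(
        path, index=False
    )


def subcycles_to_frame(subcycles: Sequence[SubCycle]) -> pd.DataFrame:
    """Sub-cycle table with columns s_max_MPa, s_min_MPa, s_a_MPa, s_m_MPa, count."""
    return pd.DataFrame(
        {
            "s_max_MPa": [c.s_max for c in subcycles],
            "s_min_MPa": [c.s_min for c in subcycles],
            "s_a_MPa": [c.s_a for c in subcycles],
            "s_m_MPa": [c.s_m for c in subcycles],
            "count": [c.count for c in subcycles],
        }
    )
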