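"""Focal / reentrant pattern classification from electrode-array AcTs.

A mapping-system-style classifier that uses only activation times in a
3x3 electrode neighbourhood.  A site is focal (F) for a beat when every
neighbour activates within the wavefront interval of the central AcT; it
is reentrant (R+ clockwise / R- counterclockwise) when activation
progresses monotonically around the ring of 8 neighbours, with the
wrap-around step allowed to land on the starting neighbour's next beat
("continuation of activation between beats").  Two parameters govern the
rules: the difference threshold delta (ms) and the wavefront interval
gamma (ms); every step difference must lie in [-delta, gamma + delta].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activation import ActivationMap
from .geometry import ElectrodeArray

__all__ = ["ClassifierParams", "PatternDetection", "classify_site", "extract_patterns"]


@dataclass
class ClassifierParams:
    delta: float = 2.0    # ms, difference threshold
    gamma: float = 100.0  # ms, wavefront interval

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def lo(self) -> float:
        return -self.delta

    @property
    def hi(self) -> float:
        return self.gamma + self.delta


def _nearest_following(acts: np.ndarray, t: float, delta: float) -> float | None:
    """Smallest AcT at or after t - delta, or None."""
    acts = np.asarray(acts)
    cand = acts[acts >= t - delta]
    return float(cand[0]) if cand.size else None


def _nearest(acts: np.ndarray, t: float) -> float | None:
    """AcT nearest to t (earlier one on ties), or None."""
    acts = np.asarray(acts)
    if acts.size == 0:
        return None
    i = int(np.argmin(np.abs(acts - t)))
    # ties: argmin returns the first (earlier) occurrence
    return float(acts[i])


def _ring_progression(ring_acts, anchor_idx: int, t0: float, p: ClassifierParams) -> bool:
    """Check a monotone progression around the ring starting at anchor_idx.

    The anchor AcT is the starting neighbour's AcT nearest the central AcT;
    each subsequent neighbour contributes its nearest-following AcT; the
    wrap step returns to the starting neighbour's next-beat AcT.  All 8
    step differences must lie in [-delta, gamma+delta] and the closed-loop
    progression must be strictly positive.
    """
    n = len(ring_acts)
    anchor = _nearest(ring_acts[anchor_idx], t0)
    if anchor is None:
        return False
    prev = anchor
    for step in range(1, n):
        acts = ring_acts[(anchor_idx + step) % n]
        c = _nearest_following(acts, prev, p.delta)
        if c is None or not (p.lo <= c - prev <= p.hi):
            return False
        prev = c
    # wrap: starting neighbour's next beat
    acts0 = np.asarray(ring_acts[anchor_idx])
    nxt = acts0[(acts0 > anchor) & (acts0 >= prev - p.delta)]
    if nxt.size == 0:
        return False
    c = float(nxt[0])
    if not (p.lo <= c - prev <= p.hi):
        return False
    return c - anchor > 0


def classify_site(
    center_acts,
    ring_acts,
    params: ClassifierParams | None = None,
) -> list[tuple[float, str]]:
    """Classify each central AcT at one site; ring ordered clockwise.

    Returns a list of (central AcT, type) with type in {"F", "R+", "R-"};
    reentrant verdicts take precedence over focal (a slowly rotating ring
    can also satisfy the focal bound).
    """
    p = params or ClassifierParams()
    if len(ring_acts) != 8:
        raise ValueError("classification requires the 8-neighbour ring")
    ring = [np.sort(np.asarray(a, dtype=float)) for a in ring_acts]
    ring_ccw = list(reversed(ring))
    out: list[tuple[float, str]] = []
    for t0 in np.sort(np.asarray(center_acts, dtype=float)):
        r_plus = any(_ring_progression(ring, s, t0, p) for s in range(8))
        r_minus = any(_ring_progression(ring_ccw, s, t0, p) for s in range(8))
        if r_plus:
            out.append((float(t0), "R+"))
            continue
        if r_minus:
            out.append((float(t0), "R-"))
            continue
        focal = True
        for acts in ring:
            c = _nearest_following(acts, t0, p.delta)
            if c is None or not (p.lo <= c - t0 <= p.hi):
                focal = False
                break
        if focal:
            out.append((float(t0), "F"))
    return out


@dataclass
class PatternDetection:
    """One pattern verdict: a type at an electrode for one central beat."""

    type: str          # "F", "R+", "R-"
    electrode: str
    time: float        # central AcT, ms
    beat: int          # index of the central AcT at that electrode


def extract_patterns(
    acts: ActivationMap,
    array: ElectrodeArray,
    params: ClassifierParams | None = None,
) -> list[PatternDetection]:
    """Run the 3x3 classifier at every interior electrode and central AcT.

    Border electrodes (without 8 grid neighbours) are never classification
    centres.  The neighbour ring order comes from the array's adjacency
    convention (north first, clockwise viewed from outside the tissue).
    """
    p = params or ClassifierParams()
    detections: list[PatternDetection] = []
    adjacency = array.adjacency
    for i, ring_idx in enumerate(adjacency):
        if ring_idx is None:
            continue
        label = array.labels[i]
        center = np.sort(np.asarray(acts[label], dtype=float))
        ring_acts = [acts[array.labels[j]] for j in ring_idx]
        beat_of = {float(t): k for k, t in enumerate(center)}
        for t, typ in classify_site(center, ring_acts, p):
            detections.append(PatternDetection(typ, label, t, beat_of[float(t)]))
    return detections
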