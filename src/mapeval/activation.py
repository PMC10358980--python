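"""Activation-time detection, phase mapping and phase-singularity analysis.

Activation times (AcTs) are the sample of maximum signal derivative within
a suprathreshold episode, subject to a refractory window; no inter-sample
interpolation is performed, so AcT resolution equals the sampling interval
(1 ms at the standard 1 kHz rate).  Phase is the delay-embedded state-space
angle theta(t) = atan2(Vm(t+d)+c, Vm(t-d)+c) with c = 30 mV, d = 2 ms;
surface phase singularities (PSs) are nodes whose ordered one-ring winds
by +-2*pi, and reentry source locations R+/R- are the centres of mass of
the two k-means clusters of PS occurrences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import TissueGeometry

__all__ = [
    "DetectorParams",
    "ActivationMap",
    "PhaseRecord",
    "ReentrySource",
    "detect_activations",
    "detect_activation_map",
    "compute_phase",
    "surface_rings",
    "detect_surface_ps",
    "ps_density",
    "cluster_reentry_sources",
]


@dataclass
class DetectorParams:
    """Derivative-threshold AcT detector parameters.

    alpha: absolute derivative threshold in mV/ms (0.2 for Vm; 1.0 for
    good-contact electrograms, 0.5 otherwise, applied with negative
    polarity); beta: refractory window in ms; polarity: sign of the
    deflection that marks activation.
    """

    alpha: float = 0.2
    beta: float = 100.0
    polarity: str = "positive"

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")


@dataclass
class ActivationMap:
    """Sorted AcT lists per site (node index or electrode label)."""

    acts: dict = field(default_factory=dict)

    def __getitem__(self, site):
        return self.acts[site]

    def sites(self):
        return list(self.acts)

    def total_count(self) -> int:
        return sum(len(v) for v in self.acts.values())


def detect_activations(
    signal: np.ndarray,
    params: DetectorParams | None = None,
    sample_interval: float = 1.0,
    t0: float = 0.0,
) -> np.ndarray:
    """Detect activation times in one signal (mV sampled uniformly).

    Forward finite differences give the derivative per sample; contiguous
    runs where the signed derivative exceeds ``alpha`` form episodes, each
    contributing its extremal-derivative sample (earliest sample on ties);
    a candidate closer than ``beta`` ms to the last accepted AcT is
    discarded (greedy in time order).  Returns AcTs in ms.
    """
    params = params or DetectorParams()
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ValueError("signal needs at least 3 samples")
    deriv = np.diff(x) / sample_interval
    if params.polarity == "negative":
        deriv = -deriv
    above = deriv > params.alpha

    acts: list[float] = []
    i = 0
    n = len(deriv)
    last = -np.inf
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        seg = deriv[i:j]
        t = (i + int(np.argmax(seg))) * sample_interval + t0
        if t - last >= params.beta:
            acts.append(t)
            last = t
        i = j
    return np.asarray(acts)


def detect_activation_map(
    signals: np.ndarray,
    sites,
    params: DetectorParams | None = None,
    sample_interval: float = 1.0,
    t0: float = 0.0,
) -> ActivationMap:
    """Run the detector over rows of ``signals``, keyed by ``sites``."""
    amap = {}
    for row, site in zip(signals, sites):
        amap[site] = detect_activations(row, params, sample_interval, t0)
    return ActivationMap(amap)


@dataclass
class PhaseRecord:
    """Node x time phase in (-pi, pi]; NaN marks undefined samples."""

    theta: np.ndarray
    times: np.ndarray
    offset: float = 30.0
    delay: float = 2.0


def compute_phase(record, offset: float = 30.0, delay: float = 2.0) -> PhaseRecord:
    """Delay-embedded phase of a Vm movie.

    theta(t) = atan2(Vm(t+delay)+offset, Vm(t-delay)+offset).  The first and
    last ``delay`` ms are undefined (NaN), as are samples where both
    embedded values sit below a degeneracy floor (1e-9 mV) in magnitude.
    """
    vm = np.asarray(record.vm, dtype=float)
    times = np.asarray(record.times)
    dt = float(times[1] - times[0])
    d = int(round(delay / dt))
    if vm.shape[1] < 2 * d + 1:
        raise ValueError("record too short for the requested phase delay")
    theta = np.full(vm.shape, np.nan)
    lead = vm[:, 2 * d:] + offset
    lag = vm[:, : vm.shape[1] - 2 * d] + offset
    th = np.arctan2(lead, lag)
    degenerate = (np.abs(lead) < 1e-9) & (np.abs(lag) < 1e-9)
    th[degenerate] = np.nan
    theta[:, d: vm.shape[1] - d] = th
    return PhaseRecord(theta=theta, times=times, offset=offset, delay=delay)


def _wrap(dphi: np.ndarray) -> np.ndarray:
    """Wrap angle differences into (-pi, pi]."""
    return -((-dphi + np.pi) % (2.0 * np.pi) - np.pi)


_RING_CACHE: dict[int, dict[int, list[int]]] = {}


def surface_rings(geom: TissueGeometry) -> dict[int, list[int]]:
    """Ordered one-ring of surface neighbours per surface node.

    Rings are ordered counter-clockwise as seen from outside the tissue
    (following the orientation of ``surface_faces``).  Nodes with open or
    non-manifold fans (mesh borders) are omitted.
    """
    key = id(geom)
    if key in _RING_CACHE:
        return _RING_CACHE[key]
    succ: dict[int, dict[int, int]] = {}
    for tri in geom.surface_faces:
        for k in range(3):
            v, a, b = int(tri[k]), int(tri[(k + 1) % 3]), int(tri[(k + 2) % 3])
            succ.setdefault(v, {})[a] = b
    rings: dict[int, list[int]] = {}
    for v, nxt in succ.items():
        start = next(iter(nxt))
        ring = [start]
        ok = True
        cur = start
        for _ in range(len(nxt)):
            cur = nxt.get(cur)
            if cur is None:
                ok = False
                break
            if cur == start:
                break
            ring.append(cur)
        else:
            ok = False
        if ok and len(ring) == len(nxt) and nxt.get(ring[-1]) == start:
            rings[v] = ring
    _RING_CACHE[key] = rings
    return rings


def detect_surface_ps(
    phase: PhaseRecord,
    geom: TissueGeometry,
    t: float,
    winding_tol: float = np.pi,
) -> list[tuple[int, int]]:
    """Surface phase singularities at time ``t``.

    For each surface node the wrapped phase differences around its ordered
    one-ring are summed; a winding of magnitude above ``winding_tol``
    (default pi, the robust midpoint between 0 and 2*pi) marks a
    singularity with charge = sign(winding), taken with respect to the
    outward surface normal.  Connected same-charge flagged nodes are merged
    into a single PS at the node of maximal |winding| (a singularity inside
    one triangle flags every ring that encloses it).
    """
    times = np.asarray(phase.times)
    it = int(np.argmin(np.abs(times - t)))
    if abs(times[it] - t) > 0.5 * (times[1] - times[0]):
        raise ValueError(f"time {t} ms not within the phase record")
    th = phase.theta[:, it]
    if np.all(np.isnan(th)):
        raise ValueError(f"phase undefined at t={t} ms")
    rings = surface_rings(geom)

    winding = {}
    for v, ring in rings.items():
        vals = th[ring]
        if np.any(np.isnan(vals)) or np.isnan(th[v]):
            continue
        d = _wrap(np.diff(np.append(vals, vals[0])))
        winding[v] = float(np.sum(d))
    flagged = {v: w for v, w in winding.items() if abs(w) > winding_tol}
    if not flagged:
        return []

    # merge connected same-charge flags into single singularities
    neighbours = {v: set(r) for v, r in rings.items()}
    seen: set[int] = set()
    out: list[tuple[int, int]] = []
    for v in sorted(flagged):
        if v in seen:
            continue
        charge = int(np.sign(flagged[v]))
        group = [v]
        stack = [v]
        seen.add(v)
        while stack:
            u = stack.pop()
            for w in neighbours.get(u, ()):
                if w in flagged and w not in seen and int(np.sign(flagged[w])) == charge:
                    seen.add(w)
                    group.append(w)
                    stack.append(w)
        rep = min(group, key=lambda u: (-abs(flagged[u]), u))
        out.append((rep, charge))
    return sorted(out)


def ps_density(
    ps_series: list[tuple[float, list[tuple[int, int]]]],
    n_nodes: int,
    window: tuple[float, float] = (1000.0, 2000.0),
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """PS occurrence counts per node over a time window.

    ``ps_series`` is a list of (time ms, [(node, charge), ...]) frames.
    Returns the per-node count array and the flat occurrence list
    [(node, charge), ...] restricted to the window.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty analysis window")
    counts = np.zeros(n_nodes, dtype=np.int64)
    occurrences: list[tuple[int, int]] = []
    for t, frame in ps_series:
        if t0 <= t <= t1:
            for node, charge in frame:
                counts[node] += 1
                occurrences.append((int(node), int(charge)))
    return counts, occurrences


@dataclass
class ReentrySource:
    """A reentrant-wave surface source: cluster of PS occurrences."""

    location: np.ndarray
    chirality: str           # "R+" or "R-"
    support: int             # number of PS occurrences in the cluster
    member_nodes: np.ndarray


def cluster_reentry_sources(
    density: np.ndarray,
    geom: TissueGeometry,
    charges: list[tuple[int, int]],
    k: int = 2,
    seed: int = 0,
) -> tuple[ReentrySource, ReentrySource]:
    """Locate R+ and R- as k-means centres of mass of PS occurrences.

    ``density`` is the per-node occurrence count (used for validation);
    ``charges`` the flat occurrence list [(node, charge), ...].  Each
    occurrence contributes one point at its node's coordinates; k-means
    (k = 2, 10 seeded restarts) splits them, each cluster centre is the
    mean of its member coordinates, and cluster chirality is the majority
    charge.  Chirality convention (asserted on analytic rotor fixtures):
    a clockwise rotor, viewed from the mapping side along the outward
    surface normal, carries negative topological charge, so the cluster
    with the smaller mean charge is reported as R+ and the other as R-.
    """
    density = np.asarray(density)
    if int(np.count_nonzero(density)) < k:
        raise ValueError(f"need at least {k} occupied nodes for k={k} clustering")
    nodes = np.array([n for n, _ in charges], dtype=np.int64)
    ch = np.array([c for _, c in charges], dtype=float)
    pts = geom.nodes[nodes]
    if np.allclose(pts, pts[0], atol=1e-12):
        raise ValueError("all PS occurrences coincide; clusters degenerate")
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(pts)
    sources = []
    for lab in range(k):
        mask = labels == lab
        if not np.any(mask):
            raise ValueError("k-means produced an empty cluster")
        loc = pts[mask].mean(axis=0)
        mean_charge = ch[mask].mean()
        sources.append((mean_charge, loc, int(mask.sum()), np.unique(nodes[mask])))
    sources.sort(key=lambda s: s[0])
    r_plus = ReentrySource(sources[0][1], "R+", sources[0][2], sources[0][3])
    r_minus = ReentrySource(sources[-1][1], "R-", sources[-1][2], sources[-1][3])
    return r_plus, r_minus
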