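"""Monodomain reaction-diffusion solver and stimulation protocols.

The monodomain equation

    chi * Cm * dVm/dt + I_ion + I_stim = div(sigma grad Vm)

is solved on P1 finite elements with no-flux boundaries: operator splitting
advances the membrane model at the solver step (Rush-Larsen gates inside
the ionic model), then an implicit (backward Euler) diffusion step with a
mass-lumped capacitive term, so each step solves one symmetric
positive-definite sparse system whose factorisation is reused.

Defaults follow the tissue parameterisation used for human atrial tissue:
chi = 1400 cm^-1, Cm = 1 uF/cm^2, isotropic conductivity, dt = 0.1 ms,
Vm saved every 1 ms.  The default conductivity is calibrated so that a
plane wave with the Nygren membrane model propagates at the human atrial
conduction velocity of 55 cm/s at the reference discretization (250 um
node spacing, dt = 0.1 ms); see docs/methods.md for the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .cells import CellModel, get_model
from .fem import assemble_operators
from .geometry import TissueGeometry

__all__ = [
    "TissueParams",
    "StimulusEvent",
    "StimulusProtocol",
    "VmRecord",
    "run_monodomain",
    "protocol_s1s2",
    "protocol_focal",
    "protocol_paced",
    "measure_cv",
    "diastolic_threshold",
]


@dataclass
class TissueParams:
    """Tissue-level monodomain parameters.

    chi: surface-to-volume ratio (cm^-1); Cm: membrane capacitance
    (uF/cm^2); sigma: isotropic conductivity (mS/cm); dt: solver step (ms);
    save_interval: Vm output interval (ms); duration: total simulated time
    (ms).
    """

    chi: float = 1400.0
    Cm: float = 1.0
    # isotropic conductivity, calibrated for a 55 cm/s plane wave with the
    # Nygren model at 250 um / 0.1 ms discretization
    sigma: float = 3.7
    dt: float = 0.1
    save_interval: float = 1.0
    duration: float = 2000.0

    def __post_init__(self):
        for name in ("chi", "Cm", "sigma", "dt", "save_interval", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        ratio = self.save_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9 or self.save_interval < self.dt:
            raise ValueError("save_interval must be an integer multiple of dt")

    @property
    def diffusivity(self) -> float:
        """sigma/(chi*Cm) in cm^2/ms.

        sigma [mS/cm] / (chi [1/cm] * Cm [uF/cm^2]) = 1e3 cm^2/s = 1 cm^2/ms
        per unit ratio, i.e. the numerical ratio is already in cm^2/ms.
        """
        return self.sigma / (self.chi * self.Cm)


@dataclass
class StimulusEvent:
    onset: float                 # ms
    duration: float              # ms
    amplitude: float | None      # uA/cm^2; None -> auto (2x diastolic threshold)
    label: str = "S1"
    nodes: np.ndarray | None = None       # explicit node set
    center: np.ndarray | None = None      # or geometric selection
    radius: float | None = None           # cm

    def resolve_nodes(self, geom: TissueGeometry) -> np.ndarray:
        if self.nodes is not None:
            nodes = np.asarray(self.nodes, dtype=np.int64)
        else:
            d = np.linalg.norm(geom.nodes - np.asarray(self.center, dtype=float), axis=1)
            nodes = np.nonzero(d <= self.radius)[0]
        if nodes.size == 0:
            raise ValueError(f"stimulus event {self.label!r} selects no nodes")
        return nodes


@dataclass
class StimulusProtocol:
    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self):
        if any(ev.onset < 0 for ev in self.events):
            raise ValueError("stimulus onsets must be non-negative")


@dataclass
class VmRecord:
    """Transmembrane-potential movie: the simulation silver standard."""

    times: np.ndarray            # ms, uniform at save_interval
    vm: np.ndarray               # (n_nodes, n_times) mV
    geometry: TissueGeometry
    protocol: StimulusProtocol | None = None
    cell_model: str = ""
    params: TissueParams | None = None

    @property
    def sample_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def trace(self, node: int) -> np.ndarray:
        return self.vm[node]


def protocol_paced(
    geom: TissueGeometry, center, radius: float = 0.5, onset: float = 0.0,
    amplitude: float | None = None, duration: float = 2.0, label: str = "S1",
) -> StimulusProtocol:
    """Single paced beat from a circular site."""
    ev = StimulusEvent(onset, duration, amplitude, label,
                       center=np.asarray(center, float), radius=radius)
    ev.resolve_nodes(geom)  # validate non-empty now
    return StimulusProtocol([ev])


def protocol_s1s2(
    geom: TissueGeometry,
    s1_center,
    s2_center,
    s1_radius: float = 0.5,
    s2_radius: float = 1.0,
    s2_delay: float = 390.0,
    amplitude: float | None = None,
    duration: float = 2.0,
) -> StimulusProtocol:
    """S1-S2 protocol: small S1 site, larger S2 site fired after a delay.

    With the S2 region straddling the repolarising tail of the S1 wave this
    induces a figure-of-eight pair of counter-rotating reentrant waves.
    """
    s1 = StimulusEvent(0.0, duration, amplitude, "S1",
                       center=np.asarray(s1_center, float), radius=s1_radius)
    s2 = StimulusEvent(s2_delay, duration, amplitude, "S2",
                       center=np.asarray(s2_center, float), radius=s2_radius)
    s1.resolve_nodes(geom)
    s2.resolve_nodes(geom)
    return StimulusProtocol([s1, s2])


def protocol_focal(sources, amplitude: float | None = None, duration: float = 2.0) -> StimulusProtocol:
    """Replicated focal activity: one event per onset per source.

    ``sources`` is a list of (center, radius, onsets); the first source is
    labelled F+, the second F-, any further ones focal-k.  Onset lists must
    be non-decreasing and non-empty.
    """
    events = []
    for k, (center, radius, onsets) in enumerate(sources):
        onsets = list(onsets)
        if not onsets:
            raise ValueError("each focal source needs at least one onset")
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("focal onset lists must be non-decreasing")
        label = "F+" if k == 0 else ("F-" if k == 1 else f"focal-{k}")
        for t in onsets:
            events.append(
                StimulusEvent(float(t), duration, amplitude, label,
                              center=np.asarray(center, float), radius=radius)
            )
    return StimulusProtocol(events)


_THRESHOLD_CACHE: dict[tuple, float] = {}


def diastolic_threshold(cell_model: CellModel, duration: float = 2.0, dt: float = 0.1) -> float:
    """Single-cell diastolic threshold (uA/cm^2) by bisection.

    The threshold is the smallest stimulus amplitude of the given duration
    that elicits a full action potential (Vm crossing 0 mV within 50 ms)
    from rest.  Deterministic; cached per model configuration.
    """
    key = (cell_model.name, getattr(cell_model, "time_scale", None), duration, dt)
    if key in _THRESHOLD_CACHE:
        return _THRESHOLD_CACHE[key]

    def fires(amp: float) -> bool:
        V, S = cell_model.initial_state(1)
        nsteps = int(round(50.0 / dt))
        for i in range(nsteps):
            t = i * dt
            stim = amp if t < duration else 0.0
            V, S = cell_model.step(V, S, dt, stim)
            if V[0] > 0.0:
                return True
        return False

    lo, hi = 0.0, 8.0
    while not fires(hi):
        hi *= 2.0
        if hi > 4096:
            raise RuntimeError("no stimulus amplitude elicits an action potential")
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    _THRESHOLD_CACHE[key] = hi
    return hi


def run_monodomain(
    geom: TissueGeometry,
    params: TissueParams,
    protocol: StimulusProtocol,
    cell_model: str | CellModel = "nygren",
    seed: int = 0,
    progress: bool = False,
) -> VmRecord:
    """Solve the monodomain equation; returns the saved Vm movie.

    Stimulus amplitudes are in uA/cm^2 (converted to dVm/dt through Cm);
    events with ``amplitude=None`` use twice the single-cell diastolic
    threshold of the membrane model.  Raises RuntimeError with a diagnostic
    if the solution becomes non-finite.
    """
    model = get_model(cell_model) if isinstance(cell_model, str) else cell_model
    n = geom.n_nodes
    M, K, _, _ = assemble_operators(geom.nodes, geom.elements)
    D = params.diffusivity  # cm^2/ms
    A = sp.diags(M) + params.dt * D * K
    solve = spla.factorized(A.tocsc())

    default_amp = None
    stim_events = []
    for ev in protocol.events:
        amp = ev.amplitude
        if amp is None:
            if default_amp is None:
                default_amp = 2.0 * diastolic_threshold(model, duration=ev.duration, dt=params.dt)
            amp = default_amp
        stim_events.append((ev.onset, ev.onset + ev.duration, amp, ev.resolve_nodes(geom)))

    V, S = model.initial_state(n)
    nsteps = int(round(params.duration / params.dt))
    save_every = int(round(params.save_interval / params.dt))
    n_saves = nsteps // save_every + 1
    vm = np.empty((n, n_saves), dtype=np.float32)
    times = np.empty(n_saves)
    vm[:, 0] = V
    times[0] = 0.0
    isave = 1

    stim_buf = np.zeros(n)
    for step in range(1, nsteps + 1):
        t = (step - 1) * params.dt
        stim_buf[:] = 0.0
        for onset, offset, amp, nodes in stim_events:
            if onset - 1e-9 <= t < offset - 1e-9:
                stim_buf[nodes] += amp / params.Cm  # mV/ms
        V, S = model.step(V, S, params.dt, stim_buf)
        V = solve(M * V)
        if step % save_every == 0:
            if not np.all(np.isfinite(V)):
                bad = int(np.argmax(~np.isfinite(V)))
                raise RuntimeError(
                    f"monodomain solve diverged at t={step * params.dt:.1f} ms (node {bad})"
                )
            vm[:, isave] = V
            times[isave] = step * params.dt
            isave += 1
    return VmRecord(times=times[:isave], vm=vm[:, :isave], geometry=geom,
                    protocol=protocol, cell_model=model.name, params=params)


def measure_cv(record: VmRecord, site_a: int, site_b: int,
               alpha: float = 0.2, beta: float = 100.0) -> float:
    """Plane-wave conduction velocity (cm/s) between two nodes.

    Uses the Vm activation-time detector (maximum-derivative with threshold
    ``alpha`` and refractory window ``beta``); each site must activate
    exactly once and site_b after site_a.
    """
    from .activation import DetectorParams, detect_activations

    if site_a == site_b:
        raise ValueError("sites must be distinct")
    dp = DetectorParams(alpha=alpha, beta=beta, polarity="positive")
    dt_samp = record.sample_interval
    acts_a = detect_activations(record.trace(site_a), dp, sample_interval=dt_samp)
    acts_b = detect_activations(record.trace(site_b), dp, sample_interval=dt_samp)
    if len(acts_a) != 1 or len(acts_b) != 1:
        raise ValueError(
            f"each site must activate exactly once (got {len(acts_a)} and {len(acts_b)})"
        )
    dt_ms = acts_b[0] - acts_a[0]
    if dt_ms <= 0:
        raise ValueError("activation order ambiguous (non-positive time difference)")
    dist = float(np.linalg.norm(record.geometry.nodes[site_b] - record.geometry.nodes[site_a]))
    return dist / dt_ms * 1e3
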