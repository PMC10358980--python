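"""AcT detection, phase mapping, PS detection, source clustering."""

from types import SimpleNamespace

import numpy as np
import pytest

from mapeval.activation import (
    DetectorParams,
    PhaseRecord,
    cluster_reentry_sources,
    compute_phase,
    detect_activations,
    detect_activation_map,
    detect_surface_ps,
    ps_density,
    surface_rings,
)
from mapeval.geometry import build_sheet_geometry, build_shell_geometry


def _two_step_signal():
    """Two identical 50 mV/ms upstrokes at t = 100 and t = 150 ms."""
    x = np.zeros(300)
    x[101:] += 50.0
    x[151:] += 50.0
    return x


def _reference_detector(signal, alpha, beta, polarity="positive"):
    """Brute-force scan oracle: independent episode/greedy implementation."""
    deriv = np.diff(np.asarray(signal, float))
    if polarity == "negative":
        deriv = -deriv
    episodes = []
    current = []
    for i, d in enumerate(deriv):
        if d > alpha:
            current.append(i)
        elif current:
            episodes.append(current)
            current = []
    if current:
        episodes.append(current)
    cands = []
    for ep in episodes:
        vals = deriv[ep]
        cands.append(float(ep[int(np.argmax(vals))]))
    out = []
    for t in cands:
        if not out or t - out[-1] >= beta:
            out.append(t)
    return np.asarray(out)


class TestDetector:
    def test_constant_trace(self):
        assert len(detect_activations(np.full(100, -80.0))) == 0

    def test_refractory_keeps_first(self):
        acts = detect_activations(_two_step_signal(),
                                  DetectorParams(alpha=0.2, beta=100.0))
        assert np.array_equal(acts, [100.0])

    def test_short_refractory_keeps_both(self):
        acts = detect_activations(_two_step_signal(),
                                  DetectorParams(alpha=0.2, beta=25.0))
        assert np.array_equal(acts, [100.0, 150.0])

    def test_negative_polarity_mirrors(self):
        x = _two_step_signal()
        pos = detect_activations(x, DetectorParams(alpha=0.2, beta=25.0))
        neg = detect_activations(-x, DetectorParams(alpha=0.2, beta=25.0,
                                                    polarity="negative"))
        assert np.array_equal(pos, neg)

    def test_idempotence_and_grid_resolution(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.normal(0, 0.4, size=500))
        p = DetectorParams(alpha=0.5, beta=30.0)
        a1 = detect_activations(x, p)
        a2 = detect_activations(x, p)
        assert np.array_equal(a1, a2)
        assert np.allclose(a1 % 1.0, 0.0)

    def test_matches_reference_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            x = np.cumsum(rng.normal(0, 0.5, size=400))
            for alpha, beta in ((0.3, 20.0), (0.8, 50.0)):
                ours = detect_activations(x, DetectorParams(alpha=alpha, beta=beta))
                ref = _reference_detector(x, alpha, beta)
                assert np.array_equal(ours, ref)

    def test_refractory_separation_property(self):
        rng = np.random.default_rng(1)
        x = np.cumsum(rng.normal(0, 0.6, size=600))
        p = DetectorParams(alpha=0.4, beta=40.0)
        acts = detect_activations(x, p)
        if len(acts) > 1:
            assert np.all(np.diff(acts) >= p.beta)
        deriv = np.diff(x)
        for t in acts:
            assert deriv[int(t)] > p.alpha

    def test_sample_interval_and_offset(self):
        x = _two_step_signal()
        acts = detect_activations(x, DetectorParams(alpha=0.2, beta=10.0),
                                  sample_interval=0.5, t0=1000.0)
        assert np.array_equal(acts, [1050.0, 1075.0])

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_activations(np.zeros(2))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            DetectorParams(alpha=0.0)
        with pytest.raises(ValueError):
            DetectorParams(beta=-1.0)
        with pytest.raises(ValueError):
            DetectorParams(polarity="both")

    def test_map_keys(self):
        sigs = np.vstack([_two_step_signal(), np.zeros(300)])
        amap = detect_activation_map(sigs, ["a", "b"],
                                     DetectorParams(alpha=0.2, beta=25.0))
        assert set(amap.sites()) == {"a", "b"}
        assert amap.total_count() == 2

    def test_sensitivity_identity_on_atrial_traces(self, nygren_sheet_record):
        # seven spread sites: AcT lists identical across alpha and beta choices
        rec = nygren_sheet_record
        nodes = [820, 1640, 2460, 3280, 4100, 4920, 5740]
        baseline = {n: detect_activations(rec.trace(n),
                                          DetectorParams(alpha=0.2, beta=100.0))
                    for n in nodes}
        for alpha in (0.1, 0.2, 0.3):
            for beta in (100.0, 150.0):
                for n in nodes:
                    acts = detect_activations(
                        rec.trace(n), DetectorParams(alpha=alpha, beta=beta))
                    assert np.array_equal(acts, baseline[n])


class TestPhase:
    def _record(self, vm, dt=1.0):
        vm = np.atleast_2d(vm)
        times = np.arange(vm.shape[1]) * dt
        return SimpleNamespace(vm=vm, times=times)

    def test_degenerate_constant(self):
        ph = compute_phase(self._record(np.full(100, -30.0)))
        assert np.all(np.isnan(ph.theta))

    def test_boundary_undefined(self):
        ph = compute_phase(self._record(np.zeros(50)))
        assert np.all(np.isnan(ph.theta[:, :2]))
        assert np.all(np.isnan(ph.theta[:, -2:]))
        assert not np.any(np.isnan(ph.theta[:, 2:-2]))

    def test_sinusoid_winds_once_per_cycle(self):
        # period 16 ms puts the +-2 ms delay embedding in quadrature, so the
        # state-space trajectory is a circle winding 2*pi per cycle
        period = 16.0
        t = np.arange(0, 600.0)
        vm = -30.0 + 50.0 * np.sin(2 * np.pi * t / period)
        ph = compute_phase(self._record(vm))
        th = ph.theta[0, 2:-2]
        d = np.diff(th)
        d = -((-d + np.pi) % (2 * np.pi) - np.pi)
        total = d.sum()
        assert abs(total) == pytest.approx(2 * np.pi * (len(th) - 1) / period,
                                           rel=1e-6)

    def test_too_short_record(self):
        with pytest.raises(ValueError):
            compute_phase(self._record(np.zeros(4)))


def _phase_record_from_theta(geom, theta_nodes):
    theta = np.repeat(theta_nodes[:, None], 5, axis=1)
    return PhaseRecord(theta=theta, times=np.arange(5.0))


class TestSurfacePS:
    def test_planar_ramp_no_ps(self):
        g = build_sheet_geometry(21, 21, 0.1)
        th = np.angle(np.exp(1j * 4.0 * g.nodes[:, 0]))
        ph = _phase_record_from_theta(g, th)
        assert detect_surface_ps(ph, g, 2.0) == []

    def test_single_rotor_charge_plus_one(self):
        g = build_sheet_geometry(21, 21, 0.1)
        x0, y0 = 1.03, 0.97
        th = np.arctan2(g.nodes[:, 1] - y0, g.nodes[:, 0] - x0)
        ph = _phase_record_from_theta(g, th)
        ps = detect_surface_ps(ph, g, 2.0)
        assert len(ps) == 1
        node, charge = ps[0]
        assert charge == 1
        assert np.linalg.norm(g.nodes[node][:2] - [x0, y0]) < 0.15

    def test_two_rotor_field_net_zero(self):
        g = build_sheet_geometry(41, 21, 0.1)
        x, y = g.nodes[:, 0], g.nodes[:, 1]
        th = np.angle(np.exp(1j * (np.arctan2(y - 1.0, x - 1.0)
                                   - np.arctan2(y - 1.0, x - 3.0))))
        ph = _phase_record_from_theta(g, th)
        ps = detect_surface_ps(ph, g, 2.0)
        assert len(ps) == 2
        charges = sorted(c for _, c in ps)
        assert charges == [-1, 1]

    def test_closed_shell_net_charge_zero(self):
        g = build_shell_geometry(1.0, 3)
        th = np.arctan2(g.nodes[:, 1], g.nodes[:, 0])
        ph = _phase_record_from_theta(g, th)
        ps = detect_surface_ps(ph, g, 2.0)
        assert len(ps) >= 2
        assert sum(c for _, c in ps) == 0

    def test_time_outside_record_rejected(self):
        g = build_sheet_geometry(5, 5, 0.1)
        ph = _phase_record_from_theta(g, np.zeros(g.n_nodes))
        with pytest.raises(ValueError):
            detect_surface_ps(ph, g, 50.0)

    def test_rings_are_ccw_from_outside(self):
        g = build_sheet_geometry(9, 9, 0.1)
        rings = surface_rings(g)
        # interior nodes of the triangulated grid have 6-neighbour rings
        center = 4 * 9 + 4
        ring = rings[center]
        assert len(ring) == 6
        pts = g.nodes[ring][:, :2] - g.nodes[center][:2]
        area = 0.5 * np.sum(pts[:, 0] * np.roll(pts[:, 1], -1)
                            - np.roll(pts[:, 0], -1) * pts[:, 1])
        assert area > 0  # counter-clockwise seen from +z
        # border nodes have open fans and are omitted
        assert 0 not in rings


class TestPSDensity:
    def test_pinned_ps_counts(self):
        frames = [(1000.0 + k, [(7, 1)]) for k in range(1000)]
        counts, occ = ps_density(frames, 20, window=(1000.0, 2000.0))
        assert counts[7] == 1000
        assert counts.sum() == 1000
        assert len(occ) == 1000

    def test_empty_series(self):
        counts, occ = ps_density([], 10)
        assert counts.sum() == 0 and occ == []

    def test_conservation(self):
        rng = np.random.default_rng(3)
        frames = []
        total = 0
        for k in range(200):
            n_ps = rng.integers(0, 3)
            frame = [(int(rng.integers(0, 50)), int(rng.choice([-1, 1])))
                     for _ in range(n_ps)]
            total += n_ps
            frames.append((1000.0 + k, frame))
        counts, occ = ps_density(frames, 50, window=(1000.0, 1300.0))
        assert counts.sum() == total == len(occ)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            ps_density([], 10, window=(2000.0, 1000.0))


class TestClusterSources:
    def _geom(self):
        return build_sheet_geometry(41, 41, 0.1)

    def test_exact_centres(self):
        g = self._geom()
        # occurrences at two tight node groups with opposite charges
        left = [0, 1, 41]          # around (0, 0)
        right = [40, 39, 81]       # around (4, 0)
        charges = [(n, -1) for n in left] * 10 + [(n, 1) for n in right] * 10
        density = np.zeros(g.n_nodes)
        for n, _ in charges:
            density[n] += 1
        rp, rm = cluster_reentry_sources(density, g, charges, seed=0)
        assert np.allclose(rp.location, g.nodes[left].mean(axis=0))
        assert np.allclose(rm.location, g.nodes[right].mean(axis=0))
        assert rp.chirality == "R+" and rm.chirality == "R-"

    def test_chirality_convention(self):
        # the negative-charge cluster is reported as R+ (clockwise), the
        # positive-charge cluster as R- (counterclockwise)
        g = self._geom()
        rp, rm = cluster_reentry_sources(
            *self._two_cluster_inputs(g, jitter=0.0), seed=0)
        assert rp.chirality == "R+" and rm.chirality == "R-"

    def _two_cluster_inputs(self, g, jitter=0.05, n_each=100, seed=7):
        rng = np.random.default_rng(seed)
        charges = []
        density = np.zeros(g.n_nodes)
        for cx, cy, ch in ((1.0, 2.0, -1), (3.0, 2.0, 1)):
            for _ in range(n_each):
                p = np.array([[cx + rng.normal(0, jitter),
                               cy + rng.normal(0, jitter), 0.0]])
                node, _ = g.nearest_surface_nodes(p)
                charges.append((int(node[0]), ch))
                density[int(node[0])] += 1
        return density, g, charges

    def test_jittered_recovery(self):
        g = self._geom()
        jitter = 0.05
        density, _, charges = self._two_cluster_inputs(g, jitter=jitter)
        rp, rm = cluster_reentry_sources(density, g, charges, seed=0)
        assert np.linalg.norm(rp.location[:2] - [1.0, 2.0]) < 2 * jitter
        assert np.linalg.norm(rm.location[:2] - [3.0, 2.0]) < 2 * jitter
        assert rp.support + rm.support == 200

    def test_degenerate_rejected(self):
        g = self._geom()
        density = np.zeros(g.n_nodes)
        density[5] = 10
        with pytest.raises(ValueError):
            cluster_reentry_sources(density, g, [(5, 1)] * 10)

    def test_too_few_occupied_nodes(self):
        g = self._geom()
        with pytest.raises(ValueError):
            cluster_reentry_sources(np.zeros(g.n_nodes), g, [])
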