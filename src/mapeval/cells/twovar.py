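"""Two-variable phenomenological excitable model (Aliev-Panfilov form).

A fast reaction kinetics used for tissue-scale fixtures where only the
wave dynamics matter (rotor induction, long reentry runs), not ionic
detail.  The dimensionless excitation variable u is mapped linearly to a
transmembrane potential, and the dimensionless time unit is scaled to
milliseconds so action-potential duration and rotor cycle length land in
a physiological range.
"""

from __future__ import annotations

import numpy as np

from .base import CellModel


class TwoVariableModel(CellModel):
    name = "twovar"
    n_states = 1  # the recovery variable v
    gate_slice = slice(0, 0)

    def __init__(
        self,
        k: float = 8.0,
        a: float = 0.1,
        eps0: float = 0.002,
        mu1: float = 0.2,
        mu2: float = 0.3,
        time_scale: float = 12.9,  # ms per dimensionless time unit
        v_rest_mV: float = -80.0,
        amplitude_mV: float = 100.0,
    ):
        self.k = k
        self.a = a
        self.eps0 = eps0
        self.mu1 = mu1
        self.mu2 = mu2
        self.time_scale = time_scale
        self.v_rest = v_rest_mV
        self.amplitude = amplitude_mV

    def initial_state(self, n_nodes: int):
        V = np.full(n_nodes, self.v_rest)
        S = np.zeros((n_nodes, 1))
        return V, S

    def step(self, V, S, dt_ms, i_stim=0.0):
        u = (np.asarray(V, dtype=float) - self.v_rest) / self.amplitude
        v = np.array(S[:, 0], dtype=float, copy=True)
        h = dt_ms / self.time_scale
        stim_u = np.asarray(i_stim, dtype=float) * dt_ms / self.amplitude
        k, a = self.k, self.a
        eps = self.eps0 + self.mu1 * v / (u + self.mu2)
        du = -k * u * (u - a) * (u - 1.0) - u * v
        dv = eps * (-v - k * u * (u - a - 1.0))
        u = u + h * du + stim_u
        v = v + h * dv
        u = np.clip(u, -0.05, 1.5)
        return self.v_rest + self.amplitude * u, v[:, None]
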