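"""Nygren et al. (1998) adult human atrial cell model.

Implemented from the published equations: sustained-outward/transient-outward
formulation, L-type Ca current with Ca-dependent inactivation switching,
Na/K pump, Na/Ca exchanger, sarcolemmal Ca pump, restricted subsarcolemmal
(diadic) space, cleft-space ion accumulation, intracellular Ca buffering
(calmodulin, troponin, troponin-Mg) and a two-compartment SR with
calsequestrin buffering.

Units follow the original formulation: time constants in seconds,
potentials in mV, concentrations in mM, currents in pA, volumes in nL.
The 12 gating variables are advanced with the Rush-Larsen exponential
update; concentrations, buffers and SR release states with forward Euler
(two internal substeps per call, which keeps the fast diadic-space calcium
dynamics stable at the 0.1 ms tissue step).
"""

from __future__ import annotations

import numpy as np

from .base import CellModel

# Physical constants
R = 8314.0       # mJ mol^-1 K^-1
T = 306.15       # K
F = 96487.0      # C mol^-1

# Membrane
CM = 0.05        # nF

# Maximum conductances / permeabilities
P_NA = 0.0016        # nL s^-1
G_CAL = 6.75         # nS
E_CA_APP = 60.0      # mV
K_CA = 0.025         # mM
G_T = 7.5            # nS
G_SUS = 2.75         # nS
G_KS = 1.0           # nS
G_KR = 0.5           # nS
G_K1 = 3.0           # nS
G_B_NA = 0.060599    # nS
G_B_CA = 0.078681    # nS

# Pumps / exchangers
I_NAK_MAX = 70.8253  # pA
K_NAK_K = 1.0        # mM
K_NAK_NA = 11.0      # mM
I_CAP_MAX = 4.0      # pA
K_CAP = 0.0002       # mM
K_NACA = 0.0374842   # pA mM^-4
GAMMA = 0.45
D_NACA = 0.0003      # mM^-4
PHI_NA_EN = -1.68    # pA (electroneutral Na influx)

# Compartment volumes (nL) and cleft time constants (s)
VOL_I = 0.005884
VOL_C = 0.136 * VOL_I
VOL_D = 0.02 * VOL_I
TAU_DI = 0.01
TAU_NA = 14.3
TAU_K = 10.0
TAU_CA = 24.7
NA_B = 130.0
K_B = 5.4
CA_B = 1.8
MG_I = 2.5

# SR
VOL_UP = 0.0003969
VOL_REL = 0.0000441
I_UP_MAX = 2800.0    # pA
K_CYCA = 0.0003
K_SRCA = 0.5
K_XCS = 0.4
TAU_TR = 0.01
ALPHA_REL = 200000.0  # pA mM^-1
K_REL_I = 0.0003
K_REL_D = 0.003
R_RECOV = 0.815

# State layout: 12 gates first (Rush-Larsen), then concentrations/buffers/SR.
GATES = ["m", "h1", "h2", "dL", "fL1", "fL2", "r", "s", "rsus", "ssus", "n", "pa"]
OTHERS = [
    "Na_c", "K_c", "Ca_c", "Na_i", "K_i", "Ca_i", "Ca_d",
    "O_C", "O_TC", "O_TMgC", "O_TMgMg", "F1", "F2",
    "Ca_up", "Ca_rel", "O_Calse",
]
STATE_NAMES = GATES + OTHERS

_Y0 = {
    "m": 3.2017e-3, "h1": 0.8814, "h2": 0.8742,
    "dL": 1.3005e-5, "fL1": 0.9986, "fL2": 0.9986,
    "r": 1.0678e-3, "s": 0.949,
    "rsus": 1.5949e-4, "ssus": 0.9912,
    "n": 4.8357e-3, "pa": 0.0001,
    "Na_c": 130.011, "K_c": 5.3581, "Ca_c": 1.8147,
    "Na_i": 8.5547, "K_i": 129.435, "Ca_i": 6.729e-5, "Ca_d": 7.2495e-5,
    "O_C": 0.0275, "O_TC": 0.0133, "O_TMgC": 0.1961, "O_TMgMg": 0.7094,
    "F1": 0.4284, "F2": 0.0028,
    "Ca_up": 0.6646, "Ca_rel": 0.6465, "O_Calse": 0.4369,
}
_V0 = -74.2525


def _gate_rates(V: np.ndarray):
    """Steady states and time constants (s) of the 12 gates."""
    inf = {}
    tau = {}
    inf["m"] = 1.0 / (1.0 + np.exp(-(V + 27.12) / 8.21))
    tau["m"] = 4.2e-5 * np.exp(-(((V + 25.57) / 28.8) ** 2)) + 2.4e-5
    h_inf = 1.0 / (1.0 + np.exp((V + 63.6) / 5.3))
    inf["h1"] = h_inf
    inf["h2"] = h_inf
    tau["h1"] = 0.03 / (1.0 + np.exp((V + 35.1) / 3.2)) + 0.0003
    tau["h2"] = 0.12 / (1.0 + np.exp((V + 35.1) / 3.2)) + 0.003
    inf["dL"] = 1.0 / (1.0 + np.exp(-(V + 9.0) / 5.8))
    tau["dL"] = 0.0027 * np.exp(-(((V + 35.0) / 30.0) ** 2)) + 0.002
    f_inf = 1.0 / (1.0 + np.exp((V + 27.4) / 7.1))
    inf["fL1"] = f_inf
    inf["fL2"] = f_inf
    tau["fL1"] = 0.161 * np.exp(-(((V + 40.0) / 14.4) ** 2)) + 0.01
    tau["fL2"] = 1.3323 * np.exp(-(((V + 40.0) / 14.2) ** 2)) + 0.0626
    inf["r"] = 1.0 / (1.0 + np.exp(-(V - 1.0) / 11.0))
    tau["r"] = 0.0035 * np.exp(-((V / 30.0) ** 2)) + 0.0015
    inf["s"] = 1.0 / (1.0 + np.exp((V + 40.5) / 11.5))
    tau["s"] = 0.4812 * np.exp(-(((V + 52.45) / 14.97) ** 2)) + 0.01414
    inf["rsus"] = 1.0 / (1.0 + np.exp(-(V + 4.3) / 8.0))
    tau["rsus"] = 0.009 / (1.0 + np.exp((V + 5.0) / 12.0)) + 0.0005
    inf["ssus"] = 0.4 / (1.0 + np.exp((V + 20.0) / 10.0)) + 0.6
    tau["ssus"] = 0.047 / (1.0 + np.exp((V + 60.0) / 10.0)) + 0.3
    inf["n"] = 1.0 / (1.0 + np.exp(-(V - 19.9) / 12.7))
    tau["n"] = 0.7 + 0.4 * np.exp(-(((V - 20.0) / 20.0) ** 2))
    inf["pa"] = 1.0 / (1.0 + np.exp(-(V + 15.0) / 6.0))
    tau["pa"] = 0.03118 + 0.21718 * np.exp(-(((V + 20.1376) / 22.1996) ** 2))
    return inf, tau


class NygrenModel(CellModel):
    name = "nygren"
    n_states = len(STATE_NAMES)
    v_rest = _V0
    gate_slice = slice(0, len(GATES))

    def __init__(self, substeps: int = 2):
        self.substeps = int(substeps)
        self._idx = {nm: i for i, nm in enumerate(STATE_NAMES)}

    def initial_state(self, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
        V = np.full(n_nodes, _V0)
        S = np.empty((n_nodes, self.n_states))
        for nm, i in self._idx.items():
            S[:, i] = _Y0[nm]
        return V, S

    # -- currents -----------------------------------------------------------
    def currents(self, V: np.ndarray, S: np.ndarray) -> dict[str, np.ndarray]:
        ix = self._idx
        g = {nm: S[:, ix[nm]] for nm in STATE_NAMES}
        FRT = F / (R * T)
        E_Na = (1.0 / FRT) * np.log(g["Na_c"] / g["Na_i"])
        E_K = (1.0 / FRT) * np.log(g["K_c"] / g["K_i"])
        E_Ca = (0.5 / FRT) * np.log(g["Ca_c"] / g["Ca_i"])

        # GHK-type Na current; remove the V=0 singularity with a Taylor limit
        vf = V * FRT
        expv = np.exp(vf)
        denom = np.where(np.abs(vf) < 1e-6, 1.0, expv - 1.0)
        ghk = np.where(
            np.abs(vf) < 1e-6,
            (np.exp(-E_Na * FRT) - 1.0) / FRT,  # limit as V -> 0
            V * (np.exp((V - E_Na) * FRT) - 1.0) / denom,
        )
        i_Na = P_NA * g["m"] ** 3 * (0.9 * g["h1"] + 0.1 * g["h2"]) * g["Na_c"] * FRT * F * ghk

        f_Ca = g["Ca_d"] / (g["Ca_d"] + K_CA)
        i_CaL = G_CAL * g["dL"] * (f_Ca * g["fL1"] + (1.0 - f_Ca) * g["fL2"]) * (V - E_CA_APP)

        i_t = G_T * g["r"] * g["s"] * (V - E_K)
        i_sus = G_SUS * g["rsus"] * g["ssus"] * (V - E_K)
        i_Ks = G_KS * g["n"] * (V - E_K)
        p_i = 1.0 / (1.0 + np.exp((V + 55.0) / 24.0))
        i_Kr = G_KR * g["pa"] * p_i * (V - E_K)
        i_K1 = (
            G_K1
            * g["K_c"] ** 0.4457
            * (V - E_K)
            / (1.0 + np.exp(1.5 * (V - E_K + 3.6) * FRT))
        )
        i_B_Na = G_B_NA * (V - E_Na)
        i_B_Ca = G_B_CA * (V - E_Ca)
        i_NaK = (
            I_NAK_MAX
            * g["K_c"] / (g["K_c"] + K_NAK_K)
            * g["Na_i"] ** 1.5 / (g["Na_i"] ** 1.5 + K_NAK_NA ** 1.5)
            * (V + 150.0) / (V + 200.0)
        )
        i_CaP = I_CAP_MAX * g["Ca_i"] / (g["Ca_i"] + K_CAP)
        vf_g = GAMMA * vf
        i_NaCa = (
            K_NACA
            * (
                g["Na_i"] ** 3 * g["Ca_c"] * np.exp(vf_g)
                - g["Na_c"] ** 3 * g["Ca_i"] * np.exp((GAMMA - 1.0) * vf)
            )
            / (1.0 + D_NACA * (g["Na_c"] ** 3 * g["Ca_i"] + g["Na_i"] ** 3 * g["Ca_c"]))
        )
        return {
            "i_Na": i_Na, "i_CaL": i_CaL, "i_t": i_t, "i_sus": i_sus,
            "i_K1": i_K1, "i_Kr": i_Kr, "i_Ks": i_Ks,
            "i_B_Na": i_B_Na, "i_B_Ca": i_B_Ca,
            "i_NaK": i_NaK, "i_CaP": i_CaP, "i_NaCa": i_NaCa,
        }

    # -- integration --------------------------------------------------------
    def step(self, V, S, dt_ms, i_stim=0.0):
        h = (dt_ms / self.substeps) * 1e-3  # s
        ix = self._idx
        V = np.array(V, dtype=float, copy=True)
        S = np.array(S, dtype=float, copy=True)
        stim_mV_s = np.asarray(i_stim, dtype=float) * 1e3  # mV/ms -> mV/s
        for _ in range(self.substeps):
            cur = self.currents(V, S)
            i_tot = sum(cur.values())

            # Rush-Larsen gates
            inf, tau = _gate_rates(V)
            for nm in GATES:
                i = ix[nm]
                S[:, i] = inf[nm] + (S[:, i] - inf[nm]) * np.exp(-h / tau[nm])

            c = {nm: S[:, ix[nm]] for nm in OTHERS}
            i_di = (c["Ca_d"] - c["Ca_i"]) * 2.0 * F * VOL_D / TAU_DI
            i_up = I_UP_MAX * (
                c["Ca_i"] / K_CYCA - K_XCS ** 2 * c["Ca_up"] / K_SRCA
            ) / ((c["Ca_i"] + K_CYCA) / K_CYCA + K_XCS * (c["Ca_up"] + K_SRCA) / K_SRCA)
            i_tr = (c["Ca_up"] - c["Ca_rel"]) * 2.0 * F * VOL_REL / TAU_TR
            i_rel = ALPHA_REL * (c["F2"] / (c["F2"] + 0.25)) ** 2 * (c["Ca_rel"] - c["Ca_i"])
            r_i4 = (c["Ca_i"] / (c["Ca_i"] + K_REL_I)) ** 4
            r_d4 = (c["Ca_d"] / (c["Ca_d"] + K_REL_D)) ** 4
            r_act = 203.8 * (r_i4 + r_d4)
            r_inact = 33.96 + 339.6 * r_i4

            dOC = 200000.0 * c["Ca_i"] * (1.0 - c["O_C"]) - 476.0 * c["O_C"]
            dOTC = 78400.0 * c["Ca_i"] * (1.0 - c["O_TC"]) - 392.0 * c["O_TC"]
            dOTMgC = 200000.0 * c["Ca_i"] * (1.0 - c["O_TMgC"] - c["O_TMgMg"]) - 6.6 * c["O_TMgC"]
            dOTMgMg = 2000.0 * MG_I * (1.0 - c["O_TMgC"] - c["O_TMgMg"]) - 666.0 * c["O_TMgMg"]
            dOCalse = 480.0 * c["Ca_rel"] * (1.0 - c["O_Calse"]) - 400.0 * c["O_Calse"]

            na_flux = cur["i_Na"] + cur["i_B_Na"] + 3.0 * cur["i_NaK"] + 3.0 * cur["i_NaCa"] + PHI_NA_EN
            k_flux = cur["i_t"] + cur["i_sus"] + cur["i_K1"] + cur["i_Kr"] + cur["i_Ks"] - 2.0 * cur["i_NaK"]
            ca_mem = cur["i_CaL"] + cur["i_B_Ca"] + cur["i_CaP"] - 2.0 * cur["i_NaCa"]

            d = {}
            d["Na_c"] = (NA_B - c["Na_c"]) / TAU_NA + na_flux / (VOL_C * F)
            d["K_c"] = (K_B - c["K_c"]) / TAU_K + k_flux / (VOL_C * F)
            d["Ca_c"] = (CA_B - c["Ca_c"]) / TAU_CA + ca_mem / (2.0 * VOL_C * F)
            d["Na_i"] = -na_flux / (VOL_I * F)
            d["K_i"] = -k_flux / (VOL_I * F)
            d["Ca_i"] = -(
                -i_di + cur["i_B_Ca"] + cur["i_CaP"] - 2.0 * cur["i_NaCa"] + i_up - i_rel
            ) / (2.0 * VOL_I * F) - (0.045 * dOC + 0.08 * dOTC + 0.16 * dOTMgC)
            d["Ca_d"] = -(cur["i_CaL"] + i_di) / (2.0 * VOL_D * F)
            d["O_C"] = dOC
            d["O_TC"] = dOTC
            d["O_TMgC"] = dOTMgC
            d["O_TMgMg"] = dOTMgMg
            d["F1"] = R_RECOV * (1.0 - c["F1"] - c["F2"]) - r_act * c["F1"]
            d["F2"] = r_act * c["F1"] - r_inact * c["F2"]
            d["Ca_up"] = (i_up - i_tr) / (2.0 * VOL_UP * F)
            d["Ca_rel"] = (i_tr - i_rel) / (2.0 * VOL_REL * F) - 31.0 * dOCalse
            d["O_Calse"] = dOCalse

            for nm in OTHERS:
                S[:, ix[nm]] += h * d[nm]
            V = V + h * (-i_tot / CM + stim_mV_s)
        return V, S
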