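"""Cell-model interface and registry."""

from __future__ import annotations

import numpy as np

_REGISTRY: dict[str, type] = {}


class CellModel:
    """Reaction part of the monodomain equation for one membrane model.

    Subclasses advance the transmembrane potential Vm (mV) and their own
    state vector over a time step, given an externally imposed rate
    ``i_stim`` in mV/ms (stimulus current divided by membrane capacitance).
    All methods are vectorised over nodes.
    """

    name: str = "abstract"
    n_states: int = 0
    v_rest: float = float("nan")

    # Bounds used by state-sanity checks: gate variables live in [0, 1].
    gate_slice: slice = slice(0, 0)

    def initial_state(self, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (V, S): resting Vm (n,) and state array (n, n_states)."""
        raise NotImplementedError

    def step(
        self, V: np.ndarray, S: np.ndarray, dt_ms: float, i_stim: np.ndarray | float = 0.0
    ) -> tuple[np.ndarray, np.ndarray]:
        """Advance reaction terms by ``dt_ms``; returns new (V, S)."""
        raise NotImplementedError


def register_model(name: str, cls: type) -> None:
    _REGISTRY[name] = cls


def get_model(name: str, **kwargs) -> CellModel:
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown cell model {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    return cls(**kwargs)
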