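"""Frozen desk-scale simulation fixtures for the evaluation library.

Stands in for the large anatomical-chamber simulations: a 4 cm x 4 cm
triangulated sheet carries (a) a figure-of-eight reentry induced by an
S1-S2 cross-gradient protocol and (b) a focal-replication run that paces
the measured R+ and R- source locations with the measured reentrant beat
trains.  Together the two entries reproduce the evaluation design of one
paced beat, six reentrant beats per chirality and six focal beats per
source (25 ground-truth events).

The reentry entry uses the registered two-variable phenomenological
membrane model with its time scale set so that the action-potential
duration (~240 ms) and the resulting rotor cycle length (~160 ms) land in
the human atrial range; at sigma = 0.8 mS/cm the S2 delay of 350 ms sits
inside the vulnerable window and the two counter-rotating waves persist
beyond 2 s.  These values were fixed once during fixture design and are
exercised, not fitted, by the test suite.
"""

from __future__ import annotations

import numpy as np

from .workflow import Library, LibraryEntry, build_entry, save_entry

__all__ = [
    "REENTRY_TIME_SCALE",
    "reentry_entry_config",
    "focal_entry_config",
    "build_standard_library",
]

REENTRY_TIME_SCALE = 6.0       # ms per dimensionless unit of the 2-var model
_SHEET = {"kind": "sheet", "nx": 81, "ny": 81, "spacing": 0.05}
_CELL = {"name": "twovar", "time_scale": REENTRY_TIME_SCALE}
_PARAMS = {"sigma": 0.8, "duration": 2000.0}


def reentry_entry_config(identifier: str = "reentry-f8", seed: int = 1) -> dict:
    """Figure-of-eight entry: S1 edge pacing, S2 disc at delay 350 ms."""
    return {
        "identifier": identifier,
        "activity": "reentry",
        "geometry": dict(_SHEET),
        "protocol": {
            "kind": "s1s2",
            "s1_center": [0.0, 2.0, 0.0], "s1_radius": 0.5,
            "s2_center": [2.0, 1.0, 0.0], "s2_radius": 1.0,
            "s2_delay": 350.0,
        },
        "cell_model": dict(_CELL),
        "params": dict(_PARAMS),
        "analysis_window": [1000.0, 1998.0],
        "seed": seed,
        "metadata": {"chamber": "sheet-4cm", "description": "figure-of-eight reentry"},
    }


def focal_entry_config(
    reentry_entry: LibraryEntry,
    identifier: str = "focal-replication",
    seed: int = 2,
    start: float = 100.0,
    source_radius: float = 0.15,
) -> dict:
    """Focal replication of a reentry entry's sources and beat trains.

    Paces the R+ and R- locations with onset trains whose inter-beat
    intervals equal the measured reentrant cycle lengths, shifted so the
    first beat fires at ``start`` ms.
    """
    sources = []
    for chirality in ("R+", "R-"):
        evs = sorted(
            (ev for ev in reentry_entry.events if ev.type == chirality),
            key=lambda e: e.ref_time,
        )
        if not evs:
            raise ValueError(f"reentry entry has no {chirality} events to replicate")
        times = np.array([ev.ref_time for ev in evs])
        onsets = (times - times[0] + start).tolist()
        center = [float(v) for v in evs[0].location]
        sources.append({"center": center, "radius": source_radius, "onsets": onsets})
    span = max(s["onsets"][-1] for s in sources)
    return {
        "identifier": identifier,
        "activity": "focal",
        "geometry": dict(_SHEET),
        "protocol": {"kind": "focal", "sources": sources},
        "cell_model": dict(_CELL),
        "params": {"sigma": _PARAMS["sigma"], "duration": float(span + 400.0)},
        "seed": seed,
        "metadata": {"chamber": "sheet-4cm", "description": "focal replication of reentry sources"},
    }


def build_standard_library(out_dir=None, seed: int = 1) -> Library:
    """Build the two-entry standard library (reentry + focal replication)."""
    lib = Library()
    reentry = build_entry(reentry_entry_config(seed=seed))
    lib.entries[reentry.identifier] = reentry
    focal = build_entry(focal_entry_config(reentry, seed=seed + 1))
    lib.entries[focal.identifier] = focal
    if out_dir is not None:
        from pathlib import Path

        for entry in lib.entries.values():
            save_entry(entry, Path(out_dir) / entry.identifier)
    return lib
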