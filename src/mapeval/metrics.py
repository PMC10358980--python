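"""Performance metrics: activation-time and activation-pattern agreement.

Compares mapping-system output against the simulation silver standard.
Activation times are matched one-to-one within a tolerance Tol; the AcT
performance metric is

    AcTPM = fC * (1 - fS) * 100

with fC the fraction of silver-standard AcTs matched and fS the fraction
of unmatched (spurious) measured AcTs, both normalised by the number of
silver-standard AcTs at the same site (fS capped at 1).  Activation
patterns are correct when a detection of the identical type lies within
100 ms and 1 cm of the true event; the pattern performance metric is

    AcPPM = fC * (1 - fS) * (1 - fM) * 100

adding fM, the fraction of truth beats matched only by a wrong pattern
type.  Temporal localisation error E_T (paced/focal beats only) and
spatial error E_X (bounded by the 1 cm matching window) summarise the
accuracy of correct detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activation import ActivationMap
from .geometry import ElectrodeArray, TissueGeometry
from .patterns import PatternDetection

__all__ = [
    "PatternEvent",
    "GroundTruth",
    "AcTReport",
    "AcPReport",
    "compare_act",
    "actpm",
    "compare_patterns",
    "acppm",
    "tolerance_sweep",
]

TRUTH_TYPES = ("P", "R+", "R-", "F+", "F-")


@dataclass
class PatternEvent:
    """One ground-truth pattern beat.

    Paced/focal events carry their stimulation time as ``ref_time``;
    reentrant events have no stimulation time, so ``ref_time`` is the
    midpoint of the beat window.
    """

    type: str               # P, R+, R-, F+, F-
    beat: int
    location: np.ndarray    # 3-D cm, surface location
    ref_time: float         # ms

    def __post_init__(self):
        if self.type not in TRUTH_TYPES:
            raise ValueError(f"unknown truth type {self.type!r}")
        self.location = np.asarray(self.location, dtype=float)

    @property
    def detection_type(self) -> str:
        """The classifier type a correct detection must carry."""
        return self.type if self.type in ("R+", "R-") else "F"


@dataclass
class GroundTruth:
    """Silver-standard content for one library entry."""

    events: list[PatternEvent] = field(default_factory=list)
    vm_acts: dict = field(default_factory=dict)      # node -> AcT array (ms)
    surface_points: np.ndarray | None = None


@dataclass
class AcTReport:
    tol: float
    fC: float
    fS: float
    n_correct: int
    n_spurious: int
    n_missed: int
    n_truth: int
    rms: float               # ms, over matched pairs (NaN if none)
    rms_sd: float            # ms, SD across electrodes of per-electrode RMS
    actpm: float
    per_electrode: pd.DataFrame = field(repr=False, default=None)


@dataclass
class AcPReport:
    per_type: pd.DataFrame = field(repr=False, default=None)
    correct: list = field(default_factory=list)
    spurious: list = field(default_factory=list)
    misclassified: list = field(default_factory=list)

    def acppm(self, typ: str) -> float:
        return float(self.per_type.loc[typ, "AcPPM"])


def _match_one_site(measured: np.ndarray, truth: np.ndarray, tol: float):
    """Optimal one-to-one matching of measured to truth AcTs within tol.

    Solves the assignment problem that first maximises the number of
    matched pairs and then minimises the total |difference| (pairs farther
    apart than tol are infeasible).  With refractory-separated AcTs and
    tol below half the minimum inter-AcT spacing this coincides with
    greedy nearest-in-time matching; unlike greedy it is provably monotone
    in tol.  Returns (matched (truth, measured) pairs, unmatched measured).
    """
    from scipy.optimize import linear_sum_assignment

    measured = np.sort(np.asarray(measured, dtype=float))
    truth = np.sort(np.asarray(truth, dtype=float))
    if measured.size == 0 or truth.size == 0:
        return [], list(measured)
    diff = np.abs(measured[None, :] - truth[:, None])      # (n_truth, n_meas)
    feasible = diff <= tol
    # infeasible edges cost far more than any full feasible assignment, so
    # the minimum-cost assignment uses as many feasible edges as possible
    big = (diff[feasible].sum() if feasible.any() else 0.0) + tol + 1.0
    cost = np.where(feasible, diff, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(truth[it], measured[im]) for it, im in zip(rows, cols)
             if feasible[it, im]]
    used_m = {im for it, im in zip(rows, cols) if feasible[it, im]}
    unmatched = [measured[im] for im in range(len(measured)) if im not in used_m]
    return pairs, unmatched


def compare_act(
    egm_acts: ActivationMap,
    truth: GroundTruth,
    mapping: dict,
    tol: float,
) -> AcTReport:
    """Compare electrode AcTs against nearest-node silver-standard AcTs.

    ``mapping`` sends each electrode site key to its nearest surface node.
    fC = matched / total truth AcTs; fS = unmatched measured / total truth
    AcTs, capped at 1; RMS over matched differences; RMS-SD is the standard
    deviation across electrodes of the per-electrode RMS.
    """
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    rows = []
    all_diffs = []
    tot_truth = tot_matched = tot_spurious = 0
    for site in egm_acts.sites():
        node = mapping[site]
        tr = np.asarray(truth.vm_acts[node], dtype=float)
        pairs, unmatched = _match_one_site(egm_acts[site], tr, tol)
        diffs = [mv - tv for tv, mv in pairs]
        all_diffs.extend(diffs)
        n_t = len(tr)
        n_c = len(pairs)
        n_s = len(unmatched)
        fc = n_c / n_t if n_t else 0.0
        fs = min(n_s / n_t, 1.0) if n_t else (1.0 if n_s else 0.0)
        rms = float(np.sqrt(np.mean(np.square(diffs)))) if diffs else np.nan
        rows.append({
            "site": site, "n_truth": n_t, "n_correct": n_c, "n_spurious": n_s,
            "fC": fc, "fS": fs, "rms": rms,
        })
        tot_truth += n_t
        tot_matched += n_c
        tot_spurious += n_s
    per = pd.DataFrame(
        rows, columns=["site", "n_truth", "n_correct", "n_spurious", "fC", "fS", "rms"],
    ).set_index("site")
    fC = tot_matched / tot_truth if tot_truth else 0.0
    fS = min(tot_spurious / tot_truth, 1.0) if tot_truth else (1.0 if tot_spurious else 0.0)
    rms = float(np.sqrt(np.mean(np.square(all_diffs)))) if all_diffs else np.nan
    site_rms = per["rms"].dropna()
    rms_sd = float(site_rms.std(ddof=0)) if len(site_rms) else np.nan
    return AcTReport(
        tol=tol, fC=fC, fS=fS,
        n_correct=tot_matched, n_spurious=tot_spurious,
        n_missed=tot_truth - tot_matched, n_truth=tot_truth,
        rms=rms, rms_sd=rms_sd, actpm=actpm(fC, fS), per_electrode=per,
    )


def actpm(fC: float, fS: float) -> float:
    """AcT performance metric: fC*(1-fS)*100; 100 is perfect."""
    if not (0.0 <= fC <= 1.0 and 0.0 <= fS <= 1.0):
        raise ValueError("fC and fS must lie in [0, 1]")
    return fC * (1.0 - fS) * 100.0


def acppm(fC: float, fS: float, fM: float) -> float:
    """AcP performance metric: fC*(1-fS)*(1-fM)*100."""
    for v in (fC, fS, fM):
        if not (0.0 <= v <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
    return fC * (1.0 - fS) * (1.0 - fM) * 100.0


def compare_patterns(
    detections: list[PatternDetection],
    truth: GroundTruth,
    geom: TissueGeometry,
    array: ElectrodeArray,
    time_window: float = 100.0,
    dist_window: float = 1.0,
) -> AcPReport:
    """Score pattern detections against the ground-truth event list.

    A detection is eligible for a truth beat when its central AcT lies
    within ``time_window`` of the beat's reference time and its electrode
    within ``dist_window`` of the true location.  Each truth event takes at
    most one correct (identical-type) detection, the spatially nearest;
    further same-type eligible detections are duplicates (neither correct
    nor spurious).  An event with only wrong-type eligible detections
    counts one misclassification.  Detections eligible for no event are
    spurious, attributed to their own chirality for R types and to the
    nearest-in-time paced/focal class otherwise.
    """
    pos = {lab: array.positions[i] for i, lab in enumerate(array.labels)}
    consumed: set[int] = set()
    correct: list[tuple[PatternEvent, PatternDetection]] = []
    misclassified: list[tuple[PatternEvent, PatternDetection]] = []

    def eligible(ev: PatternEvent):
        out = []
        for i, det in enumerate(detections):
            if i in consumed:
                continue
            if abs(det.time - ev.ref_time) > time_window:
                continue
            d = float(np.linalg.norm(pos[det.electrode] - ev.location))
            if d > dist_window:
                continue
            out.append((d, i, det))
        out.sort(key=lambda x: (x[0], x[1]))
        return out

    # pass 1: correct matches and duplicates
    for ev in truth.events:
        elig = [e for e in eligible(ev) if e[2].type == ev.detection_type]
        if not elig:
            continue
        _, i0, det0 = elig[0]
        consumed.add(i0)
        correct.append((ev, det0))
        for _, i, _ in elig[1:]:
            consumed.add(i)  # duplicate: neither correct nor spurious

    matched_events = {id(ev) for ev, _ in correct}
    # pass 2: misclassifications
    for ev in truth.events:
        if id(ev) in matched_events:
            continue
        elig = [e for e in eligible(ev) if e[2].type != ev.detection_type]
        if elig:
            _, i0, det0 = elig[0]
            consumed.add(i0)
            misclassified.append((ev, det0))

    spurious = [det for i, det in enumerate(detections) if i not in consumed]

    # per-type bookkeeping
    rows = {}
    for typ in TRUTH_TYPES:
        evs = [ev for ev in truth.events if ev.type == typ]
        n = len(evs)
        n_c = sum(1 for ev, _ in correct if ev.type == typ)
        n_m = sum(1 for ev, _ in misclassified if ev.type == typ)
        rows[typ] = {"n_truth": n, "n_correct": n_c, "n_misclassified": n_m,
                     "n_spurious": 0}

    focal_types = [t for t in ("P", "F+", "F-") if rows[t]["n_truth"]]
    for det in spurious:
        if det.type in ("R+", "R-"):
            typ = det.type
        else:
            # nearest-in-time paced/focal class
            best, typ = np.inf, focal_types[0] if focal_types else "P"
            for t in focal_types:
                for ev in truth.events:
                    if ev.type == t and abs(ev.ref_time - det.time) < best:
                        best, typ = abs(ev.ref_time - det.time), t
        rows[typ]["n_spurious"] += 1

    table = []
    for typ in TRUTH_TYPES:
        r = rows[typ]
        n = r["n_truth"]
        if n == 0:
            fc = fm = 0.0
            fs = min(float(r["n_spurious"]), 1.0)
        else:
            fc = r["n_correct"] / n
            fm = r["n_misclassified"] / n
            fs = min(r["n_spurious"] / n, 1.0)
        e_x = [float(np.linalg.norm(pos[det.electrode] - ev.location))
               for ev, det in correct if ev.type == typ]
        e_t = [abs(det.time - ev.ref_time)
               for ev, det in correct if ev.type == typ and typ != "R+" and typ != "R-"]
        table.append({
            "type": typ, **r, "fC": fc, "fS": fs, "fM": fm,
            "AcPPM": acppm(fc, fs, fm),
            "E_X": float(np.mean(e_x)) if e_x else np.nan,
            "E_T": float(np.mean(e_t)) if e_t else np.nan,
        })
    per_type = pd.DataFrame(table).set_index("type")
    return AcPReport(per_type=per_type, correct=correct, spurious=spurious,
                     misclassified=misclassified)


def tolerance_sweep(
    egm_acts: ActivationMap,
    truth: GroundTruth,
    mapping: dict,
    tol_values,
) -> pd.DataFrame:
    """AcTPM, %S and RMS-SD as a function of the matching tolerance."""
    tol_values = list(tol_values)
    if not tol_values:
        raise ValueError("tol_values must be non-empty")
    if any(t < 0 for t in tol_values):
        raise ValueError("tolerances must be non-negative")
    rows = []
    for tol in tol_values:
        rep = compare_act(egm_acts, truth, mapping, tol)
        rows.append({"tol": tol, "AcTPM": rep.actpm, "pct_spurious": 100.0 * rep.fS,
                     "rms": rep.rms, "rms_sd": rep.rms_sd})
    return pd.DataFrame(rows)
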