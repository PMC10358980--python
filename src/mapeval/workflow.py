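"""Blinded evaluation workflow: library management and session protocol.

An Administrator builds a library of pre-computed simulations.  Each entry
holds four items: the Vm movie, per-node activation times, the list of
paced/focal events, and the reentry source locations.  A blinded session
then runs in a fixed order: the user receives the surface point cloud
(step: export), registers their electrode table (register), declares the
per-electrode noise levels (declare), receives noisy electrograms with no
ground-truth fields (issue), and finally returns activation-time and
pattern predictions which are scored against the silver standard
(evaluate).  Issuing electrograms before electrodes and noise levels are
registered is a protocol-order error.  All randomness derives from one
recorded master seed, so identical configurations reproduce identical
reports.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import io as mio
from .activation import (
    ActivationMap,
    DetectorParams,
    cluster_reentry_sources,
    compute_phase,
    detect_activation_map,
    detect_surface_ps,
    ps_density,
    ReentrySource,
)
from .electrograms import ElectrogramParams, add_noise, compute_electrograms
from .geometry import TissueGeometry, build_sheet_geometry, build_shell_geometry
from .metrics import (
    AcPReport,
    AcTReport,
    GroundTruth,
    PatternEvent,
    compare_act,
    compare_patterns,
    tolerance_sweep,
)
from .patterns import PatternDetection
from .simulator import (
    TissueParams,
    VmRecord,
    protocol_focal,
    protocol_paced,
    protocol_s1s2,
    run_monodomain,
)

__all__ = [
    "LibraryEntry",
    "Library",
    "EvaluationSession",
    "build_library",
    "load_library",
    "export_surface_points",
    "issue_blinded_electrograms",
    "evaluate_session",
    "validate_report",
    "session_to_manifest",
    "session_from_manifest",
]


@dataclass
class LibraryEntry:
    """One pre-computed simulation with its four silver-standard items."""

    identifier: str
    record: VmRecord
    act_map: ActivationMap                  # node -> Vm AcT list
    events: list[PatternEvent]
    sources: list[ReentrySource]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.record is None or self.act_map is None:
            raise ValueError("library entry must carry Vm record and AcT map")
        if self.events is None or self.sources is None:
            raise ValueError("library entry must carry event list and source list")

    @property
    def geometry(self) -> TissueGeometry:
        return self.record.geometry

    def ground_truth(self) -> GroundTruth:
        return GroundTruth(
            events=list(self.events),
            vm_acts=dict(self.act_map.acts),
            surface_points=self.geometry.nodes[self.geometry.surface_nodes],
        )


@dataclass
class Library:
    entries: dict[str, LibraryEntry] = field(default_factory=dict)
    invalid: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, identifier: str) -> LibraryEntry:
        return self.entries[identifier]

    def identifiers(self) -> list[str]:
        return sorted(self.entries)


def _build_geometry(cfg: dict) -> TissueGeometry:
    kind = cfg["kind"]
    if kind == "sheet":
        return build_sheet_geometry(cfg["nx"], cfg["ny"], cfg["spacing"])
    if kind == "shell":
        return build_shell_geometry(cfg["radius"], cfg.get("subdivisions", 3))
    raise ValueError(f"unknown geometry kind {kind!r}")


def _build_protocol(cfg: dict, geom: TissueGeometry):
    kind = cfg["kind"]
    if kind == "paced":
        return protocol_paced(
            geom, cfg["center"], radius=cfg.get("radius", 0.5),
            onset=cfg.get("onset", 0.0), amplitude=cfg.get("amplitude"),
        )
    if kind == "s1s2":
        return protocol_s1s2(
            geom, cfg["s1_center"], cfg["s2_center"],
            s1_radius=cfg.get("s1_radius", 0.5),
            s2_radius=cfg.get("s2_radius", 1.0),
            s2_delay=cfg.get("s2_delay", 390.0),
            amplitude=cfg.get("amplitude"),
        )
    if kind == "focal":
        return protocol_focal(
            [(s["center"], s["radius"], s["onsets"]) for s in cfg["sources"]],
            amplitude=cfg.get("amplitude"),
        )
    raise ValueError(f"unknown protocol kind {kind!r}")


def _reentry_ground_truth(
    record: VmRecord,
    act_map: ActivationMap,
    window: tuple[float, float],
    seed: int,
) -> tuple[list[PatternEvent], list[ReentrySource]]:
    """R+/R- events from PS-density clustering over the analysis window.

    Sources come from k-means on PS occurrences.  Each source's beats are
    the windowed AcTs of a representative node near the source: nodes very
    close to a rotor core have reduced Vm amplitude and can drop a beat,
    so among the nodes within 0.5 cm of the source location the modal
    windowed beat count is taken as the consensus, and the node nearest
    the centre that carries the modal count is the representative.  Each
    of its AcTs is the beat-window reference time of one event.
    """
    geom = record.geometry
    phase = compute_phase(record)
    times = record.times
    series = []
    for t in times[(times >= window[0]) & (times <= window[1])]:
        try:
            series.append((float(t), detect_surface_ps(phase, geom, float(t))))
        except ValueError:
            continue
    density, occurrences = ps_density(series, geom.n_nodes, window)
    if not occurrences:
        raise RuntimeError("no phase singularities found in the analysis window")
    r_plus, r_minus = cluster_reentry_sources(density, geom, occurrences, seed=seed)
    events: list[PatternEvent] = []
    for src in (r_plus, r_minus):
        dists = np.linalg.norm(geom.nodes - src.location, axis=1)
        cand = np.nonzero(dists <= 0.5)[0]
        if cand.size == 0:
            cand, _ = geom.nearest_surface_nodes(src.location[None, :])
        windowed = {}
        for n in cand:
            acts = np.asarray(act_map[int(n)], dtype=float)
            windowed[int(n)] = acts[(acts >= window[0]) & (acts <= window[1])]
        counts = np.array([len(v) for v in windowed.values()])
        modal = int(np.bincount(counts).argmax())
        rep = min((n for n, v in windowed.items() if len(v) == modal),
                  key=lambda n: (dists[n], n))
        for b, t in enumerate(windowed[rep]):
            events.append(PatternEvent(src.chirality, b, src.location, float(t)))
    return events, [r_plus, r_minus]


def build_entry(config: dict) -> LibraryEntry:
    """Run one simulation config into a complete library entry.

    Config keys: identifier, geometry {kind,...}, protocol {kind,...},
    cell_model, seed, params (TissueParams overrides), activity
    ("paced" | "focal" | "reentry"), analysis_window [t0, t1] for reentry,
    metadata (free-form).
    """
    geom = _build_geometry(config["geometry"])
    params = TissueParams(**config.get("params", {}))
    protocol = _build_protocol(config["protocol"], geom)
    seed = int(config.get("seed", 0))
    cell_cfg = config.get("cell_model", "nygren")
    if isinstance(cell_cfg, dict):
        from .cells import get_model as _get_model

        opts = dict(cell_cfg)
        model_name = opts.pop("name")
        cell_model = _get_model(model_name, **opts)
    else:
        model_name = cell_cfg
        cell_model = cell_cfg
    record = run_monodomain(geom, params, protocol, cell_model, seed=seed)
    act_map = detect_activation_map(
        record.vm, list(range(geom.n_nodes)), DetectorParams(),
        sample_interval=record.sample_interval,
    )
    activity = config.get("activity", "paced")
    sources: list[ReentrySource] = []
    if activity == "reentry":
        window = tuple(config.get("analysis_window", (1000.0, 2000.0)))
        events, sources = _reentry_ground_truth(record, act_map, window, seed)
        # the S1 pacing beat is itself a ground-truth paced event; the S2
        # induction stimulus is not (it creates the reentry, not a beat)
        for ev in protocol.events:
            if ev.label == "S1":
                center = np.asarray(ev.center, dtype=float)
                node, _ = geom.nearest_surface_nodes(center[None, :])
                events.insert(0, PatternEvent("P", 0, geom.nodes[int(node[0])],
                                              ev.onset))
    elif activity in ("paced", "focal"):
        events = []
        beat_count: dict[str, int] = {}
        for ev in protocol.events:
            typ = "P" if activity == "paced" else ev.label
            if typ not in ("P", "F+", "F-"):
                typ = "F+"  # extra focal sources scored with the first class
            b = beat_count.get(ev.label, 0)
            beat_count[ev.label] = b + 1
            center = np.asarray(ev.center, dtype=float)
            node, _ = geom.nearest_surface_nodes(center[None, :])
            events.append(PatternEvent(typ, b, geom.nodes[int(node[0])], ev.onset))
    else:
        raise ValueError(f"unknown activity {activity!r}")
    meta = dict(config.get("metadata", {}))
    meta.update(activity=activity, seed=seed, cell_model=model_name)
    return LibraryEntry(config["identifier"], record, act_map, events, sources, meta)


def build_library(configs: list[dict], out_dir=None) -> Library:
    """Build entries for all configs; failures invalidate only their entry."""
    lib = Library()
    for cfg in configs:
        ident = cfg["identifier"]
        try:
            entry = build_entry(cfg)
        except Exception as exc:  # noqa: BLE001 - per-entry isolation is the contract
            lib.invalid[ident] = f"{type(exc).__name__}: {exc}"
            continue
        lib.entries[ident] = entry
        if out_dir is not None:
            save_entry(entry, Path(out_dir) / ident)
    return lib


def save_entry(entry: LibraryEntry, entry_dir) -> None:
    """Persist one entry: mesh, Vm store, AcT table, ground truth, metadata."""
    import h5py

    entry_dir = Path(entry_dir)
    entry_dir.mkdir(parents=True, exist_ok=True)
    mio.write_vtk(entry.geometry, entry_dir / "mesh.vtk")
    with h5py.File(entry_dir / "vm.h5", "w") as f:
        f.create_dataset("time_ms", data=entry.record.times)
        f.create_dataset("vm", data=entry.record.vm)
    mio.write_act_table(entry.act_map.acts, entry_dir / "acts.csv")
    truth = {
        "events": [
            {"type": ev.type, "beat": ev.beat,
             "location": [float(v) for v in ev.location],
             "ref_time": float(ev.ref_time)}
            for ev in entry.events
        ],
        "sources": [
            {"chirality": s.chirality, "location": [float(v) for v in s.location],
             "support": int(s.support),
             "member_nodes": [int(n) for n in s.member_nodes]}
            for s in entry.sources
        ],
    }
    (entry_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    meta = {"identifier": entry.identifier, "format_version": 1, **entry.metadata}
    (entry_dir / "meta.json").write_text(json.dumps(meta, indent=1))


def load_entry(entry_dir) -> LibraryEntry:
    import h5py

    entry_dir = Path(entry_dir)
    geom = mio.read_vtk(entry_dir / "mesh.vtk")
    with h5py.File(entry_dir / "vm.h5", "r") as f:
        times = f["time_ms"][...]
        vm = f["vm"][...]
    record = VmRecord(times=times, vm=vm, geometry=geom)
    raw = mio.read_act_table(entry_dir / "acts.csv")
    act_map = ActivationMap({int(k): v for k, v in raw.items()})
    for n in range(geom.n_nodes):
        act_map.acts.setdefault(n, np.empty(0))
    truth = json.loads((entry_dir / "truth.json").read_text())
    events = [PatternEvent(e["type"], e["beat"], np.array(e["location"]),
                           e["ref_time"]) for e in truth["events"]]
    sources = [
        ReentrySource(np.array(s["location"]), s["chirality"], s["support"],
                      np.array(s["member_nodes"], dtype=np.int64))
        for s in truth["sources"]
    ]
    meta = json.loads((entry_dir / "meta.json").read_text())
    ident = meta.pop("identifier")
    meta.pop("format_version", None)
    return LibraryEntry(ident, record, act_map, events, sources, meta)


def load_library(lib_dir) -> Library:
    lib = Library()
    for sub in sorted(Path(lib_dir).iterdir()):
        if not sub.is_dir() or not (sub / "meta.json").exists():
            continue
        try:
            entry = load_entry(sub)
        except Exception as exc:  # noqa: BLE001 - isolate corrupt entries
            lib.invalid[sub.name] = f"{type(exc).__name__}: {exc}"
            continue
        lib.entries[entry.identifier] = entry
    return lib


def export_surface_points(entry: LibraryEntry, path) -> None:
    """Step: surface export.  Coordinates only — no Vm, AcT or event data."""
    mio.write_surface_points(entry.geometry, path)


class _PointSet:
    """Registered user electrodes: labelled points without grid structure."""

    def __init__(self, labels: list[str], positions: np.ndarray):
        self.labels = list(labels)
        self.positions = np.asarray(positions, dtype=float)
        self.n_electrodes = len(self.labels)


@dataclass
class EvaluationSession:
    """Blinded session state; enforces the protocol order.

    register_electrodes -> declare_noise -> issue electrograms ->
    ingest predictions -> evaluate.  The session records the master seed
    and derives every noise seed from it, so a session re-run from the
    same inputs is bit-identical.
    """

    master_seed: int = 0
    electrodes: _PointSet | None = None
    noise_levels: dict[str, float] | None = None
    issued: dict[str, dict] = field(default_factory=dict)
    predictions: dict[str, dict] = field(default_factory=dict)
    reports: dict[str, dict] = field(default_factory=dict)

    def register_electrodes(self, labels, positions) -> None:
        if len(set(labels)) != len(list(labels)):
            raise ValueError("electrode labels must be unique")
        self.electrodes = _PointSet(labels, positions)
        self.noise_levels = None  # declarations are per electrode table

    def declare_noise(self, levels) -> None:
        """Declare per-electrode noise (mV/ms): scalar or {label: level}."""
        if self.electrodes is None:
            raise RuntimeError("protocol order: register electrodes before noise")
        if np.isscalar(levels):
            levels = {lab: float(levels) for lab in self.electrodes.labels}
        missing = [lab for lab in self.electrodes.labels if lab not in levels]
        if missing:
            raise ValueError(f"noise level missing for electrodes: {missing}")
        if any(v < 0 for v in levels.values()):
            raise ValueError("noise levels must be non-negative")
        self.noise_levels = {lab: float(levels[lab]) for lab in self.electrodes.labels}

    def noise_seed(self, entry_id: str) -> int:
        return (self.master_seed * 1000003 + zlib.crc32(entry_id.encode())) % (2**31)

    def ingest_predictions(self, entry_id: str, acts: dict,
                           patterns: list[PatternDetection]) -> None:
        """Store user predictions; sites must be registered electrode labels."""
        if self.electrodes is None:
            raise RuntimeError("protocol order: register electrodes first")
        known = set(self.electrodes.labels)
        bad = sorted({s for s in acts if s not in known}
                     | {d.electrode for d in patterns if d.electrode not in known})
        if bad:
            raise ValueError(f"prediction sites not registered: {bad}")
        self.predictions[entry_id] = {"acts": {k: np.sort(np.asarray(v, dtype=float))
                                               for k, v in acts.items()},
                                      "patterns": list(patterns)}


def issue_blinded_electrograms(
    session: EvaluationSession,
    entry: LibraryEntry,
    egm_params: ElectrogramParams | None = None,
):
    """Compute and noise the entry's electrograms for the session's array.

    Requires electrodes and noise declarations (protocol order).  The
    returned set carries declared noise levels but no seed; the seed stays
    session-side for reproducibility.
    """
    if session.electrodes is None or session.noise_levels is None:
        raise RuntimeError(
            "protocol order: electrodes and noise levels must be registered "
            "before electrograms are issued"
        )
    clean = compute_electrograms(entry.record, session.electrodes, egm_params)
    levels = np.array([session.noise_levels[lab] for lab in clean.labels])
    noisy = add_noise(clean, levels, seed=session.noise_seed(entry.identifier))
    blinded = type(noisy)(labels=noisy.labels, times=noisy.times, phi_e=noisy.phi_e,
                          noise_levels=noisy.noise_levels, noise_seed=None,
                          array=None)
    session.issued[entry.identifier] = {
        "seed": session.noise_seed(entry.identifier),
        "labels": list(clean.labels),
    }
    return blinded


def _report_float(x) -> float | None:
    x = float(x)
    return None if np.isnan(x) else x


def evaluate_session(
    session: EvaluationSession,
    entry: LibraryEntry,
    tol: float = 10.0,
    sweep_tols=(0.5, 1.0, 2.0, 5.0, 10.0, 15.0),
) -> dict:
    """Score the ingested predictions for one entry; returns the report dict.

    The report carries the AcT comparison at ``tol``, the per-type pattern
    comparison, a tolerance sweep and full provenance; it validates against
    the packaged report schema.
    """
    if entry.identifier not in session.predictions:
        raise RuntimeError("no predictions ingested for this entry")
    pred = session.predictions[entry.identifier]
    truth = entry.ground_truth()
    geom = entry.geometry
    pts = session.electrodes
    nearest, _ = geom.nearest_surface_nodes(pts.positions)
    mapping = {lab: int(n) for lab, n in zip(pts.labels, nearest)}

    acts = ActivationMap(dict(pred["acts"]))
    act_rep: AcTReport = compare_act(acts, truth, mapping, tol)
    pat_rep: AcPReport = compare_patterns(pred["patterns"], truth, geom, pts)
    sweep = tolerance_sweep(acts, truth, mapping, sweep_tols)

    params = entry.record.params
    report = {
        "schema_version": 1,
        "entry": entry.identifier,
        "provenance": {
            "master_seed": int(session.master_seed),
            "noise_seed": int(session.noise_seed(entry.identifier)),
            "cell_model": entry.record.cell_model or str(entry.metadata.get("cell_model", "")),
            "tissue_params": ({} if params is None else {
                "chi": params.chi, "Cm": params.Cm, "sigma": params.sigma,
                "dt": params.dt, "save_interval": params.save_interval,
                "duration": params.duration,
            }),
            "noise_levels": dict(session.noise_levels or {}),
        },
        "act": {
            "tol": float(tol),
            "fC": act_rep.fC, "fS": act_rep.fS, "AcTPM": act_rep.actpm,
            "rms": _report_float(act_rep.rms), "rms_sd": _report_float(act_rep.rms_sd),
            "n_correct": int(act_rep.n_correct), "n_spurious": int(act_rep.n_spurious),
            "n_missed": int(act_rep.n_missed), "n_truth": int(act_rep.n_truth),
            "per_electrode": [
                {"site": str(site), "n_truth": int(r["n_truth"]),
                 "n_correct": int(r["n_correct"]), "n_spurious": int(r["n_spurious"]),
                 "fC": float(r["fC"]), "fS": float(r["fS"]),
                 "rms": _report_float(r["rms"])}
                for site, r in act_rep.per_electrode.iterrows()
            ],
        },
        "patterns": {
            "per_type": [
                {"type": str(typ), "n_truth": int(r["n_truth"]),
                 "n_correct": int(r["n_correct"]),
                 "n_misclassified": int(r["n_misclassified"]),
                 "n_spurious": int(r["n_spurious"]),
                 "fC": float(r["fC"]), "fS": float(r["fS"]), "fM": float(r["fM"]),
                 "AcPPM": float(r["AcPPM"]),
                 "E_T": _report_float(r["E_T"]), "E_X": _report_float(r["E_X"])}
                for typ, r in pat_rep.per_type.iterrows()
            ],
        },
        "tolerance_sweep": [
            {"tol": float(r["tol"]), "AcTPM": float(r["AcTPM"]),
             "pct_spurious": float(r["pct_spurious"]),
             "rms": _report_float(r["rms"]), "rms_sd": _report_float(r["rms_sd"])}
            for _, r in sweep.iterrows()
        ],
    }
    validate_report(report)
    session.reports[entry.identifier] = report
    return report


def session_to_manifest(session: EvaluationSession, path) -> None:
    """Persist session state as a structured-text (JSON) manifest."""
    manifest = {
        "format_version": 1,
        "master_seed": int(session.master_seed),
        "electrodes": (None if session.electrodes is None else {
            "labels": session.electrodes.labels,
            "positions": session.electrodes.positions.tolist(),
        }),
        "noise_levels": session.noise_levels,
        "issued": session.issued,
    }
    Path(path).write_text(json.dumps(manifest, indent=1))


def session_from_manifest(path) -> EvaluationSession:
    manifest = json.loads(Path(path).read_text())
    session = EvaluationSession(master_seed=int(manifest["master_seed"]))
    el = manifest.get("electrodes")
    if el is not None:
        session.register_electrodes(el["labels"], np.array(el["positions"]))
    if manifest.get("noise_levels") is not None:
        session.declare_noise(manifest["noise_levels"])
    session.issued = dict(manifest.get("issued", {}))
    return session


def validate_report(report: dict) -> None:
    """Validate a report against the packaged JSON schema."""
    import jsonschema

    schema = json.loads(
        resources.files("mapeval").joinpath("schemas/report.schema.json").read_text()
    )
    jsonschema.validate(report, schema)
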