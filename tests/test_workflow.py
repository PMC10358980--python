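"""Library management and the blinded evaluation protocol."""

import json

import numpy as np
import pandas as pd
import pytest

from mapeval.geometry import place_uniform_array
from mapeval.metrics import PatternEvent
from mapeval.patterns import PatternDetection
from mapeval.workflow import (
    EvaluationSession,
    build_entry,
    build_library,
    evaluate_session,
    export_surface_points,
    issue_blinded_electrograms,
    load_entry,
    load_library,
    save_entry,
    session_from_manifest,
    session_to_manifest,
    validate_report,
)


def small_entry_config(identifier="mini-paced", seed=3, duration=150.0):
    return {
        "identifier": identifier,
        "activity": "paced",
        "geometry": {"kind": "sheet", "nx": 21, "ny": 21, "spacing": 0.05},
        "protocol": {"kind": "paced", "center": [0.0, 0.5, 0.0],
                     "radius": 0.2, "onset": 5.0},
        "cell_model": {"name": "twovar", "time_scale": 6.0},
        "params": {"sigma": 0.8, "duration": duration},
        "seed": seed,
        "metadata": {"chamber": "sheet-1cm"},
    }


@pytest.fixture(scope="module")
def mini_entry():
    return build_entry(small_entry_config())


class TestStandardLibrary:
    def test_two_entries_with_25_events(self, std_library):
        lib, _ = std_library
        assert len(lib.entries) == 2
        assert not lib.invalid
        events = [ev for e in lib.entries.values() for ev in e.events]
        assert len(events) == 25
        by_type = {t: sum(1 for ev in events if ev.type == t)
                   for t in ("P", "R+", "R-", "F+", "F-")}
        assert by_type == {"P": 1, "R+": 6, "R-": 6, "F+": 6, "F-": 6}

    def test_reentry_sources_counter_rotating(self, std_library):
        lib, _ = std_library
        entry = lib["reentry-f8"]
        assert [s.chirality for s in entry.sources] == ["R+", "R-"]
        d = np.linalg.norm(entry.sources[0].location - entry.sources[1].location)
        assert d > 0.5  # two distinct cores

    def test_persisted_and_reloadable(self, std_library):
        lib, out = std_library
        lib2 = load_library(out)
        assert sorted(lib2.entries) == sorted(lib.entries)
        e1 = lib["reentry-f8"]
        e2 = lib2["reentry-f8"]
        assert np.allclose(e1.record.vm, e2.record.vm)
        for n in (0, 100, 4000):
            assert np.allclose(e1.act_map[n], e2.act_map[n])
        assert len(e1.events) == len(e2.events)


class TestLibraryBuild:
    def test_empty_config_list(self):
        lib = build_library([])
        assert lib.entries == {} and lib.invalid == {}

    def test_invalid_entry_isolated(self, tmp_path):
        bad = small_entry_config("broken")
        bad["protocol"] = {"kind": "paced", "center": [50.0, 50.0, 0.0],
                          "radius": 0.01}
        good = small_entry_config("fine")
        lib = build_library([bad, good], out_dir=tmp_path)
        assert "fine" in lib.entries
        assert "broken" in lib.invalid
        assert (tmp_path / "fine" / "meta.json").exists()

    def test_rebuild_determinism(self, mini_entry):
        again = build_entry(small_entry_config())
        assert np.array_equal(mini_entry.record.vm, again.record.vm)
        for n in range(0, mini_entry.geometry.n_nodes, 37):
            assert np.array_equal(mini_entry.act_map[n], again.act_map[n])

    def test_paced_event_recorded(self, mini_entry):
        assert len(mini_entry.events) == 1
        ev = mini_entry.events[0]
        assert ev.type == "P" and ev.ref_time == 5.0

    def test_save_load_round_trip(self, mini_entry, tmp_path):
        save_entry(mini_entry, tmp_path / "mini")
        back = load_entry(tmp_path / "mini")
        assert back.identifier == mini_entry.identifier
        assert np.allclose(back.record.vm, mini_entry.record.vm)
        assert len(back.events) == len(mini_entry.events)
        assert back.metadata["activity"] == "paced"


class TestExportBlinding:
    def test_surface_export_schema(self, mini_entry, tmp_path):
        path = tmp_path / "surface.csv"
        export_surface_points(mini_entry, path)
        header = pd.read_csv(path, nrows=0).columns.tolist()
        assert header == ["id", "x", "y", "z"]
        df = pd.read_csv(path)
        assert len(df) == len(mini_entry.geometry.surface_nodes)


def _register(session, entry, noise=0.0):
    arr = place_uniform_array(entry.geometry, [0.5, 0.5, 0.0], pitch=0.15)
    session.register_electrodes(arr.labels, arr.positions)
    if noise is not None:
        session.declare_noise(noise)
    return arr


class TestSessionProtocol:
    def test_issue_before_registration_rejected(self, mini_entry):
        session = EvaluationSession(master_seed=1)
        with pytest.raises(RuntimeError):
            issue_blinded_electrograms(session, mini_entry)

    def test_issue_before_noise_rejected(self, mini_entry):
        session = EvaluationSession(master_seed=1)
        _register(session, mini_entry, noise=None)
        with pytest.raises(RuntimeError):
            issue_blinded_electrograms(session, mini_entry)

    def test_noise_before_electrodes_rejected(self):
        with pytest.raises(RuntimeError):
            EvaluationSession().declare_noise(1.0)

    def test_missing_noise_labels_rejected(self, mini_entry):
        session = EvaluationSession()
        _register(session, mini_entry, noise=None)
        with pytest.raises(ValueError):
            session.declare_noise({"a1": 1.0})

    def test_reissue_identical(self, mini_entry):
        session = EvaluationSession(master_seed=17)
        _register(session, mini_entry, noise=0.5)
        a = issue_blinded_electrograms(session, mini_entry)
        b = issue_blinded_electrograms(session, mini_entry)
        assert np.array_equal(a.phi_e, b.phi_e)
        # blinded: the issued set carries no seed
        assert a.noise_seed is None
        assert session.issued[mini_entry.identifier]["seed"] == \
            session.noise_seed(mini_entry.identifier)

    def test_per_electrode_noise_respected(self, mini_entry):
        session = EvaluationSession(master_seed=2)
        arr = _register(session, mini_entry, noise=None)
        levels = {lab: (1.0 if i % 2 else 0.0)
                  for i, lab in enumerate(arr.labels)}
        session.declare_noise(levels)
        noisy = issue_blinded_electrograms(session, mini_entry)
        session2 = EvaluationSession(master_seed=2)
        _register(session2, mini_entry, noise=0.0)
        clean = issue_blinded_electrograms(session2, mini_entry)
        dt = noisy.sample_interval
        for i, lab in enumerate(arr.labels):
            diff = np.abs(noisy.phi_e[i] - clean.phi_e[i])
            assert diff.max() <= levels[lab] * dt + 1e-12
            if levels[lab] > 0:
                assert diff.max() > 0

    def test_noise_seed_formula(self):
        import zlib

        session = EvaluationSession(master_seed=5)
        expected = (5 * 1000003 + zlib.crc32(b"abc")) % (2 ** 31)
        assert session.noise_seed("abc") == expected

    def test_unknown_prediction_sites_rejected(self, mini_entry):
        session = EvaluationSession()
        _register(session, mini_entry)
        with pytest.raises(ValueError, match="z9"):
            session.ingest_predictions("mini-paced", {"z9": [1.0]}, [])
        with pytest.raises(ValueError):
            session.ingest_predictions(
                "mini-paced", {}, [PatternDetection("F", "nope", 1.0, 0)])


class TestEvaluation:
    def _truth_predictions(self, session, entry):
        pts = session.electrodes
        nearest, _ = entry.geometry.nearest_surface_nodes(pts.positions)
        acts = {lab: np.asarray(entry.act_map[int(n)])
                for lab, n in zip(pts.labels, nearest)}
        return acts

    def test_self_test_perfect_scores(self, mini_entry):
        session = EvaluationSession(master_seed=1)
        arr = _register(session, mini_entry)
        issue_blinded_electrograms(session, mini_entry)
        acts = self._truth_predictions(session, mini_entry)
        ev = mini_entry.events[0]
        i_near = int(np.argmin(np.linalg.norm(
            arr.positions - ev.location, axis=1)))
        patterns = [PatternDetection("F", arr.labels[i_near], ev.ref_time, 0)]
        session.ingest_predictions(mini_entry.identifier, acts, patterns)
        report = evaluate_session(session, mini_entry)
        assert report["act"]["AcTPM"] == 100.0
        p_row = next(r for r in report["patterns"]["per_type"]
                     if r["type"] == "P")
        assert p_row["AcPPM"] == 100.0
        validate_report(report)

    def test_empty_predictions(self, mini_entry):
        session = EvaluationSession(master_seed=1)
        _register(session, mini_entry)
        issue_blinded_electrograms(session, mini_entry)
        session.ingest_predictions(mini_entry.identifier, {}, [])
        report = evaluate_session(session, mini_entry)
        assert report["act"]["fC"] == 0.0
        assert all(r["fC"] == 0.0 for r in report["patterns"]["per_type"])

    def test_evaluate_without_predictions_rejected(self, mini_entry):
        session = EvaluationSession()
        _register(session, mini_entry)
        with pytest.raises(RuntimeError):
            evaluate_session(session, mini_entry)

    def test_report_schema_enforced(self):
        with pytest.raises(Exception):
            validate_report({"schema_version": 1})

    def test_report_determinism(self, mini_entry):
        reports = []
        for _ in range(2):
            session = EvaluationSession(master_seed=9)
            _register(session, mini_entry, noise=0.5)
            issue_blinded_electrograms(session, mini_entry)
            acts = self._truth_predictions(session, mini_entry)
            session.ingest_predictions(mini_entry.identifier, acts, [])
            reports.append(evaluate_session(session, mini_entry))
        assert json.dumps(reports[0], sort_keys=True) == \
            json.dumps(reports[1], sort_keys=True)


class TestManifest:
    def test_round_trip(self, mini_entry, tmp_path):
        session = EvaluationSession(master_seed=11)
        _register(session, mini_entry, noise=0.25)
        issue_blinded_electrograms(session, mini_entry)
        path = tmp_path / "session.json"
        session_to_manifest(session, path)
        back = session_from_manifest(path)
        assert back.master_seed == 11
        assert back.electrodes.labels == session.electrodes.labels
        assert np.allclose(back.electrodes.positions, session.electrodes.positions)
        assert back.noise_levels == session.noise_levels
        assert back.issued.keys() == session.issued.keys()
        # the restored session issues bit-identical electrograms
        a = issue_blinded_electrograms(session, mini_entry)
        b = issue_blinded_electrograms(back, mini_entry)
        assert np.array_equal(a.phi_e, b.phi_e)


class TestFocalEntries:
    def test_focal_events_from_protocol(self):
        cfg = small_entry_config("mini-focal", duration=400.0)
        cfg["activity"] = "focal"
        cfg["protocol"] = {"kind": "focal", "sources": [
            {"center": [0.3, 0.3, 0.0], "radius": 0.15, "onsets": [5.0, 205.0]},
            {"center": [0.7, 0.7, 0.0], "radius": 0.15, "onsets": [5.0, 205.0]},
        ]}
        entry = build_entry(cfg)
        types = sorted(ev.type for ev in entry.events)
        assert types == ["F+", "F+", "F-", "F-"]
        assert [ev.beat for ev in entry.events if ev.type == "F+"] == [0, 1]
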