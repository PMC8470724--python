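"""Interpretation engine: concatenation, filters, bar plots, audit trail."""

from __future__ import annotations

import dataclasses
import random

import numpy as np
import pandas as pd
import pytest

from ngms.annotate import Annotation
from ngms.interpret import (
    AuditError,
    AuditEvent,
    AuditLog,
    FilterSpec,
    InterpretationRecord,
    TransitionError,
    apply_filters,
    barplot_data,
    concatenate_modes,
    diagnostic_preset,
    records_to_frame,
    replay,
)
from ngms.pipeline import patient_records
from ngms.stats import p_from_z
from _oracles import filter_oracle


def make_record(i, mode="positive", altered=False, panel=False, **kwargs):
    annotations = ()
    if panel:
        annotations = (
            Annotation(f"F{i}", "panel", "HMDB0000001", "metabolite", "M+H", 0, 0.5, 100.0, 0.01),
        )
    defaults = dict(
        feature_id=f"F{i}",
        ion_mode=mode,
        mz=100.0 + i,
        rt=1.0 + (i % 12),
        patient_mean=1e6,
        reference_median=1e5,
        fold_change=10.0 if altered else 1.0,
        z=8.0 if altered else 0.1,
        p_value=float(p_from_z(8.0 if altered else 0.1)),
        altered=altered,
        direction="up" if altered else "",
        annotations=annotations,
    )
    defaults.update(kwargs)
    return InterpretationRecord(**defaults)


def random_records(rng, n=120):
    out = []
    for i in range(n):
        altered = rng.random() < 0.3
        out.append(
            make_record(
                i,
                mode="positive" if rng.random() < 0.5 else "negative",
                altered=altered,
                panel=rng.random() < 0.4,
                fold_change=float(rng.uniform(0.01, 60)),
                p_value=float(rng.uniform(0, 1)),
                direction=str(rng.choice(["up", "down", ""])),
            )
        )
    return out


class TestConcatenateModes:
    def test_case_study_sized_concatenation(self):
        pos = [make_record(i, "positive") for i in range(712)]
        neg = [make_record(10000 + i, "negative") for i in range(681)]
        combined = concatenate_modes(pos, neg)
        assert len(combined) == 1393

    def test_empty_negative_set_is_identity(self):
        pos = [make_record(i) for i in range(5)]
        assert concatenate_modes(pos, []) == pos

    def test_mode_filter_recovers_partition(self):
        pos = [make_record(i, "positive") for i in range(7)]
        neg = [make_record(100 + i, "negative") for i in range(5)]
        combined = concatenate_modes(pos, neg)
        assert apply_filters(combined, FilterSpec(ion_mode="positive")) == pos
        assert apply_filters(combined, FilterSpec(ion_mode="negative")) == neg

    def test_wrong_mode_record_rejected(self):
        with pytest.raises(ValueError):
            concatenate_modes([make_record(0, "negative")], [])


class TestApplyFilters:
    def test_empty_spec_is_identity(self):
        records = random_records(np.random.default_rng(0))
        assert apply_filters(records, FilterSpec()) == records

    def test_panel_requirement_counts(self):
        records = [make_record(i, panel=(i < 42)) for i in range(100)]
        out = apply_filters(records, FilterSpec(require_panel=True))
        assert len(out) == 42

    def test_subset_idempotent_and_matches_oracle(self):
        rng = np.random.default_rng(20260929)
        for _ in range(100):
            records = random_records(rng, n=60)
            spec = FilterSpec(
                rt_range=(1.0, float(rng.uniform(2, 13))),
                max_p_value=float(rng.uniform(0, 1)) if rng.random() < 0.7 else None,
                min_abs_fold_change=float(rng.uniform(1, 8)) if rng.random() < 0.7 else None,
                require_panel=bool(rng.random() < 0.5),
                require_altered=bool(rng.random() < 0.5),
            )
            out = apply_filters(records, spec)
            assert out == filter_oracle(records, spec)
            assert apply_filters(out, spec) == out
            assert set(r.feature_id for r in out) <= set(r.feature_id for r in records)

    def test_composition_equals_conjunction(self):
        rng = np.random.default_rng(5)
        records = random_records(rng)
        s1 = FilterSpec(require_altered=True)
        s2 = FilterSpec(require_panel=True)
        combined = FilterSpec(require_altered=True, require_panel=True)
        assert apply_filters(apply_filters(records, s1), s2) == apply_filters(
            records, combined
        )

    def test_two_sided_fold_change(self):
        up = make_record(1, fold_change=5.0)
        down = make_record(2, fold_change=0.1)
        mid = make_record(3, fold_change=1.2)
        out = apply_filters([up, down, mid], FilterSpec(min_abs_fold_change=2.0))
        assert out == [up, down]

    def test_malformed_range_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(rt_range=(5.0, 1.0))


class TestDiagnosticPreset:
    def test_preset_selects_exactly_spiked_panel_features(self, vlcadd_run):
        records = []
        for mode, result in vlcadd_run.results.items():
            mode_records, _ = patient_records(
                result, vlcadd_run.batch.worklist, "P01", vlcadd_run.config
            )
            records.extend(mode_records)
        hits = apply_filters(records, diagnostic_preset())
        spiked = {
            s.compound for s in vlcadd_run.spec.spikes if s.sample_id == "P01"
        }
        assert hits
        hit_compounds = set()
        for record in hits:
            assert record.altered and record.has_panel_annotation
            hit_compounds.update(record.panel_compounds())
        assert hit_compounds == spiked

    def test_removing_panel_requirement_enlarges_result(self, vlcadd_run):
        result = vlcadd_run.results["positive"]
        records, _ = patient_records(
            result, vlcadd_run.batch.worklist, "P01", vlcadd_run.config
        )
        with_panel = apply_filters(records, diagnostic_preset())
        without = apply_filters(records, FilterSpec(require_altered=True))
        assert len(without) >= len(with_panel)

    def test_preset_roundtrips_through_json(self):
        preset = diagnostic_preset()
        assert FilterSpec.from_json(preset.to_json()) == preset


class TestBarplot:
    def test_bar_count_and_role_partition(self, vlcadd_run):
        result = vlcadd_run.results["positive"]
        fid = result.sample_matrix.dropna().index[0]
        bars = barplot_data(
            fid, result.sample_matrix, vlcadd_run.batch.worklist, "P01"
        )
        assert len(bars) == 22  # 20 patients + QC pool + validation
        assert set(bars["role"]) == {
            "patient of interest",
            "other patients",
            "QC pool",
            "validation",
        }
        assert (bars["role"] == "patient of interest").sum() == 1

    def test_bar_ratio_reproduces_fold_change(self, vlcadd_run):
        result = vlcadd_run.results["positive"]
        _records, stats = patient_records(
            result, vlcadd_run.batch.worklist, "P01", vlcadd_run.config
        )
        fid = stats[stats["altered"]].index[0]
        bars = barplot_data(fid, result.sample_matrix, vlcadd_run.batch.worklist, "P01")
        poi = bars.loc[bars["role"] == "patient of interest", "intensity"].iloc[0]
        others = bars.loc[bars["role"] == "other patients", "intensity"].median()
        assert poi / others == pytest.approx(stats.loc[fid, "fold_change"], rel=1e-6)

    def test_unknown_feature_rejected(self, vlcadd_run):
        result = vlcadd_run.results["positive"]
        with pytest.raises(KeyError):
            barplot_data("NOPE", result.sample_matrix, vlcadd_run.batch.worklist)


class TestImmutability:
    def test_result_fields_reject_mutation(self):
        record = make_record(1)
        with pytest.raises(dataclasses.FrozenInstanceError):
            record.fold_change = 99.0
        with pytest.raises(dataclasses.FrozenInstanceError):
            record.altered = True

    def test_filters_do_not_mutate_records(self):
        records = random_records(np.random.default_rng(2), n=30)
        snapshot = [dataclasses.replace(r) for r in records]
        apply_filters(records, FilterSpec(require_altered=True))
        concatenate_modes(
            [r for r in records if r.ion_mode == "positive"],
            [r for r in records if r.ion_mode == "negative"],
        )
        assert records == snapshot


class TestAuditTrail:
    def event(self, action, role="data_analyst", target="S1", text=""):
        return AuditEvent.now("alice", role, target, action, text)

    def test_annotation_appears_in_replay(self):
        log = AuditLog()
        log.record_event(self.event("annotate", target="F1", text="likely C14:1"))
        state = log.replay()
        assert state["annotations"]["F1"] == [("alice", "likely C14:1")]

    def test_approval_requires_lab_specialist(self):
        log = AuditLog()
        log.record_event(self.event("review"))
        log.record_event(self.event("review"))
        with pytest.raises(AuditError):
            log.record_event(self.event("approve", role="data_analyst"))
        log.record_event(self.event("approve", role="lab_specialist"))
        assert log.replay()["sample_status"]["S1"] == "approved"

    def test_out_of_order_transition_rejected(self):
        log = AuditLog()
        with pytest.raises(TransitionError):
            log.record_event(self.event("approve", role="lab_specialist"))
        log.record_event(self.event("review"))
        log.record_event(self.event("review"))
        with pytest.raises(TransitionError):
            log.record_event(self.event("review"))

    def test_rejected_event_leaves_log_untouched(self):
        log = AuditLog()
        log.record_event(self.event("review"))
        n = len(log)
        with pytest.raises(TransitionError):
            log.record_event(self.event("approve", role="lab_specialist"))
        assert len(log) == n

    def test_replay_equals_fold_on_random_valid_sequences(self):
        rng = random.Random(20260929)
        for _ in range(100):
            log = AuditLog()
            statuses = {}
            expected_annotations = {}
            for _step in range(rng.randint(1, 30)):
                kind = rng.random()
                if kind < 0.5:
                    target = f"F{rng.randint(1, 5)}"
                    text = f"note{rng.randint(0, 99)}"
                    log.record_event(self.event("annotate", target=target, text=text))
                    expected_annotations.setdefault(target, []).append(("alice", text))
                else:
                    sample = f"S{rng.randint(1, 3)}"
                    state = statuses.get(sample, "new")
                    if state == "new":
                        log.record_event(self.event("review", target=sample))
                        statuses[sample] = "in_review"
                    elif state == "in_review":
                        log.record_event(self.event("review", target=sample))
                        statuses[sample] = "reviewed"
                    elif state == "reviewed":
                        log.record_event(
                            self.event("approve", role="lab_specialist", target=sample)
                        )
                        statuses[sample] = "approved"
                    # approved samples receive no further state events
            state = log.replay()
            assert state["sample_status"] == statuses
            assert state["annotations"] == expected_annotations

    def test_persistence_roundtrip_is_append_only(self, tmp_path):
        path = tmp_path / "audit.jsonl"
        log = AuditLog(path)
        log.record_event(self.event("annotate", target="F1", text="x"))
        log.record_event(self.event("review"))
        reloaded = AuditLog(path)
        assert len(reloaded) == 2
        assert reloaded.replay() == log.replay()
        reloaded.record_event(self.event("review"))
        assert len(AuditLog(path)) == 3

    def test_unknown_role_rejected(self):
        with pytest.raises(AuditError):
            AuditEvent.now("bob", "intern", "S1", "annotate")


def test_records_to_frame_summarizes_annotations():
    records = [make_record(1, panel=True, altered=True), make_record(2)]
    frame = records_to_frame(records)
    assert list(frame["feature_id"]) == ["F1", "F2"]
    assert frame.loc[0, "panel_compounds"] == "metabolite"
    assert frame.loc[1, "n_annotations"] == 0
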