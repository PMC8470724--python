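"""Interpretation engine: mode concatenation, filtering, audit trail.

The clinical reviewer works on a concatenated positive+negative table of
per-feature results. Result columns are immutable once created (frozen
records); the only thing users may add is commentary, which lives in an
append-only, role-tagged audit log. Replaying the log reconstructs the
review state exactly — the log is the state.

Review of a sample walks a linear state machine
``new -> in_review -> reviewed -> approved``; the final approval is
reserved to the clinical laboratory specialist role.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import Annotation
from .batch_io import (
    ROLE_PATIENT,
    ROLE_QC_POOL,
    ROLE_VALIDATION,
    SessionConfig,
    Worklist,
)

__all__ = [
    "InterpretationRecord",
    "FilterSpec",
    "AuditEvent",
    "AuditError",
    "TransitionError",
    "AuditLog",
    "SAMPLE_STATES",
    "ROLES",
    "concatenate_modes",
    "apply_filters",
    "diagnostic_preset",
    "barplot_data",
    "replay",
    "records_to_frame",
]

ROLES = ("data_analyst", "lab_specialist")
SAMPLE_STATES = ("new", "in_review", "reviewed", "approved")


class AuditError(PermissionError):
    """Role is not permitted to perform the action."""


class TransitionError(ValueError):
    """Review-state transition out of order."""


@dataclass(frozen=True)
class InterpretationRecord:
    """One mass feature's results as shown to the reviewer. Immutable."""

    feature_id: str
    ion_mode: str
    mz: float
    rt: float
    patient_mean: float
    reference_median: float
    fold_change: float
    z: float
    p_value: float
    altered: bool
    direction: str
    annotations: tuple[Annotation, ...] = ()

    @property
    def has_panel_annotation(self) -> bool:
        return any(a.level == "panel" for a in self.annotations)

    def panel_compounds(self) -> tuple[str, ...]:
        return tuple(
            sorted({a.compound_name for a in self.annotations if a.level == "panel"})
        )


@dataclass(frozen=True)
class FilterSpec:
    """Conjunction of optional predicates over interpretation records.

    ``min_abs_fold_change`` is two-sided: a record passes with
    FC >= x or FC <= 1/x, since IEMs present both as accumulation and as
    deficiency of a metabolite.
    """

    rt_range: tuple[float, float] | None = None
    mz_range: tuple[float, float] | None = None
    max_p_value: float | None = None
    min_abs_fold_change: float | None = None
    annotation_level: str | None = None  # "panel" | "mz_only"
    require_panel: bool = False
    require_altered: bool = False
    direction: str | None = None
    ion_mode: str | None = None

    def __post_init__(self) -> None:
        for rng, label in ((self.rt_range, "rt_range"), (self.mz_range, "mz_range")):
            if rng is not None and rng[0] > rng[1]:
                raise ValueError(f"{label} is not well-ordered: {rng}")
        if self.min_abs_fold_change is not None and self.min_abs_fold_change < 1:
            raise ValueError("min_abs_fold_change must be >= 1")

    def matches(self, record: InterpretationRecord) -> bool:
        if self.rt_range is not None and not (
            self.rt_range[0] <= record.rt <= self.rt_range[1]
        ):
            return False
        if self.mz_range is not None and not (
            self.mz_range[0] <= record.mz <= self.mz_range[1]
        ):
            return False
        if self.max_p_value is not None and not (
            record.p_value <= self.max_p_value
        ):
            return False
        if self.min_abs_fold_change is not None:
            fc = record.fold_change
            if not (fc >= self.min_abs_fold_change or fc <= 1.0 / self.min_abs_fold_change):
                return False
        if self.annotation_level is not None and not any(
            a.level == self.annotation_level for a in record.annotations
        ):
            return False
        if self.require_panel and not record.has_panel_annotation:
            return False
        if self.require_altered and not record.altered:
            return False
        if self.direction is not None and record.direction != self.direction:
            return False
        if self.ion_mode is not None and record.ion_mode != self.ion_mode:
            return False
        return True

    def to_json(self) -> str:
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FilterSpec":
        payload = json.loads(text)
        for key in ("rt_range", "mz_range"):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def concatenate_modes(
    records_pos: Sequence[InterpretationRecord],
    records_neg: Sequence[InterpretationRecord],
) -> list[InterpretationRecord]:
    """Union of both ion modes, mode labels preserved, no cross-mode merging."""
    for record in list(records_pos) + list(records_neg):
        if record.ion_mode not in ("positive", "negative"):
            raise ValueError(
                f"record {record.feature_id} lacks a valid ion mode label"
            )
    for record in records_pos:
        if record.ion_mode != "positive":
            raise ValueError(f"record {record.feature_id} is not positive mode")
    for record in records_neg:
        if record.ion_mode != "negative":
            raise ValueError(f"record {record.feature_id} is not negative mode")
    return list(records_pos) + list(records_neg)


def apply_filters(
    records: Sequence[InterpretationRecord], spec: FilterSpec
) -> list[InterpretationRecord]:
    """Records satisfying every present predicate, input order preserved."""
    return [r for r in records if spec.matches(r)]


def diagnostic_preset(config: SessionConfig | None = None) -> FilterSpec:
    """The diagnostic filter preset: altered features with a panel annotation."""
    return FilterSpec(require_altered=True, require_panel=True)


def barplot_data(
    feature_id: str,
    sample_matrix: pd.DataFrame,
    worklist: Worklist,
    patient_of_interest: str | None = None,
) -> pd.DataFrame:
    """Per-sample averaged intensities of one feature, labeled by role.

    Order follows the worklist; the patient of interest is labeled
    distinctly so the bar plot can color it.
    """
    if feature_id not in sample_matrix.index:
        raise KeyError(f"unknown feature {feature_id!r}")
    row = sample_matrix.loc[feature_id]
    labels = {
        ROLE_PATIENT: "other patients",
        ROLE_QC_POOL: "QC pool",
        ROLE_VALIDATION: "validation",
        "blank": "blank",
    }
    records = []
    for sample in worklist.samples():
        if sample not in row.index:
            continue
        role = worklist.role_of(sample)
        label = labels.get(role, role)
        if sample == patient_of_interest:
            label = "patient of interest"
        records.append(
            {
                "sample_id": sample,
                "role": label,
                "intensity": row[sample],
            }
        )
    return pd.DataFrame(records, columns=["sample_id", "role", "intensity"])


# ---------------------------------------------------------------------------
# Audit trail


@dataclass(frozen=True)
class AuditEvent:
    """One append-only audit entry."""

    timestamp: str
    user: str
    role: str
    target: str  # feature_id or sample_id
    action: str  # "annotate" | "review" | "approve"
    text: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise AuditError(f"unknown role {self.role!r}")
        if self.action not in ("annotate", "review", "approve"):
            raise ValueError(f"unknown action {self.action!r}")

    @classmethod
    def now(cls, user: str, role: str, target: str, action: str, text: str = "") -> "AuditEvent":
        return cls(
            timestamp=datetime.now(timezone.utc).isoformat(),
            user=user,
            role=role,
            target=target,
            action=action,
            text=text,
        )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AuditEvent":
        return cls(**json.loads(text))


def _apply_event(
    event: AuditEvent,
    annotations: dict[str, list[tuple[str, str]]],
    statuses: dict[str, str],
) -> None:
    """Apply one validated event to the replay state; raises on violations."""
    if event.action == "annotate":
        annotations.setdefault(event.target, []).append((event.user, event.text))
        return
    current = statuses.get(event.target, "new")
    if event.action == "review":
        if current == "new":
            statuses[event.target] = "in_review"
        elif current == "in_review":
            statuses[event.target] = "reviewed"
        else:
            raise TransitionError(
                f"cannot review sample {event.target} in state {current!r}"
            )
        return
    # approve
    if event.role != "lab_specialist":
        raise AuditError("approval requires the lab_specialist role")
    if current != "reviewed":
        raise TransitionError(
            f"cannot approve sample {event.target} in state {current!r}"
        )
    statuses[event.target] = "approved"


def replay(events: Iterable[AuditEvent]) -> dict:
    """Fold the event log into the current review state.

    Returns ``{"annotations": {target: [(user, text), ...]},
    "sample_status": {sample: state}}``. Pure function of the log.
    """
    annotations: dict[str, list[tuple[str, str]]] = {}
    statuses: dict[str, str] = {}
    for event in events:
        _apply_event(event, annotations, statuses)
    return {"annotations": annotations, "sample_status": statuses}


class AuditLog:
    """Append-only audit trail, optionally persisted as JSON lines."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self.events: list[AuditEvent] = []
        if self.path is not None and self.path.exists():
            for line in self.path.read_text().splitlines():
                if line.strip():
                    self.events.append(AuditEvent.from_json(line))

    def record_event(self, event: AuditEvent) -> None:
        """Validate against the replayed state, then append. Invalid
        events are rejected without touching the log."""
        annotations: dict[str, list[tuple[str, str]]] = {}
        statuses: dict[str, str] = {}
        for existing in self.events:
            _apply_event(existing, annotations, statuses)
        _apply_event(event, annotations, statuses)  # raises if invalid
        self.events.append(event)
        if self.path is not None:
            with open(self.path, "a") as handle:
                handle.write(event.to_json() + "\n")

    def replay(self) -> dict:
        return replay(self.events)

    def __len__(self) -> int:
        return len(self.events)


def records_to_frame(records: Sequence[InterpretationRecord]) -> pd.DataFrame:
    """Flatten records for TSV/XLSX export (one row per record; panel
    compound names and best annotation summarized)."""
    rows = []
    for r in records:
        best = r.annotations[0] if r.annotations else None
        rows.append(
            {
                "feature_id": r.feature_id,
                "ion_mode": r.ion_mode,
                "mz": r.mz,
                "rt": r.rt,
                "patient_mean": r.patient_mean,
                "reference_median": r.reference_median,
                "fold_change": r.fold_change,
                "z": r.z,
                "p_value": r.p_value,
                "altered": r.altered,
                "direction": r.direction,
                "n_annotations": len(r.annotations),
                "panel_compounds": ";".join(r.panel_compounds()),
                "best_annotation": (
                    f"{best.compound_name}|{best.adduct_name}|+{best.isotope_index}"
                    if best
                    else ""
                ),
            }
        )
    return pd.DataFrame(rows)
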