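"""End-to-end orchestration: align -> annotate -> stats -> interpret.

Thin glue over the stage modules, shared by the CLI, the acceptance
script and the tests. One ``ModeResult`` per ion mode carries the
aligned features, intensity matrices and per-feature annotations; the
per-patient analysis turns a mode result into immutable interpretation
records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .align import AlignedFeature, align, to_matrix
from .annotate import (
    Annotation,
    CompoundRecord,
    IonIndex,
    PanelEntry,
    annotate_library,
    annotate_panel,
    build_ion_index,
)
from .batch_io import PeakList, SessionConfig, Worklist
from .interpret import InterpretationRecord
from .stats import Thresholds, average_duplicates, feature_statistics

__all__ = ["ModeResult", "process_mode", "patient_records", "panel_altered_sets"]


@dataclass
class ModeResult:
    """Everything the interpretation stage needs for one ion mode."""

    ion_mode: str
    features: list[AlignedFeature]
    matrix: pd.DataFrame  # features x injections
    sample_matrix: pd.DataFrame  # features x samples (duplicate-averaged)
    partial: pd.DataFrame
    annotations: dict[str, list[Annotation]]  # feature_id -> annotations

    @property
    def feature_by_id(self) -> dict[str, AlignedFeature]:
        return {f.feature_id: f for f in self.features}


def process_mode(
    peaklists: Sequence[PeakList],
    worklist: Worklist,
    config: SessionConfig,
    panel: Sequence[PanelEntry],
    library: Sequence[CompoundRecord],
    ion_mode: str,
) -> ModeResult:
    """Align one mode's peak lists and annotate every feature."""
    mode_lists = [pl for pl in peaklists if pl.ion_mode == ion_mode]
    features = align(mode_lists, config.mz_tolerance_ppm, config.rt_tolerance_min)
    matrix = to_matrix(features, worklist)
    sample_matrix, partial = average_duplicates(matrix, worklist)
    panel_index = build_ion_index(panel, ion_mode)
    library_index = build_ion_index(library, ion_mode)
    annotations: dict[str, list[Annotation]] = {}
    for feature in features:
        anns = annotate_panel(
            feature, panel_index, config.mz_tolerance_ppm, config.rt_tolerance_min
        )
        anns += annotate_library(feature, library_index, config.mz_tolerance_ppm)
        if anns:
            annotations[feature.feature_id] = anns
    return ModeResult(
        ion_mode=ion_mode,
        features=features,
        matrix=matrix,
        sample_matrix=sample_matrix,
        partial=partial,
        annotations=annotations,
    )


def patient_records(
    result: ModeResult,
    worklist: Worklist,
    target_sample: str,
    config: SessionConfig,
) -> tuple[list[InterpretationRecord], pd.DataFrame]:
    """Statistics of one sample versus the batch, as immutable records."""
    stats = feature_statistics(
        result.sample_matrix,
        worklist,
        target_sample,
        Thresholds.from_config(config),
        partial=result.partial,
    )
    by_id = result.feature_by_id
    records = []
    for feature_id, row in stats.iterrows():
        feature = by_id[feature_id]
        records.append(
            InterpretationRecord(
                feature_id=feature_id,
                ion_mode=result.ion_mode,
                mz=feature.consensus_mz,
                rt=feature.consensus_rt,
                patient_mean=float(row["patient_mean"])
                if pd.notna(row["patient_mean"])
                else float("nan"),
                reference_median=float(row["reference_median"])
                if pd.notna(row["reference_median"])
                else float("nan"),
                fold_change=float(row["fold_change"])
                if pd.notna(row["fold_change"])
                else float("nan"),
                z=float(row["z"]) if pd.notna(row["z"]) else float("nan"),
                p_value=float(row["p_value"])
                if pd.notna(row["p_value"])
                else float("nan"),
                altered=bool(row["altered"]),
                direction=str(row["direction"]),
                annotations=tuple(result.annotations.get(feature_id, ())),
            )
        )
    return records, stats


def panel_altered_sets(
    mode_results: Mapping[str, ModeResult],
    worklist: Worklist,
    config: SessionConfig,
    samples: Sequence[str] | None = None,
) -> dict[str, set[str]]:
    """Per sample, the set of panel metabolites altered in any mode.

    The release-regression comparison consumes exactly this summary for
    two pipeline versions.
    """
    from .batch_io import ROLE_PATIENT

    if samples is None:
        samples = worklist.samples(ROLE_PATIENT)
    out: dict[str, set[str]] = {}
    for sample in samples:
        names: set[str] = set()
        for result in mode_results.values():
            records, _ = patient_records(result, worklist, sample, config)
            for record in records:
                if record.altered and record.has_panel_annotation:
                    names.update(record.panel_compounds())
        out[sample] = names
    return out
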