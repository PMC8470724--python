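"""Analytical QC, validation-plasma gating and release regression checks.

Three QC metrics are computed per monitored standard across injections:
retention-time repeatability (worst relative deviation from the median
RT, in %), response repeatability (sample-s.d. coefficient of variation
of the recovered intensities, in %) and mass accuracy (worst absolute
ppm error). A standard passes only if all three clear its thresholds.

The validation plasma — control plasma spiked with known IEM metabolites
at diagnostic concentrations — is processed exactly like a patient; the
data-processing gate requires every spiked metabolite to emerge as
significantly increased in at least one expected ion mode. Only when
both the analytical QC and the validation gate pass may an
interpretation session be opened.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignedFeature
from .annotate import Annotation, PanelEntry
from .batch_io import PeakList, Worklist
from .chem import AdductSpec, DEFAULT_ADDUCTS, ElementalFormula, get_adduct, ion_mz, ppm_error

__all__ = [
    "StandardDef",
    "Recovery",
    "QCRow",
    "ValidationReportRow",
    "QualityError",
    "recover_standards",
    "qc_metrics",
    "validation_report",
    "session_gate",
    "diagnostics_data",
    "compare_sessions",
    "write_qc_report",
]


class QualityError(ValueError):
    pass


@dataclass(frozen=True)
class StandardDef:
    """A monitored QC standard and its recovery thresholds."""

    name: str
    formula: ElementalFormula
    adduct_name: str
    ion_mode: str
    expected_rt: float
    kind: str = "external"  # "internal" | "external"
    max_rt_delta_pct: float = 10.0
    max_response_cv_pct: float = 30.0
    max_abs_ppm: float = 5.0
    #: internal standards must be recovered in at least this fraction of
    #: their injections (occasional misses are tolerated; systematic loss
    #: is not)
    min_found_fraction: float = 0.90

    def __post_init__(self) -> None:
        if self.kind not in ("internal", "external"):
            raise QualityError(f"standard kind must be internal|external: {self.kind!r}")
        if min(self.max_rt_delta_pct, self.max_response_cv_pct, self.max_abs_ppm) <= 0:
            raise QualityError("thresholds must be positive")

    def theoretical_mz(self, adducts: Mapping[str, AdductSpec] | None = None) -> float:
        return ion_mz(self.formula.mass, get_adduct(self.adduct_name, adducts))


@dataclass(frozen=True)
class Recovery:
    """Best in-tolerance peak for one (injection, standard), or absence."""

    injection_id: str
    standard: str
    found: bool
    rt: float | None = None
    intensity: float | None = None
    ppm: float | None = None


def recover_standards(
    peaklists: Sequence[PeakList],
    defs: Sequence[StandardDef],
    mz_tol: float,
    rt_tol: float,
    adducts: Mapping[str, AdductSpec] | None = None,
) -> list[Recovery]:
    """Find each standard's ion in each injection of its mode.

    The best candidate minimizes |ppm error|, ties broken by |RT delta|.
    Absence is data ("not found"), never an exception.
    """
    if not defs:
        raise QualityError("no standards defined")
    out = []
    for std in defs:
        theo = std.theoretical_mz(adducts)
        for pl in peaklists:
            if pl.ion_mode != std.ion_mode:
                continue
            mz = pl.peaks["mz"].to_numpy(float)
            rt = pl.peaks["rt"].to_numpy(float)
            inten = pl.peaks["intensity"].to_numpy(float)
            ppm = (mz - theo) / theo * 1e6
            ok = (np.abs(ppm) <= mz_tol) & (np.abs(rt - std.expected_rt) <= rt_tol)
            if not ok.any():
                out.append(Recovery(pl.injection_id, std.name, found=False))
                continue
            idx = np.flatnonzero(ok)
            order = idx[
                np.lexsort(
                    (np.abs(rt[idx] - std.expected_rt), np.abs(ppm[idx]))
                )
            ]
            best = order[0]
            out.append(
                Recovery(
                    pl.injection_id,
                    std.name,
                    found=True,
                    rt=float(rt[best]),
                    intensity=float(inten[best]),
                    ppm=float(ppm[best]),
                )
            )
    return out


@dataclass
class QCRow:
    """QC metrics of one standard across injections."""

    standard: str
    kind: str
    n_found: int
    n_injections: int
    rt_delta_pct: float | None
    response_cv_pct: float | None
    worst_abs_ppm: float | None
    rt_pass: bool
    response_pass: bool
    ppm_pass: bool
    found_pass: bool

    @property
    def overall_pass(self) -> bool:
        return self.rt_pass and self.response_pass and self.ppm_pass and self.found_pass


def qc_metrics(
    recoveries: Sequence[Recovery], defs: Sequence[StandardDef]
) -> list[QCRow]:
    """Repeatability and accuracy metrics per standard.

    * rt_delta_pct  = max_i |rt_i - median(rt)| / median(rt) * 100
    * response_cv   = sd(n-1) / mean * 100
    * worst_abs_ppm = max_i |ppm_i|

    A standard recovered in fewer than two injections has undefined
    repeatability and fails; internal standards additionally fail when
    absent from any of their injections.
    """
    by_std: dict[str, list[Recovery]] = {}
    for rec in recoveries:
        by_std.setdefault(rec.standard, []).append(rec)
    rows = []
    for std in defs:
        recs = by_std.get(std.name, [])
        hits = [r for r in recs if r.found]
        n_found, n_inj = len(hits), len(recs)
        if n_found < 2:
            rows.append(
                QCRow(
                    standard=std.name,
                    kind=std.kind,
                    n_found=n_found,
                    n_injections=n_inj,
                    rt_delta_pct=None,
                    response_cv_pct=None,
                    worst_abs_ppm=(
                        max(abs(r.ppm) for r in hits) if hits else None
                    ),
                    rt_pass=False,
                    response_pass=False,
                    ppm_pass=bool(hits)
                    and max(abs(r.ppm) for r in hits) <= std.max_abs_ppm,
                    found_pass=False,
                )
            )
            continue
        rts = np.array([r.rt for r in hits])
        intens = np.array([r.intensity for r in hits])
        ppms = np.array([r.ppm for r in hits])
        med_rt = float(np.median(rts))
        rt_delta_pct = float(np.max(np.abs(rts - med_rt)) / med_rt * 100.0)
        cv = float(np.std(intens, ddof=1) / np.mean(intens) * 100.0)
        worst_ppm = float(np.max(np.abs(ppms)))
        rows.append(
            QCRow(
                standard=std.name,
                kind=std.kind,
                n_found=n_found,
                n_injections=n_inj,
                rt_delta_pct=rt_delta_pct,
                response_cv_pct=cv,
                worst_abs_ppm=worst_ppm,
                rt_pass=rt_delta_pct <= std.max_rt_delta_pct,
                response_pass=cv <= std.max_response_cv_pct,
                ppm_pass=worst_ppm <= std.max_abs_ppm,
                found_pass=(
                    (n_found / n_inj >= std.min_found_fraction)
                    if std.kind == "internal" and n_inj
                    else True
                ),
            )
        )
    return rows


@dataclass
class ValidationReportRow:
    """One spiked-metabolite feature in the validation report."""

    name: str
    feature_mass: float | None
    rt_delta_pct: float | None
    mean_intensity: float | None
    increased_pos: bool
    increased_neg: bool


def validation_report(
    stats_by_mode: Mapping[str, pd.DataFrame],
    annotations_by_mode: Mapping[str, Mapping[str, Sequence[Annotation]]],
    features_by_mode: Mapping[str, Sequence[AlignedFeature]],
    spiked: Sequence[tuple[str, tuple[str, ...]]],
    panel: Sequence[PanelEntry],
) -> tuple[list[ValidationReportRow], bool, list[str]]:
    """Check that every spiked metabolite is significantly increased.

    ``stats_by_mode`` holds the validation sample's feature statistics
    per ion mode (computed like any patient); ``annotations_by_mode``
    maps feature_id -> panel annotations. ``spiked`` lists
    (compound name, expected modes).

    Returns (rows, gate, missing): the gate passes iff every spiked
    compound is altered-up in at least one expected mode; ``missing``
    names the compounds that are not.
    """
    panel_by_name = {p.name: p for p in panel}
    feature_lookup = {
        mode: {f.feature_id: f for f in feats}
        for mode, feats in features_by_mode.items()
    }
    rows: list[ValidationReportRow] = []
    missing: list[str] = []
    for name, modes in spiked:
        entry = panel_by_name.get(name)
        if entry is None:
            raise QualityError(f"spiked compound {name!r} is not in the panel")
        increased_by_mode: dict[str, bool] = {}
        best_rows: list[ValidationReportRow] = []
        for mode in modes:
            stats = stats_by_mode.get(mode)
            if stats is None:
                increased_by_mode[mode] = False
                continue
            annots = annotations_by_mode.get(mode, {})
            hit = False
            for fid, ann_list in annots.items():
                for ann in ann_list:
                    if ann.level != "panel" or ann.compound_name != name:
                        continue
                    if fid not in stats.index:
                        continue
                    row = stats.loc[fid]
                    increased = bool(row["altered"]) and row["direction"] == "up"
                    hit = hit or increased
                    feature = feature_lookup.get(mode, {}).get(fid)
                    expected = entry.expected_rt.get(mode)
                    rt_delta_pct = (
                        abs(feature.consensus_rt - expected) / expected * 100.0
                        if feature is not None and expected
                        else None
                    )
                    best_rows.append(
                        ValidationReportRow(
                            name=name,
                            feature_mass=(
                                feature.consensus_mz if feature else None
                            ),
                            rt_delta_pct=rt_delta_pct,
                            mean_intensity=float(row["patient_mean"]),
                            increased_pos=increased and mode == "positive",
                            increased_neg=increased and mode == "negative",
                        )
                    )
            increased_by_mode[mode] = hit
        if not any(increased_by_mode.get(m, False) for m in modes):
            missing.append(name)
        if best_rows:
            rows.extend(best_rows)
        else:
            rows.append(
                ValidationReportRow(
                    name=name,
                    feature_mass=None,
                    rt_delta_pct=None,
                    mean_intensity=None,
                    increased_pos=False,
                    increased_neg=False,
                )
            )
    return rows, not missing, missing


def session_gate(qc_rows: Sequence[QCRow], validation_gate: bool) -> bool:
    """Interpretation may start only when analytical QC and the
    validation-plasma gate both pass."""
    return all(row.overall_pass for row in qc_rows) and bool(validation_gate)


def diagnostics_data(
    matrix: pd.DataFrame,
    features: Sequence[AlignedFeature] | None = None,
    eic_targets: Mapping[str, float] | None = None,
    mz_tol: float = 5.0,
) -> dict:
    """Numbers behind the session diagnostic plots.

    * ``pca_scores``: first two principal-component scores per injection,
      from the log10, feature-centred intensity matrix (missing values
      filled with the feature minimum before centring);
    * ``rt_shift``: per-injection median RT deviation from the feature
      consensus (needs ``features``);
    * ``eic``: per named target m/z, the (injection, rt, intensity)
      points of matching features.
    """
    kept = matrix.dropna(how="all")
    dropped = len(matrix) - len(kept)
    if kept.empty or kept.shape[1] < 2:
        raise QualityError("matrix too degenerate for diagnostics")
    log = np.log10(kept.where(kept > 0))
    filled = log.apply(lambda row: row.fillna(row.min()), axis=1)
    centered = filled.sub(filled.mean(axis=1), axis=0).fillna(0.0)
    # SVD of features x injections; injection scores from right singular vectors
    u, s, vt = np.linalg.svd(centered.to_numpy(), full_matrices=False)
    k = min(2, len(s))
    scores = pd.DataFrame(
        (vt[:k].T * s[:k]),
        index=kept.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    out = {"pca_scores": scores, "n_dropped_features": dropped}

    if features is not None:
        shifts: dict[str, list[float]] = {}
        for feat in features:
            for inj, rt in feat.member_rts.items():
                shifts.setdefault(inj, []).append(rt - feat.consensus_rt)
        out["rt_shift"] = pd.Series(
            {inj: float(np.median(v)) for inj, v in sorted(shifts.items())}
        )

    if eic_targets and features is not None:
        eic: dict[str, pd.DataFrame] = {}
        for name, target_mz in eic_targets.items():
            rows = []
            for feat in features:
                if abs(ppm_error(feat.consensus_mz, target_mz)) <= mz_tol:
                    for inj, inten in sorted(feat.intensities.items()):
                        rows.append(
                            (inj, feat.member_rts.get(inj), inten)
                        )
            eic[name] = pd.DataFrame(
                rows, columns=["injection", "rt", "intensity"]
            )
        out["eic"] = eic
    return out


def compare_sessions(
    results_old: Mapping[str, set[str]],
    results_new: Mapping[str, set[str]],
) -> tuple[pd.DataFrame, bool]:
    """Release regression check on panel-annotated altered metabolites.

    Inputs map sample id -> set of panel metabolite names altered in that
    sample. The report lists, per sample, metabolites present in only one
    session; it passes iff every symmetric difference is empty and both
    sessions cover the same samples.
    """
    rows = []
    ok = True
    for sample in sorted(set(results_old) | set(results_new)):
        if sample not in results_old or sample not in results_new:
            rows.append(
                {
                    "sample_id": sample,
                    "only_old": "",
                    "only_new": "",
                    "note": "sample missing from one session",
                }
            )
            ok = False
            continue
        only_old = sorted(results_old[sample] - results_new[sample])
        only_new = sorted(results_new[sample] - results_old[sample])
        if only_old or only_new:
            ok = False
            rows.append(
                {
                    "sample_id": sample,
                    "only_old": ";".join(only_old),
                    "only_new": ";".join(only_new),
                    "note": "discrepancy",
                }
            )
    report = pd.DataFrame(
        rows, columns=["sample_id", "only_old", "only_new", "note"]
    )
    return report, ok


def write_qc_report(
    qc_rows: Sequence[QCRow],
    path_tsv: str | Path,
    path_xlsx: str | Path | None = None,
) -> pd.DataFrame:
    """Write the QC report as TSV (and optionally XLSX)."""
    table = pd.DataFrame(
        [
            {
                "standard": r.standard,
                "kind": r.kind,
                "n_found": r.n_found,
                "n_injections": r.n_injections,
                "rt_delta_pct": r.rt_delta_pct,
                "response_cv_pct": r.response_cv_pct,
                "worst_abs_ppm": r.worst_abs_ppm,
                "rt_pass": r.rt_pass,
                "response_pass": r.response_pass,
                "ppm_pass": r.ppm_pass,
                "found_pass": r.found_pass,
                "overall_pass": r.overall_pass,
            }
            for r in qc_rows
        ]
    )
    table.to_csv(path_tsv, sep="\t", index=False)
    if path_xlsx is not None:
        table.to_excel(path_xlsx, index=False)
    return table
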