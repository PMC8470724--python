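"""Single-patient statistical selection against the batch.

Screening is an n-of-1 problem: one patient is compared against the
other patients measured in the same analytical batch, which act as the
reference population. Per mass feature:

* duplicate injections of a sample are arithmetically averaged;
* fold change = patient mean / median of the other patients' means
  (denominator floored at the configured intensity floor);
* a robust z-score, (patient - median) / (1.4826 * MAD), with the
  denominator floored at max(1.4826*MAD, 0.05*median, floor) so constant
  references cannot produce infinite scores;
* a two-sided standard-normal tail probability as a descriptive ranking
  aid (no multiple-testing correction — features are triaged, not
  formally tested);
* an "altered" flag when |z|, fold change and intensity clear the
  configured thresholds, with an up/down direction.

Missing-value policy: a feature absent in the patient but observed in at
least half of the reference patients is evaluated at the intensity floor
(so a truly absent metabolite can be flagged as decreased); reference
medians are taken over observed values only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

from .batch_io import ROLE_PATIENT, SessionConfig, Worklist

__all__ = [
    "Thresholds",
    "StatsError",
    "average_duplicates",
    "patient_fold_change",
    "robust_z",
    "p_from_z",
    "select_altered",
    "feature_statistics",
    "MAD_CONSISTENCY",
]

MAD_CONSISTENCY = 1.4826


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class Thresholds:
    """Selection thresholds for the altered-feature flag."""

    z_min: float = 3.0
    fc_up: float = 2.0
    fc_down: float = 0.5
    intensity_floor: float = 1000.0

    def __post_init__(self) -> None:
        if self.z_min <= 0:
            raise StatsError("z_min must be positive")
        if not (self.fc_up >= 1 >= self.fc_down > 0):
            raise StatsError("need fc_up >= 1 >= fc_down > 0")
        if self.intensity_floor <= 0:
            raise StatsError("intensity_floor must be positive")

    @classmethod
    def from_config(cls, config: SessionConfig) -> "Thresholds":
        return cls(
            z_min=config.z_min,
            fc_up=config.fc_up,
            fc_down=config.fc_down,
            intensity_floor=config.intensity_floor,
        )


def average_duplicates(
    matrix: pd.DataFrame, worklist: Worklist
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse injection columns to per-sample means.

    Returns ``(sample_matrix, partial)`` where ``partial`` flags cells
    averaged from some-but-not-all of a sample's injections (a peak was
    missing in one duplicate). Missing everywhere stays NaN.
    """
    if matrix.empty:
        raise StatsError("empty intensity matrix")
    inj_to_sample: dict[str, str] = {}
    for entry in worklist.entries:
        inj_to_sample[entry.injection_id] = entry.sample_id
    unknown = [c for c in matrix.columns if c not in inj_to_sample]
    if unknown:
        raise StatsError(f"matrix columns not in worklist: {unknown}")
    sample_order: list[str] = []
    groups: dict[str, list[str]] = {}
    for column in matrix.columns:
        sample = inj_to_sample[column]
        if sample not in groups:
            groups[sample] = []
            sample_order.append(sample)
        groups[sample].append(column)
    means = {}
    partial = {}
    for sample in sample_order:
        cols = matrix[groups[sample]]
        n_obs = cols.notna().sum(axis=1)
        means[sample] = cols.mean(axis=1, skipna=True)
        partial[sample] = (n_obs > 0) & (n_obs < len(groups[sample]))
    return (
        pd.DataFrame(means, columns=sample_order),
        pd.DataFrame(partial, columns=sample_order),
    )


def p_from_z(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided standard-normal tail probability of a z-score."""
    return erfc(np.abs(z) / math.sqrt(2.0))


def patient_fold_change(
    feature_row: pd.Series, patient_id: str, floor: float = 1000.0
) -> float:
    """Fold change of one sample against the median of the others.

    ``feature_row`` holds per-sample averaged intensities; the reference
    is every other sample in the row. Requires >= 3 observed reference
    values.
    """
    others = feature_row.drop(index=patient_id).dropna()
    if len(others) < 3:
        raise StatsError(
            f"insufficient reference: {len(others)} other samples with values"
        )
    value = feature_row[patient_id]
    if pd.isna(value):
        raise StatsError(f"sample {patient_id} has no value for this feature")
    return float(value) / max(float(others.median()), floor)


def robust_z(
    feature_row: pd.Series, patient_id: str, floor: float = 1000.0
) -> float:
    """Median/MAD robust z-score of one sample against the others."""
    others = feature_row.drop(index=patient_id).dropna()
    if len(others) < 3:
        raise StatsError(
            f"insufficient reference: {len(others)} other samples with values"
        )
    value = float(feature_row[patient_id])
    med = float(others.median())
    mad = float((others - med).abs().median())
    denom = max(MAD_CONSISTENCY * mad, 0.05 * med, floor)
    return (value - med) / denom


def select_altered(stats: pd.DataFrame, thresholds: Thresholds) -> pd.DataFrame:
    """Apply the three-way selection rule to a statistics table.

    Adds/overwrites ``altered`` and ``direction`` columns: a feature is
    altered-up when |z| >= z_min, FC >= fc_up and the patient mean clears
    the intensity floor; altered-down when |z| >= z_min and FC <= fc_down.
    """
    out = stats.copy()
    z_ok = out["z"].abs() >= thresholds.z_min
    up = (
        z_ok
        & (out["fold_change"] >= thresholds.fc_up)
        & (out["patient_mean"] >= thresholds.intensity_floor)
    )
    down = z_ok & (out["fold_change"] <= thresholds.fc_down)
    out["altered"] = (up | down).fillna(False)
    direction = np.where(up, "up", np.where(down, "down", ""))
    out["direction"] = direction
    return out


def feature_statistics(
    sample_matrix: pd.DataFrame,
    worklist: Worklist,
    target_sample: str,
    thresholds: Thresholds,
    partial: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full per-feature statistics of one sample versus the batch.

    ``sample_matrix`` is features x samples (duplicate-averaged). The
    reference population is every *patient* sample except the target, so
    QC pools, blanks and validation plasma never contaminate the
    reference — and a validation sample can itself be the target,
    "processed in identical manner to patient samples".

    Returns a DataFrame indexed by feature_id with columns patient_mean,
    reference_median, n_reference, fold_change, z, p_value, altered,
    direction, status.
    """
    if target_sample not in sample_matrix.columns:
        raise StatsError(f"sample {target_sample!r} not in matrix")
    reference_ids = [
        s
        for s in worklist.samples(ROLE_PATIENT)
        if s != target_sample and s in sample_matrix.columns
    ]
    if len(reference_ids) < 2:
        raise StatsError(
            f"need >= 2 reference patients, have {len(reference_ids)}"
        )
    floor = thresholds.intensity_floor
    ref = sample_matrix[reference_ids]
    n_obs = ref.notna().sum(axis=1)
    med = ref.median(axis=1, skipna=True)
    mad = ref.sub(med, axis=0).abs().median(axis=1, skipna=True)

    patient = sample_matrix[target_sample].astype(float)
    # absent in patient but seen in >= half the reference: evaluate at floor
    imputable = patient.isna() & (n_obs >= math.ceil(len(reference_ids) / 2))
    effective = patient.copy()
    effective[imputable] = floor

    insufficient = n_obs < 3
    usable = effective.notna() & ~insufficient

    fc = pd.Series(np.nan, index=sample_matrix.index)
    z = pd.Series(np.nan, index=sample_matrix.index)
    fc[usable] = effective[usable] / np.maximum(med[usable], floor)
    denom = np.maximum.reduce(
        [MAD_CONSISTENCY * mad[usable], 0.05 * med[usable], np.full(usable.sum(), floor)]
    )
    z[usable] = (effective[usable] - med[usable]) / denom

    status = pd.Series("ok", index=sample_matrix.index)
    status[imputable] = "patient_missing"
    status[patient.isna() & ~imputable] = "missing"
    status[insufficient] = "insufficient_reference"
    if partial is not None and target_sample in partial.columns:
        status[(status == "ok") & partial[target_sample]] = "partial"

    stats = pd.DataFrame(
        {
            "patient_mean": effective,
            "reference_median": med,
            "n_reference": n_obs,
            "fold_change": fc,
            "z": z,
            "p_value": p_from_z(z.to_numpy()),
            "status": status,
        }
    )
    stats.loc[~usable, "p_value"] = np.nan
    stats = select_altered(stats, thresholds)
    stats.loc[~usable, ["altered"]] = False
    return stats
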