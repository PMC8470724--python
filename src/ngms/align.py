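"""Cross-injection mass feature alignment.

Groups per-injection (m/z, RT, intensity) peaks into batch-level mass
features: each feature gets a consensus m/z and retention time (medians
over its members) and a per-injection intensity vector. The grouping is
deterministic and oracle-checkable:

1. sort all peaks by m/z and cut where the gap between neighbours
   exceeds the ppm tolerance (1-D single linkage);
2. within each m/z bin, single-linkage cut on RT gaps larger than the
   RT tolerance;
3. divisive refinement: while any member deviates from the bin median by
   more than the tolerance (in either dimension), split at the largest
   internal gap of that dimension — this guarantees every member of the
   reported feature lies within tolerance of the consensus;
4. one peak per injection per feature: if an injection contributes
   several candidate peaks, the most intense is kept (ties: closest to
   the consensus m/z, then first in input order) and the rest re-enter
   the pool for another grouping round.

Every input peak ends up in exactly one feature. Missing injections stay
missing (no zero-filling); imputation policy belongs to the statistics
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .batch_io import PeakList, Worklist

__all__ = ["AlignedFeature", "align", "to_matrix", "AlignmentError"]


class AlignmentError(ValueError):
    pass


@dataclass
class AlignedFeature:
    """A batch-level mass feature with per-injection intensities."""

    feature_id: str
    consensus_mz: float
    consensus_rt: float
    ion_mode: str
    intensities: dict[str, float]  # injection_id -> intensity
    member_rts: dict[str, float] = field(default_factory=dict)
    member_mzs: dict[str, float] = field(default_factory=dict)

    @property
    def support(self) -> int:
        return len(self.intensities)


def _gap_split(order: np.ndarray, values: np.ndarray, is_over: callable) -> list[np.ndarray]:
    """Cut a sorted index array wherever consecutive values violate ``is_over``."""
    if len(order) == 0:
        return []
    cuts = [0]
    v = values[order]
    for i in range(1, len(order)):
        if is_over(v[i - 1], v[i]):
            cuts.append(i)
    cuts.append(len(order))
    return [order[cuts[i]:cuts[i + 1]] for i in range(len(cuts) - 1)]


def _refine(
    idx: np.ndarray, mz: np.ndarray, rt: np.ndarray, mz_tol: float, rt_tol: float
) -> list[np.ndarray]:
    """Split a candidate group until every member is within tolerance of
    the group median in both m/z (ppm) and RT (minutes)."""
    idx = idx[np.lexsort((rt[idx], mz[idx]))]
    med_mz = float(np.median(mz[idx]))
    dev_ppm = np.abs(mz[idx] - med_mz) / med_mz * 1e6
    if dev_ppm.max() > mz_tol and len(idx) > 1:
        by_mz = idx[np.argsort(mz[idx], kind="stable")]
        gaps = np.diff(mz[by_mz])
        cut = int(np.argmax(gaps)) + 1
        out = []
        for part in (by_mz[:cut], by_mz[cut:]):
            out.extend(_refine(part, mz, rt, mz_tol, rt_tol))
        return out
    med_rt = float(np.median(rt[idx]))
    dev_rt = np.abs(rt[idx] - med_rt)
    if dev_rt.max() > rt_tol and len(idx) > 1:
        by_rt = idx[np.argsort(rt[idx], kind="stable")]
        gaps = np.diff(rt[by_rt])
        cut = int(np.argmax(gaps)) + 1
        out = []
        for part in (by_rt[:cut], by_rt[cut:]):
            out.extend(_refine(part, mz, rt, mz_tol, rt_tol))
        return out
    return [idx]


def _cluster_round(
    idx: np.ndarray, mz: np.ndarray, rt: np.ndarray, mz_tol: float, rt_tol: float
) -> list[np.ndarray]:
    """One grouping pass: m/z linkage, RT linkage, divisive refinement."""
    by_mz = idx[np.argsort(mz[idx], kind="stable")]
    groups: list[np.ndarray] = []
    for mz_bin in _gap_split(
        by_mz, mz, lambda a, b: (b - a) / a * 1e6 > mz_tol
    ):
        by_rt = mz_bin[np.argsort(rt[mz_bin], kind="stable")]
        for rt_bin in _gap_split(by_rt, rt, lambda a, b: b - a > rt_tol):
            groups.extend(_refine(rt_bin, mz, rt, mz_tol, rt_tol))
    return groups


def align(
    peaklists: Sequence[PeakList],
    mz_tol: float,
    rt_tol: float,
) -> list[AlignedFeature]:
    """Group peaks from many injections into aligned features.

    All peak lists must share one ion mode; tolerances must be positive.
    Features are returned sorted by (consensus m/z, consensus RT) with
    ids ``<mode-prefix>F000001``...
    """
    if mz_tol <= 0 or rt_tol <= 0:
        raise AlignmentError("tolerances must be positive")
    non_empty = [pl for pl in peaklists if len(pl)]
    if not non_empty:
        raise AlignmentError("need at least one non-empty peak list")
    modes = {pl.ion_mode for pl in peaklists}
    if len(modes) != 1:
        raise AlignmentError(f"mixed ion modes in alignment input: {sorted(modes)}")
    mode = modes.pop()

    mz_parts, rt_parts, int_parts, inj_parts = [], [], [], []
    for pl in non_empty:
        mz_parts.append(pl.peaks["mz"].to_numpy(float))
        rt_parts.append(pl.peaks["rt"].to_numpy(float))
        int_parts.append(pl.peaks["intensity"].to_numpy(float))
        inj_parts.extend([pl.injection_id] * len(pl))
    mz = np.concatenate(mz_parts)
    rt = np.concatenate(rt_parts)
    intensity = np.concatenate(int_parts)
    injections = np.array(inj_parts)

    members: list[np.ndarray] = []
    pool = np.arange(len(mz))
    while len(pool):
        leftovers: list[int] = []
        for group in _cluster_round(pool, mz, rt, mz_tol, rt_tol):
            med_mz = float(np.median(mz[group]))
            kept: dict[str, int] = {}
            for peak in group:
                inj = injections[peak]
                if inj not in kept:
                    kept[inj] = peak
                    continue
                other = kept[inj]
                # keep the more intense; ties -> closer to consensus m/z,
                # then earlier input order
                key_new = (
                    -intensity[peak],
                    abs(mz[peak] - med_mz),
                    peak,
                )
                key_old = (
                    -intensity[other],
                    abs(mz[other] - med_mz),
                    other,
                )
                if key_new < key_old:
                    kept[inj] = peak
                    leftovers.append(other)
                else:
                    leftovers.append(peak)
            # dedup moves the median: re-refine the kept set so every
            # member stays within tolerance of its feature consensus
            kept_idx = np.array(sorted(kept.values()))
            members.extend(_refine(kept_idx, mz, rt, mz_tol, rt_tol))
        pool = np.array(sorted(leftovers), dtype=int)

    # deterministic output order and ids
    order = sorted(
        range(len(members)),
        key=lambda i: (
            float(np.median(mz[members[i]])),
            float(np.median(rt[members[i]])),
        ),
    )
    prefix = "P" if mode == "positive" else "N"
    features = []
    for rank, i in enumerate(order, start=1):
        group = members[i]
        features.append(
            AlignedFeature(
                feature_id=f"{prefix}F{rank:06d}",
                consensus_mz=float(np.median(mz[group])),
                consensus_rt=float(np.median(rt[group])),
                ion_mode=mode,
                intensities={injections[p]: float(intensity[p]) for p in group},
                member_rts={injections[p]: float(rt[p]) for p in group},
                member_mzs={injections[p]: float(mz[p]) for p in group},
            )
        )
    return features


def to_matrix(
    features: Sequence[AlignedFeature], worklist: Worklist
) -> pd.DataFrame:
    """Features x injections intensity matrix (NaN = not detected).

    Columns follow worklist order for the features' ion mode; raising if
    a feature carries an injection the worklist does not know.
    """
    if not features:
        return pd.DataFrame()
    mode = features[0].ion_mode
    columns = [e.injection_id for e in worklist.for_mode(mode).entries]
    known = set(columns)
    for feature in features:
        stray = set(feature.intensities) - known
        if stray:
            raise AlignmentError(
                f"feature {feature.feature_id} references injections not in "
                f"worklist: {sorted(stray)}"
            )
    data = {
        f.feature_id: [f.intensities.get(c, np.nan) for c in columns]
        for f in features
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=columns
    ).rename_axis("feature_id")
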