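"""Brute-force reference implementations used to cross-check the
package's optimized operations. Deliberately naive: union-find over all
pairs, linear scans, per-record predicate evaluation."""

from __future__ import annotations

import math
from statistics import median


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)

    def components(self, items) -> list[list]:
        groups: dict[int, list] = {}
        for item in items:
            groups.setdefault(self.find(item), []).append(item)
        return [sorted(g) for g in groups.values()]


def _linkage_components(indices, value, linked) -> list[list[int]]:
    """Connected components of the pairwise-linkage graph (brute force)."""
    idx = sorted(indices)
    pos = {p: i for i, p in enumerate(idx)}
    uf = UnionFind(len(idx))
    for a in idx:
        for b in idx:
            if a < b and linked(value(a), value(b)):
                uf.union(pos[a], pos[b])
    return [[idx[i] for i in comp] for comp in uf.components(range(len(idx)))]


def _refine_oracle(group, mz, rt, mz_tol, rt_tol) -> list[list[int]]:
    group = sorted(group, key=lambda p: (mz[p], rt[p]))
    med_mz = median(mz[p] for p in group)
    if (
        max(abs(mz[p] - med_mz) / med_mz * 1e6 for p in group) > mz_tol
        and len(group) > 1
    ):
        by_mz = sorted(group, key=lambda p: mz[p])
        gaps = [mz[by_mz[i + 1]] - mz[by_mz[i]] for i in range(len(by_mz) - 1)]
        cut = gaps.index(max(gaps)) + 1
        return _refine_oracle(by_mz[:cut], mz, rt, mz_tol, rt_tol) + _refine_oracle(
            by_mz[cut:], mz, rt, mz_tol, rt_tol
        )
    med_rt = median(rt[p] for p in group)
    if max(abs(rt[p] - med_rt) for p in group) > rt_tol and len(group) > 1:
        by_rt = sorted(group, key=lambda p: rt[p])
        gaps = [rt[by_rt[i + 1]] - rt[by_rt[i]] for i in range(len(by_rt) - 1)]
        cut = gaps.index(max(gaps)) + 1
        return _refine_oracle(by_rt[:cut], mz, rt, mz_tol, rt_tol) + _refine_oracle(
            by_rt[cut:], mz, rt, mz_tol, rt_tol
        )
    return [group]


def align_oracle(mz, rt, intensity, injection, mz_tol, rt_tol):
    """Reference peak partition: pairwise single-linkage components in
    m/z, then RT within each component, divisive refinement, and
    injection dedup with leftover re-pooling. Returns a set of frozensets
    of peak indices."""
    features: list[list[int]] = []
    pool = list(range(len(mz)))
    while pool:
        clusters: list[list[int]] = []
        for mz_comp in _linkage_components(
            pool, lambda p: mz[p], lambda a, b: abs(b - a) / min(a, b) * 1e6 <= mz_tol
        ):
            for rt_comp in _linkage_components(
                mz_comp, lambda p: rt[p], lambda a, b: abs(b - a) <= rt_tol
            ):
                clusters.extend(_refine_oracle(rt_comp, mz, rt, mz_tol, rt_tol))
        leftovers: list[int] = []
        for cluster in clusters:
            med_mz = median(mz[p] for p in cluster)
            best: dict[str, int] = {}
            for p in cluster:
                inj = injection[p]
                if inj not in best:
                    best[inj] = p
                    continue
                q = best[inj]
                key_p = (-intensity[p], abs(mz[p] - med_mz), p)
                key_q = (-intensity[q], abs(mz[q] - med_mz), q)
                if key_p < key_q:
                    best[inj] = p
                    leftovers.append(q)
                else:
                    leftovers.append(p)
            features.extend(
                _refine_oracle(sorted(best.values()), mz, rt, mz_tol, rt_tol)
            )
        pool = sorted(leftovers)
    return {frozenset(f) for f in features}


def match_mz_oracle(observed, ions, tolerance):
    """Exhaustive scan over all candidate ions."""
    hits = []
    for ion in ions:
        err = (observed - ion.mz) / ion.mz * 1e6
        if abs(err) <= tolerance:
            hits.append((ion, err))
    hits.sort(key=lambda pair: (abs(pair[1]), pair[0].mz, pair[0].compound_id))
    return hits


def annotate_panel_oracle(feature, panel, mz_tol, rt_tol, registry):
    """Exhaustive double filter: ppm gate AND retention-time gate."""
    from ngms.chem import ion_mz

    hits = []
    for entry in panel:
        expected = entry.expected_rt.get(feature.ion_mode)
        if expected is None:
            continue
        for adduct_name in entry.allowed_adducts:
            adduct = registry[adduct_name]
            if adduct.polarity != feature.ion_mode:
                continue
            for k in range(entry.max_isotope + 1):
                theo = ion_mz(entry.formula.mass, adduct, k)
                err = (feature.consensus_mz - theo) / theo * 1e6
                if abs(err) <= mz_tol and abs(feature.consensus_rt - expected) <= rt_tol:
                    hits.append((entry.name, adduct.name, k))
    return sorted(hits)


def annotate_library_oracle(feature, library, mz_tol, registry):
    from ngms.chem import ion_mz

    hits = []
    for record in library:
        for adduct in registry.values():
            if adduct.polarity != feature.ion_mode:
                continue
            for k in range(2):
                theo = ion_mz(record.formula.mass, adduct, k)
                err = (feature.consensus_mz - theo) / theo * 1e6
                if abs(err) <= mz_tol:
                    hits.append((record.id, adduct.name, k))
    return sorted(hits)


def filter_oracle(records, spec):
    """Evaluate every FilterSpec predicate independently per record."""
    out = []
    for r in records:
        checks = []
        if spec.rt_range is not None:
            checks.append(spec.rt_range[0] <= r.rt <= spec.rt_range[1])
        if spec.mz_range is not None:
            checks.append(spec.mz_range[0] <= r.mz <= spec.mz_range[1])
        if spec.max_p_value is not None:
            checks.append(r.p_value <= spec.max_p_value)
        if spec.min_abs_fold_change is not None:
            x = spec.min_abs_fold_change
            checks.append(r.fold_change >= x or r.fold_change <= 1.0 / x)
        if spec.annotation_level is not None:
            checks.append(any(a.level == spec.annotation_level for a in r.annotations))
        if spec.require_panel:
            checks.append(any(a.level == "panel" for a in r.annotations))
        if spec.require_altered:
            checks.append(r.altered)
        if spec.direction is not None:
            checks.append(r.direction == spec.direction)
        if spec.ion_mode is not None:
            checks.append(r.ion_mode == spec.ion_mode)
        if all(checks):
            out.append(r)
    return out
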