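"""Two-tier metabolite annotation and adduct/isotopologue grouping.

High-confidence annotation requires agreement in *both* m/z (ppm) and
retention time against the diagnostic panel, whose retention times are
known on the local chromatographic setup. Everything else can only be
annotated by m/z against a compound library (HMDB-style extract), at
lower confidence — one feature may collect many isobaric candidates.

A CAMERA-like grouping step relates co-eluting features that are
different ionic species of one neutral molecule: two features are linked
whenever, under some registered (adduct, 13C-isotopologue) assignment,
they imply the same neutral mass within the ppm tolerance.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import chem
from .align import AlignedFeature
from .chem import (
    AdductSpec,
    C13_MASS_DELTA,
    DEFAULT_ADDUCTS,
    ElementalFormula,
    TheoreticalIon,
    get_adduct,
    ion_mz,
    ppm_error,
)

__all__ = [
    "PanelEntry",
    "CompoundRecord",
    "Annotation",
    "AnnotationError",
    "IonIndex",
    "build_ion_index",
    "annotate_panel",
    "annotate_library",
    "group_related_features",
    "AdductGroup",
    "read_panel",
    "write_panel",
    "read_library",
    "write_library",
]


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class PanelEntry:
    """A diagnostic-panel metabolite with setup-specific retention times."""

    name: str
    formula: ElementalFormula
    hmdb_id: str
    expected_rt: Mapping[str, float]  # ion mode -> minutes
    allowed_adducts: tuple[str, ...] = ("M+H", "M-H")
    max_isotope: int = 1

    def __post_init__(self) -> None:
        if not self.expected_rt:
            raise AnnotationError(
                f"panel entry {self.name!r} needs an expected RT in >= 1 mode"
            )
        if self.max_isotope < 0:
            raise AnnotationError("max_isotope must be >= 0")

    @property
    def neutral_mass(self) -> float:
        return self.formula.mass


@dataclass(frozen=True)
class CompoundRecord:
    """A library compound: m/z-only annotation, no retention time."""

    id: str
    name: str
    formula: ElementalFormula

    @property
    def neutral_mass(self) -> float:
        return self.formula.mass


@dataclass(frozen=True)
class Annotation:
    """A (feature, compound, adduct, isotopologue) assignment."""

    feature_id: str
    level: str  # "panel" | "mz_only"
    compound_id: str
    compound_name: str
    adduct_name: str
    isotope_index: int
    ppm_error: float
    theoretical_mz: float
    rt_delta: float | None = None  # minutes, panel level only

    def __post_init__(self) -> None:
        if self.level not in ("panel", "mz_only"):
            raise AnnotationError(f"unknown annotation level {self.level!r}")
        if self.level == "mz_only" and self.rt_delta is not None:
            raise AnnotationError("m/z-only annotations carry no rt_delta")


class IonIndex:
    """Sorted theoretical-ion index with ppm-window lookup."""

    def __init__(
        self,
        ions: Sequence[TheoreticalIon],
        entries: Mapping[str, object] | None = None,
        ion_mode: str = "positive",
    ):
        self.ions = sorted(ions, key=lambda ion: (ion.mz, ion.compound_id))
        self._mzs = [ion.mz for ion in self.ions]
        self.entries = dict(entries or {})  # compound_id -> PanelEntry/CompoundRecord
        self.ion_mode = ion_mode

    def __len__(self) -> int:
        return len(self.ions)

    def query(self, observed: float, tolerance: float) -> list[tuple[TheoreticalIon, float]]:
        tol = tolerance * 1e-6
        lo = bisect.bisect_left(self._mzs, observed / (1.0 + tol))
        hi = bisect.bisect_right(self._mzs, observed / (1.0 - tol))
        hits = []
        for ion in self.ions[lo:hi]:
            err = ppm_error(observed, ion.mz)
            if abs(err) <= tolerance:
                hits.append((ion, err))
        hits.sort(key=lambda pair: (abs(pair[1]), pair[0].isotope_index, pair[0].mz, pair[0].compound_id))
        return hits


def build_ion_index(
    compounds: Sequence[PanelEntry | CompoundRecord],
    ion_mode: str,
    adducts: Mapping[str, AdductSpec] | None = None,
    max_isotope: int = 1,
) -> IonIndex:
    """Predict one ion per (compound, mode-compatible adduct, isotopologue).

    Panel entries contribute only in modes where they have an expected RT
    and only via their allowed adducts; library compounds are tried
    against every registered adduct of the requested polarity.
    """
    if not compounds:
        raise AnnotationError("empty compound list")
    registry = DEFAULT_ADDUCTS if adducts is None else adducts
    ions: list[TheoreticalIon] = []
    entries: dict[str, object] = {}
    for compound in compounds:
        if isinstance(compound, PanelEntry):
            if ion_mode not in compound.expected_rt:
                continue
            names = compound.allowed_adducts
            n_iso = compound.max_isotope
            cid = compound.hmdb_id or compound.name
        else:
            names = tuple(registry)
            n_iso = max_isotope
            cid = compound.id
        try:
            mass = compound.neutral_mass
        except chem.FormulaError as err:
            raise AnnotationError(f"compound {cid!r}: {err}") from err
        entries[cid] = compound
        for adduct_name in names:
            adduct = get_adduct(adduct_name, registry)
            if adduct.polarity != ion_mode:
                continue
            for k in range(n_iso + 1):
                ions.append(
                    TheoreticalIon(cid, adduct.name, k, ion_mz(mass, adduct, k))
                )
    return IonIndex(ions, entries, ion_mode)


def annotate_panel(
    feature: AlignedFeature,
    panel_index: IonIndex,
    mz_tol: float,
    rt_tol: float,
) -> list[Annotation]:
    """Panel annotations: m/z within ppm tolerance AND RT within window.

    Sorted by absolute ppm error, then isotope index.
    """
    out = []
    for ion, err in panel_index.query(feature.consensus_mz, mz_tol):
        entry: PanelEntry = panel_index.entries[ion.compound_id]
        expected = entry.expected_rt.get(feature.ion_mode)
        if expected is None:
            continue
        rt_delta = feature.consensus_rt - expected
        if abs(rt_delta) <= rt_tol:
            out.append(
                Annotation(
                    feature_id=feature.feature_id,
                    level="panel",
                    compound_id=ion.compound_id,
                    compound_name=entry.name,
                    adduct_name=ion.adduct_name,
                    isotope_index=ion.isotope_index,
                    ppm_error=err,
                    theoretical_mz=ion.mz,
                    rt_delta=rt_delta,
                )
            )
    out.sort(key=lambda a: (abs(a.ppm_error), a.isotope_index, a.compound_id))
    return out


def annotate_library(
    feature: AlignedFeature,
    library_index: IonIndex,
    mz_tol: float,
) -> list[Annotation]:
    """m/z-only library annotations; possibly many per feature."""
    out = []
    for ion, err in library_index.query(feature.consensus_mz, mz_tol):
        record = library_index.entries[ion.compound_id]
        out.append(
            Annotation(
                feature_id=feature.feature_id,
                level="mz_only",
                compound_id=ion.compound_id,
                compound_name=getattr(record, "name", ion.compound_id),
                adduct_name=ion.adduct_name,
                isotope_index=ion.isotope_index,
                ppm_error=err,
                theoretical_mz=ion.mz,
            )
        )
    out.sort(key=lambda a: (abs(a.ppm_error), a.isotope_index, a.compound_id))
    return out


@dataclass
class AdductGroup:
    """Co-eluting features interpreted as ionic species of one molecule."""

    group_id: int
    members: list[tuple[str, str | None, int | None, float | None]]
    # (feature_id, adduct_name, isotope_index, inferred_neutral_mass)

    @property
    def feature_ids(self) -> list[str]:
        return [m[0] for m in self.members]


def _neutral_candidates(
    mz: float, registry: Mapping[str, AdductSpec], ion_mode: str, max_isotope: int
) -> list[tuple[str, int, float]]:
    out = []
    for adduct in registry.values():
        if adduct.polarity != ion_mode:
            continue
        for k in range(max_isotope + 1):
            mass = (mz * adduct.charge - adduct.mass_shift - k * C13_MASS_DELTA) / (
                adduct.molecule_multiplier
            )
            if mass > 0:
                out.append((adduct.name, k, mass))
    return out


def group_related_features(
    features: Sequence[AlignedFeature],
    rt_window: float,
    mz_tol: float,
    adducts: Mapping[str, AdductSpec] | None = None,
    max_isotope: int = 1,
) -> list[AdductGroup]:
    """Group co-eluting features whose m/z differences match registered
    adduct/isotopologue deltas.

    Two features join one group when they co-elute within ``rt_window``
    and some pair of candidate (adduct, isotope) assignments implies the
    same neutral mass within ``mz_tol`` ppm. Features with no such
    partner form singleton groups with an undetermined assignment.
    """
    registry = DEFAULT_ADDUCTS if adducts is None else adducts
    modes = {f.ion_mode for f in features}
    if len(modes) > 1:
        raise AnnotationError("grouping requires a single ion mode")
    feats = sorted(features, key=lambda f: (f.consensus_mz, f.consensus_rt))
    candidates = [
        _neutral_candidates(f.consensus_mz, registry, f.ion_mode, max_isotope)
        for f in feats
    ]

    parent = list(range(len(feats)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            if abs(feats[i].consensus_rt - feats[j].consensus_rt) > rt_window:
                continue
            linked = any(
                abs(ai[2] - aj[2]) / aj[2] * 1e6 <= mz_tol
                for ai in candidates[i]
                for aj in candidates[j]
            )
            if linked:
                union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(feats)):
        clusters.setdefault(find(i), []).append(i)
    groups = []
    for gid, idxs in enumerate(sorted(clusters.values(), key=lambda c: c[0]), start=1):
        members: list[tuple[str, str | None, int | None, float | None]] = []
        if len(idxs) == 1:
            members.append((feats[idxs[0]].feature_id, None, None, None))
            groups.append(AdductGroup(group_id=gid, members=members))
            continue
        # consensus neutral mass = the candidate-mass cluster explaining the
        # most members; ties prefer the interpretation with the fewest 13C
        # substitutions (monoisotopic reading), then the lower mass
        pool = [
            (i, name, k, m) for i in idxs for (name, k, m) in candidates[i]
        ]
        best_mass, best_score = None, (-1, 0, 0.0)
        for _, _, _, m0 in pool:
            supporters: dict[int, int] = {}
            for i, _, k, m in pool:
                if abs(m - m0) / m0 * 1e6 <= mz_tol:
                    supporters[i] = min(k, supporters.get(i, k))
            score = (len(supporters), -sum(supporters.values()), -m0)
            if score > best_score:
                best_score, best_mass = score, m0
        for i in sorted(idxs):
            viable = [
                (abs(m - best_mass), k, name, m)
                for (name, k, m) in candidates[i]
                if abs(m - best_mass) / best_mass * 1e6 <= mz_tol
            ]
            if viable:
                _, k, name, m = min(viable)
                members.append((feats[i].feature_id, name, k, m))
            else:
                members.append((feats[i].feature_id, None, None, None))
        groups.append(AdductGroup(group_id=gid, members=members))
    return groups


# ---------------------------------------------------------------------------
# Panel / library TSV I/O


def write_panel(panel: Sequence[PanelEntry], path: str | Path) -> None:
    rows = []
    for e in panel:
        rows.append(
            {
                "name": e.name,
                "formula": str(e.formula),
                "hmdb_id": e.hmdb_id,
                "rt_pos": e.expected_rt.get("positive", ""),
                "rt_neg": e.expected_rt.get("negative", ""),
                "adducts": ";".join(e.allowed_adducts),
                "max_isotope": e.max_isotope,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> list[PanelEntry]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in table.iterrows():
        expected_rt = {}
        for key, mode in (("rt_pos", "positive"), ("rt_neg", "negative")):
            value = row.get(key)
            if pd.notna(value) and str(value).strip():
                expected_rt[mode] = float(value)
        out.append(
            PanelEntry(
                name=row["name"],
                formula=ElementalFormula.parse(row["formula"]),
                hmdb_id=row["hmdb_id"],
                expected_rt=expected_rt,
                allowed_adducts=tuple(
                    a for a in str(row["adducts"]).split(";") if a
                ),
                max_isotope=int(row.get("max_isotope") or 1),
            )
        )
    return out


def write_library(library: Sequence[CompoundRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"id": c.id, "name": c.name, "formula": str(c.formula)} for c in library]
    ).to_csv(path, sep="\t", index=False)


def read_library(path: str | Path) -> list[CompoundRecord]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return [
        CompoundRecord(
            id=row["id"],
            name=row["name"],
            formula=ElementalFormula.parse(row["formula"]),
        )
        for _, row in table.iterrows()
    ]
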