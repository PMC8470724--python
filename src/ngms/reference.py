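"""Shipped demonstration panel, compound library and QC standards.

The production diagnostic panel (hundreds of metabolites with locally
calibrated retention times) is laboratory-specific; the package ships a
small demonstration panel instead, containing the long-chain
acylcarnitines that characterize VLCAD deficiency plus the validation
plasma spike compounds, and accepts any user panel TSV.

Retention times for the acylcarnitines follow the reversed-phase
elution order observed on a UHPLC setup (long-chain species late,
13.4-15.1 min). The polar validation compounds are given plausible
early retention times (0.6-5.3 min); these are simulator conventions,
not measured values. The library adds ~20 abundant plasma metabolites
acting as annotation background.
"""

from __future__ import annotations

from typing import Sequence

from .annotate import CompoundRecord, PanelEntry
from .chem import ElementalFormula
from .quality import StandardDef

__all__ = [
    "ACYLCARNITINES",
    "VALIDATION_COMPOUNDS",
    "BACKGROUND_COMPOUNDS",
    "VLCADD_FOLDS",
    "demo_panel",
    "demo_library",
    "demo_standards",
    "validation_spike_list",
]

# Long-chain acylcarnitine species perturbed in VLCAD deficiency:
# (name, formula, HMDB id, RT [min], allowed positive adducts)
ACYLCARNITINES: list[tuple[str, str, str, float, tuple[str, ...]]] = [
    ("Tetradecenoylcarnitine (C14:1)", "C21H39NO4", "HMDB0002014", 13.37, ("M+H",)),
    ("Dodecanoylcarnitine (C12:0)", "C19H37NO4", "HMDB0002250", 12.24, ("M+H", "M+Na")),
    ("Tetradecadienylcarnitine (C14:2)", "C21H37NO4", "HMDB0013331", 12.82, ("M+H",)),
    ("Myristoylcarnitine (C14:0)", "C21H41NO4", "HMDB0005066", 13.82, ("M+H",)),
    ("Hexadecenoylcarnitine (C16:1)", "C23H43NO4", "HMDB0013207", 14.08, ("M+H",)),
    ("Palmitoylcarnitine (C16:0)", "C23H45NO4", "HMDB0000222", 14.52, ("M+H", "M+Na")),
    ("Linoleylcarnitine (C18:2)", "C25H45NO4", "HMDB0006469", 14.32, ("M+H",)),
    ("Oleylcarnitine (C18:1)", "C25H47NO4", "HMDB0013338", 14.69, ("M+H",)),
    ("Stearoylcarnitine (C18:0)", "C25H49NO4", "HMDB0000848", 15.08, ("M+H",)),
]

#: Fold changes of the nine acylcarnitines in the VLCADD case scenario,
#: in the same order as ``ACYLCARNITINES``.
VLCADD_FOLDS: dict[str, float] = {
    "Tetradecenoylcarnitine (C14:1)": 407.936,
    "Dodecanoylcarnitine (C12:0)": 51.387,
    "Tetradecadienylcarnitine (C14:2)": 156.804,
    "Myristoylcarnitine (C14:0)": 354.890,
    "Hexadecenoylcarnitine (C16:1)": 1227.147,
    "Palmitoylcarnitine (C16:0)": 59.362,
    "Linoleylcarnitine (C18:2)": 66.594,
    "Oleylcarnitine (C18:1)": 74.586,
    "Stearoylcarnitine (C18:0)": 29.269,
}

# Validation plasma spikes: (name, formula, HMDB id, RT [min],
# positive adducts, negative adducts, expected modes)
VALIDATION_COMPOUNDS: list[
    tuple[str, str, str, float, tuple[str, ...], tuple[str, ...], tuple[str, ...]]
] = [
    ("Dihydrouracil", "C4H6N2O2", "HMDB0000076", 1.10, ("M+H",), (), ("positive",)),
    ("Ornithine", "C5H12N2O2", "HMDB0000214", 0.80, ("M+H", "M+Na"), (), ("positive",)),
    ("Xanthine", "C5H4N4O2", "HMDB0000292", 2.40, ("M+H", "M+Na"), ("M-H",), ("positive", "negative")),
    ("Pimelic acid", "C7H12O4", "HMDB0000857", 5.30, ("M+H", "M+Na"), ("M-H",), ("positive", "negative")),
    ("L-Phenylalanine", "C9H11NO2", "HMDB0000159", 3.60, ("M+H", "M+Na"), ("M-H",), ("positive", "negative")),
    ("L-Tyrosine", "C9H11NO3", "HMDB0000158", 2.90, ("M+H", "M+Na"), ("M-H",), ("positive", "negative")),
    ("N-Acetylmannosamine", "C8H15NO6", "HMDB0001129", 1.60, ("M+Na",), ("M+Cl",), ("positive", "negative")),
    ("gamma-Glutamylphenylalanine", "C14H18N2O5", "HMDB0000594", 4.70, ("M+H",), ("M-H",), ("positive", "negative")),
    ("L-Palmitoylcarnitine", "C23H45NO4", "HMDB0000222", 14.52, ("M+H", "M+Na"), (), ("positive",)),
    ("Mesaconic acid", "C5H6O4", "HMDB0000749", 4.20, (), ("M-H",), ("negative",)),
]

# Abundant plasma metabolites used as annotation/alignment background:
# (name, formula, HMDB-style id, RT [min], positive adducts, negative adducts)
BACKGROUND_COMPOUNDS: list[
    tuple[str, str, str, float, tuple[str, ...], tuple[str, ...]]
] = [
    ("Creatinine", "C4H7N3O", "HMDB0000562", 0.90, ("M+H",), ()),
    ("D-Glucose", "C6H12O6", "HMDB0000122", 1.20, ("M+Na",), ("M-H",)),
    ("L-Alanine", "C3H7NO2", "HMDB0000161", 0.70, ("M+H",), ()),
    ("L-Leucine", "C6H13NO2", "HMDB0000687", 3.20, ("M+H",), ()),
    ("L-Valine", "C5H11NO2", "HMDB0000883", 2.10, ("M+H",), ()),
    ("L-Tryptophan", "C11H12N2O2", "HMDB0000929", 4.40, ("M+H",), ("M-H",)),
    ("Uric acid", "C5H4N4O3", "HMDB0000289", 1.90, (), ("M-H",)),
    ("Citric acid", "C6H8O7", "HMDB0000094", 1.40, (), ("M-H",)),
    ("L-Lactic acid", "C3H6O3", "HMDB0000190", 1.00, (), ("M-H",)),
    ("Hippuric acid", "C9H9NO3", "HMDB0000714", 5.10, ("M+H",), ("M-H",)),
    ("Caffeine", "C8H10N4O2", "HMDB0001847", 6.20, ("M+H",), ()),
    ("Cortisol", "C21H30O5", "HMDB0000063", 9.50, ("M+H",), ("M-H",)),
    ("Taurine", "C2H7NO3S", "HMDB0000251", 0.60, (), ("M-H",)),
    ("L-Glutamine", "C5H10N2O3", "HMDB0000641", 0.85, ("M+H",), ()),
    ("L-Carnitine", "C7H15NO3", "HMDB0000062", 0.65, ("M+H",), ()),
    ("Acetylcarnitine", "C9H17NO4", "HMDB0000201", 1.80, ("M+H",), ()),
    ("Uridine", "C9H12N2O6", "HMDB0000296", 2.20, (), ("M-H",)),
    ("L-Kynurenine", "C10H12N2O3", "HMDB0000684", 3.90, ("M+H",), ()),
    ("Choline", "C5H13NO", "HMDB0000097", 0.55, ("M+H",), ()),
    ("Succinic acid", "C4H6O4", "HMDB0000254", 2.60, (), ("M-H",)),
]


def demo_panel() -> list[PanelEntry]:
    """Demonstration diagnostic panel: acylcarnitines + validation spikes."""
    entries: list[PanelEntry] = []
    for name, formula, hmdb, rt, adducts in ACYLCARNITINES:
        entries.append(
            PanelEntry(
                name=name,
                formula=ElementalFormula.parse(formula),
                hmdb_id=hmdb,
                expected_rt={"positive": rt},
                allowed_adducts=adducts,
                max_isotope=1,
            )
        )
    for name, formula, hmdb, rt, pos, neg, modes in VALIDATION_COMPOUNDS:
        if name == "L-Palmitoylcarnitine":
            continue  # already present as Palmitoylcarnitine (C16:0)
        expected_rt = {}
        if "positive" in modes:
            expected_rt["positive"] = rt
        if "negative" in modes:
            expected_rt["negative"] = rt
        entries.append(
            PanelEntry(
                name=name,
                formula=ElementalFormula.parse(formula),
                hmdb_id=hmdb,
                expected_rt=expected_rt,
                allowed_adducts=pos + neg,
                max_isotope=1,
            )
        )
    return entries


def demo_library() -> list[CompoundRecord]:
    """Demonstration compound library: panel compounds + plasma background."""
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for entry in demo_panel():
        if entry.hmdb_id in seen:
            continue
        seen.add(entry.hmdb_id)
        records.append(
            CompoundRecord(id=entry.hmdb_id, name=entry.name, formula=entry.formula)
        )
    for name, formula, hmdb, _rt, _pos, _neg in BACKGROUND_COMPOUNDS:
        if hmdb in seen:
            continue
        seen.add(hmdb)
        records.append(
            CompoundRecord(id=hmdb, name=name, formula=ElementalFormula.parse(formula))
        )
    return records


def demo_standards() -> list[StandardDef]:
    """Demonstration QC standards.

    External standards are evaluated on the QC-pool injections; the
    internal stand-ins are endogenous compounds expected in every
    injection of their mode.
    """
    return [
        StandardDef(
            name="L-Phenylalanine",
            formula=ElementalFormula.parse("C9H11NO2"),
            adduct_name="M+H",
            ion_mode="positive",
            expected_rt=3.60,
            kind="external",
        ),
        StandardDef(
            name="L-Tyrosine",
            formula=ElementalFormula.parse("C9H11NO3"),
            adduct_name="M+H",
            ion_mode="positive",
            expected_rt=2.90,
            kind="external",
        ),
        StandardDef(
            name="Mesaconic acid",
            formula=ElementalFormula.parse("C5H6O4"),
            adduct_name="M-H",
            ion_mode="negative",
            expected_rt=4.20,
            kind="external",
        ),
        StandardDef(
            name="Creatinine",
            formula=ElementalFormula.parse("C4H7N3O"),
            adduct_name="M+H",
            ion_mode="positive",
            expected_rt=0.90,
            kind="internal",
        ),
        StandardDef(
            name="Uric acid",
            formula=ElementalFormula.parse("C5H4N4O3"),
            adduct_name="M-H",
            ion_mode="negative",
            expected_rt=1.90,
            kind="internal",
        ),
    ]


def validation_spike_list() -> list[tuple[str, tuple[str, ...]]]:
    """(panel name, expected modes) of the validation plasma spikes."""
    out = []
    for name, _f, _h, _rt, _pos, _neg, modes in VALIDATION_COMPOUNDS:
        panel_name = (
            "Palmitoylcarnitine (C16:0)" if name == "L-Palmitoylcarnitine" else name
        )
        out.append((panel_name, modes))
    return out
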