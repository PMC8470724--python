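"""Deterministic simulator of a screening batch.

Replaces the mass spectrometer for testing: given a compound set with
known formulas, adducts and retention times, it emits one centroided
peak list per injection plus the worklist and a ground-truth table, so
every downstream stage (alignment, annotation, statistics, QC gates)
can be exercised against known answers.

Noise model
-----------
* biological variation: one log-normal factor per (sample, compound),
  shared by that sample's duplicate injections (sigma = the compound's
  ``log_sigma``, default the spec-wide ``intensity_lognormal_sigma``);
* technical variation: an independent log-normal factor per injection
  with sigma one third of the biological sigma, so duplicate averaging
  is meaningful;
* m/z read with ppm-scale Gaussian noise, RT with Gaussian jitter;
* the first 13C isotopologue at a fixed fraction (default 0.20) of the
  monoisotopic peak; adducts at fixed relative abundances;
* peaks dropped independently with ``dropout_rate``.

Spiked (sample, compound) pairs — the simulated pathology and the
validation plasma — get the spike fold *deterministically* in place of
the biological factor, emulating spiking at a controlled concentration;
QC-pool injections likewise carry no biological factor (one pooled
material re-injected).

Random streams are derived per (seed, sample, injection, mode), so
adding samples to a spec never perturbs the peaks of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .batch_io import (
    ROLE_PATIENT,
    ROLE_QC_POOL,
    ROLE_VALIDATION,
    PeakList,
    SampleEntry,
    SessionConfig,
    Worklist,
    sha256_file,
    write_peaklist,
    write_session,
    write_worklist,
)
from .chem import ElementalFormula, get_adduct, ion_mz
from . import annotate as _annotate
from .reference import (
    ACYLCARNITINES,
    BACKGROUND_COMPOUNDS,
    VALIDATION_COMPOUNDS,
    VLCADD_FOLDS,
    demo_library,
    demo_panel,
    validation_spike_list,
)

__all__ = [
    "SimCompound",
    "Spike",
    "SimSpec",
    "SimBatch",
    "SimSpecError",
    "simulate_batch",
    "vlcadd_scenario",
    "write_batch",
]

#: Relative ESI response per adduct species.
ADDUCT_ABUNDANCE: Mapping[str, float] = {
    "M+H": 1.0,
    "M-H": 1.0,
    "M+Na": 0.30,
    "M+K": 0.10,
    "M+Cl": 0.40,
}

_MODE_INDEX = {"positive": 0, "negative": 1}


class SimSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SimCompound:
    """A simulated metabolite: chemistry, chromatography, abundance."""

    name: str
    formula: str
    rt: Mapping[str, float]  # ion mode -> minutes
    adducts: Mapping[str, tuple[str, ...]]  # ion mode -> adduct names
    base_intensity: float = 1.0e6
    log_sigma: float | None = None  # biological sigma; None -> spec default

    def __post_init__(self) -> None:
        if not self.rt:
            raise SimSpecError(f"compound {self.name!r} has no retention time")
        if self.base_intensity <= 0:
            raise SimSpecError(f"compound {self.name!r}: base intensity must be > 0")
        ElementalFormula.parse(self.formula)  # validates


@dataclass(frozen=True)
class Spike:
    """A fold-change perturbation of one compound in one sample."""

    sample_id: str
    compound: str
    fold: float
    mode: str | None = None  # None -> all modes of the compound

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise SimSpecError(f"spike fold must be > 0: {self}")


@dataclass
class SimSpec:
    """Parameters of one simulated analytical batch."""

    n_patients: int = 20
    injections_per_sample: int = 2
    n_qc_pool: int = 3
    n_validation: int = 2
    compounds: Sequence[SimCompound] = ()
    mz_ppm_sd: float = 2.0
    rt_jitter_sd_min: float = 0.02
    intensity_lognormal_sigma: float = 0.2
    spikes: Sequence[Spike] = ()
    dropout_rate: float = 0.0
    seed: int = 0
    max_isotope: int = 1
    isotope1_fraction: float = 0.20
    modes: tuple[str, ...] = ("positive", "negative")

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise SimSpecError("need >= 4 patients for single-patient statistics")
        if self.injections_per_sample < 1:
            raise SimSpecError("injections_per_sample must be >= 1")
        if min(self.mz_ppm_sd, self.rt_jitter_sd_min, self.intensity_lognormal_sigma) < 0:
            raise SimSpecError("noise standard deviations must be >= 0")
        if not (0 <= self.dropout_rate < 1):
            raise SimSpecError("dropout_rate must be in [0, 1)")
        if not self.compounds:
            raise SimSpecError("compound set is empty")
        names = {c.name for c in self.compounds}
        samples = set(self.sample_ids()) | {self.qc_sample_id(), self.validation_sample_id()}
        for spike in self.spikes:
            if spike.compound not in names:
                raise SimSpecError(f"spike names unknown compound {spike.compound!r}")
            if spike.sample_id not in samples:
                raise SimSpecError(f"spike names unknown sample {spike.sample_id!r}")

    def sample_ids(self) -> list[str]:
        return [f"P{i:02d}" for i in range(1, self.n_patients + 1)]

    @staticmethod
    def qc_sample_id() -> str:
        return "QC01"

    @staticmethod
    def validation_sample_id() -> str:
        return "VAL01"


@dataclass
class SimBatch:
    """Simulator output: peak lists, worklist and the truth table."""

    peaklists: list[PeakList]
    worklist: Worklist
    ground_truth: pd.DataFrame

    def peaklists_for(self, mode: str) -> list[PeakList]:
        return [pl for pl in self.peaklists if pl.ion_mode == mode]


def _crc(text: str) -> int:
    return zlib.crc32(text.encode())


def _bio_factors(spec: SimSpec, sample_id: str) -> dict[str, float]:
    """Per-compound biological log-normal factors of one sample."""
    rng = np.random.default_rng(
        [spec.seed % (2**31), _crc(sample_id) % (2**31), 0xB10]
    )
    out = {}
    for compound in spec.compounds:
        sigma = (
            compound.log_sigma
            if compound.log_sigma is not None
            else spec.intensity_lognormal_sigma
        )
        out[compound.name] = float(np.exp(sigma * rng.standard_normal()))
    return out


def _spike_map(spec: SimSpec) -> dict[tuple[str, str, str], float]:
    out: dict[tuple[str, str, str], float] = {}
    for spike in spec.spikes:
        compound = next(c for c in spec.compounds if c.name == spike.compound)
        modes = (spike.mode,) if spike.mode else tuple(compound.rt)
        for mode in modes:
            out[(spike.sample_id, spike.compound, mode)] = spike.fold
    return out


def _simulate_injection(
    spec: SimSpec,
    sample_id: str,
    role: str,
    injection_index: int,
    mode: str,
    bio: Mapping[str, float],
    spikes: Mapping[tuple[str, str, str], float],
) -> PeakList:
    rng = np.random.default_rng(
        [
            spec.seed % (2**31),
            _crc(sample_id) % (2**31),
            injection_index,
            _MODE_INDEX[mode],
        ]
    )
    rows: list[tuple[float, float, float]] = []
    entry_id = f"{sample_id}:{injection_index}:{mode}"
    if role == "blank":
        return PeakList(entry_id, mode, pd.DataFrame(columns=["mz", "rt", "intensity"]))
    for compound in spec.compounds:
        if mode not in compound.rt:
            continue
        sigma = (
            compound.log_sigma
            if compound.log_sigma is not None
            else spec.intensity_lognormal_sigma
        )
        fold = spikes.get((sample_id, compound.name, mode), 1.0)
        spiked = (sample_id, compound.name, mode) in spikes
        bio_factor = 1.0 if (role == ROLE_QC_POOL or spiked) else bio[compound.name]
        mass = ElementalFormula.parse(compound.formula).mass
        for adduct_name in compound.adducts.get(mode, ()):
            adduct = get_adduct(adduct_name)
            level0 = (
                compound.base_intensity
                * ADDUCT_ABUNDANCE.get(adduct.name, 0.2)
                * bio_factor
                * fold
            )
            for k in range(spec.max_isotope + 1):
                # fixed draw order keeps streams stable under dropout
                tech = float(np.exp((sigma / 3.0) * rng.standard_normal()))
                mz_eps = rng.standard_normal() * spec.mz_ppm_sd * 1e-6
                rt_eps = rng.standard_normal() * spec.rt_jitter_sd_min
                drop = rng.random()
                if drop < spec.dropout_rate:
                    continue
                mz = ion_mz(mass, adduct, k) * (1.0 + mz_eps)
                rt = max(compound.rt[mode] + rt_eps, 0.0)
                intensity = level0 * (spec.isotope1_fraction**k) * tech
                rows.append((mz, rt, intensity))
    frame = pd.DataFrame(rows, columns=["mz", "rt", "intensity"]).sort_values(
        "mz", kind="stable", ignore_index=True
    )
    return PeakList(entry_id, mode, frame)


def simulate_batch(spec: SimSpec) -> SimBatch:
    """Simulate all injections of a batch, plus worklist and ground truth."""
    spikes = _spike_map(spec)
    plan: list[tuple[str, str, int]] = []  # (sample, role, injection_index)
    for sample in spec.sample_ids():
        for inj in range(1, spec.injections_per_sample + 1):
            plan.append((sample, ROLE_PATIENT, inj))
    for inj in range(1, spec.n_qc_pool + 1):
        plan.append((spec.qc_sample_id(), ROLE_QC_POOL, inj))
    for inj in range(1, spec.n_validation + 1):
        plan.append((spec.validation_sample_id(), ROLE_VALIDATION, inj))

    bio_cache = {
        sample: _bio_factors(spec, sample)
        for sample in {p[0] for p in plan}
    }

    peaklists: list[PeakList] = []
    entries: list[SampleEntry] = []
    for mode in spec.modes:
        for sample, role, inj in plan:
            peaklists.append(
                _simulate_injection(
                    spec, sample, role, inj, mode, bio_cache[sample], spikes
                )
            )
            entries.append(
                SampleEntry(
                    sample_id=sample,
                    role=role,
                    injection_index=inj,
                    ion_mode=mode,
                    datafile=f"peaks/{sample}_{inj}_{mode}.tsv",
                )
            )
    worklist = Worklist(run_id=f"SIM{spec.seed:06d}", entries=entries)

    truth_rows = []
    sample_roles = {p[0]: p[1] for p in plan}
    for sample, role in sample_roles.items():
        for compound in spec.compounds:
            mass = ElementalFormula.parse(compound.formula).mass
            for mode in spec.modes:
                if mode not in compound.rt:
                    continue
                fold = spikes.get((sample, compound.name, mode), 1.0)
                for adduct_name in compound.adducts.get(mode, ()):
                    adduct = get_adduct(adduct_name)
                    for k in range(spec.max_isotope + 1):
                        truth_rows.append(
                            {
                                "sample_id": sample,
                                "compound": compound.name,
                                "mode": mode,
                                "adduct": adduct.name,
                                "isotope": k,
                                "expected_mz": ion_mz(mass, adduct, k),
                                "expected_rt": compound.rt[mode],
                                "fold": fold,
                                "spiked": (sample, compound.name, mode) in spikes,
                                "expected_detected": spec.dropout_rate < 1.0,
                            }
                        )
    ground_truth = pd.DataFrame(truth_rows)
    return SimBatch(peaklists=peaklists, worklist=worklist, ground_truth=ground_truth)


def _scenario_compounds() -> list[SimCompound]:
    """The demonstration compound set: panel metabolites + plasma background."""
    compounds: list[SimCompound] = []
    # deterministic spread of base abundances across the compound set
    cycle = [2.0e5, 5.0e5, 1.0e6, 2.0e6, 5.0e6]
    i = 0
    for name, formula, _hmdb, rt, adducts in ACYLCARNITINES:
        compounds.append(
            SimCompound(
                name=name,
                formula=formula,
                rt={"positive": rt},
                adducts={"positive": adducts},
                base_intensity=cycle[i % len(cycle)],
            )
        )
        i += 1
    for name, formula, _hmdb, rt, pos, neg, modes in VALIDATION_COMPOUNDS:
        if name == "L-Palmitoylcarnitine":
            continue  # identical molecule already in the acylcarnitine set
        rt_map: dict[str, float] = {}
        adduct_map: dict[str, tuple[str, ...]] = {}
        if "positive" in modes and pos:
            rt_map["positive"] = rt
            adduct_map["positive"] = pos
        if "negative" in modes and neg:
            rt_map["negative"] = rt
            adduct_map["negative"] = neg
        compounds.append(
            SimCompound(
                name=name,
                formula=formula,
                rt=rt_map,
                adducts=adduct_map,
                base_intensity=cycle[i % len(cycle)],
            )
        )
        i += 1
    for name, formula, _hmdb, rt, pos, neg in BACKGROUND_COMPOUNDS:
        rt_map = {}
        adduct_map = {}
        if pos:
            rt_map["positive"] = rt
            adduct_map["positive"] = pos
        if neg:
            rt_map["negative"] = rt
            adduct_map["negative"] = neg
        compounds.append(
            SimCompound(
                name=name,
                formula=formula,
                rt=rt_map,
                adducts=adduct_map,
                base_intensity=cycle[i % len(cycle)],
            )
        )
        i += 1
    return compounds


#: Panel name of the simulated VLCADD case sample.
VLCADD_PATIENT = "P01"
#: Fold at which the validation plasma spikes are simulated.
VALIDATION_SPIKE_FOLD = 10.0


def vlcadd_scenario(seed: int = 17, dropout_rate: float = 0.01) -> SimSpec:
    """A packaged VLCAD-deficiency batch.

    Twenty patients in duplicate, three QC-pool and two validation
    injections per mode; patient ``P01`` carries the nine long-chain
    acylcarnitines spiked at their case-study fold changes (positive
    mode); the validation plasma carries the ten validation-panel
    compounds spiked at fold 10 in their expected modes.
    """
    compounds = _scenario_compounds()
    spikes = [
        Spike(VLCADD_PATIENT, name, fold, mode="positive")
        for name, fold in VLCADD_FOLDS.items()
    ]
    for panel_name, modes in validation_spike_list():
        for mode in modes:
            spikes.append(
                Spike(
                    SimSpec.validation_sample_id(),
                    panel_name,
                    VALIDATION_SPIKE_FOLD,
                    mode=mode,
                )
            )
    return SimSpec(
        n_patients=20,
        injections_per_sample=2,
        n_qc_pool=3,
        n_validation=2,
        compounds=compounds,
        spikes=spikes,
        dropout_rate=dropout_rate,
        seed=seed,
    )


def write_batch(
    batch: SimBatch,
    out_dir: str | Path,
    config: SessionConfig | None = None,
) -> Worklist:
    """Write a simulated batch to a session directory.

    Emits ``peaks/*.tsv``, ``worklist.tsv`` (with SHA-256 checksums),
    ``ground_truth.tsv``, the demonstration ``panel.tsv`` and
    ``library.tsv``, and a read-only ``session.json``. Returns the
    worklist with checksums filled in.
    """
    out_dir = Path(out_dir)
    (out_dir / "peaks").mkdir(parents=True, exist_ok=True)
    by_id = {pl.injection_id: pl for pl in batch.peaklists}
    entries = []
    for entry in batch.worklist.entries:
        peaklist = by_id[entry.injection_id]
        path = out_dir / entry.datafile
        write_peaklist(peaklist, path)
        entries.append(replace(entry, checksum=sha256_file(path)))
    worklist = Worklist(run_id=batch.worklist.run_id, entries=entries)
    write_worklist(worklist, out_dir / "worklist.tsv")
    batch.ground_truth.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
    _annotate.write_panel(demo_panel(), out_dir / "panel.tsv")
    _annotate.write_library(demo_library(), out_dir / "library.tsv")
    if config is None:
        config = SessionConfig()
    session_path = out_dir / "session.json"
    if not session_path.exists():
        write_session(config, session_path)
    return worklist
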