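"""Reading, writing and integrity-checking the pipeline's external artifacts.

A screening session revolves around a handful of plain files: a worklist
(TSV) declaring every injection and its role in the batch, one centroided
peak list per injection (TSV or mzML), a diagnostic panel and a compound
library (TSV), and a write-once session configuration (JSON). This module
owns all of that I/O plus SHA-256 transfer verification, so the analysis
modules never touch the filesystem directly.

Retention times are minutes everywhere; mzML scan times recorded in
seconds are converted on read.
"""

from __future__ import annotations

import hashlib
import json
import os
import stat
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROLE_PATIENT",
    "ROLE_QC_POOL",
    "ROLE_VALIDATION",
    "ROLE_BLANK",
    "WorklistError",
    "PeakListError",
    "SessionError",
    "SampleEntry",
    "Worklist",
    "PeakList",
    "SessionConfig",
    "IntegrityReport",
    "parse_worklist",
    "write_worklist",
    "verify_checksums",
    "sha256_file",
    "read_peaklist",
    "write_peaklist",
    "read_session",
    "write_session",
]

ROLE_PATIENT = "patient"
ROLE_QC_POOL = "qc_pool"
ROLE_VALIDATION = "validation"
ROLE_BLANK = "blank"

_ROLE_ALIASES = {
    "patient": ROLE_PATIENT,
    "qc_pool": ROLE_QC_POOL,
    "qcpool": ROLE_QC_POOL,
    "qc pool": ROLE_QC_POOL,
    "qc": ROLE_QC_POOL,
    "validation": ROLE_VALIDATION,
    "blank": ROLE_BLANK,
}

_MODES = ("positive", "negative")


class WorklistError(ValueError):
    """Malformed or internally inconsistent worklist."""


class PeakListError(ValueError):
    """Malformed peak list file."""


class SessionError(RuntimeError):
    """Session configuration violation (overwrite, invalid thresholds...)."""


def normalize_role(text: str) -> str:
    try:
        return _ROLE_ALIASES[text.strip().lower()]
    except KeyError:
        raise WorklistError(f"unknown sample role {text!r}")


def normalize_mode(text: str) -> str:
    t = text.strip().lower()
    if t in ("positive", "pos", "+", "esi+"):
        return "positive"
    if t in ("negative", "neg", "-", "esi-"):
        return "negative"
    raise WorklistError(f"unknown ion mode {text!r}")


@dataclass(frozen=True)
class SampleEntry:
    """One injection: a sample measured once in one ion mode."""

    sample_id: str
    role: str
    injection_index: int
    ion_mode: str
    datafile: str
    checksum: str | None = None

    def __post_init__(self) -> None:
        if self.injection_index < 1:
            raise WorklistError(
                f"injection_index must be >= 1: {self.sample_id} "
                f"has {self.injection_index}"
            )
        if self.role not in (ROLE_PATIENT, ROLE_QC_POOL, ROLE_VALIDATION, ROLE_BLANK):
            raise WorklistError(f"unknown role {self.role!r}")
        if self.ion_mode not in _MODES:
            raise WorklistError(f"unknown ion mode {self.ion_mode!r}")

    @property
    def injection_id(self) -> str:
        """Canonical injection key, e.g. ``P01:2:positive``."""
        return f"{self.sample_id}:{self.injection_index}:{self.ion_mode}"


@dataclass
class Worklist:
    """Ordered injections of one analytical run."""

    run_id: str
    entries: list[SampleEntry]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for entry in self.entries:
            key = (entry.sample_id, entry.injection_index, entry.ion_mode)
            if key in seen:
                raise WorklistError(
                    f"duplicate worklist entry {entry.sample_id} "
                    f"injection {entry.injection_index} {entry.ion_mode}"
                )
            seen.add(key)

    def for_mode(self, mode: str) -> "Worklist":
        mode = normalize_mode(mode)
        return Worklist(
            self.run_id, [e for e in self.entries if e.ion_mode == mode]
        )

    def samples(self, role: str | None = None) -> list[str]:
        """Distinct sample ids in worklist order, optionally by role."""
        out: list[str] = []
        for e in self.entries:
            if role is not None and e.role != role:
                continue
            if e.sample_id not in out:
                out.append(e.sample_id)
        return out

    def injections_of(self, sample_id: str, mode: str | None = None) -> list[SampleEntry]:
        return [
            e
            for e in self.entries
            if e.sample_id == sample_id
            and (mode is None or e.ion_mode == normalize_mode(mode))
        ]

    def role_of(self, sample_id: str) -> str:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e.role
        raise KeyError(f"sample {sample_id!r} not in worklist")

    def modes(self) -> list[str]:
        return [m for m in _MODES if any(e.ion_mode == m for e in self.entries)]


_WORKLIST_COLUMNS = [
    "sample_id",
    "role",
    "injection_index",
    "ion_mode",
    "datafile",
    "checksum",
]


def parse_worklist(path: str | Path) -> Worklist:
    """Read a worklist TSV; roles and modes are normalized case-insensitively.

    The optional first line ``# run_id: X`` names the run; otherwise the
    file stem is used.
    """
    path = Path(path)
    run_id = path.stem
    with open(path) as handle:
        first = handle.readline()
        if first.startswith("#"):
            if ":" in first:
                run_id = first.split(":", 1)[1].strip() or run_id
            table = pd.read_csv(handle, sep="\t", dtype=str)
        else:
            handle.seek(0)
            table = pd.read_csv(handle, sep="\t", dtype=str)
    missing = [c for c in _WORKLIST_COLUMNS[:5] if c not in table.columns]
    if missing:
        raise WorklistError(f"worklist {path} lacks required columns {missing}")
    entries = []
    for i, row in table.iterrows():
        try:
            entries.append(
                SampleEntry(
                    sample_id=str(row["sample_id"]).strip(),
                    role=normalize_role(str(row["role"])),
                    injection_index=int(row["injection_index"]),
                    ion_mode=normalize_mode(str(row["ion_mode"])),
                    datafile=str(row["datafile"]).strip(),
                    checksum=(
                        str(row["checksum"]).strip()
                        if "checksum" in table.columns
                        and pd.notna(row.get("checksum"))
                        and str(row.get("checksum")).strip()
                        else None
                    ),
                )
            )
        except WorklistError as err:
            raise WorklistError(f"worklist row {i + 2}: {err}") from err
    return Worklist(run_id=run_id, entries=entries)


def write_worklist(worklist: Worklist, path: str | Path) -> None:
    rows = [
        {
            "sample_id": e.sample_id,
            "role": e.role,
            "injection_index": e.injection_index,
            "ion_mode": e.ion_mode,
            "datafile": e.datafile,
            "checksum": e.checksum or "",
        }
        for e in worklist.entries
    ]
    with open(path, "w", newline="") as handle:
        handle.write(f"# run_id: {worklist.run_id}\n")
        pd.DataFrame(rows, columns=_WORKLIST_COLUMNS).to_csv(
            handle, sep="\t", index=False
        )


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class IntegrityReport:
    """Per-entry checksum verification outcome."""

    statuses: list[tuple[str, str, str]]  # (injection_id, status, detail)
    strict: bool = False

    @property
    def passed(self) -> bool:
        bad = {"fail"} | ({"unverified"} if self.strict else set())
        return all(status not in bad for _, status, _ in self.statuses)

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "strict": self.strict,
                "entries": [
                    {"injection": inj, "status": status, "detail": detail}
                    for inj, status, detail in self.statuses
                ],
            },
            indent=2,
        )


def verify_checksums(
    worklist: Worklist,
    base_dir: str | Path | None = None,
    strict: bool = False,
) -> IntegrityReport:
    """Recompute SHA-256 digests of each entry's datafile.

    Entries without a recorded checksum are reported ``unverified`` and do
    not fail the report unless ``strict``. Missing files are failures, not
    exceptions.
    """
    base = Path(base_dir) if base_dir is not None else Path(".")
    statuses = []
    for entry in sorted(worklist.entries, key=lambda e: e.injection_id):
        path = base / entry.datafile
        if entry.checksum is None:
            statuses.append((entry.injection_id, "unverified", "no recorded checksum"))
            continue
        if not path.exists():
            statuses.append((entry.injection_id, "fail", f"missing file {path}"))
            continue
        actual = sha256_file(path)
        if actual == entry.checksum.lower():
            statuses.append((entry.injection_id, "pass", ""))
        else:
            statuses.append(
                (entry.injection_id, "fail", f"digest mismatch ({actual[:12]}...)")
            )
    return IntegrityReport(statuses=statuses, strict=strict)


# ---------------------------------------------------------------------------
# Peak lists


@dataclass
class PeakList:
    """Centroided peaks of one injection: m/z, RT (minutes), intensity."""

    injection_id: str
    ion_mode: str
    peaks: pd.DataFrame  # columns: mz, rt, intensity

    def __post_init__(self) -> None:
        required = ["mz", "rt", "intensity"]
        if list(self.peaks.columns)[:3] != required:
            self.peaks = self.peaks.reindex(columns=required)
        if self.peaks[required].isna().any().any():
            raise PeakListError(f"{self.injection_id}: NaN values in peak list")
        if len(self.peaks):
            if (self.peaks["mz"] <= 0).any():
                raise PeakListError(f"{self.injection_id}: non-positive m/z")
            if (self.peaks["rt"] < 0).any():
                raise PeakListError(f"{self.injection_id}: negative retention time")
            if (self.peaks["intensity"] < 0).any():
                raise PeakListError(f"{self.injection_id}: negative intensity")
        self.peaks = self.peaks.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.peaks)


def read_peaklist(
    path: str | Path,
    fmt: str | None = None,
    injection_id: str | None = None,
    ion_mode: str = "positive",
) -> PeakList:
    """Read a peak list from TSV (mz/rt/intensity columns) or centroided mzML."""
    path = Path(path)
    if fmt is None:
        fmt = "mzml" if path.suffix.lower() == ".mzml" else "tsv"
    injection_id = injection_id or path.stem
    if fmt == "tsv":
        table = pd.read_csv(path, sep="\t")
        if not {"mz", "rt", "intensity"}.issubset(table.columns):
            raise PeakListError(f"{path}: expected columns mz, rt, intensity")
        return PeakList(injection_id, normalize_mode(ion_mode), table)
    if fmt == "mzml":
        return _read_mzml(path, injection_id, normalize_mode(ion_mode))
    raise PeakListError(f"unknown peak list format {fmt!r}")


_MZML_ACCESSIONS = {
    "MS:1000511": "ms_level",
    "MS:1000127": "centroid",
    "MS:1000128": "profile",
    "MS:1000016": "scan_start_time",
    "MS:1000514": "mz_array",
    "MS:1000515": "intensity_array",
    "MS:1000523": "float64",
    "MS:1000521": "float32",
    "MS:1000574": "zlib",
    "MS:1000576": "no_compression",
}


def _decode_binary_array(node) -> "np.ndarray":
    import base64
    import zlib as _zlib

    dtype = "<f8"
    compressed = False
    payload = b""
    for child in node:
        tag = child.tag.rsplit("}", 1)[-1]
        if tag == "cvParam":
            kind = _MZML_ACCESSIONS.get(child.get("accession"))
            if kind == "float32":
                dtype = "<f4"
            elif kind == "zlib":
                compressed = True
        elif tag == "binary" and child.text:
            payload = base64.b64decode(child.text.strip())
    if compressed:
        payload = _zlib.decompress(payload)
    return np.frombuffer(payload, dtype=dtype)


def _read_mzml(path: Path, injection_id: str, ion_mode: str) -> PeakList:
    """Minimal centroided-mzML reader (MS1 spectra, base64 float arrays,
    optional zlib compression). Scan times in seconds are converted to
    minutes; profile-mode spectra are rejected."""
    import xml.etree.ElementTree as ET

    rows_mz: list[np.ndarray] = []
    rows_rt: list[np.ndarray] = []
    rows_int: list[np.ndarray] = []
    for _event, spectrum in ET.iterparse(str(path)):
        if spectrum.tag.rsplit("}", 1)[-1] != "spectrum":
            continue
        ms_level = 1
        profile = False
        rt_min = 0.0
        arrays: dict[str, np.ndarray] = {}
        for node in spectrum.iter():
            tag = node.tag.rsplit("}", 1)[-1]
            if tag == "cvParam":
                kind = _MZML_ACCESSIONS.get(node.get("accession"))
                if kind == "ms_level":
                    ms_level = int(node.get("value"))
                elif kind == "profile":
                    profile = True
                elif kind == "scan_start_time":
                    value = float(node.get("value"))
                    unit = (node.get("unitName") or "minute").lower()
                    rt_min = value / 60.0 if unit == "second" else value
        if profile:
            raise PeakListError(
                f"{path}: profile-mode spectra are unsupported; centroid first"
            )
        if ms_level != 1:
            spectrum.clear()
            continue
        for node in spectrum.iter():
            if node.tag.rsplit("}", 1)[-1] != "binaryDataArray":
                continue
            values = _decode_binary_array(node)
            for child in node:
                kind = _MZML_ACCESSIONS.get(child.get("accession", ""))
                if kind == "mz_array":
                    arrays["mz"] = values
                elif kind == "intensity_array":
                    arrays["intensity"] = values
        if "mz" in arrays and "intensity" in arrays:
            n = len(arrays["mz"])
            rows_mz.append(np.asarray(arrays["mz"], dtype=float))
            rows_int.append(np.asarray(arrays["intensity"], dtype=float))
            rows_rt.append(np.full(n, rt_min))
        spectrum.clear()
    if rows_mz:
        frame = pd.DataFrame(
            {
                "mz": np.concatenate(rows_mz),
                "rt": np.concatenate(rows_rt),
                "intensity": np.concatenate(rows_int),
            }
        )
    else:
        frame = pd.DataFrame(columns=["mz", "rt", "intensity"])
    return PeakList(injection_id, ion_mode, frame)


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    peaklist.peaks.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Session configuration


@dataclass
class SessionConfig:
    """Parameters of one processing session, persisted write-once.

    Tolerances drive alignment and annotation; the significance thresholds
    drive the single-patient selection; the seed drives any simulation.
    """

    mz_tolerance_ppm: float = 5.0
    rt_tolerance_min: float = 0.5
    z_min: float = 3.0
    fc_up: float = 2.0
    fc_down: float = 0.5
    intensity_floor: float = 1000.0
    panel_path: str = "panel.tsv"
    library_path: str = "library.tsv"
    random_seed: int = 0
    mode_list: tuple[str, ...] = ("positive", "negative")

    def __post_init__(self) -> None:
        if self.mz_tolerance_ppm <= 0 or self.rt_tolerance_min <= 0:
            raise SessionError("tolerances must be positive")
        if self.z_min <= 0:
            raise SessionError("z_min must be positive")
        if self.fc_up < 1:
            raise SessionError(f"fc_up must be >= 1: {self.fc_up}")
        if not (0 < self.fc_down <= 1):
            raise SessionError(f"fc_down must be in (0, 1]: {self.fc_down}")
        if self.intensity_floor <= 0:
            raise SessionError("intensity_floor must be positive")
        self.mode_list = tuple(normalize_mode(m) for m in self.mode_list)


def write_session(config: SessionConfig, path: str | Path) -> None:
    """Serialize a session config as JSON and mark the file read-only.

    Re-writing an existing session file is refused: the session record is
    the audit anchor of a run.
    """
    path = Path(path)
    if path.exists():
        raise SessionError(f"session file already exists: {path}")
    payload = asdict(config)
    payload["mode_list"] = list(config.mode_list)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    path.chmod(stat.S_IRUSR | stat.S_IRGRP | stat.S_IROTH)


def read_session(path: str | Path) -> SessionConfig:
    payload = json.loads(Path(path).read_text())
    payload["mode_list"] = tuple(payload.get("mode_list", ("positive", "negative")))
    return SessionConfig(**payload)
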