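"""Shared fixtures: simulated batches, processed runs, mzML builders."""

from __future__ import annotations

import base64
from types import SimpleNamespace

import numpy as np
import pytest

from ngms.batch_io import SessionConfig
from ngms.pipeline import process_mode
from ngms.reference import demo_library, demo_panel
from ngms.synth import SimCompound, SimSpec, Spike, simulate_batch, vlcadd_scenario


@pytest.fixture(scope="session")
def vlcadd_run():
    """One fully processed VLCADD scenario batch (both ion modes)."""
    spec = vlcadd_scenario(seed=11)
    batch = simulate_batch(spec)
    config = SessionConfig(random_seed=11)
    panel, library = demo_panel(), demo_library()
    results = {
        mode: process_mode(
            batch.peaklists_for(mode), batch.worklist, config, panel, library, mode
        )
        for mode in ("positive", "negative")
    }
    return SimpleNamespace(
        spec=spec,
        batch=batch,
        config=config,
        panel=panel,
        library=library,
        results=results,
    )


def small_spec(seed: int = 0, spikes=(), **kwargs) -> SimSpec:
    """A reduced batch spec for fast unit tests: 6 patients, 6 compounds."""
    compounds = [
        SimCompound(
            "Tetradecenoylcarnitine (C14:1)",
            "C21H39NO4",
            rt={"positive": 13.37},
            adducts={"positive": ("M+H",)},
            base_intensity=1.0e6,
        ),
        SimCompound(
            "Palmitoylcarnitine (C16:0)",
            "C23H45NO4",
            rt={"positive": 14.52},
            adducts={"positive": ("M+H", "M+Na")},
            base_intensity=2.0e6,
        ),
        SimCompound(
            "L-Phenylalanine",
            "C9H11NO2",
            rt={"positive": 3.60, "negative": 3.60},
            adducts={"positive": ("M+H",), "negative": ("M-H",)},
            base_intensity=5.0e6,
        ),
        SimCompound(
            "Creatinine",
            "C4H7N3O",
            rt={"positive": 0.90},
            adducts={"positive": ("M+H",)},
            base_intensity=1.0e6,
        ),
        SimCompound(
            "Uric acid",
            "C5H4N4O3",
            rt={"negative": 1.90},
            adducts={"negative": ("M-H",)},
            base_intensity=8.0e5,
        ),
        SimCompound(
            "Mesaconic acid",
            "C5H6O4",
            rt={"negative": 4.20},
            adducts={"negative": ("M-H",)},
            base_intensity=4.0e5,
        ),
    ]
    defaults = dict(
        n_patients=6,
        injections_per_sample=2,
        n_qc_pool=2,
        n_validation=1,
        compounds=compounds,
        spikes=list(spikes),
        seed=seed,
    )
    defaults.update(kwargs)
    return SimSpec(**defaults)


@pytest.fixture()
def small_batch():
    spec = small_spec(seed=3, spikes=[Spike("P02", "Tetradecenoylcarnitine (C14:1)", 50.0, "positive")])
    return SimpleNamespace(spec=spec, batch=simulate_batch(spec))


# ---------------------------------------------------------------------------
# Minimal mzML builder for reader tests


def _encode(values) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode()


def mzml_spectrum(index, rt_sec, mzs, intensities, centroid=True, unit="second"):
    mode_param = (
        '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
        if centroid
        else '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>'
    )
    mz_b64, int_b64 = _encode(mzs), _encode(intensities)
    return f"""
      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(mzs)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        {mode_param}
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt_sec}" unitName="{unit}"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>"""


def mzml_document(spectra) -> str:
    body = "".join(spectra)
    return (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        f'  <run id="run"><spectrumList count="{len(spectra)}">{body}\n'
        "  </spectrumList></run>\n</mzML>\n"
    )
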