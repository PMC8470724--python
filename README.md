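# ngms-pipeline

Untargeted LC-QTOF-MS metabolomics screening for inborn errors of
metabolism (IEM), as a tested, scriptable Python package.

In a diagnostic metabolomics laboratory, one patient's plasma is profiled
against the other patients measured in the same analytical batch. A genetic
enzyme defect leaves a metabolic fingerprint: substrates of the broken step
accumulate (sometimes several-hundred-fold), products are depleted. The
computational problem is to turn tens of thousands of raw (m/z, retention
time, intensity) peaks per injection into a short, auditable list of
significantly altered, confidently annotated metabolites — under the
traceability rules of an accredited clinical laboratory.

This package implements that pipeline end to end:

* **`ngms.batch_io`** — worklist/peak-list/session I/O (TSV, centroided
  mzML, JSON), SHA-256 transfer verification, write-once session configs;
* **`ngms.align`** — cross-injection grouping of peaks into mass features
  with consensus m/z and RT (deterministic, oracle-checkable clustering);
* **`ngms.chem` / `ngms.annotate`** — monoisotopic masses, adduct and
  ¹³C-isotopologue m/z arithmetic; two-tier annotation: high-confidence
  matches against a diagnostic panel (m/z **and** retention time) and
  lower-confidence m/z-only matches against a compound library; CAMERA-style
  grouping of co-eluting adduct/isotopologue features;
* **`ngms.stats`** — single-patient selection: duplicate-averaged intensity,
  fold change versus the median of the other patients, a median/MAD robust
  z-score, and configurable altered-feature flags;
* **`ngms.quality`** — analytical QC (RT repeatability, response CV, mass
  accuracy of monitored standards), the validation-plasma gate (every spiked
  metabolite must emerge significantly increased), session gating, PCA/RT
  diagnostics, and release regression comparison;
* **`ngms.interpret`** — the interpretation engine: ion-mode concatenation,
  filter presets, bar-plot data, immutable result records and an append-only,
  role-tagged audit trail with a review/approval state machine;
* **`ngms.synth`** — a deterministic batch simulator (log-normal biological
  and technical variation, ppm-scale m/z noise, RT jitter, configurable
  spikes) standing in for the mass spectrometer, with a ground-truth table.

## The statistics at the core

For feature $i$ and patient $p$, with duplicate-averaged intensities
$x_{ip}$ and the other patients $q \neq p$ of the batch as reference:

$$\mathrm{FC}_{ip} = \frac{x_{ip}}{\mathrm{median}_{q\neq p}\, x_{iq}}, \qquad
z_{ip} = \frac{x_{ip} - \mathrm{median}_{q}\, x_{iq}}{1.4826\,\mathrm{MAD}_{q}\, x_{iq}}$$

with the denominator floored (see `docs/methods.md`) so constant references
cannot produce infinite scores. A feature is *altered up* when
$|z| \ge z_{\min}$, $\mathrm{FC} \ge \mathrm{fc}_{up}$ and the intensity
clears a floor; *altered down* when $|z| \ge z_{\min}$ and
$\mathrm{FC} \le \mathrm{fc}_{down}$. The diagnostic preset then keeps
altered features carrying a panel annotation (m/z within 5 ppm **and** RT
within 0.5 min of the panel entry).

## Worked example

A simulated VLCAD-deficiency batch: 20 patients in duplicate, QC-pool and
validation-plasma injections, patient `P01` carrying nine long-chain
acylcarnitines spiked at case-study fold changes:

```python
from ngms import SessionConfig, apply_filters, diagnostic_preset
from ngms.pipeline import process_mode, patient_records
from ngms.reference import demo_panel, demo_library
from ngms.synth import simulate_batch, vlcadd_scenario

batch = simulate_batch(vlcadd_scenario(seed=17))
config = SessionConfig(random_seed=17)
records = []
for mode in ("positive", "negative"):
    result = process_mode(batch.peaklists_for(mode), batch.worklist,
                          config, demo_panel(), demo_library(), mode)
    mode_records, _ = patient_records(result, batch.worklist, "P01", config)
    records.extend(mode_records)
hits = apply_filters(records, diagnostic_preset())
```

This prints (one row per compound, via `records_to_frame`):

```
162 records, 23 altered, 23 diagnostic-preset hits
feature_id      mz    rt  fold_change      z                  panel_compounds
  PF000096 398.326 14.08       1230.7 7948.9    Hexadecenoylcarnitine (C16:1)
  PF000091 371.298 13.37        397.8 2354.0   Tetradecenoylcarnitine (C14:1)
  PF000094 373.314 13.82        340.9 1692.2       Myristoylcarnitine (C14:0)
  PF000086 368.279 12.82        149.5 1664.6 Tetradecadienylcarnitine (C14:2)
  PF000111 426.358 14.69         76.9  425.1           Oleylcarnitine (C18:1)
  PF000104 423.327 14.52         64.0  306.7       Palmitoylcarnitine (C16:0)
  PF000108 424.342 14.32         63.3  331.0        Linoleylcarnitine (C18:2)
  PF000084 366.262 12.24         49.5  368.5      Dodecanoylcarnitine (C12:0)
  PF000114 429.377 15.08         32.7  129.4        Stearoylcarnitine (C18:0)
  PF000026 153.041  2.40          0.0   -5.4                         Xanthine
```

All nine spiked acylcarnitines are recovered as altered-up, panel-annotated
features with fold-change estimates close to the simulated folds (e.g.
1230.7 vs 1227.1 for C16:1; some rows show an adduct or first-¹³C
isotopologue ion of the compound, hence m/z like 371.298 or 423.327). The
xanthine row is an instructive screening artifact: both duplicate injections
of the patient randomly dropped that peak, so the feature is evaluated at
the intensity floor and flagged as *decreased* — exactly the kind of
candidate a technician would check in the raw data before reporting.

The same workflow is available from the shell, one session directory per
run:

```bash
ngms simulate --scenario vlcadd --seed 17 --out session/
ngms ingest   --session-dir session/ --strict   # SHA-256 verification
ngms qc       --session-dir session/            # analytical QC report (TSV+XLSX)
ngms validate --session-dir session/            # validation-plasma gate
ngms report   --session-dir session/ --patient P01 --preset diagnostic
```

`ngms report` refuses to run while the session gate (analytical QC +
validation plasma) is closed.

## What the simulator does and does not show

The simulator reproduces the *structure* of a diagnostic batch (roles,
duplicates, adducts, isotopologues, realistic noise magnitudes), not real
plasma: no chromatographic peak shapes, matrix effects, drift, or the
thousands of unknown background features of a real run. Passing tests
demonstrate the pipeline's correctness and its recovery behavior under
controlled conditions; analytical performance on instrument data is a
property of the assay, not of this code. See `docs/methods.md` for the
model, parameter choices and limitations.
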