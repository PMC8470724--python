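# Methods

This note documents the models, conventions and numerical choices behind
the package, in the spirit of a methods appendix: what is computed, with
which parameters, and what the synthetic validation does and does not
demonstrate.

## Mass arithmetic

Monoisotopic masses use IUPAC/CODATA values to ≥ 7 decimals
(C = 12 exactly, H = 1.00782503, N = 14.00307400, O = 15.99491462,
Na = 22.98976928, …). Adduct shifts are electron-corrected: the proton is
1.00727647 Da, M+Na adds Na − e⁻ = 22.98922070 Da, M+Cl adds
Cl + e⁻ = 34.96940126 Da. Isotopologues model ¹³C substitutions only,
spaced 1.0033548 Da/charge; ¹⁵N/¹⁸O channels are below the resolution this
pipeline needs and are not modeled. Report display rounds half-even to
3 decimals, the printed precision of QTOF feature tables. ppm errors are
signed, (observed − theoretical)/theoretical × 10⁶.

The default adduct registry ships M+H, M−H, M+Na, M+K and M+Cl; any
registry can be supplied as TSV. M+Cl matters in practice: sugar-like
metabolites (e.g. N-acetylmannosamine) are commonly observed as chloride
adducts in negative mode.

## Feature alignment

Peaks from all injections of one ion mode are grouped by a deterministic,
three-stage procedure: 1-D single-linkage in m/z (cut when the relative gap
between m/z-sorted neighbours exceeds the ppm tolerance), single-linkage in
RT within each m/z bin, then divisive refinement — while any member deviates
from the group median by more than the tolerance in either dimension, the
group splits at its largest internal gap. Refinement is what guarantees the
advertised invariant (every member within tolerance of the consensus), which
pure single-linkage cannot on chained peaks. If an injection contributes two
peaks to one group, the more intense is kept (ties: nearest the consensus
m/z, then input order) and the loser re-enters the pool for another round,
so every input peak is assigned to exactly one feature. After deduplication
the kept set is refined again, because removing peaks moves the median.

Consensus m/z and RT are member medians. Defaults: 5 ppm, 0.5 min —
conventional QTOF/UHPLC windows. No RT warping is applied; a per-injection
median RT-shift diagnostic is provided instead. The whole procedure is
checked peak-for-peak against a brute-force union-find oracle in the tests.

A practical consequence of 2 ppm instrument noise against a 5 ppm window:
a feature occasionally sheds an outlier peak into a small "sliver" feature.
Downstream code therefore never assumes one feature per theoretical ion.

## Annotation

Two confidence tiers, mirroring how a diagnostic laboratory works:

* **panel** — the metabolite's retention time is known on the local setup,
  so a match requires both |ppm| ≤ 5 and |ΔRT| ≤ 0.5 min;
* **mz_only** — anything outside the panel can only be matched by mass, so
  one feature may collect many isobaric candidates.

Ion indexes are sorted lists of theoretical (compound, adduct,
isotopologue) ions, binary-searched per query and verified against linear
scans. Adduct grouping links co-eluting features whenever some registered
(adduct, isotope) assignment gives them the same neutral mass within
tolerance; the group's consensus mass is the candidate-mass cluster
explaining the most members, with ties resolved toward the fewest ¹³C
substitutions (otherwise an isotopologue pair is self-consistently — and
wrongly — explained one ¹³C unit high).

The shipped demonstration panel holds the nine long-chain acylcarnitines of
the VLCADD case plus the ten validation-plasma compounds; the demonstration
library adds ~20 abundant plasma metabolites. Production panels are
laboratory-specific and are supplied as TSV. Panel retention times for the
polar validation compounds are plausible values for a reversed-phase UHPLC
gradient (0.6–5.3 min), chosen once as simulator/panel conventions; the
acylcarnitine RTs are the case-table values (12.2–15.1 min).

## Single-patient statistics

Screening is an n-of-1 comparison. Duplicate injections are arithmetically
averaged (a missing duplicate yields a flagged "partial" mean). For patient
p and feature i, against the other patients q of the batch:

* fold change FC = x_ip / max(median_q x_iq, floor);
* robust z = (x_ip − median_q) / max(1.4826·MAD_q, 0.05·median_q, floor);
* p-value = two-sided standard-normal tail of z, via erfc. p-values are
  descriptive ranking aids; no multiple-testing correction is applied,
  because the decision rule is the threshold flag, not an error rate.

The MAD floor terms prevent infinite scores on (near-)constant references;
the absolute floor (default 1000 counts, the instrument noise scale) also
defines how a feature *absent* in the patient but present in at least half
the reference is scored — it is evaluated at the floor, so deficiencies are
detectable as "down" flags. Because the floors are absolute counts, exact
scale invariance of FC and z holds whenever the floors are inactive, i.e.
at realistic intensities; the invariance tests run in that regime.

Defaults z_min = 3, fc_up = 2, fc_down = 0.5 are deliberately conservative
screening thresholds and are configurable per session. Statistics require
≥ 3 observed reference patients per feature; otherwise the feature is
reported with an `insufficient_reference` status instead of numbers.

Only patient-role samples form the reference, so QC pools, blanks and the
validation plasma never contaminate the batch median, while any sample
(including the validation plasma) can be the analysis target.

## Quality control and gating

Per monitored standard across its injections: RT repeatability
max|rt − median|/median × 100; response repeatability sd(n−1)/mean × 100
(sample-sd CV, the QC convention); mass accuracy max |ppm|. Defaults:
≤ 10 % RT delta, ≤ 30 % CV, ≤ 5 ppm. External standards are evaluated on
QC-pool injections and fail if recovered in fewer than two; internal
stand-ins must additionally be recovered in ≥ 90 % of their injections —
tolerating the occasional stochastic miss while catching systematic loss.

The validation plasma is processed exactly like a patient; its report lists
every spiked compound with feature mass, RT delta % (|observed −
panel RT|/panel RT × 100) and per-mode increased flags. The gate passes iff
every spiked compound is altered-up in at least one expected ion mode, and
the session gate opens only when analytical QC *and* the validation gate
pass. Release validation compares, per patient, the sets of panel-annotated
altered metabolites between two pipeline versions; any symmetric difference
fails.

Diagnostics are numbers, not figures: first-two-PC scores per injection
(SVD of the log₁₀, feature-centred matrix, missing values filled with the
feature minimum), per-injection median RT shift, and extracted-ion point
series for named targets.

## Interpretation engine

Result records are frozen objects; the only mutable state is the audit
log, an append-only JSON-lines file of role-tagged events. Replaying the
log is a pure fold and reconstructs all user annotations and sample review
states; invalid events (approval by a non-specialist, out-of-order
transitions in new → in_review → reviewed → approved) are rejected without
touching the log. Filters are conjunctions of optional predicates
(RT/m/z ranges, p-value, two-sided fold change, annotation level, panel
membership, direction, mode); the diagnostic preset is
`altered ∧ panel-annotated`. Fold-change filtering is two-sided by default
because IEMs present both as accumulation and as deficiency.

## The batch simulator

The simulator emulates the *structure* of a diagnostic batch so that every
stage has a ground truth:

* 20 patients × 2 injections + 3 QC-pool + 2 validation injections per
  ion mode (all configurable);
* per compound: base intensity (2×10⁵–5×10⁶ counts across the set), one
  biological log-normal factor per sample (σ = 0.2 — a typical
  between-individual CV for plasma metabolites), an independent technical
  factor per injection (σ/3, so duplicate averaging is meaningful),
  first-¹³C isotopologue at 0.20 of the monoisotopic peak (≈ a C₂₀
  compound), fixed adduct abundances (M+H/M−H 1.0, M+Na 0.3, M+Cl 0.4,
  M+K 0.1);
* m/z noise 2 ppm (QTOF-grade), RT jitter 0.02 min, peak dropout 1 % in
  the packaged scenario;
* spiked (sample, compound) pairs receive the spike fold *deterministically*
  in place of the biological factor — a spike is a controlled
  concentration, not a biological draw — and QC-pool injections likewise
  carry technical noise only, being one pooled material;
* random streams are derived per (seed, sample, injection, mode), so
  enlarging a batch never changes existing samples' peaks, and a fixed
  seed reproduces byte-identical output.

The packaged VLCADD scenario spikes nine long-chain acylcarnitines into
patient P01 at the case fold changes (29–1227) and the ten validation
compounds into the validation plasma at fold 10, in both ion modes.

**Accuracy budget.** The pipeline's fold-change estimate of a spiked
feature scatters around the true fold by ≈ √((σ/3)²/2 + (1.253·σ′/√19)²)
in log scale — technical noise of the patient mean plus sampling noise of
the 19-patient reference median (σ′ ≈ 0.206) — about 7.5 %, dominated by
the reference median. Individual estimates therefore fall within 20 % of
the simulated fold ~98–99 % of the time, but the *joint* event that all
nine compounds do so simultaneously holds in only ~87 % of batches; this is
a property of median-of-19 screening itself, not of the implementation,
and the recovery study reports detection (per batch) and fold accuracy
(per estimate) as separate rates.

**Not modeled:** chromatographic peak shapes and profile spectra, matrix
effects and ionization suppression, inter-batch drift, the thousands of
unidentified background features of real plasma, and correlated biology
(the simulator draws compounds independently). Passing tests demonstrate
algorithmic correctness and recovery under the stated noise model, not
clinical performance.

## Numerical and policy choices

* Checksums: SHA-256; entries without a recorded digest are "unverified"
  (promotable to failures with `--strict`).
* mzML: a minimal reader for centroided MS1 spectra (base64 32/64-bit
  float arrays, optional zlib, scan times converted to minutes);
  profile-mode spectra are rejected with instructions to centroid first.
  Writing mzML is out of scope; TSV peak lists are the native format.
* Session configs are validated, serialized to JSON, and made read-only;
  rewriting an existing session file is an error, anchoring traceability.
* All tie-breaks (alignment, annotation ordering, grouping) are explicit
  and deterministic; two runs on identical inputs are identical.
* Worklist roles are normalized case-insensitively
  ({patient, qc/qcpool/qc_pool, validation, blank}); retention times are
  minutes everywhere.
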