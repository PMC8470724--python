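"""Analytical QC metrics, validation gate, diagnostics, release checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ngms.align import AlignedFeature
from ngms.annotate import Annotation
from ngms.batch_io import PeakList
from ngms.chem import ElementalFormula, get_adduct, ion_mz
from ngms.pipeline import patient_records
from ngms.quality import (
    QCRow,
    QualityError,
    Recovery,
    StandardDef,
    compare_sessions,
    diagnostics_data,
    qc_metrics,
    recover_standards,
    session_gate,
    validation_report,
    write_qc_report,
)
from ngms.reference import demo_standards, validation_spike_list
from ngms.synth import simulate_batch, vlcadd_scenario

PHE = StandardDef(
    name="L-Phenylalanine",
    formula=ElementalFormula.parse("C9H11NO2"),
    adduct_name="M+H",
    ion_mode="positive",
    expected_rt=3.60,
)
PHE_MZ = PHE.theoretical_mz()


def peaklist(injection_id, rows, mode="positive"):
    return PeakList(
        injection_id, mode, pd.DataFrame(rows, columns=["mz", "rt", "intensity"])
    )


class TestRecoverStandards:
    def test_in_tolerance_peak_recovered(self):
        pl = peaklist("i1", [(PHE_MZ * (1 + 2e-6), 3.65, 5e6)])
        recs = recover_standards([pl], [PHE], mz_tol=5.0, rt_tol=0.5)
        assert recs[0].found and recs[0].ppm == pytest.approx(2.0, abs=0.01)

    def test_absence_is_not_found(self):
        pl = peaklist("i1", [(200.0, 3.6, 1e6)])
        recs = recover_standards([pl], [PHE], 5.0, 0.5)
        assert recs == [Recovery("i1", "L-Phenylalanine", found=False)]

    def test_wrong_mode_injection_skipped(self):
        pl = peaklist("i1", [(PHE_MZ, 3.6, 1e6)], mode="negative")
        assert recover_standards([pl], [PHE], 5.0, 0.5) == []

    def test_best_candidate_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(1, 40))
            rows = list(
                zip(
                    PHE_MZ * (1 + rng.normal(0, 4e-6, n)),
                    3.6 + rng.normal(0, 0.3, n),
                    rng.uniform(1e3, 1e7, n),
                )
            )
            pl = peaklist("i1", rows)
            rec = recover_standards([pl], [PHE], 5.0, 0.5)[0]
            candidates = [
                (abs((mz - PHE_MZ) / PHE_MZ * 1e6), abs(rt - 3.6), mz, rt, it)
                for mz, rt, it in rows
                if abs((mz - PHE_MZ) / PHE_MZ * 1e6) <= 5.0 and abs(rt - 3.6) <= 0.5
            ]
            if not candidates:
                assert not rec.found
            else:
                best = min(candidates)
                assert rec.found
                assert rec.rt == pytest.approx(best[3])
                assert rec.intensity == pytest.approx(best[4])


class TestQCMetrics:
    def recs(self, rts, intens, ppms):
        return [
            Recovery(f"i{k}", "L-Phenylalanine", True, rt, it, ppm)
            for k, (rt, it, ppm) in enumerate(zip(rts, intens, ppms))
        ]

    def test_identical_rts_give_zero_delta(self):
        rows = qc_metrics(self.recs([3.6] * 3, [100.0] * 3, [1.0] * 3), [PHE])
        assert rows[0].rt_delta_pct == 0.0

    def test_constant_response_gives_zero_cv(self):
        rows = qc_metrics(self.recs([3.6] * 3, [100.0, 100.0, 100.0], [0.0] * 3), [PHE])
        assert rows[0].response_cv_pct == 0.0

    def test_sample_sd_cv_convention(self):
        rows = qc_metrics(self.recs([3.6] * 3, [90.0, 100.0, 110.0], [0.0] * 3), [PHE])
        assert rows[0].response_cv_pct == pytest.approx(10.0, abs=0.01)
        rows = qc_metrics(
            self.recs([3.6] * 3, [90.0, 100.0, 110.0], [0.0] * 3),
            [PHE],
        )
        # sd([90,100,110], ddof=1)/mean = 10/100 -> 10%; the 8.165% figure
        # is the population-sd value and must NOT be produced
        assert rows[0].response_cv_pct != pytest.approx(8.165, abs=0.01)

    def test_worst_abs_ppm_and_threshold(self):
        rows = qc_metrics(self.recs([3.6] * 3, [100.0] * 3, [1.0, -4.9, 2.0]), [PHE])
        assert rows[0].worst_abs_ppm == pytest.approx(4.9)
        assert rows[0].ppm_pass

    def test_single_recovery_fails_repeatability(self):
        rows = qc_metrics(self.recs([3.6], [100.0], [1.0]), [PHE])
        assert rows[0].rt_delta_pct is None and not rows[0].overall_pass

    def test_injection_order_invariance(self):
        a = qc_metrics(self.recs([3.5, 3.6, 3.7], [90, 100, 110], [1, 2, 3]), [PHE])[0]
        b = qc_metrics(
            list(reversed(self.recs([3.5, 3.6, 3.7], [90, 100, 110], [1, 2, 3]))), [PHE]
        )[0]
        assert (a.rt_delta_pct, a.response_cv_pct, a.worst_abs_ppm) == (
            b.rt_delta_pct,
            b.response_cv_pct,
            b.worst_abs_ppm,
        )

    def test_internal_standard_must_be_found_everywhere(self):
        internal = StandardDef(
            name="Creatinine",
            formula=ElementalFormula.parse("C4H7N3O"),
            adduct_name="M+H",
            ion_mode="positive",
            expected_rt=0.9,
            kind="internal",
        )
        recs = [
            Recovery("i0", "Creatinine", True, 0.9, 100.0, 1.0),
            Recovery("i1", "Creatinine", True, 0.9, 100.0, 1.0),
            Recovery("i2", "Creatinine", False),
        ]
        rows = qc_metrics(recs, [internal])
        assert not rows[0].found_pass and not rows[0].overall_pass

    def test_report_writer_roundtrip(self, tmp_path):
        rows = qc_metrics(self.recs([3.6] * 3, [90, 100, 110], [1, 2, 3]), [PHE])
        table = write_qc_report(rows, tmp_path / "qc.tsv", tmp_path / "qc.xlsx")
        back = pd.read_csv(tmp_path / "qc.tsv", sep="\t")
        assert back["overall_pass"].tolist() == table["overall_pass"].tolist()
        assert (tmp_path / "qc.xlsx").stat().st_size > 0


class TestValidationGate:
    def _run_validation(self, vlcadd_run):
        stats_by_mode, ann_by_mode, feats_by_mode = {}, {}, {}
        for mode, result in vlcadd_run.results.items():
            _records, stats = patient_records(
                result, vlcadd_run.batch.worklist, "VAL01", vlcadd_run.config
            )
            stats_by_mode[mode] = stats
            ann_by_mode[mode] = result.annotations
            feats_by_mode[mode] = result.features
        return stats_by_mode, ann_by_mode, feats_by_mode

    def test_all_spikes_present_gate_passes(self, vlcadd_run):
        stats_by_mode, ann_by_mode, feats_by_mode = self._run_validation(vlcadd_run)
        rows, gate, missing = validation_report(
            stats_by_mode,
            ann_by_mode,
            feats_by_mode,
            validation_spike_list(),
            vlcadd_run.panel,
        )
        assert gate and missing == []
        flagged = {r.name for r in rows if r.increased_pos or r.increased_neg}
        assert {name for name, _ in validation_spike_list()} <= flagged

    def test_omitted_spike_fails_naming_compound(self, vlcadd_run):
        spec = vlcadd_scenario(seed=11)
        dropped = "Mesaconic acid"
        spec_no_spike = type(spec)(
            **{
                **spec.__dict__,
                "spikes": [
                    s
                    for s in spec.spikes
                    if not (s.sample_id == "VAL01" and s.compound == dropped)
                ],
            }
        )
        batch = simulate_batch(spec_no_spike)
        from ngms.pipeline import process_mode

        stats_by_mode, ann_by_mode, feats_by_mode = {}, {}, {}
        for mode in ("positive", "negative"):
            result = process_mode(
                batch.peaklists_for(mode),
                batch.worklist,
                vlcadd_run.config,
                vlcadd_run.panel,
                vlcadd_run.library,
                mode,
            )
            _r, stats = patient_records(result, batch.worklist, "VAL01", vlcadd_run.config)
            stats_by_mode[mode] = stats
            ann_by_mode[mode] = result.annotations
            feats_by_mode[mode] = result.features
        _rows, gate, missing = validation_report(
            stats_by_mode,
            ann_by_mode,
            feats_by_mode,
            validation_spike_list(),
            vlcadd_run.panel,
        )
        assert not gate and missing == [dropped]

    def test_unknown_spiked_compound_is_configuration_error(self, vlcadd_run):
        stats_by_mode, ann_by_mode, feats_by_mode = self._run_validation(vlcadd_run)
        with pytest.raises(QualityError, match="Nonexistine"):
            validation_report(
                stats_by_mode,
                ann_by_mode,
                feats_by_mode,
                [("Nonexistine", ("positive",))],
                vlcadd_run.panel,
            )

    def test_gate_monotone_under_added_detections(self, vlcadd_run):
        """Adding an extra altered-up annotated feature never flips pass->fail."""
        stats_by_mode, ann_by_mode, feats_by_mode = self._run_validation(vlcadd_run)
        _rows, gate, _missing = validation_report(
            stats_by_mode, ann_by_mode, feats_by_mode,
            validation_spike_list(), vlcadd_run.panel,
        )
        assert gate
        mode = "positive"
        stats = stats_by_mode[mode]
        fid = stats.index[0]
        extra_ann = dict(ann_by_mode[mode])
        extra_ann[fid] = list(extra_ann.get(fid, [])) + [
            Annotation(fid, "panel", "HMDB0000159", "L-Phenylalanine", "M+H", 0, 0.1, 166.0863, 0.0)
        ]
        _rows2, gate2, _m2 = validation_report(
            {**stats_by_mode}, {**ann_by_mode, mode: extra_ann}, feats_by_mode,
            validation_spike_list(), vlcadd_run.panel,
        )
        assert gate2


class TestSessionGate:
    def qc_row(self, ok=True):
        return QCRow("std", "external", 3, 3, 1.0, 2.0, 1.0, ok, ok, ok, True)

    def test_truth_table(self):
        assert session_gate([self.qc_row(True)], True)
        assert not session_gate([self.qc_row(False)], True)
        assert not session_gate([self.qc_row(True)], False)
        assert not session_gate([self.qc_row(False)], False)


class TestDiagnostics:
    def test_identical_injections_get_identical_pca_scores(self):
        matrix = pd.DataFrame(
            {"a": [1e5, 2e6, 3e4], "b": [1e5, 2e6, 3e4], "c": [5e5, 1e6, 9e4]},
            index=["F1", "F2", "F3"],
        )
        scores = diagnostics_data(matrix)["pca_scores"]
        assert np.allclose(scores.loc["a"], scores.loc["b"])

    def test_constant_rt_shift_recovered(self):
        rng = np.random.default_rng(6)
        features = []
        for i in range(40):
            rt = float(rng.uniform(1, 14))
            features.append(
                AlignedFeature(
                    f"F{i}",
                    100.0 + i,
                    rt,
                    "positive",
                    {"a": 1.0, "b": 1.0},
                    member_rts={"a": rt - 0.05, "b": rt + 0.05},
                )
            )
        matrix = pd.DataFrame(
            {"a": np.ones(40), "b": np.ones(40)},
            index=[f.feature_id for f in features],
        )
        shift = diagnostics_data(matrix, features=features)["rt_shift"]
        assert shift["b"] - shift["a"] == pytest.approx(0.1, abs=0.02)

    def test_pca_scores_reproduce_covariance_eigenstructure(self):
        """On a tiny matrix the PC1 score variance must equal the leading
        eigenvalue of the injection covariance (independent eigen route)."""
        matrix = pd.DataFrame(
            np.array(
                [
                    [1.0e4, 2.0e4, 8.0e4],
                    [3.0e5, 2.5e5, 1.0e5],
                    [7.0e3, 9.0e3, 2.0e4],
                ]
            ),
            index=["F1", "F2", "F3"],
            columns=["a", "b", "c"],
        )
        scores = diagnostics_data(matrix)["pca_scores"]
        log = np.log10(matrix.to_numpy())
        centered = log - log.mean(axis=1, keepdims=True)
        cov = centered.T @ centered
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert (scores["PC1"] ** 2).sum() == pytest.approx(eigvals[0], rel=1e-9)
        assert (scores["PC2"] ** 2).sum() == pytest.approx(eigvals[1], rel=1e-9)

    def test_eic_points_returned_for_named_target(self):
        features = [
            AlignedFeature(
                "F1", 370.2952, 13.37, "positive",
                {"a": 1e6, "b": 2e6},
                member_rts={"a": 13.36, "b": 13.38},
            )
        ]
        matrix = pd.DataFrame({"a": [1e6, 1], "b": [2e6, 1]}, index=["F1", "F2"])
        out = diagnostics_data(
            matrix, features=features, eic_targets={"C14:1": 370.2952}
        )
        assert len(out["eic"]["C14:1"]) == 2


class TestCompareSessions:
    def test_identical_sessions_pass(self):
        results = {"P01": {"A", "B"}, "P02": set()}
        report, ok = compare_sessions(results, {k: set(v) for k, v in results.items()})
        assert ok and report.empty

    def test_discrepancy_listed_and_fails(self):
        old = {"P01": {"A", "B"}}
        new = {"P01": {"B"}}
        report, ok = compare_sessions(old, new)
        assert not ok
        assert report.loc[0, "only_old"] == "A"

    def test_sample_coverage_mismatch_fails(self):
        report, ok = compare_sessions({"P01": set()}, {"P01": set(), "P02": {"A"}})
        assert not ok and "P02" in report["sample_id"].tolist()

    def test_matches_set_oracle_random(self):
        rng = np.random.default_rng(10)
        names = [f"M{i}" for i in range(10)]
        for _ in range(30):
            old = {
                f"P{i}": {n for n in names if rng.random() < 0.3} for i in range(5)
            }
            new = {
                f"P{i}": {n for n in names if rng.random() < 0.3} for i in range(5)
            }
            report, ok = compare_sessions(old, new)
            expect_ok = all(old[s] == new[s] for s in old)
            assert ok == expect_ok
            for _, row in report.iterrows():
                s = row["sample_id"]
                assert set(row["only_old"].split(";")) - {""} == old[s] - new[s]
                assert set(row["only_new"].split(";")) - {""} == new[s] - old[s]
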