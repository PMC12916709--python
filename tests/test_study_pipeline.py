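import warnings

import numpy as np
import pytest

from hospdea.bootstrap import BootstrapConfig
from hospdea.errors import MissingOutputError, PanelValidationError
from hospdea.pipeline import (
    PeriodScheme,
    StudyConfig,
    decompose_inefficiency,
    dmu_adequacy,
    export_report,
    period_summary,
    rts_tally,
    run_study,
)
from hospdea.synthetic import Shock, generate_panel


SMALL_BOOT = BootstrapConfig(B=100, seed=0)


def quiet_run(panel, config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(panel, config)


class TestPeriodScheme:
    def test_default_partition(self):
        scheme = PeriodScheme()
        assert scheme.names == ["pre_pandemic", "pandemic", "post_pandemic"]
        assert scheme.assign(2015) == "pre_pandemic"
        assert scheme.assign(2020) == "pandemic"
        assert scheme.assign(2024) == "post_pandemic"
        assert scheme.years("pandemic") == [2020, 2021]
        with pytest.raises(ValueError):
            scheme.assign(1999)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            PeriodScheme(periods=(("a", 2015, 2019), ("b", 2019, 2021)))
        with pytest.raises(ValueError):
            PeriodScheme(periods=(("a", 2019, 2015),))


class TestPeriodSummary:
    def test_means_and_overall(self):
        scheme = PeriodScheme()
        yearly = {y: float(y - 2014) for y in range(2015, 2025)}
        out = period_summary(yearly, scheme)
        assert out["pre_pandemic"] == pytest.approx(np.mean([1, 2, 3, 4, 5]))
        assert out["pandemic"] == pytest.approx(np.mean([6, 7]))
        assert out["post_pandemic"] == pytest.approx(np.mean([8, 9, 10]))
        assert out["overall"] == pytest.approx(5.5)
        # overall equals the length-weighted mean of the period means
        weighted = (5 * out["pre_pandemic"] + 2 * out["pandemic"]
                    + 3 * out["post_pandemic"]) / 10
        assert out["overall"] == pytest.approx(weighted)


class TestDecomposition:
    def test_identity_exact(self):
        tri = decompose_inefficiency(0.8340, 0.8950)
        assert tri.overall_reduction == pytest.approx(
            tri.pure_gap + tri.scale_gap, abs=1e-15
        )

    def test_printed_style_percentages(self):
        assert decompose_inefficiency(0.8340, 0.8950).as_percent() == (16.6, 10.5, 6.1)

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            decompose_inefficiency(0.9, 0.8)  # TE above PTE is impossible
        with pytest.raises(ValueError):
            decompose_inefficiency(0.0, 0.5)
        with pytest.raises(ValueError):
            decompose_inefficiency(0.5, 1.2)


class TestRtsTally:
    def test_counts_conserve_period_lengths(self):
        scheme = PeriodScheme()
        labels = {("H1", y): ("drs" if y < 2022 else "crs")
                  for y in range(2015, 2025)}
        t = rts_tally(labels, scheme)
        assert (t[["crs", "drs", "irs", "indeterminate"]].sum(axis=1)
                == t["years_in_period"]).all()
        assert t["years_in_period"].sum() == 10

    def test_all_drs_rows(self):
        # a hospital labelled DRS in every year tallies (0, 5, 0), (0, 2, 0),
        # (0, 3, 0) across the three default periods
        scheme = PeriodScheme()
        labels = {("H1", y): "drs" for y in range(2015, 2025)}
        t = rts_tally(labels, scheme).set_index("period")
        assert list(t.loc["pre_pandemic", ["crs", "drs", "irs"]]) == [0, 5, 0]
        assert list(t.loc["pandemic", ["crs", "drs", "irs"]]) == [0, 2, 0]
        assert list(t.loc["post_pandemic", ["crs", "drs", "irs"]]) == [0, 3, 0]

    def test_missing_label_rejected(self):
        with pytest.raises(PanelValidationError):
            rts_tally({("H1", 2015): "drs", ("H1", 2016): None}, PeriodScheme())


class TestAdequacy:
    def test_thresholds(self):
        assert dmu_adequacy(4, 2, 30) == (18, True)
        assert dmu_adequacy(2, 3, 30) == (15, True)
        assert dmu_adequacy(4, 2, 3) == (18, False)
        assert dmu_adequacy(1, 1, 6) == (6, True)
        with pytest.raises(ValueError):
            dmu_adequacy(0, 1, 5)


@pytest.fixture(scope="module")
def report():
    sp = generate_panel(seed=13, shock=Shock())
    cfg = StudyConfig(frontier_scope="pooled", bootstrap=SMALL_BOOT, seed=13)
    return quiet_run(sp.panel, cfg)


class TestRunStudy:
    def test_yearly_scores_structure(self, report):
        df = report.yearly_scores
        assert len(df) == 60  # 2 domains x 30 hospital-years
        assert set(df["domain"]) == {"operational", "financial"}
        for col in ("te_ccr", "pte_bcc", "se", "te_ccr_bc", "pte_bcc_bc"):
            assert df[col].between(0, 1 + 1e-9).all(), col
        # SE identity on every row
        assert np.allclose(df["se"], df["te_ccr"] / df["pte_bcc"])
        # bias correction lowers scores for nearly all DMUs (the DEA bias is
        # toward the sample frontier; individual replicates can fluctuate)
        assert (df["te_ccr_bc"] <= df["te_ccr"] + 1e-9).mean() >= 0.9

    def test_intervals_ordered(self, report):
        df = report.yearly_scores
        assert (df["te_ccr_lo"] <= df["te_ccr_hi"] + 1e-12).all()
        assert (df["pte_bcc_lo"] <= df["pte_bcc_hi"] + 1e-12).all()

    def test_decomposition_identity_on_every_row(self, report):
        d = report.decomposition
        assert len(d) > 0
        assert np.allclose(
            d["overall_reduction"], d["pure_gap"] + d["scale_gap"], atol=1e-12
        )
        # each pct field is rounded to 1 dp independently, so the printed
        # identity can drift by at most 0.15 percentage points
        assert np.allclose(
            d["overall_pct"], d["pure_pct"] + d["scale_pct"], atol=0.15
        )

    def test_period_tables_cover_all_periods(self, report):
        det = report.period_means_deterministic
        assert set(det["period"]) == {
            "pre_pandemic", "pandemic", "post_pandemic", "overall"
        }
        assert set(det["measure"]) == {"te_ccr", "pte_bcc", "se"}

    def test_second_stage_present(self, report):
        assert set(report.second_stage) == {"operational", "financial"}
        for fit in report.second_stage.values():
            if isinstance(fit, dict):
                assert "error" in fit  # recorded honestly, not silently
            else:
                assert fit.n_obs == 30

    def test_metadata(self, report):
        assert report.metadata["n_records"] == 30
        assert report.metadata["config"]["frontier_scope"] == "pooled"

    def test_reproducible(self):
        sp = generate_panel(seed=21)
        cfg = StudyConfig(frontier_scope="pooled", bootstrap=SMALL_BOOT, seed=21)
        a = quiet_run(sp.panel, cfg)
        b = quiet_run(sp.panel, cfg)
        assert a.yearly_scores.equals(b.yearly_scores)
        assert a.decomposition.equals(b.decomposition)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_per_year_scope_warns_about_adequacy_and_tallies_rts(self):
        sp = generate_panel(seed=5)
        cfg = StudyConfig(bootstrap=SMALL_BOOT, seed=5, run_second_stage=False)
        with pytest.warns(UserWarning, match="threshold"):
            report = run_study(sp.panel, cfg)
        assert report.metadata["adequacy_warnings"]
        t = report.rts_tallies
        assert t is not None
        assert (t[["crs", "drs", "irs", "indeterminate"]].sum(axis=1)
                == t["years_in_period"]).all()
        # every hospital-year classified: 3 hospitals x 10 years
        assert t["years_in_period"].sum() == 30


class TestFallbacks:
    def test_fixture_without_fallback_fails_loudly(self, fixture_panel):
        cfg = StudyConfig(bootstrap=SMALL_BOOT, fallback="none")
        with pytest.raises(MissingOutputError, match="surgical_procedures"):
            quiet_run(fixture_panel, cfg)

    def test_drop_surgical_runs_on_fixture(self, fixture_panel):
        cfg = StudyConfig(
            frontier_scope="pooled", bootstrap=SMALL_BOOT,
            fallback="drop_surgical", run_second_stage=False,
            rts_domains=(), seed=2,
        )
        report = quiet_run(fixture_panel, cfg)
        assert report.metadata["fallbacks"]["operational"] == "operational_single_output"
        assert report.metadata["fallbacks"]["financial"] == "financial_no_surgery"
        assert len(report.yearly_scores) == 60

    def test_synthetic_surgical_is_flagged_and_reproducible(self, fixture_panel):
        cfg = StudyConfig(
            frontier_scope="pooled", bootstrap=SMALL_BOOT,
            fallback="synthetic_surgical", run_second_stage=False,
            rts_domains=(), seed=2,
        )
        a = quiet_run(fixture_panel, cfg)
        b = quiet_run(fixture_panel, cfg)
        assert a.metadata["fallbacks"]["surgical_procedures"] == "synthetic"
        assert a.yearly_scores.equals(b.yearly_scores)


class TestExport:
    def test_files_written_and_rounded(self, tmp_path):
        sp = generate_panel(seed=3)
        cfg = StudyConfig(
            frontier_scope="pooled", bootstrap=SMALL_BOOT,
            run_second_stage=False, rts_domains=(), seed=3,
        )
        report = quiet_run(sp.panel, cfg)
        written = export_report(report, tmp_path)
        assert (tmp_path / "yearly_scores.csv").exists()
        assert (tmp_path / "run_metadata.json").exists()
        import pandas as pd

        back = pd.read_csv(tmp_path / "yearly_scores.csv")
        # scores are reported at 4 decimal places
        assert (back["te_ccr"].round(4) == back["te_ccr"]).all()
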