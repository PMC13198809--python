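import math

import numpy as np
import pytest

import boneref as br
from boneref import normative_tables as nt
from boneref.precision_trend import DEFAULT_AGE_GRID, summary_table
from boneref.synthetic_cohort import ParameterTrend


class TestMuSigmaCv:
    def test_published_female_tibia_density_row(self):
        rng = np.random.default_rng(0)
        vals = 0.266 + 0.036 * rng.standard_normal(4000)
        mu, sigma, cv = br.cohort_mu_sigma(vals)
        assert cv == pytest.approx(sigma / mu)
        # published row: mu 0.266, sigma 0.036 -> sigma/mu printed 0.135
        assert 0.036 / 0.266 == pytest.approx(0.135, abs=5e-4)

    def test_constant_values(self):
        mu, sigma, cv = br.cohort_mu_sigma([0.3, 0.3, 0.3])
        assert sigma == 0.0 and cv == 0.0

    def test_cv_scale_invariant(self):
        vals = [1.0, 1.2, 0.9, 1.1]
        _, _, cv1 = br.cohort_mu_sigma(vals)
        _, _, cv2 = br.cohort_mu_sigma([10 * v for v in vals])
        assert cv2 == pytest.approx(cv1)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            br.cohort_mu_sigma([1.0])


class TestPrecisionError:
    def test_identical_repeats_zero_error(self):
        assert br.precision_error_st([[10.0, 10.0], [5.0, 5.0, 5.0]]) == 0.0

    def test_two_participant_arithmetic(self):
        # participant CVs are 0% and sqrt(2)/10 = 14.142%; RMS -> 10.0%
        assert br.precision_error_st([[10.0, 10.0], [9.0, 11.0]]) == pytest.approx(10.0)

    def test_monte_carlo_matches_configured_cv(self):
        """1000 simulated repeat pairs, each scan at 0.427% CV, recover PE_st."""
        rng = np.random.default_rng(7)
        true = rng.uniform(0.2, 0.35, 1000)
        scans = true[:, None] * (1.0 + rng.normal(0.0, 0.00427, (1000, 2)))
        pe = br.precision_error_st(scans)
        assert pe == pytest.approx(0.427, abs=0.03)

    def test_generator_repeat_pairs_recover_configured_cv(self):
        """End to end: the synthetic precision subgroup reproduces its CV."""
        cfg = br.SyntheticConfig(
            seed=19,
            n_female=1000,
            n_male=0,
            n_repeat={"F": 1000, "M": 0},
            trends={
                ("F", "tibia", "Tot.vBMD"): ParameterTrend(
                    young_mean=0.266, young_sd=0.036, annual_change=0.0, repeat_cv=0.427
                )
            },
        )
        groups: dict[str, list[float]] = {}
        for r in br.generate_cohort(cfg):
            groups.setdefault(r.participant_id, []).append(r.measurements["Tot.vBMD"])
        pe = br.precision_error_st(list(groups.values()))
        assert pe == pytest.approx(0.427, abs=0.03)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="group 1"):
            br.precision_error_st([[10.0, 10.0], [9.0]])


class TestMedianAnnualChange:
    def test_flat_curve_zero_change(self):
        curve = br.ReferenceCurve.from_curvature(
            "Tot.vBMD", "F", "tibia", baseline_mean=0.266, baseline_sd=0.036, c=0.0
        )
        assert br.median_annual_change(curve) == 0.0

    def test_inverse_forward_round_trip(self):
        """solve_curvature then median_annual_change returns the target rate."""
        c = br.solve_curvature(-0.753, 0.266)
        curve = br.ReferenceCurve.from_curvature(
            "Tot.vBMD", "F", "tibia", baseline_mean=0.266, baseline_sd=0.036, c=c
        )
        assert br.median_annual_change(curve) == pytest.approx(-0.753, abs=1e-6)

    @pytest.mark.parametrize("rate", [-0.5, 0.4])
    def test_sign_follows_curvature(self, rate):
        c = br.solve_curvature(rate, 1.0)
        curve = br.ReferenceCurve.from_curvature(
            "Tb.DA", "F", "tibia", baseline_mean=1.0, baseline_sd=0.1, c=c
        )
        assert math.copysign(1, br.median_annual_change(curve)) == math.copysign(1, c)

    def test_grid_is_integer_ages_38_to_92(self):
        assert DEFAULT_AGE_GRID[0] == 38.0 and DEFAULT_AGE_GRID[-1] == 92.0
        assert len(DEFAULT_AGE_GRID) == 55


class TestTrendAssessmentInterval:
    def test_arithmetic(self):
        assert br.trend_assessment_interval(1.0, 1.8) == pytest.approx(1.0)

    def test_published_female_tibia_row(self):
        # PE 0.427%, rate -0.753 %/yr -> 1.0207 yr, printed 1.021
        tai = br.trend_assessment_interval(0.427, -0.753)
        assert tai == pytest.approx(1.021, abs=5e-4)

    def test_zero_trend_not_assessable(self):
        assert math.isinf(br.trend_assessment_interval(0.5, 0.0))

    def test_homogeneity(self):
        base = br.trend_assessment_interval(1.0, -0.5)
        assert br.trend_assessment_interval(2.0, -0.5) == pytest.approx(2 * base)
        assert br.trend_assessment_interval(1.0, -1.0) == pytest.approx(base / 2)

    def test_negative_pe_rejected(self):
        with pytest.raises(ValueError):
            br.trend_assessment_interval(-0.1, 1.0)


def _tai_interval(row, decimals_pe, decimals_rate):
    """TAI range consistent with half-ULP rounding of the printed inputs."""
    hp = 0.5 * 10.0**-decimals_pe
    hr = 0.5 * 10.0**-decimals_rate
    pe_lo, pe_hi = row.pe_st - hp, row.pe_st + hp
    r_lo, r_hi = abs(row.annual_change) - hr, abs(row.annual_change) + hr
    lo = br.trend_assessment_interval(pe_lo, r_hi)
    hi = br.trend_assessment_interval(pe_hi, r_lo) if r_lo > 0 else math.inf
    return lo, hi


class TestPublishedTableConsistency:
    """The shipped descriptive table must be internally consistent."""

    def test_tai_reproducible_from_pe_and_rate_all_rows(self):
        df = nt.descriptive_statistics()
        for row in df.itertuples(index=False):
            dp = nt.printed_decimals(row.sex, row.site, row.parameter, "pe_st")
            dr = nt.printed_decimals(row.sex, row.site, row.parameter, "annual_change")
            lo, hi = _tai_interval(row, dp, dr)
            assert lo * 0.99 <= row.tai_st <= hi * 1.01, (
                f"{row.sex}/{row.site}/{row.parameter}: printed TAI {row.tai_st} "
                f"outside rounding-consistent range [{lo:.3f}, {hi:.3f}]"
            )

    def test_cv_matches_mu_sigma_on_well_resolved_rows(self):
        """sigma/mu agrees with the printed CV at 3 dp in >= 90% of rows where
        input rounding permits a unique 3-dp value; remaining low-precision
        rows (e.g. Ct.Po) are covered by an interval check."""
        df = nt.descriptive_statistics()
        exact_eligible = exact_hits = 0
        for row in df.itertuples(index=False):
            dm = nt.printed_decimals(row.sex, row.site, row.parameter, "mu")
            ds = nt.printed_decimals(row.sex, row.site, row.parameter, "sigma")
            hm, hs = 0.5 * 10.0**-dm, 0.5 * 10.0**-ds
            lo = (row.sigma - hs) / (row.mu + hm)
            hi = (row.sigma + hs) / (row.mu - hm)
            assert lo - 5e-4 <= row.cv <= hi + 5e-4, (
                f"{row.sex}/{row.site}/{row.parameter}: printed CV {row.cv} "
                f"inconsistent with printed mu/sigma"
            )
            if round(lo, 3) == round(hi, 3):  # rounding permits a unique 3-dp CV
                exact_eligible += 1
                exact_hits += round(row.sigma / row.mu, 3) == round(row.cv, 3)
        assert exact_eligible > 0
        assert exact_hits / exact_eligible >= 0.9


class TestSummarize:
    def _cohort(self):
        cfg = br.SyntheticConfig(
            seed=13,
            n_female=120,
            n_male=0,
            n_repeat={"F": 25, "M": 0},
            trends={
                ("F", "tibia", "Tot.vBMD"): ParameterTrend(
                    young_mean=0.266, young_sd=0.036, annual_change=-0.753, repeat_cv=0.427
                )
            },
        )
        return br.generate_cohort(cfg)

    def test_row_composition_against_generator_truth(self):
        records = self._cohort()
        curve = br.fit_reference_curve(records, "Tot.vBMD", "F", "tibia")
        s = br.summarize_stratum(records, "Tot.vBMD", "F", "tibia", curve)
        assert s.pe_st == pytest.approx(0.427, abs=0.2)
        assert s.annual_change == pytest.approx(-0.753, abs=0.35)
        assert s.tai_st == pytest.approx(1.8 * s.pe_st / abs(s.annual_change), rel=1e-9)
        assert s.assessable

    def test_imported_pe_constant_wins(self):
        records = self._cohort()
        curve = br.fit_reference_curve(records, "Tot.vBMD", "F", "tibia")
        s = br.summarize_stratum(records, "Tot.vBMD", "F", "tibia", curve, pe_st=0.427)
        assert s.pe_st == 0.427

    def test_no_repeats_no_precision_columns(self):
        records = [r for r in self._cohort() if r.repeat_index == 0]
        s = br.summarize_stratum(records, "Tot.vBMD", "F", "tibia")
        assert s.pe_st is None and s.tai_st is None and not s.assessable
        row = s.as_row()
        assert row["pe_st"] is None and row["tai_st"] is None

    def test_infinite_tai_serialized_as_flag(self):
        s = br.PrecisionSummary(
            "Tb.DA", br.Sex.F, br.Site.TIBIA, 1.7, 0.07, 0.04, 1.0, 0.0, math.inf
        )
        row = summary_table([s]).iloc[0]
        assert row["not_assessable"]
        assert row["tai_st"] is None or (isinstance(row["tai_st"], float) and math.isnan(row["tai_st"]))
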