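"""Lognormal calibration and the synthetic-cohort generator."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import binom

import screenacc as sa
from screenacc import reference
from screenacc.simulate import SYMPTOMS


class TestCalibration:
    def test_anchors_reproduced_to_numerical_precision(self):
        params = sa.calibrate_lognormal(19, 0.400, 34, 0.200)
        assert params.survival(19) == pytest.approx(0.400, abs=1e-10)
        assert params.survival(34) == pytest.approx(0.200, abs=1e-10)

    def test_specificity_anchors(self):
        # comparator calibrated through 1 - SPE exceedances
        params = sa.calibrate_lognormal(19, 1 - 0.816, 34, 1 - 0.936)
        assert params.survival(19) == pytest.approx(0.184, abs=1e-10)
        assert params.survival(34) == pytest.approx(0.064, abs=1e-10)

    def test_median_is_exp_mu(self):
        params = sa.calibrate_lognormal(19, 0.45, 34, 0.10)
        assert params.survival(np.exp(params.mu)) == pytest.approx(0.5, abs=1e-12)

    def test_rounded_variant_targets_half_step(self):
        params = sa.calibrate_lognormal(19, 0.4, 34, 0.2, rounded=True)
        assert params.survival(19.5) == pytest.approx(0.4, abs=1e-10)
        assert params.survival(34.5) == pytest.approx(0.2, abs=1e-10)

    def test_degenerate_spacing_trips_sigma_guard(self):
        with pytest.raises(sa.CalibrationError, match="sigma"):
            sa.calibrate_lognormal(19, 0.5, 34, 0.5 - 1e-12)

    @pytest.mark.parametrize("p1, p2", [(0.3, 0.3), (0.2, 0.4), (1.0, 0.5), (0.5, 0.0)])
    def test_invalid_exceedances_rejected(self, p1, p2):
        with pytest.raises(sa.CalibrationError):
            sa.calibrate_lognormal(19, p1, 34, p2)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            sa.LognormalParams(mu=1.0, sigma=0.0)


class TestCohortSpec:
    def test_default_spec_matches_study_conditions(self, default_spec):
        assert default_spec.n == reference.COHORT_SIZE
        assert default_spec.asthma_prevalence == pytest.approx(37 / 447)
        # expected outcome counts reproduce the published table
        for s in ("cough_night", "cough_day", "rhinitis"):
            pa, pn = default_spec.symptom_probs[s]
            expected = 37 * pa + 410 * pn
            assert expected == pytest.approx(reference.OUTCOME_COUNTS[s], rel=1e-9)
        # expected isolated-asthma count is the published 5
        prod = np.prod([1 - default_spec.symptom_probs[s][0] for s in SYMPTOMS])
        assert 37 * prod == pytest.approx(5, rel=1e-9)

    def test_invalid_probability_rejected(self, default_spec):
        probs = dict(default_spec.symptom_probs)
        probs["wheeze"] = (1.2, 0.1)
        with pytest.raises(ValueError, match="wheeze"):
            replace(default_spec, symptom_probs=probs)

    def test_bad_sizes_rejected(self, default_spec):
        with pytest.raises(ValueError):
            replace(default_spec, n=0)
        with pytest.raises(ValueError):
            replace(default_spec, feno_floor=-1)


class TestGeneration:
    def test_seed_determinism_byte_identical(self, tmp_path, default_spec):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        sa.write_cohort_csv(sa.generate_cohort(default_spec), a)
        sa.write_cohort_csv(sa.generate_cohort(default_spec), b)
        assert a.read_bytes() == b.read_bytes()
        other = sa.generate_cohort(replace(default_spec, seed=default_spec.seed + 1))
        assert not other.equals(sa.generate_cohort(default_spec))

    def test_asthma_count_within_binomial_bounds(self, default_spec):
        counts = [
            sa.generate_cohort(replace(default_spec, seed=s))["asthma"].sum()
            for s in range(20)
        ]
        lo, hi = binom.ppf([0.0005, 0.9995], 447, 37 / 447)
        assert all(lo <= c <= hi for c in counts)

    def test_single_record_cohort(self, default_spec):
        df = sa.generate_cohort(replace(default_spec, n=1))
        assert len(df) == 1
        assert df.loc[0, "feno_ppb"] >= default_spec.feno_floor

    def test_all_prevalences_zero_gives_symptom_free_cohort(self, default_spec):
        spec = replace(
            default_spec,
            n=500,
            asthma_prevalence=0.0,
            symptom_probs={s: (0.0, 0.0) for s in SYMPTOMS},
        )
        df = sa.generate_cohort(spec)
        assert (df[list(sa.INDICATOR_COLUMNS)] == 0).all().all()
        # all values then come from the symptom-free distribution
        emp = (df["feno_ppb"] > 19).mean()
        expected = spec.group_distributions["healthy"].survival(19.5)
        assert emp == pytest.approx(expected, abs=0.06)

    def test_floor_clamping(self, default_spec):
        df = sa.generate_cohort(replace(default_spec, n=2000, feno_floor=12))
        assert df["feno_ppb"].min() >= 12

    def test_rounding_shifts_exceedance_by_half_step(self):
        """Empirical exceedance on rounded values equals the continuous
        survival at c + 0.5, not at c."""
        params = sa.calibrate_lognormal(19, 0.4, 34, 0.2)  # continuous anchors
        rng = np.random.default_rng(11)
        x = np.rint(params.sample(400_000, rng))
        emp = (x > 19).mean()
        assert emp == pytest.approx(params.survival(19.5), abs=0.003)
        assert abs(emp - params.survival(19.0)) > 0.005  # the bias is real


class TestRecovery:
    def test_recovers_calibrated_anchors(self, default_spec):
        spec = replace(
            default_spec,
            group_distributions={
                **default_spec.group_distributions,
                "asthma": sa.calibrate_lognormal(19, 0.400, 34, 0.200, rounded=True),
                "healthy": sa.calibrate_lognormal(19, 0.184, 34, 0.064, rounded=True),
            },
        )
        rec = sa.recover_metrics(spec, 200_000, [19, 24, 34])
        assert rec[19].sen == pytest.approx(0.400, abs=0.005)
        assert rec[34].sen == pytest.approx(0.200, abs=0.005)
        assert rec[19].spe == pytest.approx(0.816, abs=0.005)
        assert rec[34].spe == pytest.approx(0.936, abs=0.005)

    def test_zero_size_rejected(self, default_spec):
        with pytest.raises(ValueError):
            sa.recover_metrics(default_spec, 0, [19])


class TestSpecFile:
    def test_load_roundtrip_and_overrides(self, tmp_path):
        p = tmp_path / "spec.toml"
        p.write_text(
            "seed = 9\nn = 100\nfeno_floor = 6\nasthma_prevalence = 0.2\n"
            "[symptoms.given_asthma]\ncough_night = 0.9\n"
            "[feno.asthma]\nmu = 3.0\nsigma = 0.5\n"
        )
        spec = sa.load_cohort_spec(p)
        assert (spec.seed, spec.n, spec.feno_floor) == (9, 100, 6)
        assert spec.asthma_prevalence == 0.2
        assert spec.symptom_probs["cough_night"][0] == 0.9
        assert spec.group_distributions["asthma"] == sa.LognormalParams(3.0, 0.5)
        # untouched entries keep the study defaults
        assert spec.symptom_probs["rhinitis"][0] == pytest.approx(106 / 447)

    def test_seed_mandatory(self, tmp_path):
        p = tmp_path / "spec.toml"
        p.write_text("n = 10\n")
        with pytest.raises(ValueError, match="seed"):
            sa.load_cohort_spec(p)
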