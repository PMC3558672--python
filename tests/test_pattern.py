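"""Three-stage skeleton: evaluation, least-squares recovery, phenotype calls."""

import math

import numpy as np
import pytest

from ovisim import NoReproductionError
from ovisim.pattern import (
    ClassifierThresholds,
    ThreeStageParams,
    classify_phenotype,
    fit_three_stage,
    reproduction_end,
    three_stage_curve,
    three_stage_value,
)
from ovisim.simulate import ReproductivePattern

M_FLY = ThreeStageParams(t0=3, T=16, RC=66.0, tau=18.0, LS=60)

# grid of generating parameter sets for exact-recovery checks (the first is
# the reference m-type skeleton)
RECOVERY_GRID = [
    (3, 16, 66.0, 18.0, 60),
    (2, 10, 30.0, 5.0, 45),
    (2, 10, 55.0, 12.0, 45),
    (2, 16, 30.0, 12.0, 60),
    (2, 24, 66.0, 5.0, 45),
    (2, 24, 55.0, 18.0, 80),
    (3, 10, 66.0, 12.0, 80),
    (3, 16, 30.0, 5.0, 45),
    (3, 24, 55.0, 5.0, 60),
    (3, 24, 30.0, 18.0, 80),
    (4, 10, 55.0, 18.0, 60),
    (4, 16, 66.0, 12.0, 45),
    (4, 24, 66.0, 18.0, 80),
    (4, 10, 30.0, 12.0, 60),
    (2, 30, 40.0, 8.0, 70),
    (3, 12, 45.0, 25.0, 90),
    (5, 20, 70.0, 10.0, 55),
    (2, 8, 25.0, 6.0, 40),
    (6, 30, 50.0, 15.0, 75),
    (3, 18, 60.0, 20.0, 70),
]


class TestThreeStageValue:
    def test_plateau_endpoint_is_continuous(self):
        assert three_stage_value(M_FLY, M_FLY.T) == M_FLY.RC
        just_after = three_stage_value(M_FLY, M_FLY.T + 1e-9)
        assert just_after == pytest.approx(M_FLY.RC)

    def test_time_constant_definition(self):
        assert three_stage_value(M_FLY, M_FLY.T + M_FLY.tau) == pytest.approx(
            M_FLY.RC / math.e
        )

    def test_zero_before_first_egg(self):
        assert three_stage_value(M_FLY, M_FLY.t0 - 1) == 0.0

    def test_domain_error_outside_life(self):
        with pytest.raises(ValueError, match="domain"):
            three_stage_value(M_FLY, 0)
        with pytest.raises(ValueError, match="domain"):
            three_stage_value(M_FLY, M_FLY.LS + 1)

    @pytest.mark.parametrize("raw", RECOVERY_GRID[:5])
    def test_non_increasing_after_first_egg(self, raw):
        params = ThreeStageParams(*raw)
        curve = three_stage_curve(params)[params.t0 - 1 :]
        assert (np.diff(curve) <= 1e-12).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ThreeStageParams(t0=5, T=3, RC=10.0, tau=1.0, LS=20)
        with pytest.raises(ValueError):
            ThreeStageParams(t0=1, T=3, RC=10.0, tau=0.0, LS=20)


class TestFitRecovery:
    @pytest.mark.parametrize("raw", RECOVERY_GRID)
    def test_exact_data_recovered_with_zero_residual(self, raw):
        truth = ThreeStageParams(*raw)
        fit = fit_three_stage(three_stage_curve(truth))
        assert fit.rss < 1e-8
        assert fit.params.t0 == truth.t0
        assert fit.params.T == truth.T
        assert fit.params.LS == truth.LS
        assert fit.params.RC == pytest.approx(truth.RC, rel=1e-9)
        assert fit.params.tau == pytest.approx(truth.tau, rel=1e-6)

    def test_integer_rounded_m_fly_recovered_closely(self):
        pattern = np.round(three_stage_curve(M_FLY))
        fit = fit_three_stage(pattern)
        assert abs(fit.params.T - M_FLY.T) <= 1
        assert abs(fit.params.RC - M_FLY.RC) <= 1.0
        assert abs(fit.params.tau - M_FLY.tau) <= 0.1 * M_FLY.tau

    def test_pure_plateau_has_no_tail(self):
        pattern = np.full(30, 7.0)
        fit = fit_three_stage(pattern)
        assert fit.params.T == 30
        assert fit.params.RC == 7.0
        assert fit.rss == 0.0

    def test_all_zero_pattern_is_an_error(self):
        with pytest.raises(NoReproductionError):
            fit_three_stage(np.zeros(20))

    def test_tie_breaks_toward_smallest_plateau_end(self):
        # two trailing zero days: T = day of last egg fits exactly, and so
        # does any later T (RC unchanged, zero tail) - the earliest wins
        pattern = np.array([0.0, 5.0, 5.0, 5.0, 0.0, 0.0])
        fit = fit_three_stage(pattern)
        assert fit.params.T == 4


def _pattern_from(curve: np.ndarray) -> ReproductivePattern:
    eggs = tuple(int(v) for v in np.round(curve))
    return ReproductivePattern(daily_eggs=eggs, life_span=len(eggs))


class TestClassification:
    def test_death_mid_plateau_is_overload(self):
        eggs = (0, 0) + (66,) * 18
        pattern = ReproductivePattern(daily_eggs=eggs, life_span=20)
        call = classify_phenotype(pattern, fit_three_stage(np.array(eggs, float)))
        assert call.label == "s"
        assert call.death_cause == "overload"

    def test_long_post_reproductive_survival_is_l(self):
        truth = ThreeStageParams(t0=3, T=10, RC=50.0, tau=4.0, LS=60)
        pattern = _pattern_from(three_stage_curve(truth))
        call = classify_phenotype(pattern, fit_three_stage(pattern))
        assert call.label == "l"
        assert call.death_cause == "senescence"

    def test_death_at_reproduction_end_is_m(self):
        truth = ThreeStageParams(t0=3, T=16, RC=66.0, tau=18.0, LS=60)
        pattern = _pattern_from(three_stage_curve(truth))
        call = classify_phenotype(pattern, fit_three_stage(pattern))
        assert call.label == "m"
        assert call.death_cause == "senescence"

    def test_appending_zero_days_keeps_l(self):
        truth = ThreeStageParams(t0=3, T=10, RC=50.0, tau=4.0, LS=60)
        base = _pattern_from(three_stage_curve(truth))
        extended = ReproductivePattern(
            daily_eggs=base.daily_eggs + (0,) * 15, life_span=base.life_span + 15
        )
        for pat in (base, extended):
            call = classify_phenotype(pat, fit_three_stage(pat))
            assert call.label == "l"

    def test_truncation_before_reproduction_end_never_l(self):
        truth = ThreeStageParams(t0=3, T=10, RC=50.0, tau=4.0, LS=60)
        curve = three_stage_curve(truth)
        cut = int(reproduction_end(truth)) - 1
        truncated = _pattern_from(curve[:cut])
        call = classify_phenotype(truncated, fit_three_stage(truncated))
        assert call.label != "l"

    def test_thresholds_are_reported_in_evidence(self):
        eggs = (0, 0) + (66,) * 18
        pattern = ReproductivePattern(daily_eggs=eggs, life_span=20)
        thresholds = ClassifierThresholds(epsilon=0.1, post_margin=3.0)
        call = classify_phenotype(pattern, fit_three_stage(np.array(eggs, float)),
                                  thresholds)
        assert call.evidence["thresholds"] == thresholds
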