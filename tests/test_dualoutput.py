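import numpy as np
import pytest

from mcifkit import (
    DualOutputParams,
    FengInput,
    McifFitConfig,
    SpilloverParams,
    TimeActivityCurve,
    TwoTissueParams,
    build_frame_schedule,
    extract_mcif,
    fit_mcif,
    model_idif_frames,
    model_myo_frames,
    objective_o1,
    objective_o2,
    tissue_curve,
)


def make_params(feng, S_mb=0.3, S_bm=0.2, r_b=0.8, r_m=0.7, kin=(0.3, 0.4, 0.08, 0.0)):
    return DualOutputParams(
        input=feng,
        kinetics=TwoTissueParams(*kin),
        contamination=SpilloverParams(S_mb=S_mb, S_bm=S_bm, r_b=r_b, r_m=r_m),
    )


class TestModelOutputs:
    def test_idif_reduces_to_blood_without_contamination(self, feng, schedule23):
        p = make_params(feng, S_mb=0.0, r_b=1.0)
        expected = feng.curve().frame_average(schedule23.starts, schedule23.ends)
        assert np.allclose(model_idif_frames(p, schedule23), expected, rtol=1e-12)

    def test_idif_linear_combination(self, feng, schedule23):
        p = make_params(feng, S_mb=0.3, r_b=0.8)
        ca = feng.curve().frame_average(schedule23.starts, schedule23.ends)
        ct = tissue_curve(p.kinetics, feng).frame_average(schedule23.starts, schedule23.ends)
        assert np.allclose(model_idif_frames(p, schedule23), 0.3 * ct + 0.8 * ca, rtol=1e-12)

    def test_myo_reduces_to_tissue_without_contamination(self, feng, schedule23):
        p = make_params(feng, S_bm=0.0, r_m=1.0)
        expected = tissue_curve(p.kinetics, feng).frame_average(schedule23.starts, schedule23.ends)
        assert np.allclose(model_myo_frames(p, schedule23), expected, rtol=1e-12)

    def test_myo_pure_blood_spillover_when_no_uptake(self, feng, schedule23):
        p = make_params(feng, S_bm=0.5, kin=(0.0, 0.3, 0.1, 0.0))
        ca = feng.curve().frame_average(schedule23.starts, schedule23.ends)
        assert np.allclose(model_myo_frames(p, schedule23), 0.5 * ca, rtol=1e-12)


class TestObjectives:
    def test_self_residual_is_zero(self, feng, schedule23):
        p = make_params(feng)
        idif = TimeActivityCurve(schedule23, model_idif_frames(p, schedule23))
        myo = TimeActivityCurve(schedule23, model_myo_frames(p, schedule23))
        assert objective_o1(p, idif, myo) == pytest.approx(0.0, abs=1e-18)
        assert objective_o2(p, idif, myo) == pytest.approx(0.0, abs=1e-18)

    def test_uniform_offset_counts_frames(self, feng, schedule23):
        p = make_params(feng)
        idif = TimeActivityCurve(schedule23, model_idif_frames(p, schedule23) + 1.0)
        myo = TimeActivityCurve(schedule23, model_myo_frames(p, schedule23))
        assert objective_o1(p, idif, myo) == pytest.approx(23.0, rel=1e-10)

    def test_o1_matches_brute_force_loop(self, feng, schedule23):
        rng = np.random.default_rng(5)
        p = make_params(feng)
        idif_v = model_idif_frames(p, schedule23) + rng.normal(0, 2, 23)
        myo_v = model_myo_frames(p, schedule23) + rng.normal(0, 2, 23)
        idif = TimeActivityCurve(schedule23, idif_v, allow_negative=True)
        myo = TimeActivityCurve(schedule23, myo_v, allow_negative=True)
        brute = sum(
            (model_idif_frames(p, schedule23)[i] - idif_v[i]) ** 2
            + (model_myo_frames(p, schedule23)[i] - myo_v[i]) ** 2
            for i in range(23)
        )
        assert objective_o1(p, idif, myo) == pytest.approx(brute, rel=1e-12)

    def test_o1_invariant_under_frame_permutation_of_identical_frames(self, feng, schedule23):
        # two frames with identical data contribute symmetrically to the sum
        p = make_params(feng)
        v = model_idif_frames(p, schedule23)
        v2 = v.copy()
        v2[[3, 4]] = v2[[4, 3]]
        myo = TimeActivityCurve(schedule23, model_myo_frames(p, schedule23))
        a = objective_o1(p, TimeActivityCurve(schedule23, v, allow_negative=True), myo)
        v_sym = v.copy()
        v_sym[3] = v_sym[4] = v[[3, 4]].mean()
        b = objective_o1(p, TimeActivityCurve(schedule23, v_sym, allow_negative=True), myo)
        v_sym2 = v_sym.copy()
        v_sym2[[3, 4]] = v_sym2[[4, 3]]
        c = objective_o1(p, TimeActivityCurve(schedule23, v_sym2, allow_negative=True), myo)
        assert b == pytest.approx(c, rel=1e-14)
        assert a >= 0 and b >= 0

    def test_o2_single_term_square(self, feng, schedule23):
        p = make_params(feng)
        idif_v = model_idif_frames(p, schedule23)
        myo_v = model_myo_frames(p, schedule23)
        shifted = np.minimum(idif_v, idif_v.max() - 2.0)  # data blood peak 2 below model peak
        idif = TimeActivityCurve(schedule23, shifted)
        myo = TimeActivityCurve(schedule23, myo_v)
        o2 = objective_o2(p, idif, myo)
        assert o2 == pytest.approx(4.0, rel=1e-9)

    def test_schedule_mismatch_rejected(self, feng, schedule23):
        p = make_params(feng)
        other = build_frame_schedule([(23, 60)])
        idif = TimeActivityCurve(schedule23, model_idif_frames(p, schedule23))
        myo = TimeActivityCurve(other, np.ones(23))
        with pytest.raises(ValueError):
            objective_o1(p, idif, myo)


class TestFitMcif:
    def test_o_total_is_sum_of_components(self, truth, clean_study):
        cfg = McifFitConfig(
            n_starts=2, seed=1, fix_k4=True,
            r_b_fixed=truth.dual.contamination.r_b,
            r_m_fixed=truth.dual.contamination.r_m,
        )
        fit = fit_mcif(clean_study.pet_idif, clean_study.pet_myo, cfg)
        assert fit.o_total == pytest.approx(fit.o1 + fit.o2)
        assert fit.o1 >= 0 and fit.o2 >= 0

    def test_noiseless_recovery_of_input_auc(self, truth, clean_study):
        cfg = McifFitConfig(
            n_starts=3, seed=1, fix_k4=True,
            r_b_fixed=truth.dual.contamination.r_b,
            r_m_fixed=truth.dual.contamination.r_m,
        )
        fit = fit_mcif(clean_study.pet_idif, clean_study.pet_myo, cfg)
        auc_true = truth.dual.input.auc(60.0)
        auc_fit = fit.params.input.auc(60.0)
        assert abs(auc_fit - auc_true) / auc_true < 0.02

    def test_underdetermined_schedule_rejected(self, feng):
        sched = build_frame_schedule([(10, 360)])
        p = make_params(feng)
        idif = TimeActivityCurve(sched, model_idif_frames(p, sched))
        myo = TimeActivityCurve(sched, model_myo_frames(p, sched))
        with pytest.raises(ValueError, match="15 parameters"):
            fit_mcif(idif, myo)

    def test_deterministic_given_seed(self, truth, clean_study):
        cfg = McifFitConfig(
            n_starts=2, seed=9, fix_k4=True,
            r_b_fixed=truth.dual.contamination.r_b,
            r_m_fixed=truth.dual.contamination.r_m,
        )
        a = fit_mcif(clean_study.pet_idif, clean_study.pet_myo, cfg)
        b = fit_mcif(clean_study.pet_idif, clean_study.pet_myo, cfg)
        assert a.params == b.params
        assert a.o_total == b.o_total


@pytest.fixture(scope="module")
def fit(truth, clean_study):
    cfg = McifFitConfig(
        n_starts=3, seed=1, fix_k4=True,
        r_b_fixed=truth.dual.contamination.r_b,
        r_m_fixed=truth.dual.contamination.r_m,
    )
    return fit_mcif(clean_study.pet_idif, clean_study.pet_myo, cfg)


class TestExtractMcif:
    def test_recovers_generating_curve_pointwise(self, fit, truth):
        t = np.linspace(0.5, 60, 120)
        mcif = extract_mcif(fit, times=t)
        peak = truth.dual.input.peak()[1]
        assert np.max(np.abs(mcif.activities - truth.dual.input(t))) <= 0.02 * peak

    def test_zero_before_appearance_delay(self, fit):
        tau = fit.params.input.tau
        if tau > 1e-3:
            series = extract_mcif(fit, times=np.array([tau / 2, 30.0]))
            assert series.activities[0] == 0.0

    def test_auc_consistent_with_closed_form(self, fit, schedule23):
        tac = extract_mcif(fit, schedule=schedule23)
        # frame-averaged values times frame widths telescope into int_0^60 Ca
        approx = float(np.sum(tac.values * schedule23.durations))
        assert approx == pytest.approx(fit.params.input.auc(60.0), rel=1e-10)
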