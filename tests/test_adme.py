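import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qivikit as qk
from qivikit.adme import (
    BloodPlasmaMeasurement,
    DepletionTimeseries,
    PermeabilityTimeseries,
    REDMeasurement,
    bp_ratio,
    clint_from_depletion,
    fill_missing_parameters,
    fub_from_red,
    ke_p_from_bp,
    papp_from_timeseries,
    renal_clearance,
    scale_clint,
)
from qivikit.records import CompoundRecord, Provenance, ValidationError
from qivikit.synthetic import GeneratorConfig, gen_depletion_ts, gen_permeability_ts


def _linear_series(slope, c0=10.0, area=1.12, vr=1.5):
    t = np.array([1800.0, 3600.0, 5400.0, 7200.0])
    return PermeabilityTimeseries(
        times=t, receiver_conc=slope * t, c0=c0, area=area, receiver_volume=vr,
    )


class TestPapp:
    def test_hand_arithmetic(self):
        # slope 2.688e-5 nmol/mL/s, Vr 1.5 mL, A 1.12 cm2, C0 10 nmol/mL
        est = papp_from_timeseries(_linear_series(2.688e-5))
        assert est.value == pytest.approx(3.6e-6, rel=1e-6)

    def test_zero_slope_zero_papp(self):
        est = papp_from_timeseries(_linear_series(0.0))
        assert est.value == 0.0

    def test_negative_slope_clamps_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            est = papp_from_timeseries(_linear_series(-1e-6))
        assert est.value == 0.0
        assert "clamped" in caplog.text

    def test_noise_free_round_trip(self):
        cfg = GeneratorConfig(seed=1, cv=0.0, replicates=3)
        reps = gen_permeability_ts(3.92e-6, cfg)
        est = papp_from_timeseries(reps)
        assert est.value == pytest.approx(3.92e-6, abs=1e-9)
        assert est.sd == pytest.approx(0.0, abs=1e-15)

    def test_noisy_replicates_recover_within_cv(self):
        recovered = []
        for seed in range(30):
            cfg = GeneratorConfig(seed=seed, cv=0.1, replicates=3)
            recovered.append(papp_from_timeseries(
                gen_permeability_ts(3.92e-6, cfg)).value)
        med = np.median(recovered) / 3.92e-6
        assert 0.9 < med < 1.1

    def test_too_few_points(self):
        ts = PermeabilityTimeseries(times=[60.0], receiver_conc=[0.1], c0=10,
                                    area=1.12, receiver_volume=1.5)
        with pytest.raises(ValidationError):
            papp_from_timeseries(ts)


class TestClint:
    def test_closed_form_half_life(self):
        # t1/2 = 60 min -> k = ln2/60, Clint = k*100/0.0525 = 22.0
        t = np.array([0.0, 15, 30, 60, 120, 240.0])
        dep = DepletionTimeseries(times=t, conc=1500 * np.exp(-math.log(2) / 60 * t))
        out = clint_from_depletion(dep)
        assert out["k"] == pytest.approx(math.log(2) / 60, rel=1e-9)
        assert out["half_life"] == pytest.approx(60.0, rel=1e-9)
        assert out["clint"] == pytest.approx(22.007, rel=1e-3)

    def test_flat_profile_returns_zero(self):
        dep = DepletionTimeseries(times=[0.0, 30, 60, 120], conc=[5.0, 5, 5, 5])
        out = clint_from_depletion(dep)
        assert out["clint"] == 0.0
        assert out["half_life"] == math.inf

    def test_printed_constant_behind_flag(self):
        t = np.array([0.0, 15, 30, 60, 120, 240.0])
        dep = DepletionTimeseries(times=t, conc=1500 * np.exp(-0.01 * t))
        default = clint_from_depletion(dep)
        legacy = clint_from_depletion(dep, legacy_half_life_constant=True)
        assert default["half_life"] == pytest.approx(math.log(2) / 0.01)
        assert legacy["half_life"] == pytest.approx(0.639 / 0.01)

    def test_rescaling_invariance(self):
        cfg = GeneratorConfig(seed=9, cv=0.05)
        dep = gen_depletion_ts(5.27, cfg)
        scaled = DepletionTimeseries(
            times=dep.times, conc=np.asarray(dep.conc) * 137.0,
            incubation_volume=dep.incubation_volume, cells=dep.cells,
        )
        a = clint_from_depletion(dep)
        b = clint_from_depletion(scaled)
        assert a["clint"] == pytest.approx(b["clint"], rel=1e-9)

    def test_noisy_recovery_within_15pct(self):
        hits = 0
        for seed in range(40):
            cfg = GeneratorConfig(seed=seed, cv=0.05)
            out = clint_from_depletion(gen_depletion_ts(5.27, cfg))
            if abs(out["clint"] - 5.27) / 5.27 < 0.15:
                hits += 1
        assert hits >= 36  # >= 90% of seeds


class TestFub:
    def test_no_binding(self):
        est = fub_from_red([REDMeasurement(c_buffer=10.0, c_plasma=10.0)])
        assert est.value == 1.0

    def test_direct_ratio(self):
        est = fub_from_red([REDMeasurement(c_buffer=1.0, c_plasma=10.0)])
        assert est.value == pytest.approx(0.1)

    def test_replicate_mean_sd(self):
        meas = [REDMeasurement(c_buffer=b, c_plasma=1.0)
                for b in (0.059, 0.060, 0.061)]
        est = fub_from_red(meas)
        assert est.value == pytest.approx(0.06, abs=1e-12)
        assert est.sd == pytest.approx(0.001, rel=1e-9)

    def test_dilution_correction_pulls_down(self):
        meas = [REDMeasurement(c_buffer=2.0, c_plasma=10.0,
                               plasma_fraction_in_test=0.5)]
        raw = fub_from_red(meas).value
        corrected = fub_from_red(meas, dilution_correction=True).value
        assert corrected < raw
        # fu' = 0.2 at 50% plasma -> fub = 1/(2*(1/0.2-1)+1) = 1/9
        assert corrected == pytest.approx(1.0 / 9.0, rel=1e-9)


class TestBloodPlasma:
    def test_uniform_distribution(self):
        assert bp_ratio(BloodPlasmaMeasurement(ke_p=1.0, haematocrit=0.3)) == 1.0

    def test_published_example(self):
        kbp = bp_ratio(BloodPlasmaMeasurement(ke_p=0.84, haematocrit=0.375))
        assert kbp == pytest.approx(0.94, abs=0.0001)

    def test_excluded_from_erythrocytes(self):
        kbp = bp_ratio(BloodPlasmaMeasurement(ke_p=0.0, haematocrit=0.375))
        assert kbp == pytest.approx(0.625)

    @given(st.floats(0.0, 3.0), st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_inverse_composes_to_identity(self, kep, h):
        kbp = bp_ratio(BloodPlasmaMeasurement(ke_p=kep, haematocrit=h))
        assert ke_p_from_bp(kbp, h) == pytest.approx(kep, abs=1e-9)

    def test_raw_pair_pathway(self):
        m = BloodPlasmaMeasurement(haematocrit=0.375, c_plasma_from_blood=1.0,
                                   c_plasma_only=0.94)
        assert bp_ratio(m) == pytest.approx(0.94, abs=1e-9)


class TestScaling:
    def test_unit_conversion_oracle(self, rat_phys):
        # 1 uL/min/1e6 * 107 * 11.9 g = 1273.3 uL/min = 76.4 mL/h
        out = scale_clint(1.0, "PHH", 1.0, rat_phys)
        assert out == pytest.approx(76.398, rel=1e-4)

    def test_zero_clint(self, rat_phys):
        assert scale_clint(0.0, "PHH", 0.5, rat_phys) == 0.0

    def test_published_scaled_value_within_10pct(self):
        phys19 = qk.default_physiology("rat_results_liver")
        out = scale_clint(5.27, "PHH", 0.06, phys19)
        assert out == pytest.approx(10060.66, rel=0.10)

    def test_linear_in_clint_inverse_in_fub(self, rat_phys):
        base = scale_clint(2.0, "PHH", 0.5, rat_phys)
        assert scale_clint(4.0, "PHH", 0.5, rat_phys) == pytest.approx(2 * base)
        assert scale_clint(2.0, "PHH", 0.25, rat_phys) == pytest.approx(2 * base)

    def test_nonrestrictive_toggle(self, rat_phys):
        r = scale_clint(2.0, "PHH", 0.5, rat_phys, restrictive=True)
        nr = scale_clint(2.0, "PHH", 0.5, rat_phys, restrictive=False)
        assert r == pytest.approx(2 * nr)

    def test_microsome_pathway_uses_mppgl(self, rat_phys):
        out = scale_clint(1.0, "microsomes", 1.0, rat_phys)
        assert out == pytest.approx(46 * 11.9 * 60 / 1000, rel=1e-9)

    def test_renal_examples(self):
        assert renal_clearance(9.6, 0.94, body_weight=0.35) == pytest.approx(
            189.5, abs=0.05)
        assert renal_clearance(125.0, 1.0) == pytest.approx(7500.0)
        assert renal_clearance(125.0, 0.0) == 0.0


class TestReadAcross:
    def _poor(self, name="poor-one", **kw):
        fields = dict(name=name, mw=200.0, logPow=1.5, chem_class="triazole",
                      data_status="poor")
        fields.update(kw)
        return CompoundRecord(**fields)

    def _rich(self, name, papp):
        return CompoundRecord(name=name, mw=250.0, logPow=2.0,
                              chem_class="triazole", fub=0.5, papp=papp,
                              clint_value=1.0, bp_ratio=0.95)

    def test_worst_case_and_defaults(self):
        poor = self._poor(fub=0.8)
        filled = fill_missing_parameters([self._rich("a", 2e-6),
                                          self._rich("b", 4e-6), poor])
        rec = filled[2]
        assert rec.clint_value == 0.0
        assert rec.provenance["clint_value"] is Provenance.WORST_CASE
        assert rec.bp_ratio == 1.0
        assert rec.provenance["bp_ratio"] is Provenance.READ_ACROSS
        assert rec.papp == pytest.approx(3e-6)
        assert rec.provenance["papp"] is Provenance.READ_ACROSS

    def test_fub_from_qsar_fallback(self):
        poor = self._poor(fub_qsar=0.7)
        filled = fill_missing_parameters([self._rich("a", 2e-6), poor])
        assert filled[1].fub == 0.7
        assert filled[1].provenance["fub"] is Provenance.QSAR

    def test_fub_missing_no_fallback_errors(self):
        with pytest.raises(ValidationError, match="fub"):
            fill_missing_parameters([self._rich("a", 2e-6), self._poor()])

    def test_no_classmates_errors(self):
        poor = self._poor(fub=0.5)
        with pytest.raises(ValidationError, match="class-mates"):
            fill_missing_parameters([poor])

    def test_idempotent_and_preserves_measured(self):
        rich = self._rich("a", 2e-6)
        poor = self._poor(fub=0.8)
        once = fill_missing_parameters([rich, poor])
        twice = fill_missing_parameters(once)
        assert twice[1].papp == once[1].papp
        assert twice[1].clint_value == once[1].clint_value
        assert twice[0].papp == rich.papp
        assert twice[0].provenance["papp"] is Provenance.MEASURED
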