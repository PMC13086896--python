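import math

import numpy as np
import pytest

import qivikit as qk
from qivikit.partitioning import unity_partition_set
from qivikit.pbk import (
    SEGMENTS,
    TISSUES,
    ModelError,
    ModelSpec,
    PKSummary,
    absorption_rate_constant,
    build_model,
    prediction_factor,
    simulate,
    summarize,
)
from qivikit.records import (
    CompoundRecord,
    DoseEvent,
    DosingSchedule,
    GITSegment,
    ValidationError,
)
from tests.conftest import gavage


class TestAbsorptionRateConstant:
    def test_zero_papp(self, rat_phys):
        seg = rat_phys.segment("jejunum")
        assert absorption_rate_constant(0.0, seg, seg.volume_fasted) == 0.0

    def test_proportional_to_papp_printed_ratio(self, rat_phys):
        """ka ratio for the measured Papp pair matches the printed rate
        constants (1.40E-2 / 1.04E-2 = 1.346) within 1%."""
        seg = rat_phys.segment("jejunum")
        ka1 = absorption_rate_constant(3.92e-6, seg, seg.volume_fasted)
        ka2 = absorption_rate_constant(2.90e-6, seg, seg.volume_fasted)
        assert ka1 / ka2 == pytest.approx(3.92 / 2.90, rel=1e-12)
        assert ka1 / ka2 == pytest.approx(1.40e-2 / 1.04e-2, rel=0.01)

    def test_printed_rate_from_implied_lumen_volume(self):
        """With the 68.43 mL lumen volume implied by the printed value, the
        whole small intestine yields ka = 1.40e-2 1/h for Papp 3.92e-6."""
        si = GITSegment(name="jejunum", volume_fasted=68.43, ph_fasted=6.0,
                        surface_area=67.88, transit_time=4.0)
        ka = absorption_rate_constant(3.92e-6, si, si.volume_fasted)
        assert ka == pytest.approx(1.40e-2, rel=0.005)

    def test_zero_volume_errors(self, rat_phys):
        seg = rat_phys.segment("jejunum")
        with pytest.raises(ValidationError):
            absorption_rate_constant(1e-6, seg, 0.0)


class TestBuildModel:
    def test_reference_assembly(self, rat_phys, teb):
        m = build_model(teb, rat_phys)
        assert m.clint_scaled == pytest.approx(6710.3, rel=1e-3)
        assert m.ka_per_segment["stomach"] == 0.0
        assert all(m.ka_per_segment[s] > 0 for s in SEGMENTS if s != "stomach")

    def test_incomplete_record_errors(self, rat_phys):
        rec = CompoundRecord(name="gap", mw=100, logPow=1.0, fub=0.5)
        with pytest.raises(ModelError, match="papp"):
            build_model(rec, rat_phys)

    def test_worst_case_record_renal_only(self, rat_phys):
        rec = CompoundRecord(name="wc", mw=100, logPow=0.5, fub=1.0,
                             papp=1e-6, clint_value=0.0, bp_ratio=1.0,
                             water_solubility=1e4)
        m = build_model(rec, rat_phys)
        assert m.clint_scaled == 0.0
        assert m.cl_renal > 0

    def test_missing_kp_raises(self, rat_phys, teb):
        pset = unity_partition_set()
        del pset.kp["adipose"]
        with pytest.raises(ModelError, match="adipose"):
            ModelSpec(physiology=rat_phys, compound=teb, partition_set=pset,
                      clint_scaled=0.0, cl_renal=0.0,
                      ka_per_segment={s: 0.0 for s in SEGMENTS},
                      solubility_cap=math.inf)


class TestSimulate:
    def test_zero_dose_identically_zero(self, rat_phys, teb):
        m = build_model(teb, rat_phys)
        ts = simulate(m, DosingSchedule(events=[], duration=0.0), 4.0,
                      rtol=1e-6, atol=1e-9, n_points=50)
        assert np.all(ts.venous_plasma == 0.0)

    def test_mass_balance_within_0p1pct(self, teb_rat_sim, cyr_rat_sim):
        for _, ts in (teb_rat_sim, cyr_rat_sim):
            assert ts.mass_balance_residual().max() < 1e-3

    def test_states_non_negative(self, teb_rat_sim):
        _, ts = teb_rat_sim
        for arr in ts.compartments.values():
            assert np.all(arr >= 0.0)

    def test_dose_linearity_below_solubility(self, rat_phys, cyr):
        m = build_model(cyr, rat_phys)
        s1 = summarize(simulate(m, gavage(0.05, 24), 24, rtol=1e-8, atol=1e-12),
                       cyr.fub)
        s2 = summarize(simulate(m, gavage(0.1, 24), 24, rtol=1e-8, atol=1e-12),
                       cyr.fub)
        assert s2.cmax / s1.cmax == pytest.approx(2.0, rel=1e-4)
        assert s2.auc / s1.auc == pytest.approx(2.0, rel=1e-4)

    def test_conservation_without_elimination(self, rat_phys):
        rec = CompoundRecord(name="inert", mw=100, logPow=0.5, fub=1.0,
                             papp=5e-6, clint_value=0.0, bp_ratio=1.0,
                             water_solubility=1e5)
        m = build_model(rec, rat_phys)
        m = ModelSpec(physiology=m.physiology, compound=m.compound,
                      partition_set=m.partition_set, clint_scaled=0.0,
                      cl_renal=0.0, ka_per_segment=m.ka_per_segment,
                      solubility_cap=m.solubility_cap, fub=1.0, bp=1.0)
        ts = simulate(m, gavage(1.0, 48), 48.0, rtol=1e-8, atol=1e-11)
        body = sum(ts.compartments[t] for t in TISSUES)
        body = body + ts.compartments["venous_blood"] + ts.compartments["arterial_blood"]
        total_burden = body + ts.excreted["fecal"] + sum(
            ts.compartments[f"lumen_{s}_{p}"] for s in SEGMENTS
            for p in ("dissolved", "solid")
        )
        assert np.allclose(total_burden, 1.0, rtol=1e-6)
        assert ts.excreted["hepatic"][-1] == 0.0
        assert ts.excreted["renal"][-1] == 0.0

    def test_cmax_auc_monotone_in_clearance(self, rat_phys, cyr):
        base = build_model(cyr, rat_phys)
        summaries = []
        for factor in (0.5, 1.0, 2.0):
            m = ModelSpec(
                physiology=base.physiology, compound=base.compound,
                partition_set=base.partition_set,
                clint_scaled=base.clint_scaled * factor,
                cl_renal=base.cl_renal * factor,
                ka_per_segment=base.ka_per_segment,
                solubility_cap=base.solubility_cap,
                fub=base.fub, bp=base.bp,
            )
            ts = simulate(m, gavage(1.0, 24), 24, rtol=1e-7, atol=1e-10)
            summaries.append(summarize(ts, cyr.fub))
        assert summaries[0].cmax > summaries[1].cmax > summaries[2].cmax
        assert summaries[0].auc > summaries[1].auc > summaries[2].auc

    def test_rat_human_both_finite(self, rat_phys, human_phys, teb):
        for phys, dose in ((rat_phys, 0.7), (human_phys, 140.0)):
            m = build_model(teb, phys)
            ts = simulate(m, gavage(dose, 24), 24, rtol=1e-6, atol=1e-9,
                          n_points=200)
            s = summarize(ts, teb.fub, mw=teb.mw)
            assert np.isfinite(s.cmax) and s.cmax > 0
            assert np.isfinite(s.auc) and s.auc > 0

    def test_one_compartment_analytic_limit(self, teb):
        """All Kp = 1, pre-distributed dose, renal-only elimination, fast
        flows: venous plasma follows C(t) = (D/V) exp(-CL t / V)."""
        phys = qk.default_physiology("rat")
        for c in phys.compartments:
            c.blood_flow *= 1000.0
        phys.cardiac_output *= 1000.0
        comp = CompoundRecord(name="probe", mw=300, logPow=1.0, fub=1.0,
                              papp=1e-6, clint_value=0.0, bp_ratio=1.0,
                              water_solubility=1e4)
        m = ModelSpec(physiology=phys, compound=comp,
                      partition_set=unity_partition_set(),
                      clint_scaled=0.0, cl_renal=200.0,
                      ka_per_segment={s: 0.0 for s in SEGMENTS},
                      solubility_cap=math.inf, fub=1.0, bp=1.0)
        vols = {t: phys.compartment(t).volume for t in TISSUES}
        vtot = sum(vols.values()) + phys.blood_volume
        dose = 1.0
        init = {t: dose * vols[t] / vtot for t in TISSUES}
        init["venous"] = dose * phys.blood_volume * 2 / 3 / vtot
        init["arterial"] = dose * phys.blood_volume / 3 / vtot
        ts = simulate(m, DosingSchedule(events=[], duration=0), 20.0,
                      initial_amounts=init, rtol=1e-10, atol=1e-14)
        analytic = dose / vtot * np.exp(-(0.2 / vtot) * ts.times)
        assert np.max(np.abs(ts.venous_plasma - analytic) / analytic) < 1e-3

    def test_repeated_boluses_accumulate(self, rat_phys, cyr):
        m = build_model(cyr, rat_phys)
        sched = DosingSchedule(
            events=[DoseEvent(time=float(t), amount=0.2) for t in (0, 4, 8)],
            duration=12.0,
        )
        ts = simulate(m, sched, 16.0, rtol=1e-7, atol=1e-10)
        assert ts.dose_total == pytest.approx(0.6)
        assert ts.mass_balance_residual().max() < 1e-3


class TestSummaries:
    def test_constant_profile(self):
        from qivikit.pbk import ConcentrationTimeseries

        t = np.linspace(0, 10, 11)
        ts = ConcentrationTimeseries(
            times=t, venous_blood=np.full(11, 2.0),
            venous_plasma=np.full(11, 2.0), unbound_plasma=np.full(11, 0.2),
            compartments={}, excreted={}, dose_total=1.0,
        )
        s = summarize(ts, 0.1)
        assert s.cmax == 2.0
        assert s.tmax == 0.0  # first attainment
        assert s.auc == pytest.approx(20.0)

    def test_triangular_peak_location(self):
        from qivikit.pbk import ConcentrationTimeseries

        t = np.linspace(0, 10, 2001)
        c = np.where(t < 4.16, t / 4.16, (10 - t) / (10 - 4.16))
        ts = ConcentrationTimeseries(
            times=t, venous_blood=c, venous_plasma=c, unbound_plasma=c,
            compartments={}, excreted={}, dose_total=1.0,
        )
        assert summarize(ts, 1.0).tmax == pytest.approx(4.16, abs=0.01)

    def test_unbound_molar_conversion(self):
        from qivikit.pbk import ConcentrationTimeseries

        ts = ConcentrationTimeseries(
            times=np.array([0.0, 1.0]), venous_blood=np.array([0.0, 7.14]),
            venous_plasma=np.array([0.0, 7.14]),
            unbound_plasma=np.array([0.0, 0.4284]),
            compartments={}, excreted={}, dose_total=1.0,
        )
        s = summarize(ts, 0.06, mw=307.0)
        assert s.cmax_unbound_molar == pytest.approx(1.395e-6, rel=1e-3)

    def test_empty_series_errors(self):
        from qivikit.pbk import ConcentrationTimeseries

        ts = ConcentrationTimeseries(
            times=np.array([]), venous_blood=np.array([]),
            venous_plasma=np.array([]), unbound_plasma=np.array([]),
            compartments={}, excreted={}, dose_total=0.0,
        )
        with pytest.raises(ValidationError):
            summarize(ts, 0.5)

    def test_prediction_factors(self):
        pred = PKSummary(cmax=7.14, tmax=4.16, auc=4.44, cmax_unbound=0.4,
                         cmax_unbound_molar=1e-6)
        obs = PKSummary(cmax=4.63, tmax=1.53, auc=4.41, cmax_unbound=0.3,
                        cmax_unbound_molar=1e-6)
        f = prediction_factor(pred, obs)
        assert f["cmax_factor"] == pytest.approx(1.542, abs=0.001)
        assert f["cmax_within_twofold"]
        assert f["auc_factor"] == pytest.approx(1.007, abs=0.001)
        same = prediction_factor(obs, obs)
        assert same["cmax_factor"] == 1.0
        with pytest.raises(ValidationError):
            prediction_factor(pred, PKSummary(0.0, 1.0, 1.0, 0.0, 0.0))
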