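"""Synthetic raw-data generators with known ground truth.

Every generator is a deterministic function of (config, seed) and emits data
in the exact shapes the estimators consume, so each pipeline stage is testable
end to end without any external dataset. Noise is multiplicative lognormal by
default (concentrations stay positive), with per-assay coefficients of
variation at the scale of the replicate spreads reported for the measured
reference compounds (Papp ~23%, b/p ~22%, fub ~2%, depletion ~5%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .adme import DepletionTimeseries, PermeabilityTimeseries
from .records import ChemClass, CompoundRecord, DataStatus, ValidationError

#: default relative noise per assay, from measured replicate spreads
DEFAULT_CV = {"papp": 0.23, "clint": 0.05, "fub": 0.02, "bp": 0.22,
              "invivo": 0.10}

#: sampling designs from the assay protocols
PAPP_TIMES_MIN = (30.0, 60.0, 90.0, 120.0)
DEPLETION_TIMES_MIN = (0.0, 15.0, 30.0, 60.0, 120.0, 240.0)


@dataclass
class GeneratorConfig:
    seed: int
    noise: str = "lognormal"  # or "gaussian"
    cv: float = 0.1
    replicates: int = 3

    def __post_init__(self):
        if self.cv < 0 or self.replicates < 1:
            raise ValidationError("cv must be >= 0 and replicates >= 1")
        if self.noise not in ("lognormal", "gaussian"):
            raise ValidationError(f"unknown noise model '{self.noise}'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noisy(values: np.ndarray, cfg: GeneratorConfig, rng) -> np.ndarray:
    if cfg.cv == 0:
        return values.copy()
    if cfg.noise == "lognormal":
        s = np.sqrt(np.log1p(cfg.cv ** 2))
        return values * rng.lognormal(-0.5 * s * s, s, size=values.shape)
    return np.clip(values * (1 + cfg.cv * rng.standard_normal(values.shape)),
                   1e-12, None)


def gen_compound(seed: int, chem_class=ChemClass.TRIAZOLE,
                 data_status=DataStatus.RICH) -> CompoundRecord:
    """A plausible triazole/triazine-like record; data-poor records have
    Clint and b/p blanked (and possibly Papp/fub) to exercise read-across."""
    rng = np.random.default_rng(seed)
    chem_class = ChemClass(chem_class)
    if chem_class is ChemClass.TRIAZINE:
        logp = rng.uniform(-1.5, 2.0)  # class-typical hydrophilicity
    else:
        logp = rng.uniform(0.5, 4.0)
    rec = dict(
        name=f"synthetic-{chem_class.value}-{seed}",
        chem_class=chem_class,
        mw=rng.uniform(69.0, 500.0),
        logPow=logp,
        water_solubility=float(10 ** rng.uniform(1.0, 4.5)),
        henry_pc=float(10 ** rng.uniform(-6.0, -1.0)),
        compound_type="neutral",
        fub=float(np.clip(rng.uniform(0.01, 1.0), 0.01, 1.0)),
        papp=float(10 ** rng.uniform(-7.0, -5.0)),
        clint_value=float(rng.uniform(0.0, 10.0)),
        bp_ratio=float(rng.uniform(0.7, 1.1)),
        data_status=data_status,
    )
    if DataStatus(data_status) is DataStatus.POOR:
        rec["clint_value"] = None
        rec["bp_ratio"] = None
        if rng.uniform() < 0.5:
            rec["papp"] = None
        if rng.uniform() < 0.5:
            rec["fub_qsar"] = rec["fub"]
            rec["fub"] = None
    return CompoundRecord(**rec)


def gen_permeability_ts(
    papp_true: float,
    config: GeneratorConfig,
    c0: float = 10.0,  # nmol/mL donor
    area: float = 1.12,  # cm2 (12-well insert)
    receiver_volume: float = 1.5,  # mL
    times_min=PAPP_TIMES_MIN,
) -> list:
    """Replicated sink-condition receiver series.

    Under sink conditions the cumulative receiver concentration is linear:
    C_rec(t) = Papp * A * C0 / Vr * t.
    """
    if papp_true < 0:
        raise ValidationError("papp_true must be >= 0")
    rng = config.rng()
    t_s = np.asarray(times_min, float) * 60.0
    clean = papp_true * area * c0 / receiver_volume * t_s
    out = []
    for rep in range(config.replicates):
        out.append(PermeabilityTimeseries(
            times=t_s,
            receiver_conc=_noisy(clean, config, rng),
            c0=c0, area=area, receiver_volume=receiver_volume,
            replicate_id=rep,
        ))
    return out


def gen_depletion_ts(
    clint_true: float,
    config: GeneratorConfig,
    incubation_volume: float = 100.0,  # uL
    cells: float = 0.0525,  # 1e6 viable cells
    c0: float = 1500.0,  # nM (1.5 uM dosing)
    times_min=DEPLETION_TIMES_MIN,
) -> DepletionTimeseries:
    """Exponential substrate depletion at k = Clint * N / V, noisy triplicates."""
    if clint_true < 0:
        raise ValidationError("clint_true must be >= 0")
    rng = config.rng()
    t = np.asarray(times_min, float)
    k = clint_true * cells / incubation_volume  # 1/min
    clean = c0 * np.exp(-k * t)
    conc = np.vstack([
        _noisy(clean, config, rng) for _ in range(config.replicates)
    ])
    return DepletionTimeseries(
        times=t, conc=conc, incubation_volume=incubation_volume, cells=cells,
    )


def gen_red_measurements(fub_true: float, config: GeneratorConfig,
                         c_plasma: float = 10.0) -> list:
    """RED buffer/plasma pairs with replicate noise on the buffer side."""
    from .adme import REDMeasurement

    if not (0 < fub_true <= 1):
        raise ValidationError("fub_true must be in (0, 1]")
    rng = config.rng()
    buffers = _noisy(np.full(config.replicates, fub_true * c_plasma),
                     config, rng)
    return [
        REDMeasurement(c_buffer=float(min(b, c_plasma)), c_plasma=c_plasma,
                       replicate_id=i)
        for i, b in enumerate(buffers)
    ]


def gen_invivo_profile(
    model,
    schedule,
    config: GeneratorConfig,
    n_obs: int = 10,
    horizon: Optional[float] = None,
    rtol: float = 1e-6,
):
    """Sparse noisy plasma observations from a simulated profile.

    Returns ``(times, concentrations, truth)`` where ``truth`` records the
    generating ADME parameters for recovery tests.
    """
    from .pbk import simulate

    if not 8 <= n_obs <= 12:
        n_obs = min(max(n_obs, 8), 12)
    horizon = horizon or schedule.duration + 24.0
    ts = simulate(model, schedule, horizon, rtol=rtol, atol=1e-10)
    rng = config.rng()
    # observation times spread over the profile, denser early
    t_obs = np.unique(np.round(
        np.quantile(ts.times[ts.venous_plasma > 0],
                    np.linspace(0.02, 0.98, n_obs)), 3))
    c_clean = np.interp(t_obs, ts.times, ts.venous_plasma)
    keep = c_clean > 0
    t_obs, c_clean = t_obs[keep], c_clean[keep]
    c_obs = _noisy(c_clean, config, rng)
    truth = {
        "fub": model.compound.fub,
        "papp": model.compound.papp,
        "clint": model.compound.clint_value,
        "solubility": model.compound.water_solubility,
    }
    return t_obs, c_obs, truth
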