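"""In vitro ADME parameter estimation, clearance scaling and read-across.

Estimators turn raw assay time series into the compound parameters the PBK
model consumes:

* Caco-2 permeability: Papp = Vr * (dC/dt) / (A * C0), slope by ordinary least
  squares of the sink-corrected cumulative receiver concentration vs time.
* Hepatocyte/microsome substrate depletion: k = -slope of ln(Ct/C0) vs t with
  1/y weighting, half-life = ln(2)/k, Clint = k * V / N.
* Rapid equilibrium dialysis: fub = C_buffer / C_plasma.
* Blood:plasma ratio: Kb/p = Ke/p * H + (1 - H).

Whole-body scaling: Clint_scaled = Clint / fub * HPGL * Wl (hepatocytes) or
Clint / fub * MPPGL * Wl (microsomes); renal clearance = GFR * fub.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import (
    ChemClass,
    ClintSystem,
    CompoundRecord,
    PhysiologyRecord,
    Provenance,
    ValidationError,
)

log = logging.getLogger(__name__)

LN2 = math.log(2.0)
#: the depletion half-life constant as printed in the source assay protocol;
#: retained only behind the ``legacy_half_life_constant`` compatibility flag
PRINTED_HALF_LIFE_CONSTANT = 0.639


# ---------------------------------------------------------------------------
# raw assay containers
# ---------------------------------------------------------------------------

@dataclass
class PermeabilityTimeseries:
    """Cumulative receiver-compartment concentrations under sink conditions."""

    times: Sequence[float]  # s
    receiver_conc: Sequence[float]  # nmol/mL, cumulative (sink-corrected)
    c0: float  # nmol/mL donor at t=0
    area: float  # cm2
    receiver_volume: float  # mL
    direction: str = "AB"
    replicate_id: int = 0

    def __post_init__(self):
        t = np.asarray(self.times, float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError("permeability times must be strictly increasing")
        if self.c0 <= 0 or self.area <= 0 or self.receiver_volume <= 0:
            raise ValidationError("C0, area and receiver volume must be > 0")


@dataclass
class DepletionTimeseries:
    """Substrate depletion in a hepatocyte (or microsome) incubation."""

    times: Sequence[float]  # min
    conc: Sequence[float]  # nM, one profile per replicate column or flat
    incubation_volume: float = 100.0  # uL
    cells: float = 0.0525  # 1e6 viable cells (or mg protein for microsomes)

    def __post_init__(self):
        t = np.asarray(self.times, float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError("depletion times must be strictly increasing")
        if self.incubation_volume <= 0 or self.cells <= 0:
            raise ValidationError("incubation volume and cell count must be > 0")
        c = np.asarray(self.conc, float)
        if np.any(c <= 0):
            raise ValidationError("depletion concentrations must be > 0")


@dataclass
class REDMeasurement:
    c_buffer: float
    c_plasma: float
    plasma_fraction_in_test: float = 0.5
    replicate_id: int = 0

    def __post_init__(self):
        if self.c_plasma <= 0:
            raise ValidationError("plasma concentration must be > 0")
        if self.c_buffer < 0:
            raise ValidationError("buffer concentration must be >= 0")
        if self.c_buffer > self.c_plasma:
            warnings.warn(
                "C_buffer exceeds C_plasma: apparent fub > 1", stacklevel=2
            )


@dataclass
class BloodPlasmaMeasurement:
    """Either a precomputed Ke/p or a raw plasma-from-blood / plasma-only pair."""

    haematocrit: float = 0.375
    ke_p: Optional[float] = None
    c_plasma_from_blood: Optional[float] = None
    c_plasma_only: Optional[float] = None

    def __post_init__(self):
        if not (0 < self.haematocrit < 1):
            raise ValidationError("haematocrit must be in (0, 1)")
        if self.ke_p is None:
            if self.c_plasma_from_blood is None or self.c_plasma_only is None:
                raise ValidationError(
                    "provide ke_p or both raw plasma concentrations"
                )
            if self.c_plasma_from_blood <= 0 or self.c_plasma_only <= 0:
                raise ValidationError("raw concentrations must be > 0")

    def erythrocyte_plasma_ratio(self) -> float:
        if self.ke_p is not None:
            return self.ke_p
        h = self.haematocrit
        return (self.c_plasma_only / self.c_plasma_from_blood - (1 - h)) / h


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

@dataclass
class EstimateWithSpread:
    value: float
    sd: float
    replicates: list = field(default_factory=list)


def papp_from_timeseries(ts) -> EstimateWithSpread:
    """Apparent permeability (cm/s) from cumulative receiver concentrations.

    Accepts a single :class:`PermeabilityTimeseries` or a list of replicates;
    returns the replicate mean with sample SD (n-1). A negative OLS slope
    (evaporation/degradation artefact) clamps to Papp = 0 with a warning.
    """
    replicates = ts if isinstance(ts, (list, tuple)) else [ts]
    values = []
    for rep in replicates:
        t = np.asarray(rep.times, float)
        c = np.asarray(rep.receiver_conc, float)
        if t.size < 2:
            raise ValidationError("need at least 2 time points for a slope")
        slope = np.polyfit(t, c, 1)[0]  # nmol/mL/s
        if slope < 0:
            log.warning(
                "negative receiver slope (%.3g) clamped to zero permeability",
                slope,
            )
            slope = 0.0
        values.append(rep.receiver_volume * slope / (rep.area * rep.c0))
    values = np.asarray(values)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return EstimateWithSpread(float(values.mean()), sd, list(values))


def clint_from_depletion(
    dep: DepletionTimeseries, legacy_half_life_constant: bool = False
) -> dict:
    """Elimination rate, half-life and in vitro intrinsic clearance.

    Weighted least squares of ln(Ct/C0) vs t with weights proportional to the
    reciprocal fitted concentration (the common "1/y" kinetics convention,
    applied as 1/observed on the linear scale). A non-negative slope clamps to
    k = 0 (stable compound, Clint = 0).
    """
    t = np.asarray(dep.times, float)
    c = np.atleast_2d(np.asarray(dep.conc, float))
    if c.shape[0] == t.size and c.ndim == 2 and c.shape[1] != t.size:
        c = c.T
    if t.size < 3:
        raise ValidationError("need at least 3 time points for depletion fit")
    cbar = c.mean(axis=0) if c.shape[0] > 1 else c[0]
    y = np.log(cbar / cbar[0])
    w = 1.0 / cbar  # 1/y weighting on the concentration scale
    # weighted straight line through the data (intercept free)
    W = np.diag(w)
    X = np.column_stack([t, np.ones_like(t)])
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    slope = beta[0]
    if slope >= 0:
        return {"k": 0.0, "clint": 0.0, "half_life": math.inf}
    k = -slope  # 1/min
    const = PRINTED_HALF_LIFE_CONSTANT if legacy_half_life_constant else LN2
    half_life = const / k
    clint = k * dep.incubation_volume / dep.cells  # uL/min/1e6 cells
    return {"k": k, "clint": clint, "half_life": half_life}


def fub_from_red(
    measurements: Sequence[REDMeasurement], dilution_correction: bool = False
) -> EstimateWithSpread:
    """Fraction unbound in plasma from RED buffer/plasma pairs.

    Default is the direct ratio fub = C_buffer/C_plasma. With
    ``dilution_correction`` the measured fraction from diluted plasma (dilution
    factor D = 1/plasma_fraction_in_test) is mapped to undiluted plasma via
    fub = 1/(D*(1/fu' - 1) + 1), the standard single-site dilution correction.
    """
    if not measurements:
        raise ValidationError("need at least one RED replicate")
    vals = []
    for m in measurements:
        fu = m.c_buffer / m.c_plasma
        if dilution_correction:
            if fu <= 0:
                fu = np.nan
            else:
                d = 1.0 / m.plasma_fraction_in_test
                fu = 1.0 / (d * (1.0 / fu - 1.0) + 1.0)
        vals.append(min(fu, 1.0) if np.isfinite(fu) else 0.0)
    vals = np.asarray(vals)
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return EstimateWithSpread(float(vals.mean()), sd, list(vals))


def bp_ratio(meas: BloodPlasmaMeasurement) -> float:
    """Blood:plasma ratio Kb/p = Ke/p * H + (1 - H)."""
    kep = meas.erythrocyte_plasma_ratio()
    if kep < 0:
        raise ValidationError(f"erythrocyte:plasma ratio {kep:.3g} is negative")
    return kep * meas.haematocrit + (1.0 - meas.haematocrit)


def ke_p_from_bp(kb_p: float, haematocrit: float) -> float:
    """Inverse of :func:`bp_ratio`: Ke/p = (Kb/p - (1 - H)) / H."""
    if not (0 < haematocrit < 1):
        raise ValidationError("haematocrit must be in (0, 1)")
    return (kb_p - (1.0 - haematocrit)) / haematocrit


# ---------------------------------------------------------------------------
# whole-body scaling
# ---------------------------------------------------------------------------

def scale_clint(
    clint: float,
    system: ClintSystem | str,
    fub: float,
    phys: PhysiologyRecord,
    restrictive: bool = True,
) -> float:
    """Scale in vitro intrinsic clearance to the whole liver, in mL/h.

    Hepatocytes: Clint/fub * HPGL * Wl; microsomes: Clint/fub * MPPGL * Wl.
    The 1/fub factor (restrictive clearance) is on by default and can be
    switched off for non-restrictive clearance.
    """
    system = ClintSystem(system)
    if clint < 0:
        raise ValidationError("Clint must be >= 0")
    if not (0 < fub <= 1):
        raise ValidationError(f"fub={fub} must be in (0, 1]")
    factor = phys.hpgl if system is ClintSystem.PHH else phys.mppgl
    ul_per_min = (clint / fub if restrictive else clint) * factor * phys.liver_weight
    return ul_per_min * 60.0 / 1000.0  # uL/min -> mL/h


def renal_clearance(
    gfr: float, fub: float, body_weight: Optional[float] = None
) -> float:
    """Renal plasma clearance CL_renal = GFR_total * fub, in mL/h.

    ``gfr`` is mL/min total; pass ``body_weight`` (kg) when ``gfr`` is
    mL/min/kg instead.
    """
    if gfr < 0 or not (0 <= fub <= 1):
        raise ValidationError("GFR must be >= 0 and fub in [0, 1]")
    total = gfr * body_weight if body_weight is not None else gfr
    return total * fub * 60.0


# ---------------------------------------------------------------------------
# read-across gap filling
# ---------------------------------------------------------------------------

@dataclass
class ReadAcrossPolicy:
    """How data-poor records are completed.

    Missing Clint -> 0 (worst case: no clearance); missing b/p -> 1; missing
    Papp -> class mean of measured values; missing fub -> in silico fallback.
    """

    clint_worst_case: float = 0.0
    bp_default: float = 1.0
    papp_strategy: str = "class_mean"


def fill_missing_parameters(
    records: Sequence[CompoundRecord], policy: Optional[ReadAcrossPolicy] = None
) -> list:
    """Complete data-poor records by read-across; measured values are kept.

    Idempotent: re-running on already-filled records changes nothing.
    """
    policy = policy or ReadAcrossPolicy()
    class_papp: dict = {}
    for rec in records:
        if rec.papp is not None and rec.provenance.get("papp") in (
            Provenance.MEASURED,
            Provenance.DASHBOARD,
        ):
            class_papp.setdefault(ChemClass(rec.chem_class), []).append(rec.papp)

    out = []
    for rec in records:
        changes: dict = {}
        prov: dict = {}
        if rec.clint_value is None:
            changes["clint_value"] = policy.clint_worst_case
            prov["clint_value"] = Provenance.WORST_CASE
        if rec.bp_ratio is None:
            changes["bp_ratio"] = policy.bp_default
            prov["bp_ratio"] = Provenance.READ_ACROSS
        if rec.papp is None:
            mates = class_papp.get(ChemClass(rec.chem_class), [])
            if not mates:
                raise ValidationError(
                    f"no measured Papp among {rec.chem_class} class-mates for "
                    f"'{rec.name}'"
                )
            changes["papp"] = float(np.mean(mates))
            prov["papp"] = Provenance.READ_ACROSS
        if rec.fub is None:
            if rec.fub_qsar is None:
                raise ValidationError(
                    f"'{rec.name}' has no measured fub and no in silico fallback"
                )
            changes["fub"] = rec.fub_qsar
            prov["fub"] = Provenance.QSAR
        if changes:
            rec = rec.copy(**changes)
            rec.provenance.update(prov)
        out.append(rec)
    return out
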