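"""Exposure scenarios, allometric scaling, margins of exposure and the
compound x assay QIVIVE comparison report.

A drinking-water scenario doses concentration x 2 L/day in five equal boluses
at 0/4/8/12/16 h for five consecutive days; LOAEL-type inputs (mg/kg bw/day)
convert through body weight to the same schedule. The scenario's unbound
steady-state Cmax (mol/L) from the human PBK model is compared to free
in vitro benchmark concentrations and to other scenarios via margins of
exposure (ratios of like concentrations).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .pbk import build_model, simulate, summarize
from .physiology import default_physiology
from .records import (
    CompoundRecord,
    DoseEvent,
    DosingSchedule,
    PhysiologyRecord,
    Route,
    ValidationError,
)

log = logging.getLogger(__name__)

DOSE_HOURS = (0.0, 4.0, 8.0, 12.0, 16.0)


@dataclass
class ExposureScenario:
    """Repeated oral exposure through drinking water (or a LOAEL equivalent)."""

    water_concentration: float  # ug/L, or mg/kg bw/day when source == "loael"
    source: str = "surface_water"  # groundwater|surface_water|max_solubility|loael
    intake: float = 2.0  # L/day
    doses_per_day: int = 5
    days: int = 5
    body_weight: float = 70.0  # kg

    def __post_init__(self):
        if min(self.water_concentration, self.intake, self.body_weight) < 0:
            raise ValidationError("scenario quantities must be >= 0")
        if self.doses_per_day < 1 or self.days < 1:
            raise ValidationError("need at least one dose per day and one day")


def total_exposure(scenario: ExposureScenario) -> float:
    """Total dissolved intake (mg) = concentration x intake x days."""
    return scenario.water_concentration / 1000.0 * scenario.intake * scenario.days


def build_exposure(
    scenario: ExposureScenario, solubility: Optional[float] = None
) -> DosingSchedule:
    """Bolus schedule for the scenario; capped at water solubility.

    The daily intake (concentration x 2 L) is split into ``doses_per_day``
    equal boluses at 0/4/8/12/16 h each day. A concentration above the
    compound's water solubility is capped with a warning (the max-solubility
    worst case uses the cap itself).
    """
    if scenario.source == "loael":
        conc_mg_l = (scenario.water_concentration * scenario.body_weight
                     / scenario.intake)
    else:
        conc_mg_l = scenario.water_concentration / 1000.0
    if solubility is not None and solubility > 0 and conc_mg_l > solubility:
        log.warning(
            "%s concentration %.3g mg/L above water solubility %.3g mg/L; "
            "capped", scenario.source, conc_mg_l, solubility,
        )
        conc_mg_l = solubility
    daily = conc_mg_l * scenario.intake  # mg/day
    per_event = daily / scenario.doses_per_day
    hours = DOSE_HOURS[: scenario.doses_per_day]
    events = [
        DoseEvent(time=24.0 * day + h, amount=per_event,
                  route=Route.DRINKING_WATER_BOLUS)
        for day in range(scenario.days)
        for h in hours
        if per_event > 0
    ]
    return DosingSchedule(events=events, duration=scenario.days * 24.0)


def allometric_scale(
    loael_animal: float, bw_animal: float, bw_human: float,
    exponent: float = 0.75,
) -> float:
    """Body-weight^exponent scaling of a mg/kg bw/day LOAEL to humans."""
    if bw_animal <= 0 or bw_human <= 0:
        raise ValidationError("body weights must be > 0")
    return loael_animal * (bw_animal / bw_human) ** (1.0 - exponent)


def scenario_unbound_cmax(
    compound: CompoundRecord,
    scenario: ExposureScenario,
    phys: Optional[PhysiologyRecord] = None,
    rtol: float = 1e-6,
) -> float:
    """Unbound steady-state Cmax (mol/L) for the scenario in the human model.

    Simulates the full multi-day schedule plus one trailing day and takes the
    maximum over the final dosing day.
    """
    phys = phys or default_physiology("human")
    if scenario.water_concentration == 0:
        return 0.0
    model = build_model(compound, phys, Route.DRINKING_WATER_BOLUS)
    schedule = build_exposure(scenario, solubility=compound.water_solubility)
    horizon = scenario.days * 24.0 + 24.0
    ts = simulate(model, schedule, horizon, rtol=rtol, atol=1e-10)
    window = ((scenario.days - 1) * 24.0, scenario.days * 24.0)
    summ = summarize(ts, compound.fub, mw=compound.mw, window=window)
    return summ.cmax_unbound_molar


def margin_of_exposure(reference_cmax: float, exposure_cmax: float) -> float:
    """MoE = reference / exposure (ratio of like concentrations)."""
    if exposure_cmax <= 0:
        log.warning("zero exposure concentration: margin of exposure undefined")
        return math.inf
    if reference_cmax < 0:
        raise ValidationError("reference concentration must be >= 0")
    return reference_cmax / exposure_cmax


#: a free benchmark within this factor of the LOAEL-derived unbound Cmax (or
#: below it) counts as protective ("same order of magnitude")
PROTECTIVE_FACTOR = 10.0


def qivive_report(
    compounds: dict,
    corrected_ecs: pd.DataFrame,
    scenarios: dict,
    phys: Optional[PhysiologyRecord] = None,
    rtol: float = 1e-6,
) -> pd.DataFrame:
    """Compound x assay QIVIVE table.

    ``compounds``: name -> complete CompoundRecord. ``corrected_ecs``: output
    of ``vivd.batch_correct`` (columns compound, assay, nominal_ec, free_ec,
    active). ``scenarios``: name -> dict with per-compound concentrations
    ``groundwater_ug_per_l``, ``surface_water_ug_per_l``,
    ``loael_mg_per_kg_day`` (max-solubility uses the record itself).

    Every input row appears exactly once in the output; rows with missing
    scenario data are flagged incomplete rather than dropped.
    """
    phys = phys or default_physiology("human")
    cmax_cache: dict = {}

    def cmax_for(name: str, source: str, value: float) -> float:
        key = (name, source)
        if key not in cmax_cache:
            sc = ExposureScenario(
                water_concentration=value, source=source,
                body_weight=phys.body_weight,
            )
            cmax_cache[key] = scenario_unbound_cmax(
                compounds[name], sc, phys, rtol=rtol
            )
        return cmax_cache[key]

    rows = []
    for row in corrected_ecs.itertuples(index=False):
        name = row.compound
        rec = compounds.get(name)
        sc = scenarios.get(name, {})
        out = {
            "compound": name,
            "assay": row.assay,
            "nominal_ec": row.nominal_ec,
            "free_ec": row.free_ec,
            "active": bool(getattr(row, "active", True)),
            "incomplete": False,
        }
        needed = ("groundwater_ug_per_l", "surface_water_ug_per_l",
                  "loael_mg_per_kg_day")
        if rec is None or any(k not in sc for k in needed):
            out["incomplete"] = True
            rows.append(out)
            continue
        cu_loael = cmax_for(name, "loael", sc["loael_mg_per_kg_day"])
        cu_surface = cmax_for(name, "surface_water", sc["surface_water_ug_per_l"])
        cu_ground = cmax_for(name, "groundwater", sc["groundwater_ug_per_l"])
        cu_sol = cmax_for(name, "max_solubility",
                          rec.water_solubility * 1000.0)  # mg/L -> ug/L
        out.update(
            unbound_cmax_loael=cu_loael,
            unbound_cmax_surface=cu_surface,
            unbound_cmax_ground=cu_ground,
            unbound_cmax_solubility=cu_sol,
            moe_surface=margin_of_exposure(cu_loael, cu_surface),
            moe_ground=margin_of_exposure(cu_loael, cu_ground),
            protective=(
                bool(row.free_ec <= cu_loael * PROTECTIVE_FACTOR)
                if row.free_ec == row.free_ec else False
            ),
        )
        rows.append(out)
    return pd.DataFrame(rows)
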