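"""Equilibrium in vitro disposition (VIVD-style) mass balance.

A nominal assay concentration distributes instantaneously among free medium,
serum protein and lipid, well plastic, headspace and cells. All partition
coefficients derive from logPow correlations for neutral organics (bundled,
user-overridable constants); ionizable compounds partition with their neutral
fraction at medium pH and additionally accumulate in acidic organelles by ion
trapping (pH-partition across the organelle membrane).

The closed linear balance solved for the free medium concentration C_free:

  nominal * V_med = C_free * ( V_med * (1 + K_prot*[prot] + K_lip*[lip])
                               + K_plastic * A_plastic
                               + K_aw * V_air + K_cell * V_cells )
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .partitioning import ionization_fractions
from .records import CompoundRecord, ValidationError

log = logging.getLogger(__name__)

R_GAS = 8.314  # J/mol/K

#: logPow correlation constants (slope, intercept) -- editable module-level
#: defaults; partition coefficients for serum protein and lipid are L/kg,
#: plastic is L/m2 (polystyrene)
PROTEIN_CORR = (0.71, 0.42)
LIPID_CORR = (1.01, 0.12)
PLASTIC_CORR = (0.92, -3.60)

#: bovine serum composition, g/L at 100% serum
SERUM_PROTEIN_G_PER_L = 38.0
SERUM_LIPID_G_PER_L = 2.5

#: generic cell composition (volume fractions) and organelle pH set
CELL_F_WATER = {"cytosol": 0.69, "lysosome": 0.01, "mitochondria": 0.05}
CELL_PH = {"cytosol": 7.0, "lysosome": 4.75, "mitochondria": 8.0}
CELL_F_NEUTRAL_LIPID = 0.005
CELL_F_PHOSPHOLIPID = 0.01


@dataclass
class AssayConditions:
    assay: str
    medium_volume: float  # L
    headspace_volume: float = 0.0  # L
    serum_fraction: float = 0.0  # v/v
    albumin_g_per_l: Optional[float] = None  # overrides serum-derived protein
    lipid_g_per_l: Optional[float] = None
    cell_count: float = 0.0
    mean_cell_volume: float = 2e-12  # L
    plastic_area: float = 0.0  # m2
    medium_ph: float = 7.4
    temperature: float = 310.15  # K
    cell_f_water: dict = field(default_factory=lambda: dict(CELL_F_WATER))
    cell_ph: dict = field(default_factory=lambda: dict(CELL_PH))

    def __post_init__(self):
        if min(self.medium_volume, self.headspace_volume, self.cell_count,
               self.plastic_area) < 0 or self.medium_volume == 0:
            raise ValidationError("volumes/areas must be >= 0, medium > 0")
        if not (0 <= self.serum_fraction <= 1):
            raise ValidationError("serum fraction must be in [0, 1]")
        if not (0 < self.medium_ph < 14):
            raise ValidationError("medium pH out of range")

    @property
    def protein_g_per_l(self) -> float:
        if self.albumin_g_per_l is not None:
            return self.albumin_g_per_l
        return self.serum_fraction * SERUM_PROTEIN_G_PER_L

    @property
    def lipid_conc_g_per_l(self) -> float:
        if self.lipid_g_per_l is not None:
            return self.lipid_g_per_l
        return self.serum_fraction * SERUM_LIPID_G_PER_L


#: bundled conditions for the endocrine assay battery: reporter-gene assays
#: (AR/ER/TR antagonism) in 96-well plates with 5% serum, H295R
#: steroidogenesis with 2.5% serum, TTR binding cell-free in buffer with the
#: carrier protein only
ASSAY_REGISTRY = {
    "AR": AssayConditions("AR", medium_volume=2e-4, headspace_volume=3e-4,
                          serum_fraction=0.05, cell_count=5e4,
                          mean_cell_volume=2e-12, plastic_area=1e-4),
    "ER": AssayConditions("ER", medium_volume=2e-4, headspace_volume=3e-4,
                          serum_fraction=0.05, cell_count=5e4,
                          mean_cell_volume=2e-12, plastic_area=1e-4),
    "TR": AssayConditions("TR", medium_volume=2e-4, headspace_volume=3e-4,
                          serum_fraction=0.05, cell_count=5e4,
                          mean_cell_volume=2e-12, plastic_area=1e-4),
    "TTR": AssayConditions("TTR", medium_volume=2e-4, headspace_volume=3e-4,
                           serum_fraction=0.0, albumin_g_per_l=0.25,
                           lipid_g_per_l=0.0, cell_count=0.0,
                           plastic_area=1e-4),
    "H295R": AssayConditions("H295R", medium_volume=2e-4, headspace_volume=3e-4,
                             serum_fraction=0.025, cell_count=1e5,
                             mean_cell_volume=2.5e-12, plastic_area=1e-4),
}


@dataclass
class VIVDResult:
    nominal: float  # mol/L
    free_medium: float
    protein_bound: float  # medium-referenced
    air: float  # headspace-volume-referenced
    plastic: float  # medium-referenced
    cell: float  # cell-volume-referenced
    correction_factor: float
    mass_balance_residual: float


def _corr(pair, logp: float) -> float:
    slope, intercept = pair
    k = 10.0 ** (slope * logp + intercept)
    if k < 0:  # pragma: no cover - power of ten is always positive
        log.warning("negative correlation result clipped to 0")
        return 0.0
    return k


def cell_partition_coefficient(compound: CompoundRecord, cond: AssayConditions) -> float:
    """Cell:free-medium concentration ratio, including organelle ion trapping."""
    f_med = ionization_fractions(compound, cond.medium_ph)["f_neutral"]
    water = 0.0
    for org, fvol in cond.cell_f_water.items():
        f_org = ionization_fractions(compound, cond.cell_ph[org])["f_neutral"]
        water += fvol * f_med / f_org
    kow = 10.0 ** compound.logPow
    kmw = _corr(LIPID_CORR, compound.logPow)
    return (water
            + CELL_F_NEUTRAL_LIPID * kow * f_med
            + CELL_F_PHOSPHOLIPID * kmw * f_med)


def vivd_partition(
    compound: CompoundRecord, cond: AssayConditions, nominal: float
) -> VIVDResult:
    """Distribute a nominal concentration (mol/L) over all assay phases."""
    if compound.mw <= 0 or compound.logPow is None:
        raise ValidationError("compound needs MW and logPow for VIVD")
    f_med = ionization_fractions(compound, cond.medium_ph)["f_neutral"]
    k_aw = compound.henry_pc / (R_GAS * cond.temperature) * f_med
    k_prot = _corr(PROTEIN_CORR, compound.logPow) * f_med  # L/kg
    k_lip = _corr(LIPID_CORR, compound.logPow) * f_med
    k_pl = _corr(PLASTIC_CORR, compound.logPow) * f_med  # L/m2
    k_cell = cell_partition_coefficient(compound, cond)

    v_med = cond.medium_volume
    v_cells = cond.cell_count * cond.mean_cell_volume
    bound_prot = (k_prot * cond.protein_g_per_l / 1000.0
                  + k_lip * cond.lipid_conc_g_per_l / 1000.0)
    denom = (v_med * (1.0 + bound_prot)
             + k_pl * cond.plastic_area
             + k_aw * cond.headspace_volume
             + k_cell * v_cells)
    c_free = nominal * v_med / denom
    protein = c_free * bound_prot
    plastic = c_free * k_pl * cond.plastic_area / v_med
    air = c_free * k_aw
    cell = c_free * k_cell
    recovered = (c_free + protein + plastic
                 + air * cond.headspace_volume / v_med
                 + cell * v_cells / v_med)
    residual = abs(recovered - nominal) / nominal if nominal else 0.0
    return VIVDResult(
        nominal=nominal, free_medium=c_free, protein_bound=protein,
        air=air, plastic=plastic, cell=cell,
        correction_factor=c_free / nominal if nominal else 1.0,
        mass_balance_residual=residual,
    )


def correct_benchmark(
    nominal_ec: float, compound: CompoundRecord, cond: AssayConditions
) -> float:
    """Free-medium benchmark concentration (mol/L) from the nominal one."""
    if nominal_ec <= 0:
        raise ValidationError("nominal benchmark concentration must be > 0")
    return vivd_partition(compound, cond, nominal_ec).free_medium


def batch_correct(
    table: pd.DataFrame,
    compounds: dict,
    registry: Optional[dict] = None,
) -> pd.DataFrame:
    """Correct a compound x assay table of nominal benchmark concentrations.

    ``table`` needs columns ``compound``, ``assay``, ``nominal_ec`` (mol/L)
    and optionally ``active`` (bool; IR1.5-at-maximum rows are inactive).
    Rows whose inputs cannot be resolved are flagged, not dropped.
    """
    registry = registry or ASSAY_REGISTRY
    unknown = set(table["assay"]) - set(registry) if len(table) else set()
    if unknown:
        raise ValidationError(
            f"unknown assay(s) {sorted(unknown)}; known: {sorted(registry)}"
        )
    rows = []
    for row in table.itertuples(index=False):
        rec = dict(row._asdict())
        rec.setdefault("active", True)
        comp = compounds.get(row.compound)
        if comp is None or not row.nominal_ec > 0:
            rec.update(free_ec=math.nan, correction_factor=math.nan,
                       flagged_incomplete=True)
        else:
            res = vivd_partition(comp, registry[row.assay], row.nominal_ec)
            rec.update(free_ec=res.free_medium,
                       correction_factor=res.correction_factor,
                       flagged_incomplete=False)
        rows.append(rec)
    columns = list(table.columns) + [
        "active", "free_ec", "correction_factor", "flagged_incomplete",
    ]
    columns = list(dict.fromkeys(columns))
    return pd.DataFrame(rows, columns=columns)
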