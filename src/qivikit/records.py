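"""Domain records: compounds, physiology, dosing.

Canonical units are fixed package-wide and every reader converts on ingest:
molecular weight g/mol, water solubility mg/L (20 degC), Henry's law constant
Pa*m3/mol, Papp cm/s, Clint uL/min/1e6 cells (hepatocytes) or uL/min/mg protein
(microsomes), volumes L (GIT lumen mL), flows L/h, times h, amounts mg,
concentrations mg/L unless a field says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional


class ChemClass(str, Enum):
    TRIAZOLE = "triazole"
    TRIAZINE = "triazine"
    OTHER = "other"


class CompoundType(str, Enum):
    NEUTRAL = "neutral"
    MONOPROTIC_ACID = "monoprotic_acid"
    MONOPROTIC_BASE = "monoprotic_base"
    DIPROTIC_ACID = "diprotic_acid"
    DIPROTIC_BASE = "diprotic_base"
    ZWITTERION = "zwitterion"


class ClintSystem(str, Enum):
    PHH = "PHH"
    MICROSOMES = "microsomes"


class DataStatus(str, Enum):
    RICH = "rich"
    POOR = "poor"


class Provenance(str, Enum):
    MEASURED = "measured"
    DASHBOARD = "dashboard"
    QSAR = "qsar"
    READ_ACROSS = "read_across"
    WORST_CASE = "worst_case"
    ABSENT = "absent"


class ValidationError(ValueError):
    """An input record violates a documented invariant."""


#: number of pKa values each ionization type requires
_REQUIRED_PKAS = {
    CompoundType.NEUTRAL: 0,
    CompoundType.MONOPROTIC_ACID: 1,
    CompoundType.MONOPROTIC_BASE: 1,
    CompoundType.DIPROTIC_ACID: 2,
    CompoundType.DIPROTIC_BASE: 2,
    CompoundType.ZWITTERION: 2,
}


@dataclass
class CompoundRecord:
    """Physicochemical and in vitro ADME parameters for one chemical.

    Optional assay-derived fields carry a provenance flag so read-across fills
    are distinguishable from measurements. ``fub_qsar`` holds an in silico
    fraction-unbound prediction used only as a read-across fallback.
    """

    name: str
    mw: float
    logPow: float
    chem_class: ChemClass = ChemClass.OTHER
    water_solubility: float = 0.0
    henry_pc: float = 0.0
    pka1: Optional[float] = None
    pka2: Optional[float] = None
    compound_type: CompoundType = CompoundType.NEUTRAL
    fub: Optional[float] = None
    fub_qsar: Optional[float] = None
    papp: Optional[float] = None
    clint_value: Optional[float] = None
    clint_system: ClintSystem = ClintSystem.PHH
    bp_ratio: Optional[float] = None
    data_status: DataStatus = DataStatus.RICH
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.chem_class = ChemClass(self.chem_class)
        self.compound_type = CompoundType(self.compound_type)
        self.clint_system = ClintSystem(self.clint_system)
        self.data_status = DataStatus(self.data_status)
        self.validate()
        for fname in ("fub", "papp", "clint_value", "bp_ratio"):
            if getattr(self, fname) is None:
                self.provenance.setdefault(fname, Provenance.ABSENT)
            else:
                self.provenance.setdefault(fname, Provenance.MEASURED)

    def validate(self) -> None:
        bad = []
        if not self.mw > 0:
            bad.append(f"mw={self.mw} (must be > 0)")
        if self.water_solubility < 0:
            bad.append(f"water_solubility={self.water_solubility} (must be >= 0)")
        if self.fub is not None and not (0 < self.fub <= 1):
            bad.append(f"fub={self.fub} (must be in (0, 1])")
        if self.fub_qsar is not None and not (0 < self.fub_qsar <= 1):
            bad.append(f"fub_qsar={self.fub_qsar} (must be in (0, 1])")
        if self.papp is not None and self.papp < 0:
            bad.append(f"papp={self.papp} (must be >= 0)")
        if self.clint_value is not None and self.clint_value < 0:
            bad.append(f"clint_value={self.clint_value} (must be >= 0)")
        if self.bp_ratio is not None and not self.bp_ratio > 0:
            bad.append(f"bp_ratio={self.bp_ratio} (must be > 0)")
        n_pka = sum(p is not None for p in (self.pka1, self.pka2))
        need = _REQUIRED_PKAS[CompoundType(self.compound_type)]
        if n_pka < need:
            bad.append(
                f"compound_type={self.compound_type} requires {need} pKa value(s), "
                f"got {n_pka}"
            )
        for p in (self.pka1, self.pka2):
            if p is not None and not math.isfinite(p):
                bad.append(f"pKa={p} (must be finite)")
        if bad:
            raise ValidationError(
                f"compound '{self.name}': invalid field(s): " + "; ".join(bad)
            )

    def copy(self, **changes) -> "CompoundRecord":
        rec = replace(self, **changes)
        rec.provenance = dict(self.provenance)
        for key in changes:
            rec.provenance.pop(key, None)
        rec.__post_init__()
        return rec


class GITSegmentName(str, Enum):
    STOMACH = "stomach"
    DUODENUM = "duodenum"
    JEJUNUM = "jejunum"
    ILEUM = "ileum"
    COLON = "colon"
    RECTUM = "rectum"


#: intestinal segments in anatomical transit order
GIT_ORDER = [
    GITSegmentName.STOMACH,
    GITSegmentName.DUODENUM,
    GITSegmentName.JEJUNUM,
    GITSegmentName.ILEUM,
    GITSegmentName.COLON,
    GITSegmentName.RECTUM,
]


@dataclass
class GITSegment:
    """One gut segment: lumen fluid volume, pH, absorptive area, transit.

    ``transit_time`` is this segment's share of its group's transit time
    (stomach / small intestine / large intestine); ``volume_fasted`` is the
    resident lumen fluid volume in mL used for dissolution and absorption.
    """

    name: GITSegmentName
    volume_fasted: float  # mL
    ph_fasted: float
    surface_area: float  # cm2, effective absorptive area
    transit_time: float  # h
    secretion_rate: float = 0.0  # mL/h
    volume_fed: Optional[float] = None
    ph_fed: Optional[float] = None

    def __post_init__(self):
        self.name = GITSegmentName(self.name)
        bad = []
        if self.volume_fasted < 0 or self.surface_area < 0 or self.secretion_rate < 0:
            bad.append("volumes/areas/rates must be >= 0")
        for ph in (self.ph_fasted, self.ph_fed):
            if ph is not None and not (0 < ph < 14):
                bad.append(f"pH={ph} out of (0, 14)")
        if self.transit_time <= 0 and self.name is not GITSegmentName.RECTUM:
            bad.append("transit_time must be > 0 (rectum may be terminal)")
        if bad:
            raise ValidationError(f"GIT segment {self.name}: " + "; ".join(bad))


@dataclass
class Compartment:
    name: str
    volume: float  # L
    blood_flow: float  # L/h


@dataclass
class PhysiologyRecord:
    """Species anatomy, blood flows, GIT geometry and clearance physiology."""

    species: str
    body_weight: float  # kg
    blood_volume: float  # L
    haematocrit: float
    cardiac_output: float  # L/h
    compartments: list  # list[Compartment]
    git_segments: list  # list[GITSegment]
    liver_weight: float  # g
    hpgl: float  # 1e6 cells / g liver
    mppgl: float  # mg protein / g liver
    gfr: float  # mL/min (total for the reference body weight)
    gfr_per_kg: Optional[float] = None  # mL/min/kg where the source states it so
    git_transit: dict = field(default_factory=dict)  # group transit times, h
    anatomy: dict = field(default_factory=dict)  # printed anatomical reference values

    def __post_init__(self):
        self.compartments = [
            c if isinstance(c, Compartment) else Compartment(**c)
            for c in self.compartments
        ]
        self.git_segments = [
            g if isinstance(g, GITSegment) else GITSegment(**g)
            for g in self.git_segments
        ]
        self.validate()

    def validate(self) -> None:
        bad = []
        if not self.body_weight > 0:
            bad.append("body_weight must be > 0")
        if not self.gfr > 0:
            bad.append("GFR must be > 0")
        if not (0 < self.haematocrit < 1):
            bad.append("haematocrit must be in (0, 1)")
        # systemic flows (lung is in series and carries cardiac output itself)
        q = sum(c.blood_flow for c in self.compartments if c.name != "lung")
        if abs(q - self.cardiac_output) > 0.01 * self.cardiac_output:
            bad.append(
                f"systemic blood flows sum to {q:.4g} L/h, cardiac output is "
                f"{self.cardiac_output:.4g} L/h (must agree within 1%)"
            )
        liv = self.compartment("liver")
        if liv is None:
            bad.append("a 'liver' compartment is required")
        elif abs(liv.volume * 1000.0 - self.liver_weight) > 0.05 * self.liver_weight:
            # 1 g liver ~ 1 mL
            bad.append(
                f"liver compartment volume {liv.volume} L inconsistent with "
                f"liver_weight {self.liver_weight} g"
            )
        if bad:
            raise ValidationError(f"physiology '{self.species}': " + "; ".join(bad))

    def compartment(self, name: str) -> Optional[Compartment]:
        for c in self.compartments:
            if c.name == name:
                return c
        return None

    def segment(self, name) -> Optional[GITSegment]:
        name = GITSegmentName(name)
        for g in self.git_segments:
            if g.name is name:
                return g
        return None


class Route(str, Enum):
    GAVAGE = "gavage"
    DRINKING_WATER_BOLUS = "drinking_water_bolus"


@dataclass
class DoseEvent:
    time: float  # h
    amount: float  # mg
    route: Route = Route.GAVAGE

    def __post_init__(self):
        self.route = Route(self.route)
        if self.time < 0:
            raise ValidationError(f"dose time {self.time} h is negative")
        if self.amount < 0:
            raise ValidationError(f"dose amount {self.amount} mg is negative")


@dataclass
class DosingSchedule:
    events: list  # list[DoseEvent]
    duration: float  # h

    def __post_init__(self):
        self.events = [
            e if isinstance(e, DoseEvent) else DoseEvent(**e) for e in self.events
        ]
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("dose event times must be strictly increasing")
        if times and times[-1] > self.duration:
            raise ValidationError("dose events extend beyond schedule duration")

    @property
    def total_amount(self) -> float:
        return sum(e.amount for e in self.events)
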