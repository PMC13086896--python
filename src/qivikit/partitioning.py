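"""Ionization and mechanistic tissue:plasma partition coefficients.

Implements the Rodgers-Rowland scheme: every tissue takes up drug into extra-
and intracellular water (with Henderson-Hasselbalch ion partitioning between
plasma pH 7.4 and intracellular pH 7.0), into neutral lipid and neutral
phospholipid (driven by the octanol:water partition coefficient; vegetable
oil:water for adipose), and additionally associates either with acidic
phospholipids (moderate-to-strong bases, ionized intracellularly) or with
tissue albumin/lipoprotein (acids, neutrals, very weak bases, zwitterions).
The method predicts Kpu (tissue:unbound plasma); Kp = Kpu * fub.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

from .records import CompoundRecord, CompoundType, ValidationError

#: basic pKa at or above this uses the acidic-phospholipid association equation
BASE_PKA_THRESHOLD = 7.0

#: plasma composition (fractions of plasma volume)
PLASMA_F_NL = 0.0023
PLASMA_F_NP = 0.0013

#: blood-cell composition used to back out the acidic-phospholipid association
#: constant from a measured blood:plasma ratio
BLOOD_CELL = {
    "f_iw": 0.603,
    "f_nl": 0.0017,
    "f_np": 0.0029,
    "ap_mg_per_g": 0.5,
    "ph": 7.22,
}

DEFAULT_HAEMATOCRIT = 0.375


@dataclass
class TissueComposition:
    tissue: str
    f_water_extracellular: float
    f_water_intracellular: float
    f_neutral_lipid: float
    f_neutral_phospholipid: float
    acidic_phospholipid: float  # mg/g
    albumin_ratio: float
    lipoprotein_ratio: float
    intracellular_ph: float = 7.0
    plasma_ph: float = 7.4

    def __post_init__(self):
        fracs = (
            self.f_water_extracellular,
            self.f_water_intracellular,
            self.f_neutral_lipid,
            self.f_neutral_phospholipid,
        )
        if any(not (0 <= f <= 1) for f in fracs) or sum(fracs) > 1.0 + 1e-9:
            raise ValidationError(
                f"tissue '{self.tissue}': volume fractions must lie in [0,1] "
                "and sum to at most 1"
            )
        for ph in (self.intracellular_ph, self.plasma_ph):
            if not (0 < ph < 14):
                raise ValidationError(f"tissue '{self.tissue}': pH {ph} out of range")


@dataclass
class PartitionSet:
    """Tissue -> Kp (tissue:plasma) map with the fub it was computed for."""

    kp: dict
    fub: float
    method: str = "rodgers_rowland"

    def __post_init__(self):
        bad = {t: v for t, v in self.kp.items() if not v > 0}
        if bad:
            raise ValidationError(f"non-positive Kp values: {bad}")

    def __getitem__(self, tissue: str) -> float:
        return self.kp[tissue]


def load_tissue_compositions(path: Optional[str] = None) -> dict:
    """Bundled (or user-supplied CSV) tissue composition table."""
    if path is None:
        text = (
            resources.files("qivikit.data")
            .joinpath("tissue_composition.csv")
            .read_text()
        )
        df = pd.read_csv(_io.StringIO(text), comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    out = {}
    for row in df.itertuples(index=False):
        out[row.tissue] = TissueComposition(
            tissue=row.tissue,
            f_water_extracellular=row.f_water_ec,
            f_water_intracellular=row.f_water_ic,
            f_neutral_lipid=row.f_nl,
            f_neutral_phospholipid=row.f_np,
            acidic_phospholipid=row.ap_mg_per_g,
            albumin_ratio=row.albumin_ratio,
            lipoprotein_ratio=row.lipoprotein_ratio,
        )
    return out


# ---------------------------------------------------------------------------
# ionization
# ---------------------------------------------------------------------------

def ionization_fractions(compound: CompoundRecord, ph: float) -> dict:
    """Henderson-Hasselbalch species fractions at a given pH.

    Returns ``f_neutral``, ``f_anionic``, ``f_cationic``, ``f_zwitterionic``
    summing to 1. For zwitterions pKa1 is read as the acidic and pKa2 as the
    basic constant, with the two sites treated independently.
    """
    ctype = CompoundType(compound.compound_type)
    if ctype is CompoundType.NEUTRAL:
        return {"f_neutral": 1.0, "f_anionic": 0.0, "f_cationic": 0.0,
                "f_zwitterionic": 0.0}
    if compound.pka1 is None or (
        ctype in (CompoundType.DIPROTIC_ACID, CompoundType.DIPROTIC_BASE,
                  CompoundType.ZWITTERION)
        and compound.pka2 is None
    ):
        raise ValidationError(
            f"compound '{compound.name}' of type {ctype} is missing pKa values"
        )
    f = {"f_neutral": 0.0, "f_anionic": 0.0, "f_cationic": 0.0,
         "f_zwitterionic": 0.0}
    if ctype is CompoundType.MONOPROTIC_ACID:
        r = 10.0 ** (ph - compound.pka1)
        f["f_neutral"] = 1.0 / (1.0 + r)
        f["f_anionic"] = r / (1.0 + r)
    elif ctype is CompoundType.MONOPROTIC_BASE:
        r = 10.0 ** (compound.pka1 - ph)
        f["f_neutral"] = 1.0 / (1.0 + r)
        f["f_cationic"] = r / (1.0 + r)
    elif ctype is CompoundType.DIPROTIC_ACID:
        pk1, pk2 = sorted((compound.pka1, compound.pka2))
        r1 = 10.0 ** (ph - pk1)
        r2 = 10.0 ** (2 * ph - pk1 - pk2)
        d = 1.0 + r1 + r2
        f["f_neutral"] = 1.0 / d
        f["f_anionic"] = (r1 + r2) / d
    elif ctype is CompoundType.DIPROTIC_BASE:
        pk1, pk2 = sorted((compound.pka1, compound.pka2), reverse=True)
        r1 = 10.0 ** (pk1 - ph)
        r2 = 10.0 ** (pk1 + pk2 - 2 * ph)
        d = 1.0 + r1 + r2
        f["f_neutral"] = 1.0 / d
        f["f_cationic"] = (r1 + r2) / d
    else:  # zwitterion: pka1 acidic site, pka2 basic site
        ra = 10.0 ** (ph - compound.pka1)
        rb = 10.0 ** (compound.pka2 - ph)
        pa = ra / (1.0 + ra)  # deprotonated acid site
        pb = rb / (1.0 + rb)  # protonated base site
        f["f_neutral"] = (1 - pa) * (1 - pb)
        f["f_anionic"] = pa * (1 - pb)
        f["f_cationic"] = (1 - pa) * pb
        f["f_zwitterionic"] = pa * pb
    return f


def _ionized_ratio(compound: CompoundRecord, ph: float) -> float:
    """(1 - f_neutral)/f_neutral: total ionized-to-neutral ratio at pH."""
    f = ionization_fractions(compound, ph)
    fn = f["f_neutral"]
    if fn <= 0:
        return math.inf
    return (1.0 - fn) / fn


def _is_strong_base(compound: CompoundRecord) -> bool:
    ctype = CompoundType(compound.compound_type)
    if ctype is CompoundType.MONOPROTIC_BASE:
        return compound.pka1 >= BASE_PKA_THRESHOLD
    if ctype is CompoundType.DIPROTIC_BASE:
        return max(compound.pka1, compound.pka2) >= BASE_PKA_THRESHOLD
    return False


# ---------------------------------------------------------------------------
# Rodgers-Rowland Kp
# ---------------------------------------------------------------------------

def _lipid_p(compound: CompoundRecord, tissue: str) -> float:
    """Neutral-lipid partition coefficient; vegetable oil scale for adipose."""
    if tissue == "adipose":
        return 10.0 ** (1.115 * compound.logPow - 1.35)
    return 10.0 ** compound.logPow


def tissue_plasma_kp(
    compound: CompoundRecord,
    comp: TissueComposition,
    fub: float,
    bp_ratio: Optional[float] = None,
    haematocrit: float = DEFAULT_HAEMATOCRIT,
) -> float:
    """Tissue:plasma partition coefficient Kp = Kpu * fub.

    Moderate-to-strong bases (basic pKa >= 7) partition via acidic
    phospholipid association calibrated from the blood:plasma ratio; all
    other types via neutral lipid/phospholipid plus albumin (acids, neutrals)
    or lipoprotein (weak bases, zwitterions) association.
    """
    if not (0 < fub <= 1):
        raise ValidationError(f"fub={fub} must be in (0, 1]")
    ctype = CompoundType(compound.compound_type)
    x = _ionized_ratio(compound, comp.intracellular_ph)
    y = _ionized_ratio(compound, comp.plasma_ph)
    p = _lipid_p(compound, comp.tissue)
    p_plasma = 10.0 ** compound.logPow

    water = comp.f_water_extracellular + (1.0 + x) / (1.0 + y) * comp.f_water_intracellular
    lipid = (p * comp.f_neutral_lipid
             + (0.3 * p + 0.7) * comp.f_neutral_phospholipid) / (1.0 + y)

    if _is_strong_base(compound):
        kb_p = 1.0 if bp_ratio is None else bp_ratio
        h = haematocrit
        kpu_bc = (kb_p - (1.0 - h)) / (h * fub)
        bc = BLOOD_CELL
        x_bc = _ionized_ratio(compound, bc["ph"])
        lipid_bc = (p_plasma * bc["f_nl"]
                    + (0.3 * p_plasma + 0.7) * bc["f_np"]) / (1.0 + y)
        water_bc = (1.0 + x_bc) / (1.0 + y) * bc["f_iw"]
        ka_ap = (kpu_bc - water_bc - lipid_bc) * (1.0 + y) / (bc["ap_mg_per_g"] * x_bc)
        ka_ap = max(ka_ap, 0.0)
        assoc = ka_ap * comp.acidic_phospholipid * x / (1.0 + y)
    else:
        plasma_lipid = (p_plasma * PLASMA_F_NL
                        + (0.3 * p_plasma + 0.7) * PLASMA_F_NP) / (1.0 + y)
        residual = max(1.0 / fub - 1.0 - plasma_lipid, 0.0)
        if ctype in (CompoundType.NEUTRAL, CompoundType.MONOPROTIC_ACID,
                     CompoundType.DIPROTIC_ACID):
            ratio = comp.albumin_ratio
        else:  # weak bases, zwitterions
            ratio = comp.lipoprotein_ratio
        assoc = residual * ratio

    kpu = water + lipid + assoc
    return max(kpu, 1e-12) * fub


def predict_partition_set(
    compound: CompoundRecord,
    fub: Optional[float] = None,
    compositions: Optional[dict] = None,
) -> PartitionSet:
    """Kp for every bundled tissue; ``fub`` defaults to the record's value."""
    fub = fub if fub is not None else compound.fub
    if fub is None:
        raise ValidationError(
            f"compound '{compound.name}' has no fub; fill it before predicting Kp"
        )
    comps = compositions or load_tissue_compositions()
    kp = {
        t: tissue_plasma_kp(compound, c, fub, bp_ratio=compound.bp_ratio)
        for t, c in comps.items()
    }
    return PartitionSet(kp=kp, fub=fub, method="rodgers_rowland")


def unity_partition_set(fub: float = 1.0, compositions: Optional[dict] = None) -> PartitionSet:
    """Fallback for degenerate records: all Kp = 1, clearly flagged."""
    comps = compositions or load_tissue_compositions()
    return PartitionSet(kp={t: 1.0 for t in comps}, fub=fub, method="unity")
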