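"""Readers and writers for compound tables, physiology configs and results.

Compound tables are CSV/JSON/YAML with columns named exactly like the
CompoundRecord fields (canonical units). Results serialize to JSON
(summaries, VIVD results) and CSV (timeseries with columns ``time_h``,
``conc_plasma_mg_per_L``, ``conc_unbound_mg_per_L``; QIVIVE tables one row
per compound x assay).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .pbk import ConcentrationTimeseries, PKSummary
from .records import CompoundRecord, ValidationError
from .vivd import VIVDResult

_COMPOUND_FIELDS = [
    "name", "chem_class", "mw", "logPow", "water_solubility", "henry_pc",
    "pka1", "pka2", "compound_type", "fub", "fub_qsar", "papp",
    "clint_value", "clint_system", "bp_ratio", "data_status",
]
_REQUIRED = ("name", "mw", "logPow")


def _infer_format(path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    return {"yml": "yaml"}.get(suffix, suffix or "csv")


def _clean(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return value


def load_compound_table(path, fmt: Optional[str] = None) -> list:
    """Parse a compound table into validated records.

    Missing optional fields become ``provenance=absent``; invariant
    violations raise a :class:`ValidationError` naming the row and fields.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        rows = pd.read_csv(path, comment="#").to_dict("records")
    elif fmt == "json":
        rows = json.loads(Path(path).read_text())
    elif fmt == "yaml":
        rows = yaml.safe_load(Path(path).read_text())
    else:
        raise ValidationError(f"unsupported compound table format '{fmt}'")
    if isinstance(rows, dict):
        rows = [rows]
    records = []
    for i, raw in enumerate(rows):
        row = {k: _clean(v) for k, v in raw.items() if k in _COMPOUND_FIELDS}
        missing = [k for k in _REQUIRED if row.get(k) is None]
        if missing:
            raise ValidationError(
                f"row {i}: missing required column(s) {missing}"
            )
        defaults = {"chem_class": "other", "compound_type": "neutral",
                    "clint_system": "PHH", "data_status": "rich",
                    "water_solubility": 0.0, "henry_pc": 0.0}
        for k, v in defaults.items():
            if row.get(k) is None:
                row[k] = v
        try:
            records.append(CompoundRecord(**row))
        except (ValidationError, TypeError, ValueError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return records


def write_compound_table(records, path, fmt: Optional[str] = None) -> None:
    fmt = _infer_format(path, fmt)
    rows = []
    for rec in records:
        d = {k: getattr(rec, k) for k in _COMPOUND_FIELDS}
        for k, v in d.items():
            if hasattr(v, "value"):
                d[k] = v.value
        rows.append(d)
    if fmt == "csv":
        pd.DataFrame(rows).to_csv(path, index=False)
    elif fmt == "json":
        Path(path).write_text(json.dumps(rows, indent=1))
    elif fmt == "yaml":
        Path(path).write_text(yaml.safe_dump(rows, sort_keys=False))
    else:
        raise ValidationError(f"unsupported format '{fmt}'")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_results(obj, path, fmt: Optional[str] = None) -> None:
    """Serialize a result object; see module docstring for schemas."""
    fmt = _infer_format(path, fmt)
    path = Path(path)
    if isinstance(obj, PKSummary):
        payload = {"cmax": obj.cmax, "tmax": obj.tmax, "auc": obj.auc,
                   "cmax_unbound": obj.cmax_unbound,
                   "cmax_unbound_molar": obj.cmax_unbound_molar}
        path.write_text(json.dumps(payload, indent=1))
    elif isinstance(obj, VIVDResult):
        path.write_text(json.dumps(asdict(obj), indent=1))
    elif isinstance(obj, ConcentrationTimeseries):
        pd.DataFrame({
            "time_h": obj.times,
            "conc_plasma_mg_per_L": obj.venous_plasma,
            "conc_unbound_mg_per_L": obj.unbound_plasma,
        }).to_csv(path, index=False)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    else:
        raise ValidationError(f"cannot serialize {type(obj).__name__}")


def read_pk_summary(path) -> PKSummary:
    d = json.loads(Path(path).read_text())
    return PKSummary(cmax=d["cmax"], tmax=d["tmax"], auc=d["auc"],
                     cmax_unbound=d["cmax_unbound"],
                     cmax_unbound_molar=d["cmax_unbound_molar"])


def read_vivd_result(path) -> VIVDResult:
    return VIVDResult(**json.loads(Path(path).read_text()))


def read_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_physiology_file(path):
    """Physiology from a YAML config (``species`` selects embedded defaults)."""
    from .physiology import load_physiology

    return load_physiology(yaml.safe_load(Path(path).read_text()))
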