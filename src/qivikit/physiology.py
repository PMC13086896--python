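"""Embedded species physiology and its loader.

`default_physiology` returns the bundled reference physiology for rat or human
(see ``data/reference_physiology.yaml``); user YAML configs can override any
value via :func:`load_physiology`.
"""

from __future__ import annotations

import copy
from importlib import resources

import yaml

from .records import PhysiologyRecord, ValidationError

_CACHE: dict = {}


def _reference_table() -> dict:
    if "table" not in _CACHE:
        text = (
            resources.files("qivikit.data")
            .joinpath("reference_physiology.yaml")
            .read_text()
        )
        _CACHE["table"] = yaml.safe_load(text)
    return copy.deepcopy(_CACHE["table"])


def _resolve_profile(table: dict, key: str) -> dict:
    try:
        entry = table[key]
    except KeyError:
        raise ValidationError(
            f"unknown species/profile '{key}'; known: {sorted(table)}"
        ) from None
    if "inherit" in entry:
        base = _resolve_profile(table, entry.pop("inherit"))
        overrides = entry.pop("compartments_override", {})
        base.update(entry)
        for cname, fields in overrides.items():
            for comp in base["compartments"]:
                if comp["name"] == cname:
                    comp.update(fields)
        return base
    return entry


def _build(entry: dict) -> PhysiologyRecord:
    entry.pop("si_lumen_volume_total", None)
    entry.pop("li_lumen_volume_total", None)
    return PhysiologyRecord(**entry)


def default_physiology(species: str) -> PhysiologyRecord:
    """Embedded defaults for ``rat``, ``human`` or a named profile.

    Profiles: ``rat`` (11.9 g liver), ``rat_results_liver`` (19 g liver
    alternative), ``human`` (70 kg male, 125 mL/min GFR).
    """
    return _build(_resolve_profile(_reference_table(), species))


def load_physiology(config: dict) -> PhysiologyRecord:
    """Build a physiology from a user config dict (e.g. parsed YAML).

    ``species`` selects the embedded defaults; every other key overrides the
    default value. Compartment overrides are merged by compartment name.
    """
    config = copy.deepcopy(config)
    species = config.pop("species", None)
    if species is None:
        raise ValidationError("physiology config must name a 'species'")
    entry = _resolve_profile(_reference_table(), species)
    comp_over = config.pop("compartments_override", {})
    seg_over = config.pop("git_segments_override", {})
    entry.update(config)
    for cname, fields in comp_over.items():
        for comp in entry["compartments"]:
            if comp["name"] == cname:
                comp.update(fields)
    for sname, fields in seg_over.items():
        for seg in entry["git_segments"]:
            if seg["name"] == sname:
                seg.update(fields)
    return _build(entry)
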