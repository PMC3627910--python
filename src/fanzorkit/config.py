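"""Flat key-value configuration files.

A config file is plain text, one ``key = value`` per line, ``#`` comments and
blank lines ignored. Keys name dataclass fields of the parameter objects used
across the toolkit (MotifSpec, HelitronParams, ScoringScheme, TSD-calling
parameters); unknown keys are rejected so typos fail loudly. The simulator
additionally accepts ``familyN.<key>`` groups (see :func:`parse_family_specs`).
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Any, TypeVar

from fanzorkit.simulate import (
    FamilySpec,
    Helitron1Structure,
    Helitron2Structure,
    TirStructure,
    TsdModel,
)

T = TypeVar("T")


def load_config(path: str | Path | None) -> dict[str, str]:
    """Parse a flat key-value config file into a string map."""
    if path is None:
        return {}
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def _coerce(value: str, typ: Any) -> Any:
    if typ in (int, "int"):
        return int(value)
    if typ in (float, "float"):
        return float(value)
    if typ in (bool, "bool"):
        if value.lower() in ("1", "true", "yes", "on"):
            return True
        if value.lower() in ("0", "false", "no", "off"):
            return False
        raise ValueError(f"not a boolean: {value!r}")
    return value


def build_params(cls: type[T], cfg: dict[str, str], **overrides: Any) -> T:
    """Instantiate a parameter dataclass from config values plus overrides.

    Only keys naming simple (int/float/bool/str) fields of ``cls`` are
    consumed; compound fields must be set programmatically.
    """
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in cfg.items():
        if key in fields:
            typ = fields[key].type
            typ = {"int": int, "float": float, "bool": bool, "str": str}.get(typ, typ)
            if typ in (int, float, bool, str):
                kwargs[key] = _coerce(value, typ)
    kwargs.update(overrides)
    return cls(**kwargs)


_STRUCTURES = {
    "none": lambda args: None,
    "tir": lambda args: TirStructure(arm_len=int(args[0]) if args else 33),
    "helitron1": lambda args: Helitron1Structure(),
    "helitron2": lambda args: Helitron2Structure(),
}


def _parse_structure(text: str):
    kind, *args = text.split(":")
    if kind not in _STRUCTURES:
        raise ValueError(f"unknown structure {text!r}")
    return _STRUCTURES[kind](args)


def _parse_tsd(text: str) -> TsdModel:
    kind, *args = text.split(":")
    if kind == "none":
        return TsdModel("none")
    if kind == "fixed":
        return TsdModel("fixed", int(args[0]), int(args[0]))
    if kind == "uniform":
        return TsdModel("uniform", int(args[0]), int(args[1]))
    raise ValueError(f"unknown tsd model {text!r}")


def parse_family_specs(cfg: dict[str, str]) -> list[FamilySpec]:
    """Collect ``familyN.<key>`` groups from a simulator config.

    Recognized per-family keys: id, element_len, structure (``none``,
    ``tir[:arm_len]``, ``helitron1``, ``helitron2``), copies,
    substitution_rate, truncation_prob, truncation_mean_frac, tsd (``none``,
    ``fixed:L``, ``uniform:LO:HI``), tsd_prob, target_preference.
    """
    groups: dict[str, dict[str, str]] = {}
    for key, value in cfg.items():
        m = re.fullmatch(r"(family\d+)\.(\w+)", key)
        if m:
            groups.setdefault(m.group(1), {})[m.group(2)] = value
    specs = []
    for name in sorted(groups, key=lambda g: int(g.removeprefix("family"))):
        g = groups[name]
        specs.append(
            FamilySpec(
                family_id=g.get("id", name),
                element_len=int(g.get("element_len", 2100)),
                structure=_parse_structure(g.get("structure", "none")),
                copy_number=int(g.get("copies", 0)),
                substitution_rate=float(g.get("substitution_rate", 0.0)),
                truncation_prob=float(g.get("truncation_prob", 0.0)),
                truncation_mean_frac=float(g.get("truncation_mean_frac", 0.3)),
                tsd_model=_parse_tsd(g.get("tsd", "none")),
                tsd_prob=float(g.get("tsd_prob", 1.0)),
                target_preference_prob=float(g.get("target_preference", 0.0)),
            )
        )
    return specs
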