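"""Severity-score engine: band-table lookup plus per-score special terms.

Nine scoring systems (SOFA, PIRO, ViEWS, SCS, MEDS, MEWS, SAPS II,
APACHE II, REMS) are described declaratively in JSON fixtures shipped with
the package.  Each numeric component carries an ordered table of half-open
``[lo, hi)`` bands mapping a physiologic range to integer points; terms that
are not simple band lookups (categorical items, boolean flags, and composite
rules such as the APACHE II oxygenation term) are ``special_terms`` resolved
by a small hook registry.

Band tables must partition the real line: gaps or overlaps are a fixture
configuration error and are rejected at load time, never clamped at lookup
time.
"""
from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources
from math import inf
from typing import Optional

__all__ = [
    "SCORE_NAMES", "FixtureError", "ScoreError", "Band", "ComponentDef",
    "SpecialTerm", "ScoreDefinition", "ScoreResult", "Snapshot",
    "avpu_to_gcs", "load_score_definition", "load_all_definitions",
    "load_normal_values", "band_points", "compute_score", "compute_all_scores",
]

SCORE_NAMES = ("SOFA", "PIRO", "ViEWS", "SCS", "MEDS", "MEWS", "SAPS2", "APACHE2", "REMS")

_FIXTURE_FILES = {
    "SOFA": "sofa.json", "PIRO": "piro.json", "ViEWS": "views.json",
    "SCS": "scs.json", "MEDS": "meds.json", "MEWS": "mews.json",
    "SAPS2": "saps2.json", "APACHE2": "apache2.json", "REMS": "rems.json",
}

#: AVPU -> near-equivalent Glasgow Coma Scale, after the published
#: conversion studies (alert 15, responds to voice 13, to pain 8,
#: unresponsive 3).  Strictly monotone decreasing.
AVPU_GCS = {"A": 15, "V": 13, "P": 8, "U": 3}


class FixtureError(ValueError):
    """A scoring fixture is malformed (gap, overlap, or missing entry)."""


class ScoreError(ValueError):
    """A snapshot cannot be scored (missing component, out-of-range total)."""


def avpu_to_gcs(avpu: str) -> int:
    """Convert an AVPU level to its near-equivalent Glasgow Coma Scale value."""
    try:
        return AVPU_GCS[avpu]
    except KeyError:
        raise ScoreError(f"unknown AVPU level {avpu!r}; expected one of A,V,P,U") from None


@dataclass(frozen=True)
class Band:
    lo: float  # inclusive; -inf for an open lower end
    hi: float  # exclusive; +inf for an open upper end
    points: int


@dataclass
class ComponentDef:
    """One banded numeric component: ordered half-open intervals -> points."""

    name: str
    unit: str
    direction: str  # which extreme is worse: 'low' | 'high' | 'both'
    bands: list

    def __post_init__(self):
        self.bands = sorted(self.bands, key=lambda b: b.lo)
        prev_hi = -inf
        for b in self.bands:
            if b.lo != prev_hi:
                raise FixtureError(
                    f"{self.name}: bands have a gap or overlap at {b.lo} (expected {prev_hi})")
            if b.hi <= b.lo:
                raise FixtureError(f"{self.name}: empty band [{b.lo}, {b.hi})")
            prev_hi = b.hi
        if prev_hi != inf:
            raise FixtureError(f"{self.name}: bands do not cover the upper range (end at {prev_hi})")
        self._los = [b.lo for b in self.bands]

    def lookup(self, value: float) -> int:
        """Points for ``value`` via binary search over the band lower edges."""
        idx = bisect_right(self._los, value) - 1
        band = self.bands[idx]
        if not (band.lo <= value < band.hi):  # pragma: no cover - partition guarantees
            raise FixtureError(f"{self.name}: value {value} falls outside every band")
        return band.points

    def normal_midpoint(self) -> float:
        """Midpoint of the zero-point band (used for 'both'-direction tie-breaks)."""
        zero = [b for b in self.bands if b.points == 0]
        if not zero:
            return self.bands[0].lo
        b = min(zero, key=lambda b: b.points)
        lo = b.lo if b.lo != -inf else b.hi - 1.0
        hi = b.hi if b.hi != inf else b.lo + 1.0
        return 0.5 * (lo + hi)


@dataclass
class SpecialTerm:
    """A non-band term: categorical map, boolean flag, age-style band table,
    or a named hook for composite logic."""

    name: str
    kind: str  # 'bands' | 'flag' | 'categorical' | 'hook'
    component: Optional[str] = None
    points: int = 0
    map: Optional[dict] = None
    bands: Optional[ComponentDef] = None
    hook: Optional[str] = None
    extra: dict = field(default_factory=dict)


@dataclass
class ScoreDefinition:
    name: str
    version: str
    total_range: tuple
    normal_floor: int
    components: list
    special_terms: list
    provenance: str = ""

    def component(self, name: str) -> ComponentDef:
        for c in self.components:
            if c.name == name:
                return c
        raise FixtureError(f"{self.name}: no banded component {name!r}")

    def windowed_inputs(self) -> set:
        """Snapshot keys that vary over time and need window aggregation."""
        needed = {c.name for c in self.components}
        for t in self.special_terms:
            if t.kind == "hook":
                needed |= set(_HOOK_INPUTS.get(t.hook, ()))
            elif t.component is not None:
                needed.add(t.component)
        return needed & set(_WINDOWED)


@dataclass
class ScoreResult:
    name: str
    total: int
    per_component: dict
    defaulted_components: set = field(default_factory=set)


class Snapshot:
    """Per-window worst physiologic values plus static patient context.

    ``values`` maps canonical component names to values; ``provenance``
    records, per component, whether the value was measured in the window,
    carried from an earlier-in-clock-time window, or assumed normal.
    """

    def __init__(self, values: dict, provenance: Optional[dict] = None):
        self.values = dict(values)
        self.provenance = dict(provenance or {})

    def get(self, name: str):
        try:
            return self.values[name]
        except KeyError:
            raise ScoreError(f"snapshot is missing required component {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.values


# --- fixture loading -------------------------------------------------------

def _load_json(filename: str) -> dict:
    with resources.files("wardscore.fixtures").joinpath(filename).open() as fh:
        return json.load(fh)


def _parse_bands(raw: list) -> list:
    return [Band(lo=-inf if b["lo"] is None else float(b["lo"]),
                 hi=inf if b["hi"] is None else float(b["hi"]),
                 points=int(b["points"])) for b in raw]


def load_score_definition(name: str) -> ScoreDefinition:
    """Load one score's fixture by canonical name (e.g. ``'SOFA'``)."""
    try:
        raw = _load_json(_FIXTURE_FILES[name])
    except KeyError:
        raise FixtureError(f"unknown score {name!r}; expected one of {SCORE_NAMES}") from None
    components = [
        ComponentDef(name=c["name"], unit=c.get("unit", ""),
                     direction=c.get("direction", "high"),
                     bands=_parse_bands(c["bands"]))
        for c in raw["components"]
    ]
    terms = []
    for t in raw.get("special_terms", []):
        term = SpecialTerm(
            name=t["name"], kind=t["kind"], component=t.get("component"),
            points=int(t.get("points", 0)), map=t.get("map"),
            hook=t.get("hook"),
            extra={k: v for k, v in t.items()
                   if k not in ("name", "kind", "component", "points", "map", "bands", "hook")},
        )
        if t.get("bands") is not None:
            term.bands = ComponentDef(name=t["name"], unit="",
                                      direction=t.get("direction", "high"),
                                      bands=_parse_bands(t["bands"]))
        if term.kind == "hook" and term.hook not in _HOOKS:
            raise FixtureError(f"{raw['name']}: unknown hook {term.hook!r}")
        terms.append(term)
    return ScoreDefinition(
        name=raw["name"], version=raw.get("version", ""),
        total_range=tuple(raw["total_range"]), normal_floor=int(raw.get("normal_floor", 0)),
        components=components, special_terms=terms, provenance=raw.get("provenance", ""),
    )


def load_all_definitions() -> dict:
    return {name: load_score_definition(name) for name in SCORE_NAMES}


def load_normal_values() -> dict:
    """The shared normal-values fixture (imputation defaults and generator baselines)."""
    raw = _load_json("normal_values.json")
    return {k: v for k, v in raw.items() if not k.startswith("_")}


def band_points(component: ComponentDef, value: float) -> int:
    """Points earned by ``value`` under a component's band table."""
    return component.lookup(float(value))


# --- special-term hooks ----------------------------------------------------

_HOOKS = {}
#: Time-varying snapshot keys each hook reads (used for window aggregation).
_HOOK_INPUTS = {
    "sofa_cardiovascular": ("map",),
    "apache2_oxygenation": ("fio2", "pao2", "paco2"),
    "gcs_deficit": ("gcs",),
    "apache2_chronic_health": (),
    "saps2_oxygenation": ("pao2_fio2_ratio",),
    "meds_tachypnea_hypoxia": ("respiratory_rate", "spo2"),
    "meds_septic_shock": ("systolic_bp",),
}

#: Components aggregated per window (everything else in a snapshot is static).
_WINDOWED = (
    "heart_rate", "respiratory_rate", "systolic_bp", "diastolic_bp", "map",
    "temperature", "spo2", "fio2", "avpu", "gcs", "wbc", "platelets",
    "bilirubin", "creatinine", "bun", "sodium", "potassium", "bicarbonate",
    "hematocrit", "glucose", "albumin", "lactate", "band_fraction", "pao2",
    "paco2", "ph", "pao2_fio2_ratio", "supplemental_o2",
)


def _hook(name):
    def deco(fn):
        _HOOKS[name] = fn
        return fn
    return deco


_VASOPRESSOR_POINTS = {"none": 0, "low": 2, "mid": 3, "high": 4}


@_hook("sofa_cardiovascular")
def _sofa_cardiovascular(snapshot: Snapshot, term: SpecialTerm) -> int:
    """Hypotension (MAP < 70) scores 1; vasopressor support overrides to 2-4."""
    hypotension = 1 if snapshot.get("map") < 70 else 0
    vaso = snapshot.values.get("vasopressor_level", "none")
    return max(hypotension, _VASOPRESSOR_POINTS.get(vaso, 0))


@_hook("apache2_oxygenation")
def _apache2_oxygenation(snapshot: Snapshot, term: SpecialTerm) -> int:
    """A-aDO2 grading at FiO2 >= 0.5, PaO2 grading below."""
    fio2 = snapshot.get("fio2")
    pao2 = snapshot.get("pao2")
    if fio2 >= 0.5:
        aado2 = fio2 * 713.0 - snapshot.get("paco2") / 0.8 - pao2
        if aado2 >= 500:
            return 4
        if aado2 >= 350:
            return 3
        if aado2 >= 200:
            return 2
        return 0
    if pao2 < 55:
        return 4
    if pao2 < 61:
        return 3
    if pao2 < 71:
        return 1
    return 0


@_hook("gcs_deficit")
def _gcs_deficit(snapshot: Snapshot, term: SpecialTerm) -> int:
    return 15 - int(round(snapshot.get("gcs")))


@_hook("apache2_chronic_health")
def _apache2_chronic_health(snapshot: Snapshot, term: SpecialTerm) -> int:
    flags = term.extra.get("flags", ())
    return 5 if any(bool(snapshot.values.get(f, False)) for f in flags) else 0


@_hook("saps2_oxygenation")
def _saps2_oxygenation(snapshot: Snapshot, term: SpecialTerm) -> int:
    if not snapshot.values.get("mechanical_ventilation", False):
        return 0
    ratio = snapshot.get("pao2_fio2_ratio")
    if ratio < 100:
        return 11
    if ratio < 200:
        return 9
    return 6


@_hook("meds_tachypnea_hypoxia")
def _meds_tachypnea_hypoxia(snapshot: Snapshot, term: SpecialTerm) -> int:
    return 3 if (snapshot.get("respiratory_rate") > 20 or snapshot.get("spo2") < 90) else 0


@_hook("meds_septic_shock")
def _meds_septic_shock(snapshot: Snapshot, term: SpecialTerm) -> int:
    septic = bool(snapshot.values.get("severe_sepsis", False))
    return 3 if (septic and snapshot.get("systolic_bp") < 90) else 0


# --- scoring ---------------------------------------------------------------

def _term_points(term: SpecialTerm, snapshot: Snapshot) -> int:
    if term.kind == "flag":
        return term.points if bool(snapshot.get(term.component)) else 0
    if term.kind == "categorical":
        value = snapshot.get(term.component)
        try:
            return int(term.map[value])
        except KeyError:
            raise ScoreError(
                f"term {term.name!r}: value {value!r} not in categorical map") from None
    if term.kind == "bands":
        return term.bands.lookup(float(snapshot.get(term.component)))
    if term.kind == "hook":
        return int(_HOOKS[term.hook](snapshot, term))
    raise FixtureError(f"unknown special-term kind {term.kind!r}")


def compute_score(definition: ScoreDefinition, snapshot: Snapshot) -> ScoreResult:
    """Score one snapshot under one definition.

    Deterministic: per-component points are band lookups of the snapshot
    values; special terms are applied per the fixture.  The total must fall
    in the definition's declared range.
    """
    per_component = {}
    defaulted = set()
    for comp in definition.components:
        value = snapshot.get(comp.name)
        per_component[comp.name] = comp.lookup(float(value))
        if snapshot.provenance.get(comp.name) == "normal_default":
            defaulted.add(comp.name)
    for term in definition.special_terms:
        per_component[term.name] = _term_points(term, snapshot)
        if term.component and snapshot.provenance.get(term.component) == "normal_default":
            defaulted.add(term.component)
    total = int(sum(per_component.values()))
    lo, hi = definition.total_range
    if not (lo <= total <= hi):
        raise ScoreError(
            f"{definition.name}: total {total} outside declared range [{lo}, {hi}]")
    return ScoreResult(name=definition.name, total=total,
                       per_component=per_component, defaulted_components=defaulted)


def compute_all_scores(snapshot: Snapshot, definitions: Optional[dict] = None) -> dict:
    """Apply all nine scores to one snapshot; errors carry the score name."""
    definitions = definitions or load_all_definitions()
    results = {}
    for name in sorted(definitions):
        try:
            results[name] = compute_score(definitions[name], snapshot)
        except (ScoreError, FixtureError) as exc:
            raise ScoreError(f"{name}: {exc}") from exc
    return results
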