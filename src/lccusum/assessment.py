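"""Pass/fail assessment of a simulated hip-fracture procedure.

A procedure is scored against a *conjunctive* set of criteria: it passes
iff every criterion holds, and the verdict lists every violated
criterion.  There is no weighting or partial credit — the downstream
LC-CUSUM chart consumes only the binary verdict.

The default rule set encodes the clinically established criteria for
guide-wire placement in dynamic hip screw (DHS) fixation:

* tip–apex distance (TAD) ≤ 20 mm — a TAD above 20 mm is a validated
  predictor of fixation failure;
* wire placement in the center–center or center–inferior zone of the
  femoral head;
* no breach of cortical bone;
* no more than 3 attempts to place the K-wire.

Boundary semantics are inclusive: failure requires being *strictly*
beyond a threshold (TAD of exactly 20 mm or exactly 3 attempts passes).
Competency levels 0 and 1 share the wire rule set; level 2 (the full DHS
procedure) extends it with reamer, plate-angle and shaft-screw criteria.
Fluoroscopy time, radiograph count and total time are recorded but never
influence the verdict under the default rules.

Because the complete operational criterion list is configuration, not
code, rule sets load from a small YAML document (:func:`load_ruleset`);
the shipped default file reproduces the built-in rules exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "PLACEMENT_ZONES",
    "PASSING_ZONES",
    "WireMetrics",
    "DhsMetrics",
    "Verdict",
    "Criterion",
    "Ruleset",
    "default_ruleset",
    "load_ruleset",
    "assess",
    "assess_wire",
    "assess_dhs",
]

#: Closed vocabulary of guide-wire placement zones in the femoral head.
PLACEMENT_ZONES = frozenset(
    {
        "center-center",
        "center-inferior",
        "center-superior",
        "inferior",
        "superior",
        "anterior",
        "posterior",
        "other",
    }
)

#: Zones compatible with a passing procedure under the default rules.
PASSING_ZONES = frozenset({"center-center", "center-inferior"})


class MetricsError(ValueError):
    """Invalid metric value (e.g. unknown placement zone)."""


class RulesetError(ValueError):
    """Malformed or inconsistent rule-set configuration."""


@dataclass(frozen=True)
class WireMetrics:
    """Metrics of a single K-wire placement procedure."""

    tip_apex_distance: float
    placement_zone: str
    cortical_breach: bool
    kwire_attempts: int
    fluoroscopy_time: float = 0.0
    radiograph_count: int = 0
    total_time: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tip_apex_distance >= 0.0) or self.tip_apex_distance != self.tip_apex_distance:
            raise MetricsError(
                f"tip_apex_distance must be finite and >= 0, got "
                f"{self.tip_apex_distance}"
            )
        if self.placement_zone not in PLACEMENT_ZONES:
            raise MetricsError(
                f"unknown placement_zone {self.placement_zone!r}; expected one "
                f"of {sorted(PLACEMENT_ZONES)}"
            )
        if self.kwire_attempts < 1:
            raise MetricsError(
                f"kwire_attempts must be >= 1, got {self.kwire_attempts}"
            )
        if self.fluoroscopy_time < 0 or self.total_time < 0 or self.radiograph_count < 0:
            raise MetricsError("time and radiograph metrics must be >= 0")


@dataclass(frozen=True)
class DhsMetrics(WireMetrics):
    """Metrics of a full DHS procedure (wire metrics plus implant steps)."""

    reamer_breach: bool = False
    plate_angle_appropriate: bool = True
    cortical_drill_outside_mm: float = 0.0
    shaft_screw_bicortical: bool = True

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.cortical_drill_outside_mm < 0:
            raise MetricsError(
                f"cortical_drill_outside_mm must be >= 0, got "
                f"{self.cortical_drill_outside_mm}"
            )


_METRIC_FIELDS = frozenset(f.name for f in fields(DhsMetrics))


@dataclass(frozen=True)
class Verdict:
    """Binary pass/fail verdict plus the list of violated criteria."""

    passed: bool
    failed_criteria: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_criteria) == 0):
            raise ValueError("passed must hold iff failed_criteria is empty")


_COMPARATORS = {
    "le": lambda v, t: v <= t,
    "lt": lambda v, t: v < t,
    "ge": lambda v, t: v >= t,
    "gt": lambda v, t: v > t,
    "eq": lambda v, t: v == t,
    "in": lambda v, t: v in t,
    "is": lambda v, t: bool(v) == bool(t),
}


@dataclass(frozen=True)
class Criterion:
    """One pass condition: ``metric <comparator> value`` must hold to pass."""

    id: str
    metric: str
    comparator: str
    value: object

    def __post_init__(self) -> None:
        if self.metric not in _METRIC_FIELDS:
            raise RulesetError(f"unknown metric {self.metric!r}")
        if self.comparator not in _COMPARATORS:
            raise RulesetError(
                f"unknown comparator {self.comparator!r}; expected one of "
                f"{sorted(_COMPARATORS)}"
            )

    def satisfied(self, metrics: WireMetrics) -> bool:
        if not hasattr(metrics, self.metric):
            raise MetricsError(
                f"criterion {self.id!r} requires metric {self.metric!r} "
                f"absent from {type(metrics).__name__}"
            )
        return _COMPARATORS[self.comparator](getattr(metrics, self.metric), self.value)


#: Mapping competency level -> ordered criteria (all must hold to pass).
Ruleset = Mapping[int, tuple[Criterion, ...]]

_WIRE_CRITERIA = (
    Criterion("tad", "tip_apex_distance", "le", 20.0),
    Criterion("placement_zone", "placement_zone", "in", PASSING_ZONES),
    Criterion("cortical_breach", "cortical_breach", "is", False),
    Criterion("kwire_attempts", "kwire_attempts", "le", 3),
)

_DHS_CRITERIA = _WIRE_CRITERIA + (
    Criterion("reamer_breach", "reamer_breach", "is", False),
    Criterion("plate_angle", "plate_angle_appropriate", "is", True),
    Criterion("shaft_screw", "shaft_screw_bicortical", "is", True),
)


def default_ruleset() -> Ruleset:
    """Built-in rules: levels 0 and 1 share the wire set; level 2 extends it."""
    return {0: _WIRE_CRITERIA, 1: _WIRE_CRITERIA, 2: _DHS_CRITERIA}


def default_ruleset_path() -> Path:
    """Path of the shipped YAML file reproducing the built-in rules."""
    return Path(str(resources.files("lccusum").joinpath("data/default_ruleset.yaml")))


def _parse_entry(entry: object, level: object, index: int) -> Criterion:
    if not isinstance(entry, Mapping):
        raise RulesetError(
            f"level {level} entry {index}: expected a mapping, got {type(entry).__name__}"
        )
    unknown = set(entry) - {"id", "metric", "comparator", "threshold", "allowed", "value"}
    if unknown:
        raise RulesetError(
            f"level {level} entry {index}: unknown keys {sorted(unknown)}"
        )
    try:
        metric = entry["metric"]
        comparator = entry["comparator"]
    except KeyError as exc:
        raise RulesetError(
            f"level {level} entry {index}: missing required key {exc.args[0]!r}"
        ) from None
    if "allowed" in entry:
        value: object = frozenset(entry["allowed"])
    elif "threshold" in entry:
        value = entry["threshold"]
    elif "value" in entry:
        value = entry["value"]
    else:
        raise RulesetError(
            f"level {level} entry {index}: needs one of threshold/allowed/value"
        )
    try:
        return Criterion(
            id=str(entry.get("id", metric)),
            metric=str(metric),
            comparator=str(comparator),
            value=value,
        )
    except RulesetError as exc:
        raise RulesetError(f"level {level} entry {index}: {exc}") from None


def load_ruleset(source: Union[str, Path]) -> Ruleset:
    """Load a per-level criterion configuration from YAML text or a file.

    The document maps competency level (0/1/2) to a list of entries, each
    with keys ``metric``, ``comparator`` and one of ``threshold`` /
    ``allowed`` / ``value`` (plus an optional ``id``).  Unknown metric
    names, comparators and malformed entries are rejected with the level
    and entry index.  Duplicate entries for a metric are all applied
    (conjunction).  An empty criterion list means every procedure passes.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml"))):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise RulesetError("ruleset document must map levels to criterion lists")
    levels_doc = doc.get("levels", doc)
    ruleset: dict[int, tuple[Criterion, ...]] = {}
    for level, entries in levels_doc.items():
        try:
            lvl = int(level)
        except (TypeError, ValueError):
            raise RulesetError(f"level key {level!r} is not an integer") from None
        if entries is None:
            entries = []
        if not isinstance(entries, Sequence) or isinstance(entries, (str, bytes)):
            raise RulesetError(f"level {level}: criteria must be a list")
        ruleset[lvl] = tuple(
            _parse_entry(entry, level, i) for i, entry in enumerate(entries)
        )
    return ruleset


def assess(
    metrics: WireMetrics, level: int, ruleset: Optional[Ruleset] = None
) -> Verdict:
    """Assess one procedure at a competency level against a rule set.

    Pure function of (metrics, ruleset): the verdict is passed iff every
    criterion for the level holds, with every violated criterion listed.
    """
    rules = (ruleset if ruleset is not None else default_ruleset()).get(level)
    if rules is None:
        raise RulesetError(f"no criteria configured for competency level {level}")
    failed = tuple(c.id for c in rules if not c.satisfied(metrics))
    return Verdict(passed=not failed, failed_criteria=failed)


def assess_wire(metrics: WireMetrics, ruleset: Optional[Ruleset] = None) -> Verdict:
    """Assess a K-wire placement (competency levels 0/1)."""
    return assess(metrics, 0, ruleset)


def assess_dhs(metrics: DhsMetrics, ruleset: Optional[Ruleset] = None) -> Verdict:
    """Assess a full DHS procedure (competency level 2)."""
    return assess(metrics, 2, ruleset)
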