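"""The scoring table: interval bands mapping clinical values to points.

The scale's bands are data, not code, so that a multicenter revision of the
cut-offs is a configuration change.  Each band is an interval with explicit
endpoint closure, because the published cut-offs mix conventions: the
noradrenaline "low risk" band is upper-inclusive ((0, 0.5] mg/h) while its
"high risk" band is lower-inclusive ([2, inf) mg/h), and no single half-open
convention covers both.  Table validation proves that each parameter's bands
tile its physical range with no gaps and no overlaps, so every valid value
maps to exactly one band.

Gap-closing choices applied to the printed bands (the scored quantities are
continuous, so printed edges like "25-29.9" are read as half-open reals):

* BMI below 18.5 (underweight, not assigned in the published scale) scores
  0 with an ``underweight_unspecified`` flag.
* eGFR >= 60 (better than the lowest published KDOQI risk band) scores 0
  with an ``above_kdoqi_bands`` flag.
* P/F exactly 100 mmHg, between "less than 100" and "101 to 200", is
  assigned to the severe band - conservative toward severity.
* PEEP above the printed 20 cm H2O ceiling keeps 3 points and is flagged
  ``peep_above_band``.
* Noradrenaline gaps 0.5-0.6 and 1.9-2 mg/h close toward the higher band.
* The AI bands "51-74%" become (0.50, 0.75) on the probability scale so
  every probability in [0, 1] maps to exactly one band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import yaml

from .records import MAX_POINTS, Parameter, ParameterScore

__all__ = ["Band", "ScoringTable", "default_table", "DEFAULT_TABLE_VERSION"]

DEFAULT_TABLE_VERSION = "costas-1.0"

#: PEEP values above this are outside the published bands (flag only).
PEEP_PRINTED_MAX = 20.0

#: Induced-hypertension MAP targets, recorded as protocol constants only;
#: they gate no scoring rule.
MAP_TARGET_MMHG = (80.0, 90.0)
MAP_PERSISTENT_SPASM_MMHG = 100.0


@dataclass(frozen=True)
class Band:
    """One scoring interval: value in the interval earns ``points``."""

    lower: float
    upper: float
    points: int
    label: str
    lower_closed: bool = True
    upper_closed: bool = False
    flags: tuple[str, ...] = ()

    def contains(self, x: float) -> bool:
        above = x > self.lower or (self.lower_closed and x == self.lower)
        below = x < self.upper or (self.upper_closed and x == self.upper)
        return above and below

    def to_dict(self) -> dict:
        d = {
            "lower": self.lower,
            "upper": self.upper,
            "points": self.points,
            "label": self.label,
            "lower_closed": self.lower_closed,
            "upper_closed": self.upper_closed,
        }
        if self.flags:
            d["flags"] = list(self.flags)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Band":
        return cls(
            lower=float(d["lower"]),
            upper=float(d["upper"]),
            points=int(d["points"]),
            label=str(d["label"]),
            lower_closed=bool(d.get("lower_closed", True)),
            upper_closed=bool(d.get("upper_closed", False)),
            flags=tuple(d.get("flags", ())),
        )


INF = math.inf

_DEFAULT_BANDS: dict[Parameter, tuple[Band, ...]] = {
    Parameter.age: (
        Band(0, 65, 0, "<65 years"),
        Band(65, INF, 1, ">=65 years"),
    ),
    Parameter.smoking: (
        Band(0, 1, 0, "non-smoker"),
        Band(1, INF, 1, "smoker"),
    ),
    Parameter.iaa: (
        Band(0, 50, 0, "<50% stenosis"),
        Band(50, INF, 1, ">=50% stenosis"),
    ),
    Parameter.bmi: (
        Band(0, 18.5, 0, "underweight", lower_closed=False, flags=("underweight_unspecified",)),
        Band(18.5, 25, 0, "normal weight"),
        Band(25, 30, 1, "overweight"),
        Band(30, INF, 2, "obesity"),
    ),
    Parameter.egfr: (
        Band(0, 30, 2, "high risk"),
        Band(30, 45, 1, "moderate risk"),
        Band(45, 60, 0, "low risk"),
        Band(60, INF, 0, "no risk", flags=("above_kdoqi_bands",)),
    ),
    # Berlin ARDS severity; upper-inclusive bands, P/F = 100 falls in
    # "severe" (conservative).
    Parameter.pf_ratio: (
        Band(0, 100, 3, "severe", upper_closed=True),
        Band(100, 200, 2, "moderate", lower_closed=False, upper_closed=True),
        Band(200, 300, 1, "mild", lower_closed=False, upper_closed=True),
        Band(300, INF, 0, "no ventilation impairment", lower_closed=False),
    ),
    Parameter.peep: (
        Band(0, 5, 0, "minimal"),
        Band(5, 10, 1, "mild"),
        Band(10, 15, 2, "moderate"),
        Band(15, INF, 3, "severe"),
    ),
    # [0,0] is a point band: exactly no noradrenaline.
    Parameter.noradrenaline: (
        Band(0, 0, 0, "no noradrenaline", upper_closed=True),
        Band(0, 0.5, 1, "low risk", lower_closed=False, upper_closed=True),
        Band(0.5, 2, 2, "moderate risk", lower_closed=False),
        Band(2, INF, 3, "high risk"),
    ),
    Parameter.ai_risk: (
        Band(0, 0.5, 0, "low risk", upper_closed=True),
        Band(0.5, 0.75, 1, "moderate risk", lower_closed=False),
        Band(0.75, INF, 2, "high risk"),
    ),
}


@dataclass(frozen=True)
class ScoringTable:
    """Ordered interval bands for each of the nine parameters.

    The shipped default reproduces the published scale exactly; alternative
    tables can be loaded from YAML for local calibration, subject to the
    same structural validation (complete, non-overlapping coverage; maxima
    summing to the scale's 18-point ceiling when the default maxima are
    kept).
    """

    bands: Mapping[Parameter, tuple[Band, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_BANDS)
    )
    version: str = DEFAULT_TABLE_VERSION

    def __post_init__(self) -> None:
        missing = set(Parameter) - set(self.bands)
        if missing:
            raise ValueError(f"scoring table missing parameters: {sorted(p.value for p in missing)}")
        for param, bands in self.bands.items():
            self._check_coverage(param, bands)

    @staticmethod
    def _check_coverage(param: Parameter, bands: tuple[Band, ...]) -> None:
        if not bands:
            raise ValueError(f"{param.value}: no bands")
        ordered = sorted(bands, key=lambda b: (b.lower, b.upper))
        first, last = ordered[0], ordered[-1]
        if first.lower != 0:
            raise ValueError(f"{param.value}: bands must start at 0")
        if not math.isinf(last.upper):
            raise ValueError(f"{param.value}: last band must be unbounded above")
        for prev, nxt in zip(ordered, ordered[1:]):
            if prev.upper != nxt.lower:
                raise ValueError(
                    f"{param.value}: gap or overlap between {prev.label!r} and {nxt.label!r}"
                )
            # At a shared edge exactly one side must own the point -
            # except a zero-width point band, whose closed upper edge is
            # its whole support.
            zero_width = prev.lower == prev.upper
            if not zero_width and prev.upper_closed == nxt.lower_closed:
                raise ValueError(
                    f"{param.value}: edge {prev.upper} claimed by "
                    f"{'both' if prev.upper_closed else 'neither of'} "
                    f"{prev.label!r} and {nxt.label!r}"
                )
            if zero_width and nxt.lower_closed:
                raise ValueError(f"{param.value}: edge {prev.upper} claimed twice")

    def lookup(self, parameter: Parameter, value: float) -> Band:
        """Return the unique band containing ``value`` for ``parameter``."""
        if not math.isfinite(value) or value < 0:
            raise ValueError(f"{parameter.value}: value {value!r} outside physical range")
        for band in self.bands[parameter]:
            if band.contains(value):
                return band
        # Open lower edge at 0 (BMI, P/F) can leave exactly 0 unmatched;
        # that is a validation failure upstream, not a scoring case.
        raise ValueError(f"{parameter.value}: value {value!r} not covered by any band")

    def score(self, parameter: Parameter, value: float, extra_flags: Iterable[str] = ()) -> ParameterScore:
        band = self.lookup(parameter, value)
        return ParameterScore(
            parameter=parameter,
            points=band.points,
            category_label=band.label,
            flags=tuple(band.flags) + tuple(extra_flags),
        )

    def max_points(self, parameter: Parameter) -> int:
        return max(b.points for b in self.bands[parameter])

    @property
    def total_max(self) -> int:
        """Maximum attainable total across all nine parameters."""
        return sum(self.max_points(p) for p in Parameter)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "parameters": {
                p.value: [b.to_dict() for b in self.bands[p]] for p in Parameter
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringTable":
        bands = {
            Parameter(name): tuple(Band.from_dict(b) for b in blist)
            for name, blist in d["parameters"].items()
        }
        return cls(bands=bands, version=str(d.get("version", "custom")))

    def to_yaml(self, path: Optional[str] = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "ScoringTable":
        """Load a table from a YAML string or a path to a YAML file."""
        if "\n" not in source and source.endswith((".yaml", ".yml")):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(source)
        return cls.from_dict(data)

    def with_version(self, version: str) -> "ScoringTable":
        return replace(self, version=version)


_DEFAULT: Optional[ScoringTable] = None


def default_table() -> ScoringTable:
    """The shipped scoring table (singleton)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ScoringTable()
        assert _DEFAULT.total_max == sum(MAX_POINTS.values())
    return _DEFAULT
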