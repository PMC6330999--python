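"""Genome-adaptive Mamdani fuzzy inference for homoeolog confidence.

The system has three input variables (synteny score, evolutionary distance,
total copy number) and one output (confidence, 0-100).  Each variable has a
discretized universe of discourse and a small set of Gaussian membership
classes.  Synteny classes are fixed -- the score always lives in [0, 1] --
while the distance and copy-number classes adapt to the genome at hand
through three cohort statistics: the maximum distance, and the median and
maximum total copy number.  A "low" distance in wheat is therefore not the
same crisp value as in cotton, but plays the same linguistic role.

Inference follows the conventional Mamdani configuration: fuzzification of
crisp inputs into class degrees, rule firing with AND = min / OR = max /
NOT = complement, truncation of each rule's consequent class at the firing
strength, pointwise-max aggregation over rules, and centroid
defuzzification on the discretized confidence universe.  Because the output
classes are Gaussians truncated by the universe bounds, the raw centroid of
even a perfect pair falls short of 100; per cohort, scores are therefore
rescaled by the linear map that keeps the minimum fixed and sends the
maximum to exactly 100.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from homeoconf.features import PairFeatures, compute_features, DEFAULT_WINDOW_SIZE
from homeoconf.io import GenomeAnnotation, PairTable, ScoredPair, ValidationError
from homeoconf.rules import RuleSet, Degrees

INPUT_NAMES = ("synteny", "distance", "copynr")
CONFIDENCE = "confidence"


@dataclass(frozen=True)
class Universe:
    """A variable's admissible range [lo, hi] discretized with a fixed step.

    The grid runs lo, lo+step, ... inclusively; when hi - lo is not an
    integer multiple of step, hi is appended as the final point so the bound
    itself is always representable.
    """

    lo: float
    hi: float
    step: float

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValidationError(f"universe step must be > 0, got {self.step}")
        if not self.lo < self.hi:
            raise ValidationError(f"universe needs lo < hi, got [{self.lo}, {self.hi}]")

    @property
    def grid(self) -> np.ndarray:
        n = int(math.floor((self.hi - self.lo) / self.step + 1e-9))
        pts = self.lo + self.step * np.arange(n + 1)
        if pts[-1] < self.hi - 1e-9 * self.step:
            pts = np.append(pts, self.hi)
        return pts

    def clip(self, x: float) -> float:
        return min(max(x, self.lo), self.hi)


@dataclass(frozen=True)
class MembershipClass:
    """A Gaussian fuzzy set: degree(x) = exp(-(x - center)^2 / (2 sd^2))."""

    label: str
    center: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValidationError(
                f"membership class {self.label!r}: sd must be > 0, got {self.sd}"
            )

    def degree(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = np.exp(-((x - self.center) ** 2) / (2.0 * self.sd**2))
        return float(out) if out.ndim == 0 else out


def membership_degree(x: float, cls: MembershipClass) -> float:
    """Gaussian membership degree of a crisp value; always in (0, 1]."""
    return float(cls.degree(x))


@dataclass(frozen=True)
class FuzzyVariable:
    """A named universe plus its membership classes (3 inputs / 5 output)."""

    name: str
    universe: Universe
    classes: tuple[MembershipClass, ...]

    def __post_init__(self) -> None:
        labels = [c.label for c in self.classes]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"variable {self.name}: duplicate class labels")

    def cls(self, label: str) -> MembershipClass:
        for c in self.classes:
            if c.label == label:
                return c
        raise KeyError(f"variable {self.name}: no class {label!r}")


@dataclass(frozen=True)
class GenomeStats:
    """Cohort statistics that anchor the adaptive membership classes."""

    distance_max: float
    copynr_median: float
    copynr_max: int

    def __post_init__(self) -> None:
        if self.distance_max < 0:
            raise ValidationError("distance_max must be >= 0")
        if self.copynr_median < 2 or self.copynr_max < 2:
            raise ValidationError("copy numbers start at 2 for a one-to-one pair")
        if self.copynr_max < self.copynr_median:
            raise ValidationError("copynr_max must be >= copynr_median")


@dataclass
class FuzzyModel:
    """The full control system: three input variables, the output, the rules."""

    variables: dict[str, FuzzyVariable]
    ruleset: RuleSet
    stats: GenomeStats
    _consequent_curves: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def confidence(self) -> FuzzyVariable:
        return self.variables[CONFIDENCE]

    def consequent_curve(self, label: str) -> np.ndarray:
        """Output class sampled on the confidence grid (cached)."""
        if label not in self._consequent_curves:
            grid = self.confidence.universe.grid
            self._consequent_curves[label] = self.confidence.cls(label).degree(grid)
        return self._consequent_curves[label]

    def to_dict(self) -> dict:
        """JSON-serializable dump of universes, classes, stats and rules."""
        return {
            "stats": {
                "distance_max": self.stats.distance_max,
                "copynr_median": self.stats.copynr_median,
                "copynr_max": self.stats.copynr_max,
            },
            "variables": {
                name: {
                    "universe": {
                        "lo": var.universe.lo,
                        "hi": var.universe.hi,
                        "step": var.universe.step,
                    },
                    "classes": [
                        {"label": c.label, "center": c.center, "sd": c.sd}
                        for c in var.classes
                    ],
                }
                for name, var in self.variables.items()
            },
            "rules": [
                {"if": r.text or str(r.antecedent), "then": r.consequent}
                for r in self.ruleset
            ],
        }


def genome_stats(features: Sequence[PairFeatures]) -> GenomeStats:
    """Cohort statistics from per-pair features.

    The median of an even-length copy-number list is the mean of the two
    middle values.
    """
    if not features:
        raise ValidationError("cannot compute genome statistics from zero pairs")
    distances = [f.distance for f in features]
    copynrs = [f.total_copy_nr for f in features]
    return GenomeStats(
        distance_max=float(max(distances)),
        copynr_median=float(np.median(copynrs)),
        copynr_max=int(max(copynrs)),
    )


DISTANCE_STEP = 0.01
SYNTENY_STEP = 0.01
COPYNR_STEP = 1.0
CONFIDENCE_STEP = 1.0


def build_model(stats: GenomeStats, ruleset: RuleSet | None = None) -> FuzzyModel:
    """Construct the genome-adapted control system from cohort statistics.

    Universes: distance 0..distance_max (step 0.01), synteny 0..1 (step
    0.01), copy number 2..copynr_max (step 1), confidence 0..100 (step 1).
    Class centers/sds follow the adaptive scheme described in the module
    docstring.  Degenerate cohorts (all distances zero, or no pair above
    copy number 2) get a minimal non-degenerate fallback with a warning.
    """
    if ruleset is None:
        ruleset = RuleSet.default()

    dmax = stats.distance_max
    if dmax <= 0:
        warnings.warn(
            "distance_max is 0; substituting one grid step (0.01) to keep the "
            "distance universe non-degenerate",
            stacklevel=2,
        )
        dmax = DISTANCE_STEP
    distance = FuzzyVariable(
        name="distance",
        universe=Universe(0.0, dmax, DISTANCE_STEP),
        classes=(
            MembershipClass("low", 0.0, dmax / 10.0),
            MembershipClass("med", dmax / 4.0, dmax / 10.0),
            MembershipClass("high", dmax, dmax / 2.5),
        ),
    )

    synteny = FuzzyVariable(
        name="synteny",
        universe=Universe(0.0, 1.0, SYNTENY_STEP),
        classes=(
            MembershipClass("low", 0.0, 0.15),
            MembershipClass("med", 0.3, 0.15),
            MembershipClass("high", 1.0, 0.4),
        ),
    )

    median = stats.copynr_median
    cmax = stats.copynr_max
    if cmax <= 2:
        warnings.warn(
            "all pairs are one-to-one (copynr_max = 2); extending the copy "
            "universe to [2, 3] with a fixed high class",
            stacklevel=2,
        )
        copy_hi = 3.0
        high_cls = MembershipClass("high", 3.0, 1.2)
    else:
        copy_hi = float(cmax)
        high_cls = MembershipClass("high", float(cmax), cmax / 2.5)
    copynr = FuzzyVariable(
        name="copynr",
        universe=Universe(2.0, copy_hi, COPYNR_STEP),
        classes=(
            MembershipClass("low", median, median),
            MembershipClass("med", 4.0 * median, 1.5 * median),
            high_cls,
        ),
    )

    confidence = FuzzyVariable(
        name=CONFIDENCE,
        universe=Universe(0.0, 100.0, CONFIDENCE_STEP),
        classes=(
            MembershipClass("very low", 0.0, 20.0),
            MembershipClass("low", 50.0, 10.0),
            MembershipClass("med", 70.0, 10.0),
            MembershipClass("high", 90.0, 10.0),
            MembershipClass("very high", 100.0, 10.0),
        ),
    )

    return FuzzyModel(
        variables={
            "synteny": synteny,
            "distance": distance,
            "copynr": copynr,
            CONFIDENCE: confidence,
        },
        ruleset=ruleset,
        stats=stats,
    )


def fuzzify(features: PairFeatures, model: FuzzyModel) -> dict[tuple[str, str], float]:
    """Map crisp features to membership degrees per (variable, class).

    Inputs are clipped to their universe bounds first, so a model frozen on
    one cohort can still score pairs whose feature values fall outside the
    range seen when the model was built.
    """
    crisp = {
        "synteny": features.synteny_score,
        "distance": features.distance,
        "copynr": float(features.total_copy_nr),
    }
    degrees: dict[tuple[str, str], float] = {}
    for name in INPUT_NAMES:
        value = crisp[name]
        if not math.isfinite(value):
            raise ValidationError(f"non-finite value {value!r} for input {name}")
        var = model.variables[name]
        x = var.universe.clip(value)
        for cls in var.classes:
            degrees[(name, cls.label)] = membership_degree(x, cls)
    return degrees


def evaluate_rules(degrees: Degrees, model: FuzzyModel) -> np.ndarray:
    """Aggregate rule outputs into one membership curve on the confidence grid.

    Each rule's firing strength truncates (pointwise min) its consequent
    class curve; the aggregate is the pointwise max over rules.
    """
    grid = model.confidence.universe.grid
    aggregate = np.zeros_like(grid)
    for rule in model.ruleset:
        strength = rule.firing_strength(degrees)
        curve = np.minimum(model.consequent_curve(rule.consequent), strength)
        np.maximum(aggregate, curve, out=aggregate)
    return aggregate


def centroid_defuzzify(curve: np.ndarray, universe: Universe) -> float:
    """Discrete centroid sum(grid * curve) / sum(curve) of an aggregated curve."""
    grid = universe.grid
    curve = np.asarray(curve, dtype=float)
    if curve.shape != grid.shape:
        raise ValidationError(
            f"curve length {curve.shape} does not match universe grid {grid.shape}"
        )
    total = curve.sum()
    if total <= 0:
        raise ValidationError("cannot defuzzify an all-zero membership curve")
    return float((grid * curve).sum() / total)


def infer_confidence(features: PairFeatures, model: FuzzyModel) -> float:
    """One pair through the whole inference chain: a raw crisp confidence."""
    degrees = fuzzify(features, model)
    aggregate = evaluate_rules(degrees, model)
    return centroid_defuzzify(aggregate, model.confidence.universe)


def scale_scores(raw: Sequence[float]) -> list[float]:
    """Per-cohort rescaling: keep the minimum, send the maximum to 100.

    The raw centroid of even a perfect pair stays well below 100 because the
    top output class is truncated at the universe bound, so cohorts are
    linearly stretched: scaled = min + (x - min) * (100 - min) / (max - min).
    A constant cohort (max = min) maps to 100 everywhere.
    """
    if len(raw) == 0:
        raise ValidationError("cannot scale an empty score list")
    lo, hi = min(raw), max(raw)
    if not (0 <= lo and hi <= 100):
        raise ValidationError("raw scores must lie in [0, 100]")
    if hi == lo:
        return [100.0 for _ in raw]
    factor = (100.0 - lo) / (hi - lo)
    # the cohort maximum maps to 100 exactly, immune to rounding
    return [100.0 if x == hi else lo + (x - lo) * factor for x in raw]


def score_pairs(
    table: PairTable,
    annotation: GenomeAnnotation,
    window_size: int = DEFAULT_WINDOW_SIZE,
    ruleset: RuleSet | None = None,
    scale: bool = True,
    model: FuzzyModel | None = None,
) -> list[ScoredPair]:
    """Score every pair in the table; the main entry point of the package.

    Pipeline: compute per-pair features, derive cohort statistics, build the
    genome-adapted fuzzy model, run each pair through
    fuzzify -> rule evaluation -> centroid defuzzification, then rescale the
    cohort so its maximum is exactly 100 (unless ``scale`` is off, in which
    case the scaled column repeats the raw scores).  Deterministic; row
    order preserved.  Pass a prebuilt ``model`` to score under frozen
    membership functions instead of readapting to this cohort.
    """
    features = compute_features(table, annotation, window_size)
    if model is None:
        model = build_model(genome_stats(features), ruleset)
    raw = [infer_confidence(f, model) for f in features]
    scaled = scale_scores(raw) if scale else list(raw)
    return [
        ScoredPair(
            pair=p,
            synteny_score=f.synteny_score,
            total_copy_nr=f.total_copy_nr,
            raw_confidence=r,
            scaled_confidence=s,
        )
        for p, f, r, s in zip(table.pairs, features, raw, scaled)
    ]
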