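"""Stage reference model and maturational-stage classifier.

The reference model holds, for each maturational phase (pre-pubertal,
pubertal, post-pubertal), the published per-outcome summary statistics:
mean and SD for the eight normally distributed outcomes (SWIA, BW, BH,
BS at C3/C4) and median plus range for the three concavity depths,
together with the group sizes (59 / 220 / 115 subjects).

No classification rule accompanies the published reference values, so
two transparent rules are provided, both derivable from the summary
statistics alone:

``gaussian`` (default)
    Equal-prior naive-Bayes score: the per-stage score is the sum of
    normal log-densities for the eight mean/SD outcomes plus triangular
    log-densities on (min, mode=median, max) for the three CDs.  The
    triangular density is floored at a small ``eps`` so boundary or
    out-of-range values stay finite, and degenerate published ranges
    (e.g. pre-pubertal CD3 "0 (0–0)") are widened to a ±0.25 mm
    half-width — half the 0.5 mm reporting resolution of the source
    measurements.
``centroid``
    Robust scaled L1 distance: −Σ |value − location| / scale with
    location = mean (median for CD) and scale = SD (half-range + 0.25 mm
    for CD).

The highest score wins; ties (score gap below ``tie_tol``) resolve to
the developmentally earlier stage with ``ambiguous=True``.  Priors are
equal despite the unbalanced group sizes: the study's stage mix reflects
its sampling, not the prior for a new patient.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

from .landmarks import STAGES
from .measures import CD_OUTCOMES, NORMAL_OUTCOMES, OUTCOMES, MeasurementProfile

__all__ = [
    "ReferenceError",
    "NormalSummary",
    "RangeSummary",
    "StageParams",
    "StageReference",
    "StageCall",
    "load_reference",
    "save_reference",
    "location_profile",
    "classify",
    "PUBLISHED_ETA_SQUARED",
    "PUBLISHED_LETTERS",
]

#: Density floor for the triangular CD score (keeps boundary values finite).
TRIANGULAR_FLOOR = 1e-6

#: Half-width (mm) used to widen degenerate (zero-range) CD summaries and to
#: floor the centroid CD scale; half the 0.5 mm reporting step of the source.
CD_RESOLUTION_HALFWIDTH = 0.25

DEFAULT_TIE_TOL = 1e-9


class ReferenceError(ValueError):
    """Invalid or incomplete stage reference configuration."""


@dataclass(frozen=True)
class NormalSummary:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.sd > 0 and math.isfinite(self.sd) and math.isfinite(self.mean)):
            raise ReferenceError(f"invalid mean/sd summary ({self.mean}, {self.sd}): sd must be > 0")


@dataclass(frozen=True)
class RangeSummary:
    median: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.median <= self.max):
            raise ReferenceError(
                f"invalid median/range summary: need min <= median <= max, "
                f"got ({self.min}, {self.median}, {self.max})"
            )


@dataclass(frozen=True)
class StageParams:
    """Reference summaries for one maturational stage."""

    n: int
    normal: Mapping[str, NormalSummary]
    cd: Mapping[str, RangeSummary]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ReferenceError(f"stage group size must be positive, got {self.n}")
        missing = [k for k in NORMAL_OUTCOMES if k not in self.normal]
        missing += [k for k in CD_OUTCOMES if k not in self.cd]
        if missing:
            raise ReferenceError(f"stage reference missing outcomes: {missing}")
        extra = [k for k in self.normal if k not in NORMAL_OUTCOMES]
        extra += [k for k in self.cd if k not in CD_OUTCOMES]
        if extra:
            raise ReferenceError(f"stage reference has unknown outcomes: {extra}")


@dataclass(frozen=True)
class StageReference:
    """Per-stage, per-outcome reference summaries for all three stages."""

    stages: Mapping[str, StageParams]

    def __post_init__(self) -> None:
        missing = [s for s in STAGES if s not in self.stages]
        if missing:
            raise ReferenceError(f"reference missing stages: {missing}")
        extra = [s for s in self.stages if s not in STAGES]
        if extra:
            raise ReferenceError(f"reference has unknown stages: {extra}")

    def __getitem__(self, stage: str) -> StageParams:
        try:
            return self.stages[stage]
        except KeyError:
            raise ReferenceError(f"unknown stage {stage!r} (expected one of {STAGES})") from None

    def to_dict(self) -> dict:
        return {
            "stages": {
                s: {
                    "n": p.n,
                    "normal": {k: {"mean": v.mean, "sd": v.sd} for k, v in p.normal.items()},
                    "cd": {k: {"median": v.median, "min": v.min, "max": v.max}
                           for k, v in p.cd.items()},
                }
                for s, p in ((s, self[s]) for s in STAGES)
            }
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "StageReference":
        try:
            raw_stages = payload["stages"]
        except (KeyError, TypeError):
            raise ReferenceError("reference config must have a top-level 'stages' table") from None
        stages = {}
        problems = []
        for s, block in raw_stages.items():
            try:
                stages[s] = StageParams(
                    n=int(block["n"]),
                    normal={k: NormalSummary(float(v["mean"]), float(v["sd"]))
                            for k, v in block.get("normal", {}).items()},
                    cd={k: RangeSummary(float(v["median"]), float(v["min"]), float(v["max"]))
                        for k, v in block.get("cd", {}).items()},
                )
            except (ReferenceError, KeyError, TypeError, ValueError) as err:
                problems.append(f"stage {s!r}: {err}")
        if problems:
            raise ReferenceError("; ".join(problems))
        return cls(stages=stages)


# ---------------------------------------------------------------------------
# published defaults: stage-specific reference values
# (mean, sd) for the normal outcomes; (median, min, max) for the CDs

_DEFAULT_N = {"pre-pubertal": 59, "pubertal": 220, "post-pubertal": 115}

_DEFAULT_NORMAL = {
    "swia_c3": {"pre-pubertal": (73.63, 3.72), "pubertal": (79.19, 4.23), "post-pubertal": (82.58, 3.84)},
    "swia_c4": {"pre-pubertal": (74.29, 3.98), "pubertal": (78.80, 3.77), "post-pubertal": (82.14, 4.18)},
    "bw_c3":   {"pre-pubertal": (12.39, 1.16), "pubertal": (13.49, 1.34), "post-pubertal": (12.65, 1.10)},
    "bw_c4":   {"pre-pubertal": (12.42, 1.13), "pubertal": (13.53, 1.35), "post-pubertal": (12.90, 1.13)},
    "bh_c3":   {"pre-pubertal": (7.47, 1.14),  "pubertal": (10.19, 1.54), "post-pubertal": (12.86, 1.00)},
    "bh_c4":   {"pre-pubertal": (7.47, 1.11),  "pubertal": (9.95, 1.48),  "post-pubertal": (12.42, 1.16)},
    "bs_c3":   {"pre-pubertal": (1.69, 0.25),  "pubertal": (1.35, 0.22),  "post-pubertal": (0.99, 0.09)},
    "bs_c4":   {"pre-pubertal": (1.69, 0.27),  "pubertal": (1.38, 0.21),  "post-pubertal": (1.04, 0.10)},
}

_DEFAULT_CD = {
    "cd_c2": {"pre-pubertal": (1.0, 0.0, 1.0), "pubertal": (1.5, 0.5, 2.5), "post-pubertal": (2.0, 1.0, 3.0)},
    "cd_c3": {"pre-pubertal": (0.0, 0.0, 0.0), "pubertal": (1.5, 0.0, 3.0), "post-pubertal": (2.0, 1.0, 3.5)},
    "cd_c4": {"pre-pubertal": (0.0, 0.0, 0.0), "pubertal": (1.0, 0.0, 2.5), "post-pubertal": (2.0, 1.0, 3.0)},
}

#: Published one-way effect sizes (eta squared) for the three-stage comparison.
PUBLISHED_ETA_SQUARED = {
    "swia_c3": 0.329, "swia_c4": 0.289,
    "cd_c2": 0.402, "cd_c3": 0.505, "cd_c4": 0.464,
    "bw_c3": 0.123, "bw_c4": 0.103,
    "bh_c3": 0.627, "bh_c4": 0.590,
    "bs_c3": 0.584, "bs_c4": 0.538,
}

#: Published compact-letter groupings per outcome (pre, pubertal, post);
#: A marks the highest location, groups sharing a letter do not differ.
PUBLISHED_LETTERS = {
    "swia_c3": ("C", "B", "A"), "swia_c4": ("C", "B", "A"),
    "cd_c2": ("B", "AB", "A"), "cd_c3": ("B", "A", "A"), "cd_c4": ("C", "B", "A"),
    "bw_c3": ("B", "A", "B"), "bw_c4": ("C", "A", "B"),
    "bh_c3": ("C", "B", "A"), "bh_c4": ("C", "B", "A"),
    "bs_c3": ("A", "B", "C"), "bs_c4": ("A", "B", "C"),
}


def _default_reference() -> StageReference:
    stages = {}
    for s in STAGES:
        stages[s] = StageParams(
            n=_DEFAULT_N[s],
            normal={k: NormalSummary(*_DEFAULT_NORMAL[k][s]) for k in NORMAL_OUTCOMES},
            cd={k: RangeSummary(*_DEFAULT_CD[k][s]) for k in CD_OUTCOMES},
        )
    return StageReference(stages=stages)


def load_reference(config=None) -> StageReference:
    """Return the built-in published reference, or load a complete override.

    ``config`` may be None (defaults), a path to a ``.json`` or ``.toml``
    file, a file-like object (JSON), or an already-parsed mapping.
    """
    if config is None:
        return _default_reference()
    if isinstance(config, Mapping):
        return StageReference.from_dict(config)
    if hasattr(config, "read"):
        return StageReference.from_dict(json.load(config))
    path = str(config)
    if path.endswith(".toml"):
        import tomllib

        with open(path, "rb") as fh:
            return StageReference.from_dict(tomllib.load(fh))
    with open(path, "r", encoding="utf-8") as fh:
        return StageReference.from_dict(json.load(fh))


def save_reference(ref: StageReference, path) -> None:
    """Write a reference as JSON (round-trips through :func:`load_reference`)."""
    payload = json.dumps(ref.to_dict(), indent=1) + "\n"
    if hasattr(path, "write"):
        path.write(payload)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(payload)


def location_profile(ref: StageReference, stage: str) -> MeasurementProfile:
    """The profile sitting exactly at a stage's reference locations.

    Uses the published means for the normal outcomes (including BS) and
    medians for the CDs.
    """
    params = ref[stage]
    values = {k: params.normal[k].mean for k in NORMAL_OUTCOMES}
    values.update({k: params.cd[k].median for k in CD_OUTCOMES})
    return MeasurementProfile.from_outcomes(values)


# ---------------------------------------------------------------------------
# classifier


@dataclass(frozen=True)
class StageCall:
    """A stage assignment with per-stage scores and diagnostics.

    ``z`` holds, per stage, the per-outcome standardised deviations of
    the profile from that stage's reference locations ((x − mean)/sd, or
    (x − median)/(half-range + 0.25 mm) for CD).
    """

    stage: str
    scores: Mapping[str, float]
    z: Mapping[str, Mapping[str, float]]
    ambiguous: bool
    method: str


def _triangular_logpdf(x: float, lo: float, mode: float, hi: float) -> float:
    """Log of a floored triangular density on (lo, mode, hi).

    Degenerate supports (hi == lo) are widened symmetrically about the
    mode by :data:`CD_RESOLUTION_HALFWIDTH`.
    """
    if hi - lo < 1e-12:
        lo = mode - CD_RESOLUTION_HALFWIDTH
        hi = mode + CD_RESOLUTION_HALFWIDTH
    w = hi - lo
    if x < lo or x > hi:
        f = 0.0
    elif x < mode:
        f = 2.0 * (x - lo) / (w * (mode - lo))
    elif x > mode:
        f = 2.0 * (hi - x) / (w * (hi - mode))
    else:
        f = 2.0 / w
    return math.log(max(f, TRIANGULAR_FLOOR))


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _normal_logpdf(x: float, mean: float, sd: float) -> float:
    z = (x - mean) / sd
    return -0.5 * z * z - math.log(sd) - _LOG_SQRT_2PI


def classify(
    p: MeasurementProfile,
    ref: StageReference | None = None,
    method: str = "gaussian",
    tie_tol: float = DEFAULT_TIE_TOL,
) -> StageCall:
    """Assign a maturational stage to a measurement profile.

    See the module docstring for the two scoring rules.  Returns a
    :class:`StageCall`; ``ambiguous`` is set when the top two stage
    scores differ by less than ``tie_tol`` (the earlier stage wins the
    tie deterministically).
    """
    if ref is None:
        ref = _default_reference()
    if method not in ("gaussian", "centroid"):
        raise ValueError(f"unknown classification method {method!r}")

    scores: dict[str, float] = {}
    z: dict[str, dict[str, float]] = {}
    for stage in STAGES:
        params = ref[stage]
        total = 0.0
        zs: dict[str, float] = {}
        for k in NORMAL_OUTCOMES:
            x = getattr(p, k)
            summ = params.normal[k]
            zs[k] = (x - summ.mean) / summ.sd
            if method == "gaussian":
                total += _normal_logpdf(x, summ.mean, summ.sd)
            else:
                total -= abs(zs[k])
        for k in CD_OUTCOMES:
            x = getattr(p, k)
            summ = params.cd[k]
            scale = (summ.max - summ.min) / 2.0 + CD_RESOLUTION_HALFWIDTH
            zs[k] = (x - summ.median) / scale
            if method == "gaussian":
                total += _triangular_logpdf(x, summ.min, summ.median, summ.max)
            else:
                total -= abs(x - summ.median) / scale
        scores[stage] = total
        z[stage] = zs

    best = max(STAGES, key=lambda s: (scores[s], -STAGES.index(s)))
    # deterministic tie-break toward the earlier stage
    for stage in STAGES:
        if scores[stage] >= scores[best] - tie_tol:
            best = stage
            break
    runner_up = max(scores[s] for s in STAGES if s != best)
    ambiguous = abs(scores[best] - runner_up) < tie_tol
    return StageCall(stage=best, scores=scores, z=z, ambiguous=ambiguous, method=method)
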