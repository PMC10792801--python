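"""Stage-conditioned synthetic cohorts: profiles and landmark geometry.

The published stage characterisation lives at the *measurement* level
(per-stage summary statistics), not at the landmark level, so the
generator samples measurement profiles first and then constructs a
landmark configuration whose computed measurements equal the sampled
profile exactly — the inverse of the measurement geometry.  The
inverse-construction round trip (``profile(profile_to_landmarks(p)) == p``
to 1e-9 with zero jitter) is the module's core contract.

Sampling model per stage:

* the six drawn normal outcomes (SWIA, BW, BH at C3/C4) are
  ``Normal(mean, sd)``, independent by default (no covariances are
  published); an optional correlation matrix over these six can be
  supplied for sensitivity studies;
* BS is *derived* as BW/BH after drawing, preserving the profile
  identity rather than being drawn from its own published summary;
* the three concavity depths are ``Triangular(min, mode=median, max)``;
  a degenerate published range (pre-pubertal CD3/CD4 ``0 (0–0)``) is a
  point mass at 0.

Landmark construction per vertebra (before jitter/rigid motion): the
lower border CL is horizontal with ``lp`` at the local origin and ``la``
a template length anterior; ``d`` sits at the CL midpoint, displaced
superiorly by CD; the posterior border rises vertically to ``up`` at
height ``BH + BW/tan(SWIA)`` so that the superior border, leaving ``up``
at the SWIA angle, carries its midpoint ``um`` at perpendicular distance
BW from the posterior line and BH from the lower line; ``ua`` mirror-
extends the superior border (``um`` is its midpoint) and ``am`` is the
anterior-border midpoint.  Template free parameters (CL length,
inter-vertebral gap, CL tilt) do not affect any measured outcome.

Optional annotation jitter (``Normal(0, jitter_sd²)`` per coordinate,
emulating hand-tracing error) and a random rigid motion (rotation within
±20°, the plausible head-tilt range that keeps the global +y axis
anatomically superior, plus translation) are applied last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import Point2D
from .landmarks import STAGES, SubjectAnnotation, VertebraLandmarks
from .measures import (
    CD_OUTCOMES,
    NORMAL_OUTCOMES,
    OUTCOMES,
    MeasurementProfile,
    profile as measure_profile,
)
from .staging import StageReference, load_reference

__all__ = [
    "DRAWN_NORMAL_OUTCOMES",
    "InfeasibleProfileError",
    "TemplateParams",
    "SyntheticConfig",
    "CohortTable",
    "sample_profile",
    "profile_to_landmarks",
    "generate_cohort",
]

#: The normal outcomes drawn directly (BS is derived as BW/BH).
DRAWN_NORMAL_OUTCOMES: tuple[str, ...] = (
    "swia_c3", "swia_c4", "bw_c3", "bw_c4", "bh_c3", "bh_c4",
)

_RETRY_CAP = 100


class InfeasibleProfileError(ValueError):
    """A profile admits no valid landmark construction (or repeated resampling failed)."""


@dataclass(frozen=True)
class TemplateParams:
    """Free layout parameters the profile does not pin down.

    Anatomically plausible defaults; none of them affects a measured
    outcome (guaranteed by the round-trip property).
    """

    cl_length: float = 14.0        #: traced lower-border length, mm
    gap: float = 4.0               #: inter-vertebral gap, mm
    cl_tilt_deg: float = 0.0       #: fixed tilt of the lower borders, degrees
    rigid_rotation_deg: float = 20.0   #: half-range of the random rotation
    rigid_translation_mm: float = 30.0  #: half-range of the random translation


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort generation settings; defaults emulate the reference study sample."""

    stage_counts: Mapping[str, int] = field(
        default_factory=lambda: {"pre-pubertal": 59, "pubertal": 220, "post-pubertal": 115}
    )
    seed: int = 0
    jitter_sd: float = 0.0
    reference: StageReference | None = None
    template: TemplateParams = field(default_factory=TemplateParams)
    correlation: np.ndarray | None = None
    rigid_motion: bool = True
    landmarks: bool = True  #: set False for fast measurement-level cohorts

    def __post_init__(self) -> None:
        for s, c in self.stage_counts.items():
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r} in stage_counts")
            if c < 0:
                raise ValueError(f"stage count must be >= 0, got {c} for {s}")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class CohortTable:
    """Long-format outcome records plus per-subject profile access."""

    table: pd.DataFrame  #: columns subject_id, stage, outcome, vertebra, value
    profiles: Mapping[str, MeasurementProfile]
    stages: Mapping[str, str]  #: subject_id -> true stage

    def wide(self) -> pd.DataFrame:
        """One row per subject: true stage and the 11 outcome columns."""
        df = self.table.assign(
            key=lambda d: d["outcome"] + "_" + d["vertebra"].str.lower()
        ).pivot(index="subject_id", columns="key", values="value")
        df.insert(0, "stage", pd.Series(dict(self.stages)))
        return df[["stage", *OUTCOMES]]

    def groups_by_outcome(self) -> dict[str, dict[str, np.ndarray]]:
        """{outcome_key: {stage: values array}} for the statistics pipeline."""
        wide = self.wide()
        return {
            key: {s: wide.loc[wide["stage"] == s, key].to_numpy() for s in STAGES}
            for key in OUTCOMES
        }


def _draw_triangular(rng: np.random.Generator, lo: float, mode: float, hi: float) -> float:
    if hi - lo < 1e-12:
        return float(mode)  # point mass, e.g. the flat pre-pubertal inferior border
    return float(rng.triangular(lo, mode, hi))


def sample_profile(
    stage: str,
    ref: StageReference | None = None,
    rng: np.random.Generator | None = None,
    correlation: np.ndarray | None = None,
) -> MeasurementProfile:
    """Draw one measurement profile from a stage's reference distributions."""
    if ref is None:
        ref = load_reference()
    if rng is None:
        rng = np.random.default_rng()
    params = ref[stage]

    if correlation is not None:
        corr = np.asarray(correlation, dtype=float)
        k = len(DRAWN_NORMAL_OUTCOMES)
        if corr.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k}x{k} over {DRAWN_NORMAL_OUTCOMES}")
        chol = np.linalg.cholesky(corr)
    else:
        chol = None

    for _ in range(_RETRY_CAP):
        z = rng.standard_normal(len(DRAWN_NORMAL_OUTCOMES))
        if chol is not None:
            z = chol @ z
        values: dict[str, float] = {}
        for name, zi in zip(DRAWN_NORMAL_OUTCOMES, z):
            summ = params.normal[name]
            values[name] = summ.mean + summ.sd * float(zi)
        ok = (
            0.0 < values["swia_c3"] < 180.0
            and 0.0 < values["swia_c4"] < 180.0
            and all(values[k] > 0 for k in ("bw_c3", "bw_c4", "bh_c3", "bh_c4"))
        )
        if not ok:
            continue
        values["bs_c3"] = values["bw_c3"] / values["bh_c3"]
        values["bs_c4"] = values["bw_c4"] / values["bh_c4"]
        for k in CD_OUTCOMES:
            summ = params.cd[k]
            values[k] = _draw_triangular(rng, summ.min, summ.median, summ.max)
        return MeasurementProfile.from_outcomes(values)
    raise InfeasibleProfileError(
        f"could not draw a feasible profile for stage {stage!r} in {_RETRY_CAP} tries"
    )


# ---------------------------------------------------------------------------
# inverse geometry


def _construct_vertebra(
    vertebra: str,
    cl_length: float,
    cd: float,
    swia: float | None = None,
    bw: float | None = None,
    bh: float | None = None,
) -> dict[str, tuple[float, float]]:
    """Local-frame landmark coordinates: lp at origin, CL along +x toward la."""
    if cd < 0:
        raise InfeasibleProfileError(f"{vertebra}: concavity depth must be >= 0, got {cd}")
    pts = {"lp": (0.0, 0.0), "la": (cl_length, 0.0), "d": (cl_length / 2.0, cd)}
    if vertebra == "C2":
        return pts
    if not (0.0 < swia < 180.0):
        raise InfeasibleProfileError(f"{vertebra}: SWIA {swia} outside (0, 180)")
    if bw is None or bh is None or bw <= 0 or bh <= 0:
        raise InfeasibleProfileError(f"{vertebra}: BW and BH must be positive")
    rad = math.radians(swia)
    s = bw / math.sin(rad)              # um sits this far along the superior border
    height = bh + s * math.cos(rad)     # posterior-corner height making BH hold at um
    if height <= 1e-6:
        raise InfeasibleProfileError(
            f"{vertebra}: infeasible profile (SWIA {swia:.2f}, BW {bw:.2f}, BH {bh:.2f} "
            "put the posterosuperior corner at or below the lower border)"
        )
    ux, uy = math.sin(rad), -math.cos(rad)  # unit direction of CS from up toward ua
    pts["up"] = (0.0, height)
    pts["um"] = (s * ux, height + s * uy)
    pts["ua"] = (2.0 * s * ux, height + 2.0 * s * uy)
    pts["am"] = ((pts["ua"][0] + pts["la"][0]) / 2.0, (pts["ua"][1] + pts["la"][1]) / 2.0)
    return pts


def profile_to_landmarks(
    p: MeasurementProfile,
    rng: np.random.Generator | None = None,
    template: TemplateParams | None = None,
    *,
    subject_id: str = "synthetic",
    true_stage: str | None = None,
    jitter_sd: float = 0.0,
    rigid_motion: bool = False,
) -> SubjectAnnotation:
    """Construct landmarks whose measurements equal ``p`` (before jitter).

    With ``jitter_sd == 0`` and ``rigid_motion=False`` the construction is
    deterministic and exact; ``rng`` is only needed when jitter or a
    random rigid motion is requested.
    """
    if template is None:
        template = TemplateParams()
    if (jitter_sd > 0 or rigid_motion) and rng is None:
        raise ValueError("rng is required for jitter or random rigid motion")

    local = {
        "C2": _construct_vertebra("C2", template.cl_length, p.cd_c2),
        "C3": _construct_vertebra("C3", template.cl_length, p.cd_c3,
                                  p.swia_c3, p.bw_c3, p.bh_c3),
        "C4": _construct_vertebra("C4", template.cl_length, p.cd_c4,
                                  p.swia_c4, p.bw_c4, p.bh_c4),
    }

    tilt = math.radians(template.cl_tilt_deg)
    ct, st = math.cos(tilt), math.sin(tilt)

    # stack anatomically: C4 at the bottom, C2 on top
    coords: dict[str, dict[str, tuple[float, float]]] = {}
    y_offset = 0.0
    for vertebra in ("C4", "C3", "C2"):
        pts = local[vertebra]
        coords[vertebra] = {
            name: (x * ct - y * st, x * st + y * ct + y_offset)
            for name, (x, y) in pts.items()
        }
        span = max(y for (_, y) in pts.values()) - min(y for (_, y) in pts.values())
        y_offset += span + template.gap

    if jitter_sd > 0:
        for pts in coords.values():
            for name in pts:
                dx, dy = rng.normal(0.0, jitter_sd, size=2)
                x, y = pts[name]
                pts[name] = (x + dx, y + dy)

    if rigid_motion:
        theta = math.radians(
            rng.uniform(-template.rigid_rotation_deg, template.rigid_rotation_deg)
        )
        tx, ty = rng.uniform(-template.rigid_translation_mm,
                             template.rigid_translation_mm, size=2)
        c, s_ = math.cos(theta), math.sin(theta)
        for pts in coords.values():
            for name in pts:
                x, y = pts[name]
                pts[name] = (x * c - y * s_ + tx, x * s_ + y * c + ty)

    def make(vertebra: str) -> VertebraLandmarks:
        return VertebraLandmarks(
            vertebra, {n: Point2D(x, y) for n, (x, y) in coords[vertebra].items()}
        )

    return SubjectAnnotation(
        subject_id=subject_id,
        c2=make("C2"),
        c3=make("C3"),
        c4=make("C4"),
        true_stage=true_stage,
    )


# ---------------------------------------------------------------------------
# cohorts


def generate_cohort(cfg: SyntheticConfig) -> tuple[CohortTable, list[SubjectAnnotation]]:
    """Generate a stage-conditioned cohort, deterministic given ``cfg.seed``.

    Returns the long-format outcome table (measured from the generated
    landmarks, so annotation jitter propagates into the outcomes) and
    the full landmark annotations.  With ``cfg.landmarks=False`` the
    sampled profiles are tabulated directly and no annotations are
    built (empty list returned).
    """
    rng = np.random.default_rng(cfg.seed)
    ref = cfg.reference if cfg.reference is not None else load_reference()
    profiles: dict[str, MeasurementProfile] = {}
    stages: dict[str, str] = {}
    annotations: list[SubjectAnnotation] = []
    short = {"pre-pubertal": "pre", "pubertal": "pub", "post-pubertal": "post"}

    for stage in STAGES:
        count = cfg.stage_counts.get(stage, 0)
        width = max(3, len(str(max(count, 1))))
        for i in range(count):
            sid = f"{short[stage]}-{i + 1:0{width}d}"
            for attempt in range(_RETRY_CAP):
                drawn = sample_profile(stage, ref, rng, cfg.correlation)
                if not cfg.landmarks:
                    profiles[sid] = drawn
                    break
                try:
                    subject = profile_to_landmarks(
                        drawn, rng, cfg.template,
                        subject_id=sid, true_stage=stage,
                        jitter_sd=cfg.jitter_sd, rigid_motion=cfg.rigid_motion,
                    )
                    profiles[sid] = measure_profile(subject)
                except (InfeasibleProfileError, ValueError):
                    continue
                annotations.append(subject)
                break
            else:
                raise InfeasibleProfileError(
                    f"stage {stage!r}: no feasible subject after {_RETRY_CAP} resamples"
                )
            stages[sid] = stage

    records = []
    for sid, p in profiles.items():
        for key in OUTCOMES:
            outcome, vert = key.rsplit("_", 1)
            records.append(
                {"subject_id": sid, "stage": stages[sid], "outcome": outcome,
                 "vertebra": vert.upper(), "value": getattr(p, key)}
            )
    table = pd.DataFrame.from_records(
        records, columns=["subject_id", "stage", "outcome", "vertebra", "value"]
    )
    return CohortTable(table=table, profiles=profiles, stages=stages), annotations
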