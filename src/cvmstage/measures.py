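"""The three staging outcomes computed from vertebral landmarks.

For each subject the engine produces an 11-value measurement profile:

* **SWIA** (Superior Wall Inclination Angle), C3 and C4: the angle
  between the superior border (``ua``–``up``) and the posterior border
  (``up``–``lp``), measured at their shared posterosuperior corner
  ``up``.  Rises with maturation as the superior border loses its
  pre-pubertal anterior taper.
* **CD** (Concavity Depth), C2, C3 and C4: perpendicular distance from
  the deepest point ``d`` of the inferior border to the lower-border
  line ``la``–``lp``, positive toward anatomical superior.  A convex
  (downward-bulging) border yields a negative raw value, which is
  clamped to 0 and flagged: concavity depth is undefined for convex
  borders and the published per-stage ranges all start at 0.
* **BW / BH / BS** (Body Width, Height, Shape), C3 and C4: BW is the
  perpendicular distance from the superior-border midpoint ``um`` to
  the posterior-border line, BH its distance to the lower-border line,
  and BS the dimensionless ratio BW / BH — falling from >1 (wide
  trapezoid) toward ~1 (square) with maturation.

SWIA and BS are invariant under similarity transforms; CD, BW and BH are
invariant under rigid motions and scale linearly with uniform scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .geometry import GeometryError, LineSeg, Point2D, angle_at_vertex, perp_distance
from .landmarks import SubjectAnnotation, VertebraLandmarks

__all__ = [
    "OUTCOMES",
    "NORMAL_OUTCOMES",
    "CD_OUTCOMES",
    "MeasurementError",
    "MeasurementProfile",
    "compute_swia",
    "compute_cd",
    "compute_body_dims",
    "compute_bs",
    "profile",
    "profiles_to_wide",
    "profiles_to_long",
]

#: The 11 outcomes, in canonical reporting order.
OUTCOMES: tuple[str, ...] = (
    "swia_c3", "swia_c4",
    "cd_c2", "cd_c3", "cd_c4",
    "bw_c3", "bw_c4",
    "bh_c3", "bh_c4",
    "bs_c3", "bs_c4",
)

#: Outcomes summarised by mean/SD in the reference model.
NORMAL_OUTCOMES: tuple[str, ...] = (
    "swia_c3", "swia_c4", "bw_c3", "bw_c4", "bh_c3", "bh_c4", "bs_c3", "bs_c4",
)

#: Outcomes summarised by median/range (non-normal) in the reference model.
CD_OUTCOMES: tuple[str, ...] = ("cd_c2", "cd_c3", "cd_c4")


class MeasurementError(ValueError):
    """A measurement could not be computed from the given landmarks."""


@dataclass(frozen=True)
class MeasurementProfile:
    """The 11 staging outcomes for one subject, plus raw CD diagnostics.

    ``cd_raw_*`` carry the signed pre-clamp concavity depths; a negative
    raw value marks a convex inferior border (``cd`` is then 0).
    Profiles produced by :func:`profile` or by the synthetic sampler
    satisfy ``bs_cX == bw_cX / bh_cX`` exactly; the dataclass itself
    stores whatever was measured or specified (e.g. published per-stage
    location values, where the mean ratio differs slightly from the
    ratio of means).
    """

    swia_c3: float
    swia_c4: float
    cd_c2: float
    cd_c3: float
    cd_c4: float
    bw_c3: float
    bw_c4: float
    bh_c3: float
    bh_c4: float
    bs_c3: float
    bs_c4: float
    cd_raw_c2: float
    cd_raw_c3: float
    cd_raw_c4: float

    def __post_init__(self) -> None:
        for name in ("swia_c3", "swia_c4"):
            v = getattr(self, name)
            if not (0.0 < v < 180.0):
                raise MeasurementError(f"{name}={v!r} outside (0, 180) degrees")
        for name in ("bw_c3", "bw_c4", "bh_c3", "bh_c4", "bs_c3", "bs_c4"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise MeasurementError(f"{name}={v!r} must be positive")
        for name in CD_OUTCOMES:
            cd = getattr(self, name)
            raw = getattr(self, "cd_raw" + name[2:])
            if cd < 0 or not math.isfinite(cd):
                raise MeasurementError(f"{name}={cd!r} must be >= 0")
            if abs(cd - max(raw, 0.0)) > 1e-9:
                raise MeasurementError(f"{name} must equal max(raw, 0)")

    @classmethod
    def from_outcomes(cls, values: Mapping[str, float]) -> "MeasurementProfile":
        """Build from the 11 outcome values; raw CDs default to the clamped CDs."""
        kwargs = {k: float(values[k]) for k in OUTCOMES}
        for cd in CD_OUTCOMES:
            kwargs["cd_raw" + cd[2:]] = float(values.get("cd_raw" + cd[2:], kwargs[cd]))
        return cls(**kwargs)

    def as_dict(self, raw: bool = False) -> dict[str, float]:
        d = {k: getattr(self, k) for k in OUTCOMES}
        if raw:
            for cd in CD_OUTCOMES:
                d["cd_raw" + cd[2:]] = getattr(self, "cd_raw" + cd[2:])
        return d

    @property
    def convexity_flags(self) -> dict[str, bool]:
        """True where the inferior border was convex (raw CD < 0, clamped)."""
        return {cd: getattr(self, "cd_raw" + cd[2:]) < 0 for cd in CD_OUTCOMES}


def _require(v: VertebraLandmarks, op: str, allowed: tuple[str, ...]) -> None:
    if v.vertebra_id not in allowed:
        raise MeasurementError(f"{op} is defined for {allowed}, not {v.vertebra_id}")


def compute_swia(v: VertebraLandmarks) -> float:
    """Superior Wall Inclination Angle (degrees) for C3 or C4.

    The superior border (toward ``ua``) and the posterior border (toward
    ``lp``) intersect at ``up`` by construction, so the angle between the
    two borders is the interior angle at that posterosuperior corner.
    """
    _require(v, "SWIA", ("C3", "C4"))
    try:
        return angle_at_vertex(v["up"], v["ua"], v["lp"])
    except GeometryError as err:
        raise MeasurementError(f"{v.vertebra_id} SWIA: {err}") from None


def compute_cd(v: VertebraLandmarks) -> tuple[float, float]:
    """Concavity depth for any vertebra: returns ``(cd, cd_raw)`` in mm.

    ``cd_raw`` is the signed perpendicular distance of ``d`` from the
    lower-border line ``la``–``lp``, oriented so anatomical superior
    (global +y, after the reader has normalised the frame) is positive;
    ``cd = max(cd_raw, 0)``.
    """
    try:
        line = LineSeg(v["la"], v["lp"])
    except GeometryError as err:
        raise MeasurementError(f"{v.vertebra_id} CD: {err}") from None
    s = perp_distance(v["d"], line, signed=True)
    # left normal of direction la->lp has y-component (lp.x - la.x)/|u|;
    # flip the sign so the +y (superior) side is positive.
    ux, _ = line.unit_direction()
    if abs(ux) < 1e-9:
        raise MeasurementError(
            f"{v.vertebra_id} CD: lower border is vertical; cannot orient "
            "the superior side (is the input frame y-up?)"
        )
    raw = s if ux > 0 else -s
    return max(raw, 0.0), raw


def compute_body_dims(v: VertebraLandmarks) -> tuple[float, float]:
    """Body width and height (mm) for C3 or C4.

    BW = unsigned distance from ``um`` to the posterior-border line
    (``up``–``lp``); BH = unsigned distance from ``um`` to the
    lower-border line (``la``–``lp``).
    """
    _require(v, "body dimensions", ("C3", "C4"))
    try:
        bw = perp_distance(v["um"], LineSeg(v["up"], v["lp"]))
        bh = perp_distance(v["um"], LineSeg(v["la"], v["lp"]))
    except GeometryError as err:
        raise MeasurementError(f"{v.vertebra_id} body dimensions: {err}") from None
    return bw, bh


def compute_bs(bw: float, bh: float) -> float:
    """Body shape: the dimensionless ratio BW / BH."""
    if not (bh > 0):
        raise MeasurementError(f"body height must be positive, got {bh!r}")
    return bw / bh


def profile(subject: SubjectAnnotation) -> MeasurementProfile:
    """Compute the full 11-outcome measurement profile for one subject.

    A pure, deterministic function of the landmark coordinates.
    """
    try:
        values: dict[str, float] = {}
        for v, tag in ((subject.c3, "c3"), (subject.c4, "c4")):
            values[f"swia_{tag}"] = compute_swia(v)
            bw, bh = compute_body_dims(v)
            values[f"bw_{tag}"] = bw
            values[f"bh_{tag}"] = bh
            values[f"bs_{tag}"] = compute_bs(bw, bh)
        for v, tag in ((subject.c2, "c2"), (subject.c3, "c3"), (subject.c4, "c4")):
            cd, raw = compute_cd(v)
            values[f"cd_{tag}"] = cd
            values[f"cd_raw_{tag}"] = raw
    except MeasurementError as err:
        raise MeasurementError(f"subject {subject.subject_id}: {err}") from None
    return MeasurementProfile(**values)


# ---------------------------------------------------------------------------
# tabular output


def profiles_to_wide(
    profiles: Mapping[str, MeasurementProfile], raw: bool = False
) -> pd.DataFrame:
    """One row per subject, the 11 outcomes (plus raw CDs) as columns."""
    rows = {sid: p.as_dict(raw=raw) for sid, p in profiles.items()}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "subject_id"
    return df


def profiles_to_long(profiles: Mapping[str, MeasurementProfile]) -> pd.DataFrame:
    """Long format: subject_id, outcome, vertebra, value."""
    records = []
    for sid in sorted(profiles):
        p = profiles[sid]
        for key in OUTCOMES:
            outcome, vert = key.rsplit("_", 1)
            records.append(
                {"subject_id": sid, "outcome": outcome, "vertebra": vert.upper(),
                 "value": getattr(p, key)}
            )
    return pd.DataFrame.from_records(records)
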