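"""Landmark data model and annotation file I/O.

The staging system marks 17 named points on the second, third and fourth
cervical vertebrae (C2, C3, C4) of a lateral cephalometric radiograph:
3 points on C2 (``la``, ``lp``, ``d``) and 7 on each of C3 and C4
(``la``, ``lp``, ``ua``, ``up``, ``d``, ``um``, ``am``).  Point names are
the conventional short forms:

==== ==========================================================
name meaning
==== ==========================================================
la   most anterior point on the inferior border of the body
lp   most posterior point on the inferior border of the body
ua   most anterior point of the superior border of the body
up   most posterior point of the superior border of the body
d    most superior (deepest) point of the inferior border
um   middle point on the superior border of the body
am   middle point on the anterior border of the body
==== ==========================================================

Concatenated forms like ``C3lp`` are accepted on input, case-insensitively,
and stored as canonical lower-case short names.

Supported dialects
------------------
long-csv
    Header ``subject_id,vertebra,point,x_mm,y_mm``; one row per landmark.
    Optional extra columns ``true_stage`` and ``scale_factor`` (constant
    within subject) are honoured.
json
    A top-level array with one object per subject:
    ``{"S1": {"C2": {"la": [x, y], ...}, ...}, "true_stage": "...",
    "scale_factor": 1.0}`` where ``true_stage``/``scale_factor`` are
    optional reserved keys.
tps
    Standard morphometrics ``LM=`` / ``ID=`` records (read-only).  TPS
    files carry no landmark semantics, so a sidecar mapping file
    (CSV: ``index,vertebra,point``, 1-based index) is required.

Internally the frame is mm with +x anterior and +y superior.  Pixel-space
(y-down) sources must be read with ``y_down=True``, which negates y.
"""

from __future__ import annotations

import io
import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .geometry import Point2D

__all__ = [
    "VERTEBRAE",
    "STAGES",
    "C2_POINTS",
    "C34_POINTS",
    "REQUIRED_POINTS",
    "AnnotationError",
    "VertebraLandmarks",
    "SubjectAnnotation",
    "read_annotations",
    "write_annotations",
    "apply_scale",
]

VERTEBRAE: tuple[str, ...] = ("C2", "C3", "C4")

#: Maturational phases, in developmental order.
STAGES: tuple[str, ...] = ("pre-pubertal", "pubertal", "post-pubertal")

C2_POINTS: tuple[str, ...] = ("d", "la", "lp")
C34_POINTS: tuple[str, ...] = ("am", "d", "la", "lp", "ua", "um", "up")

REQUIRED_POINTS: dict[str, tuple[str, ...]] = {
    "C2": C2_POINTS,
    "C3": C34_POINTS,
    "C4": C34_POINTS,
}

LONG_CSV_COLUMNS = ("subject_id", "vertebra", "point", "x_mm", "y_mm")

_JSON_RESERVED = {"true_stage", "scale_factor"}


class AnnotationError(ValueError):
    """Invalid or incomplete landmark annotation input."""


def normalize_vertebra(name: str) -> str:
    v = str(name).strip().upper()
    if v not in VERTEBRAE:
        raise AnnotationError(f"unknown vertebra {name!r} (expected one of {VERTEBRAE})")
    return v


def normalize_point_name(vertebra: str, point: str) -> str:
    """Canonicalise a point name, accepting ``"lp"`` or ``"C3lp"`` forms."""
    v = normalize_vertebra(vertebra)
    p = str(point).strip().lower()
    if p.startswith(v.lower()):
        p = p[len(v):]
    if p not in REQUIRED_POINTS[v]:
        raise AnnotationError(
            f"unknown point {point!r} for vertebra {v} "
            f"(expected one of {REQUIRED_POINTS[v]})"
        )
    return p


@dataclass(frozen=True)
class VertebraLandmarks:
    """Named 2D landmarks for one vertebra (3 points for C2, 7 for C3/C4)."""

    vertebra_id: str
    points: Mapping[str, Point2D]

    def __post_init__(self) -> None:
        v = normalize_vertebra(self.vertebra_id)
        object.__setattr__(self, "vertebra_id", v)
        canonical: dict[str, Point2D] = {}
        for name, pt in self.points.items():
            short = normalize_point_name(v, name)
            if short in canonical:
                raise AnnotationError(f"duplicate landmark {v}{short}")
            if not isinstance(pt, Point2D):
                pt = Point2D(float(pt[0]), float(pt[1]))
            canonical[short] = pt
        required = REQUIRED_POINTS[v]
        missing = [n for n in required if n not in canonical]
        if missing:
            raise AnnotationError(
                f"missing landmark {v}{missing[0]}" if len(missing) == 1
                else f"missing landmarks {', '.join(v + n for n in missing)}"
            )
        # plane endpoints must be distinct
        if canonical["la"] == canonical["lp"]:
            raise AnnotationError(f"{v}: lower-border endpoints la and lp coincide")
        if "ua" in canonical and canonical["ua"] == canonical["up"]:
            raise AnnotationError(f"{v}: superior-border endpoints ua and up coincide")
        object.__setattr__(self, "points", canonical)

    def __getitem__(self, name: str) -> Point2D:
        return self.points[normalize_point_name(self.vertebra_id, name)]

    def __iter__(self) -> Iterator[tuple[str, Point2D]]:
        for name in sorted(self.points):
            yield name, self.points[name]


@dataclass(frozen=True)
class SubjectAnnotation:
    """One traced radiograph: landmark sets for C2, C3 and C4.

    ``scale_factor`` records the magnification correction already divided
    out of the coordinates (1.0 = untouched film frame); ``true_stage``
    carries ground truth for cohorts where it is known (e.g. synthetic
    cohorts or panel-staged samples).
    """

    subject_id: str
    c2: VertebraLandmarks
    c3: VertebraLandmarks
    c4: VertebraLandmarks
    scale_factor: float = 1.0
    true_stage: str | None = None

    def __post_init__(self) -> None:
        for attr, vid in (("c2", "C2"), ("c3", "C3"), ("c4", "C4")):
            got = getattr(self, attr).vertebra_id
            if got != vid:
                raise AnnotationError(
                    f"subject {self.subject_id}: field {attr!r} holds {got}, expected {vid}"
                )
        if not (self.scale_factor > 0 and math.isfinite(self.scale_factor)):
            raise AnnotationError(
                f"subject {self.subject_id}: scale_factor must be positive"
            )
        if self.true_stage is not None and self.true_stage not in STAGES:
            raise AnnotationError(
                f"subject {self.subject_id}: unknown stage {self.true_stage!r} "
                f"(expected one of {STAGES})"
            )

    @property
    def vertebrae(self) -> tuple[VertebraLandmarks, VertebraLandmarks, VertebraLandmarks]:
        return (self.c2, self.c3, self.c4)

    def iter_points(self) -> Iterator[tuple[str, str, Point2D]]:
        """Yield (vertebra, point, Point2D) in canonical order (C2<C3<C4, alpha)."""
        for v in self.vertebrae:
            for name, pt in v:
                yield v.vertebra_id, name, pt


def apply_scale(subject: SubjectAnnotation, factor: float) -> SubjectAnnotation:
    """Divide all coordinates by ``factor`` (magnified-film mm -> true mm).

    The cephalostat used in the reference protocol magnifies by 1.4;
    ``apply_scale(s, 1.4)`` converts film-frame coordinates to anatomical
    size.  The correction is recorded multiplicatively in
    ``scale_factor``, so scaling by ``a`` then ``b`` equals scaling by
    ``a * b`` and ``apply_scale(apply_scale(s, 2), 0.5)`` restores the
    original frame.
    """
    if not (factor > 0 and math.isfinite(factor)):
        raise AnnotationError(f"scale factor must be positive, got {factor!r}")

    def scaled(v: VertebraLandmarks) -> VertebraLandmarks:
        return VertebraLandmarks(
            v.vertebra_id,
            {n: Point2D(p.x / factor, p.y / factor) for n, p in v.points.items()},
        )

    return replace(
        subject,
        c2=scaled(subject.c2),
        c3=scaled(subject.c3),
        c4=scaled(subject.c4),
        scale_factor=subject.scale_factor * factor,
    )


# ---------------------------------------------------------------------------
# reading


def _coerce_float(value, context: str) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise AnnotationError(f"non-numeric coordinate {value!r} for {context}") from None
    if not math.isfinite(x):
        raise AnnotationError(f"non-finite coordinate {value!r} for {context}")
    return x


def _assemble_subject(
    subject_id: str,
    rows: Iterable[tuple[str, str, float, float]],
    *,
    y_down: bool,
    scale_factor: float = 1.0,
    true_stage: str | None = None,
) -> SubjectAnnotation:
    """Build a SubjectAnnotation from (vertebra, point, x, y) records."""
    by_vertebra: dict[str, dict[str, Point2D]] = {v: {} for v in VERTEBRAE}
    for vertebra, point, x, y in rows:
        try:
            v = normalize_vertebra(vertebra)
            p = normalize_point_name(v, point)
        except AnnotationError as err:
            raise AnnotationError(f"subject {subject_id}: {err}") from None
        if p in by_vertebra[v]:
            raise AnnotationError(f"duplicate landmark {v}{p} for subject {subject_id}")
        by_vertebra[v][p] = Point2D(x, -y if y_down else y)
    landmarks = {}
    for v in VERTEBRAE:
        try:
            landmarks[v] = VertebraLandmarks(v, by_vertebra[v])
        except AnnotationError as err:
            raise AnnotationError(f"{err} for subject {subject_id}") from None
    return SubjectAnnotation(
        subject_id=subject_id,
        c2=landmarks["C2"],
        c3=landmarks["C3"],
        c4=landmarks["C4"],
        scale_factor=scale_factor,
        true_stage=true_stage,
    )


def _read_long_csv(source, y_down: bool) -> list[SubjectAnnotation]:
    df = pd.read_csv(source, dtype=str)
    missing = [c for c in LONG_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"long-csv input missing columns {missing}")
    subjects: list[SubjectAnnotation] = []
    for subject_id, grp in df.groupby("subject_id", sort=True):
        rows = []
        for rec in grp.itertuples(index=False):
            ctx = f"subject {subject_id} {rec.vertebra}{rec.point}"
            rows.append(
                (rec.vertebra, rec.point, _coerce_float(rec.x_mm, ctx), _coerce_float(rec.y_mm, ctx))
            )
        scale = 1.0
        stage = None
        if "scale_factor" in grp.columns:
            vals = grp["scale_factor"].dropna().unique()
            if len(vals) > 1:
                raise AnnotationError(f"subject {subject_id}: inconsistent scale_factor")
            if len(vals) == 1:
                scale = _coerce_float(vals[0], f"subject {subject_id} scale_factor")
        if "true_stage" in grp.columns:
            vals = grp["true_stage"].dropna().unique()
            if len(vals) > 1:
                raise AnnotationError(f"subject {subject_id}: inconsistent true_stage")
            if len(vals) == 1:
                stage = str(vals[0])
        subjects.append(
            _assemble_subject(str(subject_id), rows, y_down=y_down,
                              scale_factor=scale, true_stage=stage)
        )
    return subjects


def _read_json(source, y_down: bool) -> list[SubjectAnnotation]:
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    if not isinstance(payload, list):
        raise AnnotationError("json input must be a top-level array of subject objects")
    subjects = []
    for obj in payload:
        if not isinstance(obj, dict):
            raise AnnotationError("each json subject entry must be an object")
        ids = [k for k in obj if k not in _JSON_RESERVED]
        if len(ids) != 1:
            raise AnnotationError(
                f"json subject entry must have exactly one subject key, got {ids}"
            )
        subject_id = ids[0]
        body = obj[subject_id]
        rows = []
        for vertebra, pts in body.items():
            for point, xy in pts.items():
                ctx = f"subject {subject_id} {vertebra}{point}"
                if not isinstance(xy, (list, tuple)) or len(xy) != 2:
                    raise AnnotationError(f"{ctx}: coordinates must be [x, y]")
                rows.append((vertebra, point, _coerce_float(xy[0], ctx), _coerce_float(xy[1], ctx)))
        subjects.append(
            _assemble_subject(
                str(subject_id),
                rows,
                y_down=y_down,
                scale_factor=float(obj.get("scale_factor", 1.0)),
                true_stage=obj.get("true_stage"),
            )
        )
    subjects.sort(key=lambda s: s.subject_id)
    return subjects


def _read_tps_map(tps_map) -> dict[int, tuple[str, str]]:
    df = pd.read_csv(tps_map, dtype=str)
    for col in ("index", "vertebra", "point"):
        if col not in df.columns:
            raise AnnotationError("tps sidecar map needs columns index,vertebra,point")
    mapping: dict[int, tuple[str, str]] = {}
    for rec in df.itertuples(index=False):
        i = int(rec.index)
        if i in mapping:
            raise AnnotationError(f"tps sidecar map: duplicate index {i}")
        mapping[i] = (rec.vertebra, rec.point)
    return mapping


def _read_tps(source, y_down: bool, tps_map) -> list[SubjectAnnotation]:
    if tps_map is None:
        raise AnnotationError(
            "the tps dialect is unlabeled and requires a sidecar point map "
            "(tps_map=, CSV with columns index,vertebra,point)"
        )
    mapping = _read_tps_map(tps_map)
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    subjects = []
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].upper().startswith("LM="):
            raise AnnotationError(f"tps parse error near line {i + 1}: expected LM= record")
        n = int(lines[i].split("=", 1)[1])
        coords = []
        for j in range(n):
            parts = lines[i + 1 + j].split()
            if len(parts) != 2:
                raise AnnotationError(f"tps parse error: bad coordinate line {lines[i + 1 + j]!r}")
            coords.append((_coerce_float(parts[0], "tps x"), _coerce_float(parts[1], "tps y")))
        i += 1 + n
        subject_id = None
        while i < len(lines) and "=" in lines[i] and not lines[i].upper().startswith("LM="):
            key, val = lines[i].split("=", 1)
            if key.upper() == "ID":
                subject_id = val.strip()
            i += 1  # SCALE=, IMAGE= etc. are ignored
        if subject_id is None:
            raise AnnotationError("tps record missing ID= line")
        if set(mapping) != set(range(1, n + 1)):
            raise AnnotationError(
                f"tps sidecar map must cover indices 1..{n} exactly"
            )
        rows = [(*mapping[k + 1], x, y) for k, (x, y) in enumerate(coords)]
        subjects.append(_assemble_subject(subject_id, rows, y_down=y_down))
    subjects.sort(key=lambda s: s.subject_id)
    return subjects


def read_annotations(
    source,
    dialect: str = "long-csv",
    *,
    y_down: bool = False,
    tps_map=None,
) -> list[SubjectAnnotation]:
    """Read subject annotations from a path or file-like object.

    Parameters
    ----------
    source : path or file-like
    dialect : {"long-csv", "json", "tps"}
    y_down : bool
        Negate y on read (for pixel-space, y-down sources).
    tps_map : path or file-like, optional
        Sidecar point map, required for the tps dialect.
    """
    if dialect == "long-csv":
        return _read_long_csv(source, y_down)
    if dialect == "json":
        return _read_json(source, y_down)
    if dialect == "tps":
        return _read_tps(source, y_down, tps_map)
    raise AnnotationError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# writing


def _fmt(x: float) -> str:
    # repr() of a float is the shortest string that round-trips exactly,
    # which makes write->read->write byte-stable.
    return repr(float(x))


def write_annotations(
    subjects: Sequence[SubjectAnnotation],
    dialect: str = "long-csv",
    path=None,
) -> str | None:
    """Write annotations in a deterministic order (subject, C2<C3<C4, point alpha).

    Returns the serialised text when ``path`` is None, otherwise writes to
    ``path`` (a filesystem path or a file-like object) and returns None.
    """
    ordered = sorted(subjects, key=lambda s: s.subject_id)
    if dialect == "long-csv":
        lines = [",".join(LONG_CSV_COLUMNS)]
        for s in ordered:
            for vertebra, point, pt in s.iter_points():
                lines.append(f"{s.subject_id},{vertebra},{point},{_fmt(pt.x)},{_fmt(pt.y)}")
        text = "\n".join(lines) + "\n"
    elif dialect == "json":
        payload = []
        for s in ordered:
            entry: dict = {
                s.subject_id: {
                    v.vertebra_id: {name: [pt.x, pt.y] for name, pt in v}
                    for v in s.vertebrae
                }
            }
            if s.true_stage is not None:
                entry["true_stage"] = s.true_stage
            if s.scale_factor != 1.0:
                entry["scale_factor"] = s.scale_factor
            payload.append(entry)
        text = json.dumps(payload, indent=1) + "\n"
    else:
        raise AnnotationError(f"unsupported write dialect {dialect!r} (tps is read-only)")

    if path is None:
        return text
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return None
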