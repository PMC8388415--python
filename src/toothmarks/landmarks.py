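"""Landmark containers, morphologika/TPS I/O, and tooth-score measurements.

Tooth scores are analysed through the 7-landmark model of their mid-length
cross-section: LM1 and LM7 are the left/right shoulders, LM4 the deepest
point, and LM2/LM3 (left wall) and LM5/LM6 (right wall) are *computational*
landmarks placed at equal arc-length thirds along each wall so that no analyst
subjectivity enters.  Seven measurements derive from the configuration:

======  =====================================================================
WIS     width of the incision at the surface, |LM1 - LM7|        (mm)
WIM     width of the incision midway, |LM2 - LM6|                (mm)
WIB     width of the incision near the base, |LM3 - LM5|         (mm)
D       perpendicular distance of LM4 from the LM1-LM7 chord     (mm)
LDC     left depth at convergent, |LM1 - LM4|                    (mm)
RDC     right depth at convergent, |LM7 - LM4|                   (mm)
OA      opening angle: interior angle of the LM1-LM4-LM7 triangle
        at the LM4 corner                                        (degrees)
======  =====================================================================

Tooth pits use a 3D 30-landmark model: 5 fixed Type II landmarks (length
endpoints LM1/LM2, width endpoints LM3/LM4, deepest point LM5) followed by a
5x5 computational patch in row-major order.  Orientation rule: LM1 is the
length endpoint farther from the width axis.

Coordinates are stored in millimetres; angles are exposed in degrees at the
interface and handled in radians internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreProfile2D",
    "PitConfig3D",
    "ScoreMetrics",
    "LandmarkDataset",
    "MorphologikaError",
    "GeometryError",
    "read_morphologika",
    "write_morphologika",
    "read_tps",
    "compute_wall_landmarks",
    "score_metrics",
    "metrics_table",
]

METRIC_NAMES = ("WIS", "WIM", "WIB", "D", "LDC", "RDC", "OA")
LINEAR_METRICS = ("WIS", "WIM", "WIB", "D", "LDC", "RDC")


class MorphologikaError(ValueError):
    """Malformed morphologika file (message names the offending line)."""


class GeometryError(ValueError):
    """Degenerate landmark geometry."""


@dataclass
class ScoreProfile2D:
    """A 7-landmark 2D tooth-score cross-section (coordinates in mm)."""

    landmarks: np.ndarray
    specimen_id: str
    group_labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.shape != (7, 2):
            raise ValueError(
                f"{self.specimen_id}: expected 7 2D landmarks, got shape "
                f"{self.landmarks.shape}"
            )
        if not np.all(np.isfinite(self.landmarks)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinates")
        # LM4 and the wall landmarks must sit on one side of the LM1-LM7 chord
        # (depth non-negative under the orientation the configuration itself
        # defines, so mirrored digitisations remain valid).
        s4 = _signed_depth(self.landmarks)
        lm = self.landmarks
        for idx in (1, 2, 4, 5):
            wall = lm.copy()
            wall[3] = lm[idx]
            s = _signed_depth(wall)
            if s * s4 < -1e-9 or (abs(s4) < 1e-12 and abs(s) > 1e-9):
                raise ValueError(
                    f"{self.specimen_id}: wall landmark LM{idx+1} lies on the "
                    f"opposite side of the LM1-LM7 chord from LM4"
                )


@dataclass
class PitConfig3D:
    """A 30-landmark 3D tooth-pit configuration: 5 fixed + 5x5 patch (mm)."""

    landmarks: np.ndarray
    specimen_id: str
    group_labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.shape != (30, 3):
            raise ValueError(
                f"{self.specimen_id}: expected 30 3D landmarks, got shape "
                f"{self.landmarks.shape}"
            )
        lm = self.landmarks
        length = np.linalg.norm(lm[0] - lm[1])
        width = np.linalg.norm(lm[2] - lm[3])
        if length < width - 1e-9:
            raise ValueError(
                f"{self.specimen_id}: length axis |LM1-LM2| ({length:.4g}) "
                f"shorter than width axis |LM3-LM4| ({width:.4g})"
            )
        d1, d2 = _axis_distances(lm)
        if d1 < d2 - 1e-9:
            raise ValueError(
                f"{self.specimen_id}: LM1 must be the length endpoint farther "
                f"from the width axis (d1={d1:.4g} < d2={d2:.4g})"
            )


def _axis_distances(lm: np.ndarray) -> tuple[float, float]:
    """Distances of LM1 and LM2 from the width axis (line through LM3-LM4)."""
    a, b = lm[2], lm[3]
    u = b - a
    nu = np.linalg.norm(u)
    if nu == 0:
        return 0.0, 0.0
    u = u / nu

    def dist(p):
        v = p - a
        return float(np.linalg.norm(v - (v @ u) * u))

    return dist(lm[0]), dist(lm[1])


@dataclass(frozen=True)
class ScoreMetrics:
    """The seven derived tooth-score measurements (mm; OA in degrees)."""

    WIS: float
    WIM: float
    WIB: float
    D: float
    LDC: float
    RDC: float
    OA: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


class LandmarkDataset:
    """A homogeneous collection of landmark configurations with metadata.

    Coordinates are held as an array of shape ``(n_specimens, k, dim)``.
    Metadata (park, captivity, prey_size, ...) is a DataFrame indexed by
    specimen id.
    """

    def __init__(
        self,
        coords: np.ndarray,
        specimen_ids: Sequence[str],
        metadata: pd.DataFrame | None = None,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3:
            raise ValueError("coords must have shape (n, landmarks, dim)")
        if coords.shape[2] not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        if len(specimen_ids) != coords.shape[0]:
            raise ValueError("specimen_ids length does not match coords")
        if len(set(specimen_ids)) != len(specimen_ids):
            raise ValueError("specimen ids must be unique")
        self.coords = coords
        self.specimen_ids = list(specimen_ids)
        if metadata is None:
            metadata = pd.DataFrame(index=pd.Index(self.specimen_ids, name="specimen_id"))
        else:
            metadata = metadata.copy()
            missing = set(self.specimen_ids) - set(metadata.index)
            if missing:
                raise ValueError(f"metadata missing for specimens: {sorted(missing)[:5]}")
            metadata = metadata.loc[self.specimen_ids]
        self.metadata = metadata

    # -- basic protocol ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @property
    def dimensionality(self) -> int:
        return self.coords.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.coords.shape

    def __len__(self) -> int:
        return self.n

    def profiles(self) -> list[ScoreProfile2D]:
        """View as validated 2D score profiles (requires 7x2 configurations)."""
        return [
            ScoreProfile2D(self.coords[i], self.specimen_ids[i],
                           dict(self.metadata.iloc[i].dropna()))
            for i in range(self.n)
        ]

    def pits(self) -> list[PitConfig3D]:
        """View as validated 3D pit configurations (requires 30x3)."""
        return [
            PitConfig3D(self.coords[i], self.specimen_ids[i],
                        dict(self.metadata.iloc[i].dropna()))
            for i in range(self.n)
        ]

    def subset(self, mask) -> "LandmarkDataset":
        mask = np.asarray(mask)
        ids = [s for s, m in zip(self.specimen_ids, mask) if m]
        return LandmarkDataset(self.coords[mask], ids, self.metadata.loc[ids])


# ---------------------------------------------------------------------------
# morphologika I/O
# ---------------------------------------------------------------------------

_KNOWN_BLOCKS = {"individuals", "landmarks", "dimensions", "names", "labels",
                 "labelvalues", "rawpoints"}


def read_morphologika(path: str | Path) -> LandmarkDataset:
    """Read a morphologika landmark file.

    Dialect: case-insensitive ``[keyword]`` block headers, whitespace-delimited
    values, an optional ``[labels]``/``[labelvalues]`` pair providing per-
    specimen group metadata.  Unknown blocks are skipped with a logged warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    blocks: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip().lower()
            if current not in _KNOWN_BLOCKS:
                logger.warning("%s:%d: ignoring unknown block [%s]", path.name,
                               lineno, current)
            blocks.setdefault(current, [])
            continue
        if current is None:
            raise MorphologikaError(f"{path.name}:{lineno}: data before any block header")
        blocks[current].append((lineno, line))

    def _int_block(name: str) -> int:
        if name not in blocks or not blocks[name]:
            raise MorphologikaError(f"{path.name}: missing [{name}] block")
        lineno, value = blocks[name][0]
        try:
            return int(value.split()[0])
        except ValueError as exc:
            raise MorphologikaError(
                f"{path.name}:{lineno}: [{name}] is not an integer: {value!r}"
            ) from exc

    n = _int_block("individuals")
    k = _int_block("landmarks")
    dim = _int_block("dimensions")
    if dim not in (2, 3):
        raise MorphologikaError(f"{path.name}: [dimensions] must be 2 or 3, got {dim}")

    names = [v for _, v in blocks.get("names", [])]
    if names and len(names) != n:
        raise MorphologikaError(
            f"{path.name}: [names] lists {len(names)} ids for {n} individuals"
        )
    if not names:
        names = [f"specimen_{i+1}" for i in range(n)]

    raw = blocks.get("rawpoints", [])
    coords = np.full((n, k, dim), np.nan)
    spec_idx = -1
    row = 0
    for lineno, line in raw:
        if line.startswith("'") or line.startswith("‘"):
            spec_idx += 1
            row = 0
            if spec_idx >= n:
                raise MorphologikaError(
                    f"{path.name}:{lineno}: more specimens than declared ({n})"
                )
            continue
        parts = line.split()
        if len(parts) != dim:
            raise MorphologikaError(
                f"{path.name}:{lineno}: expected {dim} coordinates, got "
                f"{len(parts)}: {line!r}"
            )
        if spec_idx < 0:
            raise MorphologikaError(f"{path.name}:{lineno}: coordinates before specimen marker")
        if row >= k:
            raise MorphologikaError(
                f"{path.name}:{lineno}: specimen {names[spec_idx]!r} has more "
                f"than {k} landmark rows"
            )
        try:
            coords[spec_idx, row] = [float(x) for x in parts]
        except ValueError as exc:
            raise MorphologikaError(
                f"{path.name}:{lineno}: non-numeric coordinate in {line!r}"
            ) from exc
        row += 1

    if spec_idx + 1 != n:
        raise MorphologikaError(
            f"{path.name}: declared {n} individuals but found {spec_idx + 1}"
        )
    if np.isnan(coords).any():
        bad = int(np.argwhere(np.isnan(coords).any(axis=(1, 2)))[0][0])
        raise MorphologikaError(
            f"{path.name}: specimen {names[bad]!r} has fewer than {k} landmark rows"
        )

    metadata = None
    if "labels" in blocks and blocks["labels"]:
        label_names: list[str] = []
        for _, v in blocks["labels"]:
            label_names.extend(v.split())
        values = [v for _, v in blocks.get("labelvalues", [])]
        rows = []
        for lineno_v, v in blocks.get("labelvalues", []):
            parts = v.split()
            if len(parts) != len(label_names):
                raise MorphologikaError(
                    f"{path.name}:{lineno_v}: expected {len(label_names)} label "
                    f"values, got {len(parts)}"
                )
            rows.append(parts)
        if rows and len(rows) != n:
            raise MorphologikaError(
                f"{path.name}: [labelvalues] lists {len(rows)} rows for {n} individuals"
            )
        if rows:
            metadata = pd.DataFrame(rows, columns=label_names,
                                    index=pd.Index(names, name="specimen_id"))

    return LandmarkDataset(coords, names, metadata)


def write_morphologika(dataset: LandmarkDataset, path: str | Path,
                       precision: int = 10) -> None:
    """Write a dataset as a morphologika file (lossless at given precision)."""
    path = Path(path)
    out = [
        "[individuals]", str(dataset.n),
        "[landmarks]", str(dataset.n_landmarks),
        "[dimensions]", str(dataset.dimensionality),
        "[names]", *dataset.specimen_ids,
    ]
    if dataset.metadata.shape[1] > 0:
        cols = list(dataset.metadata.columns)
        out += ["[labels]", " ".join(cols), "[labelvalues]"]
        for _, r in dataset.metadata.iterrows():
            out.append(" ".join(str(r[c]) for c in cols))
    out.append("[rawpoints]")
    fmt = f"%.{precision}g"
    for i, sid in enumerate(dataset.specimen_ids):
        out.append(f"' {sid}")
        for pt in dataset.coords[i]:
            out.append(" ".join(fmt % x for x in pt))
    path.write_text("\n".join(out) + "\n")


def read_tps(path: str | Path) -> LandmarkDataset:
    """Read a TPS landmark file (LM=/LM3= records with ID= and optional SCALE=)."""
    path = Path(path)
    configs: list[np.ndarray] = []
    ids: list[str] = []
    current: list[list[float]] = []
    expected = 0
    scale = 1.0
    cur_id: str | None = None

    def _flush(lineno: int) -> None:
        nonlocal current, cur_id, scale, expected
        if expected == 0:
            return
        if len(current) != expected:
            raise MorphologikaError(
                f"{path.name}:{lineno}: expected {expected} landmarks, got {len(current)}"
            )
        configs.append(np.asarray(current) * scale)
        ids.append(cur_id or f"specimen_{len(ids)+1}")
        current, cur_id, scale, expected = [], None, 1.0, 0

    lineno = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM=") or upper.startswith("LM3="):
            _flush(lineno)
            expected = int(line.split("=", 1)[1])
        elif upper.startswith("ID="):
            cur_id = line.split("=", 1)[1].strip()
        elif upper.startswith("SCALE="):
            scale = float(line.split("=", 1)[1])
        elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
            logger.warning("%s:%d: ignoring TPS field %r", path.name, lineno, line)
        else:
            current.append([float(x) for x in line.split()])
    _flush(lineno + 1)
    if not configs:
        raise MorphologikaError(f"{path.name}: no landmark records found")
    dims = {c.shape[1] for c in configs}
    ks = {c.shape[0] for c in configs}
    if len(dims) > 1 or len(ks) > 1:
        raise MorphologikaError(f"{path.name}: mixed landmark counts or dimensionality")
    return LandmarkDataset(np.stack(configs), ids)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _signed_depth(lm: np.ndarray) -> float:
    """Signed perpendicular distance of LM4 below the LM1-LM7 chord.

    Positive when LM4 lies on the side of the chord that makes the profile a
    depression (the cross product convention assumes LM1 -> LM7 reads left to
    right across the mark).
    """
    a, b, p = lm[0], lm[6], lm[3]
    u = b - a
    nu = np.linalg.norm(u)
    if nu == 0:
        raise GeometryError("LM1 and LM7 coincide")
    # right-handed: below the chord <=> negative cross z; flip sign so that
    # a depression has positive depth.
    cross = u[0] * (p[1] - a[1]) - u[1] * (p[0] - a[0])
    return float(-cross / nu)


def _arc_positions(poly: np.ndarray, fracs: Iterable[float]) -> np.ndarray:
    """Points at given arc-length fractions along a polyline."""
    poly = np.asarray(poly, dtype=float)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise GeometryError("wall polyline has zero length")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    out = []
    for f in fracs:
        target = f * total
        i = int(np.searchsorted(cum, target, side="right") - 1)
        i = min(i, len(seg) - 1)
        t = (target - cum[i]) / seg[i] if seg[i] > 0 else 0.0
        out.append(poly[i] + t * (poly[i + 1] - poly[i]))
    return np.asarray(out)


def compute_wall_landmarks(
    profile: np.ndarray,
    shoulders_and_base: tuple[int, int, int],
    specimen_id: str = "profile",
    group_labels: Mapping | None = None,
) -> ScoreProfile2D:
    """Place the four computational landmarks on a digitised cross-section.

    Parameters
    ----------
    profile : polyline of >= 3 vertices tracing the cross-section (mm).
    shoulders_and_base : vertex indices of (LM1, LM4, LM7) within the polyline,
        with LM4 strictly between the shoulders.

    LM2/LM3 are placed at 1/3 and 2/3 of the left-wall arc length (LM1 toward
    LM4); LM5/LM6 at 1/3 and 2/3 from LM4 toward LM7, so LM5 is nearer the
    base and LM6 nearer the shoulder, mirroring the LM2/LM3 order.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 2 or profile.shape[1] != 2 or profile.shape[0] < 3:
        raise ValueError("profile must be an (m, 2) polyline with m >= 3")
    i1, i4, i7 = shoulders_and_base
    if not (min(i1, i7) < i4 < max(i1, i7)):
        raise GeometryError("LM4 index must lie strictly between the shoulders")
    left = profile[min(i1, i4):max(i1, i4) + 1]
    if i1 > i4:
        left = left[::-1]
    right = profile[min(i4, i7):max(i4, i7) + 1]
    if i4 > i7:
        right = right[::-1]
    lm2, lm3 = _arc_positions(left, [1 / 3, 2 / 3])
    lm5, lm6 = _arc_positions(right, [1 / 3, 2 / 3])
    lm = np.stack([profile[i1], lm2, lm3, profile[i4], lm5, lm6, profile[i7]])
    return ScoreProfile2D(lm, specimen_id, dict(group_labels or {}))


def score_metrics(config: ScoreProfile2D) -> ScoreMetrics:
    """Derive the seven tooth-score measurements from a 7-landmark profile."""
    lm = config.landmarks
    lm1, lm2, lm3, lm4, lm5, lm6, lm7 = lm
    if np.allclose(lm1, lm7):
        raise GeometryError(f"{config.specimen_id}: LM1 and LM7 coincide")
    wis = float(np.linalg.norm(lm1 - lm7))
    wim = float(np.linalg.norm(lm2 - lm6))
    wib = float(np.linalg.norm(lm3 - lm5))
    ldc = float(np.linalg.norm(lm1 - lm4))
    rdc = float(np.linalg.norm(lm7 - lm4))
    d = abs(_signed_depth(lm))
    v1 = lm1 - lm4
    v2 = lm7 - lm4
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise GeometryError(f"{config.specimen_id}: LM4 coincides with a shoulder")
    cosang = np.clip((v1 @ v2) / (n1 * n2), -1.0, 1.0)
    oa = math.degrees(math.acos(cosang))
    return ScoreMetrics(wis, wim, wib, d, ldc, rdc, oa)


def metrics_table(dataset: LandmarkDataset) -> pd.DataFrame:
    """Score metrics for every profile in a 2D dataset, joined with metadata."""
    rows = {}
    for prof in dataset.profiles():
        rows[prof.specimen_id] = score_metrics(prof).as_dict()
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "specimen_id"
    return table.join(dataset.metadata)
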