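"""Saccade data model, table I/O, unit conversion and AOI filtering.

Conventions
-----------
* Screen coordinates are in pixels with the origin at the **top-left** corner
  and y increasing downward (the native convention of eye-tracker exports).
* Saccade direction is the absolute angle in degrees, in [0, 360), measured
  against the horizontal screen axis with 0 = rightward.  The rotation sense
  is counter-clockwise *after inverting screen-y*, so 90 deg = upward on the
  screen, matching mathematical polar plots.  Pass ``clockwise=True`` to
  :func:`derive_saccades` for sources that use the opposite sense.
* Saccade amplitude is either in degrees of visual angle
  (``AmplitudeUnit.DEG``) or screen pixels (``AmplitudeUnit.PX``); a table
  never mixes units.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AmplitudeUnit",
    "ScreenGeometry",
    "AOI",
    "FixationRecord",
    "SaccadeRecord",
    "SaccadeTable",
    "FormatError",
    "ConfigurationError",
    "ValidationError",
    "read_saccade_table",
    "write_saccade_table",
    "pixels_per_degree",
    "convert_amplitudes",
    "derive_saccades",
    "filter_by_aoi",
]


class FormatError(ValueError):
    """Malformed or unusable input file."""


class ConfigurationError(ValueError):
    """Missing or inconsistent configuration (geometry, units, bandwidths)."""


class ValidationError(ValueError):
    """Data violates a documented invariant."""


class AmplitudeUnit(str, enum.Enum):
    DEG = "deg_visual_angle"
    PX = "px"


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry, sufficient to convert visual angle to pixels.

    Either set ``ppd_override`` (a known pixels-per-degree factor, used
    verbatim) or provide ``width_mm`` and ``viewing_distance_mm`` so the
    factor can be derived from the screen subtense.
    """

    width_px: int
    height_px: int
    width_mm: float | None = None
    viewing_distance_mm: float | None = None
    ppd_override: float | None = None

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen resolution must be positive")
        for name in ("width_mm", "viewing_distance_mm", "ppd_override"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive, got {v}")

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenGeometry":
        known = {"width_px", "height_px", "width_mm", "viewing_distance_mm", "ppd_override"}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown geometry keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"invalid geometry: {exc}") from exc


@dataclass(frozen=True)
class AOI:
    """Rectangular area of interest; membership is half-open:
    a point (px, py) belongs iff x <= px < x+width and y <= py < y+height,
    so shared edges between adjacent AOIs are never double-counted."""

    name: str
    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"AOI {self.name!r}: width and height must be > 0")

    def contains(self, px: float, py: float) -> bool:
        return (self.x <= px < self.x + self.width) and (self.y <= py < self.y + self.height)

    def check_within(self, geometry: ScreenGeometry) -> None:
        if (
            self.x < 0
            or self.y < 0
            or self.x + self.width > geometry.width_px
            or self.y + self.height > geometry.height_px
        ):
            raise ValidationError(f"AOI {self.name!r} extends beyond the screen bounds")

    @classmethod
    def from_dict(cls, d: dict) -> "AOI":
        try:
            return cls(
                name=str(d["name"]),
                x=float(d["x"]),
                y=float(d["y"]),
                width=float(d["width"]),
                height=float(d["height"]),
            )
        except KeyError as exc:
            raise ConfigurationError(f"AOI definition missing key {exc}") from exc


@dataclass(frozen=True)
class FixationRecord:
    x: float
    y: float
    onset: float
    offset: float
    participant: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("fixation coordinates must be finite")
        if self.offset < self.onset:
            raise ValueError("fixation offset precedes onset")


@dataclass(frozen=True)
class SaccadeRecord:
    """One saccade: direction (deg, [0, 360)), amplitude, optional endpoints."""

    direction_deg: float
    amplitude_value: float
    amplitude_unit: AmplitudeUnit
    start_xy: tuple[float, float] | None = None
    end_xy: tuple[float, float] | None = None
    participant: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.direction_deg):
            raise ValueError("direction must be finite")
        d = float(self.direction_deg) % 360.0
        object.__setattr__(self, "direction_deg", 0.0 if d >= 360.0 else d)
        if not (math.isfinite(self.amplitude_value) and self.amplitude_value >= 0):
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude_value}")
        object.__setattr__(self, "amplitude_unit", AmplitudeUnit(self.amplitude_unit))


#: tolerance (px) for endpoint-distance vs. amplitude consistency
_ENDPOINT_TOL_PX = 0.5


@dataclass(frozen=True)
class SaccadeTable:
    """Ordered collection of saccades sharing one amplitude unit.

    Construction rejects mixed amplitude units outright (silent unit mixing
    is the classic source of scale bugs in amplitude analyses).  When a
    geometry is attached, endpoint pairs are checked for consistency with the
    stored amplitude to 0.5 px.
    """

    records: tuple[SaccadeRecord, ...]
    geometry: ScreenGeometry | None = None
    source: str = ""
    n_skipped: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        units = {r.amplitude_unit for r in self.records}
        if len(units) > 1:
            raise ValidationError(
                f"mixed amplitude units in one table: {sorted(u.value for u in units)}"
            )
        self._check_endpoints()

    def _check_endpoints(self) -> None:
        if not self.records:
            return
        ppd = None
        if self.unit is AmplitudeUnit.DEG:
            try:
                ppd = pixels_per_degree(self.geometry) if self.geometry else None
            except ConfigurationError:
                ppd = None
        for i, r in enumerate(self.records):
            if r.start_xy is None or r.end_xy is None:
                continue
            if r.amplitude_unit is AmplitudeUnit.PX:
                amp_px = r.amplitude_value
            elif ppd is not None:
                amp_px = r.amplitude_value * ppd
            else:
                continue  # deg amplitude, no conversion factor: not checkable
            dist = math.hypot(r.end_xy[0] - r.start_xy[0], r.end_xy[1] - r.start_xy[1])
            if abs(dist - amp_px) > _ENDPOINT_TOL_PX:
                raise ValidationError(
                    f"record {i}: endpoint distance {dist:.2f} px inconsistent "
                    f"with amplitude {amp_px:.2f} px (tolerance {_ENDPOINT_TOL_PX} px)"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def unit(self) -> AmplitudeUnit:
        if not self.records:
            raise ValidationError("empty table has no amplitude unit")
        return self.records[0].amplitude_unit

    @property
    def directions_deg(self) -> np.ndarray:
        return np.array([r.direction_deg for r in self.records], dtype=float)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([r.amplitude_value for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "direction_deg": r.direction_deg,
                    "amplitude": r.amplitude_value,
                    "amplitude_unit": r.amplitude_unit.value,
                    "start_x": None if r.start_xy is None else r.start_xy[0],
                    "start_y": None if r.start_xy is None else r.start_xy[1],
                    "end_x": None if r.end_xy is None else r.end_xy[0],
                    "end_y": None if r.end_xy is None else r.end_xy[1],
                    "participant": r.participant,
                    "group": r.group,
                }
            )
        cols = [
            "direction_deg", "amplitude", "amplitude_unit",
            "start_x", "start_y", "end_x", "end_y", "participant", "group",
        ]
        return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

#: maximum tolerated fraction of unparseable rows before the column map is
#: presumed wrong
_MAX_SKIP_FRACTION = 0.5


def read_saccade_table(
    path,
    column_map: dict[str, str],
    unit: AmplitudeUnit | str,
    *,
    delimiter: str | None = None,
    geometry: ScreenGeometry | None = None,
) -> SaccadeTable:
    """Read a delimited saccade export (CSV/TSV with a header row).

    ``column_map`` maps field names to column names in the file and must name
    at least ``direction`` and ``amplitude``; optional fields are
    ``start_x``, ``start_y``, ``end_x``, ``end_y``, ``participant`` and
    ``group``.  Directions are reduced modulo 360 into [0, 360).  Rows whose
    direction or amplitude cannot be parsed as a number are dropped; the drop
    count is kept in ``table.n_skipped``.  More than half the rows skipped is
    treated as a wrong column map and raises :class:`FormatError`.
    """
    unit = AmplitudeUnit(unit)
    for required in ("direction", "amplitude"):
        if required not in column_map:
            raise FormatError(f"column_map must map the {required!r} field")
    try:
        if delimiter is None:
            df = pd.read_csv(path, sep=None, engine="python")
        else:
            df = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc

    missing = [c for c in column_map.values() if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: mapped column(s) {missing} not found; columns are {list(df.columns)}"
        )

    direction = pd.to_numeric(df[column_map["direction"]], errors="coerce")
    amplitude = pd.to_numeric(df[column_map["amplitude"]], errors="coerce")
    ok = direction.notna() & amplitude.notna()
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("%s: skipped %d unparseable row(s)", path, n_skipped)
    if len(df) > 0 and n_skipped / len(df) > _MAX_SKIP_FRACTION:
        raise FormatError(
            f"{path}: {n_skipped}/{len(df)} rows unparseable - check the column map"
        )

    def _col(fld):
        name = column_map.get(fld)
        return df[name] if name is not None and name in df.columns else None

    sx, sy = _col("start_x"), _col("start_y")
    ex, ey = _col("end_x"), _col("end_y")
    part, grp = _col("participant"), _col("group")

    records = []
    for i in df.index[ok]:
        start = end = None
        if sx is not None and sy is not None and pd.notna(sx[i]) and pd.notna(sy[i]):
            start = (float(sx[i]), float(sy[i]))
        if ex is not None and ey is not None and pd.notna(ex[i]) and pd.notna(ey[i]):
            end = (float(ex[i]), float(ey[i]))
        records.append(
            SaccadeRecord(
                direction_deg=float(direction[i]),
                amplitude_value=float(amplitude[i]),
                amplitude_unit=unit,
                start_xy=start,
                end_xy=end,
                participant=None if part is None or pd.isna(part[i]) else str(part[i]),
                group=None if grp is None or pd.isna(grp[i]) else str(grp[i]),
            )
        )
    if not records:
        raise FormatError(f"{path}: no usable saccade rows after filtering")
    return SaccadeTable(
        records=tuple(records), geometry=geometry, source=str(path), n_skipped=n_skipped
    )


def write_saccade_table(table: SaccadeTable, path) -> None:
    """Write the canonical saccade CSV (see :meth:`SaccadeTable.to_frame`)."""
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------


def pixels_per_degree(geometry: ScreenGeometry) -> float:
    """Pixels-per-degree conversion factor for a screen geometry.

    Returns ``ppd_override`` verbatim when set.  Otherwise computes the mean
    horizontal factor over the full screen subtense:

        ppd = width_px / (2 * atan(width_mm / (2 * d_mm)) in degrees)
    """
    if geometry.ppd_override is not None:
        return float(geometry.ppd_override)
    if geometry.width_mm is None or geometry.viewing_distance_mm is None:
        raise ConfigurationError(
            "pixels_per_degree needs ppd_override, or width_mm and viewing_distance_mm"
        )
    subtense_deg = math.degrees(
        2.0 * math.atan(geometry.width_mm / (2.0 * geometry.viewing_distance_mm))
    )
    return geometry.width_px / subtense_deg


def convert_amplitudes(table: SaccadeTable, target_unit: AmplitudeUnit | str) -> SaccadeTable:
    """Convert all amplitudes to ``target_unit``; directions are untouched.

    deg -> px multiplies by the table geometry's pixels-per-degree factor,
    px -> deg divides; converting to the current unit returns the table as is.
    """
    target_unit = AmplitudeUnit(target_unit)
    if not table.records:
        return table
    if table.unit is target_unit:
        return table
    if table.geometry is None:
        raise ConfigurationError("amplitude unit conversion requires a screen geometry")
    ppd = pixels_per_degree(table.geometry)
    factor = ppd if target_unit is AmplitudeUnit.PX else 1.0 / ppd
    new = tuple(
        replace(r, amplitude_value=r.amplitude_value * factor, amplitude_unit=target_unit)
        for r in table.records
    )
    return SaccadeTable(
        records=new, geometry=table.geometry, source=table.source, n_skipped=table.n_skipped
    )


# ---------------------------------------------------------------------------
# Saccade derivation from fixations
# ---------------------------------------------------------------------------


def direction_from_displacement(dx: float, dy: float, *, clockwise: bool = False) -> float:
    """Angle (deg, [0, 360)) of a screen displacement vs. the horizontal axis.

    Screen-y increases downward, so y is inverted before taking the angle:
    with the default counter-clockwise sense, (0, -100) - a move up the
    screen - maps to 90 deg.
    """
    ang = math.degrees(math.atan2(-dy, dx))
    if clockwise:
        ang = -ang
    return ang % 360.0


def derive_saccades(
    fixations,
    geometry: ScreenGeometry | None = None,
    *,
    clockwise: bool = False,
) -> SaccadeTable:
    """Build a saccade table from consecutive fixations (per participant).

    Amplitude is the Euclidean endpoint distance in pixels; direction follows
    :func:`direction_from_displacement`.  Zero-length displacements are
    dropped (their direction is undefined) with a logged count.  Fewer than
    two fixations yields an empty table; out-of-order onsets raise
    :class:`ValidationError`.
    """
    fixations = list(fixations)
    by_participant: dict[str, list[FixationRecord]] = {}
    for f in fixations:
        by_participant.setdefault(f.participant, []).append(f)

    records = []
    n_zero = 0
    for pid, fixs in by_participant.items():
        onsets = [f.onset for f in fixs]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError(
                f"fixations for participant {pid!r} are not in chronological order"
            )
        for prev, cur in zip(fixs, fixs[1:]):
            dx, dy = cur.x - prev.x, cur.y - prev.y
            amp = math.hypot(dx, dy)
            if amp == 0.0:
                n_zero += 1
                continue
            records.append(
                SaccadeRecord(
                    direction_deg=direction_from_displacement(dx, dy, clockwise=clockwise),
                    amplitude_value=amp,
                    amplitude_unit=AmplitudeUnit.PX,
                    start_xy=(prev.x, prev.y),
                    end_xy=(cur.x, cur.y),
                    participant=pid or None,
                )
            )
    if n_zero:
        logger.info("derive_saccades: dropped %d zero-length displacement(s)", n_zero)
    return SaccadeTable(records=tuple(records), geometry=geometry, source="fixations")


# ---------------------------------------------------------------------------
# AOI filtering
# ---------------------------------------------------------------------------


def filter_by_aoi(table: SaccadeTable, aois) -> SaccadeTable:
    """Keep saccades that start in some AOI *and* end in some AOI.

    Same AOI for both endpoints means a "within"-AOI saccade, different AOIs a
    "between"-AOI saccade; both are kept, everything else is dropped.  All
    records must carry endpoints.
    """
    aois = list(aois)
    if table.geometry is not None:
        for a in aois:
            a.check_within(table.geometry)
    kept = []
    for i, r in enumerate(table.records):
        if r.start_xy is None or r.end_xy is None:
            raise ValidationError(f"record {i} lacks endpoints; AOI filtering needs them")
        start_in = any(a.contains(*r.start_xy) for a in aois)
        end_in = any(a.contains(*r.end_xy) for a in aois)
        if start_in and end_in:
            kept.append(r)
    return SaccadeTable(
        records=tuple(kept),
        geometry=table.geometry,
        source=table.source,
        n_skipped=table.n_skipped,
    )
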