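"""Readers and writers for the dendro and tabular formats the pipeline touches.

Ring widths travel through the package in 1/100 mm (the unit of the Tucson
decadal format with the ``999`` terminator); files measured in 0.001 mm
(terminator ``-9999``) are rescaled on read.  IADF presence is carried
separately, as a wide year x core CSV matrix of {0, 1, NA} flags, because the
Tucson format has no slot for per-ring event marks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES_CODES",
    "RingSeries",
    "SiteMeta",
    "RwlParseError",
    "read_rwl",
    "write_rwl",
    "read_iadf_flags",
    "write_iadf_flags",
    "read_site_table",
    "write_site_table",
]

#: Four-letter species codes of the network's eleven species.
SPECIES_CODES = frozenset(
    {
        "ARUN",  # Arbutus unedo
        "ERAR",  # Erica arborea
        "LADE",  # Larix decidua
        "PIAB",  # Picea abies
        "PIHA",  # Pinus halepensis
        "PINI",  # Pinus nigra
        "PIPI",  # Pinus pinaster
        "PIPN",  # Pinus pinea
        "PISY",  # Pinus sylvestris
        "QUIL",  # Quercus ilex
        "QURO",  # Quercus robur
    }
)

#: Flag value for "ring present but IADF presence unreadable".
MISSING_FLAG = -1


class RwlParseError(ValueError):
    """Raised when a Tucson/decadal file cannot be decoded."""


@dataclass
class RingSeries:
    """One core's annual ring-width series with per-ring IADF flags.

    Parameters
    ----------
    core_id:
        Measurement series identifier (max 8 characters in Tucson files).
    tree_id, site_id:
        Grouping identifiers; several cores may share a tree.
    species_code:
        Four-letter code from :data:`SPECIES_CODES`.
    first_year:
        Calendar year of the first ring.
    widths:
        Ring widths in 1/100 mm, one per consecutive calendar year.
    iadf_flags:
        Per-ring IADF presence: 1, 0, or :data:`MISSING_FLAG` for unreadable
        rings; always the same length as ``widths``.
    pith_offset:
        Rings missing to the pith; cambial age of ring ``i`` is
        ``pith_offset + i + 1``.
    """

    core_id: str
    tree_id: str
    site_id: str
    species_code: str
    first_year: int
    widths: np.ndarray
    iadf_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    pith_offset: int = 0

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.iadf_flags is None:
            self.iadf_flags = np.full(len(self.widths), MISSING_FLAG, dtype=int)
        self.iadf_flags = np.asarray(self.iadf_flags, dtype=int)
        if self.widths.ndim != 1:
            raise ValueError("widths must be one-dimensional")
        if np.any(self.widths < 0):
            raise ValueError(f"{self.core_id}: negative ring width")
        if len(self.iadf_flags) != len(self.widths):
            raise ValueError(f"{self.core_id}: iadf_flags length != widths length")
        if not set(np.unique(self.iadf_flags)) <= {0, 1, MISSING_FLAG}:
            raise ValueError(f"{self.core_id}: flags must be 0, 1 or missing")
        if self.species_code not in SPECIES_CODES:
            raise ValueError(f"{self.core_id}: unknown species code {self.species_code!r}")
        if self.pith_offset < 0:
            raise ValueError(f"{self.core_id}: pith_offset must be >= 0")

    def __len__(self) -> int:
        return len(self.widths)

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        """Calendar years, strictly consecutive from ``first_year``."""
        return np.arange(self.first_year, self.first_year + len(self.widths))

    @property
    def cambial_ages(self) -> np.ndarray:
        """Cambial age of each ring (1-based from the pith)."""
        return self.pith_offset + np.arange(1, len(self.widths) + 1)

    def with_flags(self, flags: Sequence[int]) -> "RingSeries":
        return replace(self, iadf_flags=np.asarray(flags, dtype=int))


@dataclass(frozen=True)
class SiteMeta:
    """Site-level metadata: location and the species sampled there."""

    site_id: str
    latitude: float
    longitude: float
    altitude: float
    country: str
    species_codes: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not (-90 <= self.latitude <= 90) or not (-180 <= self.longitude <= 180):
            raise ValueError(f"{self.site_id}: coordinates out of range")
        if self.altitude < 0:
            raise ValueError(f"{self.site_id}: altitude must be >= 0 m a.s.l.")
        unknown = set(self.species_codes) - SPECIES_CODES
        if unknown:
            raise ValueError(f"{self.site_id}: unknown species codes {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Tucson / decadal RWL
# ---------------------------------------------------------------------------

_TERMINATORS = {999: 1.0, -9999: 0.1}  # terminator -> factor to 1/100 mm


def read_rwl(
    path: str | Path,
    *,
    site_id: str = "",
    species_code: str = "PISY",
) -> list[RingSeries]:
    """Read a Tucson/decadal ring-width file.

    The width unit is auto-detected from the end-of-series marker: ``999``
    means 0.01 mm (stored as-is), ``-9999`` means 0.001 mm (rescaled to
    1/100 mm).  IADF flags are set missing; use :func:`read_iadf_flags` to
    populate them.

    ``site_id`` and ``species_code`` are attached to every series because the
    Tucson format itself carries neither.
    """
    path = Path(path)
    raw: dict[str, list[tuple[int, list[int]]]] = {}
    order: list[str] = []
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not sid or len(rest) < 2:
                raise RwlParseError(f"{path.name}:{lineno}: malformed decade line")
            try:
                year = int(rest[0])
                values = [int(tok) for tok in rest[1:]]
            except ValueError as exc:
                raise RwlParseError(
                    f"{path.name}:{lineno}: malformed decade line ({exc})"
                ) from None
            raw.setdefault(sid, []).append((year, values))
            if sid not in order:
                order.append(sid)

    out: list[RingSeries] = []
    for sid in order:
        rows = raw[sid]
        values: list[int] = []
        expected_year: int | None = None
        first_year = rows[0][0]
        terminator: int | None = None
        for year, row_vals in rows:
            if terminator is not None:
                raise RwlParseError(f"{path.name}: duplicate series ID {sid!r}")
            if expected_year is not None and year != expected_year:
                raise RwlParseError(
                    f"{path.name}: series {sid!r} year jump at {year} (expected {expected_year})"
                )
            for v in row_vals:
                if v in _TERMINATORS:
                    terminator = v
                    break
                values.append(v)
            # next row starts at the following decade boundary
            expected_year = ((year // 10) + 1) * 10
        if terminator is None:
            raise RwlParseError(f"{path.name}: series {sid!r} has no end-of-series marker")
        factor = _TERMINATORS[terminator]
        out.append(
            RingSeries(
                core_id=sid,
                tree_id=sid,
                site_id=site_id,
                species_code=species_code,
                first_year=first_year,
                widths=np.asarray(values, dtype=float) * factor,
            )
        )
    return out


def write_rwl(series: Iterable[RingSeries], path: str | Path) -> None:
    """Write series to Tucson/decadal format (unit 0.01 mm, terminator 999).

    Widths are written as integers; non-integral widths are rounded to the
    format's 0.01 mm resolution.  ``write_rwl`` then ``read_rwl`` is the
    identity on integral-width series.
    """
    path = Path(path)
    lines: list[str] = []
    for s in series:
        if len(s.core_id) > 8:
            raise ValueError(f"core_id {s.core_id!r} exceeds the 8-character field")
        vals = [int(round(v)) for v in s.widths] + [999]
        year = s.first_year
        i = 0
        while i < len(vals):
            decade_end = (year // 10) * 10 + 9
            take = min(decade_end - year + 1, len(vals) - i)
            row = vals[i : i + take]
            lines.append(f"{s.core_id:<8}{year:4d}" + "".join(f"{v:6d}" for v in row))
            i += take
            year += take
    path.write_text("\n".join(lines) + "\n", encoding="ascii")


# ---------------------------------------------------------------------------
# IADF flag matrix
# ---------------------------------------------------------------------------


def read_iadf_flags(path: str | Path, series: Sequence[RingSeries]) -> list[RingSeries]:
    """Populate IADF flags from a wide year x core CSV matrix.

    The file has a ``year`` column and one 0/1/NA column per core.  Flags are
    aligned by calendar year; years outside a core's span and NA cells stay
    missing.  A flag column that matches no core is an error (flags for a core
    we have no widths for indicate a mismatched pair of files).
    """
    df = pd.read_csv(path)
    if "year" not in df.columns:
        raise ValueError("flag file must have a 'year' column")
    by_id = {s.core_id: s for s in series}
    unmatched = [c for c in df.columns if c != "year" and c not in by_id]
    if unmatched:
        raise ValueError(f"flag columns match no series: {unmatched}")
    years = df["year"].to_numpy(dtype=int)
    out = []
    for s in series:
        flags = np.full(len(s), MISSING_FLAG, dtype=int)
        if s.core_id in df.columns:
            col = df[s.core_id]
            bad = col.dropna()[~col.dropna().isin([0, 1])]
            if len(bad):
                raise ValueError(
                    f"core {s.core_id}: flag values outside {{0,1,NA}}: {bad.unique().tolist()}"
                )
            for year, val in zip(years, col):
                if pd.isna(val):
                    continue
                idx = year - s.first_year
                if 0 <= idx < len(s):
                    flags[idx] = int(val)
        out.append(s.with_flags(flags))
    return out


def write_iadf_flags(series: Sequence[RingSeries], path: str | Path) -> None:
    """Write the wide year x core flag matrix consumed by :func:`read_iadf_flags`."""
    if not series:
        raise ValueError("no series to write")
    y0 = min(s.first_year for s in series)
    y1 = max(s.last_year for s in series)
    years = np.arange(y0, y1 + 1)
    data: dict[str, object] = {"year": years}
    for s in series:
        col = np.full(len(years), np.nan)
        sl = slice(s.first_year - y0, s.first_year - y0 + len(s))
        col[sl] = np.where(s.iadf_flags == MISSING_FLAG, np.nan, s.iadf_flags)
        data[s.core_id] = col
    df = pd.DataFrame(data)
    df.to_csv(path, index=False, float_format="%.0f")


# ---------------------------------------------------------------------------
# Site table
# ---------------------------------------------------------------------------


def read_site_table(path: str | Path) -> list[SiteMeta]:
    """Read the site metadata CSV (site_id, latitude, longitude, altitude, country).

    An optional ``species_codes`` column holds ;-separated codes.
    """
    df = pd.read_csv(path)
    required = {"site_id", "latitude", "longitude", "altitude", "country"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    if df.empty:
        warnings.warn("site table is empty", stacklevel=2)
        return []
    if df["site_id"].duplicated().any():
        dupes = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate site_id: {dupes}")
    sites: list[SiteMeta] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        try:
            lat, lon, alt = (float(row[c]) for c in ("latitude", "longitude", "altitude"))
            if math.isnan(lat) or math.isnan(lon):
                raise ValueError("non-numeric coordinates")
            codes = frozenset()
            if "species_codes" in df.columns and isinstance(row["species_codes"], str):
                codes = frozenset(row["species_codes"].split(";"))
            sites.append(
                SiteMeta(str(row["site_id"]), lat, lon, alt, str(row["country"]), codes)
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"row {i} ({row['site_id']}): {exc}")
    if errors:
        raise ValueError("invalid site rows:\n" + "\n".join(errors))
    return sites


def write_site_table(sites: Sequence[SiteMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "latitude": [s.latitude for s in sites],
            "longitude": [s.longitude for s in sites],
            "altitude": [s.altitude for s in sites],
            "country": [s.country for s in sites],
            "species_codes": [";".join(sorted(s.species_codes)) for s in sites],
        }
    ).to_csv(path, index=False)
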