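"""Predominant wind direction from gridded monthly u/v components.

The convention throughout is the *leeward* (blowing-towards) angle in the
mathematical frame: 0 deg = towards east, 90 deg = towards north, measured
counter-clockwise, in the half-open interval (-180, 180].  Angles are binned
into four 90-degree cardinal sectors and the modal sector over the twelve
months of a single reference year defines the predominant direction at a
location.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CARDINALS",
    "WindGrid",
    "WindSample",
    "wind_speed",
    "leeward_angle",
    "categorize_direction",
    "predominant_direction",
    "sample_wind_at",
    "wind_samples_for_points",
]

#: Cardinal categories in mode tie-break priority order.
CARDINALS = ("N", "E", "S", "W")


def wind_speed(u: float, v: float) -> float:
    """Absolute wind speed sqrt(u^2 + v^2) in m/s."""
    return math.hypot(u, v)


def leeward_angle(u: float, v: float) -> float:
    """Direction the wind blows *towards*, in degrees in (-180, 180].

    Computed as atan2(v/ws, u/ws) * 180/pi, which equals atan2(v, u) in
    degrees.  Raises for zero wind speed, where the direction is undefined.
    """
    if u == 0.0 and v == 0.0:
        raise ValueError("leeward angle undefined for zero wind speed")
    ang = math.degrees(math.atan2(v, u))
    # atan2 can return -180.0 for (u<0, v=-0.0); fold onto (-180, 180].
    if ang <= -180.0:
        ang = 180.0
    return ang


def categorize_direction(angle: float) -> str:
    """Bin a leeward angle into one of the four cardinal sectors.

    Half-open sectors (math-angle convention):
    E = [-45, 45), N = [45, 135), W = [135, 180] U (-180, -135), S = [-135, -45).
    """
    if not (-180.0 < angle <= 180.0) :
        raise ValueError(f"angle {angle!r} outside (-180, 180]")
    if -45.0 <= angle < 45.0:
        return "E"
    if 45.0 <= angle < 135.0:
        return "N"
    if -135.0 <= angle < -45.0:
        return "S"
    return "W"


def predominant_direction(uv_monthly) -> str:
    """Modal cardinal category over monthly (u, v) pairs.

    Zero-speed months carry no direction and are dropped from the tally.
    Ties are broken by the fixed order N > E > S > W.
    """
    counts = {c: 0 for c in CARDINALS}
    n_valid = 0
    for u, v in uv_monthly:
        if u == 0.0 and v == 0.0:
            continue
        counts[categorize_direction(leeward_angle(u, v))] += 1
        n_valid += 1
    if n_valid == 0:
        raise ValueError("all months have zero wind speed; direction undefined")
    return max(CARDINALS, key=lambda c: (counts[c], -CARDINALS.index(c)))


@dataclass(frozen=True)
class WindSample:
    """Per-plant wind summary: monthly categories and their mode."""

    plant_id: str
    monthly_angles: tuple
    monthly_categories: tuple
    predominant: str


@dataclass
class WindGrid:
    """Regular grid of monthly zonal/meridional wind components.

    ``u`` and ``v`` have shape (12, ny, nx); ``x`` (nx,) and ``y`` (ny,) are
    cell-centre coordinates with regular spacing (metres in synthetic mode,
    degrees when emulating a 0.125-degree forcing grid).
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != (12, self.y.size, self.x.size):
            raise ValueError(f"u has shape {self.u.shape}, expected (12, ny, nx)")
        if self.v.shape != self.u.shape:
            raise ValueError("u and v shapes differ")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("wind components must be finite")
        for coord in (self.x, self.y):
            if coord.size > 1:
                steps = np.diff(coord)
                if not np.allclose(steps, steps[0]):
                    raise ValueError("grid spacing must be regular")

    @property
    def extent(self) -> tuple:
        """(xmin, ymin, xmax, ymax) of cell centres."""
        return (self.x.min(), self.y.min(), self.x.max(), self.y.max())

    def to_dataframe(self) -> pd.DataFrame:
        mm, yy, xx = np.meshgrid(np.arange(1, 13), self.y, self.x, indexing="ij")
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "month": mm.ravel().astype(int),
                "u": self.u.ravel(),
                "v": self.v.ravel(),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "WindGrid":
        """Rebuild a grid from tidy (x, y, month, u, v) rows.

        Accepts ``lon``/``lat`` as synonyms for ``x``/``y``.
        """
        df = df.rename(columns={"lon": "x", "lat": "y", "lon_or_x": "x", "lat_or_y": "y"})
        x = np.unique(df["x"].to_numpy())
        y = np.unique(df["y"].to_numpy())
        u = np.full((12, y.size, x.size), np.nan)
        v = np.full_like(u, np.nan)
        xi = np.searchsorted(x, df["x"].to_numpy())
        yi = np.searchsorted(y, df["y"].to_numpy())
        mi = df["month"].to_numpy(dtype=int) - 1
        u[mi, yi, xi] = df["u"].to_numpy()
        v[mi, yi, xi] = df["v"].to_numpy()
        if np.isnan(u).any() or np.isnan(v).any():
            raise ValueError("wind table does not cover the full grid x 12 months")
        return cls(x=x, y=y, u=u, v=v)


def _nearest_index(coords: np.ndarray, value: float, half_cell: float) -> int:
    if value < coords[0] - half_cell or value > coords[-1] + half_cell:
        raise ValueError(
            f"point coordinate {value} outside grid extent "
            f"[{coords[0] - half_cell}, {coords[-1] + half_cell}]"
        )
    # np.argmin takes the first minimum, i.e. the lower-index cell on a tie.
    return int(np.argmin(np.abs(coords - value)))


def sample_wind_at(grid: WindGrid, point) -> np.ndarray:
    """Monthly (u, v) series of the grid cell whose centre is nearest ``point``.

    Points up to half a cell outside the outermost centres are accepted.
    A point equidistant between two centres resolves to the lower-index cell.
    Returns an array of shape (12, 2).
    """
    px, py = float(point[0]), float(point[1])
    hx = (grid.x[1] - grid.x[0]) / 2 if grid.x.size > 1 else np.inf
    hy = (grid.y[1] - grid.y[0]) / 2 if grid.y.size > 1 else np.inf
    try:
        ix = _nearest_index(grid.x, px, hx)
        iy = _nearest_index(grid.y, py, hy)
    except ValueError as exc:
        raise ValueError(f"point ({px}, {py}) outside wind grid: {exc}") from None
    return np.stack([grid.u[:, iy, ix], grid.v[:, iy, ix]], axis=1)


def wind_samples_for_points(grid: WindGrid, points: pd.DataFrame) -> pd.DataFrame:
    """Predominant direction for each row of ``points`` (plant_id, x, y).

    Returns a frame with plant_id, predominant_direction, and the 12 monthly
    cardinal categories as a joined string (for inspection/output).
    """
    rows = []
    for rec in points.itertuples(index=False):
        uv = sample_wind_at(grid, (rec.x, rec.y))
        cats = [
            categorize_direction(leeward_angle(u, v)) if (u, v) != (0.0, 0.0) else "-"
            for u, v in uv
        ]
        rows.append(
            {
                "plant_id": rec.plant_id,
                "predominant_direction": predominant_direction(uv),
                "monthly_categories": "".join(cats),
            }
        )
    return pd.DataFrame(rows, columns=["plant_id", "predominant_direction", "monthly_categories"])
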