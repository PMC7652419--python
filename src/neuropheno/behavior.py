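"""Prepulse-inhibition scoring and arena zone-occupancy metrics.

Two families of behavioural readouts:

* **Sensorimotor gating.**  Acoustic startle trials (load-cell amplitudes)
  come in blocks: a first block of tone-only pulses (120 dB) measuring the
  basal startle, and a second block mixing tone-only trials with trials in
  which a weak prepulse (+4/+8/+16 dB over a 65 dB background) precedes the
  tone.  Percent prepulse inhibition is
  ``100 × (mean tone-only − mean prepulse) / mean tone-only``.

* **Anxiety-related occupancy.**  An overhead-tracked centroid trajectory
  (t, x, y) in a named arena — open field with an anxiogenic centre zone,
  elevated plus maze with open/closed arms, or light–dark box — is scored
  for total path length, percent distance and percent time in a zone, and
  debounced entry counts.

Zone membership is by the tracked centre point; an entry requires the
animal to stay on the new side of the boundary for at least ``debounce``
consecutive samples, suppressing boundary jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

__all__ = [
    "Arena",
    "open_field_arena",
    "plus_maze_arena",
    "light_dark_arena",
    "Track",
    "ppi_percent",
    "basal_startle",
    "zone_metrics",
    "oft_metrics",
    "epm_metrics",
    "ld_metrics",
]

PREPULSE_LEVELS = (4, 8, 16)  # dB above the 65 dB background
TONE_ONLY = "tone_only"


def prepulse_condition(level: int) -> str:
    return f"prepulse_+{level}dB"


@dataclass
class Arena:
    """A named arena: outer boundary polygon plus named zone polygons."""

    name: str
    boundary: Polygon
    zones: dict[str, Polygon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.boundary.area <= 0:
            raise ValueError("arena must have positive area")
        for zname, z in self.zones.items():
            if not self.boundary.buffer(1e-9).covers(z):
                raise ValueError(f"zone {zname!r} is not contained in the arena")

    def contains(self, x, y) -> np.ndarray:
        return shapely.contains_xy(self.boundary, x, y)

    def zone_contains(self, zone: str, x, y) -> np.ndarray:
        if zone not in self.zones:
            raise KeyError(f"unknown zone {zone!r}; have {sorted(self.zones)}")
        return shapely.contains_xy(self.zones[zone], x, y)


def open_field_arena(size: float = 40.0, center: float = 20.0) -> Arena:
    """Square open field (default 40×40 cm) with a centred anxiogenic zone
    (default 20×20 cm)."""
    m = (size - center) / 2.0
    return Arena(
        "open_field",
        boundary=box(0, 0, size, size),
        zones={"center": box(m, m, m + center, m + center)},
    )


def plus_maze_arena(arm_len: float = 30.0, arm_w: float = 5.0) -> Arena:
    """Elevated plus maze: two open and two closed arms (30×5 cm each) around
    a central square that belongs to neither arm type."""
    h = arm_w / 2.0
    # centre at the origin; open arms run north-south, closed east-west
    north = box(-h, h, h, h + arm_len)
    south = box(-h, -h - arm_len, h, -h)
    east = box(h, -h, h + arm_len, h)
    west = box(-h - arm_len, -h, -h, h)
    centre = box(-h, -h, h, h)
    return Arena(
        "plus_maze",
        boundary=unary_union([north, south, east, west, centre]),
        zones={
            "open_arms": unary_union([north, south]),
            "closed_arms": unary_union([east, west]),
            "center": centre,
        },
    )


def light_dark_arena(
    light: tuple[float, float] = (25.0, 25.0), dark: tuple[float, float] = (15.0, 25.0)
) -> Arena:
    """Two-chamber light–dark box (default 25×25 light, 15×25 dark) joined
    along the shared wall."""
    lw, lh = light
    dw, dh = dark
    light_p = box(0, 0, lw, lh)
    dark_p = box(lw, 0, lw + dw, dh)
    return Arena(
        "light_dark",
        boundary=unary_union([light_p, dark_p]),
        zones={"light": light_p, "dark": dark_p},
    )


@dataclass
class Track:
    """A sampled centroid trajectory inside an arena."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs: float
    arena: Arena

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal length")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")


# ---------------------------------------------------------------------------
# startle / PPI


def ppi_percent(
    trials: pd.DataFrame,
    level: int,
    tone_block: int | None = 2,
) -> float:
    """Percent prepulse inhibition at one prepulse level.

    ``trials`` columns: ``condition`` (``tone_only`` or ``prepulse_+NdB``),
    ``amplitude``, ``block``.  The tone-only mean is taken from
    ``tone_block`` (the block containing the prepulse trials, by default);
    pass None to average every tone-only trial.  Negative values (startle
    facilitation) are allowed.
    """
    tone = trials[trials["condition"] == TONE_ONLY]
    if tone_block is not None:
        tone = tone[tone["block"] == tone_block]
    pp = trials[trials["condition"] == prepulse_condition(level)]
    if tone.empty or pp.empty:
        raise ValueError("need tone-only and prepulse trials for this level")
    tone_mean = tone["amplitude"].mean()
    if tone_mean == 0:
        raise ValueError("tone-only mean startle is zero; PPI undefined")
    return float(100.0 * (tone_mean - pp["amplitude"].mean()) / tone_mean)


def basal_startle(trials: pd.DataFrame, block: int = 1) -> float:
    """Basal startle: mean tone-only amplitude of the first block."""
    tone = trials[(trials["condition"] == TONE_ONLY) & (trials["block"] == block)]
    if tone.empty:
        raise ValueError(f"no tone-only trials in block {block}")
    return float(tone["amplitude"].mean())


# ---------------------------------------------------------------------------
# zone occupancy


def _debounced_runs(inside: np.ndarray, debounce: int) -> np.ndarray:
    """Debounced in-zone state: a state flip requires ``debounce``
    consecutive samples of the opposite state."""
    state = np.empty_like(inside)
    cur = bool(inside[0])
    run = 0
    for i, s in enumerate(inside):
        if bool(s) != cur:
            run += 1
            if run >= debounce:
                cur = bool(s)
                run = 0
        else:
            run = 0
        state[i] = cur
    return state


def zone_metrics(track: Track, zone: str, debounce: int = 2) -> dict[str, float]:
    """Path-length and occupancy metrics for one named zone.

    Returns total_distance (cm), pct_distance_in_zone, pct_time_in_zone,
    and the debounced entry count (a track that starts inside the zone
    counts its initial visit as one entry).
    """
    inside = track.arena.zone_contains(zone, track.x, track.y)
    dx, dy = np.diff(track.x), np.diff(track.y)
    steps = np.hypot(dx, dy)
    total = float(np.sum(steps))
    # a step belongs to the zone of its starting sample
    dist_in = float(np.sum(steps[inside[:-1]])) if steps.size else 0.0
    pct_time = float(100.0 * np.mean(inside))
    state = _debounced_runs(inside.astype(bool), max(debounce, 1))
    entries = int(state[0]) + int(np.sum(state[1:] & ~state[:-1]))
    return {
        "total_distance": total,
        "pct_distance_in_zone": 100.0 * dist_in / total if total > 0 else 0.0,
        "pct_time_in_zone": pct_time,
        "entries": entries,
        "time_in_zone_s": float(np.sum(inside) / track.fs),
    }


def oft_metrics(track: Track, debounce: int = 2) -> dict[str, float]:
    """Open-field measures: total distance, percent distance and time in the
    centre, and centre entries."""
    m = zone_metrics(track, "center", debounce)
    return {
        "total_distance": m["total_distance"],
        "pct_distance_center": m["pct_distance_in_zone"],
        "pct_time_center": m["pct_time_in_zone"],
        "center_entries": m["entries"],
    }


def epm_metrics(track: Track, debounce: int = 2) -> dict[str, float]:
    """Elevated-plus-maze measures keyed to open-arm occupancy."""
    open_m = zone_metrics(track, "open_arms", debounce)
    closed_m = zone_metrics(track, "closed_arms", debounce)
    center_m = zone_metrics(track, "center", debounce)
    return {
        "total_distance": open_m["total_distance"],
        "pct_distance_open": open_m["pct_distance_in_zone"],
        "pct_time_open": open_m["pct_time_in_zone"],
        "pct_time_closed": closed_m["pct_time_in_zone"],
        "pct_time_center": center_m["pct_time_in_zone"],
        "open_entries": open_m["entries"],
    }


def ld_metrics(track: Track, debounce: int = 2) -> dict[str, float]:
    """Light–dark box measures: time in and entries to the light chamber."""
    light = zone_metrics(track, "light", debounce)
    return {
        "time_in_light_s": light["time_in_zone_s"],
        "pct_time_light": light["pct_time_in_zone"],
        "light_entries": light["entries"],
        "total_distance": light["total_distance"],
    }
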