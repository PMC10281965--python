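"""Parametric guide templates: spiral, square wave, triangular wave.

Templates are the on-screen polylines the participants trace. The spiral
is traced outward from its center; the two waves are traced left to
right from their leftmost point. Coordinates are screen points (origin
top-left, y downward); sizes are package defaults, since the true
on-screen dimensions of the study guides are not published. The traced
*durations* are controlled by the simulator, not by template size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ShapeTemplate:
    shape: str
    points: np.ndarray  # (n, 2) polyline
    start_index: int = 0

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("template needs an (n>=2, 2) polyline")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValueError("consecutive template points must be distinct")
        object.__setattr__(self, "points", pts)

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.hypot(*np.diff(self.points, axis=0).T)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.points, fmt="%.6f", delimiter=",",
                   header="x,y", comments="")


def _check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


def make_spiral(turns: int = 3, spacing: float = 40.0,
                points_per_turn: int = 64) -> ShapeTemplate:
    """Archimedean spiral ``r = spacing * theta / (2 pi)``, wound outward.

    The polyline has ``turns * points_per_turn + 1`` vertices; the start
    point (index 0) is the center, matching the instruction to trace the
    spiral from the center.
    """
    _check_positive(turns=turns, spacing=spacing,
                    points_per_turn=points_per_turn)
    if points_per_turn < 8:
        raise ValueError("points_per_turn must be >= 8")
    theta = np.linspace(0.0, 2.0 * np.pi * turns,
                        int(turns) * int(points_per_turn) + 1)
    r = spacing * theta / (2.0 * np.pi)
    pts = np.column_stack((r * np.cos(theta), r * np.sin(theta)))
    return ShapeTemplate(shape="spiral", points=pts, start_index=0)


def make_square_wave(cycles: int = 3, amplitude: float = 60.0,
                     wavelength: float = 160.0) -> ShapeTemplate:
    """Left-to-right square wave with excursions +-amplitude about the
    baseline (peak-to-peak ``2 * amplitude``).

    Each cycle alternates horizontal half-wavelength runs with vertical
    jumps, so the exact arc length is
    ``cycles * (wavelength + 4 * amplitude)``. Corners are exact right
    angles; any rounding happens in the simulator, not here.
    """
    _check_positive(cycles=cycles, amplitude=amplitude, wavelength=wavelength)
    a, half = amplitude, wavelength / 2.0
    pts = [(0.0, -a)]
    x = 0.0
    for _ in range(int(cycles)):
        x += half
        pts.append((x, -a))   # top run
        pts.append((x, a))    # drop
        x += half
        pts.append((x, a))    # bottom run
        pts.append((x, -a))   # rise
    return ShapeTemplate(shape="square", points=np.asarray(pts),
                         start_index=0)


def make_triangular_wave(cycles: int = 3, amplitude: float = 60.0,
                         wavelength: float = 160.0) -> ShapeTemplate:
    """Left-to-right zigzag alternating right-ascending and
    right-descending strokes, peak-to-peak ``2 * amplitude``.

    Each half-cycle spans ``wavelength / 2`` horizontally and
    ``2 * amplitude`` vertically, so the exact arc length is
    ``2 * cycles * sqrt((wavelength / 2)**2 + (2 * amplitude)**2)``.
    """
    _check_positive(cycles=cycles, amplitude=amplitude, wavelength=wavelength)
    a, half = amplitude, wavelength / 2.0
    n_seg = 2 * int(cycles)
    xs = half * np.arange(n_seg + 1)
    ys = np.where(np.arange(n_seg + 1) % 2 == 0, a, -a)
    return ShapeTemplate(shape="triangular",
                         points=np.column_stack((xs, ys.astype(float))),
                         start_index=0)


def default_template(shape: str) -> ShapeTemplate:
    """The package-default template for a shape name."""
    if shape == "spiral":
        return make_spiral()
    if shape == "square":
        return make_square_wave()
    if shape == "triangular":
        return make_triangular_wave()
    raise ValueError(f"unknown shape {shape!r}")
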