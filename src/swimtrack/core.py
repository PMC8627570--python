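"""Core in-memory containers shared by the generator, the tracker and the
kinematics estimators.

Coordinates
-----------
A midline is an ordered head-to-tail polyline.  Sequences produced by the
synthetic generator live in a right-handed lab frame with y up and distances
in body lengths (BL); sequences produced from images live in pixel
coordinates with the image convention (x = column, y = row, row increasing
downward), flagged with ``y_down=True`` so that downstream code can restore a
right-handed lateral sign convention ("positive to the swimmer's left").

All kinematic quantities are ultimately reported in BL and seconds, using
the body length measured from the curves themselves, which makes the whole
analysis invariant to the pixel scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["BodyMidline", "MidlineSequence", "arc_lengths"]


def arc_lengths(xy: np.ndarray) -> np.ndarray:
    """Total polyline length per frame for an (n_frames, n_points, 2) array."""
    seg = np.linalg.norm(np.diff(xy, axis=-2), axis=-1)
    return seg.sum(axis=-1)


@dataclass
class BodyMidline:
    """One midline at one instant.

    Parameters
    ----------
    points:
        (n_points, 2) array of (x, y) coordinates, ordered head to tail.
    s:
        Normalized arc-length parameter in [0, 1], strictly increasing.
    body_length:
        Measured curve length in the same units as ``points``.
    frame_index, time_s:
        Position of this midline in its source sequence.
    """

    points: np.ndarray
    s: np.ndarray
    body_length: float
    frame_index: int = 0
    time_s: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("midline points must be an (n, 2) array")
        if len(self.s) != len(self.points):
            raise ValidationError("s and points must have the same length")
        if np.any(np.diff(self.s) <= 0):
            raise ValidationError("arc-length parameter must be strictly increasing")
        if not (self.body_length > 0):
            raise ValidationError("body_length must be positive")


@dataclass
class MidlineSequence:
    """A time-ordered stack of midlines sharing one point grid.

    Attributes
    ----------
    xy:
        (n_frames, n_points, 2) coordinates, head to tail along axis 1.
    frame_rate_hz:
        Uniform frame spacing is assumed.
    pixels_per_bl:
        Image scale if the coordinates are pixels; ``None`` for BL units.
    y_down:
        True when the y axis points down (image row convention).
    length_tol:
        Maximum allowed relative deviation of any frame's measured body
        length from the sequence mean (the body is inextensible; large
        deviations indicate tracking failures).
    """

    xy: np.ndarray
    frame_rate_hz: float
    pixels_per_bl: float | None = None
    y_down: bool = False
    length_tol: float = 0.05
    body_length_hint: float | None = None
    lengths: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[2] != 2:
            raise ValidationError("xy must be (n_frames, n_points, 2)")
        if self.xy.shape[0] < 1 or self.xy.shape[1] < 4:
            raise ValidationError("need at least 1 frame and 4 points per midline")
        if not (self.frame_rate_hz > 0):
            raise ValidationError("frame_rate_hz must be positive")
        self.lengths = arc_lengths(self.xy)
        mean_len = float(self.lengths.mean())
        if mean_len <= 0:
            raise ValidationError("degenerate midlines (zero length)")
        dev = np.abs(self.lengths - mean_len) / mean_len
        if dev.max() > self.length_tol:
            raise ValidationError(
                f"body length varies by {dev.max():.1%} across frames "
                f"(tolerance {self.length_tol:.0%}); tracking is unreliable"
            )

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def n_points(self) -> int:
        return self.xy.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    @property
    def s(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_points)

    @property
    def body_length(self) -> float:
        """Mean measured curve length (px or BL depending on units).

        ``body_length_hint`` overrides the naive polyline length; it is set
        by the denoiser, because the raw arc length of a noisy polyline is
        biased upward (every zig-zag adds length).
        """
        if self.body_length_hint is not None:
            return float(self.body_length_hint)
        return float(self.lengths.mean())

    def centroids(self) -> np.ndarray:
        """(n_frames, 2) mean position of the midline points."""
        return self.xy.mean(axis=1)

    def midline(self, j: int) -> BodyMidline:
        return BodyMidline(
            points=self.xy[j],
            s=self.s,
            body_length=float(self.lengths[j]),
            frame_index=j,
            time_s=j / self.frame_rate_hz,
        )

    def flipped(self) -> "MidlineSequence":
        """Head/tail-reversed copy."""
        return MidlineSequence(
            self.xy[:, ::-1],
            self.frame_rate_hz,
            pixels_per_bl=self.pixels_per_bl,
            y_down=self.y_down,
            length_tol=self.length_tol,
            body_length_hint=self.body_length_hint,
        )
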