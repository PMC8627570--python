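"""Synthetic anguilliform swimmer: ground-truth midlines, rendered
silhouette stacks, and whole virtual cohorts.

The kinematic model is a head-to-tail traveling wave with a geometrically
growing amplitude envelope riding on a body of fixed (unit) arc length that
translates at constant forward speed:

    h(s, t) = A(s) * sin(2*pi*(s/lambda - f*t)),   A(s) = A_tail * r**(s - 1)

with ``s`` the arc-length position in [0, 1] (0 = head), ``lambda`` the body
wavelength in BL, ``f`` the wave frequency in Hz, ``A_tail`` half the
peak-to-peak tail amplitude, and ``r`` the caudal/rostral amplitude ratio
(so A(1)/A(0) = r).  The axial coordinate of each body point is compressed
so that the curve's arc length is exactly one body length at every instant —
the body is inextensible, and all BL-normalized quantities extracted
downstream refer to the same length that generated them.

There is no fluid-structure coupling: the model is purely kinematic, which
is all the downstream analysis consumes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import cumulative_trapezoid
from scipy.spatial import cKDTree

from .core import MidlineSequence
from .errors import FieldOfViewError, SamplingRateError, ValidationError

__all__ = [
    "SwimmerParams",
    "RenderSpec",
    "CohortSpec",
    "SyntheticMidlines",
    "RenderResult",
    "PRINTED_GROUP_PARAMS",
    "TREATMENTS",
    "body_wave",
    "generate_midline_sequence",
    "render_frames",
    "generate_cohort",
    "params_from_row",
]

TREATMENTS = ("sham", "fifth_gill", "mid_body")

#: Group-level kinematic parameters (mean, SD) used as cohort defaults:
#: wavelength (BL), peak-to-peak amplitude (BL), wave frequency (Hz),
#: swimming speed (BL/s) and caudal/rostral amplitude ratio for sham
#: controls, rostrally (5th gill) transected and mid-body transected
#: lampreys.  Speed was reported pooled across the two transected groups.
PRINTED_GROUP_PARAMS: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "sham": {
        "wavelength_bl": (0.79, 0.01),
        "amp_pp_tail_bl": (0.16, 0.01),
        "frequency_hz": (3.6, 0.31),
        "speed_bl_s": (1.83, 0.08),
        "amp_ratio": (4.8, 0.43),
    },
    "fifth_gill": {
        "wavelength_bl": (0.53, 0.06),
        "amp_pp_tail_bl": (0.11, 0.02),
        "frequency_hz": (4.1, 0.81),
        "speed_bl_s": (1.12, 0.35),
        "amp_ratio": (1.7, 0.49),
    },
    "mid_body": {
        "wavelength_bl": (0.61, 0.08),
        "amp_pp_tail_bl": (0.13, 0.01),
        "frequency_hz": (3.7, 0.32),
        "speed_bl_s": (1.12, 0.35),
        "amp_ratio": (1.9, 0.18),
    },
}

# physical truncation bounds for cohort sampling
_PARAM_BOUNDS = {
    "wavelength_bl": (0.05, 5.0),
    "amp_pp_tail_bl": (0.005, 0.8),
    "frequency_hz": (0.2, 30.0),
    "speed_bl_s": (0.05, 10.0),
    "amp_ratio": (1.0, 30.0),
}


@dataclass(frozen=True)
class SwimmerParams:
    """Kinematic parameters of one synthetic swimmer trial."""

    body_length_mm: float = 120.0
    wavelength_bl: float = 0.79
    frequency_hz: float = 3.6
    amp_pp_tail_bl: float = 0.16
    amp_ratio: float = 4.8
    speed_bl_s: float = 1.83
    heading_deg: float = 0.0
    noise_sd_bl: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.wavelength_bl > 0):
            raise ValidationError("wavelength_bl must be positive")
        if not (self.frequency_hz > 0):
            raise ValidationError("frequency_hz must be positive")
        if not (0 <= self.amp_pp_tail_bl < 1):
            raise ValidationError("amp_pp_tail_bl must be in [0, 1)")
        if self.amp_ratio < 1:
            raise ValidationError("amp_ratio must be >= 1 (amplitude grows caudally)")
        if self.noise_sd_bl < 0:
            raise ValidationError("noise_sd_bl must be >= 0")
        if not (self.body_length_mm > 0):
            raise ValidationError("body_length_mm must be positive")


def _envelope(params: SwimmerParams, s: np.ndarray) -> np.ndarray:
    a_tail = params.amp_pp_tail_bl / 2.0
    return a_tail * params.amp_ratio ** (s - 1.0)


def body_wave(params: SwimmerParams, s: np.ndarray, t: float | np.ndarray) -> np.ndarray:
    """Analytic lateral displacement h(s, t) in BL (broadcasts over t)."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    phase = 2.0 * np.pi * (s / params.wavelength_bl - params.frequency_hz * t[..., None])
    return _envelope(params, s) * np.sin(phase)


@dataclass
class SyntheticMidlines:
    """Generated midline sequence plus its noise-free ground truth."""

    observed: MidlineSequence
    truth: MidlineSequence
    params: SwimmerParams


def generate_midline_sequence(
    params: SwimmerParams,
    frame_rate_hz: float,
    n_frames: int,
    n_points: int = 100,
    origin: tuple[float, float] = (0.0, 0.0),
) -> SyntheticMidlines:
    """Generate a lab-frame midline sequence for one steadily swimming trial.

    The wave travels head to tail in the body frame while the body advances
    along ``heading_deg`` at ``speed_bl_s``.  Coordinates are in BL in a
    right-handed frame.  When ``noise_sd_bl > 0``, isotropic Gaussian noise
    of that SD is added independently to every observed point; the noise-free
    truth is returned alongside.

    Raises
    ------
    SamplingRateError
        If ``frame_rate_hz < 10 * frequency_hz`` (the generator's sampling
        adequacy bound: at least ten samples per wave period).
    """
    if frame_rate_hz < 10.0 * params.frequency_hz:
        raise SamplingRateError(
            f"frame_rate_hz={frame_rate_hz:g} < 10 x frequency_hz="
            f"{10 * params.frequency_hz:g}; at least 10 samples per wave "
            "period are required to resolve the oscillation"
        )
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    if n_points < 4:
        raise ValidationError("n_points must be >= 4")

    n_fine = max(1001, 8 * n_points + 1)
    s_fine = np.linspace(0.0, 1.0, n_fine)
    times = np.arange(n_frames) / frame_rate_hz

    lam, f = params.wavelength_bl, params.frequency_hz
    env = _envelope(params, s_fine)
    denv = env * np.log(params.amp_ratio)  # dA/ds
    phase = 2.0 * np.pi * (s_fine[None, :] / lam - f * times[:, None])
    h_fine = env[None, :] * np.sin(phase)
    dh_ds = denv[None, :] * np.sin(phase) + env[None, :] * (2 * np.pi / lam) * np.cos(phase)

    slack = 1.0 - dh_ds**2
    if slack.min() <= 0.0:
        raise ValidationError(
            "body-wave slope |dh/ds| reaches 1; amplitude too large for this "
            "wavelength (the inextensible body cannot fold back on itself)"
        )
    # axial coordinate chosen so the curve's arc length equals s exactly
    x_axial = cumulative_trapezoid(np.sqrt(slack), s_fine, axis=1, initial=0.0)

    s_out = np.linspace(0.0, 1.0, n_points)
    x_out = np.empty((n_frames, n_points))
    for j in range(n_frames):
        x_out[j] = np.interp(s_out, s_fine, x_axial[j])
    h_out = _envelope(params, s_out)[None, :] * np.sin(
        2.0 * np.pi * (s_out[None, :] / lam - f * times[:, None])
    )

    # head leads: head at U*t, body trailing behind along the heading
    xb = params.speed_bl_s * times[:, None] - x_out
    yb = h_out
    th = np.deg2rad(params.heading_deg)
    c, sn = np.cos(th), np.sin(th)
    xy = np.empty((n_frames, n_points, 2))
    xy[..., 0] = origin[0] + c * xb - sn * yb
    xy[..., 1] = origin[1] + sn * xb + c * yb

    truth = MidlineSequence(xy, frame_rate_hz, pixels_per_bl=None, y_down=False)
    if params.noise_sd_bl > 0:
        rng = np.random.default_rng(params.seed)
        noisy = xy + rng.normal(0.0, params.noise_sd_bl, size=xy.shape)
        observed = MidlineSequence(
            noisy, frame_rate_hz, pixels_per_bl=None, y_down=False, length_tol=0.5
        )
    else:
        observed = truth
    return SyntheticMidlines(observed=observed, truth=truth, params=params)


def _default_width_profile(s: np.ndarray) -> np.ndarray:
    """Half-width vs arc position, normalized to a maximum of 1.

    Blunt rounded head, taper to a pointed tail.  The terminal taper is
    deliberately steep: the silhouette keeps a resolvable (super-pixel)
    width until very near the tip, as a real body with a caudal fin does.
    A profile that drifts below one pixel over the last few percent of the
    body would leave a sliver no imaging system could segment, making the
    rendered tip systematically unmeasurable.
    """
    w = np.clip(s, 0, 1) ** 0.30 * np.clip(1.0 - s, 0, 1) ** 0.20
    return w / w.max()


@dataclass
class RenderSpec:
    """How to rasterize a midline sequence into silhouette frames."""

    pixels_per_bl: float = 100.0
    image_size: tuple[int, int] | None = None  # (rows, cols); None = auto fit
    background: int = 230
    foreground: int = 25
    max_half_width_bl: float = 0.035
    margin_px: int = 8
    width_profile: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not (self.pixels_per_bl > 0):
            raise ValidationError("pixels_per_bl must be positive")
        if self.max_half_width_bl <= 0:
            raise ValidationError("max_half_width_bl must be positive")
        if not (0 <= self.foreground < self.background <= 255):
            raise ValidationError("need 0 <= foreground < background <= 255")


@dataclass
class RenderResult:
    frames: np.ndarray  # (n_frames, rows, cols) uint8
    midlines_px: MidlineSequence  # ground truth in pixel coordinates (y down)
    spec: RenderSpec


def render_frames(seq: MidlineSequence, spec: RenderSpec | None = None) -> RenderResult:
    """Rasterize a BL-frame midline sequence into grayscale silhouette frames.

    The body is drawn as a tube around the midline whose half-width follows
    ``spec.width_profile`` scaled to ``max_half_width_bl``, with a one-pixel
    soft edge.  Returns the frame stack together with the ground-truth
    midlines converted to pixel coordinates (image convention, y down).

    Raises
    ------
    FieldOfViewError
        If a fixed ``image_size`` is given and the body (plus its width)
        leaves it; the message names the first offending frame.
    """
    spec = spec or RenderSpec()
    wp = spec.width_profile or _default_width_profile
    ppb = spec.pixels_per_bl
    w_max_px = spec.max_half_width_bl * ppb
    pad = w_max_px + 2.0

    xy = seq.xy
    xmin, ymin = xy[..., 0].min(), xy[..., 1].min()
    xmax, ymax = xy[..., 0].max(), xy[..., 1].max()

    if spec.image_size is None:
        cols = int(np.ceil((xmax - xmin) * ppb + 2 * (pad + spec.margin_px)))
        rows = int(np.ceil((ymax - ymin) * ppb + 2 * (pad + spec.margin_px)))
        off_x = pad + spec.margin_px - xmin * ppb
        off_y = pad + spec.margin_px + ymax * ppb  # y flips: row = off_y - y*ppb
    else:
        rows, cols = spec.image_size
        # center the trajectory bounding box in the image
        off_x = (cols - (xmax - xmin) * ppb) / 2.0 - xmin * ppb
        off_y = (rows - (ymax - ymin) * ppb) / 2.0 + ymax * ppb

    px = np.empty_like(xy)
    px[..., 0] = xy[..., 0] * ppb + off_x
    px[..., 1] = off_y - xy[..., 1] * ppb  # image rows grow downward

    lo_x = px[..., 0].min(axis=1) - pad
    lo_y = px[..., 1].min(axis=1) - pad
    hi_x = px[..., 0].max(axis=1) + pad
    hi_y = px[..., 1].max(axis=1) + pad
    bad = np.nonzero(
        (lo_x < 0) | (lo_y < 0) | (hi_x > cols - 1) | (hi_y > rows - 1)
    )[0]
    if bad.size:
        raise FieldOfViewError(
            f"body leaves the {rows}x{cols} field of view at frame {bad[0]}"
        )

    s_grid = seq.s
    frames = np.full((seq.n_frames, rows, cols), spec.background, dtype=np.uint8)
    span = spec.background - spec.foreground
    for j in range(seq.n_frames):
        pts = px[j]
        # dense resample so the union of per-point disks approximates a tube
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate(([0.0], np.cumsum(seg)))
        n_dense = max(2, int(np.ceil(cum[-1] / 0.3)) + 1)
        u = np.linspace(0.0, cum[-1], n_dense)
        dx = np.interp(u, cum, pts[:, 0])
        dy = np.interp(u, cum, pts[:, 1])
        ds = np.interp(u, cum, s_grid)
        tree = cKDTree(np.column_stack([dx, dy]))

        r0 = max(int(np.floor(pts[:, 1].min() - pad)), 0)
        r1 = min(int(np.ceil(pts[:, 1].max() + pad)) + 1, rows)
        c0 = max(int(np.floor(pts[:, 0].min() - pad)), 0)
        c1 = min(int(np.ceil(pts[:, 0].max() + pad)) + 1, cols)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        q = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)
        dist, idx = tree.query(q, workers=-1)
        w_px = wp(ds[idx]) * w_max_px
        cover = np.clip(w_px - dist + 0.5, 0.0, 1.0)  # 1-px soft edge
        tile = frames[j, r0:r1, c0:c1].astype(float)
        tile -= span * cover.reshape(rr.shape)
        frames[j, r0:r1, c0:c1] = np.clip(tile, 0, 255).astype(np.uint8)

    midlines_px = MidlineSequence(
        px, seq.frame_rate_hz, pixels_per_bl=ppb, y_down=True,
        length_tol=seq.length_tol,
    )
    return RenderResult(frames=frames, midlines_px=midlines_px, spec=spec)


@dataclass
class CohortSpec:
    """Virtual study design: group sizes and parameter distributions.

    Defaults reproduce the study conditions the analysis is built around:
    3 sham controls, 11 rostrally (5th gill) transected and 3 mid-body
    transected individuals, group kinematic means/SDs as in
    ``PRINTED_GROUP_PARAMS``, and percent axon regeneration uniform over
    33.3-84.2% for transected animals (missing for sham).
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"sham": 3, "fifth_gill": 11, "mid_body": 3}
    )
    trials_per_individual: int = 3
    within_individual_cv: float = 0.08
    regeneration_range: tuple[float, float] = (33.3, 84.2)
    group_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: PRINTED_GROUP_PARAMS
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in TREATMENTS:
                raise ValidationError(f"unknown treatment group {g!r}")
            if n < 1:
                raise ValidationError(f"group {g!r} needs n >= 1 (got {n})")
        lo, hi = self.regeneration_range
        if not (0 <= lo <= hi <= 100):
            raise ValidationError("regeneration_range must lie within [0, 100]")
        if self.trials_per_individual < 1:
            raise ValidationError("trials_per_individual must be >= 1")
        if self.within_individual_cv < 0:
            raise ValidationError("within_individual_cv must be >= 0")
        for g, pars in self.group_params.items():
            for name, (_, sd) in pars.items():
                if sd < 0:
                    raise ValidationError(f"{g}.{name}: SD must be >= 0")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


# documented draw order per individual (then regen, then per-trial jitters)
_DRAW_ORDER = ("wavelength_bl", "amp_pp_tail_bl", "frequency_hz",
               "speed_bl_s", "amp_ratio")


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a virtual cohort and return a one-row-per-trial parameter table.

    Individual-level parameters are truncated-normal draws at the group
    mean/SD; per-trial wave frequency and speed are jittered around the
    individual mean with CV ``within_individual_cv`` (speed co-varies with
    frequency, reflecting speed modulation through tail-beat frequency at
    roughly constant stride).  Regeneration percentage is uniform over
    ``regeneration_range`` for transected individuals and missing (NaN) for
    sham.  A single RNG stream seeded from ``spec.seed`` with a fixed draw
    order makes the cohort bit-for-bit reproducible.

    Columns: individual_id, treatment, regeneration_pct, trial,
    wavelength_bl, frequency_hz, amp_pp_tail_bl, amp_ratio, speed_bl_s,
    trial_seed.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for group in TREATMENTS:
        n = spec.n_per_group.get(group, 0)
        pars = spec.group_params[group]
        for i in range(n):
            ind_id = f"{group}_{i + 1:02d}"
            base = {
                name: _trunc_normal(rng, *pars[name], *_PARAM_BOUNDS[name])
                for name in _DRAW_ORDER
            }
            if group == "sham":
                regen = np.nan
            else:
                regen = float(rng.uniform(*spec.regeneration_range))
            for k in range(spec.trials_per_individual):
                cv = spec.within_individual_cv
                jf = _trunc_normal(rng, 1.0, cv, 0.5, 1.5)
                ju = _trunc_normal(rng, 1.0, cv / 2.0, 0.5, 1.5)
                trial_seed = int(rng.integers(0, 2**31 - 1))
                rows.append({
                    "individual_id": ind_id,
                    "treatment": group,
                    "regeneration_pct": regen,
                    "trial": k + 1,
                    "wavelength_bl": base["wavelength_bl"],
                    "frequency_hz": base["frequency_hz"] * jf,
                    "amp_pp_tail_bl": base["amp_pp_tail_bl"],
                    "amp_ratio": base["amp_ratio"],
                    "speed_bl_s": base["speed_bl_s"] * jf * ju,
                    "trial_seed": trial_seed,
                })
    return pd.DataFrame(rows)


def params_from_row(row: Mapping, noise_sd_bl: float = 0.0) -> SwimmerParams:
    """Build SwimmerParams for one cohort-table row."""
    return SwimmerParams(
        wavelength_bl=float(row["wavelength_bl"]),
        frequency_hz=float(row["frequency_hz"]),
        amp_pp_tail_bl=float(row["amp_pp_tail_bl"]),
        amp_ratio=float(row["amp_ratio"]),
        speed_bl_s=float(row["speed_bl_s"]),
        noise_sd_bl=noise_sd_bl,
        seed=int(row.get("trial_seed", 0)),
    )


def write_params_json(params: SwimmerParams, path) -> None:
    """Echo generator parameters to a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(asdict(params), fh, indent=2, sort_keys=True)
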