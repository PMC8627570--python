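"""Traveling-body-wave kinematics from a midline sequence.

Everything here operates on the lateral excursion field h(s, t): the signed
perpendicular distance of the midline point at arc position s from the mean
travel axis, in body lengths.  From it we extract the quantities a
swimming-performance comparison needs:

* forward swimming speed U (BL/s) from the centroid track,
* wave frequency f (Hz) from zero crossings of the tail excursion,
* maximum peak-to-peak amplitude A_pp (BL) and its along-body envelope,
* caudal/rostral amplitude growth ratio,
* body wavelength lambda (BL) from extrema spacing along the body,
* wave (phase) speed V (BL/s) from the phase gradient of the dominant
  frequency component, cross-checked against lambda*f,
* a steady-state admissibility filter on cycle-averaged speeds.

All estimators are invariant to rigid transforms of the input coordinates
and to the pixel scale, because positions are referenced to the measured
body length and to the principal axis of the centroid track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks

from .core import MidlineSequence
from .errors import (
    IncoherentWaveError,
    InsufficientCyclesError,
    NoNetTravelError,
    NoOscillationError,
    ValidationError,
    WaveNotResolvedError,
)

__all__ = [
    "ExcursionField",
    "WaveKinematics",
    "SteadyStateResult",
    "denoise_sequence",
    "body_frame",
    "estimate_speed",
    "estimate_frequency",
    "estimate_amplitude",
    "estimate_wavelength",
    "estimate_wave_speed",
    "steady_state_filter",
    "waves_per_body",
    "compute_wave_kinematics",
]

#: analysis stations: "tail" and "head" are placed slightly inside the body
#: ends because the extreme points of a tracked midline are the least
#: reliable part of the curve.
TAIL_STATION = 0.95
HEAD_STATION = 0.05


@dataclass
class ExcursionField:
    """Lateral displacement h over (arc position, time), in BL.

    ``h[i, j]`` is the excursion of station ``s[i]`` at time ``times[j]``,
    positive to the swimmer's left.  ``com_track`` is the body-centroid
    track and ``heading`` the unit vector of mean travel, both in BL.
    """

    h: np.ndarray
    s: np.ndarray
    times: np.ndarray
    heading: np.ndarray
    com_track: np.ndarray
    body_length: float

    @property
    def frame_rate_hz(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])

    def station_index(self, s0: float) -> int:
        return int(np.argmin(np.abs(self.s - s0)))


@dataclass
class WaveKinematics:
    """Per-trial wave parameters (the row the statistics consume)."""

    speed_bl_s: float
    frequency_hz: float
    amp_pp_bl: float
    wavelength_bl: float
    wave_speed_bl_s: float
    waves_per_body: float
    amp_ratio: float
    n_cycles: int
    frequency_period_sd_s: float = float("nan")
    wavelength_fit_based: bool = False
    steady: bool = True
    wave_speed_consistent: bool = True


@dataclass
class SteadyStateResult:
    passed: bool
    cycle_speeds_bl_s: np.ndarray
    mean_speed_bl_s: float
    tolerance: float


def _point_noise_sd(xy: np.ndarray) -> float:
    """Per-point noise SD from second differences along the body.

    For IID point noise, var(second difference) = 6 sigma^2; the smooth body
    shape contributes negligibly at typical point densities.
    """
    d2 = np.diff(xy, n=2, axis=1)
    return float(np.sqrt((d2**2).mean() / 6.0))


def denoise_sequence(seq: MidlineSequence, noise_sd: float | None = None) -> MidlineSequence:
    """Suppress independent per-point noise in raw midlines.

    Two effects of measurement noise matter downstream and are treated
    separately:

    * Lateral jitter is removed by a zero-phase moving average applied to
      each material point's trajectory *in time* (window ~1/10 of the
      dominant oscillation period).  Temporal smoothing adds no spatial
      bias: it cannot distort the amplitude envelope or the wavelength the
      way along-the-body smoothing can.
    * The measured body length of a noisy polyline is biased upward (every
      zig-zag adds length, by ~(sigma/spacing)^2 relative).  The length is
      therefore re-measured on a decimated copy of each smoothed midline,
      whose point spacing is large against the residual noise, and attached
      to the returned sequence as its calibrated body length.

    ``noise_sd`` is estimated from second differences along the body when
    not given.  Sequences that are already smooth are returned unchanged.
    """
    xy = seq.xy
    n = seq.n_points
    bl0 = float(seq.lengths.mean())
    if noise_sd is None:
        noise_sd = _point_noise_sd(xy)

    def _robust_length(arr: np.ndarray) -> float:
        n_dec = min(n, 25)
        idx_dec = np.linspace(0, n - 1, n_dec).round().astype(int)
        seg = np.linalg.norm(np.diff(arr[:, idx_dec], axis=1), axis=2)
        return float(seg.sum(axis=1).mean())

    if noise_sd <= 2e-4 * bl0 or seq.n_frames < 8:
        return seq
    if noise_sd <= 1.5e-3 * bl0:
        # jitter small enough for the harmonic estimators to absorb, but the
        # naive arc length is already percent-level biased: recalibrate only
        return MidlineSequence(
            xy, seq.frame_rate_hz, pixels_per_bl=seq.pixels_per_bl,
            y_down=seq.y_down, length_tol=seq.length_tol,
            body_length_hint=_robust_length(xy),
        )

    # temporal window from the dominant period of the liveliest point
    var_per_point = xy.var(axis=0).sum(axis=1)
    tail_idx = int(np.argmax(var_per_point))
    x = xy[:, tail_idx, 1] - xy[:, tail_idx, 1].mean()
    spec = np.abs(np.fft.rfft(x))
    spec[0] = 0.0
    k = int(np.argmax(spec))
    win = max(2, int(round(seq.n_frames / max(k, 1) / 10.0))) if k > 0 else 2
    win = min(win, max(2, seq.n_frames // 4))
    kernel = np.ones(win) / win
    sm = np.empty_like(xy)
    for axis_pts in range(n):
        for d in range(2):
            col = xy[:, axis_pts, d]
            padded = np.concatenate([col[win - 1 :: -1], col, col[: -win - 1 : -1]])
            sm[:, axis_pts, d] = np.convolve(padded, kernel, mode="same")[win : win + len(col)]

    return MidlineSequence(
        sm, seq.frame_rate_hz, pixels_per_bl=seq.pixels_per_bl,
        y_down=seq.y_down, length_tol=seq.length_tol,
        body_length_hint=_robust_length(sm),
    )


def body_frame(seq: MidlineSequence, min_travel_bl: float = 0.1) -> ExcursionField:
    """Project a midline sequence into the swim-direction frame.

    The heading is the principal axis of the body-centroid track (sign
    aligned with the net displacement); h is the perpendicular offset of
    every midline point from the heading line through the track's mean,
    normalized by the measured body length.
    """
    bl = seq.body_length
    com = seq.centroids()
    net = com[-1] - com[0]
    if np.linalg.norm(net) / bl < min_travel_bl:
        raise NoNetTravelError(
            f"centroid track spans {np.linalg.norm(net) / bl:.3f} BL "
            f"(< {min_travel_bl} BL); cannot define a heading"
        )
    centered = com - com.mean(axis=0)
    # principal axis of the track
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    u = vt[0]
    if np.dot(u, net) < 0:
        u = -u
    # right-handed normal; for image (y-down) input flip so that positive h
    # is to the swimmer's left in the physical plane
    n = np.array([-u[1], u[0]])
    if seq.y_down:
        n = -n
    rel = seq.xy - com.mean(axis=0)
    h = (rel @ n).T / bl  # (n_points, n_frames)
    com_bl = (com - com.mean(axis=0)) / bl
    return ExcursionField(
        h=h, s=seq.s, times=seq.times, heading=u, com_track=com_bl, body_length=bl
    )


def estimate_speed(seq: MidlineSequence, field: ExcursionField | None = None) -> float:
    """Forward swimming speed U in BL/s.

    Net centroid displacement along the heading divided by elapsed time and
    body length.
    """
    field = field or body_frame(seq)
    disp = (field.com_track[-1] - field.com_track[0]) @ field.heading
    dt = field.times[-1] - field.times[0]
    if dt <= 0:
        raise ValidationError("need at least two frames to estimate speed")
    return float(disp / dt)


def _interp_crossings(t: np.ndarray, x: np.ndarray, direction: int) -> np.ndarray:
    """Times of zero crossings of x(t) in the given direction (+1 up, -1 down),
    located by linear interpolation between samples."""
    s = np.sign(x)
    # resolve exact zeros by propagating the previous sign
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
    if direction > 0:
        idx = idx[x[idx] < 0]
    else:
        idx = idx[x[idx] > 0]
    frac = x[idx] / (x[idx] - x[idx + 1])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def _station_series(field: ExcursionField, station: float) -> np.ndarray:
    """Mean-subtracted excursion time series at a station, lightly low-passed.

    A zero-phase moving average with a window of ~1/10 of the (FFT-rough)
    dominant period suppresses frame-to-frame tracking jitter that would
    otherwise produce spurious zero crossings, without moving the crossing
    times of the underlying near-sinusoid.
    """
    i = field.station_index(station)
    x = field.h[i] - field.h[i].mean()
    if len(x) < 8:
        return x
    spec = np.abs(np.fft.rfft(x))
    spec[0] = 0.0
    k = int(np.argmax(spec))
    if k == 0:
        return x
    period_frames = len(x) / k
    win = int(round(period_frames / 10.0))
    if win < 2:
        return x
    kernel = np.ones(win) / win
    padded = np.concatenate([x[win - 1 :: -1], x, x[: -win - 1 : -1]])
    sm = np.convolve(padded, kernel, mode="same")
    return sm[win : win + len(x)]


def estimate_frequency(
    field: ExcursionField,
    station: float = TAIL_STATION,
    noise_floor_bl: float = 1e-3,
) -> tuple[float, float]:
    """Wave frequency f (Hz) from tail-excursion zero crossings.

    f is the reciprocal of the mean period between successive same-sign zero
    crossings of h(station, t) (crossings located by linear interpolation);
    the SD of the individual periods is returned alongside.
    """
    i = field.station_index(station)
    if np.max(np.abs(field.h[i] - field.h[i].mean())) < noise_floor_bl:
        raise NoOscillationError(
            f"excursion at s={station:.2f} is flat (max |h| < {noise_floor_bl} BL)"
        )
    x = _station_series(field, station)
    ups = _interp_crossings(field.times, x, +1)
    downs = _interp_crossings(field.times, x, -1)
    if len(ups) + len(downs) < 3:
        raise InsufficientCyclesError(
            "fewer than 3 zero crossings at the tail; need >= 2 cycles"
        )
    periods = np.concatenate([np.diff(ups), np.diff(downs)])
    if len(periods) == 0:
        raise InsufficientCyclesError("no complete same-sign crossing pair")
    f = 1.0 / float(periods.mean())
    return f, float(periods.std(ddof=1)) if len(periods) > 1 else 0.0


def _cycle_edges(field: ExcursionField, station: float = TAIL_STATION) -> np.ndarray:
    x = _station_series(field, station)
    ups = _interp_crossings(field.times, x, +1)
    if len(ups) >= 3:
        # drop spurious edges from residual jitter near the zero line
        med = np.median(np.diff(ups))
        keep = [ups[0]]
        for t in ups[1:]:
            if t - keep[-1] >= 0.5 * med:
                keep.append(t)
        ups = np.asarray(keep)
    if len(ups) < 2:
        raise InsufficientCyclesError("fewer than one full cycle at the tail station")
    return ups


def estimate_amplitude(
    field: ExcursionField,
    head_station: float = HEAD_STATION,
    tail_station: float = TAIL_STATION,
    frequency_hz: float | None = None,
    n_harmonics: int = 3,
) -> tuple[float, np.ndarray, float]:
    """Peak-to-peak amplitude envelope and caudal/rostral growth ratio.

    For each full tail-beat cycle the peak-to-peak excursion is computed at
    every station and the per-cycle envelopes are averaged.  The raw sample
    extremes of max(h) - min(h) are biased upward by per-frame measurement
    jitter, so within each cycle the excursion is first projected onto a
    mean-plus-harmonics model (harmonics 1..``n_harmonics`` of the
    tail-beat frequency) and the peak-to-peak value read off the smooth
    reconstruction.

    Returns ``(amp_pp_bl, envelope, amp_ratio)`` where ``amp_pp_bl`` is the
    envelope maximum over the body ("maximum amplitude, peak to peak") and
    ``amp_ratio`` is the amplitude growth across one whole body length,
    obtained from a log-linear fit of the envelope between ``head_station``
    and ``tail_station`` (exact for a geometric envelope and robust to
    endpoint artifacts).
    """
    if frequency_hz is None:
        frequency_hz, _ = estimate_frequency(field, station=tail_station)
    f = frequency_hz
    edges = _cycle_edges(field, tail_station)
    env = np.zeros(len(field.s))
    n_used = 0
    t_fine = np.linspace(0.0, 1.0 / f, 256)
    for k in range(len(edges) - 1):
        sel = (field.times >= edges[k]) & (field.times <= edges[k + 1])
        tt = field.times[sel]
        if sel.sum() < 2 * n_harmonics + 2:
            continue  # cycle too sparsely sampled for the harmonic fit
        cols = [np.ones_like(tt)]
        cols_fine = [np.ones_like(t_fine)]
        for m in range(1, n_harmonics + 1):
            cols += [np.cos(2 * np.pi * m * f * tt), np.sin(2 * np.pi * m * f * tt)]
            cols_fine += [np.cos(2 * np.pi * m * f * t_fine),
                          np.sin(2 * np.pi * m * f * t_fine)]
        design = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(design, field.h[:, sel].T, rcond=None)
        recon = np.column_stack(cols_fine) @ coef  # (t_fine, n_s)
        env += recon.max(axis=0) - recon.min(axis=0)
        n_used += 1
    if n_used == 0:
        raise InsufficientCyclesError("no cycle with enough frames for amplitude fit")
    env /= n_used

    # stations beyond the tail analysis station sit in the tip-extension
    # zone of a tracked midline rather than on the band-refined interior;
    # take the maximum over the reliable core and, when the envelope is
    # still growing there, extrapolate the tail-region log-slope to s = 1
    # (exact for a geometric envelope, a no-op for a uniform one)
    core = field.s <= tail_station + 1e-9
    env_core = env[core]
    s_core = field.s[core]
    i_max = int(np.argmax(env_core))
    amp_pp = float(env_core[i_max])
    if i_max == len(env_core) - 1 and np.all(env_core > 0):
        tail_band = s_core >= s_core[-1] - 0.2
        if tail_band.sum() >= 3:
            slope_tail = np.polyfit(s_core[tail_band],
                                    np.log(env_core[tail_band]), 1)[0]
            amp_pp = float(env_core[-1] * np.exp(slope_tail * (1.0 - s_core[-1])))
    band = (field.s >= head_station - 1e-9) & (field.s <= tail_station + 1e-9)
    with np.errstate(divide="ignore"):
        log_env = np.log(env[band])
    if not np.all(np.isfinite(log_env)):
        raise NoOscillationError("zero envelope inside the analysis band")
    slope = np.polyfit(field.s[band], log_env, 1)[0]
    amp_ratio = float(np.exp(slope))
    return amp_pp, env, amp_ratio


def _refine_extremum(s: np.ndarray, g: np.ndarray, i: int) -> float:
    """Parabolic sub-grid refinement of an extremum location."""
    if i <= 0 or i >= len(g) - 1:
        return float(s[i])
    denom = g[i - 1] - 2.0 * g[i] + g[i + 1]
    if denom == 0:
        return float(s[i])
    delta = 0.5 * (g[i - 1] - g[i + 1]) / denom
    return float(s[i] + np.clip(delta, -1, 1) * (s[1] - s[0]))


def _sinusoid_fit_wavelength(s: np.ndarray, g: np.ndarray) -> float:
    """Fallback: fit a single sinusoid in s to the (envelope-normalized)
    excursion profiles of all frames (g: (n_s, n_frames)) and return its
    period."""

    def ssr(lam: float) -> float:
        k = 2.0 * np.pi / lam
        basis = np.column_stack([np.sin(k * s), np.cos(k * s), np.ones_like(s)])
        coef, *_ = np.linalg.lstsq(basis, g, rcond=None)
        resid = g - basis @ coef
        return float((resid**2).sum())

    lams = np.geomspace(0.25, 8.0, 120)
    vals = [ssr(l) for l in lams]
    i = int(np.argmin(vals))
    lo = lams[max(i - 1, 0)]
    hi = lams[min(i + 1, len(lams) - 1)]
    res = minimize_scalar(ssr, bounds=(lo, hi), method="bounded")
    return float(res.x)


def estimate_wavelength(
    field: ExcursionField,
    prominence_frac: float = 0.2,
    noise_floor_bl: float = 1e-3,
    s_band: tuple[float, float] = (0.02, 0.99),
) -> tuple[float, bool]:
    """Body wavelength lambda (BL) from wave extrema spacing.

    Per frame, the excursion profile h(s) is normalized by the per-station
    peak-to-peak envelope (so the low-amplitude head region is not
    suppressed), extrema are located with a prominence filter of
    ``prominence_frac`` of the local peak-to-peak amplitude and refined to
    sub-grid precision, and lambda is twice the mean arc-length spacing of
    adjacent extrema ("distance between wave peaks or troughs").  Spacings
    are pooled over all frames.  When no frame shows two interior extrema
    (wavelength comparable to or longer than the body), a single sinusoid in
    s is fitted instead and its period returned with the ``fit_based`` flag.

    Returns ``(wavelength_bl, fit_based)``.
    """
    env_pp = field.h.max(axis=1) - field.h.min(axis=1)
    if env_pp.max() < 2 * noise_floor_bl:
        raise WaveNotResolvedError("no lateral wave along the body (flat excursion)")
    env = np.maximum(env_pp / 2.0, 0.05 * env_pp.max() / 2.0)
    band = (field.s >= s_band[0]) & (field.s <= s_band[1])
    s = field.s[band]
    g_all = (field.h[band] / env[band, None]).T  # (n_frames, n_s)

    spacings: list[float] = []
    prom = prominence_frac * 2.0  # 20% of the (normalized) peak-to-peak of 2
    for g in g_all:
        ext: list[float] = []
        for sign in (+1.0, -1.0):
            peaks, _ = find_peaks(sign * g, prominence=prom)
            ext.extend(_refine_extremum(s, sign * g, int(p)) for p in peaks)
        ext.sort()
        if len(ext) >= 2:
            spacings.extend(np.diff(ext))
    if spacings:
        return 2.0 * float(np.mean(spacings)), False
    lam = _sinusoid_fit_wavelength(s, g_all.T)
    if not np.isfinite(lam) or lam <= 0:
        raise WaveNotResolvedError("wavelength fit did not converge")
    return lam, True


def estimate_wave_speed(
    field: ExcursionField,
    frequency_hz: float | None = None,
    stations: tuple[float, float] = (0.3, TAIL_STATION),
    n_stations: int = 14,
    min_r2: float = 0.9,
) -> float:
    """Wave (phase) speed V in BL/s from the phase gradient along the body.

    The phase of the dominant-frequency component of h(s_i, t) is computed
    at ``n_stations`` stations inside ``stations`` by correlating against
    exp(-2*pi*i*f*t) over a whole number of periods; V = -2*pi*f / slope of
    the unwrapped phase versus s.  A fit with R^2 below ``min_r2`` or a
    non-negative slope (no rearward-traveling wave) raises
    ``IncoherentWaveError``.
    """
    if frequency_hz is None:
        frequency_hz, _ = estimate_frequency(field)
    f = frequency_hz
    t = field.times
    total = t[-1] - t[0]
    n_cyc = int(np.floor(total * f))
    if n_cyc < 2:
        raise InsufficientCyclesError("need >= 2 cycles to estimate wave speed")
    keep = t - t[0] <= n_cyc / f + 1e-12
    tt = t[keep]

    s_q = np.linspace(stations[0], stations[1], n_stations)
    idx = np.unique([field.station_index(sq) for sq in s_q])
    if len(idx) < 5:
        raise ValidationError("too few distinct stations for a phase fit")
    carrier = np.exp(-2j * np.pi * f * tt)
    z = field.h[np.ix_(idx, np.nonzero(keep)[0])] @ carrier
    phi = np.unwrap(np.angle(z))
    s_used = field.s[idx]
    slope, intercept = np.polyfit(s_used, phi, 1)
    resid = phi - (slope * s_used + intercept)
    ss_tot = float(((phi - phi.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    if r2 < min_r2:
        raise IncoherentWaveError(
            f"phase-vs-position fit R^2={r2:.3f} < {min_r2}; no coherent traveling wave"
        )
    if slope >= -1e-6:
        raise IncoherentWaveError(
            "phase does not decrease toward the tail; no rearward-traveling wave"
        )
    return float(-2.0 * np.pi * f / slope)


def steady_state_filter(
    seq: MidlineSequence,
    tolerance: float = 0.15,
    field: ExcursionField | None = None,
) -> SteadyStateResult:
    """Admissibility check: cycle-averaged speed must not drift.

    The clip is split into full tail-beat cycles (upward zero crossings of
    the tail excursion); the centroid advance along the heading within each
    cycle, divided by the cycle duration, gives per-cycle speeds.  The clip
    passes iff every cycle speed is within ``tolerance`` (default 15%) of
    their mean — the quantitative version of requiring that instantaneous
    velocities not deviate from the clip-averaged velocity.
    """
    field = field or body_frame(seq)
    edges = _cycle_edges(field)
    if len(edges) < 3:
        raise InsufficientCyclesError("need >= 2 full cycles for the steady-state check")
    along = field.com_track @ field.heading
    pos = np.interp(edges, field.times, along)
    speeds = np.diff(pos) / np.diff(edges)
    mean = float(speeds.mean())
    passed = bool(np.all(np.abs(speeds - mean) <= tolerance * abs(mean)))
    return SteadyStateResult(
        passed=passed, cycle_speeds_bl_s=speeds, mean_speed_bl_s=mean,
        tolerance=tolerance,
    )


def waves_per_body(wavelength_bl: float) -> float:
    """Number of simultaneous waves on the body: 1 / lambda (lambda in BL)."""
    if not (wavelength_bl > 0):
        raise ValidationError("wavelength must be positive")
    return 1.0 / wavelength_bl


def compute_wave_kinematics(
    seq: MidlineSequence,
    steady_tolerance: float = 0.15,
    wave_speed_rtol: float = 0.10,
    denoise: bool = True,
) -> WaveKinematics:
    """Run the full per-trial kinematic extraction on one midline sequence."""
    if denoise:
        seq = denoise_sequence(seq)
    field = body_frame(seq)
    steady = steady_state_filter(seq, tolerance=steady_tolerance, field=field)
    speed = estimate_speed(seq, field)
    freq, period_sd = estimate_frequency(field)
    amp_pp, _, amp_ratio = estimate_amplitude(field)
    lam, fit_based = estimate_wavelength(field)
    v = estimate_wave_speed(field, frequency_hz=freq)
    consistent = abs(v - lam * freq) <= wave_speed_rtol * lam * freq
    n_cycles = len(_cycle_edges(field)) - 1
    return WaveKinematics(
        speed_bl_s=speed,
        frequency_hz=freq,
        amp_pp_bl=amp_pp,
        wavelength_bl=lam,
        wave_speed_bl_s=v,
        waves_per_body=waves_per_body(lam),
        amp_ratio=amp_ratio,
        n_cycles=n_cycles,
        frequency_period_sd_s=period_sd,
        wavelength_fit_based=fit_based,
        steady=steady.passed,
        wave_speed_consistent=consistent,
    )
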