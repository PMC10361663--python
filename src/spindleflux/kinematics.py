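"""Photoactivated-pulse kinematics.

A photoactivated stripe of molecules shows up as a Gaussian bump in the
pole-to-pole intensity profile.  Per frame, the profile is fitted with

    I(x) = offset + A exp(-(x - mu)^2 / (2 sigma^2))

and the centre ``mu`` tracked over time.  Because the raw fitted
velocity depends on where along the axis the stripe was placed, the
centre-versus-time track is fitted with a second-order polynomial
``x(t) = x0 + u0 t + (1/2) a t^2`` and the constant-acceleration
equations of motion are used to extrapolate the velocity the pulse
would have at a common reference landmark (the chromosome edge, or the
pole), where x = 0:

    x(t*) = 0,    uc = u0 + a t*

with ``t*`` the real root of smallest magnitude (extrapolation backward
in time is permitted).  This puts every cell's velocity at the same
reference point so that conditions can be averaged and compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from spindleflux import image_prep
from spindleflux.image_prep import LineProfile, SpindleAxis
from spindleflux.stack import ImageStack


@dataclass
class GaussianFitResult:
    """Single-Gaussian profile fit (optionally with a constant offset)."""

    amplitude: float
    center: float  # μm along the axis from pole_a
    sigma: float  # μm
    offset: float
    r_squared: float
    converged: bool


@dataclass
class CenterTrack:
    """Gaussian-centre trajectory; times relative to the first
    post-activation frame, only converged fits included."""

    times: np.ndarray  # s
    centers: np.ndarray  # μm
    r_squared: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.centers = np.asarray(self.centers, float)
        self.r_squared = np.asarray(self.r_squared, float)
        if not (len(self.times) == len(self.centers) == len(self.r_squared)):
            raise ValueError("times, centers and r_squared must have equal length")


@dataclass
class KinematicsResult:
    """Equations-of-motion summary at the reference landmark.

    ``u0`` (μm/min) and ``a`` (μm/min²) come from the quadratic fit of
    the centre track expressed as distance from the landmark; ``x0``
    (μm) is the stripe-centre-to-landmark distance; ``t_star`` (min)
    solves ``x0 + u0 t + a t²/2 = 0`` (smallest-|t| real root); and
    ``uc = u0 + a t_star``.  ``roots`` retains both roots for audit.
    ``sign_convention`` states what positive velocity means.
    """

    u0: float
    a: float
    x0: float
    t_star: float
    uc: float
    roots: tuple
    sign_convention: str = "away_from_landmark_positive"
    r2_quadratic: float = math.nan
    n_frames_used: int = 0
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# profile fitting


def fit_gaussian(profile: LineProfile, with_offset: bool = True) -> GaussianFitResult:
    """Least-squares Gaussian fit of one pole-to-pole profile."""
    x, y = profile.positions, profile.intensities
    if len(x) < 7:
        raise ValueError(f"need >= 7 profile samples, got {len(x)}")
    if np.ptp(y) == 0:
        return GaussianFitResult(math.nan, math.nan, math.nan, math.nan, 0.0, False)
    off0 = float(np.min(y))
    amp0 = float(np.max(y) - off0)
    mu0 = float(x[int(np.argmax(y))])
    # moment-based width guess over the above-baseline mass
    w = np.clip(y - off0, 0, None)
    sig0 = float(np.sqrt(np.sum(w * (x - mu0) ** 2) / max(np.sum(w), 1e-12)))
    sig0 = min(max(sig0, (x[1] - x[0])), (x[-1] - x[0]))
    span = float(x[-1] - x[0])

    if with_offset:
        model = lambda xx, A, mu, sig, off: off + A * np.exp(-((xx - mu) ** 2) / (2 * sig ** 2))
        p0 = [amp0, mu0, sig0, off0]
        bounds = ([0.0, x[0], (x[1] - x[0]) / 4, -np.inf],
                  [np.inf, x[-1], 2 * span, np.inf])
    else:
        model = lambda xx, A, mu, sig: A * np.exp(-((xx - mu) ** 2) / (2 * sig ** 2))
        p0 = [amp0 + off0, mu0, sig0]
        bounds = ([0.0, x[0], (x[1] - x[0]) / 4], [np.inf, x[-1], 2 * span])
    try:
        popt, _ = curve_fit(model, x, y, p0=p0, bounds=bounds, maxfev=10000)
    except (RuntimeError, ValueError):
        return GaussianFitResult(math.nan, math.nan, math.nan, math.nan, 0.0, False)
    yhat = model(x, *popt)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if with_offset:
        amp, mu, sig, off = map(float, popt)
    else:
        amp, mu, sig = map(float, popt)
        off = 0.0
    if not (x[0] <= mu <= x[-1]) or sig <= 0:
        return GaussianFitResult(amp, mu, abs(sig), off, r2, False)
    return GaussianFitResult(amp, mu, sig, off, r2, True)


def track_centers(profiles: list, activation_index: int, times: np.ndarray,
                  with_offset: bool = True, min_frames: int = 4,
                  min_r2: float = 0.0, window_um: float | None = 2.5) -> CenterTrack:
    """Gaussian centres of the post-activation frames versus time.

    ``profiles`` and ``times`` cover the whole stack; frames before
    ``activation_index`` are ignored, frames whose fit fails to converge
    (or falls below ``min_r2``) are dropped and counted.

    With ``window_um`` set (the default), each frame after the first is
    fitted only within that distance of the previous centre.  This keeps
    the fit on the pulse once exchanged molecules have rebuilt a diffuse
    spindle-wide background around it.
    """
    times = np.asarray(times, float)
    kept_t, kept_c, kept_r2, dropped = [], [], [], 0
    prev_center: float | None = None
    for i in range(activation_index, len(profiles)):
        prof = profiles[i]
        if window_um is not None and prev_center is not None:
            sel = np.abs(prof.positions - prev_center) <= window_um
            if sel.sum() >= 7:
                prof = LineProfile(prof.positions[sel], prof.intensities[sel],
                                   prof.width_used, prof.clipped)
        fit = fit_gaussian(prof, with_offset=with_offset)
        if fit.converged and fit.r_squared >= min_r2:
            kept_t.append(times[i] - times[activation_index])
            kept_c.append(fit.center)
            kept_r2.append(fit.r_squared)
            prev_center = fit.center
        else:
            dropped += 1
    if len(kept_t) < min_frames:
        raise ValueError(
            f"only {len(kept_t)} usable post-activation frames (< {min_frames})"
        )
    return CenterTrack(np.array(kept_t), np.array(kept_c), np.array(kept_r2), dropped)


# ---------------------------------------------------------------------------
# kinematics


def fit_kinematics(track: CenterTrack) -> tuple[float, float, np.ndarray, float]:
    """Quadratic fit of centre vs time.

    Returns ``(u0, a, coeffs, r2)`` with u0 in μm/min, a in μm/min² and
    ``coeffs = (c0, c1, c2)`` of the fit ``mu(t) = c0 + c1 t + c2 t²``
    in minutes/μm units (so ``u0 = c1``, ``a = 2 c2``).
    """
    if len(track.times) < 4:
        raise ValueError("need >= 4 points for a quadratic fit")
    if len(np.unique(track.times)) < 3:
        raise ValueError("duplicate times make the quadratic design rank-deficient")
    t_min = track.times / 60.0
    coeffs = np.polynomial.polynomial.polyfit(t_min, track.centers, 2)
    c0, c1, c2 = map(float, coeffs)
    yhat = c0 + c1 * t_min + c2 * t_min ** 2
    ss_tot = float(np.sum((track.centers - track.centers.mean()) ** 2))
    r2 = 1.0 - float(np.sum((track.centers - yhat) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return c1, 2.0 * c2, np.array([c0, c1, c2]), r2


def velocity_at_reference(u0: float, a: float, x0: float,
                          sign_convention: str = "away_from_landmark_positive") -> KinematicsResult:
    """Extrapolate the velocity at the landmark (x = 0).

    Solves ``x0 + u0 t + a t²/2 = 0`` for the real root of smallest
    magnitude (negative roots allowed — backward extrapolation) and
    evaluates ``uc = u0 + a t*``.  Units: μm, μm/min, μm/min², min.
    """
    if x0 < 0:
        raise ValueError(f"x0 must be a distance >= 0, got {x0}")
    if a == 0:
        if u0 == 0:
            raise ValueError("u0 = 0 and a = 0: the pulse never reaches the reference")
        t_star = -x0 / u0
        roots = (t_star,)
    else:
        disc = u0 * u0 - 2.0 * a * x0
        if disc < 0:
            raise ValueError("no real crossing: the trajectory never reaches the reference")
        sq = math.sqrt(disc)
        if u0 == 0:
            roots = (sq / a, -sq / a)
        else:
            # cancellation-free quadratic roots (Citardauq form for the
            # small root, so a -> 0 degrades gracefully to -x0/u0)
            q = -(u0 + math.copysign(sq, u0))
            roots = (q / a, 2.0 * x0 / q if q != 0 else 0.0)
        t_star = min(roots, key=abs)
    uc = u0 + a * t_star
    return KinematicsResult(u0=u0, a=a, x0=x0, t_star=t_star, uc=uc,
                            roots=roots, sign_convention=sign_convention)


def measure_x0(axis: SpindleAxis, stripe_center_um: float,
               landmark: str = "chrom_edge") -> float:
    """Unsigned axis distance from the stripe centre to the landmark.

    ``stripe_center_um`` is in axis coordinates (μm from pole_a).  For
    ``landmark='chrom_edge'`` the nearer chromosome-band edge is used;
    for ``landmark='pole'`` the nearer pole.
    """
    length = axis.length_um
    if not 0 <= stripe_center_um <= length:
        raise ValueError(
            f"stripe centre {stripe_center_um:.3f} μm lies outside the spindle span (0, {length:.3f})"
        )
    if landmark == "chrom_edge":
        lo, hi = axis.chrom_edges
        return float(min(abs(stripe_center_um - lo), abs(stripe_center_um - hi)))
    if landmark == "pole":
        return float(min(stripe_center_um, length - stripe_center_um))
    raise ValueError(f"landmark must be 'chrom_edge' or 'pole', got {landmark!r}")


# ---------------------------------------------------------------------------
# end-to-end


def pa_experiment(stack: ImageStack, activation_index: int,
                  stripe_center_um: float | None = None,
                  landmark: str = "chrom_edge", register: bool = True,
                  width_um: float = 2.0, with_offset: bool = True,
                  chrom_edges: tuple | None = None,
                  reporter_as_mask: bool = False) -> KinematicsResult:
    """Photoactivation analysis of one cell.

    Registers the stack, finds the spindle axis on the reference channel
    (or, for activated-tubulin runs, on the post-activation reporter
    signal itself via ``reporter_as_mask``), extracts per-frame
    pole-to-pole profiles of the reporter, tracks the Gaussian centre,
    fits the quadratic kinematics in landmark coordinates and
    extrapolates ``uc``.  The reported ``uc_poleward`` is signed with
    poleward motion positive.

    ``stripe_center_um`` is the activation-stripe centre in axis
    coordinates (μm from pole_a); when omitted, the first tracked centre
    stands in for it.
    """
    if not 0 <= activation_index < stack.n_frames - 3:
        raise ValueError("activation_index leaves too few post-activation frames")
    if register:
        from spindleflux.frap import register_stack_safe
        stack, _ = register_stack_safe(stack)
    geom_frame = (stack.frame(activation_index, "reporter") if reporter_as_mask
                  else stack.frame(0, "reference"))
    try:
        mask = image_prep.segment_spindle(geom_frame)
        axis = image_prep.find_axis(
            mask, None if reporter_as_mask else geom_frame,
            stack.pixel_size, chrom_edges=chrom_edges)
    except ValueError as exc:
        raise ValueError(f"geometry stage failed: {exc}") from exc

    profiles = [image_prep.extract_profile(stack.frame(t, "reporter"), axis, width_um)
                for t in range(stack.n_frames)]
    track = track_centers(profiles, activation_index, stack.timestamps,
                          with_offset=with_offset)

    if stripe_center_um is None:
        stripe_center_um = float(track.centers[0])
    x0 = measure_x0(axis, stripe_center_um, landmark)

    # landmark coordinate: distance from the landmark, increasing away from it
    if landmark == "chrom_edge":
        lo, hi = axis.chrom_edges
        edge = lo if abs(stripe_center_um - lo) <= abs(stripe_center_um - hi) else hi
        direction = 1.0 if stripe_center_um >= edge else -1.0
        landmark_pos = edge
        away_is_poleward = True  # away from the chromosome edge = toward a pole
    else:
        pole_pos = 0.0 if stripe_center_um <= axis.length_um / 2 else axis.length_um
        direction = 1.0 if stripe_center_um >= pole_pos else -1.0
        landmark_pos = pole_pos
        away_is_poleward = False  # away from the pole = toward the equator

    d_track = CenterTrack(track.times, (track.centers - landmark_pos) * direction,
                          track.r_squared, track.n_dropped)
    u0, a, coeffs, r2 = fit_kinematics(d_track)
    try:
        result = velocity_at_reference(u0, a, x0)
    except ValueError as exc:
        raise ValueError(f"reference-velocity stage failed: {exc}") from exc
    uc_poleward = result.uc if away_is_poleward else -result.uc
    result.r2_quadratic = r2
    result.n_frames_used = len(track.times)
    result.extras = {
        "uc_poleward": uc_poleward,
        "landmark": landmark,
        "landmark_position_um": landmark_pos,
        "stripe_center_um": stripe_center_um,
        "quad_coeffs": tuple(map(float, coeffs)),
        "n_dropped": track.n_dropped,
        "track_times_s": track.times.tolist(),
        "track_centers_um": track.centers.tolist(),
    }
    return result
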