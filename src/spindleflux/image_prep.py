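"""From raw two-channel stacks to registered, compartmentalized measurements.

The reference channel (tubulin or H2B) anchors all geometry: frames are
rigid-registered to frame 0 against it, the spindle mask is segmented
from it, the pole-to-pole axis is its mask's principal axis, and the
chromosome band is the central trough of its axial intensity profile
(the gap in microtubule staining at the chromosome plate).  The spindle
is then split into six zones — pole / intermediate / chromosome on the
bleached and unbleached halves — and mean reporter intensities, line
profiles and summary geometry are extracted.

Axis convention: positions are measured in micrometres from ``pole_a``
(the pole at the lower image-x end) along the pole-to-pole axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage import filters, measure, transform
from skimage.registration import phase_cross_correlation

from spindleflux.stack import ImageStack

ZONE_NAMES = {
    1: "bleached_pole",
    2: "bleached_intermediate",
    3: "bleached_chromosome",
    4: "unbleached_chromosome",
    5: "unbleached_intermediate",
    6: "unbleached_pole",
}


@dataclass
class SpindleAxis:
    """Pole-to-pole axis with the chromosome-band boundaries.

    ``pole_a`` / ``pole_b`` are (x, y) pixel coordinates; ``chrom_edges``
    are two axis positions in μm from ``pole_a`` bounding the chromosome
    band; ``pixel_size`` is μm/px.
    """

    pole_a: tuple
    pole_b: tuple
    chrom_edges: tuple
    pixel_size: float

    def __post_init__(self) -> None:
        if np.allclose(self.pole_a, self.pole_b):
            raise ValueError("pole_a and pole_b must be distinct")
        lo, hi = sorted(self.chrom_edges)
        length = self.length_um
        if not (0 < lo and hi < length):
            raise ValueError(
                f"chrom_edges {self.chrom_edges} must lie strictly between the poles (0, {length:.3f})"
            )
        self.chrom_edges = (lo, hi)

    @property
    def length_um(self) -> float:
        return float(np.hypot(self.pole_b[0] - self.pole_a[0],
                              self.pole_b[1] - self.pole_a[1]) * self.pixel_size)

    @property
    def unit(self) -> np.ndarray:
        v = np.array([self.pole_b[0] - self.pole_a[0], self.pole_b[1] - self.pole_a[1]], float)
        return v / np.linalg.norm(v)

    def axial_position_um(self, x_px, y_px) -> np.ndarray:
        """Project pixel coordinates onto the axis (μm from pole_a)."""
        u = self.unit
        dx = np.asarray(x_px, float) - self.pole_a[0]
        dy = np.asarray(y_px, float) - self.pole_a[1]
        return (dx * u[0] + dy * u[1]) * self.pixel_size


@dataclass
class ZoneSet:
    """Six-zone spindle partition (labels 1..6 per :data:`ZONE_NAMES`)."""

    labels: np.ndarray
    zone_names: dict = field(default_factory=lambda: dict(ZONE_NAMES))
    bleached_side: str = "a"  # which pole's half was bleached: 'a' or 'b'

    def mask(self, name: str) -> np.ndarray:
        for lab, nm in self.zone_names.items():
            if nm == name:
                return self.labels == lab
        raise KeyError(name)

    def rois(self) -> dict:
        """Named ROI masks: whole spindle, both halves, and the six zones."""
        spindle = self.labels > 0
        bleached = np.isin(self.labels, [1, 2, 3])
        out = {
            "whole_spindle": spindle,
            "bleached_half": bleached,
            "unbleached_half": spindle & ~bleached,
        }
        for lab, nm in self.zone_names.items():
            out[nm] = self.labels == lab
        return out


@dataclass
class RoiTrace:
    """Per-frame mean intensity of one ROI, with the background trace."""

    roi_name: str
    times: np.ndarray
    mean_intensity: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.mean_intensity = np.asarray(self.mean_intensity, float)
        self.background = np.asarray(self.background, float)
        if not (len(self.times) == len(self.mean_intensity) == len(self.background)):
            raise ValueError("times, mean_intensity and background must have equal length")
        if np.any(self.background < 0):
            raise ValueError("background must be >= 0")

    def background_subtracted(self) -> np.ndarray:
        return self.mean_intensity - self.background


@dataclass
class LineProfile:
    """Pole-to-pole intensity profile averaged across a band of fixed width."""

    positions: np.ndarray  # μm from pole_a
    intensities: np.ndarray
    width_used: float  # μm
    clipped: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.intensities = np.asarray(self.intensities, float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("profile positions must be monotone increasing")


# ---------------------------------------------------------------------------
# registration


def _correlation_peak(ref: np.ndarray, mov: np.ndarray) -> float:
    """Peak of the normalized cross-power spectrum (translation-invariant score)."""
    f = np.fft.fft2(ref) * np.conj(np.fft.fft2(mov))
    denom = np.abs(f)
    denom[denom == 0] = 1.0
    return float(np.abs(np.fft.ifft2(f / denom)).max())


def _estimate_rigid(ref: np.ndarray, mov: np.ndarray,
                    max_rotation_deg: float = 15.0) -> tuple[float, float, float]:
    """Estimate (angle_deg, dy, dx) aligning ``mov`` to ``ref``.

    Rotation by coarse grid + bounded refinement of the phase-correlation
    peak; translation by upsampled phase cross-correlation.
    """
    angles = np.arange(-max_rotation_deg, max_rotation_deg + 0.5, 1.0)
    scores = [_correlation_peak(ref, transform.rotate(mov, -a, preserve_range=True))
              for a in angles]
    a0 = angles[int(np.argmax(scores))]
    res = optimize.minimize_scalar(
        lambda a: -_correlation_peak(ref, transform.rotate(mov, -a, preserve_range=True)),
        bounds=(a0 - 1.5, a0 + 1.5), method="bounded",
        options={"xatol": 1e-3},
    )
    angle = float(res.x)
    rotated = transform.rotate(mov, -angle, preserve_range=True)
    shift, _, _ = phase_cross_correlation(ref, rotated, upsample_factor=50,
                                          normalization=None)
    return angle, float(shift[0]), float(shift[1])


def _apply_rigid(img: np.ndarray, angle: float, dy: float, dx: float) -> np.ndarray:
    out = transform.rotate(img, -angle, preserve_range=True, order=1)
    return ndimage.shift(out, (dy, dx), order=1, mode="constant", cval=0.0)


def register_stack(stack: ImageStack, ref_channel: str = "reference",
                   max_rotation_deg: float = 15.0) -> tuple[ImageStack, list]:
    """Rigid-register every frame to frame 0 using the reference channel.

    Returns the registered stack and a list of per-frame
    ``(angle_deg, dy_px, dx_px)`` transforms (frame 0 is the identity).
    Both channels receive the frame's transform.
    """
    if stack.n_frames < 2:
        raise ValueError("registration needs at least 2 frames")
    ref_stack = stack.channel(ref_channel)
    if np.ptp(ref_stack[0]) == 0:
        raise ValueError("reference channel is constant; cannot register")
    target = ref_stack[0]
    out = stack.pixels.copy()
    transforms: list = [(0.0, 0.0, 0.0)]
    for t in range(1, stack.n_frames):
        angle, dy, dx = _estimate_rigid(target, ref_stack[t], max_rotation_deg)
        transforms.append((angle, dy, dx))
        for c in range(stack.pixels.shape[1]):
            out[t, c] = _apply_rigid(stack.pixels[t, c], angle, dy, dx)
    registered = ImageStack(out, stack.pixel_size, stack.timestamps.copy(),
                            dict(stack.channel_roles))
    return registered, transforms


# ---------------------------------------------------------------------------
# segmentation & geometry


def segment_spindle(frame: np.ndarray, smooth_sigma: float = 2.0) -> np.ndarray:
    """Binary spindle mask: Otsu threshold on a smoothed copy, largest
    connected component, holes filled."""
    frame = np.asarray(frame, float)
    if np.ptp(frame) == 0:
        raise ValueError("cannot segment a constant image")
    smoothed = ndimage.gaussian_filter(frame, smooth_sigma)
    thr = filters.threshold_otsu(smoothed)
    mask = smoothed > thr
    if not mask.any():
        raise ValueError("empty mask after thresholding")
    if mask.mean() > 0.5:
        raise ValueError(
            "foreground covers most of the image; inverted contrast or no spindle present"
        )
    labeled = measure.label(mask)
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    mask = labeled == int(np.argmax(sizes))
    return ndimage.binary_fill_holes(mask)


def _principal_axis(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Centroid, unit direction (x, y) and major/minor axis ratio of a mask."""
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    vals, vecs = np.linalg.eigh(cov)
    ratio = np.sqrt(vals[1] / max(vals[0], 1e-12))
    return centroid, vecs[:, 1], float(ratio)


def find_axis(mask: np.ndarray, reference: np.ndarray | None = None,
              pixel_size: float = 1.0, chrom_edges: tuple | None = None,
              min_axis_ratio: float = 1.2) -> SpindleAxis:
    """Locate the poles and the chromosome band.

    Poles are the extremal mask points along the mask's principal axis
    (``pole_a`` at the lower image-x end).  The chromosome band is the
    half-depth extent of the central trough of the reference channel's
    axial profile, unless ``chrom_edges`` (μm from pole_a) is supplied.
    """
    if not mask.any():
        raise ValueError("mask is empty")
    centroid, u, ratio = _principal_axis(mask)
    if ratio < min_axis_ratio:
        raise ValueError(f"mask too round for an axis (ratio {ratio:.2f} < {min_axis_ratio})")
    ys, xs = np.nonzero(mask)
    s = (xs - centroid[0]) * u[0] + (ys - centroid[1]) * u[1]
    # poles = extremal mask points on (within 2 px of) the principal-axis
    # line, averaged over the extreme 1-px slice: robust to blunt tips
    d_perp = -(xs - centroid[0]) * u[1] + (ys - centroid[1]) * u[0]
    near = np.abs(d_perp) <= 2.0
    sn = s[near]
    lo = near.copy()
    lo[near] = sn <= sn.min() + 1.0
    hi = near.copy()
    hi[near] = sn >= sn.max() - 1.0
    p_lo = (float(xs[lo].mean()), float(ys[lo].mean()))
    p_hi = (float(xs[hi].mean()), float(ys[hi].mean()))
    pole_a, pole_b = sorted([p_lo, p_hi])  # pole_a at lower x (ties: lower y)

    if chrom_edges is None:
        if reference is None:
            raise ValueError("need a reference image or explicit chrom_edges")
        chrom_edges = _chromosome_trough(mask, reference, pole_a, pole_b, pixel_size)
    return SpindleAxis(pole_a, pole_b, tuple(chrom_edges), pixel_size)


def _chromosome_trough(mask, reference, pole_a, pole_b, pixel_size) -> tuple:
    """Half-depth edges of the central minimum of the axial reference profile."""
    axis = SpindleAxis(pole_a, pole_b, (1e-6, 2e-6), pixel_size)  # edges placeholder
    ys, xs = np.nonzero(mask)
    s = axis.axial_position_um(xs, ys)
    length = axis.length_um
    n_bins = max(int(round(length / pixel_size)), 8)
    bins = np.linspace(0, length, n_bins + 1)
    idx = np.clip(np.digitize(s, bins) - 1, 0, n_bins - 1)
    vals = np.asarray(reference, float)[ys, xs]
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    profile = sums / np.maximum(counts, 1)
    profile = ndimage.gaussian_filter1d(profile, 2.0)
    centers = 0.5 * (bins[:-1] + bins[1:])

    window = (centers > 0.3 * length) & (centers < 0.7 * length)
    wi = np.flatnonzero(window)
    trough = wi[int(np.argmin(profile[wi]))]
    left_base = profile[wi[0]:trough].max() if trough > wi[0] else profile[trough]
    right_base = profile[trough + 1:wi[-1] + 1].max() if trough < wi[-1] else profile[trough]
    level = profile[trough] + 0.5 * (min(left_base, right_base) - profile[trough])
    if level <= profile[trough]:
        raise ValueError("no chromosome-band trough found in the reference profile")
    lo = trough
    while lo > 0 and profile[lo] < level:
        lo -= 1
    hi = trough
    while hi < n_bins - 1 and profile[hi] < level:
        hi += 1
    return (float(centers[lo]), float(centers[hi]))


def compartmentalize(mask: np.ndarray, axis: SpindleAxis,
                     bleach_mask: np.ndarray) -> ZoneSet:
    """Split the spindle into six zones.

    Each half (split at the axis midpoint) is divided into three
    equal-length axial bins labelled pole / intermediate / chromosome
    from the pole inward.  The half containing the bleach geometry is
    the bleached half.
    """
    ys, xs = np.nonzero(mask)
    s = np.clip(axis.axial_position_um(xs, ys), 0, axis.length_um)
    length = axis.length_um

    in_bleach = bleach_mask & mask
    n_in = int(in_bleach.sum())
    if n_in == 0:
        raise ValueError("bleach geometry does not overlap the spindle mask")
    bys, bxs = np.nonzero(in_bleach)
    bs = axis.axial_position_um(bxs, bys)
    frac_a = float(np.mean(bs < length / 2))
    if min(frac_a, 1 - frac_a) > 0.4:
        raise ValueError(
            f"bleach geometry straddles both halves ({frac_a:.0%} / {1 - frac_a:.0%})"
        )
    bleached_side = "a" if frac_a >= 0.5 else "b"

    # zone index 0/1/2 = pole/intermediate/chromosome within each half
    third = length / 6.0
    half_a = s < length / 2
    dist_from_pole = np.where(half_a, s, length - s)
    zone = np.minimum((dist_from_pole / third).astype(int), 2)
    on_bleached = half_a if bleached_side == "a" else ~half_a
    # labels: bleached 1,2,3 pole->chromosome; unbleached 6,5,4 pole->chromosome
    lab = np.where(on_bleached, zone + 1, 6 - zone)
    labels = np.zeros(mask.shape, dtype=np.int8)
    labels[ys, xs] = lab
    return ZoneSet(labels, bleached_side=bleached_side)


# ---------------------------------------------------------------------------
# measurement


def extract_zone_traces(stack: ImageStack, rois: dict,
                        background_roi: np.ndarray | None = None) -> list:
    """Mean reporter intensity per frame for each named ROI mask.

    No normalization is applied.  The background trace is the mean over
    ``background_roi`` if given, else the per-frame 1st-percentile pixel
    value of the reporter channel.
    """
    reporter = stack.channel("reporter")
    if background_roi is not None:
        if not background_roi.any():
            raise ValueError("background ROI is empty")
        background = reporter[:, background_roi].mean(axis=1)
    else:
        background = np.percentile(reporter.reshape(stack.n_frames, -1), 1, axis=1)
    traces = []
    for name, roi in rois.items():
        if not roi.any():
            raise ValueError(f"ROI {name!r} is empty")
        means = reporter[:, roi].mean(axis=1)
        traces.append(RoiTrace(name, stack.timestamps, means, background))
    return traces


def extract_profile(frame: np.ndarray, axis: SpindleAxis,
                    width_um: float = 2.0, step_px: float = 1.0) -> LineProfile:
    """Pole-to-pole intensity profile averaged across a band of physical width.

    Samples at ``step_px`` (≤ 1 px) steps from pole_a to pole_b, averaging
    across perpendicular offsets spanning ``width_um``.  Samples falling
    outside the image are dropped and the profile flagged ``clipped``.
    """
    if width_um <= 0:
        raise ValueError("width_um must be > 0")
    length_px = axis.length_um / axis.pixel_size
    n_s = int(np.ceil(length_px / step_px)) + 1
    s_px = np.linspace(0, length_px, n_s)
    half_w_px = 0.5 * width_um / axis.pixel_size
    n_o = max(int(np.ceil(2 * half_w_px)) + 1, 1)
    offsets = np.linspace(-half_w_px, half_w_px, n_o) if n_o > 1 else np.array([0.0])
    u = axis.unit
    n_vec = np.array([-u[1], u[0]])
    xs = axis.pole_a[0] + s_px[None, :] * u[0] + offsets[:, None] * n_vec[0]
    ys = axis.pole_a[1] + s_px[None, :] * u[1] + offsets[:, None] * n_vec[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = ndimage.map_coordinates(np.asarray(frame, float), [ys, xs],
                                       order=1, mode="constant", cval=np.nan)
        clipped = bool(np.isnan(vals).any())
        intensities = np.nanmean(vals, axis=0)
    if np.isnan(intensities).any():
        raise ValueError("profile band lies entirely outside the image at some positions")
    if clipped:
        warnings.warn("profile band clipped at the image boundary", stacklevel=2)
    return LineProfile(s_px * axis.pixel_size, intensities, width_um, clipped)


def extract_profiles(stack: ImageStack, axis: SpindleAxis, role: str = "reporter",
                     width_um: float = 2.0) -> list:
    """Per-frame :func:`extract_profile` on one channel of a stack."""
    return [extract_profile(stack.frame(t, role), axis, width_um)
            for t in range(stack.n_frames)]


def measure_spindle_length(axis: SpindleAxis) -> float:
    """Pole-to-pole distance in μm."""
    return axis.length_um


def spindle_bound_ratio(reporter_frame: np.ndarray, reference_frame: np.ndarray,
                        mask: np.ndarray) -> float:
    """Mean reporter / mean reference over the spindle mask (both
    background-subtracted upstream)."""
    if not mask.any():
        raise ValueError("mask is empty")
    ref_mean = float(np.asarray(reference_frame, float)[mask].mean())
    if ref_mean <= 0:
        raise ValueError(f"reference mean over mask must be > 0, got {ref_mean}")
    return float(np.asarray(reporter_frame, float)[mask].mean()) / ref_mean
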