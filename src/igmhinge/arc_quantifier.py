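"""Angular motion-range quantification from density-map cross-sections.

The measurement pipeline mirrors how flexible-arm "clouds" in a cryo-EM map
are quantified by hand in an image viewer, made reproducible:

1. smooth the map with an isotropic 3-D Gaussian (default sigma = 3 px);
2. cut six consecutive cross-sections around the mid-plane of the cloud,
   separately for the in-plane and the out-of-plane measurement axis;
3. on each section, sample grey values along an arc of fixed radius centered
   on the pivot (the hinge), as a function of the angle;
4. estimate background mean and standard deviation away from the cloud and
   apply the signal-to-background criterion
   ``(grey - BKG_mean) / BKG_sd >= 2``: walking outward from the central
   peak, the angle at which the ratio first falls to the threshold is the
   boundary of the motion range;
5. optionally refine each boundary to the center of the outermost
   orientation lobe by a log-quadratic (Gaussian) fit to the outer falloff,
   which removes the outward bias the raw crossing acquires from the finite
   blur of the map when the background is nearly noise-free.

Angles are degrees, radii are pixels unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .errors import (
    ConfigError,
    DegenerateBackgroundError,
    DegenerateFitError,
    GeometryError,
    NoSignalError,
    SamplingError,
    WindowTooSmallError,
)
from .density_sim import DensityMap
from .model_geometry import PivotFrame

DEFAULT_SMOOTH_SIGMA_PX = 3.0
DEFAULT_SNR_THRESHOLD = 2.0


# ---------------------------------------------------------------------------
# smoothing and sections
# ---------------------------------------------------------------------------


def smooth_map(density: DensityMap, sigma_px: float = DEFAULT_SMOOTH_SIGMA_PX
               ) -> DensityMap:
    """Isotropic 3-D Gaussian filter; ``sigma_px = 0`` returns a copy."""
    if sigma_px < 0:
        raise ValueError("smoothing sigma must be non-negative")
    out = density.copy()
    if sigma_px > 0:
        out.values = ndimage.gaussian_filter(density.values, sigma_px)
    return out


@dataclass(frozen=True)
class PlaneDef:
    """An oriented section plane: point + orthonormal in-plane basis (e1, e2)."""

    point: tuple
    e1: tuple
    e2: tuple

    def basis(self):
        p = np.asarray(self.point, float)
        e1 = np.asarray(self.e1, float)
        e2 = np.asarray(self.e2, float)
        e1 = e1 / np.linalg.norm(e1)
        e2 = e2 - (e2 @ e1) * e1
        e2 = e2 / np.linalg.norm(e2)
        return p, e1, e2

    @property
    def normal(self):
        _, e1, e2 = self.basis()
        return np.cross(e1, e2)


@dataclass
class CrossSection:
    """A 2-D grey-value image sampled on a plane through a map.

    ``image[iu, iv]`` sits at ``point + (iu - cu) * px * e1 + (iv - cv) * px
    * e2`` where ``(cu, cv) = center_px``.
    """

    image: np.ndarray
    pixel_size: float
    plane: PlaneDef
    center_px: tuple
    provenance: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, float)
        if self.pixel_size <= 0:
            raise ConfigError("pixel size must be positive")


def extract_cross_section(density: DensityMap, plane: PlaneDef,
                          half_extent: float | None = None,
                          pixel_size: float | None = None,
                          provenance: str = "") -> CrossSection:
    """Trilinear section of a map on a 2-D lattice in the given plane.

    The lattice is centered on ``plane.point`` at the map's voxel pitch by
    default.  Points outside the grid read as 0; the plane must intersect
    the grid.
    """
    px = density.voxel_size if pixel_size is None else float(pixel_size)
    p, e1, e2 = plane.basis()
    if half_extent is None:
        half_extent = 0.5 * float(max(density.shape)) * density.voxel_size
    n = int(np.floor(half_extent / px))
    u = np.arange(-n, n + 1) * px
    pts = (p[None, None, :] + u[:, None, None] * e1[None, None, :]
           + u[None, :, None] * e2[None, None, :])
    vox = density.world_to_voxel(pts.reshape(-1, 3))
    inside = ((vox >= 0) & (vox <= np.asarray(density.shape) - 1)).all(axis=1)
    if not inside.any():
        raise GeometryError("section plane does not intersect the map grid")
    img = ndimage.map_coordinates(density.values, vox.T, order=1,
                                  mode="constant", cval=0.0)
    return CrossSection(img.reshape(2 * n + 1, 2 * n + 1), px, plane,
                        (float(n), float(n)), provenance)


def to_8bit(section: CrossSection) -> CrossSection:
    """Linear min-max rescale to the integer range 0-255 (round half up).

    A constant image maps to all zeros.
    """
    img = section.image
    lo = float(img.min())
    hi = float(img.max())
    if hi <= lo:
        out = np.zeros_like(img)
    else:
        out = np.floor((img - lo) / (hi - lo) * 255.0 + 0.5)
    return CrossSection(out, section.pixel_size, section.plane,
                        section.center_px, section.provenance + "|8bit")


# ---------------------------------------------------------------------------
# arcs and profiles
# ---------------------------------------------------------------------------


@dataclass
class ArcFit:
    """Least-squares circle through arc points (pixel units)."""

    center: tuple
    radius: float
    rms_residual: float


def fit_arc_circle(points: np.ndarray) -> ArcFit:
    """Fit a circle to >= 3 non-collinear 2-D points.

    Algebraic (Kasa) fit followed by geometric refinement of the radial
    residuals.
    """
    pts = np.asarray(points, float).reshape(-1, 2)
    if pts.shape[0] < 3:
        raise DegenerateFitError("need at least 3 points")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[-1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateFitError("points are collinear")
    a = np.column_stack([2 * pts, np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    (cx, cy, c), *_ = np.linalg.lstsq(a, b, rcond=None)
    r0 = float(np.sqrt(c + cx ** 2 + cy ** 2))

    def resid(q):
        return np.hypot(pts[:, 0] - q[0], pts[:, 1] - q[1]) - q[2]

    sol = optimize.least_squares(resid, x0=[cx, cy, r0])
    cx, cy, r = sol.x
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    if r <= 0:
        raise DegenerateFitError("fitted radius is non-positive")
    return ArcFit((float(cx), float(cy)), float(r), rms)


def detect_arc_points(section: CrossSection, center_px,
                      radius_window: tuple, angles_deg: np.ndarray
                      ) -> np.ndarray:
    """Ridge points of an arc: per angle, the radius of maximal grey value.

    Scans radially inside ``radius_window = (r_min, r_max)`` along each given
    angle and returns the (u, v) pixel coordinates of the maxima, suitable
    for :func:`fit_arc_circle`.
    """
    cu, cv = center_px
    r = np.arange(radius_window[0], radius_window[1] + 1e-9, 0.5)
    out = []
    for ang in np.radians(np.asarray(angles_deg, float)):
        uu = cu + r * np.cos(ang)
        vv = cv + r * np.sin(ang)
        vals = ndimage.map_coordinates(section.image, np.vstack([uu, vv]),
                                       order=1, mode="constant", cval=0.0)
        k = int(np.argmax(vals))
        out.append((uu[k], vv[k]))
    return np.asarray(out)


@dataclass
class AngularProfile:
    """Grey values along an arc of fixed radius versus angle (degrees)."""

    angles: np.ndarray
    values: np.ndarray
    radius_label: str = ""
    radius_px: float = 0.0

    def __post_init__(self):
        self.angles = np.asarray(self.angles, float)
        self.values = np.asarray(self.values, float)
        if self.angles.size != self.values.size:
            raise ConfigError("one grey value per angle required")
        if np.any(np.diff(self.angles) <= 0):
            raise ConfigError("angles must be strictly increasing")

    def value_at(self, angle: float) -> float:
        return float(np.interp(angle, self.angles, self.values))


def angular_profile(section: CrossSection, center_px, radius_px: float,
                    window_deg: float, step_deg: float = 1.0,
                    radius_label: str = "") -> AngularProfile:
    """Bilinear grey-value samples along the arc of given radius.

    Angle 0 is the section's ``e1`` axis (the frame's zero axis projected
    into the section); positive angles turn toward ``e2``.
    """
    cu, cv = center_px
    n_u, n_v = section.image.shape
    angles = np.arange(-window_deg, window_deg + step_deg / 2, step_deg)
    rad = np.radians(angles)
    uu = cu + radius_px * np.cos(rad)
    vv = cv + radius_px * np.sin(rad)
    if (uu.min() < 0 or vv.min() < 0 or uu.max() > n_u - 1 or vv.max() > n_v - 1):
        raise GeometryError("sampling ring exits the section image")
    vals = ndimage.map_coordinates(section.image, np.vstack([uu, vv]),
                                   order=1, mode="constant", cval=0.0)
    return AngularProfile(angles, vals, radius_label, radius_px)


# ---------------------------------------------------------------------------
# background and boundaries
# ---------------------------------------------------------------------------


@dataclass
class BackgroundStats:
    """Background grey-value statistics (sample mean / sd, n-1 denominator)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise SamplingError("background needs at least 2 pixels")
        if self.sd < 0:
            raise SamplingError("negative standard deviation")


def background_stats(section: CrossSection,
                     exclusion_mask: np.ndarray | None = None) -> BackgroundStats:
    """Mean and sd of pixels outside the exclusion mask."""
    img = section.image
    if exclusion_mask is None:
        vals = img.ravel()
    else:
        mask = np.asarray(exclusion_mask, bool)
        if mask.shape != img.shape:
            raise ConfigError("exclusion mask shape mismatch")
        vals = img[~mask]
    if vals.size < 2:
        raise SamplingError(f"only {vals.size} background pixels after exclusion")
    return BackgroundStats(float(vals.mean()), float(vals.std(ddof=1)),
                           int(vals.size))


def radial_exclusion_mask(section: CrossSection, center_px,
                          radius_px: float) -> np.ndarray:
    """Mask of pixels within ``radius_px`` of the center (True = excluded)."""
    cu, cv = center_px
    u, v = np.ogrid[:section.image.shape[0], :section.image.shape[1]]
    return (u - cu) ** 2 + (v - cv) ** 2 <= radius_px ** 2


def snr_ratio(grey: float, bkg: BackgroundStats) -> float:
    """Signal-to-background ratio ``(grey - mean) / sd``."""
    if bkg.sd <= 0:
        raise DegenerateBackgroundError("background sd is zero")
    return (float(grey) - bkg.mean) / bkg.sd


@dataclass
class Boundary:
    """One signed motion-range boundary on one section."""

    angle: float
    raw_crossing: float
    sign: int
    flag: str = ""


def motion_boundary(profile: AngularProfile, bkg: BackgroundStats,
                    threshold: float = DEFAULT_SNR_THRESHOLD,
                    sd_floor: float = 0.0) -> tuple:
    """Boundary angles where the SNR ratio first falls to the threshold.

    Walks outward from the central peak in each sign direction and linearly
    interpolates the angle at which ``(grey - BKG_mean)/BKG_sd`` crosses the
    threshold.  ``sd_floor`` substitutes for the background sd when the
    background is (nearly) noise-free.  Returns ``(negative, positive)``
    boundary angles.
    """
    sd = max(bkg.sd, sd_floor)
    if sd <= 0:
        raise DegenerateBackgroundError("background sd is zero (no sd floor)")
    level = bkg.mean + threshold * sd
    angles = profile.angles
    vals = profile.values
    i0 = int(np.argmin(np.abs(angles)))
    if vals[i0] < level:
        raise NoSignalError(
            f"central profile value {vals[i0]:.4g} below threshold {level:.4g}")

    def walk(direction: int) -> float:
        i = i0
        while True:
            j = i + direction
            if j < 0 or j >= angles.size:
                raise WindowTooSmallError(
                    "profile never falls below threshold inside the window",
                    edge_angle=float(angles[i]))
            if vals[j] < level:
                # linear interpolation between samples i and j
                frac = (vals[i] - level) / (vals[i] - vals[j])
                return float(angles[i] + frac * (angles[j] - angles[i]))
            i = j

    return walk(-1), walk(+1)


def refine_boundary_to_lobe(profile: AngularProfile, bkg: BackgroundStats,
                            crossing: float, sign: int,
                            band: tuple = (0.15, 0.9)) -> tuple:
    """Refine a threshold crossing to the center of the edge orientation lobe.

    Fits ``log(grey - BKG_mean)`` as a quadratic in angle over the outer
    falloff (samples between ``band`` fractions of the local lobe peak) and
    returns the parabola vertex.  Falls back to the raw crossing when the fit
    is not credible (too few samples, wrong curvature, vertex outside the
    falloff).  Returns ``(angle, flag)``.
    """
    angles = profile.angles
    vals = profile.values - bkg.mean
    # local lobe peak: first local maximum walking inward from the crossing
    idx = np.argsort(np.abs(angles - crossing))[0]
    i = int(idx)
    inward = -sign
    while 0 < i + inward < angles.size - 1 and vals[i + inward] >= vals[i]:
        i += inward
    # continue to the top of this lobe
    while 0 < i + inward < angles.size - 1 and vals[i + inward] > vals[i]:
        i += inward
    peak_val = vals[i]
    if peak_val <= 0:
        return crossing, "no-lobe"
    lo, hi = band
    sel = []
    j = i
    while 0 <= j < angles.size and (angles[j] - crossing) * sign <= 0:
        if lo * peak_val <= vals[j] <= hi * peak_val:
            sel.append(j)
        j += sign
    sel = [k for k in sel if vals[k] > 0]
    if len(sel) < 4:
        return crossing, "fit-fallback"
    x = angles[sel]
    y = np.log(vals[sel])
    c2, c1, _ = np.polyfit(x, y, 2)
    if c2 >= -1e-12:
        return crossing, "fit-fallback"
    vertex = -c1 / (2.0 * c2)
    lobe_sigma = float(np.sqrt(-1.0 / (2.0 * c2)))
    span = abs(crossing - angles[i]) + 2.0 * abs(angles[1] - angles[0])
    if not (min(angles[i], crossing) - span <= vertex
            <= max(angles[i], crossing) + span):
        return crossing, "fit-fallback"
    return float(vertex), f"lobe-fit(sigma={lobe_sigma:.2f})"


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class SubunitConfig:
    """Parameters of one subunit's motion-range measurement.

    Radii are in Angstrom (converted to pixels per section); the boundary is
    measured on ``boundary_arc`` (``"outer"`` = Fab variable domain,
    ``"inner"`` = Fab constant domain, ``"cmu2"``).
    """

    label: str = "subunit"
    radii: dict = field(default_factory=dict)   # label -> radius in Angstrom
    boundary_arc: str = "outer"
    window_deg: float = 110.0
    step_deg: float = 1.0
    n_sections: int = 6
    section_spacing_vox: float = 1.0
    smooth_sigma_px: float = DEFAULT_SMOOTH_SIGMA_PX
    use_8bit: bool = False
    threshold: float = DEFAULT_SNR_THRESHOLD
    background_radius_factor: float = 1.5
    refine: str = "lobe"          # "lobe" or "crossing"
    fit_arc_center: bool = False
    axes: tuple = ("in-plane", "out-of-plane")

    def __post_init__(self):
        if self.boundary_arc not in self.radii and self.radii:
            raise ConfigError(
                f"boundary arc {self.boundary_arc!r} not among radii "
                f"{sorted(self.radii)}")


@dataclass
class MotionRange:
    """Per-axis motion-range result with per-section replicates."""

    axis: str
    subunit: str
    boundaries_neg: list
    boundaries_pos: list
    raw_neg: list
    raw_pos: list
    flags: list

    @property
    def boundary_negative(self) -> float:
        return float(np.mean(self.boundaries_neg))

    @property
    def boundary_positive(self) -> float:
        return float(np.mean(self.boundaries_pos))

    @property
    def half_range(self) -> float:
        """Mean absolute boundary over both signs and all sections."""
        return float(np.mean(np.abs(np.concatenate(
            [self.boundaries_neg, self.boundaries_pos]))))


def _section_planes(frame: PivotFrame, axis: str, n_sections: int,
                    spacing: float):
    """Oriented planes of the 6 consecutive sections for one axis.

    In-plane sections are parallel to the platform (normal = plane normal);
    the out-of-plane sections contain the platform normal and the zero axis.
    In both, the profile's angle-0 direction is the frame's in-plane zero
    axis and the positive angle direction matches the frame's sign
    convention.
    """
    a0 = frame.in_plane_zero
    n = frame.plane_normal * frame.beta_sign
    y0 = frame.in_plane_ortho
    if axis == "in-plane":
        e1, e2, stack = a0, frame.in_plane_ortho, frame.plane_normal
    elif axis == "out-of-plane":
        e1, e2, stack = a0, n, y0
    else:
        raise ConfigError(f"unknown axis {axis!r}")
    offsets = (np.arange(n_sections) - (n_sections - 1) / 2.0) * spacing
    for k, off in enumerate(offsets):
        point = frame.pivot + off * stack
        yield k, PlaneDef(tuple(point), tuple(e1), tuple(e2))


def measure_section(section: CrossSection, cfg: SubunitConfig,
                    center_px=None) -> dict:
    """Boundaries of a single section: background, profiles, crossings."""
    if cfg.use_8bit:
        section = to_8bit(section)
    center = section.center_px if center_px is None else center_px
    px = section.pixel_size
    radii_px = {k: v / px for k, v in cfg.radii.items()}
    r_out = max(radii_px.values())
    if cfg.fit_arc_center:
        angles = np.linspace(-40, 40, 17)
        pts = detect_arc_points(section, center, (0.7 * r_out, 1.2 * r_out),
                                angles)
        try:
            center = fit_arc_circle(pts).center
        except DegenerateFitError:
            pass
    bkg_mask = radial_exclusion_mask(section, center,
                                     cfg.background_radius_factor * r_out)
    bkg = background_stats(section, bkg_mask)
    profiles = {k: angular_profile(section, center, r, cfg.window_deg,
                                   cfg.step_deg, radius_label=k)
                for k, r in radii_px.items()}
    prof = profiles[cfg.boundary_arc]
    peak_contrast = float(prof.values.max()) - bkg.mean
    sd_floor = 1e-3 * max(peak_contrast, 0.0)
    if cfg.use_8bit:
        sd_floor = max(sd_floor, 0.5)  # quantization floor: half a grey level
    neg, pos = motion_boundary(prof, bkg, cfg.threshold, sd_floor=sd_floor)
    result = {"background": bkg, "profiles": profiles, "center_px": center,
              "raw": (neg, pos)}
    if cfg.refine == "lobe":
        rn, fn = refine_boundary_to_lobe(prof, bkg, neg, -1)
        rp, fp = refine_boundary_to_lobe(prof, bkg, pos, +1)
        result["boundaries"] = (rn, rp)
        result["flags"] = (fn, fp)
    else:
        result["boundaries"] = (neg, pos)
        result["flags"] = ("", "")
    return result


def motion_range(density: DensityMap, frame: PivotFrame,
                 cfg: SubunitConfig) -> dict:
    """Full pipeline: smooth, section, profile, threshold -> per-axis ranges.

    Returns a dict mapping axis name to :class:`MotionRange`.
    """
    smoothed = smooth_map(density, cfg.smooth_sigma_px)
    spacing = cfg.section_spacing_vox * density.voxel_size
    half_extent = None
    results = {}
    for axis in cfg.axes:
        b_neg, b_pos, r_neg, r_pos, flags = [], [], [], [], []
        for k, plane in _section_planes(frame, axis, cfg.n_sections, spacing):
            try:
                section = extract_cross_section(smoothed, plane, half_extent,
                                                provenance=f"{axis}#{k}")
                res = measure_section(section, cfg)
            except (NoSignalError, WindowTooSmallError, GeometryError,
                    SamplingError) as exc:
                raise type(exc)(f"section {k} ({axis}): {exc}") from exc
            b_neg.append(res["boundaries"][0])
            b_pos.append(res["boundaries"][1])
            r_neg.append(res["raw"][0])
            r_pos.append(res["raw"][1])
            flags.append(res["flags"])
        results[axis] = MotionRange(axis, cfg.label, b_neg, b_pos,
                                    r_neg, r_pos, flags)
    return results


def motion_range_table(ranges: dict):
    """Tidy per-section table (subunit, axis, sign, section, boundary)."""
    import pandas as pd

    rows = []
    for axis, mr in ranges.items():
        for sign, values in (("-", mr.boundaries_neg), ("+", mr.boundaries_pos)):
            for k, b in enumerate(values):
                rows.append({"subunit": mr.subunit, "axis": axis, "sign": sign,
                             "section": k, "boundary_deg": b})
    return pd.DataFrame(rows)


def motion_range_summary(ranges: dict) -> dict:
    """JSON-ready summary of per-axis boundaries."""
    return {axis: {"negative_deg": mr.boundary_negative,
                   "positive_deg": mr.boundary_positive,
                   "half_range_deg": mr.half_range,
                   "per_section_negative": list(map(float, mr.boundaries_neg)),
                   "per_section_positive": list(map(float, mr.boundaries_pos))}
            for axis, mr in ranges.items()}
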