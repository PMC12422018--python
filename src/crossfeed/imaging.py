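"""Quantification of two-channel range-expansion colony images.

A colony grown from a drop of a two-strain co-culture expands radially and
develops angular sectors of the two fluorescently labelled strains.  The
analysis follows a fixed sequence:

1. maximum-intensity projection of each channel's z-stack,
2. Otsu thresholding of both channels and union of the foregrounds to
   segment the colony,
3. second-moment ellipse fit of the largest connected component,
4. mapping of the slightly elliptical colony onto an equivalent circle of
   radius ``rho_0 = (a + b)/2`` (rotation by the major-axis angle, then
   anisotropic scaling),
5. sampling of both channels along concentric ellipses in the 87.5-95%
   fractional-radius band, uniformly in arc length with a step of one pixel,
6. strain frequency as the intensity ratio ``f_yellow = F_Y / (F_Y + F_B)``
   summed over the band, and sector width as the arc-length lag at which the
   ellipse-averaged circular autocorrelation of a channel first drops below
   a threshold (default 0.2).

All outputs are in micrometres.  The inoculum radius ``rho_c`` (default
1.89e3 um, set by the deposited droplet volume) defines the growth length
``l_growth = rho_0 - rho_c``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.special import ellipeinc
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "ColonyImage",
    "ColonyGeometry",
    "AnnulusProfile",
    "SectorMeasurements",
    "AnalysisConfig",
    "ImageAnalysisError",
    "ColonyNotFoundError",
    "DegenerateHistogramError",
    "NoDecorrelationError",
    "UndefinedFrequencyError",
    "max_project",
    "otsu_threshold",
    "fit_geometry",
    "equivalent_circle_transform",
    "arc_length",
    "extract_annulus",
    "yellow_frequency",
    "sector_width",
    "analyze_colony",
    "detect_outliers",
    "read_colony_tiff",
    "write_colony_tiff",
]


class ImageAnalysisError(RuntimeError):
    """Base class for colony image-analysis failures."""


class ColonyNotFoundError(ImageAnalysisError):
    pass


class DegenerateHistogramError(ImageAnalysisError):
    pass


class NoDecorrelationError(ImageAnalysisError):
    """The averaged autocorrelation never drops below the threshold.

    Expected for near-monoculture patterns, where a channel has no sector
    structure to decorrelate from.
    """


class UndefinedFrequencyError(ImageAnalysisError):
    pass


@dataclass
class ColonyImage:
    """Two-channel z-stack with physical pixel size.

    ``channels`` maps channel name ('yellow' = proline-auxotroph label,
    'blue' = tryptophan-auxotroph label by default) to a ``(z, y, x)`` array.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float

    def __post_init__(self) -> None:
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        if len({s for s in shapes.values()}) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        for ch, arr in self.channels.items():
            if arr.ndim != 3:
                raise ValueError(f"channel {ch} must be a (z, y, x) stack")


@dataclass(frozen=True)
class ColonyGeometry:
    """Fitted colony ellipse and derived equivalent-circle quantities.

    ``center`` is (x, y) in pixel coordinates (x = column, y = row); ``a``,
    ``b`` the semi-major/minor axes in um; ``phi`` the major-axis angle in
    radians measured from the +x axis toward +y; ``rho_0 = (a + b)/2`` the
    equivalent-circle radius; ``l_growth = rho_0 - rho_c``.
    """

    center: tuple[float, float]
    a: float
    b: float
    phi: float
    rho_c: float
    pixel_size: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("need a >= b > 0")

    @property
    def rho_0(self) -> float:
        return 0.5 * (self.a + self.b)

    @property
    def l_growth(self) -> float:
        return self.rho_0 - self.rho_c


@dataclass
class AnnulusProfile:
    """Arc-length-resampled channel signals along concentric ellipses.

    One entry per concentric ellipse at fractional radius ``t`` (scaled copy
    of the fitted ellipse, ``t`` within the analysis band).  ``signals[ch][i]``
    is the closed periodic signal of channel ``ch`` on ellipse ``i``, sampled
    uniformly in arc length with step ``arc_steps[i]`` (um, approximately one
    pixel).
    """

    fractional_radii: np.ndarray
    arc_steps: np.ndarray
    circumferences: np.ndarray
    signals: dict[str, list[np.ndarray]]
    band: tuple[float, float]

    @property
    def n_ellipses(self) -> int:
        return len(self.fractional_radii)


@dataclass(frozen=True)
class SectorMeasurements:
    """Per-colony pattern summary: sector-width lags and strain frequency."""

    sector_width_yellow: float
    sector_width_blue: float
    f_yellow: float
    F_Y: float
    F_B: float
    autocorr_threshold: float
    flags: tuple[str, ...] = ()


@dataclass
class AnalysisConfig:
    """Tunable knobs of the image pipeline (all lengths in um)."""

    pixel_size: float | None = None       # fallback when metadata has none
    rho_c: float = 1.89e3
    band: tuple[float, float] = (0.875, 0.95)
    autocorr_threshold: float = 0.2
    channel_names: tuple[str, str] = ("yellow", "blue")
    use_binary_signal: bool = False       # autocorrelate Otsu-binarized signal
    background_subtract: bool = False     # subtract per-channel median background
    save_artifacts: bool = False
    out_dir: str | None = None


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a ``(z, y, x)`` stack along z."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ImageAnalysisError("need a non-empty (z, y, x) stack")
    return stack.max(axis=0)


def otsu_threshold(plane: np.ndarray) -> float:
    """Otsu's between-class-variance-maximizing intensity threshold.

    Returned as the midpoint between the two classes' facing extremes, so it
    lies strictly between them; the induced partition is ``plane > t``.
    """
    plane = np.asarray(plane)
    if np.all(plane == plane.flat[0]):
        raise DegenerateHistogramError("constant image has no Otsu threshold")
    t = float(threshold_otsu(plane))
    lo = plane[plane <= t]
    hi = plane[plane > t]
    if lo.size and hi.size:
        t = 0.5 * (float(lo.max()) + float(hi.min()))
    return t


def fit_geometry(mask: np.ndarray, pixel_size: float,
                 rho_c: float = 1.89e3) -> ColonyGeometry:
    """Second-moment ellipse of the largest connected foreground component.

    Holes are filled first; satellite blobs are ignored.  The returned angle
    ``phi`` is measured from the +x (column) axis toward +y (row).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ColonyNotFoundError("empty foreground mask")
    filled = ndimage.binary_fill_holes(mask)
    labels = cc_label(filled)
    regions = regionprops(labels)
    region = max(regions, key=lambda r: r.area)
    cy, cx = region.centroid
    a_px = region.axis_major_length / 2.0
    b_px = region.axis_minor_length / 2.0
    # regionprops orientation is the angle of the major axis against the row
    # axis; convert to angle against +x measured toward +y.
    phi = np.pi / 2.0 - region.orientation
    if phi > np.pi / 2.0:
        phi -= np.pi
    if b_px <= 0:
        raise ColonyNotFoundError("degenerate (collinear) colony mask")
    return ColonyGeometry(center=(cx, cy), a=a_px * pixel_size,
                          b=b_px * pixel_size, phi=float(phi),
                          rho_c=rho_c, pixel_size=pixel_size)


def _rotation(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, s], [-s, c]])   # rotation by -phi


def equivalent_circle_transform(points: np.ndarray,
                                geometry: ColonyGeometry) -> np.ndarray:
    """Map centred colony points onto the equivalent circle.

    ``points`` is ``(n, 2)`` in (x, y) um relative to the colony centre.  The
    map is ``M_s @ M_rho``: rotation by ``-phi`` so the major axis aligns
    with x, then scaling by ``(rho_0/a, rho_0/b)``.  The fitted ellipse
    boundary maps to a circle of radius ``rho_0``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rho0 = geometry.rho_0
    m_rho = _rotation(geometry.phi)
    m_s = np.diag([rho0 / geometry.a, rho0 / geometry.b])
    return pts @ (m_s @ m_rho).T


def arc_length(theta: float | np.ndarray, a: float, b: float) -> float | np.ndarray:
    """Arc length of the ellipse from parametric angle 0 to ``theta``.

    ``d_arc = int_0^theta sqrt(a^2 sin^2 v + b^2 cos^2 v) dv``, evaluated via
    the incomplete elliptic integral of the second kind:
    ``b * E(theta | 1 - (a/b)^2)``.
    """
    m = 1.0 - (a / b) ** 2
    out = b * ellipeinc(theta, m)
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return float(out)
    return out


def _ellipse_points(t: float, geometry: ColonyGeometry,
                    n_samples: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Pixel coordinates of ``n_samples`` points uniform in arc length.

    Returns (rows, cols, circumference_um) for the concentric ellipse at
    fractional radius ``t``.
    """
    a_t, b_t = t * geometry.a, t * geometry.b
    circ = arc_length(2.0 * np.pi, a_t, b_t)
    # invert the (monotone) arc-length function on a dense parametric grid
    nu_dense = np.linspace(0.0, 2.0 * np.pi, 8 * n_samples + 1)
    s_dense = arc_length(nu_dense, a_t, b_t)
    s_targets = np.arange(n_samples) * (circ / n_samples)
    nu = np.interp(s_targets, s_dense, nu_dense)
    xy = np.column_stack([a_t * np.cos(nu), b_t * np.sin(nu)])
    rot = _rotation(-geometry.phi)          # rotate by +phi into image frame
    xy_img = xy @ rot.T
    px = geometry.pixel_size
    cols = geometry.center[0] + xy_img[:, 0] / px
    rows = geometry.center[1] + xy_img[:, 1] / px
    return rows, cols, float(circ)


def extract_annulus(planes: dict[str, np.ndarray], geometry: ColonyGeometry,
                    band: tuple[float, float] = (0.875, 0.95),
                    allow_partial: bool = False) -> AnnulusProfile:
    """Sample both channels along concentric ellipses within the band.

    Concentric ellipses are scaled copies of the fitted ellipse at fractional
    radii spanning ``band``, one per pixel of radial step; each is sampled by
    bilinear interpolation at points uniformly spaced in arc length (step of
    about one pixel), yielding closed periodic signals.
    """
    if not (0.0 < band[0] <= band[1] <= 1.0):
        raise ImageAnalysisError("band must lie within (0, 1]")
    px = geometry.pixel_size
    rho0_px = geometry.rho_0 / px
    n_ellipses = max(1, int(round((band[1] - band[0]) * rho0_px)))
    if band[0] == band[1]:
        n_ellipses = 1
    radii = np.linspace(band[0], band[1], n_ellipses)
    shape = next(iter(planes.values())).shape
    signals: dict[str, list[np.ndarray]] = {ch: [] for ch in planes}
    steps, circs = [], []
    for t in radii:
        a_t = t * geometry.a
        circ = arc_length(2.0 * np.pi, a_t, t * geometry.b)
        n_samples = max(8, int(round(circ / px)))
        rows, cols, circ = _ellipse_points(t, geometry, n_samples)
        if not allow_partial and (
                rows.min() < -0.5 or cols.min() < -0.5
                or rows.max() > shape[0] - 0.5 or cols.max() > shape[1] - 0.5):
            raise ImageAnalysisError(
                f"annulus at fractional radius {t:.3f} leaves the image")
        for ch, plane in planes.items():
            vals = ndimage.map_coordinates(np.asarray(plane, dtype=float),
                                           [rows, cols], order=1, mode="nearest")
            signals[ch].append(vals)
        steps.append(circ / n_samples)
        circs.append(circ)
    return AnnulusProfile(fractional_radii=radii, arc_steps=np.array(steps),
                          circumferences=np.array(circs), signals=signals,
                          band=band)


def yellow_frequency(profile: AnnulusProfile,
                     yellow: str = "yellow", blue: str = "blue") -> float:
    """Intensity-weighted strain frequency ``F_Y / (F_Y + F_B)`` in the band."""
    F_Y = float(sum(s.sum() for s in profile.signals[yellow]))
    F_B = float(sum(s.sum() for s in profile.signals[blue]))
    if F_Y + F_B <= 0:
        raise UndefinedFrequencyError("total intensity in the band is zero")
    return F_Y / (F_Y + F_B)


def _circular_acf(x: np.ndarray) -> np.ndarray:
    """Circular autocorrelation of a mean-subtracted, normalized signal."""
    x = x - x.mean()
    var = np.mean(x * x)
    if var <= 0:
        raise ImageAnalysisError("zero-variance signal")
    f = np.fft.rfft(x)
    acf = np.fft.irfft(f * np.conj(f), n=len(x)) / (len(x) * var)
    return acf.real


def sector_width(profile: AnnulusProfile, channel: str,
                 threshold: float = 0.2) -> float:
    """Decorrelation-length sector width of one channel (um).

    Per concentric ellipse, the circular autocorrelation of the
    mean-subtracted, variance-normalized signal is computed as a function of
    arc-length lag; the functions are averaged across the ellipses of the
    colony (on a common lag grid, up to half the smallest circumference), and
    the smallest lag at which the average first falls below ``threshold`` is
    returned, with linear interpolation between lag samples.  Constant
    (zero-variance) ellipses are skipped; if every ellipse is constant, or
    the average never crosses the threshold, an error is raised (the latter
    is expected for near-monoculture patterns).
    """
    acfs, steps, circs = [], [], []
    for sig, step, circ in zip(profile.signals[channel], profile.arc_steps,
                               profile.circumferences):
        try:
            acfs.append(_circular_acf(np.asarray(sig, dtype=float)))
        except ImageAnalysisError:
            continue
        steps.append(step)
        circs.append(circ)
    if not acfs:
        raise ImageAnalysisError(
            f"channel {channel!r} is constant on every ellipse")
    lag_max = min(circs) / 2.0
    grid_step = float(np.median(steps))
    grid = np.arange(0.0, lag_max, grid_step)
    avg = np.zeros_like(grid)
    for acf, step in zip(acfs, steps):
        lags = np.arange(len(acf)) * step
        avg += np.interp(grid, lags, acf)
    avg /= len(acfs)
    below = np.nonzero(avg < threshold)[0]
    if len(below) == 0:
        raise NoDecorrelationError(
            f"averaged autocorrelation of {channel!r} never falls below "
            f"{threshold} within half the circumference")
    i = int(below[0])
    if i == 0:
        return 0.0
    # linear interpolation of the crossing between grid[i-1] and grid[i]
    y0, y1 = avg[i - 1], avg[i]
    frac = (y0 - threshold) / (y0 - y1)
    return float(grid[i - 1] + frac * grid_step)


def detect_outliers(values, tuning: float = 4.685) -> tuple[np.ndarray, np.ndarray]:
    """Flag replicate values receiving zero Tukey-bisquare weight.

    A constant (location) model is fitted by iteratively reweighted least
    squares with the bisquare weight function ``w(u) = (1 - u^2)^2`` for
    ``|u| < 1`` (else 0), ``u = residual / (tuning * scale)``, with the
    robust scale fixed at ``MAD / 0.6745`` of the residuals about the median.
    Points with zero final weight are outliers.  If the majority of values
    coincide the robust scale is zero; any value off the median is then an
    outlier (infinitely many scale units away).  Identical values are never
    excluded.

    Returns
    -------
    (kept_values, excluded_mask)
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for outlier detection")
    med = np.median(x)
    scale = np.median(np.abs(x - med)) / 0.6745
    if scale == 0:
        excluded = x != med
        return x[~excluded], excluded
    loc = med
    for _ in range(100):
        u = (x - loc) / (tuning * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        if w.sum() == 0:
            break
        new_loc = np.sum(w * x) / np.sum(w)
        if abs(new_loc - loc) < 1e-12 * max(1.0, abs(loc)):
            loc = new_loc
            break
        loc = new_loc
    u = (x - loc) / (tuning * scale)
    w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
    excluded = w == 0
    return x[~excluded], excluded


def write_colony_tiff(path: str | Path, image: ColonyImage,
                      channel_order: tuple[str, str] = ("yellow", "blue")) -> None:
    """Write a two-channel z-stack as a ZCYX TIFF with pixel-size metadata."""
    arr = np.stack([image.channels[ch] for ch in channel_order], axis=1)
    tifffile.imwrite(
        str(path), arr.astype(np.float32), imagej=True,
        resolution=(1.0 / image.pixel_size, 1.0 / image.pixel_size),
        metadata={"axes": "ZCYX", "unit": "um",
                  "channels": ",".join(channel_order)},
    )


def read_colony_tiff(path: str | Path, pixel_size: float | None = None,
                     channel_names: tuple[str, str] = ("yellow", "blue"),
                     ) -> ColonyImage:
    """Read a two-channel z-stack TIFF (ZCYX, or CYX for single planes).

    Pixel size is taken from the TIFF resolution metadata when present (um
    per pixel); otherwise ``pixel_size`` must be given.
    """
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        meta_px = None
        try:
            page = tif.pages[0]
            xres = page.tags["XResolution"].value
            res = xres[0] / xres[1]
            # (1, 1) is tifffile's placeholder for "no resolution set"
            if res > 0 and tuple(xres) != (1, 1):
                meta_px = 1.0 / res
        except (KeyError, IndexError, ZeroDivisionError, TypeError):
            meta_px = None
    px = meta_px if meta_px is not None else pixel_size
    if px is None:
        raise ImageAnalysisError(
            f"{path}: no pixel size in metadata and none supplied")
    if arr.ndim == 3:            # (c, y, x) single plane
        arr = arr[None, ...]
    if arr.ndim != 4 or arr.shape[1] != len(channel_names):
        raise ImageAnalysisError(
            f"{path}: expected a ZCYX stack with {len(channel_names)} "
            f"channels, got shape {arr.shape}")
    channels = {ch: np.ascontiguousarray(arr[:, i]).astype(float)
                for i, ch in enumerate(channel_names)}
    return ColonyImage(channels=channels, pixel_size=float(px))


def analyze_colony(image: "ColonyImage | str | Path",
                   config: AnalysisConfig | None = None,
                   ) -> tuple[SectorMeasurements, ColonyGeometry]:
    """Full per-colony analysis: projection, segmentation, annulus metrics.

    Accepts an in-memory :class:`ColonyImage` or a TIFF path.  Stage failures
    are re-raised with a stage label; a colony touching the image border is
    flagged (not rejected) and measured anyway.  A channel for which the
    autocorrelation never decorrelates (near-monoculture) yields a NaN width
    and a flag instead of a hard error.
    """
    cfg = config or AnalysisConfig()
    if not isinstance(image, ColonyImage):
        image = read_colony_tiff(image, pixel_size=cfg.pixel_size,
                                 channel_names=cfg.channel_names)
    flags: list[str] = []
    ch_y, ch_b = cfg.channel_names
    planes = {ch: max_project(stack) for ch, stack in image.channels.items()}
    if cfg.background_subtract:
        planes = {ch: np.clip(p - np.median(p), 0.0, None)
                  for ch, p in planes.items()}
    try:
        masks = {ch: p > otsu_threshold(p) for ch, p in planes.items()}
    except DegenerateHistogramError as exc:
        raise ColonyNotFoundError(f"thresholding: {exc}") from exc
    # a channel without real signal thresholds its noise into salt-and-pepper;
    # a binary opening removes that speckle while leaving the colony intact
    masks = {ch: ndimage.binary_opening(m, structure=np.ones((3, 3)))
             for ch, m in masks.items()}
    union = masks[ch_y] | masks[ch_b]
    if not union.any():
        raise ColonyNotFoundError("segmentation: no foreground pixels")
    geometry = fit_geometry(union, image.pixel_size, rho_c=cfg.rho_c)
    if geometry.rho_0 <= geometry.rho_c:
        flags.append("colony_smaller_than_inoculum")
    filled = ndimage.binary_fill_holes(union)
    border = (filled[0].any() or filled[-1].any()
              or filled[:, 0].any() or filled[:, -1].any())
    if border:
        flags.append("touches_border")
    if cfg.use_binary_signal:
        planes_for_profile = {ch: masks[ch].astype(float) for ch in planes}
    else:
        planes_for_profile = planes
    try:
        profile = extract_annulus(planes_for_profile, geometry, band=cfg.band)
    except ImageAnalysisError:
        if not border:
            raise
        # colony extends past the field of view: sample what is visible
        # (edge padding) rather than rejecting the colony
        profile = extract_annulus(planes_for_profile, geometry, band=cfg.band,
                                  allow_partial=True)
        flags.append("annulus_clipped")
    F_Y = float(sum(s.sum() for s in profile.signals[ch_y]))
    F_B = float(sum(s.sum() for s in profile.signals[ch_b]))
    f_yellow = yellow_frequency(profile, yellow=ch_y, blue=ch_b)
    widths = {}
    for ch in (ch_y, ch_b):
        try:
            widths[ch] = sector_width(profile, ch,
                                      threshold=cfg.autocorr_threshold)
        except (NoDecorrelationError, ImageAnalysisError):
            widths[ch] = float("nan")
            flags.append(f"no_decorrelation_{ch}")
    measurements = SectorMeasurements(
        sector_width_yellow=widths[ch_y], sector_width_blue=widths[ch_b],
        f_yellow=f_yellow, F_Y=F_Y, F_B=F_B,
        autocorr_threshold=cfg.autocorr_threshold, flags=tuple(flags),
    )
    if cfg.save_artifacts and cfg.out_dir is not None:
        _save_artifacts(Path(cfg.out_dir), union, profile, measurements,
                        geometry)
    return measurements, geometry


def _save_artifacts(out_dir: Path, mask: np.ndarray, profile: AnnulusProfile,
                    measurements: SectorMeasurements,
                    geometry: ColonyGeometry) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(out_dir / "colony_mask.tif"),
                     mask.astype(np.uint8) * 255)
    rows = []
    for i, t in enumerate(profile.fractional_radii):
        for ch, sigs in profile.signals.items():
            sig = sigs[i]
            for j, v in enumerate(sig):
                rows.append({"ellipse": i, "fractional_radius": t,
                             "channel": ch,
                             "arc_um": j * profile.arc_steps[i],
                             "intensity": v})
    pd.DataFrame(rows).to_csv(out_dir / "annulus_profiles.csv", index=False)
    record = {
        "f_yellow": measurements.f_yellow,
        "sector_width_yellow": measurements.sector_width_yellow,
        "sector_width_blue": measurements.sector_width_blue,
        "rho_0": geometry.rho_0, "l_growth": geometry.l_growth,
        "a": geometry.a, "b": geometry.b, "phi": geometry.phi,
        "flags": list(measurements.flags),
    }
    (out_dir / "measurements.json").write_text(json.dumps(record, indent=2))
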