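"""Seeded synthetic range-expansion colonies with known ground truth.

The generator renders the statistical structure the image pipeline assumes:
an elliptical colony (slight ellipticity, arbitrary orientation) with a
mixed-speckle inoculum disc of radius ``rho_c`` and an annular expansion
zone carrying radially coherent angular sectors of the two labelled strains.
Per-sector arc widths are drawn lognormally around a configurable mean
(a strictly periodic alternating mode exists for analytic oracle tests),
sector boundaries drift radially, intensities carry Poisson shot noise and
Gaussian read noise, and the z-stack attenuates the in-focus signal toward
the stack extremes so that a maximum projection recovers it.

Everything is reproducible from the spec's seed.  Ground truth includes the
exact per-pixel strain label map and the noiseless channel planes, so the
analyzer can be validated against the *identical* measurement definitions
applied to the clean pattern.

The geometric scale of the default colony (equivalent radius ~0.5 mm) is
reduced relative to real range expansions (several mm) to keep rendered
images small; the analysis-band structure, sector statistics and noise are
what matter for validating the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .fitting import CommunitySpec, ObservedSummary
from .imaging import (
    AnalysisConfig,
    AnnulusProfile,
    ColonyGeometry,
    ColonyImage,
    extract_annulus,
    sector_width,
    write_colony_tiff,
    yellow_frequency,
)

__all__ = [
    "SyntheticColonySpec",
    "GroundTruth",
    "GenerationError",
    "generate_colony",
    "ground_truth_measurements",
    "generate_batch",
    "generate_observations",
]


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SyntheticColonySpec:
    """Ground-truth description of one synthetic colony.

    Lengths in um, angles in radians.  ``sector_scale`` is the mean arc
    width of a sector at the colony rim (radius ``rho_0``); the two strains'
    mean widths are split as ``2*f*scale`` (yellow) and ``2*(1-f)*scale``
    (blue) so that their average is ``sector_scale`` and the yellow arc
    fraction is ``target_yellow_fraction``.  ``boundary_wander`` is the
    standard deviation of each boundary's lateral arc drift per um of radial
    growth.  ``periodic=True`` renders strictly alternating equal-width
    sectors for analytic autocorrelation oracles.
    """

    a: float = 560.0
    b: float = 520.0
    phi: float = 0.3
    rho_c: float = 180.0
    pixel_size: float = 1.3
    target_yellow_fraction: float = 0.5
    sector_scale: float = 60.0
    sector_width_dispersion: float = 0.3
    boundary_wander: float = 0.05
    intensity_yellow: float = 180.0
    intensity_blue: float = 170.0
    background: float = 1.5
    read_noise_sd: float = 1.0
    shot_noise: bool = True
    n_z_planes: int = 15
    periodic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.a >= self.b > self.rho_c > 0):
            raise ValueError("need a >= b > rho_c > 0")
        if not 0.0 < self.target_yellow_fraction <= 1.0:
            raise ValueError("target_yellow_fraction must be in (0, 1]")
        if not self.sector_scale > 0:
            raise ValueError("sector_scale must be positive")

    @property
    def rho_0(self) -> float:
        return 0.5 * (self.a + self.b)


@dataclass
class GroundTruth:
    """Exact description of the rendered pattern.

    ``label_map``: -1 outside the colony, 0 yellow, 1 blue (per pixel of the
    max projection).  ``ideal_planes``: the noiseless max-projection
    intensity of each channel.  ``boundary_angles``/``boundary_slopes``
    describe sector boundaries at the rim and their radial drift.
    ``sector_labels[k]`` is 0/1 for the sector after ``boundary_angles[k]``.
    ``realized_yellow_fraction`` is the yellow share of the rim arc length.
    """

    spec: SyntheticColonySpec
    label_map: np.ndarray
    ideal_planes: dict[str, np.ndarray]
    boundary_angles: np.ndarray
    boundary_slopes: np.ndarray
    sector_labels: np.ndarray
    realized_yellow_fraction: float
    center_px: tuple[float, float] = (0.0, 0.0)

    def geometry(self, rho_c: float | None = None) -> ColonyGeometry:
        """True colony geometry (useful for noiseless re-measurement)."""
        s = self.spec
        return ColonyGeometry(center=self.center_px, a=s.a, b=s.b, phi=s.phi,
                              rho_c=s.rho_c if rho_c is None else rho_c,
                              pixel_size=s.pixel_size)


def _draw_sector_widths(spec: SyntheticColonySpec,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float]:
    """Alternating sector arc widths at the rim summing to the circumference.

    Returns (widths_um, labels, realized_yellow_fraction); retries until the
    realized fraction is within 5% (relative) of the target.
    """
    circ = 2.0 * np.pi * spec.rho_0
    f = spec.target_yellow_fraction
    if f == 1.0:   # monoculture: a single yellow sector covers the rim
        return np.array([circ]), np.array([0], dtype=int), 1.0
    mean_y = 2.0 * f * spec.sector_scale
    mean_b = 2.0 * (1.0 - f) * spec.sector_scale
    if spec.periodic:
        pair = mean_y + mean_b
        n_pairs = max(1, int(round(circ / pair)))
        widths = np.empty(2 * n_pairs)
        widths[0::2] = f * circ / n_pairs          # exact tiling of the rim
        widths[1::2] = (1.0 - f) * circ / n_pairs
        labels = np.tile([0, 1], n_pairs)
        return widths, labels, f
    sigma = spec.sector_width_dispersion
    for _ in range(100):
        n_guess = int(np.ceil(circ / spec.sector_scale)) + 8
        wy = mean_y * rng.lognormal(-0.5 * sigma ** 2, sigma, size=n_guess)
        wb = mean_b * rng.lognormal(-0.5 * sigma ** 2, sigma, size=n_guess)
        inter = np.empty(2 * n_guess)
        inter[0::2], inter[1::2] = wy, wb
        cum = np.cumsum(inter)
        n_used = int(np.searchsorted(cum, circ)) + 1
        n_used += n_used % 2                        # whole pairs
        n_used = min(n_used, 2 * n_guess)
        widths = inter[:n_used] * (circ / inter[:n_used].sum())
        labels = np.tile([0, 1], n_used // 2)
        realized = widths[labels == 0].sum() / circ
        if abs(realized - f) / f <= 0.05:
            return widths, labels, float(realized)
    raise GenerationError(
        "could not realize the target yellow fraction within 5% "
        "after 100 attempts; reduce dispersion or sector scale")


def generate_colony(spec: SyntheticColonySpec) -> tuple[ColonyImage, GroundTruth]:
    """Render a two-channel z-stack colony and its ground truth.

    Deterministic per ``spec.seed`` (bit-identical images on repeat calls).
    """
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size
    margin = 6
    half = int(np.ceil(spec.a / px)) + margin
    n = 2 * half + 1
    c = float(half)
    widths, labels, realized = _draw_sector_widths(spec, rng)
    bounds = np.concatenate([[0.0], np.cumsum(widths)]) / spec.rho_0  # angles
    slopes = rng.normal(0.0, spec.boundary_wander, size=len(widths))

    # equivalent-circle coordinates of every pixel
    yy, xx = np.mgrid[0:n, 0:n]
    x = (xx - c) * px
    y = (yy - c) * px
    cphi, sphi = np.cos(spec.phi), np.sin(spec.phi)
    xr = cphi * x + sphi * y          # rotate by -phi
    yr = -sphi * x + cphi * y
    rho0 = spec.rho_0
    xe = xr * (rho0 / spec.a)
    ye = yr * (rho0 / spec.b)
    r = np.hypot(xe, ye)
    theta = np.mod(np.arctan2(ye, xe), 2.0 * np.pi)

    label_map = np.full((n, n), -1, dtype=np.int8)
    inoc = r <= spec.rho_c
    if spec.target_yellow_fraction == 1.0:
        label_map[inoc] = 0
    else:
        # mixed-colour speckle in the inoculum disc (correlation length ~2 px)
        speck = ndimage.gaussian_filter(rng.standard_normal((n, n)), 2.0)
        label_map[inoc] = np.where(speck[inoc] > 0, 0, 1)

    ring = (r > spec.rho_c) & (r <= rho0)
    # sector boundaries drift with radius; resolve ring pixels in ~1 px
    # radial bins so each bin sees one consistent set of boundary angles
    n_bins = max(1, int(np.ceil((rho0 - spec.rho_c) / px)))
    edges = np.linspace(spec.rho_c, rho0, n_bins + 1)
    ring_idx = np.nonzero(ring)
    r_ring = r[ring_idx]
    th_ring = theta[ring_idx]
    bin_of = np.clip(np.searchsorted(edges, r_ring, side="right") - 1,
                     0, n_bins - 1)
    lab_ring = np.empty(r_ring.size, dtype=np.int8)
    starts = bounds[:-1]          # sector k begins at starts[k] (rim angles)
    for bi in range(n_bins):
        sel = bin_of == bi
        if not sel.any():
            continue
        r_mid = 0.5 * (edges[bi] + edges[bi + 1])
        shift = slopes * (r_mid - rho0) / r_mid        # arc drift -> angle
        moved = np.mod(starts + shift, 2.0 * np.pi)
        order = np.argsort(moved)
        bnds = moved[order]
        sector_after = labels[order]
        k = np.searchsorted(bnds, th_ring[sel], side="right")
        # angles before the first moved boundary wrap into the last sector
        lab_ring[sel] = sector_after[np.where(k > 0, k - 1, len(bnds) - 1)]
    label_map[ring_idx] = lab_ring

    intensities = {"yellow": spec.intensity_yellow, "blue": spec.intensity_blue}
    ideal = {}
    for ci, ch in enumerate(("yellow", "blue")):
        plane = np.full((n, n), spec.background, dtype=float)
        plane[label_map == ci] += intensities[ch]
        ideal[ch] = plane

    nz = spec.n_z_planes
    centre = (nz - 1) / 2.0
    att = np.exp(-0.5 * ((np.arange(nz) - centre) / max(nz / 4.0, 1.0)) ** 2)
    att[int(round(centre))] = 1.0  # max projection recovers the ideal plane
    stacks = {}
    for ch in ("yellow", "blue"):
        signal = ideal[ch] - spec.background
        stack = signal[None, :, :] * att[:, None, None] + spec.background
        if spec.shot_noise:
            stack = rng.poisson(stack).astype(float)
        if spec.read_noise_sd > 0:
            stack = stack + rng.normal(0.0, spec.read_noise_sd, size=stack.shape)
        stacks[ch] = np.clip(stack, 0.0, None).astype(np.float32)

    image = ColonyImage(channels=stacks, pixel_size=px)
    truth = GroundTruth(
        spec=spec, label_map=label_map, ideal_planes=ideal,
        boundary_angles=bounds, boundary_slopes=slopes, sector_labels=labels,
        realized_yellow_fraction=realized, center_px=(c, c),
    )
    return image, truth


def ground_truth_measurements(truth: GroundTruth,
                              config: AnalysisConfig | None = None,
                              ) -> dict[str, float]:
    """Apply the pipeline's measurement definitions to the noiseless pattern.

    Uses the *true* geometry and the noiseless ideal planes, so the returned
    frequency and sector-width lags are the ground truth against which the
    full noisy analysis should be compared (the width metric is a
    decorrelation lag, not a geometric width, so it is defined by the same
    autocorrelation procedure).
    """
    cfg = config or AnalysisConfig()
    geom = truth.geometry()
    profile = extract_annulus(truth.ideal_planes, geom, band=cfg.band)
    out = {"f_yellow": yellow_frequency(profile)}
    for ch in ("yellow", "blue"):
        try:
            out[f"sector_width_{ch}"] = sector_width(
                profile, ch, threshold=cfg.autocorr_threshold)
        except Exception:
            out[f"sector_width_{ch}"] = float("nan")
    return out


def generate_batch(out_dir: str | Path, specs: list[SyntheticColonySpec],
                   community_labels: list[str] | None = None) -> pd.DataFrame:
    """Write TIFF fixtures + ground-truth JSON sidecars and a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = community_labels or ["community"] * len(specs)
    if len(labels) != len(specs):
        raise ValueError("community_labels must match specs")
    rows = []
    for i, (spec, lbl) in enumerate(zip(specs, labels)):
        image, truth = generate_colony(spec)
        name = f"colony_{i:03d}"
        tif_path = out_dir / f"{name}.tif"
        write_colony_tiff(tif_path, image)
        sidecar = {
            "spec": asdict(spec),
            "realized_yellow_fraction": truth.realized_yellow_fraction,
            "ground_truth": {k: (None if np.isnan(v) else v)
                             for k, v in ground_truth_measurements(truth).items()},
        }
        (out_dir / f"{name}.ground_truth.json").write_text(
            json.dumps(sidecar, indent=2))
        rows.append({"file": str(tif_path), "community_label": lbl,
                     "colony_id": name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def generate_observations(community: CommunitySpec, l_pro: float, l_trp: float,
                          noise_sd: float, n_replicates: int, seed: int = 0,
                          community_label: str = "Ctr",
                          **pair_kw) -> list[ObservedSummary]:
    """Forward-model observed summaries with multiplicative Gaussian noise.

    ``f`` and ``r_rel`` are predicted from the community model at the true
    leakage rates and each replicate perturbs them by ``N(1, noise_sd)``
    factors; draws pushing a value outside its domain are resampled (bounded
    retries).  ``noise_sd=0`` returns the exact forward predictions.
    """
    pred = community.predict(l_pro, l_trp, **pair_kw)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        f = pred.f_dP
        r = pred.r_rel
        if noise_sd > 0:
            for _attempt in range(1000):
                f = pred.f_dP * (1.0 + rng.normal(0.0, noise_sd))
                if 0.0 < f < 1.0:
                    break
            else:
                raise GenerationError("could not sample f inside (0, 1)")
            for _attempt in range(1000):
                r = pred.r_rel * (1.0 + rng.normal(0.0, noise_sd))
                if 0.0 < r <= 1.0:
                    break
            else:
                raise GenerationError("could not sample r_rel inside (0, 1]")
        out.append(ObservedSummary(community_label=community_label,
                                   f_dP_obs=float(f), r_rel_obs=float(r)))
    return out
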