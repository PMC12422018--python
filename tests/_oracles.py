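"""Independent oracles the tests compare the implementation against."""

import numpy as np

from crossfeed.imaging import AnnulusProfile


def brute_force_otsu_mask(image: np.ndarray) -> np.ndarray:
    """Foreground mask from exhaustive between-class-variance maximization.

    Tries every integer cut of an 8-bit image and keeps the one maximizing
    ``w0 * w1 * (m0 - m1)^2``.  Returns the induced foreground partition
    (``x > t``), which is what any correct Otsu implementation must agree on.
    """
    x = np.asarray(image).ravel()
    best_t, best_v = None, -1.0
    for t in range(int(x.min()), int(x.max())):
        lo, hi = x[x <= t], x[x > t]
        if lo.size == 0 or hi.size == 0:
            continue
        v = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return np.asarray(image) > best_t


def mc_partner_count(R: float, L: float, W: float, rho: float,
                     rng: np.random.Generator,
                     n_samples: int = 200_000) -> tuple[float, float]:
    """Monte-Carlo estimate (value, standard error) of the partner count.

    Samples points uniformly in a bounding box around a spherocylinder (axis
    segment of half-length (L - W)/2 on the z-axis, radius W/2) and counts
    those whose distance to the segment lies in (W/2, W/2 + R]; the shell
    volume over the analytic cell volume, times rho, is the partner count.
    """
    half_seg = (L - W) / 2.0
    ext_xy = W / 2.0 + R
    ext_z = half_seg + W / 2.0 + R
    pts = rng.uniform(-1.0, 1.0, size=(n_samples, 3))
    pts[:, :2] *= ext_xy
    pts[:, 2] *= ext_z
    box_vol = (2 * ext_xy) ** 2 * (2 * ext_z)
    dz = np.clip(np.abs(pts[:, 2]) - half_seg, 0.0, None)
    d = np.sqrt(pts[:, 0] ** 2 + pts[:, 1] ** 2 + dz ** 2)
    inside = (d > W / 2.0) & (d <= W / 2.0 + R)
    frac = inside.mean()
    shell_vol = frac * box_vol
    se_vol = box_vol * np.sqrt(frac * (1 - frac) / n_samples)
    cell_vol = np.pi * (W / 2.0) ** 2 * (L - W) + 4.0 / 3.0 * np.pi * (W / 2.0) ** 3
    return rho * shell_vol / cell_vol, rho * se_vol / cell_vol


def pulse_train_lag(s_a: float, s_b: float, threshold: float = 0.2) -> float:
    """Analytic decorrelation lag of an ideal alternating two-level pattern.

    A periodic pulse train with sector widths ``s_a``/``s_b`` has normalized
    autocovariance ``1 - tau * (s_a + s_b) / (s_a * s_b)`` near zero lag, so
    it crosses ``threshold`` at ``(1 - threshold) * s_a s_b / (s_a + s_b)``
    — identical for both channels.
    """
    return (1.0 - threshold) * s_a * s_b / (s_a + s_b)


def profile_from_signals(signals: dict[str, list[np.ndarray]],
                         arc_step: float = 1.0) -> AnnulusProfile:
    """Wrap raw periodic signals in an AnnulusProfile (one step for all)."""
    any_ch = next(iter(signals.values()))
    steps = np.full(len(any_ch), arc_step)
    circs = np.array([len(s) * arc_step for s in any_ch])
    radii = np.linspace(0.875, 0.95, len(any_ch))
    return AnnulusProfile(fractional_radii=radii, arc_steps=steps,
                          circumferences=circs, signals=signals,
                          band=(0.875, 0.95))
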