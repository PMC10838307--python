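"""Rasterized perturbed-ellipse nucleus masks with analytic ground truth.

A nucleus is an ellipse whose boundary radius is modulated by low-order
harmonics: r(θ) = r_ellipse(θ) · (1 + Σ_k a_k cos(kθ + φ_k)). The
senescent archetype draws larger semi-axes and stronger perturbation.
With zero perturbation the mask is the exact rasterized ellipse, so
closed-form oracles (area πab, gyration, calipers, ...) apply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._seeds import child_rng

__all__ = ["GroundTruthShape", "generate_nucleus_mask", "ARCHETYPES"]

#: semi-axis ranges (pixels) and harmonic perturbation amplitude per archetype
ARCHETYPES = {
    "normal": {"semi_major": (9.0, 13.0), "axis_ratio": (0.7, 0.95), "perturbation": 0.04},
    "senescent": {"semi_major": (17.0, 25.0), "axis_ratio": (0.55, 0.9), "perturbation": 0.10},
}


@dataclass(frozen=True)
class GroundTruthShape:
    """Generating parameters of one synthetic nucleus."""

    center: tuple[float, float]  # (row, col), pixels
    semi_major: float
    semi_minor: float
    angle: float  # radians, major axis vs column axis
    perturbation: float  # total harmonic amplitude bound


def _harmonic_perturbation(rng: np.random.Generator, amplitude: float):
    if amplitude == 0:
        return lambda theta: np.zeros_like(theta)
    orders = np.arange(2, 6)
    amps = rng.uniform(0.25, 1.0, size=orders.size)
    amps *= amplitude / amps.sum()
    phases = rng.uniform(0, 2 * np.pi, size=orders.size)

    def pert(theta):
        return sum(a * np.cos(k * theta + p) for a, k, p in zip(amps, orders, phases))

    return pert


def generate_nucleus_mask(
    archetype: str = "normal",
    seed: int = 0,
    image_size: int = 128,
    perturbation: float | None = None,
    angle: float | None = None,
) -> tuple[np.ndarray, GroundTruthShape]:
    """Generate one labeled nucleus mask and its ground-truth shape.

    Parameters
    ----------
    archetype:
        ``"normal"`` or ``"senescent"``.
    seed:
        Drives all random draws (axes, orientation, harmonics).
    image_size:
        Side of the square image, pixels.
    perturbation:
        Override the archetype's harmonic amplitude (0 → exact ellipse).
    angle:
        Override the random orientation (radians).

    Returns
    -------
    (mask, truth):
        ``mask`` is a boolean array with one connected foreground
        component centered in the image; ``truth`` records the generating
        ellipse so analytic oracles can be evaluated.
    """
    try:
        params = ARCHETYPES[archetype]
    except KeyError:
        raise ValueError(
            f"unknown archetype {archetype!r}; expected one of {sorted(ARCHETYPES)}"
        ) from None
    rng = child_rng(seed, f"mask/{archetype}")
    a = rng.uniform(*params["semi_major"])
    b = a * rng.uniform(*params["axis_ratio"])
    amp = params["perturbation"] if perturbation is None else float(perturbation)
    if amp < 0:
        raise ValueError(f"perturbation must be >= 0 (got {amp})")
    theta0 = rng.uniform(0, np.pi) if angle is None else float(angle)

    max_extent = a * (1 + amp)
    if 2 * max_extent + 2 > image_size:
        raise ValueError(
            f"semi_major={a:.2f} (with perturbation {amp}) exceeds image_size="
            f"{image_size}; increase image_size or reduce semi_major"
        )

    center = ((image_size - 1) / 2.0, (image_size - 1) / 2.0)
    pert = _harmonic_perturbation(rng, amp)

    rr, cc = np.mgrid[0:image_size, 0:image_size].astype(float)
    dy = rr - center[0]
    dx = cc - center[1]
    # rotate into the ellipse frame and normalize by the semi-axes
    u = (dx * np.cos(theta0) + dy * np.sin(theta0)) / a
    v = (-dx * np.sin(theta0) + dy * np.cos(theta0)) / b
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    mask = rho <= 1.0 + pert(theta)

    truth = GroundTruthShape(
        center=center, semi_major=a, semi_minor=b, angle=theta0, perturbation=amp
    )
    return mask, truth
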