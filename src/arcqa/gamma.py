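"""2D gamma-index comparison of dose distributions.

The gamma value at each reference point is the minimum, over a search disk
around the point, of the combined dose-difference / distance-to-agreement
metric.  The evaluated image is upsampled by bilinear interpolation before
the search so sub-pixel agreement is found.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GammaCriteria", "DoseImage", "GammaError", "gamma_map", "passing_rate"]


class GammaError(ValueError):
    """Invalid input to the gamma comparison."""


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma acceptance criteria.

    Defaults follow a strict SRS protocol: 3% dose difference, 1 mm
    distance-to-agreement, 10% low-dose threshold, global normalization.
    """

    dose_diff: float = 3.0  # percent
    dta: float = 1.0  # mm
    low_dose_threshold: float = 10.0  # percent of normalization
    normalization: str = "global"  # "global" | "local"
    search_radius_factor: float = 3.0  # search disk radius, multiples of dta
    upsample: int = 10

    def __post_init__(self):
        if self.dose_diff <= 0 or self.dta <= 0 or self.low_dose_threshold <= 0:
            raise GammaError("criteria must be positive")
        if self.normalization not in ("global", "local"):
            raise GammaError(f"unknown normalization {self.normalization!r}")


@dataclass
class DoseImage:
    """A 2D dose grid with uniform pixel spacing (mm)."""

    dose: np.ndarray
    pixel_spacing: float = 1.0

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.ndim != 2:
            raise GammaError("dose must be a 2D array")
        if self.pixel_spacing <= 0:
            raise GammaError("pixel spacing must be positive")
        if np.any(self.dose < 0):
            raise GammaError("dose values must be non-negative")


def _upsample_bilinear(img: np.ndarray, factor: int) -> np.ndarray:
    """Corner-aligned bilinear upsampling; output (n-1)*f+1 per axis."""
    n, m = img.shape
    yi = np.arange((n - 1) * factor + 1) / factor
    xi = np.arange((m - 1) * factor + 1) / factor
    y0 = np.clip(np.floor(yi).astype(int), 0, n - 2)
    x0 = np.clip(np.floor(xi).astype(int), 0, m - 2)
    fy = (yi - y0)[:, None]
    fx = (xi - x0)[None, :]
    tl = img[np.ix_(y0, x0)]
    tr = img[np.ix_(y0, x0 + 1)]
    bl = img[np.ix_(y0 + 1, x0)]
    br = img[np.ix_(y0 + 1, x0 + 1)]
    return (tl * (1 - fy) * (1 - fx) + tr * (1 - fy) * fx
            + bl * fy * (1 - fx) + br * fy * fx)


def gamma_map(reference: DoseImage, evaluated: DoseImage,
              criteria: GammaCriteria | None = None) -> np.ndarray:
    """Gamma value at every reference pixel.

    The evaluated image is upsampled ``criteria.upsample`` times and the
    minimum is searched within a disk of radius
    ``criteria.search_radius_factor * dta``.
    """
    criteria = criteria or GammaCriteria()
    ref = reference.dose
    ev = evaluated.dose
    if ref.shape != ev.shape or reference.pixel_spacing != evaluated.pixel_spacing:
        raise GammaError("reference and evaluated images must share the grid")
    ref_max = float(ref.max())
    if ref_max <= 0:
        raise GammaError("reference image has no dose")

    spacing = reference.pixel_spacing
    U = criteria.upsample
    radius = criteria.search_radius_factor * criteria.dta
    fine = _upsample_bilinear(ev, U)
    fine_spacing = spacing / U
    r_px = int(np.floor(radius / fine_spacing))

    if criteria.normalization == "global":
        tol = criteria.dose_diff / 100.0 * ref_max
    else:
        tol = criteria.dose_diff / 100.0 * np.maximum(ref, 1e-12 * ref_max)

    # offsets sorted by distance so the search can stop early once the
    # distance term alone exceeds the current worst gamma
    dy, dx = np.mgrid[-r_px:r_px + 1, -r_px:r_px + 1]
    dist = np.hypot(dy, dx) * fine_spacing
    keep = dist <= radius + 1e-12
    order = np.argsort(dist[keep])
    offsets = np.stack([dy[keep][order], dx[keep][order]], axis=1)
    dists = dist[keep][order]

    n, m = ref.shape
    pad = r_px
    fine_padded = np.full((fine.shape[0] + 2 * pad, fine.shape[1] + 2 * pad), np.nan)
    fine_padded[pad:-pad or None, pad:-pad or None] = fine

    gamma = np.full((n, m), np.inf)
    for (oy, ox), r in zip(offsets, dists):
        dist_term = (r / criteria.dta) ** 2
        if dist_term >= np.nanmax(gamma ** 2):
            break
        sub = fine_padded[pad + oy: pad + oy + (n - 1) * U + 1: U,
                          pad + ox: pad + ox + (m - 1) * U + 1: U]
        with np.errstate(invalid="ignore"):
            cand = ((sub - ref) / tol) ** 2 + dist_term
        np.fmin(gamma, np.sqrt(cand), out=gamma, where=~np.isnan(cand))
    return gamma


def passing_rate(gamma: np.ndarray, reference: DoseImage,
                 criteria: GammaCriteria | None = None) -> float:
    """Percentage of above-threshold reference pixels with gamma <= 1."""
    criteria = criteria or GammaCriteria()
    ref = reference.dose
    if gamma.shape != ref.shape:
        raise GammaError("gamma and reference shapes differ")
    cutoff = criteria.low_dose_threshold / 100.0 * float(ref.max())
    mask = ref >= cutoff
    n = int(mask.sum())
    if n == 0:
        raise GammaError("no reference pixel above the low-dose threshold")
    return 100.0 * float(np.sum(gamma[mask] <= 1.0)) / n
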