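"""PSF characterization from fluorescent-bead z-stacks and a theoretical
two-photon resolution model.

Beads (0.2 um microspheres) imaged in 3-D are isolated (no neighbor within
25 px, fully contained in the stack), sub-pixel registered at their
centroids, and averaged; the lateral and axial FWHM of the averaged XY and
XZ profiles give the empirical resolution. The theoretical model converts
an effective numerical aperture — limited by beam clipping through the
implanted glass prism — into Gaussian 1/e widths and FWHMs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BeadProfile",
    "OpticalModel",
    "PrismGeometry",
    "detect_beads",
    "measure_psf",
    "theoretical_resolution",
    "effective_na",
    "profile_fwhm",
]

_FWHM_PER_1E = 2.0 * np.sqrt(np.log(2.0))  # FWHM = 2*sqrt(ln 2) * (1/e half-width)


@dataclass
class BeadProfile:
    centroids_px: np.ndarray  # (n_beads, 3) in (z, y, x)
    xy_profile: np.ndarray
    xz_profile: np.ndarray
    fwhm_lateral_um: float
    fwhm_axial_um: float
    n_beads: int


@dataclass(frozen=True)
class OpticalModel:
    wavelength_um: float
    numerical_aperture: float
    refractive_index: float
    omega_xy_um: float
    omega_z_um: float
    fwhm_xy_um: float
    fwhm_z_um: float


@dataclass(frozen=True)
class PrismGeometry:
    """Geometry of the implanted glass prism that clips the beam."""

    aperture_mm: float  # imaging-face width
    glass_path_mm: float  # longest path through glass
    n_glass: float = 1.5
    objective_na_cap: float = 0.8


def detect_beads(
    stack: np.ndarray,
    min_separation_px: float = 25.0,
    require_contained: bool = True,
    threshold: float | None = None,
) -> np.ndarray:
    """Centroids of isolated beads in a 3-D stack.

    Blobs are segmented above ``threshold`` (default: half the stack
    maximum above background). A blob is excluded when any other blob's
    centroid lies closer than ``min_separation_px`` (isolation rule) or,
    with ``require_contained``, when it touches the first or last z-plane.
    Returns an (n, 3) float array of (z, y, x) intensity centroids.
    """
    s = np.asarray(stack, dtype=float)
    if s.ndim != 3 or s.size == 0:
        raise ValueError("stack must be a non-empty 3-D array")
    if np.any(s < 0):
        raise ValueError("stack must be nonnegative")
    bg = np.median(s)
    if threshold is None:
        threshold = bg + 0.5 * (s.max() - bg)
    labels, n = ndimage.label(s > threshold)
    if n == 0:
        return np.zeros((0, 3))
    objs = ndimage.find_objects(labels)
    cents = np.array(ndimage.center_of_mass(s, labels, np.arange(1, n + 1)))
    keep = np.ones(n, dtype=bool)
    if require_contained:
        nz = s.shape[0]
        for i, sl in enumerate(objs):
            if sl[0].start == 0 or sl[0].stop == nz:
                keep[i] = False
    if n > 1:
        d = np.sqrt(((cents[:, None, :] - cents[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        keep &= d.min(axis=1) >= min_separation_px
    return cents[keep]


def _subpixel_centroid(
    stack: np.ndarray, c: np.ndarray, win_xy: int = 7, win_z: int = 9
) -> np.ndarray:
    """Center-of-mass refinement within a fixed window around c=(z,y,x)."""
    nz, ny, nx = stack.shape
    hz, hx = win_z // 2, win_xy // 2
    z0, y0, x0 = (int(round(v)) for v in c)
    zsl = slice(max(0, z0 - hz), min(nz, z0 + hz + 1))
    ysl = slice(max(0, y0 - hx), min(ny, y0 + hx + 1))
    xsl = slice(max(0, x0 - hx), min(nx, x0 + hx + 1))
    sub = stack[zsl, ysl, xsl]
    sub = sub - sub.min()
    if sub.sum() == 0:
        return np.asarray(c, dtype=float)
    com = ndimage.center_of_mass(sub)
    return np.array([zsl.start + com[0], ysl.start + com[1], xsl.start + com[2]])


def profile_fwhm(profile: np.ndarray, spacing: float = 1.0) -> float:
    """FWHM of a 1-D profile by linear interpolation at half maximum.

    Background (median of the two border samples on each side) is
    subtracted first; the width is between the two half-maximum crossings
    bracketing the peak.
    """
    y = np.asarray(profile, dtype=float)
    if y.size < 3:
        raise ValueError("profile too short")
    bg = np.median(np.concatenate([y[:2], y[-2:]]))
    y = y - bg
    peak = int(np.argmax(y))
    half = y[peak] / 2.0
    if y[peak] <= 0:
        raise ValueError("profile has no peak above background")
    # left crossing
    i = peak
    while i > 0 and y[i] > half:
        i -= 1
    if y[i] > half:
        left = 0.0
    else:
        left = i + (half - y[i]) / (y[i + 1] - y[i])
    j = peak
    n = y.size
    while j < n - 1 and y[j] > half:
        j += 1
    if y[j] > half:
        right = float(n - 1)
    else:
        right = j - (half - y[j]) / (y[j - 1] - y[j])
    return float((right - left) * spacing)


def measure_psf(
    stack: np.ndarray,
    centroids: np.ndarray,
    xy_um_per_px: float,
    z_um_per_plane: float,
    half_xy_px: int = 20,
    half_z_planes: int = 15,
) -> BeadProfile:
    """Average registered bead profiles and measure lateral/axial FWHM.

    Each bead is sub-pixel registered at its centroid (center of mass in a
    fixed window, then a sub-pixel shift), XY and XZ patches around the
    centroid are averaged across beads, and the FWHM of the central row of
    each averaged profile is returned in um. FWHMs are amplitude-invariant
    (each bead patch is peak-normalized before averaging).
    """
    s = np.asarray(stack, dtype=float)
    cents = np.atleast_2d(np.asarray(centroids, dtype=float))
    if cents.shape[0] < 1:
        raise ValueError("need at least one centroid")
    nz, ny, nx = s.shape
    for c in cents:
        if not (0 <= c[0] < nz and 0 <= c[1] < ny and 0 <= c[2] < nx):
            raise ValueError(f"centroid {c} outside stack")
    xy_sum = np.zeros((2 * half_xy_px + 1, 2 * half_xy_px + 1))
    xz_sum = np.zeros((2 * half_z_planes + 1, 2 * half_xy_px + 1))
    for c in cents:
        c = _subpixel_centroid(s, c)
        # shift so the centroid sits on the integer grid point nearest it
        frac = c - np.round(c)
        zi, yi, xi = (int(v) for v in np.round(c))
        z_lo, z_hi = zi - half_z_planes, zi + half_z_planes + 1
        y_lo, y_hi = yi - half_xy_px, yi + half_xy_px + 1
        x_lo, x_hi = xi - half_xy_px, xi + half_xy_px + 1
        pad_z = (max(0, -z_lo), max(0, z_hi - nz))
        pad_y = (max(0, -y_lo), max(0, y_hi - ny))
        pad_x = (max(0, -x_lo), max(0, x_hi - nx))
        patch = s[
            max(0, z_lo) : min(nz, z_hi),
            max(0, y_lo) : min(ny, y_hi),
            max(0, x_lo) : min(nx, x_hi),
        ]
        patch = np.pad(patch, (pad_z, pad_y, pad_x), mode="edge")
        patch = ndimage.shift(patch, -frac, order=1, mode="nearest")
        peak = patch.max()
        if peak > 0:
            patch = patch / peak
        xy_sum += patch[half_z_planes]
        xz_sum += patch[:, half_xy_px, :]
    xy_mean = xy_sum / cents.shape[0]
    xz_mean = xz_sum / cents.shape[0]
    fwhm_lat = profile_fwhm(xy_mean[half_xy_px, :], xy_um_per_px)
    fwhm_ax = profile_fwhm(xz_mean[:, half_xy_px], z_um_per_plane)
    return BeadProfile(
        centroids_px=cents,
        xy_profile=xy_mean,
        xz_profile=xz_mean,
        fwhm_lateral_um=fwhm_lat,
        fwhm_axial_um=fwhm_ax,
        n_beads=cents.shape[0],
    )


def theoretical_resolution(
    wavelength_um: float, na: float, n: float = 1.33
) -> OpticalModel:
    """Gaussian-approximation two-photon resolution.

    1/e half-widths:

    * omega_XY = 0.320*lambda/(sqrt(2)*NA)            for NA <= 0.7
      omega_XY = 0.325*lambda/(sqrt(2)*NA^0.91)       for NA  > 0.7
    * omega_Z  = (0.532*lambda/sqrt(2)) * 1/(n - sqrt(n^2 - NA^2))

    FWHM = 2*sqrt(ln 2) * omega. The lateral branch switch at NA = 0.7 is
    the published form and is mildly discontinuous (~2%) there.
    """
    if wavelength_um <= 0:
        raise ValueError("wavelength must be positive")
    if not (0 < na < n):
        raise ValueError("require 0 < NA < n (axial formula undefined otherwise)")
    rt2 = np.sqrt(2.0)
    if na <= 0.7:
        omega_xy = 0.320 * wavelength_um / (rt2 * na)
    else:
        omega_xy = 0.325 * wavelength_um / (rt2 * na**0.91)
    omega_z = (0.532 * wavelength_um / rt2) / (n - np.sqrt(n**2 - na**2))
    return OpticalModel(
        wavelength_um=wavelength_um,
        numerical_aperture=na,
        refractive_index=n,
        omega_xy_um=float(omega_xy),
        omega_z_um=float(omega_z),
        fwhm_xy_um=float(_FWHM_PER_1E * omega_xy),
        fwhm_z_um=float(_FWHM_PER_1E * omega_z),
    )


def effective_na(geometry: PrismGeometry) -> float:
    """Effective NA of the prism-clipped beam.

    The imaging-face aperture limits the half-angle of the focusing cone
    through the glass path; the invariant n*sin(theta) converts the
    in-glass half-angle to an effective NA, capped by the objective's NA.
    """
    g = geometry
    if min(g.aperture_mm, g.glass_path_mm, g.n_glass, g.objective_na_cap) <= 0:
        raise ValueError("all geometry fields must be positive")
    half_angle = np.arctan((g.aperture_mm / 2.0) / g.glass_path_mm)
    return float(min(g.n_glass * np.sin(half_angle), g.objective_na_cap))


# Prism variants used with this preparation: v1 images CA1/CA2 (1 mm prism,
# 2 mm total glass path), v2 images the whole transverse circuit (1.5 mm
# prism, 2.5 mm path).
PRISM_V1 = PrismGeometry(aperture_mm=1.0, glass_path_mm=2.0)
PRISM_V2 = PrismGeometry(aperture_mm=1.5, glass_path_mm=2.5)
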