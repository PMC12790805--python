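"""Featureless cylindrically-averaged initial models.

The azimuthal average is the reference map RASTR subtraction relies on: it
captures the tube's radial density profile (membrane leaflets plus a
smeared protein annulus) while containing no azimuthal protein features.
It is built exactly the way the source workflow describes: every aligned
particle is backprojected with its measured psi/shift, a *random* rot
(phi) and tilt drawn from {90, 270}, and the resulting map is averaged
along the tube (z) axis to strip residual features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import (
    DensityVolume,
    EulerTriplet,
    _cifft2,
    _freq_grid_2d,
    reconstruct_backproject,
)

__all__ = [
    "azimuthal_average",
    "radial_profile",
    "symmetrize_cylindrical",
    "assign_random_views",
    "outer_surface_radius",
]


def assign_random_views(records: pd.DataFrame, seed) -> pd.DataFrame:
    """Return a copy of records with random rot and tilt 90/270 assigned.

    The in-plane psi and shifts (from tube alignment) are kept; rot is
    uniform on [0, 360) and tilt is 90 or 270 equiprobably, which encodes
    the unresolved tube polarity.
    """
    rng = np.random.default_rng(seed)
    out = records.copy()
    n = len(out)
    out["rlnAngleRot"] = rng.uniform(0.0, 360.0, n)
    out["rlnAngleTilt"] = rng.choice([90.0, 270.0], n)
    return out


def azimuthal_average(
    stack: np.ndarray,
    records: pd.DataFrame,
    seed,
    ctf_mode: str = "none",
    optics=None,
    pixel_size: float | None = None,
    symmetrize: bool = True,
) -> DensityVolume:
    """Backproject at random phi and average along z.

    ``records`` must carry rlnAnglePsi and origin columns from tube
    alignment; rot/tilt are (re)assigned randomly from ``seed``.  The
    z-averaging replaces every slice by the mean slice, which makes the
    output exactly z-invariant and approximately cylindrically symmetric.

    With ``symmetrize=True`` (default) the z-averaged map is built as an
    exactly cylindrical volume straight from the Fourier accumulator: the
    kz=0 plane's coefficients are ring-averaged *weighted by their
    sampling density*, so azimuthal coverage gaps left by an unlucky
    random-phi draw do not bias the radial structure, and the output is
    rotationally invariant by construction.  ``symmetrize=False`` returns
    the plain backproject-then-z-average map (useful for inspecting the
    residual ripple).
    """
    if len(records) == 0:
        raise ValueError("empty particle selection")
    recs = assign_random_views(records, seed)
    if not symmetrize:
        vol = reconstruct_backproject(
            stack, recs, ctf_mode=ctf_mode, optics=optics, pixel_size=pixel_size
        )
        mean_slice = vol.voxels.mean(axis=0)
        vol.voxels[:] = mean_slice[None, :, :]
        return vol

    stack = np.asarray(stack)
    if pixel_size is None:
        pixel_size = optics.pixel_size
    n = stack.shape[1]

    # z-averaging keeps only the kz=0 plane of the backprojection, so the
    # accumulation is done directly there: every slice sample within one
    # frequency row of kz=0 deposits its *exact* Fourier value at its
    # *continuous* in-plane radius (half-pixel ring bins, tent weight in
    # kz).  This avoids the radial interpolation error of 3D gridding,
    # which is what limits accuracy on steeply oscillating transforms.
    from .geometry import _cfft2, _slice_coords, rotation_matrix
    from .synthetic_data import ctf_2d

    nbins = int(np.ceil(n * np.sqrt(2))) * 2 + 2
    num_r = np.zeros(nbins)
    wsum = np.zeros(nbins)
    ky, kx = _freq_grid_2d(n)
    c = n // 2
    for i in range(stack.shape[0]):
        euler = EulerTriplet(
            float(recs["rlnAngleRot"].iloc[i]),
            float(recs["rlnAngleTilt"].iloc[i]),
            float(recs["rlnAnglePsi"].iloc[i]),
        )
        f = _cfft2(stack[i].astype(np.float64))
        sx = float(recs.get("rlnOriginXAngst", pd.Series(0.0, index=recs.index)).iloc[i]) / pixel_size
        sy = float(recs.get("rlnOriginYAngst", pd.Series(0.0, index=recs.index)).iloc[i]) / pixel_size
        if sx or sy:
            f = f * np.exp(2j * np.pi * (kx * sx + ky * sy) / n)
        if ctf_mode == "phase_flip":
            ctf = ctf_2d(n, pixel_size, optics, float(recs["rlnDefocusU"].iloc[i]))
            sign = np.sign(ctf)
            sign[sign == 0] = 1.0
            f = f * sign
        coords = _slice_coords(n, rotation_matrix(euler))  # (z, y, x) + c
        kz = coords[0].ravel() - c
        sel = np.abs(kz) < 1.0
        wz = 1.0 - np.abs(kz[sel])
        kr = np.hypot(coords[2].ravel()[sel] - c, coords[1].ravel()[sel] - c)
        rbin = np.round(2.0 * kr).astype(int)
        vals = f.ravel()[sel].real * wz
        np.add.at(num_r, rbin, vals)
        np.add.at(wsum, rbin, wz)
    ring = np.zeros(nbins)
    ok = wsum > 1e-12
    ring[ok] = num_r[ok] / wsum[ok]
    spec2d = np.interp(
        2.0 * np.hypot(kx, ky).ravel(), np.arange(nbins), ring
    ).reshape(n, n)
    # the z-mean of a 3D inverse transform carries an extra 1/N relative
    # to the plain 2D inverse of the kz=0 plane
    zslice = _cifft2(spec2d).real / n
    vol = np.broadcast_to(zslice, (n, n, n)).copy()
    # exact radial symmetrization removes the square-grid pixelization of
    # the radial spectrum's inverse transform
    return symmetrize_cylindrical(DensityVolume(vol, pixel_size))


def radial_profile(volume: DensityVolume):
    """Mean density in one-voxel cylindrical annuli about the z axis.

    Returns ``(radii_angstrom, values)``; radii are annulus centers.
    """
    n = volume.boxsize
    c = n // 2
    ax = np.arange(n) - c
    r = np.hypot(ax[:, None], ax[None, :])  # in voxels, (y, x)
    rbin = np.round(r).astype(int)
    nmax = rbin.max() + 1
    zmean = volume.voxels.mean(axis=0)
    sums = np.bincount(rbin.ravel(), weights=zmean.ravel(), minlength=nmax)
    counts = np.bincount(rbin.ravel(), minlength=nmax)
    prof = sums / np.maximum(counts, 1)
    return np.arange(nmax) * volume.pixel_size, prof


def outer_surface_radius(volume: DensityVolume) -> float:
    """Radius (angstrom) of the outer membrane leaflet in an azimuthal map.

    The radial profile of a decorated tube peaks at both leaflets (and
    weakly at the smeared protein annuli); the tube *surface* for ROI
    placement is the outermost strong peak — the same outermost-tall-peak
    criterion the diameter measurement uses.
    """
    from scipy import signal

    radii, prof = radial_profile(volume)
    rng = prof.max() - prof.min()
    if rng <= 0:
        raise ValueError("featureless radial profile")
    peaks, _ = signal.find_peaks(prof, prominence=0.03 * rng)
    if len(peaks) == 0:
        return float(radii[int(np.argmax(prof))])
    base = np.percentile(prof, 10.0)
    height = prof[peaks] - base
    strong = peaks[height >= 0.6 * height.max()]
    return float(radii[strong.max()])


def symmetrize_cylindrical(volume: DensityVolume) -> DensityVolume:
    """Replace the volume by its exact cylindrical symmetrization.

    Every voxel takes the z-averaged mean of its radial annulus
    (linearly interpolated in radius), making the map an exact function
    of r.  Used to stabilize the RASTR subtraction cache, which relies on
    rotational invariance of the reference about z.
    """
    radii, prof = radial_profile(volume)
    n = volume.boxsize
    c = n // 2
    ax = np.arange(n) - c
    r = np.hypot(ax[:, None], ax[None, :]) * volume.pixel_size
    vals = np.interp(r.ravel(), radii, prof).reshape(n, n)
    out = np.broadcast_to(vals, (n, n, n)).copy()
    return DensityVolume(out, volume.pixel_size)


def azimuthal_power_fraction(volume: DensityVolume, r_min: float, r_max: float, n_theta: int = 360):
    """Fraction of angular Fourier power in non-zero orders within a band.

    Samples the z-averaged map on polar rings between ``r_min`` and
    ``r_max`` (angstrom) and returns sum(|c_k|^2, k != 0) / |c_0|^2 — the
    testable form of "contains no high-resolution protein features".
    """
    from scipy import ndimage as ndi

    n = volume.boxsize
    c = n // 2
    zmean = volume.voxels.mean(axis=0)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    p_nonzero = 0.0
    p_zero = 0.0
    for r_ang in np.arange(r_min, r_max, volume.pixel_size):
        r_px = r_ang / volume.pixel_size
        ys = c + r_px * np.sin(theta)
        xs = c + r_px * np.cos(theta)
        ring = ndi.map_coordinates(zmean, np.stack([ys, xs]), order=1)
        ck = np.fft.fft(ring) / n_theta
        p_zero += np.abs(ck[0]) ** 2
        p_nonzero += float(np.sum(np.abs(ck[1:]) ** 2))
    if p_zero == 0:
        return np.inf
    return p_nonzero / p_zero
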