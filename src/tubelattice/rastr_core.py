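"""ROI signal subtraction on tube surfaces (RASTR).

Isolates a locally ordered patch of a decorated tubule: a soft spherical
region of interest (ROI) is placed on the tube surface, everything
*outside* it is modeled by the featureless azimuthal average, the model's
projection is subtracted from each raw particle, and the image is
re-centered on the ROI so the patch can be treated as a single particle.

The rot (phi) bookkeeping follows the tube-frame convention: a sub-particle
whose mask sits at tube azimuth ``alpha`` gets ``rot' = rot + alpha``; with
``rot' = 90`` or ``270`` the ROI lies exactly on the tube silhouette (edge
view), which is where stacked and relaxed lattice states are
distinguishable in projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    DensityVolume,
    EulerTriplet,
    FourierProjector,
    Shift2D,
    fourier_shift_2d,
    project_point,
)
from .azimuthal import symmetrize_cylindrical

__all__ = [
    "SphericalMask",
    "make_spherical_mask",
    "subtract_outside_roi",
    "make_rastr_subparticles",
    "ROI_RADIUS_LADDER",
]

# The ROI-size scan ladder used to find the locally ordered patch size.
ROI_RADIUS_LADDER = (425.0, 250.0, 185.0, 130.0)


@dataclass(frozen=True)
class SphericalMask:
    """Soft-edged sphere in tube-frame cylindrical coordinates.

    ``center_cyl`` is (radial distance angstrom, azimuth degrees, z
    angstrom); values are 1 inside ``radius - soft_edge``, fall to 0 at
    ``radius`` with a cosine edge.
    """

    center_cyl: tuple[float, float, float]
    radius: float
    soft_edge: float = 20.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("mask radius must be positive")
        if self.soft_edge < 0 or self.soft_edge > self.radius:
            raise ValueError("soft_edge must be in [0, radius]")

    @property
    def center_xyz(self) -> np.ndarray:
        r, az, z = self.center_cyl
        a = math.radians(az)
        return np.array([r * math.cos(a), r * math.sin(a), z])

    def rotated(self, delta_az: float) -> "SphericalMask":
        r, az, z = self.center_cyl
        return SphericalMask((r, az + delta_az, z), self.radius, self.soft_edge)


def make_spherical_mask(
    center_cyl,
    radius: float,
    soft_edge: float,
    boxsize: int,
    pixel_size: float,
) -> DensityVolume:
    """Voxelize a soft spherical mask; values in [0, 1].

    Exactly 1 inside ``radius - soft_edge``, exactly 0 outside ``radius``,
    cosine falloff between.  Raises if the sphere misses the box entirely.
    """
    mask = SphericalMask(tuple(center_cyl), radius, soft_edge)
    n = boxsize
    c = n // 2
    half = n * pixel_size / 2.0
    center = mask.center_xyz
    if np.any(np.abs(center) - radius > half):
        raise ValueError("sphere lies entirely outside the box")
    ax = (np.arange(n) - c) * pixel_size
    dz = ax[:, None, None] - center[2]
    dy = ax[None, :, None] - center[1]
    dx = ax[None, None, :] - center[0]
    d = np.sqrt(dz**2 + dy**2 + dx**2)
    vals = np.zeros((n, n, n))
    inner = radius - soft_edge
    vals[d <= inner] = 1.0
    if soft_edge > 0:
        band = (d > inner) & (d < radius)
        vals[band] = 0.5 * (1.0 + np.cos(math.pi * (d[band] - inner) / soft_edge))
    return DensityVolume(vals, pixel_size)


def _ls_scale(target: np.ndarray, model: np.ndarray, weight=None) -> float:
    """Least-squares amplitude of ``model`` in ``target``.

    ``weight`` restricts the fit (e.g. to pixels outside the projected
    ROI, where the complement model should explain everything); with no
    usable pixels or a vanishing model the scale falls back to 1 / 0.
    """
    if weight is not None:
        t = target * weight
        m = model * weight
    else:
        t, m = target, model
    denom = float(np.sum(m * m))
    if denom < 1e-12 * max(1.0, float(np.sum(target * target))):
        return 0.0
    if weight is not None and np.sum(weight) < 0.1 * weight.size:
        return 1.0
    return float(np.sum(t * m) / denom)


def subtract_outside_roi(
    image: np.ndarray,
    record,
    azavg: DensityVolume,
    mask: SphericalMask,
    optics=None,
    projectors=None,
) -> np.ndarray:
    """Subtract the projected non-ROI azimuthal signal from one particle.

    The complement model ``azavg * (1 - mask)`` is projected at the
    record's orientation and shifts, CTF-modulated when ``optics`` and a
    defocus are available, amplitude-fitted to the particle by least
    squares, and subtracted.  What remains is the ROI signal plus noise.

    ``record`` is a mapping with rlnAngleRot/Tilt/Psi, rlnOriginX/YAngst
    and optionally rlnDefocusU.  ``projectors`` may carry cached
    ``(FourierProjector(azavg), FourierProjector(azavg*mask_at_azimuth_0))``
    built by :func:`make_rastr_subparticles`; without it both are built on
    the fly.
    """
    if azavg.boxsize != image.shape[0]:
        raise ValueError("azavg grid does not match image size")
    apix = azavg.pixel_size
    euler = EulerTriplet(
        float(record["rlnAngleRot"]),
        float(record["rlnAngleTilt"]),
        float(record["rlnAnglePsi"]),
    )
    shift = Shift2D(
        float(record.get("rlnOriginXAngst", 0.0)) / apix,
        float(record.get("rlnOriginYAngst", 0.0)) / apix,
    )
    if projectors is None:
        mvol = make_spherical_mask(
            mask.center_cyl, mask.radius, mask.soft_edge, azavg.boxsize, apix
        )
        fp_az = FourierProjector(azavg)
        fp_mask = FourierProjector(DensityVolume(azavg.voxels * mvol.voxels, apix))
        fp_foot = FourierProjector(mvol)
        mask_az0 = mask.center_cyl[1]
    else:
        fp_az, fp_mask, fp_foot, mask_az0 = projectors

    base = fp_az.project(euler, shift)
    # rotating the mask to azimuth alpha equals rotating the view:
    # proj(azavg * mask_alpha, rot) = proj(azavg * mask_0, rot + alpha)
    # (exact for a cylindrically symmetric azavg)
    delta = mask.center_cyl[1] - mask_az0
    euler_m = EulerTriplet(euler.rot + delta, euler.tilt, euler.psi)
    roi_part = fp_mask.project(euler_m, shift)
    complement = base - roi_part
    if optics is not None and "rlnDefocusU" in record:
        from .synthetic_data import apply_ctf

        complement = apply_ctf(complement, optics, float(record["rlnDefocusU"]))
    # amplitude-fit where the ROI does not project, so retained ROI signal
    # cannot bias the scale
    footprint = fp_foot.project(euler_m, shift)
    outside = (footprint < 0.05 * max(footprint.max(), 1e-12)).astype(float)
    beta = _ls_scale(np.asarray(image, float), complement, weight=outside)
    return np.asarray(image, float) - beta * complement


def make_rastr_subparticles(
    stack: np.ndarray,
    records: pd.DataFrame,
    azavg: DensityVolume,
    mask_radius: float,
    n_masks: int = 4,
    phi_mode: str = "random",
    seed=0,
    sub_box: int = 128,
    soft_edge: float = 20.0,
    surface_radius: float | None = None,
    optics=None,
):
    """Create ROI-subtracted, re-centered sub-particles.

    For every particle, ``n_masks`` spherical masks of ``mask_radius`` are
    placed on the tube surface (radius ``surface_radius``; default the
    outer-leaflet radius detected in the azimuthal average).  Mask azimuths are uniform random (``phi_mode="random"``)
    or chosen so the sub-particle rot alternates between 90 and 270
    (``"edge"``, silhouette views).  Each sub-particle is the subtracted
    image re-centered on the mask center (Fourier shift) and cropped to
    ``sub_box``; its record carries rot' = rot + mask azimuth and shifts
    re-expressed in the mask-centered frame, so the sub-stack reconstructs
    the ROI neighborhood in a tube frame whose azimuth 0 passes through
    the mask center.

    Returns ``(sub_stack, sub_records)`` with ``n_masks * n`` entries.
    """
    if n_masks < 1:
        raise ValueError("n_masks must be >= 1")
    if phi_mode not in ("random", "edge"):
        raise ValueError(f"unknown phi_mode {phi_mode!r}")
    stack = np.asarray(stack)
    n = stack.shape[0]
    box = stack.shape[1]
    if sub_box > box:
        raise ValueError("sub_box larger than particle box")
    apix = azavg.pixel_size
    rng = np.random.default_rng(seed)

    # exact rotational invariance lets one masked projector serve every
    # mask azimuth
    azavg_sym = symmetrize_cylindrical(azavg)
    if surface_radius is None:
        from .azimuthal import outer_surface_radius

        surface_radius = outer_surface_radius(azavg_sym)
    mask0 = SphericalMask((surface_radius, 0.0, 0.0), mask_radius, soft_edge)
    mvol0 = make_spherical_mask(mask0.center_cyl, mask_radius, soft_edge, box, apix)
    masked0 = DensityVolume(azavg_sym.voxels * mvol0.voxels, apix)
    projectors = (
        FourierProjector(azavg_sym),
        FourierProjector(masked0),
        FourierProjector(mvol0),
        0.0,
    )

    lo = box // 2 - sub_box // 2
    hi = lo + sub_box
    sub_images = np.empty((n_masks * n, sub_box, sub_box), dtype=np.float32)
    rows = []
    k = 0
    copy_cols = [
        c
        for c in records.columns
        if c.startswith("tl_") or c in ("rlnDefocusU",)
    ]
    for i in range(n):
        rec = records.iloc[i]
        rot = float(rec["rlnAngleRot"])
        tilt = float(rec["rlnAngleTilt"])
        psi = float(rec["rlnAnglePsi"])
        sx = float(rec.get("rlnOriginXAngst", 0.0)) / apix
        sy = float(rec.get("rlnOriginYAngst", 0.0)) / apix
        for j in range(n_masks):
            if phi_mode == "random":
                alpha = float(rng.uniform(0.0, 360.0))
            else:
                alpha = ((90.0 if j % 2 == 0 else 270.0) - rot) % 360.0
            mask = mask0.rotated(alpha)
            sub = subtract_outside_roi(
                stack[i].astype(np.float64),
                rec,
                azavg_sym,
                mask,
                optics=optics,
                projectors=projectors,
            )
            offset = project_point(
                mask.center_xyz,
                EulerTriplet(rot, tilt, psi),
                Shift2D(sx, sy),
                apix,
            )
            recentered = fourier_shift_2d(sub, -offset[0], -offset[1])
            sub_images[k] = recentered[lo:hi, lo:hi]
            row = {
                "rlnImageName": f"{k + 1:06d}@subparticles.mrcs",
                "rlnAngleRot": (rot + alpha) % 360.0,
                "rlnAngleTilt": tilt,
                "rlnAnglePsi": psi,
                "rlnOriginXAngst": (sx - offset[0]) * apix,
                "rlnOriginYAngst": (sy - offset[1]) * apix,
                "tl_parent_index": float(i),
                "tl_mask_azimuth": alpha,
                "tl_recenter_dx": float(offset[0]),
                "tl_recenter_dy": float(offset[1]),
            }
            for c in copy_cols:
                row[c] = rec[c]
            rows.append(row)
            k += 1
    return sub_images, pd.DataFrame(rows)
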