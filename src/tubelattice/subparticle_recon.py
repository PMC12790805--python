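"""Sub-particle extraction and reconstruction at model-derived coordinates.

Focuses refinement on a small 3D site — here the variable-domain (VD)
membrane-contact position at the center of a lattice tetramer.  Offsets of
the site's projection are computed per particle from pure geometry, a
small box is re-extracted around each offset, the rot (phi) metadata is
adjusted so every site lands in a common frame, and the sub-stack is
backprojected without any symmetry.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .geometry import (
    DensityVolume,
    EulerTriplet,
    Shift2D,
    fourier_shift_2d,
    project_point,
    reconstruct_backproject,
)

__all__ = [
    "compute_subparticle_offsets",
    "extract_subparticles",
    "reconstruct_subparticle",
    "nine_offset_points",
]


def nine_offset_points(spec, radius: float | None = None) -> np.ndarray:
    """The 3x3 grid of contact-site coordinates around a lattice center.

    Tube-frame positions (angstrom) at the VD radius: the central contact
    site plus its neighbors one tetramer step (two subunits) away in
    azimuth and one rung step in z — nine sites covering the center of
    the stacked lattice.
    """
    if radius is None:
        radius = spec.layer_radii["VD"]
    step_az = 2.0 * 360.0 / spec.subunits_per_rung  # tetramer = 2 subunits
    step_z = spec.rung_spacing_stacked
    pts = []
    for dz in (-1, 0, 1):
        for da in (-1, 0, 1):
            a = math.radians(da * step_az + dz * spec.rung_twist)
            pts.append(
                [radius * math.cos(a), radius * math.sin(a), dz * step_z]
            )
    return np.array(pts)


def compute_subparticle_offsets(points, records: pd.DataFrame, pixel_size: float):
    """Projected offsets and rot adjustments for each (particle, point).

    For tube-frame point ``p`` and particle orientation/shift from the
    records, the image-plane offset is ``project_point(p)`` (pixels from
    the box center) and the rot adjustment is the azimuth of ``p`` about
    the tube axis: adding it to the particle's rot re-expresses the view
    in a tube frame rotated so that ``p`` sits at azimuth zero.  Pure
    geometry; no image access.

    Returns ``(offsets, sub_records)`` with offsets of shape
    ``(n_particles, n_points, 2)`` and one adjusted record per
    (particle, point) in particle-major order.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n_pts = points.shape[0]
    azimuths = np.degrees(np.arctan2(points[:, 1], points[:, 0]))
    offsets = np.empty((len(records), n_pts, 2))
    rows = []
    for i in range(len(records)):
        rec = records.iloc[i]
        euler = EulerTriplet(
            float(rec["rlnAngleRot"]),
            float(rec["rlnAngleTilt"]),
            float(rec["rlnAnglePsi"]),
        )
        shift = Shift2D(
            float(rec.get("rlnOriginXAngst", 0.0)) / pixel_size,
            float(rec.get("rlnOriginYAngst", 0.0)) / pixel_size,
        )
        for j in range(n_pts):
            off = project_point(points[j], euler, shift, pixel_size)
            offsets[i, j] = off
            row = dict(rec)
            row["rlnAngleRot"] = (euler.rot + azimuths[j]) % 360.0
            # after re-centering on p the sub-image is centered on the
            # site: zero origins put the site at the reconstruction center
            row["rlnOriginXAngst"] = 0.0
            row["rlnOriginYAngst"] = 0.0
            row["tl_point_index"] = float(j)
            row["tl_parent_index"] = float(i)
            rows.append(row)
    return offsets, pd.DataFrame(rows)


def extract_subparticles(
    stack: np.ndarray,
    offsets: np.ndarray,
    box: int,
    boundary: str = "error",
):
    """Crop a ``box``-sized window centered (sub-pixel) at each offset.

    Re-centering uses a Fourier shift (periodic) followed by an integer
    center crop, keeping centering error below 0.1 px.  With
    ``boundary="error"`` a window that would leave the parent image
    raises, naming the particle; ``"pad_mean"`` pads the parent with its
    mean intensity first so wrapped content is replaced by a neutral
    level.
    """
    stack = np.asarray(stack)
    n, parent = stack.shape[0], stack.shape[1]
    if box > parent:
        raise ValueError("sub-particle box exceeds parent box")
    if boundary not in ("error", "pad_mean"):
        raise ValueError(f"unknown boundary policy {boundary!r}")
    offsets = np.asarray(offsets, dtype=float)
    if offsets.ndim == 2:
        offsets = offsets[:, None, :]
    n_pts = offsets.shape[1]
    half = box // 2
    out = np.empty((n * n_pts, box, box), dtype=np.float64)
    k = 0
    for i in range(n):
        img = stack[i].astype(np.float64)
        for j in range(n_pts):
            dx, dy = offsets[i, j]
            if boundary == "error":
                if (
                    abs(dx) + half > parent // 2
                    or abs(dy) + half > parent // 2
                ):
                    raise ValueError(
                        f"sub-particle window leaves the image for particle "
                        f"{i} (offset {dx:.1f},{dy:.1f} px)"
                    )
                work = img
            else:
                pad = box
                work = np.pad(img, pad, mode="constant", constant_values=img.mean())
            shifted = fourier_shift_2d(work, -dx, -dy)
            c = work.shape[0] // 2
            out[k] = shifted[c - half : c + half, c - half : c + half]
            k += 1
    return out


def reconstruct_subparticle(
    sub_stack: np.ndarray,
    sub_records: pd.DataFrame,
    pixel_size: float,
    ctf_mode: str = "none",
    optics=None,
) -> DensityVolume:
    """Backproject extracted sub-particles with their adjusted records.

    No symmetry is imposed.  The reconstruction converges on the site's
    neighborhood with the site at its tube-frame position rotated to
    azimuth zero (the frame established by the rot adjustment).
    """
    return reconstruct_backproject(
        sub_stack, sub_records, ctf_mode=ctf_mode, optics=optics,
        pixel_size=pixel_size,
    )
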