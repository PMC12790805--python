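"""Constrained projection matching, FSC resolution estimation, and
helical-lattice parameter estimation.

Projection matching scores low-pass-limited normalized cross-correlation
(not a likelihood) between each particle and reference projections on a
local angular grid, optimizing shifts by FFT correlation; only score
improvements are accepted.  Stages mirror the coarse-to-fine ladder used
in practice (wider particle fraction and tighter resolution limit as
refinement proceeds).

Lattice parameters (rise and twist between adjacent rungs) are estimated
from the refined map's self-correlation under a helical transform,
evaluated efficiently on a cylindrical resampling of the asymmetric
(cylindrical-average-subtracted) density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import (
    DensityVolume,
    EulerTriplet,
    FourierProjector,
    Shift2D,
    _cfft2,
    _cifft2,
    _freq_grid_2d,
)
from .azimuthal import symmetrize_cylindrical

__all__ = [
    "FSCCurve",
    "LatticeParams",
    "Stage",
    "compute_fsc",
    "projection_match",
    "multireference_assign",
    "estimate_lattice_params",
]


# ---------------------------------------------------------------------------
# FSC


@dataclass
class FSCCurve:
    """Fourier shell correlation between two maps.

    ``frequencies`` are shell centers in 1/angstrom (strictly increasing up
    to Nyquist); ``values`` in [-1, 1].
    """

    frequencies: np.ndarray
    values: np.ndarray

    def resolution_at(self, threshold: float = 0.143) -> float:
        """Resolution (angstrom) at the first crossing below ``threshold``.

        Linear interpolation between shells; returns ``inf`` if the curve
        never reaches the threshold (featureless input) and the Nyquist
        resolution if it never drops below it.
        """
        v = self.values
        f = self.frequencies
        if v[0] < threshold:
            return math.inf
        for i in range(1, len(v)):
            if v[i] < threshold:
                f_cross = f[i - 1] + (f[i] - f[i - 1]) * (
                    (v[i - 1] - threshold) / (v[i - 1] - v[i])
                )
                return 1.0 / f_cross
        return 1.0 / f[-1]


def compute_fsc(vol_a: DensityVolume, vol_b: DensityVolume) -> FSCCurve:
    """Shell-wise normalized cross-correlation of Fourier coefficients.

    Shells with zero power in either map get correlation 0.
    """
    if vol_a.voxels.shape != vol_b.voxels.shape:
        raise ValueError("volumes must share a grid")
    n = vol_a.boxsize
    fa = np.fft.fftn(vol_a.voxels)
    fb = np.fft.fftn(vol_b.voxels)
    k = np.fft.fftfreq(n) * n  # integer frequency grid
    kz, ky, kx = np.meshgrid(k, k, k, indexing="ij")
    shell = np.round(np.sqrt(kx**2 + ky**2 + kz**2)).astype(int)
    nshell = n // 2
    cross = np.zeros(nshell, dtype=complex)
    pa = np.zeros(nshell)
    pb = np.zeros(nshell)
    flat = shell.ravel()
    sel = flat < nshell
    np.add.at(cross, flat[sel], (fa * np.conj(fb)).ravel()[sel])
    np.add.at(pa, flat[sel], (np.abs(fa) ** 2).ravel()[sel])
    np.add.at(pb, flat[sel], (np.abs(fb) ** 2).ravel()[sel])
    denom = np.sqrt(pa * pb)
    vals = np.zeros(nshell)
    ok = denom > 0
    vals[ok] = cross.real[ok] / denom[ok]
    freqs = np.arange(nshell) / (n * vol_a.pixel_size)
    # shell 0 is the DC term; report from shell 1 with strictly increasing f
    return FSCCurve(freqs[1:], vals[1:])


def _lowpass_2d(image: np.ndarray, pixel_size: float, res_limit: float | None):
    if not res_limit:
        return image
    n = image.shape[0]
    ky, kx = _freq_grid_2d(n)
    f = np.hypot(kx, ky) / (n * pixel_size)
    keep = f <= 1.0 / res_limit
    return _cifft2(_cfft2(image) * keep).real


# ---------------------------------------------------------------------------
# projection matching


@dataclass(frozen=True)
class Stage:
    """One refinement stage of the coarse-to-fine ladder."""

    search_deg: float
    step_deg: float
    res_limit: float  # angstrom
    fraction: float = 1.0  # particle fraction refined in this stage


def _norm(img: np.ndarray) -> float:
    return float(np.sqrt(np.sum((img - img.mean()) ** 2)))


def _best_shift_score(ref_f: np.ndarray, img_f: np.ndarray, n: int, max_shift: float):
    """Peak cross-correlation (and shift) between two centered transforms."""
    cc = _cifft2(img_f * np.conj(ref_f)).real
    c = n // 2
    w = int(math.ceil(max_shift))
    win = cc[c - w : c + w + 1, c - w : c + w + 1]
    iy, ix = np.unravel_index(np.argmax(win), win.shape)
    score = win[iy, ix]
    dy, dx = iy - w, ix - w
    # parabolic sub-pixel refinement, clamped to the window
    def para(m, i, axis):
        if 0 < i < m.shape[axis] - 1:
            if axis == 0:
                y0, y1, y2 = m[i - 1, ix], m[i, ix], m[i + 1, ix]
            else:
                y0, y1, y2 = m[iy, i - 1], m[iy, i], m[iy, i + 1]
            d = y0 - 2 * y1 + y2
            if abs(d) > 1e-12:
                return 0.5 * (y0 - y2) / d
        return 0.0

    return score, (dx + para(win, ix, 1), dy + para(win, iy, 0))


def projection_match(
    stack: np.ndarray,
    records: pd.DataFrame,
    reference: DensityVolume,
    stages,
    angles=("rot", "tilt", "psi"),
    max_shift: float = 6.0,
    seed=0,
):
    """Local orientation refinement against a reference map.

    Per stage, for the stage's particle fraction (lowest-score particles
    first, so poorly aligned ones are revisited): grid-search the
    permitted ``angles`` around the current values (coordinate descent:
    rot/tilt plane first, then psi), score each candidate by low-pass
    limited normalized cross-correlation with FFT shift optimization, and
    accept only improvements.  Returns ``(new_records, scores)``.
    """
    stages = [s if isinstance(s, Stage) else Stage(*s) for s in stages]
    if not stages:
        raise ValueError("empty stage list")
    stack = np.asarray(stack)
    n_part, n = stack.shape[0], stack.shape[1]
    if reference.boxsize != n:
        raise ValueError("reference grid does not match stack")
    apix = reference.pixel_size
    fp = FourierProjector(reference)
    out = records.copy().reset_index(drop=True)
    rng = np.random.default_rng(seed)

    cur_scores = np.full(n_part, -np.inf)
    ky, kx = _freq_grid_2d(n)

    def score_candidate(img_f, img_norm, euler):
        ref = fp.project(euler)
        refl = _lowpass_2d(ref, apix, res)
        rnorm = _norm(refl)
        if rnorm == 0 or img_norm == 0:
            return -np.inf, (0.0, 0.0)
        ref_f = _cfft2(refl - refl.mean())
        raw, sh = _best_shift_score(ref_f, img_f, n, max_shift)
        return raw / (rnorm * img_norm), sh

    for stage in stages:
        res = stage.res_limit
        # lowest-scoring fraction first; ties broken deterministically
        order = np.argsort(cur_scores, kind="stable")
        m = max(1, int(round(stage.fraction * n_part)))
        subset = order[:m]
        for i in subset:
            img = _lowpass_2d(stack[i].astype(float), apix, res)
            img_f = _cfft2(img - img.mean())
            img_norm = _norm(img)
            rot0 = float(out.at[i, "rlnAngleRot"])
            tilt0 = float(out.at[i, "rlnAngleTilt"])
            psi0 = float(out.at[i, "rlnAnglePsi"])
            best = (cur_scores[i], rot0, tilt0, psi0, None)
            offs = np.arange(-stage.search_deg, stage.search_deg + 1e-9, stage.step_deg)
            # coordinate descent over the angular grid, repeated until the
            # best candidate stops moving (a single rot/tilt-then-psi pass
            # can stall when the starting psi is off)
            for _ in range(3):
                prev_best = best[:4]
                rot_c = best[1] + offs if "rot" in angles else [best[1]]
                tilt_c = best[2] + offs if "tilt" in angles else [best[2]]
                for r_ in rot_c:
                    for t_ in tilt_c:
                        s, sh = score_candidate(
                            img_f, img_norm, EulerTriplet(r_, t_, best[3])
                        )
                        if s > best[0]:
                            best = (s, r_ % 360.0, t_ % 360.0, best[3], sh)
                psi_c = best[3] + offs if "psi" in angles else []
                for p_ in psi_c:
                    s, sh = score_candidate(
                        img_f, img_norm, EulerTriplet(best[1], best[2], p_)
                    )
                    if s > best[0]:
                        best = (s, best[1], best[2], p_ % 360.0, sh)
                if best[:4] == prev_best:
                    break
            if best[4] is not None:
                cur_scores[i] = best[0]
                out.at[i, "rlnAngleRot"] = best[1]
                out.at[i, "rlnAngleTilt"] = best[2]
                out.at[i, "rlnAnglePsi"] = best[3]
                # cross-correlation peak at (dx, dy) means the image is the
                # reference shifted by +d: record it as the new origin
                out.at[i, "rlnOriginXAngst"] = best[4][0] * apix
                out.at[i, "rlnOriginYAngst"] = best[4][1] * apix
    return out, cur_scores


def multireference_assign(
    stack: np.ndarray,
    records: pd.DataFrame,
    references,
    res_limit: float = 20.0,
    max_shift: float = 6.0,
):
    """Assign each particle to the best-matching of K reference maps.

    A deterministic, simplified stand-in for multi-class 3D
    classification: per particle, the reference whose projection at the
    particle's current orientation correlates best (with shift
    optimization) wins.  Returns an integer class vector and the score
    matrix.
    """
    stack = np.asarray(stack)
    n_part, n = stack.shape[0], stack.shape[1]
    fps = [FourierProjector(r) for r in references]
    apix = references[0].pixel_size
    scores = np.zeros((n_part, len(fps)))
    for i in range(n_part):
        img = _lowpass_2d(stack[i].astype(float), apix, res_limit)
        img_f = _cfft2(img - img.mean())
        img_norm = _norm(img)
        e = EulerTriplet(
            float(records["rlnAngleRot"].iloc[i]),
            float(records["rlnAngleTilt"].iloc[i]),
            float(records["rlnAnglePsi"].iloc[i]),
        )
        for k, fp in enumerate(fps):
            ref = _lowpass_2d(fp.project(e), apix, res_limit)
            rnorm = _norm(ref)
            if rnorm == 0 or img_norm == 0:
                continue
            raw, _ = _best_shift_score(_cfft2(ref - ref.mean()), img_f, n, max_shift)
            scores[i, k] = raw / (rnorm * img_norm)
    return scores.argmax(axis=1), scores


# ---------------------------------------------------------------------------
# lattice parameters


@dataclass
class LatticeParams:
    """Helical lattice parameters relating adjacent rungs."""

    rise: float  # angstrom
    twist: float  # degrees, positive = right-handed
    handedness: str
    score: float
    success: bool
    score_map: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.success and self.rise <= 0:
            raise ValueError("rise must be positive")


def _cylindrical_resample(
    volume: DensityVolume, r_min: float, r_max: float, n_theta: int
):
    """Sample a volume on a (z, theta, r) grid; returns array + radii (px)."""
    n = volume.boxsize
    c = n // 2
    apix = volume.pixel_size
    radii = np.arange(r_min / apix, r_max / apix + 1e-9, 1.0)
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    tt, rr = np.meshgrid(theta, radii, indexing="ij")
    ys = c + rr * np.sin(tt)
    xs = c + rr * np.cos(tt)
    out = np.empty((n, n_theta, len(radii)))
    for z in range(n):
        out[z] = ndimage.map_coordinates(
            volume.voxels[z], np.stack([ys.ravel(), xs.ravel()]), order=1
        ).reshape(n_theta, len(radii))
    return out, radii


def estimate_lattice_params(
    volume: DensityVolume,
    rise_range=(30.0, 80.0),
    twist_range=(-6.0, 6.0),
    annulus=(150.0, 280.0),
    n_theta: int = 480,
    margin: float = 2.0,
) -> LatticeParams:
    """Estimate rung rise and twist from a lattice-bearing map.

    The cylindrically symmetric component is removed, the residual is
    resampled on a (z, theta, r) grid over the protein ``annulus``
    (angstrom), and the normalized self-correlation under the helical
    transform (z shift = rise, azimuth shift = twist) is evaluated for all
    lags at once by FFT.  The argmax inside the search window is refined
    parabolically.  The fit is flagged unsuccessful when the peak does not
    exceed ``margin`` times the median |score| over the window (the
    cylindrical-baseline check) or when the asymmetric residual carries no
    power, as for an azimuthally symmetric map.

    Note: for a lattice of closed rings with S subunits per rung, twist is
    only identifiable modulo 360/S; choose ``twist_range`` narrower than
    one subunit step (the default suits the bundled generator).
    """
    if rise_range[0] >= rise_range[1] or twist_range[0] >= twist_range[1]:
        raise ValueError("empty search range")
    apix = volume.pixel_size
    resid = DensityVolume(
        volume.voxels - symmetrize_cylindrical(volume).voxels, apix
    )
    cyl, radii = _cylindrical_resample(resid, annulus[0], annulus[1], n_theta)
    nz = cyl.shape[0]

    total_power = float(np.sum(cyl**2))
    vol_power = float(np.sum(volume.voxels**2))
    if total_power < 1e-9 * max(vol_power, 1e-30):
        return LatticeParams(0.0, 0.0, "none", 0.0, False)

    # linear correlation in z (zero-padded), circular in theta
    pad = np.zeros((2 * nz, n_theta, cyl.shape[2]))
    pad[:nz] = cyl
    f = np.fft.fft2(pad, axes=(0, 1))
    corr = np.fft.ifft2(f * np.conj(f), axes=(0, 1)).real
    # weight shells by radius (annulus area) and sum
    corr = (corr * radii[None, None, :]).sum(axis=2)
    # overlap length for each z lag (0..nz-1 forward, wrap for negative)
    lag_overlap = np.minimum(np.arange(2 * nz), 2 * nz - np.arange(2 * nz))
    lag_overlap = np.maximum(nz - lag_overlap, 1)
    norm0 = corr[0, 0]
    score_map = corr / norm0 * (nz / lag_overlap)[:, None]

    # search window
    z_lo = max(1, int(math.floor(rise_range[0] / apix)))
    z_hi = min(nz - 1, int(math.ceil(rise_range[1] / apix)))
    dtheta = 360.0 / n_theta
    t_lo = int(math.floor(twist_range[0] / dtheta))
    t_hi = int(math.ceil(twist_range[1] / dtheta))
    zs = np.arange(z_lo, z_hi + 1)
    ts = np.arange(t_lo, t_hi + 1)
    win = score_map[np.ix_(zs, ts % n_theta)]
    iz, it = np.unravel_index(np.argmax(win), win.shape)
    best = float(win[iz, it])
    med = float(np.median(np.abs(win)))
    success = best > margin * max(med, 1e-12) and best > 0.05

    # parabolic refinement
    def para(v0, v1, v2):
        d = v0 - 2 * v1 + v2
        return 0.5 * (v0 - v2) / d if abs(d) > 1e-12 else 0.0

    dz = float(zs[iz])
    if 0 < iz < len(zs) - 1:
        dz += para(win[iz - 1, it], win[iz, it], win[iz + 1, it])
    dt = float(ts[it])
    if 0 < it < len(ts) - 1:
        dt += para(win[iz, it - 1], win[iz, it], win[iz, it + 1])

    rise = dz * apix
    # circular correlation peaks at lag (+rise, +twist): a site at
    # (theta, z) implies one at (theta + twist, z + rise); positive theta
    # lag is rotation x toward y (verified against a known helix)
    twist = dt * dtheta
    hand = "right" if twist > 0 else ("left" if twist < 0 else "none")
    if not success:
        return LatticeParams(0.0, 0.0, "none", best, False, score_map)
    return LatticeParams(rise, twist, hand, best, True, score_map)
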