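"""Forward model for protein-decorated lipid nanotubes.

Emulates boxed cryo-EM particle images of a GalCer-like nanotube (~20 nm
inner lumen) decorated by a locally ordered protein lattice with two
conformational states:

* **stacked** — circumferential rungs at short, regular spacing with both a
  bottom and a top G-domain layer between rungs, plus rod-like
  variable-domain (VD) densities contacting the outer membrane leaflet
  under tetramer centers;
* **relaxed** — bottom G-domain layer only, with longer and more variable
  rung spacing and no membrane contact.

The density model is deliberately coarse-grained: two concentric Gaussian
shells for the bilayer leaflets plus Gaussian pseudo-domain blobs at
lattice sites (stalk, bottom G, top G, VD contact).  Images are central
slice projections of these volumes, modulated by a standard CTF and
degraded with additive white Gaussian noise.  Every particle carries its
ground truth (angles, shifts, state, defocus) in ``tl_*`` metadata columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    DensityVolume,
    EulerTriplet,
    FourierProjector,
    Shift2D,
    rotation_matrix,
)

__all__ = [
    "TubeLatticeSpec",
    "OpticsParams",
    "LatticeSite",
    "build_lattice_volume",
    "build_membrane_volume",
    "build_volume_from_sites",
    "electron_wavelength",
    "ctf_2d",
    "apply_ctf",
    "simulate_particles",
    "noise_sd_for_snr",
    "DEFAULT_SPEC",
    "DEFAULT_OPTICS",
]


@dataclass(frozen=True)
class TubeLatticeSpec:
    """Generative parameters of one decorated nanotube.

    All lengths in angstrom, angles in degrees.  The default geometry keeps
    the ordering membrane < VD < stalk < bottom G < top G of the radial
    layers; absolute protein-layer radii are free simulator parameters (the
    source data constrain only the ordering and the ~20 nm lumen).
    """

    lumen_diameter: float = 200.0
    leaflet_radii: tuple[float, float] = (100.0, 140.0)
    layer_radii: dict = field(
        default_factory=lambda: {
            "VD": 150.0,
            "stalk": 190.0,
            "bottomG": 230.0,
            "topG": 260.0,
        }
    )
    rung_rise: float = 50.0
    twist_per_subunit: float = -12.0
    subunits_per_rung: int = 30
    rung_twist: float = -5.0
    rung_spacing_stacked: float = 50.0
    rung_spacing_relaxed: float = 65.0
    spacing_jitter_sd: float = 2.0
    stacked_fraction: float = 0.5
    blob_sd: float = 8.0
    # the G-domain head is bulky; equal peak amplitudes under-weight it at
    # edge views relative to the quasi-continuous stalk ring, whereas the
    # top-G layer is a clearly visible edge-view feature in the system
    # this generator emulates
    topG_amplitude: float = 2.0
    contact_on: bool = True

    def __post_init__(self):
        if self.lumen_diameter <= 0:
            raise ValueError("lumen_diameter must be positive")
        r_in, r_out = self.leaflet_radii
        order = [r_in, r_out] + [
            self.layer_radii[k] for k in ("VD", "stalk", "bottomG", "topG")
        ]
        if any(b <= a for a, b in zip(order, order[1:])):
            raise ValueError(
                "radii must be strictly ordered membrane < VD < stalk < "
                f"bottomG < topG, got {order}"
            )
        if self.rung_spacing_relaxed < self.rung_spacing_stacked:
            raise ValueError("relaxed rung spacing must be >= stacked spacing")
        if not 0.0 <= self.stacked_fraction <= 1.0:
            raise ValueError("stacked_fraction must be in [0, 1]")
        if self.blob_sd <= 0 or self.spacing_jitter_sd < 0:
            raise ValueError("invalid blob_sd / spacing_jitter_sd")
        if self.subunits_per_rung < 1:
            raise ValueError("subunits_per_rung must be >= 1")


@dataclass(frozen=True)
class OpticsParams:
    """Microscope parameters for the CTF model."""

    pixel_size: float = 4.0
    voltage: float = 300.0  # kV
    spherical_aberration: float = 2.7  # mm
    amplitude_contrast: float = 0.07
    defocus_range: tuple[float, float] = (5000.0, 20000.0)  # angstrom underfocus

    def __post_init__(self):
        if self.pixel_size <= 0 or self.voltage <= 0:
            raise ValueError("pixel_size and voltage must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must be in [0, 1]")
        if self.defocus_range[0] > self.defocus_range[1]:
            raise ValueError("defocus range min must be <= max")


DEFAULT_SPEC = TubeLatticeSpec()
DEFAULT_OPTICS = OpticsParams()


@dataclass(frozen=True)
class LatticeSite:
    """One pseudo-domain blob: tube-frame position, label and amplitude."""

    position: tuple[float, float, float]  # (x, y, z) angstrom
    label: str  # stalk | bottomG | topG | contact
    rung: int
    subunit: int
    amplitude: float = 1.0


# ---------------------------------------------------------------------------
# volume construction


def _cyl(radius: float, azimuth_deg: float, z: float):
    a = math.radians(azimuth_deg)
    return (radius * math.cos(a), radius * math.sin(a), z)


def lattice_sites(
    spec: TubeLatticeSpec, state: str, boxsize: int, pixel_size: float, rng
) -> list[LatticeSite]:
    """Lattice site list for one tube realization.

    Rung z positions follow a random walk: the gap to the next rung is the
    state's nominal spacing plus N(0, spacing_jitter_sd), so disorder
    accumulates with distance (local order only).  Azimuthal offsets of
    successive rungs advance by ``rung_twist`` and likewise accumulate an
    angular jitter of matching arc length at the stalk radius.
    """
    if state not in ("stacked", "relaxed", "mixed"):
        raise ValueError(f"unknown state {state!r}")
    half = boxsize * pixel_size / 2.0
    sites: list[LatticeSite] = []
    r_stalk = spec.layer_radii["stalk"]
    step = 360.0 / spec.subunits_per_rung
    jitter_deg = math.degrees(spec.spacing_jitter_sd / r_stalk)

    # walk outward from z=0 in both directions so the center is well covered
    spacing = {
        "stacked": spec.rung_spacing_stacked,
        "relaxed": spec.rung_spacing_relaxed,
    }
    rung_positions = [(0, 0.0, 0.0)]  # (index, z, azimuth offset)
    z, az, idx = 0.0, 0.0, 0
    while True:
        rung_state = state if state != "mixed" else (
            "stacked" if rng.random() < spec.stacked_fraction else "relaxed"
        )
        gap = spacing[rung_state] + rng.normal(0.0, spec.spacing_jitter_sd)
        z += max(gap, spec.blob_sd)
        az += spec.rung_twist + rng.normal(0.0, jitter_deg)
        idx += 1
        if z > half + spacing["relaxed"]:
            break
        rung_positions.append((idx, z, az))
    z, az, idx = 0.0, 0.0, 0
    while True:
        rung_state = state if state != "mixed" else (
            "stacked" if rng.random() < spec.stacked_fraction else "relaxed"
        )
        gap = spacing[rung_state] + rng.normal(0.0, spec.spacing_jitter_sd)
        z -= max(gap, spec.blob_sd)
        az -= spec.rung_twist + rng.normal(0.0, jitter_deg)
        idx -= 1
        if z < -half - spacing["relaxed"]:
            break
        rung_positions.append((idx, z, az))

    r_leaf_out = spec.leaflet_radii[1]
    for idx, z_r, az_r in rung_positions:
        rung_state = state
        if state == "mixed":
            rung_state = "stacked" if rng.random() < spec.stacked_fraction else "relaxed"
        for i in range(spec.subunits_per_rung):
            a = az_r + i * math.copysign(step, spec.twist_per_subunit)
            a += rng.normal(0.0, jitter_deg)
            sites.append(LatticeSite(_cyl(r_stalk, a, z_r), "stalk", idx, i))
            sites.append(
                LatticeSite(_cyl(spec.layer_radii["bottomG"], a, z_r), "bottomG", idx, i)
            )
            if rung_state == "stacked":
                sites.append(
                    LatticeSite(
                        _cyl(spec.layer_radii["topG"], a, z_r),
                        "topG",
                        idx,
                        i,
                        amplitude=spec.topG_amplitude,
                    )
                )
                # VD-membrane contact rod under tetramer centers (every
                # second subunit), bridging outer leaflet and VD layer
                if spec.contact_on and i % 2 == 0:
                    r0, r1 = r_leaf_out, spec.layer_radii["VD"]
                    nrod = max(2, int(round((r1 - r0) / (spec.blob_sd / 1.5))) + 1)
                    for r in np.linspace(r0, r1, nrod):
                        sites.append(
                            LatticeSite(_cyl(float(r), a, z_r), "contact", idx, i, 0.8)
                        )
    return sites


def build_volume_from_sites(
    sites, boxsize: int, pixel_size: float, blob_sd: float
) -> np.ndarray:
    """Render Gaussian blobs (unit peak x amplitude) onto a voxel grid."""
    n = boxsize
    c = n // 2
    vol = np.zeros((n, n, n))
    reach = max(2, int(math.ceil(3.0 * blob_sd / pixel_size)))
    ax = np.arange(-reach, reach + 1)
    inv2s2 = (pixel_size**2) / (2.0 * blob_sd**2)
    for s in sites:
        x, y, z = (np.asarray(s.position) / pixel_size)
        ix, iy, iz = int(round(x)), int(round(y)), int(round(z))
        ez = np.exp(-((ax + iz - z) ** 2) * inv2s2)
        ey = np.exp(-((ax + iy - y) ** 2) * inv2s2)
        ex = np.exp(-((ax + ix - x) ** 2) * inv2s2)
        zsl = slice(iz + c - reach, iz + c + reach + 1)
        ysl = slice(iy + c - reach, iy + c + reach + 1)
        xsl = slice(ix + c - reach, ix + c + reach + 1)
        # clip blobs at the box edge
        z0, z1 = max(zsl.start, 0), min(zsl.stop, n)
        y0, y1 = max(ysl.start, 0), min(ysl.stop, n)
        x0, x1 = max(xsl.start, 0), min(xsl.stop, n)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        blob = s.amplitude * (
            ez[z0 - zsl.start : z1 - zsl.start, None, None]
            * ey[None, y0 - ysl.start : y1 - ysl.start, None]
            * ex[None, None, x0 - xsl.start : x1 - xsl.start]
        )
        vol[z0:z1, y0:y1, x0:x1] += blob
    return vol


def build_membrane_volume(
    spec: TubeLatticeSpec, boxsize: int, pixel_size: float
) -> DensityVolume:
    """Undecorated nanotube: the two leaflet shells only."""
    return DensityVolume(_membrane_shells(spec, boxsize, pixel_size), pixel_size)


def _membrane_shells(spec: TubeLatticeSpec, boxsize: int, pixel_size: float):
    n = boxsize
    c = n // 2
    ax = (np.arange(n) - c) * pixel_size
    r = np.hypot(ax[:, None], ax[None, :])  # (y, x) radial distance
    shell = np.zeros_like(r)
    sd = spec.blob_sd
    for radius in spec.leaflet_radii:
        shell += np.exp(-((r - radius) ** 2) / (2.0 * sd**2))
    return np.broadcast_to(shell, (n, n, n)).copy()


def build_lattice_volume(
    spec: TubeLatticeSpec,
    state: str,
    boxsize: int,
    pixel_size: float,
    seed=None,
):
    """Build a decorated-tube volume; returns ``(DensityVolume, sites)``.

    ``state`` is ``"stacked"``, ``"relaxed"`` or ``"mixed"`` (per-rung draw
    by ``stacked_fraction``).  The box must contain the outermost protein
    layer plus 3 blob widths.
    """
    need = 2 * (spec.layer_radii["topG"] + 3 * spec.blob_sd)
    if boxsize * pixel_size < need:
        raise ValueError(
            f"box ({boxsize * pixel_size:.0f} A) too small for topG radius; "
            f"needs >= {need:.0f} A"
        )
    rng = np.random.default_rng(seed)
    sites = lattice_sites(spec, state, boxsize, pixel_size, rng)
    vol = _membrane_shells(spec, boxsize, pixel_size)
    vol += build_volume_from_sites(sites, boxsize, pixel_size, spec.blob_sd)
    return DensityVolume(vol, pixel_size), sites


# ---------------------------------------------------------------------------
# CTF


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in angstrom."""
    v = voltage_kv * 1e3
    return 12.2639 / math.sqrt(v * (1.0 + 0.97845e-6 * v))


def ctf_2d(n: int, pixel_size: float, optics: OpticsParams, defocus: float):
    """Centered CTF grid, ``CTF(f) = -(sqrt(1-A^2) sin chi + A cos chi)``.

    ``chi(f) = pi lambda dz f^2 - (pi/2) Cs lambda^3 f^4`` with defocus in
    angstrom (positive = underfocus) and Cs converted from mm.
    """
    lam = electron_wavelength(optics.voltage)
    k = (np.arange(n) - n // 2) / (n * pixel_size)  # cycles / angstrom
    f2 = k[:, None] ** 2 + k[None, :] ** 2
    cs = optics.spherical_aberration * 1e7  # mm -> angstrom
    chi = math.pi * lam * defocus * f2 - 0.5 * math.pi * cs * lam**3 * f2**2
    a = optics.amplitude_contrast
    return -(math.sqrt(1.0 - a**2) * np.sin(chi) + a * np.cos(chi))


def apply_ctf(image: np.ndarray, optics: OpticsParams, defocus: float) -> np.ndarray:
    """Multiply the image spectrum by the CTF; returns a real image."""
    from .geometry import _cfft2, _cifft2

    n = image.shape[-1]
    ctf = ctf_2d(n, optics.pixel_size, optics, defocus)
    return _cifft2(_cfft2(image) * ctf).real


def phase_flip_stack(
    stack: np.ndarray,
    defoci,
    optics: OpticsParams,
    amplitude_floor: float | None = None,
) -> np.ndarray:
    """CTF sign correction: multiply each image's spectrum by sign(CTF).

    With ``amplitude_floor`` set (e.g. 0.2) the amplitude is corrected
    too — dividing by ``max(|CTF|, floor)`` — so band contrasts become
    comparable across the defocus spread instead of carrying each
    micrograph's low-frequency attenuation.
    """
    from .geometry import _cfft2, _cifft2

    stack = np.asarray(stack)
    n = stack.shape[-1]
    out = np.empty(stack.shape, dtype=np.float64)
    for i in range(stack.shape[0]):
        ctf = ctf_2d(n, optics.pixel_size, optics, float(defoci[i]))
        s = np.sign(ctf)
        s[s == 0] = 1.0
        if amplitude_floor is not None:
            s = s / np.maximum(np.abs(ctf), amplitude_floor)
        out[i] = _cifft2(_cfft2(stack[i].astype(np.float64)) * s).real
    return out


# ---------------------------------------------------------------------------
# particle simulation


def noise_sd_for_snr(clean: np.ndarray, snr: float) -> float:
    """Noise sigma so that signal variance / noise variance = snr.

    Signal variance is measured over the tube-occupied region, taken as
    pixels whose clean magnitude exceeds 10% of the stack's 99th
    percentile magnitude.
    """
    mag = np.abs(clean)
    thresh = 0.1 * np.percentile(mag, 99.0)
    occ = mag > thresh
    if not occ.any():
        raise ValueError("no signal region found")
    sig_var = np.var(clean[occ])
    return math.sqrt(sig_var / snr)


def simulate_particles(
    spec: TubeLatticeSpec = DEFAULT_SPEC,
    optics: OpticsParams = DEFAULT_OPTICS,
    n: int = 100,
    noise_sd: float | None = None,
    snr: float | None = None,
    phi_mode: str = "random",
    seed=0,
    boxsize: int = 160,
    n_lattice_variants: int = 4,
    shift_perp_max: float = 8.0,
    shift_axial_max: float = 25.0,
):
    """Simulate boxed tube particles; returns ``(stack, records)``.

    Per particle: the state is drawn by ``stacked_fraction``; a lattice
    realization is drawn from a small pool of pre-built state volumes; rot
    (phi) is uniform on [0, 360) (``phi_mode="random"``) or drawn from
    {90, 270} (``"edge"``); tilt is 90 or 270 equiprobably; psi is uniform
    on [0, 360); shifts are uniform with the across-tube component within
    ``shift_perp_max`` and the along-tube component within
    ``shift_axial_max`` (angstrom).  The projection is CTF-modulated at a
    defocus drawn from ``optics.defocus_range`` and white Gaussian noise of
    ``noise_sd`` is added (``snr`` converts to a matching sigma; exactly
    one of the two may be given, default is noise-free).

    Fully reproducible from ``seed``: records include all ground truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if phi_mode not in ("random", "edge"):
        raise ValueError(f"unknown phi_mode {phi_mode!r}")
    if noise_sd is not None and snr is not None:
        raise ValueError("give noise_sd or snr, not both")
    rng = np.random.default_rng(seed)

    n_var = max(1, int(n_lattice_variants))
    projectors = {}
    for state in ("stacked", "relaxed"):
        vols = []
        for v in range(n_var):
            lattice_seed = int(rng.integers(0, 2**31 - 1))
            # skip states that cannot be drawn (keeps the seed stream
            # stable regardless)
            if (state == "stacked" and spec.stacked_fraction == 0.0) or (
                state == "relaxed" and spec.stacked_fraction == 1.0
            ):
                continue
            vol, _ = build_lattice_volume(
                spec, state, boxsize, optics.pixel_size, seed=lattice_seed
            )
            vols.append(FourierProjector(vol))
        projectors[state] = vols

    apix = optics.pixel_size
    states, rots, tilts, psis, sxs, sys_, dfs, variants = [], [], [], [], [], [], [], []
    clean = np.empty((n, boxsize, boxsize))
    for i in range(n):
        state = "stacked" if rng.random() < spec.stacked_fraction else "relaxed"
        variant = int(rng.integers(0, n_var))
        rot = (
            rng.uniform(0.0, 360.0)
            if phi_mode == "random"
            else float(rng.choice([90.0, 270.0]))
        )
        tilt = float(rng.choice([90.0, 270.0]))
        psi = rng.uniform(0.0, 360.0)
        # shift: axial component along the projected tube axis, perpendicular
        # component across it
        ax_shift = rng.uniform(-shift_axial_max, shift_axial_max) / apix
        perp_shift = rng.uniform(-shift_perp_max, shift_perp_max) / apix
        # projected tube axis direction for (tilt, psi): image of +z
        e = EulerTriplet(rot, tilt, psi)
        zdir = rotation_matrix(e) @ np.array([0.0, 0.0, 1.0])
        u = zdir[:2]
        norm = np.linalg.norm(u)
        u = u / norm if norm > 1e-6 else np.array([1.0, 0.0])
        nvec = np.array([-u[1], u[0]])
        s = ax_shift * u + perp_shift * nvec
        defocus = rng.uniform(*optics.defocus_range)
        img = projectors[state][variant].project(e, Shift2D(s[0], s[1]))
        clean[i] = apply_ctf(img, optics, defocus)
        states.append(state)
        rots.append(rot)
        tilts.append(tilt)
        psis.append(psi)
        sxs.append(s[0] * apix)
        sys_.append(s[1] * apix)
        dfs.append(defocus)
        variants.append(variant)

    if snr is not None:
        noise_sd = noise_sd_for_snr(clean, snr)
    stack = clean
    if noise_sd:
        stack = clean + rng.normal(0.0, noise_sd, size=clean.shape)

    records = pd.DataFrame(
        {
            "rlnImageName": [f"{i + 1:06d}@stack.mrcs" for i in range(n)],
            "rlnAngleRot": rots,
            "rlnAngleTilt": tilts,
            "rlnAnglePsi": psis,
            "rlnOriginXAngst": sxs,
            "rlnOriginYAngst": sys_,
            "rlnDefocusU": dfs,
            "tl_state": states,
            "tl_variant": np.array(variants, dtype=float),
            "tl_diameter": np.full(n, 2.0 * spec.leaflet_radii[1]),
            "tl_true_rot": rots,
            "tl_true_tilt": tilts,
            "tl_true_psi": psis,
            "tl_true_sx": sxs,
            "tl_true_sy": sys_,
            "tl_noise_sd": np.full(n, float(noise_sd or 0.0)),
        }
    )
    return stack.astype(np.float32), records
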