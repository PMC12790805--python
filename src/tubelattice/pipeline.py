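"""End-to-end workflows chaining the processing stages.

These drivers reproduce the two self-contained measurements the package
is built around:

* membrane-peak diameter measurement of undecorated nanotubes
  (:func:`lumen_diameter_pipeline`), and
* edge-view RASTR + 2D classification recovery of the stacked-state
  fraction of a simulated mixed dataset
  (:func:`stacked_fraction_pipeline`).

Each consumes a single integer seed; every stage's randomness is derived
from it through ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import numpy as np

from .synthetic_data import (
    DEFAULT_OPTICS,
    TubeLatticeSpec,
    build_membrane_volume,
    simulate_particles,
)
from .geometry import EulerTriplet, FourierProjector, Shift2D
from .tube_align import align_stack, estimate_psi_shift, measure_diameter
from .azimuthal import azimuthal_average
from .rastr_core import make_rastr_subparticles
from .classify import band_geometry_from_spec, quantify_stacked_fraction

__all__ = ["lumen_diameter_pipeline", "stacked_fraction_pipeline"]


def _subseeds(seed, n):
    return [int(s) for s in np.random.SeedSequence(int(seed)).generate_state(n) >> 1]


def lumen_diameter_pipeline(
    seed,
    n: int = 50,
    spec: TubeLatticeSpec | None = None,
    boxsize: int = 160,
    pixel_size: float = 4.0,
):
    """Measure the inner-lumen diameter of noise-free synthetic tubes.

    Projects ``n`` undecorated-tube images at random orientations and
    in-plane angles, estimates psi/shift, measures the outer-leaflet
    diameter by membrane peak detection, and converts to the
    lumen-equivalent diameter by subtracting twice the generator's known
    bilayer thickness.  Returns a dict with per-particle diameters and
    the mean lumen diameter in nanometers.
    """
    spec = spec or TubeLatticeSpec()
    rng = np.random.default_rng(_subseeds(seed, 1)[0])
    vol = build_membrane_volume(spec, boxsize, pixel_size)
    fp = FourierProjector(vol)
    bilayer = 2.0 * (spec.leaflet_radii[1] - spec.leaflet_radii[0])
    diameters = []
    for _ in range(n):
        e = EulerTriplet(rng.uniform(0, 360), 90.0, rng.uniform(0, 360))
        img = fp.project(e, Shift2D(*rng.uniform(-2, 2, 2)))
        psi, shift, _ = estimate_psi_shift(img)
        diameters.append(measure_diameter(img, psi, shift, pixel_size))
    diameters = np.array(diameters)
    lumen = diameters - bilayer
    return {
        "outer_diameters_angstrom": diameters,
        "lumen_mean_nm": float(lumen.mean() / 10.0),
        "lumen_sd_nm": float(lumen.std() / 10.0),
        "n": n,
    }


def stacked_fraction_pipeline(
    stacked_fraction: float,
    seed,
    n: int = 1000,
    snr: float = 0.1,
    spec: TubeLatticeSpec | None = None,
    optics=DEFAULT_OPTICS,
    mask_radius: float = 185.0,
    k: int = 20,
    n_azavg: int = 500,
    n_lattice_variants: int = 4,
):
    """Recover a generator mixing fraction through the full RASTR chain.

    simulate -> per-particle psi/shift alignment -> random-phi azimuthal
    average -> edge-mode ROI subtraction (two silhouette sub-particles per
    particle) -> deterministic 2D classification -> per-class top-G band
    call -> summed stacked fraction with a binomial 95% CI at the parent
    particle count.
    """
    spec = spec or TubeLatticeSpec(stacked_fraction=stacked_fraction)
    if spec.stacked_fraction != stacked_fraction:
        raise ValueError("spec.stacked_fraction disagrees with the argument")
    s_sim, s_az, s_views, s_rastr, s_cls = _subseeds(seed, 5)

    stack, records = simulate_particles(
        spec, optics, n=n, snr=snr, seed=s_sim,
        n_lattice_variants=n_lattice_variants,
    )
    aligned = align_stack(stack, optics.pixel_size)
    recs = records.copy()
    for c in ("rlnAnglePsi", "rlnOriginXAngst", "rlnOriginYAngst"):
        recs[c] = aligned[c]
    keep = np.asarray(aligned["rlnAnglePsi"].notna())
    stack = stack[keep]
    recs = recs[keep].reset_index(drop=True)

    azavg = azimuthal_average(
        stack[: min(n_azavg, len(recs))],
        recs.iloc[: min(n_azavg, len(recs))],
        seed=s_az,
        ctf_mode="phase_flip",
        optics=optics,
        pixel_size=optics.pixel_size,
    )
    rng = np.random.default_rng(s_views)
    recs = recs.assign(
        rlnAngleRot=rng.uniform(0.0, 360.0, len(recs)),
        rlnAngleTilt=rng.choice([90.0, 270.0], len(recs)),
    )
    sub, subrec = make_rastr_subparticles(
        stack, recs, azavg, mask_radius, n_masks=2, phi_mode="edge",
        seed=s_rastr, optics=optics,
    )
    geometry = band_geometry_from_spec(spec, mask_radius)
    fraction, ci, classes = quantify_stacked_fraction(
        sub, subrec, k=k, seed=s_cls, geometry=geometry,
        pixel_size=optics.pixel_size, mask_radius=mask_radius, optics=optics,
    )
    return {
        "fraction": fraction,
        "ci95": ci,
        "classes": classes,
        "n_particles": int(len(recs)),
        "n_subparticles": int(len(subrec)),
        "generator_fraction": float(np.mean(records["tl_state"] == "stacked")),
        "sub_records": subrec,
    }
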