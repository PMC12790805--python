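"""FSC, projection matching, and lattice-parameter estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter

from tubelattice.geometry import (
    DensityVolume,
    EulerTriplet,
    FourierProjector,
    Shift2D,
    _cfftn,
    _cifftn,
)
from tubelattice.refine3d import (
    LatticeParams,
    Stage,
    compute_fsc,
    estimate_lattice_params,
    multireference_assign,
    projection_match,
)
from tubelattice.synthetic_data import (
    LatticeSite,
    TubeLatticeSpec,
    build_lattice_volume,
    build_volume_from_sites,
)

APIX = 4.0


def angerr(a, b):
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


class TestFSC:
    def test_identical_maps_give_unity(self):
        rng = np.random.default_rng(0)
        v = DensityVolume(rng.normal(size=(64, 64, 64)), APIX)
        fsc = compute_fsc(v, v)
        assert np.all(fsc.values > 0.999)
        assert np.all(np.diff(fsc.frequencies) > 0)

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(1)
        a = DensityVolume(rng.normal(size=(64, 64, 64)), APIX)
        b = DensityVolume(rng.normal(size=(64, 64, 64)), APIX)
        fsc = compute_fsc(a, b)
        assert np.all(np.abs(fsc.values[5:]) < 0.2)

    def test_lowpass_crossing_at_filter_frequency(self):
        rng = np.random.default_rng(2)
        n = 64
        v = rng.normal(size=(n, n, n))
        k = np.fft.fftshift(np.fft.fftfreq(n, d=APIX))
        kz, ky, kx = np.meshgrid(k, k, k, indexing="ij")
        keep = np.sqrt(kx**2 + ky**2 + kz**2) <= 1.0 / 20.0
        vlp = DensityVolume(_cifftn(_cfftn(v) * keep).real, APIX)
        fsc = compute_fsc(DensityVolume(v, APIX), vlp)
        res = fsc.resolution_at(0.143)
        shell = 1.0 / (n * APIX)
        assert abs(1.0 / res - 1.0 / 20.0) <= shell

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_fsc(
                DensityVolume(np.zeros((16, 16, 16)), APIX),
                DensityVolume(np.zeros((32, 32, 32)), APIX),
            )


@pytest.fixture(scope="module")
def blob_phantom():
    rng = np.random.default_rng(3)
    ph = gaussian_filter(np.pad(rng.normal(size=(24, 24, 24)), 12), 2.0)
    return DensityVolume(ph, APIX)


class TestProjectionMatch:
    def test_grid_coincident_particle_recovered_exactly(self, blob_phantom):
        fp = FourierProjector(blob_phantom)
        e = EulerTriplet(40.0, 80.0, 100.0)
        img = fp.project(e)
        recs = pd.DataFrame(
            {
                "rlnAngleRot": [38.0], "rlnAngleTilt": [82.0], "rlnAnglePsi": [102.0],
                "rlnOriginXAngst": [0.0], "rlnOriginYAngst": [0.0],
            }
        )
        out, scores = projection_match(
            img[None], recs, blob_phantom, [Stage(4.0, 2.0, 20.0, 1.0)]
        )
        assert out.rlnAngleRot[0] == pytest.approx(40.0)
        assert out.rlnAngleTilt[0] == pytest.approx(80.0)
        assert out.rlnAnglePsi[0] == pytest.approx(100.0)

    def test_local_refinement_recovers_perturbed_angles(self, blob_phantom):
        """<= 5 deg perturbations search +-10 deg at 1 deg: median absolute
        angular error below 1 deg after two passes."""
        fp = FourierProjector(blob_phantom)
        rng = np.random.default_rng(4)
        n = 24
        true, imgs = [], []
        for _ in range(n):
            e = EulerTriplet(rng.uniform(0, 360), rng.uniform(60, 120), rng.uniform(0, 360))
            true.append(e)
            imgs.append(fp.project(e, Shift2D(*rng.uniform(-2, 2, 2))))
        recs = pd.DataFrame(
            {
                "rlnAngleRot": [e.rot + rng.uniform(-5, 5) for e in true],
                "rlnAngleTilt": [e.tilt + rng.uniform(-5, 5) for e in true],
                "rlnAnglePsi": [e.psi + rng.uniform(-5, 5) for e in true],
                "rlnOriginXAngst": np.zeros(n),
                "rlnOriginYAngst": np.zeros(n),
            }
        )
        stages = [Stage(10.0, 1.0, 20.0, 1.0)] * 2
        out, scores = projection_match(imgs := np.array(imgs), recs, blob_phantom, stages)
        errs = [
            max(
                angerr(out.rlnAngleRot[i], true[i].rot),
                angerr(out.rlnAngleTilt[i], true[i].tilt),
                angerr(out.rlnAnglePsi[i], true[i].psi),
            )
            for i in range(n)
        ]
        assert np.median(errs) < 1.0

    def test_scores_non_decreasing_across_iterations(self, blob_phantom):
        fp = FourierProjector(blob_phantom)
        rng = np.random.default_rng(5)
        n = 8
        true = [
            EulerTriplet(rng.uniform(0, 360), rng.uniform(60, 120), rng.uniform(0, 360))
            for _ in range(n)
        ]
        imgs = np.array([fp.project(e) for e in true])
        recs = pd.DataFrame(
            {
                "rlnAngleRot": [e.rot + rng.uniform(-4, 4) for e in true],
                "rlnAngleTilt": [e.tilt + rng.uniform(-4, 4) for e in true],
                "rlnAnglePsi": [e.psi + rng.uniform(-4, 4) for e in true],
                "rlnOriginXAngst": np.zeros(n),
                "rlnOriginYAngst": np.zeros(n),
            }
        )
        prev = np.full(n, -np.inf)
        cur = recs
        for _ in range(3):
            cur, scores = projection_match(
                imgs, cur, blob_phantom, [Stage(6.0, 2.0, 20.0, 1.0)]
            )
            assert np.all(scores >= prev - 1e-12)
            prev = scores

    def test_zero_search_range_is_identity(self, blob_phantom):
        rng = np.random.default_rng(6)
        imgs = np.array([FourierProjector(blob_phantom).project(EulerTriplet(10, 90, 20))])
        recs = pd.DataFrame(
            {
                "rlnAngleRot": [11.0], "rlnAngleTilt": [91.0], "rlnAnglePsi": [19.0],
                "rlnOriginXAngst": [0.0], "rlnOriginYAngst": [0.0],
            }
        )
        out, _ = projection_match(
            imgs, recs, blob_phantom, [Stage(0.0, 1.0, 20.0, 1.0)], max_shift=0.5
        )
        assert out.rlnAngleRot[0] == 11.0
        assert out.rlnAngleTilt[0] == 91.0
        assert out.rlnAnglePsi[0] == 19.0

    def test_empty_stage_list_rejected(self, blob_phantom):
        with pytest.raises(ValueError):
            projection_match(np.zeros((1, 48, 48)), pd.DataFrame(), blob_phantom, [])

    def test_multireference_assignment_separates_templates(self, blob_phantom):
        rng = np.random.default_rng(7)
        other = DensityVolume(
            gaussian_filter(np.pad(rng.normal(size=(24, 24, 24)), 12), 2.0), APIX
        )
        refs = [blob_phantom, other]
        eulers = [
            EulerTriplet(rng.uniform(0, 360), rng.uniform(60, 120), rng.uniform(0, 360))
            for _ in range(10)
        ]
        imgs = []
        labels = []
        for i, e in enumerate(eulers):
            k = i % 2
            labels.append(k)
            imgs.append(FourierProjector(refs[k]).project(e))
        recs = pd.DataFrame(
            {
                "rlnAngleRot": [e.rot for e in eulers],
                "rlnAngleTilt": [e.tilt for e in eulers],
                "rlnAnglePsi": [e.psi for e in eulers],
            }
        )
        assign, _ = multireference_assign(np.array(imgs), recs, refs)
        assert list(assign) == labels


class TestLatticeParams:
    def test_strict_helix_recovered(self):
        """A 1-start helix (rise 50 A, twist -12 deg per subunit) is the
        unique operator in the searched window."""
        sites = [
            LatticeSite(
                (
                    190.0 * math.cos(math.radians(-12.0 * j)),
                    190.0 * math.sin(math.radians(-12.0 * j)),
                    50.0 * j,
                ),
                "stalk", j, 0,
            )
            for j in range(-8, 9)
        ]
        vol = DensityVolume(build_volume_from_sites(sites, 160, APIX, 8.0), APIX)
        lp = estimate_lattice_params(
            vol, rise_range=(40, 60), twist_range=(-180, 180), annulus=(160, 220)
        )
        assert lp.success
        assert abs(lp.rise - 50.0) <= 1.0
        assert abs(lp.twist - (-12.0)) <= 1.0
        assert lp.handedness == "left"

    def test_generator_lattice_recovered(self):
        spec = TubeLatticeSpec(spacing_jitter_sd=0.0)
        vol, _ = build_lattice_volume(spec, "stacked", 160, APIX, seed=0)
        lp = estimate_lattice_params(
            vol, rise_range=(40, 60), twist_range=(-6, 6), annulus=(150, 280)
        )
        assert lp.success
        assert abs(lp.rise - spec.rung_spacing_stacked) <= 1.0
        assert abs(lp.twist - spec.rung_twist) <= 1.0

    def test_symmetric_volume_flags_failure(self):
        n = 160
        ax = (np.arange(n) - n // 2) * APIX
        r = np.hypot(ax[:, None], ax[None, :])
        sym = DensityVolume(
            np.broadcast_to(np.exp(-((r - 190.0) ** 2) / 128.0), (n, n, n)).copy(),
            APIX,
        )
        lp = estimate_lattice_params(
            sym, rise_range=(40, 60), twist_range=(-6, 6), annulus=(150, 280)
        )
        assert not lp.success

    def test_jittered_lattice_rise_within_3A(self):
        spec = TubeLatticeSpec(spacing_jitter_sd=5.0)
        vol, _ = build_lattice_volume(spec, "stacked", 160, APIX, seed=1)
        lp = estimate_lattice_params(
            vol, rise_range=(40, 60), twist_range=(-6, 6), annulus=(150, 280)
        )
        assert lp.success
        assert abs(lp.rise - spec.rung_spacing_stacked) <= 3.0

    def test_empty_search_range_rejected(self):
        vol = DensityVolume(np.zeros((32, 32, 32)), APIX)
        with pytest.raises(ValueError):
            estimate_lattice_params(vol, rise_range=(60, 40))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            LatticeParams(-1.0, 0.0, "left", 1.0, True)
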