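"""2D classification of RASTR sub-particles and stacked-state scoring.

Classification is deterministic: images are masked, band-pass filtered and
normalized, reduced by PCA, and clustered by k-means whose initial centers
come from quantile groups along the first principal component (a
permutation-invariant, seeded initialization).  Class averages are means
of the raw member images.

The stacked-vs-relaxed call is made per class, as in the source workflow
(class averages are inspected and classes "with the top-G feature" are
summed): the score is the mean intensity in the top-G radial band of the
class average, normalized by the stalk band, with the membrane position
and band offsets supplied by a :class:`StateBandGeometry`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.decomposition import PCA
from sklearn.cluster import KMeans

__all__ = [
    "ClassAverageSet",
    "StateBandGeometry",
    "classify_2d",
    "score_class_stacked",
    "quantify_stacked_fraction",
    "canonicalize_edge_subparticles",
    "band_geometry_from_spec",
]


@dataclass
class StateBandGeometry:
    """Radial band definitions in the edge-view sub-particle frame.

    The sub-particle is centered on the membrane surface with the tube
    axis horizontal and the outward normal pointing to +y (rows above the
    center).  Offsets are angstrom distances from the membrane (outward
    positive); each band spans ``offset ± half_width``.
    """

    stalk_offset: float
    topg_offset: float
    half_width: float
    x_half_width: float  # restrict scoring to the ROI along the axis


def band_geometry_from_spec(spec, mask_radius: float) -> StateBandGeometry:
    """Derive scoring bands from the generator's layer radii.

    For real data the same numbers would come from the refined map's
    radial profile; here the simulator spec is the ground truth.
    """
    surface = spec.leaflet_radii[1]
    return StateBandGeometry(
        stalk_offset=spec.layer_radii["stalk"] - surface,
        topg_offset=spec.layer_radii["topG"] - surface,
        half_width=2.0 * spec.blob_sd,
        x_half_width=0.6 * mask_radius,
    )


@dataclass
class ClassAverageSet:
    """K class averages with member assignments and per-class state calls."""

    averages: np.ndarray  # (k, N, N)
    assignments: np.ndarray  # (n,) int
    counts: np.ndarray  # (k,) int
    scores: np.ndarray | None = None  # per-class stacked score
    is_stacked: np.ndarray | None = None  # per-class boolean call

    def __post_init__(self):
        if self.counts.sum() != len(self.assignments):
            raise ValueError("class counts must sum to the particle count")


def _preprocess(stack: np.ndarray, pixel_size: float, mask_radius: float | None,
                bandpass: tuple[float, float] = (200.0, 15.0)) -> np.ndarray:
    """Mask, band-pass and normalize images for clustering."""
    n = stack.shape[1]
    lo_sd = bandpass[0] / (2.355 * pixel_size)  # high-pass: remove slow ramps
    hi_sd = bandpass[1] / (2.355 * pixel_size)  # low-pass: suppress noise
    c = n // 2
    if mask_radius is not None:
        ax = (np.arange(n) - c) * pixel_size
        r = np.hypot(ax[:, None], ax[None, :])
        mask = np.clip((mask_radius - r) / (0.2 * mask_radius + 1e-9), 0.0, 1.0)
    else:
        mask = np.ones((n, n))
    out = np.empty_like(stack, dtype=np.float64)
    for i, img in enumerate(stack):
        f = ndimage.gaussian_filter(img.astype(np.float64), hi_sd)
        f = f - ndimage.gaussian_filter(f, lo_sd)
        f = f * mask
        sd = f.std()
        out[i] = (f - f.mean()) / (sd if sd > 0 else 1.0)
    return out


def classify_2d(
    stack: np.ndarray,
    k: int,
    n_iter: int = 50,
    seed=0,
    pixel_size: float = 4.0,
    mask_radius: float | None = None,
    n_components: int = 32,
) -> ClassAverageSet:
    """Deterministic 2D classification of pre-aligned particles.

    PCA-reduced, band-pass filtered images are k-means clustered.  The
    initial centers are means of k quantile groups along PC1, so the
    result is reproducible and invariant to particle order.  Class
    averages are computed from the raw (unfiltered) images.
    """
    stack = np.asarray(stack)
    n = stack.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds particle count {n}")
    if k == 1:
        avg = stack.astype(np.float64).mean(axis=0)[None]
        return ClassAverageSet(avg, np.zeros(n, int), np.array([n]))

    feats = _preprocess(stack, pixel_size, mask_radius).reshape(n, -1)
    n_comp = min(n_components, n - 1, feats.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=int(seed) & 0x7FFFFFFF)
    z = pca.fit_transform(feats)

    # permutation-invariant seeding: quantile groups along PC1
    order = np.argsort(z[:, 0], kind="stable")
    groups = np.array_split(order, k)
    init = np.stack([z[g].mean(axis=0) for g in groups])
    km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=n_iter, random_state=0)
    labels = km.fit_predict(z)

    counts = np.bincount(labels, minlength=k)
    avgs = np.zeros((k, stack.shape[1], stack.shape[2]))
    for j in range(k):
        if counts[j]:
            avgs[j] = stack[labels == j].astype(np.float64).mean(axis=0)
    return ClassAverageSet(avgs, labels, counts)


def _membrane_row(profile: np.ndarray, center: int, w: int) -> int:
    """Membrane row: the outermost strong peak within ``center +- w``.

    The inner leaflet (one bilayer further in) can be equally tall, so a
    plain argmax is not enough.
    """
    from scipy.signal import find_peaks

    win = profile[center - w : center + w + 1]
    pk, _ = find_peaks(win, prominence=0.05 * (win.max() - win.min() + 1e-12))
    if len(pk):
        tall = pk[(win[pk] - win.min()) >= 0.6 * (win.max() - win.min())]
        return center - w + int(tall.max() if len(tall) else pk[int(np.argmax(win[pk]))])
    return center - w + int(np.argmax(win))


def _band_means(img: np.ndarray, geometry: StateBandGeometry, pixel_size: float):
    """Stalk/top-G/background band means, anchored on the membrane row.

    Class averages can carry a small common vertical offset (members
    cluster by residual centering error), so the membrane row re-anchors
    the band positions before measuring.
    """
    n = img.shape[0]
    c = n // 2
    xs = (np.arange(n) - c) * pixel_size
    cols = np.abs(xs) <= geometry.x_half_width
    prof = img[:, cols].mean(axis=1)
    w = max(2, int(round(2.5 * geometry.half_width / pixel_size)))
    anchor = _membrane_row(prof, c, w)
    ys = (np.arange(n) - anchor) * pixel_size  # outward distance from membrane

    def band(lo, hi):
        rows = (ys >= lo) & (ys <= hi)
        if not rows.any():
            raise ValueError("band lies outside the image")
        return float(img[np.ix_(rows, cols)].mean())

    hw = geometry.half_width
    stalk = band(geometry.stalk_offset - hw, geometry.stalk_offset + hw)
    topg = band(geometry.topg_offset - hw, geometry.topg_offset + hw)
    bg_lo = geometry.topg_offset + 2.0 * hw
    bg = band(bg_lo, bg_lo + 2.0 * hw)
    return stalk, topg, bg


def score_class_stacked(
    class_average: np.ndarray,
    geometry: StateBandGeometry,
    pixel_size: float = 4.0,
    threshold: float = 0.5,
    stalk_reference: float | None = None,
):
    """Score one edge-view class average for the stacked-state feature.

    Score = (top-G band mean - background) / (stalk band mean -
    background); background is taken beyond the top-G band where no
    density is expected.  ``is_stacked = score > threshold``.

    The stalk layer is present in both lattice states, so when scoring
    many classes of one dataset the denominator should be the *global*
    stalk level (``stalk_reference``, stalk minus background measured on
    the overall mean image): a per-class stalk estimate can reach noise
    scale in small classes and destabilize the ratio.
    """
    img = np.asarray(class_average, dtype=np.float64)
    stalk, topg, bg = _band_means(img, geometry, pixel_size)
    denom = stalk_reference if stalk_reference is not None else (stalk - bg)
    score = (topg - bg) / denom if abs(denom) > 1e-12 else 0.0
    return float(score), bool(score > threshold)


def canonicalize_edge_subparticles(
    stack: np.ndarray, records: pd.DataFrame
) -> np.ndarray:
    """Rotate edge sub-particles to a common frame for classification.

    Each image is rotated by -psi so the tube axis runs along x.  The
    outward membrane normal in the original image points from the tube
    axis toward the re-centering offset (``tl_recenter_dx/dy``, recorded
    at extraction); when its direction after the -psi rotation points to
    -y the image is mirrored vertically, so the canonical frame always
    has the tube interior below and the protein layers above the
    membrane.  (The mirror flips apparent handedness, which the band
    score does not use.)
    """
    out = np.empty_like(stack, dtype=np.float64)
    n = stack.shape[1]
    c = float(n // 2)
    for i, img in enumerate(stack):
        psi = float(records["rlnAnglePsi"].iloc[i])
        a = math.radians(psi)
        ca, sa = math.cos(a), math.sin(a)
        A = np.array([[ca, sa], [-sa, ca]])  # sample at +psi = rotate by -psi
        img2 = ndimage.affine_transform(
            img.astype(np.float64), A, offset=np.array([c, c]) - A @ np.array([c, c]),
            order=1, mode="constant", cval=0.0,
        )
        dx = float(records["tl_recenter_dx"].iloc[i])
        dy = float(records["tl_recenter_dy"].iloc[i])
        # outward normal after the -psi rotation
        outward_y = -sa * dx + ca * dy
        if outward_y < 0:
            img2 = np.flip(img2, axis=0)
            img2 = np.roll(img2, 1, axis=0)  # keep the center at index N/2
        out[i] = img2
    return out


def quantify_stacked_fraction(
    stack: np.ndarray,
    records: pd.DataFrame,
    k: int,
    seed=0,
    geometry: StateBandGeometry | None = None,
    pixel_size: float = 4.0,
    mask_radius: float | None = None,
    threshold: float = 0.5,
    optics=None,
):
    """Fraction of particles in stacked-state classes, with binomial CI.

    Edge-view sub-particles are canonicalized, classified into ``k``
    classes, each class average is scored for the top-G band, and the
    members of stacked-called classes are summed.  Returns ``(fraction,
    (ci_low, ci_high), ClassAverageSet)``; the 95% CI uses the normal
    approximation at the number of *parent* particles if recorded
    (sub-particles of one particle are not independent), else the
    sub-particle count.
    """
    if geometry is None:
        raise ValueError("band geometry required (see band_geometry_from_spec)")
    if optics is not None and "rlnDefocusU" in records:
        from .synthetic_data import phase_flip_stack

        # sign + amplitude CTF correction keeps band contrasts comparable
        # across the defocus spread; the moderate floor limits the
        # low-frequency boost (an aggressive one amplifies the membrane
        # halo into the scoring bands)
        stack = phase_flip_stack(
            stack, np.asarray(records["rlnDefocusU"], dtype=float), optics,
            amplitude_floor=0.4,
        )
    canon = canonicalize_edge_subparticles(stack, records)
    # per-particle vertical alignment on the membrane row: removes the
    # residual centering offset as a clustering nuisance (the counterpart
    # of the translational alignment inside a full 2D classifier)
    if geometry is not None:
        c = canon.shape[1] // 2
        wcol = max(2, int(0.6 * (mask_radius or 100.0) / pixel_size))
        for i in range(canon.shape[0]):
            prof = ndimage.gaussian_filter1d(
                canon[i][:, c - wcol : c + wcol].mean(axis=1), 2.0
            )
            dy = _membrane_row(prof, c, 8) - c
            if dy:
                canon[i] = np.roll(canon[i], -dy, axis=0)
    cas = classify_2d(
        canon, k, seed=seed, pixel_size=pixel_size, mask_radius=mask_radius
    )
    g_stalk, _, g_bg = _band_means(canon.mean(axis=0), geometry, pixel_size)
    stalk_ref = g_stalk - g_bg
    scores = np.zeros(len(cas.counts))
    calls = np.zeros(len(cas.counts), dtype=bool)
    for j in range(len(cas.counts)):
        if cas.counts[j] == 0:
            continue
        scores[j], calls[j] = score_class_stacked(
            cas.averages[j], geometry, pixel_size, threshold, stalk_reference=stalk_ref
        )
    cas.scores = scores
    cas.is_stacked = calls
    n_sub = len(records)
    frac = float(cas.counts[calls].sum()) / n_sub
    if "tl_parent_index" in records:
        n_eff = int(records["tl_parent_index"].nunique())
    else:
        n_eff = n_sub
    half = 1.96 * math.sqrt(max(frac * (1.0 - frac), 1e-12) / n_eff)
    return frac, (max(0.0, frac - half), min(1.0, frac + half)), cas
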