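# Methods

## The problem

A fission-protein lattice assembled on a lipid nanotube is only locally
ordered: rungs (circumferential filaments) keep a well-defined spacing
and inter-rung contacts over a few hundred angstroms, but the order does
not propagate around or along the whole tube, so global helical
averaging fails. The workflow implemented here isolates one locally
ordered surface patch per particle — region-of-interest (ROI) signal
subtraction, "RASTR" — and processes the patches as single particles.
Two lattice conformations are distinguished: **stacked** (bottom and top
G-domain layers between rungs, short regular spacing, and rod-like
variable-domain (VD) densities contacting the outer membrane leaflet)
and **relaxed** (bottom layer only, longer variable spacing, no membrane
contact).

## Geometry and the projector pair

Euler angles are intrinsic ZYZ (`R = Rz(psi) Ry(tilt) Rz(rot)`, degrees);
a volume point `p` appears in a projection at `(R p)_xy / pixel + shift`.
Volumes are cubic, tube axis along z, origin at voxel `N/2`; shifts are
in pixels and move the image content by `+s`. A stored tilt of 270°
encodes the opposite tube polarity and maps to tilt 90° with psi + 180°.

Projection uses the Fourier central-slice theorem: the 2D transform of a
projection is a central plane of the volume's 3D transform, sampled with
trilinear interpolation (`FourierProjector`; the 3D FFT is cached, so a
projection costs ~2 ms at box 160). Backprojection is the *exact
adjoint* (trilinear gridding of image transforms onto the 3D frequency
grid), followed by division by the accumulated sampling weight, floored
at half the median positive weight. The floor choice matters: a plain
small floor turns barely-touched voxels into full-amplitude ghosts
(numerator and weight both tiny), while the median-scaled floor
attenuates them proportionally and makes the reconstruction exactly
invariant under duplicating every particle. No interpolation-envelope
correction is applied: axis-aligned orientations are exact and oblique
ones carry a small (<~15% at half-box radius) radial amplitude droop
that is identical for every image the package produces, so internal
comparisons are unaffected.

Phase flipping (multiplication by sign(CTF)) is available wherever
images enter a reconstruction; classification additionally divides by
`max(|CTF|, 0.2)` so band contrasts are comparable across the defocus
spread.

## Synthetic data

The generator is deliberately coarse-grained: two concentric Gaussian
shells for the bilayer leaflets (radii 100/140 Å, width 8 Å — a 200 Å
inner lumen) and Gaussian pseudo-domain blobs at lattice sites. Radial
layer order is membrane < VD (150 Å) < stalk (190 Å) < bottom G (230 Å)
< top G (260 Å); the absolute protein radii are free model parameters
(only the ordering and the lumen size are constrained by the system
emulated). Rungs are rings of 30 subunits; rung z-positions follow a
random walk (state spacing 50 Å stacked / 65 Å relaxed plus N(0,
jitter)), so disorder accumulates with distance — local order only.
Successive rungs advance azimuthally by the rung twist (default −5°; a
multiple of the 12° subunit step would make the twist unidentifiable
modulo the ring symmetry). The stacked state adds top-G blobs
(amplitude 2.0: the bulky G-domain head would otherwise be
under-weighted at edge views relative to the quasi-continuous stalk
ring, whereas it is the clearly visible discriminating feature of the
emulated system) and VD contact rods bridging the outer leaflet and the
VD radius under every second subunit (tetramer centers).

Particles are projections at random orientations (tilt 90/270 for a tube
lying in the ice plane), CTF-modulated (300 kV, Cs 2.7 mm, amplitude
contrast 0.07, defocus 0.5–2 µm) with additive white Gaussian noise.
"SNR" means signal variance over the tube-occupied region divided by
noise variance. Default scale: 4 Å/px, raw box 160 px (640 Å — the
outermost protein layer spans 520 Å and must fit at edge views with a
margin), sub-particle box 128 px. A small pool of lattice realizations
(default 4 per state) stands in for per-particle lattice variability.

What the generator does **not** model: membrane curvature changes
between states, diameter spread between tubes, azimuthal decoherence of
the lattice, structured noise/ice gradients, dose or detector physics.
Passing recovery tests therefore demonstrate the pipeline's
correctness under the stated forward model, not performance on real
micrographs.

## Tube alignment and diameter

The in-plane angle maximizes the variance of the across-tube profile
(mean along the tube axis) over a global 4° grid on a 2×-binned image,
refined on a 1° grid with a parabolic fit; lattice stripes are
suppressed for the angle search by smoothing the profile (they would
otherwise make the *along*-tube direction win on strongly decorated
tubes). Detection: pure noise has profile variance near var(image)/rows,
any tube exceeds it several-fold (threshold 1.7×). The across-tube shift
comes from the symmetric midpoint of the outer membrane peak pair; the
along-tube component is unobservable and left at zero.

Diameter = separation of the outermost tall mirror-symmetric profile
peak pair (membrane leaflets give the tallest peaks; smeared protein
layers only form shoulders), sub-pixel refined, then corrected for
tangent-chord geometry: the projection of a shell of radius R peaks
~6 Å *inside* R (for an 8 Å shell width), and the measurement inverts
the projected-shell model by fixed-point iteration. Binning uses 20
equal bins across the observed range by default, ties to the lower bin.

## Azimuthal average

The reference map for subtraction is the z-averaged backprojection of
all particles at *random* azimuth (the in-plane angle and shift are
measured, the azimuth is unknowable before refinement). Because
z-averaging keeps only the kz = 0 plane of the accumulated transform,
the default implementation accumulates directly there: every central
slice sample within one frequency row of kz = 0 deposits its exact
transform value at its continuous in-plane radius (half-pixel ring bins,
tent weight in kz), and rings are weighted averages. This is the
backproject → z-average → symmetrize limit computed without gridding
interpolation; the output is exactly cylindrical, exactly independent of
the random-azimuth draw, and its radial profile matches a direct
inverse-Abel transform of the across-tube profile at r ≈ 0.99.
`symmetrize=False` gives the literal backproject-then-z-average map for
inspection of the residual (~6%) angular ripple.

## RASTR subtraction

The ROI is a soft sphere (cosine edge, default 20 Å) centered on the
tube surface — the outer-leaflet radius detected from the azimuthal
average's radial profile (outermost strong peak; the inner leaflet can
be the taller one). The subtraction model is the azimuthal average
*outside* the ROI, projected at the particle's orientation and
CTF-modulated; its amplitude is least-squares fitted **outside the
projected ROI footprint** (a whole-image fit is biased high because ROI
content overlaps the complement in projection) and subtracted. The image
is re-centered on the mask center (Fourier shift) and cropped. The rot
bookkeeping `rot' = rot + mask azimuth` makes `rot' = 90/270` exactly
the silhouette (edge) views, where the two lattice states are
distinguishable in projection. Because the reference is exactly
cylindrical, one masked projector serves every mask azimuth through
`proj(azavg·mask_a, rot) = proj(azavg·mask_0, rot + a)`.

## Classification and stacked-state quantification

Edge sub-particles are rotated to a canonical frame (tube axis
horizontal, outward normal up). The unresolved 180° polarity of the
measured psi is fixed from pure metadata: the outward normal is the
re-centering offset direction rotated by −psi; images where it points
down are mirrored (verified against ground-truth projections for all
rot/tilt/psi-branch combinations). Residual vertical centering error is
removed by re-anchoring each image on its membrane row. Classification
is deterministic: masked, band-pass-filtered, normalized images → PCA
(32 components) → k-means with quantile-of-PC1 initial centers
(permutation-invariant and reproducible given the seed).

The per-class stacked score is the top-G band mean (120 ± 16 Å outside
the membrane row) minus background, normalized by the stalk band
(50 ± 16 Å); a class is called stacked above 0.5. Two operational
details stabilize the call: the denominator uses the *global* stalk
level (per-class stalk estimates reach noise scale in ~100-member
classes), and band rows are re-anchored per class on the membrane peak.
The stacked fraction is the summed membership of stacked-called classes;
its 95% CI uses the binomial normal approximation at the parent-particle
count (the two silhouette sub-particles of one particle are not
independent).

## Refinement and lattice parameters

Projection matching scores low-pass-limited normalized
cross-correlation (not a likelihood) on a local angular grid with FFT
shift optimization, accepting only improvements; stages follow a
coarse-to-fine ladder in resolution limit and particle fraction, and a
simple multi-reference assignment (best-correlating of K references)
stands in for multi-class 3D classification. FSC is shell-wise
normalized cross-correlation with the resolution read at the 0.143
crossing by linear interpolation.

Lattice parameters (rise and twist between adjacent rungs) come from the
map's self-correlation under the helical transform, evaluated on a
cylindrical (z, theta, r) resampling of the *asymmetric residual* (the
cylindrical average is subtracted first) for all lags at once by FFT;
the argmax in the search window is refined parabolically. The fit is
flagged failed when the peak does not exceed twice the median |score|
over the window or the residual carries no power — a cylindrically
symmetric map therefore fails cleanly. For a lattice of closed rings
with S subunits per rung the twist is only identifiable modulo 360/S;
the search window should be narrower than one subunit step.

## Sub-particle reconstruction

A site of interest (the VD membrane contact at a tetramer center, and
its eight lattice neighbors — the nine-offset scheme) is given in
tube-frame coordinates. Offsets are pure geometry
(`project_point`); the rot adjustment (the site's azimuth) re-expresses
each view in a frame with the site at azimuth zero, and re-centered
sub-images with zero origins reconstruct the site at the box center.
Extraction is Fourier-shift + integer crop (centering error < 0.1 px),
with either an error or mean-padding boundary policy. In the resulting
maps the membrane is z-invariant, so contact density is assessed on the
z-mean-subtracted residual: the stacked state shows a bridge at the
site more than 3× the between-rung level; the relaxed state shows none.

## Problem sizes and numerical choices

Recovery runs use 1000 particles at box 160 and SNR 0.1 (the two
reported mixing fractions, 60.3% and 25.7%, are recovered within the
95% binomial CI at that n); the diameter benchmark uses 50 noise-free
projections; refinement and reconstruction demonstrations use a few
hundred particles, with the end-to-end refinement check run on 2×-binned
data. Quantification uses ROI radius 185 Å (the top-G layer sits 120 Å
outside the membrane and would be truncated by a 130 Å sphere's soft
edge), k = 20 classes, and two silhouette sub-particles per particle.
All randomness is derived from a single integer seed via
`SeedSequence` spawning.

## Known limitations

* The forward model's rigid-ring lattices make the ROI-size contrast of
  a real locally-ordered specimen only partly reproducible: a small ROI
  resolves the rung periodicity, but a large ROI does not lose it,
  because alignment or phase clustering always locks onto the coherent
  center of a patch under random-walk spacing disorder. Reproducing the
  large-ROI failure would need azimuthal decoherence, diameter spread,
  or curvature variation, which are out of the model.
* Scoring bands derive from the generator's layer radii; for real data
  they would be read off the refined map's radial profile (not
  implemented).
* Projection-matching is greedy NCC, which can stall in local optima for
  search ranges much wider than the perturbations tested; global angle
  assignment (3D classification) is out of scope.
* The no-oversampling Fourier projector trades a small radial amplitude
  envelope for speed; comparisons against external references should use
  per-shell-normalized measures (FSC, correlations), as the tests do.
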