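# tubelattice

Reconstruction tools for cryo-EM particles of protein-decorated membrane
nanotubes whose protein coat is **locally ordered but not globally
helical** — the situation encountered for dynamin-family fission proteins
(such as Drp1) assembled on galactosylceramide (GalCer) lipid nanotubes.
Standard helical reconstruction fails on such specimens; the approach
implemented here isolates a small surface patch of each tube by signal
subtraction and treats the patches as single particles.

The package provides the complete processing chain plus a matched
synthetic-data generator, so every stage can be validated against ground
truth:

1. **synthetic_data** — forward model of a decorated nanotube (two
   membrane leaflet shells plus Gaussian pseudo-domain lattices) with two
   conformational states: *stacked* (bottom and top G-domain layers,
   short regular rung spacing, membrane-contact rods) and *relaxed*
   (bottom layer only, longer and more variable spacing); projection,
   CTF, noise, and full ground-truth metadata.
2. **tube_align** — per-particle in-plane angle (psi) and across-tube
   shift estimation, membrane diameter measurement by peak detection,
   and modal diameter-bin selection.
3. **azimuthal** — the featureless cylindrically averaged initial model:
   particles are backprojected with random azimuth (phi) and tilt 90/270
   and averaged along the tube axis.
4. **rastr_core** — ROI signal subtraction (RASTR): a soft spherical
   mask on the tube surface defines a region of interest; the azimuthal
   average's projection outside it is subtracted from each raw particle
   and the image is re-centered on the ROI.
5. **refine3d** — constrained projection matching, Fourier shell
   correlation (FSC), and helical lattice-parameter (rise/twist)
   estimation by self-correlation under the helical transform.
6. **classify** — deterministic PCA + k-means 2D classification of edge
   (silhouette) sub-particles and per-class scoring of the stacked-state
   feature (the top G-domain band); stacked fraction with binomial CI.
7. **subparticle_recon** — sub-particle extraction and reconstruction at
   a model-derived 3D coordinate (the variable-domain membrane-contact
   site), using the nine-offset scheme around a lattice tetramer center.

The core geometric statistic everywhere is the central-slice relation
`F_2D[P_R V](k) = F_3D[V](R^T (k_x, k_y, 0))` for Euler rotation
`R = R_z(psi) R_y(tilt) R_z(rot)`: projection is slice extraction from
the volume transform, and reconstruction is its exact adjoint with
sampling-weight normalization.

## Worked example

Recover the stacked-state fraction of a simulated mixed dataset
(1000 particles, signal-to-noise variance ratio 0.1, 60.3% stacked):

```python
from tubelattice import stacked_fraction_pipeline

out = stacked_fraction_pipeline(0.603, seed=11, n=1000, snr=0.1)
print(f"recovered stacked fraction: {out['fraction']:.3f}")
print(f"95% CI: {out['ci95'][0]:.3f} - {out['ci95'][1]:.3f}")
print(f"generator (realized): {out['generator_fraction']:.3f}")
```

prints

```
recovered stacked fraction: 0.589
95% CI: 0.559 - 0.620
generator (realized): 0.620
```

i.e. the edge-view RASTR + classification chain reads the conformational
mixture back out of the images to within the binomial sampling error of
the 1000-particle draw (exact values vary with the seed; residual method
error of the class-level calls is about ±2–3%).

The same stages are scriptable from the shell:

```bash
tubelattice simulate --n 500 --seed 1 --snr 0.1 --out stack.mrcs --star particles.star
tubelattice align    --stack stack.mrcs --star particles.star --out aligned.star
tubelattice azavg    --stack stack.mrcs --star aligned.star --out azavg.mrc --seed 7
tubelattice rastr    --stack stack.mrcs --star aligned.star --azavg azavg.mrc \
                     --radius 185 --nmasks 2 --phi-mode edge --seed 3 --out sub
tubelattice quantify --stack sub.mrcs --star sub.star --k 20 --report states.json
```

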