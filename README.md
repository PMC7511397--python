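# afmbend

Automated, unbiased measurement of local DNA bend angles in atomic force
microscopy (AFM) topographs — at the positions of bound proteins (e.g. DNA
glycosylases searching for base damage) and at defined DNA sites such as a
lesion placed at 50% of the fragment length — with decomposition of the
resulting angle distributions into conformational states and
cross-validation against worm-like-chain statistics and ensemble FRET.

It is written for single-molecule biophysicists who image protein–DNA
complexes on mica and want a reproducible, scriptable replacement for the
manual ImageJ/FIESTA/Origin workflow, plus a synthetic scene generator that
renders DNA and protein with known ground truth so every stage of the
pipeline can be validated without microscope data.

## The measurement

A topograph is median-filtered, thresholded (Yen's automatic criterion on
the 8-bit histogram), and split by a blob shape filter (ellipse elongation
and perimeter) into DNA filaments and protein peaks. Filaments are thinned
to one-pixel skeletons, refined to sub-pixel backbone traces by fitting a
Gaussian to the height profile across the ridge at every 2 nm node, and
interpolated with a natural cubic spline resampled at 0.1 nm arc length.
Protein peaks (localized by connected components with an area window) are
assigned to the nearest trace; a peak is DNA-bound when its distance to the
backbone is at most the sum of the protein and DNA radii.

The bend angle at an arc position s₀ (a bound protein, or the midpoint of a
length-filtered fragment) is

**Θ = 180° − Φ**,

where Φ is the angle between tangents placed at s₀ ± q and q is the query
point distance (default 8 nm, which must extend past the protein radius);
secant geometry is available as an alternative and reproduces tangent
geometry at half the query distance. Angles are unsigned, so bend-angle
histograms are fit with sums of *folded* Gaussians
N(θ; μ, σ) + N(−θ; μ, σ), by least squares with counting-statistics
weights; the number of states is the smallest k whose fit reaches an R²
threshold (0.94 for protein complexes, 0.97 for lesion sites).

Two independent consistency checks accompany the angle analysis:

* **Worm-like chain.** For 2D-equilibrated DNA,
  ⟨R²⟩₂D = 4·L_P·L_c·{1 − (2L_P/L_c)(1 − e^(−L_c/2L_P))}; inverting this at
  the measured mean squared end-to-end distance gives the persistence
  length L_P and verifies equilibrated deposition.
* **Ensemble FRET.** E = (I_AD·ε_AA − I_AA·ε_AD)/(I_AA·ε_DD) from corrected
  acceptor peak intensities, r = R₀(1/E − 1)^(1/6) (R₀ = 5.6 nm for
  Cy3/Cy5), and Θ = 180° − arccos((r² − b² − c²)/(−2bc)) with arms
  b = c = 7.17/2 nm; a geometric forward simulator predicts the ensemble E
  of an AFM-derived state population under random binding positions.

## Worked example

```python
from afmbend import (PipelineConfig, SceneSpec, generate_scene,
                     run_pipeline, fit_folded_mixture, estimate_lp)
from afmbend.fret import (StatePopulation, angle_from_efficiency,
                          simulate_population_e)

# thirty synthetic images of protein-DNA complexes, 45 deg imposed bend
specs = [SceneSpec(n_molecules=8, imposed_bend_deg=45.0,
                   place_protein=True, rng_seed=s) for s in range(30)]
images = [generate_scene(s)[0] for s in specs]
config = PipelineConfig(elongation_range=(0.0, 1.0))
table, mixture, qc = run_pipeline(images, config, mode="complexes")
angles = table.loc[table.exclusion_reason == "none", "bend_angle_deg"]
print(f"{len(table)} candidate sites, {len(angles)} measured angles")
print(fit_folded_mixture(angles, k=1, seed=0).summary())
print(f"Lp from measured <R^2>: {estimate_lp(17214.0, 172.0):.1f} nm")
print(f"bend angle from E=0.291: {angle_from_efficiency(0.291):.1f} deg")
e, se = simulate_population_e(StatePopulation([(8.0, 1.0)]),
                              n_draws=100_000, seed=1)
print(f"predicted ensemble E for 8 deg state: {e:.3f}")
```

prints

```
244 candidate sites, 227 measured angles
46 deg +/- 65 deg (100%)  [R^2 = 0.783]
Lp from measured <R^2>: 45.3 nm
bend angle from E=0.291: 50.1 deg
predicted ensemble E for 8 deg state: 0.186
```

The 227 sites out of 244 candidates show the bookkeeping: every candidate
appears in the table, measured or excluded with a reason (peak at a
fragment end, closer than 50 nm to another bound protein, off DNA, or an
aggregate outside the area window). The single folded-Gaussian state
recovers the imposed 45° bend (reported as center ± 2σ width; the ~32°
width is the thermal worm-like-chain background at an 8 nm query
distance, not measurement error). The persistence length of 45 nm from the
2D WLC inversion confirms equilibrated molecules, and the FRET block maps
a measured ensemble efficiency to a bend angle and back.

The same analyses are available from the shell:

```bash
afmbend simulate --seed 1 --n-images 10 --out scenes/
afmbend analyze-complexes scenes/*/scene.tif --out results/ \
        --query-distance 8 --geometry tangent
afmbend fit-angles results/angles_complexes.csv --out results/fit \
        --r2-threshold 0.94
afmbend fret-calc intensities.json --out fret.csv
afmbend wlc results/trace_summary.csv
```

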