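# dynstalk

Quantitative analyses of the dynein motor domain: stalk sequence/length
conservation, rigid-body motion of the AAA+ ring between nucleotide
states, and single-molecule motility and saturation kinetics — each stage
paired with a synthetic-data generator carrying exact ground truth, so
every estimator is verifiable by parameter recovery without external
downloads.

## Who this is for

Dynein (and more broadly motor-protein) labs and structural
bioinformaticians who need reproducible, scriptable versions of analyses
that are usually done interactively: Jalview-style column conservation
and domain length histograms on heavy-chain alignments; Chimera-style
subdomain superpositions, displacement fields and rotation angles between
two states of the AAA ring; µManager-style localization → linking →
straightening → displacement statistics for TIRF assays; and hyperbolic
fits of ATPase / cosedimentation titrations.

## The quantities at the core

* **Stalk length conservation.** For a domain delineated by anchor
  residues of a reference sequence, the per-sequence ungapped length
  within the alignment span, its histogram, and the *modal fraction* —
  the fraction of sequences with exactly the modal length. The stalk
  coiled-coil (CC1 + CC2) is the canonical application: its length is far
  better conserved than its sequence.
* **Ring subdomain motion.** The motor domain is split into 13 rigid
  bodies (AAA1L…AAA6s + linker). After Kabsch superposition on a named
  body (e.g. AAA1L), the per-Cα displacement field b−a quantifies what
  moved; the angle between residue-triple axes (e.g. the arginine-finger
  / Sensor-II / insert-loop axis of AAA2L) quantifies domain rotation,
  `θ = arccos |u·v| ∈ [0°, 90°]`; the arginine-finger–Walker-A Cα
  distance proxies nucleotide-pocket closure; subdomain interface gaps
  (min Cα–Cα and centroid distances) quantify ring opening.
* **Motility statistics.** Emitters are localized by Poisson maximum
  likelihood of an integrated 2-D Gaussian, linked by nearest-neighbor
  search, straightened by PCA onto the filament axis, and summarized by
  displacements over 1-s intervals (for a diffusive motor these are
  N(0, 2DΔt) with zero mean). Tracks are classified
  directional / diffusive / static / transient by explicit thresholds;
  microtubule polarity comes from plus-end-directed kinesin reference
  tracks.
* **Saturation kinetics.** ATPase and microtubule-binding titrations are
  fit to `k_obs = (A − b)·[MT]/(K + [MT]) + b` (A = k_cat or B_M; K = K_M
  or K_d; b = basal). Flat titrations report A and K as unidentifiable
  rather than as numbers.

## Worked example

Run the full synthetic pipeline with one seed:

```bash
stalk run --seed 9 --outdir demo_run
```

which prints (abridged):

```
# dynstalk pipeline report

package version: 0.1.0
seed: 9

## Sequence conservation
- modal_fraction: 0.9900497512437811
- mean_amas_score: 1.5666666666666667

## Structure dynamics
- rotation_angle_deg: 20.00000000000001
- subdomain_summary: {... 'AAA2L': (4.09, 8.64), 'AAA5s': (8.0, 8.0) ...}

## Single-molecule motility
- accuracy: 0.975
- mean_disp: 14.781005591044288
- sd_disp: 140.9824261187663

## Saturation kinetics
- amplitude: 14.984...  - K: 0.480...  - basal: 0.709...
```

Reading this: the synthetic stalk family was generated with 1% of
sequences carrying an indel, and the length analysis recovers a modal
fraction of 0.99; a 20° rotation applied to the AAA2L body is recovered
exactly after AAA1L alignment, and the 8 Å translation applied to AAA5s
appears as an 8.0 Å displacement-field magnitude; 97.5% of synthetic
tracks are assigned their generating phenotype, and the diffusive tracks'
1-s displacements have near-zero mean with SD ≈ √(2DΔt) ≈ 141 nm; the
kinetic fit recovers the generating parameters (k_cat 15.18 s⁻¹, K_M
0.50 µM, k_basal 0.75 s⁻¹) from noisy data.

Library use mirrors the CLI one-to-one, e.g.:

```python
from dynstalk.synth import simulate_kinetics, KineticTruth
from dynstalk.sm import fit_saturation

ds = simulate_kinetics(KineticTruth(15.18, 0.50, 0.75),
                       [0, 0.25, 0.5, 1, 2, 5], noise_sd=0.5,
                       replicates=3, seed=1)
fit = fit_saturation(ds.x, ds.y, role="atpase")
print(fit.amplitude, fit.K, fit.basal)   # 15.243  0.485  0.639
```

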