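# Methods

This note documents the models, estimators, defaults and numerical choices
behind each `dynstalk` stage, what the synthetic generators do and do not
emulate, and the design decisions taken where the underlying procedures are
conventionally under-specified.

## Scientific setting

The dynein motor domain couples three spatially separated elements: a ring
of six AAA+ ATPase domains (each with a large `AAAxL` and small `AAAxs`
subdomain, plus the N-terminal linker — 13 quasi-rigid bodies in total), a
microtubule-binding domain (MTBD), and the ~135 Å antiparallel coiled-coil
stalk (helices CC1 and CC2) that connects them. The analyses here quantify
(i) how strongly the stalk's *length* is conserved across dynein families,
(ii) how the 13 ring bodies move between nucleotide states (ATP-analogue
AMPPNP versus post-hydrolysis ADP-vanadate), and (iii) how single motors
move along microtubules and how their ATPase/binding responds to
microtubule concentration.

## Sequence conservation (`dynstalk.seqcons`)

**Curation** is a rule pipeline over `(id, sequence)` records. Default
rules: length within 1,000–6,000 aa (heavy-chain scale), ≤1% ambiguous `X`
residues, exact-duplicate removal (first occurrence kept). Each rejection
is logged with the first failing rule; the active rule set should be
recorded with downstream results. The thresholds are package defaults —
curation criteria for such datasets are rarely published in full — and are
fully configurable.

**Domain delineation** maps anchor residues (1-based positions in the
ungapped reference row) to alignment columns by counting non-gap reference
characters. Anchors for CC1/CC2 are configuration values; the shipped
yeast defaults (CC1 3008–3125, CC2 3231–3344, Dyn1 numbering) are
package-defined approximations and must be validated against any specific
alignment before quoting conservation percentages.

**Length distributions** count non-gap characters per sequence within the
annotated column span (spans may be combined, e.g. CC1+CC2 for the whole
stalk). Mode ties break deterministically toward the smaller length. The
headline statistic is the modal fraction — the fraction of sequences with
exactly the modal domain length.

**Column conservation** re-implements the AMAS-style 0–10 score from the
Taylor/Zvelebil ten-property table (hydrophobic, polar, small, tiny,
aliphatic, aromatic, positive, negative, charged, proline): the score is
the number of properties on which all residues of a column agree (all
members or all non-members); full identity is flagged separately.
`hydrophobic_fraction` uses the set {A,C,F,I,L,M,V,W,Y} by default
(configurable). **Charge variation** has no standard formula; it is
defined here as `min(n_acidic, n_basic)/n` with acidic={D,E},
basic={H,K,R} — zero when no acidic↔basic switching exists, maximal (0.5)
for an even split, and symmetric under exchanging the two classes. The
charge consensus is `acidic`/`basic` when that class reaches the consensus
threshold (default 0.5), `mixed` when both do. Gap policy: by default gaps
are excluded from a column before scoring; a `strict` policy instead
treats any gap as breaking identity and all properties. All-gap columns
are emitted flagged, with metrics missing.

## Structure dynamics (`dynstalk.structdyn`)

**Rigid-body partition.** The 13-body residue-range tables for the yeast
Dyn1 and human dynein-2 numbering schemes ship as JSON config. The exact
ranges used in published rigid-body fits are not printed anywhere; the
shipped tables are package-defined approximations chosen to contain the
catalytic motif residues (yeast Walker-A K1802, Walker-B D1848, Q1829,
Sensor-II R1971, insert-loop G2116, arginine finger R2209; human K1695,
D1741, R1867, G2020, R2109) and are user-overridable. Stalk, buttress and
MTBD fall outside the 13 bodies and are reported as unassigned.

**Superposition** is the closed-form Kabsch least-squares rigid transform
over matched Cα pairs, with the determinant sign correction excluding
reflections. Degenerate (collinear) selections and selections with fewer
than three pairs are rejected. Residue correspondence is by identical
numbering within one scheme, or by global Needleman–Wunsch alignment
(BLOSUM62, gap open −11, extend −1) of the selected Cα sequences for
cross-species comparisons. Residues missing a Cα on either side are
dropped, never imputed.

**Displacement fields** superpose state b onto state a over the chosen
reference subdomain(s) and report per-residue vectors b−a and their
magnitudes, plus per-subdomain mean/max summaries. By construction the
reference subdomain reads ≈0.

**Rotation angles** fit each residue triple's axis as the total-least-
squares line through its three Cα (first principal direction through the
centroid) and report `arccos |u·v|`, bounding angles to [0°, 90°]; the
axis of a triple is sign-free, so this convention is the natural one. The
published procedure does not define the axis fit; the principal-line
interpretation is a package decision.

**Pocket closure and interface gaps.** Nucleotide-pocket closure is
proxied by the Cα–Cα distance between the arginine finger and the
Walker-A lysine. Subdomain interface gaps report both the minimum Cα–Cα
distance across the pair and the centroid–centroid distance; comparisons
between states must use the same metric.

Units: Å for coordinates and distances, degrees for angles, 1-based
inclusive residue numbering throughout.

## Single-molecule motility (`dynstalk.sm`)

**Localization.** Candidates are local maxima of a difference-of-Gaussians
band-pass image above a robust (MAD-based) noise threshold, default 5
SDs. Each candidate is fit in a 7-pixel window by maximizing the Poisson
likelihood of an integrated symmetric 2-D Gaussian plus constant
background (parameters x, y, photons, background; L-BFGS-B with bounds).
Non-converged or edge-stuck fits are dropped; near-duplicate detections
within one PSF sigma are suppressed. The reported precision is the
information bound for this model, `var = s_a²/N · (16/9 + 8π s_a² b / N)`
with `s_a² = σ² + a²/12` in pixel units — a package-defined estimator.
Camera geometry defaults to 159 nm pixels.

**Linking** is greedy nearest-neighbor: per frame transition, candidate
(track, localization) pairs within `max_jump` (default 500 nm at 1-s
frames) are assigned closest-first, ties to the lowest track id; unmatched
localizations open tracks; a track closes after `max_gap` (default 1)
consecutive missed frames. These parameters are explicit config and are
recorded in outputs; published tracker settings for this assay class are
typically unavailable.

**Straightening** projects each track onto the leading principal component
of its (x, y) scatter. Orientation follows a supplied reference direction
(e.g. kinesin polarity) or, absent one, makes the track's own net
displacement non-negative. Tracks with parallel/perpendicular spread
ratio < 1.05 are flagged unreliable.

**Displacement statistics** tile each track with non-overlapping windows
of the chosen interval (default 1 s; overlapping windows available for
sensitivity analysis), linearly interpolating positions at window edges
when frames do not align. The arithmetic mean and SD are the primary
statistics; a Gaussian is also least-squares fit to the 20-nm-binned
histogram because histogram-level fits are common in this literature, and
both are reported. For pure 1-D diffusion the displacement distribution is
N(0, 2DΔt) — the property the diffusive-phenotype analysis relies on.

**Phenotype calls** use explicit thresholds (defaults: min velocity
20 nm/s, min dwell 5 s, min D 1,000 nm²/s, drift significance 3 SEM),
applied in order: *transient* when the track is shorter than the dwell
threshold; *directional* when the mean interval displacement is
significantly nonzero and the velocity clears the floor; *diffusive* when
the MSD-fit D (through-origin fit over the first three lags, slope/2)
clears its floor; else *static*. The thresholds are package defaults tuned
on synthetic data and are not claimed to reproduce any manual
classification. **Polarity** is the sign of the summed net displacement of
kinesin reference tracks that classify as directional; no passing track or
conflicting signs → undetermined.

**Saturation kinetics.** Both ATPase and cosedimentation data follow
`y = (A − b)·x/(K + x) + b` (A = k_cat or B_M, K = K_M or K_d in µM
tubulin dimer, b = basal). Fitting is bounded nonlinear least squares
(all parameters ≥ 0) initialized from the zero-concentration mean, the
maximum response, and the half-rise concentration; standard errors come
from the residual covariance. At least four distinct concentrations
including x = 0 are required. Identifiability: when the hyperbola does not
improve on a constant (flat data, or amplitude ≈ basal), A and K are
reported as *unidentifiable* — `None`, never a number — and only the basal
value is quoted, mirroring how microtubule-insensitive motors must be
reported.

Units: nm and s for tracking, µM for concentrations, s⁻¹ for rates.

## Synthetic generators (`dynstalk.synth`)

Each generator records its generating parameters so analyses are tested by
parameter recovery. Seeds are mandatory; a fixed seed gives bit-identical
output; no global random state is used.

* **Sequence families**: per-column substitutions at a given rate,
  acidic↔basic charge swaps at selected columns, and indels assigned to an
  *exact* rounded fraction of sequences (so modal-length fractions are
  exact by construction, not binomial). Because every edit is recorded,
  the true multiple alignment is reconstructed directly — no aligner runs.
  Default study conditions used in the acceptance computation: 534
  sequences (the curated-set scale), 5% substitution rate, 1% of
  sequences carrying a 2-residue stalk deletion.
* **Structure pairs**: 13 Gaussian Cα clouds (default 25 atoms, 8 Å
  spread) on a 60 Å ring, contiguously numbered; state b applies one exact
  rigid transform per body. Recovery of a 20° rotation applied to the
  AAA2L body about an axis perpendicular to a residue-triple axis, after
  AAA1L alignment, reproduces the angle to machine precision. No attempt
  is made to generate realistic protein geometry, coiled coils, or side
  chains — these pairs test the estimators, not the biology.
* **Trajectories**: directional (constant drift v, optional run length),
  1-D diffusive along the filament axis (increments N(0, 2DΔt)),
  transient (static binding events with exponential dwell, invisible while
  unbound — matching evanescent-field visibility), and static modes.
  Localization error is isotropic Gaussian noise on true positions *only*
  when movies are not rendered; rendered movies derive noise purely from
  Poisson statistics, separating tracker tests from localizer tests.
  Frame intervals of 0.1 s and 2 s mirror common acquisition settings; the
  default panel uses 1-s intervals, 60-s tracks, 20-nm localization noise
  (the true localization precision of the emulated instrument is not
  published; this is a free parameter, not a calibration).
* **Movies**: integrated-Gaussian PSF per emitter plus uniform background,
  Poisson-sampled; emitters outside the field of view are clipped and
  counted. No photophysics (blinking/bleaching), EM-gain model, or 3-D
  PSF.
* **Kinetics**: exact hyperbola plus zero-mean Gaussian noise;
  concentration grids must span ≥ 4·K so the plateau is constrained.

What passing recovery tests show — and do not show: they verify the
estimators are correct under their own assumptions (Gaussian/Poisson
noise, rigid bodies, exponential dwells). Real data add model violations
(drift, aberrations, heterogeneous motors, alignment errors) these
generators deliberately exclude.

## Pipeline (`dynstalk.pipeline`, `stalk` CLI)

Configuration is file-based (YAML) with CLI overrides (precedence CLI >
file > defaults); unknown keys are rejected before any stage runs, listing
every violation. All stage randomness derives from the single top-level
seed via per-stage seed sequences. The manifest records package version, a
hash of the result-affecting config (output location excluded), and
SHA-256 checksums of every file written; identical configs reproduce
identical checksums. A failing stage aborts downstream stages but
preserves completed outputs, and the report marks absent sections rather
than fabricating them.

## Problem sizes and tolerances

The default verification workloads are sized for interactive use: 10,000
one-second Brownian steps for displacement statistics (moments then match
theory within a few percent), 500 seeded kinetic fits at noise SD 0.5 for
the ≤5% median-error check, 120-track phenotype panels, 13×25-atom
structure pairs. Rotation/displacement round trips are asserted at 1e-6
(degrees/Å); Kabsch is additionally validated against exhaustive
orientation searches (a 0.05° single-axis grid where the optimum is
provably single-axis, and a coarse SO(3) grid as a lower-bound check) and
against an independent library implementation. Monte-Carlo assertions use
3-SE bands or 10% relative tolerances as stated in each test.

## Known limitations

* The shipped subdomain ranges and stalk anchors are approximations; any
  quantitative claim on real structures or alignments should re-validate
  them (both are plain JSON overrides).
* Analyses of the real deposited coordinate files and the curated
  alignment require those files to be supplied locally; the package never
  fetches remote data.
* The localizer assumes a symmetric Gaussian PSF and constant local
  background; the linker is greedy, not globally optimal, and will swap
  identities of crossing molecules closer than `max_jump`.
* Gliding-assay geometry is reduced to pre-assigned, pre-straightened
  tracks; no kymographs, drift correction, or channel registration.
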