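# Methods

## Model

The package simulates the pericentromeric-heterochromatin (PCH) domain of
an early-embryo nucleus as four interacting species in a spherical
confinement: the PCH fibre (H) as a semiflexible bead-spring chain, an
rDNA block (rD) embedded contiguously in its middle, and two free protein
species — Fibrillarin (F, the nucleolar dense-fibrillar proxy) and an
amphiphile (X) with affinity for both F and H.  All quantities are in
reduced units: the bead diameter σ (≈30 nm, ≈5 kbp of chromatin) and the
thermal energy k<sub>B</sub>T.

Energy terms:

- bonds between consecutive chain beads, V = k<sub>s</sub>(r − σ)² with
  k<sub>s</sub> = 100 k<sub>B</sub>T/σ² (stiff, near-rigid bonds);
- bending at each bonded triple, V = k<sub>b</sub>(1 + cos θ).  The
  functional form is the standard minimal choice; k<sub>b</sub> = l<sub>p</sub>/σ
  reproduces a persistence length of l<sub>p</sub> beads in a free chain,
  2 beads (60 nm) by default;
- non-bonded pairs, truncated 12-6 Lennard-Jones.  Attractive pairs use
  cutoff 2.5σ; excluded-volume-only pairs the WCA form (ε = 1, cutoff
  2<sup>1/6</sup>σ).  Both are cut *and shifted* so the energy is
  continuous at the cutoff; forces are unaffected by the shift.  Directly
  bonded (1–2) pairs are excluded from the non-bonded sum so the bond
  length distribution peaks at σ with width (2k<sub>s</sub>)<sup>−1/2</sup>;
- a purely repulsive WCA wall acting on the distance to the confinement
  sphere surface.

The confinement radius follows from the chromatin volume fraction φ with
beads of radius σ/2: R<sub>c</sub> = (N<sub>G</sub>/8φ)<sup>1/3</sup>σ,
which for the 72,000-bead diploid genome at φ = 0.1 gives 44.8σ, rounding
to the quoted 45σ.  (Taking the full diameter σ as the bead radius would
give 90σ instead; the σ/2 convention is the one consistent with the
quoted radius.)  Protein bead counts come from number densities,
N = c·(4/3)πR<sub>c</sub>³; the reference Fibrillarin concentration
0.013σ⁻³ puts 4,962 F beads in the full nucleus.

Default interaction hierarchy (+rDNA reference state, k<sub>B</sub>T):
rD−F = F−F = 2.0 > X−X = 1.75 > F−X = 1.5 > X−H = 1.0 > H−H = 0.35, all
other pairs excluded-volume.  The text constrains ε<sub>XX</sub> to
(1.5, 2.0) and ε<sub>XH</sub> to (0.35, 1.5) without printing values;
the defaults take the midpoints and both are exposed in the configuration.
The −rDNA variant removes the rD−F attraction and raises X−H to 1.5
(= F−X), the boundary of the stated neocondensate regime X−H ≥ F−X; both
knobs remain configurable.  The rDNA block is 20% of the 10,000-bead
chain (2,000 beads); the alternative reading of the source count
(4,000) is selectable by configuration.

## Dynamics

Underdamped Langevin dynamics with the BAOAB splitting: half-kick,
half-drift, exact Ornstein–Uhlenbeck friction/noise step, half-drift,
half-kick.  Defaults m = 1, γ = 1, dt = 0.005; a construction-time bound
refuses dt > 0.01 (the bond term sets the fastest frequency,
ω = √(2k<sub>s</sub>/m) ≈ 14).  Noise comes from one global NumPy
Mersenne-Twister stream seeded per run and drawn in fixed bead order, so
identical seeds give bit-identical trajectories.  Pair interactions use a
cell-list-built half neighbour list with a 0.6σ skin, rebuilt when any
bead moves half a skin; forces from the list are exactly those of a
brute-force all-pairs evaluation (verified in the suite).  Pair and wall
forces are evaluated at a floor distance of 0.3σ when beads overlap more
deeply (only relevant during push-off; occurrences are counted in the
run provenance).

Staged protocol: (1) a short push-off with per-bead force magnitudes
capped at 20 to relax random-placement overlaps; (2) optionally an
annealing stage (below); (3) equilibration and (4) production at the
target temperature, with frames, kinetic temperature and potential energy
sampled on a fixed stride.

### Annealing for organization runs

At the reference attraction strengths the condensed F and X phases sit
below the Lennard-Jones triple point (T/ε ≈ 0.50 and 0.57): they are
effectively solid, and a random initial mixture freezes into whatever
aggregate forms first — wetting and engulfment then barely progress on
any affordable timescale.  The organization benchmarks therefore anneal:
a hold slightly above the X-phase condensation temperature
(k<sub>B</sub>T = 1.3, where X is vapour but F remains condensed since
ε<sub>FF</sub>/k<sub>B</sub>T = 1.54), then a slow ramp down through the
X condensation point so X deposits onto the Fibrillarin surface and the
PCH phase, followed by equilibration and production at k<sub>B</sub>T = 1.
This is a numerical equilibration device: all classified configurations
are produced at the target temperature.

### Direct coexistence for condensation thresholds

Spontaneous nucleation near the condensation boundary is rate-limited by
the simulated volume: a marginally supersaturated Fibrillarin gas (e.g.
c = 0.0013 at ε = 2) never nucleates on any affordable run even though
its condensed phase is stable, and cold quenches produce many small
clusters whose coarsening into one majority cluster is equally
unaffordable.  The condensation columns therefore use the standard
direct-coexistence construction: each cell starts from a preformed
droplet (60% of the beads packed at liquid density) surrounded by
vapour, runs at the working temperature, and is classified condensed if
a majority cluster survives the run and not condensed if the droplet
evaporates.  This measures the stability boundary of the condensed
phase — what a phase diagram reports — rather than a volume-dependent
nucleation rate.  Droplets at these bead counts carry a curvature
(Kelvin) penalty that biases thresholds slightly upward; the dilute
column therefore runs in a doubled nuclear volume (its bead count is
small anyway) to keep its droplet as large as possible — at exactly
nuclear volume the dilute ε = 2 droplet fraction sits right at the 0.5
classification boundary.

## Observables and classifications

- Clusters: connected components of the graph linking beads of one
  species within 1.5σ (first coordination shell).  A species is
  *condensed* when its largest cluster holds ≥ 0.5 of its beads
  (inclusive), sustained over the final three saved frames.
- Radius of gyration: RMS distance from the subset centroid.
- d<sub>HF</sub>, d<sub>FX</sub>: distance between centres of mass of the
  two species' largest clusters (all beads, flagged, when a species is
  uncondensed).
- Surface coverage: F-cluster surface beads are those with fewer than 8
  same-species neighbours within 1.5σ (an LJ-liquid monolayer criterion;
  for denser-than-liquid degenerate inputs the outermost radial quintile
  is used instead); coverage is the fraction of surface beads with an X
  bead within the contact cutoff.  Verdicts: none < 0.1 ≤ partial < 0.75
  ≤ complete.
- rDNA interior fraction: fraction of rD beads closer to the F-cluster
  centre than its 80th-percentile radial extent; ≥ 0.5 is interior
  condensation, below (with surface contact ≥ 0.25) is wrapping.
- Layering: radial medians of F, X, H about the F-cluster centre
  (X-cluster centre if F and X are dissociated, i.e. their centre
  distance exceeds the sum of 80th-percentile extents).  *layered* =
  median<sub>F</sub> < median<sub>X</sub> < median<sub>H</sub> with
  complete X coverage of F; *neocondensate_in_H* = F–X dissociated with
  the X centre inside the H condensate and F farther from H than X;
  *partial_wetting*/*dissociated*/*none* otherwise.  Benchmark runs take
  the majority verdict over the final three frames.

All verdicts are invariant under rigid motions of the configuration
(tested), and the cluster finder is validated against a brute-force
union-find oracle.

## Benchmark problem sizes

The named experiments are exercised at reduced copies of the full system
produced by `scale_system`, which shrinks bead counts by a factor s and
the confinement radius by s<sup>1/3</sup> so all densities and all ε are
unchanged.  Sizes used by the test suite and the acceptance script:

| quantity | system | size |
|---|---|---|
| condensation, dense column | F-only, R<sub>c</sub> = 22.5σ (1/8 volume) | 620 beads |
| condensation, dilute column | F-only, R<sub>c</sub> = 56.7σ (2x volume) | 992 beads |
| collapse onset | isolated chain, weak confinement | N = 400 |
| wetting (F-X = 1.5) / ±rDNA organization | four species at 1/24 | ≈1,660 beads |
| low-F-X wetting point, depletion series | four species at 1/32 | ≈1,245 beads |
| rDNA engulfment | three species at 1/32 | ≈470 beads |

Dilute-end condensation is aggregation-limited and uses the longest runs
(order 10⁶ steps); organization runs use the annealing protocol above.
Finite size shifts quantitative boundaries, and two shifts are large
enough to change classifications at these sizes: (i) the coil–globule
onset moves up with decreasing N (the transition sharpens toward its
large-N location only for chains far longer than desk scale), and
(ii) complete wetting requires enough X beads per unit F surface — the X
reservoir scales with system volume but the F-cluster surface only as
N<sup>2/3</sup>, and with both protein phases below their triple points
the X cap cannot spread, so X sits as a partial-coverage lens on F at
benchmark scale even when the radial ordering median<sub>F</sub> <
median<sub>X</sub> < median<sub>H</sub> is in place.  The suite reports
these quantities as measured; they are the two known scale-limited
classifications.

## Synthetic nucleus volumes

The generator renders the four observed organizations — nucleolus with a
PCH shell directly on its edge ("surrounded"), elongated PCH apposed to
the nuclear envelope ("extended"), a compact PCH ball with a separated
Fibrillarin neocondensate ("compact"), and a hollow PCH shell whose core
is filled by a distinct protein phase ("void") — as crisp geometric masks
with controllable sizes, plus flat background, additive Gaussian noise
and optional exponential photobleaching for time series.  Ground-truth
masks are returned with every volume, so the imaging metrics can be
checked exactly: on noise-free volumes segmentation must recover the
masks voxel-for-voxel, shell occupancy of the surrounded ground truth is
1 by construction, and volumes/distances/aspect ratios must match the
constructed geometry to discretization tolerance.  What the generator
does **not** emulate: a realistic point-spread function, anisotropic
optical sectioning, autofluorescence gradients, or nucleus-to-nucleus
variability — passing these tests shows the measurement code is correct,
not that segmentation of real microscopy is easy.

## Imaging metrics

Segmentation: optional rolling-ball-style background subtraction
(morphological opening over a (2r+1) window), Gaussian denoising, then
Otsu or Yen auto-thresholding and connected-component labelling
(26-neighbourhood in 3D, 8 in 2D).  "Centre of geometry" is the
unweighted mask centroid.  Shell occupancy dilates the nucleolar mask
with a discrete ball (1 px = one dilation step), subtracts the original,
and reports the shell fraction overlapped by the target channel.
Nearest distances are between centroids in physical units with
anisotropic voxel sizes.  Aspect ratio is major/minor axis of the
moment-equivalent ellipse (minor axis floored at one pixel for
degenerate masks, with a warning).  Circularity is 4πA/P² with a
4-direction Crofton perimeter — circularity values depend on the
perimeter estimator, which is why it is pinned and documented.  Line
profiles are sampled with linear interpolation and each channel is
normalized to its own maximum.  Time-series traces normalize mean
intensity to the T = 0 value and record vanished segments as gaps.

## Numerical choices and limitations

- The Otsu/Yen thresholds, labelling, morphology and region properties
  are delegated to scikit-image/scipy.ndimage; tests hold them to
  independent oracles (exhaustive between-class-variance search, voxel
  counting, analytic moments).
- The engine is single-threaded by design (reproducibility over speed);
  no hydrodynamics, electrostatics, bond breaking or transcription
  kinetics are modelled.
- Classification thresholds (0.5 condensed fraction, 0.1/0.75 wetting,
  0.5 interior) are declared package conventions: the source phenomena
  are described qualitatively, so any quantitative reproduction depends
  on such operational definitions.
- At benchmark scales the wetting and layering verdicts are sensitive to
  the X-bead budget relative to the F surface; below ~1/24 of full size
  "complete" coverage becomes geometrically unreachable and verdicts
  degrade to partial wetting regardless of the physics.
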