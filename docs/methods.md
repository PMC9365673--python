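# Methods

This note documents the models behind `droplens`: what each analysis
computes, what the synthetic generators plant and how, which numerical
choices were open and how they were settled, and what the tests do and do
not demonstrate about real data.

## Coordinate model

Coordinates are nm, times ps, boxes strictly orthorhombic (triclinic input
is rejected — the membranes this package targets are built flat, and the
restriction keeps minimum-image distances exact and cheap). All
cutoff-based statistics reduce to minimum-image distances; centres of
geometry are computed PBC-aware through per-axis circular means, so a
molecule or a protein ring straddling the boundary is centred correctly.
GRO files are parsed with strict fixed-column validation and molecules are
inferred from runs of (residue number, residue name) against a species
registry, since the format itself carries no molecule block; protein
residues (names like `S165`) are grouped into protomers by the minimal
repeating unit of the residue-label sequence. A frames TSV
(`frame, time_ps, bead_id, x, y, z, box_*`) is provided as a lossless
plain-text trajectory format, with a YAML layout sidecar carrying the
chemistry.

## Ring enrichment

A lipid counts as inside the ring when the **lateral** (xy) minimum-image
distance from its molecular centre of geometry to the protein centre of
geometry is below the ring radius (default 6 nm). Lateral distance is the
default because the null model is an area fraction — the share of membrane
surface the ring occupies, `π r²/(Lx·Ly)` — and a 3D mode exists behind a
flag. Molecule-level counting (centre of geometry, not any-bead) avoids
double counting; an any-bead mode is available for sensitivity analysis.
Fractions are averaged over the analysis window, by default the final 3/5
of the trajectory, matching the convention of analysing the equilibrated
tail of production runs. Classification (enriched / depleted / neutral)
uses a configurable margin δ = 0.25 around ratio 1; the value is a
reporting convenience, not a hypothesis test.

## Contacts and residence times

Occupancy is the fraction of window frames in which *any* bead of a residue
lies within the contact cutoff (0.6 nm) of *any* bead of a lipid of the
species — or of a specific bead chemical group when resolved by group,
which is how carboxyl-ester-specific binding is exposed. Aggregation
reports min/median/max across protomers × replicates rather than
mean ± SD, the convention for per-protomer occupancy bars.

Residence times use a dual cutoff (0.55 / 1.0 nm): an event opens at the
first frame below the lower cutoff while no event is open and closes at the
first frame above the upper one; the duration is the frame count in
[open, close). The asymmetry suppresses boundary flicker — a contact
rattling around a single cutoff would fragment one binding event into many.
Events still open at the trajectory end are censored and excluded from
median/IQR by default (inclusion would bias durations toward truncation);
a flag includes them. With lower = upper the scheme provably reduces to
single-cutoff run lengths, which the tests assert, along with per-series
dominance of dual-cutoff over single-cutoff durations.

## Spatial statistics

z-density profiles are computed per frame relative to the bilayer midplane
(PBC-aware mean z of all phospholipid beads — bilayers drift along z in
NPT ensembles), histogrammed at 0.1 nm, frame-averaged, shifted so the
phospholipid acyl-chain-tip peak sits at z = 0, and scaled to unit maximum.
Registration uses the argmax bin; a tie beyond 1.5 bins raises an error
reporting the tie positions rather than silently picking one.

Clustering is single-linkage under the minimum-image distance with a 0.6 nm
cutoff, computed by union-find over kd-tree neighbour pairs (the kd-tree
handles the periodic box). Sizes are counted in molecules — beads of one
molecule are pre-merged — because the scientific quantity is how many
*lipids* have coalesced; a bead-level mode exists for parity with generic
cluster-size tools. The concentration dependence of the time-averaged
largest-cluster fraction is summarised with a five-parameter logistic
(asymmetric Hill), fitted by least squares. The curve is descriptive — a
guide to the eye — so fit quality is reported but nothing downstream
depends on it; a strictly constant response is rejected with a pointer to a
null model instead of returning meaningless parameters.

## CG parameterization

Mapping uses mass-weighted centroids (squalene: one bead per isoprene unit,
six beads in a linear chain). Equilibrium bond lengths and angles are the
sample means over the mapped trajectory; force constants come from
Boltzmann inversion, `k = k_B T/σ²` with k_B = 0.0083145 kJ mol⁻¹ K⁻¹
(bond variance in nm² → kJ mol⁻¹ nm⁻²; angle variance in rad² →
kJ mol⁻¹ rad⁻²). Inversion is offered as the principled initialiser for
force constants; the traditional manual tuning loop that iterates CG
simulations is replaced here by a closed sample-and-compare loop — Gaussian
sampling of the implied harmonic ensembles plus the overlap coefficient
`Σ min(p, q)` on shared bins — because an MD engine is out of scope. Zero
variance is rejected explicitly: that observable is a rigid constraint, not
a harmonic term. The itp-style emitter writes 1-based indices with harmonic
functs (1 for bonds, 2 for angles) and round-trips through its parser to
printed precision.

Synthetic reference ensembles for validation are built by sampling chain
conformations from the planted harmonic parameters (bond lengths and
angles Gaussian, dihedrals uniform, standard internal-to-Cartesian
construction) and expanding bead centres into fixed equal-mass atom
clusters whose offsets sum to zero — so the mapping provably inverts the
atomisation, and extract → invert recovers the plant limited only by
sampling error (≈ √(2/n) relative on variances).

## Synthetic trajectory generator

The generator's purpose is to endow trajectories with exactly the
statistics the analyses measure — it is a statistical emulator, not
physical dynamics.

*Enrichment.* Lipid molecules carry a lateral Metropolis random walk
(Gaussian steps, σ = 0.5 nm) whose acceptance weight is `w` inside the ring
and 1 outside, with `w = E(1−a)/(1−E·a)` for planted enrichment ratio E and
ring area fraction a. The stationary inside fraction is then exactly `E·a`,
i.e. the measured enrichment ratio converges to E. E is defined relative
to the *system-mean* density (inside fraction over area fraction) — the
quantity the enrichment analysis reports — so planted and recovered values
live on the same scale. `E·a ≥ 1` is geometrically impossible and raises a
plant error. Positions are initialised from the stationary law, so no
burn-in is needed; 25 walk substeps separate saved frames, emulating the
sparse frame saving of long production runs (frames 1 ns apart by default).
Frames remain mildly autocorrelated, as real trajectory frames are; the
recovery tolerance (±10%) was chosen with that in mind.

*z laws.* Each bead's z is resampled every frame from its chemical group's
Gaussian law about the midplane — interfacial phospholipid groups
leaflet-mirrored (headgroup 2.1, phosphate 1.9, glycerol-ester 1.5, acyl
0.8 nm, SDs 0.1–0.25 nm), acyl tips and neutral-lipid groups centred at 0.
These defaults reproduce the canonical bilayer ordering: PL esters
peripheral, NL esters at the membrane centre, which is the geometric point
the z-density analysis exists to show.

*Contact kinetics.* For each planted (labelled residue, species) pair, one
lipid per protomer follows a two-state Markov chain (per-frame p_on/p_off;
mean dwell 1/p_off frames). Bound frames place the lipid so its minimum
bead distance to the residue falls in [0.7·0.55, 0.55) nm; unbound frames
in (1.0, 2.0] nm, along the outward radial direction so no other residue
comes closer — the dual-cutoff segmentation of the planted distances is
therefore exact, and recovered dwell distributions are geometric with the
planted mean.

*Clustering.* A planted largest-cluster fraction keeps that share of a
species chain-linked (consecutive members 0.30–0.45 nm apart, below the
0.6 nm cutoff) around a drifting nucleation centre while the rest are
rejection-sampled at ≥ 0.9 nm from everything, so the per-frame largest
cluster is exact by construction.

## Synthetic imaging generator

Droplets are spheres intersected with each z-plane: anti-aliased circular
cross-sections of plane-dependent radius, additive amplitude 150 counts
over a background of 10, Gaussian blur σ = 0.6 px (≈ 30 nm — deconvolved
super-resolution data have near-PSF-free edges), then Poisson counting
noise plus Gaussian read noise (SD 2). The default stack geometry is 35
planes over 8.4 µm at 0.05 µm pixels. Droplet z-centres are uniform within
the imaged depth, so the maximum projection samples a cross-section up to
half a z-step (0.12 µm) off the equator; for a 0.5 µm droplet this biases
the projected diameter ≈ −3% on average, partially offset by blur, leaving
the end-to-end pipeline bias under ≈ 1% — within the ±5% recovery
tolerance, as the acceptance checks measure. Cells are non-overlapping
disks (radius 2 µm, the scale of a yeast cell); droplets are placed
non-touching inside their cell, and when an extreme count draw cannot fit
without touching, the cell keeps as many droplets as geometry allows with
the ground truth recording what was actually planted. Sub-resolution
droplets (< 2 px across) are rendered and flagged.

What the generator does **not** emulate: realistic PSFs (only Gaussian
blur), multi-channel imaging, cytoplasmic autofluorescence textures,
out-of-focus haze between cells, or droplet motion during acquisition.
Passing the recovery tests therefore shows the measurement chain is
unbiased under the stated optical model, not that segmentation is robust to
every real-world artefact.

## Morphometry and statistics

Thresholding defaults to inter-class-variance maximisation (Otsu), the
default family of the common particle-analysis tools; the method is
configurable and recorded in output metadata. Watershed runs before
measurement, and the circularity filter after — overlap-merged particles
that watershed fails to split are then removed by circularity rather than
mis-measured. Ellipse axes come from second central moments
(moment-equivalent ellipse); the perimeter estimate is the weighted
boundary walk of `skimage.regionprops`, and circularity 4πA/P² is clipped
at 1.0 since pixelated disks can exceed it slightly.

Distribution fitting operates on histogram counts (0.05 µm bins) with
3-parameter Gaussian and log-normal count models by unweighted least
squares; AIC = n·ln(RSS/n) + 2k, and the Akaike weight of the preferred
model is reported as the selection certainty. Count-model fitting (rather
than maximum likelihood on raw diameters) is deliberate: it is the
procedure used by the graphing software this pipeline mirrors, and the one
the recovery tolerances refer to. An ML mode is not provided. The extra
sum-of-squares F-test compares nested Gaussian fits (shared vs separate
means; amplitudes and SDs always free). Kruskal–Wallis delegates to
`scipy.stats.kruskal` (identical mid-rank tie correction; the all-tied 0/0
case is guarded to H = 0) and is cross-checked against a brute-force rank
computation in the tests; Dunn's z tests are implemented directly (pooled
mid-ranks, tie correction `Σ(t³−t)/(12(N−1))`, Bonferroni or Šidák
family-wise adjustment) as no installed package provides them.

## Validation scale

The acceptance checks run at desk scale: ≥ 1,000 droplets across ~35
small fields per diameter population, 200 cells for the ≥3-droplet
fraction, 400 for the ≥1-droplet fraction, 10⁵ frames for dwell-time
recovery, 10⁵ samples for the Boltzmann round trip, and 10⁴ lipids for the
uniform-placement null. These sizes put sampling error comfortably inside
each pre-registered tolerance (e.g. SE of a mean diameter ≈ 1% at
n = 1,000; binomial SD ≈ 2–3 points at 200–400 cells) while keeping the
whole suite within minutes on one CPU.

## Known limitations

- Orthorhombic boxes only; no XTC/TRR readers (text formats are the
  interchange; binary adapters would be thin wrappers).
- The Metropolis walk is not a physical diffusion model; kinetic lipids
  bypass the z laws while bound (they track the residue depth).
- The 5PL clustering fit is descriptive; midpoints are only trustworthy to
  about one concentration step on sparse curves.
- Per-cell counting assumes cells are resolvable disks provided as masks;
  there is no cell segmentation from transmitted-light images.
- Occupancy analyses scan residue–lipid pairs frame by frame; systems far
  larger than the tens-of-thousands-of-beads scale used here would want a
  neighbour-list fast path.
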