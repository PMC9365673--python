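# droplens

Coarse-grained membrane trajectory statistics and lipid-droplet morphometry
for studies of neutral-lipid (NL) storage.

Lipid droplets form at ER sites marked by Seipin, an oligomeric membrane
protein whose ring-like luminal domain concentrates neutral lipids —
triacylglycerol (TAG), steryl esters (SE), retinyl esters (RE), squalene
(SQL) — inside the ring while phospholipids and free fatty acids are
excluded. Quantifying that behaviour takes a stack of small, well-defined
analyses over coarse-grained (CG) trajectories, a parameterization recipe
for CG lipids that have no published bead model, and a fluorescence
morphometry pipeline for the droplets the cell actually makes. `droplens`
packages all of it, together with synthetic-data generators that plant every
statistic with known ground truth so the analysis layer is testable end to
end.

## What it computes

**Trajectory side** (GRO-dialect coordinate files, concatenated multi-frame
GRO, or an internal frames TSV; lengths in nm, times in ps):

- *Ring enrichment* — the fraction of a lipid species whose molecular centre
  of geometry lies within a lateral radius r (default 6 nm) of the protein
  complex's centre, averaged over the trajectory tail (default the final
  3/5). Its null is the ring's share of membrane area, `π r² / (Lx·Ly)`;
  the ratio fraction/null is the enrichment (>1 concentrated, <1 excluded).
- *Contact occupancy* — fraction of frames in which a residue is within
  0.6 nm of any bead of a lipid, per protomer, optionally resolved by bead
  chemical group (glycerol backbone, carboxyl ester, acyl chain, ...);
  aggregated as min/median/max across protomers and replicates.
- *Dual-cutoff residence times* — a binding event opens when the
  residue–lipid minimum distance drops below 0.55 nm and closes only when it
  exceeds 1.0 nm, suppressing boundary flicker; durations are reported in
  frames and ns with censoring flags, medians and IQRs.
- *z-density profiles* — bead histograms along the bilayer normal,
  registered so the phospholipid acyl-chain-tip peak defines z = 0 and
  scaled to unit maximum.
- *NL clustering* — single-linkage cluster sizes (molecule-level, 0.6 nm
  cutoff, periodic) and the largest-cluster fraction as a function of NL
  concentration, with a five-parameter logistic fitted to the curve.

**CG parameterization** (`droplens.cgmap`): atoms → beads at mass-weighted
centroids (squalene: one bead per isoprene unit — 6 beads, 5 bonds,
4 angles), bond/angle distributions extracted over an atomistic trajectory,
equilibrium values from the means, force constants by Boltzmann inversion
`k = k_B·T/σ²`, a Gaussian sampler for the implied harmonic ensembles, the
overlap coefficient `Σ min(p,q)` to compare CG and atomistic distributions,
and an itp-style parameter block writer/parser.

**Imaging side** (`droplens.morphometry`, multi-page TIFF z-stacks):
maximum-intensity projection → automatic (Otsu) thresholding →
distance-transform watershed → per-particle measurement (area, perimeter,
moment-equivalent ellipse axes, circularity 4πA/P²) → filters (area ≥
0.01 µm², circularity 0.8–1.0) → droplet diameter = major axis. Diameter
histograms (0.05 µm bins) are fitted with Gaussian and log-normal count
models by unweighted least squares and compared via Akaike's Information
Criterion; group statistics include the extra sum-of-squares F-test on
Gaussian means, Kruskal–Wallis, and Dunn's post hoc test. Per-cell droplet
counts come from centroid containment in a cell mask.

**Synthetic data** (`droplens.synthetic`): a membrane/ring-protein builder,
a planted-statistics trajectory generator (Metropolis random walk with a
stationary inside-ring density equal to the planted enrichment × area
fraction; per-group Gaussian z laws; two-state Markov contact kinetics whose
bound/unbound states sit unambiguously below/above the dual cutoffs;
chain-linked cluster plants), and a fluorescence z-stack renderer (spheres
sliced into 35 planes over 8.4 µm, 0.05 µm pixels, Gaussian blur, counting
noise + read noise, optional cell disks). All generators are bit-reproducible
under a fixed seed and return ground-truth tables.

## Worked example

```python
from droplens import AnalysisConfig
from droplens.synthetic import (RingSpec, build_membrane_system,
                                PlantedStatistics, simulate_planted_trajectory)
from droplens.enrichment import ring_occupancy_fraction, enrichment_summary

system, frame0 = build_membrane_system(
    {"TAG": 1, "SE": 3, "POPC": 96}, 800, box=(40, 40, 12),
    protein=RingSpec(protomer_count=11, ring_radius=3.0), seed=0)
plant = PlantedStatistics(enrichment={"TAG": 5.0, "SE": 4.0, "POPC": 0.6})
traj, truth = simulate_planted_trajectory(system, frame0, plant,
                                          n_frames=300, seed=1)
cfg = AnalysisConfig()   # ring radius 6 nm, final 3/5 of the run
results = [ring_occupancy_fraction(traj, cfg, sp)
           for sp in ("TAG", "SE", "POPC")]
print(enrichment_summary(results).round(4).to_string(index=False))
```

prints

```
species  fraction   null  ratio replicate
    TAG    0.3229 0.0707 4.5683      None
     SE    0.3037 0.0707 4.2965      None
   POPC    0.0448 0.0707 0.6339      None
```

— a third of all TAG/SE molecules sit inside a ring that covers 7% of the
membrane (enrichment ≈ 4.3–4.6, recovering the planted 5.0/4.0 up to
sampling noise), while the phospholipid is depleted. On the imaging side:

```python
from droplens.pipelines import measure_planted_population
from droplens.stats import diameter_histogram, fit_distributions

res = measure_planted_population(("gaussian", 0.52, 0.18), 300, seed=11)
pair = fit_distributions(diameter_histogram(res["measured"]))
print(pair.summary())
```

```
model                RSS         AIC    weight    location     scale
gaussian           137.8      42.637    0.9997      0.5214    0.1846 *
lognormal          339.5      58.870    0.0003      0.4801    0.3529
chosen: gaussian (certainty 99.9702%)
```

— the pipeline measures a mean diameter of 0.524 µm for a planted
0.52 ± 0.18 µm Gaussian population and the AIC comparison identifies the
generating model.

A console script exposes the same pipelines
(`droplens simulate-traj | simulate-images | analyze-ring |
analyze-contacts | analyze-density | analyze-clusters | cgmap |
measure-lds | report`); every invocation writes a JSON manifest with the
config snapshot, input digests and seeds, so any result file can be
regenerated exactly.

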