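# Methods

## Scientific setting

Proteins that traverse the secretory pathway fold in the endoplasmic
reticulum (ER), where most acquire disulfide bonds. Disulfide formation is an
oxidation and ultimately requires a terminal electron acceptor — canonically
molecular oxygen — so hypoxia stresses oxidative folding. Transcripts induced
by hypoxia are, almost by definition, proteins that must be produced exactly
when oxygen is scarce; if an oxygen-independent folding route exists but is
imperfect, selection should have favoured "simple" disulfide architectures in
hypoxia-induced ER cargo: denser but shorter-range bonds and fewer unpaired
cysteines, both of which reduce the need for error-prone disulfide
isomerization.

This package implements the quantitative side of that comparison:

1. an annotation model and TSV dialect for signal peptides, topological
   domains, subcellular locations and disulfide features;
2. the ER-cargo filter and the hypoxia-induction grouping;
3. per-protein disulfide-architecture metrics;
4. two-group rank statistics;
5. pulse-chase densitometry fractions and the derived folding-fitness
   percentage;
6. membrane-localization quantification from fluorescence images;
7. synthetic generators for every input class, with exact ground truth.

## The cargo filter and grouping

A protein is ER cargo when it has a signal peptide, its subcellular location
matches "secreted" or "cell membrane" (case-insensitive substring), and no
location matches "endoplasmic reticulum" or "golgi apparatus" — residents of
the folding and sorting compartments are excluded because they are not cargo
in transit. Membrane beats secreted when both match.

Induction grouping uses gene-level linear fold changes after 24 h anoxia in
HCT116 and HepG2 colorectal/hepatoma lines: **induced** if the fold change
exceeds 2 in at least one cell line; **noninduced** if it is below 1.2 in
every measured line. The two bands are not exhaustive: intermediate patterns
are reported as `EXCLUDED`, genes without measurements as `UNMEASURED`;
neither enters the two-group comparisons, but both are counted rather than
silently dropped. Thresholds are configurable (`SelectionConfig`).

## Disulfide metrics

For each cargo protein, within its *effective region*:

* `D` — intrachain disulfides; `I` — interchain disulfides (one cysteine of
  this chain each; the partner is on another chain);
* `bonds_per_100aa` = 100·(D+I)/effective_length;
* `bond_range` — residues strictly between the paired cysteines, j−i−1, per
  intrachain bond with both coordinates known (the alternative convention
  j−i is available as `range_convention="delta"`; the two differ by exactly
  1 and published group means cannot adjudicate between them);
* `fraction_cys_bonded` = (2D+I)/n_cysteines; every cysteine not annotated
  in a bond is treated as a free thiol, so `n_free_cys` =
  n_cysteines − 2D − I. The identity 2D + I + free = total cysteines holds
  for every record with defined metrics.

The effective region is the full chain for secreted proteins; for membrane
proteins, the union of topological domains annotated "Cytoplasmic" is removed
first, because cytosolic segments never see the ER oxidative machinery.
Cysteines, bond endpoints, and the density denominator all refer to this
region; a bond is dropped iff either known endpoint lies outside it. The
signal peptide is retained in the denominator — removing it is an upstream
annotation choice, and whether the published per-100-aa denominator trimmed
it is unstated. Bonds with unknown coordinates still count toward D or I
(the architecture exists even when the coordinate is missing) but contribute
no range; a protein with no cysteines in its region has an undefined bonded
fraction and is omitted (and counted) in fraction comparisons.

## Group statistics

Metric distributions across proteins are heavily right-skewed, so group
contrasts use the two-sided Mann–Whitney U test, reported in the
min(U_x, U_y) convention. With pooled n ≤ 14 and no ties the exact null
distribution is used (the threshold balances runtime against fidelity and is
configurable); otherwise the normal approximation with midranks,
tie-corrected variance and continuity correction, which is within
|Δp| ≤ 0.01 of exact already at 20+20. Degenerate input (all pooled values
identical) is flagged and returns p = 1. Bond ranges are compared per bond
(pooled across proteins of a group) by default, matching a
one-point-per-bond presentation; a per-protein-mean alternative is
available. Densitometry summaries use the pooled-variance Student's t test.
Group summaries report n, mean ± SEM (n−1 denominator), median and IQR. No
multiple-testing correction is applied by default (six raw comparisons);
Benjamini–Hochberg is available as an option.

## Pulse-chase fractions

Band intensities are background-subtracted arbitrary units; all fractions
are ratios and therefore invariant under global rescaling. "Relative to the
X-min chase point" is read as division by the *total* signal (numerator band
+ source band) at the reference time — 15 min for secretion (the earliest
point at which folding intermediates have resolved), 0 min for
dimerization — so loss or gain versus the reference stays visible.
Golgi-form fractions use contemporaneous same-lane normalization. Dimer
intensity is taken as-is, with no stoichiometric doubling for the two
labeled monomers per dimer (the published quantification does not state
one). Oxidative folding fitness is 100 × (anoxic fraction / normoxic
fraction) at the longest assayed chase time, capped at 100%.

## Membrane localization

The whole-cell area is the inverse of the background annotation. The
membrane compartment is approximated by dilating the background inward by a
physical distance (default 2 μm) with a Euclidean disk of radius
round(distance / μm-per-pixel) — 18 px at the reference calibration of
0.1083 μm/pixel — and intersecting with the cell area; equivalently, a cell
pixel is in the band iff its Euclidean distance to the nearest background
pixel is at most the radius (the test suite checks this equivalence against
a distance-transform oracle). Whether the original interactive protocol
dilated the background inward or a cell annotation outward is ambiguous;
inward dilation of the background is implemented as stated. Two conventions
are reported: the integrated-intensity fraction Σ(band)/Σ(cell), bounded in
[0,1] and used as the headline number, and the mean-intensity ratio
mean(band)/mean(cell), which is unbounded; a protocol that measures mean
intensities but reports a bounded ~0.8 "fraction" is only consistent with
the integrated convention, hence the default. Interactive segmentation is
out of scope: the background mask is an input.

## Synthetic generators

The generators define the study conditions; they are deterministic under a
fixed seed and every artifact passes the corresponding module's validators.

**Proteome** (`simulate_proteome`). 112 induced and 313 noninduced cargo
(the published group sizes), split evenly between secreted and membrane
(the published analysis does not state the split), plus planted `EXCLUDED`,
`UNMEASURED` and non-cargo records to exercise the filter. Lengths are
log-normal (median 420 aa, σ = 0.5, floor 80). Per-protein bond counts are
Gamma-mixed Poisson: a rate λ ~ Gamma(shape k, mean μ) with μ the group
target (secreted 1.3/0.83, membrane 0.95/0.58 bonds/100 aa), then
N ~ Poisson(λ·L_eff/100), giving right-skewed per-protein densities whose
group mean equals μ. Intrachain spans are geometric with mean equal to the
group target range (secreted 24.25/31.02; membrane 28/28, the membrane
contrast being null by design); the span is drawn once per bond and only
the start position is retried on collisions, so realized pooled mean ranges
land within ~1% of the targets. Free cysteines are Poisson (induced 1.5,
noninduced 3.5 per protein), which makes the induced bonded fraction higher
by construction. Membrane proteins get an extracellular/cytoplasmic
topology (cytosolic tail 5–30% of length) and Poisson(1) planted cytosolic
free cysteines that the metrics must exclude. A small fraction of bonds is
interchain (p = 0.1, written `a..?; /note=Interchain`) or has an unknown
partner coordinate (p = 0.02) whose real cysteine is still emitted, so
conservation holds exactly. Fold changes are drawn inside the planted
group's band (induced > 2.2 in ≥ 1 line; noninduced < 1.15 in all measured
lines; excluded in [1.25, 1.95]).

*Dispersion calibration.* The dispersion shape k is the one free parameter.
Two desiderata pull in opposite directions: per-group SEMs of the printed
magnitude (≈ 0.08–0.19 at the printed n) imply SD/mean ≈ 1.0–1.3 (k ≲ 1),
but at that dispersion a 112-vs-313 study replicates at p < 0.05 only
~85–90% of the time. The package prioritizes reliable parameter recovery: a
300-run power analysis on the limiting contrast (secreted bond density, 56
vs 157 after the class split) sets k = 6.0, giving ~98% power while keeping
the skewed, zero-inflated look of real per-protein densities. Consequently
the synthetic SEMs are ~2-fold smaller than the printed ones; simulated
p-values are correspondingly more extreme, and passing recovery tests show
the pipeline detects effects of the published size at the published n — not
that the synthetic dispersion equals the real proteome's.

**Gels** (`simulate_gel`). First-order conversion F(t) = f∞(1−e^(−kt)) from
the source band (lysate, monomer, ER form) to the converted band (secreted,
dimer, Golgi form), total signal conserved per lane set (the
no-degradation regime), multiplicative log-normal noise with mean 1 and a
chosen CV. `rate_for_target` plants an exact fraction at a given chase time
(e.g. 80% secreted at 120 min); at zero noise the quantification recovers
the planted curve to float precision.

**Cells** (`simulate_cells`). Non-touching disk cells (radius 22–32 px, at
least rim width + interior) on background in a 256×256 raster at
0.1083 μm/pixel. Each cell receives a fixed total signal;
`membrane_fraction` of it is spread uniformly over the rim (cell pixels
within 2 μm of background — geometrically identical to the measurement
band), the rest over the interior, followed by Poisson counting noise at
~50–100 counts/pixel. The planted fraction is therefore the measured
integrated fraction by construction at zero noise, and recovered within
±0.05 under noise. What the generator does *not* emulate: out-of-focus
blur and the microscope PSF, nonzero background fluorescence, irregular
cell shapes, touching cells, and segmentation error — so recovery here
validates the band arithmetic and calibration, not robustness to imaging
artifacts. The same caveat applies to the proteome generator (no annotation
errors or database incompleteness) and the gel generator (no lane
background or saturation).

## Numerical choices and degenerate inputs

* Coordinates are 1-based inclusive everywhere (annotation convention); no
  0-based representation leaks out of any API.
* Disk radius and rim width round to the nearest pixel; a calibration so
  coarse the radius rounds to zero is an error, not a silent no-op.
* Zero reference totals (gel), empty cell masks and zero total cell
  intensity (imaging), empty comparison groups (stats) raise explicit
  errors rather than propagating NaN.
* Zero pooled variance in the t test: p = 1 with equal means, p = 0
  (flagged) otherwise.
* Generator placement loops are bounded (200 position retries per bond, 20
  per protein; 500 per cell) and fail loudly when a configuration is
  infeasible.
* Problem sizes in the test suite: the brute-force metrics cross-check runs
  on a 1,000-record proteome; recovery checks use 100 seeded runs at
  112 vs 313; null calibration uses 1,000 simulations at 15 vs 15; image
  recovery uses 20 seeded 256×256 images.

## Known limitations

* The published group comparison itself is not reproducible from first
  principles: it depends on a specific annotation-database release and
  unpublished microarray gene lists. The pipeline consumes such files; it
  cannot regenerate them, and all quantitative validation is therefore
  property- and simulation-based.
* Interchain bonds are modeled as one engaged cysteine per chain; more
  exotic stoichiometries (e.g. one residue bridging two partners) are not
  represented.
* Isoforms are out of scope; one record per accession.
* The image module quantifies a supplied background segmentation; it does
  not segment.
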