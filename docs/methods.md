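# Methods

This note documents the models, conventions and design choices behind
`osmoquant`: a pipeline that discovers and quantifies the sulfonate
osmolyte cysteinolic acid (2-amino-3-hydroxy-1-propanesulfonic acid,
C3H9NO4S) in centroided LC-HRMS data, exercised end to end on seeded
synthetic runs that emulate salinity-stress experiments in marine
microalgae.

## Mass convention

All m/z arithmetic derives from a single embedded table of monoisotopic
masses and natural isotopic abundances (IUPAC/NIST values, >= 6
decimals) in `osmoquant.chem`. Protonation uses the proton mass
1.0072765 Da, i.e. the electron is accounted for; with the neutral
monoisotopic mass of cysteinolic acid at 155.025229 Da this puts
[M+H]+ at 156.032505 Da. The 34S-32S gap computed from the table is
1.995796 Da and the per-sulfur 34S/32S abundance ratio is 0.04474 —
the two numbers behind the "M+2 sulfur signature" used for screening.

## Isotope patterns

Patterns are computed by convolving per-element isotope distributions at
full mass precision and then merging isotopologues closer than 0.0025 Da
(abundance-weighted mean mass per group). The merge width is what a
70k-resolution Orbitrap separates around m/z 150–200: the diagnostic 34S
peak at +1.99580 Da stays resolved from the 18O (+2.00425) and 13C2
(+2.00671) isotopologues, exactly as in the real spectra. A coarser
nominal-mass (integer nucleon) aggregation was considered and rejected:
it pulls the merged M+2 centroid to ~+1.997 Da, outside the +-0.0005 Da
window the sulfur flag tests, and would misrepresent what the instrument
actually measures. Patterns are pruned below 1e-4 relative abundance by
default.

## Synthetic runs

The generator replaces the wet lab and defines the study conditions:

* **Acquisition geometry**: 18-min runs (the length of the HILIC
  gradient), one centroid scan every 0.5 s, m/z 75–200.
* **Chromatography**: each analyte elutes as a pure Gaussian with
  sigma = 0.05 min, rendered over +-5 sigma, carrying its full isotope
  envelope in every scan. Peak shape asymmetry (EMG tailing) is not
  modeled; the integration tests only need a known closed-form area.
* **Response**: the XIC area (intensity x minutes) of the monoisotopic
  trace equals response-factor x concentration(uM). Response factors are
  the published calibration slopes (1.27e7 for cysteinolic acid).
* **Noise**: multiplicative log-normal noise on every centroid
  (technical CV 2% by default; the within-run technical CV is not
  reported, 2% is a typical Orbitrap value), plus a Poisson baseline
  (2 random centroids per scan, exponential intensities, scale 5e4).
* **Biology**: per-replicate true per-cell amounts are jittered by a
  mean-preserving log-normal with biological CV 10%, N = 3 replicates —
  the replication level of the reported experiments.
* **Bookkeeping**: a known culture volume (30 mL) at a known cell
  density is filtered, extracted into 1.0 mL, diluted 3-fold
  (50 uL + 100 uL diluent), and the *post-dilution* concentration is
  rendered into the run, so quantification must undo the whole chain.

Everything is driven by `numpy.random.default_rng` seeds derived through
`SeedSequence`; identical seeds give bit-identical runs.

What the generator does **not** emulate: retention drift and alignment
error, ion suppression and matrix effects, profile-mode peak shapes,
chimeric MS/MS, mass-calibration drift (an optional linear drift hook
exists but is off by default), and carry-over. Passing recovery tests
therefore demonstrate that the analysis chain is self-consistent and
unbiased under the stated noise model — not that it is robust to every
artifact of real chromatography.

## Packaged scenarios

Condition means for the salinity experiments are encoded from the
reported survey baseline (22.3 fmol/cell for xenic *T. weissflogii* at
35 PSU) and the reported fold changes: 2.0x after 24 h at 50 PSU and
2.4x after two generations at 50 PSU in xenic cultures; a 1.5x higher
baseline and a 2.6x long-term increase in axenic cultures. The axenic
short-term response was reported only as not significant and is encoded
as a 1.1x nudge. Cell volumes are back-derived from paired
fmol-per-cell and mM values (fmol/pL = mM): 2.7875 pL for
*T. weissflogii*, 0.7117 pL for *P. minimum*. Cell densities
(5e4–2e6 cells/mL by species size) and the cysteinolic acid retention
time (4.5 min) are package choices, fixed once.

## Screening

* **XIC tolerance**: 5 ppm everywhere at MS1 — the published
  "+-0.0005%" window re-expressed.
* **Feature detection**: centroids are binned into m/z traces (gap-based
  splitting with a recursive spread check so stray baseline points
  cannot bridge two nearby analytes), local maxima picked with
  `scipy.signal.find_peaks`, peak bounds walked out to twice the noise
  floor, areas by trapezoid. Noise is the MAD of the trace with the
  run-wide centroid-intensity MAD as a floor; a noise-free trace has
  infinite S/N. Defaults: S/N >= 3, >= 5 scans. The vendor software's
  algorithm is unknown; these are declared defaults validated on
  synthetic ground truth only.
* **Deisotoping**: a feature whose m/z sits ~+1 or ~+2 Da above a
  larger co-eluting feature is marked as an isotopologue child and
  excluded from candidate counting, so each compound is counted once.
* **Sulfur flag**: an envelope entry within +-0.0005 Da of +1.995796 Da
  whose area ratio lies in 0.7–1.3x the per-sulfur natural ratio
  (0.0313–0.0581). The flag is scale-invariant by construction.
* **Differential screen**: features matched across samples by greedy
  nearest-neighbour (5 ppm, +-0.3 min); candidates need mean fold change
  >= 1.5 and two-sided Welch p <= 0.05 across replicates. This is a
  discovery filter, not an inference procedure: p-values are reported
  raw, with no multiple-testing correction, and with < 2 replicates per
  condition the test is skipped and flagged.

## MS/MS annotation

Fragments are explained as multisets of up to two neutral losses (H2O,
NH3, CO2, SO3, H2SO3) subtracted from the precursor formula, assigned by
minimal |ppm error|, ties toward fewer losses. "Loss of water and the
sulfonic group" is operationalized as the combined loss H2O + H2SO3
leaving the C3H6N+ iminium ion at 56.049476: a plain SO3 loss does not
reproduce the published fragment. The default fragment tolerance is
10 ppm rather than the 5 ppm MS1 convention, because low-m/z fragment
calibration is routinely worse — the published 56.04979 value itself
sits 5.6 ppm above its exact mass (the -H2O fragment at 138.02196 is
within 0.15 ppm).

## Quantification

Calibration is through-origin least squares (the published curves all
have the form y = m x), with r the Pearson correlation of the points
and the residual SD on n-1 degrees of freedom. LOD = 3.3 sigma/m and
LOQ = 10 sigma/m (ICH convention — the published LOD:LOQ ratios of
~3.0–3.3 match no single convention exactly, so the package makes its
convention explicit and configurable rather than chasing the printed
values). Concentrations below the limits are flagged
(below-LOD "-", between LOD and LOQ "+"), never imputed.

Units: measured uM x dilution x extract volume gives total fmol
(1 uM in 1 mL = 1e6 fmol); divided by cells filtered gives fmol/cell;
divided by the geometric cell volume in pL gives mM. Geometric volumes
come from standard solids (sphere, cylinder, prolate spheroid;
1 um^3 = 1e-3 pL).

## Statistics

One-way ANOVA with the classical between/within decomposition (the
degenerate all-identical case returns p = 1 with a warning); Tukey HSD
adjusted p-values from the studentized-range distribution
(`scipy.stats.tukey_hsd`); significance labels ** (p <= 0.01),
* (p <= 0.05), n.s. Fold changes are ratios of group means computed on
fmol/cell, the scale on which the salinity responses are reported.
Survey tables report mean +- SD over biological replicates.

## Recovery experiments and problem sizes

The headline recovery experiments (`osmoquant.recovery`, run by
`scripts/acceptance.py` and the acceptance tests) average over 10
independent seeds; per seed, one calibration batch (6 levels x 3
replicates, technical CV 5%) is simulated, fitted, and shared across the
scenarios quantified under that seed, mirroring per-batch calibration.
Per-scenario seed streams are decorrelated by a species-salted
`SeedSequence`, so ratios between scenarios retain their sampling
variability. The 10-seed averages reproduce the encoded fold changes
within a few percent; single seeds scatter with SE ~ CV/sqrt(3) per
condition mean.

## Known limitations

* Quantification is targeted (XIC at a configured m/z and RT); the
  untargeted feature detector is used for discovery only.
* No cross-run RT alignment beyond a fixed RT tolerance; fine for
  synthetic data with exact retention times, insufficient for real
  multi-batch studies.
* Single-charge adducts only ([M+H]+, [M+Na]+, [M-H]-); no fine
  isotope structure beyond the 0.0025 Da merge width.
* The Welch-test screen at N = 3 has limited power for fold changes
  below ~2 at 10% CV; the packaged fixtures sit comfortably above this.
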