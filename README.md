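# osmoquant

Discovery and quantification of the sulfonate osmolyte **cysteinolic
acid** (2-amino-3-hydroxy-1-propanesulfonic acid, C3H9NO4S) in
LC-HRMS metabolomics data — built for analysts studying how marine
microalgae balance osmotic stress with highly polar compatible solutes.

Marine phytoplankton respond to salinity shifts by accumulating small
zwitterionic and sulfonate metabolites. This package implements the full
measurement chain used to identify and quantify such an osmolyte:

1. **Sulfur-signature mining** — detect chromatographic features in
   centroided runs and flag sulfur-containing compounds by the
   diagnostic M+2 isotopologue spacing of Δm = 1.99580 Da (³⁴S–³²S),
   with relative abundance ≈ 0.0447 per sulfur atom;
2. **Differential screening** — select features up-regulated under
   elevated salinity (fold change ≥ 1.5, Welch p ≤ 0.05 across
   biological replicates);
3. **MS/MS neutral-loss annotation** — explain fragment peaks as loss
   combinations from the precursor formula (−H₂O at 138.0219;
   −(H₂O + H₂SO₃) leaving the C₃H₆N⁺ iminium ion at 56.0495);
4. **Quantification** — external through-origin calibration
   (y = m·x, LOD = 3.3 σ/m, LOQ = 10 σ/m), then normalization to
   per-cell amounts and intracellular concentration:

   ```
   fmol/cell = (c_measured [µM] × dilution × V_extract [mL] × 10⁶) / N_cells
   mM        = (fmol/cell) / V_cell [pL]          (fmol/pL ≡ mM)
   ```
5. **Statistics** — one-way ANOVA with Tukey HSD across salinity
   conditions, and survey-style mean ± SD tables with "+"/"−"
   censoring marks.

Because raw instrument data at desk scale are not available, the package
ships a seeded **synthetic-data generator** (`osmoquant.simulate`) that
renders centroided runs with Gaussian elution profiles, full isotope
envelopes, log-normal technical noise and biological replicate scatter —
plus packaged scenarios encoding the reported salinity experiments in
*Thalassiosira weissflogii* and an eight-species survey panel.

## Worked example

Run the numbered analysis scripts in order (outputs land in
`results/`, intermediate simulated runs in `scratch/`):

```bash
python analysis/01_simulate_experiments.py
python analysis/02_screen_candidates.py
```

```
1 up-regulated candidate(s):
  m/z 156.03251 @ 4.50 min  fold change 2.32  p = 0.0173  sulfur signature: yes
```

The screen of the simulated xenic salinity experiment returns exactly
one candidate: a feature at the m/z of protonated cysteinolic acid,
2.3-fold up-regulated at 50 PSU, carrying the ³⁴S isotope signature.

```bash
python analysis/03_annotate_msms.py
```

```
  156.03232  -> precursor        theory 156.03251  error -1.19 ppm
  138.02196  -> -(H2O)           theory 138.02194  error +0.14 ppm
  56.04979   -> -(H2O+H2SO3)     theory 56.04948  error +5.61 ppm
```

The candidate's MS/MS peaks are explained by water loss and the combined
loss of water plus the sulfonic group — the structural evidence for a
C3 sulfonate.

```bash
python analysis/04_quantify_salinity.py
```

```
tw_xenic: 35 PSU = 23.1 fmol/cell, 50 PSU (24 h) = 42.9 fmol/cell, 50 PSU = 53.6 fmol/cell
  35 PSU -> 50 PSU (24 h): 1.85x (Tukey p = 0.0171, *)
  35 PSU -> 50 PSU: 2.32x (Tukey p = 0.00205, **)
  ...
tw_axenic: 35 PSU = 35.4 fmol/cell, 50 PSU (24 h) = 39.4 fmol/cell, 50 PSU = 81.7 fmol/cell
  35 PSU -> 50 PSU: 2.31x (Tukey p = 4.28e-05, **)
```

Per-cell amounts recovered through the whole chain (XIC integration →
calibration inversion → cell normalization) reproduce the configured
salinity response: roughly a doubling after short-term stress and a
2.3–2.6× increase after two generations at 50 PSU, with the axenic
baseline ~1.5× the xenic one.

```bash
python analysis/05_species_survey.py
```

```
               cysteinolic acid (fmol/cell) cysteinolic acid (mM)
P. minimum                       52.3 ± 7.6               74 ± 11
T. weissflogii                 23.84 ± 0.40           8.55 ± 0.14
...
```

The survey panel recovers each species' per-cell amount and, divided by
the geometric cell volume, intracellular concentrations in the tens of
mM — the range where an osmolyte is physiologically meaningful.

The same chain is available as a CLI (`osmoquant run --out DIR --seed N`,
or stage by stage: `simulate`, `screen`, `annotate`, `quantify`,
`stats`), driven by a YAML config that surfaces every tolerance in one
place.

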