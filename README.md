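# sipflux

Analysis pipeline for DNA stable-isotope probing (SIP) microcosm studies
of **suboxic methane oxidation and nitrogen fixation** in soils.  It is
aimed at microbial ecologists who incubate soil under a ¹³C-CH₄ / ¹⁵N-N₂
headspace and need to turn raw isotope and qPCR measurements into
process rates, labeling calls and community shifts.

The package covers four linked analyses:

1. **Isotope mass-balance potentials.**  For each microcosm bottle the
   methane-oxidation potential is the sum of two label sinks, headspace
   ¹³C-CO₂ and ¹³C assimilated into soil organic carbon (SOC), and the
   N₂-fixation potential is the ¹⁵N accumulated in soil organic nitrogen
   (SON).  With atom-% excess ΔA = A(day 90) − A(day 0):

   ```
   Gas13C = (Cgas/100) · (ΔA/100) · (Vh/1000) / Vs · 10⁹ / (m·t)   [nmol C g⁻¹ dws d⁻¹]
   SOC13C = (Csoc/100) · m · (ΔA/100) / M · 10⁹ / (m·t)            [nmol C g⁻¹ dws d⁻¹]
   F15N   = (Cson/100) · m · (ΔA/100) / M · 10⁹ / (m·t)            [nmol N g⁻¹ dws d⁻¹]
   ```

   where Cgas is the headspace CO₂ volume percent, Vh the headspace gas
   volume (mL at 1 atm), Vs the molar gas volume (L/mol), Csoc/Cson the
   organic C/N pools as percent of dry soil mass m (g), M the heavy
   isotope's molar mass (g/mol) and t the incubation length (days).

2. **CsCl gradient labeling calls.**  qPCR gene-copy profiles over
   buoyant-density fractions are compared between ¹³C-fed and ¹²C-fed
   microcosms; a peak shift ≥ 0.010 g/mL toward the heavy band calls the
   gene's carriers isotopically labeled.

3. **Community arithmetic.**  Relative abundances, within-guild
   methanotroph compositions (Methylosinus, Methylocaldum,
   Methylobacter, Methylomicrobium, Crenothrix), day-0 → day-90 shifts
   reported both as percentage points and fold change, and clone-library
   percentages.

4. **Group statistics.**  One-way ANOVA across depths with Tukey-HSD
   compact letter display, and Welch t-tests for labeled-vs-control
   contrasts.

A synthetic-data module generates all pipeline inputs (noisy microcosm
measurements, Gaussian gradient bands, Dirichlet-multinomial count
tables), plus a deterministic fixture set anchored to published summary
values for an alpine swamp soil profile.

## Worked example

```
sipflux simulate --paper-fixtures --outdir inputs --seed 1
cat > config.yaml <<EOF
microcosm_csv: inputs/microcosm_measurements.csv
gradient_csv: inputs/gradient_fractions.csv
community_csv: inputs/community_counts.csv
clone_csv: inputs/clone_counts.csv
outdir: out
seed: 1
EOF
sipflux run --config config.yaml
```

`out/report.md` then contains (abridged):

```
- top_0_20: CH4 oxidation 57.67 (CO2 share 67%) [a]; N2 fixation 0.41 [a]
- mid_40_60: CH4 oxidation 144.17 (CO2 share 74%) [b]; N2 fixation 0.57 [b]
- deep_60_80: CH4 oxidation 120.14 (CO2 share 81%) [c]; N2 fixation 0.13 [c]

- CH4 mid_40_60/top_0_20: 2.5
- N2 mid_40_60/deep_60_80: 4.4

- nifH: peak 1.720 vs 1.720 g/mL (shift +0.000) -> not labeled
- pmoA: peak 1.734 vs 1.720 g/mL (shift +0.014) -> labeled

- bacteria_top_0_20: Methylobacter (28.85%)
```

Reading: the intermediate depth (40–60 cm) oxidizes methane fastest
(144.17 nmol C g⁻¹ dws d⁻¹, 2.5× the topsoil) and fixes the most N₂
(0.57 nmol N g⁻¹ dws d⁻¹, 4.4× the deep layer); most methane-derived
carbon leaves as CO₂ (67–81 %, rising with depth).  The pmoA peak shift
of +0.014 g/mL shows the methanotrophs incorporated ¹³C into their DNA,
while diazotrophs (nifH) show no shift; Methylobacter dominates the
heavy-DNA clone libraries at every depth.  Bracketed letters are Tukey
groups at α = 0.05 — depths sharing no letter differ significantly.

The same analyses are available as a library (`sipflux.isotope_flux`,
`sipflux.sip_gradient`, `sipflux.community`, `sipflux.group_stats`,
`sipflux.synthetic_data`, `sipflux.interface`).

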