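# Methods

## Study design the pipeline assumes

Soil from three depths of a waterlogged alpine swamp profile (0–20,
40–60, 60–80 cm) is incubated 90 days at 4 °C in sealed 120-mL bottles
whose headspace has been argon-flushed to suboxic conditions and then
over-pressurized to ~3 atm with a 3:1:1 ¹³CH₄:¹⁵N₂:Ar mix (~360 mL of
gas at 1 atm equivalent).  Three replicate bottles per depth receive the
heavy isotopes; parallel controls receive unlabeled gas.  At the
endpoint, isotope-ratio measurements give the atom-% of ¹³C in headspace
CO₂ and in SOC and of ¹⁵N in SON; density-gradient ultracentrifugation
plus qPCR profiles pmoA and nifH over CsCl fractions; amplicon and
clone-library counts describe the community.

## Mass-balance model

Each potential converts an atom-% excess (ΔA, day 90 minus day 0) into
moles of labeled atoms in a pool, normalized per gram of dry soil per
day.  The gas pool uses the ideal-gas molar volume (headspace CO₂ is a
volume fraction); the two soil pools use the heavy isotope's molar mass
(SOC/SON are mass fractions of dry soil).  All unit conversions
(percent → fraction, mL → L, mol → nmol) are applied explicitly inside
the operations; inputs are always stored as percent in [0, 100].

Assumptions and conventions:

- Single-endpoint design: rates are averages over the full incubation;
  no kinetics are modeled.
- The day-0 subtraction is the only natural-abundance correction.
- A negative excess (possible in controls through instrument drift) is
  propagated and flagged `negative_excess`, never clamped — clamping
  would hide QC problems.
- The soil dry mass m cancels in the SOC and SON equations; the CO₂
  equation scales as 1/m.  These invariants are property-tested.
- An exact algebraic inverse (`inverse_atom_excess`) maps a target
  potential back to the ΔA that produces it; forward∘inverse is the
  identity to < 1e-9 relative and is the backbone of both the simulator
  and the fixture construction.

Key parameters (defaults): headspace gas volume Vh = 360 mL interpreted
as the 1-atm-equivalent injected volume (not 120 mL at 3 atm — the two
are numerically similar but not identical; configurable); molar volume
Vs = 22.4 L/mol (STP); molar masses 13.0 and 15.0 g/mol (nominal integer
isotope masses; exact masses selectable); m = 5 g; t = 90 d.

## Gradient labeling model

¹³C-labeled DNA bands ~0.01–0.02 g/mL heavier in CsCl than unlabeled
DNA.  The analysis is categorical: the copy-number peak density of the
labeled profile minus that of the control profile, compared to a
threshold of 0.010 g/mL — midway between the observed pmoA shift
(1.734 − 1.720 = 0.014 g/mL) and the null nifH shift, and configurable.
The peak is the strict argmax by default (optional odd-window moving
average for noisy profiles); ties break toward the lower density, which
is conservative against false labeling calls.  Copy-number-weighted
mean density is reported alongside as a robustness diagnostic.
Fractions are sorted by density on ingest and duplicate densities
averaged.  Heavy/light reporting windows are [1.725, 1.745] and
[1.700, 1.725) g/mL.

## Community arithmetic

Guild compositions are computed **within** the five-genus aerobic
methanotroph panel (genus names matched case-insensitively).  A change
between timepoints is reported both as percentage points (final −
initial) and as fold change (final / initial, undefined at zero
baseline); the two are mutually consistent by construction and
round-trip from any (pp, fold ≠ 1) pair.  Clone-library percentages use
half-up rounding to two decimals for display, keeping raw ratios
recoverable.  Dominant-taxon ties break alphabetically.

## Group statistics

Depth effects: classical one-way fixed-effects ANOVA; all-constant
input is reported as F = 0, p = 1.  Post-hoc separation: Tukey HSD —
the standard choice for a balanced n = 3 design; Fisher's LSD is
available behind a flag for sensitivity analysis.  Letters come from
the insert–absorb compact-letter-display algorithm, whose defining
invariant (two groups share a letter iff their adjusted p ≥ α) is
property-tested against arbitrary significance patterns.
Labeled-vs-control contrasts use Welch's unequal-variance two-sided
t-test (independent samples; the degenerate zero-variance/equal-means
case returns p = 1).  α = 0.05 throughout; no multiple-testing
correction beyond Tukey within a family.

## Synthetic data: what it emulates and what it does not

`simulate_microcosm` places multiplicative Gaussian noise (default
relative sd 0.05) on the atom-% excess, because the isotope-ratio
measurement is the noisy quantity in this design; pool sizes are treated
as fixed per depth.  Controls drift around natural abundance (¹³C 1.08,
¹⁵N 0.3663 atom-%) with a small absolute sd (0.002 atom-%).
`simulate_gradient` draws Gaussian bands (sd 0.008 g/mL) over a 15-point
density grid spanning 1.70–1.75 g/mL with multiplicative lognormal
noise (log-sd 0.1); the grid points nearest 1.720 and 1.734 g/mL are
snapped onto those values exactly so the canonical band centers are
grid-representable.  `simulate_community` draws genus counts from a
multinomial, optionally Dirichlet-overdispersed, at library size 10 000.
All generators are pure functions of (config, seed).

Not emulated: temporal dynamics, gas transport, GC-content effects on
buoyant density, band broadening, sequencing error, compositional
coupling between guild and whole-community abundances.  Passing tests
therefore demonstrate correctness of the arithmetic and the inferential
machinery under the stated noise model, not robustness to every
real-data pathology.

## Fixture reconstruction

The deterministic fixture set anchors the per-depth true values to
published summary numbers for this system: CH₄-oxidation totals
{57.67, 144.17, 120.14} and N₂ fixation {0.41, 0.57, 0.13} nmol g⁻¹
dws d⁻¹ for top/intermediate/deep.  Decisions taken where the summary
values underdetermine the raw data:

- CO₂ shares {67, 74, 81}% — endpoints and monotonic increase with
  depth are reported; the intermediate value is the midpoint
  (assumption, recorded in `fixture_metadata`).
- Replicate spread: reported ± values are treated as the sd of n = 3
  replicate-derived potentials (sd vs sem is not stated); replicates
  are laid out symmetrically (mean − sd, mean, mean + sd) so replicate
  means are exact and the sample sd equals the target.  Depths without
  a reported ± use the same relative sd as the intermediate depth.
- Clone libraries: totals 52/50/47 (bacteria) and 32/31/31 (archaea)
  reconstructed so that the overall totals (149, 94) and every reported
  percentage are reproduced to two decimals; counts are fixed integers,
  never sampled, so the percentage targets are exact.  Non-focal taxa
  filling the remainder are plausible wetland genera, not observed data.
- Within-guild compositions: the reported intermediate-depth composition
  and the reported percentage-point/fold pairs are not jointly
  satisfiable as within-guild percentages; the fixtures anchor the
  top-soil Methylobacter trajectory exactly (2.35 → 35.25%, +32.9 pp,
  15-fold) and keep the fold anchor (5.0×, 1.3×) at the other depths
  while closing each row to 100%.
- Pool sizes (CO₂ 0.8–1.2 %, SOC 6–10 %, SON 0.40–0.60 %) are realistic
  settings for organic-rich swamp soil, not measurements.

## Numerical choices

- Display rounding: potentials 2 decimals, fold ratios 1 decimal,
  percentages 2 decimals (half-up via `decimal`); full precision in all
  data files.
- CSV dialect fixed (UTF-8, comma, "." decimal, mandatory header) with a
  `#` provenance header (version, seed, config hash — the hash covers
  analysis parameters, not output paths) so fixtures are bit-exact.
- Degenerate inputs: zero-total profiles/samples/libraries are domain
  errors; an empty or missing optional input skips its pipeline stage
  with a warning rather than failing the run.
- Test problem sizes: 100 random parameter sets for the inversion
  round-trip, 10 000 permutations for the ANOVA oracle, 200 simulations
  for the bias check — small enough to keep the default suite under a
  minute while leaving Monte-Carlo error well below the tested margins.

## Known limitations

- The categorical labeling call ignores partial labeling; quantitative
  SIP (atom-fraction excess from the density shift) is out of scope.
- Whether gradient copy numbers are absolute or ratio-normalized does
  not affect the peak location (normalization is scale-invariant), but
  the pipeline does not attempt cross-profile quantitative comparison.
- Potentials assume complete capture of the label in the three measured
  pools; any label in biomass turnover products or dissolved CO₂ is
  unaccounted.
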