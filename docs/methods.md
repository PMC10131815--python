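# Methods

## Scope and model

`vesikin` quantifies the journey of an LNP-delivered therapeutic mRNA:
dose mass → copy number → copies per particle → per-cell uptake kinetics →
per-EV re-secretion → protein yield. The package separates three layers:

1. **Deterministic arithmetic** (seqchem, stoichiometry, qpcr_quant,
   particle_metrics): molecular weights, mole conversions, standard-curve
   interpolation, normalizations. These are exact formulas with validated
   inputs.
2. **Statistics** (kinetics): rank-based tests appropriate for small-n
   assay replicates with no distributional assumptions.
3. **Simulation** (synthetic_data): a seeded generator that emulates the
   statistical and kinetic structure of the measurements so the whole
   pipeline can be exercised and its recovery error measured without any
   laboratory data.

## Molecular weights

RNA: per-base average residue masses A 329.2, U 306.2, C 305.2, G 345.2
g/mol, plus an optional flat 159.0 g/mol for the 5′ triphosphate of an
uncapped transcript (default on). The mass depends only on base
composition, so it is permutation-invariant and additive under
concatenation. Chemically modified bases (5-methyl-C, pseudouridine) are
treated as their parent bases: the modification mass differences are small
relative to the construct mass, and the convention keeps the formula a
pure function of the printed sequence. No secondary structure, counter-ion
or isotope corrections are applied.

Protein: sum of standard average amino-acid residue masses (Expasy table)
plus one water, 18.0153 g/mol. For the shipped 191-aa VEGF-A protein this
gives 22.31364 kDa, matching the reported construct value to ≈1e-5
relative. Monoisotopic masses would deviate by >10 Da and are deliberately
not offered.

Full-length construct MW: the capped, UTR-flanked, polyadenylated 852-nt
construct is not printable from its CDS, so its molecular weight cannot be
computed from sequence. The package ships `vegfa.FULL_LENGTH_MW =
277 900 g/mol` as a **derived** constant, back-solved from the standard
dose identity 3 µg ≡ 6.5×10¹² copies, and everywhere accepts a
user-supplied override. The 576-nt CDS mass (186 160.2 g/mol with
triphosphate) is a sub-quantity of the construct, not a substitute.

## Copy-number arithmetic

Avogadro is fixed at the exact 2019 SI value 6.02214076×10²³ /mol. Copy
counts are kept as reals: they estimate molecule numbers from bulk mass,
so fractional values are meaningful; integer rounding happens only at
display (copies per particle to the nearest integer, yields to two
significant figures). The mass↔copies pair is an exact inverse (round-trip
relative error < 1e-12, property-tested).

## qPCR absolute quantification

The regression is Cq on log₁₀(quantity in ng) — slope in Cq per decade —
fitted by ordinary least squares over all standard replicate wells of the
7-point, 10-fold series (100 … 0.0001 ng). R² is the squared Pearson
correlation; the quality gate is strict (R² > 0.975, not ≥). Technical
replicate Cq values of an unknown are averaged on the Cq scale before
interpolation (the conservative default; averaging on the quantity scale
would weight low-Cq outliers geometrically). Interpolated quantities
outside the fitted span are flagged as extrapolated but returned. The
GAPDH internal control, where present, is carried through as a QC column
only: absolute quantities are interpolated directly, with no ΔΔCq
normalization. Reverse-transcription efficiency is not modelled (an
implicit factor 1.0); the quantification is therefore of cDNA-equivalent
input, as in the underlying assay design.

## Particle metrics

NTA summaries are mean ± SEM over captures (SEM = sd/√n with n−1 degrees
of freedom); a single capture reports SEM as unavailable rather than zero.
Concentrations are multiplied back by the dilution factor.

LNP particle counts: the default mode is a transparent calibration —
total dose copies divided by a copies-per-particle constant (26 for the
shipped formulation). A geometric mode estimates the per-particle payload
from the sphere volume at the z-average diameter, an assumed core density
(default 1.1 g/cm³) and the lipid:mRNA w/w ratio; on the default
formulation it lands within one order of magnitude of the calibration and
is labelled an approximation. A light-scattering/refractive-index particle
count is out of scope.

Radiolabel uptake: all CPM terms are blank-subtracted, the sample is
linearly interpolated between the medium-only (0%) and t0-spiked (100%)
references, and uptake% = 100 − remaining%, clamped to [0, 100] with a
flag. Duplicate readings are averaged before normalization. Per-row blanks
are accepted; a single blank may be broadcast.

N:P ratio: with the lipid phase specified in molar terms and the mRNA
phase tied to it by the w/w ratio, the aqueous:ethanol mixing ratio
cancels from the mole arithmetic; the helper therefore needs only the
lipid molar masses (not printed with the formulation — user-supplied) and
a mean nucleotide residue mass. Its output is documented as not
reproducing the reported 3.08 exactly for that reason.

## Nonparametric battery

Mann-Whitney U is two-sided, exact (full U distribution) when the smaller
sample has n ≤ 8 and the pooled data are tie-free, otherwise the normal
approximation with tie and continuity correction. The exact path is
verified against complete permutation enumeration for all group sizes ≤ 6.

Kruskal-Wallis uses scipy's tie-corrected H. Dunn's post hoc z-statistics
are computed on the pooled ranks with the tie-corrected variance
(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ); unbalanced group sizes
follow this pooled-rank formula directly. Friedman uses within-block
ranks; its Dunn follow-up uses SE = √(k(k+1)/(6n)). Pairwise p-values are
adjusted by Holm by default (configurable to Bonferroni or none): the
original analyses name Dunn's test without naming a correction, and Holm
dominates Bonferroni uniformly at equal family-wise control, so it is the
less wasteful default. Monte-Carlo null calibrations (10 000 reps, seeded)
hold the omnibus type-I error in [0.04, 0.06] at α = 0.05 for the designs
used in the tests. Stars in reports follow the 0.05/0.01/0.001/0.0001
convention.

## The simulator

The generator is bookkeeping, not mechanism: first-order fluxes between
pools {medium, cell_internalized, cell_translatable, degraded, EV} with
protein accumulation from the translatable pool, integrated by forward
Euler on a fixed grid (dt ≤ 0.05 h, default 0.01 h). Copy conservation
(medium + cell pools + degraded + EV = dose) holds at every step to better
than 1e-9 relative, by construction. An optional wash event empties the
medium pool at a configurable time, reproducing wash-out experiments
qualitatively.

Flux structure: medium drains at `k_uptake`; only the fraction `f_escape`
of the uptaken flux enters the detectable intracellular pool (the
remainder is routed directly to the degraded pool, standing in for
endolysosomal destruction and recycling of material never recovered by the
assay); the internalized pool matures into the translatable pool at
`k_process`; both intracellular pools decay at `k_deg`; EV egress draws
from the translatable pool at `k_ev` (giving EV loading its observed lag
behind cellular uptake); protein is produced at `k_translate` per
translatable copy per hour and split `f_secrete` : (1−f_secrete) between
supernatant and lysate. Per-cell values divide pool totals by `n_cells`;
per-EV values divide the EV pool by the cumulative EV count
`ev_rate · n_cells · t`.

### Default calibration

The defaults are fixed to the study conditions they emulate and are not
free parameters of the tests:

| parameter | default | meaning |
|---|---|---|
| dose_copies | 6.5e12 | mRNA copies in the standard 3 µg dose |
| n_cells | 4e5 | cells per well at seeding |
| k_uptake | 0.35 /h | medium → cell; leaves 17% in medium at 5 h |
| f_escape | 5.831e-4 | fraction of uptaken copies reaching the detectable pool |
| k_process | 0.6 /h | internalized → translatable transit |
| k_deg | 1.3 /h | intracellular mRNA decay (t½ ≈ 32 min) |
| k_ev | 2.701 /h | translatable → EV egress |
| ev_rate | 10 /cell/h | EV production rate |
| k_translate | 3343.8 /h | protein copies per translatable mRNA per hour (≈0.9/s) |
| f_secrete | 0.6 | secreted fraction of produced protein |
| heterogeneity_sigma | 1.0 | lognormal shape of per-cell payload spread |
| positivity_threshold | 50 copies | detection threshold for a "positive" cell |
| cq_sd | 0.2 | Gaussian Cq noise per well |
| elisa_cv | 0.15 | lognormal ELISA coefficient of variation |
| nta_sigma | 0.15 | lognormal NTA capture noise |

With these values the latent trajectory reproduces four anchor
observations simultaneously: per-cell copies peak at 1 h at ≈1355 among
the sampled timepoints {0.5, 1, 5, 24} h; per-EV copies peak at 5 h at
≈31; ≤20% of the dose remains in the medium at 5 h; ≥90% (in fact ≈99.6%)
of cells score payload-positive at 2 h; and total protein at 24 h is
≈1×10¹² copies (supernatant > lysate). The amplitude parameters
(`f_escape`, `k_ev`, `k_translate`) were solved once, by fixed-point
iteration against the first two anchors and the protein total, after the
shape rates (`k_uptake`, `k_process`, `k_deg`) were chosen to give the
sampled peak ordering; they are shipped as constants and not revisited.

`ev_rate = 10` EVs/cell/h deserves a note: bulk NTA concentrations from
concentrated conditioned media suggest far higher EV numbers, but a
higher rate is arithmetically incompatible with simultaneously holding
≈31 copies per EV and ≈1355 copies per cell under copy conservation — the
EV pool would have to exceed everything the cells ever contained. The
chosen rate keeps the per-unit anchors exactly and the EV copy budget
inside the escaped-pool budget; absolute EV concentrations in the
synthetic NTA tables are therefore lower than concentrated-pellet NTA
measurements, a known limitation.

### Noise models and reproducibility

qPCR observation: copies → ng via the construct MW, ng → Cq via a
noise-free true curve (default slope −log₂10, intercept 20 Cq at 1 ng),
plus Gaussian noise (sd `cq_sd`) per well. Each latent value is emitted as
6 biological × 3 technical replicates — the assay's layout — and the
7-point standard series shares the noise model. ELISA and NTA use
multiplicative lognormal noise parameterized to have mean exactly 1 and
the stated CV, so noisy observations are unbiased on the linear scale.
Positivity draws per-cell copies from a lognormal across cells whose mean
equals the latent per-cell mean. With all noise parameters at zero, every
observation operator inverts exactly through the quantification pipeline
(property-tested to 1e-6 relative or better).

One `SeedSequence` per dataset spawns independent, deterministic
sub-streams per table: identical seeds give bitwise-identical datasets;
different seeds share the identical latent ground truth and differ only
in noise draws.

### What the simulator does and does not show

Passing recovery tests demonstrates that the quantification chain is
unbiased and within tolerance **under the assumed noise model** (Gaussian
Cq of sd 0.2, lognormal ELISA of CV 15%, a correctly specified standard
series). Real data add effects the generator does not emulate: plate and
batch effects, RT-efficiency variation, inhibitors, EV co-isolates,
between-well cell-count error, non-lognormal heterogeneity, and LNP
re-secretion at late times (the medium pool here only ever drains). The
simulator therefore validates the software, not the assay.

## Problem sizes

The test suite and the acceptance script run the simulator to 24 h at
dt = 0.01 h (2 400 steps), quantify 6×3 wells per compartment, sample
20 000 cells for positivity, and use 10 000 Monte-Carlo replicates for the
null calibrations — sizes chosen so the full suite completes in well under
a minute while keeping Monte-Carlo standard errors a few times smaller
than the bands they check.

## Numerical and design choices

- Strict QC inequality (R² > 0.975) and explicit override-with-warning
  rather than silent pass-through.
- Extrapolation beyond the standard span is flagged, never forbidden.
- Peak ties break toward the earlier timepoint, with a tie flag.
- Degenerate test inputs (constant pooled sample, identical columns)
  return statistic 0 and p = 1 instead of NaN.
- `translation_yield` and `fold_ratio` validate entity labels and positive
  denominators; copy counts refuse negative values at construction.
- The CLI exits nonzero on QC failure unless `--force`; reports echo every
  constant used.

## Known limitations

- The full-length construct MW is a derived constant, not a measurement;
  all absolute copy numbers inherit its uncertainty proportionally.
- Copies-per-particle calibration (26) is formulation-specific; the
  geometric estimator is order-of-magnitude only.
- The simulator's late-time behaviour (re-secretion of intact LNPs after
  24 h) is not modelled.
- Dunn's test follows the pooled-rank normal approximation; very small or
  very unbalanced groups inherit its conservatism.
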