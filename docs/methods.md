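# Methods

## qPCR quantification and uncertainty model

The calibration model is the standard log-linear one: Ct = m·log₁₀(c) +
b, fitted by ordinary least squares on a dilution series (≥3 distinct
positive concentrations). The residual standard deviation comes from the
residual mean square on n − 2 degrees of freedom, and the amplification
efficiency is the slope-derived E = 10^(−1/m) − 1 (m = −3.3219 ⇔ E =
100%). No efficiency correction beyond the slope is applied, and
multi-plate calibration drift is out of scope.

Inverse prediction inverts the mean of the Ct replicates,
c = 10^((C̄t − b)/m). Its uncertainty combines, on the log₁₀ scale and
in quadrature, the replicate standard error of the mean and the curve's
residual sd, each divided by |m|, then converts multiplicatively
(sd_c = c·ln10·sd_log). This is a first-order treatment; a dedicated
test verifies it agrees with a Monte-Carlo resampling sd within 10% when
relative uncertainties are below ~20%, which covers the working range of
the assay. A single replicate gets sem 0 (the curve term still
contributes); this understates the uncertainty and is visible in the
output rather than hidden by a fallback.

The DNase-subtraction estimator is the difference of two inverse
predictions: buffer-only (original eDNA + DNA released by the reaction
itself) minus DNase-treated (released DNA only), with quadrature
uncertainties. Negative estimates are reported and flagged, never
clamped — clamping would bias pooled means upward, and near-zero true
concentrations legitimately produce small negative draws.

Copy-number conversion uses copies/mL = c·10⁻⁶ g mL⁻¹ · N_A / (L·m_bp)
with m_bp = 650 g·mol⁻¹ per double-stranded base pair (the standard
convention, configurable) and genome length L. Shipped default lengths —
phage 2972: 34,704 bp; phage 858: 35,543 bp; *S. thermophilus* DGCC7710:
1.85 Mb — are literature values and overridable everywhere they are
used.

Pooling across lysates reports both a spread-based standard error (sd of
the point estimates over √n) and a propagation-based one
(√Σsdᵢ²/n). They answer different questions — between-lysate
variability versus measurement error — and which is appropriate depends
on which dominates, so neither is privileged.

Parentheses notation ("0.5(1)", "1.3(4)e10") rounds the uncertainty to
one significant digit by default (multi-digit allowed on parsing, e.g.
"0.5(12)" = 0.5 ± 1.2) and the value to the same decimal place;
scientific notation engages at |exponent| ≥ 5. The notation decision is
made on the *rounded* value so a rounding carry across a decade cannot
break the parse/format round trip.

## BIM-assay statistics

Plate counts from different days are not comparable — culture density
and lysate batch vary — so each day's counts are normalised to the mean
count of that day's reference condition and reported as log₂ fold
changes. Baselines never pool across days. Zero-CFU plates are kept with
a 0.5 pseudo-count and a flag; dropping them would censor exactly the
plates a strong treatment effect produces.

The comparison procedure mirrors heteroscedasticity-aware practice:

1. Bartlett's test of homoscedasticity on the groups;
2. if Bartlett's p ≥ α **and** all groups have exactly equal n:
   classical one-way ANOVA followed by Tukey's HSD;
3. otherwise: Welch's ANOVA (heteroscedastic F with Welch–Satterthwaite
   denominator df) followed by Games-Howell, whose pairwise p-values use
   unpooled variances, per-pair Welch df, and the studentized-range
   distribution with the number of groups as range parameter,
   q = |Δ|·√2/SE.

Only comparisons against the designated control are reported by default;
all pairs are available behind a flag. MOI sweeps are analysed
independently per nearest-MOI bin (default width 0.05) with no
multiple-testing correction across bins. A zero-variance group makes the
Welch weights undefined; the implementation falls back to the classical
branch with an explicit warning rather than failing the whole analysis.
Bartlett, classical ANOVA and Tukey HSD come from scipy; Welch's ANOVA
and Games-Howell are implemented here (scipy has no public versions) and
are cross-checked against pingouin in the test suite.

Percent change is 100·(1 − mean_t/mean_c) — positive for a reduction —
with a delta-method sd from both sems. The default compares raw-count
means; a log2 mode back-transforms mean log₂ fold changes (geometric
means) instead, since it is not generally knowable from a summary figure
which a report used. Note Games-Howell and Tukey agree closely only when
variances are genuinely equal and p is not extreme; because the error
dfs differ (2(n−1) per pair vs k(n−1) pooled), their relative p
difference necessarily diverges as p → 0. The equivalence test therefore
uses balanced fixtures with exactly equal group variances and effects
keeping p in a moderate range.

## Spacer-provenance tests

The hypothesis "eDNA donates the sequences acquired as spacers" predicts
that BIMs arising after supplementing a specific DNA fragment should
preferentially carry spacers mapping to that fragment. The test chains
independent assumption factors into a per-trial probability p, as a
sum-of-products ledger in which every factor carries a provenance note:

- an **attributable fraction**: the share of BIMs due to the eDNA
  effect. For a measured increase f it is f/(1+f) (excess over total);
  for a measured reduction r under eDNA removal it is r directly;
- a **supplementation share** s/(s + background) when the donated DNA of
  interest is spiked over an ambient concentration;
- the **target coverage** of the detection assay (fraction of
  protospacers the sequencing or multiplex primers can see);
- sampling losses (e.g. the fraction of extracted DNA used as template).

With zero matching spacers observed in n trials, the surprise value is
the zero-detection probability P₀ = (1 − p)ⁿ, computed via
exp(n·log1p(−p)) so n in the thousands keeps full precision; P₀ < α
rejects the donation hypothesis. A ledger whose terms sum above 1 raises
an error rather than being clipped. The additive-background ledger form
is reproduced as printed in the source analyses; a coherent variant that
weights the background by the non-eDNA fraction is available behind a
flag (`fragment_mapping_ledger(coherent=True)`) and gives a slightly
smaller p.

The retention-sensitivity bound asks how much combined DNA loss
(extraction efficiency × PCR detectability) the rejection survives:
solving (1 − r·p)ⁿ ≤ α gives r* = (1 − α^{1/n})/p, with r* > 1 reported
as "not rejectable at any retention". Expected trial counts for liquid
cultures are the plain product cultures × volume × CFU/mL × per-cell
acquisition rate.

## Protospacer scanning

PAM motifs are IUPAC-degenerate patterns matched on both strands with
overlapping matches all reported (regex lookahead). A genome N never
satisfies a non-N motif position; a motif N matches anything. Each PAM
match is paired with the fixed-length protospacer on the configured side
(CR1's NNAGAAW sits 3′ of the protospacer), and coordinates are 0-based
half-open with BED-style output. Amplicon counting defaults to
*containment of the full protospacer + PAM footprint* — an amplicon can
only template an acquisition event it fully contains — with an overlap
mode available. Spacer back-mapping is exact substring search on both
strands (a Hamming scan handles small mismatch tolerances; indels are
not modelled, as acquired spacers are exact protospacer copies up to
sequencing error). Cross-phage uniqueness is decided by exact presence
of the protospacer sequence anywhere in the other genome, either strand:
such a spacer would be protective against both phages.

The default motifs/lengths (CR1 NNAGAAW, CR3 NGGNG, 30 nt) are
literature conventions for strain DGCC7710, not measured quantities;
they are plain configuration and every scan accepts an explicit motif.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analysis
assumes, with defaults fixed at the study conditions:

- **Phage pair**: one uniform-random ~34.7 kb genome; the partner
  substitutes bases at rate 0.65 inside a 3,979 bp variable region
  (coordinates 28,505–32,484) and 0.0265 elsewhere, landing the overall
  identity at ~90% with clustered differences. Substitution-only — no
  indels — so coordinates remain comparable across the pair.
- **qPCR**: Ct = m·log₁₀(c) + b + N(0, 0.2²) per replicate (three
  replicates); zero concentrations produce a censored high Ct with a
  flag.
- **Plate counts**: CFU ~ Poisson(cells × 10⁻⁶ acquisition rate ×
  condition multiplier × MOI response), with 3×10⁷ cells per plate
  (≈30-colony baselines at the optimal MOI), a shared log-normal day
  multiplier (sd 0.2) that the baseline normalisation is designed to
  remove, and a log-normal-shaped MOI response peaking at 0.35. Default
  condition multipliers: untreated/buffer 1.0, DNase 0.6 (the 40%
  reduction), fragment supplementation 1.7 (the 70% increase).
- **Spacer acquisition**: each BIM draws its array (CR1 with probability
  0.9), then its spacer — from the target set with the configured bias
  (the "eDNA donates sequence" world) or uniformly over all
  protospacers. A vectorised batch counterpart generates target-hit
  counts for calibration runs of 10⁵ replicates and is tested to agree
  with the per-record simulator.

Not emulated: phage replication kinetics, competence regulation and its
medium dependence, plate-to-plate overdispersion beyond Poisson (a
negative-binomial knob exists but defaults off), day-condition
interactions, sequencing error in spacers, and indel divergence. Passing
tests therefore demonstrate the estimators and decision procedures are
correct and calibrated *under the stated generative model* — not that
real assays meet those assumptions. The day-to-day variance component in
particular is a test-power choice, not a measured quantity.

## Numerical choices and problem sizes

- Probabilities near 0/1 go through log1p/expm1 paths.
- The studentized-range distribution comes from scipy; p-values are
  clipped to [0, 1]. Degenerate pairs (zero SE) get p = 1 for zero
  difference, p = 0 otherwise.
- Simulation scales used by the test suite: 500 seeded assay simulations
  for effect-size recovery coverage, 2,000 null pipelines for type-I
  calibration (observed ≈0.035 ≤ 0.07 at nominal 0.05 — conservative,
  as expected when only control comparisons of a familywise-corrected
  post hoc are counted), 10⁵ replicates for zero-detection calibration,
  100 random 10 kb genomes for scanner/oracle equivalence. These sizes
  give comfortable statistical margins for the assertions made.
- All generators are deterministic given (config, seed); hypothesis
  property tests are derandomised by the pytest profile defaults.

## Known limitations

- First-order propagation breaks down for relative uncertainties beyond
  ~20%; the subtraction estimator's sd is then indicative only.
- The Welch/Games-Howell branch with very small groups (n = 2–3) has
  poorly estimated per-group variances; the procedure runs but p-values
  are approximate, as with any Games-Howell implementation.
- The ledger framework treats its factors as known constants; factor
  uncertainty (e.g. the ±10% on a measured fold change) is not
  propagated into P₀. The retention bound is the intended sensitivity
  instrument for that class of doubt.
- `unique_protospacers` uses exact sequence presence; a single
  substitution makes a protospacer "unique" even though a spacer with
  one mismatch may retain partial protection in vivo.
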