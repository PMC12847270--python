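# Methods

This note documents the models and numerical choices behind the pipeline:
what each stage computes, where its defaults come from, and what the
synthetic-data generator does and does not emulate.

## Experimental design and data model

The experimental unit is a plot sample, one cell of a
5 treatments × 2 depths × 3 replicates design (30 samples). Treatments are
RT (rice monoculture, 100 % chemical fertilizer — the control), IRT
(rice–eel co-culture, 100 % chemical), I70 (co-culture, 70 % chemical), IS
(70 % chemical + 30 % of nitrogen from straw) and IO (70 % chemical + 30 %
from organic fertilizer); depths are 0–20 and 20–40 cm. Custom designs
(other treatment/depth labels) are accepted when declared. Chemistry units
are carried as metadata and never converted; all analyses downstream of the
raw tables (percent change, GRA) are scale-free, so unit choices do not
affect conclusions.

## Aggregate stability indices

Wet sieving distributes a 50 g soil aliquot over six size classes
(>2, 1–2, 0.5–1, 0.25–0.5, 0.053–0.25, <0.053 mm). With mass proportions
W_i and representative class diameters X_i:

* R0.25 = (mass in the four classes with lower bound ≥ 0.25 mm) / total;
* MWD = Σ X_i W_i (mm);
* GMD = exp(Σ W_i ln X_i / Σ W_i) (mm).

Choices:

* **X_i defaults to the class midpoint** — 1.5, 0.75, 0.375, 0.1515,
  0.0265 mm — except the open-top >2 mm class, which uses its lower bound
  2.0 mm rather than an invented cap. All six are configurable
  (`AggregateStability(diameters=...)`).
* **W_i are fractions, not percent.** GMD's explicit Σ W_i denominator only
  makes sense with one consistent convention; unnormalized weights are
  accepted for GMD because the denominator is computed explicitly.
* Classes with W_i = 0 are excluded from the GMD sum, so a zero diameter in
  an unused class cannot poison the logarithm; a positive weight on a
  non-positive diameter is a domain error.
* GMD ≤ MWD always (weighted AM–GM), with equality exactly when all mass
  sits in one class; the test suite checks this on 1000 random samples,
  along with scale invariance and monotonicity under moving mass to larger
  classes.

## Alpha diversity

For counts n_i with total N and S taxa observed positive: Shannon
H = −Σ p_i ln p_i in nats, Simpson defaults to Gini–Simpson 1 − Σ p_i²
(the common amplicon-pipeline convention; Σ p_i² and 1/Σ p_i² are
available), and Pielou J = H/ln S. Natural logs keep H and the Pielou
denominator self-consistent. J is undefined at S = 1 and is returned as NaN
(a flagged missing value, deliberately neither 0 nor an error). No
rarefaction is applied by default; an optional seeded subsampling to fixed
depth (multivariate hypergeometric, i.e. without replacement) is available.
Which Simpson variant and log base a given study used is often
unrecoverable from its text; the variant switch exists for that reason.

## Treatment effects

Each variable is analyzed separately within each depth: one-way ANOVA over
treatments followed by Tukey HSD at α = 0.05 (statsmodels), condensed into
a compact letter display by the insert-and-absorb algorithm (split every
column containing a significantly different pair, then absorb subset
columns). Letter 'a' is assigned to the highest-mean group, following the
agronomy figure convention. The display satisfies both guarantees: no pair
sharing a letter is rejected, and every non-rejected pair shares a letter
(tested exhaustively on 5-group fixtures). The block structure of the field
layout is intentionally not modelled — the analysis mirrors the one-way
convention of the motivating study.

Percent change versus the control (RT by default) is 100 (a/b − 1);
multi-treatment prose averages are unweighted means of per-treatment
percent changes. `tukey_reject` provides decision-only Tukey–Kramer tests
with a cached studentized-range critical value for simulation loops; it is
verified against statsmodels pairwise decisions.

No multiple-testing correction is applied across variables (per-variable
α = 0.05), matching common practice in this literature. Pearson
correlations between physicochemical variables and gene copies are
pairwise, with constant columns flagged NaN rather than erroring.

## Grey relational analysis

The GRA input is an m × k positive matrix of treatment-level index means;
depth-specific versions of an index enter as separate columns, giving one
GRD per treatment. Steps: mean normalization y = X/colmean (removes scale;
every column averages 1), then one of two coefficient constructions:

* **deng_standard** (default): per-index ideal = column max for
  benefit-type indices (min for cost-type), deviations
  Δ_i(k) = |ideal(k) − y_i(k)|, global Δmin/Δmax over the matrix,
  ε_i(k) = (Δmin + ρΔmax)/(Δ_i(k) + ρΔmax). Every ε and every GRD
  β_i = mean_k ε_i(k) lies in (0, 1], and β = 1 exactly for a treatment
  that is ideal on every index. Dominance (weakly best everywhere,
  strictly somewhere) guarantees rank 1; ε increases with ρ off the
  reference. These properties are all tested.
* **paper_literal**: a formula family seen in applied agronomy work. After
  a min–max rescale ω = (ymax − y)/(ymax − ymin) (best → 0; cost-type
  columns are flipped first), the coefficient is evaluated against a fixed
  reference constant a (default 0):
  ε_i = (|a − vmin| + ρ|a − vmax|)/(|a − v_i| + ρ|a − vmax|). Read
  verbatim, these coefficients can exceed 1, and the construction rewards
  proximity of ω to a — with a = 0 on ω, the two modes agree
  directionally. Whether such formulas should read the ω or the y matrix
  is ambiguous in the sources that print them; the default is ω with a
  `literal_on="y"` switch. The mode exists for side-by-side comparison:
  published GRD tables in this literature sometimes contain values above 1
  that no consistent reading of the usual formula chain reproduces, so
  values are best compared at the ranking level, not the value level.

Defaults: ρ = 0.5, a = 0, all indices benefit-type. The default index set
is SOM, TN, TP, AN, AP, R0.25, MWD, GMD, bacterial and fungal gene copies,
each at both depths (20 columns). pH is excluded by default because its
optimum is interior (neither high nor low pH is "better"), making both
benefit and cost orientations wrong; diversity indices (Simpson, Pielou)
can be added with a flag. Ties in GRD keep input row order and are flagged.

## Synthetic-data generator

The generator exists so every downstream stage is testable without field
data. It emulates:

* the 5 × 2 × 3 design (any replicate count configurable);
* strictly positive measurements via mean-parameterized lognormals:
  ``sigma² = ln(1 + cv²)``, ``mu = ln(mean) − sigma²/2``, so the draw's
  expectation is exactly baseline × multiplier at any cv (default
  noise_cv = 0.08, a typical field-replicate scale);
* multiplicative treatment effects, matching how such studies report
  percent changes;
* sieve compositions via a Dirichlet per depth (subsoil silt/clay-heavier),
  with a per-treatment factor on the macroaggregate-class concentrations;
  masses scale to the 50 g aliquot exactly;
* taxon counts via Dirichlet-multinomial (concentration 300, 200 taxa,
  20 000 reads/sample) around a lognormal rank-abundance base community,
  tilted per treatment by p ∝ p_base^γ (γ < 1 evens the community and
  raises Simpson/Pielou).

At noise_cv = 0 every continuous value equals its expectation exactly and
counts are the largest-remainder rounding of the expected composition.
Each table kind draws from its own child RNG stream, so generating a
subset of tables does not change the others; a fixed seed gives
byte-identical files.

**Calibration.** `default_calibration()` sets gene-copy baselines to the
motivating experiment's control means (bacteria 1.654×10⁷ and 1.29×10⁷,
fungi 2.60×10⁶ and 1.71×10⁶ copies g⁻¹ at 0–20 / 20–40 cm) and treatment
multipliers from its reported percent changes where printed (e.g. IO
topsoil bacteria 1.7865) or from treatment-to-control mean ratios
otherwise; chemistry multipliers encode its reported percent-change
statements, with unreported effects at 1. Chemistry *baselines* (SOM 20
g/kg topsoil etc.) are placeholder magnitudes, not study values — the
source reports chemistry only graphically — and are irrelevant to
percent-change and ranking analyses, which are scale-free. Sieve-shift
factors and evenness tilts are qualitative: they reproduce the direction
and rough size of the reported aggregate and diversity effects, not exact
index values. `monotone_calibration(step)` instead orders every multiplier
RT < I70 < IRT < IS < IO, a clean dominance test bed for the ranking stage.

What the generator does **not** emulate: spatial block effects and field
heterogeneity, depth correlation within a plot, measurement rounding,
taxon-taxon covariance beyond the Dirichlet, and any real sequence-level
structure. Passing tests therefore demonstrate correctness of the
computations and recoverability of multiplicative effects under idealized
replication — not that real paddy soils behave this way.

## Problem sizes used in validation

Parameter-recovery checks run at 200 replicates with cv = 0.05, averaging
estimates over 10 generated datasets for a stable Monte-Carlo mean
(single-dataset standard error for the largest multipliers is about 1
percentage point); detection-power checks run 200 seeded rounds of
ANOVA + Tukey on the variables carrying ≥1.3× effects. The aggregate-index
property suite uses 1000 random compositions; Simpson maximality is
verified by exhaustive search over all compositions of 12 reads into 3
taxa. All are sized to make the statistical assertions sharp, and run in
about a minute.

## Known limitations

* The GRA literal mode is a documented reading of an ambiguous formula
  family, not a recommendation; use `deng_standard` for new analyses.
* The effects stage assumes approximately normal within-group errors
  (ANOVA/Tukey); the generator's lognormal noise at cv ≤ 0.1 is close
  enough, but heavy-tailed real data may not be.
* One-way ANOVA ignores the randomized-block structure; a mixed model
  would be the statistically fuller treatment.
* No plotting is shipped; the report is Markdown tables formatted directly
  from the stage CSVs.
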