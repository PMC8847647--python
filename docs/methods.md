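# Methods

## The switch analysis

`lipidtraffic` analyses how lipid variables are *distributed* over a network
of tissue compartments in two phenotype groups, rather than how abundant
they are. Tissues are nodes; an edge joins two compartments that exchange
lipids directly. The packaged default network is a six-compartment,
serum-centred star (serum adjacent to liver, heart, vastus muscle, adipose
and brain), reflecting serum's role as the transport hub between synthesis
(liver), oxidation (heart, muscle, liver), storage (adipose) and structural
use (CNS).

For each group *g* and compartment *c*, a variable's presence fraction
*B* is the proportion of that group's samples in *c* with signal strength
strictly greater than 0. The variable is **present** in the cell when
*B* ≥ θ with θ = 0.66 by default. Three points of rigour:

- the bound is **closed**: *B* exactly equal to θ counts as present;
- the comparison is done in exact rational arithmetic
  (`count·q ≥ p·n` for θ = p/q), so 6-of-8 (0.75) and 66-of-100 cases
  never depend on floating-point rounding;
- θ is read from its decimal spelling (`Fraction("0.66") = 33/50`), not
  from the binary float.

Each group's presence pattern then classifies every variable:

- **U-type** — present in exactly one compartment (locally produced or
  retained);
- **A-type** — present in every compartment (ubiquitous);
- **B-type**, per edge — present in both endpoints of that edge.

B-lists are deliberately non-exclusive: a network-wide lipid is on every
edge, so the A-list is a subset of every B-list. Variables present in two
or more non-adjacent compartments (possible on sparse networks) are kept in
the per-variable traceability record under `shared-nonadjacent`; variables
detected nowhere are reported in a `not-detected` list rather than dropped.
The two groups are classified fully independently and only compared
afterwards.

## Overlap statistics

Two groups' lists for the same scope (e.g. U-type TGs in adipose) are
aligned over the union of their members in a canonical order (lipid class,
total carbons, double bonds, raw name — a stable tie-break so results are
reproducible) as equal-length 0/1 vectors. The Jaccard-Tanimoto
coefficient is J = |x∧y| / |x∨y|.

The significance value uses a **fixed-margins exchangeable null**: each
group keeps its list size, the positions are random. The intersection size
is then hypergeometric, and since J is strictly increasing in the
intersection for fixed margins, the one-sided-toward-dissimilarity p-value
is the exact hypergeometric lower tail. Small p therefore means the two
lists share *fewer* members than equally sized random lists would — the
groups genuinely differ — which is how these p-values are read in
practice; a two-sided option (summing outcomes no more probable than the
observed one) is exposed.

Alternatives to exact enumeration, both seeded and using the add-one
estimator (1 + hits)/(1 + n_resamples):

- `permutation` — permutes one vector's positions (same null, Monte
  Carlo);
- `bootstrap` — redraws both vectors as independent Bernoulli fields at
  the observed marginal rates (a parametric relaxation in which margins
  vary around their observed values).

`auto` uses exact enumeration up to a union of 170 variables and
permutation (10,000 resamples, seed mandatory) beyond. p-values are stored
at full precision and displayed to two decimals in figures. No
multiple-testing correction is applied across scopes; overlap results are
reported raw.

## Abundance statistics

Signal intensities are skewed and heteroscedastic, so group comparisons
are two-sided Mann-Whitney rank-sum tests: the exact null distribution
when both groups have ≤ 8 observations and no ties, the normal
approximation with tie correction otherwise. Family-wise control uses the
Bonferroni threshold α/m, reported to 3 significant figures (0.05 over 33
variables → 0.00152).

The **error-normalised fold change** is the log2 fold change standardised
by its delta-method standard error:

    ENFC = log2(m_case / m_control) / SE,
    SE   = sqrt( s_case²/(n_case·m_case²) + s_ctl²/(n_ctl·m_ctl²) ) / ln 2.

This particular formula is an interpretation of the name — dimensionless,
zero exactly at fold change 1, and exactly antisymmetric (the
implementation computes `log(m1) − log(m2)`, whose IEEE negation is exact,
rather than `log(m1/m2)`). If both groups are exactly constant the SE is
zero and the ENFC is reported as signed infinity (0 for equal means). The
formula is isolated in one function so an alternative normalisation can be
substituted.

Diagnostic fatty-acid ratios (e.g. FA(15:0)/FA(17:0), a dairy-intake
marker) are computed per sample and then averaged, which supports a
per-sample rank test between groups; the ratio-of-group-means alternative
is an option. Samples with a zero denominator are excluded with a warning.

## The synthetic-data generator

The generator plants a known U/A/B structure: per variable and group, one
of `A`, `U@compartment`, `B@edge` or `absent`, in shared, control-only and
case-only variants. Defaults emulate a six-tissue rodent feeding study:
the default network, n = 8 samples per group per compartment, and ~292
variables across TG/PC/PE/SM/DG/FA classes (odd-chain species included)
with control-only counts exceeding case-only counts, so the control group
shows the wider lipid variety. Where present, abundances are lognormal
(per-variable location drawn N(11.5, 1.5²) on the natural-log scale,
within-cell sigma 0.5 — a realistic ~50 % CV); 20 variables carry a
planted 2-fold case/control effect. Dropout zeroes each present sample
independently; dropout ≥ 0.34 is refused because the expected presence
fraction 1 − dropout would fall below the 0.66 rule by construction.

What the generator does **not** emulate: correlated dropout (in real
direct-infusion data, missingness is concentration-dependent), adduct and
isotope structure, ionisation-mode effects, between-compartment abundance
correlation, and technical replication. Passing recovery tests therefore
demonstrate correctness of the classification logic under the stated
noise model, not robustness to every artefact of real spectra.

### Recovery metrics, and why there are two

`truth_recovery_report` scores a run against the planted truth with:

- `recovery_rate` — the fraction of (group, compartment, variable)
  **presence calls** matching the planted pattern; the headline metric,
  because it measures what the binarisation actually decides, cell by
  cell;
- `category_recovery_rate` — the stricter fraction of (group, variable)
  records whose *entire* recovered compartment set equals the planted one,
  plus a planted-vs-recovered category confusion matrix.

The distinction matters under dropout. With n = 8 and θ = 0.66, a present
cell needs ≥ 6 non-zero samples; at dropout 0.3 a cell survives with
P(Bin(8, 0.7) ≥ 6) ≈ 0.55, so a planted A-type keeps all six compartments
with probability ≈ 0.55⁶ ≈ 0.03 and strict category recovery collapses to
≈ 0.4 even though ~82 % of individual presence calls are correct. At
dropout 0 both metrics are exactly 1, and the test suite asserts this as a
hard invariant.

## Numerical and design choices

- **TG-derived glycerides**: a DG is linked to a TG when the carbon and
  double-bond differences fit one plausible acyl chain (10–26 C, 0–6 DB);
  for an MG the window is doubled (two lost chains). The window spans the
  observed biological FA range with margin; it is a package choice, made
  configurable.
- **Odd-chain** is defined on the total carbon count — at sum-composition
  level per-chain parity is unknowable.
- Adduct annotations in names (e.g. chloride adducts) are stored verbatim
  and ignored for classification; unknown class tokens parse to `other`
  when the `(C:D)` core is present.
- Missing/NA abundance cells are read as 0 (not detected), with a counted
  warning — presence is defined on signal > 0, so absence of a value and a
  zero are equivalent downstream.
- Figures (network pie map, per-variable wiring diagram) are deterministic
  text SVG with a JSON sidecar of every plotted number; counts are taken
  from the classification structures and never recomputed, and the test
  suite asserts that equality.
- Problem sizes in the test and acceptance runs (20 seeds for the dropout
  study, 1,000 null pairs for calibration, 100 pairs for the
  permutation-vs-exact check) were chosen to keep Monte-Carlo error well
  below the margins being asserted while running in seconds.

## Known limitations

- Exactly two groups per run; multi-group designs need pairwise runs.
- The fixed-margins null conditions on list sizes; it does not model
  uncertainty in the binarisation step itself.
- The ENFC formula is one defensible reading of "error-normalised fold
  change"; comparisons with other software should confirm the formula
  used.
- No FDR procedures (Bonferroni only) and no flux/kinetic inference — the
  analysis infers distribution, not transport rates.
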