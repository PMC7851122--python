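# Methods

## The analysis in one paragraph

Each participant (ego) in a PERSNET-style survey names an unlimited
roster of network members (alters), rates the presence and strength of
ties among the first 10 alters, and describes every alter's demographics
and habits. From each record the package computes six structural metrics
(size, density, Burt constraint, effective size, max/mean degree) and a
set of compositional metrics (kin/distant/non-exercising/negative/
football percentages, sex and race diversity, age spread, two homogeneity
scores). Two cohorts are then contrasted metric by metric: medians and
IQRs, a univariate Mann–Whitney test, and an ordinary least-squares model
`metric ~ group + age + race + education + employment + income +
domestic status` whose group-coefficient t-test gives the adjusted
p-value. Because the motivating survey data are confidential, a seeded
generator produces cohorts with known ground truth for every validation
stage.

## Structural metrics: conventions

**Tie coding.** The inter-relater records strengths in {0, 1, 2}
(none / tie / especially close). Density, degrees and effective size use
presence coding (strength ≥ 1); constraint is the one metric that uses
the raw strengths, since it is defined through proportional *investment*
rather than counts. Both choices are switchable
(`burt_constraint(..., tie_weights="binary")`,
`effective_size(..., method="burt")`) and both variants are checked
against independent oracles (a loop-level transcription of the published
formulas, and networkx's `constraint` / `effective_size` on the
equivalent weighted ego graph).

**Constraint.** Computed on the ego-plus-alters graph with unit
ego–alter weights: p_ij = (z_ij + z_ji)/Σ_q (z_iq + z_qi), dyadic
constraint c_ej = (p_ej + Σ_{q≠e,j} p_eq p_qj)², reported as
100·Σ_j c_ej. The ×100 convention puts cohort medians in the ~40–60
range typical of published tables. Closed forms used as exact anchors:
a star egonet gives 100/k; a complete binary egonet gives
100(2k−1)²/k³ (ego invests 1/k in each alter and each alter invests 1/k
in every contact, so c_ej = ((2k−1)/k²)²). A single alter gives 100.
Note constraint is *not* monotone under adding a tie: a new tie
renormalizes every node's investments and can shrink the ego's indirect
paths; only density (monotone up) and effective size (monotone down) are
asserted as monotonicity properties.

**The 10-alter cap.** Tie data exist only for the first 10 roster
entries, so density, constraint, effective size and degrees are computed
on that subnetwork; network size always counts the full roster. Records
with one alter have density undefined, constraint 100, effective size 1,
degrees 0. Empty rosters leave every tie-based metric missing.

## Composition metrics: conventions

Composition uses the full roster (the name-interpreter section covers
all alters). Every percentage and proportion uses a non-missing
denominator: alters with the relevant item blank drop out, and the
metric is missing exactly when the denominator is empty. Diversity
indices are IQV = (K/(K−1))(1 − Σ p²) with K fixed by the design (2 for
sex, 3 for race: White/Black/Other; finer input codes map through a
declared dictionary). For K = 2 and no missing sexes, IQV = 4p(1−p) =
1 − M² where M is the majority-male score — both identities are tested.
The same-race proportion (and the other homogeneity score) is left
missing for rosters smaller than two, matching the convention of
excluding trivial networks from homogeneity summaries.

## Quality control

`validate_record` is total and classifies each record:
`nonexistent_network` (empty roster), `incomplete` (an alter with sex,
race *and* kin all blank, or a missing tie section with roster ≥ 2),
`inaccurate` (an age outside [0, 120] — the only inaccuracy detectable
without re-contacting participants), plus informational flags
`size_lt_2` and `asymmetric_ties_repaired`. Only the first three exclude
a record. Asymmetric tie cells (both `tie_i_j` and `tie_j_i` present and
disagreeing) are repaired to the maximum — conservative presence coding.

## The adjusted model

Covariate codings: age in years (continuous); race binary White vs
non-White; education as an ordered 1–5 integer; employment as three
dummies with "employed" the reference; income in $1000s (continuous);
domestic status binary married. These are the most conventional minimal
codings; they are config-exposed (`CovariateSpec`) because survey
analyses differ on exactly these choices. The fit is complete-case (no
imputation) and `n_used` is reported with every contrast. A covariate
level absent from the complete cases yields a constant design column and
is dropped (it is inestimable — the analogue of an aliased coefficient);
genuine collinearity raises an error naming the offending columns. No
multiplicity correction is applied to the primary p-values; a
Benjamini–Hochberg `q_bh` column is attached as supplementary output.

Mann–Whitney uses exact enumeration when both sides have ≤ 8
observations and no ties, otherwise the normal approximation with tie
correction (no continuity correction, so identical samples give p = 1).
Chi-squared is Pearson's without Yates correction (the general r×c
convention).

## The synthetic cohort generator

The generator emulates the survey's record structure with per-group
parameter blocks (`GroupParams`) and is deterministic given a seed.
Distributional forms are design choices — the motivating study reports
only medians and IQRs:

- roster size: zero-truncated negative binomial (base mean 7.8 at the
  reference age of 48 y, dispersion 8) with a log-linear age link
  (+0.0066/y);
- tie density: per-ego Beta (mean 0.68, concentration 3) with a
  logit-linear age link (+0.0175/y); present ties are strength 2 with
  probability 0.5;
- alter attributes, conditionally independent given the ego: sex via a
  per-ego Beta-Bernoulli male share (concentration 40); race by the
  homophily mixture h·ego-race + (1−h)·population with h = 0.92 (White),
  0.55 (Black), 0.5 (Other); kin/distant/non-exercise/negative flags via
  Beta-Bernoulli shares; alter ages normal around the ego's age
  (sd 12.5 y); NFL contacts a sub-Bernoulli of organized-football
  contacts (0.42 × 0.12), players only;
- ego covariates: ages normal (58.5 ± 12.5 vs 39.5 ± 9), lognormal
  incomes, categorical education/employment/race at the published
  frequencies; players draw four independent chronic-affliction flags
  (sleep 0.235, pain 0.085, cardiometabolic 0.16, neurocognitive 0.04 →
  ~43% any), controls a single indicator (0.227) — mirroring how the two
  cohorts are actually surveyed.

**Why the age links.** The published raw medians show players with
larger, denser networks (8 vs 7; 0.75 vs 0.68) yet *no* adjusted
structural difference. The generator reproduces exactly that pattern by
letting size and density depend on ego age with link parameters shared
by both groups: the groups' different age distributions create the raw
gaps, and the age-adjusted group effect on every structural metric is
zero by construction. The links are mild enough that linear adjustment
leaves no measurable residual confounding (null-calibration simulations
hold per-metric type-I error at ~5%).

**Planted contrasts.** The default ("paper-like") configuration plants
the compositional signature directly: alter male share 0.68 vs 0.50
(reproducing sex-diversity medians ≈ 0.85 vs 0.89–0.94), kin share 0.37
vs 0.44, and lower homophily for Black egos (who are far more frequent
among players), yielding markedly more racially diverse networks for
Black egos. Two other presets exist: `"null"` (identical blocks, 300 per
group — type-I calibration) and `"structure-shift"` (size/density
genuinely shifted, composition identical — a positive control).

**Known calibration offsets.** The planted kin gap (medians ≈ 37 vs 43)
is wider than the published 40.0 vs 42.9 because a 3-point median gap is
not reliably recoverable at ~300 per group; the published contrast was
presumably carried by distributional differences beyond the medians.
Realized effective-size medians (~2.5) sit below the published 3.5
because ES = k − 2t/k at the published size and density medians implies
~2.5–2.8; the published ES median is not jointly consistent with its
size/density medians under the binary formula, so size and density were
preferred as calibration targets. Supplement-style sex-diversity IQRs
above 1 cannot arise from raw IQV ∈ [0, 1] and are not reproduced.

**What the generator does not emulate.** Joint dependence among alter
attributes (kin × distance × sex) — attributes are conditionally
independent given the ego; longitudinal network change (the design is
cross-sectional); and real missingness mechanisms (the injector blanks
items completely at random at configured rates). Passing pipeline tests
on these cohorts therefore validates the *computations and the
statistical machinery*, not the substantive realism of any particular
dependence structure.

## Problem sizes used in validation

Oracle equivalence runs 1,000 random egonets (k ≤ 10, strengths in
{0,1,2}). Null calibration uses 400 replicates at 300 per group
(Monte-Carlo SE ≈ 1.1% against a [2%, 9%] acceptance band); signature
recovery uses 50 replicates at 300 per group. Replicated simulations
feed records directly into the metrics and comparison stages; the CSV
serialization path is exercised separately by round-trip tests.

## Limitations

- The exact field codes of the original instrument are not public; the
  wide-CSV dialect here is a declared convention, not a reconstruction.
- Whether the original analysis computed constraint on weighted or
  dichotomized ties is unknown; both are implemented and oracle-checked,
  weighted being the default.
- Education is treated as equally-spaced ordinal in the adjustment;
  income enters untransformed (in $1000s). Both are config-exposed.
- The race covariate is binary (White vs non-White), so compositional
  differences that vary *within* the non-White category (e.g. race
  diversity of Black vs Other egos) are only partially absorbed by
  adjustment; on the default preset the race-diversity contrast is
  therefore often significant even though the motivating study reported
  it null in the main comparison.
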