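# Methods

## Scope and data model

The unit of observation is one cohort's summary lifespan (mean or
median, in days) for one strain under stated conditions. Strains are
identified at the **gene level**: two strains perturbing the same genes
with different alleles are the same model (alleles are recorded on the
interventions for auditability but do not distinguish models). The
canonical strain name concatenates the distinct gene symbols in
case-insensitive alphabetical order (byte-order tiebreak) joined by
`;`; the wild type has the reserved name `wild type`.

Epistasis is only ever inferred **within one experiment**. Because
published records rarely name an explicit experiment identifier, the
default grouping key is `(study_id, temperature_c, diet)`; loaders can
override it via a column-mapping configuration. Between-lab lifespan
variation is large enough (wild-type worms differ by a factor of two
across studies at the same temperature) that cross-experiment inference
is refused by design; there is deliberately no flag to enable it in the
classification pipeline, and the display-interval fallback (below) is
the only place a cross-study comparison is made.

When a model has several cohorts within one experiment, their lifespans
are averaged (arithmetic mean) before any delta is computed. When a
study reports both mean and median lifespan, the mean is preferred; the
choice is recorded per observation.

## Inclusion rules

An experiment group is retained when (a) at least one n ≥ 2 mutant in
the group has an (n−1)-mutant it was incrementally constructed from,
and (b) at least one mutant cohort exceeds some wild-type cohort of the
group by strictly more than 10%. Both conditions are existential, which
makes the filter **monotone in evidence**: adding observations can only
add witnesses, never flip a pass into a fail. (An earlier formulation
compared against the group's mean WT; a property test showed that
adding a long-lived WT cohort could then retract a pass, so the
comparison is cohort-level.) For groups lacking a WT control entirely,
the caller may assert `assume_prior_lag` — that one intervention is an
established lifespan modulator — which the software cannot verify and
therefore never infers.

## Classification

Effects are percent lifespan changes versus the same-experiment WT,
Δ = (LS − LS(WT))·100/LS(WT). The five pair categories are compared on
absolute deltas and partition the Δ(G1,G2) axis completely: for singles
(+30, +20) the boundaries sit exactly at 20 (antagonistic→dependent),
30 (dependent→almost additive, both endpoints belonging to the
dependent band) and 50 (the one-point additive band, then
synergistic). Numerical choices:

* **Additive tolerance** ε: |Δ12| counts as additive when within a
  relative ε of |Δ1|+|Δ2|, ε = 1e-9 by default (exact additivity is
  essentially theoretical; the parameter exists so a user can widen the
  band deliberately, e.g. to absorb digitization error).
* **Zero or opposite single effects**: no shared direction exists, so
  the pair is `not_assessable_mixed_directions` rather than forced into
  a category. The direction test uses exact sign by default
  (`direction_tol` configurable).
* **Opposite-direction doubles**: a double mutant shifted against the
  shared direction of its singles is antagonistic with
  `phenotype_direction="opposite"`.
* All comparisons are made in **percent changes, not raw lifespans**;
  the two are not equivalent for sums, and the pair rules are defined
  in changes.

### Full synergism (n ≥ 2)

Evaluated only when the WT, the combination and every proper gene
subset have same-experiment lifespans; otherwise `insufficient_data`.
For n = 2 the evaluation reduces exactly to the pair classifier (a
property enforced on random inputs). For n > 2 the default, flexible
definition requires |Δ(combination)| to exceed |Δ(S)| + |Δ(S̄)| for
every bipartition (S, S̄); subsets with mixed effect directions make
the call `not_assessable_mixed_directions`. Non-synergistic n > 2
calls are labelled `not_synergistic` — the five detailed categories are
reported only for pairs, where they are defined — and carry the
violated bipartition with the largest summed effect plus that split's
pair-style category as auxiliary detail.

A **strict** variant (flag `strict=True`) additionally requires every
sub-combination of size ≥ 2 to be synergistic. The two variants differ
in a way that matters: *strict* full synergism provably implies simple
synergism (the pair inequality chains upward by induction), while the
flexible definition does not — equal singles +45 with dependent pairs
+15 and a triple at +90 beat every single+pair split (60 < 90) yet fall
short of the summed singles (135). The test suite asserts the
implication for the strict variant and the counterexample for the
flexible one.

### Simple synergism

|Δ(combination)| > Σ|Δ(single_i)| with all signs shared, requiring only
the singles and the final n-mutant. Cheap, but a strongly synergistic
subgroup can mask a dependent partner: the packaged false-positive
scenario (singles +40/+35/+30, pairs +135/+125/+70, triple +110) is
called simple-synergistic from singles + triple alone and refuted by
the full evaluation once the pairs are known.

### Monotony along assayed paths

An n-mutant can be built along n! orderings of its interventions. Each
path whose every node has a same-experiment lifespan is *known*; a
known path is monotonic-positive iff lifespan strictly increases at
every step (negative: strictly decreases). One non-monotonic known path
means the combination contains dependency relationships; zero known
paths means no verdict. Ties count as non-monotonic (strict
inequality; `tie_tolerance` configurable, default 0). Mixed directions
among monotonic paths cannot occur: a positive path must end above the
WT lifespan and a negative one below it, and the endpoint is fixed
within a group.

Path enumeration is exhaustive over permutations (or over the graph,
choosing the lexicographically smallest added gene first, for the
network API). n rarely exceeds 4 in curated data, so factorial
enumeration is not a practical constraint; both implementations are
cross-checked against a brute-force recursive walk for n ≤ 5.

## Intervention network and display intervals

The per-organism network has one node per observed strain and an edge
wherever one strain's gene set is the other's plus exactly one gene.
Edges aggregate across studies (the network is a browsing aid);
monotony always re-derives per-experiment sub-lattices. Node color
encodes direction (green long-lived, red short-lived), intensity the
mean percent effect scaled to the largest in the graph, size the record
count.

The displayed effect for a combination is the [min, max] interval of
its per-experiment deltas. Experiments without their own WT control are
bracketed against the species-wide minimum and maximum WT lifespan —
restricted to the same temperature stratum when the observation's
temperature is recorded and WT data exist there, since WT lifespan
differs systematically by a factor ≈ 1.3 between 15 °C and 20 °C in
worms; a pooled mode is available (`stratify_temperature=False`).

## Synthetic data generator

The generator emulates the statistical structure the classifier
assumes: per-experiment cohorts with a WT control, all singles, and a
completeness-sampled subset of higher-order mutants over a configured
gene panel. Interaction models for the noise-free deltas:

* `additive_deltas` — Δ(S) = Σ singles (the additive null);
* `multiplicative_lifespans` — LS(S)/WT = Π(1 + δᵢ/100), i.e. mildly
  synergistic in delta space for same-sign effects;
* `masking` — Δ(S) equals the largest-magnitude single (classical
  epistatic masking; for pairs this lands exactly on the dependent
  band's boundary);
* `custom_table` — explicit subset→delta overrides (unspecified subsets
  fall back to additivity). Overrides take precedence under every model.

Observed lifespans multiply the noise-free value by log-normal noise
with a configured coefficient of variation, mean-corrected so the
expectation is unbiased; log-normality keeps lifespans positive. The
default test-suite noise band tops out at CV = 0.18, the observed
between-lab spread of wild-type *C. elegans* lifespans at 15 °C
(SD ≈ 4.36 d on a mean of ≈ 23.66 d); CV = 0.06 represents a
well-controlled within-lab replicate series. Ground-truth categories
are computed analytically from the noise-free deltas with the same pair
rules the classifier applies (bipartition verdicts for n > 2), so
recovery is a clean round trip.

What the generator does **not** emulate: survival-curve shape,
censoring, cohort sizes, allele-specific effect differences,
temperature-dependent effect sizes, or correlated errors between
strains sharing a control. Passing recovery tests therefore demonstrate
the classifier's correctness and noise sensitivity on summary
lifespans, not robustness to every artefact of real survival data.

Recovery experiments in the shipped tests and acceptance script use
150–400 replicates per condition over a 3-gene panel
(+30/+20/−15), sizes at which the Monte-Carlo standard error of a
recovery rate is ≈ 1–2 points; the monotone-degradation check allows
3 points of slack accordingly.

## Known limitations

* The SQL dump dialect of the public database is not parsed (CSV and
  JSON only), and the deposit itself is not redistributed; summary
  tables are recomputed from a user-supplied local dump.
* Classification uses point estimates only; no survival-curve
  statistics (log-rank and friends) are computed, mirroring how the
  curated categories are defined.
* Missing intermediates are never imputed from other studies.
* Boundary equalities (the ≤ in the dependent band) are applied
  exactly; real data landing on a boundary to machine precision is
  vanishingly rare, but digitized values rounded to one decimal can sit
  on it, in which case the dependent label wins by construction.
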