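# Methods

## Evidence model

The diagnostic evidence is a single binary test (TERTp hotspot mutation
present/absent) characterised by four conditional probabilities.
P(+|malignant) is pooled from ten published melanoma series as a plain
case-weighted average of their prevalences, Σ nᵢpᵢ / Σ nᵢ = 0.4122 over
1,507 cases.  No heterogeneity (random-effects) modelling is attempted: the
pooled value is a descriptive average, not a meta-analytic estimate, and
the wide spread across series (0.17–0.75) is deliberately not propagated as
uncertainty.  P(+|benign) = 0.014 is a fixed point estimate from the
largest published nevus series.  By default the malignant-side likelihood
is rounded to two decimals (0.41/0.59) before use, with the complement
derived from the rounded value so the pair still sums to one exactly;
`rounding_decimals=None` keeps the unrounded 0.4122.  Both choices
reproduce the reference posterior grid at two decimals (a tested
property), so the rounding is presentational, not substantive.

## ddPCR calling

An assay is called mutated at ≥6 mutant droplets; a valid negative
additionally requires ≥600 total positive droplets, pinning the analytical
sensitivity at 6/600 = 1%.  The droplet floor is attached only to negative
calls: six mutant droplets are positive evidence regardless of total
loading.  Two assays (C228T, C250T) combine disjunctively into one lesion
status; a lesion is wild-type only when both assays validly ran, so a
wild-type plus a failed assay remains inconclusive.  The
mutated-plus-failed combination is called mutated — a documented
convention, since one positive assay suffices for the disjunction even if
the other never produced data.  No 2D amplitude thresholding, droplet
clustering or Poisson concentration estimation is modelled; the calling
rule consumes already-counted droplets.

## Bayesian update and bands

Priors 0.25/0.5/0.75 attach to the three uncertain preliminary categories;
confidently benign or malignant lesions bypass testing entirely.  The
posterior is computed at full float precision and rounded only for
display.  Band boundaries are fixed as [0, 0.1) benign, [0.1, 0.2) likely
benign, [0.2, 0.5] ambiguous, (0.5, 0.9] likely malignant, (0.9, 1]
malignant.  The half-open conventions are the only assignment consistent
with all published example classifications (0.17 → likely benign, 0.37 →
ambiguous, 0.64 → likely malignant, 0.91 → malignant) while keeping the
ambiguous band closed at both ends; they matter only on sets of measure
zero but are pinned by boundary tests.  Inconclusive assays short-circuit:
posterior = prior, final category = preliminary category, excluded from
every tested-cohort denominator.

"Uncertainty reduction" is operationalised as (lesions finalised in the
benign management group + preliminarily ambiguous lesions finalised in the
malignant group) / conclusively tested lesions.  Likely-malignant lesions
confirmed malignant are not counted, since their management was already
the melanoma pathway; with the reference cohort this gives 58/151 = 38%.

## Micro-costing

Scenario A re-excises every conclusively tested uncertain lesion at the
re-excision tariff (default 1,274 €/patient); Scenario B tests each
(default 570.5 €/sample, optionally itemised into per-activity
personnel/materials/equipment/overhead/failure components that must sum to
the tariff within 0.01 €) and re-excises only the residual ambiguous band.
Malignant-pathway costs are excluded from both arms by construction: they
are indicated and unavoidable once malignancy is established, so they
cancel out of the comparison.  Monetary arithmetic uses `decimal.Decimal`
end to end, so all totals are exact to the cent and sub-cent quantities
from the batch discount (570.5 × 0.67 = 382.235 €) are represented
exactly.  A batch discount (reference value 33%) applies when more than
two samples share a ddPCR run.  The break-even resolved fraction is
cost_test/cost_reexcision ≈ 0.448: savings are positive when more than
~45% of tested lesions leave the ambiguous band.

The tariff table in the source series prints slightly different grand
totals (192,345/36,129 €) than its own running text (192,374/36,158.50 €);
only the text values equal 151 × 1,274 € exactly, so this package
reproduces the text values.  An
`include_inconclusive_as_ambiguous` option adds the untestable lesions to
both arms' ambiguous counts as a sensitivity analysis (they need
re-excision either way, so including them reduces neither arm's validity
but changes both totals equally plus one extra test per lesion).

## Synthetic cohorts and microsimulation

The generator emulates the reference series' marginal structure: category
mix proportional to 115/49/87/39/77 over 367 lesions, latent malignancy
Bernoulli with the category's prior (0 for confidently benign, 1 for
confidently malignant — these groups bypass testing), assay failure 24/175
≈ 0.137 among uncertain lesions, and test results drawn from the
likelihoods conditional on the latent state.  By default the truth is
generated from the same priors the inference uses — the well-specified
case that calibration tests require; `true_malignancy_rates` overrides
support misspecification experiments.  Notably, the reference series
itself shows 0/44 mutations among likely-benign lesions, lower than the
model-implied 0.25 × 0.41 + 0.75 × 0.014 ≈ 0.113; the simulator follows
the model, and this divergence is a known gap between the generative
assumptions and the observed series.  The generator does not simulate
droplet counts, lesion morphology, inter-observer variation in the
preliminary category, or any survival/progression outcomes — so passing
calibration tests demonstrates internal consistency of the Bayesian
machinery, not real-world accuracy of the priors.

All randomness descends from one integer seed through
`numpy.random.SeedSequence`; the microsimulator spawns one independent
substream per replicate, making every cohort and replicate set exactly
reproducible and order-independent.  Default problem sizes — 10,000
lesions for calibration, 50,000 for parameter recovery, 500 replicates of
367-lesion cohorts for the savings distribution — keep Monte Carlo noise
well below the 3-standard-error acceptance bands used in the tests while
the full suite runs in seconds.

## Numerical and degenerate cases

Posterior denominators vanish only when the observed result has prior
probability zero (e.g. a perfect test observed "impossible" data); this
raises an explicit degeneracy error rather than returning NaN.  Priors 0
and 1 are absorbing.  Empty cohorts yield all-zero tables; empty item
lists cost zero.  Category labels are case-insensitive on input and
canonical snake_case on output; prevalences accept both `43%` and `0.43`.

## Limitations

Only the C228T/C250T hotspots are modelled; rarer TERTp variants are
outside scope, so "wild-type" means wild-type for these two assays.  The
costing is a two-arm budget comparison, not a health-economic evaluation:
no QALYs, discounting, or downstream melanoma treatment costs.  Tariffs
are setting-specific defaults, fully configurable.  Multi-marker evidence
combination (Ki-67, clinical factors) is not implemented.
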