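# Methods

## Model and procedure

The analysis treats each speaker as one observation: a binary diagnostic
label `y_i` (1 = ASD) and a vector of per-word tag usage rates
`x_ij = c_ij / w_i`, where `c_ij` is the count of lexicogrammatical tag
`j` in speaker `i`'s transcribed speech and `w_i` the total number of
words/morphemes they produced. Normalization by `w_i` (and nothing else —
no per-1000 scaling, no log or arcsine transform) makes rates comparable
across speakers who talk very different amounts; it is exactly invertible
(`c_ij = x_ij · w_i`) and homogeneous (rescaling all counts and word
counts together leaves `x` unchanged).

The classifier is a logistic regression
`logit P(y=1|x) = β₀ + Σⱼ βⱼ x_ij`. With ~135 features against ~135
speakers the unpenalized MLE is typically non-identified (separable), so
fitting maximizes the Bernoulli log-likelihood minus `(λ/2)·Σⱼ βⱼ²`; the
intercept is never penalized. Optimization is damped Newton (IRLS with
step-halving), which is deterministic, monotone in the penalized
objective, and stops when the gradient sup-norm falls below `1e-8`. At
`λ = 0` a diverging fit (coefficients drifting beyond ±30 while the
gradient vanishes) is flagged as non-convergent with a suggestion to set
`λ > 0`, since separable data admit no maximum.

Coefficient inference is by nonparametric bootstrap over speakers:
`B` resamples of `n` speakers drawn with replacement from all `n` rows
(non-stratified; a resample containing a single class is redrawn and
counted, and a redraw rate above 50% aborts — stratified resampling is
available as an option). Each resample is refit; tag `j` is summarized by
the sample mean and SD (denominator `B−1`) of its coefficient across
resamples, and the null hypothesis `βⱼ = 0` is tested with the
normal-approximation two-sided tail

    p_j = 2 · (1 − Φ(|mean_j| / sd_j)).

This moments-based form was adopted because it reproduces 21 of the 46
published discriminator rows' p-values to all four printed decimals from
their printed mean/SD columns, and all 46 rows are consistent with it
once the 4-decimal rounding of the printed moments is propagated (the
remaining 25 rows — e.g. benefactive *do*, printed p 0.0031 vs 0.0039
recomputed — are rounding-limited, not discrepant). Percentile or BCa
intervals are deliberately out of scope: they cannot be reconstructed
from printed moments.

Discriminators are the tags with `p < α` (strict inequality, default
`α = 0.05`), with no multiple-testing adjustment by default — matching
the published selection of 46 items from 135 — and Benjamini–Hochberg
available as an explicitly labelled extension. Selections can be
restricted to the clause/phrase structural level (the packaged annotation
marks the 20 such items among the 46) and grouped into seven
cognitive-functional domains; both annotations are data in the scheme
JSON, not logic, so users can re-derive them under different theoretical
commitments.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `B` | 10,000 | bootstrap refits; tests and the acceptance script use 200–500 so that calibration experiments with dozens of replicate corpora finish in minutes — SDs at B=500 are within a few percent of their B=10,000 values |
| `penalty` (λ) | 1.0 | ridge weight on unstandardized per-word rates; on this scale fitted coefficients land in the ±0.25 range of the published table |
| `α` | 0.05 | selection level, strict `<` |
| `k` | 5 | stratified CV folds |
| `standardize` | False | z-score features inside the fit (fold-safe in CV), mapping coefficients back to the raw scale |
| `threshold` | 0.5 | probability cut for the positive (ASD) class |

One interaction deserves emphasis: per-word rates have magnitude ~1e-2,
so λ = 1 on the raw scale is *strong* shrinkage for prediction — strong
enough that the classifier falls back to the class prior even when groups
are cleanly separated. That is harmless for inference (the test statistic
`mean/sd` is insensitive to the common shrinkage factor, and the
coefficient scale matches the published table) but wrong for evaluating
classification. Classifier metrics are therefore computed with
`standardize=True`, i.e. ridge on unit-variance features, which is the
standard practice for penalized classification; inference keeps the raw
scale. Both configurations are exposed, and `fit_meta` records what was
used.

## The synthetic corpus

No clinical corpus is distributable, so the generator emulates the study
design: `n_pos = 64` ASD and `n_neg = 71` non-ASD speakers; per-speaker
word counts log-normal with median 1,000 and log-SD 0.6 (interviews had
no length restriction, so heavy right skew is realistic; a median of
~1,000 morphemes matches semi-structured interview responses); tag counts
Poisson — optionally negative-binomial with shape θ for overdispersion —
with mean `w_i · exp(b_j + y_i·d_j)`. The baseline rate defaults to
`exp(b_j) = 0.01` per word (one occurrence per 100 words, a mid-range
frequency for grammatical tags). The `table1_preset` sets `d_j = ±0.5`
with signs copied from the published table (positive for parallel
clauses, exemplifying elaboration, existential process, and filler
*unto*; negative for the other 42 items; zero for tags outside the 46);
the magnitude 0.5 is a documented default — printed coefficients are
log-odds per unit frequency, not rate-scale effect sizes, and are not
reused as such.

What the generator does **not** emulate: correlation between tags within
a speaker (no covariance information is published; tags are drawn
independently), zero-inflation, topic or task effects, age/IQ structure,
and annotation noise. Consequently, passing calibration and recovery
checks demonstrates that the *inference machinery* is correct and
well-calibrated under the design's sample sizes and count scales — not
that real ASD speech is classified with any particular accuracy. The
published headline metrics (80% accuracy, 82% precision, 73% sensitivity,
87% specificity) belong to a deep-network model on the original corpus
and are not reproducible here; the package's CV checks instead verify
the two boundary conditions that are checkable: near-perfect accuracy on
strongly separated synthetic data and chance-level accuracy on null data.

## Numerical choices and degenerate inputs

- SD uses the `B−1` denominator; at `B = 1` the SD is zero and p-values
  are reported as NaN with a warning rather than fabricated.
- `p < α` uses strict inequality, so a tag at exactly `p = 0.05` is not
  selected.
- Selection output is ordered by p ascending with ties broken by scheme
  order (stable sort), making reports deterministic.
- Undefined classification ratios (e.g. precision with no positive
  predictions) are NaN with a warning, never silently 0.
- The Newton solver adds a 1e-12 diagonal jitter so the IRLS solve stays
  well-posed when fitted probabilities saturate.
- All randomness flows through `numpy.random.default_rng(seed)`; the
  bootstrap, the generator, CV fold assignment, and the full pipeline are
  bit-reproducible given their seeds, and pipeline artifacts embed the
  complete parameterization (seed, B, λ, α, k, version).

## Design decisions that were genuinely open

- **Resampling scheme.** Plain resampling of all speakers (non-stratified)
  was chosen as the minimal reading of "a random sample drawn with
  replacement"; stratified resampling is an option. Degenerate
  single-class resamples are redrawn and counted rather than dropped, so
  `B` retained fits are always reported.
- **Tag inventory.** The full annotation scheme is not published; the
  packaged default enumerates the 46 published discriminator items
  verbatim plus clearly named synthetic placeholder tags to reach 135
  items in 15 categories. The scheme is user-replaceable JSON, and every
  function takes it as an argument.
- **Analyzed tag count.** Reported counts of the inventory vary between
  135 analyzed items and a 140-tag scheme (159 in the source corpus); the
  default scheme uses 135, and nothing in the code depends on the exact
  number.
- **Domain mapping.** Encoded as data from the results narrative: the 20
  clause/phrase discriminators map to seven domains, several to two
  (projection items to working memory + mental space construction;
  negotiating particles to joint attention + weak central coherence;
  parallel clauses and exemplifying elaboration to weak central coherence
  + restricted/repetitive behaviors).
- **Validation protocol.** No protocol is published for the classifier
  metrics; stratified 5-fold CV with pooled held-out predictions is the
  package's choice.

## Known limitations

- The normal-approximation p-value ignores bootstrap-distribution skew;
  with `m ≈ n` the ridge-stabilized refits are near-Gaussian in practice
  (the type-I calibration check verifies the 5% level empirically), but
  heavy-tailed coefficient distributions would not be detected.
- Bootstrap inference after ridge shrinkage tests the penalized
  coefficient, not the unpenalized log-odds; signs and ordering are
  robust to this, absolute magnitudes are not.
- Independence of tags in the generator likely makes synthetic recovery
  easier than on real, collinear features.
- The pipeline starts from tag counts; transcription and SFL annotation
  quality are upstream of everything here.
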