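# tagdisc

Discovery of lexicogrammatical discriminators of autism-spectrum (ASD)
speech by bootstrap logistic-regression inference over annotated tag
frequencies.

## The problem

Verbally fluent speakers with ASD differ from non-ASD speakers not only
pragmatically but in *which* grammatical resources they select: fewer
embedded (rankshifted) clauses, fewer causal/conditional constructions,
fewer interpersonal sentence-final particles, more existential processes
and repetitive parallel structures. Given interview transcripts annotated
with a systemic-functional-linguistics (SFL) tag scheme — ~135
lexicogrammatical items in up to 15 categories — the question is which
tags are statistically reliable *discriminators* between the diagnostic
groups, and which cognitive-functional domains (working memory,
inferential ability, mental space construction, joint attention, weak
central coherence, self/other differentiation, restricted and repetitive
behaviors) they point to.

The statistical difficulty is the design: two groups of roughly 64 and 71
speakers against ~135 features. `tagdisc` implements the interpretable
"Tag Linear Model" analysis for this setting:

1. **Normalization.** Each speaker's tag counts `c_ij` are divided by
   their total word count `w_i`, giving per-word usage rates
   `x_ij = c_ij / w_i` independent of speech quantity.
2. **Bootstrap inference.** For `b = 1..B` (default `B = 10,000`), draw
   `n` speakers with replacement, refit a ridge-penalized logistic
   regression `logit P(ASD) = β₀ + Σⱼ βⱼ x_ij`, and record the
   coefficients. Each tag is summarized by its bootstrap mean and SD, and
   a two-sided p-value for `βⱼ = 0` via the normal approximation
   `p = 2(1 − Φ(|mean|/SD))`.
3. **Selection and interpretation.** Tags with `p < α` (default 0.05, no
   multiplicity adjustment; Benjamini–Hochberg optional) are
   discriminators; they can be restricted to clause/phrase-level items and
   grouped by cognitive-functional domain.
4. **Classification.** The same model, cross-validated with stratified
   k-fold, yields accuracy / precision / sensitivity (recall on ASD) /
   specificity (recall on non-ASD).

Because no clinical corpus is distributed, the package ships a synthetic
corpus generator (log-normal word counts; Poisson or negative-binomial
tag counts with log-linear group effects) that reproduces the study's
design (64/71 speakers, 135 tags), including a preset whose effect signs
follow the published discriminator table.

## Worked example

```python
import tagdisc as td

scheme = td.default_scheme()                       # 135 tags, 15 categories
config = td.table1_preset(scheme, seed=7)          # published effect signs
records = td.generate_corpus(config)               # 64 ASD + 71 non-ASD
features = td.normalize_features(records, scheme)  # x_ij = c_ij / w_i

result = td.bootstrap_coefficients(features, B=500, penalty=1.0, seed=7)
selected = td.select_discriminators(result, alpha=0.05)
print(f"{len(selected)} of {scheme.n_tags} tags significant at p < 0.05")

top = selected[0]
print(f"top discriminator: {top.tag}")
print(f"  mean={top.mean:+.4f}  SD={top.sd:.4f}  p={top.p_value:.4f}")

filtered = td.filter_structural_level(selected, scheme, "clause_phrase")
print(f"{len(filtered.selected)} at clause/phrase level")
report = td.map_to_domains([s.tag for s in filtered.selected], scheme)
for domain, tags in report.items():
    if tags:
        print(f"  {domain}: {len(tags)} item(s)")

metrics = td.cross_validate(features, k=5, penalty=1.0, seed=7,
                            standardize=True)
print(f"5-fold CV: accuracy={metrics.accuracy:.2f} "
      f"precision={metrics.precision:.2f} "
      f"sensitivity={metrics.sensitivity:.2f} "
      f"specificity={metrics.specificity:.2f}")
```

Output:

```
50 of 135 tags significant at p < 0.05
top discriminator: Clause complexes-parallel clauses
  mean=+0.2191  SD=0.0205  p=0.0000
20 at clause/phrase level
  working memory: 5 item(s)
  inferential ability: 6 item(s)
  mental space construction: 5 item(s)
  joint attention: 6 item(s)
  weak central coherence: 8 item(s)
  self/other differentiation and agency: 1 item(s)
  restricted and repetitive behaviors: 2 item(s)
5-fold CV: accuracy=1.00 precision=1.00 sensitivity=1.00 specificity=1.00
```

Reading the numbers: on this synthetic corpus 46 tags carry a planted
group effect, and the bootstrap flags 50 at `p < 0.05` (the planted ones
plus a few false positives, consistent with the 5% level over 89 null
tags). The positive mean for parallel clauses means ASD speakers use them
*more*; the clause/phrase-level subset maps onto the seven cognitive
domains exactly as the packaged annotation specifies; and with strong
planted effects the cross-validated classifier separates the groups
perfectly — on real speech all four metrics would be far lower.

The same stages are available from the shell:

```sh
tagdisc simulate --preset table1 --seed 7 --out counts.tsv
tagdisc bootstrap --counts counts.tsv --B 10000 --seed 7 --out results.csv
tagdisc report --results results.csv --level clause_phrase --out domains.json
tagdisc run --counts counts.tsv --out-dir report/ --B 10000 --seed 7
```

Input format: tab-separated, header `speaker_id  group  word_count` plus
one integer column per tag; groups `ASD` / `non-ASD`. The tag scheme
(identifiers, categories, domain map, structural levels) is a JSON file
and fully user-replaceable; `src/tagdisc/resources/default_scheme.json`
documents the layout.

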