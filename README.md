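# pcombine

Combine `L` independent p-values with positive weights into a single
significance level, with numerics that stay stable even when weights are
equal or nearly equal.

The combined p-value is the tail probability `Pr(T >= t)` of
`T = sum_i w_i E_i` (unit exponentials `E_i`) at the observed statistic
`t = -sum_i w_i ln p_i`. Four evaluators are provided:

- **fisher** — all weights equal: the Erlang tail `Q(L, -sum ln p_i)`.
- **good** — all weights distinct: the classic pairwise-prefactor formula.
  Catastrophically unstable when weights are nearly equal; the cancellation
  index in the result diagnoses this, and extended precision (default
  50 digits, raised adaptively) keeps the exact formula usable.
- **gc** — the general case: weights grouped, equal within a group. Exact
  survival function of the hypoexponential with repeated rates, via
  partial fractions at adaptive extended precision.
- **expansion** — the stable route for arbitrary (including nearly
  degenerate) weights: normalized inverse weights are clustered within a
  radius, and the combined p-value is expanded in powers of the
  within-cluster deviations. No near-equal differences are ever formed, so
  plain double precision suffices, and truncation at a chosen order carries
  an explicit error bound.

Two independent oracles (seeded Monte Carlo; high-precision Laplace-domain
inversion cross-checked against partial fractions) and a deterministic
fixture generator back the test suite and are exported for user
verification.

## CLI

Input is tab- or comma-delimited text with a header; column `p_value` is
required, `weight` (default 1) and `id` are optional.

```sh
pcombine --input pvalues.tsv                        # method chosen automatically
pcombine --input pvalues.tsv --method expansion --radius 0.05 --order 4
pcombine --input pvalues.tsv --method good --digits 16 --strict   # exit 3 on instability
pcombine --input pvalues.tsv --mc-check --mc-samples 1000000 --seed 1
```

The JSON (or `--format tsv`) report carries the combined p-value, the raw
unclipped value, the cancellation index, the cluster table (centers,
multiplicities, deviation moments), the expansion order and truncation
bound, and an echo of the inputs. Logs go to stderr. Exit codes: 0 ok,
2 input error, 3 instability under `--strict`.

## Library

```python
from pcombine import (WeightedPValueSet, expansion_combine, ExpansionConfig,
                      good_combine, gc_combine, gc_parameters_from_set)

s = WeightedPValueSet([0.008, 0.0086, 0.0009], [0.545, 0.5453, 0.5452])
r = expansion_combine(s, ExpansionConfig(max_order=4, radius=0.05))
r.pvalue, r.truncation_bound, r.cancellation_index
```

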