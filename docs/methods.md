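# Methods

`osmodry` analyzes 3-factor osmotic-dehydration experiments laid out as
Box–Behnken designs (BBD): temperature `T` (°C), osmotic-solution
concentration `Conc` (% mass) and process time `t` (h), with 12 edge-midpoint
runs plus replicated center points.  The bundled reference experiment
(builtin name `table1`) dehydrates beetroot cubes in sugar beet molasses over
`T` ∈ {20, 40, 60} °C, `Conc` ∈ {60, 70, 80} % and `t` ∈ {1, 3, 5} h — 15
runs, 13 measured responses.  All statistics operate on the tabulated
replicate *means*; replicate-level raw data are not part of the fixture, so
standard deviations are carried as metadata only.

## Dehydration indices

From a gravimetric mass balance (masses `m_i`, `m_f`, `m_d`; water fractions
`z_i`, `z_f`; dry-matter fractions `s_i`, `s_f`):

* `WL = (m_i·z_i − m_f·z_f) / m_i`  (g water / g fresh sample)
* `SG = (m_f·s_f − m_i·s_i) / m_i`  (g solids / g fresh sample)
* `DMC = 100 · m_d / m`, with the denominator selectable.

The `basis` switch of `compute_dmc` exists because the two natural
denominators disagree in the field's shorthand: the index is sometimes
written over the fresh mass `m_i`, while the oven-drying protocol that
produces the numbers divides by the measured (post-process) mass `m_f`.
The default is `measured`, because the reference table's DMC values for
dehydrated samples are only consistent with that convention; `fresh` is
kept available explicitly.

Whenever `z + s = 1` at both states, `WL − SG = (m_i − m_f)/m_i` is an
algebraic identity.  `MassBalance` deliberately does **not** enforce the
fraction-sum constraint at construction, so that `mass_balance_check` can
flag corrupted records (returning the signed residual) instead of refusing
to represent them.

## Standard-score ranking

Each response is a criterion with a direction.  Benefit criteria are
normalized as `(x − min)/(max − min)`, cost criteria as
`(max − x)/(max − min)`; a run's standard score `SS` is the arithmetic
*mean* of its normalized scores, so `SS ∈ [0, 1]` regardless of how many
criteria are active (a raw sum would change scale with the criterion count).
Criteria are equally weighted.  Default directions: the antioxidant IC50s
(`DPPH`, `ABTS`) are costs — a lower half-inhibition concentration means a
stronger antioxidant — and so is `acidity`; the other ten responses are
benefits.  This is the unique natural assignment under which the reference
experiment's declared optimum (run 8: 60 °C, 70 %, 5 h) wins; directions are
user-overridable per column.  Constant columns score 0.5 with a warning;
`SS` ties are broken by ascending run id, also with a warning.

On the bundled means these defaults give `SS(run 8) = 0.8589`, against a
published 0.847 for the same experiment; the source does not disclose
whether rounding, replicate-level data or a different direction assignment
produced its value, so the package reports its own computation and leaves
directions configurable rather than tuning them.

## Multivariate characterization

* **Correlations** — product-moment coefficients over the `n = 15` run
  means; two-sided p-values from the exact transform
  `t = r·sqrt((n−2)/(1−r²))` on `n−2` degrees of freedom.  No
  multiple-testing adjustment is applied (none is conventional in this
  literature); pairs involving constant columns are reported missing.
* **Clustering** — complete-linkage agglomeration on city-block (Manhattan)
  distances over the **raw, unstandardized** response vectors.  With
  heterogeneous units the potassium/sodium columns (thousands of mg/kg)
  dominate the distances; that is intentional, matching the reference
  analysis whose dendrogram heights (~16 000) are only attainable on raw
  units.  Flat labels come from cutting the monotone merge tree at a
  requested cluster count.
* **PCA** — eigendecomposition of the correlation matrix (z-scored
  columns).  Covariance PCA would put nearly all variance on K/Na and is
  not offered.  Loadings are unit-norm eigenvectors, so
  `L·diag(λ)·Lᵀ` reconstructs the correlation matrix; per-component
  variable contributions are squared loadings rescaled to sum to 100 %.
  Component signs are fixed by making each component's largest-magnitude
  loading positive, a deterministic convention with no statistical content.

## MLP response models

One network per response: `y = f_out(w₂·f_hid(W₁x + b₁) + b₂)` with 3
inputs, `H` hidden units and one output; activations from
{identity, logistic, tanh, exponential} (defaults: tanh hidden, identity
output).  Inputs and output are min–max normalized with bounds estimated
from the **training split only**; values outside the bounds map outside
[0, 1] and warn.  Exponential/logistic arguments are clipped at ±40 to keep
the loss finite; restarts that still go non-finite are discarded with a log
entry.

Training minimizes the sum-of-squares error on the training split with
BFGS using analytic (backpropagation) gradients, capped at `max_iter`
iterations (default 200 — BFGS is a batch method, so the iteration cap
plays the role an epoch limit plays for incremental learners).  The
15 rows are split 60/20/20 into train/test/validation by a seeded shuffle
(sizes 9/3/3; split sizes round the first two fractions and give the
remainder to validation).  Center replicates may land in any split — no
stratification is imposed.  For each `H` in `hidden_range` (default 3–10)
and each of `restarts` (default 50) random initializations
(`N(0, 0.5²)`), the fitted model with the highest **test-split** r² is
kept; the validation split is reported but never used for selection.  With
more free parameters than training rows the networks can interpolate, so
train-split r² near 1 is expected and model comparison rests on the held-out
splits.

Two exact limits anchor correctness: with identity activations and `H = 1`
the SOS optimum is the ordinary-least-squares fit (verified against the
normal equations to 1e-6), and min–max normalization absorbs affine maps of
the inputs, so rescaled factors yield identical denormalized predictions.

## Connection-weight sensitivity (Yoon's method)

For a trained network, the signed relative importance of input `i` is

    RI_i = 100 · Σ_k (w_ik · w_k) / Σ_i |Σ_k (w_ik · w_k)|

over hidden units `k`, using only weights (no biases), on the normalized
scale the network was trained on.  By construction Σ|RI| = 100 per output,
and RI is invariant to positive rescaling of either layer's weights.  Being
weight-based, RI is meaningful in sign and rank rather than in precise
magnitude; the synthetic-surface tests therefore check sign recovery across
seeds, not values.

## Goodness of fit

For observed/predicted vectors of length `N`: reduced χ² = SSE/(N−n),
RMSE = sqrt(SSE/N), MBE (mean signed error), SSE, AARD =
(100/N)·Σ|Δ/pred|, and r² = 1 − SSE/SST, plus residual mean, sd, variance,
skewness and excess kurtosis (moment estimators, small-sample bias
correction off by default).  Two conventions are deliberate:

* **MPE equals AARD.**  As conventionally printed in this literature the
  two formulas are identical; both are implemented verbatim instead of
  silently substituting the signed textbook MPE.
* **χ²'s `n`.**  The natural choice for a network is its free-parameter
  count (`3H + 2H + 1`), and `gof_report` takes it as an argument.  But on
  a 15-record table every searched topology has ≥ 16 parameters, which
  would make the denominator non-positive; the batch `fit_report_table`
  therefore caps `n` at `N − 1` with a warning.  Percent-scale metrics are
  reported missing when any prediction is zero.

## Synthetic experiments

`synthetic_bbd` generates BBD tables from quadratic surfaces on *coded*
factors (−1/0/+1): `y = β₀ + Σβᵢxᵢ + Σβᵢᵢxᵢ² + Σβᵢⱼxᵢxⱼ + N(0, σ)`, seeded
and bitwise reproducible, floored at zero.  Coding means each linear
coefficient's sign *is* the ground-truth effect direction, which is what
the sensitivity-recovery tests exploit.  The default 13-surface bundle
mirrors the reference experiment qualitatively — dehydration indices,
minerals and betaine rise with `T` and `t`, IC50s and acidity fall, so the
synthetic SS optimum sits at the high-temperature/long-time corner — with
noise on the order of the reference table's center-replicate scatter (≈1–4 %
of each response's range).

What the generator does **not** emulate: replicate-level noise hierarchies
(one Gaussian per response, homoscedastic), mechanistic osmotic-diffusion
kinetics, correlated measurement error between responses, and non-Gaussian
assay error.  Tests passing on synthetic tables therefore demonstrate that
the estimators recover known structure under idealized noise, not that the
estimators are robust to real assay pathologies.

## Reference-data caveats

The bundled `table1` reproduces its source table verbatim (thousands
separators stripped).  Three published summaries of that experiment are
**not** reproducible from the tabulated means with the stated methods, and
the corresponding acceptance-suite tests fail by design rather than being
weakened:

* several published pairwise correlations differ from the recomputed ones
  by far more than print rounding (e.g. DMC–WL recomputes to 0.77 against a
  published 0.958);
* the published PCA variance split (52.13 % / 72.0 % cumulative) differs
  from the recomputed one (62.8 % / 80.7 %);
* the published four-cluster memberships are not the complete-linkage
  city-block partition of the tabulated means.

Two table cells (run 7's water loss, printed with an anomalous near-minimum
value at the longest process time, and run 2's potassium, printed with a
standard deviation almost as large as its mean) behave like typos: plausible
single-cell corrections bring all published correlations within ≈0.02.  The
package does not apply such corrections — the fixture stays verbatim, and
the discrepancies are surfaced here and in the failing tests.  The mineral
unit is recorded as mg/kg (the table header) although parts of the source
narrative quote mg/100 g; run 8's Mg value is likewise inconsistent with the
narrative's grouping of run 8 among the mineral-richest runs.  None of this
affects the ranking, index, modeling or sensitivity machinery, whose
correctness is established against closed forms, brute-force oracles and
synthetic ground truth.

## Problem sizes and numerical choices

The test suite and example configurations run the full topology search
(H = 3…10, 50 restarts) for single responses and smaller sweeps elsewhere;
these sizes were chosen as comfortable desk-scale settings for a 15-run
table.  Key tolerances: mass-balance identity 1e-9; OLS-equivalence 1e-6;
metric oracles 1e-10; PCA reconstruction 1e-8; BFGS gradient tolerance
1e-10.  All randomness (splits, initializations, synthetic noise) flows
from explicit integer seeds through `numpy.random.default_rng`; pipeline
runs with identical config and seed produce byte-identical artifacts.
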