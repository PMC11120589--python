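# osmodry

Analysis toolkit for **osmotic dehydration experiments** on 3-factor
Box–Behnken designs: which combination of temperature, osmotic-solution
concentration and immersion time yields the best semi-dried product?

Osmotic dehydration immerses plant tissue (here: beetroot cubes in sugar
beet molasses) in a hypertonic solution; water leaves the tissue while
solutes enter.  A 15-run Box–Behnken design over temperature `T`,
concentration `Conc` and time `t` is characterized by 13 responses — dry
matter content, water loss, solid gain, minerals (Mg, K, Na, Ca),
antioxidant IC50s (DPPH, ABTS), flavonoids, phenols, acidity and betaine —
and the package covers the full computational workflow around such a table:

* **Dehydration indices** from gravimetric mass balances, with the
  `WL − SG = (m_i − m_f)/m_i` consistency check:
  `WL = (m_i·z_i − m_f·z_f)/m_i`, `SG = (m_f·s_f − m_i·s_i)/m_i`,
  `DMC = 100·m_d/m`.
* **Standard-score ranking**: min–max normalize each response as a benefit
  or cost criterion and rank runs by the mean normalized score
  `SS ∈ [0, 1]`; the SS argmax is the recommended operating point.
* **Multivariate views**: Pearson correlation matrix with exact t-test
  p-values, complete-linkage/city-block hierarchical clustering of runs,
  and correlation-matrix PCA with variance decomposition and variable
  contributions.
* **MLP response models** `y = f₂(w₂·f₁(W₁x + b₁) + b₂)` (3-H-1, min–max
  normalized, trained by BFGS with analytic gradients, restarts and a
  hidden-width search; 60/20/20 seeded splits).
* **Connection-weight sensitivity** (Yoon's method):
  `RI_i = 100·Σ_k w_ik w_k / Σ_i|Σ_k w_ik w_k|`, the signed relative
  importance of each factor, summing to 100 % in absolute value.
* **Goodness-of-fit suite**: reduced χ², RMSE, MBE, MPE, SSE, AARD, r² and
  residual moments.
* **Synthetic experiments**: Box–Behnken tables simulated from quadratic
  surfaces with known coefficient signs and seeded Gaussian noise, so every
  estimator can be tested against ground truth.

The reference experiment ships as a packaged fixture (`table1`, plus the
28-day storage series `table4`), so everything below runs offline.

## Worked example

```python
from osmodry import load_design_table, standard_scores, pearson_matrix, \
    train_response, yoon_ri
from osmodry.ann import TrainConfig

table = load_design_table("table1")

ranking = standard_scores(table)
print(f"optimal run: {ranking.best_run}  SS = {ranking.ss[ranking.best_run]:.4f}")

corr = pearson_matrix(table)
print(f"r(K, Na) = {corr.r.loc['K','Na']:.3f}  (p = {corr.p.loc['K','Na']:.2e})")

fit = train_response(table, "betaine", TrainConfig(hidden_range=(3, 4, 5),
                                                   restarts=20, seed=42))
print(f"best net: {fit.name}  train r2 = {fit.r2['train']:.3f}")
print(yoon_ri(fit.model).round(1).to_string())
```

prints

```
optimal run: 8  SS = 0.8589
r(K, Na) = 0.942  (p = 1.51e-07)
best net: MLP 3-5-1  train r2 = 1.000
T       49.1
Conc    19.9
t       31.0
```

Run 8 (60 °C, 70 % molasses, 5 h) maximizes the standard score: it combines
the highest dry matter, solid gain, betaine, flavonoid and phenol levels
with the lowest IC50s (strongest antioxidant activity).  Potassium and
sodium uptake move together almost perfectly (r = 0.94).  For betaine, the
selected 5-hidden-unit network interpolates the training rows, and the
connection weights assign positive influence to all three factors, with
temperature and time dominating — longer, warmer immersion in molasses
enriches betaine.

The same workflow is scriptable end to end:

```bash
osmodry score --input table1 --out scores.csv
osmodry ann --input table1 --responses DMC,betaine --restarts 50 --out models.json
osmodry simulate --seed 1 --out synthetic.csv
osmodry run --config config.yaml     # full pipeline bundle into an output dir
```

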