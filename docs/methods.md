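# Methods

## Statistical model

The analysis unit is a transect of `n_lquadrats` L-quadrats, each divided
into `m_subquadrats` S-quadrats, with every species scored present/absent in
every S-quadrat. For species *i* the pipeline computes

* occurrence frequency `p_i = (Σ counts) / (m·N)`, the fraction of all
  S-quadrats occupied;
* count variance `v_i` across L-quadrats;
* the log-scale pair `x_i = log(p_i(1−p_i)/m)`, `y_i = log(v_i/m²)`;
* the community OLS fit `y = α + βx` with residuals `ε_i`;
* the heterogeneity index `δ_i = y_i − x_i` and its classification
  (patchy / random / uniform by the sign of δ, with an optional tolerance
  band for noisy estimates);
* community indices `δ_c = Σp_iδ_i/Σp_i` and Shannon–Wiener `H'` (natural
  log, frequencies normalized to sum to one);
* the δ-vs-p trend, fitted by default as a power form `δ = a·p^b` via OLS
  on (ln p, ln δ).

The key identity underlying the x-axis: under independent Bernoulli(p)
occupancy the per-L-quadrat count is Binomial(m, p) with variance
`m·p(1−p)`, so `y = x` exactly in expectation — any vertical displacement
measures departure from spatial randomness at the S-quadrat scale.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `m_subquadrats` | 4 | S-quadrats per L-quadrat (25 cm quadrat split into 12.5 cm cells) |
| `log_base` | 10 | base of both transforms; β and R² are base-invariant, α and δ scale by ln 10 under a base change |
| `variance_estimator` | `sample` (N−1) | unbiased for the binomial variance under the random null, so E[y]=x holds exactly; `population` (N) available |
| `classification_tolerance` | 0 | half-width of the "random" band on δ; 0 is the strict sign criterion |
| `rounding` | 4 d.p. | report output only; internal precision is full |

R² is defined as the squared Pearson correlation of x and y, which for
simple OLS with intercept equals 1 − SSE/SST. Degenerate fits are refused
(fewer than 3 points, constant x); data constant in y are assigned R² = 0
rather than a 0/0.

## Exclusion rules

The log transforms are undefined for species with `p ∈ {0, 1}` or `v = 0`
(absent, ubiquitous, or perfectly constant counts). Such species are
excluded from the regression and carry an explicit reason; at least three
includable species are required. Exclusions are reported, never silent.

## Reconstruction mode

When only a published summary (p, δ per species) is available, the
regression points are rebuilt as `x = log(p(1−p)/m)`, `y = x + δ` and the
fit is recomputed. This reproduces every published quantity that depends
only on (p, δ): the fit coefficients, R², the residuals ε, δ_c, H', and the
δ-vs-p trend. The count variance v is not recoverable from a summary. Note
that a δ printed for a minimum-frequency species (one presence in 200
S-quadrats gives δ ≈ 0.002 under either variance estimator, not the 0.011
carried by the bundled table) cannot be re-derived from any raw count
configuration; reconstruction mode therefore takes the printed δ at face
value, and raw-data mode is validated against synthetic ground truth
instead.

## Synthetic data generator

Three per-species occupancy models operationalize the pattern taxonomy the
classifier targets:

* **random** — i.i.d. Bernoulli(p) cells; expected δ = 0;
* **clustered** — per-L-quadrat occupancy probability drawn from a Beta
  with mean p and intra-class correlation ρ (shapes `a = p(1−ρ)/ρ`,
  `b = (1−p)(1−ρ)/ρ`), then m conditionally independent Bernoulli draws.
  Counts are beta-binomial with variance `m·p(1−p)(1+(m−1)ρ)`, hence the
  closed form `δ = log(1+(m−1)ρ)` used for parameter-recovery tests;
* **regular** — `round(p·N·m)` presences placed deterministically so
  per-L counts differ by at most one; variance falls below binomial
  (δ < 0), or is exactly zero when the total divides N (the species is then
  excluded downstream, which is itself a tested behavior).

One master seed is split into per-species substreams
(`numpy.random.SeedSequence.spawn`), so a fixed seed yields a bit-identical
matrix and adding a species never perturbs the others' draws.

What the generator emulates is the within-L-quadrat aggregation that the
statistics actually see. It does **not** model along-transect
autocorrelation, zonation gradients, interspecific association, or
detection error — all present in real shore data. Passing recovery tests
therefore demonstrates that the estimator chain is correct and calibrated
under its own model, not that field data meet the model's assumptions.

Default validation problem sizes: N = 20000 L-quadrats for null-calibration
and recovery checks (δ̂ within ±0.02 of the closed form, averaged over 10
seeds), N = 500–5000 for integration tests. These sizes keep each
individual δ̂'s sampling noise a few thousandths, well inside the asserted
tolerances.

## Numerical and design choices

* **Base 10 logs by default** — reconstructing the bundled published table
  with base 10 reproduces its printed residuals and R²; the base remains
  configurable, and base-change behavior (β, R² invariant; α, δ scaled) is
  property-tested.
* **Sample (N−1) variance by default** — the unbiasedness argument above;
  the choice only shifts δ by log(N/(N−1)) ≈ 0.004 at N = 50, but the
  sample estimator makes the random-null identity exact at any N.
* **Power form for the δ-vs-p trend** — on the bundled data the power form
  explains R² ≈ 0.559 versus ≈ 0.13 for a straight line, and a power trend
  is the natural choice for a quantity built from logs. Pairs with δ ≤ 0
  are dropped from the power fit with a warning (their log is undefined);
  a linear form on the raw scale is selectable.
* **Multi-transect files** — analyzed per transect by default; pooling
  concatenates transects into one analysis unit with renumbered L-quadrats.
  The bundled survey's frequencies are multiples of 1/200, consistent with
  a single 200-S-quadrat unit.
* **1-based file indices, 0-based internal indices** — the converters in
  the I/O layer are the only place the mapping occurs.
* **Ties at δ = 0** — classified "random"; with a tolerance t the band is
  |δ| ≤ t inclusive.

## Known limitations

* δ is a single-scale index: it only detects aggregation at the S-quadrat /
  L-quadrat scale and says nothing about patch sizes larger than one
  L-quadrat.
* No confidence intervals are attached to δ_i or δ_c; the OLS confidence
  band exported for plotting covers the regression mean only.
* Reconstruction mode inherits the rounding of the published table
  (4 d.p.), which bounds the agreement achievable on refitted quantities at
  roughly 1e-4.
* The classifier's strict sign criterion calls any δ > 0 "patchy", however
  small; for finite surveys a tolerance reflecting sampling noise in δ̂ is
  more honest, and the reports always print δ alongside the label.
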