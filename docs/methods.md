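# Methods

## The mosaic-distribution statistic

A section of chimeric epidermis is reduced to a 1D binary sequence (the
*trace*) by sampling the label mask along an ordered basal-layer path.  The
reduction is explicit and reproducible: the path is either supplied as a
0-based, row-major, 8-connected polyline, or auto-traced as the deepest
non-background pixel of each raster column (with intermediate points
inserted at depth jumps so connectivity holds).  Background pixels on the
path are skipped, never imputed; skipping more than 10% of the path is
logged as a warning with a reason code.

For a trace with `n_pos` donor (EGFP+) and `n_neg` host (EGFP−) pixels,
composition probabilities are the per-pixel frequencies
`P_pos = n_pos/n`, `P_neg = n_neg/n`.  Each maximal same-label region of
length `L` receives the block probability `P_label^L` — the probability
that `L` i.i.d. draws at the observed composition would all carry that
label — and the natural-log score `L·ln(P_label)`.  Natural logs are used
throughout; the base only rescales scores.

**Arrangement invariance.**  Summing log scores over all regions gives
`n_pos·ln(P_pos) + n_neg·ln(P_neg)` *identically*, for every arrangement of
a fixed composition.  The total log product therefore carries no
information about clustering.  This is why the package (a) exposes the
per-region score distribution, whose shape does discriminate — clustered
traces concentrate mass in long, low-probability regions — and (b) answers
the directional question "more contiguous than random?" with statistics
whose null distribution does depend on arrangement: the run count `R`, the
longest run, or the mean per-region log score (which equals the invariant
total divided by `R`, and so orders arrangements exactly as `R` does).

**Null models.**  The null is uniform random arrangement conditional on
composition.  Analytically, `R` has the Wald–Wolfowitz moments

    E[R]   = 1 + 2·n_pos·n_neg / n
    Var[R] = 2·n_pos·n_neg·(2·n_pos·n_neg − n) / (n²·(n − 1))

(variance 0 at n = 1).  Empirically, a seeded permutation test shuffles the
labels; the one-sided p-value toward contiguity uses the add-one estimator
`(b + 1)/(n_perm + 1)` (never 0), with `n_perm = 10,000` by default and a
mandatory explicit seed.  Single-label traces admit exactly one arrangement
under this null, so they are reported as *not testable*
(`testable = False`, p = NaN) rather than p = 1.

**Aggregation.**  Sections can be tested per trace or pooled per animal.
Pooling concatenates *run lists*, not pixel sequences, so no artificial
junction region appears between non-adjacent fields; the pooled permutation
null shuffles each section independently and sums the run counts (the
analytic moments add likewise).  Both per-label and pooled score summaries
are retained, since either comparison convention is defensible.

## Persistence (effect size)

The companion effect size to the test is a persistence estimate from the
label-change count.  The raw same-label transition frequency
`stay_freq = 1 − changes/(n − 1)` is reported with its binomial SE, but it
conflates clustering with composition: an i.i.d. trace with `P_pos = p` has
expected stay frequency `q = p² + (1 − p)²  > 1/2` whenever p ≠ 1/2.  The
headline estimate therefore converts to the redraw parameterisation of the
generator actually used here (stay probability `θ + (1 − θ)·π_s`), under
which the marginal stay frequency is `θ + (1 − θ)·q`; inverting with the
trace's own composition gives `θ̂ = (stay_freq − q)/(1 − q)`, which is 0 in
expectation for i.i.d. traces of any composition, 1 for a single run, and
negative for arrangements more alternating than random (clipped to
[−1, 1]).  Its SE is the delta-method scaling `se(stay_freq)/(1 − q)`.

## Synthetic generators

The generators define the conditions every statistical claim is tested
under; all are deterministic given their config (including seed).

* **bernoulli** — i.i.d. labels at composition `p_pos`; the intermingled,
  wild-type-chimera-like pattern and the exact null of the test.
* **markov** — two-state chain whose next label repeats the current one
  with probability θ and is otherwise redrawn from the stationary
  composition.  This keeps the stationary composition at `p_pos` for all
  θ ∈ [0, 1) and collapses to the Bernoulli generator at θ = 0 — by
  construction the two consume the same uniform stream, so the reduction is
  exact seed by seed.  Power studies use θ ∈ {0, 0.5, 0.8, 0.95} at length
  500: at this length the run-count deficit at θ = 0.5 is already ≈11 null
  SDs, so power saturates at 1 from θ = 0.5 upward and only the
  θ = 0 → 0.5 step shows a strict rise.
* **encroachment** — a minimal 1D lattice caricature of niche takeover:
  sites start i.i.d. donor at `donor_seed_fraction`; each step visits sites
  in a fresh seeded random order and a visited donor site converts each
  adjacent host site with probability `adhesion_deficit` (host sites never
  convert donor sites).  Donor occupancy is monotone non-decreasing; at
  deficit 1 the lattice is absorbed once any donor exists.  Random visit
  order avoids directional sweep artifacts.  The model's only claim is to
  produce segmented-versus-intermingled patterns for exercising the
  statistic; it encodes no rates, mechanics, or apoptosis and supports no
  quantitative biological inference.

A mask renderer lays any trace along a flat basal band over background so
the full image → path → trace → statistic chain is testable end to end;
render → write → read → extract is the identity on traces.

What the synthetic conditions do **not** emulate: curved or interrupted
basal layers, segmentation noise and mislabelled pixels, three-label
ambiguity, section-to-section composition drift within an animal, and any
2D patch geometry.  Passing tests establish the statistical machinery, not
robustness to imaging artifacts.

## Coverage model

Donor skin coverage is an area fraction: donor pixels over non-background
pixels for label masks, or the fraction above a threshold for intensity
images — Otsu's method by default (deterministic and parameter-free), a
fixed threshold on request, and the effective threshold always recorded.

Expected coverage versus global chimerism `c` (%) is modelled as a logistic
in log10-chimerism,

    coverage(c) = 100 / (1 + exp(−slope·(log10 c − log10 c50))),

chosen over an unbounded log-linear law so predictions stay in [0, 100] and
the half-coverage chimerism `c50` is a model parameter rather than a
derived quantity; `coverage_at(fit, c50) = 50` exactly by construction.
`(log10 c50, slope)` are fitted jointly by Levenberg–Marquardt least
squares (start: median log10 c, slope 1); if the optimizer fails, a
linear-in-log10 fallback is reported with `method = "linear_log"` and the
slope matched to the logistic's midpoint derivative.  The fit is
scale-equivariant: rescaling chimerism units rescales `c50` and leaves the
slope unchanged.  Confidence intervals for `c50` are a seeded percentile
bootstrap resampling *animals* (the independent unit), never pixels;
bootstrap replicates with degenerate chimerism or failed fits are dropped.
Flat data leave `c50` weakly identified — the reported CI then spans far
beyond the data rather than being truncated.

The reference synthetic condition is half-coverage at 1.6% chimerism,
slope 2 per log10 unit, 5-percentage-point Gaussian observation noise, and
40 animals log-uniform over 0.1–100% chimerism; recovery simulations at
this condition bound the median `ĉ50` error within ±10% and give ≥90%
coverage of 95% bootstrap CIs.

## Numerical and reporting choices

* Region probabilities are computed in log space; `p^L` underflows harmlessly
  to the reported `exp(log_score)`.
* Permutation matrices are shuffled row-wise in one vectorized pass; the
  longest-run statistic is computed with a `reduceat` over forced row
  boundaries.
* Sub-seeds for multi-trace analyses come from `numpy.random.SeedSequence`
  spawned off the user's single seed; all derived seeds stay below 2³¹.
* Results serialize with fixed field order and 6 significant digits, so
  identical configs produce byte-identical files and write → read → write
  is idempotent.
* Percentages in count summaries are rounded half-up to one decimal
  (`8/79 → 10.1%`); full precision is retained alongside and in JSON.
* Problem sizes in the validation suite (trace length 500 for
  calibration/power, length 10,000 for persistence recovery, 40 animals and
  100 datasets for coverage recovery, 20,000 permutations against
  exhaustive enumeration on traces up to length 12) were chosen so
  Monte-Carlo error is small against each tolerance while the whole suite
  runs in minutes on one core.

## Known limitations

* The 1D reduction discards patch geometry; no 2D spatial statistics
  (Ripley's K, Moran's I) are attempted.
* Raw p-values only; no multiple-testing correction across animals.
* Chimerism enters as a given percentage — estimating it from flow
  cytometry is out of scope, as is segmenting raw fluorescence micrographs
  into label masks.
* The encroachment simulator is a pattern generator, not a mechanistic
  model; its parameters have no units attachable to real tissue.
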