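# Methods

## Scope and model

`evomedia` optimizes the composition of a cell-culture medium when the only
available readout is a noisy, slow, plate-level bioassay. The search space is
a box of final-medium concentrations (µg/ml, *including* the basal medium's
own contribution — components can be added on top of the basal medium but
never removed, so every lower bound is at or above the basal concentration).
Each component's range is discretized into `n + 1` grid values; a genetic
algorithm searches the product grid using a binary encoding, and fitness is
measured — on real plates or a simulator — as the relative increase in
metabolic activity (RIMA) over the unmodified basal medium.

## Encoding

A gene of `b = ⌈log₂(n + 1)⌉` bits (most-significant bit first) indexes the
grid. Because `2^b` may exceed `n + 1`, surplus codes are **clipped** to the
upper endpoint rather than rescaled: clipping keeps the printed step size
exact and every decoded value on the grid, at the cost of a small sampling
bias toward the upper bound (the clipped mass is `(2^b − n − 1)/2^b`, at most
just under ½). Rescaling was the rejected alternative; it would spread codes
evenly but move values off the printed grid. Encoding a concentration takes
the nearest grid index, with half-way ties rounded to even (deterministic and
unbiased). The packaged amino-acid table has 20 optimizable components
(gene lengths 3–6 bits, 91 bits total); two components are held fixed and
carry no gene. One row of the source table is typographically ambiguous; the
packaged CSV documents the adopted reading in its header (the only reading
consistent with the table's common ~3.125 µg/ml step and a six-bit gene).

## The genetic algorithm

Defaults: population 30 (fills a 96-well plate in triplicate plus a control),
crossover probability 0.95, per-bit mutation rate 0.02, roulette-wheel
selection, no elitism (an `elitism: 0|1` flag exists and is logged).
Generation 1 is uniform random; offspring are produced by drawing two parents
from the wheel, single-point crossover (uniform cut in `1..L−1`, suffixes
exchanged), and independent bit flips. Chromosomes are kept **unique within a
generation** by rejection re-draw with an attempt cap of 1000 — each
treatment is a distinct composition worth a well. Every offspring's parents,
cut position, and flipped bits are logged, so a campaign is fully auditable.

### Fitness scaling

Fitness entering the wheel is floored at zero (control-subtracted values can
be negative). Two scalings are available:

- `raw` — probability `fᵢ / Σf`. This is the textbook wheel, but RIMA values
  cluster in a narrow band around 1 (typically 0.9–1.6), so raw proportional
  selection is nearly uniform and the search barely progresses at realistic
  budgets. In our noiseless benchmark it recovered the planted optimum in
  1 of 20 campaigns.
- `window` (default) — the generation minimum is subtracted before
  normalizing, the classical windowing fix for exactly this compression;
  an all-equal generation falls back to uniform selection. The same benchmark
  recovers the optimum in 18 of 20 campaigns.

`roulette_select` itself defaults to `raw` (its contract is the proportional
wheel); breeding uses the configured scaling.

Termination is user-driven: the tool reports a stagnation metric (relative
change in best fitness between the last two generations) but never stops a
campaign on its own — with triplicate noise, the per-generation best is a
noisy statistic and that judgment belongs to the experimenter.

### Ask/tell and state

`Campaign.ask()` breeds (or initializes) the pending generation; `tell()`
accepts a fitness table that must cover exactly the pending treatment ids
(missing, extra, or duplicated ids are reported by name) and freezes the
generation. One seeded PCG64 generator drives the whole campaign and its
state is serialized with the campaign JSON, so a run interrupted between
wet-lab generations resumes bit-identically.

## Plate design and recipes

A generation maps to paired plates — one seeded with cells, one cell-free
background plate with the identical treatment map — filled row-major,
treatments first in replicate blocks, controls in the trailing wells
(30 treatments + 1 control in triplicate = 93 of 96 wells). Deterministic
placement is the default so layouts are byte-stable and auditable; a seeded
randomized layout is available to mitigate edge effects. Stock volumes per
treatment follow from mass balance: at a stock of `S` g/L (≡ µg/µl), reaching
`target` µg/ml over `basal` in `V` ml takes `(target − basal)·V/S` µl, with
the diluent (DIW/basal make-up) absorbing the remainder. Defaults are 5 g/L
stocks, 4.6 g/L for the two components whose stocks are diluted by the NaOH
needed to dissolve them. The cell suspension's own volume contribution is
ignored in the recipe math (a documented simplification).

## Response analysis

Order of operations: background-subtract per replicate (cells minus
cell-free, paired by replicate index), then average, then divide by the
control mean. This makes RIMA background-free and invariant to any common
gain rescaling; the control scores exactly 1. Unmatched replicates are
dropped with a warning, never imputed. Significance versus the control is a
two-sided equal-variance Student's t test on net replicates at α = 0.05,
uncorrected by default (per-treatment calls at n = 3 are advisory and the
assay's convention is per-comparison testing); a Benjamini–Hochberg
false-discovery-rate option (`correction="bh"`) is available. Zero-variance inputs
(possible in noiseless simulation) short-circuit to t = 0, p = 1 for equal
means and p = 0 otherwise; "zero" variance is judged relative to the
measurement scale (round-off on ~10³ RFU values is not evidence).
Cross-animal variation for a single treatment uses one-way fixed-effects
ANOVA on net RFU grouped by individual; all-identical inputs return F = 0,
p = 1 by convention. Negative net RFU is retained for statistics and floored
at zero only when exported as GA fitness.

Convergence diagnostics report, per component and generation, the
concentrations of the top-k and bottom-k treatments against the allowed
range, the min–max envelope width of the top set, and the Pearson correlation
between component concentration and fitness pooled over all scored
treatments. Note the correlation is linear: it flags components with a
monotone trend (optimum near a range edge); a dominant component whose
optimum is mid-range is better seen in the envelope plots.

## Synthetic landscape

The simulator plants a single-optimum response surface

```
surface(x) = max_gain^(1 − d(x)),   d(x) = clip(d₀(x)/d₀(control), 0, d_max)
```

with `d₀(x) = Σᵢ qᵢ zᵢ² + Σᵢⱼ qᵢⱼ zᵢ zⱼ` a non-negative quadratic in the
range-normalized offsets `zᵢ = (xᵢ − θ*ᵢ)/(upperᵢ − lowerᵢ)` from the planted
optimum θ*. Normalizing by the control composition pins `surface(control) = 1`
and `surface(θ*) = max_gain` exactly, so a scored campaign's RIMA scale is
interpretable by construction. Defaults: `max_gain = 1.6` (the magnitude of
the strongest observed treatment effects in this assay class),
`d_max = 1.25` (treatments can fall below the control, to ~0.89), baseline
1000 RFU, cell-free background 100 RFU.

`sample_landscape` draws θ* uniformly on-grid, curvatures log-uniform in
[0.5, 2] *scaled by each component's squared normalized control offset*
(floored at half its in-box reach). The scaling matters: without it,
components whose basal concentration lies far below their optimizable range
dominate `d₀(control)` and the surface is nearly flat across the design box
(simulated treatments would span ~1.49–1.60), unlike the wide
treatment-to-treatment spread this assay actually produces; with it,
simulated treatments span roughly 1.1–1.55. Interactions are present for a
configured fraction of component pairs with coefficients uniform in ±0.3.

Wells are simulated as `background + baseline·individual_effect·surface(x) +
N(0, noise_sd)` (cells) and `background + N(0, noise_sd)` (cell-free),
truncated at zero; `noise_cv` sets `noise_sd` as a fraction of the baseline
biological signal. Individual (per-animal) effects multiply only the
biological signal, not the background, so a nutrition-free control shows no
individual differences. What the simulator does **not** model: multiplicative
(signal-proportional) reader noise, spatial plate effects, evaporation,
time-course kinetics, or any mechanistic metabolism — passing recovery tests
therefore demonstrates the optimizer and analysis pipeline, not biological
validity of any particular medium.

## Benchmarks and problem sizes

`recovery_experiment` runs the full ask/tell loop against a landscape and
reports the best-RIMA trajectory and the grid distance to θ* of both the
final generation's best individual and the campaign-wide best (the
composition an experimenter would carry forward; without elitism the final
generation can lose it). Packaged study sizes: noiseless recovery uses
5-component spaces (basal = lower = 25 µg/ml, 15 steps of 3.125 µg/ml,
matching a typical optimizable row), 15 generations × 30, 20 seeded runs,
success = campaign best within 2 grid steps per component of θ* in ≥ 80% of
runs. The full-scale benchmark uses the packaged 20-component table at the
wet-lab budget — 4 generations × 30 treatments × 3 replicates, 10% replicate
CV, 10% interaction density — and checks that the mean final-generation best
RIMA exceeds the mean generation-1 best across 20 seeds. The true (noiseless)
best improves by ≈ +0.05 RIMA over such a campaign while the *measured* best
carries winner's-curse noise of similar magnitude — mirroring the practical
observation that per-generation best RIMA is a weak progress signal at
triplicate scale, while population-level improvement and shrinking
concentration envelopes are the more reliable indicators.

Statistical calibration checks: the t test's type-I rate under a simulated
global null is ~5% over 10,000 independent treatment/control pairs; a
two-group ANOVA equals the squared pooled t to 1e−10; the ANOVA's power for
3 animals × 3 replicates with between-animal variance 25× the replicate
variance matches the closed-form random-effects value 0.935; and the RIMA of
an optimum treatment at 10% CV, n = 3, spreads per the delta method for a
ratio of means (SD ≈ 0.154 at gain 1.6, so ±0.2 captures ≈ 80.6%).
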