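# Methods

This note documents the models, the synthetic study design, the numerical
choices and the limitations of the package. Notation: inputs are infrared
temperature *T* (°C), air velocity *V* (m/s), target moisture content *MC*
(% dry basis) and loading direction *D* (1 sutural, 2 longitudinal,
3 vertical); responses are drying time DT (min), specific energy
consumption SEC (MJ/kg), high kernel rate HR (%), whole kernel rate WR (%)
and shell-breaking rate SR (%).

## Process metrics

The process formulas are closed-form and dimensionally simple:
HR = 100·(M_A+M_B+M_C)/ΣM and WR = 100·M_A/ΣM from the kernel class
masses (A whole, B half, C quarter, D crushed), SR = 100·L/N from crack
counts, dry-basis moisture M = 100·(W_T−W_d)/W_d, SEC = E/m, shell–kernel
clearance (A+B+C−a−b−c−6d)/6 over the three axes, and hardness F_r/D_r.
Model quality is scored per response by RMSE and R² = 1 − SSR/SST on the
denormalized scale.

Report arithmetic conventions, fixed by checking them against the shipped
comparison tables: the relative validation error divides by the
*experimental* value; the percent change between two Pareto groups divides
by the *reference* group; RMSE reduction divides by the *baseline* model.
All three compute at full precision and are rounded only for reporting
(two decimals for validation errors, one for group comparisons; the RMSE
reduction row mixes one- and two-decimal printing and the fixtures record
each value's printed precision).

## Surrogate network

The surrogate is a three-layer feed-forward network, 4 inputs → *j* hidden
→ 5 outputs. Inputs and targets are min–max normalized to (−1, 1) against
the *training* data; the hidden layer applies logsig(x) = 1/(1+e^−x) or
tansig(x) = 2/(1+e^−2x) − 1; the output layer is linear, and predictions
are denormalized by the inverse transform. The direction code *D* enters
as its numeric value 1/2/3 and is normalized like the continuous inputs —
an ordinal encoding: the network sees longitudinal as "between" sutural
and vertical. With only three levels and a flexible hidden layer this is
harmless in practice, but it is an assumption, not a fact about the
process.

Candidate hidden sizes come from the standard sizing heuristics
(j < n−1, j < √(n+m)+a with a ∈ {0..10}, j = log₂n, j = 2n+1, all
intersected with j > 1; the root bound is treated as closed when it lands
on an integer), giving j ∈ {2..13} for the 4→5 network. The topology
search trains ten fresh random initializations per (transfer, j) pair on
one fixed split and averages R²/RMSE per response; the selected pair
minimizes the mean rank over the ten score columns, ties to the smaller
network. On the synthetic study, logsig with a large hidden layer wins —
j = 12 is used as the default topology throughout.

### Training

Training hyperparameters are the package's own choices (none are inherited
from a published protocol): full-batch gradient descent on the
normalized-scale MSE with momentum 0.9 and a variable step — steps that
increase the loss by more than 4 % are rejected (step size ×0.7, momentum
memory cleared), accepted improving steps grow the step by ×1.05 from an
initial 0.05. The trainer tracks the best parameters seen and reports the
best-so-far loss per epoch, so the returned model is never worse than its
initialization and the history is monotone by construction. Defaults:
4000 epochs, error goal 10⁻⁵. Saturation was checked at 10k and 20k
epochs: no further hold-out gain, and mild overfitting of the
lowest-variance responses, so 4000 is kept. Untrained networks initialize
uniformly in (−3, 3), matching the GA gene range, so BP-only and
GA-initialized runs start from the same distribution.

A representational caveat: a j-unit hidden layer spans only j independent
feature functions, so a 4–2–5 network can reproduce a multi-output linear
map only up to rank 2. The training tests therefore use a rank-2 target
when checking exact recovery with j = 2.

## GA initialization (GA-ANN)

The real-coded GA minimizes the network's training MSE over the flattened
parameter vector (order: input→hidden weights row-major, hidden
thresholds, hidden→output weights row-major, output thresholds; length
j·4 + j + 5j + 5, i.e. 125 genes for j = 12). Published settings:
population 200, 1000 generations, crossover 0.90, mutation 0.10, genes in
(−3, 3). Operator choices are ours: binary tournament selection
(scale-invariant to fitness magnitude), per-gene arithmetic blend
crossover, per-gene Gaussian mutation with σ = 10 % of the gene range
clipped back into range, and 2 elites (1 % of the default population).
Fitness is evaluated on raw genomes without inner BP refinement; BP runs
once, after the GA, from the best genome. BP training may leave the
(−3, 3) box — the range bounds initialization and mutation only. With
zero GA generations the hybrid collapses exactly to the BP baseline
(same random initialization and seed stream), which the tests use as a
degenerate-path check.

On the synthetic study at the reduced budget (population 60, 100
generations), GA initialization lowers the mean test RMSE versus plain BP
on every paired seed tried, with the largest gains on DT — consistent
with the argument that the GA's value is escaping poor random starts.

## Five-objective optimization

The optimizer minimizes (DT, SEC, −HR, −WR, −SR) over the operating
window 40 ≤ T ≤ 55, 1 ≤ V ≤ 4, 10 ≤ MC ≤ 25, D ∈ {1, 2, 3}, using the
surrogate as the objective function. The core is the standard elitist
nondominated-sorting GA: fast nondominated sort, crowding distance
(boundary members infinite, interior members the normalized cuboid
perimeter), binary tournament on (rank, crowding), simulated-binary
crossover (η = 15) and clipped Gaussian mutation for the continuous
genes, uniform inheritance and random-reset mutation for *D*. Published
settings: population 120, 1000 generations, crossover 0.90, mutation
0.10, Pareto front fraction 0.3.

Two memetic refinements are layered on top, both enabled by default and
switchable off in `MOOConfig`:

* **Lattice enumeration.** One surrogate evaluation costs microseconds,
  so the optimizer also sweeps a factorial lattice of the window at the
  natural reporting resolution (1 °C × 0.25 m/s × 1 % × 3 directions,
  ≈10⁴ points) and pools it with the GA's evaluation archive.
* **Pareto local search.** The pooled nondominated set is polished by
  coordinate probes (graded steps of 25 %, 5 % and 1 % of each range,
  bound snaps, and the two alternative directions), iterated until the
  pool stops changing or a round cap is hit.

The returned set is the nondominated subset of *everything evaluated
during the run*, capped at ⌈fraction · population⌉ members selected by
crowding distance. The refinements exist because many-objective NSGA-II
with a small population converges poorly: diversity-preserving truncation
retains interior points that a systematic sweep dominates, and this was
measured to persist even at 1500 generations. With refinement on, fronts
are verified internally nondominated and undominated by dense independent
sweeps of the same surrogate.

The front size cap is ⌈0.3 · 120⌉ = 36 at published settings; the actual
returned set may be smaller (only nondominated members are returned). No
knee-point or preference rule is applied — picking the single operating
point from the front is left to the user, and `summarize_pareto` supports
that choice by reporting per-response percent changes against a reference
group and the per-response extremes.

A note on printed Pareto tables: values rounded for reporting can make a
formally dominated pair (ties in two columns, strict differences
elsewhere). The shipped 30-row fixture has exactly one such pair, so
nondomination is *not* enforced when loading fixture tables; it is
enforced (exactly) on optimizer output.

## Synthetic study design

The real 192-run campaign is not publicly deposited, so the generator
emulates it: a deterministic surface with additive Gaussian noise over
the full factorial design T ∈ {40, 45, 50, 55}, V ∈ {1, 2, 3, 4},
MC ∈ {10, 15, 20, 25}, D ∈ {1, 2, 3}. Functional forms:

    DT  = A0 · (M0 − MC)^p / [(1 + aT(T−40)) (1 + aV(V−1))]
    SEC = (P0 + cT(T−40) + cV(V−1)) · DT / (60 · mass)
    HR  = h0 − hM(MC−10) + dir_HR
    WR  = HR · (w0 − wM(MC−10)/100 + dir_WR)
    SR  = clip(s0 − sM(MC−10) + sT·max(0, T−50) + dir_SR, 0, 100)

with M0 = 30.12 % (initial moisture of the fresh commodity) and the
defaults A0 = 9.81, p = 1.6, aT = 0.015, aV = 0.09, P0 = 1.7, cT = 0.01,
cV = 0.02, mass = 2 kg, h0 = 87, hM = 2.4, dir_HR = (+2, 0, −3),
w0 = 0.57, wM = 0.75, dir_WR = (+0.01, 0, −0.015), s0 = 86.5, sM = 1.5,
sT = 1.8, dir_SR = (−2, 0, +4). These constants are calibration choices
placing the grid extremes near the published optimization-result
magnitudes (DT ≈ 86–1200 min, SEC ≈ 1.3–17 MJ/kg, HR ≈ 48–89 %,
WR ≈ 21–52 %, SR ≈ 62–99.5 %); they are not measurements. The additive
power model for SEC cannot reach the lowest published SEC (≈0.8 MJ/kg)
at the fast-drying corner while keeping power increasing in temperature;
the shortfall (≈1.3 vs 0.8) is accepted rather than distorting the form.

The surface reproduces the qualitative findings: DT falls monotonically
in T, V and MC (moisture dominating, via the slow last drying stage);
SEC falls in V and MC; HR and WR fall in MC with sutural ≥ longitudinal ≥
vertical; SR falls in MC, gains above 50 °C (shell hardening), and is
highest under vertical loading. WR ≤ HR holds by construction.

Noise defaults are σ = (10 min, 0.2 MJ/kg, 1.5, 1.5, 2.0 points),
small relative to the signal spans. Noisy draws are clipped into the
valid response ranges (DT, SEC > 0; 0 ≤ WR ≤ HR ≤ 100; 0 ≤ SR ≤ 100),
never resampled, preserving seed determinism.

**What the synthetic study does not show.** Passing recovery tests on
this surface demonstrates that the pipeline can learn and optimize a
smooth, low-interaction response surface under modest noise — it says
nothing about the real process's interaction structure, replicate
variance, or measurement bias. One quantitative consequence worth
knowing: SR carries the least signal relative to its noise
(Var(true SR) ≈ 92 against σ² = 4 over the design), so even a perfect
model's hold-out R² for SR has an expected ceiling near 0.958, and on an
unlucky 38-run hold-out realization the ceiling itself can dip below
0.95 (the fixed-seed suite hits exactly such a realization: the
noise-free surface scores 0.947 there, and the trained surrogate 0.942,
within 0.006 of that ceiling). The other four responses sit comfortably
above 0.95.

## Seeding and reproducibility

Every stochastic component (noise draw, split, GA, optimizer, weight
initialization) takes an explicit seed; a pipeline run expands one global
seed into per-stage seeds through a fixed stage-index scheme
(`SeedSequence([global, stage_index])`), so stages re-run independently
and bit-identically. All randomness flows through NumPy `Generator`
objects; no global state is touched.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the pipeline at reduced
search budgets chosen as the package's standard quick-analysis setting:
GA 60×100 for surrogate initialization, optimizer 60×150 with refinement
on, 4000 BP epochs. The published-scale settings (GA 200×1000, optimizer
120×1000) are the config defaults and run in a few minutes.

## Known limitations

* The surrogate treats *D* ordinally (see above).
* The optimizer's refinement assumes objective evaluations are cheap; for
  an expensive simulator the lattice and local-search stages should be
  switched off.
* `evaluate` scores raw denormalized predictions without clipping to the
  physically valid ranges (the standard surrogate-evaluation convention;
  measured effect of clipping on the study scores is < 0.001 R²). Single
  condition predictions via `forward` do clip, because they construct a
  validated response object.
* No statistical significance machinery (replicate ANOVA etc.) is
  included; the factorial design here carries no replicates.
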