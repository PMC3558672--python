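# Methods

`ovisim` simulates the lifetime egg-laying pattern of a single *Drosophila*
female as the output of three coupled subsystems, then summarizes patterns
with a five-parameter piecewise skeleton and classifies each fly's
resource-allocation phenotype. This note states the model as implemented,
the numerical and design choices made where the formulation was open, and
what the package's checks do and do not establish.

## The model

### Energy budget

Time runs in whole days, `k = 1, 2, ...` from hatching (adult eclosion);
all bookkeeping is end-of-day. The energy reserve integrates intake minus
expenditure:

    E(k) = E0 + Σ_{i≤k} [P1(i) − P2(i)],      P2(k) = Ps + α·s(k)

where `Ps` is constant somatic upkeep, `α` the energy cost per egg and
`s(k)` the day's egg count. Intake senesces with cumulative metabolic
expenditure `D(k) = Σ P2` as a proxy for accrued oxidative damage:

    P1(k) = P1MAX · exp(−β1 · D(k−1)).

For small `β1` this yields the characteristic period of near-constancy
followed by quasi-exponential decline. Tying the decline to cumulative
*expenditure* (rather than to age) is a model choice: damage accrues with
metabolic work, so intense reproduction accelerates the fly's own aging.

**Senescence onset** `T` is the first day with strict `P2 > P1` (a tie does
not trigger it); once set it never moves. **Death** is the first day with
`E ≤ 0` at day's end; transient overdraft is not allowed. `E0 = 0` by
default; a positive value is accepted so that pathological configurations
(expenditure exceeding intake from day one) die on day 1 rather than at
hatching.

### Protein → yolk pipeline

Dietary protein arrives at `a` egg-equivalents/day (one unit = the protein
provisioning one egg) and pools as raw protein `x`. Each day an amount
`n(k)` is admitted to a processing system of capacity `L`; it matures into
yolk during the day and is handed to the ovarioles the next day
(`y(k) = n(k−1)`). Processing machinery remains occupied for two days per
admission, so the occupancy variable is

    x_y(k) = x_y(k−1) + n(k) − n(k−2)   (= n(k) + n(k−1)),

and admission is the largest value compatible with availability and the
capacity bound `x_y(k) ≤ N(k)`:

    n(k) = max(0, min(x(k−1) + a, N(k) − [x_y(k−1) − n(k−2)])).

The two-day occupancy is load-bearing: it caps steady throughput at `L/2`,
giving the plateau law `RC = min(L/2, a)`, and for `a > L/2` it drives
period-2 forced oscillations of the admission — which is exactly why the
package rejects `a > L/2` at validation rather than modelling that regime.

Capacity itself ages after senescence onset, with the same oxidative logic
but a larger vulnerability (`β2 > β1`: the protein system ages faster than
the energy system):

    N(k) = L,                                    k ≤ T or no onset yet
    N(k) = L · exp(−β2 · W(k)),   W(k) = Σ_{i=k−T}^{k−1} P2(i),   k > T,

the sum running over the trailing `T` days (days before hatching contribute
nothing). Note `W` is a *moving window*: when laying collapses and `P2`
falls, old high-expenditure days age out of the window and `N` partially
recovers. An emergent consequence is that senescent flies sustain a low
residual laying rate rather than dropping to strict zero — a low late-life
plateau superimposed on the exponential decline. The phenotype classifier's
trailing-mean rule is robust to this residual rate.

Mass accounting: the day-`k` emission `y(k) = n(k−1)` is handed to the
ovariole loader on day `k` while its machinery stays occupied until the end
of day `k`; `x_y` is therefore a capacity-occupancy variable, not a mass
store. The conserved identity, checked to 1e−9 at every day of every test
run, is

    x0 + a·k = x(k) + n(k) + buffer(k) + in_ovarioles(k) + laid(k).

### Ovariole bank

The fly carries `J` identical ovarioles, each holding at most `M`
simultaneously maturing oocytes. Emitted yolk accumulates in a ready
buffer; ovarioles are loaded in a fixed round-robin order whose cursor
persists across days (fair under scarcity), each receiving a portion of
`min(free space, ⌊buffer⌋)` whole eggs — abundant yolk fills ovarioles
completely with portions of exactly `M`. Every portion independently draws
an integer maturation time `ξ ~ Uniform{p+1, …, p+q}` and the *whole
portion* is laid on its due day. Laying precedes loading within a day, so
freed space is refilled immediately. Sub-egg remainders persist in the
buffer; no mass is created or destroyed.

This module is the model's only source of randomness (one seeded generator
per fly, consumed exclusively by the `ξ` draws) and it does not age: nothing
in it depends on `β1`, `β2` or absolute time beyond due dates. With `q = 1`
the simulated pattern is exactly deterministic; with `q ≥ 2` the tooth-like
day-to-day scatter of real oviposition records appears with nothing random
in the environment.

A structural consequence worth knowing: portions occupy their slots for `ξ`
days, so the bank's mean throughput cannot exceed `J·M / E[ξ]`. The plateau
law `RC = min(L/2, a)` therefore holds only when the bank is not the
bottleneck, i.e. `J·M ≥ a·E[ξ]`. The curated defaults (`J·M = 150` against
`a·E[ξ] = 125`) respect this; an undersized bank (e.g. `J·M = 100` at
`a = 50`, `q = 4`) caps the plateau near 40 eggs/day instead.

### Daily event order

Within day `k`: (1) capacity `N(k)`; (2) pipeline emits `y(k)` and admits
`n(k)`; (3) ripe portions are laid, giving `s(k)`; (4) the emitted yolk is
loaded into the freed space; (5) intake `P1(k)` is realized; (6) the energy
ledger is updated with the day's actual laying cost, possibly marking onset;
(7) record; stop on death (`LS = k`) or at `max_days` (run flagged censored,
never silently truncated). Laying before loading implements immediate
refilling; updating energy last makes the reproductive cost consistent with
the eggs actually laid.

## Pattern skeleton and phenotype call

The three-stage skeleton of a pattern is

    f(t) = 0            t < t0        (maturation)
    f(t) = RC           t0 ≤ t ≤ T    (adult plateau)
    f(t) = RC·e^{−(t−T)/τ}   T < t ≤ LS   (senescent tail),

fitted by least squares: `t0` = first day with a positive count, `LS` =
pattern length, exhaustive search of integer `T ∈ [t0, LS]` with, per
candidate, `RC` = plateau mean and `τ` from a bounded one-parameter
least-squares fit on the raw tail counts (τ ∈ [1e−3, 1e6]; coarse log-spaced
scan, 181 points, then bounded scalar refinement in the bracketing
interval). Ties in the residual break toward the smallest `T`. Fitting raw
counts rather than log-counts keeps zero days in the tail usable. A
constant pattern gets `T = LS` and a nominal `τ = 1` (no tail to estimate).
Least squares is this package's choice of fitting criterion; all-zero
patterns are a `NoReproductionError`.

Phenotypes compare the reproductive window with the life span. Reproduction
is deemed complete at `R_end = T + τ·ln(1/ε)`, where the fitted rate falls
to `ε·RC` (`ε = 0.05`; the notion of "completed reproduction" is narrative
in origin, the number is ours). The call is:

* **s** — trailing 3-day mean of `s` at death ≥ 0.5·RC: death mid-laying;
  cause = reproductive overload;
* **l** — `LS ≥ R_end + λ` with `λ = 5` days of post-reproductive survival;
  cause = senescence;
* **m** — otherwise; cause = senescence.

All four thresholds (ε, 0.5, 3 days, λ) are `ClassifierThresholds` fields,
logged with every call. The simulator also emits a raw ledger-based death
cause using the *predicted* plateau `min(L/2, a)` (it cannot see the fit);
the classifier's fit-based call is the authoritative one and the two agree
in practice because the fitted plateau tracks `a`.

## Curated defaults and what they emulate

No complete published parameter set exists for individual patterns, so the
package ships one configuration chosen once for biological plausibility and
kept fixed:

| parameter | value | rationale |
|---|---|---|
| `a` | 50 egg-eq/day | plateau near 50 eggs/day, typical of well-fed *D. melanogaster* |
| `L` | 120 egg-eq | `a ≤ L/2` with margin; processing, not diet, limits only overfed flies |
| `J`, `M` | 30, 5 | 30 ovarioles within the real 30–45 range; `J·M = 150 ≥ a·E[ξ] = 125` |
| `p`, `q` | 0, 4 | maturation 1–4 days |
| `Ps` | 40 /day | upkeep is the larger budget share; stopping laying saves 43% of plateau spend |
| `α` | 0.6 /egg | plateau expenditure `Ps + α·a = 70`/day |
| `β1` | 6e−4 | senescence onset in the third week of life at the mid P1MAX |
| `β2` | 2.4e−3 | = 4·β1; protein processing ages faster than the energy system |
| `E0`, `x0` | 0 | life starts with no reserves |
| `max_days` | 500 | censoring cap for no-aging runs |

Sweeping `P1MAX` through (82, 115, 165) — scarce, balanced, ample energy —
produces modal phenotypes s, m, l with mean life spans ≈ 26, 58, 99 days
and overload/senescence death causes in the expected pattern (20 seeds per
point). This regime separation, not any specific published trajectory, is
what the defaults are calibrated to reproduce.

What the generator does **not** emulate: environmental variability (diet,
temperature, density — all randomness is internal), mating and sperm
effects, within-day timing, ovariole aging or heterogeneity beyond `ξ`, and
egg retention/resorption. Passing tests therefore show internal consistency
of the mechanism and qualitative agreement with the s/m/l phenomenology;
they do not validate the model against any specific experimental animal.

## Numerical and degenerate-input choices

* All protein/energy quantities are real-valued; quantization to whole eggs
  happens only at ovariole loading, so the ledgers conserve exactly
  (verified to 1e−9 relative, via `math.fsum`/cumulative sums).
* Buffer floor: a portion is created only when ≥ 1 egg-equivalent is
  available; `⌊buffer⌋` is taken without an epsilon guard, so float drift
  can at worst delay one egg by one day, never create mass.
* `q = 1` makes `ξ` a constant; the run is then bit-deterministic even
  across RNG refactors (draws still occur, but the distribution is a point
  mass).
* Sterile configs (`a = 0`) run to energy exhaustion with an all-zero
  pattern; the fitter refuses them, the sweep labels them `degenerate`.
* `validate_config` reports *all* violations at once, naming parameters;
  `a > L/2` is a hard error, `β2 ≤ β1` a warning promotable to an error.

## Problem sizes used in the shipped checks

Conservation is stress-tested on 50 randomly drawn valid configurations
(≤ 300 days each); plateau and variance checks use single 250-day no-aging
runs; the maturation-time test uses 1e5 draws; fit recovery uses 20
noiseless parameter sets plus 200 Poisson-noise replicates of the reference
m-type skeleton (t0 = 3, T = 16, RC = 66, τ = 18, LS = 60); the regime
sweep uses 3 × 20 seeded flies. These sizes make the full suite run in well
under a minute while leaving the stochastic assertions comfortable margins.

## Known limitations

* The bank-throughput cap `J·M/E[ξ]` silently flattens the plateau below
  `min(L/2, a)` when the bank is undersized; the package warns through the
  methods here, not at runtime, since an undersized bank is a legitimate
  regime to study.
* The moving-window capacity law lets `N` partially recover after the
  laying collapse (see above); if a strictly monotone senescent decline is
  wanted, a cumulative-since-onset damage integral would be the variant to
  implement.
* Fitted `τ` is weakly identified when the tail is short or the pattern is
  censored mid-plateau; `rss` and the evidence dict should be consulted
  before interpreting it.
* One fly is simulated at a time; there is no shared environment, so cohort
  variance reflects only internal stochasticity.
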