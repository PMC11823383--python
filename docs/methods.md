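# Methods

## Log-probit concentration–response model

Each treatment arm is modelled as a graded concentration–response on the
classical probit scale. A well's effect fraction is
`e = clamp(1 − v/v_control, 0, 1)` from its viability reading `v` (% of
control), and for `e ∈ (0, 1)` the probit is `y = Φ⁻¹(e) + 5`, so the
median effect sits at `y = 5` exactly. The model is a straight line

    y = b·log10(d) + a,      d in µM,

fitted by **unweighted ordinary least squares on per-well points**. The
median inhibitory concentration and its uncertainty follow from the
fitted coefficients:

    IC50 = 10^((5 − a)/b)
    Var(log10 IC50) = (Var(a) + 2·g·Cov(a,b) + g²·Var(b)) / b²,  g = (5 − a)/b
    SEM(IC50) = ln(10) · IC50 · sqrt(Var(log10 IC50))

(first-order delta method). Design choices, in decreasing order of
consequence:

* **OLS, not iteratively weighted probit ML.** Published analyses of
  this kind report plain linear equations with R²; the unweighted fit
  reproduces them and is the package's default and baseline. The
  classical weighted alternative would change SEMs, not IC50s, at
  realistic noise (see *Calibration* below for the consequence).
* **Per-well fitting** (`aggregation="per_well"`), so `n_items` is the
  well count — the "number of items" that enters the downstream degrees
  of freedom. A `per_dose_mean` mode is available.
* **Saturated wells** (effect exactly 0 or 1) carry no probit
  information and are dropped by default; a winsorising policy
  (`saturation="clamp"`, bounds `1/(2m)` with `m` replicates per dose)
  is available. Dose-zero control wells never enter the fit.
* Base-10 logarithms throughout; an estimated non-positive slope is
  returned but flagged, and flagged fits are refused downstream.

## Parallelism and the additive prediction

Whether the two single-drug lines share a slope decides the geometry of
the additivity reference. The test is Welch-style on the slope
estimates,

    t = (b_A − b_B) / sqrt(se_A² + se_B²),

with Welch–Satterthwaite degrees of freedom using each line's residual
degrees of freedom (`n_items − 2`); `p > α` (default α = 0.05) is read
as parallel.

**Parallel case.** The additive total-dose expectation of a fixed-ratio
mixture contributing fraction `f` of drug A's IC50 (f = 0.5 for 1:1) is
the straight 50 % isobole value

    IC50_add = f·IC50_A + (1−f)·IC50_B,
    SEM_add  = sqrt((f·SEM_A)² + ((1−f)·SEM_B)²).

**Non-parallel case.** With unequal slopes the relative potency
`B-dose equivalent of a` = `10^((b_A·log10(a) + a_A − a_B)/b_B)` varies
with effect level, and Loewe additivity yields two curved 50 %-effect
isoboles instead of one line:

    (i)  dose_b + b_eq(dose_a) = IC50_B      ("B frame")
    (ii) dose_a + a_eq(dose_b) = IC50_A      ("A frame")

Both run from (IC50_A, 0) to (0, IC50_B). Each is intersected with the
fixed-ratio ray `(a, b) = T·(f·IC50_A, (1−f)·IC50_B)/IC50_add_straight`
by **bisection on log10 T** (xtol 1e-12; initial bracket
`[min(IC50_A, IC50_B)·1e-4, IC50_A + IC50_B]`, expanded by up to four
decades each way before failing with diagnostics). The smaller and
larger intersection totals are the lower and upper additive IC50. As
`b_A → b_B` both isoboles collapse onto the straight line and the bounds
coincide with the parallel formula (asserted to 1e-6 relative in the
tests). SEMs of the bounds use the same delta-method idea as the
parallel case: a central-difference gradient of each bound with respect
to the four line coefficients, combined with the block-diagonal
coefficient covariance of the two independent fits.

## Interaction classification

The mixture's fitted IC50 is compared with the additive reference by the
unpaired Welch t-test,

    t  = |IC50_mix − IC50_ref| / sqrt(SEM_mix² + SEM_ref²)
    df = (SEM_mix² + SEM_ref²)² / (SEM_mix⁴/(n_mix−1) + SEM_ref⁴/(n_ref−1)),

with fractional df allowed. For a non-parallel prediction the reference
is the bound **nearer** to the observed mixture IC50 (ties to the lower
bound) — an explicit rule chosen to match how such comparisons are
exhibited in practice; `n_ref` is the summed well count of the two
single-drug series. `p > α` → additive; otherwise the sign of the
difference gives synergy (mixture below the reference) or antagonism.
The published five-cell-line summary packaged with the module reproduces
its printed t and df values to print precision under exactly this
reading (the tabulated "±" values are standard errors, the n values are
well counts).

## Synthetic plates and what they do (not) show

The generator emulates a 96-well MTT-style screen:

* mean viability `100·(1 − Φ(slope·(log10 d − log10 IC50)))` with
  additive Gaussian noise on the **viability scale** (default sd 2 % of
  control), truncated to [0, 100] — plate-reader absorbance noise, which
  deliberately stresses the probit transform;
* default single-drug grids of six two-fold dilutions spanning 0.25×–8×
  the true IC50, 8 replicate wells per dose;
* fixed-ratio mixtures on the ray through `(f·A50, (1−f)·B50)`, total
  doses at the same six dilutions of the additive reference total; the
  generated effect at component doses (a, b) solves the Loewe
  dose-equivalence equation `a/A(E) + b/B(E) = λ` by bracketed
  root-finding (λ = 1 additive, λ < 1 synergy, λ > 1 antagonism). The
  mixture series inherits replicate count and noise level from drug A's
  truth.
* Reproducibility: a `(seed, stream_label)` pair seeds an independent
  NumPy generator per stream (label hashed into the seed sequence), so a
  whole study is reproducible from one integer while arms stay
  statistically independent.

Calibration simulations use one fixed scenario chosen once: drug A with
IC50 50 µM and probit slope 2.3 (a mid-potency inhibitor like EX527),
drug B with IC50 0.8 µM and the same slope, f = 0.5. Problem sizes are
500 replicate plates for recovery, 1000 pipeline runs for the type-I
rate and 500 for synergy power — enough for Monte-Carlo standard errors
of well under 0.01 on a rate.

What the simulator does **not** emulate: plate-position (edge) effects,
heteroscedastic or multiplicative absorbance error, pipetting serial
correlation across a dilution series, batch effects between plates, and
non-probit (e.g. biphasic) response shapes. Passing calibration here
therefore shows the statistical machinery is self-consistent under its
own model, not that real screens meet these assumptions.

## Calibration results and a known, deliberate conservatism

Under the default conditions the IC50 recovery bias is ≈ 0.002 in log10
units (well inside the 0.02 documented tolerance; truncation at the
dose-grid extremes contributes mild bias), and strong synergy (λ = 0.3)
is detected in ~100 % of runs. The classifier's **type-I error under
additive truth is ≈ 0.01, below the nominal α = 0.05**. This is a
structural property, not a bug: Gaussian noise on the viability scale is
heteroscedastic on the probit scale (variance `∝ 1/φ(Φ⁻¹(e))²`), so the
homoscedastic OLS formulas overstate the IC50's SEM (by ~25 % at the
default design) and understate the slope's SE. The Welch comparison
inherits the inflated SEMs and becomes conservative — it under-rejects
additivity, never over-rejects. The classical remedy is Finney-style
weighted probit ML, which is intentionally not the default (see the
first design choice above). For the same reason the parallelism test is
exactly calibrated under probit-scale noise (measured 0.047 at α = 0.05)
but slightly anticonservative under viability-scale noise.

## Signed pathway search

The causal network module treats a SIGNOR-style edge list
(`source<TAB>effect<TAB>target`, effects up/down/physical/unknown, glyph
aliases accepted, optional non-negative weight column) as a directed
multigraph; multi-edges carry distinct effects. Net path sign is the
product of edge signs with two conventions that matter: **unknown is
absorbing**, and **physical-interaction edges are sign-neutral** (they
pass the incoming sign through) — the latter is required for a
down-regulation upstream of a physical complex-membership edge to yield
a net negative path. Shortest paths are breadth-first over directed
edges with unit edge cost (user-supplied weights enable weighted
variants); simple-path enumeration is depth-capped (default 8, hard cap
12) and returns a deterministic (length, node-sequence, effect-sequence)
ordering. The packaged fixture network is the curated union of the
published SIRT1→tubulin and SIRT3→tubulin pathway strings; on it the
shortest SIRT1→Tubulin path has 4 edges, SIRT3→Tubulin has 7, and the
enumerated signs are 2 positive + 1 unknown (SIRT1) and 4 negative + 4
positive (SIRT3). External database distance scores are not reproduced
(they depend on proprietary edge weights).

## Degenerate inputs and numerical conventions

* Fewer than two distinct informative dose levels, or all-saturated
  arms: unfittable-dataset error naming the arm.
* Two-point fits have zero residual df; their SEs are reported as 0.
* Zero slope: degenerate-fit error on IC50 extraction.
* Equal slopes with zero slope variance: parallelism t = 0/p = 1 if
  identical, p = 0 with a degenerate-variance flag if not.
* Both SEMs zero in a Welch comparison: p = 1 if means equal, else p = 0
  flagged degenerate.
* Mixture dose levels whose Loewe equation has no effect solution in
  (0, 1) are skipped with a warning.
* Report formatting: concentrations to 4 significant figures, t/df/p to
  3 decimals.

## Limitations

* Re-analysis of published summaries can only be as internally
  consistent as the source table; the packaged summary therefore carries
  equations only for the cell lines whose printed equation → IC50
  pairings are self-consistent (see the JSON's `_notes`).
* The non-parallel lower/upper bounds depend on both drugs' line
  coefficients; when one drug's line comes from elsewhere (as for
  paclitaxel in the packaged summary), the bounds are taken from the
  table rather than recomputed.
* Type II analysis (effect levels other than 50 %), three-drug isoboles,
  Bliss independence and Hill/4PL fitting are out of scope.
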