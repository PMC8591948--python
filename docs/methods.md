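# Methods

## Vergence formulas

Both formulas are thin-lens Gaussian-optics chains from corneal power and
effective lens position (ELP) to spectacle-plane refraction, evaluated with
the published constants: aqueous/vitreous index 1.336, vertex distance
12 mm, keratometric radius `r = 337.5/K` mm.

**SRK/T.** The corrected axial length `LCOR` equals `L` up to 24.2 mm and
`−3.446 + 1.715·L − 0.0237·L²` beyond; corneal width
`Cw = −5.41 + 0.58412·LCOR + 0.098·K`; corneal height
`H = r − sqrt(r² − (Cw/2)²)`; the ELP is `H + 0.62467·A − 68.747 − 3.336`
for A-constant `A`; the optical axial length adds retinal thickness
`0.65696 − 0.02029·L`. The refraction at power `P` and the closed-form
emmetropia power follow from the two-surface vergence identity with the
SRK/T fictitious corneal index 1.333. When `(Cw/2)² > r²` (very long, very
steep eyes) the published convention clamps `H = r`; this package emits a
warning rather than an error because the published formula proceeds.

**Haigis.** ELP `d = a0 + a1·ACD + a2·L` (mm). Corneal power uses index
1.3315 on the same keratometric radius. In meters, the vergence needed at
the cornea is `z = n/(d + n/(n/(L−d) − P))` with `n = 1.336`; the
corneal-plane refraction `z − DC` is vertex-corrected by
`Rx = RC/(1 + 0.012·RC)`. The ELP that reproduces an observed refraction is
found by bracketed bisection on `d ∈ [0.5, L−0.5]` mm to 1e-10 mm; the
chain is monotone in `d` there, so the root is unique when the observed
value is attainable at all. A closed-form quadratic inversion exists but
the numeric route keeps one code path and is robust near the bracket ends.

## Constant optimization

The criterion is the standard personalization convention: zero mean signed
prediction error on the training cohort. For SRK/T the mean error is
monotone in `A`, so Brent root-finding on `[110, 126]` converges in a few
iterations; the result is accepted only if the residual mean error is below
1e-4 D. For Haigis, each eye's zero-error ELP is back-solved and
`(a0, a1, a2)` is the OLS fit of that ELP on `(1, ACD, L)` — Haigis's own
published procedure. OLS zeroes the mean *ELP* residual, not the mean
*refraction* residual; on noisy cohorts the residual mean refraction error
is small (|mean| < 0.05 D in tests) but not exactly zero. Eyes whose
observed refraction no ELP can reproduce (possible at extreme powers) are
skipped and counted. Default constants are never synthesized from an
A-constant heuristic; callers must supply them explicitly.

## SVR adaptation

Inputs are six features in fixed order: SRK/T predicted refraction at the
implanted power (computed with the cohort-optimized base A-constant), axial
length, mean keratometry, ACD, lens thickness, WTW. Central corneal
thickness and age are deliberately excluded. The regression target is the
observed postoperative spherical equivalent, so the trained model *is* a
predicted-refraction calculator (a residual-target parameterization would
be equivalent up to the ε-tube and is not offered).

Features are z-scored with training-cohort statistics — mandatory for an
RBF kernel mixing millimeter and diopter scales. Hyperparameters are chosen
by grid search, `C ∈ {0.1, 1, 10, 100}` × `γ ∈ {0.001, 0.01, 0.1, 1}` with
`ε = 0.1` D fixed (below the 0.25 D clinical resolution of refraction),
minimizing 5-fold cross-validated MSE. Folds are grouped by patient —
fellow eyes are strongly correlated, and splitting them across folds makes
CV optimistic — and fold assignment is a seeded permutation of patients
dealt round-robin, so training is deterministic under (data, seed). Ties in
CV loss resolve toward smaller C, then smaller γ (the least flexible
model). The winner is refit on the full training set.

Prediction is an explicit kernel expansion over the stored standardized
support vectors, `f(x) = Σ αᵢ·exp(−γ‖xᵢ−z‖²) + b`, both for the in-memory
model and after JSON (de)serialization, so a reloaded model reproduces
predictions bit for bit. Queries more than 6 training SDs from the training
mean in any feature return a value but emit an extrapolation warning. The
underlying solver (scikit-learn's SVR) is an exchangeable component; any
solver with ε-insensitive RBF-SVR semantics yields the same calculator
state up to optimizer tolerance.

## Outcome statistics

Error bands are inclusive (|PE| ≤ 0.25/0.50/1.00 D) and the hyperopic tail
strict (PE > +0.50 D), so the ±0.50 band and the tail partition the
hyperopic side cleanly. MedAE uses the mean-of-middle-two median; SD uses
n−1. Signed errors are compared with uncorrected one-way repeated-measures
ANOVA (eyes as subjects) plus Holm-adjusted paired t-tests; a pair with
numerically zero difference variance is reported as degenerate (p = 1 if
identical, p at the floating-point floor if constant-offset). Absolute
errors use the tie-corrected Friedman statistic (mid-ranks) with
Scheffé-type simultaneous pairwise comparisons on rank sums:
`(Rᵢ−Rⱼ)²/Var(Rᵢ−Rⱼ)` referred to χ²(k−1), where
`Var(Rᵢ−Rⱼ) = 2(A−C)/(k−1)` from the squared-rank sum `A` and its fully
tied floor `C`. Band proportions use Pearson chi-squared with per-cell
adjusted standardized residuals
`(O−E)/sqrt(E(1−row/N)(1−col/N))`, flagged at |r| > 1.96. Group
comparisons of demographics use Welch's unequal-variance t-test.

## Synthetic cohorts

The generator reproduces the statistical shape of a single-site cataract
cohort: per-parameter normal marginals truncated to the reference profile's
observed ranges (axial length 23.92 ± 1.54 mm, keratometry 44.35 ± 1.54 D,
ACD 3.15 ± 0.40 mm, lens thickness 4.63 ± 0.44 mm, CCT 518.4 ± 32.2 µm,
WTW 11.7 ± 0.4 mm, age 72.8 ± 8.7 y), correlated through a configurable
matrix whose defaults are literature-typical signs (L–ACD +0.4, L–K −0.3,
L–LT −0.3, ACD–LT −0.5) — assumptions, not estimates of any particular
dataset. Truncation is by resampling (≤100 attempts per eye), which keeps
marginals near-normal inside the ranges. About 38% of patients contribute
both eyes.

Outcomes follow a truth formula (SRK/T or Haigis with stated constants):
the implanted power is the half-diopter grid power closest to a −0.20 D
target (ties to the higher, more myopic power — the conventional
surgeon-side choice), and the observed refraction is the truth prediction
plus an optional linear biometry bias (e.g. 0.15 D per mm of WTW above
11.7), a per-patient shared effect (SD 0.2 D, inducing the inter-eye
correlation that patient-grouped CV exists for), and i.i.d. Gaussian noise
(SD 0.35 D). Everything is deterministic under the spec seed.

What the generator does **not** emulate: device-specific measurement error,
non-Gaussian outcome tails, pathological eyes (post-refractive-surgery,
staphyloma), or real nonlinear deviations between a population's optics and
any vergence formula. Passing tests therefore demonstrate that the pipeline
recovers known structure under its stated noise model — not clinical
accuracy on real eyes.

## Workflow and determinism

`run_study` chains simulate/load → eligibility filter (CDVA ≥ 0.8, i.e.
16/20; records without acuity pass with a logged warning) → patient split
(validation = one random eye each of N patients; fellow eyes go to training
by default to preserve the training-set arithmetic, or are dropped under
`strict_split` when leakage-aversion matters more) → constant optimization
→ SVR training → evaluation → report files. A single master seed feeds
named substreams (cohort, split, folds), and no output embeds wall-clock
time, so a rerun is byte-identical. Stage failures surface as
stage-specific nonzero exit codes in the CLI.

## Problem sizes and limitations

Study-scale checks use ~1,600-eye cohorts (1,160 patients, ~1,200 training
eyes, 400 validation eyes) — the package's chosen working size for
demonstrating constant recovery and adaptation. With outcome noise ~0.4 D
and a WTW bias of SD 0.06 D, the theoretically available MedAE improvement
from bias removal is only a few thousandths of a diopter, so MedAE
comparisons between SRK/T and the adapted method at n = 400 hover at the
edge of sampling noise; the error-vs-WTW R², by contrast, separates the
methods decisively. On real cohorts the learnable structure is larger (a
population's optics deviate nonlinearly from any formula), which is where
the adaptation earns its keep.

Out of scope: proprietary formulas (Barrett Universal II, Hill-RBF, Kane,
Pearl-DGS), toric/astigmatism planning, post-refractive-surgery eyes, and
biometer-native file formats.
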