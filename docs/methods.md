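# Methods

## Model

A project in country j is a stream of per-period incremental effects over
t = 1..T: health Δh_t (QALYs gained or DALYs averted, sign-equivalent,
improvement positive), health-care costs Δc_ht and consumption costs Δc_ct
(real currency; negative Δc_ct is a consumption benefit). Effects accrue at
the end of each period and are valued at decision time with factor
(1+r)^(−t); t = 1 is the first period after the decision. The package does
not model sub-annual periods, currency conversion, equity weighting, or the
econometric estimation of any parameter.

Three parameter paths convert between numeraires. k_ht (> 0) is the health
opportunity-cost threshold: the marginal cost per unit of health in the
health-care system, so Δc_ht/k_ht is the health displaced by the project's
budget impact. k_ct (≥ 0) is the consumption/net-production opportunity cost
per unit of health-care expenditure. V_ht (> 0) is the consumption value of
a unit of health. The per-period identities (see README) compose these into
net health, equivalent-resource and equivalent-consumption effects. Both
consumption representations of health-care costs — the consumption value of
displaced health V_ht·(Δc_ht/k_ht) and the net-production loss k_ct·Δc_ht —
are carried as separate columns of the extensive table and never substituted
for one another; the equivalent-consumption net effect deliberately counts
health-care costs through both channels (forgone health valued at V, and
forgone production at k_c), as the accounting composes them.

Parameter paths are anchored at period 1: a base value b with growth g
expands to b·(1+g)^(t−1), so the period-1 value equals the stated base.
V_ht grows at (income elasticity of demand for health) × g_c; k_ct grows at
g_c unless overridden. A single g_c feeds the Ramsey rate, V_h growth and
k_c growth, so revising growth expectations revises every dependent
parameter consistently.

## Discounting

Consumption effects are discounted at the Ramsey rate r_c = δ + η·g_c
(pure time preference plus a wealth/inequality-aversion effect). Health
effects at r_h anchored on the principal's real borrowing/saving rate r_s
net of threshold growth; resource effects at r_s itself. Dual rates
(r_h + gk_h for ICER costs; r_c − gV_h and r_c − gV_h + gk_h for
consumption-side reporting) embed parameter growth in the rate instead of
the stream; they are provided for familiarity and reported only alongside
the extensive tables.

Two compounding conventions are first class. `approx_subtractive`
reproduces the textbook arithmetic (r_h = r_s − gk_h, etc.).
`exact_multiplicative` — the default — composes gross rates
((1+r_h) = (1+r_s)/(1+gk_h)), which turns the cross-numeraire relations
into exact identities: discounting k_ht·Δh_t at r_s equals
(k_h1/(1+gk_h)) times discounting Δh_t at r_h, and the consumption-,
health- and resource-numeraire present values at their matched dual rates
are proportional by positive constants, so their adopt/reject signs always
coincide. Reports state the convention in use.

**ICER alignment.** Because paths are anchored at period 1, a flat scalar
dual cost rate (1+r_h)(1+gk_h)−1 applied as (1+r)^(−t) would carry a
spurious constant factor (1+gk_h) relative to the path algebra. The ICER
therefore discounts costs with a schedule whose growth adjustment enters
with exponent t−1 (first forward rate r_h, thereafter (1+r_h)(1+gk_h)−1),
making "ICER < k_h1" coincide exactly with a positive discounted net health
benefit whenever the discounted health effect is positive. When it is zero
the ICER is refused as undefined; in the dominant/dominated quadrants the
ratio is labelled by quadrant rather than read as a price. Verdicts use the
exact sign of present values with no tolerance band; rounding is the
caller's decision.

**Scope of perspectives.** The health-family rates (r_s, r_h) and the
consumption-family rate (r_c) are independent inputs reflecting two
normative stances (opportunity cost of public finance vs Ramsey welfare
discounting). Within each family the decisions provably coincide; across
families they need not, and the package does not force them to — a project
can pass a net-health test at r_h and fail a consumption-NPV test at r_c.
This is a feature of the framework, not a numerical defect.

**Declining term structure.** A growth-scenario set {(g_i, p_i)} implies
Ramsey rates r_i and a certainty-equivalent factor F(t) = Σ p_i (1+r_i)^(−t)
(evaluated in log space for long horizons), with annualised term rate
R(t) = F(t)^(−1/t) − 1. R(t) is non-increasing, starts below the
probability-weighted mean rate (Jensen) and converges to the minimum
scenario rate like ln(1/p_min)/t, so convergence checks at finite horizons
are only informative for scenario sets whose probabilities are
non-negligible and whose rates are well separated; the tests use sets with
probabilities ≥ 0.27 and rate gaps ≥ 0.04. A constant rate built from point
growth over more than 30 periods triggers a logged advisory recommending
scenario-based declining rates; behaviour never changes silently.

**Risk.** A per-period catastrophic hazard p_cat (events with no recovery;
a warning is emitted above 0.1%) thins every discount factor by
(1−p_cat)^t. It is applied to whichever schedule it is attached to — in
`npv_country`, the consumption schedule. An additive premium (signed) on
all forward rates represents project risk: positive for procyclical
payoffs, negative for countercyclical ones. Hazard and premium do not
commute; `npv_country` applies hazard first, then premium. No CAPM-style
beta estimation is attempted; the premium is user supplied.

**Pure time preference.** δ defaults to 0 — a normative stance commonly
taken for social choices with intergenerational effects — but is a free
input (0–1% is a conventional range), not a decided question.

## Defaults

The `conservative` profile sets k_c = 1 (one unit of health-care spending
displaces one unit of net production), income elasticity of demand for
health 1 (V_h grows at g_c), η = 1 (r_c = g_c), δ = 0, p_cat = 0. The
`alternative` profile raises the elasticity to 1.5 and η to 2 (r_c = 2g_c).
Every default filled into a loaded context is logged at INFO and echoed in
reports, so each number is traceable to user input or a named default.
Configuration precedence is CLI flag > context file > profile.

## Synthetic data

`fixtures.make_project` draws seeded toy projects with magnitudes chosen to
resemble appraisals in low- and middle-income settings: health effects
uniform on (−10, 20) QALYs, health-care costs on (−5,000, 20,000) and
consumption costs on (−2,000, 5,000) currency units per period, thresholds
k_h1 on (200, 5,000) (cost per DALY averted at or below typical income per
head), V_h1/k_h1 on (1, 4) (demand-side values above supply-side
thresholds), g_c on (0, 5%), gk_h on (0, 4%), r_s on (1%, 6%), η ∈ {1, 2},
elasticity ∈ {1, 1.5}, δ = 0, k_c = 1. Horizons are short (default T = 5;
randomised tests use T ≤ 10), matching the package's validation scope.
The generator emulates magnitudes and growth structure only: streams are
serially independent, parameter paths are exactly geometric, and there is
no parameter uncertainty, correlation between countries, or measurement
error — so passing tests demonstrate the accounting and discounting
algebra, not robustness to real-data estimation problems.

`fixtures.generate_fixture` writes streams CSV, contexts YAML and an
expected-results JSON computed by `oracle_npv`, a deliberately naive
per-term Python loop over the accounting identities that shares no
arithmetic with the vectorised library path; fixture output is
byte-identical under a fixed seed.

## Numerical choices

- Validation collects all violations before raising, naming series and
  1-based period.
- k_h = 0 is an error, not infinity: opportunity cost must be finite.
- A zero k_c base is legal and stays zero under growth.
- Scenario probabilities must sum to 1 within 1e−9.
- CSV readers use round-trip float parsing so render → parse reproduces
  tables exactly; files are UTF-8, comma-separated, `.` decimal, header
  required.
- Currency is a label only; global aggregation refuses to sum NPVs across
  different labels rather than convert.

## Limitations

Parameter estimation (k_ht from expenditure/outcome data, V_ht from stated
or revealed preference) is out of scope; the package starts from supplied
values. Risk handling is reduced-form (hazard + additive premium). The
declining schedule assumes growth uncertainty resolves as a one-shot
scenario draw held for the whole horizon, the standard
certainty-equivalent construction; serially correlated growth shocks would
flatten the decline. Equity weighting across beneficiaries or countries is
not provided: the global NPV is an unweighted sum.
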