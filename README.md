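# healthnpv

Multi-numeraire appraisal of health-related projects over time.

Decision makers appraising health projects — a health technology, a public
health programme, a supranational investment with effects in many countries —
face time streams of three kinds of effect: incremental health benefits
(Δh_t, QALYs gained or DALYs averted), incremental health-care costs (Δc_ht)
and incremental consumption costs (Δc_ct). Folding expectations about how
thresholds and values evolve into a single discount rate makes analyses
opaque; `healthnpv` instead makes each conversion explicit and discounts
each numeraire at its matched rate.

## The accounting

Three country-specific parameter paths do the conversions:

- **k_ht** — the health opportunity-cost threshold (cost per QALY/DALY at the
  margin of the health-care budget): Δc_ht/k_ht is health forgone elsewhere,
  k_ht·Δh_t is the resource-equivalent of health gained;
- **k_ct** — consumption (net production) forgone per unit of health-care
  expenditure;
- **V_ht** — the consumption value of a unit of health (demand-side
  willingness to pay), typically above k_ht.

Per period, the project's net effect in each numeraire is

    net health benefit      NHB_t  = Δh_t − Δc_ht/k_ht
    net consumption cost    NCC_t  = Δc_ct + k_ct·Δc_ht
    equivalent consumption  EC_t   = V_ht·NHB_t − NCC_t
    equivalent health       EH_t   = NHB_t − NCC_t/V_ht
    equivalent resources    ER_t   = k_ht·EH_t

Each stream is discounted at its matched rate: equivalent consumption at the
Ramsey rate r_c = δ + η·g_c; health at r_h = r_s − gk_h (r_s the principal's
real borrowing/saving rate, gk_h threshold growth); resources at r_s. Under
the default exact multiplicative convention ((1+r_h) = (1+r_s)/(1+gk_h)) the
three representations are proportional by positive constants, so they always
agree on adopt vs reject. Dual-discounted ICERs (costs at a rate embedding
threshold growth, compared against the period-1 threshold k_h1) are
reproduced for familiarity, but the extensive period-by-period accounting is
the primary output.

A country's NPV is Σ_t EC_t/(1+r_c)^t with everything country specific; a
multi-country project's **global NPV is the sum of country-specific NPVs**,
never a common-rate discounting of pooled effects. Growth-scenario sets
{(g_i, p_i)} produce a declining certainty-equivalent term structure; a
per-period hazard of unrecoverable catastrophe (≤ 0.1%) and an additive
project risk premium (signed; negative for countercyclical payoffs) can be
layered on.

## Worked example

A single-period project gains 10 QALYs for 5,000 in health-care costs and
200 in consumption costs, in a country with k_h = 1000, k_c = 1,
V_h = 3000, g_c = 3% (η = 1, δ = 0 ⇒ r_c = 3%) and r_s = 5%:

```python
from healthnpv import (CountryContext, DiscountSpec, EffectStream, GrowthSpec,
                       ParameterPath, npv_country)

stream = EffectStream("A", delta_h=[10.0], delta_c_h=[5000.0], delta_c_c=[200.0])
params = ParameterPath(k_h=[1000.0], k_c=[1.0], V_h=[3000.0])
context = CountryContext(
    "A", params,
    DiscountSpec(delta=0.0, eta=1.0, growth=0.03, r_s=0.05),
    GrowthSpec(g_c=0.03),
)
result = npv_country(stream, context)
print("NPV:", result.npv)
print("verdict:", result.verdict.value)
print("ICER:", result.icer.value, "vs k_h1 =", result.icer.threshold)
print("net health PV:", result.pv_net_health)
```

prints

```
NPV: 9514.563106796117
verdict: adopt
ICER: 499.99999999999994 vs k_h1 = 1000.0
net health PV: 4.761904761904762
```

Reading the numbers: the 5,000 health-care cost displaces 5 QALYs elsewhere
(5000/1000), leaving a net health benefit of 5 QALYs worth 15,000 in
consumption (V_h = 3000); net consumption costs are 5,200 (200 direct plus
5,000 forgone net production at k_c = 1); the equivalent consumption effect
is 9,800, worth 9,514.56 at decision time when discounted one period at
r_c = 3%. The ICER of 500 per QALY sits below the 1,000 threshold — the
same adopt verdict the net health benefit of 4.76 discounted QALYs gives.
`render_extensive_report(result, format="text")` prints the full
period-by-period accounting behind these numbers.

The same analysis runs from files via the CLI:

```
appraise fixtures --seed 42 --countries 3 --horizon 5 --out fx/
appraise evaluate --streams fx/streams.csv --contexts fx/contexts.yaml --out results/
appraise rates --context fx/contexts.yaml --horizon 50
```

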