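# mecsd — performance dynamics of medical–elderly-care integrated institutions

`mecsd` simulates how the performance of a Chinese medical–elderly-care
integrated institution (an elderly-care home that also provides medical,
rehabilitation and health-management services, typically through a
cooperation contract with a medical institution) evolves over its first
ten years, and how sensitive that performance is to the three levers a
manager or policy-maker controls: **element input** (staff and
facilities), **service level** (content and quality of the integrated
services) and **policy support** (government subsidies, quality norms,
talent supply).

It is written for health-systems and policy researchers who want a
tested, scriptable system-dynamics (SD) pipeline instead of a GUI
modelling tool: a small simulation kernel with Vensim-compatible
function semantics, a fully parameterised institutional model on top of
it, the scenario/sensitivity protocol, a behavioural calibration
procedure, and Monte Carlo robustness utilities.

## The model

Institutional performance `P` is a stock on a monthly clock,

```
P(t+1) = P(t) + [ I(t) + O(t) + S(t) ],        P(0) = 1
```

where the monthly increment has three subsystems (all variables
dimensionless, exogenous levels in [0, 1]):

* **Institutional input** `I = 0.1·ISR + 0.5·Element_input + 0.2·Capital`,
  with information-system resources gated by an Internet-usage lookup,
  capital composed of operating investment (base 0.5, plus 10% of
  profitability from month 36 via `STEP`) and annual one-month subsidy
  pulses `Policy_support · PULSE_TRAIN(12, 1, 12, 120)`.
* **Service output** `O = 0.8·(capability + level + sustainability)`,
  with `capability = content · quality`,
  `quality = SMOOTH(Policy_support, 60, 0.1) · maturity(t)` (quality
  norms take five years to bite; institutional maturity is an S-shaped
  running-in curve), and
  `sustainability = (recognition + financial status) / staff turnover`.
* **Institutional satisfaction**
  `S = 0.35·recognition + 0.65·personnel satisfaction`, where elderly
  satisfaction equals `level / complaint rate` with
  `complaint rate = 1/quality`, and family satisfaction follows the
  elderly with a two-month first-order delay (`DELAY1`).

A reinforcing loop closes the system: higher increments raise
profitability, which funds the next round of operating investment.
Constants not fixed by the design carry provenance `ASSUMED` with
declared bounds and are set by `mecsd.calibration`, which minimises
residuals against the documented reference behaviour (flat increment in
years 1–2, fastest growth in years 3–8, plateau after year 8 at an
annual increment of about 5.5, sensitivity orderings, emergence
targets).  See `docs/methods.md` for every closure decision.

## Worked example

```
$ mecsd report --out-dir out
     scenario  performance_120  improvement_rate_120_pct
     baseline        43.472349                  0.000000
           E3        53.536861                 23.151524
           S3        60.118972                 38.292438
           P3        60.540663                 39.262461
comprehensive       104.329853                139.991292
      extreme        15.047326                -65.386445
emergence gap(120) = 39.28 percentage points
```

Reading the table: after 120 months the baseline institution has
accumulated a performance level of 43.5 (its annual performance
increment has plateaued at about 5.6).  Raising element input by 60%
(scenario E3) lifts endpoint performance by 23%; raising service level
(S3) by 38%; raising policy support (P3) by 39% — policy is the
strongest single lever, and its effect arrives late because quality
norms and talent supply act through a 60-month smoothing.  Raising all
three levers together yields a 140% improvement, far more than the 101%
sum of the single-factor effects: the 39-point emergence gap is the
system's "whole greater than the sum of its parts" behaviour, produced
by the multiplicative couplings (content × quality, level × quality,
staff × professionalism).  Under extreme conditions (all levers cut to
10%) performance stays 65% below baseline throughout.

Other entry points: `mecsd run | extreme | sensitivity --factor
{element,service,policy} | comprehensive | calibrate | envelope`, each
writing trajectory/rate CSVs and a reproducibility manifest.  The same
functionality is available as a library (`mecsd.run_baseline`,
`mecsd.run_single_factor`, `mecsd.calibrate`, ...).

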