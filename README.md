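# surgesim

Agent-based simulation of surgical care-seeking in coastal Guinea, built to
answer a design question for conditional cash-transfer programs: **how large
does a cash transfer have to be before patients stop skipping scheduled
surgery, and is there any point in paying more?**

Surgical care in low-income settings is nominally available but widely
forgone — "no-show" rates near 30% are reported even where surgery itself is
free, because transport, food, lodging and fees still fall on the patient.
`surgesim` simulates a population of 100,000 agents on a 60 km × 60 km plane
centred on the Conakry region choosing among nine surveyed hospitals (or
staying home) and traces the no-show rate as a function of the transfer size
*t*, from 0 to 1,000,000 Guinean francs (GNF) in 10,000 GNF steps.

## The model

Each agent *i* evaluates every alternative *j* in their choice set — the
hospitals offering the procedure they need, plus the stay-home option — by a
random-utility rule:

```
V_ij = γ_i Q_j − δ_i D_ij + λ_i c(Y_i, P_j, t)          (hospitals)
V_i,home = α_home,i + λ_i c(Y_i, 0, t)                  (stay home)
```

* `Q_j ∈ [0, 1]` — hospital quality: eleven staffing/OR/case-volume survey
  domains, each standardized against the best-performing hospital, averaged.
* `D_ij` — planar distance in km.
* `c(Y, P, t) = min(Y − P + t, Y) / Y` — perceived affordability: the share
  of monthly income `Y` left after paying price `P` net of the transfer
  `t`, capped at 1 once the transfer covers the price.
* `γ, δ, λ, α_home` — preference weights, drawn per agent from normal
  distributions.

Choice follows the multinomial logit implied by i.i.d. Gumbel utility noise
(McFadden), so agent *i* picks alternative *k* with probability
`exp(V_ik) / Σ_j exp(V_ij)`. The primary outcome is the **no-show rate**:
the fraction of agents choosing home.

The two free weight means (`α_home`, `λ`) are calibrated so the simulation
reproduces two published anchors: a 56.6% no-show rate with no transfer and
30.0% at a 280,000 GNF transfer. Everything else is fixed by the survey
table (prices, quality) and the demographic marginals (gender, education,
wealth quintiles, age bands, and a quantized log-normal income distribution
with median 554,986 GNF and IQR 341,936–842,990 GNF).

Because the affordability term is capped, utilities stop changing once *t*
reaches the most expensive procedure on offer (600,000 GNF): the
dose-response curve declines monotonically up to that dose and is exactly
flat beyond it — the model's central result is that the only optimum is
"pay for everything".

## Worked example

```python
from dataclasses import replace
import surgesim as ss

sim = ss.load_config()                      # packaged calibrated defaults
s0   = ss.run_batch(sim.at_dose(0.0))       # 50 runs x 20,000 agents
s280 = ss.run_batch(sim.at_dose(280_000.0))
print(f"t=0      no-show {100*s0.mean_no_show:.1f}% "
      f"(95% UI {100*s0.ui_low:.1f}-{100*s0.ui_high:.1f}%)")
print(f"t=280k   no-show {100*s280.mean_no_show:.1f}% "
      f"(95% UI {100*s280.ui_low:.1f}-{100*s280.ui_high:.1f}%)")

sweep = ss.dose_sweep(replace(sim, n_runs=10, batch_size=5000))
p = ss.detect_plateau(sweep)
print(f"plateau  {p.dose:,.0f} GNF at no-show {100*p.rate:.1f}%")
```

prints

```
t=0      no-show 56.6% (95% UI 56.0-57.2%)
t=280k   no-show 30.0% (95% UI 29.4-30.7%)
plateau  600,000 GNF at no-show 16.8%
```

With no transfer, 56.6% of agents needing surgery stay home; a 280,000 GNF
transfer (roughly the mean surveyed cost of surgery) cuts that to 30%; the
curve keeps improving until the transfer matches the highest surveyed price
(600,000 GNF ≈ 67 USD) and then freezes at ~17% — the residual no-shows are
driven by distance and quality, which money does not fix.

The same pipeline is available from the shell:

```bash
surgesim report                      # survey cost summary + quality scores
surgesim generate --n 100000 --seed 1
surgesim calibrate --seed 1
surgesim sweep --plot
surgesim subgroups --dose 280000
```

Every command writes a `manifest.json` (config hash, seed, package version,
output inventory) next to its outputs.

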