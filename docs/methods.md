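# Methods

## Model overview

`surgesim` is an agent-based discrete-choice model of surgical
care-seeking. Two entity types exist: **agents** (people needing one of
four index procedures: laparotomy, cesarean section, goiter removal,
mandibulectomy) and **hospitals** (the nine surveyed coastal facilities).
Each agent makes a single decision — where to seek surgery, or to forgo it
— under a random-utility rule; no learning, interaction between agents, or
capacity constraints are modelled, and utilization is unconstrained on the
supply side.

The deterministic utility of hospital *j* for agent *i* is
`γ_i Q_j − δ_i D_ij + λ_i c(Y_i, P_j, t)`; the stay-home alternative has
quality, distance and price all zero plus an agent-specific offset
`α_home,i`. Terms constant across alternatives for a given agent (a global
intercept and demographic main effects) cancel in the logit ratio and are
omitted from computation; the offset `α_home` absorbs their net effect on
the care/home margin and is the natural calibration lever. The stochastic
utility component is i.i.d. Gumbel and is realized implicitly by using the
multinomial-logit choice probabilities (softmax over deterministic
utilities) rather than by adding explicit noise — the two are
mathematically equivalent.

### The money term

The affordability function is the capped net-income share

    c(Y, P, t) = min(Y − P + t, Y) / Y.

It equals 1 whenever the transfer covers the price (and always at home),
increases strictly in `t` below that, and can go negative when the
uncovered price exceeds a month's income. The cap is a substantive
modelling choice: once `t` exceeds every price in the facility table
(600,000 GNF), all utilities become invariant in `t`, which makes the
dose-response curve flatten *exactly* at the most expensive procedure —
the mechanism behind the "pay-for-everything" optimum. A
`log_consumption` variant (`log` of residual consumption normalized by
`log` income, same cap) is available through the `money_form` config
switch for sensitivity analysis. No mechanism in this utility produces a
*rise* in no-show above the cap; a slow rise reported in some accounts of
very large transfers is deliberately not engineered in.

## Synthetic population

The generator emulates the study population from printed marginals, not
from microdata:

* **Categoricals** — gender (P(male) = 0.5), education
  (none/primary/secondary = 0.53422/0.16642/0.29936), wealth quintiles
  (≈0.2 each), age bands 5–14/15–21/22–49/50+ =
  0.33261/0.08264/0.17547/0.40928. Attributes are sampled independently;
  no joint distribution is published, so independence is the minimal
  assumption, with two deliberate exceptions below. The age distribution
  is reproduced as printed (including 40.9% aged 50+) rather than
  reconciled against national age pyramids, because the model validates
  against its own survey table.
* **Income | wealth** — monthly income is log-normal, fitted to the
  printed median (554,986 GNF; pins μ exactly) and IQR (341,936–842,990
  GNF; σ = ln(q75/q25)/(2·z0.75) ≈ 0.669, the least-squares fit to both
  quartiles in log space). A two-parameter family cannot match median and
  both quartiles simultaneously; the residual quartile error is ≈3.4%.
  The distribution is "quantized" by partitioning at its own
  20/40/60/80% quantiles; quintile *q* draws from band *q* by inverse-CDF
  sampling restricted to ((q−1)/5, q/5), so band membership is exact by
  construction and pooling equally weighted quintiles recovers the full
  distribution. Income is interpreted as **monthly** household income
  (the external benchmark it is compared against is a monthly figure).
* **Procedure | gender × age** — uniform over the four procedures, with
  cesarean draws reassigned uniformly to the other three for anyone who
  is not a woman in the 15–21 or 22–49 bands. Uniform keeps the 600,000
  GNF maximum price binding for a quarter of agents, which the plateau
  location depends on. This is the one channel through which demographics
  affect outcomes (cesareans are mostly free in the survey).
* **Space** — a 60 km × 60 km plane. Positions come from a two-component
  mixture: weight 0.65 on a dense cluster (independent per-axis truncated
  normals, centre (10, 12) km, σ = 6 km) representing the capital's
  coastal peninsula, and 0.35 uniform background. Only the qualitative
  density gradient matters to the distance terms; the parameters are
  config-exposed. Hospital positions are fixed synthetic coordinates
  shipped with the package (six of nine within the cluster's 2σ radius),
  since real facility GPS positions are not published.

What the generator does **not** emulate: household/family structure,
spatial correlation of wealth and income (assigned at random, as the
source model also did), road-network travel (distance is Euclidean on the
plane), regional price variation beyond the surveyed table, and any joint
demographic structure beyond the two conditionals above. Tests passing on
this population therefore validate the *mechanism*, not forecasts for any
real district.

## Facility model

The survey table distinguishes three states per cell: a value (0 is a
valid, free price), "—" (unknown — the respondent could not report it) and
"NA" (the hospital does not offer the procedure). Unknowns are imputed
with the arithmetic mean of the column's known entries; "NA" is
structural, never imputed, and removes the hospital from that procedure's
choice sets. One reported inconsistency — a hospital reporting 40 cases
but 0 operating rooms — is kept as reported (0 is a value, not a gap).
Price summary statistics are computed over *known* entries only, before
imputation. Quality `Q_j` is the unweighted mean over the eleven
staffing/OR/volume domains of `x_jd / max_j x_jd` (imputed values
included; prices excluded, since price enters the utility separately); it
is invariant to rescaling any domain and a domain whose maximum is 0 is
dropped with a warning.

## Simulation engine

Each run draws a fresh batch of 20,000 agents and their preference
weights, computes the (up to 10-alternative) choice sets and logit
probabilities, and samples one choice per agent. Per-run integer seeds
are derived from the master seed via `numpy.random.SeedSequence`, so any
summary is bit-reproducible from (config, master seed). Default batch
count is 50 runs — enough for the across-run 95% uncertainty interval
(UI) to stabilize at the scale of the published bands; the full-scale
10,000-run protocol is a config change. UIs are empirical
2.5th/97.5th percentiles **across runs** (not across agents), with the
linear-interpolation quantile definition (numpy's default). Each run also
records the *expected* no-show rate — the mean stay-home probability —
which has the same estimand with the final categorical draw integrated
out.

## Calibration

Free parameters: the means of `α_home` and `λ` (two anchors, two degrees
of freedom). The quality and distance weight means are fixed at
γ = (1.5, 0.3) and δ = (0.06, 0.015) per km — values chosen once so that
both terms measurably shift hospital market shares over the 0–85 km
distances and 0.05–0.89 quality range the geometry produces. SDs of the
drawn weights are set to roughly 20% of each mean (the λ SD tracks its
fitted mean; the α_home SD is fixed at 0.3), giving agent heterogeneity
without sign-flipping more than a few percent of draws.

The objective is the summed squared gap between anchor targets and the
**expected** no-show rate averaged over a fixed block of 5 seeds × 20,000
agents (common random numbers), which makes the objective a smooth,
deterministic function of the parameters. A 5 × 5 coarse grid scan picks
the Nelder–Mead starting point; convergence requires every anchor
reproduced within ±1.5 percentage points (the packaged fit lands within
0.01 pp). With the packaged configuration the fit is
`α_home = −0.405`, `λ = 2.752`; these are stored in the default config
and regenerate with `surgesim calibrate`.

## Dose sweep and plateau detection

The sweep covers 0 to 1,000,000 GNF in 10,000 GNF increments (101 doses).
Every dose reuses the same master seed (common random numbers), and the
default sweep statistic is the expected rate, so the per-dose means are
deterministic in the dose and the Monte-Carlo budget can be small (10
runs × 5,000 agents by default). Under the capped money term, doses at or
beyond the maximum facility price yield bit-identical utilities and hence
bit-identical summaries.

`detect_plateau` returns the smallest grid dose after which every
adjacent change in the mean is below ε in absolute value, requiring the
plateau to span at least two grid points and returning a `None` sentinel
otherwise. The default ε = 1e−9 is a numerical-zero test, appropriate
because the deterministic sweep is *exactly* flat beyond the cap and
changes by ~1e−4 per step just below it; sampled-statistic curves need an
ε commensurate with their Monte-Carlo noise instead.

## Subgroup analysis

Per-run no-show rates are tracked by gender, education, age band and
wealth quintile; the overall rate always equals the stratum-size-weighted
mean over any complete partition. For each stratum variable the first
level is the reference; the table reports each level's across-run mean
and 95% UI plus the run-by-run difference from the reference with its own
interval. A difference is **flagged significant when the two strata's 95%
UIs are disjoint** — the convention consistent with how every other
quantity here is reported (percentile intervals across runs). This is a
conservative rule; the cesarean channel does create real few-tenths-of-a-
percentage-point gender and fertile-age gaps at intermediate doses, and a
looser rule (difference interval excluding zero) can flag them. The
conservative rule is the package default and is what the shipped tests
pin down; a genuinely disadvantaged stratum (e.g. incomes 10× lower)
separates cleanly under either rule.

## Numerical choices

* Softmax is computed with per-row max-shift; unavailable alternatives
  carry −∞ utility and exactly zero probability.
* Categorical sampling is inverse-CDF against the row cumulative sum.
* The income inverse-CDF uses `scipy.special.ndtri`; uniform variates are
  clipped to (1e−12, 1−1e−12) so incomes stay finite and positive.
* Printed-style cost integers follow the source report's own (mixed)
  conventions: the cesarean mean truncates toward zero, other means round
  to nearest.
* Degenerate inputs: an agent whose procedure no hospital offers faces
  {home} only and is a forced no-show; a zero-SD weight model is valid
  (point-mass weights); a cluster with σ = 0 collapses to its centre.

## Problem sizes

Default desk-scale sizes — 50 runs × 20,000 agents for dose summaries,
5 seed-blocks × 20,000 agents per calibration objective evaluation, 10
runs × 5,000 agents per sweep dose — were chosen as the smallest budgets
at which the across-run UI brackets the anchor bands and the sweep's
adjacent-dose differences are resolved; all are config parameters and
scale up without code changes.

## Known limitations

Single-decision horizon (no re-presentation after an initial no-show);
no hospital capacity or queueing; Euclidean rather than road distance;
preference weights independent of demographics; marginal (not joint)
demographic structure; the four-procedure case mix is uniform rather than
epidemiological. The model is calibrated to two aggregate anchors, so
subgroup-level predictions inherit no independent validation.
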