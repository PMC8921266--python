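# poomkit

Tools for studying how partially oxidized organic matter (POOM) links the
burial of organic carbon to the rise of atmospheric oxygen, and for dating
the expansion of the oxidative metabolisms that produce it.

The package is aimed at geobiologists and molecular evolutionists who work
with two kinds of objects:

* **Burial kinetics.** A two-pool first-order degradation model of
  sedimentary organic carbon. A labile pool g₁ always degrades (rate
  constant k₁); a POOM pool g₂ degrades only while exposed to oxygen (rate
  constant k₂ < k₁) and is protected once buried in anoxic sediment.
  While oxygen is present, oxidative metabolisms convert g₁ to POOM at rate
  k₁₂:

      dg₁/dt = −(k₁ + k₁₂) g₁,            t ≥ 0
      dg₂/dt = k₁₂ g₁ − k₂ g₂,            0 ≤ t ≤ t_ox

  with g₁(0) = (1−a) g₀, g₂(0) = a g₀, where t_ox is the oxygen-exposure
  time. Burial efficiency is g₂(t_ox)/g₀. When k₁₂ > k\* ≡ a k₂/(1−a),
  burial efficiency *increases* with oxygen exposure up to a critical time
  t_ox\* — a positive feedback in which oxygen begets burial begets oxygen.
  The package provides the closed-form solution, the threshold k\*, the
  critical time t_ox\*, a numerical integrator for cross-checking, and a
  regime classifier.

* **Chronogram post-processing.** Posterior ensembles of time-calibrated
  trees (one Newick per line, datedist style) with burn-in handling;
  weighted age distributions for horizontal gene transfer (HGT) events
  derived from reconciliation replicate tables (leaf recipients deleted,
  internal recipients weighted by replicate fractions); box summaries
  (weighted mean, 2.5/25/75/97.5 weighted percentiles) and overlap
  probabilities with geological windows such as the Great Oxidation Event
  (2400–2300 Ma); binned lineages-through-time diversification rates
  rᵢ = log(Nᵢ₊₁/Nᵢ)/Δt at Δt = 100 Myr; and white-noise tests of the rate
  fluctuations against a constant-rate branching null (Monte-Carlo power
  spectrum peak test and Ljung–Box test at 25 lags).

A synthetic-data module generates all inputs — piecewise-rate Yule trees,
posterior-style jittered ensembles, reconciliation-style HGT tables — with
ground truth attached, so the entire pipeline is testable offline.

## Worked example

Kinetics, in the positive-feedback regime (a = 0.05, k₁ = 1, k₂ = 0.1,
k₁₂ = 0.5, t_ox = 2; time in units of 1/k₁):

```sh
poomkit kinetics --a 0.05 --k1 1.0 --k2 0.1 --k12 0.5 --t-ox 2.0 \
    --out-dir out/kin
cat out/kin/kinetics_summary.json
```

```json
{
  "burial_efficiency": 0.3018281449662605,
  "k_star": 0.005263157894736844,
  "regime": "positive",
  "t_ox_star": 1.836128007481148
}
```

k₁₂ = 0.5 far exceeds the threshold k\* ≈ 0.0053, so the regime is
positive: burial efficiency rises with oxygen exposure, peaking at
t_ox\* ≈ 1.84 (in units of 1/k₁), where 30.2% of the deposited carbon
survives as protected POOM — six times the initial POOM fraction of 5%.

Diversification rates on a synthetic posterior ensemble:

```sh
poomkit simulate --seed 1 --n-trees 40 --root-age 2500 --rate 0.002 \
    --n-events 5 --out-dir out/sim
poomkit divrate --trees out/sim/trees.nwk --null-reps 199 --seed 1 \
    --max-lag 10 --out-dir out/div
```

`out/div/divrate_report.json` reports (for this seed) a mean rate
r̄ ≈ 0.0036/Myr over 21 bins of 100 Myr, a spectral peak p-value of 0.62
and a minimum Ljung–Box p-value of 0.20 across lags 1–10 — as expected,
a constant-rate simulation shows no evidence of temporal structure, in
contrast to what bursty diversification histories produce. Per-bin
counts, rates and fluctuations are written to `out/div/rates.csv`.

HGT event dating against the same ensemble:

```sh
poomkit hgt-ages --trees out/sim/trees.nwk --events out/sim/hgt_events.tsv \
    --window GOE:2400:2300 --out-dir out/hgt
```

writes per-event older/younger bound box statistics (`hgt_summary.csv`)
and window-overlap probabilities (`hgt_report.json`). A config-driven
`poomkit run --config run.yaml` executes any subset of stages
reproducibly; identical config + seed gives byte-identical outputs.

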