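# socialhmm

Hidden-Markov digital phenotyping of passively collected smartphone data.

Passive monitoring apps record when a participant uses social media or
communication apps, makes or receives calls, or simply has the phone
unlocked. `socialhmm` turns those event logs into an interpretable
behavioural phenotype: the **total socially active dwell time** — the
percentage of a participant's (non-missing) hours spent in a latent
"socially active" behavioural state — and relates it to diagnostic group
(healthy controls, schizophrenia, Alzheimer disease, subjective cognitive
complaints) and clinical scales (SFS, loneliness, MMSE, PANSS). It is aimed
at researchers analysing passive-sensing studies in psychiatry and
neurology, where sparse, zero-inflated, block-missing hourly time series are
the norm.

## The model

Five binary channels x_t = (x_t1 … x_t5) per hour (social-media apps,
communication apps, incoming calls, outgoing calls, overall phone usage)
are emitted by a latent state z_t ∈ {1…N}:

    p(x_t | z_tn = 1) = ∏_c φ_nc^x_tc (1 − φ_nc)^(1 − x_tc)
    p(z_1n = 1) = π_n
    A_mn(c_t) = p(z_tn = 1 | z_{t−1,m} = 1, c_t) = softmax_n(β_mn · c_t)

with c_t the one-hot encoded hour of day (24 columns, no intercept,
destination state 1 the zero-fixed reference), so every hour has its own
transition matrix — this is what captures diurnal rhythm. Missing hours are
marginalised out of the likelihood (no imputation). Fitting is by EM; the
number of states (2–4) is compared by BIC; decoding uses the Viterbi
algorithm without retraining; the model is trained only on high-data-quality
healthy controls ("reference-group" training) and applied to everyone else.

With two states, state 1 has near-zero emission probabilities everywhere
(socially *inactive*) and state 2 has high phone-usage and
communication-app probabilities (socially *active*). Total dwell time is
`100 × #(observed hours decoded active) / #(observed hours)`.

Downstream, dwell time enters OLS models of the clinical scores
(`score ~ dwell + age + group + group:dwell`) and a multinomial logistic
model of group membership (HC reference, odds ratio per 1% dwell with Wald
CIs), with per-family multiplicity adjustment `min(1, m·p)` (Benjamini–
Hochberg also available).

Because no public data accompany the method, the package ships a
first-class synthetic-data generator (`socialhmm.simulate`) producing
event-level logs, availability gaps and clinical tables with known ground
truth, so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np, pandas as pd
from socialhmm import io as shio
from socialhmm.simulate import SimulationConfig, simulate_cohort
from socialhmm.pipeline import PipelineConfig, run_pipeline

cfg = SimulationConfig(n_per_group={"HC": 40, "SZ": 6, "AD": 8, "SCC": 16},
                       days=28, seed=7)
logs, truths, table, _ = simulate_cohort(cfg)
shio.write_events_csv(list(logs.values()), "events.csv")
table.to_csv("clinical.csv", index=False)

pc = PipelineConfig(events_csv="events.csv", clinical_csv="clinical.csv",
                    out_dir="out", n_retain=5, n_restarts=5, seed=11,
                    families=["sfs", "group"])
bundle = run_pipeline(pc)
```

This simulates a 70-participant cohort (28 days each), bins events into
hourly binary channels, assigns high-availability HCs to training, fits the
2-state hour-covariate HMM, decodes the validation participants and runs
the analyses. Printing the key quantities:

```
train: 12 validation: 58
loglik: -11446.0  BIC: 23419.4
pi: [0.833 0.167]
phi:
[[0.    0.    0.    0.    0.128]
 [0.51  0.635 0.095 0.118 1.   ]]
active state: 2
group          # mean estimated dwell time (%) per validation group
AD     25.0
HC     38.3
SCC    32.7
SZ     37.0
SZ: coef -0.0585  OR 0.9432 (0.8035-1.1071)  adj p 1.0000
AD: coef -0.3887  OR 0.6780 (0.5430-0.8465)  adj p 0.0018
SCC: coef -0.1873  OR 0.8292 (0.7214-0.9530)  adj p 0.0251
```

State 1 is silent on every channel (inactive); state 2 shows phone usage
with high communication-app probability (active). Sequences mostly start at
midnight in the inactive state (π₁ = 0.83). The AD group — simulated with a
suppressed transition score into the active state — shows markedly lower
dwell times (25% vs 38% in HCs), and the group logistic model recovers a
significantly negative dwell coefficient for AD (odds of AD membership fall
by a factor 0.68 per additional % dwell, adjusted p ≈ .002), with a smaller
effect for SCC and none for SZ — the ordering built into the generator.

The same workflow is available from the shell:

```sh
socialhmm simulate --config sim.yaml --out data/
socialhmm preprocess --events data/events.csv --threshold 0.0 --out hourly.csv
socialhmm fit --hourly hourly.csv --states 2 --restarts 10 --seed 7 --out model.json
socialhmm decode --model model.json --hourly hourly.csv --out paths.csv
socialhmm phenotype --model model.json --paths paths.csv --out dwell.csv
socialhmm analyze --dwell dwell.csv --clinical data/clinical.csv --family group --out results.csv
socialhmm run --config pipeline.yaml   # everything at once
```

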