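# tymbal

Acoustic and behavioral analysis of duty-cycle signalling in sonar-jamming
tiger moths (Erebidae: Arctiinae), built around a synthetic-data generator so
the whole pipeline runs without field recordings.

Arctiine moths such as *Bertholdia trigona* and *Carales arizonensis* produce
trains of short (~0.3 ms) broadband ultrasonic clicks with their metathoracic
tymbals. One tymbal flexion-plus-relaxation is a *modulation cycle* (MC): an
active half-cycle of clicks, a passive half, and a ~4 ms silent interval. The
trait of interest is the **duty cycle** — the fraction of time occupied by
sound within a sliding 100 ms window,

```
DC = mean click duration × click count in window / window length × 100,
```

reported from the window with the most clicks across an individual's
recordings. High duty cycles jam bat sonar; this package addresses the
parallel question of whether females *prefer* high-duty-cycle males, for
researchers in bioacoustics and behavioral ecology who need a tested,
reproducible version of that analysis chain.

The package provides:

* **`tymbal_model`** — domain types (clicks, modulation cycles, recordings)
  and synthesis of click trains with known ground truth, including per-male
  maximum-duty-cycle phenotypes drawn from species distributions
  (*B. trigona* 41 ± 13%, max 67%; *C. arizonensis* 30 ± 11%, max 49%).
* **`click_analysis`** — envelope-threshold click detection, the sliding
  100 ms duty-cycle statistic, species summaries (mean ± SD, max), and a
  z-test on the between-species variance difference.
* **`stimulus_builder`** — playback stimuli at 10 / 25 / 45% duty cycle plus
  silence and white-noise controls: 600 ms emissions separated by 2.4 s
  silence, randomized session schedules, WAV/CSV export.
* **`behavior_sim`** — synthetic playback trials (Bernoulli response,
  censored exponential latency under proportional hazards) and mate-choice
  trials over male acoustic phenotypes S++ (intact) / S+ (reduced) / S−
  (mute).
* **`behavior_stats`** — logistic GLM by IRLS with Bonferroni-adjusted
  all-pairs contrasts; Cox proportional-hazards "female response rate
  ratios" vs the 45% duty-cycle reference (Newton on the Breslow partial
  likelihood); exact Fisher 2×2 and Freeman–Halton 2×3 tests by complete
  enumeration in integer arithmetic; acceptance-rate tabulation.
* **`pipeline` / `tymbal` CLI** — seeded, reproducible end-to-end runs.

## Worked example

```
$ tymbal all --seed 1
Bertholdia trigona: mean=40.0% sd=10.2 max=63.3%
Carales arizonensis: mean=32.5% sd=11.3 max=48.1%
variance z=-0.38 p=0.7051
...
Response fraction by stimulus category:
  silence      0.046 (fitted 0.046)
  dc45         0.713 (fitted 0.713)
  white_noise  0.704 (fitted 0.704)
...
Response rate ratios vs the 45% duty-cycle reference (Cox):
  dc10         0.13 (95% CI 0.07-0.22)
  dc25         0.29 (95% CI 0.19-0.43)
  white_noise  1.23 (95% CI 0.89-1.69)
...
Bertholdia trigona: S++:82%  S+:18%  S-:0%  p=9.755e-05
Carales arizonensis: S++:38%  S-:62%  p=0.6193
```

Reading the output: 30 synthetic *B. trigona* males score a mean maximum
duty cycle of 40% (generating mean 41%) through the full
synthesis → detection → statistic chain; simulated females respond to 71% of
45%-duty-cycle presentations (fitted GLM probability equals the observed
proportion in this saturated model); response *rates* fall steeply below the
45% reference; and in mate-choice trials muted males are never accepted. The
per-category fractions and rate ratios here are estimates from one seeded
run of the simulated experiment at its field sample sizes (54 females, 25
choice trials), so they scatter around the generating parameters. Library
use of the same machinery:

```python
from tymbal import IndividualProfile, synthesize_click_train, score_individual

rec = synthesize_click_train(IndividualProfile("B. trigona", target_max_dc=45, seed=7))
print(score_individual(rec))   # 45 +/- 1
```

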