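# alliumsim

A process-based growth and yield simulator for hardneck garlic
(*Allium sativum*), built for exploring planting-date strategy under
contrasting and changing climates.

Garlic is planted in autumn as a clove, overwinters as a small plant, and
bulks its bulb in spring. Yield therefore hinges on three temperature-driven
processes that this package models mechanistically:

* **Dynamic phyllochron.** The maximal leaf tip appearance rate starts from
  a sigmoid of seed-bulb storage duration,
  `r0 = LTAR_max,a / (1 + exp(-alpha (SD - SD_m)))`, and after each leaf
  appearance converges linearly toward half the asymptote,
  `LTAR_max = r0 + (r1 - r0) * min(k, N_g) / N_g` with `r1 = LTAR_max,a / 2`,
  completing at the generic leaf number `N_g`. Leaves appear when the
  integral of `LTAR_max * f(T)` (beta thermal response `f`) crosses one;
  the scape appears three phyllochron-equivalents after reproductive onset.
* **Cold stress, two-fold.** Recoverable *cold injury* scales leaf
  elongation: a cold-day counter `D` rises below 0 degC and decays above it;
  apparent injury `C = clip(ln(a (T - T_c,i) + b), 0, 1)` combines with
  exposure into an effect `E = 1 - C^(1/D)` that ratchets downward within an
  episode, and `LER = E * LER_p`. Irreversible *cold damage* is a logistic
  mortality `M(T) = 1 / (1 + exp(s (T - T_c,d)))` (one half at
  `T_c,d = -15` degC) applied multiplicatively to plant density on frost days.
* **Carbon budget.** Canopy assimilation comes from a coupled
  Farquhar/Ball-Berry/energy-balance C3 model over sunlit and shaded big
  leaves (or a radiation-use-efficiency fallback). Assimilate forms a pool
  drained daily: maintenance respiration (Q10) first, the remainder
  converted to structural growth at efficiency `Y_g` and split among root,
  leaf, sheath, scape and bulb by a stage-dependent partitioning table.
  Fresh bulb yield is `bulb_dry / (1 - moisture) * PD / 1000` kg m^-2 at 85%
  bulb moisture.

A synthetic weather generator supplies hourly series for two named
profiles — a humid-subtropical winter (mild, frost-free) and a
humid-continental winter (recurring hard frost) — so every pathway,
including stand-killing cold, can be exercised reproducibly from a seed.

## Worked example

```python
from alliumsim import SimulationConfig, run_season, synthesize_weather

weather = synthesize_weather("subtropical", years=2, seed=1)
result = run_season(SimulationConfig(), weather)
print(f"bulb {result.bulb_dry:.2f} g dry -> {result.fresh_yield:.2f} kg m^-2 "
      f"at PD {result.final_pd:.0f}")
print([e for e in result.events if not e[1].startswith('leaf')][:4])
```

prints

```
bulb 12.69 g dry -> 3.81 kg m^-2 at PD 45
[(datetime.date(2020, 10, 19), 'vegetative'), (datetime.date(2021, 3, 27), 'R1'),
 (datetime.date(2021, 4, 13), 'R2'), (datetime.date(2021, 4, 13), 'R3')]
```

i.e. an October 10 planting emerges after nine days, turns reproductive in
late March, shows (and immediately loses) its scape in mid-April, and is
harvested on May 15 with 12.7 g of bulb dry matter per plant — 3.8 kg m^-2
fresh at 45 surviving plants m^-2. The same configuration run on the
continental profile collapses to essentially zero yield because winter
mortality reduces the stand a thousand-fold.

The same machinery is scriptable from the shell:

```sh
alliumsim genweather --profile continental --years 2 --seed 0 --out w.csv
alliumsim simulate --weather w.csv --out run/
alliumsim scan --profile subtropical --seeds 10 --out scan/
```

`scan` runs the full factorial of 12 planting dates (day-of-year 240 to 350
in 10-day steps) against seeded weather datasets and writes the
yield-vs-planting-date curve (mean, SD, n) plus per-replicate optimal dates
(ties broken toward the earlier date).

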