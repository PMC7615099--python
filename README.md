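# urbansense

Spatiotemporal estimation of urban noise and fine particulate matter
(PM2.5) from street-level imagery, rebuilt as a tested, fully synthetic
pipeline.

Street cameras co-located with low-cost pollution monitors offer a way to
estimate air and noise pollution where reference networks are sparse —
but how well do image-based models *generalise*, to unseen times and
unseen places? This package implements the complete analysis for that
question on a seeded synthetic monitoring campaign (10 long-term fixed
sites + 135 one-week rotating sites across four land-use classes): data
generation, timestamp repair and ±30 s image–pollution pairing, ordinal
classification with two model families, spatial cross-validation designs,
null-model benchmarking, distribution-similarity analysis and feature
attribution. It is aimed at exposure-assessment and environmental-health
researchers prototyping such pipelines, and at anyone who needs a
controlled test bed where the ground truth is known by construction.

## The model in brief

Pollution is framed as **ordinal classification**: noise into 10 classes
(≤39, 40–<45, …, ≥80 dBA) and PM2.5 into 11 (0–<5, …, ≥150 µg/m³). Two
classifier families are trained on identical record sets:

* an **end-to-end convolutional network** on raw frames, trained with an
  ordinal cross-entropy

  L(p, y) = −log p_y + λ Σ_k φ_t(z_k),

  where the z_k are adjacent-class gaps that are all ≤ 0 exactly when
  the predicted probability profile is unimodal with its peak at the true
  class y, and φ_t is a smooth log-barrier; and

* a **gradient-boosted tree model** on interpretable per-image object
  counts (cars, persons, taxis, umbrellas, tro-tros, …; 16 retained
  categories).

Every model is benchmarked against a **null** that knows only the
training class distribution (expected accuracy Σ_c p_train(c)·p_test(c)
in closed form), and cross-site transfer is analysed against the
**Bhattacharyya coefficient** Σ_c √(p_c·q_c) between train and test
class distributions. Five designs probe generalisability: same-site
(1a), site-to-site (1b), leave-one-fixed-site-out (2a), leave-sites-out
folds over rotating sites (2b), and the sampling-allocation question
(2c): many records from few places versus few records from many places.

See `docs/methods.md` for the generative model, parameter defaults and
numerical details.

## Worked example

```python
import urbansense as us
from urbansense import models as md, orchestration as orch

world = us.make_world(n_fixed=1, n_rotating=0, seed=3,
                      fixed_recording_days=10, n_clock_failures=0)
result = orch.run_question("1a", world, md.TrainConfig(seed=3, epochs=10),
                           seed=3, families=("gbm", "cnn"), target="pm25")
for fam in ("gbm", "cnn"):
    r = result.reports[fam]
    print(f"{fam}: exact {r.exact_accuracy:.3f}  ±1 {r.pm1_accuracy:.3f}  "
          f"null {r.null_accuracy:.3f}  improvement {r.improvement:+.3f}")
```

Output from this exact run:

```
gbm: exact 0.241  ±1 0.469  null 0.152  improvement +0.088
cnn: exact 0.631  ±1 0.959  null 0.152  improvement +0.479
```

Read: on ~5,000 paired records at one site, the count-based model lifts
exact PM2.5 class accuracy about 9 points above the distribution-only
null (24.1% vs 15.2%), while the image model — which can see the planted
haze/red-tint encoding of PM2.5 — reaches 63% exact and 96% within one
class. On the noise target the ordering reverses: object counts carry the
activity signal that drives noise, so the boosted trees lead there. Both
patterns mirror the qualitative behaviour expected of the two families.

A command-line interface covers the pipeline stages:

```bash
urbansense generate --out campaign/ --seed 1        # synthetic campaign to disk
urbansense ingest --root campaign/ --out records.csv
urbansense split --records records.csv --question 2b --folds 10 --seed 1 --out plans/
urbansense run --question 2c --seed 1 --families gbm --out runs/2c/
```

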