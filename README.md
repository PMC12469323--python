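# varstep

Coarse-to-fine **variable-step learning-rate search** for gradient-trained
classifiers, with exact replay of recorded tuning runs, synthetic
accuracy-response surfaces, equal-step / exhaustive-grid baselines, and the
confusion-matrix metrics used to evaluate the resulting models.

## The problem

Picking the learning rate lr ∈ (0, 1] dominates both the cost and the
quality of training a small CNN. Sweeping a fine grid of precision *km*
(e.g. every 0.005) costs ⌊1/km⌋ = 200 full training runs; a handful of
equally spaced values is cheap but routinely lands on a poor local plateau.
Validation accuracy as a function of lr is, in practice, a broad single bump
on a log scale, which a bracketing search can exploit.

`varstep` implements that search as a black-box 1-D optimizer. The
objective is any callable `lr -> validation accuracy`; model training never
happens inside this package. It was built around the tuning of five
lightweight fish-species classifiers (ResNet18, ShuffleNet, EfficientNet,
MobileNetV3, YOLOv8 on perch / snapper / cod plus an "other" interference
class), whose recorded (lr, accuracy) tables ship as replay fixtures.

## The method

**Round 0 — large-interval fast positioning.** Evaluate, in ascending
order, the union of a log ladder inside the conventional experience
interval and an equal-step ladder above it:

    lr = k2 / 10^n,        n = 1..5          (1e-5, 1e-4, 1e-3, 0.01, 0.1)
    lr = m (k2 - k1) / p,  m = 2..10         (0.2, 0.3, ..., 1.0)

with k1 = 0.1, k2 = 1, p = 9 — 14 candidates.

**Interruption rule.** Within any round, three consecutive fresh
evaluations below 80% accuracy abandon the rest of the round (those
training runs would be wasted); a single success resets the count.

**Refinement — inter-cell precise optimization.** Bracket the best point
lr_b between its nearest evaluated neighbours (lr_l, lr_r) and subdivide
each side with a gap-dependent step

    s2 = km         if gap <= 10 km,
    s2 = gap / p    otherwise,

proposing lr_l + j·s2 (below lr_b) and lr_b + j·s2 (up to lr_r). Already
evaluated rates are served from a cache — no learning rate is ever trained
twice. The search stops when the best accuracy exceeds 99%, the bracket
holds no unevaluated candidate, or both bracket gaps are ≤ km.

On the recorded ResNet18 run this finds the optimum lr = 0.01 (96.33%) in
14 evaluations instead of 200 — a 93.0% reduction; on ShuffleNet,
lr = 0.015 (96.74%) in 22.

## Worked example

```bash
$ varstep search --objective fixture:resnet18 --km 0.005 --out demo/
best_lr: 0.01
best_accuracy: 96.33%
evaluations: 14
termination: exhausted
```

The search replayed the recorded ResNet18 tuning run: 7 evaluations in
round 0 (interrupted after 0.1, 0.2, 0.3 all fell below 80%), 6 in the
first refinement of the bracket (0.001, 0.01, 0.1), one final point 0.015
in the bracket (0.006, 0.01, 0.02), then no unevaluated candidate remained
("exhausted"). `demo/trace.csv` holds every visited candidate with its
round, accuracy and cache flag; `demo/summary.json` the headline numbers.

The same engine runs on a synthetic surface (YAML spec with a log-Gaussian
bump; `--seed` freezes its noise field) or on any `lr,accuracy` CSV.

Classifier evaluation from a confusion-count table (`class,tp,fp,fn`):

```bash
$ varstep metrics src/varstep/data/confusion_resnet18.csv --out demo/
perch: P=0.930 R=1.000 F1=0.964
snapper: P=0.951 R=0.975 F1=0.963
cod: P=0.961 R=0.913 F1=0.936
other: P=0.882 R=0.838 F1=0.859
overall_accuracy: 93.13%
```

P = TP/(TP+FP), R = TP/(TP+FN), F1 their harmonic mean, overall accuracy
ΣTP/320 test images. `varstep compare` sets the search against the
equal-step baseline (best of b evenly spaced rates) and the exhaustive
km-grid; `varstep fixtures --out DIR` re-emits every packaged table.

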