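# msdelm

Bird species recognition from song recordings, built around an extreme
learning machine (ELM) whose input-side parameters are tuned by
multi-strategy differential evolution (M-SDE) and stabilized by a
majority-vote ensemble. The package covers the whole workflow: differential
MFCC feature extraction from WAV audio, the optimizer, the single and
ensemble classifiers, a repeated-run evaluation protocol with hypothesis
tests, and synthetic data generators so everything runs without any
recordings.

## The method

**ELM.** A single-hidden-layer feedforward network maps a K-dimensional
feature vector x to P class scores f(x) = g(xWᵀ + b)β. The input weights
W (L×K) and hidden thresholds b (L) are fixed, and the output weights β are
the minimum-norm least-squares solution β = H⁺Y, where H is the N×L
hidden-layer output matrix on the training set, Y the one-hot targets, and
H⁺ the Moore–Penrose pseudoinverse. Training is a single linear solve —
fast, but accuracy fluctuates with the random (W, b).

**M-SDE.** Instead of accepting random (W, b), they are encoded as one
D = L(K+1) vector and optimized by differential evolution: per generation
one mutation strategy is drawn uniformly from
{DE/rand/2, DE/best/2, DE/current to best/1} — global search, fast local
convergence, and diversity with precision, respectively — with binomial
crossover, uniform regeneration of out-of-bounds components, and greedy
selection (a trial replaces its target only when strictly fitter). The
control parameters adapt: the scaling factor follows
F(t) = F₀·2^exp(1 − T/(T+1−t)), decaying from 2F₀ to F₀ over the T
generations, and the crossover probability is redrawn each generation as
CR = 0.5(1 + u), u ~ U(0,1). The objective is the training-set RMSE of the
network outputs against the one-hot targets, with β re-solved in closed
form for every candidate (W, b).

**Ensemble.** Ten base classifiers with hidden sizes spanning 4× to 10× the
feature dimension vote by majority, H(x) = argmax_j Σᵢ y_ij(x); ties go to
the smallest class index. The ensemble both lifts accuracy and removes the
need to pick a single best hidden size.

**Features.** Recordings are mono 16 kHz WAVs. After endpoint detection
(double threshold on short-time energy and zero-crossing rate), each 25 ms
frame yields 13 MFCCs; first- and second-order regression differences
(Δ, ΔΔ with window K = 2) are appended to give 39-d frames, and each run of
4 consecutive frames is stacked into one 156-d sample.

## Worked example

```python
import numpy as np
from msdelm import (ClusterSpec, DeConfig, gen_clusters, run_experiment)

table = gen_clusters(ClusterSpec(n_classes=5, samples_per_class=100,
                                 df=20, separation=3.0, seed=42))
de = DeConfig(NP=30, T=15)
for model in ("ELM", "M-SDE_ELM", "M-SDE_EnELM"):
    hs = 40 if model != "M-SDE_EnELM" else None
    rep = run_experiment(model, table, runs=10, master_seed=0,
                         hidden_size=hs, de_cfg=de)
    mean, std = rep.aggregate()["accuracy"]
    print(f"{model:12s} {100 * mean:.2f} +/- {100 * std:.2f}%")
```

prints

```
ELM          91.07 +/- 2.61%
M-SDE_ELM    92.40 +/- 1.94%
M-SDE_EnELM  93.33 +/- 1.54%
```

Each line is the mean ± sample standard deviation of test accuracy over ten
independent stratified 7:3 train/test splits of the five-class synthetic
benchmark: DE tuning improves the single classifier, the ensemble improves
it further, and the standard deviation shrinks at each step — the ensemble
is the most stable model.

The same experiments are available from the shell:

```sh
msdelm synth clusters -o clusters.csv          # or: msdelm synth songs + msdelm extract
msdelm run -m M-SDE_EnELM -d clusters.csv -o reports/
msdelm compare reports/M-SDE_EnELM_runs.csv reports/ELM_runs.csv
msdelm ablate -d clusters.csv                  # single/dual/multi-strategy sweep
```

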