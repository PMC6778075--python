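"""Compare entropy-H acquisition against random acquisition.

Runs the reduced-scale active-learning benchmark: starting from 10 labelled
tiles per class, each step acquires the 50 pool tiles the current model is
most uncertain about (or a random 50), retrains from a fresh
initialisation, and records test accuracy.  The comparison is noisy for any
single dataset, so — as in the full protocol — it is averaged here over 3
dataset seeds x 2 initialisations.  The area under the accuracy-vs-size
curve summarises how quickly each strategy learns.
"""

import numpy as np

import tilebayes as tb

model_cfg = tb.ModelConfig(n_classes=4, input_size=16, filters=(8, 16, 32))
aucs = {"random": [], "entropy_H": []}
for seed in (0, 1, 2):
    dataset = tb.generate_dataset(
        4, 75, size=16, confusable_pair=(2, 3), confusability=0.95, seed=100 + seed
    )
    cfg = tb.AcquisitionConfig(
        seed_per_class=10, step_size=50, T=16, n_inits=2, n_splits=1,
        epochs_per_step=18, seed=seed,
    )
    traces = tb.compare_strategies(dataset, model_cfg, cfg, strategies=("random", "entropy_H"))
    for name, trace in traces.items():
        aucs[name].append(tb.trace_auc(trace))
        accs = " ".join(f"{a:.3f}" for a in trace.accuracies)
        print(f"seed {seed} {name:>10}: sizes {trace.sizes}  accuracy {accs}")
for name, values in aucs.items():
    print(f"mean curve AUC {name:>10}: {np.mean(values):.4f}")
print("A higher AUC means the strategy reaches good accuracy with fewer annotations.")
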