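"""Quantify how separable the two vocal types become over training.

Per vocalization, 18 modulation features (F1/F3 CV + MD and SE quartiles)
are embedded in 2-D with UMAP separately for the start and end epochs (the
first and last quartiles of the sampled days); a random forest is trained
on 70% of each embedding and scored on the rest. The DeLong test compares
the two AUCs: a negative D with small p means the end-of-training model
discriminates significantly better — the vocal types diverged.
"""

import numpy as np

import formantmod as fm

cfg = fm.SynthConfig(seed=4)
days = sorted(set(int(round(d)) for d in np.linspace(1, 54, 16)))
cleaned, _ = fm.apply_qc(fm.simulate_dataset(cfg, days=days))
summaries = fm.summarize_dataset(cleaned)
features = fm.build_features(summaries)

start, end, delong = fm.compare_epochs(features, seed=4)
for rep in (start, end):
    m = rep.metrics
    print(
        f"{rep.epoch:>5}: OOB error {rep.oob_error:.2f} | AUC {rep.auc:.2f} | "
        f"balanced acc {m['balanced_accuracy']:.2f} "
        f"(sens {m['sensitivity']:.2f}, spec {m['specificity']:.2f})"
    )
print(
    f"DeLong start vs end: D = {delong['D']:.2f}, df = {delong['df']:.1f}, "
    f"p = {delong['p']:.3g}"
)
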