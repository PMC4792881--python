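"""Sleep-architecture metrics: percent time, bout number, mean bout duration.

Compares the metrics of a decoded hypnogram with those of the generating
one. Small per-epoch errors matter little for percent time but are
amplified in bout counts, which is why bout metrics are the acid test of a
scorer.
"""

from sleepseg import (
    LIGHT_CHAIN,
    fit_pipeline,
    score,
    simulate_features,
    simulate_hypnogram,
    sleep_metrics,
)

truth = simulate_hypnogram(LIGHT_CHAIN, T=5400, seed=2)
feats = simulate_features(truth, seed=3)
model = fit_pipeline(feats, seed=0)
decoded = score(model, feats, "hmm")

for name, h in (("reference", truth), ("decoded", decoded)):
    m = sleep_metrics(h)
    print(f"\n{name} hypnogram ({m.n_epochs} epochs):")
    print(m.to_frame().to_string(index=False,
                                 float_format=lambda x: f"{x:8.2f}"))

# percent_time sums to 100 across states; mean_bout_s is NaN for a state
# with no bouts. A good dynamic scorer reproduces bout counts closely.
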