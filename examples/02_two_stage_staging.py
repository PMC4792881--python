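"""Stage epochs into Wake/NREM/REM with the two-stage k-means.

Stage 1 splits the EMG-tone axis into Wake vs. sleep; stage 2 splits the
sleep epochs on the delta/theta axis into NREM vs. REM. No labels are used
anywhere — agreement with the generating states is computed only afterward.
"""

import numpy as np

from sleepseg import (
    LIGHT_CHAIN,
    Hypnogram,
    agreement,
    fit_state_clusters,
    simulate_features,
    simulate_hypnogram,
)

truth = simulate_hypnogram(LIGHT_CHAIN, T=5400, seed=0)  # ~6 h
feats = simulate_features(truth, seed=1)

model = fit_state_clusters(feats)
pred = Hypnogram(labels=model.training_labels, epoch_s=feats.epoch_s)

print(f"EMG-axis centroids (sleep, wake): {np.round(model.emg_centroids, 2)}")
print(f"sleep delta/theta centroids (REM, NREM): "
      f"{np.round(model.sleep_dt_centroids, 2)}")
rep = agreement(truth, pred)
print(f"overall agreement with generating states: {rep.overall:.1f}%")
for s, name in enumerate(("WAKE", "NREM", "REM")):
    print(f"{name:>4}: sensitivity {rep.sensitivity[s]:5.1f}%  "
          f"specificity {rep.specificity[s]:5.1f}%")

# The centroid split, not a fixed threshold, decides which cluster is Wake:
# the higher EMG centroid is always Wake, the higher delta/theta sleep
# centroid always NREM.
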