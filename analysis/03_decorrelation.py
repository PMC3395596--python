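"""Temporal decorrelation of odor responses at a balanced operating point
(g_exc = 0.0004 µS, g_slow = 0.0002 µS).

Writes results/decorrelation.csv with four per-bin series: the onset
correlation of PN responses and of the raw inputs (how fast activity moves
away from its onset pattern) and the similar-odor correlation of PN
responses and inputs. PN responses decorrelate from their onset pattern
far faster than the inputs do, and the similar-odor correlation falls over
the stimulus while the input correlation does not decay.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from alnet.experiments import decorrelation_experiment

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

res = decorrelation_experiment(master_seed=1, n_trials=5)
nb = len(res["pn_similar_series"])
onset_pad = nb - len(res["pn_onset_series"])
df = pd.DataFrame({
    "bin": np.arange(nb),
    "t_ms": 25.0 * np.arange(nb),
    "pn_similar": res["pn_similar_series"],
    "input_similar": res["input_similar_series"],
    "pn_onset": np.concatenate([[np.nan] * onset_pad,
                                res["pn_onset_series"]]),
    "input_onset": np.concatenate([[np.nan] * onset_pad,
                                   res["input_onset_series"]]),
})
df.to_csv(OUT / "decorrelation.csv", index=False)
bins = res["stimulus_bins"]
print(f"onset+200 ms correlation: PN {res['pn_onset_series'][8]:.3f} vs "
      f"input {res['input_onset_series'][8]:.3f}")
print(f"similar-odor PN correlation: {res['pn_similar_series'][bins[0]]:.3f}"
      f" at onset -> {res['pn_similar_series'][bins[-4:]].mean():.3f} late")
print(f"similar-odor input correlation stays at "
      f"{res['input_similar_series'][bins[-4:]].mean():.3f}")
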