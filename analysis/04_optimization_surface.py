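"""The reliability/separability criterion M = C_trials + (1 − C_odors)
over a (g_exc, g_slow) grid for a similar-odor pair.

Writes results/surface.csv (C_trials, C_odors, M and the classification
error per grid cell) and prints the argmax of M. Both nonzero lateral
excitation and nonzero slow inhibition are required at the optimum.
"""
from pathlib import Path

import pandas as pd

from alnet.experiments import tradeoff_experiment

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

res = tradeoff_experiment(master_seed=1)
rows = []
for i, ge in enumerate(res["ge_values"]):
    for j, gs in enumerate(res["gs_values"]):
        rows.append({"g_exc": ge, "g_slow": gs,
                     "C_trials": res["C_trials"][i, j],
                     "C_odors": res["C_odors"][i, j],
                     "M": res["M"][i, j],
                     "error": res["error"][i, j]})
df = pd.DataFrame(rows)
df.to_csv(OUT / "surface.csv", index=False)
i, j = res["argmax"]
print(df.to_string(index=False,
                   float_format=lambda x: f"{x:.4g}"))
print(f"argmax M at g_exc={res['ge_values'][i]}, "
      f"g_slow={res['gs_values'][j]}")
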