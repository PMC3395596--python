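"""Two-odor classification error across master seeds.

Writes results/classification_error.csv: the hierarchical-clustering
error for a similar-odor pair per (g_exc, g_slow) cell and per master
seed. High error is expected where lateral excitation is maximal and slow
inhibition absent; balanced cells classify best.
"""
from pathlib import Path

import pandas as pd

from alnet.experiments import tradeoff_experiment

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for seed in (1, 2, 3):
    res = tradeoff_experiment(master_seed=seed)
    for i, ge in enumerate(res["ge_values"]):
        for j, gs in enumerate(res["gs_values"]):
            rows.append({"master_seed": seed, "g_exc": ge, "g_slow": gs,
                         "error": res["error"][i, j]})
df = pd.DataFrame(rows)
df.to_csv(OUT / "classification_error.csv", index=False)
print(df.groupby(["g_exc", "g_slow"])["error"].mean().unstack().round(2))
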