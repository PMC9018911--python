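"""Global structure-function coupling: edge-wise fits of FC on every
predictor, plus the decay of variance explained with hop distance.

For each subject, every predictor's vectorised upper triangle is regressed
against FC; fits are then stratified by binary shortest-path hop count to
show that most explanatory power sits on directly connected pairs.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from commcouple.regression import global_coupling, hop_decomposition
from commcouple.synthetic import SyntheticConfig, generate_subjects

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = SyntheticConfig(n_nodes=60, n_systems=6, density=0.2)
geometry, subjects, truth = generate_subjects(cfg, 8, seed=42)
labels = subjects[0][1].labels

rows = []
hop_rows = []
for s, (sc, stack, fc) in enumerate(subjects):
    r2, n_used = global_coupling(fc, stack)
    for lbl, v, n in zip(labels, r2, n_used):
        rows.append({"subject": s, "predictor": lbl, "r2": v, "n_used": n})
    hops, hr2 = hop_decomposition(fc, stack, sc)
    for hi, h in enumerate(hops):
        for lbl, v in zip(labels, hr2[hi]):
            hop_rows.append({"subject": s, "hops": int(h), "predictor": lbl,
                             "r2": v})

glob = pd.DataFrame(rows)
glob.to_csv(OUT / "global_coupling.tsv", sep="\t", index=False)
hop = pd.DataFrame(hop_rows)
hop.to_csv(OUT / "hop_decomposition.tsv", sep="\t", index=False)

mean_r2 = glob.groupby("predictor").r2.mean().sort_values(ascending=False)
print("top global predictors (mean R2 across subjects):")
print(mean_r2.head(8).round(3).to_string())
by_hop = hop.groupby("hops").r2.mean()
# note: unlike empirical FC, the synthetic mixture plants signal on all
# pairs alike, so no decay with hop distance is expected here
print("\nmean R2 by hop distance:")
print(by_hop.round(3).to_string())
print(f"wrote {OUT / 'global_coupling.tsv'} and {OUT / 'hop_decomposition.tsv'}")
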