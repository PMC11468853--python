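"""Sparsity sweep (0.05-0.30) and AUC summaries of all graph metrics."""
import pandas as pd

from klsnet.pipeline import stage_metrics
from study_config import study_config

out = stage_metrics(study_config())
table = pd.read_csv(out["metric_aucs"], sep="\t")
glob = table[table.node == "global"].pivot_table(index="metric", values="auc")
print(f"wrote {out['metric_aucs']} ({table.subject_id.nunique()} subjects)")
print("cohort-mean global metric AUCs over the sparsity range:")
print(glob.round(4).to_string())
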