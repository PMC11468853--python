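"""Covariate-adjusted group tests, FDR, and network-based statistics."""
import json

import pandas as pd

from klsnet.pipeline import stage_nbs, stage_stats
from study_config import study_config

cfg = study_config()
stats_out = stage_stats(cfg)
gs = pd.read_csv(stats_out["group_stats"], sep="\t")
sig_nodal = gs[(gs.node != "global") & (gs.p_fdr < 0.05)]
sig_global = gs[(gs.node == "global") & (gs.p < 0.05)]
print("significant global metrics (p < 0.05):")
print(sig_global[["metric", "t", "p"]].to_string(index=False))
print("significant nodal metric AUCs (FDR p < 0.05):")
print(sig_nodal[["metric", "node", "t", "p", "p_fdr"]].to_string(index=False))

nbs_out = stage_nbs(cfg)
report = json.load(open(nbs_out["nbs_report"]))
for comp in report["components"]:
    tag = "SIGNIFICANT" if comp["p_fwe"] < 0.05 else "n.s."
    print(f"NBS component: {len(comp['nodes'])} nodes, {comp['size']} edges, "
          f"p_fwe = {comp['p_fwe']:.4f} [{tag}]")
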