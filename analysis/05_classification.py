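"""Nested-CV classification of patients vs controls from the significant
connectome features."""
import json

from klsnet.pipeline import stage_classify
from study_config import study_config

out = stage_classify(study_config())
cls = json.load(open(out["classification"]))
print(f"{out['n_features']} features entered the classifiers")
for model, d in cls["models"].items():
    print(f"{model.upper():4s} accuracy {d['accuracy']:.3f} "
          f"(perm p = {d['p_accuracy']:.4f}), AUC {d['auc']:.3f}, "
          f"sensitivity {d['sensitivity']:.3f}, specificity {d['specificity']:.3f}")
print("top-20% features shared by all models:", cls["top_shared_features"])
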