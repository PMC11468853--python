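"""Build each subject's KLS morphological similarity network."""
import json

from klsnet.pipeline import stage_network
from study_config import study_config

out = stage_network(study_config())
meta = json.load(open(out["meta"]))
print(f"wrote per-subject {len(meta['node_ids'])}x{len(meta['node_ids'])} "
      f"KLS matrices to {out['kls_dir']}")
print(f"KDE: gaussian kernel, {meta['bw_method']} bandwidth, "
      f"{meta['grid_size']}-point grid on {meta['grid_bounds']}")
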