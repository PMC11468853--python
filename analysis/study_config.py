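"""Shared configuration for the numbered analysis scripts.

The study runs the full individual-morphological-connectome pipeline on the
default planted-effect synthetic cohort (12 regions, 20 patients + 20
controls, a weakened 10-edge subnetwork among regions 1-5 and a weakened
node at region 8), writing every stage output under results/study/.
"""
from klsnet.pipeline import PipelineConfig


def study_config() -> PipelineConfig:
    return PipelineConfig(out_dir="results/study", seed=7)
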