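"""Chemist-instruction training with DPO: teach the model to prefer
molecules with an acyclic N–N bond (the photoswitch motif).

Runs one seed of the scaled-down comparison: the relaxed-criterion rate
of 500 fresh samples is measured before and after 300 DPO steps on 200
preference pairs (LoRA rank 8 on the attention projections, β = 0.1).
Expect a severalfold rate increase with sample validity retained.
Takes a few minutes on one CPU.
"""

from azogen.pipeline import PipelineConfig, instruction_training_experiment

result = instruction_training_experiment(seed=1, cfg=PipelineConfig())

n = result["n_samples"]
print(f"relaxed-criterion rate before DPO: {result['pre_relaxed']}/{n} "
      f"({100 * result['pre_relaxed'] / n:.1f}%)")
print(f"relaxed-criterion rate after  DPO: {result['post_relaxed']}/{n} "
      f"({100 * result['post_relaxed'] / n:.1f}%)")
print(f"sample validity: {result['pre_validity']:.2f} -> {result['post_validity']:.2f}")
# The direction (a severalfold increase in criterion-satisfying
# molecules at a fixed generation budget) is the reproducible claim of
# instruction training; exact counts vary with the seed.
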