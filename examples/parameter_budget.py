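"""The architecture's parameter budget, block by block and per ablation.

Builds the pinned reference configuration (22 electrodes, 750 samples,
4 classes) and prints where its 10,824 trainable parameters live, then
the totals for all eight ablation variants — removing a block always
shrinks the model, the triple ablation being smallest.
"""

from mstsefnet import (ABLATION_VARIANTS, build_model, count_parameters,
                       make_ablation_variant)
from mstsefnet.model import architecture_summary, reference_config

cfg = reference_config()
model = build_model(cfg, seed=0)
print(f"reference configuration: {cfg.n_channels} ch x {cfg.n_samples} samples, "
      f"{cfg.n_classes} classes")
print(f"total trainable parameters: {count_parameters(model)}\n")

by_block: dict[str, int] = {}
for row in architecture_summary(model):
    block = row["layer"].split(".")[0].split("[")[0]
    by_block[block] = by_block.get(block, 0) + row["parameters"]
for block, n in by_block.items():
    print(f"  {block:14s} {n:6d}")

print("\nablation variants:")
for v in ABLATION_VARIANTS:
    n = count_parameters(build_model(make_ablation_variant(cfg, v), seed=0))
    print(f"  {v:16s} {n:6d}")
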