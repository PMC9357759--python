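"""Two-stream score fusion: joint coordinates vs bone vectors.

Trains one classifier on raw joint coordinates and a second on per-bone
coordinate differences (child minus parent along the skeleton tree), then
combines their class probabilities as alpha*u_joint + (1-alpha)*u_bone
over a grid of fusion weights.
"""

from msstgcn import ModelConfig
from msstgcn.training_eval import two_stream_alpha_sweep

small = ModelConfig(num_classes=4, num_layers=3, channel_plan=(8, 8, 16), gamma=4)
result = two_stream_alpha_sweep(
    seed=5, num_classes=4, n_train=14, n_test=6, epochs=18,
    model_config=small, csv_path="/tmp/alpha_sweep.csv",
)

print("alpha   fused top-1")
for alpha, acc in result["sweep"].items():
    marker = "  <- best" if alpha == result["best_alpha"] else ""
    print(f"{alpha:>5.1f}   {100 * acc:>6.1f}%{marker}")
print(f"\nbest fusion weight on this run: alpha = {result['best_alpha']}")
print("wrote /tmp/alpha_sweep.csv (alpha, top1_percent)")
print("(alpha = 1 would trust only the joint stream, alpha = 0 only the bone stream)")
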