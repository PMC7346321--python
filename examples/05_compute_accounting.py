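"""Analytic cost and receptive-field accounting of the pyramid CNN.

With the number of feature maps fixed, each stride-2 max-pooling halves
the representation length, so per-block multiply-accumulate cost halves at
every level and the total stays below twice the first block regardless of
depth. Meanwhile the receptive field of a deep feature roughly doubles per
downsampling, covering distances of order 2**L.
"""

from endcnn import EnDCNNConfig, count_macs, cumulative_stride, receptive_field

cfg = EnDCNNConfig()  # depth 15 = region embedding + 7 blocks x 2 conv layers
L = 1024
macs = count_macs(cfg, L)
print(f"document length {L}, {cfg.num_blocks} blocks, m={cfg.feature_maps}:")
for i, c in enumerate(macs):
    ratio = f"  (x{c / macs[i - 1]:.2f})" if i else ""
    print(f"  block {i}: {c:>13,} MACs{ratio}")
print(f"total / first block = {sum(macs) / macs[0]:.4f}  (bounded by 2)")

print("\nreceptive field by number of pooling stages:")
for pools in range(0, 11, 2):
    print(f"  L={pools:>2}: stride {cumulative_stride(pools):>5}, "
          f"covers {receptive_field(cfg, pools):>6} characters")
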