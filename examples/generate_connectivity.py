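"""Counter-based connectivity weights: reproducible without storage.

Generates a gaussian weight matrix from the stateless Squares generator,
then regenerates single entries directly from their (i, j) address —
the reason the hardware can produce weights in-stream instead of
consuming DRAM bandwidth for them.
"""

import numpy as np

import ehhsim as e

key = e.make_key(2024)
print(f"Squares key from seed 2024: {key:#018x}")

n = 100
w = e.generate_weights(n, "gaussian", key=key, mu=0.5, sigma=0.15, symmetric=True)
off = w[~np.eye(n, dtype=bool)]
print(f"{n}x{n} gaussian weights: mean {off.mean():.4f}, sd {off.std():.4f}, "
      f"range [{off.min():.4f}, {off.max():.4f}]")

i, j = 17, 83
direct = e.weight_entry(i, j, n, "gaussian", key=key, symmetric=True)
print(f"entry ({i},{j}) regenerated without the matrix: {direct:.12f}")
print(f"matches stored matrix exactly: {direct == w[i, j]}")

u = e.uniform01(np.arange(10_000, dtype=np.uint64), key)
print(f"10k uniforms: mean {u.mean():.4f} (expect 0.5), "
      f"min {u.min():.2e}, max {u.max():.6f} — all inside [0, 1)")
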