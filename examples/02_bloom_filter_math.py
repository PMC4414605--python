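"""Bloom-filter parameter math and an empirical check.

With r bits per inserted element and k hash functions, the false-positive
rate is F = (1 - e^(-k/r))^k; the optimal k is r*ln(2), where F = 0.6185^r.
At the default r=8 this gives k=5 and F just above 2%. The empirical rate
of a real filter built at those parameters should match the model closely.
"""

import math

from dispatchmap import BloomFilter, fpr, optimal_k
import numpy as np

k = optimal_k(8)
print(f"default: r=8 bits/element -> k={k} hash functions, "
      f"model FPR = {100 * fpr(8, k):.3f}%")
print(f"closed form at real-valued optimum: "
      f"F^(1/r) = {fpr(16, 16 * math.log(2)) ** (1 / 16):.4f} (any r)")

# empirical check: 20,000 random 20-mers in, 20,000 negatives queried
rng = np.random.default_rng(0)
bases = np.frombuffer(b"ACGT", dtype=np.uint8)
kmers = {row.tobytes().decode() for row in rng.choice(bases, size=(40_000, 20))}
kmers = sorted(kmers)[:40_000]
n = 20_000
f = BloomFilter(m=8 * n, k=k, b=20)
for key in kmers[:n]:
    f.insert(key)
hits = sum(f.contains(key) for key in kmers[n : 2 * n])
print(f"empirical FPR over {n} negative queries: {100 * hits / n:.3f}% "
      f"(model {100 * fpr(8, k):.3f}%)")
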