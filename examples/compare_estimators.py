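"""Compare the six between-node dependence measures on one edge.

Generates a linear edge and a cosine edge of equal designed strength and
shows what each estimator reports.  Pearson and Spearman see almost nothing
on the cosine edge (cos is an even function of a symmetric parent), while
the maximal correlation coefficient recovers the full strength in both
cases — the property the pathway benchmark exploits.
"""

import numpy as np

from mccsp import METHOD_NAMES, edge_strength

rng = np.random.default_rng(0)
n, w = 500, 0.9
x = rng.standard_normal(n)

phi = (np.cos(x) - np.cos(x).mean()) / np.cos(x).std()
edges = {
    "linear": w * x + np.sqrt(1 - w**2) * rng.standard_normal(n),
    "cosine": w * phi + np.sqrt(1 - w**2) * rng.standard_normal(n),
}

print(f"designed strength corr(phi(x), y) = {w}")
print(f"{'measure':>10} {'linear edge':>12} {'cosine edge':>12}")
for m in METHOD_NAMES:
    vals = [edge_strength(x, y, m) for y in edges.values()]
    print(f"{m:>10} {vals[0]:12.3f} {vals[1]:12.3f}")

print("\nmi is in nats (unbounded above); all others lie in [0, 1]. "
      "Only mcc tracks the designed strength on the nonlinear edge.")
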