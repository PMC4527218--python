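"""Coverage-uniformity diagnostics: normalized depth, Poisson reference, GC strata.

Builds MDA-like (over-dispersed) and DOP-like (even) 100 kb depth tracks,
normalizes them, and compares their spread against the Poisson(30) no-bias
reference; windows are also stratified by GC content.
"""

import numpy as np
import pandas as pd

from scwga import (
    DepthTrack,
    gc_stratify,
    normalized_depth,
    pairwise_reproducibility,
    poisson_reference,
)

rng = np.random.default_rng(11)
n = 2000


def track(dispersion, seed):
    r = np.random.default_rng(seed)
    depth = 30.0 * r.lognormal(0, dispersion, n)
    return DepthTrack(pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n) * 100_000,
        "end": (np.arange(n) + 1) * 100_000,
        "depth": depth,
        "gc": r.uniform(0.25, 0.60, n),
    }))


iqr = lambda v: float(np.subtract(*np.percentile(v, [75, 25])))  # noqa: E731

mda = track(0.6, 1)
dop = track(0.15, 2)
reference = poisson_reference(lam=30.0, n_draws=1000, seed=3)

for name, t in (("MDA-like", mda), ("DOP-like", dop)):
    norm = normalized_depth(t)["normalized_depth"]
    print(f"{name:9s} normalized depth IQR = {iqr(norm):.3f}")
print(f"Poisson(30) reference IQR      = {iqr(reference.normalized):.3f}")

labels = gc_stratify(mda)
counts = {s: int((labels == s).sum()) for s in ("LowGC", "MiddleGC", "HighGC")}
print(f"GC strata of MDA-like track    : {counts}")

corr = pairwise_reproducibility([
    normalized_depth(track(0.15, s))["normalized_depth"] for s in (4, 5)
])
print(f"DOP-like replicate correlation = {corr[0, 1]:.3f}")
# The wider the normalized-depth IQR relative to the Poisson reference, the
# stronger the amplification bias; independent replicates of an even method
# stay uncorrelated only through noise (flat truth), so |r| is small here.
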