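"""Measure the null calibration of the smaller-tail bootstrap p-value.

The smaller-tail convention (the lesser of the two tail fractions around
zero, not doubled) is a one-sided quantity: under independence its null
distribution is close to uniform on [0, 0.5], so thresholding it at 0.05
rejects about twice the nominal rate even asymptotically, and the pairs
bootstrap of Pearson r is further anticonservative at n = 16.  This driver
quantifies both conventions so users can choose deliberately.
"""

import numpy as np

from megnpt.stats import bootstrap_correlation

SEED = 2026
N = 16
REPLICATES = 1000
RESAMPLES = 2000


def main() -> None:
    rng = np.random.default_rng(SEED)
    p = np.empty(REPLICATES)
    for i in range(REPLICATES):
        x = rng.standard_normal(N)
        y = rng.standard_normal(N)
        p[i] = bootstrap_correlation(x, y, n_resamples=RESAMPLES,
                                     seed=int(rng.integers(2**31))).p_value
    lit = float(np.mean(p <= 0.05))
    two = float(np.mean(2 * p <= 0.05))
    print(f"null rejection at p <= 0.05 (independent normals, n = {N}, "
          f"{REPLICATES} replicates x {RESAMPLES} resamples):")
    print(f"  smaller-tail (as reported): {lit:.3f}")
    print(f"  doubled / two-sided:        {two:.3f}")
    print("  nominal level:              0.050")
    print("takeaway: treat smaller-tail p-values as one-sided quantities; use")
    print("--two-sided for conventional two-sided inference, and expect mild")
    print("anticonservativeness at n = 16 either way")


if __name__ == "__main__":
    main()
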