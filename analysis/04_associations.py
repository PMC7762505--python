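"""Bootstrap-correlation scan over the full variable family with BH-FDR.

Joins the spectral summaries with the derived scores into one row per
participant and tests every unordered pair among: age, treatment exposure
(period days, session count, session frequency), both instruments' initial,
last, estimated, change and estimated-change scores, and the three spectral
parameters (MF, IAF, SE).  20,000 paired resamples per pair; one BH family
across all pairs.
"""

from pathlib import Path

from megnpt.io import read_table, write_table
from megnpt.pipeline import DEFAULT_FAMILY, wide_table
from megnpt.stats import pairwise_association_scan

SEED = 2026
RESULTS = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    scores = read_table(RESULTS / "scores.tsv")
    spectra = read_table(RESULTS / "spectral.tsv")
    wide = wide_table(scores, spectra)
    write_table(wide, RESULTS / "wide.tsv")
    family = [v for v in DEFAULT_FAMILY if v in wide.columns]
    assoc = pairwise_association_scan(wide, family, n_resamples=20000, seed=SEED)
    write_table(assoc, RESULTS / "associations.tsv")
    print(f"wrote {RESULTS / 'associations.tsv'} ({len(assoc)} pairs)")
    hits = assoc[assoc.reject]
    print(f"  {len(hits)} pairs rejected at q = 0.05:")
    for _, row in hits.iterrows():
        print(f"    {row.var_x:>16s} ~ {row.var_y:<16s} r = {row.r:+.2f}  "
              f"p = {row.p:.4f}  q = {row.q:.4f}")
    spectral_hits = hits[(hits.var_x.isin(["mf", "iaf", "se"]))
                         | (hits.var_y.isin(["mf", "iaf", "se"]))]
    print(f"  of which involving a spectral parameter: {len(spectral_hits)}")


if __name__ == "__main__":
    main()
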