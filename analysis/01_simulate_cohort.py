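"""Simulate the study-scale synthetic cohort.

Generates 16 participants with MMSE-like and ADAS-like assessments around a
126-245 day treatment period, one resting-state recording spec each, and a
built-in correlation of -0.5 between the recording's median frequency and
the score change.  Writes the cohort table and reports the realised latent
correlation and any score-clipping events.
"""

from pathlib import Path

from megnpt.io import write_table
from megnpt.synth import CohortSpec, simulate_cohort

SEED = 2026
RESULTS = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    cspec = CohortSpec(n_participants=16, target_mf_outcome_corr=-0.5, seed=SEED)
    cohort, specs, info = simulate_cohort(cspec)
    write_table(cohort, RESULTS / "cohort.tsv")
    print(f"wrote {RESULTS / 'cohort.tsv'} ({len(cohort)} rows, {len(specs)} recordings)")
    for inst, r in info.realized_latent_corr.items():
        print(f"  realised MF-outcome correlation ({inst}): {r:+.3f} (target -0.5)")
    print(f"  score clipping events: {info.n_clipped}")
    print("  note: at n = 16 the realised correlation scatters widely around the target")


if __name__ == "__main__":
    main()
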