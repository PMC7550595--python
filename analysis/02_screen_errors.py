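"""Screen every locus × population for genotyping errors.

Runs the Micro-Checker-style diagnostics (null alleles, stutter,
large-allele dropout) on the pooled sample of each population of the
study-like synthetic dataset and tabulates the flags next to the loci
that truly carry a simulated null allele.
"""

import argparse
from pathlib import Path

import pandas as pd

from matearray.error_screen import screen_dataset
from matearray.simulate import STUDY_NULL_LOCI, generate_study_like_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--reps", type=int, default=1000)
    ap.add_argument("--out", type=Path, default=Path("scratch/analysis"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    dataset, _ = generate_study_like_dataset(args.seed)
    results = screen_dataset(dataset, alpha=args.alpha, n_reps=args.reps,
                             seed=args.seed)
    rows = [
        {
            "population": r.population, "locus": r.locus,
            "null_flag": r.null_allele_flag, "stutter_flag": r.stutter_flag,
            "dropout_flag": r.dropout_flag,
            "null_frequency": round(r.null_frequency_estimate, 4),
            "mc_p": round(r.monte_carlo_p, 4),
            "truly_null": r.locus in STUDY_NULL_LOCI.get(r.population, []),
        }
        for r in results
    ]
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "error_screen.tsv", sep="\t", index=False)

    hits = table[table.truly_null & table.null_flag]
    seeded = table[table.truly_null]
    fp = table[~table.truly_null & table.null_flag]
    print(f"seeded null loci detected: {len(hits)}/{len(seeded)}")
    print(f"false positives (family-structure bias expected): {len(fp)}")
    print(table[table.null_flag | table.stutter_flag | table.dropout_flag]
          .to_string(index=False))


if __name__ == "__main__":
    main()
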