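#!/usr/bin/env python
"""Report the sex-association outcome of the screen.

Reads results/screen/screen_results.tsv, compares every chimera's detection
counts against the -log10 p cutoff of 1.3, and checks the findings against
the planted ground truth in results/cohort/truth.tsv.
"""

from pathlib import Path

import pandas as pd

from chimscreen.simulate import ROLE_PLANTED, read_truth

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    df = pd.read_csv(BASE / "screen" / "screen_results.tsv", sep="\t")
    truth = read_truth(BASE / "cohort" / "truth.tsv")
    planted_keys = {r.chimera_key for r in truth.by_role(ROLE_PLANTED)}

    print(f"chimeras tested: {df['p'].notna().sum()}")
    sig = df[df["significant"]]
    print(f"significant at -log10 p >= 1.3: {len(sig)}")
    for row in sig.itertuples(index=False):
        key = (row.gene5, row.gene3, row.pos5, row.pos3)
        tag = "PLANTED" if key in planted_keys else "background (false positive)"
        print(
            f"  {row.gene5}-{row.gene3}: {row.n_female_detected} F / "
            f"{row.n_male_detected} M detected, chi2={row.chi2:.1f}, "
            f"-log10 p={row.neg_log10_p:.2f}, %female={row.pct_female:.1f}  [{tag}]"
        )
    recovered = planted_keys <= {
        (r.gene5, r.gene3, r.pos5, r.pos3) for r in sig.itertuples(index=False)
    }
    print(f"planted chimera recovered: {recovered}")


if __name__ == "__main__":
    main()
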