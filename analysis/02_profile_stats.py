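#!/usr/bin/env python
"""Per-variable statistics: derived sums/ratios, means ± SE, Mann-Whitney.

Appends the default derived variables (class sums, product/precursor
ratios, double bond index, average chain length) to the cohort table and
tests every variable between RA and OA with the exact Mann-Whitney U
test (n = 8 + 8).  Writes the full statistics table under results/.
"""

from pathlib import Path

from lipidsig.io import read_profile_table
from lipidsig.profiles import compare_groups, compute_derived

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pm = compute_derived(read_profile_table(OUT / "cohort.tsv"))
    table = compare_groups(pm, by="diagnosis", alpha=0.05)
    table.to_csv(OUT / "group_stats.tsv", sep="\t")
    sig = table[table["significant"]].sort_values("p")
    print(f"{len(table)} variables tested; "
          f"{len(sig)} significant at p <= 0.05:")
    for var, row in sig.iterrows():
        direction = "higher" if row["mean_RA"] > row["mean_OA"] else "lower"
        print(f"  {var}: {direction} in RA "
              f"(RA {row['mean_RA']:.3g} vs OA {row['mean_OA']:.3g}, "
              f"p = {row['p']:.3g})")


if __name__ == "__main__":
    main()
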