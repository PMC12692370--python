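"""Expand diagnostic categories into homogeneous prefix groups.

Reads results/cohort.tsv and results/code_map.tsv (from 01_simulate_cohort),
runs the recursive threshold-driven subdivision, and writes the group table
and patient assignments.  Reports how the group count scales with the
threshold — the homogeneity/df trade-off at the heart of the expansion.
"""

import pathlib

import casemix as cm

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = cm.synthetic.read_cohort(OUT / "cohort.tsv")
    code_map = cm.load_code_map(OUT / "code_map.tsv")

    grouping = cm.expand_categories(cohort, code_map)  # default: 0.3% of n
    grouping.groups_table().to_csv(OUT / "groups.tsv", sep="\t", index=False)
    grouping.assignment_table().to_csv(OUT / "assignments.tsv", sep="\t",
                                       index=False)
    print(f"threshold T={grouping.threshold_used} -> {grouping.n_groups} groups "
          f"from {len(code_map.categories())} categories")

    print("\nthreshold sweep (fraction of cohort -> groups):")
    for frac in (0.05, 0.02, 0.01, 0.003, 0.001):
        g = cm.expand_categories(cohort, code_map, threshold_fraction=frac)
        print(f"  {frac:>6.3f}  T={g.threshold_used:>5d}  groups={g.n_groups}")


if __name__ == "__main__":
    main()
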