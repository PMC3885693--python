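"""Recruitment structure: waves, tree sizes, channels, graph exports.

Reads results/cohort.csv (run 01_simulate_cohort.py first), reconstructs
the recruitment forest, tallies recruitment success per invitation channel,
and exports the trees as GraphML/DOT for graph tooling.
"""

from collections import Counter
from pathlib import Path

from rdsnet import build_forest, export_forest, read_participants, recruitment_summary

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_participants(RESULTS / "cohort.csv")
    forest = build_forest(records)

    sizes = Counter(len(m) for m in forest.components().values())
    waves = Counter(forest.wave.values())
    print(f"{len(forest)} participants in {len(forest.components())} trees")
    print("tree-size distribution:", dict(sorted(sizes.items())))
    print("participants per wave:", dict(sorted(waves.items())))
    multi = sum(1 for m in forest.components().values() if len(m) >= 2)
    print(f"{multi} trees with two or more participants")

    summary = recruitment_summary(records, forest)
    summary["by_channel"].to_csv(RESULTS / "recruitment_by_channel.csv")
    print("\nrecruiters by number of successful recruitments (rows: channel):")
    print(summary["by_channel"].to_string())
    print(
        f"\n{summary['coupons_issued']} coupons issued; "
        f"{summary['entries']} entries ({summary['entry_rate']:.1%}); "
        f"{summary['completions']} completions ({summary['completion_rate']:.1%})"
    )

    (RESULTS / "forest.graphml").write_text(export_forest(forest, "graphml", records))
    (RESULTS / "forest.dot").write_text(export_forest(forest, "dot", records))
    print(f"\ngraph exports written to {RESULTS}/forest.graphml and .dot")


if __name__ == "__main__":
    main()
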