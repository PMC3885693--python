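"""Intraclass correlations: how homogeneous are recruitment trees?

Fits the intercept-only two-level model (respondents within recruitment
components) by REML for each analysis variable and reports
ICC = s2_between / (s2_between + s2_within).
"""

from pathlib import Path

from rdsnet import build_forest, icc_report, read_participants

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_participants(RESULTS / "cohort.csv")
    forest = build_forest(records)
    table = icc_report(records, forest)
    table.to_csv(RESULTS / "icc.csv", index=False)
    print("intraclass correlations (two-level REML):")
    print(table.round(3).to_string(index=False))
    high = table[table["icc"] > 0.1]["attribute"].tolist()
    print(
        f"\nvariables with appreciable within-tree homogeneity (ICC > 0.1): "
        f"{', '.join(high) if high else 'none'}"
    )


if __name__ == "__main__":
    main()
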