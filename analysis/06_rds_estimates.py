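"""Volz-Heckathorn population estimates and equilibrium diagnostics.

Inverse-degree-weighted population shares for gender and education, plus
sample-composition curves over waves and over increasing sample size (the
visual check of whether composition stabilised away from the seeds).
"""

from pathlib import Path

from rdsnet import build_forest, composition_curves, read_participants, vh_estimate

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_participants(RESULTS / "cohort.csv")
    forest = build_forest(records)

    for attribute in ("gender", "education"):
        est = vh_estimate(records, attribute)
        est.as_frame().to_csv(RESULTS / f"vh_{attribute}.csv", index=False)
        print(f"{attribute}: raw vs Volz-Heckathorn shares "
              f"(n={est.n_used}, excluded={est.excluded})")
        print(est.as_frame().round(3).to_string(index=False))
        print()

        curves = composition_curves(records, forest, attribute)
        curves["by_wave"].to_csv(
            RESULTS / f"composition_{attribute}_by_wave.csv", index=False)
        curves["by_sample_size"].to_csv(
            RESULTS / f"composition_{attribute}_by_size.csv", index=False)
    print(f"composition curves written to {RESULTS}")


if __name__ == "__main__":
    main()
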