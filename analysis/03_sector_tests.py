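"""Per-sector genotype comparison of the patterning profiles, by region.

Two-sided per-sector t-tests on per-cochlea sector frequencies (control vs
knockout, n = 3 each), with raw p driving the significance stars and
BH-adjusted p reported alongside. Writes results/sector_tests_<region>.csv.
"""

from pathlib import Path

from cortiquant import StarConfig, read_mosaics, run_experiment_comparison

OUT = Path("results")
STAR = StarConfig(axis_mode="given", given_axis_angle=0.0)


def main() -> None:
    mosaics = read_mosaics(OUT / "mosaics.csv")
    for region in ("base", "mid", "apex"):
        ctrl = [m for m in mosaics if m.region == region and m.genotype == "control"]
        tko = [m for m in mosaics if m.region == region and m.genotype == "etv_tko"]
        report = run_experiment_comparison(ctrl, tko, STAR)
        path = OUT / f"sector_tests_{region}.csv"
        report.sector_tests.to_csv(path, index=False)
        sig = report.sector_tests[report.sector_tests["label"] != ""]
        print(f"{region}: {len(sig)}/16 sectors differ (raw p < 0.05): "
              f"{list(sig['sector'])}")
    print(f"wrote {OUT}/sector_tests_<region>.csv")


if __name__ == "__main__":
    main()
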