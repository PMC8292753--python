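"""Light-exposure characterization of the synthetic cohort.

Window AUC metrics for every observation day (individual and outdoor),
seasonal Tukey comparisons of total daily exposure, and the RSE of the
four fixed-duration windows (which time of day is most/least variable).
Per-day tables land in scratch/run; cohort summaries in results/.
"""
from pathlib import Path

import pandas as pd

from circalux.ingest import Manifest
from circalux.inference import seasonal_comparison
from circalux.light import relative_standard_error
from circalux.pipeline import stage_light

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"

FIXED = [
    "fixed_morning_0500_1100", "fixed_afternoon_1100_1700",
    "fixed_evening_1700_2300", "fixed_latenight_2300_0500",
]


def main():
    manifest = Manifest.load(ROOT / "scratch" / "cohort" / "manifest.yaml")
    RUN.mkdir(parents=True, exist_ok=True)
    stage_light(manifest, RUN)

    exposures = pd.read_csv(RUN / "exposures.csv")
    summary = pd.read_csv(RUN / "exposure_summary.csv")
    summary.to_csv(RESULTS / "light_exposure_summary.csv", index=False)

    ind = exposures[exposures["role"] == "individual"]
    rse_rows = [
        {"window": w,
         "rse_pct": relative_standard_error(
             ind.loc[ind["window"] == w, "auc_log10lux_min"].dropna())}
        for w in FIXED
    ]
    rse = pd.DataFrame(rse_rows).sort_values("rse_pct", ascending=False)
    rse.to_csv(RESULTS / "rse_fixed_windows.csv", index=False)
    print("RSE of fixed windows (individuals), most variable first:")
    print(rse.to_string(index=False))

    for role in ("individual", "outdoor"):
        tot = exposures[(exposures["role"] == role) & (exposures["window"] == "total_day")]
        groups = {s: g["auc_log10lux_min"].dropna().to_numpy()
                  for s, g in tot.groupby("season")}
        tukey = seasonal_comparison(groups)
        tukey.to_csv(RESULTS / f"tukey_total_day_{role}.csv", index=False)
        sig = tukey[tukey["p_adj"] < 0.05]
        print(f"\nTukey ({role} total-day AUC): "
              f"{len(sig)}/{len(tukey)} season pairs differ at 0.05")
        if len(sig):
            print(sig.to_string(index=False))


if __name__ == "__main__":
    main()
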