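"""Generate the default synthetic cohort.

Writes the sensor-file tree (outdoor sites + participants, four seasons)
under scratch/cohort and a small per-season bookkeeping table under
results/. Downstream drivers (02-05) consume the manifest written here.
"""
from pathlib import Path

import pandas as pd

from circalux.ingest import Manifest
from circalux.synth import SynthParams, gen_cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 0


def main():
    params = SynthParams(seed=SEED)
    mpath = gen_cohort(params, ROOT / "scratch" / "cohort")
    manifest = Manifest.load(mpath)

    rows = []
    for season in params.seasons:
        n_part = params.participants_per_season[season]
        rows.append(
            {
                "season": season,
                "participants": n_part,
                "days_per_participant": params.days_per_season,
                "pre_qc_days": n_part * params.days_per_season,
                "outdoor_sites": 2,
            }
        )
    table = pd.DataFrame(rows)
    out = ROOT / "results" / "cohort_counts.csv"
    out.parent.mkdir(exist_ok=True)
    table.to_csv(out, index=False)

    print(f"cohort manifest: {mpath} ({len(manifest.entries)} sensor files)")
    print(table.to_string(index=False))
    print(f"total pre-QC observation days: {table['pre_qc_days'].sum()}")


if __name__ == "__main__":
    main()
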