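"""Process the simulated cohort into weekly mobility-indicator matrices.

Reads the raw fixes written by 01_simulate.py (regenerates them when
absent), runs outlier removal, 3 AM day splitting, stop/move segmentation,
validity assessment and inclusion for each of the five data conditions
(3d/8h ... 5d/10h), and writes per-condition indicator matrices, the
inclusion grid and a descriptive-statistics table under results/.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from mobispace.pipeline import (
    PipelineConfig,
    descriptive_stats,
    preprocess_participant,
    process_cohort,
    write_indicator_matrix,
    write_segments_csv,
)
from mobispace.synthetic import generate_cohort
from mobispace.trajectory import HomeLocation, Trajectory, read_fixes

SEED = 1
RUN_SEED = 1


def load_cohort():
    raw = ROOT / "scratch" / "cohort"
    files = sorted(raw.glob("P*_fixes.csv"))
    if not files:
        print("raw fixes not found; regenerating cohort")
        return [(t, a) for t, _, a, _ in generate_cohort(n=95, rng_seed=SEED)]
    import json

    cohort = []
    for f in files:
        (traj,) = read_fixes(f)
        gt = json.loads((raw / f"{traj.participant_id}_truth.json").read_text())
        addr = HomeLocation(gt["address_home"]["lat"], gt["address_home"]["lon"])
        cohort.append((traj, addr))
    return cohort


def main() -> None:
    res = ROOT / "results" / "processing"
    res.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig()

    cohort = load_cohort()
    pweeks = [preprocess_participant(t, a, config) for t, a in cohort]
    write_segments_csv(pweeks, res)

    grid = []
    for condition in config.conditions:
        matrix, report = process_cohort(pweeks, condition, run_seed=RUN_SEED, config=config)
        key = f"{condition[0]}d_{condition[1]:g}h"
        write_indicator_matrix(matrix, res / f"indicators_{key}.csv", run_id=0, seed=RUN_SEED)
        report.to_csv(res / f"inclusion_{key}.csv", index=False)
        grid.append({"condition": key, "n_included": len(matrix)})
        if condition == (3, 8.0):
            stats = descriptive_stats(matrix)
            stats.to_csv(res / "descriptives_3d_8h.csv")
            print(f"\ndescriptive statistics, condition {key} (n={len(matrix)}):")
            print(
                stats.loc[
                    ["TOH", "MaxDist", "CHull", "NumLoc", "DurATM", "DurPTM", "RevisitedLS"]
                ].round(2).to_string()
            )

    grid_df = pd.DataFrame(grid)
    grid_df.to_csv(ROOT / "results" / "inclusion_grid.csv", index=False)
    print("\nparticipants included per data condition:")
    print(grid_df.to_string(index=False))


if __name__ == "__main__":
    main()
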