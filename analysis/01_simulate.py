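"""Simulate the synthetic study cohort.

Generates 95 participant-weeks of GPS fixes (one week each, home anchor,
out-of-home visits, walk/vehicle trips, GPS noise, in-building signal
gaps), writes the raw fixes and the planted ground truth under scratch/
(large, regenerable) and a small cohort summary under results/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from mobispace.pipeline import PipelineConfig
from mobispace.synthetic import generate_cohort
from mobispace.trajectory import haversine_km

SEED = 1
N_PARTICIPANTS = 95


def main() -> None:
    out_raw = ROOT / "scratch" / "cohort"
    out_raw.mkdir(parents=True, exist_ok=True)
    res = ROOT / "results"
    res.mkdir(exist_ok=True)

    cohort = generate_cohort(n=N_PARTICIPANTS, rng_seed=SEED)

    summary = []
    for traj, truth, address, profile in cohort:
        rows = [
            {
                "participant_id": f.participant_id,
                "timestamp": f.timestamp.isoformat(),
                "lat": f.lat,
                "lon": f.lon,
            }
            for f in traj.fixes
        ]
        pd.DataFrame(rows).to_csv(out_raw / f"{traj.participant_id}_fixes.csv", index=False)
        gt = {
            "participant_id": truth.participant_id,
            "address_home": {"lat": address.lat, "lon": address.lon},
            "scheduled_oh_min": truth.total_scheduled_oh_min,
            "days": [
                {
                    "date": d.logical_date.isoformat(),
                    "n_stops": len(d.stops),
                    "n_trips": len(d.trips),
                    "scheduled_oh_min": d.scheduled_oh_min,
                }
                for d in truth.days
            ],
        }
        (out_raw / f"{truth.participant_id}_truth.json").write_text(json.dumps(gt, indent=2))
        summary.append(
            {
                "participant_id": traj.participant_id,
                "n_fixes": len(traj.fixes),
                "scheduled_oh_min_per_day": truth.total_scheduled_oh_min / 7,
                "address_error_m": haversine_km(
                    profile.home.lat, profile.home.lon, address.lat, address.lon
                )
                * 1000,
                "extent_scale_km": profile.extent_scale_km,
                "timing_mode": profile.timing_mode,
            }
        )

    df = pd.DataFrame(summary)
    df.to_csv(res / "cohort_summary.csv", index=False)
    (res / "simulation_config.json").write_text(
        json.dumps({"seed": SEED, "n": N_PARTICIPANTS, "pipeline": json.loads(PipelineConfig().to_json())}, indent=2)
    )

    print(f"simulated {len(cohort)} participant-weeks (seed {SEED})")
    print(f"median fixes per participant: {df.n_fixes.median():.0f}")
    print(f"median scheduled OH time: {df.scheduled_oh_min_per_day.median():.0f} min/day")
    print(f"participants with address error > 170 m: {(df.address_error_m > 170).sum()}")
    print(f"raw fixes under {out_raw}, summary under {res / 'cohort_summary.csv'}")


if __name__ == "__main__":
    main()
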