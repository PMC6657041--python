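"""Exploratory factor analysis of the weekly mobility indicators.

For each of the five data conditions, repeats the EFA ten times while
re-drawing the random study-day selection: transformation, KMO/Bartlett,
non-graphical scree factor-count estimation, ML extraction with varimax
rotation, and the cross-run pair matrix. Writes the full report JSON, an
exemplary loading table, and pair-matrix heatmaps under results/efa/.
"""

import json
import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from mobispace.pipeline import PipelineConfig, preprocess_participant, run_cohort_study
from mobispace.synthetic import generate_cohort

SEED = 1
BASE_SEED = 1


def main() -> None:
    res = ROOT / "results" / "efa"
    res.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig()

    cohort = generate_cohort(n=95, rng_seed=SEED)
    pweeks = [preprocess_participant(t, a, config) for t, _, a, _ in cohort]

    report = run_cohort_study(pweeks, config=config, base_seed=BASE_SEED)
    (res / "efa_report.json").write_text(json.dumps(report, indent=2))

    for key, cond in report["conditions"].items():
        ok_runs = [r for r in cond["runs"] if "error" not in r]
        failed = len(cond["runs"]) - len(ok_runs)
        ns = [r["n_factors"] for r in ok_runs]
        print(
            f"{key}: {len(ok_runs)} runs ok ({failed} failed), "
            f"chosen n_factors {sorted(ns)}"
        )
        if not ok_runs:
            continue
        # exemplary run: the first successful one
        ex = ok_runs[0]
        loadings = pd.DataFrame(ex["loadings"])
        loadings.to_csv(res / f"loadings_{key}_run{ex['seed']}.csv")
        print(
            f"  exemplary run: n_factors={ex['n_factors']}, "
            f"cumulative variance {100 * ex['cumulative_variance']:.0f}%, "
            f"fit p={ex['fit_p'] if ex['fit_p'] is None else round(ex['fit_p'], 3)}, "
            f"KMO={ex['kmo']:.2f}, Bartlett p={ex['bartlett_p']:.1e}"
        )

        if cond["pair_matrix"] is not None:
            pm = pd.DataFrame(cond["pair_matrix"])
            fig, ax = plt.subplots(figsize=(9, 8))
            im = ax.imshow(pm.to_numpy(), cmap="viridis", vmin=0, vmax=len(ok_runs))
            ax.set_xticks(range(len(pm)), pm.columns, rotation=90, fontsize=7)
            ax.set_yticks(range(len(pm)), pm.index, fontsize=7)
            fig.colorbar(im, label="co-appearances across runs")
            ax.set_title(f"Indicator pair matrix, condition {key}")
            fig.tight_layout()
            fig.savefig(res / f"pair_matrix_{key}.png", dpi=120)
            plt.close(fig)

    print(f"\nfull report: {res / 'efa_report.json'}")


if __name__ == "__main__":
    main()
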