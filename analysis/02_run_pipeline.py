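"""Run the full prioritisation pipeline on the simulated workspace.

Fits the maxent suitability model for the virtual species, projects it
onto the baseline and future climates, classifies habitat with the
LTP/maxSSS thresholds, computes habitat-area change, scores the shipped
scorecard, and builds the priority and comparison tables.  The small
summary tables are copied into results/; rasters stay in scratch/.

Run analysis/01_simulate.py first.
"""

import shutil
from pathlib import Path

import pandas as pd

from invrisk.pipeline import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
WORKSPACE = ROOT / "scratch" / "workspace"
RESULTS = ROOT / "results"


def main() -> None:
    if not (WORKSPACE / "config.yml").exists():
        raise SystemExit("workspace missing - run analysis/01_simulate.py first")
    cfg = RunConfig.from_yaml(WORKSPACE / "config.yml")
    manifest = run_pipeline(cfg)
    out = Path(cfg.out_dir)
    RESULTS.mkdir(exist_ok=True)
    for name in ("evaluation.csv", "change_metrics.csv", "risk_scores.csv",
                 "priority.csv", "comparison.csv"):
        shutil.copy(out / name, RESULTS / name)

    ev = pd.read_csv(RESULTS / "evaluation.csv", comment="#").iloc[0]
    pr = pd.read_csv(RESULTS / "priority.csv", comment="#").iloc[0]
    print(f"modelled {manifest['n_species_modelled']} species (seed {manifest['seed']})")
    print(
        f"held-out AUC {ev.auc_test:.3f} ({ev.auc_band}); thresholds "
        f"LTP={ev.t_low_ltp:.3f}, maxSSS={ev.t_high_maxsss:.3f}"
    )
    pct = (
        "new habitat"
        if pd.isna(pr["pct_change"])
        else f"{pr['pct_change']:+.0f}%"
    )
    print(
        f"{pr['species']}: {pr['category']} (score {pr['risk_score']:.1f}), "
        f"high-risk habitat {pr['area_baseline_km2']:,.0f} -> "
        f"{pr['area_future_km2']:,.0f} km2 ({pct}), "
        f"priority tier '{pr['priority_tier']}'"
    )


if __name__ == "__main__":
    main()
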