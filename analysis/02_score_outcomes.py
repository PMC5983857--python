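#!/usr/bin/env python
"""Filter asset records and score each target's net phase III outcome.

Reads the asset table written by 01_simulate_study.py, applies the four
eligibility filters (single target, human target, non-cancer indication,
definitive phase III outcome) and scores every target in the study
universe by its best remaining outcome.
"""

from pathlib import Path

import pandas as pd

from targetscreen import outcomes as oc
from targetscreen.pipeline import score_study_outcomes

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study_dir = ROOT / "scratch" / "study"
    records = oc.read_assets(study_dir / "assets.tsv")
    import json

    manifest = json.loads((study_dir / "manifest.json").read_text())
    universe = sorted(
        {
            g
            for entry in manifest["datasets"]
            for g in pd.read_csv(
                study_dir / entry["file"], sep="\t", usecols=[0]
            ).iloc[:, 0]
        }
    )
    kept = oc.filter_assets(records)
    scored, summary = score_study_outcomes(records, universe)
    oc.write_outcomes(scored, study_dir / "outcomes.tsv")

    out = ROOT / "results" / "02_outcome_summary.tsv"
    pd.DataFrame(
        [
            {"quantity": "asset_records", "value": len(records)},
            {"quantity": "qualifying_records", "value": len(kept)},
            {"quantity": "n_success", "value": summary.n_success},
            {"quantity": "n_fail", "value": summary.n_fail},
            {"quantity": "success_rate", "value": round(summary.success_rate, 4)},
        ]
    ).to_csv(out, sep="\t", index=False)
    print(
        f"{len(records)} asset records -> {len(kept)} qualifying; "
        f"{summary.n_success} successes / {summary.n_fail} failures "
        f"(success rate {summary.success_rate:.1%})"
    )


if __name__ == "__main__":
    main()
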