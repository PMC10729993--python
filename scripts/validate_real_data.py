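#!/usr/bin/env python
"""Optional validation against a user-supplied experimental score table.

The published activity analysis of designed Cas9 PID variants depends on an
experimental score table (per-variant normalized repression plus FoldX ddG,
AlphaFold2 RMSD and pLDDT columns) that is not distributed with this package.
If you have such a table, this script recomputes the activity-detection
AUROCs and the per-score summary from it.  Nothing here is exercised by the
automated test suite beyond its import and its behaviour on a synthetic
stand-in table.

Expected input: a TSV with columns
    seq_id  activity  [rbm_energy] [classifier_score] [ddg] [rmsd] [plddt]

Usage:
    python scripts/validate_real_data.py --scores scores.tsv --out report.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from rbmdesign.scoring_eval import activity_category, auroc_active

#: score columns and whether low or high values indicate activity
SCORE_ORIENTATIONS = {
    "rbm_energy": "low",
    "classifier_score": "high",
    "ddg": "low",
    "rmsd": "low",
    "plddt": "high",
}


def validate(scores: pd.DataFrame, threshold: float = 0.5) -> dict:
    if "activity" not in scores.columns:
        raise ValueError("score table must carry an 'activity' column (nr)")
    act = scores["activity"].to_numpy(dtype=float)
    report: dict = {
        "n_sequences": int(len(scores)),
        "activity_threshold": threshold,
        "categories": {},
        "auroc": {},
    }
    cats = [activity_category(a).value for a in act]
    for cat in set(cats):
        report["categories"][cat] = cats.count(cat)
    for col, orientation in SCORE_ORIENTATIONS.items():
        if col not in scores.columns:
            continue
        vals = scores[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        try:
            report["auroc"][col] = auroc_active(
                vals[ok], act[ok], threshold=threshold,
                orientation=orientation)
        except ValueError:
            report["auroc"][col] = None
    return report


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scores", type=Path, required=True,
                        help="TSV of per-variant activities and scores")
    parser.add_argument("--out", type=Path, default=None)
    parser.add_argument("--threshold", type=float, default=0.5)
    args = parser.parse_args()
    report = validate(pd.read_csv(args.scores, sep="\t"), args.threshold)
    text = json.dumps(report, indent=2)
    if args.out:
        args.out.parent.mkdir(parents=True, exist_ok=True)
        args.out.write_text(text + "\n")
    print(text)


if __name__ == "__main__":
    main()
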