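#!/usr/bin/env python
"""ROC validation of the classified maps against ground-truth points.

Draws 100 ground-truth points per ecosystem from the hidden simulation
labels, extracts the model class and score within a 300 m buffer, and
writes per-ecosystem confusion counts, AUC and the strong/moderate verdict
to results/validation_report.csv (plus per-ecosystem ROC curves).
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from ecodegrade.io import read_features
from ecodegrade.synthetic import SimulationSpec, simulate_validation_truth
from ecodegrade.validation import (extract_model_at_points, roc_auc,
                                   validation_report)

KINDS = ("grassland", "cave", "river", "lake", "coastal")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--landscape", type=Path, default=Path("scratch/landscape"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    spec = SimulationSpec(seed=args.seed)
    rows = []
    for kind in KINDS:
        feats = read_features(args.landscape / f"{kind}_scored.geojson", kind)
        pts = simulate_validation_truth(feats, spec, n_points=100)
        ex = extract_model_at_points(list(zip(pts.x, pts.y)), feats)
        keep = ex.in_buffer.to_numpy()
        truth = pts.truth.to_numpy()[keep]
        rep = validation_report(truth, ex.model_score.to_numpy()[keep],
                                ex.model_class[keep], ecosystem=kind)
        roc = roc_auc(truth, ex.model_score.to_numpy()[keep])
        pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(
            args.results / f"roc_{kind}.csv", index=False)
        rows.append(rep)
        print(f"{kind}: AUC = {rep['auc']:.3f} ({rep['verdict']}), "
              f"tp={rep['tp']} tn={rep['tn']} fp={rep['fp']} fn={rep['fn']}")

    pd.DataFrame(rows).to_csv(args.results / "validation_report.csv", index=False)


if __name__ == "__main__":
    sys.exit(main())
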