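#!/usr/bin/env python
"""Train the per-constituent PLSR models with MCCV and outlier screening.

Applies each constituent's winning preprocessing configuration (from
02_search_preprocessing.py), chooses the component count by Monte Carlo
cross-validation, screens the training set for outliers, fits the final
NIPALS model, and reports calibration and held-out test metrics.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from nirmap.io_formats import CONSTITUENTS, average_replicates, read_references, read_spectra
from nirmap.model_selection import detect_outliers, mccv
from nirmap.pls import fit_nipals, predict, rmse, spearman_rho
from nirmap.preprocessing import PreprocessConfig, apply_pipeline


def config_from_row(row) -> PreprocessConfig:
    ranges = tuple(
        tuple(float(v) for v in part.split("-")) for part in row["ranges"].split("+")
    )
    return PreprocessConfig(ranges, row["scatter"], int(row["window"]),
                            int(row["polyorder"]), int(row["deriv"]))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--phantom", type=Path, default=Path("results/phantom"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    train = average_replicates(read_spectra(args.phantom / "train_spectra.csv"))
    test = average_replicates(read_spectra(args.phantom / "test_spectra.csv"))
    train_refs = read_references(args.phantom / "train_references.csv")
    test_refs = read_references(args.phantom / "test_references.csv")
    winners = pd.read_csv(args.out / "optimal_preprocessing.csv").set_index("constituent")

    rows = []
    for constituent in CONSTITUENTS:
        cfg = config_from_row(winners.loc[constituent])
        proc_train, ref = apply_pipeline(train, cfg)
        proc_test, _ = apply_pipeline(test, cfg, msc_reference=ref)
        y_train = train_refs.aligned_to(list(proc_train.sample_ids)).values_for(constituent)
        y_test = test_refs.aligned_to(list(proc_test.sample_ids)).values_for(constituent)

        curve = mccv(proc_train.values, y_train, 10, iterations=200, seed=args.seed)
        k = curve.chosen_n_comp
        report = detect_outliers(proc_train.values, y_train, k,
                                 sample_ids=list(proc_train.sample_ids),
                                 iterations=250, seed=args.seed)
        keep = ~pd.Series(proc_train.sample_ids).isin(report.flagged).to_numpy()
        model = fit_nipals(proc_train.values[keep], y_train[keep], k)
        yhat_tr = predict(model, proc_train.values[keep])
        yhat_te = predict(model, proc_test.values)
        model.to_json(args.out / f"model_{constituent}.json")
        rows.append({
            "constituent": constituent,
            "n_comp": k,
            "RMSECV": curve.rmsecv_at_chosen(),
            "outliers_flagged": len(report.flagged),
            "rho_training": spearman_rho(y_train[keep], yhat_tr),
            "RMSEC": rmse(y_train[keep], yhat_tr),
            "rho_test": spearman_rho(y_test, yhat_te),
            "RMSEP": rmse(y_test, yhat_te),
        })
        print(f"  {constituent}: n_comp={k}  flagged={report.flagged or 'none'}  "
              f"rho_test={rows[-1]['rho_test']:.3f}  RMSEP={rows[-1]['RMSEP']:.4g}")

    pd.DataFrame(rows).to_csv(args.out / "model_metrics.csv", index=False)
    print(f"metrics written to {args.out / 'model_metrics.csv'}")


if __name__ == "__main__":
    main()
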