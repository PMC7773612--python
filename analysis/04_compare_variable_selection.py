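#!/usr/bin/env python
"""Compare the five wavelength-selection algorithms against the base model.

For each constituent: apply the winning preprocessing configuration, run UVE,
FROG, CARS, MWPLS and IRIV on the training spectra, refit PLS on each
selected channel set with an MCCV-chosen component count, and tabulate
training/CV/test metrics (model-comparison table; best row = minimum RMSEP).
"""

import argparse
import importlib.util
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from nirmap.io_formats import CONSTITUENTS, average_replicates, read_references, read_spectra
from nirmap.preprocessing import apply_pipeline
from nirmap.variable_selection import compare_methods

_spec = importlib.util.spec_from_file_location(
    "train_models", Path(__file__).parent / "03_train_models.py"
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
config_from_row = _mod.config_from_row

METHODS = ["UVE", "FROG", "CARS", "MWPLS", "IRIV"]


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

    kwargs = {
        "UVE": {"iterations": 50},
        "FROG": {"iterations": 300},
        "CARS": {"iterations": 50},
        "MWPLS": {"window": 15},
        "IRIV": {"n_rows": 100},
    }
    for constituent in CONSTITUENTS:
        cfg = config_from_row(winners.loc[constituent])
        proc_train, ref = apply_pipeline(train, cfg)
        proc_test, _ = apply_pipeline(test, cfg, msc_reference=ref)
        y_train = train_refs.aligned_to(list(proc_train.sample_ids)).values_for(constituent)
        y_test = test_refs.aligned_to(list(proc_test.sample_ids)).values_for(constituent)
        table = compare_methods(
            proc_train.values, y_train, proc_test.values, y_test,
            methods=METHODS, max_comp=10, seed=args.seed, cv_iterations=100,
            method_kwargs=kwargs,
        )
        table.to_csv(args.out / f"model_comparison_{constituent}.csv", index=False)
        best = table[table["best"]].iloc[0]
        print(f"\n{constituent} (best: {best['method']}, RMSEP={best['RMSEP']:.4g}):")
        print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
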