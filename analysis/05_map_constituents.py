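#!/usr/bin/env python
"""Assemble measured and predicted constituent maps of the test specimen.

Places held-out grid predictions from the trained models (03) onto the 9x14
measurement lattice, imputes unmeasured edge cells as neighbour means,
embeds each map in a 20x20 zero canvas, bilinearly interpolates it to
1901x1901 pixels, and reports per-cell percent-error summaries.  Optional
PNG rendering of the measured/predicted/error panels.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from nirmap.io_formats import CONSTITUENTS, average_replicates, read_references, read_spectra
from nirmap.mapping import (
    assemble_grid,
    embed_and_interpolate,
    error_map,
    fill_missing_neighbors,
)
from nirmap.pls import PlsModel, predict
from nirmap.preprocessing import apply_pipeline

sys.path.insert(0, str(Path(__file__).parent))
import importlib.util

_spec = importlib.util.spec_from_file_location(
    "train_models", Path(__file__).parent / "03_train_models.py"
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
config_from_row = _mod.config_from_row


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--phantom", type=Path, default=Path("results/phantom"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--png", action="store_true", help="render map panels as PNG")
    args = ap.parse_args()

    train = average_replicates(read_spectra(args.phantom / "train_spectra.csv"))
    test = average_replicates(read_spectra(args.phantom / "test_spectra.csv"))
    test_refs = read_references(args.phantom / "test_references.csv")
    winners = pd.read_csv(args.out / "optimal_preprocessing.csv").set_index("constituent")

    summaries = []
    for constituent in CONSTITUENTS:
        cfg = config_from_row(winners.loc[constituent])
        _, ref = apply_pipeline(train, cfg)
        proc_test, _ = apply_pipeline(test, cfg, msc_reference=ref)
        model = PlsModel.from_json(args.out / f"model_{constituent}.json")
        yhat = predict(model, proc_test.values)
        aligned = test_refs.aligned_to(list(proc_test.sample_ids))
        y = aligned.values_for(constituent)
        coords = list(zip(aligned.table["row"].astype(int), aligned.table["col"].astype(int)))

        meas = assemble_grid(y, coords, (9, 14))
        pred = assemble_grid(yhat, coords, (9, 14))
        err_grid, summary = error_map(meas, pred)
        meas_f, pred_f = fill_missing_neighbors(meas), fill_missing_neighbors(pred)
        cm = embed_and_interpolate(meas_f)
        np.savetxt(args.out / f"map_measured_{constituent}.csv", meas_f.values, delimiter=",")
        np.savetxt(args.out / f"map_predicted_{constituent}.csv", pred_f.values, delimiter=",")
        np.savetxt(args.out / f"map_error_{constituent}.csv", err_grid, delimiter=",")
        summaries.append({"constituent": constituent, **summary,
                          "interpolated_side": cm.interpolated.shape[0]})
        print(f"  {constituent}: error % over {summary['n_cells']} cells — "
              f"min={summary['min']:.2f} max={summary['max']:.2f} "
              f"mean={summary['mean']:.2f} median={summary['median']:.2f}; "
              f"interpolated map {cm.interpolated.shape[0]}x{cm.interpolated.shape[1]}")

        if args.png:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, axes = plt.subplots(1, 3, figsize=(13, 3.2))
            for ax, (title, data) in zip(
                axes,
                [("measured", meas_f.values), ("predicted", pred_f.values),
                 ("error %", err_grid)],
            ):
                im = ax.imshow(data, interpolation="nearest")
                ax.set_title(f"{constituent} {title}")
                fig.colorbar(im, ax=ax, shrink=0.8)
            fig.tight_layout()
            fig.savefig(args.out / f"maps_{constituent}.png", dpi=110)
            plt.close(fig)

    pd.DataFrame(summaries).to_csv(args.out / "error_map_summaries.csv", index=False)
    print(f"summaries written to {args.out / 'error_map_summaries.csv'}")


if __name__ == "__main__":
    main()
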