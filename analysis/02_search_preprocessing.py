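#!/usr/bin/env python
"""Search preprocessing configurations per constituent (optimal-config table).

Reads the phantom written by 01_simulate_phantom.py, averages replicates,
and ranks every combination of wavelength-range subset, scatter correction
and Savitzky-Golay setting by Monte Carlo cross-validated RMSECV.  Writes the
winning configuration per constituent plus the full rankings.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from nirmap.io_formats import CONSTITUENTS, average_replicates, read_references, read_spectra
from nirmap.model_selection import grid_search
from nirmap.preprocessing import enumerate_configs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--phantom", type=Path, default=Path("results/phantom"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--iterations", type=int, default=50,
                    help="MCCV iterations per configuration")
    ap.add_argument("--full-grid", action="store_true",
                    help="search all 1344 configurations (slow); default is a "
                         "reduced window/derivative grid")
    args = ap.parse_args()

    train = average_replicates(read_spectra(args.phantom / "train_spectra.csv"))
    refs = read_references(args.phantom / "train_references.csv")
    if args.full_grid:
        configs = enumerate_configs()
    else:
        configs = enumerate_configs(windows=(5, 9, 13, 17), polyorders=(2,))
    print(f"searching {len(configs)} configurations, "
          f"{args.iterations} MCCV iterations each")

    winners = []
    for constituent in CONSTITUENTS:
        ranked = grid_search(train, refs, configs, constituent, max_comp=10,
                             iterations=args.iterations, seed=args.seed)
        cfg, curve = ranked[0]
        winners.append({
            "constituent": constituent,
            "ranges": "+".join(f"{lo:g}-{hi:g}" for lo, hi in cfg.ranges),
            "scatter": cfg.scatter,
            "window": cfg.window,
            "polyorder": cfg.polyorder,
            "deriv": cfg.deriv,
            "n_comp": curve.chosen_n_comp,
            "rmsecv": curve.rmsecv_at_chosen(),
        })
        print(f"  {constituent}: {cfg.label()}  "
              f"n_comp={curve.chosen_n_comp}  RMSECV={curve.rmsecv_at_chosen():.4g}")
        full = pd.DataFrame(
            [{**c.to_dict()["sg"], "ranges": c.label().split("|")[0],
              "scatter": c.scatter, "n_comp": cv.chosen_n_comp,
              "rmsecv": cv.rmsecv_at_chosen()} for c, cv in ranked]
        )
        full.to_csv(args.out / f"preprocessing_ranking_{constituent}.csv", index=False)

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(winners).to_csv(args.out / "optimal_preprocessing.csv", index=False)
    print(f"winners written to {args.out / 'optimal_preprocessing.csv'}")


if __name__ == "__main__":
    main()
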