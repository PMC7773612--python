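"""End-to-end orchestration: phantom/data in, calibration tables and maps out.

A :class:`PipelineConfig` (YAML-serialisable) describes one full run of the
study workflow per constituent:

1. generate (or load) spectra and references; average replicates;
2. search the preprocessing grid by MCCV and keep the winning configuration;
3. choose the component count by MCCV on the winning configuration;
4. screen training samples for outliers by Monte Carlo resampling;
5. optionally compare wavelength-selection methods against the base model;
6. predict the held-out grid, assemble measured/predicted/error maps.

Every stage derives its seed from the master seed through a fixed splitting
scheme (``seed + stage offset``), so a rerun with the same config is
bit-identical.  Artifacts are written under the output directory with a JSON
manifest recording seeds, stage status and every file produced.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nirmap import __version__
from nirmap.io_formats import (
    CONSTITUENTS,
    ReferenceTable,
    SpectraSet,
    average_replicates,
    read_references,
    read_spectra,
    write_references,
    write_spectra,
)
from nirmap.mapping import assemble_grid, embed_and_interpolate, error_map, fill_missing_neighbors
from nirmap.model_selection import detect_outliers, grid_search, mccv
from nirmap.pls import fit_nipals, predict, rmse, spearman_rho
from nirmap.preprocessing import (
    DEFAULT_RANGES_NM,
    PreprocessConfig,
    apply_pipeline,
    enumerate_configs,
)
from nirmap.synthetic import PhantomSpec, generate_dataset
from nirmap.variable_selection import compare_methods

__all__ = ["PipelineConfig", "validate_config", "run"]

# stage seed offsets (master seed + offset -> stage seed)
_SEED_OFFSETS = {"phantom": 1, "grid": 2, "mccv": 3, "outliers": 4, "selection": 5}


@dataclass
class PipelineConfig:
    """Everything one reproducible pipeline run needs."""

    seed: int = 0
    out_dir: str = "results/run"
    constituents: tuple[str, ...] = CONSTITUENTS
    # data source: either paths to CSVs, or a phantom spec (paths win if set)
    train_spectra_path: str | None = None
    train_references_path: str | None = None
    test_spectra_path: str | None = None
    test_references_path: str | None = None
    phantom: dict = field(default_factory=dict)
    n_train_locations: int = 115
    test_grid: tuple[int, int] = (9, 14)
    measured_cells: int = 55
    # preprocessing search
    search_scatter: tuple[str, ...] = ("none", "snv", "rnv", "msc")
    search_windows: tuple[int, ...] = (5, 9, 13, 17)
    search_polyorders: tuple[int, ...] = (2,)
    search_derivs: tuple[int, ...] = (0, 1)
    search_iterations: int = 50
    # component selection / outliers
    max_comp: int = 10
    mccv_iterations: int = 200
    mccv_ratio: float = 0.9
    outlier_iterations: int = 250
    outlier_ratio: float = 0.75
    outlier_k_sd: float = 3.0
    # variable selection
    selection_methods: tuple[str, ...] = ()
    # mapping
    canvas_side: int = 20
    spacing: float = 0.01
    render_png: bool = False

    def validation_errors(self) -> list[str]:
        errs = []
        if not self.constituents:
            errs.append("constituents: must be non-empty")
        for c in self.constituents:
            if c not in CONSTITUENTS:
                errs.append(f"constituents: unknown constituent {c!r}")
        for w in self.search_windows:
            if w % 2 == 0 or not 5 <= w <= 19:
                errs.append(f"sg.window: {w} must be odd and in 5..19")
        for p in self.search_polyorders:
            if p not in (2, 3):
                errs.append(f"sg.polyorder: {p} not in (2, 3)")
        for d in self.search_derivs:
            if d not in (0, 1, 2):
                errs.append(f"sg.deriv: {d} not in (0, 1, 2)")
        if not 0 < self.mccv_ratio < 1:
            errs.append("mccv_ratio: must be in (0, 1)")
        if not 0 < self.outlier_ratio < 1:
            errs.append("outlier_ratio: must be in (0, 1)")
        if self.measured_cells > self.test_grid[0] * self.test_grid[1]:
            errs.append("measured_cells: exceeds test grid size")
        if self.spacing <= 0:
            errs.append("spacing: must be positive")
        return errs

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_mapping(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for k, v in d.items():
            if k not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {k!r}")
            default = cls.__dataclass_fields__[k].default
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; raise with every violation at once."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"{path}: unparseable YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    cfg = PipelineConfig.from_mapping(raw)
    errs = cfg.validation_errors()
    if errs:
        raise ValueError(f"{path}: " + "; ".join(errs))
    return cfg


def _load_or_generate(cfg: PipelineConfig):
    if cfg.train_spectra_path:
        train = read_spectra(cfg.train_spectra_path)
        train_refs = read_references(cfg.train_references_path)
        test = read_spectra(cfg.test_spectra_path)
        test_refs = read_references(cfg.test_references_path)
        return train, train_refs, test, test_refs
    spec = PhantomSpec(**cfg.phantom) if cfg.phantom else PhantomSpec()
    ds = generate_dataset(
        spec,
        n_train_locations=cfg.n_train_locations,
        test_grid=cfg.test_grid,
        measured_cells=cfg.measured_cells,
        seed=cfg.seed + _SEED_OFFSETS["phantom"],
    )
    return ds.train_spectra, ds.train_references, ds.test_spectra, ds.test_references


def run(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Per constituent the run emits the winning preprocessing configuration,
    the method-comparison table, the serialised best model, and
    measured/predicted/error map CSVs.  A failing stage records its error in
    the manifest and skips the remaining stages for that constituent only.
    """
    errs = config.validation_errors()
    if errs:
        raise ValueError("; ".join(errs))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seed_offsets": _SEED_OFFSETS,
        "constituents": {},
        "files": [],
    }

    def emit(path: Path) -> Path:
        manifest["files"].append(str(path.relative_to(out)))
        return path

    t0 = time.time()
    train_raw, train_refs, test_raw, test_refs = _load_or_generate(config)
    train = average_replicates(train_raw)
    test = average_replicates(test_raw)
    write_spectra(train, emit(out / "train_spectra.csv"))
    write_references(train_refs, emit(out / "train_references.csv"))
    write_spectra(test, emit(out / "test_spectra.csv"))
    write_references(test_refs, emit(out / "test_references.csv"))

    configs = enumerate_configs(
        DEFAULT_RANGES_NM,
        config.search_scatter,
        config.search_windows,
        config.search_polyorders,
        config.search_derivs,
    )

    table1_rows = []
    for constituent in config.constituents:
        cinfo: dict = {"stages": {}}
        manifest["constituents"][constituent] = cinfo
        try:
            # --- preprocessing grid search -------------------------------
            ranked = grid_search(
                train,
                train_refs,
                configs,
                constituent,
                max_comp=config.max_comp,
                iterations=config.search_iterations,
                train_ratio=config.mccv_ratio,
                seed=config.seed + _SEED_OFFSETS["grid"],
            )
            best_cfg, best_curve = ranked[0]
            cinfo["stages"]["grid_search"] = {
                "winner": best_cfg.to_dict(),
                "rmsecv": best_curve.rmsecv_at_chosen(),
                "configs_ranked": len(ranked),
            }
            table1_rows.append(
                {
                    "constituent": constituent,
                    "ranges": "+".join(f"{lo:g}-{hi:g}" for lo, hi in best_cfg.ranges),
                    "scatter": best_cfg.scatter,
                    "window": best_cfg.window,
                    "polyorder": best_cfg.polyorder,
                    "deriv": best_cfg.deriv,
                    "rmsecv": best_curve.rmsecv_at_chosen(),
                }
            )

            proc_train, msc_ref = apply_pipeline(train, best_cfg)
            proc_test, _ = apply_pipeline(test, best_cfg, msc_reference=msc_ref)
            y_train = train_refs.aligned_to(list(proc_train.sample_ids)).values_for(constituent)
            y_test = test_refs.aligned_to(list(proc_test.sample_ids)).values_for(constituent)

            # --- component count ----------------------------------------
            cap = min(config.max_comp, proc_train.n_channels,
                      int(np.floor(config.mccv_ratio * len(y_train) + 0.5)) - 1)
            curve = mccv(
                proc_train.values, y_train, cap,
                iterations=config.mccv_iterations,
                train_ratio=config.mccv_ratio,
                seed=config.seed + _SEED_OFFSETS["mccv"],
            )
            n_comp = curve.chosen_n_comp
            cinfo["stages"]["mccv"] = {"n_comp": n_comp, "rmsecv": curve.rmsecv_at_chosen()}

            # --- outlier screen -----------------------------------------
            report = detect_outliers(
                proc_train.values, y_train, n_comp,
                sample_ids=list(proc_train.sample_ids),
                iterations=config.outlier_iterations,
                ratio=config.outlier_ratio,
                seed=config.seed + _SEED_OFFSETS["outliers"],
                k_sd=config.outlier_k_sd,
            )
            report.table.to_csv(emit(out / f"outliers_{constituent}.csv"), index=False)
            cinfo["stages"]["outliers"] = {"flagged": report.flagged}
            keep = ~np.isin(proc_train.sample_ids, report.flagged)
            Xtr, ytr = proc_train.values[keep], y_train[keep]

            # --- variable-selection comparison --------------------------
            table = compare_methods(
                Xtr, ytr, proc_test.values, y_test,
                methods=list(config.selection_methods),
                max_comp=cap,
                seed=config.seed + _SEED_OFFSETS["selection"],
                cv_iterations=config.mccv_iterations,
            )
            table.to_csv(emit(out / f"model_comparison_{constituent}.csv"), index=False)
            best_row = table[table["best"]].iloc[0]
            cinfo["stages"]["comparison"] = {
                "best_method": best_row["method"],
                "RMSEP": float(best_row["RMSEP"]),
                "rho_test": float(best_row["rho_test"]),
            }

            # --- final model + maps -------------------------------------
            model = fit_nipals(Xtr, ytr, int(best_row["n_comp"]))
            model.to_json(emit(out / f"model_{constituent}.json"))
            yhat = predict(model, proc_test.values)

            aligned = test_refs.aligned_to(list(proc_test.sample_ids))
            coords = list(zip(aligned.table["row"].astype(int), aligned.table["col"].astype(int)))
            grid_meas = fill_missing_neighbors(
                assemble_grid(y_test, coords, config.test_grid)
            )
            grid_pred = fill_missing_neighbors(
                assemble_grid(yhat, coords, config.test_grid)
            )
            err_grid, err_summary = error_map(
                assemble_grid(y_test, coords, config.test_grid),
                assemble_grid(yhat, coords, config.test_grid),
            )
            cm_meas = embed_and_interpolate(grid_meas, config.canvas_side, config.spacing)
            cm_pred = embed_and_interpolate(grid_pred, config.canvas_side, config.spacing)
            np.savetxt(emit(out / f"map_measured_{constituent}.csv"), grid_meas.values, delimiter=",")
            np.savetxt(emit(out / f"map_predicted_{constituent}.csv"), grid_pred.values, delimiter=",")
            np.savetxt(emit(out / f"map_error_{constituent}.csv"), err_grid, delimiter=",")
            cinfo["stages"]["mapping"] = {
                "error_summary": err_summary,
                "interpolated_shape": list(cm_meas.interpolated.shape),
            }
            if config.render_png:
                _render_maps(out, constituent, grid_meas.values, grid_pred.values, err_grid, emit)
            cinfo["metrics"] = {
                "rho_test": float(spearman_rho(y_test, yhat)),
                "RMSEP": float(rmse(y_test, yhat)),
                "n_comp": int(best_row["n_comp"]),
            }
            cinfo["status"] = "ok"
        except ValueError as exc:
            cinfo["status"] = f"failed: {exc}"

    if table1_rows:
        pd.DataFrame(table1_rows).to_csv(emit(out / "optimal_preprocessing.csv"), index=False)
    manifest["runtime_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _render_maps(out, constituent, meas, pred, err, emit) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    for ax, (title, data) in zip(
        axes, [("measured", meas), ("predicted", pred), ("error %", err)]
    ):
        im = ax.imshow(data, interpolation="nearest")
        ax.set_title(f"{constituent} {title}")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(emit(out / f"maps_{constituent}.png"), dpi=110)
    plt.close(fig)
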