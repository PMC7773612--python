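"""Phantom meniscus datasets: constituent fields and band-structured NIR spectra.

The generator emulates the study design the pipeline is built for: a training
set of 115 locations measured in triplicate, and an independent test specimen
measured on a 9x14 grid of which 55 central cells are acquirable (edge cells
fall outside the probe footprint).  Constituent contents follow the bulk
composition of meniscal tissue — water 70-75%, collagen 20-22% (hydroxyproline
proxy), glycosaminoglycan 0.6-0.8% (uronic-acid proxy), all as % of wet
weight.

Spectra follow a Beer-Lambert mixture of Gaussian absorbance bands,

    A(lambda) = sum_k c_k * sum_b amp_b * exp(-(lambda - center_b)^2 / 2 sigma_b^2),

distorted per spectrum by multiplicative gain (1 + N(0, sd_g)), additive
offset N(0, sd_o), a linear baseline with slope N(0, sd_s), and i.i.d. channel
noise N(0, sd_e) — exactly the distortions SNV/RNV/MSC-style scatter
correction is designed to remove.  The default band library places every band
inside 1060-1840 nm so the analysis crop ranges retain signal; water carries a
dominant band on the shoulder of the strong 1400-1450 nm absorption plus a
secondary band inside 1560-1840 nm, since the crop excludes 1366-1560 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nirmap.io_formats import CONSTITUENTS, ReferenceTable, SpectraSet, WavelengthAxis

__all__ = [
    "ComponentBand",
    "PhantomSpec",
    "PhantomDataset",
    "default_bands",
    "generate_constituent_field",
    "generate_spectrum",
    "generate_dataset",
    "central_cells_mask",
    "planted_signal_problem",
]


@dataclass(frozen=True)
class ComponentBand:
    """One Gaussian absorbance band: center (nm), width (nm, sigma), amplitude
    (absorbance units per unit concentration)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("band width must be positive")
        if not np.isfinite(self.amplitude):
            raise ValueError("band amplitude must be finite")


def default_bands() -> dict[str, list[ComponentBand]]:
    """Band library for the three constituents.

    Amplitudes are scaled so each constituent's signal variation over its
    concentration range is of comparable order; uronic acid spans only
    0.2 percentage points, hence its much larger per-unit amplitude.
    """
    return {
        # O-H first-overtone shoulder + combination band in the third window
        "water": [
            ComponentBand(1440.0, 55.0, 0.012),
            ComponentBand(1790.0, 60.0, 0.007),
        ],
        # sugar O-H / C-H bands of glycosaminoglycan, second optical window
        "uronic_acid": [
            ComponentBand(1100.0, 30.0, 0.45),
            ComponentBand(1320.0, 35.0, 0.30),
        ],
        # collagen C-H second overtone and first-overtone doublet
        "hydroxyproline": [
            ComponentBand(1215.0, 35.0, 0.010),
            ComponentBand(1690.0, 30.0, 0.012),
            ComponentBand(1760.0, 30.0, 0.008),
        ],
    }


def default_background() -> list[ComponentBand]:
    """Constituent-independent matrix absorbance (amplitude in absolute units).

    A broad baseline from the tissue matrix and probe optics; it anchors the
    absolute intensity scale so that per-spectrum normalisation (SNV/RNV/MSC)
    does not destroy concentration information.
    """
    return [ComponentBand(1250.0, 300.0, 0.40), ComponentBand(1750.0, 160.0, 0.15)]


DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "water": (70.0, 75.0),
    "uronic_acid": (0.6, 0.8),
    "hydroxyproline": (20.0, 22.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a phantom: composition ranges, band library,
    scatter/noise magnitudes, replicate count and seed."""

    ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_RANGES))
    bands: dict[str, list[ComponentBand]] = field(default_factory=default_bands)
    background: list[ComponentBand] = field(default_factory=default_background)
    gain_sd: float = 0.05
    offset_sd: float = 0.02
    slope_sd: float = 2e-5
    noise_sd: float = 1e-3
    replicates: int = 3
    smoothness: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if not (0 < lo < hi):
                raise ValueError(f"{name}: range must satisfy 0 < low < high")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.noise_sd < 0 or self.gain_sd < 0 or self.offset_sd < 0 or self.slope_sd < 0:
            raise ValueError("noise/scatter standard deviations must be >= 0")

    def to_dict(self) -> dict:
        return {
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "bands": {
                k: [[b.center, b.width, b.amplitude] for b in bs]
                for k, bs in self.bands.items()
            },
            "background": [[b.center, b.width, b.amplitude] for b in self.background],
            "gain_sd": self.gain_sd,
            "offset_sd": self.offset_sd,
            "slope_sd": self.slope_sd,
            "noise_sd": self.noise_sd,
            "replicates": self.replicates,
            "smoothness": self.smoothness,
            "seed": self.seed,
        }


@dataclass
class PhantomDataset:
    """Generated phantom: training spectra/references, gridded test
    spectra/references, and the generating truth for recovery tests."""

    train_spectra: SpectraSet
    train_references: ReferenceTable
    test_spectra: SpectraSet
    test_references: ReferenceTable
    test_mask: np.ndarray  # (rows, cols) boolean, True = measured cell
    spec: PhantomSpec


def _smooth_uniform_field(rows: int, cols: int, smoothness: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. uniform field smoothed by a moving-average kernel, rescaled to [0, 1].

    The kernel half-width equals the correlation length in cells; edges use
    shrinking windows so the output stays unbiased near the boundary.
    """
    raw = rng.uniform(size=(rows, cols))
    k = max(int(round(smoothness)), 0)
    if k == 0:
        sm = raw
    else:
        sm = np.empty_like(raw)
        for i in range(rows):
            for j in range(cols):
                i0, i1 = max(0, i - k), min(rows, i + k + 1)
                j0, j1 = max(0, j - k), min(cols, j + k + 1)
                sm[i, j] = raw[i0:i1, j0:j1].mean()
    lo, hi = sm.min(), sm.max()
    if hi - lo < 1e-12:  # single cell or degenerate field
        return np.full_like(sm, 0.5)
    return (sm - lo) / (hi - lo)


def generate_constituent_field(
    grid_shape: tuple[int, int],
    ranges: dict[str, tuple[float, float]] | None = None,
    smoothness: float = 2.0,
    seed: int = 0,
) -> ReferenceTable:
    """Spatially smooth constituent fields on a (rows, cols) grid.

    Every cell's value lies inside its constituent's configured range by
    construction (min-max rescaling of a smoothed uniform field).
    """
    rows, cols = grid_shape
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be positive")
    ranges = dict(ranges or DEFAULT_RANGES)
    for name, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ValueError(f"{name}: inverted range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    data = {
        "location_id": [f"g{r:02d}_{c:02d}" for r, c in zip(rr.ravel(), cc.ravel())],
        "row": rr.ravel(),
        "col": cc.ravel(),
    }
    for name in CONSTITUENTS:
        lo, hi = ranges[name]
        unit = _smooth_uniform_field(rows, cols, smoothness, rng)
        data[name] = (lo + (hi - lo) * unit).ravel()
    return ReferenceTable(pd.DataFrame(data))


def generate_spectrum(
    concentrations: dict[str, float],
    bands: dict[str, list[ComponentBand]],
    axis: WavelengthAxis,
    gain_sd: float = 0.0,
    offset_sd: float = 0.0,
    slope_sd: float = 0.0,
    noise_sd: float = 0.0,
    background: list[ComponentBand] | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One absorbance spectrum from the Beer-Lambert band mixture plus scatter.

    ``background`` bands contribute in absolute absorbance units regardless of
    concentrations.  With all standard deviations zero the output is the exact
    deterministic mixture, linear in each concentration.
    """
    wl = axis.wavelengths
    clean = np.zeros_like(wl)
    for b in background or []:
        clean = clean + b.amplitude * np.exp(-((wl - b.center) ** 2) / (2 * b.width**2))
    for name, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {name}")
        for b in bands.get(name, []):
            clean = clean + conc * b.amplitude * np.exp(-((wl - b.center) ** 2) / (2 * b.width**2))
    if gain_sd == 0 and offset_sd == 0 and slope_sd == 0 and noise_sd == 0:
        return clean
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    gain = 1.0 + rng.normal(0.0, gain_sd)
    offset = rng.normal(0.0, offset_sd)
    slope = rng.normal(0.0, slope_sd)
    noise = rng.normal(0.0, noise_sd, size=wl.size) if noise_sd > 0 else 0.0
    return gain * clean + offset + slope * (wl - wl.mean()) + noise


def central_cells_mask(shape: tuple[int, int], measured_cells: int) -> np.ndarray:
    """Mark the ``measured_cells`` cells closest to the grid centre as measured.

    Mimics a probe that cannot reach specimen edges; deterministic (ties broken
    by row-major index).
    """
    rows, cols = shape
    if measured_cells > rows * cols:
        raise ValueError("measured_cells exceeds grid size")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d2 = (rr - (rows - 1) / 2) ** 2 + (cc - (cols - 1) / 2) ** 2
    order = np.argsort(d2.ravel(), kind="stable")
    mask = np.zeros(rows * cols, dtype=bool)
    mask[order[:measured_cells]] = True
    return mask.reshape(shape)


def generate_dataset(
    spec: PhantomSpec,
    n_train_locations: int = 115,
    test_grid: tuple[int, int] = (9, 14),
    measured_cells: int = 55,
    axis: WavelengthAxis | None = None,
    seed: int | None = None,
) -> PhantomDataset:
    """Full phantom: replicated training spectra plus a gridded test specimen.

    Training locations draw constituent contents independently and uniformly
    within range (distinct donors); the test specimen uses a spatially smooth
    field so its maps show structure.  Every location is measured
    ``spec.replicates`` times with independent scatter/noise realisations.
    """
    axis = axis or WavelengthAxis.default()
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    # training references: independent uniform draws inside each range
    names = [f"t{i:03d}" for i in range(n_train_locations)]
    tr = {"location_id": names}
    for name in CONSTITUENTS:
        lo, hi = spec.ranges[name]
        tr[name] = rng.uniform(lo, hi, size=n_train_locations)
    train_refs = ReferenceTable(pd.DataFrame(tr))

    def measure(refs: ReferenceTable, prefix_ids: list[str]) -> SpectraSet:
        rows, ids, groups = [], [], []
        for loc in prefix_ids:
            rec = refs.table.set_index("location_id").loc[loc]
            conc = {c: float(rec[c]) for c in CONSTITUENTS}
            for r in range(spec.replicates):
                rows.append(
                    generate_spectrum(
                        conc, spec.bands, axis,
                        spec.gain_sd, spec.offset_sd, spec.slope_sd, spec.noise_sd,
                        background=spec.background,
                        rng=rng,
                    )
                )
                ids.append(f"{loc}_r{r}")
                groups.append(loc)
        return SpectraSet(np.stack(rows), axis, ids, groups)

    train_spectra = measure(train_refs, names)

    test_field = generate_constituent_field(
        test_grid, spec.ranges, spec.smoothness, seed=int(rng.integers(2**31))
    )
    mask = central_cells_mask(test_grid, measured_cells)
    measured = test_field.table[
        mask[test_field.table["row"].to_numpy(), test_field.table["col"].to_numpy()]
    ]
    test_refs = ReferenceTable(measured.reset_index(drop=True))
    test_spectra = measure(test_refs, test_refs.table["location_id"].tolist())

    return PhantomDataset(train_spectra, train_refs, test_spectra, test_refs, mask, spec)


def planted_signal_problem(
    n_samples: int = 115,
    n_informative: int = 20,
    n_channels: int = 220,
    informative_start: int = 100,
    channel_noise_sd: float = 0.1,
    dead_noise_sd: float = 0.5,
    response_noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Regression problem with one contiguous informative band and dead channels.

    Used to benchmark wavelength-selection algorithms.  Each informative
    channel carries its own latent contribution s_j (standard normal) plus
    small measurement noise, and the response is their weighted sum,
    y = sum_j w_j s_j / ||w||, with a mildly tapered band profile w; every
    informative channel therefore contributes independent information, and
    excluding any one of them genuinely degrades a calibration.  Dead
    channels are noise at the same scale as the signal, emulating the
    detector-noise/saturation regions of a real spectrum, so including them
    genuinely harms a calibration.  Returns (X, y, informative_mask).
    """
    rng = np.random.default_rng(seed)
    j = np.arange(n_informative)
    w = 0.8 + 0.2 * np.exp(-((j - n_informative / 2) ** 2) / (2 * (n_informative / 4) ** 2))
    S = rng.normal(0.0, 1.0, size=(n_samples, n_informative))
    X = rng.normal(0.0, dead_noise_sd, size=(n_samples, n_channels))
    sl = slice(informative_start, informative_start + n_informative)
    X[:, sl] = S + rng.normal(0.0, channel_noise_sd, size=(n_samples, n_informative))
    y = S @ w / np.linalg.norm(w) + rng.normal(0.0, response_noise_sd, size=n_samples)
    mask = np.zeros(n_channels, dtype=bool)
    mask[sl] = True
    return X, y, mask
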