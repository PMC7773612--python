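"""Spectral preprocessing: range cropping, scatter correction, Savitzky-Golay.

The preprocessing search space follows standard NIR practice: the useful
wavelength intervals 1060-1172, 1211-1366 and 1560-1840 nm (regions outside
are dominated by detector noise or saturated water absorption) combined in
all non-empty subsets; scatter correction by SNV, RNV or MSC (or none); and
Savitzky-Golay smoothing/differentiation with window sizes 5-19, polynomial
orders 2-3 and derivative orders 0-2.  A configuration is one point in this
grid; :func:`enumerate_configs` builds the full Cartesian product (1344
configurations for the default options).

Filtering is applied per contiguous wavelength segment so that cropping gaps
never leak across; scatter correction operates on the concatenated cropped
channels, since gain/offset distortions are per-spectrum physical effects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from nirmap.io_formats import SpectraSet, WavelengthAxis

__all__ = [
    "PreprocessConfig",
    "DEFAULT_RANGES_NM",
    "SG_WINDOWS",
    "crop_ranges",
    "snv",
    "rnv",
    "msc",
    "savitzky_golay",
    "enumerate_configs",
    "apply_pipeline",
]

DEFAULT_RANGES_NM: tuple[tuple[float, float], ...] = (
    (1060.0, 1172.0),
    (1211.0, 1366.0),
    (1560.0, 1840.0),
)
SG_WINDOWS = (5, 7, 9, 11, 13, 15, 17, 19)
SCATTER_METHODS = ("none", "snv", "rnv", "msc")


@dataclass(frozen=True)
class PreprocessConfig:
    """One preprocessing configuration: crop intervals, scatter method, SG triple."""

    ranges: tuple[tuple[float, float], ...]
    scatter: str = "none"
    window: int = 5
    polyorder: int = 2
    deriv: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "ranges", tuple((float(lo), float(hi)) for lo, hi in self.ranges)
        )
        errs = self.validation_errors()
        if errs:
            raise ValueError("; ".join(errs))

    def validation_errors(self) -> list[str]:
        errs = []
        for lo, hi in self.ranges:
            if not lo < hi:
                errs.append(f"ranges: inverted interval ({lo}, {hi})")
        for (a, b), (c, d) in itertools.combinations(self.ranges, 2):
            if max(a, c) <= min(b, d):
                errs.append(f"ranges: overlapping intervals ({a},{b}) and ({c},{d})")
        if self.scatter not in SCATTER_METHODS:
            errs.append(f"scatter: unknown method {self.scatter!r}")
        if self.window not in SG_WINDOWS:
            errs.append(f"sg.window: {self.window} not an odd size in 5..19")
        if self.polyorder not in (2, 3):
            errs.append(f"sg.polyorder: {self.polyorder} not in (2, 3)")
        if self.deriv not in (0, 1, 2):
            errs.append(f"sg.deriv: {self.deriv} not in (0, 1, 2)")
        if self.polyorder >= self.window:
            errs.append("sg.polyorder must be < sg.window")
        if self.deriv > self.polyorder:
            errs.append("sg.deriv must be <= sg.polyorder")
        return errs

    def to_dict(self) -> dict:
        return {
            "ranges": [list(r) for r in self.ranges],
            "scatter": self.scatter,
            "sg": {"window": self.window, "polyorder": self.polyorder, "deriv": self.deriv},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        sg = d.get("sg", {})
        return cls(
            ranges=tuple(tuple(r) for r in d["ranges"]),
            scatter=d.get("scatter", "none"),
            window=int(sg.get("window", 5)),
            polyorder=int(sg.get("polyorder", 2)),
            deriv=int(sg.get("deriv", 0)),
        )

    def label(self) -> str:
        rng = "+".join(f"{lo:g}-{hi:g}" for lo, hi in self.ranges)
        return f"{rng}|{self.scatter}|sg{self.window}/{self.polyorder}/{self.deriv}"


def crop_ranges(spectra: SpectraSet, ranges) -> SpectraSet:
    """Keep exactly the channels with low <= lambda <= high for some interval.

    Intervals are closed; channel order is preserved.  An empty result is an
    error (no interval intersects the axis).
    """
    wl = spectra.axis.wavelengths
    keep = np.zeros(wl.size, dtype=bool)
    for lo, hi in ranges:
        keep |= (wl >= lo) & (wl <= hi)
    if not keep.any():
        raise ValueError(f"crop ranges {list(ranges)} exclude every channel")
    return spectra.select_channels(keep)


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum z-score across channels (ddof=1)."""
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise ValueError("SNV needs at least 2 channels")
    sd = x.std(ddof=1)
    if sd < 1e-300:
        raise ValueError("SNV undefined for a constant spectrum")
    return (x - x.mean()) / sd


def rnv(spectrum: np.ndarray, percentile: float = 25.0) -> np.ndarray:
    """Robust normal variate: centre on the q-th percentile, scale by the
    standard deviation of the channels at or below it.

    Less sensitive than SNV to a few extreme channels (e.g. specular spikes).
    """
    x = np.asarray(spectrum, dtype=float)
    if x.size < 4:
        raise ValueError("RNV needs at least 4 channels")
    p = np.percentile(x, percentile)
    lower = x[x <= p]
    sd = lower.std(ddof=1) if lower.size > 1 else 0.0
    if sd < 1e-300:
        raise ValueError("RNV undefined: zero spread below the percentile")
    return (x - p) / sd


def msc(
    spectra: SpectraSet, reference: np.ndarray | None = None
) -> tuple[SpectraSet, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is least-squares fit x ~ a + b*ref and replaced by
    (x - a)/b.  The reference defaults to the channel-wise mean of the set;
    pass the stored training reference when correcting test spectra.  Returns
    (corrected set, reference used).
    """
    X = spectra.values
    if reference is None:
        if X.shape[0] < 2:
            raise ValueError("MSC needs >= 2 spectra when no reference is given")
        reference = X.mean(axis=0)
    ref = np.asarray(reference, dtype=float)
    if ref.size != X.shape[1]:
        raise ValueError("reference length does not match channel count")
    refc = ref - ref.mean()
    denom = float(refc @ refc)
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        x = X[i]
        b = float(refc @ (x - x.mean())) / denom
        if abs(b) < 1e-12:
            raise ValueError(f"MSC: flat fit (b~0) for spectrum {spectra.sample_ids[i]!r}")
        a = x.mean() - b * ref.mean()
        out[i] = (x - a) / b
    return spectra.with_values(out), ref


def savitzky_golay(
    spectra: SpectraSet, window: int, polyorder: int, deriv: int = 0
) -> SpectraSet:
    """Savitzky-Golay smoothing/differentiation applied per contiguous segment.

    Derivatives are scaled by the channel spacing (units: intensity per
    nm^deriv).  Edge channels use polynomial-fit evaluation so the channel
    count is preserved.  Cropping gaps delimit segments; a segment shorter
    than the window is an error.
    """
    wl = spectra.axis.wavelengths
    out = np.empty_like(spectra.values)
    for start, stop in spectra.axis.segments():
        n = stop - start
        if n < window:
            lo, hi = wl[start], wl[stop - 1]
            raise ValueError(
                f"segment {lo:g}-{hi:g} nm has {n} channels < window {window}"
            )
        delta = float(np.mean(np.diff(wl[start:stop])))
        out[:, start:stop] = savgol_filter(
            spectra.values[:, start:stop],
            window_length=window,
            polyorder=polyorder,
            deriv=deriv,
            delta=delta,
            axis=1,
            mode="interp",
        )
    return spectra.with_values(out)


def enumerate_configs(
    ranges: tuple[tuple[float, float], ...] = DEFAULT_RANGES_NM,
    scatter_methods: tuple[str, ...] = SCATTER_METHODS,
    windows: tuple[int, ...] = SG_WINDOWS,
    polyorders: tuple[int, ...] = (2, 3),
    derivs: tuple[int, ...] = (0, 1, 2),
) -> list[PreprocessConfig]:
    """Cartesian product of non-empty range subsets x scatter x valid SG triples.

    Invalid SG triples (polyorder >= window or deriv > polyorder) are skipped.
    Ordering is deterministic: range subsets by (size, lexicographic index),
    then scatter, window, polyorder, deriv in the given order.
    """
    subsets = [
        combo
        for size in range(1, len(ranges) + 1)
        for combo in itertools.combinations(ranges, size)
    ]
    configs = []
    for subset, scatter, w, p, d in itertools.product(
        subsets, scatter_methods, windows, polyorders, derivs
    ):
        if p >= w or d > p:
            continue
        configs.append(PreprocessConfig(subset, scatter, w, p, d))
    return configs


def apply_pipeline(
    spectra: SpectraSet,
    config: PreprocessConfig,
    msc_reference: np.ndarray | None = None,
) -> tuple[SpectraSet, np.ndarray | None]:
    """Apply crop -> scatter correction -> Savitzky-Golay in order.

    Returns (processed set, MSC reference or None).  When the config uses MSC,
    the reference fitted on a training set must be passed back in for test
    spectra so no test information leaks into the correction.
    """
    out = crop_ranges(spectra, config.ranges)
    ref = None
    if config.scatter == "snv":
        out = out.with_values(np.apply_along_axis(snv, 1, out.values))
    elif config.scatter == "rnv":
        out = out.with_values(np.apply_along_axis(rnv, 1, out.values))
    elif config.scatter == "msc":
        out, ref = msc(out, reference=msc_reference)
    out = savitzky_golay(out, config.window, config.polyorder, config.deriv)
    return out, ref
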