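"""Wavelength selection for PLS calibration: UVE, CARS, random frog, MWPLS, IRIV.

Five algorithms from the chemometric variable-selection literature, exposed
through one interface: each takes a predictor matrix, response, and component
count and returns a :class:`SelectionResult` with the selected channel
indices, a per-channel diagnostic score, and the hyperparameters used.

* UVE (uninformative variable elimination) benchmarks the stability of each
  channel's regression coefficient against artificial noise channels.
* CARS (competitive adaptive reweighted sampling) shrinks the retained
  channel set along an exponentially decreasing schedule, keeping channels
  with large coefficients by forced selection plus weighted resampling.
* Random frog runs a Metropolis-like chain over channel subsets and scores
  channels by visit frequency.
* MWPLS (moving-window PLS) fits every contiguous wavelength window and picks
  the window with minimal cross-validated error.
* IRIV (iteratively retaining informative variables) scores channels by
  comparing cross-validated error distributions of balanced random subsets
  that include versus exclude them, iterating until no channel is removed.

All stochastic methods are bit-reproducible under a fixed seed.  Fidelity
target is the algorithmic skeleton of the originating publications; every
hyperparameter is exposed and logged in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from nirmap.pls import fit_nipals, predict, rmse, spearman_rho
from nirmap.model_selection import mccv

__all__ = [
    "SelectionResult",
    "uve",
    "cars",
    "cars_schedule",
    "random_frog",
    "mwpls",
    "iriv",
    "compare_methods",
]


@dataclass
class SelectionResult:
    """Outcome of one selection run: sorted channel indices plus diagnostics."""

    method: str
    selected: np.ndarray
    scores: np.ndarray
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        sel = np.unique(np.asarray(self.selected, dtype=int))
        if sel.size and (sel.min() < 0 or sel.max() >= self.scores.size):
            raise ValueError("selected indices out of bounds")
        self.selected = sel

    def mask(self) -> np.ndarray:
        m = np.zeros(self.scores.size, dtype=bool)
        m[self.selected] = True
        return m


def _cap_comp(n_comp: int, n_train: int, n_chan: int) -> int:
    return max(1, min(n_comp, n_train - 1, n_chan))


def _make_splits(
    n: int, rng: np.random.Generator, splits: int = 3, ratio: float = 0.8
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random train/validation splits, drawn once and reused so that subset
    comparisons are paired (split noise cancels between candidates)."""
    n_train = int(np.floor(ratio * n + 0.5))
    out = []
    for _ in range(splits):
        perm = rng.permutation(n)
        out.append((perm[:n_train], perm[n_train:]))
    return out


def _cv_error(
    X: np.ndarray,
    y: np.ndarray,
    n_comp: int,
    splits: list[tuple[np.ndarray, np.ndarray]],
) -> float:
    """Mean held-out RMSE over the given splits."""
    errs = np.empty(len(splits))
    for s, (tr, va) in enumerate(splits):
        k = _cap_comp(n_comp, tr.size, X.shape[1])
        model = fit_nipals(X[tr], y[tr], k)
        errs[s] = rmse(y[va], predict(model, X[va]))
    return float(errs.mean())


def _quick_rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    n_comp: int,
    rng: np.random.Generator,
    splits: int = 3,
    ratio: float = 0.8,
) -> float:
    """Small Monte Carlo CV with freshly drawn splits (unpaired)."""
    return _cv_error(X, y, n_comp, _make_splits(X.shape[0], rng, splits, ratio))


# ---------------------------------------------------------------------------
# UVE


def uve(
    X: np.ndarray,
    y: np.ndarray,
    n_comp: int,
    n_noise: int | None = None,
    iterations: int = 100,
    seed: int = 0,
    noise_amplitude: float = 1e-10,
    subset_ratio: float = 0.9,
) -> SelectionResult:
    """Uninformative variable elimination.

    The predictor matrix is augmented with ``n_noise`` uniform-noise channels
    of negligible amplitude; over Monte Carlo resampled fits each channel j
    collects regression coefficients b_j, summarised as the reliability
    c_j = mean(b_j)/sd(b_j).  Channels whose |c_j| does not exceed the largest
    |c| observed on any noise channel are eliminated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    n_noise = p if n_noise is None else n_noise
    rng = np.random.default_rng(seed)
    noise = rng.uniform(size=(n, n_noise)) * noise_amplitude
    Xa = np.hstack([X, noise])
    n_train = int(np.floor(subset_ratio * n + 0.5))
    k = _cap_comp(n_comp, n_train, Xa.shape[1])
    coefs = np.empty((iterations, p + n_noise))
    for it in range(iterations):
        tr = rng.permutation(n)[:n_train]
        coefs[it] = fit_nipals(Xa[tr], y[tr], k).coef
    mean_b = coefs.mean(axis=0)
    sd_b = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(sd_b > 0, mean_b / sd_b, 0.0)
    cutoff = np.max(np.abs(c[p:]))
    selected = np.where(np.abs(c[:p]) > cutoff)[0]
    return SelectionResult(
        "UVE",
        selected,
        np.abs(c[:p]),
        {
            "n_noise": n_noise,
            "iterations": iterations,
            "noise_amplitude": noise_amplitude,
            "subset_ratio": subset_ratio,
            "cutoff": float(cutoff),
            "n_comp": k,
        },
        seed,
    )


# ---------------------------------------------------------------------------
# CARS


def cars_schedule(n_channels: int, iterations: int) -> np.ndarray:
    """Retained-channel counts along the exponentially decreasing schedule.

    r_i = a * exp(-k*i) with r_1 = 1 (all channels) and r_N = 2/p (two
    channels), i = 1..N; the count at iteration i is round(r_i * p).
    """
    p, N = n_channels, iterations
    if N < 2:
        raise ValueError("CARS needs at least 2 iterations")
    k = np.log(p / 2.0) / (N - 1)
    a = np.exp(k)
    i = np.arange(1, N + 1)
    return np.maximum(np.round(a * np.exp(-k * i) * p).astype(int), 2)


def cars(
    X: np.ndarray,
    y: np.ndarray,
    n_comp: int,
    iterations: int = 50,
    seed: int = 0,
    sample_ratio: float = 0.8,
    n_weight_fits: int = 5,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Each iteration estimates channel weights as the magnitude of the mean PLS
    regression coefficient over ``n_weight_fits`` random ``sample_ratio``
    sample subsets (averaging tames the coefficient noise of a single fit),
    then shrinks the surviving channel set to the scheduled count by forced
    selection (largest weight) followed by adaptive reweighted sampling with
    probabilities proportional to the weights.  The subset with the smallest
    cross-validated RMSE over all iterations is returned; every iteration's
    subset is scored on the same CV splits so the comparison is paired.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(seed)
    eval_splits = _make_splits(n, rng, splits=5)
    counts = cars_schedule(p, iterations)
    n_sub = int(np.floor(sample_ratio * n + 0.5))
    current = np.arange(p)
    best_err = np.inf
    best_subset = current.copy()
    errs = np.full(iterations, np.nan)
    subset_sizes = np.zeros(iterations, dtype=int)
    hits = np.zeros(p)
    for i in range(iterations):
        k = _cap_comp(n_comp, n_sub, current.size)
        coefs = np.empty((n_weight_fits, current.size))
        for f in range(n_weight_fits):
            tr = rng.permutation(n)[:n_sub]
            coefs[f] = fit_nipals(X[np.ix_(tr, current)], y[tr], k).coef
        w = np.abs(coefs.mean(axis=0))
        target = min(counts[i], current.size)
        # forced selection: keep the top-weight channels
        order = np.argsort(w, kind="stable")[::-1][:target]
        forced, wf = current[order], w[order]
        if counts[i] >= p:
            current = np.sort(forced)  # ratio 1: keep all channels
        elif wf.sum() > 0:
            # adaptive reweighted sampling: draw the scheduled count (with
            # replacement) from the forced set; the unique draws survive
            draw = rng.choice(forced, size=counts[i], replace=True, p=wf / wf.sum())
            current = np.unique(draw)
        else:
            current = np.sort(forced)
        if current.size < 2:
            current = np.sort(forced)[:2]
        err = _cv_error(X[:, current], y, n_comp, eval_splits)
        errs[i] = err
        subset_sizes[i] = current.size
        hits[current] += 1
        # the unpruned full set is not a selection; only proper subsets compete
        if err < best_err and current.size < p:
            best_err = err
            best_subset = current.copy()
    return SelectionResult(
        "CARS",
        best_subset,
        hits / iterations,
        {
            "iterations": iterations,
            "sample_ratio": sample_ratio,
            "best_rmsecv": float(best_err),
            "schedule": counts.tolist(),
            "subset_sizes": subset_sizes.tolist(),
            "n_comp": n_comp,
        },
        seed,
    )


# ---------------------------------------------------------------------------
# Random frog


def random_frog(
    X: np.ndarray,
    y: np.ndarray,
    n_comp: int,
    iterations: int = 1000,
    init_size: int | None = None,
    theta: float = 0.3,
    eta: float = 0.1,
    seed: int = 0,
) -> SelectionResult:
    """Random frog: a Metropolis-style chain over channel subsets.

    From the current subset V a candidate dimension n* is drawn from
    round(N(|V|, theta*|V|)) clipped to [1, p].  Shrinking keeps the n*
    channels of V with the largest PLS regression coefficients |b|; growing
    adds random outside channels and keeps the best n* of the union by |b| —
    the coefficient-guided proposal of the originating algorithm.  A candidate
    with smaller cross-validated RMSE is always accepted; otherwise it is
    accepted with the damped probability eta * err(V)/err(candidate), the
    acceptance rule of the originating algorithm (eta ~ 0.1 keeps the chain
    near good subsets while still escaping local minima).  Each channel's
    score is its visit frequency; the selected set is the ``init_size``
    most-visited channels.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    init_size = min(max(n_comp + 1, p // 10), p) if init_size is None else init_size
    if init_size > p:
        raise ValueError("init_size exceeds channel count")
    rng = np.random.default_rng(seed)
    eval_splits = _make_splits(n, rng)

    def top_by_coef(cols: np.ndarray, keep: int) -> np.ndarray:
        k = _cap_comp(n_comp, n, cols.size)
        b = np.abs(fit_nipals(X[:, cols], y, k).coef)
        return cols[np.argsort(b, kind="stable")[::-1][:keep]]

    # start the chain at the strongest-coefficient subset of the requested
    # size; a cold random start spends most of the chain re-discovering
    # channels the full-data coefficient ranking already exposes
    V = np.sort(top_by_coef(np.arange(p), init_size))
    err_V = _cv_error(X[:, V], y, n_comp, eval_splits)
    visits = np.zeros(p)
    sizes = np.zeros(iterations, dtype=int)
    for t in range(iterations):
        n_star = int(np.clip(round(rng.normal(V.size, theta * V.size)), 1, p))
        if n_star < V.size:
            cand = top_by_coef(V, n_star)
        elif n_star > V.size:
            outside = np.setdiff1d(np.arange(p), V, assume_unique=False)
            add = rng.choice(outside, size=min(n_star - V.size, outside.size), replace=False)
            cand = top_by_coef(np.concatenate([V, add]), n_star)
        else:  # same size: swap one channel to keep the chain mixing
            cand = V.copy()
            if V.size < p:
                outside = np.setdiff1d(np.arange(p), V)
                cand[rng.integers(V.size)] = rng.choice(outside)
        err_cand = _cv_error(X[:, cand], y, n_comp, eval_splits)
        if err_cand < err_V or rng.uniform() < min(1.0, eta * err_V / err_cand):
            V, err_V = np.unique(cand), err_cand
        visits[V] += 1
        sizes[t] = V.size
    prob = visits / iterations
    selected = np.argsort(prob, kind="stable")[::-1][:init_size]
    return SelectionResult(
        "FROG",
        selected,
        prob,
        {
            "iterations": iterations,
            "init_size": init_size,
            "theta": theta,
            "eta": eta,
            "mean_subset_size": float(sizes.mean()),
            "n_comp": n_comp,
        },
        seed,
    )


# ---------------------------------------------------------------------------
# MWPLS


def mwpls(
    X: np.ndarray,
    y: np.ndarray,
    n_comp: int,
    window: int = 15,
    seed: int = 0,
    cv_splits: int = 5,
) -> SelectionResult:
    """Moving-window PLS: cross-validated error of every contiguous window.

    The diagnostic score is the per-start-position RMSECV profile (padded with
    +inf beyond the last start); the selected set is the window with minimal
    RMSECV.  Deterministic given the CV seed (each window reuses the same
    splits).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if window > p:
        raise ValueError("window exceeds channel count")
    if window < n_comp + 1:
        raise ValueError("window must be at least n_comp + 1 channels")
    n_starts = p - window + 1
    profile = np.full(p, np.inf)
    for s in range(n_starts):
        rng = np.random.default_rng(seed)  # identical splits for every window
        profile[s] = _quick_rmsecv(X[:, s : s + window], y, n_comp, rng, splits=cv_splits)
    best = int(np.argmin(profile[:n_starts]))
    selected = np.arange(best, best + window)
    return SelectionResult(
        "MWPLS",
        selected,
        profile,
        {"window": window, "cv_splits": cv_splits, "best_start": best,
         "best_rmsecv": float(profile[best]), "n_comp": n_comp},
        seed,
    )


# ---------------------------------------------------------------------------
# IRIV


def _balanced_inclusion_matrix(rows: int, p: int, rng: np.random.Generator) -> np.ndarray:
    """Binary matrix with each channel included in exactly half the rows."""
    M = np.zeros((rows, p), dtype=bool)
    half = rows // 2
    for j in range(p):
        idx = rng.permutation(rows)[:half]
        M[idx, j] = True
    return M


def iriv(
    X: np.ndarray,
    y: np.ndarray,
    n_comp: int,
    seed: int = 0,
    n_rows: int = 100,
    alpha: float = 0.05,
    max_rounds: int = 12,
    protect_tol: float = 0.02,
) -> SelectionResult:
    """Iteratively retaining informative variables.

    Each round draws a balanced binary inclusion matrix (every surviving
    channel appears in half the rows) and computes the cross-validated RMSE
    of a PLS model per row; all rows in a round share the same CV splits so
    that between-row differences reflect channel membership only.  For each
    channel the error distributions of rows including versus excluding it are
    compared with a two-sided rank-sum test: inclusion lowering the mean
    error marks a channel informative (strongly when significant at
    ``alpha``, weakly otherwise); inclusion raising it marks it uninformative
    or interfering.

    Because half-inclusion subsets carry large which-channels variance, a
    channel slated for removal is first re-examined by a paired drop-one test
    on the full retained set: if removing just that channel inflates the
    retained-set cross-validated error by more than ``protect_tol``
    (relative), the channel is demonstrably informative and is kept.  Rounds
    repeat until no removal, then weakly informative channels undergo
    backward elimination on a paired split set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    p = X.shape[1]
    if p < 4:
        raise ValueError("IRIV needs at least 4 channels")
    rng = np.random.default_rng(seed)
    retained = np.arange(p)
    weak = retained.copy()
    n_strong = 0
    score = np.zeros(p)  # last-round mean error drop when included
    check_splits = _make_splits(X.shape[0], rng, splits=3)
    for _ in range(max_rounds):
        if retained.size < 4:
            break
        round_splits = _make_splits(X.shape[0], rng, splits=2)
        M = _balanced_inclusion_matrix(n_rows, retained.size, rng)
        errs = np.empty(n_rows)
        for r in range(n_rows):
            cols = retained[M[r]]
            errs[r] = np.inf if cols.size == 0 else _cv_error(X[:, cols], y, n_comp, round_splits)
        keep, drop, strong_l, weak_l = [], [], [], []
        for jj, j in enumerate(retained):
            with_j = errs[M[:, jj]]
            without_j = errs[~M[:, jj]]
            dmean = float(without_j.mean() - with_j.mean())
            score[j] = dmean
            pval = stats.mannwhitneyu(with_j, without_j, alternative="two-sided").pvalue
            if dmean > 0:
                keep.append(j)
                (strong_l if pval < alpha else weak_l).append(j)
            else:
                drop.append(j)
        # paired drop-one confirmation: an apparently uninformative channel
        # whose sole removal degrades the retained-set model is kept
        if drop:
            base = _cv_error(X[:, retained], y, n_comp, check_splits)
            for j in drop:
                trial = retained[retained != j]
                if _cv_error(X[:, trial], y, n_comp, check_splits) > (1 + protect_tol) * base:
                    keep.append(j)
                    strong_l.append(j)
        keep_arr = np.unique(np.array(keep, dtype=int))
        weak = np.array(weak_l, dtype=int)
        n_strong = len(strong_l)
        if keep_arr.size == retained.size:
            break
        retained = keep_arr
        if retained.size == 0:
            return SelectionResult(
                "IRIV", np.zeros(0, dtype=int), score,
                {"n_rows": n_rows, "alpha": alpha, "note": "all channels removed"},
                seed,
            )
    # backward elimination of weakly informative channels, paired splits
    retained_set = list(retained)
    if retained_set:
        base_err = _cv_error(X[:, retained_set], y, n_comp, check_splits)
        improved = True
        while improved and len(retained_set) > 2:
            improved = False
            for j in sorted(set(weak) & set(retained_set)):
                trial = [c for c in retained_set if c != j]
                e = _cv_error(X[:, trial], y, n_comp, check_splits)
                if e < base_err:
                    retained_set, base_err, improved = trial, e, True
                    break
    return SelectionResult(
        "IRIV",
        np.array(retained_set, dtype=int),
        score,
        {"n_rows": n_rows, "alpha": alpha, "max_rounds": max_rounds,
         "protect_tol": protect_tol, "n_strong": n_strong,
         "n_weak_final": int(len(set(weak.tolist()) & set(retained_set))),
         "n_comp": n_comp},
        seed,
    )


# ---------------------------------------------------------------------------
# Method comparison table


METHOD_FUNCS = {
    "UVE": uve,
    "CARS": cars,
    "FROG": random_frog,
    "MWPLS": mwpls,
    "IRIV": iriv,
}

REPORT_COLUMNS = [
    "method", "rho_training", "RMSEC", "RMSECV", "rho_test", "RMSEP", "n_comp",
    "n_channels", "best", "status",
]


def compare_methods(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    methods: list[str],
    max_comp: int = 15,
    seed: int = 0,
    cv_iterations: int = 100,
    method_kwargs: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Model-comparison table: a Base row (all channels) plus one row per method.

    For each wavelength-selection method, PLS is refit on the selected
    channels with an MCCV-chosen component count, then evaluated by training
    Spearman rho and RMSEC, cross-validated RMSECV, and test Spearman rho and
    RMSEP.  The best row (minimum RMSEP, ties to fewer components) is flagged;
    a failing method is recorded as failed and the comparison continues.
    """
    method_kwargs = method_kwargs or {}
    rows = []

    def evaluate(name: str, cols: np.ndarray) -> dict:
        Xtr, Xte = X_train[:, cols], X_test[:, cols]
        cap = min(max_comp, Xtr.shape[1], X_train.shape[0] - 2)
        curve = mccv(Xtr, y_train, cap, iterations=cv_iterations, seed=seed)
        k = curve.chosen_n_comp
        model = fit_nipals(Xtr, y_train, k)
        yhat_tr = predict(model, Xtr)
        yhat_te = predict(model, Xte)
        return {
            "method": name,
            "rho_training": spearman_rho(y_train, yhat_tr),
            "RMSEC": rmse(y_train, yhat_tr),
            "RMSECV": curve.rmsecv_at_chosen(),
            "rho_test": spearman_rho(y_test, yhat_te),
            "RMSEP": rmse(y_test, yhat_te),
            "n_comp": k,
            "n_channels": int(cols.size),
            "best": False,
            "status": "ok",
        }

    rows.append(evaluate("Base", np.arange(X_train.shape[1])))
    base_k = rows[0]["n_comp"]
    for name in methods:
        if name not in METHOD_FUNCS:
            rows.append({"method": name, "status": "unknown method", "best": False})
            continue
        try:
            kwargs = dict(method_kwargs.get(name, {}))
            result = METHOD_FUNCS[name](X_train, y_train, base_k, seed=seed, **kwargs)
            if result.selected.size == 0:
                raise ValueError("empty selection")
            rows.append(evaluate(name, result.selected))
        except ValueError as exc:
            rows.append({"method": name, "status": f"failed: {exc}", "best": False})
    df = pd.DataFrame(rows).reindex(columns=REPORT_COLUMNS)
    ok = df["status"] == "ok"
    if ok.any():
        cand = df[ok].sort_values(["RMSEP", "n_comp"], kind="stable")
        df.loc[cand.index[0], "best"] = True
    return df
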