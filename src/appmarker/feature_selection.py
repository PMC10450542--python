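"""Four feature-selection regimes: IG filter, embedded RF, Boruta, stability.

All selectors are pure functions of (X, y, config, seed).  X is a pandas
DataFrame of standardized features; y is a binary vector.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import fdrcorrection

Selector = Callable[[pd.DataFrame, np.ndarray, int], list[str]]


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _label_entropy(y: np.ndarray) -> float:
    return _entropy(np.bincount(y.astype(int)))


# --------------------------------------------------------------------------
# filter method: information gain


def ig_scores(X: pd.DataFrame, y: np.ndarray, n_bins: int | None = None) -> pd.Series:
    """Information gain of y given each feature, by equal-frequency binning.

    Each column is discretized into min(10, sqrt(n)) equal-frequency bins and
    the plug-in estimate IG = H(y) - H(y | bin) is computed.  Deterministic.
    """
    y = np.asarray(y).astype(int)
    n = len(y)
    if n_bins is None:
        n_bins = max(2, min(10, int(math.isqrt(n))))
    h_y = _label_entropy(y)
    scores = {}
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        edges = np.unique(np.quantile(x, qs))
        bins = np.searchsorted(edges, x, side="right")
        h_cond = 0.0
        for b in np.unique(bins):
            mask = bins == b
            h_cond += mask.mean() * _entropy(np.bincount(y[mask]))
        scores[col] = h_y - h_cond
    return pd.Series(scores)


def ig_rank(X: pd.DataFrame, y: np.ndarray, k: int) -> list[str]:
    """Top-k features by information gain (ties broken by column order)."""
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds {X.shape[1]} candidate features")
    scores = ig_scores(X, y)
    order = np.argsort(-scores.to_numpy(), kind="stable")
    return [X.columns[i] for i in order[:k]]


# --------------------------------------------------------------------------
# embedded method: random-forest importance ranking


def embedded_rf_rank(
    X: pd.DataFrame,
    y: np.ndarray,
    k: int,
    seed: int = 0,
    n_estimators: int = 100,
) -> list[str]:
    """Top-k features by impurity importance of a seeded random forest."""
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds {X.shape[1]} candidate features")
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(X.to_numpy(), np.asarray(y).astype(int))
    order = np.argsort(-rf.feature_importances_, kind="stable")
    return [X.columns[i] for i in order[:k]]


def rf_importances(
    X: pd.DataFrame, y: np.ndarray, seed: int = 0, n_estimators: int = 100
) -> pd.Series:
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(X.to_numpy(), np.asarray(y).astype(int))
    return pd.Series(rf.feature_importances_, index=X.columns)


# --------------------------------------------------------------------------
# wrapper method: Boruta-style all-relevant selection


@dataclass
class BorutaResult:
    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    hit_fraction: pd.Series
    n_iter: int

    @property
    def selected(self) -> list[str]:
        return self.confirmed


def boruta_select(
    X: pd.DataFrame,
    y: np.ndarray,
    max_depth: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
    max_iter: int = 50,
    alpha: float = 0.05,
    shadow_mult: int = 2,
) -> BorutaResult:
    """All-relevant selection against permuted shadow features.

    Each iteration appends ``shadow_mult`` permuted copies of every feature to
    the design, fits a depth-limited random forest, and scores a "hit" for
    every feature whose importance exceeds the maximum shadow importance.
    Hits are tested against Binomial(n_iter, 0.5) with a two-step correction:
    FDR (Benjamini-Hochberg) across the undecided features on each one-sided
    test, then a familywise alpha/2 for the two tests.  Features undecided
    after max_iter are resolved by comparing their median importance history
    to the median of the shadow maxima (majority hit fraction required).

    ``shadow_mult=2`` keeps the shadow-max bar high enough that spuriously
    correlated noise is rejected reliably at small n.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y).astype(int)
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape

    active = np.ones(p, dtype=bool)  # not yet rejected
    decided = np.zeros(p, dtype=bool)
    confirmed = np.zeros(p, dtype=bool)
    hits = np.zeros(p, dtype=int)
    imp_history: list[np.ndarray] = []
    shadow_max_history: list[float] = []

    it = 0
    while it < max_iter and not decided.all():
        it += 1
        act_idx = np.where(active)[0]
        # the shadow pool never shrinks: a smaller pool lowers the shadow-max
        # bar and lets spuriously correlated noise survive
        shadows = np.column_stack(
            [rng.permutation(Xv[:, j]) for _ in range(shadow_mult) for j in range(p)]
        )
        design = np.column_stack([Xv[:, act_idx], shadows])
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_depth=max_depth,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(design, y)
        imp = rf.feature_importances_
        real_imp = imp[: len(act_idx)]
        shadow_max = float(imp[len(act_idx):].max())
        full_imp = np.full(p, np.nan)
        full_imp[act_idx] = real_imp
        imp_history.append(full_imp)
        shadow_max_history.append(shadow_max)
        hits[act_idx] += (real_imp > shadow_max).astype(int)

        undecided = np.where(~decided)[0]
        if undecided.size:
            h = hits[undecided]
            p_hi = binom.sf(h - 1, it, 0.5)  # P(X >= h): evidence of relevance
            p_lo = binom.cdf(h, it, 0.5)  # P(X <= h): evidence of irrelevance
            acc_ok, _ = fdrcorrection(p_hi, alpha=alpha)
            rej_ok, _ = fdrcorrection(p_lo, alpha=alpha)
            accept = acc_ok & (p_hi <= alpha / 2.0)
            reject = rej_ok & (p_lo <= alpha / 2.0)
            for pos, idx in enumerate(undecided):
                if accept[pos]:
                    decided[idx] = True
                    confirmed[idx] = True
                elif reject[pos]:
                    decided[idx] = True
                    active[idx] = False

    # resolve leftovers conservatively: confirm only features that both beat
    # the median shadow maximum and hit in a majority of iterations
    tentative = np.where(~decided)[0]
    imp_mat = np.array(imp_history)
    shadow_median = float(np.median(shadow_max_history)) if shadow_max_history else 0.0
    for idx in tentative:
        med = np.nanmedian(imp_mat[:, idx]) if imp_mat.size else 0.0
        if np.isfinite(med) and med > shadow_median and hits[idx] > it / 2:
            confirmed[idx] = True

    result = BorutaResult(
        confirmed=[names[i] for i in np.where(confirmed)[0]],
        rejected=[names[i] for i in range(p) if decided[i] and not confirmed[i]],
        tentative=[names[i] for i in tentative],
        hit_fraction=pd.Series(hits / max(it, 1), index=names),
        n_iter=it,
    )
    return result


# --------------------------------------------------------------------------
# stable method: bootstrap stability selection


def _l1_logit(C: float) -> LogisticRegression:
    return LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", max_iter=200)


def _choose_l1_C(X: np.ndarray, y: np.ndarray, seed: int) -> float:
    """Pick the L1 penalty once per run by a small internal CV (mean F1)."""
    from sklearn.metrics import f1_score
    from sklearn.model_selection import StratifiedKFold

    classes, counts = np.unique(y, return_counts=True)
    n_splits = int(min(3, counts.min()))
    if n_splits < 2:
        return 1.0
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_c, best_score = 1.0, -np.inf
    for C in (0.25, 1.0, 4.0):
        scores = []
        for tr, va in splits:
            model = _l1_logit(C).fit(X[tr], y[tr])
            scores.append(f1_score(y[va], model.predict(X[va]), zero_division=0))
        mean = float(np.mean(scores))
        if mean > best_score:
            best_score, best_c = mean, C
    return best_c


def stability_presence(
    X: pd.DataFrame,
    y: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    C: float | None = None,
    max_retries: int = 50,
) -> pd.Series:
    """Per-feature fraction of bootstrap subsamples with a nonzero L1 coefficient.

    B bootstrap subsamples (resample participants with replacement, size n);
    single-class subsamples are redrawn up to ``max_retries`` times.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y).astype(int)
    Xv = X.to_numpy(dtype=float)
    n = len(y)
    if C is None:
        C = _choose_l1_C(Xv, y, seed)
    present = np.zeros(X.shape[1])
    for _ in range(B):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) > 1:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap subsample")
        model = _l1_logit(C).fit(Xv[idx], y[idx])
        present += (np.abs(model.coef_[0]) > 1e-8).astype(float)
    return pd.Series(present / B, index=X.columns)


def select_at_threshold(presence: pd.Series, pi_th: float) -> list[str]:
    return list(presence.index[presence.to_numpy() >= pi_th - 1e-12])


def stability_select(
    X: pd.DataFrame,
    y: np.ndarray,
    pi_th: float,
    B: int = 1000,
    seed: int = 0,
    C: float | None = None,
) -> list[str]:
    """Features present in at least pi_th of B bootstrap subsamples."""
    if not 0.5 <= pi_th <= 0.98:
        raise ValueError("pi_th must lie in [0.50, 0.98]")
    presence = stability_presence(X, y, B=B, seed=seed, C=C)
    return select_at_threshold(presence, pi_th)


def sweep_from_fractions(
    presence: pd.Series, start: float = 0.50, stop: float = 0.98
) -> dict[float, list[str]]:
    """Read the presence fractions at thresholds start, start+0.01, ...

    Stops after the first empty selection (or at ``stop``).
    """
    out: dict[float, list[str]] = {}
    t = round(start * 100)
    t_stop = round(stop * 100)
    while t <= t_stop:
        thr = t / 100.0
        sel = select_at_threshold(presence, thr)
        out[thr] = sel
        if not sel:
            break
        t += 1
    return out


def threshold_sweep(
    X: pd.DataFrame,
    y: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    C: float | None = None,
    start: float = 0.50,
    stop: float = 0.98,
) -> dict[float, list[str]]:
    """One bootstrap pass, then the 0.01-step threshold sweep over it."""
    presence = stability_presence(X, y, B=B, seed=seed, C=C)
    return sweep_from_fractions(presence, start=start, stop=stop)


# --------------------------------------------------------------------------
# selector factories with the nested-CV calling convention


def make_ig(k: int) -> Selector:
    def select(X: pd.DataFrame, y: np.ndarray, seed: int) -> list[str]:
        return ig_rank(X, y, k)

    select.__name__ = f"ig_top{k}"
    return select


def make_rf(k: int, n_estimators: int = 100) -> Selector:
    def select(X: pd.DataFrame, y: np.ndarray, seed: int) -> list[str]:
        return embedded_rf_rank(X, y, k, seed=seed, n_estimators=n_estimators)

    select.__name__ = f"rf_top{k}"
    return select


def make_boruta(
    max_depth: int = 5,
    n_estimators: int = 100,
    max_iter: int = 50,
    alpha: float = 0.05,
    shadow_mult: int = 2,
) -> Selector:
    def select(X: pd.DataFrame, y: np.ndarray, seed: int) -> list[str]:
        res = boruta_select(
            X,
            y,
            max_depth=max_depth,
            seed=seed,
            n_estimators=n_estimators,
            max_iter=max_iter,
            alpha=alpha,
            shadow_mult=shadow_mult,
        )
        return res.selected

    select.__name__ = f"boruta_depth{max_depth}"
    return select


def make_stability(pi_th: float, B: int = 1000, C: float | None = None) -> Selector:
    def select(X: pd.DataFrame, y: np.ndarray, seed: int) -> list[str]:
        return stability_select(X, y, pi_th, B=B, seed=seed, C=C)

    select.__name__ = f"stability_{pi_th:.2f}"
    return select
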