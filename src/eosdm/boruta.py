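"""All-relevant feature selection by the Boruta shadow-feature algorithm.

Each iteration appends a "shadow" copy of every active covariate with its
values independently permuted, fits a regression random forest on the
real + shadow design, and scores a *hit* for every undecided real covariate
whose importance exceeds the maximum shadow importance.  Accumulated hit
counts are tested against Binomial(iterations, 0.5) two-sidedly with
Bonferroni correction: covariates with significantly more hits than chance
are confirmed, significantly fewer are rejected (and leave the design).
Covariates still undecided at ``max_iter`` are tentative; the "rough fix"
compares their median importance history with the median of the running
maximum-shadow importance.

Selection iterations score importance with out-of-bag permutation importance
(:func:`permutation_importance`): out-of-sample evaluation is what keeps a
permuted-response null clean, since in-sample impurity importance rewards
spurious dataset-level correlations.  Impurity importance is available as a
faster alternative backend.

"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

__all__ = ["BorutaResult", "boruta_select", "permutation_importance"]

CONFIRMED = "confirmed"
TENTATIVE = "tentative"
REJECTED = "rejected"


@dataclass
class BorutaResult:
    """Outcome of a Boruta run."""

    decision: dict[str, str]  # name -> confirmed/tentative/rejected
    hits: dict[str, int]
    importance_history: pd.DataFrame  # iterations x features (NaN once dropped)
    shadow_max_history: np.ndarray
    iterations: int
    alpha: float
    seed: int
    rough_fix_keep: dict[str, bool] = field(default_factory=dict)
    decision_iteration: dict[str, int] = field(default_factory=dict)  # iteration a decision was made

    @property
    def confirmed(self) -> list[str]:
        return [n for n, d in self.decision.items() if d == CONFIRMED]

    @property
    def tentative(self) -> list[str]:
        return [n for n, d in self.decision.items() if d == TENTATIVE]

    @property
    def rejected(self) -> list[str]:
        return [n for n, d in self.decision.items() if d == REJECTED]

    def selected(self, keep_tentative: bool = True) -> list[str]:
        """Features passed downstream: confirmed plus rough-fix-kept tentatives."""
        out = list(self.confirmed)
        if keep_tentative:
            out += [n for n in self.tentative if self.rough_fix_keep.get(n, False)]
        return out

    def to_dict(self) -> dict:
        return {
            "decision": self.decision,
            "hits": self.hits,
            "rough_fix_keep": self.rough_fix_keep,
            "iterations": self.iterations,
            "alpha": self.alpha,
            "seed": self.seed,
            "importance_history": {
                c: [None if not np.isfinite(v) else float(v) for v in self.importance_history[c]]
                for c in self.importance_history.columns
            },
        }


def _forest(n_trees: int, seed: int, max_features="sqrt") -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_trees, max_features=max_features, random_state=seed, n_jobs=1
    )


def permutation_importance(
    model: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-bag permutation importance of a fitted regression forest.

    For each tree, the squared error on the tree's out-of-bag rows is
    compared with the error after permuting one covariate's values among
    those rows; the importance of the covariate is the mean increase in OOB
    squared error over trees and repeats (Breiman's mean decrease in
    accuracy).  Covariates a tree never splits on — including constant
    columns — contribute exactly zero for that tree.  Deterministic given
    seed.

    All permuted variants of a tree's used covariates are stacked into a
    single predict call per tree, which keeps the cost near one forest
    prediction rather than one per (tree, covariate).
    """
    try:
        estimators = model.estimators_
    except AttributeError:
        raise ValueError("model must be a fitted random forest") from None
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    n_samples_bootstrap = n if model.max_samples is None else max(1, round(model.max_samples * n))
    imp = np.zeros(p)
    n_used = 0
    for tree in estimators:
        oob = np.ones(n, dtype=bool)
        if model.bootstrap:
            idx = _tree_sample_indices(tree, n, n_samples_bootstrap)
            oob[idx] = False
        m = int(oob.sum())
        if m == 0:
            continue
        n_used += 1
        Xo = np.ascontiguousarray(X[oob], dtype=np.float32)
        yo = y[oob]
        t = tree.tree_
        err0 = np.mean((yo - t.predict(Xo)[:, 0]) ** 2)
        feats = np.unique(t.feature)
        feats = feats[feats >= 0]
        if feats.size == 0:
            continue
        for _ in range(n_repeats):
            big = np.broadcast_to(Xo, (feats.size,) + Xo.shape).copy()
            for k, j in enumerate(feats):
                big[k, :, j] = Xo[rng.permutation(m), j]
            preds = t.predict(big.reshape(-1, p))[:, 0].reshape(feats.size, m)
            err = np.mean((yo[None, :] - preds) ** 2, axis=1)
            imp[feats] += (err - err0) / n_repeats
    if n_used == 0:
        raise ValueError("forest has no out-of-bag samples (bootstrap disabled?)")
    return imp / n_used


def _tree_sample_indices(tree, n: int, n_samples_bootstrap: int) -> np.ndarray:
    rng = np.random.RandomState(tree.random_state)
    return rng.randint(0, n, n_samples_bootstrap)


def _oob_permutation_z(model, X, y, seed: int = 0, n_repeats: int = 1) -> np.ndarray:
    """Z-scored out-of-bag permutation importance (mean / SE over trees).

    The per-tree increase in OOB squared error under permutation is averaged
    over trees and divided by its standard error, counting trees that do not
    use a covariate as zero contribution.  Scaling by the SE penalizes
    covariates whose apparent importance rests on a handful of trees, which
    is what keeps spurious within-sample correlations from accumulating hits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    n_boot = n if model.max_samples is None else max(1, round(model.max_samples * n))
    s1 = np.zeros(p)
    s2 = np.zeros(p)
    n_used = 0
    for tree in model.estimators_:
        oob = np.ones(n, dtype=bool)
        if model.bootstrap:
            oob[_tree_sample_indices(tree, n, n_boot)] = False
        m = int(oob.sum())
        if m == 0:
            continue
        n_used += 1
        Xo = np.ascontiguousarray(X[oob], dtype=np.float32)
        yo = y[oob]
        t = tree.tree_
        err0 = np.mean((yo - t.predict(Xo)[:, 0]) ** 2)
        feats = np.unique(t.feature)
        feats = feats[feats >= 0]
        if feats.size == 0:
            continue
        diff = np.zeros(feats.size)
        for _ in range(n_repeats):
            big = np.broadcast_to(Xo, (feats.size,) + Xo.shape).copy()
            for k, j in enumerate(feats):
                big[k, :, j] = Xo[rng.permutation(m), j]
            preds = t.predict(big.reshape(-1, p))[:, 0].reshape(feats.size, m)
            diff += (np.mean((yo[None, :] - preds) ** 2, axis=1) - err0) / n_repeats
        s1[feats] += diff
        s2[feats] += diff**2
    if n_used == 0:
        raise ValueError("forest has no out-of-bag samples")
    mean = s1 / n_used
    var = s2 / n_used - mean**2
    sd = np.sqrt(np.clip(var, 0, None))
    z = np.zeros(p)
    nz = sd > 0
    z[nz] = mean[nz] / (sd[nz] / np.sqrt(n_used))
    return z


def boruta_select(
    X: pd.DataFrame,
    y,
    alpha: float = 0.01,
    max_iter: int = 100,
    n_trees: int = 500,
    seed: int = 0,
    importance: str = "permutation",
    shadow_multiplier: int = 1,
    importance_repeats: int = 1,
) -> BorutaResult:
    """Run Boruta all-relevant selection on a feature table.

    Parameters
    ----------
    X : DataFrame of named covariates (>= 2 columns, >= 5 rows).
    y : continuous response.
    alpha : level of the Bonferroni-corrected binomial hit tests.
    importance : "permutation" (default, OOB z-score), "permutation_mean"
        or "impurity" (faster, but in-sample).
    shadow_multiplier : independent permuted shadow copies per covariate;
        more copies give a higher, more stable max-shadow bar.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X), columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])
    input_names = list(X.columns)
    if len(input_names) < 2:
        raise ValueError("need at least two covariates")
    if len(X) < 5:
        raise ValueError("fewer than 5 units: selection unreliable")
    y = np.asarray(y, dtype=float)
    # canonical internal ordering makes selection invariant to column order
    names = sorted(input_names, key=str)
    Xv = X[names].to_numpy(dtype=float)
    n, p = Xv.shape

    decision = {nm: TENTATIVE for nm in names}
    decision_iter: dict[str, int] = {}
    hits = {nm: 0 for nm in names}
    tested = {nm: 0 for nm in names}
    history = np.full((max_iter, p), np.nan)
    shadow_max_hist = np.full(max_iter, np.nan)
    active = list(range(p))  # not-rejected features stay in the design

    import zlib

    def _col_rng(i, nm):
        return np.random.default_rng(np.random.SeedSequence([seed, i, zlib.crc32(str(nm).encode())]))

    it = 0
    for it in range(1, max_iter + 1):
        Xa = Xv[:, active]
        # shadows of the FULL original covariate set: the max-shadow bar
        # must not weaken as covariates are rejected, otherwise late-run
        # spurious survivors race against a handful of shadows and win
        shadows = np.column_stack(
            [
                _col_rng(it, (nm, rep)).permutation(Xv[:, j])
                for rep in range(shadow_multiplier)
                for j, nm in enumerate(names)
            ]
        )
        design = np.column_stack([Xa, shadows])
        iter_seed = int(np.random.SeedSequence([seed, it]).generate_state(1)[0] % (2**31 - 1))
        # mtry = p/3, the regression default of the reference implementations:
        # informative covariates must enter most trees for a stable z-score
        model = _forest(n_trees, seed=iter_seed, max_features=1.0 / 3.0)
        model.fit(design, y)
        if importance == "impurity":
            imp = model.feature_importances_
        elif importance == "permutation":
            imp = _oob_permutation_z(model, design, y, seed=iter_seed, n_repeats=importance_repeats)
        elif importance == "permutation_mean":
            imp = permutation_importance(model, design, y, n_repeats=1, seed=iter_seed)
        else:
            raise ValueError("importance must be 'impurity', 'permutation' or 'permutation_mean'")
        real_imp = imp[: len(active)]
        shadow_max = imp[len(active):].max()
        shadow_max_hist[it - 1] = shadow_max
        history[it - 1, active] = real_imp
        for pos, j in enumerate(active):
            nm = names[j]
            if decision[nm] != TENTATIVE:
                continue
            tested[nm] += 1
            if real_imp[pos] > shadow_max:
                hits[nm] += 1
        # two-sided binomial tests, Bonferroni over all p covariates
        thresh = alpha / (2 * p)
        newly_rejected = []
        for j in active:
            nm = names[j]
            if decision[nm] != TENTATIVE:
                continue
            k, m = hits[nm], tested[nm]
            if stats.binom.sf(k - 1, m, 0.5) < thresh:
                decision[nm] = CONFIRMED
                decision_iter[nm] = it
            elif stats.binom.cdf(k, m, 0.5) < thresh:
                decision[nm] = REJECTED
                decision_iter[nm] = it
                newly_rejected.append(j)
        if newly_rejected:
            active = [j for j in active if j not in newly_rejected]
        if all(decision[nm] != TENTATIVE for nm in names) or len(active) == 0:
            break

    # rough fix for still-tentative features
    rough_keep = {}
    shadow_median = np.nanmedian(shadow_max_hist[:it])
    for j, nm in enumerate(names):
        if decision[nm] == TENTATIVE:
            med = np.nanmedian(history[:it, j])
            rough_keep[nm] = bool(np.isfinite(med) and med > shadow_median)

    return BorutaResult(
        decision={nm: decision[nm] for nm in input_names},
        hits={nm: hits[nm] for nm in input_names},
        importance_history=pd.DataFrame(history[:it], columns=names)[input_names],
        shadow_max_history=shadow_max_hist[:it],
        iterations=it,
        alpha=alpha,
        seed=seed,
        rough_fix_keep=rough_keep,
        decision_iteration=decision_iter,
    )
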