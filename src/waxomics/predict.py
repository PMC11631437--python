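"""Random-forest prediction of g_c from wax-trait BLUPs.

Predictive ability is the Pearson correlation between pooled out-of-fold
predictions and the observed values, averaged over repeated k-fold
cross-validation (5-fold, 50 repeats by default; ntree = 1000, mtry = 10).
Variable importance is out-of-bag permutation importance: the mean increase
in a tree's OOB squared error when one feature is permuted.  A univariate
Pearson screen complements the forest.

The forest is a CART ensemble (scikit-learn trees over explicit bootstrap
samples), a standard stand-in for conditional-inference forests; the backend
is isolated behind this module so it can be swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from ._utils import derive_seed


@dataclass
class RFConfig:
    n_trees: int = 1000
    mtry: int = 10
    n_folds: int = 5
    n_repeats: int = 50
    seed: int = 0

    def validate(self, n_features: int) -> None:
        if self.mtry > n_features:
            raise ValueError("mtry exceeds the number of features")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class PredictionReport:
    per_repeat_ability: list[float]
    mean_ability: float
    n_lines: int
    dropped_lines: list[str] = field(default_factory=list)
    config: RFConfig | None = None

    def to_json_dict(self) -> dict:
        return {
            "per_repeat_ability": [float(r) for r in self.per_repeat_ability],
            "mean_ability": float(self.mean_ability),
            "n_lines": self.n_lines,
            "dropped_lines": self.dropped_lines,
        }


def _align_complete(features: pd.DataFrame, target: pd.Series):
    common = features.index.intersection(target.index)
    X = features.loc[common]
    y = target.loc[common]
    ok = ~(X.isna().any(axis=1) | y.isna())
    dropped = [str(i) for i in common[~ok]]
    return X.loc[ok], y.loc[ok], dropped


def rf_cross_validate(
    features: pd.DataFrame, target: pd.Series, config: RFConfig | None = None
) -> PredictionReport:
    """Repeated k-fold CV predictive ability of a random forest.

    Each repeat draws a fresh fold split; the repeat's predictive ability is
    the Pearson r of the pooled out-of-fold predictions against the observed
    values.  Lines with missing entries are dropped and logged.  Fully
    deterministic under ``config.seed``.
    """
    cfg = config or RFConfig()
    X, y, dropped = _align_complete(features, target)
    cfg.validate(X.shape[1])
    n = len(y)
    if n < cfg.n_folds:
        raise ValueError("fewer lines than folds")
    Xv, yv = X.to_numpy(float), y.to_numpy(float)
    abilities = []
    for rep in range(cfg.n_repeats):
        kf = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=derive_seed(cfg.seed, rep))
        preds = np.empty(n)
        for fi, (tr, te) in enumerate(kf.split(Xv)):
            rf = RandomForestRegressor(
                n_estimators=cfg.n_trees,
                max_features=cfg.mtry,
                random_state=derive_seed(cfg.seed, rep, fi),
                n_jobs=1,
            )
            rf.fit(Xv[tr], yv[tr])
            preds[te] = rf.predict(Xv[te])
        abilities.append(float(stats.pearsonr(preds, yv)[0]))
    return PredictionReport(
        per_repeat_ability=abilities,
        mean_ability=float(np.mean(abilities)),
        n_lines=n,
        dropped_lines=dropped,
        config=cfg,
    )


def rf_importance(
    features: pd.DataFrame, target: pd.Series, config: RFConfig | None = None
) -> pd.DataFrame:
    """Out-of-bag permutation importance of each feature.

    Trees are grown on explicit bootstrap samples; for each tree and feature,
    the feature is permuted among the tree's OOB lines and the increase in
    OOB squared error is recorded.  Importance is the mean increase over
    trees; a constant feature's permutation changes nothing, so its
    importance is exactly 0.  Ranks are descending by importance.
    """
    cfg = config or RFConfig()
    X, y, _ = _align_complete(features, target)
    cfg.validate(X.shape[1])
    Xv, yv = X.to_numpy(float), y.to_numpy(float)
    n, m = Xv.shape
    rng = np.random.default_rng(derive_seed(cfg.seed, 7001))
    total = np.zeros(m)
    used = np.zeros(m)
    for _t in range(cfg.n_trees):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0:
            continue
        tree = DecisionTreeRegressor(
            max_features=cfg.mtry, random_state=int(rng.integers(0, 2**31))
        )
        tree.fit(Xv[idx], yv[idx])
        base = float(np.mean((tree.predict(Xv[oob]) - yv[oob]) ** 2))
        Xo = Xv[oob].copy()
        for j in range(m):
            col = Xo[:, j].copy()
            Xo[:, j] = col[rng.permutation(oob.size)]
            err = float(np.mean((tree.predict(Xo) - yv[oob]) ** 2))
            Xo[:, j] = col
            total[j] += err - base
            used[j] += 1
    imp = np.where(used > 0, total / np.maximum(used, 1), 0.0)
    out = pd.DataFrame({"feature": X.columns, "importance": imp})
    out = out.sort_values("importance", ascending=False, kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def trait_correlations(features: pd.DataFrame, target: pd.Series) -> pd.DataFrame:
    """Pearson r and two-sided p of each feature against the target.

    p comes from t = r sqrt(n-2)/sqrt(1-r^2) on n-2 df.  Features with zero
    variance get r = NaN and are flagged.
    """
    rows = []
    for col in features.columns:
        x = features[col]
        pair = pd.concat([x, target], axis=1, join="inner").dropna()
        n = len(pair)
        if n < 3:
            raise ValueError(f"feature {col!r} has fewer than 3 paired observations")
        xv, yv = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
        if xv.std() == 0 or yv.std() == 0:
            rows.append((col, np.nan, np.nan, n, True))
            continue
        r = float(np.corrcoef(xv, yv)[0, 1])
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
        rows.append((col, r, p, n, False))
    return pd.DataFrame(rows, columns=["feature", "r", "p", "n", "degenerate"])
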