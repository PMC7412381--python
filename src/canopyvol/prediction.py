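"""Random-forest CVP prediction: feature selection, 7:3 split, global vs
local modelling, and R^2 / RMSE evaluation.

Predictors are chosen from the 21 image features by the absolute Pearson
correlation with CVP (|r| >= 0.5 by default; the threshold is inclusive and
applied to |r| because intensity-type indices correlate negatively). The
forest uses the field-standard defaults ntree = 500 and mtry = one third of
the predictor count (3 for ten predictors).

Two modelling strategies:

* GPM (global prediction modelling): one model pooled over all varieties.
* LPM (local prediction modelling): one model per variety; per-variety
  validation predictions are concatenated before computing pooled metrics,
  so GPM and LPM are compared on the same validation samples.

Evaluation metrics, for measured y_i, predicted y'_i, n samples:

    R^2  = 1 - sum_i (y_i - y'_i)^2 / sum_i (y_i - ybar)^2
    RMSE = sqrt( sum_i (y_i - y'_i)^2 / n )

R^2 may be negative for a poor model and is not clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import ConfigError, DegenerateInputError, ValidationError
from .features import FEATURE_ORDER

DEFAULT_NTREE = 500
DEFAULT_SPLIT_RATIO = 0.7
DEFAULT_CORR_THRESHOLD = 0.5


@dataclass(frozen=True)
class FeatureSelection:
    """Features retained at an absolute-correlation cutoff against CVP."""

    threshold: float
    selected: tuple[str, ...]
    correlations: dict[str, float]


@dataclass(frozen=True)
class ModelConfig:
    strategy: str = "GPM"  # "GPM" or "LPM"
    mtry: int | None = None  # None -> default_mtry(n_predictors)
    ntree: int = DEFAULT_NTREE
    split_ratio: float = DEFAULT_SPLIT_RATIO
    seed: int = 0
    group_key: str = "variety"

    def __post_init__(self):
        if self.strategy not in ("GPM", "LPM"):
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        if not 0.0 < self.split_ratio < 1.0:
            raise ConfigError("split_ratio must be in (0, 1)")
        if self.ntree < 1:
            raise ConfigError("ntree must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ConfigError("mtry must be >= 1")


@dataclass
class ModelReport:
    """Train/validation predictions with self-recomputable metrics.

    ``predictions`` holds (sample_id, set, measured, predicted[, group])
    rows; the stored r2/rmse are always recomputable from them via
    :func:`evaluate`.
    """

    strategy: str
    config: ModelConfig
    features: tuple[str, ...]
    n_train: int
    n_validation: int
    train_r2: float
    train_rmse: float
    validation_r2: float
    validation_rmse: float
    predictions: pd.DataFrame
    group_metrics: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "config": {
                "strategy": self.config.strategy,
                "mtry": self.config.mtry,
                "ntree": self.config.ntree,
                "split_ratio": self.config.split_ratio,
                "seed": self.config.seed,
                "group_key": self.config.group_key,
            },
            "features": list(self.features),
            "modelling": {"n": self.n_train, "r2": self.train_r2, "rmse": self.train_rmse},
            "validation": {
                "n": self.n_validation,
                "r2": self.validation_r2,
                "rmse": self.validation_rmse,
            },
            "group_metrics": self.group_metrics,
            "predictions": self.predictions.to_dict(orient="records"),
        }


def default_mtry(n_predictors: int) -> int:
    """mtry = floor(n_predictors / 3), clamped to at least 1."""
    if n_predictors < 1:
        raise ValidationError("need at least one predictor")
    return max(1, n_predictors // 3)


def select_by_correlation(
    correlations: dict[str, float], threshold: float = DEFAULT_CORR_THRESHOLD
) -> FeatureSelection:
    """Apply the |r| >= threshold rule to a feature -> r map.

    Selection order is the declaration order of the 21 features; NaN
    correlations are never selected.
    """
    order = [f for f in FEATURE_ORDER if f in correlations]
    order += [f for f in correlations if f not in order]
    selected = tuple(
        f
        for f in order
        if not np.isnan(correlations[f]) and abs(correlations[f]) >= threshold
    )
    return FeatureSelection(threshold=threshold, selected=selected, correlations=dict(correlations))


def select_features(
    features: pd.DataFrame,
    cvp,
    threshold: float = DEFAULT_CORR_THRESHOLD,
) -> FeatureSelection:
    """Correlate each feature column with CVP and keep those at |r| >= threshold.

    Constant columns cannot be correlated; they are excluded with a warning
    rather than aborting the run.
    """
    cvp = np.asarray(cvp, dtype=float)
    if len(features) != cvp.size or cvp.size < 3:
        raise ValidationError("need >= 3 samples with matching feature rows")
    cols = [c for c in FEATURE_ORDER if c in features.columns]
    corrs: dict[str, float] = {}
    for c in cols:
        x = features[c].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(cvp[ok]) == 0:
            warnings.warn(f"feature {c!r} is constant or too sparse; excluded")
            corrs[c] = np.nan
            continue
        corrs[c] = float(np.corrcoef(x[ok], cvp[ok])[0, 1])
    return select_by_correlation(corrs, threshold)


def split_dataset(
    samples: pd.DataFrame,
    split_ratio: float = DEFAULT_SPLIT_RATIO,
    seed: int = 0,
    strata: str | list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/validation split with train size = round(n * ratio).

    With ``strata`` (a column or list of columns), sampling balances the
    strata proportions; strata smaller than 2 trigger a fallback to a
    simple random split with a warning. Disjoint and exhaustive by
    construction; reproducible for a fixed seed.
    """
    n = len(samples)
    if n < 2:
        raise ValidationError("need at least 2 samples to split")
    n_train = int(round(n * split_ratio))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)

    if strata is not None:
        keys = [strata] if isinstance(strata, str) else list(strata)
        groups = list(samples.groupby(keys, sort=True))
        if any(len(g) < 2 for _, g in groups):
            warnings.warn("stratum with < 2 samples; falling back to simple split")
            strata = None
        else:
            train_idx: list = []
            # largest-remainder allocation of the train quota across strata
            quotas = [(len(g) * split_ratio, name, g) for name, g in groups]
            base = [(int(np.floor(q)), name, g) for q, name, g in quotas]
            remainders = sorted(
                ((q - np.floor(q), i) for i, (q, _, _) in enumerate(quotas)),
                key=lambda t: (-t[0], t[1]),
            )
            counts = [b for b, _, _ in base]
            short = n_train - sum(counts)
            for _, i in remainders:
                if short <= 0:
                    break
                if counts[i] < len(groups[i][1]):
                    counts[i] += 1
                    short -= 1
            for (name, g), k in zip(groups, counts):
                perm = rng.permutation(len(g))
                train_idx.extend(g.index[perm[:k]])
            train_mask = samples.index.isin(train_idx)
            return samples[train_mask], samples[~train_mask]

    perm = rng.permutation(n)
    train_pos = np.sort(perm[:n_train])
    val_pos = np.sort(perm[n_train:])
    return samples.iloc[train_pos], samples.iloc[val_pos]


def train_cvp_model(
    train: pd.DataFrame,
    feature_names: list[str] | tuple[str, ...],
    config: ModelConfig,
    target: str = "cvp",
) -> RandomForestRegressor:
    """Fit the bagged-tree ensemble on the training set.

    Each tree is grown on a bootstrap resample, each split drawing among
    ``mtry`` randomly chosen features; the ensemble prediction is the mean
    over trees. mtry, ntree and seed are honoured and recorded on the
    fitted object.
    """
    if len(train) == 0:
        raise ValidationError("empty training set")
    missing = [f for f in feature_names if f not in train.columns]
    if missing:
        raise ConfigError(f"features missing from training data: {missing}")
    mtry = config.mtry if config.mtry is not None else default_mtry(len(feature_names))
    if mtry > len(feature_names):
        raise ConfigError(
            f"mtry {mtry} exceeds the {len(feature_names)} selected features"
        )
    model = RandomForestRegressor(
        n_estimators=config.ntree,
        max_features=mtry,
        random_state=config.seed,
        bootstrap=True,
    )
    model.fit(train[list(feature_names)].to_numpy(), train[target].to_numpy())
    return model


def evaluate(measured, predicted) -> tuple[float, float]:
    """(R^2, RMSE) of predictions against measurements.

    R^2 = 1 - SS_res / SS_tot is undefined for a constant measured
    sequence (raises, RMSE is still computable via a direct call with a
    nonconstant target); it may be negative and is not clamped.
    """
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValidationError("need >= 2 paired values")
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateInputError("R^2 undefined: measured values are constant")
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return r2, rmse


def rmse(measured, predicted) -> float:
    """Root mean square error alone (defined even for a constant target)."""
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def relative_change(baseline: float, new: float, direction: str = "increase") -> float:
    """Percent change of a metric against a baseline, one-decimal rounded.

    ``direction='increase'`` reports (new - baseline) / baseline * 100
    (improvements); ``'decrease'`` reports (baseline - new) / baseline *
    100 (reductions).
    """
    if baseline == 0:
        raise DegenerateInputError("relative change undefined for zero baseline")
    if direction == "increase":
        pct = (new - baseline) / baseline * 100.0
    elif direction == "decrease":
        pct = (baseline - new) / baseline * 100.0
    else:
        raise ValidationError(f"direction must be 'increase' or 'decrease', got {direction!r}")
    return round(pct, 1)


def run_strategy(
    samples: pd.DataFrame,
    feature_names: list[str] | tuple[str, ...],
    config: ModelConfig,
    target: str = "cvp",
    strata: str | list[str] | None = ("variety", "stage"),
) -> ModelReport:
    """Split, train and evaluate under the configured strategy.

    GPM fits one model on the pooled training set. LPM fits one model per
    ``config.group_key`` group on the *same* seed-derived partition (so the
    GPM/LPM comparison is paired) and concatenates per-group validation
    predictions before computing pooled metrics. Modelling-set metrics are
    resubstitution (predictions on the training samples themselves) and
    labelled as such.
    """
    feature_names = tuple(feature_names)
    if strata is not None:
        strata = [s for s in ([strata] if isinstance(strata, str) else strata) if s in samples.columns]
        strata = strata or None
    train, val = split_dataset(samples, config.split_ratio, config.seed, strata=strata)

    frames = []
    group_metrics: dict[str, dict[str, float]] = {}
    if config.strategy == "GPM":
        model = train_cvp_model(train, feature_names, config, target)
        for name, part in (("modelling", train), ("validation", val)):
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": part.get("sample_id", part.index).astype(str),
                        "set": name,
                        "group": "all",
                        "measured": part[target].to_numpy(),
                        "predicted": model.predict(part[list(feature_names)].to_numpy()),
                    }
                )
            )
    else:
        key = config.group_key
        if key not in samples.columns:
            raise ConfigError(f"LPM group key {key!r} not in data")
        empty = [g for g, grp in samples.groupby(key) if len(grp) == 0]
        for g, grp in train.groupby(key, sort=True):
            gval = val[val[key] == g]
            if len(grp) == 0 or len(gval) == 0:
                raise ConfigError(f"LPM group {g!r} has an empty train or validation set")
            model = train_cvp_model(grp, feature_names, config, target)
            for name, part in (("modelling", grp), ("validation", gval)):
                frames.append(
                    pd.DataFrame(
                        {
                            "sample_id": part.get("sample_id", part.index).astype(str),
                            "set": name,
                            "group": str(g),
                            "measured": part[target].to_numpy(),
                            "predicted": model.predict(part[list(feature_names)].to_numpy()),
                        }
                    )
                )
        if empty:
            raise ConfigError(f"empty LPM groups: {empty}")

    preds = pd.concat(frames, ignore_index=True)
    tr = preds[preds["set"] == "modelling"]
    va = preds[preds["set"] == "validation"]
    train_r2, train_rmse = evaluate(tr["measured"], tr["predicted"])
    val_r2, val_rmse = evaluate(va["measured"], va["predicted"])
    if config.strategy == "LPM":
        for g, grp in va.groupby("group", sort=True):
            g_r2, g_rmse = evaluate(grp["measured"], grp["predicted"])
            group_metrics[str(g)] = {"n": int(len(grp)), "r2": g_r2, "rmse": g_rmse}
    return ModelReport(
        strategy=config.strategy,
        config=config,
        features=feature_names,
        n_train=int(len(tr)),
        n_validation=int(len(va)),
        train_r2=train_r2,
        train_rmse=train_rmse,
        validation_r2=val_r2,
        validation_rmse=val_rmse,
        predictions=preds,
        group_metrics=group_metrics,
    )
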