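"""Voxel-level tumour/benign classifier comparison (the CAD study).

Five nested feature sets — T2w+ADC alone, then with quantitative and/or
semi-quantitative DCE parameters added — are each fitted with logistic
regression (LR) and a random forest (RF), per grade stratum.  Benign voxels
are randomly down-sampled (default to 1:1 with tumour voxels) to address the
roughly 4.6:1 class imbalance, features are standardised with training-split
statistics only, and sensitivity / specificity / accuracy are reported on a
held-out 20% voxel split, with impurity-based feature importance for the RF.

Quantitative features use the Parker-AIF parameter names.  The voxel-level
split follows the study design it reproduces; its known optimism relative to
a patient-level split is documented, and grouping by patient is available
via ``group_by_patient``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupShuffleSplit, train_test_split

__all__ = [
    "FEATURE_SETS",
    "CadConfig",
    "CadResult",
    "prepare_splits",
    "train_eval",
    "run_model_grid",
    "grid_report",
]

#: the five feature sets compared in the study, in presentation order
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "T2w+ADC": ("t2w", "adc"),
    "T2w+ADC+Ktrans": ("t2w", "adc", "ktrans_parker"),
    "T2w+ADC+Ktrans+Ve": ("t2w", "adc", "ktrans_parker", "ve_parker"),
    "T2w+ADC+TTP+IRE+AUC": ("t2w", "adc", "ttp", "ire", "auc"),
    "T2w+ADC+Ktrans+Ve+TTP+AUC": (
        "t2w",
        "adc",
        "ktrans_parker",
        "ve_parker",
        "ttp",
        "auc",
    ),
}

RF_N_TREES = 500


@dataclass(frozen=True)
class CadConfig:
    """One cell of the classifier grid."""

    feature_set: str = "T2w+ADC"
    classifier: str = "rf"  # "lr" or "rf"
    stratum: str = "all"  # "low_grade", "high_grade" or "all"
    test_fraction: float = 0.20
    downsample_ratio: float = 1.0  # benign : tumour target
    seed: int = 0
    group_by_patient: bool = False

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if self.classifier not in ("lr", "rf"):
            raise ValueError("classifier must be 'lr' or 'rf'")
        if self.stratum not in ("low_grade", "high_grade", "all"):
            raise ValueError("stratum must be low_grade, high_grade or all")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.downsample_ratio <= 0:
            raise ValueError("downsample_ratio must be > 0")

    @property
    def features(self) -> tuple[str, ...]:
        return FEATURE_SETS[self.feature_set]


@dataclass
class CadResult:
    """Held-out metrics (tumour = positive class) for one grid cell."""

    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fn: int
    tn: int
    fp: int
    feature_importance: dict[str, float] | None
    config: CadConfig = field(default_factory=CadConfig)

    @property
    def confusion(self) -> dict[str, int]:
        return {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp}


@dataclass
class PreparedSplit:
    """Standardised train/test partition for one grid cell."""

    x_train: np.ndarray
    x_test: np.ndarray
    y_train: np.ndarray
    y_test: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    features: tuple[str, ...]


def _select_stratum(table: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return table
    return table[(table["label"] == "benign") | (table["stratum"] == stratum)]


def prepare_splits(table: pd.DataFrame, config: CadConfig) -> PreparedSplit:
    """Down-sample benign voxels, split 80/20 and standardise.

    The benign class is randomly down-sampled (seeded) to
    ``downsample_ratio`` times the tumour count *before* splitting; the split
    is stratified by label (or grouped by patient when requested); feature
    standardisation uses training-split statistics only, so no information
    leaks from the test voxels.
    """
    rng = np.random.RandomState(config.seed)
    sub = _select_stratum(table, config.stratum).dropna(subset=list(config.features))
    benign = sub[sub["label"] == "benign"]
    tumour = sub[sub["label"] == "tumour"]
    if len(benign) == 0 or len(tumour) == 0:
        raise ValueError("both classes must be present in the selected stratum")
    n_keep = min(len(benign), int(round(config.downsample_ratio * len(tumour))))
    benign = benign.iloc[rng.choice(len(benign), size=n_keep, replace=False)]
    data = pd.concat([benign, tumour], ignore_index=True)
    x = data[list(config.features)].to_numpy(dtype=float)
    y = (data["label"] == "tumour").to_numpy()
    if config.group_by_patient:
        splitter = GroupShuffleSplit(
            n_splits=1, test_size=config.test_fraction, random_state=config.seed
        )
        train_idx, test_idx = next(splitter.split(x, y, groups=data["patient_id"]))
        x_train, x_test = x[train_idx], x[test_idx]
        y_train, y_test = y[train_idx], y[test_idx]
    else:
        x_train, x_test, y_train, y_test = train_test_split(
            x,
            y,
            test_size=config.test_fraction,
            random_state=config.seed,
            stratify=y,
        )
    mean = x_train.mean(axis=0)
    std = x_train.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    return PreparedSplit(
        x_train=(x_train - mean) / std,
        x_test=(x_test - mean) / std,
        y_train=y_train,
        y_test=y_test,
        mean=mean,
        std=std,
        features=config.features,
    )


def _make_classifier(config: CadConfig):
    if config.classifier == "lr":
        # default sklearn penalty is the L2 ridge
        return LogisticRegression(C=1.0, max_iter=2000)
    return RandomForestClassifier(
        n_estimators=RF_N_TREES,
        max_depth=None,
        random_state=config.seed,
        n_jobs=1,
    )


def train_eval(table: pd.DataFrame, config: CadConfig) -> CadResult:
    """Fit the configured classifier and evaluate on the held-out voxels."""
    split = prepare_splits(table, config)
    if len(np.unique(split.y_train)) < 2:
        raise ValueError("training data is single-class; cannot fit")
    clf = _make_classifier(config)
    clf.fit(split.x_train, split.y_train)
    pred = clf.predict(split.x_test)
    tp = int(np.sum(pred & split.y_test))
    fn = int(np.sum(~pred & split.y_test))
    tn = int(np.sum(~pred & ~split.y_test))
    fp = int(np.sum(pred & ~split.y_test))
    total = tp + fn + tn + fp
    importance = None
    if config.classifier == "rf":
        imp = clf.feature_importances_
        importance = dict(zip(split.features, (imp / imp.sum()).tolist()))
    return CadResult(
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        accuracy=(tp + tn) / total,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        feature_importance=importance,
        config=config,
    )


def run_model_grid(
    table: pd.DataFrame,
    seed: int = 0,
    strata: tuple[str, ...] = ("low_grade", "high_grade", "all"),
    feature_sets: tuple[str, ...] | None = None,
    **config_kwargs,
) -> dict[tuple[str, str, str], CadResult | Exception]:
    """Run every (stratum, feature set, classifier) cell with one seed.

    Per-cell errors are recorded in the result map rather than aborting the
    grid.  Keys are (stratum, feature_set, classifier).
    """
    sets = feature_sets if feature_sets is not None else tuple(FEATURE_SETS)
    results: dict[tuple[str, str, str], CadResult | Exception] = {}
    for stratum in strata:
        for fset in sets:
            for clf in ("lr", "rf"):
                config = CadConfig(
                    feature_set=fset,
                    classifier=clf,
                    stratum=stratum,
                    seed=seed,
                    **config_kwargs,
                )
                try:
                    results[(stratum, fset, clf)] = train_eval(table, config)
                except Exception as exc:  # noqa: BLE001 - per-cell isolation
                    results[(stratum, fset, clf)] = exc
    return results


def grid_report(results: dict[tuple[str, str, str], CadResult | Exception]) -> pd.DataFrame:
    """Flatten a model grid into a feature-set by classifier metrics table."""
    rows = []
    for (stratum, fset, clf), res in results.items():
        row = {"stratum": stratum, "feature_set": fset, "classifier": clf}
        if isinstance(res, CadResult):
            row.update(
                sensitivity=res.sensitivity,
                specificity=res.specificity,
                accuracy_pct=100.0 * res.accuracy,
            )
        else:
            row.update(error=str(res))
        rows.append(row)
    return pd.DataFrame(rows)
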