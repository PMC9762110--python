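"""Distribution comparison and biomarker ranking over voxel feature tables.

The voxel feature table is a pandas DataFrame with one row per analysed voxel
(tumour or benign; excluded-ring voxels never appear), the MRI parameter
columns, a binary ``label`` (benign/tumour), a ``stratum``
(benign/low_grade/high_grade) and a ``patient_id``.  Voxels are pooled across
patients for all tests; voxel non-independence within patients is knowingly
ignored, and ``patient_id`` is retained for future clustered analyses.

Implemented here:

* pooled-standard-deviation Cohen's d with the conventional interpretation
  bins (negligible < 0.2, small 0.2-0.5, medium 0.5-0.8, large > 0.8);
* the two-sample Kolmogorov-Smirnov test (asymptotic p, suited to the
  10^5-10^6 voxel scale);
* a Pearson-correlation feature-pruning rule: while any pair of features
  correlates above the threshold, greedily drop the feature with the most
  supra-threshold partners, breaking ties toward the larger mean |r|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FEATURE_COLUMNS",
    "cohens_d",
    "effect_size_bin",
    "ks_two_sample",
    "correlation_prune",
    "effect_size_report",
]

#: MRI parameter columns of the voxel feature table, canonical order
FEATURE_COLUMNS = (
    "t2w",
    "adc",
    "ttp",
    "ire",
    "me",
    "auc",
    "ktrans_parker",
    "ve_parker",
    "ktrans_weinmann",
    "ve_weinmann",
    "iaugc60",
)

#: conventional effect-size interpretation bins on |d|
EFFECT_SIZE_BINS = (("negligible", 0.2), ("small", 0.5), ("medium", 0.8))


def cohens_d(group_a, group_b) -> float:
    """Cohen's d with the pooled standard deviation.

    d = (mean_a - mean_b) / s_pooled,
    s_pooled^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2).

    Antisymmetric under swapping the groups and invariant under a common
    affine transform.  Returns NaN (not estimable) when the pooled variance
    is zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    var_a = np.var(a, ddof=1)
    var_b = np.var(b, ddof=1)
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    if pooled <= 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


def effect_size_bin(d: float) -> str:
    """Interpretation bin for |d|: negligible/small/medium/large."""
    ad = abs(d)
    for name, upper in EFFECT_SIZE_BINS:
        if ad < upper:
            return name
    return "large"


def ks_two_sample(group_a, group_b) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value.

    The statistic is the maximum absolute difference of the two empirical
    CDFs; the p-value uses the asymptotic two-sample Kolmogorov distribution
    with effective n = n_a * n_b / (n_a + n_b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def correlation_prune(
    table: pd.DataFrame,
    features: list[str],
    threshold: float = 0.65,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy correlation-based feature elimination.

    Computes the Pearson correlation matrix of ``features`` over the rows of
    ``table`` and, while any |r| exceeds ``threshold``, drops the feature
    with the largest count of supra-threshold partners (ties broken toward
    the larger mean |r| against the remaining features, then lexicographic
    for full determinism).  Returns the retained names in their original
    order and the full correlation matrix.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    sub = table[list(features)].astype(float)
    constant = [f for f in features if np.nanstd(sub[f].to_numpy()) == 0]
    if constant:
        raise ValueError(f"correlation undefined for constant features: {constant}")
    corr = sub.corr(method="pearson")
    retained = list(features)
    while True:
        c = corr.loc[retained, retained].abs().to_numpy()
        np.fill_diagonal(c, 0.0)
        over = c > threshold
        if not over.any():
            break
        n_partners = over.sum(axis=1)
        mean_abs_r = c.sum(axis=1) / max(len(retained) - 1, 1)
        order = sorted(
            range(len(retained)),
            key=lambda q: (-n_partners[q], -mean_abs_r[q], retained[q]),
        )
        retained.pop(order[0])
    return retained, corr


def effect_size_report(
    table: pd.DataFrame,
    features: list[str] | None = None,
    strata: tuple[str, ...] = ("low_grade", "high_grade", "all"),
) -> pd.DataFrame:
    """Per-(parameter, stratum) effect sizes and KS tests versus benign voxels.

    Mirrors a parameter-by-stratum table of |Cohen's d| (with its
    interpretation bin), the KS statistic and asymptotic p-value, and the
    group sizes.  The ``all`` stratum pools low- and high-grade tumour
    voxels.
    """
    feats = list(features) if features is not None else [
        f for f in FEATURE_COLUMNS if f in table.columns
    ]
    benign = table[table["label"] == "benign"]
    rows = []
    for stratum in strata:
        if stratum == "all":
            tum = table[table["label"] == "tumour"]
        else:
            tum = table[table["stratum"] == stratum]
        for feat in feats:
            a = tum[feat].dropna().to_numpy()
            b = benign[feat].dropna().to_numpy()
            if a.size < 2 or b.size < 2:
                continue
            d = cohens_d(a, b)
            ks_stat, ks_p = ks_two_sample(a, b)
            rows.append(
                {
                    "parameter": feat,
                    "stratum": stratum,
                    "cohens_d_abs": abs(d),
                    "cohens_d_signed": d,
                    "effect_size_bin": effect_size_bin(d),
                    "ks_stat": ks_stat,
                    "ks_p": ks_p,
                    "n_tumour": int(a.size),
                    "n_benign": int(b.size),
                }
            )
    report = pd.DataFrame(rows)
    if not report.empty:
        order = (
            report[report["stratum"] == "all"]
            .sort_values("cohens_d_abs", ascending=False)["parameter"]
            .tolist()
        )
        if order:
            report["parameter"] = pd.Categorical(report["parameter"], order, ordered=True)
            report = report.sort_values(["parameter", "stratum"]).reset_index(drop=True)
            report["parameter"] = report["parameter"].astype(str)
    return report
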