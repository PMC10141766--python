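"""Two-way ANOVA screening of the nonlinear features.

For each feature a balanced fixed-effects two-way ANOVA with factors
class (4 imagery conditions) and channel is computed from the classical
sums-of-squares decomposition

    SS_total = SS_A + SS_B + SS_AB + SS_error,

with F = MS_factor / MS_error and p from the F distribution.  The sums
of squares are computed directly from cell means (not delegated to a
model-fitting package) so the decomposition itself is testable against
an independent reference.  The report is descriptive: it characterises
which classes drive between-class differences per feature, and does not
gate which features reach the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES, FeatureTable


@dataclass
class FactorTable:
    ss: float
    df: int
    f: float
    p: float


@dataclass
class AnovaResult:
    feature_name: str
    factor_tables: dict[str, FactorTable]
    alpha: float = 0.05
    cell_means: pd.DataFrame | None = None
    class_deviations: pd.Series | None = None

    def significant(self, factor: str = "class") -> bool:
        return self.factor_tables[factor].p < self.alpha


def two_way_anova(values: np.ndarray, factor_a: np.ndarray,
                  factor_b: np.ndarray, feature_name: str = "",
                  alpha: float = 0.05) -> AnovaResult:
    """Balanced two-way fixed-effects ANOVA with interaction.

    ``values[i]`` is one observation at levels ``factor_a[i]`` (class)
    and ``factor_b[i]`` (channel).  Requires a balanced design with at
    least 2 replicates per cell; raises naming the first offending cell
    otherwise.  A zero error mean square is reported as a degenerate-
    data warning with F = inf where the factor SS is positive.
    """
    values = np.asarray(values, dtype=float).ravel()
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    if not len(values) == len(factor_a) == len(factor_b):
        raise ValueError("values and factor labels must have equal length")
    a_levels = np.unique(factor_a)
    b_levels = np.unique(factor_b)
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError("each factor needs at least 2 levels")

    a, b = len(a_levels), len(b_levels)
    counts = np.zeros((a, b), dtype=int)
    sums = np.zeros((a, b))
    a_idx = {lv: i for i, lv in enumerate(a_levels)}
    b_idx = {lv: j for j, lv in enumerate(b_levels)}
    for v, la, lb in zip(values, factor_a, factor_b):
        counts[a_idx[la], b_idx[lb]] += 1
        sums[a_idx[la], b_idx[lb]] += v
    if counts.min() == 0:
        i, j = np.argwhere(counts == 0)[0]
        raise ValueError(f"empty cell: class={a_levels[i]!r}, "
                         f"channel={b_levels[j]!r}")
    n = counts[0, 0]
    if not (counts == n).all():
        raise ValueError("unbalanced design: unequal cell counts")
    if n < 2:
        raise ValueError("need >= 2 observations per cell for interaction")

    cell_means = sums / n
    grand = values.mean()
    a_means = cell_means.mean(axis=1)
    b_means = cell_means.mean(axis=0)

    ss_a = float(b * n * ((a_means - grand) ** 2).sum())
    ss_b = float(a * n * ((b_means - grand) ** 2).sum())
    ss_ab = float(n * ((cell_means - a_means[:, None] - b_means[None, :]
                        + grand) ** 2).sum())
    ss_total = float(((values - grand) ** 2).sum())
    ss_err = ss_total - ss_a - ss_b - ss_ab

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_err = a * b * (n - 1)
    ms_err = ss_err / df_err

    def ftab(ss: float, df: int) -> FactorTable:
        if ms_err <= 0:
            warnings.warn("zero error mean square: degenerate data",
                          RuntimeWarning, stacklevel=3)
            f = np.inf if ss > 1e-12 else 0.0
            p = 0.0 if ss > 1e-12 else 1.0
        else:
            f = (ss / df) / ms_err
            p = float(stats.f.sf(f, df, df_err))
        return FactorTable(ss=ss, df=df, f=float(f), p=p)

    cm = pd.DataFrame(cell_means, index=a_levels, columns=b_levels)
    pooled_sd = np.sqrt(ms_err) if ms_err > 0 else np.nan
    class_dev = pd.Series((a_means - grand) / pooled_sd if ms_err > 0
                          else np.full(a, np.nan), index=a_levels)
    return AnovaResult(
        feature_name=feature_name,
        factor_tables={
            "class": ftab(ss_a, df_a),
            "channel": ftab(ss_b, df_b),
            "interaction": ftab(ss_ab, df_ab),
            "error": FactorTable(ss=ss_err, df=df_err, f=np.nan, p=np.nan),
        },
        alpha=alpha, cell_means=cm, class_deviations=class_dev)


@dataclass
class ScreeningReport:
    results: dict[str, AnovaResult]
    summary: pd.DataFrame = field(default=None)

    def to_tsv(self, path) -> None:
        self.summary.to_csv(path, sep="\t")


def _balance(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices that down-sample majority classes to the minority count."""
    classes, counts = np.unique(labels, return_counts=True)
    n_min = counts.min()
    keep = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    return np.sort(np.concatenate(keep))


def screen_features(ft: FeatureTable, alpha: float = 0.05,
                    seed: int = 0) -> ScreeningReport:
    """Run one two-way (class x channel) ANOVA per feature.

    Observations are the per-trial, per-channel feature values; majority
    classes are down-sampled (seeded) if the table is unbalanced.  The
    summary lists per feature: class means +/- SD, the class p-value,
    and the class with the largest standardized mean deviation.
    """
    labels = np.asarray(ft.labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to screen")
    counts = np.unique(labels, return_counts=True)[1]
    if counts.min() < 2:
        raise ValueError("need at least 2 trials per class")
    if len(np.unique(counts)) > 1:
        keep = _balance(labels, np.random.default_rng(seed))
        ft = FeatureTable(matrix=ft.matrix.iloc[keep].reset_index(drop=True),
                          labels=labels[keep], subject_id=ft.subject_id)
        labels = ft.labels

    results: dict[str, AnovaResult] = {}
    rows = []
    for feat in FEATURE_NAMES:
        cols = [c for c in ft.matrix.columns if c.endswith(f"__{feat}")]
        if not cols:
            continue
        # long format: one observation per (trial, channel)
        vals = ft.matrix[cols].to_numpy().ravel()
        fa = np.repeat(labels, len(cols))
        fb = np.tile([c.rsplit("__", 1)[0] for c in cols], len(labels))
        res = two_way_anova(vals, fa, fb, feature_name=feat, alpha=alpha)
        results[feat] = res
        row = {"feature": feat,
               "p_class": res.factor_tables["class"].p,
               "F_class": res.factor_tables["class"].f,
               "significant": res.significant()}
        for cls in classes:
            sel = ft.matrix.loc[labels == cls, cols].to_numpy()
            row[f"{cls}_mean"] = sel.mean()
            row[f"{cls}_sd"] = sel.std()
        dev = res.class_deviations.abs()
        row["driving_class"] = dev.idxmax() if dev.notna().any() else ""
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("feature")
    return ScreeningReport(results=results, summary=summary)
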