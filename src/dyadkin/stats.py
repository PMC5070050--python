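"""Validation statistics: rank correlations, multiple-testing control,
nonparametric group tests and linear-classifier cross-validation.

The workflow these serve: correlate each of the 17 motion features with
the 8 CIB (Coding Interactive Behavior) composite scores using Spearman's
rho, control the family-wise error rate with Holm's step-down procedure,
compare groups with exact rank-sum / Fisher tests, and ask whether motion
features alone separate high-risk from low-risk dyads with a linear
max-margin classifier under seeded, stratified k-fold cross-validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _odds_ratio
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ValidationError
from .io import CANONICAL_FEATURES

#: The eight CIB composite scores, each rated on [1, 5].
CIB_COMPOSITES = (
    "maternal_sensitivity",
    "mother_intrusiveness",
    "mother_limit_setting",
    "dyadic_reciprocity",
    "negative_dyadic_status",
    "infant_avoidance",
    "infant_engagement",
    "infant_compliance",
)

_EXACT_SPEARMAN_N = 10  # full permutation enumeration up to this n


@dataclass
class CorrelationReport:
    """Feature x composite Spearman matrix with Holm-adjusted p-values."""

    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_holm: pd.DataFrame
    family: str  # "per_composite" | "global"
    family_size: int

    def to_long(self) -> pd.DataFrame:
        """Long-format table: feature, composite, rho, p_raw, p_holm."""
        rows = []
        for f in self.rho.index:
            for c in self.rho.columns:
                rows.append(
                    {
                        "feature": f,
                        "composite": c,
                        "rho": self.rho.loc[f, c],
                        "p_raw": self.p_raw.loc[f, c],
                        "p_holm": self.p_holm.loc[f, c],
                    }
                )
        return pd.DataFrame(rows)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        long = self.to_long()
        return long[long["p_holm"] < alpha].reset_index(drop=True)


@dataclass
class ClassificationResult:
    """Per-fold and pooled held-out accuracy of the linear classifier."""

    fold_accuracies: list[float]
    total_accuracy: float
    training_accuracy: float
    confusion: np.ndarray  # 2x2 counts, rows = true class, cols = predicted
    k: int
    seed: int
    classes: tuple = ()

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "total_accuracy": float(self.total_accuracy),
            "training_accuracy": float(self.training_accuracy),
            "confusion": self.confusion.tolist(),
            "k": int(self.k),
            "seed": int(self.seed),
            "classes": [str(c) for c in self.classes],
        }


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman's rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks (average ranks on ties).
    For n <= 10 the p-value comes from the exact permutation distribution
    (all n! pairings, conditional on the observed values); for larger n
    the usual t approximation with n - 2 degrees of freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("rho undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= _EXACT_SPEARMAN_N:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        r = min(max(rho, -1.0), 1.0)
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2 * sps.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (n <= 10)."""
    n = rx.size
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    count = 0
    total = 0
    chunk: list = []
    target = abs(rho_obs) - 1e-12

    def flush(chunk):
        nonlocal count, total
        perm = np.asarray(chunk)
        rhos = (ry_c[perm] @ rx_c) / denom
        count += int(np.sum(np.abs(rhos) >= target))
        total += perm.shape[0]

    for p in itertools.permutations(range(n)):
        chunk.append(p)
        if len(chunk) == 100_000:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    return count / total


# ---------------------------------------------------------------------------
# Holm step-down correction
# ---------------------------------------------------------------------------


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control).

    Sorted ascending, p_(i) is multiplied by (m - i + 1); the cumulative
    maximum enforces monotonicity and results are capped at 1. Uniformly
    less conservative than Bonferroni.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be a 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# feature x CIB correlation matrix
# ---------------------------------------------------------------------------


def correlate_features_with_cib(
    features: pd.DataFrame,
    cib: pd.DataFrame,
    family: str = "per_composite",
) -> CorrelationReport:
    """All 17 x 8 Spearman correlations with Holm correction.

    ``features`` and ``cib`` must both carry a ``session_id`` column (or
    use it as index) plus the canonical feature / composite columns.  The
    Holm family is either each composite's 17 tests (default, matching
    one corrected p per feature-composite pair within a composite) or all
    136 tests globally.

    Cells whose feature (or composite) is constant, or with fewer than 3
    complete pairs, get NaN and are excluded from the corrected family.
    """
    if family not in ("per_composite", "global"):
        raise ValidationError(f"unknown family {family!r}")
    f = _indexed(features, CANONICAL_FEATURES, "feature table")
    c = _indexed(cib, CIB_COMPOSITES, "CIB table")
    only_f = sorted(set(f.index) - set(c.index))
    only_c = sorted(set(c.index) - set(f.index))
    if only_f or only_c:
        raise ValidationError(
            "session ids do not match: "
            f"only in features={only_f}, only in CIB={only_c}"
        )
    c = c.loc[f.index]
    bad = c[list(CIB_COMPOSITES)].to_numpy(dtype=float)
    if np.nanmin(bad) < 1.0 - 1e-9 or np.nanmax(bad) > 5.0 + 1e-9:
        raise ValidationError("CIB composites must lie in [1, 5]")
    if len(f) < 5:
        raise ValidationError("need at least 5 sessions")

    rho = pd.DataFrame(
        np.nan, index=list(CANONICAL_FEATURES), columns=list(CIB_COMPOSITES)
    )
    p_raw = rho.copy()
    for feat in CANONICAL_FEATURES:
        for comp in CIB_COMPOSITES:
            x = f[feat].to_numpy(dtype=float)
            y = c[comp].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                continue
            r, p = spearman_rho(x[ok], y[ok])
            rho.loc[feat, comp] = r
            p_raw.loc[feat, comp] = p

    p_holm = p_raw.copy()
    if family == "per_composite":
        sizes = []
        for comp in CIB_COMPOSITES:
            col = p_raw[comp].to_numpy(dtype=float)
            ok = np.isfinite(col)
            if ok.any():
                adj = holm_adjust(col[ok])
                vals = p_holm[comp].to_numpy(dtype=float)
                vals[ok] = adj
                p_holm[comp] = vals
            sizes.append(int(ok.sum()))
        family_size = max(sizes)
    else:
        flat = p_raw.to_numpy(dtype=float).ravel()
        ok = np.isfinite(flat)
        flat[ok] = holm_adjust(flat[ok])
        p_holm.iloc[:, :] = flat.reshape(p_raw.shape)
        family_size = int(ok.sum())
    return CorrelationReport(
        rho=rho,
        p_raw=p_raw,
        p_holm=p_holm,
        family=family,
        family_size=family_size,
    )


def _indexed(
    df: pd.DataFrame, required: tuple[str, ...], what: str
) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} is missing columns {missing}")
    if "session_id" in df.columns:
        df = df.set_index("session_id")
    dup = df.index[df.index.duplicated()].tolist()
    if dup:
        raise ValidationError(f"{what} has duplicate session ids {dup}")
    return df


# ---------------------------------------------------------------------------
# group comparison tests
# ---------------------------------------------------------------------------


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the Mann-Whitney U statistic of ``x``
    (rank sum of x minus ``n_x (n_x + 1) / 2``).  The p-value is exact for
    ``n_x + n_y <= 20`` without ties, otherwise a normal approximation
    with tie correction (and continuity correction) is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Two-sided p sums hypergeometric probabilities of tables at most as
    probable as the observed one; the odds ratio is the conditional
    maximum-likelihood estimate.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValidationError("counts must be non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("every row and column margin must be positive")
    p = float(sps.fisher_exact(t, alternative="two-sided")[1])
    orr = float(_odds_ratio(t, kind="conditional").statistic)
    return orr, p


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_dyads(
    features, labels, k: int = 15, seed: int = 0
) -> ClassificationResult:
    """Linear max-margin classification with stratified k-fold CV.

    Rows are shuffled by ``seed`` before building stratified splits; per
    fold, features are standardised on the training part and a linear-
    kernel SVM (C=1) is fitted.  Reports per-fold accuracies, the pooled
    held-out accuracy, the whole-data training accuracy and the pooled
    2x2 confusion matrix.  Bit-reproducible given (features, labels, k,
    seed).
    """
    X = (
        features[list(CANONICAL_FEATURES)].to_numpy(dtype=float)
        if isinstance(features, pd.DataFrame)
        else np.asarray(features, dtype=float)
    )
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("features must be (n, d) matching labels")
    if not np.isfinite(X).all():
        raise ValidationError(
            "features contain NaN/inf (e.g. undefined synchrony on a "
            "session without movement onsets); impute or drop first"
        )
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError(
            f"need exactly 2 classes, got {classes.tolist()}"
        )
    n = X.shape[0]
    if not (2 <= k <= n):
        raise ValidationError(f"k must satisfy 2 <= k <= n={n}")
    counts = [int((y == c).sum()) for c in classes]
    if min(counts) < k:
        raise ValidationError(
            f"smallest class has {min(counts)} members < k={k} folds, so "
            "some folds would miss a class; use a smaller k"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    Xs, ys = X[perm], y[perm]

    def _model():
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))

    skf = StratifiedKFold(n_splits=k, shuffle=False)
    fold_acc: list[float] = []
    pred = np.empty(n, dtype=ys.dtype)
    for train, test in skf.split(Xs, ys):
        clf = _model().fit(Xs[train], ys[train])
        p = clf.predict(Xs[test])
        pred[test] = p
        fold_acc.append(float((p == ys[test]).mean()))
    total = float((pred == ys).mean())
    train_acc = float(_model().fit(Xs, ys).score(Xs, ys))
    confusion = np.array(
        [
            [int(((ys == a) & (pred == b)).sum()) for b in classes]
            for a in classes
        ]
    )
    return ClassificationResult(
        fold_accuracies=fold_acc,
        total_accuracy=total,
        training_accuracy=train_acc,
        confusion=confusion,
        k=k,
        seed=seed,
        classes=tuple(classes.tolist()),
    )
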