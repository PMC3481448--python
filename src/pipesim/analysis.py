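"""High-level evaluation: differential expression, classification, bounds.

Differential expression uses the equal-n, pooled-variance two-sample t
statistic t = |m¹ − m⁰| / sqrt((Var¹ + Var⁰)/M) with 2M − 2 degrees of
freedom, tested per protein at a raw significance level (no multiplicity
correction, matching common practice in small-sample marker screens; an
optional Benjamini-Hochberg flag is exposed). Classification uses top-|t|
feature selection on training data followed by 3-nearest-neighbour and
regularised linear-discriminant classifiers, evaluated on independent test
samples drawn from the same generative model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.neighbors import KNeighborsClassifier

from .rollup import ProteinEstimate

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "RunResult",
    "t_statistic",
    "t_scores",
    "detect_markers",
    "select_features",
    "train_and_test_classifiers",
    "quantification_upper_bound",
]


@dataclass
class AnalysisConfig:
    alpha_level: float = 0.05
    n_features: int = 20
    knn_k: int = 3
    n_test_per_class: int = 1000
    lda_ridge: float = 1e-6
    bh_fdr: bool = False  # apply Benjamini-Hochberg instead of raw alpha

    def __post_init__(self) -> None:
        if not (0 < self.alpha_level < 1):
            raise ValueError("alpha_level must be in (0, 1)")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise ValueError("knn_k must be odd and >= 1")


@dataclass
class RunResult:
    """Performance indices of one end-to-end pipeline realisation."""

    peptide_id_rate: float        # peptide species observed in >= 1 sample
    protein_quant_rate: float     # proteins quantified (non-zero row)
    qerr: float
    pct_markers_detected: float   # 0..100
    peptide_missing_rate: float
    protein_missing_rate: float
    err_lda_observed: float
    err_knn_observed: float
    err_lda_original: float
    err_knn_original: float

    def to_dict(self) -> dict[str, float]:
        from dataclasses import asdict

        return asdict(self)


def t_scores(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-row t statistics and two-sided p-values.

    ``X`` is (n_features, n_samples); ``labels`` in {0, 1} with equal class
    sizes M. Rows with zero variance in both classes get t = 0 (p = 1) when
    the means agree and t = +inf (p = 0) when they differ.
    """
    labels = np.asarray(labels)
    x0, x1 = X[:, labels == 0], X[:, labels == 1]
    M = x0.shape[1]
    if x1.shape[1] != M or M < 2:
        raise ValueError("equal class sizes with M >= 2 required")
    m0, m1 = x0.mean(axis=1), x1.mean(axis=1)
    v0, v1 = x0.var(axis=1, ddof=1), x1.var(axis=1, ddof=1)
    se = np.sqrt((v0 + v1) / M)
    num = np.abs(m1 - m0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / se
    t[(se == 0) & (num == 0)] = 0.0
    t[(se == 0) & (num > 0)] = np.inf
    p = 2.0 * stats.t.sf(t, df=2 * M - 2)
    p[np.isinf(t)] = 0.0
    return t, p


def t_statistic(x_class1: np.ndarray, x_class0: np.ndarray) -> tuple[float, float]:
    """Two-sample t score and two-sided p-value for one protein."""
    x0 = np.asarray(x_class0, dtype=float)
    x1 = np.asarray(x_class1, dtype=float)
    X = np.concatenate([x0, x1])[None, :]
    labels = np.concatenate([np.zeros(len(x0)), np.ones(len(x1))])
    t, p = t_scores(X, labels)
    return float(t[0]), float(p[0])


def detect_markers(
    estimate: ProteinEstimate,
    labels: np.ndarray,
    marker_ids: list[str],
    config: AnalysisConfig = AnalysisConfig(),
) -> float:
    """Percentage of true markers called differentially expressed.

    Each marker's estimated concentrations are t-tested across classes; a
    marker counts as detected when p < alpha (or passes BH if enabled).
    Markers never quantified score t = 0 and are not detected.
    """
    if not marker_ids:
        raise ValueError("marker_ids must be non-empty")
    idx = {pid: i for i, pid in enumerate(estimate.protein_ids)}
    rows = np.array([idx[m] for m in marker_ids])
    _, p_all = t_scores(estimate.conc_hat, labels)
    if config.bh_fdr:
        rej = _bh_reject(p_all, config.alpha_level)[rows]
    else:
        rej = p_all[rows] < config.alpha_level
    return 100.0 * float(rej.sum()) / len(marker_ids)


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passing = np.nonzero(p[order] <= thresh)[0]
    out = np.zeros(m, dtype=bool)
    if len(passing):
        out[order[: passing[-1] + 1]] = True
    return out


def select_features(
    X: np.ndarray, labels: np.ndarray, n_features: int
) -> np.ndarray:
    """Indices of the ``n_features`` rows with largest |t| on training data.

    Ties are broken toward the smaller row index; the result is sorted by
    decreasing |t|. If fewer rows than requested carry any signal the full
    ranking is still returned (the caller sees the same length).
    """
    t, _ = t_scores(X, labels)
    if X.shape[0] < n_features:
        logger.warning(
            "select_features: only %d rows available for %d requested",
            X.shape[0], n_features,
        )
        n_features = X.shape[0]
    order = np.argsort(-t, kind="stable")  # stable: ties keep smaller index first
    return order[:n_features]


class _RidgeLDA:
    """Linear discriminant with pooled covariance, tiny ridge, equal priors."""

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_RidgeLDA":
        X0, X1 = X[y == 0], X[y == 1]
        n0, n1 = len(X0), len(X1)
        m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
        S = ((n0 - 1) * np.cov(X0, rowvar=False, ddof=1)
             + (n1 - 1) * np.cov(X1, rowvar=False, ddof=1)) / (n0 + n1 - 2)
        S = np.atleast_2d(S) + self.ridge * np.eye(X.shape[1])
        self.w_ = np.linalg.solve(S, m1 - m0)
        self.c_ = float(self.w_ @ (m0 + m1) / 2.0)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (X @ self.w_ > self.c_).astype(int)


def train_and_test_classifiers(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[float, float]:
    """Misclassification rates (err_knn, err_lda) on the test set.

    Inputs are (n_samples, n_features) with features already selected on the
    training data. KNN uses Euclidean distance with majority vote among
    ``knn_k`` neighbours (brute-force search, distance ties resolved toward
    the smaller training index); LDA uses a pooled covariance with a small
    ridge for invertibility and equal class priors.
    """
    knn = KNeighborsClassifier(n_neighbors=config.knn_k, algorithm="brute")
    knn.fit(X_train, y_train)
    err_knn = float(np.mean(knn.predict(X_test) != y_test))
    lda = _RidgeLDA(ridge=config.lda_ridge).fit(X_train, y_train)
    err_lda = float(np.mean(lda.predict(X_test) != y_test))
    return err_knn, err_lda


def quantification_upper_bound(q: float, n: int) -> float:
    """P(at least 2 of n independent identification events succeed).

    With per-peptide identification probability q and n peptides per protein,
    a protein can be quantified only if at least two of its peptides are
    identified; ignoring the quality filters this binomial tail is an upper
    bound on the protein quantification probability:
    1 − (1−q)^n − n·q·(1−q)^(n−1).
    """
    if not (0 <= q <= 1):
        raise ValueError("q must be a probability")
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(1.0 - (1.0 - q) ** n - n * q * (1.0 - q) ** (n - 1))
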