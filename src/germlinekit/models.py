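"""Gene-set overrepresentation and the metastasis logistic model.

Overrepresentation uses the hypergeometric upper tail P[X >= k] over a
user-supplied universe with BH adjustment across the tested sets.  The
metastasis model is a logistic regression (fit by iteratively reweighted
least squares) on log10(PSA+1), ordinal ISUP grade, and binary any-variant
gene indicators; it is trained on one cohort and evaluated on the other,
against a control model restricted to PSA and ISUP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import adjust_fdr
from .types import ClinicalRecord

__all__ = [
    "OraResult",
    "ora_test",
    "LogisticFit",
    "fit_logistic",
    "evaluate_auc",
    "ModelEval",
    "cross_cohort_evaluate",
    "make_feature_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OraResult:
    name: str
    k: int  # query ∩ set
    K: int  # set size within universe
    n: int  # query size
    N: int  # universe size
    p: float
    q: float

    @property
    def gene_ratio(self) -> float:
        return self.k / self.n if self.n else 0.0


def ora_test(
    query: Set[str], sets: Mapping[str, Set[str]], universe: Set[str]
) -> List[OraResult]:
    """Hypergeometric overrepresentation of the query in each gene set.

    Each set is intersected with the universe before testing; the query must
    be a subset of the universe.  p = P[X >= k] with
    X ~ Hypergeometric(N, K, n); BH adjustment spans the tested sets.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query)
    if not query <= set(universe):
        raise ValueError("query genes must be contained in the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in sets.items():
        members = set(members) & set(universe)
        K = len(members)
        k = len(query & members)
        # survival function at k-1 gives P[X >= k]
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, p))
    qvals = adjust_fdr([p for (_, _, _, p) in rows])
    results = [
        OraResult(name=name, k=k, K=K, n=n, N=N, p=min(p, 1.0), q=q)
        for (name, k, K, p), q in zip(rows, qvals)
    ]
    return sorted(results, key=lambda r: (-r.gene_ratio, r.p, r.name))


@dataclass
class LogisticFit:
    coefficients: Dict[str, float]
    converged: bool
    separation: bool
    n_iter: int
    log_likelihood: float
    dropped_columns: List[str] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        names = [c for c in self.coefficients if c != "intercept"]
        missing = [c for c in names if c not in X.columns]
        if missing:
            raise ValueError(f"feature(s) missing from data: {missing}")
        eta = self.coefficients["intercept"] + X[names].to_numpy(dtype=float) @ np.array(
            [self.coefficients[c] for c in names]
        )
        return 1.0 / (1.0 + np.exp(-eta))


def _irls(
    X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
    tol: float = 1e-8, max_iter: int = 100, beta_cap: float = 15.0,
) -> Tuple[np.ndarray, bool, bool, int, float]:
    """IRLS for logistic regression; ridge penalty spares the intercept."""
    n, p = X.shape
    beta = np.zeros(p)
    penalty = np.eye(p) * ridge
    penalty[0, 0] = 0.0
    converged = separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X + penalty, xtw @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(xtw @ X + penalty, xtw @ z, rcond=None)[0]
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if ridge == 0.0 and np.max(np.abs(beta)) > beta_cap:
            separated = True
            break
        if delta < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * np.log(np.clip(mu, 1e-12, None))
                      + (1 - y) * np.log(np.clip(1 - mu, 1e-12, None))))
    return beta, converged, separated, it, ll


def fit_logistic(features: pd.DataFrame, outcome: Sequence[int]) -> LogisticFit:
    """Maximum-likelihood logistic fit with separation fallback.

    Converges when the largest coefficient update falls below 1e-8 (at most
    100 iterations).  Constant columns are dropped with a warning.  When the
    coefficients diverge (any |beta| > 15, the signature of separation) the
    model is refit with a small ridge penalty (lambda = 1e-4) and flagged.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; cannot fit")
    X = features.astype(float).copy()
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant column(s): {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    design = np.column_stack([np.ones(len(X)), X.to_numpy()])
    beta, converged, separated, n_iter, ll = _irls(design, y)
    if separated:
        beta, converged, _, n_iter, ll = _irls(design, y, ridge=1e-4)
    names = ["intercept"] + list(X.columns)
    return LogisticFit(
        coefficients=dict(zip(names, beta.tolist())),
        converged=converged,
        separation=separated,
        n_iter=n_iter,
        log_likelihood=ll,
        dropped_columns=dropped,
    )


def evaluate_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC = (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg).

    Computed through the rank form of the Mann-Whitney statistic (average
    ranks give ties half credit), identical to pair counting.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    rank_sum_pos = float(np.sum(ranks[labels == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass
class ModelEval:
    coefficients: Dict[str, float]
    auc_train: float
    auc_test: float
    roc_points: pd.DataFrame
    separation: bool = False


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    from sklearn.metrics import roc_curve

    fpr, tpr, thresholds = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})


def cross_cohort_evaluate(
    train: pd.DataFrame,
    test: pd.DataFrame,
    features: Sequence[str],
    control_features: Sequence[str],
    outcome_col: str = "metastasis",
) -> Tuple[ModelEval, ModelEval]:
    """Fit on the training cohort, score the held-out cohort.

    Returns ``(full_model, control_model)`` evaluations, each with train and
    test AUC and ROC points on the test cohort.  A feature missing from the
    test cohort is an error.
    """

    def run(cols: Sequence[str]) -> ModelEval:
        missing = [c for c in cols if c not in train.columns]
        if missing:
            raise ValueError(f"feature(s) missing from training cohort: {missing}")
        missing = [c for c in cols if c not in test.columns]
        if missing:
            raise ValueError(f"feature(s) missing from test cohort: {missing}")
        fit = fit_logistic(train[list(cols)], train[outcome_col].to_numpy())
        score_train = fit.predict(train)
        score_test = fit.predict(test)
        return ModelEval(
            coefficients=fit.coefficients,
            auc_train=evaluate_auc(score_train, train[outcome_col].to_numpy()),
            auc_test=evaluate_auc(score_test, test[outcome_col].to_numpy()),
            roc_points=_roc_points(score_test, test[outcome_col].to_numpy()),
            separation=fit.separation,
        )

    return run(features), run(control_features)


def make_feature_table(
    clinical: Sequence[ClinicalRecord],
    gene_carriers: Mapping[str, Set[str]],
    model_genes: Sequence[str],
    *,
    psa_log10: bool = True,
) -> pd.DataFrame:
    """Design table: transformed PSA, ordinal ISUP, binary gene indicators.

    ``gene_carriers`` maps gene symbol -> set of sample ids carrying any
    qualifying variant in that gene (the study's indicators use VUS-containing
    status of the model genes).  The outcome column is metastasis (M1 = 1).
    """
    rows = []
    for c in clinical:
        row = {
            "sample_id": c.sample_id,
            "psa": np.log10(c.psa + 1.0) if psa_log10 else c.psa,
            "isup": float(c.isup),
            "metastasis": 1 if c.metastasis == "M1" else 0,
        }
        for gene in model_genes:
            row[gene] = 1.0 if c.sample_id in gene_carriers.get(gene, set()) else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
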