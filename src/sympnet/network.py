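"""Cross-sectional symptom-network estimation.

A symptom network is a Gaussian graphical model (GGM) over the nine QIDS
domains: edges are partial correlations — pairwise associations conditioned
on all other symptoms — obtained from the standardized negated inverse of
the correlation matrix.  Because the domain scores are ordinal (0-3 Likert),
the input correlation matrix is Spearman's rank correlation.  Global
connectivity strength is the sum of absolute edge weights, each unordered
pair counted once.

Three estimators are provided: the unregularized partial-correlation GGM
(primary), an EBIC-selected graphical lasso (sparse sensitivity variant) and
the nonparametric full (marginal) Spearman correlation network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.covariance import graphical_lasso

__all__ = [
    "NetworkError",
    "CorrelationMatrix",
    "SymptomNetwork",
    "EstimatorConfig",
    "spearman_corr",
    "nearest_pd",
    "partial_from_corr",
    "glasso_ebic",
    "full_corr_network",
    "global_strength",
    "estimate_network",
    "estimate_phase_networks",
]


class NetworkError(ValueError):
    """Network estimation failed or its input is invalid."""


@dataclass
class CorrelationMatrix:
    """Spearman rank-correlation matrix with bookkeeping."""

    r: np.ndarray  # p x p, symmetric, unit diagonal
    n_pairs: np.ndarray  # per-pair effective sample size
    n: int  # nominal sample size
    constant_columns: tuple[int, ...] = ()

    @property
    def is_pd(self) -> bool:
        return bool(np.linalg.eigvalsh(self.r).min() > 0)


@dataclass
class SymptomNetwork:
    """Symmetric zero-diagonal edge-weight matrix over symptom domains."""

    weights: np.ndarray
    labels: tuple[str, ...]
    estimator: str  # partial | glasso | full_nonparametric
    n: int
    phase: str | None = None
    group: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def strength(self) -> float:
        return global_strength(self)


@dataclass
class EstimatorConfig:
    """Estimator choice and hyperparameters.

    gamma is the EBIC hyperparameter (0.5 is the psychometric-network
    default); the lasso penalty grid has ``n_lambda`` log-spaced values from
    ``lambda_min_ratio * lambda_max`` to ``lambda_max``; ``ridge_eps`` is the
    eigenvalue floor used to repair non-positive-definite Spearman matrices;
    ``missing`` selects pairwise-complete or listwise deletion.
    """

    estimator: str = "partial"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    ridge_eps: float = 1e-6
    missing: str = "pairwise"  # or "listwise"
    min_n: int = 50

    def __post_init__(self) -> None:
        if self.estimator not in ("partial", "glasso", "full_nonparametric"):
            raise NetworkError(f"unknown estimator {self.estimator!r}")
        if self.gamma < 0 or self.ridge_eps < 0:
            raise NetworkError("gamma and ridge_eps must be >= 0")


def spearman_corr(
    data: np.ndarray, missing: str = "pairwise", min_n: int = 10
) -> CorrelationMatrix:
    """Pairwise Spearman rank correlations with average-rank tie handling.

    ``missing="pairwise"`` uses pairwise-complete observations (maximizes
    per-pair n); ``"listwise"`` drops any row with a missing value.
    Constant columns yield missing correlations and a structured warning.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise NetworkError("data must be 2-dimensional")
    n, p = X.shape
    if n < min_n:
        raise NetworkError(f"n={n} below the minimum {min_n}")

    if missing == "listwise":
        X = X[~np.isnan(X).any(axis=1)]
        if len(X) < min_n:
            raise NetworkError(f"listwise-complete n={len(X)} below minimum")
        n = len(X)

    const = tuple(
        int(j)
        for j in range(p)
        if len(np.unique(X[~np.isnan(X[:, j]), j])) < 2
    )
    if const:
        warnings.warn(
            f"constant column(s) {const}: correlations set missing",
            stacklevel=2,
        )

    if not np.isnan(X).any():
        # fast path: rank once, Pearson on ranks
        R = stats.rankdata(X, axis=0)
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(R, rowvar=False)
        npairs = np.full((p, p), n)
    else:
        r = np.full((p, p), np.nan)
        npairs = np.zeros((p, p), dtype=int)
        np.fill_diagonal(r, 1.0)
        for i in range(p):
            npairs[i, i] = int((~np.isnan(X[:, i])).sum())
            for j in range(i + 1, p):
                ok = ~(np.isnan(X[:, i]) | np.isnan(X[:, j]))
                npairs[i, j] = npairs[j, i] = int(ok.sum())
                if ok.sum() >= 3 and i not in const and j not in const:
                    r[i, j] = r[j, i] = stats.spearmanr(X[ok, i], X[ok, j])[0]
    for j in const:
        r[j, :] = np.nan
        r[:, j] = np.nan
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r=r, n_pairs=npairs, n=n, constant_columns=const)


def nearest_pd(corr: CorrelationMatrix | np.ndarray, eps: float = 1e-6):
    """Repair a symmetric correlation matrix to positive definiteness.

    Eigenvalues below ``eps`` are clipped to ``eps`` and the result is
    re-standardized to unit diagonal.  An already-PD input is returned
    unchanged.  Returns the same type as the input; for
    :class:`CorrelationMatrix` the Frobenius repair distance is recorded
    in-place semantics are avoided — a new object is returned.
    """
    is_cm = isinstance(corr, CorrelationMatrix)
    A = corr.r if is_cm else np.asarray(corr, dtype=float)
    if not np.allclose(A, A.T, atol=1e-12):
        raise NetworkError("input matrix is not symmetric")
    w, V = np.linalg.eigh(A)
    if w.min() > eps:
        return corr
    w_clipped = np.clip(w, eps, None)
    B = (V * w_clipped) @ V.T
    d = np.sqrt(np.diag(B))
    B = B / np.outer(d, d)
    B = (B + B.T) / 2
    np.fill_diagonal(B, 1.0)
    dist = float(np.linalg.norm(B - A, "fro"))
    if is_cm:
        out = CorrelationMatrix(
            r=B, n_pairs=corr.n_pairs, n=corr.n, constant_columns=corr.constant_columns
        )
        out.repair_distance = dist  # type: ignore[attr-defined]
        return out
    return B


def _partials_from_precision(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2


def partial_from_corr(
    corr: CorrelationMatrix | np.ndarray,
    labels: tuple[str, ...] | None = None,
    n: int | None = None,
) -> SymptomNetwork:
    """GGM edge weights from a positive-definite correlation matrix.

    With Omega the inverse correlation (precision) matrix, the edge weight is
    W_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj), i.e. the partial
    correlation of i and j given all other variables; the diagonal is zero.
    """
    is_cm = isinstance(corr, CorrelationMatrix)
    R = corr.r if is_cm else np.asarray(corr, dtype=float)
    if np.isnan(R).any():
        raise NetworkError("correlation matrix contains missing entries")
    try:
        K = np.linalg.inv(R)
    except np.linalg.LinAlgError as e:
        raise NetworkError(f"correlation matrix is singular: {e}") from e
    W = _partials_from_precision(K)
    p = R.shape[0]
    return SymptomNetwork(
        weights=W,
        labels=labels or tuple(f"v{i}" for i in range(p)),
        estimator="partial",
        n=n if n is not None else (corr.n if is_cm else 0),
    )


def _gaussian_loglik(K: np.ndarray, S: np.ndarray, n: int) -> float:
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - np.trace(S @ K))


def ebic_score(K: np.ndarray, S: np.ndarray, n: int, gamma: float) -> float:
    """Extended BIC of a precision matrix: -2*loglik + E*log n + 4*gamma*E*log p
    with E the number of nonzero upper-triangle edges."""
    p = K.shape[0]
    E = int(np.count_nonzero(np.triu(K, 1)))
    return -2.0 * _gaussian_loglik(K, S, n) + E * np.log(n) + 4.0 * gamma * E * np.log(p)


def glasso_ebic(
    corr: CorrelationMatrix | np.ndarray,
    n: int,
    cfg: EstimatorConfig | None = None,
    labels: tuple[str, ...] | None = None,
    lambdas=None,
) -> SymptomNetwork:
    """Sparse GGM via graphical lasso with EBIC model selection.

    Fits the graphical lasso over a log-spaced penalty grid from
    ``lambda_min_ratio * lambda_max`` to ``lambda_max`` (lambda_max = largest
    absolute off-diagonal correlation, which shrinks the graph empty) and
    returns the partial-correlation network of the EBIC-minimizing model.
    Near-zero partials (below the solver tolerance) are treated as absent edges.  An explicit
    ``lambdas`` sequence overrides the grid (e.g. to probe the
    unregularized or fully-shrunk limits).
    """
    cfg = cfg or EstimatorConfig(estimator="glasso")
    is_cm = isinstance(corr, CorrelationMatrix)
    S = corr.r if is_cm else np.asarray(corr, dtype=float)
    lam_max = float(np.abs(S - np.diag(np.diag(S))).max())
    if lam_max == 0:
        W = np.zeros_like(S)
        return SymptomNetwork(
            weights=W,
            labels=labels or tuple(f"v{i}" for i in range(S.shape[0])),
            estimator="glasso",
            n=n,
            meta={"lambda": 0.0, "gamma": cfg.gamma},
        )
    lams = (
        np.asarray(lambdas, dtype=float)
        if lambdas is not None
        else np.geomspace(cfg.lambda_min_ratio * lam_max, lam_max, cfg.n_lambda)
    )
    best: tuple[float, float, np.ndarray] | None = None
    failures: list[float] = []
    for lam in lams:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, K = graphical_lasso(S, alpha=float(lam), max_iter=200)
        except Exception:
            failures.append(float(lam))
            continue
        K = np.where(np.abs(K) < 1e-6, 0.0, K)
        score = ebic_score(K, S, n, cfg.gamma)
        if best is None or score < best[0]:
            best = (score, float(lam), K)
    if best is None:
        raise NetworkError(f"no penalty converged over grid {lams[[0, -1]]}")
    if failures:
        warnings.warn(f"{len(failures)} penalty value(s) failed to converge")
    score, lam_star, K = best
    W = _partials_from_precision(K)
    W = np.where(np.abs(W) < 1e-6, 0.0, W)
    return SymptomNetwork(
        weights=W,
        labels=labels or tuple(f"v{i}" for i in range(S.shape[0])),
        estimator="glasso",
        n=n,
        meta={"lambda": lam_star, "gamma": cfg.gamma, "ebic": score},
    )


def full_corr_network(
    data: np.ndarray,
    missing: str = "pairwise",
    labels: tuple[str, ...] | None = None,
) -> SymptomNetwork:
    """Nonparametric sensitivity variant: marginal Spearman correlations as
    edge weights (no conditioning), diagonal zeroed."""
    cm = spearman_corr(data, missing=missing)
    W = cm.r.copy()
    np.fill_diagonal(W, 0.0)
    return SymptomNetwork(
        weights=W,
        labels=labels or tuple(f"v{i}" for i in range(W.shape[0])),
        estimator="full_nonparametric",
        n=cm.n,
    )


def global_strength(net: SymptomNetwork | np.ndarray) -> float:
    """Global connectivity strength: sum of absolute edge weights, each
    unordered pair counted once."""
    W = net.weights if isinstance(net, SymptomNetwork) else np.asarray(net)
    return float(np.abs(np.triu(W, 1)).sum())


def estimate_network(
    data: np.ndarray,
    cfg: EstimatorConfig | None = None,
    labels: tuple[str, ...] | None = None,
    phase: str | None = None,
    group: str | None = None,
) -> SymptomNetwork:
    """Estimate a symptom network from an n x p ordinal data matrix using the
    configured estimator (Spearman input, PD repair, then GGM/glasso/full)."""
    cfg = cfg or EstimatorConfig()
    if cfg.estimator == "full_nonparametric":
        net = full_corr_network(data, missing=cfg.missing, labels=labels)
    else:
        cm = spearman_corr(data, missing=cfg.missing)
        if cm.constant_columns:
            raise NetworkError(
                f"constant column(s) {cm.constant_columns} in group={group} "
                f"phase={phase}"
            )
        cm = nearest_pd(cm, cfg.ridge_eps)
        if cfg.estimator == "partial":
            net = partial_from_corr(cm, labels=labels)
        else:
            net = glasso_ebic(cm, n=cm.n, cfg=cfg, labels=labels)
        net.meta["repair_distance"] = getattr(cm, "repair_distance", 0.0)
    net.phase = phase
    net.group = group
    return net


PHASES = ("baseline", "change", "postchange")


def estimate_phase_networks(
    visits,
    bins,
    cfg: EstimatorConfig | None = None,
    domain_names: tuple[str, ...] | None = None,
) -> dict[tuple[str, str], SymptomNetwork]:
    """Estimate one network per (group bin, phase).

    For each bin, the phase data matrix stacks one visit row per member:
    week 0 for baseline, the subject's change week for the change phase and
    the subject's maximum-change week for the post-change phase.  Cells with
    fewer rows than ``cfg.min_n`` are skipped with a warning.
    """
    cfg = cfg or EstimatorConfig()
    if domain_names is None:
        from .scoring import DOMAIN_NAMES

        domain_names = DOMAIN_NAMES
    cols = list(domain_names)
    wide: dict[tuple[object, int], np.ndarray] = {}
    v = visits[["subject_id", "week", *cols]].dropna()
    for (sid, wk), row in zip(
        zip(v["subject_id"], v["week"].astype(int)), v[cols].to_numpy()
    ):
        wide[(sid, wk)] = row

    out: dict[tuple[str, str], SymptomNetwork] = {}
    for b in bins:
        for phase in PHASES:
            rows = []
            for a in b.members:
                wk = {
                    "baseline": 0,
                    "change": a.change_week,
                    "postchange": a.postchange_week,
                }[phase]
                r = wide.get((a.subject_id, wk))
                if r is not None:
                    rows.append(r)
            if len(rows) < cfg.min_n:
                warnings.warn(
                    f"group {b.label} phase {phase}: n={len(rows)} below "
                    f"floor {cfg.min_n}; network skipped"
                )
                continue
            X = np.asarray(rows, dtype=float)
            out[(b.label, phase)] = estimate_network(
                X, cfg, labels=tuple(cols), phase=phase, group=b.label
            )
    return out
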