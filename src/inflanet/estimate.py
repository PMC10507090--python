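"""Sparse regularized partial-correlation network estimation.

Pipeline: Spearman correlation -> PSD repair -> graphical-lasso penalty
path -> EBIC model selection -> partial correlations from the selected
precision matrix (w_ij = -theta_ij / sqrt(theta_ii * theta_jj)).

The LASSO penalty shrinks trivially small conditional associations to
exactly zero, so the selected model is a sparse graph keeping only the
strongest partial associations. EBIC is
``-2*loglik + E*ln(n) + 4*E*gamma*ln(p)`` with ``E`` the edge count; its
hyperparameter ``gamma`` trades discovery (0, the replication default
here) against caution (0.5). The likelihood is evaluated on the
(possibly repaired) Spearman matrix with n = subject count — a
pseudo-likelihood convention, stated as such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _glasso
from .assoc import CorrelationEstimate, nearest_psd, rank_correlation_matrix

#: entries with |w| below this are numerical zeros from coordinate descent
EDGE_EPS = 1e-10
LAMBDA_MAX_FLOOR = 1e-4


class EstimationError(RuntimeError):
    """Estimation failure (non-convergence or degenerate input)."""


@dataclass
class EstimatorSettings:
    """Knobs shared by every re-estimation in bootstraps and permutations."""

    gamma: float = 0.0
    n_lambda: int = 100
    min_ratio: float = 0.01
    missing_policy: str = "complete_rows"
    tol: float = 1e-7
    max_iter: int = 200


@dataclass
class PenaltyPath:
    lambdas: np.ndarray
    n_lambda: int
    min_ratio: float


@dataclass
class NetworkModel:
    """A regularized partial-correlation network with selection provenance."""

    weights: np.ndarray
    node_names: list[str]
    selected_lambda: float
    ebic_gamma: float
    path_lambdas: np.ndarray
    path_ebics: np.ndarray
    n: int
    p: int
    psd_repaired: bool = False

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, 1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_list(self) -> pd.DataFrame:
        iu, jv = np.triu_indices(self.p, 1)
        mask = self.weights[iu, jv] != 0
        return pd.DataFrame(
            {
                "node_a": [self.node_names[i] for i in iu[mask]],
                "node_b": [self.node_names[j] for j in jv[mask]],
                "weight": self.weights[iu[mask], jv[mask]],
            }
        )

    def weight(self, a: str, b: str) -> float:
        i, j = self.node_names.index(a), self.node_names.index(b)
        return float(self.weights[i, j])

    # -- serialization -------------------------------------------------------

    def to_edge_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.edge_list().to_csv(path, sep="\t", index=False)
        return path

    def to_matrix_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.weights, index=self.node_names, columns=self.node_names).to_csv(path)
        return path

    def to_graphml(self, path: str | Path) -> Path:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_names)
        for _, row in self.edge_list().iterrows():
            g.add_edge(row["node_a"], row["node_b"], weight=float(row["weight"]))
        path = Path(path)
        nx.write_graphml(g, path)
        return path

    def diagnostics_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "selected_lambda": self.selected_lambda,
                    "ebic_gamma": self.ebic_gamma,
                    "path_lambdas": self.path_lambdas.tolist(),
                    "path_ebics": self.path_ebics.tolist(),
                    "edge_count": self.edge_count,
                    "n": self.n,
                    "p": self.p,
                    "psd_repaired": self.psd_repaired,
                },
                indent=1,
            )
        )
        return path


def lambda_path(
    corr: CorrelationEstimate | np.ndarray, n_lambda: int = 100, min_ratio: float = 0.01
) -> PenaltyPath:
    """Log-spaced penalty sequence from lambda_max down to lambda_max*min_ratio.

    lambda_max is the largest absolute off-diagonal correlation (every
    penalty at or above it yields the empty graph), floored at 1e-4 for
    degenerate no-association inputs.
    """
    if n_lambda < 2:
        raise EstimationError("n_lambda must be >= 2")
    if not 0.0 < min_ratio < 1.0:
        raise EstimationError("min_ratio must be in (0, 1)")
    m = corr.matrix if isinstance(corr, CorrelationEstimate) else np.asarray(corr)
    off = np.abs(m - np.diag(np.diag(m)))
    lam_max = max(float(off.max()), LAMBDA_MAX_FLOOR)
    return PenaltyPath(np.geomspace(lam_max, lam_max * min_ratio, n_lambda), n_lambda, min_ratio)


def fit_glasso(
    corr: CorrelationEstimate | np.ndarray,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 200,
) -> np.ndarray:
    """One graphical-lasso fit; returns the estimated precision matrix.

    Exact zeros in the precision come out as exact zeros (the inner
    coordinate descent soft-thresholds to zero).
    """
    if lam < 0:
        raise EstimationError("lambda must be >= 0")
    S = corr.matrix if isinstance(corr, CorrelationEstimate) else np.asarray(corr, dtype=float)
    S = np.ascontiguousarray(S)
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p - 1, p))
    n_it, ok = _glasso.glasso_cd(S, float(lam), W, B, tol, max_iter, 1e-9, 500)
    if not ok:
        raise EstimationError(
            f"graphical lasso did not converge in {n_it} iterations (lambda={lam:.4g})"
        )
    return _glasso.precision_from_working(W, B)


def ebic(
    precision: np.ndarray, corr: CorrelationEstimate | np.ndarray, n: int, gamma: float
) -> float:
    """Extended BIC of a fitted precision matrix.

    ``-2*l + E*ln(n) + 4*E*gamma*ln(p)`` with
    ``l = (n/2) * (log det Theta - tr(S Theta))``; gamma=0 reduces to BIC.
    """
    if n < 3:
        raise EstimationError("n must be >= 3")
    if gamma < 0:
        raise EstimationError("gamma must be >= 0")
    S = corr.matrix if isinstance(corr, CorrelationEstimate) else np.asarray(corr)
    theta = np.asarray(precision)
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise EstimationError("precision is not positive definite; log det undefined")
    p = theta.shape[0]
    ll = (n / 2.0) * (logdet - float(np.sum(S * theta)))
    iu = np.triu_indices(p, 1)
    E = int(np.count_nonzero(np.abs(theta[iu]) > EDGE_EPS))
    return float(-2.0 * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def _path_ebics(
    thetas: np.ndarray, S: np.ndarray, n: int, gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized EBIC over a stacked precision path; returns (ebics, E)."""
    p = S.shape[0]
    signs, logdets = np.linalg.slogdet(thetas)
    traces = np.einsum("ij,kij->k", S, thetas)
    iu = np.triu_indices(p, 1)
    E = (np.abs(thetas[:, iu[0], iu[1]]) > EDGE_EPS).sum(axis=1)
    ll = (n / 2.0) * (logdets - traces)
    scores = -2.0 * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p)
    scores = np.where(signs > 0, scores, np.inf)
    return scores, E


def _select_from_path(
    S: np.ndarray, n: int, settings: EstimatorSettings
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Fit the path, score by EBIC, return (weights, lambda, lambdas, ebics).

    Ties in EBIC resolve toward the sparser (larger lambda) model because
    the path is scanned in decreasing-lambda order with a strict "<".
    """
    S = np.ascontiguousarray(S, dtype=float)
    path = lambda_path(S, settings.n_lambda, settings.min_ratio)
    thetas, iters, conv = _glasso.glasso_path(S, path.lambdas, settings.tol, settings.max_iter)
    if not conv.all():
        bad = np.where(~conv)[0]
        raise EstimationError(
            f"path fit failed to converge at lambda index {bad[0]} "
            f"(lambda={path.lambdas[bad[0]]:.4g}, {iters[bad[0]]} iterations)"
        )
    ebics, _ = _path_ebics(thetas, S, n, settings.gamma)
    best = int(np.argmin(ebics))  # first minimum = largest lambda on ties
    theta = thetas[best]
    d = np.sqrt(np.diag(theta))
    w = -theta / np.outer(d, d)
    np.fill_diagonal(w, 0.0)
    w[np.abs(w) <= EDGE_EPS] = 0.0
    return w, float(path.lambdas[best]), path.lambdas, ebics


def network_from_correlation(
    corr: CorrelationEstimate, settings: EstimatorSettings | None = None
) -> NetworkModel:
    """EBIC-glasso network from an already-computed correlation estimate."""
    settings = settings or EstimatorSettings()
    corr = nearest_psd(corr)
    w, lam, lambdas, ebics = _select_from_path(corr.matrix, corr.n_effective, settings)
    return NetworkModel(
        weights=w,
        node_names=list(corr.names),
        selected_lambda=lam,
        ebic_gamma=settings.gamma,
        path_lambdas=lambdas,
        path_ebics=ebics,
        n=corr.n_effective,
        p=corr.p,
        psd_repaired=corr.psd_repaired,
    )


def estimate_network(
    data, gamma: float = 0.0, settings: EstimatorSettings | None = None
) -> NetworkModel:
    """Full estimation pipeline from a cohort table.

    ``gamma`` overrides the settings' EBIC hyperparameter for convenience.
    """
    if settings is None:
        settings = EstimatorSettings(gamma=gamma)
    else:
        settings = EstimatorSettings(**{**asdict(settings), "gamma": gamma})
    corr = rank_correlation_matrix(data, settings.missing_policy)
    return network_from_correlation(corr, settings)


def _weights_fast(X: np.ndarray, n: int, settings: EstimatorSettings) -> np.ndarray:
    """Lean estimation from a raw numeric matrix for resampling loops.

    Identical math to :func:`estimate_network` (asserted by tests), minus
    DataFrame handling: rank transform, correlation, eigenvalue clip,
    warm-started path, EBIC selection.
    """
    from scipy.stats import rankdata

    ranks = rankdata(X, axis=0)
    sd = ranks.std(axis=0)
    if np.any(sd == 0):
        j = int(np.where(sd == 0)[0][0])
        raise EstimationError(f"constant column at index {j}")
    S = np.corrcoef(ranks, rowvar=False)
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    w_eig = np.linalg.eigvalsh(S)
    if w_eig[0] < -1e-8:
        wv, v = np.linalg.eigh(S)
        S = (v * np.clip(wv, 0.0, None)) @ v.T
        d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
        S = S / np.outer(d, d)
        S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(S, 1.0)
    w, _, _, _ = _select_from_path(S, n, settings)
    return w
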