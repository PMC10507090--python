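"""Permutation-based network comparison (NCT).

Two networks estimated with identical settings are compared on

* connectivity — the S statistic, the absolute difference in global
  strength (sum of absolute edge weights), and
* structure — the M statistic, the maximum absolute difference in any
  single edge weight.

The null distribution is built by re-estimating both networks after
randomly regrouping individuals: the independent design permutes pooled
group labels preserving group sizes; the paired design swaps each
subject's pair of observations between conditions with probability 1/2.
p-values use the add-one convention (1 + #{permuted >= observed}) /
(1 + n_permutations), hence never exactly zero.

When the omnibus tests are significant, post-hoc per-node strength
centrality and per-edge invariance tests reuse the parent permutation
stream; edge p-values are Holm-adjusted by default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .estimate import EstimatorSettings, _weights_fast

DESIGNS = ("independent", "paired")


class CompareError(ValueError):
    pass


def s_from_global_strengths(gs_a: float, gs_b: float) -> float:
    """S statistic from two global strengths: |GS(A) - GS(B)|."""
    return abs(float(gs_a) - float(gs_b))


def _gs(w: np.ndarray, iu) -> float:
    return float(np.abs(w[iu[0], iu[1]]).sum())


@dataclass
class NCTResult:
    S_observed: float
    M_observed: float
    p_S: float
    p_M: float
    n_permutations: int
    design: str
    node_names: list[str]
    weights_a: np.ndarray
    weights_b: np.ndarray
    null_S: np.ndarray
    null_M: np.ndarray
    null_node: np.ndarray  # (B, p) permuted |strength diff|
    null_edge: np.ndarray  # (B, n_edges) permuted |weight diff|
    seed: int
    alpha: float = 0.05
    settings: EstimatorSettings = field(default_factory=EstimatorSettings)

    @property
    def p(self) -> int:
        return len(self.node_names)

    @property
    def significant(self) -> bool:
        return self.p_S < self.alpha or self.p_M < self.alpha

    def global_strengths(self) -> tuple[float, float]:
        iu = np.triu_indices(self.p, 1)
        return _gs(self.weights_a, iu), _gs(self.weights_b, iu)

    def to_json(self, path: str | Path) -> Path:
        gs_a, gs_b = self.global_strengths()
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "design": self.design,
                    "S_observed": self.S_observed,
                    "M_observed": self.M_observed,
                    "p_S": self.p_S,
                    "p_M": self.p_M,
                    "global_strength_a": gs_a,
                    "global_strength_b": gs_b,
                    "n_permutations": self.n_permutations,
                    "alpha": self.alpha,
                    "seed": self.seed,
                    "settings": asdict(self.settings),
                },
                indent=1,
            )
        )
        return path

    def null_samples_to_csv(self, path: str | Path) -> Path:
        """Write the permuted S and M samples for audit."""
        path = Path(path)
        pd.DataFrame({"S": self.null_S, "M": self.null_M}).to_csv(path, index_label="permutation")
        return path


def _perm_pvalue(null: np.ndarray, observed: float) -> float:
    return float((1 + np.sum(null >= observed - 1e-12)) / (1 + null.size))


def _prep(data) -> tuple[np.ndarray, list[str]]:
    if hasattr(data, "matrix"):
        return data.matrix(), list(data.variables)
    df = pd.DataFrame(data)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def _digest(x: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(x).tobytes()).hexdigest()


def nct(
    data_a,
    data_b,
    n_permutations: int = 1000,
    settings: EstimatorSettings | None = None,
    design: str = "independent",
    seed: int = 0,
    alpha: float = 0.05,
) -> NCTResult:
    """Two-tailed permutation comparison of two networks.

    Both variable sets must match in name and order. The independent-design
    permutation stream is seeded from a canonical (content-ordered) pooling
    of the two samples, so swapping the roles of the arms leaves S, M and
    all p-values unchanged.
    """
    if design not in DESIGNS:
        raise CompareError(f"unknown design {design!r}")
    if n_permutations < 1:
        raise CompareError("n_permutations must be >= 1")
    settings = settings or EstimatorSettings()
    X_a, names_a = _prep(data_a)
    X_b, names_b = _prep(data_b)
    if names_a != names_b:
        raise CompareError("variable sets/order differ between the two tables")
    if design == "paired" and X_a.shape[0] != X_b.shape[0]:
        raise CompareError("paired design requires equal group sizes with aligned rows")
    p = X_a.shape[1]
    iu = np.triu_indices(p, 1)

    w_a = _weights_fast(X_a, X_a.shape[0], settings)
    w_b = _weights_fast(X_b, X_b.shape[0], settings)
    S_obs = s_from_global_strengths(_gs(w_a, iu), _gs(w_b, iu))
    M_obs = float(np.abs(w_a - w_b)[iu].max())

    B = n_permutations
    null_S = np.empty(B)
    null_M = np.empty(B)
    null_node = np.empty((B, p))
    null_edge = np.empty((B, iu[0].size))
    rng = np.random.default_rng(seed)

    if design == "independent":
        # canonical pooling: order the arms by content digest for symmetry
        first, second = (X_a, X_b) if _digest(X_a) <= _digest(X_b) else (X_b, X_a)
        pooled = np.vstack([first, second])
        n1 = first.shape[0]
        n = pooled.shape[0]
        for b in range(B):
            perm = rng.permutation(n)
            g1 = _weights_fast(pooled[perm[:n1]], n1, settings)
            g2 = _weights_fast(pooled[perm[n1:]], n - n1, settings)
            _record(null_S, null_M, null_node, null_edge, b, g1, g2, iu)
    else:
        n = X_a.shape[0]
        for b in range(B):
            swap = rng.random(n) < 0.5
            pa = np.where(swap[:, None], X_b, X_a)
            pb = np.where(swap[:, None], X_a, X_b)
            g1 = _weights_fast(pa, n, settings)
            g2 = _weights_fast(pb, n, settings)
            _record(null_S, null_M, null_node, null_edge, b, g1, g2, iu)

    return NCTResult(
        S_observed=S_obs,
        M_observed=M_obs,
        p_S=_perm_pvalue(null_S, S_obs),
        p_M=_perm_pvalue(null_M, M_obs),
        n_permutations=B,
        design=design,
        node_names=names_a,
        weights_a=w_a,
        weights_b=w_b,
        null_S=null_S,
        null_M=null_M,
        null_node=null_node,
        null_edge=null_edge,
        seed=seed,
        alpha=alpha,
        settings=settings,
    )


def _record(null_S, null_M, null_node, null_edge, b, g1, g2, iu) -> None:
    diff = g1 - g2
    null_S[b] = abs(float(np.abs(g1[iu[0], iu[1]]).sum() - np.abs(g2[iu[0], iu[1]]).sum()))
    null_M[b] = float(np.abs(diff)[iu].max())
    null_node[b] = np.abs(np.abs(g1).sum(axis=1) - np.abs(g2).sum(axis=1))
    null_edge[b] = np.abs(diff[iu])


def posthoc_strength_centrality(result: NCTResult) -> pd.DataFrame:
    """Per-node |strength difference| with permutation p-values.

    Reuses the parent test's permutation stream; the table reports both
    groups' raw strengths alongside the difference and p-value. Intended
    for use after a significant omnibus test (the pipeline gates on
    ``result.significant``).
    """
    if not isinstance(result, NCTResult):
        raise CompareError("posthoc tests require a parent NCTResult")
    s_a = np.abs(result.weights_a).sum(axis=1)
    s_b = np.abs(result.weights_b).sum(axis=1)
    obs = np.abs(s_a - s_b)
    pvals = [
        _perm_pvalue(result.null_node[:, i], obs[i]) for i in range(result.p)
    ]
    return pd.DataFrame(
        {
            "strength_a": s_a,
            "strength_b": s_b,
            "abs_difference": obs,
            "p_value": pvals,
        },
        index=pd.Index(result.node_names, name="node"),
    )


def posthoc_edge_invariance(
    result: NCTResult,
    adjustment: str = "holm",
    edges: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-edge |weight difference| with raw and adjusted permutation p-values.

    ``edges`` restricts the tested set (default: all node pairs);
    adjustment is Holm across the tested edges, or ``"none"`` for literal
    unadjusted replication.
    """
    if not isinstance(result, NCTResult):
        raise CompareError("posthoc tests require a parent NCTResult")
    if adjustment not in ("holm", "none"):
        raise CompareError(f"unknown adjustment {adjustment!r}")
    p = result.p
    iu = np.triu_indices(p, 1)
    names = result.node_names
    all_pairs = [(names[i], names[j]) for i, j in zip(*iu)]
    if edges is None:
        sel = np.arange(len(all_pairs))
    else:
        index = {frozenset(e): k for k, e in enumerate(all_pairs)}
        try:
            sel = np.array([index[frozenset(e)] for e in edges])
        except KeyError as exc:
            raise CompareError(f"unknown edge {exc.args[0]}") from exc
    diff = np.abs(result.weights_a - result.weights_b)[iu][sel]
    raw = np.array(
        [_perm_pvalue(result.null_edge[:, k], diff[m]) for m, k in enumerate(sel)]
    )
    if adjustment == "holm" and raw.size:
        adj = multipletests(raw, method="holm")[1]
    else:
        adj = raw.copy()
    return pd.DataFrame(
        {
            "node_a": [all_pairs[k][0] for k in sel],
            "node_b": [all_pairs[k][1] for k in sel],
            "weight_a": result.weights_a[iu][sel],
            "weight_b": result.weights_b[iu][sel],
            "abs_difference": diff,
            "p_value": raw,
            "p_adjusted": np.minimum(adj, 1.0),
        }
    )
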