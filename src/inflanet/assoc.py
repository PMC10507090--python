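"""Rank correlation input to network estimation, with PSD repair.

Spearman correlation (average ranks for ties) is used throughout because
cytokine concentrations are positively skewed and symptom items are ordinal
Likert scores. Pairwise-complete Spearman matrices can be indefinite, and
the graphical-lasso stage needs a positive semi-definite input, so a
one-pass eigenvalue-clipping repair is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

MISSING_POLICIES = ("complete_rows", "pairwise")


class AssocError(ValueError):
    """Degenerate input to correlation estimation."""


@dataclass
class CorrelationEstimate:
    """A Spearman correlation matrix with estimation provenance."""

    matrix: np.ndarray
    names: list[str]
    n_effective: int
    method: str = "spearman"
    psd_repaired: bool = False
    min_eigenvalue_before: float = field(default=np.nan)

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.matrix, index=self.names, columns=self.names).to_csv(path)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, n_effective: int) -> "CorrelationEstimate":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.columns), n_effective)


def _as_frame(data) -> pd.DataFrame:
    if hasattr(data, "data"):  # CohortTable
        return data.data
    return pd.DataFrame(data)


def rank_correlation_matrix(
    data, missing_policy: str = "complete_rows"
) -> CorrelationEstimate:
    """Spearman rank correlation matrix of a cohort table.

    ``complete_rows`` drops any row with a missing value first; ``pairwise``
    uses pairwise-complete observations and records the minimum pairwise n
    as ``n_effective`` (the conservative sample size for EBIC).
    """
    if missing_policy not in MISSING_POLICIES:
        raise AssocError(f"unknown missing policy {missing_policy!r}")
    df = _as_frame(data)
    names = [str(c) for c in df.columns]
    if missing_policy == "complete_rows":
        df = df.dropna(axis=0)
        if len(df) < 3:
            raise AssocError(f"only {len(df)} complete rows; need >= 3")
        for c in df.columns:
            if df[c].nunique() <= 1:
                raise AssocError(f"constant column: {c!r}")
        ranks = np.apply_along_axis(stats.rankdata, 0, df.to_numpy(dtype=float))
        mat = np.corrcoef(ranks, rowvar=False)
        n_eff = len(df)
    else:
        notna = df.notna().to_numpy().astype(np.int64)
        pair_n = notna.T @ notna
        n_eff = int(pair_n[np.triu_indices(len(names), 1)].min()) if len(names) > 1 else int(
            pair_n[0, 0]
        )
        if n_eff < 3:
            raise AssocError(f"minimum pairwise n is {n_eff}; need >= 3")
        for c in df.columns:
            if df[c].dropna().nunique() <= 1:
                raise AssocError(f"constant column: {c!r}")
        mat = df.corr(method="spearman").to_numpy(dtype=float)
    mat = np.clip((mat + mat.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(mat, 1.0)
    return CorrelationEstimate(mat, names, n_eff)


def nearest_psd(corr: CorrelationEstimate, tolerance: float = 1e-8) -> CorrelationEstimate:
    """Eigenvalue-clipping repair to positive semi-definiteness.

    Negative eigenvalues are clipped at zero and the diagonal renormalized
    back to a correlation matrix; returns the input unchanged (flag false)
    when the smallest eigenvalue is already >= ``-tolerance``, which makes
    the operation idempotent.
    """
    m = corr.matrix
    if not np.allclose(m, m.T, atol=1e-10):
        raise AssocError("correlation matrix must be symmetric")
    w, v = np.linalg.eigh(m)
    if w[0] >= -tolerance:
        return corr
    repaired = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(repaired), 1e-12, None))
    repaired = repaired / np.outer(d, d)
    repaired = np.clip((repaired + repaired.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(repaired, 1.0)
    return CorrelationEstimate(
        repaired,
        corr.names,
        corr.n_effective,
        method=corr.method,
        psd_repaired=True,
        min_eigenvalue_before=float(w[0]),
    )
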