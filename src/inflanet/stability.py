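"""Edge accuracy and centrality stability by resampling.

Nonparametric bootstrap: rows are resampled with replacement, the network
re-estimated with identical settings each time, and each edge's inclusion
proportion is the fraction of bootstrap networks in which it was estimated
strictly above zero. Edges present in at least 50% of the bootstrap
networks are flagged reliable (boundary inclusive). Since that rule is
articulated for positive associations, a sign-agnostic nonzero proportion
is reported alongside for negative edges.

Case-dropping bootstrap: for each drop proportion d on a grid, subsamples
of ceil((1-d)*n) rows are drawn without replacement and their strength
centralities correlated with the full-sample centralities. The
CS-coefficient is the largest d at which at least 95% of subsample
correlations reach 0.70; accepted practice wants CS above 0.25, ideally
above 0.5. Centralities are correlated with Pearson (the convention of the
reference stability tooling; a rank correlation degenerates into noise
when many nodes have near-tied strengths, as in hub-like networks) —
Spearman is available via ``correlation_method``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .estimate import EstimatorSettings, EstimationError, _weights_fast, estimate_network

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.76, 0.10), 2))  # 0.05 .. 0.75
CS_CORRELATION = 0.70
CS_CERTAINTY = 0.95


class StabilityError(RuntimeError):
    pass


def _data_matrix(data) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    """(values, names, per-row stratum labels or None).

    When the cohort carries a treatment column, resampling is stratified by
    arm so bootstrap replicates preserve group sizes.
    """
    if hasattr(data, "matrix"):  # CohortTable
        names = data.variables
        strata = None
        treat = data.names_with(role="treatment")
        if treat:
            strata = data.data[treat[0]].to_numpy()
        return data.matrix(), list(names), strata
    df = pd.DataFrame(data)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns], None


def _resample_rows(rng: np.random.Generator, n: int, strata: np.ndarray | None) -> np.ndarray:
    if strata is None:
        return rng.integers(0, n, n)
    idx = []
    for s in np.unique(strata):
        rows = np.where(strata == s)[0]
        idx.append(rng.choice(rows, size=rows.size, replace=True))
    return np.concatenate(idx)


@dataclass
class BootstrapResult:
    B: int
    B_effective: int
    node_names: list[str]
    edge_samples: np.ndarray  # (B_effective, n_edges) upper-triangle weights
    inclusion_proportion: np.ndarray  # P(weight > 0)
    nonzero_proportion: np.ndarray  # P(weight != 0), sign-agnostic
    reliable: np.ndarray  # inclusion_proportion >= 0.5
    observed_weights: np.ndarray
    settings: EstimatorSettings
    seed: int
    failures: int = 0

    def edge_table(self) -> pd.DataFrame:
        p = len(self.node_names)
        iu, jv = np.triu_indices(p, 1)
        return pd.DataFrame(
            {
                "node_a": [self.node_names[i] for i in iu],
                "node_b": [self.node_names[j] for j in jv],
                "observed": self.observed_weights[iu, jv],
                "inclusion_proportion": self.inclusion_proportion,
                "nonzero_proportion": self.nonzero_proportion,
                "reliable": self.reliable,
            }
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "B": self.B,
            "B_effective": self.B_effective,
            "failures": self.failures,
            "seed": self.seed,
            "settings": asdict(self.settings),
            "edges": self.edge_table().to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def is_reliable(inclusion_proportion: float) -> bool:
    """Reliability rule: present in at least 50% of bootstrap samples."""
    return inclusion_proportion >= 0.5


def nonparametric_edge_bootstrap(
    data,
    B: int = 1000,
    settings: EstimatorSettings | None = None,
    seed: int = 0,
) -> BootstrapResult:
    """Row-resampling bootstrap of the edge weights.

    Replicates whose estimation fails are skipped and counted; more than
    10% failures aborts with an error.
    """
    if B < 1:
        raise StabilityError("B must be >= 1")
    settings = settings or EstimatorSettings()
    X, names, strata = _data_matrix(data)
    n, p = X.shape
    observed = _weights_fast(X, n, settings)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(p, 1)
    samples = np.empty((B, iu[0].size))
    failures = 0
    kept = 0
    for b in range(B):
        rows = _resample_rows(rng, n, strata)
        try:
            w = _weights_fast(X[rows], n, settings)
        except EstimationError:
            failures += 1
            continue
        samples[kept] = w[iu]
        kept += 1
    if failures > 0.1 * B:
        raise StabilityError(f"{failures} of {B} bootstrap replicates failed (> 10%)")
    samples = samples[:kept]
    incl = (samples > 0).mean(axis=0)
    nonzero = (samples != 0).mean(axis=0)
    return BootstrapResult(
        B=B,
        B_effective=kept,
        node_names=names,
        edge_samples=samples,
        inclusion_proportion=incl,
        nonzero_proportion=nonzero,
        reliable=incl >= 0.5,
        observed_weights=observed,
        settings=settings,
        seed=seed,
        failures=failures,
    )


@dataclass
class StabilityResult:
    drop_grid: tuple[float, ...]
    correlations: dict[float, np.ndarray]  # per retained level
    cs_coefficient: float
    skipped_levels: list[float]
    correlation_threshold: float
    certainty: float
    settings: EstimatorSettings
    seed: int

    def pass_table(self) -> pd.DataFrame:
        rows = []
        for d in self.drop_grid:
            if d in self.correlations:
                c = self.correlations[d]
                rows.append(
                    {
                        "drop_proportion": d,
                        "prop_above_threshold": float((c >= self.correlation_threshold).mean()),
                        "median_correlation": float(np.median(c)),
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "cs_coefficient": self.cs_coefficient,
            "drop_grid": list(self.drop_grid),
            "skipped_levels": self.skipped_levels,
            "correlation_threshold": self.correlation_threshold,
            "certainty": self.certainty,
            "seed": self.seed,
            "settings": asdict(self.settings),
            "levels": self.pass_table().to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def cs_from_correlations(
    correlations: dict[float, np.ndarray],
    threshold: float = CS_CORRELATION,
    certainty: float = CS_CERTAINTY,
) -> float:
    """CS = max drop proportion whose subsample correlations pass, else 0."""
    passing = [
        d for d, c in correlations.items() if float((c >= threshold).mean()) >= certainty
    ]
    return max(passing) if passing else 0.0


def case_dropping_stability(
    data,
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    B: int = 1000,
    settings: EstimatorSettings | None = None,
    seed: int = 0,
    correlation_threshold: float = CS_CORRELATION,
    certainty: float = CS_CERTAINTY,
    correlation_method: str = "pearson",
) -> StabilityResult:
    """Case-dropping subset bootstrap of strength centrality (CS-coefficient).

    An undefined correlation (constant centralities in a subsample) counts
    as a failure at that draw.
    """
    settings = settings or EstimatorSettings()
    if any(not 0.0 < d < 0.95 for d in drop_grid):
        raise StabilityError("drop proportions must lie in (0, 0.95)")
    X, names, _ = _data_matrix(data)
    n, p = X.shape
    full = np.abs(_weights_fast(X, n, settings)).sum(axis=1)
    rng = np.random.default_rng(seed)
    correlations: dict[float, np.ndarray] = {}
    skipped: list[float] = []
    for d in drop_grid:
        keep = int(np.ceil((1.0 - d) * n))
        if keep < p + 1:
            skipped.append(d)
            warnings.warn(
                f"drop proportion {d} leaves {keep} rows < p+1={p + 1}; level skipped",
                stacklevel=2,
            )
            continue
        cors = np.empty(B)
        for b in range(B):
            rows = rng.choice(n, size=keep, replace=False)
            try:
                sub = np.abs(_weights_fast(X[rows], keep, settings)).sum(axis=1)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", stats.ConstantInputWarning)
                    if correlation_method == "spearman":
                        rho = stats.spearmanr(full, sub).statistic
                    else:
                        rho = stats.pearsonr(full, sub).statistic
            except (EstimationError, ValueError):
                rho = np.nan
            cors[b] = -np.inf if np.isnan(rho) else rho
        correlations[float(d)] = cors
    cs = cs_from_correlations(correlations, correlation_threshold, certainty)
    return StabilityResult(
        drop_grid=tuple(drop_grid),
        correlations=correlations,
        cs_coefficient=cs,
        skipped_levels=skipped,
        correlation_threshold=correlation_threshold,
        certainty=certainty,
        settings=settings,
        seed=seed,
    )
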