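"""Synthetic cohorts with known sparse partial-correlation structure.

Gaussian-copula generator: a latent multivariate normal with correlation
matrix equal to the *standardized inverse* of a planted sparse precision
matrix, pushed through strictly monotone per-variable marginal transforms
(lognormal-like for positively skewed cytokine concentrations, ordinal
probit thresholding for Likert symptom items, a single threshold for binary
variables). Because Spearman correlation is invariant under strictly
monotone maps, the rank structure of the generated data carries the planted
partial-correlation network exactly, which makes estimator-recovery tests
analytic.

Two-arm designs attenuate the off-diagonal of the arm-B precision by a
factor in [0, 1] (a convex combination with the diagonal, hence always
positive definite), emulating a between-group connectivity difference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, VariableMeta

TOPOLOGIES = ("empty", "chain", "hub", "block", "custom")

#: smallest admissible off-diagonal shrink factor in positive-definiteness repair
DEFAULT_SHRINK_FLOOR = 0.05
#: bisection tolerance on the smallest eigenvalue during PD repair
PD_EIG_TOL = 1e-10


class SynthError(ValueError):
    """Infeasible synthetic-network or marginal specification."""


# ---------------------------------------------------------------------------
# true networks
# ---------------------------------------------------------------------------


def partials_from_precision(precision: np.ndarray) -> np.ndarray:
    """Partial correlations -theta_ij / sqrt(theta_ii * theta_jj), zero diagonal."""
    d = np.sqrt(np.diag(precision))
    partials = -precision / np.outer(d, d)
    np.fill_diagonal(partials, 0.0)
    return partials


@dataclass
class TrueNetworkSpec:
    """A planted precision matrix and its implied partial-correlation network."""

    n_vars: int
    precision: np.ndarray
    true_partials: np.ndarray
    topology: str
    block_assignment: np.ndarray | None = None
    shrink_factor: float = 1.0

    @classmethod
    def from_precision(
        cls,
        precision: np.ndarray,
        topology: str = "custom",
        block_assignment: np.ndarray | None = None,
        shrink_factor: float = 1.0,
    ) -> "TrueNetworkSpec":
        precision = np.asarray(precision, dtype=float)
        if precision.ndim != 2 or precision.shape[0] != precision.shape[1]:
            raise SynthError("precision must be square")
        if not np.allclose(precision, precision.T, atol=1e-12):
            raise SynthError("precision must be symmetric")
        w = np.linalg.eigvalsh(precision)
        if w[0] <= 0:
            raise SynthError(f"precision not positive definite (min eigenvalue {w[0]:.3g})")
        return cls(
            n_vars=precision.shape[0],
            precision=precision,
            true_partials=partials_from_precision(precision),
            topology=topology,
            block_assignment=block_assignment,
            shrink_factor=shrink_factor,
        )

    @property
    def latent_correlation(self) -> np.ndarray:
        """Standardized inverse of the precision: the latent-normal correlation."""
        cov = np.linalg.inv(self.precision)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def global_strength(self) -> float:
        """Sum of absolute true partial correlations over the upper triangle."""
        iu = np.triu_indices(self.n_vars, 1)
        return float(np.abs(self.true_partials[iu]).sum())


#: eigenvalue margin a repaired precision matrix must clear, relative to the
#: smallest diagonal entry — keeps the implied latent correlation invertible
PD_MARGIN = 0.05


def _pd_repair(precision: np.ndarray, shrink_floor: float) -> tuple[np.ndarray, float]:
    """Shrink off-diagonals uniformly toward the diagonal until safely PD.

    Bisection on the shrink factor ``t`` (off-diagonal scaled by ``t``) with
    eigenvalue tolerance ``PD_EIG_TOL``; an already-PD input (smallest
    eigenvalue above the margin) is returned unchanged. Raises if the
    required factor falls below ``shrink_floor``.
    """
    diag = np.diag(np.diag(precision))
    off = precision - diag
    margin = PD_MARGIN * float(np.diag(precision).min())

    def min_eig(t: float) -> float:
        return float(np.linalg.eigvalsh(diag + t * off)[0])

    if min_eig(1.0) >= margin:
        return precision, 1.0
    lo, hi = 0.0, 1.0  # lo always feasible (diag PD), hi infeasible
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        if min_eig(mid) - margin > PD_EIG_TOL:
            lo = mid
        else:
            hi = mid
    if lo < shrink_floor:
        mag = float(np.abs(off).max())
        raise SynthError(
            f"edge magnitude {mag:.4g} infeasible: positive definiteness needs "
            f"shrink factor {lo:.4g} below floor {shrink_floor}"
        )
    return diag + lo * off, lo


def build_true_network(
    topology: str,
    n_vars: int,
    edge_value: float = -0.3,
    seed: int = 0,
    *,
    n_blocks: int = 2,
    shrink_floor: float = DEFAULT_SHRINK_FLOOR,
) -> TrueNetworkSpec:
    """Construct a planted sparse precision matrix of a named pattern.

    ``edge_value`` is placed at the off-diagonal precision entries of the
    pattern (unit diagonal); note the implied partial correlation is
    ``-edge_value`` for a unit diagonal.  If the raw matrix is not positive
    definite the off-diagonals are uniformly shrunk toward the diagonal
    (factor recorded in the returned spec).

    ``seed`` is accepted for interface stability; the named patterns are
    deterministic.
    """
    if topology not in TOPOLOGIES:
        raise SynthError(f"unknown topology {topology!r}")
    if topology == "custom":
        raise SynthError("use TrueNetworkSpec.from_precision for custom topologies")
    if n_vars < 2:
        raise SynthError("n_vars must be >= 2")
    theta = np.eye(n_vars)
    block_assignment = None
    if topology == "chain":
        for i in range(n_vars - 1):
            theta[i, i + 1] = theta[i + 1, i] = edge_value
    elif topology == "hub":
        theta[0, 1:] = theta[1:, 0] = edge_value
    elif topology == "block":
        sizes = [n_vars // n_blocks + (1 if i < n_vars % n_blocks else 0) for i in range(n_blocks)]
        block_assignment = np.repeat(np.arange(n_blocks), sizes)
        for b in range(n_blocks):
            idx = np.where(block_assignment == b)[0]
            for i in idx:
                for j in idx:
                    if i != j:
                        theta[i, j] = edge_value
    raw_partials = partials_from_precision(theta)
    theta, factor = _pd_repair(theta, shrink_floor)
    spec = TrueNetworkSpec.from_precision(
        theta, topology=topology, block_assignment=block_assignment, shrink_factor=factor
    )
    # shrinkage must not inflate any planted partial beyond its pre-repair magnitude
    assert np.all(np.abs(spec.true_partials) <= np.abs(raw_partials) + 1e-12)
    return spec


# ---------------------------------------------------------------------------
# marginals
# ---------------------------------------------------------------------------


@dataclass
class MarginalSpec:
    """Strictly monotone transform of a standard-normal latent score.

    families
    --------
    ``skewed_continuous``
        ``x = loc + scale * exp(shape * z)`` — lognormal-like, positively
        skewed for ``shape > 0`` (defaults give skewness > 1).
    ``ordinal``
        category index by thresholding ``z`` at strictly increasing
        ``thresholds`` (ordinal-probit convention); categories are labelled
        ``first_level .. first_level + len(thresholds)``.
    ``binary``
        one threshold; levels ``first_level`` / ``first_level + 1``.
    """

    family: str
    loc: float = 0.0
    scale: float = 1.0
    shape: float = 0.8
    thresholds: tuple[float, ...] = ()
    first_level: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("skewed_continuous", "ordinal", "binary"):
            raise SynthError(f"unknown marginal family {self.family!r}")
        if self.family == "skewed_continuous":
            if self.scale <= 0 or self.shape <= 0:
                raise SynthError("skewed_continuous requires scale > 0 and shape > 0")
            grid = np.linspace(-8, 8, 1001)
            if not np.all(np.diff(self.transform(grid)) > 0):
                raise SynthError("non-monotone transform detected")
        else:
            t = np.asarray(self.thresholds, dtype=float)
            need = 1 if self.family == "binary" else None
            if need is not None and t.size != need:
                raise SynthError("binary marginal requires exactly one threshold")
            if t.size < 1:
                raise SynthError("ordinal marginal requires >= 1 threshold (>= 2 categories)")
            if np.any(np.diff(t) <= 0):
                raise SynthError("ordinal thresholds must be strictly increasing")

    @property
    def n_categories(self) -> int | None:
        if self.family == "skewed_continuous":
            return None
        return len(self.thresholds) + 1

    @property
    def cohort_scale(self) -> str:
        return {
            "skewed_continuous": "continuous",
            "ordinal": "ordinal",
            "binary": "binary",
        }[self.family]

    def transform(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.family == "skewed_continuous":
            return self.loc + self.scale * np.exp(self.shape * z)
        return self.first_level + np.searchsorted(
            np.asarray(self.thresholds), z, side="right"
        ).astype(float)


def skewed_from_mean_sd(mean: float, sd: float) -> MarginalSpec:
    """Lognormal marginal with the given population mean and SD.

    Solves ``sigma^2 = ln(1 + sd^2/mean^2)``, ``scale = mean * exp(-sigma^2/2)``.
    Useful for calibrating cytokine marginals to published summary tables.
    """
    if mean <= 0 or sd <= 0:
        raise SynthError("mean and sd must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    return MarginalSpec(
        "skewed_continuous", scale=mean * np.exp(-sigma2 / 2), shape=float(np.sqrt(sigma2))
    )


def binary_from_rate(rate: float, first_level: int = 0) -> MarginalSpec:
    """Binary marginal where the upper level has probability ``rate``."""
    if not 0 < rate < 1:
        raise SynthError("rate must be in (0, 1)")
    return MarginalSpec("binary", thresholds=(float(stats.norm.ppf(1 - rate)),), first_level=first_level)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _arm_rng(seed: int, arm_index: int) -> np.random.Generator:
    """Per-arm substream: one global seed expands via SeedSequence([seed, arm])."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(arm_index)]))


def sample_cohort(
    spec: TrueNetworkSpec,
    marginals: list[MarginalSpec],
    n: int,
    seed: int,
    *,
    names: list[str] | None = None,
    roles: list[str] | None = None,
    instruments: list[str] | None = None,
    timepoint: str = "",
    arm_index: int = 0,
    latent: np.ndarray | None = None,
) -> CohortTable:
    """Draw a cohort from the Gaussian copula implied by ``spec``.

    Latent scores are multivariate normal with correlation equal to the
    standardized inverse of the planted precision; each column is then
    pushed through its marginal transform.  Identical inputs reproduce
    byte-identical output.  ``latent`` allows a caller (paired designs) to
    supply pre-drawn latent scores instead.
    """
    if len(marginals) != spec.n_vars:
        raise SynthError(f"need {spec.n_vars} marginals, got {len(marginals)}")
    if n < 3:
        raise SynthError("n must be >= 3")
    corr = spec.latent_correlation
    if latent is None:
        rng = _arm_rng(seed, arm_index)
        chol = np.linalg.cholesky(corr)
        latent = rng.standard_normal((n, spec.n_vars)) @ chol.T
    cols = {}
    names = names or [f"v{i + 1:02d}" for i in range(spec.n_vars)]
    roles = roles or ["cytokine"] * spec.n_vars
    instruments = instruments or [""] * spec.n_vars
    meta = []
    for j, m in enumerate(marginals):
        cols[names[j]] = m.transform(latent[:, j])
        meta.append(
            VariableMeta(names[j], roles[j], m.cohort_scale, instruments[j], timepoint)
        )
    df = pd.DataFrame(cols, index=pd.RangeIndex(n, name="subject_id"))
    return CohortTable(df, meta, timepoint=timepoint)


def attenuate_network(
    spec: TrueNetworkSpec, attenuation: float, shrink_floor: float = DEFAULT_SHRINK_FLOOR
) -> TrueNetworkSpec:
    """Scale off-diagonal precision by ``attenuation`` in [0, 1], re-check PD.

    A convex combination of a PD matrix with its (positive) diagonal, so the
    repair step is a no-op in exact arithmetic; retained defensively.
    """
    if not 0.0 <= attenuation <= 1.0:
        raise SynthError("attenuation must be in [0, 1]")
    theta = spec.precision.copy()
    diag = np.diag(np.diag(theta))
    theta = diag + attenuation * (theta - diag)
    theta, factor = _pd_repair(theta, shrink_floor)
    return TrueNetworkSpec.from_precision(
        theta,
        topology=spec.topology,
        block_assignment=spec.block_assignment,
        shrink_factor=spec.shrink_factor * factor,
    )


@dataclass
class CohortSpec:
    """Two-arm synthetic design: arm A from ``network_A``, arm B attenuated."""

    n_per_arm: tuple[int, int]
    network_A: TrueNetworkSpec
    attenuation: float
    marginals: list[MarginalSpec]
    seed: int
    names: list[str] | None = None
    roles: list[str] | None = None


@dataclass
class TwoGroupCohort:
    """Paired cohorts with their generating ground truth."""

    arm_a: CohortTable
    arm_b: CohortTable
    network_a: TrueNetworkSpec
    network_b: TrueNetworkSpec

    @property
    def true_global_strengths(self) -> tuple[float, float]:
        return self.network_a.global_strength(), self.network_b.global_strength()


def make_two_group_cohort(spec: CohortSpec) -> TwoGroupCohort:
    """Generate both arms of a two-group design with known ground truth."""
    net_b = attenuate_network(spec.network_A, spec.attenuation)
    common = dict(names=spec.names, roles=spec.roles)
    arm_a = sample_cohort(
        spec.network_A, spec.marginals, spec.n_per_arm[0], spec.seed, arm_index=0, **common
    )
    arm_b = sample_cohort(
        net_b, spec.marginals, spec.n_per_arm[1], spec.seed, arm_index=1, **common
    )
    return TwoGroupCohort(arm_a, arm_b, spec.network_A, net_b)


def write_ground_truth(spec: TrueNetworkSpec, path: str | Path) -> Path:
    """Persist precision, true partials, and true global strength as JSON."""
    path = Path(path)
    payload = {
        "n_vars": spec.n_vars,
        "topology": spec.topology,
        "shrink_factor": spec.shrink_factor,
        "precision": spec.precision.tolist(),
        "true_partials": spec.true_partials.tolist(),
        "true_global_strength": spec.global_strength(),
    }
    if spec.block_assignment is not None:
        payload["block_assignment"] = np.asarray(spec.block_assignment).tolist()
    path.write_text(json.dumps(payload, indent=1))
    return path


# ---------------------------------------------------------------------------
# full study emulation
# ---------------------------------------------------------------------------

CYTOKINES = (
    "hsCRP", "IL-1RA", "IL-1b", "IL-2", "IL-4", "IL-6",
    "IL-8", "IL-10", "IL-12", "IL-13", "TNF-a", "IFN-g",
)

#: published baseline cohort means/SDs usable as a marginal calibration preset
CYTOKINE_MEAN_SD = {
    "hsCRP": (2.52, 2.35),
    "IL-1RA": (407.49, 437.60),
    "IL-1b": (0.07, 0.26),
    "IL-2": (0.23, 0.26),
    "IL-4": (0.02, 0.02),
    "IL-6": (0.70, 0.50),
    "IL-8": (4.51, 2.95),
    "IL-10": (0.44, 0.89),
    "IL-12": (0.14, 0.16),
    "IL-13": (0.49, 0.48),
    "TNF-a": (2.50, 0.64),
    "IFN-g": (4.80, 5.93),
}

CDSS_ITEMS = (
    "depression", "hopelessness", "self_deprecation", "guilty_reference",
    "pathological_guilt", "morning_depression", "early_wakening", "suicide",
    "observed_depression",
)
PANSS_P_ITEMS = (
    "delusions", "conceptual_disorganisation", "hallucinations", "excitement",
    "grandiosity", "suspiciousness", "hostility",
)
PANSS_N_ITEMS = (
    "blunted_affect", "emotional_withdrawal", "poor_rapport", "social_withdrawal",
    "abstract_thinking", "lack_spontaneity", "stereotyped_thinking",
)

INFLUENTIAL_TRIO = ("IL-6", "TNF-a", "IFN-g")


def study_variables() -> tuple[list[str], list[str], list[str], list[str]]:
    """(names, roles, instruments, scales placeholder) for the emulated study."""
    names, roles, instruments = [], [], []
    for c in CYTOKINES:
        names.append(c); roles.append("cytokine"); instruments.append("")
    for s in CDSS_ITEMS:
        names.append(s); roles.append("symptom"); instruments.append("CDSS")
    for s in PANSS_P_ITEMS:
        names.append(s); roles.append("symptom"); instruments.append("PANSS_P")
    for s in PANSS_N_ITEMS:
        names.append(s); roles.append("symptom"); instruments.append("PANSS_N")
    for c in ("age", "sex", "BMI"):
        names.append(c); roles.append("covariate"); instruments.append("")
    return names, roles, instruments, []


def study_true_network() -> TrueNetworkSpec:
    """Planted cytokine-symptom network emulating the trial's structure.

    A pro-inflammatory hub (IL-6 strongly tied to TNF-a and IFN-g, weaker
    ties to the remaining cytokines), within-instrument symptom blocks, and
    three small cytokine-symptom bridges into the depressive items
    (IL-6 - self-deprecation, IFN-g - hopelessness, TNF-a - suspiciousness).
    """
    names, _, _, _ = study_variables()
    p = len(names)
    ix = {n: i for i, n in enumerate(names)}
    theta = np.eye(p)

    def put(a: str, b: str, partial: float) -> None:
        theta[ix[a], ix[b]] = theta[ix[b], ix[a]] = -partial

    # cytokine hub: a strongly interconnected pro-inflammatory trio plus
    # weaker spokes; magnitudes chosen so an n ~ 194 cohort yields networks
    # of the connectivity scale the emulated study reports
    for other, r in (("TNF-a", 0.45), ("IFN-g", 0.42), ("IL-8", 0.20), ("IL-10", 0.18),
                     ("IL-12", 0.18), ("IL-13", 0.18), ("IL-2", 0.15)):
        put("IL-6", other, r)
    put("TNF-a", "IFN-g", 0.35)
    put("TNF-a", "IL-8", 0.15)
    put("IFN-g", "IL-12", 0.15)
    put("hsCRP", "IL-6", 0.20)
    put("IL-1RA", "IL-1b", 0.22)
    put("IL-4", "IL-13", 0.20)
    # symptom blocks (nearest-neighbour chains within instrument + a closing edge)
    for items, r in ((CDSS_ITEMS, 0.40), (PANSS_P_ITEMS, 0.38), (PANSS_N_ITEMS, 0.40)):
        for a, b in zip(items[:-1], items[1:]):
            put(a, b, r)
        put(items[0], items[-1], r / 2)
    put("suspiciousness", "hopelessness", 0.18)  # bridges depression & suspiciousness
    put("morning_depression", "early_wakening", 0.25)
    put("pathological_guilt", "guilty_reference", 0.25)
    # cytokine-symptom bridges
    put("IL-6", "self_deprecation", 0.22)
    put("IFN-g", "hopelessness", 0.18)
    put("TNF-a", "suspiciousness", 0.18)
    # covariates
    put("age", "BMI", 0.22)
    put("BMI", "hsCRP", 0.25)
    theta, factor = _pd_repair(theta, DEFAULT_SHRINK_FLOOR)
    return TrueNetworkSpec.from_precision(theta, topology="custom", shrink_factor=factor)


def study_marginals() -> list[MarginalSpec]:
    """Marginals for the emulated study variables (calibration preset).

    Cytokines: lognormal matched to the published means/SDs. CDSS: 4-point
    items (0-3), mildly right-skewed. PANSS: 7-point items (1-7) centred
    near the published subscale means. Covariates: age/BMI mildly skewed
    continuous matched to published mean/SD, sex binary at the published
    female rate.
    """
    out = [skewed_from_mean_sd(*CYTOKINE_MEAN_SD[c]) for c in CYTOKINES]
    cdss = MarginalSpec("ordinal", thresholds=(0.0, 0.8, 1.5), first_level=0)
    out += [cdss] * len(CDSS_ITEMS)
    panss = MarginalSpec(
        "ordinal", thresholds=(-0.8, -0.1, 0.5, 1.1, 1.7, 2.3), first_level=1
    )
    out += [panss] * (len(PANSS_P_ITEMS) + len(PANSS_N_ITEMS))
    out.append(skewed_from_mean_sd(25.58, 5.19))  # age
    out.append(binary_from_rate(0.258))  # sex: 1 = female
    out.append(skewed_from_mean_sd(27.35, 6.53))  # BMI
    return out


@dataclass
class StudyCohorts:
    """Baseline and 6-month tables plus generating ground truth per arm."""

    baseline: CohortTable
    followup: CohortTable
    truth: dict[str, TrueNetworkSpec] = field(default_factory=dict)


def make_study_cohorts(
    n_per_arm: tuple[int, int] = (104, 103),
    attenuation: float = 0.45,
    seed: int = 0,
    *,
    latent_coupling: float = 0.0,
    crp_mean_sd: tuple[float, float] = (3.57, 4.68),
) -> StudyCohorts:
    """Generate a full two-arm, two-timepoint cohort emulating the trial.

    Baseline: both arms drawn from the same planted network (~207 subjects
    before screening).  Follow-up: the placebo arm keeps the baseline
    network; the active arm's network is attenuated by ``attenuation``
    (default 0.45, the ratio of the published 6-month group connectivities).
    A screening CRP column is attached (lognormal chosen so roughly 6% of
    subjects exceed the 10 mg/L exclusion threshold) along with a 1/2
    treatment column.  ``latent_coupling`` in [0, 1) correlates each
    subject's latent scores across timepoints (0 = independent draws).
    """
    if not 0.0 <= latent_coupling < 1.0:
        raise SynthError("latent_coupling must be in [0, 1)")
    names, roles, instruments, _ = study_variables()
    net = study_true_network()
    net_att = attenuate_network(net, attenuation)
    margs = study_marginals()
    crp_marg = skewed_from_mean_sd(*crp_mean_sd)

    frames = {"baseline": [], "followup": []}
    truth = {
        "baseline_placebo": net, "baseline_active": net,
        "followup_placebo": net, "followup_active": net_att,
    }
    chol = np.linalg.cholesky(net.latent_correlation)
    chol_att = np.linalg.cholesky(net_att.latent_correlation)
    offset = 0
    for arm_index, (n_arm, code) in enumerate(zip(n_per_arm, (1, 2))):
        rng = _arm_rng(seed, arm_index)
        z_base = rng.standard_normal((n_arm, net.n_vars)) @ chol.T
        z_new = rng.standard_normal((n_arm, net.n_vars)) @ (
            chol_att.T if code == 2 else chol.T
        )
        z_fu = latent_coupling * z_base + np.sqrt(1 - latent_coupling**2) * z_new
        crp = crp_marg.transform(rng.standard_normal(n_arm))
        for tp, z in (("baseline", z_base), ("followup", z_fu)):
            tbl = sample_cohort(
                net if (tp == "baseline" or code == 1) else net_att,
                margs, n_arm, seed,
                names=names, roles=roles, instruments=instruments,
                timepoint=tp, latent=z,
            )
            df = tbl.data.copy()
            df.index = pd.RangeIndex(offset, offset + n_arm, name="subject_id")
            df["CRP_screen"] = crp
            df["treatment"] = code
            meta = list(tbl.meta) + [
                VariableMeta("CRP_screen", "screening", "continuous", timepoint=tp),
                VariableMeta("treatment", "treatment", "binary", timepoint=tp),
            ]
            frames[tp].append(CohortTable(df, meta, timepoint=tp))
        offset += n_arm

    def cat(tables: list[CohortTable], tp: str) -> CohortTable:
        df = pd.concat([t.data for t in tables])
        return CohortTable(df, tables[0].meta, timepoint=tp)

    return StudyCohorts(
        baseline=cat(frames["baseline"], "baseline"),
        followup=cat(frames["followup"], "followup"),
        truth=truth,
    )
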