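"""Log-linear model of query-interval location: density, likelihood, MLE.

The density of a query start X given length Y = y is an exponential tilt of
the uniform null on the mappable start domain G0(y):

    f(x | y) = c(theta, y) * f0(x | y) * exp( sum_pi theta_pi r_pi(x | y) )

where r_pi(x|y) = prod_{i in pi} r_i(x|y) indicates simultaneous overlap of
q(x, y) with every reference set indexed by pi, and c(theta, y) normalizes.
Because r depends on x only through the overlap pattern v, everything
collapses to sums over partition cells:

    c(theta, y)^-1 = sum_v (m_v(y) / |G0(y)|) * exp(theta . s(v)).

The working log-likelihood drops the theta-free log f0 terms:

    l(theta) = theta' T + sum_i log c(theta, y_i),      l(0) = 0,

which is concave with gradient T - sum_i E_theta[s(V) | y_i] and negative
Hessian sum_i Cov_theta[s(V) | y_i] (the observed information).  The MLE is
found by damped Newton iteration with backtracking; non-convergence (a
coefficient drifting to +/- infinity, flagged at |theta| >= 5 by default) is
detected and reported, never silently returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .errors import DegenerateNullError, IdentifiabilityError, InputError
from .partition import (
    OverlapPartition,
    SufficientStats,
    TermDesign,
    canonical_terms,
    term_design,
    tuple_to_pattern,
)

__all__ = [
    "ModelSpec",
    "FitResult",
    "enrichment",
    "log_normalizer",
    "log_likelihood",
    "score_and_information",
    "fit_mle",
    "wald_ci",
    "check_identifiability",
    "check_feasibility",
    "IdentifiabilityReport",
    "FeasibilityWarning",
    "DIVERGENCE_THRESHOLD",
]

#: |theta_hat| at or above this value flags a non-convergent (divergent) fit.
DIVERGENCE_THRESHOLD = 5.0

#: hard cap on |theta| during iteration; prevents overflow, never binds for
#: converged fits (threshold above fires first).
_THETA_CAP = 30.0


@dataclass(frozen=True)
class ModelSpec:
    """An ordered list of model terms over N reference sets.

    Each term pi is a non-empty subset of {1..N}; there are at most 2^N - 1.
    Terms are stored in canonical order (by size, then lexicographically).
    """

    n_refs: int
    terms: tuple[frozenset[int], ...]

    def __init__(self, n_refs: int, terms: Sequence[Sequence[int]]):
        cterms = canonical_terms([sorted(t) for t in terms])
        for t in cterms:
            if max(t, default=0) > n_refs:
                raise InputError(
                    f"term {sorted(t)} references a set beyond N={n_refs}"
                )
        object.__setattr__(self, "n_refs", int(n_refs))
        object.__setattr__(self, "terms", cterms)

    @property
    def d(self) -> int:
        return len(self.terms)

    @classmethod
    def full(cls, n_refs: int) -> "ModelSpec":
        """All 2^N - 1 terms."""
        from itertools import combinations

        terms = [
            list(c)
            for k in range(1, n_refs + 1)
            for c in combinations(range(1, n_refs + 1), k)
        ]
        return cls(n_refs, terms)

    def term_labels(self) -> list[str]:
        return ["{" + ", ".join(str(i) for i in sorted(t)) + "}" for t in self.terms]

    def drop(self, term: Sequence[int] | frozenset[int]) -> "ModelSpec":
        fs = frozenset(term)
        if fs not in self.terms:
            raise InputError(f"term {sorted(fs)} not in model")
        return ModelSpec(self.n_refs, [sorted(t) for t in self.terms if t != fs])

    def add(self, term: Sequence[int] | frozenset[int]) -> "ModelSpec":
        fs = frozenset(term)
        return ModelSpec(self.n_refs, [sorted(t) for t in self.terms] + [sorted(fs)])


def enrichment(
    theta: np.ndarray, spec: ModelSpec, pattern: Sequence[int]
) -> float:
    """Enrichment profile h = sum_pi theta_pi r_pi at an overlap pattern.

    The background pattern (all zeros) gives 0; under the uniform null a
    pattern is enriched (depleted) relative to background iff h > 0 (< 0),
    and exp(h) is the probability fold-change versus a background start.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.d,):
        raise InputError(f"theta has shape {theta.shape}, expected ({spec.d},)")
    v = tuple(int(b) for b in pattern)
    if len(v) != spec.n_refs:
        raise InputError(
            f"pattern has {len(v)} bits, expected N={spec.n_refs}"
        )
    h = 0.0
    for coef, term in zip(theta, spec.terms):
        if all(v[i - 1] for i in term):
            h += float(coef)
    return h


# ---------------------------------------------------------------------------
# compiled per-length arrays: the numerical core works on these


@dataclass
class _LengthBlock:
    log_w: np.ndarray  # log(m_v) - log g0 per realized cell
    S: np.ndarray  # design matrix (cells x d)
    n_y: int  # number of queries of this length


def _compile(
    spec: ModelSpec, parts: Mapping[int, tuple[OverlapPartition, int]]
) -> list[_LengthBlock]:
    blocks = []
    for y, (part, n_y) in sorted(parts.items()):
        if part.g0_size <= 0 or part.masks.size == 0:
            raise DegenerateNullError(f"degenerate partition for y={y}")
        des = term_design(spec.terms, part.masks)
        log_w = np.log(part.sizes.astype(float)) - np.log(float(part.g0_size))
        log_w -= _lse(log_w)  # exact-in-math renormalization; kills rounding
        blocks.append(_LengthBlock(log_w=log_w, S=des.S, n_y=int(n_y)))
    return blocks


def _lse(a: np.ndarray) -> float:
    """Stable log-sum-exp (local: avoids scipy dispatch overhead in hot loops)."""
    m = a.max()
    return float(m + np.log(np.exp(a - m).sum()))


def _log_norm_block(theta: np.ndarray, block: _LengthBlock) -> float:
    """log c(theta, y) = -logsumexp over cells of (log_w + S theta)."""
    return -_lse(block.log_w + block.S @ theta)


def _loglik_core(theta: np.ndarray, T: np.ndarray, blocks: list[_LengthBlock]) -> float:
    ll = float(theta @ T)
    for b in blocks:
        ll += b.n_y * _log_norm_block(theta, b)
    return ll


def _score_info_core(
    theta: np.ndarray, T: np.ndarray, blocks: list[_LengthBlock]
) -> tuple[np.ndarray, np.ndarray]:
    d = T.size
    grad = T.astype(float).copy()
    info = np.zeros((d, d))
    for b in blocks:
        a = b.log_w + b.S @ theta
        a -= a.max()
        p = np.exp(a)
        p /= p.sum()
        mu = b.S.T @ p
        grad -= b.n_y * mu
        cov = (b.S.T * p) @ b.S - np.outer(mu, mu)
        info += b.n_y * cov
    return grad, info


# ---------------------------------------------------------------------------
# public operations (spec-facing signatures)


def log_normalizer(
    theta: np.ndarray, partition: OverlapPartition, design: TermDesign
) -> float:
    """log c(theta, y), computed by log-sum-exp over realized cells.

    theta = 0 gives exactly 0 (the density reduces to the null).
    """
    theta = np.asarray(theta, dtype=float)
    if partition.g0_size <= 0 or partition.masks.size == 0:
        raise DegenerateNullError("degenerate partition: empty start domain")
    log_w = np.log(partition.sizes.astype(float)) - np.log(float(partition.g0_size))
    return -float(logsumexp(log_w + design.S @ theta))


def log_likelihood(
    theta: np.ndarray,
    stats: SufficientStats,
    parts: Mapping[int, tuple[OverlapPartition, int]],
    spec: ModelSpec | None = None,
) -> float:
    """Working log-likelihood l(theta) = theta' T + sum_y n_y log c(theta, y).

    The theta-free log f0 constants are dropped, so l(0) = 0 identically and
    all model comparisons (GLRT, BIC) are unaffected.
    """
    spec = spec or ModelSpec(max((max(t) for t in stats.terms), default=1), stats.terms)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.d,):
        raise InputError(f"theta has shape {theta.shape}, expected ({spec.d},)")
    blocks = _compile(spec, parts)
    return _loglik_core(theta, stats.t.astype(float), blocks)


def score_and_information(
    theta: np.ndarray,
    stats: SufficientStats,
    parts: Mapping[int, tuple[OverlapPartition, int]],
    spec: ModelSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient T - sum_y n_y E[s(V)|y] and observed information (PSD)."""
    spec = spec or ModelSpec(max((max(t) for t in stats.terms), default=1), stats.terms)
    theta = np.asarray(theta, dtype=float)
    blocks = _compile(spec, parts)
    return _score_info_core(theta, stats.t.astype(float), blocks)


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model specification."""

    spec: ModelSpec
    theta_hat: np.ndarray
    loglik: float
    score_norm: float
    observed_information: np.ndarray
    converged: bool
    diverged_terms: list[tuple[int, ...]]
    n_obs: int
    n_iter: int = 0
    ci: dict[tuple[int, ...], tuple[float, float]] = field(default_factory=dict)

    def theta_dict(self) -> dict[tuple[int, ...], float]:
        return {
            tuple(sorted(t)): float(v)
            for t, v in zip(self.spec.terms, self.theta_hat)
        }

    def to_json_dict(self) -> dict:
        return {
            "terms": [sorted(t) for t in self.spec.terms],
            "theta_hat": [float(v) for v in self.theta_hat],
            "loglik": float(self.loglik),
            "score_norm": float(self.score_norm),
            "converged": bool(self.converged),
            "diverged_terms": [list(t) for t in self.diverged_terms],
            "n_obs": int(self.n_obs),
            "ci": {
                "{" + ",".join(map(str, k)) + "}": [float(a), float(b)]
                for k, (a, b) in self.ci.items()
            },
        }


def _newton(
    T: np.ndarray,
    blocks: list[_LengthBlock],
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
    divergence_threshold: float = DIVERGENCE_THRESHOLD,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray, bool, int]:
    """Damped Newton ascent of the concave working log-likelihood.

    Returns (theta, loglik, grad, info, converged_numerically, n_iter).
    ``converged_numerically`` means the gradient tolerance was met within the
    |theta| cap; the divergence-threshold check is applied by the caller.
    """
    d = T.size
    theta = np.zeros(d)
    if d == 0:
        return theta, 0.0, np.zeros(0), np.zeros((0, 0)), True, 0
    # gradient tolerance is relative to the scale of T: the objective and its
    # gradient are O(n), so an absolute cutoff stalls in float noise at large n
    gtol = tol * max(1.0, float(np.max(np.abs(T))))
    ll = _loglik_core(theta, T, blocks)
    grad, info = _score_info_core(theta, T, blocks)
    it = 0
    ok = False
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) <= gtol:
            ok = True
            break
        # ridge-regularized Newton direction (info is PSD; ridge handles
        # near-singular geometry and divergent trajectories)
        ridge = 0.0
        while True:
            try:
                step = np.linalg.solve(info + ridge * np.eye(d), grad)
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10.0, 1e-8)
        # Newton decrement: expected objective gain; once it is below float
        # resolution of the objective further line searches cannot succeed
        if float(grad @ step) <= 1e-12 * max(1.0, abs(ll)):
            ok = True
            break
        # backtracking line search on the concave objective
        t_step = 1.0
        for _ in range(30):
            cand = np.clip(theta + t_step * step, -_THETA_CAP, _THETA_CAP)
            cand_ll = _loglik_core(cand, T, blocks)
            if cand_ll >= ll + 1e-4 * t_step * float(grad @ (cand - theta)) or (
                cand_ll > ll
            ):
                break
            t_step *= 0.5
        else:
            # no ascent step found: at the cap or numerically stuck
            break
        theta, ll = cand, cand_ll
        grad, info = _score_info_core(theta, T, blocks)
    else:
        it = max_iter
    if np.max(np.abs(grad)) <= gtol:
        ok = True
    # a trajectory pinned at the cap is divergent even if the clipped gradient
    # happens to be small
    if np.any(np.abs(theta) >= _THETA_CAP - 1e-9):
        ok = ok and False
    return theta, ll, grad, info, ok, it


def fit_mle(
    stats: SufficientStats,
    parts: Mapping[int, tuple[OverlapPartition, int]],
    spec: ModelSpec | None = None,
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
    divergence_threshold: float = DIVERGENCE_THRESHOLD,
    alpha: float = 0.05,
) -> FitResult:
    """Maximize the working log-likelihood over theta in R^d.

    The objective is concave, so the damped Newton iteration reaches the
    unique stationary point whenever one exists.  A fit is flagged as
    diverged — ``converged=False`` with the offending terms listed — when any
    coefficient reaches ``divergence_threshold`` (default 5) in absolute
    value, the signature of a sufficient statistic at its boundary (t_pi = 0,
    or t_pi equal to a nested t_pitilde).
    """
    spec = spec or ModelSpec(
        max((max(t) for t in stats.terms), default=1), stats.terms
    )
    if tuple(stats.terms) != tuple(spec.terms):
        raise InputError("sufficient statistics and model spec terms differ")
    blocks = _compile(spec, parts)
    n_obs = sum(b.n_y for b in blocks)
    theta, ll, grad, info, num_ok, n_iter = _newton(
        stats.t.astype(float),
        blocks,
        tol=tol,
        max_iter=max_iter,
        divergence_threshold=divergence_threshold,
    )
    diverged = [
        tuple(sorted(t))
        for t, v in zip(spec.terms, theta)
        if abs(v) >= divergence_threshold
    ]
    converged = bool(num_ok and not diverged)
    fit = FitResult(
        spec=spec,
        theta_hat=theta,
        loglik=ll,
        score_norm=float(np.max(np.abs(grad))) if grad.size else 0.0,
        observed_information=info,
        converged=converged,
        diverged_terms=diverged,
        n_obs=n_obs,
        n_iter=n_iter,
    )
    if converged and spec.d > 0:
        try:
            fit.ci = wald_ci(fit, alpha)
        except IdentifiabilityError:
            pass
    return fit


def wald_ci(
    fit: FitResult, alpha: float = 0.05
) -> dict[tuple[int, ...], tuple[float, float]]:
    """Wald intervals theta_hat_pi +/- z_{1-alpha/2} * se_pi from the
    observed information.  alpha = 1 gives zero-width intervals."""
    if not (0.0 < alpha <= 1.0):
        raise InputError(f"alpha must be in (0, 1], got {alpha}")
    d = fit.spec.d
    if d == 0:
        return {}
    info = fit.observed_information
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise IdentifiabilityError(
            "observed information is singular; the model is not identifiable "
            "on this geometry (see check_identifiability)"
        ) from None
    var = np.diag(cov)
    if np.any(var < -1e-8):
        raise IdentifiabilityError(
            "observed information is not positive definite; the model is "
            "not identifiable on this geometry"
        )
    se = np.sqrt(np.maximum(var, 0.0))
    z = float(norm.ppf(1.0 - alpha / 2.0))
    return {
        tuple(sorted(t)): (float(m - z * s), float(m + z * s))
        for t, m, s in zip(fit.spec.terms, fit.theta_hat, se)
    }


@dataclass
class IdentifiabilityReport:
    identifiable: bool
    rank: int
    d: int
    missing_patterns: list[tuple[int, ...]]

    def __bool__(self) -> bool:
        return self.identifiable


def check_identifiability(
    spec: ModelSpec, partitions: Sequence[OverlapPartition]
) -> IdentifiabilityReport:
    """Is the MLE unique on this geometry?

    The likelihood depends on theta only through {theta . s(v)} over realized
    cells, so the model is identifiable iff the stacked design matrix (rows
    s(v) over all realized patterns, pooled across query lengths; the
    background contributes a zero row) has full column rank d.  For the full
    model this reduces to: all 2^N pattern cells non-empty.
    """
    if spec.d == 0:
        return IdentifiabilityReport(True, 0, 0, [])
    all_masks = np.unique(
        np.concatenate([p.masks for p in partitions])
        if partitions
        else np.zeros(0, dtype=np.int64)
    )
    des = term_design(spec.terms, all_masks)
    rank = int(np.linalg.matrix_rank(des.S)) if all_masks.size else 0
    full = 1 << spec.n_refs
    realized = set(int(m) for m in all_masks)
    missing = [
        tuple((m >> i) & 1 for i in range(spec.n_refs))
        for m in range(full)
        if m not in realized
    ]
    return IdentifiabilityReport(
        identifiable=(rank == spec.d), rank=rank, d=spec.d, missing_patterns=missing
    )


@dataclass(frozen=True)
class FeasibilityWarning:
    kind: str  # "zero_count" | "nested_equality"
    term: tuple[int, ...]
    other: tuple[int, ...] | None = None

    def __str__(self) -> str:
        if self.kind == "zero_count":
            return (
                f"t_{set(self.term)} = 0: no query overlaps all of "
                f"{set(self.term)} simultaneously; the MLE for this term "
                "diverges to -infinity"
            )
        return (
            f"t_{set(self.term)} = t_{set(self.other)} with "
            f"{set(self.other)} subset of {set(self.term)}: nested counts "
            "equal; the MLE diverges"
        )


def check_feasibility(
    stats: SufficientStats, spec: ModelSpec | None = None
) -> list[FeasibilityWarning]:
    """Predict MLE divergence from the sufficient statistics.

    Warns on t_pi = 0 for any included term and on t_pi = t_pitilde for
    nested included pairs pitilde strictly inside pi — the convergence
    conditions whose failure sends a coefficient to +/- infinity.
    """
    warnings: list[FeasibilityWarning] = []
    terms = list(stats.terms)
    tvals = {t: int(v) for t, v in zip(terms, stats.t)}
    for t in terms:
        if tvals[t] == 0:
            warnings.append(FeasibilityWarning("zero_count", tuple(sorted(t))))
    for big in terms:
        for small in terms:
            if small < big and tvals[small] == tvals[big] and tvals[big] > 0:
                warnings.append(
                    FeasibilityWarning(
                        "nested_equality", tuple(sorted(big)), tuple(sorted(small))
                    )
                )
    return warnings
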