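"""Hypothesis testing and model selection.

* Per-term generalized likelihood ratio test (GLRT): refit with theta_pi
  constrained to zero; Lambda = 2 * (l_unconstrained - l_constrained) is
  referred to a chi-square distribution with one degree of freedom.
* BIC = d log n - 2 l(theta_hat), with n the number of query intervals;
  under the working-likelihood convention the empty model has BIC = 0.
* Bidirectional stepwise selection: starting from the empty model, score
  every single-term addition and removal, take the move with the lowest
  resulting BIC, accept only strict improvements, stop when none improves.
  No hierarchy constraint is imposed: an interaction may enter without its
  lower-order terms.
* Selected significant terms are labeled primary (no significant term is a
  proper subset of theirs) or secondary.

Raw per-term p-values are reported with no multiple-testing correction; when
many terms are screened, treat small p-values accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .dataset import OverlapDataset
from .errors import ConvergenceError, InputError
from .model import FitResult, ModelSpec

__all__ = [
    "TermTest",
    "SelectionResult",
    "glrt",
    "bic",
    "stepwise_select",
    "classify_effects",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermTest:
    """GLRT of theta_pi = 0 within a fitted model."""

    term: tuple[int, ...]
    statistic: float
    p_value: float
    available: bool = True
    note: str = ""


def glrt(
    data: OverlapDataset, spec: ModelSpec, term: Sequence[int] | frozenset[int]
) -> TermTest:
    """Test whether the coefficient of one model term differs from zero.

    Fits the model twice — with theta_pi free and with theta_pi = 0 (the term
    removed) — and refers Lambda = 2 * (l_free - l_constrained) to chi2(1).
    The constrained model is nested in the free one, so Lambda >= 0 up to
    numerical tolerance.
    """
    fs = frozenset(term)
    if fs not in spec.terms:
        raise InputError(f"term {sorted(fs)} not in model spec")
    full_fit = data.fit(spec)
    constrained_fit = data.fit(spec.drop(fs))
    key = tuple(sorted(fs))
    if not (full_fit.converged and constrained_fit.converged):
        which = "unconstrained" if not full_fit.converged else "constrained"
        bad = (
            full_fit.diverged_terms
            if not full_fit.converged
            else constrained_fit.diverged_terms
        )
        return TermTest(
            term=key,
            statistic=float("nan"),
            p_value=float("nan"),
            available=False,
            note=f"{which} fit did not converge (diverged terms: {bad})",
        )
    lam = 2.0 * (full_fit.loglik - constrained_fit.loglik)
    lam = max(lam, 0.0)  # clip the numerically tiny negatives
    return TermTest(term=key, statistic=lam, p_value=float(chi2.sf(lam, df=1)))


def bic(fit: FitResult, n: int | None = None, d: int | None = None) -> float:
    """Bayesian Information Criterion: d log n - 2 l(theta_hat).

    ``n`` is the number of query intervals; the empty model (d = 0) has
    BIC = 0 under the working-likelihood convention (l(0) = 0)."""
    n = fit.n_obs if n is None else int(n)
    d = fit.spec.d if d is None else int(d)
    if d == 0:
        return 0.0
    return d * float(np.log(n)) - 2.0 * fit.loglik


@dataclass
class SelectionResult:
    """Outcome of bidirectional stepwise BIC selection."""

    spec: ModelSpec
    fit: FitResult
    bic: float
    trace: list[tuple[str, tuple[int, ...], float]] = field(default_factory=list)
    tests: dict[tuple[int, ...], TermTest] = field(default_factory=dict)
    effects: dict[tuple[int, ...], str] = field(default_factory=dict)
    skipped_candidates: list[tuple[int, ...]] = field(default_factory=list)

    def selected_terms(self) -> set[tuple[int, ...]]:
        return {tuple(sorted(t)) for t in self.spec.terms}

    def to_json_dict(self) -> dict:
        return {
            "schema_version": 1,
            "selected_terms": sorted(
                (list(t) for t in self.selected_terms()), key=lambda t: (len(t), t)
            ),
            "bic": float(self.bic),
            "fit": self.fit.to_json_dict(),
            "trace": [
                {"move": m, "term": list(t), "bic": float(b)}
                for m, t, b in self.trace
            ],
            "tests": {
                "{" + ",".join(map(str, k)) + "}": {
                    "statistic": (None if not tt.available else float(tt.statistic)),
                    "p_value": (None if not tt.available else float(tt.p_value)),
                    "available": tt.available,
                }
                for k, tt in self.tests.items()
            },
            "effects": {
                "{" + ",".join(map(str, k)) + "}": v for k, v in self.effects.items()
            },
        }

    def to_tsv(self, names: Sequence[str] | None = None) -> str:
        """Human-readable table: term, primary/secondary, theta_hat, p-value."""

        def label(t: tuple[int, ...]) -> str:
            if names:
                return "{" + ", ".join(names[i - 1] for i in t) + "}"
            return "{" + ", ".join(map(str, t)) + "}"

        theta = self.fit.theta_dict()
        rows = ["Model Term\tPrimary Effect\ttheta_hat\tp-value"]
        for t in sorted(self.selected_terms(), key=lambda t: (len(t), t)):
            tt = self.tests.get(t)
            p = "NA" if tt is None or not tt.available else f"{tt.p_value:.4g}"
            eff = self.effects.get(t, "")
            primary = {"primary": "Yes", "secondary": "No"}.get(eff, "NA")
            rows.append(f"{label(t)}\t{primary}\t{theta[t]:.4f}\t{p}")
        return "\n".join(rows) + "\n"


def _tie_key(
    move: str, term: frozenset[int]
) -> tuple[int, int, tuple[int, ...]]:
    # deterministic tie-break: removal first, then smaller |pi|, then lexicographic
    return (0 if move == "remove" else 1, len(term), tuple(sorted(term)))


def stepwise_select(
    data: OverlapDataset,
    candidates: Sequence[Sequence[int]] | None = None,
    *,
    max_order: int | None = None,
    alpha: float = 0.05,
    compute_tests: bool = True,
    divergence_threshold: float | None = None,
) -> SelectionResult:
    """Bidirectional stepwise search minimizing BIC.

    Parameters
    ----------
    data
        Preprocessed dataset.
    candidates
        Candidate term universe; defaults to all 2^N - 1 subsets, optionally
        truncated by ``max_order`` (maximum interaction order |pi|).
        Candidates with t_pi = 0 are excluded up front (their MLE diverges).
    alpha
        Significance level used for the primary/secondary effect labels.
    compute_tests
        Run a per-term GLRT on the selected model.

    Notes
    -----
    Accepted moves strictly decrease BIC, so the trace is finite and the
    search cannot cycle.  Non-convergent candidate fits are skipped with a
    logged diagnostic.  Ties are broken deterministically (removal before
    addition, then smaller term, then lexicographic order).
    """
    if candidates is None:
        full = ModelSpec.full(data.n_refs)
        cand = list(full.terms)
    else:
        cand = [frozenset(int(i) for i in t) for t in candidates]
        if len(set(cand)) != len(cand):
            raise InputError("duplicate candidate terms")
    if max_order is not None:
        cand = [t for t in cand if len(t) <= max_order]
    if not cand:
        raise InputError("candidate term list is empty")

    # feasibility screen: t_pi = 0 cannot be fit
    probe = ModelSpec(data.n_refs, [sorted(t) for t in cand])
    tvals = data.sufficient_stats(probe).as_dict()
    skipped = [tuple(sorted(t)) for t in cand if tvals[tuple(sorted(t))] == 0]
    cand = [t for t in cand if tvals[tuple(sorted(t))] > 0]

    fit_kwargs = {}
    if divergence_threshold is not None:
        fit_kwargs["divergence_threshold"] = divergence_threshold

    # internal fast path: terms as bitmasks, fits cached per term set
    def to_mask(t: frozenset[int]) -> int:
        return sum(1 << (i - 1) for i in t)

    def order_key(t: frozenset[int]) -> tuple[int, tuple[int, ...]]:
        return (len(t), tuple(sorted(t)))

    log_n = float(np.log(data.n)) if data.n > 0 else 0.0
    fit_cache: dict[frozenset[frozenset[int]], float | None] = {}

    def bic_of(terms: frozenset[frozenset[int]]) -> float | None:
        """BIC of the candidate term set, or None if its fit diverges."""
        if terms not in fit_cache:
            tmasks = [to_mask(t) for t in sorted(terms, key=order_key)]
            _, ll, ok = data.fit_masks(tmasks, **fit_kwargs)
            if ok:
                fit_cache[terms] = len(terms) * log_n - 2.0 * ll
            else:
                fit_cache[terms] = None
                logger.debug(
                    "skipping non-convergent candidate %s",
                    sorted(map(sorted, terms)),
                )
        return fit_cache[terms]

    current: frozenset[frozenset[int]] = frozenset()
    current_bic = bic_of(current)
    assert current_bic is not None  # empty model always converges
    trace: list[tuple[str, tuple[int, ...], float]] = []

    while True:
        moves: list[tuple[float, tuple[int, int, tuple[int, ...]], str, frozenset[int]]] = []
        for t in cand:
            if t in current:
                continue
            b = bic_of(current | {t})
            if b is not None:
                moves.append((b, _tie_key("add", t), "add", t))
        for t in current:
            b = bic_of(current - {t})
            if b is not None:
                moves.append((b, _tie_key("remove", t), "remove", t))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1]))
        best_bic, _, move, term = moves[0]
        if best_bic >= current_bic - 1e-10:
            break
        current = current | {term} if move == "add" else current - {term}
        current_bic = best_bic
        trace.append((move, tuple(sorted(term)), best_bic))

    spec = ModelSpec(data.n_refs, [sorted(t) for t in current])
    final_fit = data.fit(spec, with_ci=True, **fit_kwargs)
    result = SelectionResult(
        spec=spec,
        fit=final_fit,
        bic=current_bic,
        trace=trace,
        skipped_candidates=skipped,
    )
    if compute_tests and spec.d > 0:
        for t in spec.terms:
            result.tests[tuple(sorted(t))] = glrt(data, spec, t)
        result.effects = classify_effects(
            [tuple(sorted(t)) for t in spec.terms],
            {
                k: tt.p_value
                for k, tt in result.tests.items()
                if tt.available
            },
            alpha=alpha,
        )
    return result


def classify_effects(
    terms: Sequence[tuple[int, ...]],
    p_values: dict[tuple[int, ...], float],
    alpha: float = 0.05,
) -> dict[tuple[int, ...], str]:
    """Label significant terms as primary or secondary effects.

    A significant term pi is *primary* when no other significant term is a
    proper subset of pi; otherwise it is *secondary*.  Singletons are always
    primary when significant.  Non-significant terms get the label
    ``"not_significant"``.  The labeling is invariant to term order.
    """
    sig = {
        tuple(sorted(t))
        for t in terms
        if p_values.get(tuple(sorted(t)), 1.0) <= alpha
    }
    out: dict[tuple[int, ...], str] = {}
    for t in terms:
        key = tuple(sorted(t))
        if key not in sig:
            out[key] = "not_significant"
            continue
        tset = set(key)
        has_sig_subset = any(
            set(other) < tset for other in sig if other != key
        )
        out[key] = "secondary" if has_sig_subset else "primary"
    return out
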