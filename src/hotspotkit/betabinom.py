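"""Per-gene beta-binomial mixed model with stepwise fixed effects.

The per-gene histogram ``h[i]`` counts protein positions observed with
exactly ``i`` distinct mutated patients. The model decomposes it as

    h[i] = BetaBin(a, b)[i] + F[i]

where ``F`` is a vector of fixed effects absorbing the positions the
background beta-binomial cannot explain. ``F`` is built greedily: at each
step every (bin, fraction-of-bin) removal candidate is refit and the one
with the lowest divergence is committed, until the divergence drops below
a stopping threshold or a step cap is hit. Positions in bins with
``F[i] > 0`` are flagged as hotspot candidates and receive an upper-tail
beta-binomial p-value, Benjamini-Hochberg correction over warm spots
(recurrence >= 4) and a final ``q < 0.01 or recurrence >= 7`` filter.

The divergence used for fitting and stopping is the Kullback-Leibler
divergence between the normalized histogram and the model pmf
(renormalized over the observed support ``0..k``), scaled by the number
of sites. On that scale it equals half the G-statistic (the expected
log-likelihood ratio in nats), so a fixed threshold of 1 is meaningful
for histograms of any size; on the normalized scale KL shrinks like
``1/n_sites`` and a unit threshold would never trigger any fixed effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, digamma, gammaln

from hotspotkit.mutation_io import PositionCounts

logger = logging.getLogger(__name__)

#: Parameter bounds for (a, b) during optimization.
PARAM_BOUNDS = (1e-6, 1e6)
#: Deterministic multi-start grid for the optimizer.
START_POINTS = ((0.01, 10.0), (0.01, 1000.0), (1.0, 10.0), (1.0, 1000.0))
#: Floor applied to model probabilities before taking logs.
PMF_FLOOR = 1e-300

DEFAULT_WARM_MIN = 4
DEFAULT_Q_MAX = 0.01
DEFAULT_PATIENTS_MIN = 7
DEFAULT_KL_STOP = 1.0
DEFAULT_FRAC_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


@dataclass
class PositionHistogram:
    """Counts of sites per observed recurrence for one gene."""

    gene: str
    h: np.ndarray  # length k+1, h[i] = number of sites with recurrence i
    n_sites: int
    n_patients: int

    @property
    def k(self) -> int:
        return len(self.h) - 1

    def validate(self) -> None:
        if len(self.h) < 1:
            raise ValueError("histogram must have at least one bin")
        if np.any(self.h < 0):
            raise ValueError("histogram bins must be non-negative")
        if not np.isclose(self.h.sum(), self.n_sites):
            raise ValueError(
                f"histogram bins sum to {self.h.sum()}, expected n_sites={self.n_sites}"
            )
        if self.k > self.n_patients:
            raise ValueError("max recurrence exceeds number of patients")


@dataclass
class BetaBinomialFit:
    """Fitted background model.

    ``kl`` is the final scaled divergence (sites x nats) described in the
    module docstring; it is the quantity compared against the stopping
    threshold.
    """

    a: float
    b: float
    n: int
    kl: float
    converged: bool
    n_steps: int = 0

    @property
    def mean_rate(self) -> float:
        """Mean per-site mutation probability a/(a+b)."""
        return self.a / (self.a + self.b)


@dataclass
class FixedEffects:
    """Per-bin counts of sites absorbed by the fixed effect."""

    F: np.ndarray

    def flagged_bins(self) -> np.ndarray:
        return np.flatnonzero(self.F > 0)


@dataclass
class HotspotCall:
    gene: str
    protein_pos: int
    recurrence: int
    p_value: float
    q_value: float | None = None
    is_warm: bool = False
    passes_filter: bool = False
    flagged: bool = False
    transcript_id: str = ""


def build_histogram(pc: PositionCounts, n_patients: int) -> PositionHistogram:
    """Tally sites per recurrence; bin 0 holds unmutated assayable sites."""
    n_sites = pc.n_sites()
    n_mutated = len(pc.counts)
    if n_sites < n_mutated:
        raise ValueError(
            f"gene {pc.gene}: n_sites={n_sites} < {n_mutated} mutated positions"
        )
    k = pc.max_recurrence()
    if k > n_patients:
        raise ValueError(
            f"gene {pc.gene}: max recurrence {k} exceeds n_patients={n_patients}"
        )
    h = np.zeros(k + 1, dtype=np.int64)
    for rec in pc.counts.values():
        h[rec] += 1
    h[0] = n_sites - n_mutated
    return PositionHistogram(gene=pc.gene, h=h, n_sites=n_sites, n_patients=n_patients)


def betabin_logpmf(
    i: np.ndarray | int, n: int, a: float, b: float
) -> np.ndarray | float:
    """Log beta-binomial pmf, computed from log-gamma terms."""
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    i_arr = np.asarray(i)
    if np.any(i_arr < 0) or np.any(i_arr > n):
        raise ValueError("i outside 0..n")
    out = (
        gammaln(n + 1)
        - gammaln(i_arr + 1)
        - gammaln(n - i_arr + 1)
        + betaln(i_arr + a, n - i_arr + b)
        - betaln(a, b)
    )
    return out if out.ndim else float(out)


def betabin_pmf(i: np.ndarray | int, n: int, a: float, b: float) -> np.ndarray | float:
    """Beta-binomial pmf P(X = i) for X ~ BetaBin(n, a, b)."""
    return np.exp(betabin_logpmf(i, n, a, b))


def betabin_sf(i: int, n: int, a: float, b: float) -> float:
    """Inclusive upper tail P(X >= i)."""
    if i <= 0:
        return 1.0
    tail = betabin_pmf(np.arange(i, n + 1), n, a, b)
    return float(min(1.0, np.sum(tail)))


def kl_divergence(observed: np.ndarray, model: np.ndarray) -> float:
    """KL(observed || model) in nats over two probability vectors.

    Model probabilities are floored at ``PMF_FLOOR``; observed zeros
    contribute nothing.
    """
    observed = np.asarray(observed, dtype=float)
    model = np.asarray(model, dtype=float)
    if observed.shape != model.shape:
        raise ValueError("vectors must have equal length")
    model = np.maximum(model, PMF_FLOOR)
    mask = observed > 0
    return float(np.sum(observed[mask] * np.log(observed[mask] / model[mask])))


def _truncated_model(n: int, a: float, b: float, k: int) -> np.ndarray:
    """Model pmf renormalized over the observed support 0..k."""
    lp = betabin_logpmf(np.arange(k + 1), n, a, b)
    p = np.exp(lp - np.max(lp))
    total_k = p.sum()
    # renormalize over 0..k; if mass beyond k is negligible this is ~pmf
    return p / total_k


def _scaled_kl(h: np.ndarray, n: int, a: float, b: float) -> float:
    """Divergence between histogram and model on the sites x nats scale."""
    total = h.sum()
    if total <= 0:
        return 0.0
    obs = np.asarray(h, dtype=float) / total
    model = _truncated_model(n, a, b, len(h) - 1)
    return float(total) * kl_divergence(obs, model)


def _dlogpmf(i: np.ndarray, n: int, a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    """Partial derivatives of the log pmf with respect to a and b."""
    common = digamma(a + b) - digamma(n + a + b)
    da = digamma(i + a) - digamma(a) + common
    db = digamma(n - i + b) - digamma(b) + common
    return da, db


def _kl_value_grad(h: np.ndarray, n: int, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Scaled divergence and its gradient in log-parameter space."""
    a, b = float(np.exp(x[0])), float(np.exp(x[1]))
    total = h.sum()
    k = len(h) - 1
    idx = np.arange(k + 1)
    lp = betabin_logpmf(idx, n, a, b)
    shifted = np.exp(lp - np.max(lp))
    m = shifted / shifted.sum()
    obs = h / total
    mask = obs > 0
    val = float(total) * float(
        np.sum(obs[mask] * (np.log(obs[mask]) - np.log(np.maximum(m[mask], PMF_FLOOR))))
    )
    da, db = _dlogpmf(idx, n, a, b)
    # d log m_i = d lp_i - sum_j m_j d lp_j  (renormalization term)
    da_m = da - np.sum(m * da)
    db_m = db - np.sum(m * db)
    grad = -float(total) * np.array(
        [np.sum(obs[mask] * da_m[mask]) * a, np.sum(obs[mask] * db_m[mask]) * b]
    )
    return val, grad


def _negll_value_grad(h: np.ndarray, n: int, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient in log-parameter space."""
    a, b = float(np.exp(x[0])), float(np.exp(x[1]))
    idx = np.flatnonzero(h)
    lp = betabin_logpmf(idx, n, a, b)
    da, db = _dlogpmf(idx, n, a, b)
    val = -float(np.sum(h[idx] * lp))
    grad = -np.array([np.sum(h[idx] * da) * a, np.sum(h[idx] * db) * b])
    return val, grad


def fit_betabinomial(
    hist: PositionHistogram,
    init: tuple[float, float] | None = None,
    objective: str = "kl",
) -> BetaBinomialFit:
    """Fit (a, b) by bounded quasi-Newton (L-BFGS-B in log-parameter space).

    ``objective="kl"`` (default) minimizes the divergence between the
    normalized histogram and the model renormalized over ``0..k``;
    ``objective="ml"`` maximizes the untruncated multinomial likelihood.
    Starting points are ``init`` when given, otherwise a fixed 4-point
    grid; the best final objective wins, deterministically.
    """
    h = np.asarray(hist.h, dtype=float)
    n = hist.n_patients
    nonzero_bins = int(np.count_nonzero(h))

    if h.sum() <= 0 or nonzero_bins < 2:
        a0, b0 = init if init is not None else (1.0, 1000.0)
        return BetaBinomialFit(
            a=a0, b=b0, n=n, kl=_scaled_kl(h, n, a0, b0), converged=False, n_steps=0
        )

    if objective == "kl":
        def fun(x: np.ndarray):
            return _kl_value_grad(h, n, x)
    elif objective == "ml":
        def fun(x: np.ndarray):
            return _negll_value_grad(h, n, x)
    else:
        raise ValueError(f"unknown objective {objective!r}")

    lo, hi = np.log(PARAM_BOUNDS[0]), np.log(PARAM_BOUNDS[1])
    starts = [init] if init is not None else list(START_POINTS)
    best = None
    any_converged = False
    for a0, b0 in starts:
        res = minimize(
            fun,
            np.log([a0, b0]),
            method="L-BFGS-B",
            jac=True,
            bounds=[(lo, hi), (lo, hi)],
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.exp(best.x)
    return BetaBinomialFit(
        a=float(a),
        b=float(b),
        n=n,
        kl=_scaled_kl(h, n, float(a), float(b)),
        converged=any_converged,
        n_steps=int(best.nit),
    )


def stepwise_fixed_effects(
    hist: PositionHistogram,
    frac_grid: Sequence[float] = DEFAULT_FRAC_GRID,
    kl_stop: float = DEFAULT_KL_STOP,
    max_steps: int | None = None,
    min_improvement: float = 1.0,
    objective: str = "kl",
    return_trace: bool = False,
):
    """Greedy stepwise estimation of the fixed-effect vector F.

    At each step a candidate grid is scanned: for every bin ``i >= 1``
    with sites remaining and every fraction ``f`` in ``frac_grid``, the
    candidate removes ``round(f * h_i)`` sites (at least 1) from bin
    ``i`` and the background is refit on the reduced histogram. The
    candidate with the lowest divergence is committed and its removed
    sites added to ``F[i]``. Iteration stops when the divergence falls
    below ``kl_stop``, when no candidate improves it by at least
    ``min_improvement`` (the no-or-little-improvement rule; on the
    sites x nats scale sampling noise alone keeps the divergence of a
    well-fit histogram around half its bin count, so steps that buy less
    than one unit are indistinguishable from noise), or after
    ``max_steps`` (default ``3 * k``) committed steps.

    Returns ``(fit, fixed_effects)``; with ``return_trace=True`` a third
    element lists the committed divergence after each step (starting with
    the initial fit).
    """
    hist.validate()
    k = hist.k
    if max_steps is None:
        max_steps = 3 * k
    current = np.asarray(hist.h, dtype=np.int64).copy()
    F = np.zeros(k + 1, dtype=np.int64)

    fit = fit_betabinomial(hist, objective=objective)
    trace = [fit.kl]
    steps = 0
    while fit.kl >= kl_stop and steps < max_steps:
        best_cand = None  # (kl, i, f, r, fit)
        seen: set[tuple[int, int]] = set()
        for i in range(1, k + 1):
            if current[i] <= 0:
                continue
            for f in frac_grid:
                r = int(round(f * current[i]))
                r = max(r, 1)
                r = min(r, int(current[i]))
                if (i, r) in seen:
                    continue
                seen.add((i, r))
                cand = current.copy()
                cand[i] -= r
                cand_hist = PositionHistogram(
                    gene=hist.gene,
                    h=cand,
                    n_sites=int(cand.sum()),
                    n_patients=hist.n_patients,
                )
                # warm start from the current parameters for speed
                cand_fit = fit_betabinomial(
                    cand_hist, init=(fit.a, fit.b), objective=objective
                )
                if best_cand is None or cand_fit.kl < best_cand[0]:
                    best_cand = (cand_fit.kl, i, f, r, cand_fit)
        if best_cand is None or fit.kl - best_cand[0] < min_improvement:
            break  # no or little improvement: stop
        _, i, f, r, fit = best_cand
        current[i] -= r
        F[i] += r
        steps += 1
        trace.append(fit.kl)
        logger.debug(
            "%s step %d: bin %d fraction %.1f removed %d sites, kl=%.4f",
            hist.gene, steps, i, f, r, fit.kl,
        )
    fit.n_steps = steps
    logger.info(
        "%s: %d stepwise steps, final kl=%.4f, F total=%d",
        hist.gene, steps, fit.kl, int(F.sum()),
    )
    fixed = FixedEffects(F=F)
    if return_trace:
        return fit, fixed, trace
    return fit, fixed


def call_hotspots(
    pc: PositionCounts, fit: BetaBinomialFit, F: FixedEffects
) -> list[HotspotCall]:
    """One call per mutated position; flagged where its bin carries F > 0."""
    calls = []
    for pos, rec in sorted(pc.counts.items()):
        p = betabin_sf(rec, fit.n, fit.a, fit.b)
        p = max(p, np.finfo(float).tiny)
        flagged = rec < len(F.F) and F.F[rec] > 0
        calls.append(
            HotspotCall(
                gene=pc.gene,
                protein_pos=pos,
                recurrence=rec,
                p_value=p,
                flagged=bool(flagged),
                transcript_id=pc.transcript_id,
            )
        )
    return calls


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH adjusted p-values (q-values), monotone, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fdr_correct(
    calls: Sequence[HotspotCall], warm_min: int = DEFAULT_WARM_MIN
) -> list[HotspotCall]:
    """BH-correct p-values over exactly the warm subset (recurrence >= warm_min)."""
    out = list(calls)
    warm_idx = [j for j, c in enumerate(out) if c.recurrence >= warm_min]
    q = benjamini_hochberg(np.array([out[j].p_value for j in warm_idx]))
    for c in out:
        c.is_warm = c.recurrence >= warm_min
        c.q_value = None
    for j, qv in zip(warm_idx, q):
        out[j].q_value = float(qv)
    return out


def filter_hotspots(
    calls: Sequence[HotspotCall],
    q_max: float = DEFAULT_Q_MAX,
    patients_min: int = DEFAULT_PATIENTS_MIN,
) -> list[HotspotCall]:
    """Set ``passes_filter``: warm and (q < q_max or recurrence >= patients_min)."""
    out = list(calls)
    for c in out:
        qualifies = (c.q_value is not None and c.q_value < q_max) or (
            c.recurrence >= patients_min
        )
        c.passes_filter = bool(c.is_warm and qualifies)
    return out


def model_table(
    hist: PositionHistogram, fit: BetaBinomialFit, F: FixedEffects
) -> pd.DataFrame:
    """Per-bin table: observed sites, model expectation, fixed effect, tail p."""
    k = hist.k
    idx = np.arange(k + 1)
    reduced_total = hist.n_sites - int(F.F.sum())
    expected = _truncated_model(fit.n, fit.a, fit.b, k) * reduced_total
    return pd.DataFrame(
        {
            "i": idx,
            "h": np.asarray(hist.h, dtype=np.int64),
            "model_expected": expected,
            "F": np.asarray(F.F, dtype=np.int64),
            "p_tail": [betabin_sf(int(i), fit.n, fit.a, fit.b) for i in idx],
        }
    )


__all__ = [
    "PositionHistogram",
    "BetaBinomialFit",
    "FixedEffects",
    "HotspotCall",
    "build_histogram",
    "betabin_logpmf",
    "betabin_pmf",
    "betabin_sf",
    "kl_divergence",
    "fit_betabinomial",
    "stepwise_fixed_effects",
    "call_hotspots",
    "benjamini_hochberg",
    "fdr_correct",
    "filter_hotspots",
    "model_table",
    "DEFAULT_WARM_MIN",
    "DEFAULT_Q_MAX",
    "DEFAULT_PATIENTS_MIN",
    "DEFAULT_KL_STOP",
    "DEFAULT_FRAC_GRID",
]
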