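"""Bayesian inference on the joint distribution of NO persistence and
therapy response.

The cohort is summarized as counts of the four joint outcomes of two
Boolean variables — whether a patient's bone-marrow NO level failed to
normalize after induction therapy (persistent vs decreased) and whether
the patient responded to therapy (failure vs response).  The counts follow
a multinomial distribution with probability vector theta on the 3-simplex.

Inference updates a uniform prior with the multinomial likelihood by
importance sampling: theta is drawn uniformly on the simplex (which is the
prior) and weighted by the likelihood, so the weighted sample targets the
posterior.  That posterior is analytically Dirichlet(counts + 1), and the
equal-weight Dirichlet sampler here exists as an independent oracle for
the importance sampler, never as its implementation.  Conditionals such as
P(treatment failure | NO persistent) aggregate a Dirichlet into a Beta, so
their MAP and credible intervals can also be cross-checked in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import (
    InvalidParameterError,
    UnreliableEstimateError,
    rng_from_seed,
)
from .phantom import OUTCOME_LABELS, CohortTable

#: Default importance-sample count for production runs; tests use 1e5.
DEFAULT_N_SAMPLES = 1_000_000


@dataclass
class CohortPosterior:
    """Weighted posterior samples of the four multinomial probabilities."""

    theta_samples: np.ndarray  # (N, 4), each row on the simplex
    weights: np.ndarray  # (N,), normalized to sum 1
    n_samples: int
    seed: int

    def __post_init__(self):
        th = np.asarray(self.theta_samples, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if th.ndim != 2 or th.shape[1] != 4:
            raise InvalidParameterError("theta_samples must have shape (N, 4)")
        if np.any(np.abs(th.sum(axis=1) - 1.0) > 1e-12):
            raise InvalidParameterError("each theta sample must sum to 1")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("weights must be >= 0 and sum to 1")
        self.theta_samples = th
        self.weights = w

    @property
    def effective_sample_size(self) -> float:
        return float(1.0 / np.sum(self.weights**2))


@dataclass
class PosteriorSummary:
    map: float
    ci95: tuple[float, float]
    effective_sample_size: float
    flat: bool = False


def importance_posterior(
    counts: CohortTable, n_samples: int = DEFAULT_N_SAMPLES, seed: int = 0
) -> CohortPosterior:
    """Uniform-prior importance-sampling posterior of theta.

    Samples theta uniformly on the simplex (= the prior, used as the
    proposal) and weights each draw by the multinomial likelihood of the
    observed counts, computed in log space and normalized.  With all-zero
    counts the likelihood is flat and every weight equals 1/N.
    """
    if n_samples <= 0:
        raise InvalidParameterError("n_samples must be >= 1")
    rng = rng_from_seed(seed)
    theta = rng.dirichlet(np.ones(4), size=int(n_samples))
    n = counts.as_array()
    # n_i = 0 terms contribute nothing; the floor only guards log(0) there.
    logw = (n * np.log(np.maximum(theta, 1e-300))).sum(axis=1)
    logw -= logsumexp(logw)
    weights = np.exp(logw)
    weights /= weights.sum()
    return CohortPosterior(theta, weights, int(n_samples), int(seed))


def dirichlet_posterior(
    counts: CohortTable, n_samples: int = DEFAULT_N_SAMPLES, seed: int = 0
) -> CohortPosterior:
    """Analytic conjugate posterior Dirichlet(counts + 1), equal weights.

    Serves as the independent oracle for :func:`importance_posterior`.
    """
    if n_samples <= 0:
        raise InvalidParameterError("n_samples must be >= 1")
    rng = rng_from_seed(seed)
    theta = rng.dirichlet(counts.as_array() + 1.0, size=int(n_samples))
    theta /= theta.sum(axis=1, keepdims=True)  # tighten float round-off
    weights = np.full(int(n_samples), 1.0 / n_samples)
    return CohortPosterior(theta, weights, int(n_samples), int(seed))


def _as_indices(outcomes) -> list[int]:
    idx = []
    for o in outcomes:
        if isinstance(o, str):
            if o not in OUTCOME_LABELS:
                raise InvalidParameterError(
                    f"unknown outcome {o!r}; valid: {OUTCOME_LABELS}"
                )
            idx.append(OUTCOME_LABELS.index(o))
        else:
            if not (0 <= int(o) < 4):
                raise InvalidParameterError("outcome index out of range")
            idx.append(int(o))
    return sorted(set(idx))


def conditional_samples(
    post: CohortPosterior, event, condition
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted samples of P(event | condition).

    ``event`` and ``condition`` are outcome subsets (labels from
    :data:`~vascniche.phantom.OUTCOME_LABELS` or indices); the event must
    be contained in the condition.  Per posterior draw the conditional is
    the ratio of summed theta components; weights carry through unchanged.
    """
    ev = _as_indices(event)
    cond = _as_indices(condition)
    if not set(ev) <= set(cond):
        raise InvalidParameterError("event must be a subset of the condition")
    num = post.theta_samples[:, ev].sum(axis=1)
    den = post.theta_samples[:, cond].sum(axis=1)
    return num / den, post.weights


def _weighted_histogram_mode(
    samples: np.ndarray, weights: np.ndarray, n_bins: int = 200
) -> tuple[float, bool]:
    """Mode of the weighted sample density on [0, 1].

    Uses an n_bins histogram with quadratic interpolation around the peak
    bin; at a boundary bin the parabola's vertex is clamped into [0, 1].
    Returns (mode, flat_flag); a flat histogram yields (0.5, True).
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist, _ = np.histogram(samples, bins=edges, weights=weights)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = hist > 0
    if occupied.sum() > n_bins // 2:
        mean_h = hist[occupied].mean()
        if hist.max() < 1.25 * mean_h:
            return 0.5, True
    # Locate the peak on a lightly smoothed histogram (the raw argmax bin
    # is shot-noise limited), then refine with a local quadratic fit.
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(hist, kernel, mode="same")
    i = int(np.argmax(smooth))
    half = 8  # fit window +-8 bins (~0.085 wide)
    if half <= i <= n_bins - 1 - half:
        sl = slice(i - half, i + half + 1)
        a, b, _ = np.polyfit(centers[sl], hist[sl], 2)
        if a < 0:
            vertex = -b / (2.0 * a)
            lo_c, hi_c = centers[i - half], centers[i + half]
            return float(np.clip(vertex, lo_c, hi_c)), False
        return float(centers[i]), False
    # Boundary peak: fit a parabola through the five outermost bins.  If the
    # fitted density is still rising at the boundary, the mode IS the
    # boundary (a monotone density like Beta(a+1, 1) peaks at the edge);
    # otherwise take the parabola's vertex clamped to [0, 1].
    k = min(5, n_bins)
    sl = slice(0, k) if i == 0 else slice(n_bins - k, n_bins)
    x, y = centers[sl], hist[sl]
    a, b, _ = np.polyfit(x, y, 2)
    edge = 0.0 if i == 0 else 1.0
    slope_at_edge = 2.0 * a * edge + b
    if (i == 0 and slope_at_edge <= 0) or (i == n_bins - 1 and slope_at_edge >= 0):
        return edge, False
    if a < 0:
        return float(np.clip(-b / (2.0 * a), 0.0, 1.0)), False
    return float(centers[i]), False


def map_estimate(
    samples: np.ndarray,
    weights: np.ndarray,
    min_ess: float = 100.0,
) -> float:
    """Maximum-a-posteriori estimate of a scalar from weighted samples.

    Raises :class:`UnreliableEstimateError` when the effective sample size
    falls below ``min_ess``.  For a flat posterior (e.g. no data) the
    documented convention is to return 0.5 and emit a warning.
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    ess = 1.0 / np.sum(w**2)
    if ess < min_ess:
        raise UnreliableEstimateError(
            f"effective sample size {ess:.1f} < {min_ess}; MAP unreliable"
        )
    mode, flat = _weighted_histogram_mode(np.asarray(samples, dtype=float), w)
    if flat:
        warnings.warn("posterior is flat; returning 0.5 by convention", stacklevel=2)
    return mode


def beta_fit_mode(
    samples: np.ndarray,
    weights: np.ndarray,
    min_ess: float = 100.0,
) -> tuple[float, bool]:
    """Mode of a Beta distribution moment-matched to weighted samples.

    Any conditional P(event | condition) of a Dirichlet-distributed theta
    is exactly Beta-distributed, so fitting a Beta by weighted mean and
    variance and taking its analytic mode is a far lower-variance MAP
    estimator than a histogram mode.  Monotone densities (one shape
    parameter <= 1) peak at the corresponding boundary; an (approximately)
    uniform fit returns (0.5, True) by the flat-posterior convention.
    """
    s = np.asarray(samples, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    ess = 1.0 / np.sum(w**2)
    if ess < min_ess:
        raise UnreliableEstimateError(
            f"effective sample size {ess:.1f} < {min_ess}; MAP unreliable"
        )
    mu = float(np.sum(w * s))
    var = float(np.sum(w * (s - mu) ** 2))
    if var <= 0:
        return mu, False  # degenerate point mass
    common = mu * (1.0 - mu) / var - 1.0
    if common <= 0:
        return 0.5, True
    alpha = mu * common
    beta = (1.0 - mu) * common
    if alpha > 1.0 and beta > 1.0:
        return float((alpha - 1.0) / (alpha + beta - 2.0)), False
    if alpha <= 1.0 and beta <= 1.0:
        return 0.5, True
    return (0.0, False) if alpha <= 1.0 else (1.0, False)


def credible_interval(
    samples: np.ndarray,
    weights: np.ndarray,
    level: float = 0.95,
    min_ess: float = 100.0,
) -> tuple[float, float]:
    """Equal-tailed weighted credible interval at the given level."""
    if not (0.0 < level < 1.0):
        raise InvalidParameterError("level must lie in (0, 1)")
    s = np.asarray(samples, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise UnreliableEstimateError("weights sum to zero")
    w = w / w.sum()
    ess = 1.0 / np.sum(w**2)
    if ess < min_ess:
        raise UnreliableEstimateError(
            f"effective sample size {ess:.1f} < {min_ess}; interval unreliable"
        )
    order = np.argsort(s)
    s, w = s[order], w[order]
    cw = np.cumsum(w) - 0.5 * w  # midpoint rule
    alpha = (1.0 - level) / 2.0
    lo = float(np.interp(alpha, cw, s))
    hi = float(np.interp(1.0 - alpha, cw, s))
    return lo, hi


def summarize_conditional(
    post: CohortPosterior,
    event,
    condition,
    level: float = 0.95,
    map_method: str = "beta",
) -> PosteriorSummary:
    """MAP, CI95 and effective sample size of P(event | condition).

    ``map_method="beta"`` (default) uses the moment-matched Beta mode —
    exact in distribution for simplex-aggregation conditionals;
    ``"histogram"`` uses the generic weighted-histogram mode.
    """
    samples, weights = conditional_samples(post, event, condition)
    if map_method == "beta":
        m, flat = beta_fit_mode(samples, weights)
    elif map_method == "histogram":
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            m = map_estimate(samples, weights)
            flat = any("flat" in str(c.message) for c in caught)
    else:
        raise InvalidParameterError(f"unknown map_method {map_method!r}")
    ci = credible_interval(samples, weights, level=level)
    return PosteriorSummary(
        map=m,
        ci95=ci,
        effective_sample_size=1.0 / float(np.sum((weights / weights.sum()) ** 2)),
        flat=flat,
    )


# ---------------------------------------------------------------------------
# Cohort tabulation from per-patient tables


def tabulate_cohort(
    patients: pd.DataFrame, risk_group: str | None = None
) -> CohortTable:
    """Tabulate a per-patient table into 2x2 joint counts.

    Expects columns ``no_change`` in {"stable_increased", "decreased"} and
    ``response`` in {"failure", "response"}; if ``risk_group`` is given and
    the table has a ``risk_group`` column, the tabulation is restricted to
    that group (e.g. "intermediate").
    """
    for col in ("no_change", "response"):
        if col not in patients.columns:
            raise InvalidParameterError(f"patient table lacks column {col!r}")
    df = patients
    if risk_group is not None:
        if "risk_group" not in df.columns:
            raise InvalidParameterError("no risk_group column to restrict on")
        df = df[df["risk_group"] == risk_group]
    valid_no = {"stable_increased", "decreased"}
    valid_resp = {"failure", "response"}
    bad = set(df["no_change"]) - valid_no | set(df["response"]) - valid_resp
    if bad:
        raise InvalidParameterError(f"unrecognized outcome labels: {sorted(bad)}")
    persistent = df["no_change"] == "stable_increased"
    failure = df["response"] == "failure"
    counts = (
        int((persistent & failure).sum()),
        int((persistent & ~failure).sum()),
        int((~persistent & failure).sum()),
        int((~persistent & ~failure).sum()),
    )
    return CohortTable(counts=counts)


def failure_given_persistent_report(
    counts: CohortTable, n_samples: int = DEFAULT_N_SAMPLES, seed: int = 0
) -> dict:
    """The headline conditional: P(treatment failure | NO persistent).

    Runs the importance-sampling posterior and summarizes the conditional
    restricted to NO-persistent patients.
    """
    post = importance_posterior(counts, n_samples=n_samples, seed=seed)
    summ = summarize_conditional(
        post,
        event=["persistent_failure"],
        condition=["persistent_failure", "persistent_response"],
    )
    return {
        "conditional": "P(failure | NO stable/increased)",
        "counts": list(counts.counts),
        "MAP": summ.map,
        "CI95": list(summ.ci95),
        "N": n_samples,
        "seed": seed,
        "effective_sample_size": summ.effective_sample_size,
        "flat": summ.flat,
    }
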