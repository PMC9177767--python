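"""Optimal Bayesian Filter (OBF) feature statistics.

Model
-----
Each feature is either a *marker* (class-conditional distributions differ)
or a *non-marker* (one distribution for all samples).  Data blocks are
Gaussian with unknown mean and variance.  Parameters carry the Jeffreys-rule
prior in the (mu, sigma) parametrization,

    p(mu, sigma) = c / sigma^2      (improper; c is the prior's
                                     normalization constant, default 0.1)

equivalently (c/2) (sigma^2)^{-3/2} in d mu d sigma^2.  The marginal
likelihood of a block of n observations with centered sum of squares SS is
closed form:

    L(S) = (c/2) (2 pi)^{-(n-1)/2} n^{-1/2} Gamma(n/2) (SS/2)^{-n/2}

Under the non-marker model all samples form one block; under the marker
model each class is its own block (one factor of c per block).  With prior
marker probability pi the feature posterior is

    P(marker | data) = pi m1 / (pi m1 + (1 - pi) m0).

The posterior is a monotone function of the variance-ratio effect size

    a(m) = sigma_hat_total^2 / (sigma_hat_0^{2 w0} sigma_hat_1^{2 w1}),

the ratio of the total sample variance to the weighted geometric mean of
the class-conditioned variances (MLE variances, weights w_y = n_y / n).
a(m) converges to 1 for non-markers and grows with distributional
difference.

Selection rules: minimal-risk OBF keeps posteriors above 1 - alpha;
FDR-OBF keeps the largest posterior-sorted prefix whose mean (1 - posterior)
stays below alpha, bounding the sample-conditioned FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

__all__ = [
    "ObfConfig",
    "ObfResult",
    "StructurePosterior",
    "block_log_marginal",
    "block_log_marginal_stats",
    "marker_posterior",
    "am_statistic",
    "am_threshold",
    "select_minimal_risk",
    "select_fdr_obf",
    "marker_count_moments",
    "joint_posterior",
    "structured_obf",
    "obf_scan",
    "STRUCTURES",
    "STRUCTURE_PRIORS",
]


@dataclass(frozen=True)
class ObfConfig:
    """Priors of the OBF model.

    prior_marker : prior probability that a feature is a marker.
    norm_const   : normalization constant c of the improper parameter prior
                   (one factor per Gaussian block).
    alpha        : FDR level used by the selection rules.
    """

    prior_marker: float = 0.5
    norm_const: float = 0.1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.prior_marker < 1:
            raise ValueError("prior_marker must be in (0, 1)")
        if self.norm_const <= 0:
            raise ValueError("norm_const must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ObfResult:
    """Per-feature marker posterior and effect size."""

    posterior: float
    am: float
    log_m0: float
    log_m1: float


@dataclass
class StructurePosterior:
    """Posterior over the four group-partition structures (see structured_obf)."""

    posteriors: dict[str, float]
    log_marginals: dict[str, float]
    group_means: dict[str, float]
    ffpe_ineffective: bool

    @property
    def map_structure(self) -> str:
        return max(self.posteriors, key=self.posteriors.get)


def block_log_marginal_stats(n: int, ss: float, config: ObfConfig = ObfConfig()) -> float:
    """Log marginal likelihood of one Gaussian block from sufficient statistics.

    ``n`` is the block size (>= 2) and ``ss`` the sum of squared deviations
    from the block mean (> 0).
    """
    if n < 2:
        raise ValueError(f"block needs at least 2 observations, got {n}")
    if ss <= 0:
        raise ValueError(
            "degenerate block (zero sum of squared deviations); the improper "
            "marginal diverges for constant data"
        )
    c = config.norm_const
    return (
        np.log(c / 2.0)
        - (n - 1) / 2.0 * np.log(2.0 * np.pi)
        - 0.5 * np.log(n)
        + gammaln(n / 2.0)
        - n / 2.0 * np.log(ss / 2.0)
    )


def block_log_marginal(x: np.ndarray, config: ObfConfig = ObfConfig()) -> float:
    """Log marginal likelihood of one Gaussian data block."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"block needs at least 2 observations, got {n}")
    ss = float(np.sum((x - x.mean()) ** 2))
    return block_log_marginal_stats(n, ss, config)


def am_statistic(x0: np.ndarray, x1: np.ndarray) -> float:
    """Variance-ratio effect size a(m).

    Total MLE variance over the sample-size-weighted geometric mean of the
    class-conditioned MLE variances; equals 1 in expectation-free terms when
    the classes share one distribution, larger for markers.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    n0, n1 = x0.size, x1.size
    n = n0 + n1
    pooled = np.concatenate([x0, x1])
    v_tot = float(np.var(pooled))  # MLE (biased) variance
    v0 = float(np.var(x0))
    v1 = float(np.var(x1))
    if v0 <= 0 or v1 <= 0 or v_tot <= 0:
        raise ValueError("degenerate variance in a(m)")
    return v_tot / (v0 ** (n0 / n) * v1 ** (n1 / n))


def _log_odds_stats(
    n0: int, ss0: float, n1: int, ss1: float, ss_tot: float, config: ObfConfig
) -> tuple[float, float, float]:
    log_m1 = block_log_marginal_stats(n0, ss0, config) + block_log_marginal_stats(
        n1, ss1, config
    )
    log_m0 = block_log_marginal_stats(n0 + n1, ss_tot, config)
    pi = config.prior_marker
    log_odds = np.log(pi) + log_m1 - np.log1p(-pi) - log_m0
    return log_odds, log_m0, log_m1


def _posterior_from_log_odds(log_odds: float) -> float:
    # logistic in the log-domain; stable for very large |log_odds|
    if log_odds >= 0:
        return 1.0 / (1.0 + np.exp(-log_odds))
    e = np.exp(log_odds)
    return e / (1.0 + e)


def marker_posterior(
    x0: np.ndarray, x1: np.ndarray, config: ObfConfig = ObfConfig()
) -> ObfResult:
    """Posterior probability that a feature is a two-class marker."""
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    for name, x in (("class 0", x0), ("class 1", x1)):
        if x.size < 2:
            raise ValueError(f"{name} needs at least 2 observations")
        if np.sum((x - x.mean()) ** 2) <= 0:
            raise ValueError(f"degenerate variance in block {name}")
    pooled = np.concatenate([x0, x1])
    ss_tot = float(np.sum((pooled - pooled.mean()) ** 2))
    ss0 = float(np.sum((x0 - x0.mean()) ** 2))
    ss1 = float(np.sum((x1 - x1.mean()) ** 2))
    log_odds, log_m0, log_m1 = _log_odds_stats(
        x0.size, ss0, x1.size, ss1, ss_tot, config
    )
    return ObfResult(
        posterior=_posterior_from_log_odds(log_odds),
        am=am_statistic(x0, x1),
        log_m0=log_m0,
        log_m1=log_m1,
    )


def am_threshold(
    n0: int,
    n1: int,
    target_posterior: float,
    config: ObfConfig = ObfConfig(),
    total_variance: float = 1.0,
) -> float:
    """The a(m) value at which the marker posterior equals ``target_posterior``.

    The total (MLE) sample variance is held at ``total_variance`` and the
    class-conditional variances are assumed equal, so the between-class mean
    shift carries the whole effect; a(m) then equals total variance over
    within-class variance.  Solved by bracketed root finding to
    |posterior - target| < 1e-10.
    """
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs at least 2 observations")
    if not 0 < target_posterior < 1:
        raise ValueError("target posterior must be in (0, 1)")
    n = n0 + n1

    def posterior_at(am: float) -> float:
        v_within = total_variance / am
        ss0 = n0 * v_within
        ss1 = n1 * v_within
        ss_tot = n * total_variance
        log_odds, _, _ = _log_odds_stats(n0, ss0, n1, ss1, ss_tot, config)
        return _posterior_from_log_odds(log_odds)

    lo, hi = 1.0, 100.0
    f_lo = posterior_at(lo) - target_posterior
    f_hi = posterior_at(hi) - target_posterior
    if f_lo * f_hi > 0:
        raise ValueError(
            f"target {target_posterior} not attainable for a(m) in [1, 100]: "
            f"posterior ranges over [{posterior_at(lo):.6g}, {posterior_at(hi):.6g}]"
        )
    return float(
        brentq(lambda a: posterior_at(a) - target_posterior, lo, hi, xtol=1e-12)
    )


def select_minimal_risk(posteriors: np.ndarray, alpha: float) -> np.ndarray:
    """Indices of features with posterior above 1 - alpha."""
    p = np.asarray(posteriors, dtype=float)
    _check_probs(p)
    return np.flatnonzero(p > 1.0 - alpha)


def select_fdr_obf(posteriors: np.ndarray, alpha: float) -> np.ndarray:
    """Largest posterior-sorted prefix whose mean error (1 - posterior) <= alpha.

    The returned set's expected (sample-conditioned) FDR is the mean of
    1 - posterior over the set.  Indices are returned in descending-posterior
    order; empty if even the single best feature exceeds alpha.
    """
    p = np.asarray(posteriors, dtype=float)
    _check_probs(p)
    if p.size == 0:
        return np.array([], dtype=int)
    order = np.argsort(-p, kind="stable")
    err = 1.0 - p[order]
    mean_err = np.cumsum(err) / np.arange(1, p.size + 1)
    ok = np.flatnonzero(mean_err <= alpha)
    if ok.size == 0:
        return np.array([], dtype=int)
    return order[: ok[-1] + 1]


def marker_count_moments(posteriors: np.ndarray) -> tuple[float, float]:
    """Mean and sd of the number of markers, treating features independently."""
    p = np.asarray(posteriors, dtype=float)
    _check_probs(p)
    mean = float(np.sum(p))
    sd = float(np.sqrt(np.sum(p * (1.0 - p))))
    return mean, sd


def joint_posterior(per_cancer_posteriors: np.ndarray) -> np.ndarray:
    """Per-feature probability of being a marker in every cancer (independence)."""
    p = np.asarray(per_cancer_posteriors, dtype=float)
    _check_probs(p)
    if p.ndim == 1:
        return p.copy()
    return np.prod(p, axis=1)


# Structures over the three (preparation, lesion) groups:
# FN = frozen normal, FT = frozen tumor, PT = FFPE (paraffin) tumor.
STRUCTURES: dict[str, tuple[tuple[str, ...], ...]] = {
    "A": (("FN", "FT", "PT"),),          # no differentiation
    "B": (("FN", "FT"), ("PT",)),        # frozen vs FFPE
    "C": (("FT", "PT"), ("FN",)),        # tumor vs normal
    "D": (("FN", "PT"), ("FT",)),        # frozen tumor apart
}
STRUCTURE_PRIORS: dict[str, float] = {"A": 0.5, "B": 0.5 / 3, "C": 0.5 / 3, "D": 0.5 / 3}


def structured_obf(
    x_fn: np.ndarray,
    x_ft: np.ndarray,
    x_pt: np.ndarray,
    config: ObfConfig = ObfConfig(),
) -> StructurePosterior:
    """Posterior over the four partition structures of (FN, FT, PT) groups.

    Structure A pools all three groups; B separates frozen from FFPE; C
    separates tumor from normal; D isolates frozen tumor.  A mone whose MAP
    structure is B with the frozen-tumor and FFPE-tumor means on opposite
    sides of the frozen-normal mean is flagged ineffective for tumor/normal
    discrimination (the apparent effect is a preparation artifact).
    """
    groups = {
        "FN": np.asarray(x_fn, dtype=float),
        "FT": np.asarray(x_ft, dtype=float),
        "PT": np.asarray(x_pt, dtype=float),
    }
    for name, x in groups.items():
        if x.size < 2:
            raise ValueError(f"group {name} needs at least 2 observations")
        if np.sum((x - x.mean()) ** 2) <= 0:
            raise ValueError(f"degenerate variance in block {name}")

    log_marg: dict[str, float] = {}
    for s, blocks in STRUCTURES.items():
        total = 0.0
        for block in blocks:
            x = np.concatenate([groups[g] for g in block])
            total += block_log_marginal(x, config)
        log_marg[s] = total

    names = list(STRUCTURES)
    logs = np.array([np.log(STRUCTURE_PRIORS[s]) + log_marg[s] for s in names])
    post = np.exp(logs - logsumexp(logs))
    posteriors = dict(zip(names, post.tolist()))

    means = {g: float(x.mean()) for g, x in groups.items()}
    map_s = max(posteriors, key=posteriors.get)
    straddle = (means["FT"] - means["FN"]) * (means["PT"] - means["FN"]) < 0
    return StructurePosterior(
        posteriors=posteriors,
        log_marginals=log_marg,
        group_means=means,
        ffpe_ineffective=bool(map_s == "B" and straddle),
    )


def obf_scan(
    values: np.ndarray, labels: np.ndarray, config: ObfConfig = ObfConfig()
):
    """Marker posteriors for every column of a slides x features array.

    ``labels`` is a binary per-slide vector.  Degenerate features (constant
    within a block) get posterior NaN with a warning rather than aborting the
    scan.  Returns (posteriors, am_values) arrays.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    post = np.full(values.shape[1], np.nan)
    am = np.full(values.shape[1], np.nan)
    n_bad = 0
    for j in range(values.shape[1]):
        try:
            r = marker_posterior(values[~labels, j], values[labels, j], config)
        except ValueError:
            n_bad += 1
            continue
        post[j] = r.posterior
        am[j] = r.am
    if n_bad:
        warnings.warn(f"{n_bad} features skipped in OBF scan (degenerate variance)")
    return post, am


def _check_probs(p: np.ndarray) -> None:
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("posteriors must lie in [0, 1]")
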