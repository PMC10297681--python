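"""Conway-Maxwell-Poisson modelling of chainlink counts and code distances.

The chainlink-count and connectivity sets of the syndrome cohort are over-
dispersed relative to Poisson. They are modelled with the two-parameter
Conway-Maxwell-Poisson (CMP) family,

    P(n) = lambda^n / (n!)^nu / Z(lambda, nu),       n = 0, 1, 2, ...

with lambda, nu > 0. nu = 1 recovers the Poisson distribution with rate
lambda; nu < 1 gives over-dispersion, nu > 1 under-dispersion. The
normalizer Z has no closed form and is evaluated by truncated summation in
log space (connectivity values reach several thousand, far beyond naive
factorial range).

To compare two integer sets C_i, C_j the *code distance* is the excess
number of bits required to encode each set with the optimal code for the
other set rather than its own:

    D = sum_{n in C_i} log2(P_i(n)/P_j(n)) + sum_{n in C_j} log2(P_j(n)/P_i(n))

where P_i, P_j are the CMP maximum-likelihood fits of the two sets. D is
symmetric, zero for identical sets, and non-negative in expectation (it is
a plug-in estimate of n_i*KL(P_i||P_j) + n_j*KL(P_j||P_i)).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "CMPParams",
    "CountSet",
    "DistanceMatrix",
    "cmp_normalizer",
    "cmp_log_pmf",
    "fit_cmp",
    "code_distance",
    "distance_matrix",
]

#: Relative-term tolerance for normalizer truncation.
DEFAULT_TOL = 1e-12
#: Hard cap on the number of normalizer terms.
MAX_TERMS = 10**5
#: Log-probability floor (natural log) guarding underflowed pmf values.
LOG_FLOOR = -700.0


@dataclass(frozen=True)
class CMPParams:
    """Fitted or specified CMP parameters with the normalizer used."""

    lam: float
    nu: float
    log_z: float
    truncation_n: int
    log_likelihood: float | None = None
    converged: bool | None = None

    @classmethod
    def from_lam_nu(cls, lam: float, nu: float, tol: float = DEFAULT_TOL) -> "CMPParams":
        log_z, trunc = cmp_normalizer(lam, nu, tol=tol)
        return cls(lam=lam, nu=nu, log_z=log_z, truncation_n=trunc)


@dataclass(frozen=True)
class CountSet:
    """A labelled set (multiset) of non-negative integers."""

    label: str
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values):
            raise ValueError(f"{self.label!r}: negative values are not counts")


def cmp_normalizer(lam: float, nu: float, tol: float = DEFAULT_TOL,
                   max_terms: int = MAX_TERMS) -> tuple[float, int]:
    """log Z(lambda, nu) by truncated log-space summation.

    Terms are accumulated until past the mode and the next term falls below
    ``tol`` times the partial sum. For nu -> 0 the series approaches a
    geometric series and diverges unless lambda < 1; that region is guarded.
    """
    if lam <= 0 or nu <= 0:
        raise ValueError(f"CMP parameters must be positive, got lam={lam}, nu={nu}")
    if nu < 0.02 and lam >= 1.0:
        raise ValueError(
            f"normalizer diverges for nu->0 with lam>=1 (lam={lam}, nu={nu}): "
            "the series approaches a non-summable geometric limit"
        )
    log_lam = math.log(lam)
    log_partial = 0.0  # term n=0 is 1
    log_term = 0.0
    log_fact = 0.0
    log_tol = math.log(tol)
    for n in range(1, max_terms + 1):
        log_fact += math.log(n)
        prev = log_term
        log_term = n * log_lam - nu * log_fact
        log_partial = np.logaddexp(log_partial, log_term)
        if log_term < prev and log_term < log_partial + log_tol:
            return float(log_partial), n
    raise ValueError(
        f"normalizer did not converge within {max_terms} terms "
        f"(lam={lam}, nu={nu}); parameters are in a near-divergent region"
    )


def cmp_log_pmf(n: int | np.ndarray, params: CMPParams) -> float | np.ndarray:
    """log P(n) = n log lambda - nu log n! - log Z, elementwise on arrays."""
    narr = np.asarray(n)
    if np.any(narr < 0):
        raise ValueError("CMP support is the non-negative integers")
    out = narr * math.log(params.lam) - params.nu * gammaln(narr + 1.0) - params.log_z
    if np.ndim(n) == 0:
        return float(out)
    return out


def _neg_log_likelihood(x: np.ndarray, values: np.ndarray) -> float:
    lam, nu = math.exp(x[0]), math.exp(x[1])
    try:
        log_z, _ = cmp_normalizer(lam, nu)
    except ValueError:
        return 1e12
    ll = float(np.sum(values * math.log(lam) - nu * gammaln(values + 1.0) - log_z))
    if not math.isfinite(ll):
        return 1e12
    return -ll


def fit_cmp(values: CountSet | "list[int]", max_iter: int = 500) -> CMPParams:
    """Maximum-likelihood CMP fit of an integer set.

    Optimizes over (log lambda, log nu) with a bounded quasi-Newton method
    from two starts — a moment-matched point (nu0 = mean/variance, lambda0 =
    mean^nu0) and the Poisson point (lambda = mean, nu = 1) — keeping the
    better likelihood. Deterministic for fixed input.
    """
    vals = np.asarray(values.values if isinstance(values, CountSet) else values,
                      dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 values to fit")
    if np.unique(vals).size < 2:
        raise ValueError("degenerate input: all values identical")
    m = float(vals.mean())
    v = float(vals.var(ddof=1))
    if m <= 0:
        raise ValueError("cannot fit all-zero data")
    nu0 = min(max(m / v, 1e-2), 1e2) if v > 0 else 1.0
    starts = [
        (nu0 * math.log(max(m, 1e-6)), math.log(nu0)),
        (math.log(m), 0.0),
    ]
    bounds = [(-30.0, 60.0), (math.log(1e-3), math.log(1e3))]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _neg_log_likelihood, np.array(x0), args=(vals,),
            method="L-BFGS-B", bounds=bounds, options={"maxiter": max_iter},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    if not math.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(f"CMP fit failed to find a finite likelihood: {best.message}")
    lam, nu = math.exp(best.x[0]), math.exp(best.x[1])
    log_z, trunc = cmp_normalizer(lam, nu)
    return CMPParams(lam=lam, nu=nu, log_z=log_z, truncation_n=trunc,
                     log_likelihood=-float(best.fun), converged=bool(best.success))


def _floored_log_pmf(vals: np.ndarray, params: CMPParams, label: str) -> np.ndarray:
    lp = np.asarray(cmp_log_pmf(vals, params))
    if np.any(lp < LOG_FLOOR):
        logger.warning("code_distance: %d underflowed probabilities for %s "
                       "floored at exp(%g)", int(np.sum(lp < LOG_FLOOR)), label, LOG_FLOOR)
        lp = np.maximum(lp, LOG_FLOOR)
    return lp


def code_distance(ci: CountSet, cj: CountSet,
                  fit_i: CMPParams | None = None, fit_j: CMPParams | None = None,
                  as_printed: bool = False) -> float:
    """Code distance in bits between two integer sets under their CMP fits.

    The default orientation measures *excess* bits (cross-coding cost minus
    own-coding cost), which is symmetric, exactly zero for identical sets
    and non-negative in expectation. ``as_printed=True`` flips the ratio
    orientation, negating the value.
    """
    fit_i = fit_i or fit_cmp(ci)
    fit_j = fit_j or fit_cmp(cj)
    vi = np.asarray(ci.values, dtype=float)
    vj = np.asarray(cj.values, dtype=float)
    ln2 = math.log(2.0)
    d = float(
        np.sum(_floored_log_pmf(vi, fit_i, ci.label) - _floored_log_pmf(vi, fit_j, ci.label))
        + np.sum(_floored_log_pmf(vj, fit_j, cj.label) - _floored_log_pmf(vj, fit_i, cj.label))
    ) / ln2
    return -d if as_printed else d


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise code-distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray  # shape (k, k); NaN marks an unavailable pair

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_tsv(self) -> str:
        """Upper-triangular rendering, one row per label."""
        lines = ["label\t" + "\t".join(self.labels)]
        for i, lab in enumerate(self.labels):
            cells = []
            for j in range(len(self.labels)):
                if j < i:
                    cells.append("")
                elif np.isnan(self.values[i, j]):
                    cells.append("na")
                else:
                    cells.append(f"{self.values[i, j]:.1f}")
            lines.append(lab + "\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"


def distance_matrix(sets: list[CountSet], as_printed: bool = False) -> DistanceMatrix:
    """All pairwise code distances between the given sets.

    Each set is fitted once; a pair whose fit fails is marked NaN
    (unavailable) rather than aborting the whole matrix.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    fits: list[CMPParams | None] = []
    for s in sets:
        try:
            fits.append(fit_cmp(s))
        except (ValueError, RuntimeError) as exc:
            logger.warning("fit failed for %s: %s", s.label, exc)
            fits.append(None)
    k = len(sets)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if fits[i] is None or fits[j] is None:
                out[i, j] = out[j, i] = math.nan
                continue
            d = code_distance(sets[i], sets[j], fits[i], fits[j], as_printed=as_printed)
            out[i, j] = out[j, i] = d
    return DistanceMatrix(labels=tuple(s.label for s in sets), values=out)
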