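"""Probabilistic acoustic niche regions and their pairwise overlap.

Each individual's calls in score space are modelled as draws from a
multivariate normal; the individual's *niche region* at level ``alpha`` is
the alpha-probability ellipsoid of that normal.  Parameters are uncertain,
so (mean, covariance) are sampled from the conjugate noninformative
posterior: covariance from an inverse-Wishart with ``n - 1`` degrees of
freedom and the sample sum-of-squares matrix as scale, and the mean, given
a covariance draw, normal around the sample mean with that covariance over
``n``.

The directional overlap ``P(i -> j)`` is the posterior-averaged probability
that a call generated by individual *i* lands inside individual *j*'s
niche region: per Monte-Carlo draw, a call is simulated from one posterior
draw of *i* and tested for membership in the region defined by one
posterior draw of *j*.  The aggregate ANO of a focal individual sums these
probabilities over all other individuals of its sample (range 0..n-1):
small values mean the individual occupies acoustic space nobody else uses.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("hootid.niche_overlap")

__all__ = [
    "NichePosterior", "OverlapMatrix", "AggregateANO",
    "fit_niche_posterior", "plugin_posterior", "region_membership",
    "pairwise_overlap", "overlap_matrix", "aggregate_ano",
    "select_niche_dims",
]

DEFAULT_ALPHA = 0.99
DEFAULT_N_MC = 10_000


@dataclass
class NichePosterior:
    """Posterior parameter draws for one individual's call distribution.

    ``mu``: (n_draws, d) mean draws; ``sigma``: (n_draws, d, d) covariance
    draws; ``chol``: their lower Cholesky factors (cached for sampling and
    Mahalanobis evaluation).
    """

    individual_id: str
    mu: np.ndarray
    sigma: np.ndarray
    chol: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    @property
    def dims(self) -> int:
        return self.mu.shape[1]


def fit_niche_posterior(calls, individual_id: str = "", n_draws: int = DEFAULT_N_MC,
                        seed=None) -> NichePosterior:
    """Sample the noninformative-conjugate posterior for one individual.

    ``calls`` is an (n, d) array of score vectors.  Requires ``n >= 2`` and
    ``n - 1 >= d`` (the inverse-Wishart needs that many degrees of freedom);
    ``n < d + 2`` is allowed but flagged, as the posterior is then barely
    proper.  Deterministic given ``seed`` (ints or a Generator).
    """
    X = np.atleast_2d(np.asarray(calls, dtype=float))
    n, d = X.shape
    if n < 2:
        raise ValueError("need >= 2 calls to fit a niche posterior")
    if n - 1 < d:
        raise ValueError(
            f"{n} calls support at most {n - 1} dimensions; got {d} "
            "(reduce dims)"
        )
    if n < d + 2:
        logger.warning("individual %r: only %d calls for %d dims; posterior "
                       "is barely proper", individual_id, n, d)
    xbar = X.mean(axis=0)
    S = (X - xbar).T @ (X - xbar)  # sum-of-squares scale matrix
    if d > 1 and np.linalg.matrix_rank(S) < d:
        raise ValueError(
            f"individual {individual_id!r}: singular sample covariance; "
            "use fewer dimensions"
        )
    rng = np.random.default_rng(seed)
    sigma = stats.invwishart.rvs(df=n - 1, scale=S, size=n_draws, random_state=rng)
    sigma = sigma.reshape(n_draws, d, d)
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n_draws, d))
    mu = xbar + np.einsum("nij,nj->ni", chol, z) / np.sqrt(n)
    return NichePosterior(individual_id=str(individual_id), mu=mu, sigma=sigma, chol=chol)


def plugin_posterior(mean, cov, individual_id: str = "") -> NichePosterior:
    """Degenerate 'posterior' concentrated on known (mean, covariance).

    Useful for plug-in overlap computations against analytic or quadrature
    references, and as the limit object of :func:`fit_niche_posterior`.
    """
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    chol = np.linalg.cholesky(cov)
    return NichePosterior(
        individual_id=str(individual_id),
        mu=mean[None, :], sigma=cov[None, :, :], chol=chol[None, :, :],
    )


def region_membership(x, mean, covariance, alpha: float = DEFAULT_ALPHA) -> bool:
    """Is ``x`` inside the alpha-level niche region of N(mean, covariance)?

    True iff the squared Mahalanobis distance of ``x`` does not exceed the
    alpha quantile of the chi-square distribution with ``d`` degrees of
    freedom — the region that contains a fraction ``alpha`` of the normal's
    probability mass.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    covariance = np.atleast_2d(np.asarray(covariance, dtype=float))
    if x.shape != mean.shape or covariance.shape != (x.size, x.size):
        raise ValueError("dimension mismatch between x, mean and covariance")
    diff = x - mean
    m2 = float(diff @ np.linalg.solve(covariance, diff))
    return m2 <= stats.chi2.ppf(alpha, df=x.size)


def _mahal2_batch(X, mu, chol):
    """Squared Mahalanobis distances for paired batches (n,d) vs (n,d,d)."""
    diff = X - mu
    y = np.linalg.solve(chol, diff[..., None])[..., 0]  # forward solve, lower-tri
    return np.einsum("ni,ni->n", y, y)


def pairwise_overlap(focal: NichePosterior, other: NichePosterior,
                     alpha: float = DEFAULT_ALPHA, n_mc: int = DEFAULT_N_MC,
                     seed=None) -> float:
    """Monte-Carlo directional overlap: P(call of focal in other's region).

    Per draw, one posterior draw of the focal yields a simulated call
    ``X ~ N(mu_f, Sigma_f)``; membership is tested against one posterior
    draw of the other's region at level ``alpha``; the estimate averages
    the ``n_mc`` indicator values.  Deterministic given ``seed``.
    """
    if focal.dims != other.dims:
        raise ValueError(f"dimension mismatch: {focal.dims} vs {other.dims}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    rng = np.random.default_rng(seed)
    i_f = rng.integers(0, focal.n_draws, size=n_mc)
    i_o = rng.integers(0, other.n_draws, size=n_mc)
    z = rng.standard_normal((n_mc, focal.dims))
    X = focal.mu[i_f] + np.einsum("nij,nj->ni", focal.chol[i_f], z)
    m2 = _mahal2_batch(X, other.mu[i_o], other.chol[i_o])
    thresh = stats.chi2.ppf(alpha, df=focal.dims)
    return float(np.mean(m2 <= thresh))


@dataclass
class OverlapMatrix:
    """Directional overlap probabilities; rows = focal (call producer),
    columns = other (niche owner).  Diagonal is NaN (undefined)."""

    ids: list
    values: np.ndarray
    alpha: float
    n_mc: int
    seed: object

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# alpha: {self.alpha}\n# n_mc: {self.n_mc}\n"
                     f"# seed: {self.seed}\n# dims: {self.values.shape}\n")
            self.to_frame().to_csv(fh, index_label="focal")


@dataclass
class AggregateANO:
    individual_id: str
    ano: float


def _pair_seed(seed, focal_id: str, other_id: str) -> np.random.SeedSequence:
    # derived from the ids, not the pair's position, so permuting the
    # individual order permutes the matrix without changing any value
    base = 0 if seed is None else int(seed)
    return np.random.SeedSequence(
        entropy=[base, zlib.crc32(str(focal_id).encode()),
                 zlib.crc32(str(other_id).encode())]
    )


def overlap_matrix(posteriors, alpha: float = DEFAULT_ALPHA,
                   n_mc: int = DEFAULT_N_MC, seed=None) -> OverlapMatrix:
    """All ordered pairwise overlaps among a sample of individuals.

    ``posteriors`` is a sequence of :class:`NichePosterior` with distinct
    ids and equal dims.  Reproducible given ``seed``; each ordered pair gets
    an independent RNG stream derived from (seed, focal id, other id).
    """
    posteriors = list(posteriors)
    if len(posteriors) < 2:
        raise ValueError("need >= 2 individuals")
    ids = [p.individual_id for p in posteriors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids among posteriors")
    n = len(posteriors)
    values = np.full((n, n), np.nan)
    for i, focal in enumerate(posteriors):
        for j, other in enumerate(posteriors):
            if i == j:
                continue
            values[i, j] = pairwise_overlap(
                focal, other, alpha=alpha, n_mc=n_mc,
                seed=_pair_seed(seed, focal.individual_id, other.individual_id),
            )
    return OverlapMatrix(ids=ids, values=values, alpha=alpha, n_mc=n_mc, seed=seed)


def aggregate_ano(m: OverlapMatrix) -> list:
    """Aggregate acoustic niche overlap per focal individual.

    Sum of the focal's row (the focal producing calls, every other
    individual providing the region); range 0 to n-1.
    """
    out = []
    for i, ind in enumerate(m.ids):
        row = np.delete(m.values[i], i)
        out.append(AggregateANO(individual_id=ind, ano=float(np.nansum(row))))
    return out


def select_niche_dims(scores, labels=None, max_dims: int | None = None,
                      var_floor: float = 1e-8) -> int:
    """Default niche dimensionality for a sample of individuals.

    Keeps the leading PC components with explained variance above
    ``var_floor``, capped so every individual has more calls than
    dimensions (``dims <= min call count - 1``, the inverse-Wishart
    propriety limit).  The applied cap is logged: a full 11-dimensional
    normal on ~25 calls per individual is close to singular, so a guarded
    default matters.
    """
    if hasattr(scores, "explained_variance"):
        ev = np.asarray(scores.explained_variance)
        if labels is None:
            labels = scores.labels
        p = ev.size
        informative = int(np.sum(ev > var_floor))
    else:
        X = np.asarray(scores, dtype=float)
        p = X.shape[1]
        informative = int(np.sum(X.var(axis=0, ddof=1) > var_floor))
    counts = pd.Series(np.asarray(labels)).value_counts()
    cap = int(counts.min()) - 1
    dims = max(1, min(informative, cap, p if max_dims is None else max_dims))
    if dims < informative:
        logger.info("niche dims capped at %d (informative components: %d, "
                    "smallest call count: %d)", dims, informative, counts.min())
    return dims
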