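"""Sample-wide and per-individual vocal-individuality metrics.

Metrics computed in decorrelated (PC) score space:

HS — Beecher's information statistic.  Per component the identity
    information is ``0.5 * log2(SS_total / SS_within)`` bits, where the sums
    of squares come from a one-way decomposition of the component's scores
    by individual; summing over components gives the call's total identity
    information.  ``2**HS`` estimates how many individuals the signal can
    distinguish ("unique signatures").  The default report sums only
    components whose individual effect is significant (ANOVA p < 0.05); the
    all-components sum is always carried alongside, and a mean-squares
    (df-corrected) estimator is available as an alternative.

DS — discrimination score: percentage of calls assigned to the correct
    individual by linear discriminant analysis under leave-one-out
    cross-validation.  IVS = DS / (100 / n) rescales DS by the chance
    assignment rate so that samples with different numbers of individuals
    become comparable.

WID / BID — per-individual variation components: the mean Euclidean
    distance of an individual's calls to its own centroid (within), and the
    distance from the population centroid (mean over *all* calls) to the
    individual's centroid (between).  These are the statistical units for
    group comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

logger = logging.getLogger("hootid.identity_metrics")

__all__ = [
    "AnovaDecomposition", "HSResult", "DSResult", "IndividualVariation",
    "anova_decomposition", "calc_hs", "signatures_from_hs", "calc_ds",
    "calc_ivs", "calc_wid", "calc_bid", "individual_variation",
]


def _scores_and_labels(scores, labels=None):
    """Accept a PCScores, DataFrame or ndarray; pull labels off the index
    when not given explicitly."""
    if hasattr(scores, "scores"):  # PCScores
        if labels is None:
            labels = scores.labels
        scores = scores.scores
    if isinstance(scores, pd.DataFrame):
        if labels is None and "individual_id" in (scores.index.names or []):
            labels = scores.index.get_level_values("individual_id")
        scores = scores.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and labels is not None and len(labels) == X.shape[1]:
        X = X.T
    if labels is None:
        raise ValueError("labels are required when scores carry no index")
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError(f"{X.shape[0]} rows but {labels.shape[0]} labels")
    return X, labels


class AnovaDecomposition(NamedTuple):
    ss_total: float
    ss_within: float
    ss_among: float
    f_stat: float
    p_value: float
    df_among: int
    df_within: int


def anova_decomposition(values, labels) -> AnovaDecomposition:
    """One-way fixed-effects sums-of-squares decomposition by individual.

    ``ss_total`` is about the grand mean, ``ss_within`` about each
    individual's own mean; ``F = (ss_among/df_among) / (ss_within/df_within)``
    with ``df_among = k - 1`` and ``df_within = N - k``.  Degenerate inputs
    (all values equal) return F = 0, p = 1 rather than NaN.
    """
    x = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels)
    groups, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need >= 2 individuals")
    if counts.min() < 2:
        small = groups[counts < 2].tolist()
        raise ValueError(f"each individual needs >= 2 calls; too few for {small}")
    grand = x.mean()
    ss_total = float(np.sum((x - grand) ** 2))
    group_means = np.bincount(inverse, weights=x) / counts
    ss_within = float(np.sum((x - group_means[inverse]) ** 2))
    ss_among = ss_total - ss_within
    df_among = len(groups) - 1
    df_within = x.size - len(groups)
    if ss_total == 0.0:
        logger.warning("degenerate ANOVA: all values identical")
        return AnovaDecomposition(0.0, 0.0, 0.0, 0.0, 1.0, df_among, df_within)
    if ss_within == 0.0:
        return AnovaDecomposition(ss_total, 0.0, ss_among, math.inf, 0.0,
                                  df_among, df_within)
    f_stat = (ss_among / df_among) / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_among, df_within))
    return AnovaDecomposition(ss_total, ss_within, ss_among, float(f_stat), p,
                              df_among, df_within)


@dataclass
class HSResult:
    per_component_hs: np.ndarray
    per_component_p: np.ndarray
    hs_all: float
    hs_significant: float
    hs_selected: float
    n_signatures: int
    variant: str
    estimator: str


def calc_hs(scores, labels=None, variant: str = "significant_only",
            estimator: str = "ss_ratio", alpha: float = 0.05) -> HSResult:
    """Beecher's information statistic over all score components.

    Parameters
    ----------
    scores : PCScores, DataFrame or array
        Decorrelated per-call scores (components in columns).
    variant : {'significant_only', 'all'}
        Which per-component sum is reported as ``hs_selected`` (and drives
        ``n_signatures``); both sums are always returned.
    estimator : {'ss_ratio', 'ms_ratio'}
        ``ss_ratio`` is the plain sums-of-squares ratio
        ``0.5*log2(SS_total/SS_within)``; ``ms_ratio`` uses df-corrected
        mean squares ``0.5*log2((SS_total/(N-1)) / (SS_within/(N-k)))``.

    Components whose scores are numerically constant (a rotation artefact
    when rows <= columns) carry no information and contribute 0 bits.
    """
    if variant not in ("significant_only", "all"):
        raise ValueError(f"unknown variant {variant!r}")
    if estimator not in ("ss_ratio", "ms_ratio"):
        raise ValueError(f"unknown estimator {estimator!r}")
    X, labels = _scores_and_labels(scores, labels)
    n, p = X.shape
    hs = np.zeros(p)
    pvals = np.ones(p)
    total_scale = float(np.sum((X - X.mean(axis=0)) ** 2)) / max(p, 1)
    for c in range(p):
        dec = anova_decomposition(X[:, c], labels)
        if dec.ss_total <= 1e-12 * max(total_scale, 1.0):
            hs[c] = 0.0  # degenerate component: no variance, no information
            pvals[c] = 1.0
            continue
        if dec.ss_within == 0.0:
            raise ValueError(
                f"component {c}: within-individual sum of squares is 0 "
                "(duplicated calls imply infinite information)"
            )
        if estimator == "ss_ratio":
            ratio = dec.ss_total / dec.ss_within
        else:
            ratio = (dec.ss_total / (n - 1)) / (dec.ss_within / dec.df_within)
        hs[c] = 0.5 * math.log2(ratio)
        pvals[c] = dec.p_value
    hs_all = float(hs.sum())
    hs_sig = float(hs[pvals < alpha].sum())
    hs_selected = hs_sig if variant == "significant_only" else hs_all
    return HSResult(
        per_component_hs=hs, per_component_p=pvals, hs_all=hs_all,
        hs_significant=hs_sig, hs_selected=hs_selected,
        n_signatures=signatures_from_hs(max(hs_selected, 0.0)),
        variant=variant, estimator=estimator,
    )


def signatures_from_hs(hs: float) -> int:
    """Signature capacity implied by an information value: ``floor(2**hs)``.

    The floor (not rounding) is the convention that stays consistent with
    interpreting 2**HS as "how many individuals can be told apart".
    """
    if hs < 0:
        raise ValueError(f"hs must be >= 0, got {hs}")
    return int(math.floor(2.0 ** hs))


@dataclass
class DSResult:
    ds_percent: float
    n_individuals: int
    chance_percent: float
    ivs: float
    confusion: pd.DataFrame
    priors: str


def calc_ds(scores, labels=None, priors: str = "proportional",
            n_components: int | None = None) -> DSResult:
    """Discrimination score: leave-one-out LDA classification accuracy.

    For each call an LDA (shared pooled within-class covariance, class-mean
    discriminants) is fit on all other calls and the held-out call is
    classified.  ``priors='proportional'`` weights classes by their call
    counts in the full sample (the behaviour of the classic R routine);
    ``'uniform'`` gives every individual equal prior weight.
    ``n_components`` truncates the score columns, the documented fallback
    when the pooled covariance is singular.
    """
    if priors not in ("proportional", "uniform"):
        raise ValueError(f"unknown priors {priors!r}")
    X, labels = _scores_and_labels(scores, labels)
    if n_components is not None:
        X = X[:, :n_components]
    classes, y, counts = np.unique(labels, return_inverse=True, return_counts=True)
    k = len(classes)
    if k < 2:
        raise ValueError("need >= 2 individuals")
    if counts.min() < 2:
        raise ValueError("each individual needs >= 2 calls for leave-one-out LDA")
    # pooled within-class covariance must be invertible on the used columns
    centered = X - np.array([X[y == g].mean(axis=0) for g in range(k)])[y]
    pooled = centered.T @ centered / (X.shape[0] - k)
    eig = np.linalg.eigvalsh(pooled)
    if eig[0] <= 1e-10 * max(eig[-1], 1e-30):
        raise ValueError(
            "pooled within-class covariance is singular; truncate the score "
            "space with n_components"
        )
    prior_vec = counts / counts.sum() if priors == "proportional" else np.full(k, 1.0 / k)
    n = X.shape[0]
    pred = np.empty(n, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        lda = LinearDiscriminantAnalysis(solver="svd", priors=prior_vec)
        lda.fit(X[train], y[train])
        pred[i] = lda.predict(X[i][None, :])[0]
    correct = int(np.sum(pred == y))
    ds = 100.0 * correct / n
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for truth, guess in zip(y, pred):
        confusion.iloc[truth, guess] += 1
    return DSResult(
        ds_percent=ds, n_individuals=k, chance_percent=100.0 / k,
        ivs=calc_ivs(ds, k), confusion=confusion, priors=priors,
    )


def calc_ivs(ds_percent: float, n_individuals: int) -> float:
    """Index of vocal stereotypy: DS over the chance rate ``100/n``.

    Equals ``ds_percent * n_individuals / 100``, reported to 2 decimals.
    """
    if n_individuals < 2:
        raise ValueError(f"n_individuals must be >= 2, got {n_individuals}")
    if not 0.0 <= ds_percent <= 100.0:
        raise ValueError(f"ds_percent must be in [0, 100], got {ds_percent}")
    return round(ds_percent * n_individuals / 100.0, 2)


@dataclass
class IndividualVariation:
    individual_id: str
    wid: float = math.nan
    bid: float = math.nan


def calc_wid(scores, labels=None) -> list:
    """Mean within-individual distance per individual.

    Each individual's calls are reduced to Euclidean distances to the
    individual's centroid; WID is their mean.  Individuals with one call
    are skipped with a warning (their within-variation is undefined).
    """
    X, labels = _scores_and_labels(scores, labels)
    out = []
    for ind in pd.unique(labels):
        pts = X[labels == ind]
        if pts.shape[0] < 2:
            logger.warning("individual %r has < 2 calls; WID skipped", ind)
            continue
        centroid = pts.mean(axis=0)
        wid = float(np.linalg.norm(pts - centroid, axis=1).mean())
        out.append(IndividualVariation(individual_id=str(ind), wid=wid))
    return out


def calc_bid(scores, labels=None) -> list:
    """Between-individual distance per individual.

    The population centroid is the mean over *all calls* (so individuals
    with many calls pull it harder), and BID is the distance from that
    centroid to each individual's own centroid.
    """
    X, labels = _scores_and_labels(scores, labels)
    pop_centroid = X.mean(axis=0)
    out = []
    for ind in pd.unique(labels):
        centroid = X[labels == ind].mean(axis=0)
        out.append(IndividualVariation(
            individual_id=str(ind),
            bid=float(np.linalg.norm(centroid - pop_centroid)),
        ))
    return out


def individual_variation(scores, labels=None) -> pd.DataFrame:
    """WID and BID combined, one row per individual (index individual_id)."""
    wid = {v.individual_id: v.wid for v in calc_wid(scores, labels)}
    bid = {v.individual_id: v.bid for v in calc_bid(scores, labels)}
    ids = list(bid)
    return pd.DataFrame(
        {"wid": [wid.get(i, math.nan) for i in ids],
         "bid": [bid[i] for i in ids]},
        index=pd.Index(ids, name="individual_id"),
    )
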