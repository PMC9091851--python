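"""Trajectory grouping engines: K-means, complete-linkage hclust, GBTM.

Three ways of sorting RPPs into developmental groups:

* restarted Lloyd K-means on complete four-point profiles;
* agglomerative complete-linkage clustering of a trajectory distance matrix
  (DTW / edit distance / LCSS), with dendrogram cutting at a chosen k;
* group-based trajectory modelling (GBTM): a k-component mixture of
  polynomial mean curves over the quadrant index with Gaussian residuals of
  shared variance, fitted by EM from many random starts and selected by
  AIC, BIC and leave-one-out cross-validation error (CVE).

K-means and GBTM require complete RPPs; incomplete profiles belong to the
distance-based route.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import InvalidInputError, RPPTrajectory
from .distances import DistanceMatrix

__all__ = [
    "GroupingResult",
    "Dendrogram",
    "GBTMModel",
    "kmeans_cluster",
    "hclust_complete",
    "cut_tree",
    "fit_gbtm",
    "gbtm_cve",
    "gbtm_select",
]


@dataclass(frozen=True)
class GroupingResult:
    """Element -> group labelling produced by one method at one k."""

    method: str
    k: int
    labels: dict[str, int]
    objective: float
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not (1 <= g <= self.k) for g in self.labels.values()):
            raise InvalidInputError("labels must lie in 1..k")

    def labels_array(self, ids: Sequence[str] | None = None) -> np.ndarray:
        ids = list(ids) if ids is not None else sorted(self.labels)
        return np.array([self.labels[i] for i in ids], dtype=int)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over a set of leaves.

    ``merges`` is an (n-1, 4) linkage array in scipy convention: each row
    joins two clusters (indices < n are leaves) at a non-decreasing height.
    """

    merges: np.ndarray
    leaf_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        z = np.asarray(self.merges, dtype=float)
        n = len(self.leaf_ids)
        if z.shape != (n - 1, 4):
            raise InvalidInputError("need n-1 merges for n leaves")
        if np.any(np.diff(z[:, 2]) < -1e-9):
            raise InvalidInputError("merge heights must be non-decreasing")
        object.__setattr__(self, "merges", z)

    def to_newick(self) -> str:
        """Nested-text rendering of the merge tree for audit."""
        n = len(self.leaf_ids)
        nodes: dict[int, str] = {i: self.leaf_ids[i] for i in range(n)}
        for idx, (a, b, h, _) in enumerate(self.merges):
            nodes[n + idx] = f"({nodes[int(a)]},{nodes[int(b)]}):{h:.6g}"
        return nodes[n + len(self.merges) - 1] + ";"


def _require_complete(rpps: Sequence[RPPTrajectory]) -> tuple[np.ndarray, list[str]]:
    bad = [t.element_id for t in rpps if not t.is_complete]
    if bad:
        raise InvalidInputError(
            f"method requires complete 4-point RPPs; incomplete: {bad}"
        )
    ids = [t.element_id for t in rpps]
    if len(set(ids)) != len(ids):
        raise InvalidInputError("duplicate element ids")
    return np.array([t.as_array() for t in rpps]), ids


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel groups 1..k in order of first appearance (stable tie-break)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, g in enumerate(raw):
        if g not in mapping:
            mapping[g] = len(mapping) + 1
        out[i] = mapping[g]
    return out


# ---------------------------------------------------------------------------
# K-means
# ---------------------------------------------------------------------------


def kmeans_cluster(
    rpps: Sequence[RPPTrajectory],
    k: int,
    n_restarts: int = 100,
    seed: int | None = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GroupingResult:
    """Lloyd K-means on complete RPP 4-vectors, best of ``n_restarts`` starts.

    Each restart initializes centroids at k distinct profiles chosen at
    random, iterates assignment/update until the within-cluster sum of
    squares (WSS) stops improving, and asserts that the WSS never increases
    along the way.  The labelling with the smallest WSS across restarts wins;
    empty clusters are re-seeded at the point farthest from its centroid.
    """
    X, ids = _require_complete(rpps)
    n = len(X)
    if n < k:
        raise InvalidInputError(f"need at least k={k} trajectories, got {n}")
    rng = np.random.default_rng(seed)
    best_wss = np.inf
    best_labels = None
    for _ in range(n_restarts):
        centroids = X[rng.choice(n, size=k, replace=False)].copy()
        prev_wss = np.inf
        for _ in range(max_iter):
            d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            labels = d2.argmin(axis=1)
            # re-seed empty clusters at the worst-fitted point
            for g in range(k):
                if not (labels == g).any():
                    far = d2[np.arange(n), labels].argmax()
                    centroids[g] = X[far]
                    labels[far] = g
            wss = float(((X - centroids[labels]) ** 2).sum())
            assert wss <= prev_wss + 1e-7, "Lloyd objective increased"
            if prev_wss - wss < tol:
                prev_wss = wss
                break
            prev_wss = wss
            for g in range(k):
                centroids[g] = X[labels == g].mean(axis=0)
        # one final consistent assignment + objective
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        wss = float(d2[np.arange(n), labels].sum())
        if wss < best_wss - 1e-12:
            best_wss = wss
            best_labels = labels
    final = _canonical_labels(best_labels + 1)
    return GroupingResult(
        method="kmeans",
        k=k,
        labels=dict(zip(ids, (int(g) for g in final))),
        objective=best_wss,
        seed=seed,
        params={"n_restarts": n_restarts},
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------


def hclust_complete(dm: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering with complete (maximum) linkage."""
    condensed = squareform(dm.values, checks=True)
    z = hierarchy.linkage(condensed, method="complete")
    return Dendrogram(merges=z, leaf_ids=dm.ids)


def cut_tree(dendrogram: Dendrogram, k: int, method: str = "hclust") -> GroupingResult:
    """Labels from cutting the dendrogram into ``k`` clusters."""
    n = len(dendrogram.leaf_ids)
    if not (1 <= k <= n):
        raise InvalidInputError(f"k must lie in [1, {n}]")
    raw = hierarchy.cut_tree(dendrogram.merges, n_clusters=k).ravel() + 1
    labels = _canonical_labels(raw)
    height = float(dendrogram.merges[n - k - 1, 2]) if k < n else 0.0
    return GroupingResult(
        method=method,
        k=k,
        labels=dict(zip(dendrogram.leaf_ids, (int(g) for g in labels))),
        objective=height,
    )


# ---------------------------------------------------------------------------
# Group-based trajectory modelling
# ---------------------------------------------------------------------------

_QUAD_INDEX = np.arange(1.0, 5.0)
_SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class GBTMModel:
    """Fitted polynomial-mixture trajectory model.

    ``coefficients[g]`` are ascending polynomial coefficients of group g's
    mean curve over the quadrant index (1..4); residuals are Gaussian with a
    single shared standard deviation ``sigma``.  Components are ordered by
    increasing mean fitted porosity.
    """

    k: int
    degree: int
    coefficients: np.ndarray  # (k, degree+1)
    sigma: float
    weights: np.ndarray  # (k,)
    posteriors: np.ndarray  # (n, k)
    ids: tuple[str, ...]
    log_lik: float
    aic: float
    bic: float
    cve: float | None = None
    seed: int | None = None
    n_em_iter: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidInputError("sigma must be positive")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-6):
            raise InvalidInputError("mixing weights must sum to 1")
        if not np.allclose(self.posteriors.sum(axis=1), 1.0, atol=1e-6):
            raise InvalidInputError("posteriors must sum to 1 per element")

    @property
    def n_parameters(self) -> int:
        return self.k * (self.degree + 1) + (self.k - 1) + 1

    def predicted_curves(self) -> np.ndarray:
        """Group mean curves evaluated at quadrant index 1..4, shape (k, 4)."""
        X = np.vander(_QUAD_INDEX, self.degree + 1, increasing=True)
        return self.coefficients @ X.T

    def hard_labels(self) -> dict[str, int]:
        return {
            i: int(g + 1) for i, g in zip(self.ids, self.posteriors.argmax(axis=1))
        }

    def to_grouping(self) -> GroupingResult:
        return GroupingResult(
            method="gbtm",
            k=self.k,
            labels=self.hard_labels(),
            objective=self.log_lik,
            seed=self.seed,
            params={"degree": self.degree},
        )


def _log_gauss(Y: np.ndarray, curves: np.ndarray, sigma: float) -> np.ndarray:
    """(n, k) log density of each profile under each group curve."""
    resid2 = ((Y[:, None, :] - curves[None, :, :]) ** 2).sum(axis=2)
    d = Y.shape[1]
    return -0.5 * (resid2 / sigma**2 + d * np.log(2 * np.pi * sigma**2))


def _kpp_seed(Y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ style seed rows of Y."""
    n = len(Y)
    idx = [int(rng.integers(n))]
    for _ in range(k - 1):
        d2 = np.min(
            ((Y[:, None, :] - Y[idx][None, :, :]) ** 2).sum(axis=2), axis=1
        )
        total = d2.sum()
        if total <= 0:
            idx.append(int(rng.integers(n)))
        else:
            idx.append(int(rng.choice(n, p=d2 / total)))
    return Y[idx]


def _em_once(
    Y: np.ndarray,
    k: int,
    degree: int,
    rng: np.random.Generator,
    init: tuple[np.ndarray, np.ndarray, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, float, int]:
    """One EM run; returns (coeffs, weights, sigma, posteriors, logLik, iters)."""
    n, d = Y.shape
    X = np.vander(_QUAD_INDEX, degree + 1, increasing=True)
    XtX_inv_Xt = np.linalg.solve(X.T @ X, X.T)

    if init is None:
        seeds = _kpp_seed(Y, k, rng)
        d2 = ((Y[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        hard = d2.argmin(axis=1)
        gamma = np.zeros((n, k))
        gamma[np.arange(n), hard] = 1.0
        B = np.empty((k, degree + 1))
        for g in range(k):
            w = gamma[:, g]
            ybar = (w[:, None] * Y).sum(axis=0) / max(w.sum(), 1e-12)
            B[g] = XtX_inv_Xt @ ybar
        curves = B @ X.T
        resid2 = (gamma * ((Y[:, None, :] - curves[None, :, :]) ** 2).sum(axis=2)).sum()
        sigma = max(np.sqrt(resid2 / (n * d)), _SIGMA_FLOOR)
        pi = np.maximum(gamma.mean(axis=0), 1e-12)
        pi /= pi.sum()
    else:
        B, pi, sigma = init
        B = B.copy()
        pi = pi.copy()
        curves = B @ X.T

    prev_ll = -np.inf
    ll = -np.inf
    gamma = np.full((n, k), 1.0 / k)
    it = 0
    reseeds = 0
    for it in range(1, max_iter + 1):
        # E-step
        logp = _log_gauss(Y, curves, sigma) + np.log(pi)[None, :]
        m = logp.max(axis=1, keepdims=True)
        lse = m.ravel() + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        gamma = np.exp(logp - lse[:, None])
        sigma_clipped = sigma <= _SIGMA_FLOOR * (1 + 1e-9)
        if not sigma_clipped and np.isfinite(prev_ll):
            assert ll >= prev_ll - 1e-6 * (1 + abs(ll)), "EM log-likelihood decreased"
        if ll - prev_ll < tol * (1 + abs(ll)) and it > 1:
            prev_ll = ll
            break
        prev_ll = ll
        # M-step
        wsum = gamma.sum(axis=0)
        if np.any(wsum < 0.5):
            # collapsed component: re-seed it at the worst-fitted profile
            reseeds += 1
            if reseeds > 3:
                raise _DegenerateComponent()
            g_bad = int(np.argmin(wsum))
            worst = int(np.argmin(lse))
            gamma[:, g_bad] = 0.0
            gamma[worst] = 0.0
            gamma[worst, g_bad] = 1.0
            gamma /= gamma.sum(axis=1, keepdims=True)
            wsum = gamma.sum(axis=0)
            prev_ll = -np.inf  # monotonicity restarts after a re-seed
        pi = wsum / n
        for g in range(k):
            ybar = (gamma[:, g, None] * Y).sum(axis=0) / wsum[g]
            B[g] = XtX_inv_Xt @ ybar
        curves = B @ X.T
        resid2 = (gamma * ((Y[:, None, :] - curves[None, :, :]) ** 2).sum(axis=2)).sum()
        sigma = max(np.sqrt(resid2 / (n * d)), _SIGMA_FLOOR)
    return B, pi, sigma, gamma, ll, it


class _DegenerateComponent(RuntimeError):
    pass


def fit_gbtm(
    rpps: Sequence[RPPTrajectory],
    k: int,
    degree: int = 2,
    n_starts: int = 100,
    seed: int | None = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    _init: tuple[np.ndarray, np.ndarray, float] | None = None,
) -> GBTMModel:
    """Fit a k-group polynomial trajectory mixture by EM, best of ``n_starts``.

    Model: profile y_i ~ sum_g pi_g N(X beta_g, sigma^2 I_4) with X the
    Vandermonde of quadrant indices 1..4 and a shared residual sd.  Reports
    AIC = -2 logLik + 2p and BIC = -2 logLik + p log(n) with
    p = k(degree+1) + (k-1) + 1.  Components are returned ordered by
    increasing mean fitted porosity so labels are reproducible.
    """
    if not (0 <= degree <= 3):
        raise InvalidInputError("degree must lie in [0, 3] for 4-point profiles")
    Y, ids = _require_complete(rpps)
    n = len(Y)
    if n < k:
        raise InvalidInputError(f"need at least k={k} trajectories, got {n}")
    rng = np.random.default_rng(seed)
    best = None
    failures = 0
    starts = 1 if _init is not None else n_starts
    for s in range(starts):
        try:
            out = _em_once(Y, k, degree, rng, init=_init, tol=tol, max_iter=max_iter)
        except _DegenerateComponent:
            failures += 1
            continue
        if best is None or out[4] > best[4]:
            best = out
    if best is None:
        raise InvalidInputError(
            f"EM failed in all {starts} starts ({failures} degenerate); "
            "reduce k or increase sample size"
        )
    B, pi, sigma, gamma, ll, iters = best
    order = np.argsort((B @ np.vander(_QUAD_INDEX, degree + 1, increasing=True).T).mean(axis=1))
    B, pi, gamma = B[order], pi[order], gamma[:, order]
    p = k * (degree + 1) + (k - 1) + 1
    return GBTMModel(
        k=k,
        degree=degree,
        coefficients=B,
        sigma=float(sigma),
        weights=pi,
        posteriors=gamma,
        ids=tuple(ids),
        log_lik=ll,
        aic=-2 * ll + 2 * p,
        bic=-2 * ll + p * np.log(n),
        seed=seed,
        n_em_iter=iters,
    )


def gbtm_cve(
    rpps: Sequence[RPPTrajectory],
    k: int,
    degree: int = 2,
    seed: int | None = 0,
    n_starts: int = 20,
    full_model: GBTMModel | None = None,
    with_se: bool = False,
) -> float | tuple[float, float]:
    """Leave-one-element-out cross-validation error of a GBTM configuration.

    For each held-out profile the model is refitted on the remaining n-1
    (warm-started from the full-data fit); each of the held-out profile's
    four points is then predicted from the posterior computed on its *other
    three* points, so the scored point never informs its own group
    assignment.  The fold scores (mean squared prediction error) are
    averaged.
    """
    if len(rpps) < 2:
        raise InvalidInputError("CVE needs at least two trajectories")
    if full_model is None:
        full_model = fit_gbtm(rpps, k, degree, n_starts=n_starts, seed=seed)
    init = (full_model.coefficients, full_model.weights, full_model.sigma)
    d = len(_QUAD_INDEX)
    errors = []
    for i in range(len(rpps)):
        train = [t for j, t in enumerate(rpps) if j != i]
        sub = fit_gbtm(train, k, degree, seed=seed, _init=init)
        y = rpps[i].as_array()
        curves = sub.predicted_curves()  # (k, 4)
        sq = 0.0
        for j in range(d):
            rest = np.delete(np.arange(d), j)
            resid2 = ((y[rest][None, :] - curves[:, rest]) ** 2).sum(axis=1)
            logp = (
                -0.5 * (resid2 / sub.sigma**2 + (d - 1) * np.log(2 * np.pi * sub.sigma**2))
                + np.log(sub.weights)
            )
            post = np.exp(logp - logp.max())
            post /= post.sum()
            pred = float(post @ curves[:, j])
            sq += (y[j] - pred) ** 2
        errors.append(sq / d)
    mean = float(np.mean(errors))
    if with_se:
        se = float(np.std(errors, ddof=1) / np.sqrt(len(errors))) if len(errors) > 1 else 0.0
        return mean, se
    return mean


def gbtm_select(
    rpps: Sequence[RPPTrajectory],
    k_max: int = 5,
    degrees: Iterable[int] = (1, 2, 3),
    criteria: Sequence[str] = ("AIC", "BIC", "CVE"),
    n_starts: int = 30,
    n_reps: int = 3,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, dict[str, GBTMModel], dict]:
    """Model selection over group numbers 1..k_max and polynomial degrees.

    Every (k, degree) configuration is fitted in ``n_reps`` independently
    seeded repetitions; per criterion the modal best configuration across
    repetitions is flagged, and the overall best group number is the mode of
    the criterion winners.  AIC and BIC pick their minimum; CVE applies the
    one-standard-error rule — the most parsimonious configuration whose CVE
    lies within one fold-level standard error of the minimum — since
    leave-one-out scores of nested mixtures differ by less than their noise.
    Returns ``(report, best_models, summary)`` where ``report`` tabulates the
    requested criteria per rep x configuration, ``best_models`` maps
    criterion -> winning model and ``summary`` holds the flagged best
    k/degree.
    """
    criteria = tuple(c.upper() for c in criteria)
    for c in criteria:
        if c not in ("AIC", "BIC", "CVE"):
            raise InvalidInputError(f"unknown criterion {c!r}")
    if k_max < 1:
        raise InvalidInputError("k_max must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    models: dict[tuple[int, int, int], GBTMModel] = {}
    for rep in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        for k in range(1, k_max + 1):
            for degree in sorted(degrees):
                if len(rpps) < k:
                    continue
                try:
                    model = fit_gbtm(
                        rpps, k, degree, n_starts=n_starts, seed=rep_seed
                    )
                except InvalidInputError:
                    continue
                row = {"rep": rep, "k": k, "degree": degree, "logLik": model.log_lik}
                if "AIC" in criteria:
                    row["AIC"] = model.aic
                if "BIC" in criteria:
                    row["BIC"] = model.bic
                if "CVE" in criteria:
                    row["CVE"], row["CVE_se"] = gbtm_cve(
                        rpps, k, degree, seed=rep_seed, full_model=model, with_se=True
                    )
                rows.append(row)
                models[(rep, k, degree)] = model
    report = pd.DataFrame(rows)
    if report.empty:
        raise InvalidInputError("no configuration could be fitted")

    report["n_parameters"] = report.k * (report.degree + 1) + report.k

    def _cve_one_se_pick(rep_rows: pd.DataFrame) -> pd.Series:
        # fewest groups first, then fewest parameters: the question CVE
        # answers is how many trajectory groups the data support
        best_row = rep_rows.loc[rep_rows["CVE"].idxmin()]
        threshold = best_row["CVE"] + best_row["CVE_se"]
        eligible = rep_rows[rep_rows["CVE"] <= threshold]
        return eligible.sort_values(["k", "n_parameters", "degree"]).iloc[0]

    best_models: dict[str, GBTMModel] = {}
    winners_k: list[int] = []
    summary: dict = {}
    for c in criteria:
        if c == "CVE":
            per_rep = pd.DataFrame(
                [
                    _cve_one_se_pick(report[report["rep"] == r])
                    for r in sorted(report["rep"].unique())
                ]
            )
        else:
            per_rep = report.loc[report.groupby("rep")[c].idxmin()]
        # modal (k, degree) across reps; ties to smaller k then degree
        counts = per_rep.groupby(["k", "degree"]).size().sort_index()
        k_best, d_best = counts.index[np.argmax(counts.values)]
        winners_k.append(int(k_best))
        sel = report[(report.k == k_best) & (report.degree == d_best)]
        rep_best = int(sel.loc[sel[c].idxmin(), "rep"])
        best_models[c] = models[(rep_best, int(k_best), int(d_best))]
        summary[c] = {"k": int(k_best), "degree": int(d_best)}
    ks, cnt = np.unique(winners_k, return_counts=True)
    summary["best_k"] = int(ks[np.argmax(cnt)])
    deg_votes = [summary[c]["degree"] for c in criteria if summary[c]["k"] == summary["best_k"]]
    dv, dc = np.unique(deg_votes or [summary[criteria[0]]["degree"]], return_counts=True)
    summary["best_degree"] = int(dv[np.argmax(dc)])
    return report, best_models, summary
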