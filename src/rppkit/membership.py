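"""Downstream membership statistics: congruence, dissociation, prediction.

Once several grouping methods have labelled the same elements, three
questions follow:

* **Congruence** — do the methods sort elements the same way?  Group labels
  are arbitrary, so method pairs are first aligned by an optimal one-to-one
  group matching (assignment problem on the contingency table); the aligned
  agreement percentage is reported per pair, summed per method, and consensus
  tiers count the elements grouped identically by all M methods, by M-1, etc.

* **Skeletal dissociation** — are one individual's bones split across
  groups?  The signature per specimen is "0" when all its bones share a
  group, otherwise the ascending hyphen-joined bone counts per group
  (e.g. "1-3": two groups, one bone vs three).

* **Membership prediction** — can biology (age, bone, developmental
  strategy, specimen) predict the group labels?  Multinomial logistic
  regression with backward stepwise AIC elimination, second-order AICc and
  the percentage of elements whose predicted membership matches the actual
  one (PM%).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, minimize

from .core import InvalidInputError
from .grouping import GroupingResult

__all__ = [
    "CongruenceReport",
    "DissociationSignature",
    "MultinomFit",
    "StepwiseResult",
    "align_labels",
    "congruence_report",
    "dissociation",
    "multinom_fit",
    "stepwise_select",
]


# ---------------------------------------------------------------------------
# Label alignment & congruence
# ---------------------------------------------------------------------------


def align_labels(
    a: GroupingResult, b: GroupingResult
) -> tuple[dict[int, int | None], float]:
    """Optimal one-to-one group matching of ``b`` onto ``a``.

    Solves the assignment problem on the k_a x k_b contingency table of the
    shared elements, maximizing the number of co-assigned elements.  Returns
    ``(mapping, agreement_percent)`` where ``mapping`` sends each b-group to
    its matched a-group (``None`` for unmatched groups when the group counts
    differ) and agreement is matched elements / shared elements x 100.
    """
    shared = sorted(set(a.labels) & set(b.labels))
    if not shared:
        raise InvalidInputError("groupings share no elements")
    la = np.array([a.labels[i] for i in shared])
    lb = np.array([b.labels[i] for i in shared])
    ga = np.unique(la)
    gb = np.unique(lb)
    table = np.zeros((len(ga), len(gb)), dtype=int)
    for i, x in enumerate(ga):
        for j, y in enumerate(gb):
            table[i, j] = int(((la == x) & (lb == y)).sum())
    rows, cols = linear_sum_assignment(-table)
    mapping: dict[int, int | None] = {int(g): None for g in gb}
    matched = 0
    for r, c in zip(rows, cols):
        mapping[int(gb[c])] = int(ga[r])
        matched += table[r, c]
    return mapping, 100.0 * matched / len(shared)


@dataclass(frozen=True)
class CongruenceReport:
    """Cross-method agreement summary.

    ``pairwise`` holds the aligned agreement percentage per method pair;
    ``overall`` sums each method's pairwise percentages (a method congruent
    with every other scores high); ``tiers`` maps m -> percentage of elements
    grouped identically by exactly m of the M methods after aligning all of
    them to ``reference``.
    """

    methods: tuple[str, ...]
    pairwise: pd.DataFrame
    overall: dict[str, float]
    tiers: dict[int, float]
    reference: str
    n_elements: int


def congruence_report(
    groupings: Sequence[GroupingResult], reference: str | None = None
) -> CongruenceReport:
    """Pairwise, overall and consensus congruence of several groupings."""
    if len(groupings) < 2:
        raise InvalidInputError("need at least two groupings")
    methods = [g.method for g in groupings]
    if len(set(methods)) != len(methods):
        raise InvalidInputError("grouping methods must be distinct")
    shared = set(groupings[0].labels)
    for g in groupings[1:]:
        shared &= set(g.labels)
    shared = sorted(shared)
    if not shared:
        raise InvalidInputError("groupings share no elements")

    m = len(groupings)
    pair = pd.DataFrame(
        np.full((m, m), 100.0), index=methods, columns=methods
    )
    for (i, gi), (j, gj) in itertools.combinations(enumerate(groupings), 2):
        _, pct = align_labels(gi, gj)
        pair.iloc[i, j] = pair.iloc[j, i] = pct
    overall = {
        meth: float(sum(pair.loc[meth, other] for other in methods if other != meth))
        for meth in methods
    }

    if reference is None:
        reference = "kmeans" if "kmeans" in methods else methods[0]
    if reference not in methods:
        raise InvalidInputError(f"reference {reference!r} not among methods")
    ref = groupings[methods.index(reference)]
    aligned = np.empty((len(shared), m), dtype=int)
    for j, g in enumerate(groupings):
        if g.method == reference:
            aligned[:, j] = [ref.labels[i] for i in shared]
            continue
        mapping, _ = align_labels(ref, g)
        # unmatched groups get unique negative codes: always a disagreement
        aligned[:, j] = [
            mapping[g.labels[i]] if mapping[g.labels[i]] is not None else -g.labels[i]
            for i in shared
        ]
    tiers = {t: 0 for t in range(1, m + 1)}
    for row in aligned:
        _, counts = np.unique(row, return_counts=True)
        tiers[int(counts.max())] += 1
    tiers_pct = {t: 100.0 * c / len(shared) for t, c in tiers.items()}
    return CongruenceReport(
        methods=tuple(methods),
        pairwise=pair,
        overall=overall,
        tiers=tiers_pct,
        reference=reference,
        n_elements=len(shared),
    )


# ---------------------------------------------------------------------------
# Skeletal dissociation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DissociationSignature:
    """Per-specimen signature of how its bones spread across groups."""

    specimen_id: str
    n_bones: int
    signature: str
    level: int

    def __post_init__(self) -> None:
        if self.signature == "0":
            if self.level != 1:
                raise InvalidInputError("'0' signature implies a single group")
        else:
            counts = [int(c) for c in self.signature.split("-")]
            if sum(counts) != self.n_bones:
                raise InvalidInputError("signature counts must sum to n_bones")
            if len(counts) != self.level:
                raise InvalidInputError("signature length must equal level")


def dissociation(
    grouping: GroupingResult, specimen_map: Mapping[str, str]
) -> list[DissociationSignature]:
    """Skeletal-dissociation signatures of every specimen in a grouping.

    ``specimen_map`` sends each element id to its specimen.  A specimen whose
    bones all share one group signs "0"; otherwise the ascending bone counts
    per occupied group are hyphen-joined (e.g. "1-2-3").
    """
    unmapped = [e for e in grouping.labels if e not in specimen_map]
    if unmapped:
        raise InvalidInputError(f"elements without specimen mapping: {unmapped}")
    by_spec: dict[str, list[int]] = {}
    for element, label in grouping.labels.items():
        by_spec.setdefault(specimen_map[element], []).append(label)
    out = []
    for spec in sorted(by_spec):
        labels = by_spec[spec]
        counts = sorted(
            int((np.asarray(labels) == g).sum()) for g in sorted(set(labels))
        )
        level = len(counts)
        signature = "0" if level == 1 else "-".join(str(c) for c in counts)
        out.append(
            DissociationSignature(
                specimen_id=spec,
                n_bones=len(labels),
                signature=signature,
                level=level,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Multinomial logistic regression of memberships
# ---------------------------------------------------------------------------

_RIDGE = 1e-6


def _design_matrix(
    table: pd.DataFrame, predictors: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + reference-coded design for the chosen predictor columns."""
    cols: list[np.ndarray] = [np.ones(len(table))]
    names = ["(intercept)"]
    for p in predictors:
        col = table[p]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(p)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=p, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(c)
    return np.column_stack(cols), names


@dataclass(frozen=True)
class MultinomFit:
    """Maximum-likelihood softmax regression of group memberships.

    ``coef``/``se`` are (feature x non-reference-class) tables; the first
    class is the reference.  ``pm_percent`` is the share of elements whose
    modal predicted membership matches the actual label.  A tiny ridge
    penalty (1e-6) keeps separable designs finite; ``separation_warning``
    flags fits where any coefficient grew implausibly large.
    """

    response: str
    predictors: tuple[str, ...]
    classes: tuple[int, ...]
    coef: pd.DataFrame
    se: pd.DataFrame
    log_lik: float
    aic: float
    aicc: float
    n: int
    n_parameters: int
    fitted: dict[str, int]
    pm_percent: float
    converged: bool
    separation_warning: bool

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.predictors) if self.predictors else "1"
        return f"{self.response} ~ {rhs}"


def multinom_fit(
    labels: GroupingResult,
    design: pd.DataFrame,
    predictors: Sequence[str] | None = None,
    max_iter: int = 500,
) -> MultinomFit:
    """Fit a multinomial logistic regression of group labels on predictors.

    ``design`` is indexed by element id; ``predictors`` defaults to every
    column.  Numeric columns enter linearly, categorical ones are
    reference-coded.  AIC = 2p - 2 logLik and
    AICc = AIC + 2p(p+1)/(n - p - 1); PM% is the modal-class match rate.
    """
    if predictors is None:
        predictors = tuple(design.columns)
    ids = [i for i in design.index if i in labels.labels]
    if len(ids) != len(labels.labels):
        missing = sorted(set(labels.labels) - set(ids))
        raise InvalidInputError(f"design table lacks rows for elements: {missing}")
    table = design.loc[ids]
    y_raw = np.array([labels.labels[i] for i in ids])
    classes = tuple(int(c) for c in np.unique(y_raw))
    if len(classes) < 2:
        raise InvalidInputError("response has a single class; nothing to fit")
    C = len(classes)
    y = np.searchsorted(classes, y_raw)
    X, names = _design_matrix(table, predictors)
    n, p_feat = X.shape
    n_par = (C - 1) * p_feat
    onehot = np.zeros((n, C))
    onehot[np.arange(n), y] = 1.0

    def unpack(w: np.ndarray) -> np.ndarray:
        W = np.zeros((p_feat, C))
        W[:, 1:] = w.reshape(p_feat, C - 1)
        return W

    def nll_grad(w: np.ndarray) -> tuple[float, np.ndarray]:
        W = unpack(w)
        eta = X @ W
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)
        ll = float(np.sum(onehot * np.log(np.clip(P, 1e-300, None))))
        g = X.T @ (P - onehot)  # (p_feat, C)
        pen = _RIDGE * float(w @ w)
        grad = g[:, 1:].ravel() + 2 * _RIDGE * w
        return -ll + pen, grad

    res = minimize(
        nll_grad,
        np.zeros(n_par),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
    )
    W = unpack(res.x)
    eta = X @ W
    eta -= eta.max(axis=1, keepdims=True)
    P = np.exp(eta)
    P /= P.sum(axis=1, keepdims=True)
    log_lik = float(np.sum(onehot * np.log(np.clip(P, 1e-300, None))))

    # analytic Hessian of the (penalized) NLL for standard errors; parameter
    # order matches the optimizer's flat layout (feature-major over classes)
    Pnr = P[:, 1:]  # non-reference class probabilities
    S = Pnr[:, :, None] * (np.eye(C - 1)[None, :, :] - Pnr[:, None, :])
    H = np.einsum("ni,ncd,nj->icjd", X, S, X).reshape(n_par, n_par)
    H += 2 * _RIDGE * np.eye(n_par)
    try:
        cov = np.linalg.inv(H)
        se_flat = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_flat = np.full(n_par, np.nan)
    se = np.zeros((p_feat, C))
    se[:, 1:] = se_flat.reshape(p_feat, C - 1)

    aic = 2 * n_par - 2 * log_lik
    aicc = aic + (
        2 * n_par * (n_par + 1) / (n - n_par - 1) if n > n_par + 1 else np.inf
    )
    fitted_idx = P.argmax(axis=1)
    fitted = {i: classes[c] for i, c in zip(ids, fitted_idx)}
    pm = 100.0 * float((fitted_idx == y).mean())
    col_names = [f"class_{classes[c]}" for c in range(1, C)]
    coef_df = pd.DataFrame(W[:, 1:], index=names, columns=col_names)
    se_df = pd.DataFrame(se[:, 1:], index=names, columns=col_names)
    return MultinomFit(
        response=labels.method,
        predictors=tuple(predictors),
        classes=classes,
        coef=coef_df,
        se=se_df,
        log_lik=log_lik,
        aic=aic,
        aicc=float(aicc),
        n=n,
        n_parameters=n_par,
        fitted=fitted,
        pm_percent=pm,
        converged=bool(res.success),
        separation_warning=bool(np.abs(W).max() > 15.0),
    )


@dataclass(frozen=True)
class StepwiseResult:
    """Backward-elimination path with AIC/AICc/PM% per visited model."""

    path: pd.DataFrame
    aic_best: MultinomFit
    aicc_best: MultinomFit
    drop_order: tuple[str, ...]


def stepwise_select(
    labels: GroupingResult,
    design: pd.DataFrame,
    predictors: Sequence[str] | None = None,
) -> StepwiseResult:
    """Backward stepwise AIC elimination of whole predictors.

    Starting from the full model, repeatedly drops the predictor whose
    removal lowers AIC the most (all levels of a categorical at once) until
    no drop improves AIC.  Every visited model is tabulated with its AIC,
    AICc and PM%; the AIC-best and AICc-best fits are returned.
    """
    if predictors is None:
        predictors = tuple(design.columns)
    current = list(predictors)
    fits: dict[tuple[str, ...], MultinomFit] = {}

    def get_fit(preds: Sequence[str]) -> MultinomFit:
        key = tuple(preds)
        if key not in fits:
            fits[key] = multinom_fit(labels, design, preds)
        return fits[key]

    rows = []
    drop_order: list[str] = []
    fit = get_fit(current)
    rows.append(
        {
            "model": fit.formula,
            "AIC": fit.aic,
            "AICc": fit.aicc,
            "PM%": fit.pm_percent,
            "step": 0,
        }
    )
    step = 0
    while current:
        step += 1
        candidates = []
        for p in current:
            reduced = [q for q in current if q != p]
            if not reduced:
                continue
            f = get_fit(reduced)
            candidates.append((f.aic, p, f))
        if not candidates:
            break
        candidates.sort(key=lambda t: (t[0], t[1]))
        best_aic, dropped, best_fit = candidates[0]
        for aic_v, p, f in candidates:
            rows.append(
                {
                    "model": f.formula,
                    "AIC": f.aic,
                    "AICc": f.aicc,
                    "PM%": f.pm_percent,
                    "step": step,
                }
            )
        if best_aic < fit.aic:
            current.remove(dropped)
            drop_order.append(dropped)
            fit = best_fit
        else:
            break
    path = pd.DataFrame(rows).drop_duplicates(subset="model").reset_index(drop=True)
    all_fits = list(fits.values())
    aic_best = min(all_fits, key=lambda f: f.aic)
    finite = [f for f in all_fits if np.isfinite(f.aicc)]
    aicc_best = min(finite or all_fits, key=lambda f: f.aicc)
    return StepwiseResult(
        path=path,
        aic_best=aic_best,
        aicc_best=aicc_best,
        drop_order=tuple(drop_order),
    )
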