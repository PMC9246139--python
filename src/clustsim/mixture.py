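"""Model-based Gaussian mixture clustering (MGC) with BIC selection.

Each candidate solution is a finite mixture of ``g`` multivariate normals
whose covariance matrices obey one of six nested parameterizations,
spanning spherical / diagonal / full shape crossed with equal / varying
across components:

=====  ==========================  =================================
code   structure                   covariance free parameters
=====  ==========================  =================================
EII    spherical, shared            1
VII    spherical, per-component     g
EEI    diagonal, shared             p
VVI    diagonal, per-component      g * p
EEE    full, shared                 p (p + 1) / 2
VVV    full, per-component          g * p (p + 1) / 2
=====  ==========================  =================================

Fitting is by expectation-maximization with constrained M-steps.  The
number of components (1..g_max) and the family are chosen jointly by
maximizing ``BIC = 2 logL - m log N`` where ``m`` counts free parameters;
with this sign convention larger is better.

EM is initialized from the complete-linkage hierarchical partition at each
``g`` plus one k-means restart, keeping the better converged fit — a
deterministic scheme given the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .results import ClusterResult

__all__ = [
    "CovarianceModel",
    "DEFAULT_MODELS",
    "MixtureFit",
    "n_free_params",
    "bic_score",
    "em_fit",
    "select_mgc",
]

_LOG_2PI = np.log(2.0 * np.pi)


class CovarianceModel(str, Enum):
    """Covariance parameterization of the mixture components."""

    EII = "EII"  # spherical, equal volume
    VII = "VII"  # spherical, varying volume
    EEI = "EEI"  # diagonal, equal
    VVI = "VVI"  # diagonal, varying
    EEE = "EEE"  # full, equal
    VVV = "VVV"  # full, varying


#: Enumeration order doubles as the tie-breaking order (simpler first).
DEFAULT_MODELS: tuple[CovarianceModel, ...] = tuple(CovarianceModel)

_COV_PARAMS = {
    CovarianceModel.EII: lambda g, p: 1,
    CovarianceModel.VII: lambda g, p: g,
    CovarianceModel.EEI: lambda g, p: p,
    CovarianceModel.VVI: lambda g, p: g * p,
    CovarianceModel.EEE: lambda g, p: p * (p + 1) // 2,
    CovarianceModel.VVV: lambda g, p: g * p * (p + 1) // 2,
}


def n_free_params(model: CovarianceModel, g: int, p: int) -> int:
    """Free-parameter count: (g-1) mixing + g*p means + covariance terms."""
    if g < 1 or p < 1:
        raise ValueError("g and p must be >= 1")
    model = CovarianceModel(model)
    return (g - 1) + g * p + _COV_PARAMS[model](g, p)


def bic_score(loglik: float, m: int, n: int) -> float:
    """``2 logL - m log n``; selection maximizes this quantity."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2.0 * loglik - m * np.log(n)


@dataclass
class MixtureFit:
    """A fitted (g, covariance-family) mixture candidate."""

    g: int
    model: CovarianceModel
    weights: np.ndarray            # (g,)
    means: np.ndarray              # (g, p)
    covariances: np.ndarray        # (g, p, p)
    loglik: float
    m: int
    bic: float
    converged: bool
    degenerate: bool = False
    responsibilities: np.ndarray | None = None   # (n, g)
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def ok(self) -> bool:
        """Usable for model selection: converged and not degenerate."""
        return self.converged and not self.degenerate

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.responsibilities, axis=1) + 1


def _mstep(x, resp, model, reg):
    """Constrained M-step; returns (weights, means, covariances, degenerate)."""
    n, p = x.shape
    g = resp.shape[1]
    nk = resp.sum(axis=0)
    degenerate = bool(np.any(nk < 1e-8))
    nk = np.maximum(nk, 1e-10)
    weights = nk / n
    means = (resp.T @ x) / nk[:, None]

    if model in (CovarianceModel.EEE, CovarianceModel.VVV):
        scatters = np.empty((g, p, p))
        for k in range(g):
            xc = x - means[k]
            scatters[k] = (resp[:, k] * xc.T) @ xc
        if model is CovarianceModel.EEE:
            cov = scatters.sum(axis=0) / n
            covs = np.broadcast_to(cov, (g, p, p)).copy()
        else:
            covs = scatters / nk[:, None, None]
    else:
        # diagonal/spherical families need only per-variable second moments
        sq = np.empty((g, p))
        for k in range(g):
            xc = x - means[k]
            sq[k] = resp[:, k] @ (xc * xc)
        if model is CovarianceModel.EII:
            var = sq.sum() / (n * p)
            diag = np.full((g, p), var)
        elif model is CovarianceModel.VII:
            var_k = sq.sum(axis=1) / (nk * p)
            diag = np.repeat(var_k[:, None], p, axis=1)
        elif model is CovarianceModel.EEI:
            d = sq.sum(axis=0) / n
            diag = np.broadcast_to(d, (g, p)).copy()
        elif model is CovarianceModel.VVI:
            diag = sq / nk[:, None]
        else:  # pragma: no cover
            raise ValueError(f"unknown covariance model {model!r}")
        covs = np.zeros((g, p, p))
        idx = np.arange(p)
        covs[:, idx, idx] = diag

    # eigenvalue floor: fits that hit it are flagged degenerate and later
    # excluded from BIC selection
    for k in range(g):
        vals, vecs = np.linalg.eigh(covs[k])
        if vals[0] < reg:
            degenerate = True
            vals = np.maximum(vals, reg)
            covs[k] = (vecs * vals) @ vecs.T
    return weights, means, covs, degenerate


def _log_components(x, weights, means, covs):
    """(n, g) matrix of log(w_k) + log N(x | mu_k, Sigma_k)."""
    n, p = x.shape
    g = len(weights)
    out = np.empty((n, g))
    for k in range(g):
        chol = np.linalg.cholesky(covs[k])
        xc = x - means[k]
        z = solve_triangular(chol, xc.T, lower=True)
        maha = np.sum(z * z, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, k] = (
            np.log(weights[k]) - 0.5 * (p * _LOG_2PI + logdet + maha)
        )
    return out


def _resp_from_labels(labels, g):
    n = len(labels)
    resp = np.zeros((n, g))
    resp[np.arange(n), labels] = 1.0
    return resp


def em_fit(
    x: np.ndarray,
    g: int,
    model: CovarianceModel,
    init: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 500,
    reg: float = 1e-6,
) -> MixtureFit:
    """Fit one (g, family) candidate by EM from a hard initial partition.

    ``init`` is a length-n array of integer group ids covering g non-empty
    groups (any labeling; it is densified internally).  The log-likelihood
    is non-decreasing over iterations up to numerical tolerance; convergence
    is declared when the relative change drops below ``tol``.  Singular or
    floor-hitting covariances mark the fit degenerate rather than raising.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n <= g:
        raise ValueError(f"need n > g, got n={n}, g={g}")
    model = CovarianceModel(model)
    m = n_free_params(model, g, p)

    _, dense = np.unique(np.asarray(init), return_inverse=True)
    if dense.max() + 1 != g:
        raise ValueError(f"init must cover exactly {g} non-empty groups")
    resp = _resp_from_labels(dense, g)

    trace: list[float] = []
    converged = False
    degenerate = False
    loglik = -np.inf
    weights = means = covs = None
    it = 0
    for it in range(1, max_iter + 1):
        try:
            weights, means, covs, degen_step = _mstep(x, resp, model, reg)
            log_comp = _log_components(x, weights, means, covs)
        except np.linalg.LinAlgError:
            degenerate = True
            break
        degenerate = degenerate or degen_step
        row_ll = logsumexp(log_comp, axis=1)
        new_loglik = float(row_ll.sum())
        resp = np.exp(log_comp - row_ll[:, None])
        trace.append(new_loglik)
        if np.isfinite(loglik) and abs(new_loglik - loglik) <= tol * (
            1.0 + abs(new_loglik)
        ):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
        if degenerate:
            break

    if weights is None:
        weights = np.full(g, np.nan)
        means = np.full((g, p), np.nan)
        covs = np.full((g, p, p), np.nan)
    return MixtureFit(
        g=g,
        model=model,
        weights=weights,
        means=means,
        covariances=covs,
        loglik=loglik,
        m=m,
        bic=bic_score(loglik, m, n) if np.isfinite(loglik) else -np.inf,
        converged=converged,
        degenerate=degenerate,
        responsibilities=resp,
        loglik_trace=trace,
        n_iter=it,
    )


def _init_partitions(x, g, random_state=0):
    """Deterministic initial hard partitions for a given g."""
    n = x.shape[0]
    if g == 1:
        return [np.zeros(n, dtype=int)]
    z = linkage(x, method="complete")
    hac = fcluster(z, t=g, criterion="maxclust") - 1
    inits = [hac]
    km = KMeans(n_clusters=g, n_init=1, random_state=random_state).fit(x)
    if np.unique(km.labels_).size == g:
        inits.append(km.labels_)
    return inits


def select_mgc(
    x: np.ndarray,
    g_max: int = 5,
    models: tuple[CovarianceModel, ...] = DEFAULT_MODELS,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> ClusterResult:
    """Sweep g = 1..g_max across covariance families; pick the best BIC.

    Returns a :class:`ClusterResult` with hard maximum-responsibility labels
    and the full per-(g, family) BIC table.  Ties on BIC break toward fewer
    components, then the simpler family.  Raises if every candidate fit
    failed (non-convergence or degeneracy).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n <= g_max:
        raise ValueError(f"need n > g_max, got n={n}, g_max={g_max}")
    models = tuple(CovarianceModel(m) for m in models)

    fits: dict[tuple[int, CovarianceModel], MixtureFit] = {}
    for g in range(1, g_max + 1):
        inits = _init_partitions(x, g)
        for model in models:
            best = None
            for init in inits:
                fit = em_fit(x, g, model, init, tol=tol, max_iter=max_iter)
                if best is None or (fit.ok and not best.ok) or (
                    fit.ok == best.ok and fit.loglik > best.loglik
                ):
                    best = fit
            fits[(g, model)] = best

    table = pd.DataFrame(
        index=pd.RangeIndex(1, g_max + 1, name="g"),
        columns=[m.value for m in models],
        dtype=float,
    )
    for (g, model), fit in fits.items():
        table.loc[g, model.value] = fit.bic if fit.ok else np.nan

    usable = [(key, fit) for key, fit in fits.items() if fit.ok]
    if not usable:
        raise RuntimeError("all mixture fits failed to converge")
    order = {m: i for i, m in enumerate(models)}
    (g_best, model_best), fit_best = max(
        usable, key=lambda kv: (kv[1].bic, -kv[0][0], -order[kv[0][1]])
    )
    return ClusterResult(
        method="mgc",
        k_selected=g_best,
        labels=fit_best.hard_labels(),
        criterion_by_k=table,
        extras={"model": model_best.value, "bic": fit_best.bic, "fit": fit_best},
    )
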