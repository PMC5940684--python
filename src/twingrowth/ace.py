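"""Univariate ACE variance decomposition for twin pairs.

The phenotypic variance of a trait is split into additive-genetic (A),
common-environment (C) and unique-environment (E) components by maximum
likelihood over bivariate-normal twin pairs: the co-twin covariance is
``r*sigmaA2 + sigmaC2`` with kinship ``r = 1`` for MZ and ``0.5`` for DZ
pairs, while C is fully shared by both zygosities.  Covariates enter the
mean; their coefficients are profiled out by generalized least squares at
every likelihood evaluation.  Null models with sigmaA2 = 0 (CE) or
sigmaC2 = 0 (AE) give boundary likelihood-ratio tests whose null
distribution is the standard 50:50 chi-square mixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtri
from scipy.stats import chi2, rankdata

__all__ = [
    "inverse_normal_transform",
    "ace_loglik",
    "fit_ace",
    "lrt_boundary",
    "ACEResult",
    "ACEData",
    "KINSHIP",
]

#: Additive-genetic co-twin correlation by zygosity; shared environment is
#: fully correlated (1.0) in both.
KINSHIP: dict[str, float] = {"MZ": 1.0, "DZ": 0.5}

_LOG2PI = np.log(2.0 * np.pi)


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform.

    Maps value with rank r (ties averaged) to ``Phi^-1((r - 3/8)/(n + 1/4))``
    over the non-missing entries; NaNs are passed through.  Requires at least
    three distinct observed values' worth of rank information.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("inverse_normal_transform needs at least 3 values")
    obs = x[mask]
    if np.all(obs == obs[0]):
        raise ValueError("all values identical: no rank information")
    ranks = rankdata(obs, method="average")
    out[mask] = ndtri((ranks - 0.375) / (n + 0.25))
    return out


@dataclass
class ACEData:
    """Pairwise layout of one trait at one anchor.

    ``y`` is (n_pairs, 2) with NaN marking a missing co-twin; ``x`` is
    (n_pairs, 2, p) covariate design (including intercept); ``zygosity`` is
    an array of "MZ"/"DZ".
    """

    y: np.ndarray
    x: np.ndarray
    zygosity: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.zygosity = np.asarray(self.zygosity)
        if self.x is None:
            self.x = np.ones((*self.y.shape, 1))
        self.x = np.asarray(self.x, dtype=float)
        if self.y.shape[1] != 2 or self.x.shape[:2] != self.y.shape:
            raise ValueError("y must be (n, 2) and x (n, 2, p)")
        self.r = np.array([KINSHIP[z] for z in self.zygosity])
        self.complete = ~np.isnan(self.y).any(axis=1)
        self.single = ~self.complete & ~np.isnan(self.y).all(axis=1)

    @property
    def n_mz(self) -> int:
        return int(np.sum((self.zygosity == "MZ") & self.complete))

    @property
    def n_dz(self) -> int:
        return int(np.sum((self.zygosity == "DZ") & self.complete))


def _pair_loglik(resid: np.ndarray, r: np.ndarray, sa2: float, sc2: float, se2: float) -> float:
    """Sum of bivariate-normal log densities over complete pairs."""
    v = sa2 + sc2 + se2
    cz = r * sa2 + sc2
    det = v * v - cz * cz
    if v <= 0 or np.any(det <= 0):
        return -np.inf
    quad = (v * (resid[:, 0] ** 2 + resid[:, 1] ** 2) - 2 * cz * resid[:, 0] * resid[:, 1]) / det
    return float(-0.5 * np.sum(np.log(det) + quad) - resid.shape[0] * _LOG2PI)


def ace_loglik(params, data: ACEData) -> float:
    """Log-likelihood of (sigmaA2, sigmaC2, sigmaE2, beta) for twin data.

    Complete pairs contribute a bivariate normal with covariance
    ``[[v, r*sA2+sC2], [r*sA2+sC2, v]]``, ``v = sA2+sC2+sE2``; pairs with one
    missing co-twin contribute the marginal univariate density.  Returns
    ``-inf`` (never raises) when the implied covariance is not positive
    definite.
    """
    sa2, sc2, se2 = (float(p) for p in params[:3])
    beta = np.asarray(params[3], dtype=float) if len(params) > 3 else np.zeros(data.x.shape[2])
    if min(sa2, sc2) < 0 or se2 <= 0:
        return -np.inf
    resid = data.y - data.x @ beta
    ll = _pair_loglik(resid[data.complete], data.r[data.complete], sa2, sc2, se2)
    if np.any(data.single):
        v = sa2 + sc2 + se2
        rs = resid[data.single]
        obs = rs[~np.isnan(rs)]
        ll += float(-0.5 * np.sum(np.log(v) + obs**2 / v) - 0.5 * obs.size * _LOG2PI)
    return ll


def _profile_beta(data: ACEData, sa2: float, sc2: float, se2: float) -> np.ndarray:
    """GLS coefficients for the mean given variance components."""
    p = data.x.shape[2]
    a = np.zeros((p, p))
    b = np.zeros(p)
    v = sa2 + sc2 + se2
    for zyg in ("MZ", "DZ"):
        m = data.complete & (data.zygosity == zyg)
        if not m.any():
            continue
        cz = KINSHIP[zyg] * sa2 + sc2
        det = v * v - cz * cz
        w = np.array([[v, -cz], [-cz, v]]) / det  # inverse 2x2
        xs, ys = data.x[m], data.y[m]
        xw = np.einsum("nif,ij->njf", xs, w)
        a += np.einsum("njf,njg->fg", xw, xs)
        b += np.einsum("njf,nj->f", xw, ys)
    if np.any(data.single):
        xs, ys = data.x[data.single], data.y[data.single]
        obs = ~np.isnan(ys)
        xo = xs[obs]
        a += (xo.T @ xo) / v
        b += (xo.T @ ys[obs]) / v
    return np.linalg.lstsq(a, b, rcond=None)[0]


def _neg_profiled(theta: np.ndarray, data: ACEData, free: tuple[int, ...]) -> float:
    sa2 = sc2 = 0.0
    se2 = 1e-12
    vals = dict(zip(free, theta))
    sa2 = vals.get(0, 0.0)
    sc2 = vals.get(1, 0.0)
    se2 = vals.get(2, se2)
    beta = _profile_beta(data, sa2, sc2, se2)
    return -ace_loglik((sa2, sc2, se2, beta), data)


def _fit_model(data: ACEData, free: tuple[int, ...], starts: Sequence[Sequence[float]],
               vtot: float) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Maximize the profiled likelihood over the free variance components.

    ``free`` indexes into (sigmaA2, sigmaC2, sigmaE2); fixed components are
    pinned at zero (sigmaE2 is always free).  Returns (variances, beta,
    loglik, converged).
    """
    lo = 1e-10 * max(vtot, 1e-12)
    bounds = [(lo if i == 2 else 0.0, 10.0 * vtot) for i in free]
    best = None
    ok = False
    for st in starts:
        x0 = np.clip(np.asarray(st, dtype=float), [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(_neg_profiled, x0, args=(data, free), method="L-BFGS-B",
                       bounds=bounds, options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    sig = np.zeros(3)
    for i, v in zip(free, best.x):
        sig[i] = v
    beta = _profile_beta(data, *sig)
    return sig, beta, -best.fun, ok


def lrt_boundary(loglik_full: float, loglik_reduced: float) -> float:
    """Boundary LRT p-value for a single variance component.

    The null distribution of ``T = 2*(llf - llr)`` when one variance is
    tested at its boundary is a 50:50 mixture of a point mass at zero and a
    chi-square with 1 df; ``T = 0`` maps to p = 1 (conservative).
    """
    if loglik_full < loglik_reduced - 1e-6:
        raise ValueError("full-model log-likelihood below reduced model: optimizer failure")
    t = max(0.0, 2.0 * (loglik_full - loglik_reduced))
    if t == 0.0:
        return 1.0
    return float(0.5 * chi2.sf(t, df=1))


@dataclass
class ACEResult:
    """Fitted ACE decomposition of one trait at one anchor age."""

    trait: str
    anchor_ga: float
    sigma_a2: float
    sigma_c2: float
    sigma_e2: float
    h2: float
    c2: float
    e2: float
    beta: np.ndarray
    beta_names: tuple[str, ...]
    loglik: float
    loglik_ae: float
    loglik_ce: float
    loglik_e: float
    p_h2: float
    p_c2: float
    covariate_var_explained: float
    n_mz_pairs: int
    n_dz_pairs: int
    converged: bool

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k not in ("beta", "beta_names")}
        d["beta"] = dict(zip(self.beta_names, np.asarray(self.beta).tolist()))
        return d


def _falconer(data: ACEData) -> tuple[float, float]:
    """Moment estimates h2 = 2(rMZ - rDZ), c2 = 2rDZ - rMZ from co-twin
    Pearson correlations; clipped to the admissible region."""
    rs = {}
    for zyg in ("MZ", "DZ"):
        m = data.complete & (data.zygosity == zyg)
        if m.sum() < 2:
            return 0.3, 0.3
        y = data.y[m]
        rs[zyg] = float(np.corrcoef(y[:, 0], y[:, 1])[0, 1])
    h2 = np.clip(2.0 * (rs["MZ"] - rs["DZ"]), 0.0, 1.0)
    c2 = np.clip(2.0 * rs["DZ"] - rs["MZ"], 0.0, 1.0 - h2)
    return float(h2), float(c2)


def fit_ace(values, zygosity, covariates=None, *, trait: str = "", anchor_ga: float = np.nan,
            beta_names: Sequence[str] | None = None) -> ACEResult:
    """Maximum-likelihood ACE fit for one trait at one anchor.

    Parameters
    ----------
    values
        (n_pairs, 2) array of (transformed) co-twin trait values; NaN marks
        a missing co-twin (such pairs contribute marginal terms).
    zygosity
        length-n array of "MZ"/"DZ".
    covariates
        optional (n_pairs, 2, p) design; an intercept column is appended
        automatically when absent (a constant column is detected by zero
        variance).

    Notes
    -----
    The optimizer uses five starting points (Falconer moment estimates,
    equal split, E-only, and A- or C-leaning splits) plus the solutions of
    the nested AE/CE fits, which also guarantees the likelihood ordering
    loglik(ACE) >= loglik(AE), loglik(CE) >= loglik(E).
    """
    values = np.asarray(values, dtype=float)
    if covariates is None:
        x = np.ones((*values.shape, 1))
        names = ("intercept",)
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 2:  # (n_pairs, p) pair-level, same for both twins
            covariates = np.repeat(covariates[:, None, :], 2, axis=1)
        has_const = np.any(np.ptp(covariates.reshape(-1, covariates.shape[2]), axis=0) == 0)
        if has_const:
            x = covariates
            names = tuple(beta_names) if beta_names else tuple(f"x{i}" for i in range(x.shape[2]))
        else:
            x = np.concatenate([np.ones((*values.shape, 1)), covariates], axis=2)
            names = ("intercept", *(beta_names or [f"x{i}" for i in range(covariates.shape[2])]))
    data = ACEData(values, x, zygosity)
    if data.n_mz < 2 or data.n_dz < 2:
        raise ValueError("need at least 2 complete MZ and 2 complete DZ pairs")

    vtot = float(np.nanvar(values))
    h2f, c2f = _falconer(data)
    e2f = max(1.0 - h2f - c2f, 0.05)

    # nested fits first; their optima seed the full fit
    sig_e, beta_e, ll_e, _ = _fit_model(data, (2,), [[vtot]], vtot)
    starts_ae = [[h2f * vtot, max(e2f, 0.1) * vtot], [0.5 * vtot, 0.5 * vtot], [1e-4 * vtot, vtot]]
    sig_ae, _, ll_ae, _ = _fit_model(data, (0, 2), starts_ae, vtot)
    starts_ce = [[c2f * vtot, max(e2f, 0.1) * vtot], [0.5 * vtot, 0.5 * vtot], [1e-4 * vtot, vtot]]
    sig_ce, _, ll_ce, _ = _fit_model(data, (1, 2), starts_ce, vtot)

    starts = [
        [h2f * vtot, c2f * vtot, e2f * vtot],
        [vtot / 3, vtot / 3, vtot / 3],
        [1e-4 * vtot, 1e-4 * vtot, vtot],
        [0.6 * vtot, 0.2 * vtot, 0.2 * vtot],
        [0.2 * vtot, 0.6 * vtot, 0.2 * vtot],
        [sig_ae[0], 0.0, sig_ae[2]],
        [0.0, sig_ce[1], sig_ce[2]],
    ]
    sig, beta, ll, ok = _fit_model(data, (0, 1, 2), starts, vtot)
    # the reduced models are nested in ACE: if an optimizer quirk left the
    # full fit below one of them, the reduced optimum (with the dropped
    # component at its boundary) IS the full-model optimum found
    for ll_red, sig_red in ((ll_ae, (sig_ae[0], 0.0, sig_ae[2])),
                            (ll_ce, (0.0, sig_ce[1], sig_ce[2]))):
        if ll_red > ll:
            sig = np.array(sig_red)
            beta = _profile_beta(data, *sig)
            ll = ll_red

    total = float(sig.sum())
    h2, c2, e2 = (float(v / total) for v in sig)
    resid = values - x @ beta
    with np.errstate(invalid="ignore"):
        cve = 1.0 - float(np.nanvar(resid) / np.nanvar(values)) if x.shape[2] > 1 else 0.0
    cve = float(np.clip(cve, 0.0, 1.0))
    return ACEResult(
        trait=trait, anchor_ga=float(anchor_ga),
        sigma_a2=float(sig[0]), sigma_c2=float(sig[1]), sigma_e2=float(sig[2]),
        h2=h2, c2=c2, e2=e2, beta=beta, beta_names=names,
        loglik=ll, loglik_ae=ll_ae, loglik_ce=ll_ce, loglik_e=ll_e,
        p_h2=lrt_boundary(ll, ll_ce), p_c2=lrt_boundary(ll, ll_ae),
        covariate_var_explained=cve,
        n_mz_pairs=data.n_mz, n_dz_pairs=data.n_dz, converged=ok,
    )
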