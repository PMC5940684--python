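"""Bivariate ACE decomposition and the genetic correlation rho_G.

Two traits per twin give a 4-vector per pair, ordered
(twin1-trait1, twin1-trait2, twin2-trait1, twin2-trait2), with covariance

    Sigma = [[W, B], [B, W]],   W = SigmaA + SigmaC + SigmaE,
                                B = r * SigmaA + SigmaC,

where the 2x2 blocks SigmaA / SigmaC / SigmaE are the cross-trait
additive-genetic, shared-environment and unique-environment covariance
matrices and r is the zygosity kinship (1 for MZ, 0.5 for DZ).  SigmaA and
SigmaC are parameterized by Cholesky factors with nonnegative diagonals
(so they are positive semidefinite by construction); SigmaE's diagonal is
floored to keep the joint covariance invertible.  The genetic correlation
is rho_G = SigmaA[0,1] / sqrt(SigmaA[0,0] * SigmaA[1,1]); its
likelihood-ratio test constrains the SigmaA off-diagonal to zero, an
interior hypothesis, so the LRT reference is a plain chi-square with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .ace import KINSHIP

__all__ = ["BivariateResult", "fit_bivariate_ace", "rho_g_trend"]

_E_FLOOR = 1e-6
_LOG2PI = np.log(2.0 * np.pi)


def _chol2(l11, l21, l22) -> np.ndarray:
    l = np.array([[l11, 0.0], [l21, l22]])
    return l @ l.T


def _build_sigma(theta: np.ndarray, r: float, rho_zero: bool) -> np.ndarray:
    sa, sc, se = _unpack(theta, rho_zero)
    w = sa + sc + se
    b = r * sa + sc
    return np.block([[w, b], [b, w]])


def _unpack(theta: np.ndarray, rho_zero: bool):
    if rho_zero:
        a11, a22, c11, c21, c22, e11, e21, e22 = theta
        sa = np.diag([a11**2, a22**2])
    else:
        a11, a21, a22, c11, c21, c22, e11, e21, e22 = theta
        sa = _chol2(a11, a21, a22)
    sc = _chol2(c11, c21, c22)
    se = _chol2(e11, e21, e22) + _E_FLOOR * np.eye(2)
    return sa, sc, se


class _BivData:
    """Complete pairs grouped by zygosity plus a loop over incomplete ones."""

    def __init__(self, y: np.ndarray, x: np.ndarray, zygosity: np.ndarray):
        self.y = np.asarray(y, dtype=float)          # (n, 4)
        self.x = np.asarray(x, dtype=float)          # (n, 2, p) per-fetus design
        self.zygosity = np.asarray(zygosity)
        if self.y.shape[1] != 4:
            raise ValueError("y must be (n_pairs, 4)")
        self.p = self.x.shape[2]
        obs = ~np.isnan(self.y)
        self.complete = obs.all(axis=1)
        self.partial = ~self.complete & obs.any(axis=1)
        # mean design per pair: (4, 2p) rows f1t1, f1t2, f2t1, f2t2
        n = self.y.shape[0]
        self.m = np.zeros((n, 4, 2 * self.p))
        self.m[:, 0, : self.p] = self.x[:, 0]
        self.m[:, 1, self.p:] = self.x[:, 0]
        self.m[:, 2, : self.p] = self.x[:, 1]
        self.m[:, 3, self.p:] = self.x[:, 1]
        self.groups = {
            z: np.flatnonzero(self.complete & (self.zygosity == z)) for z in ("MZ", "DZ")
        }

    def n_complete(self, zyg: str) -> int:
        return len(self.groups[zyg])


def _loglik(theta: np.ndarray, data: _BivData, beta: np.ndarray, rho_zero: bool) -> float:
    ll = 0.0
    mu = data.m @ beta
    resid = data.y - mu
    for zyg, idx in data.groups.items():
        if idx.size == 0:
            continue
        sigma = _build_sigma(theta, KINSHIP[zyg], rho_zero)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return -np.inf
        inv = np.linalg.inv(sigma)
        rs = resid[idx]
        ll += -0.5 * (idx.size * (logdet + 4 * _LOG2PI) + np.einsum("ni,ij,nj->", rs, inv, rs))
    for i in np.flatnonzero(data.partial):
        sigma = _build_sigma(theta, KINSHIP[data.zygosity[i]], rho_zero)
        o = ~np.isnan(data.y[i])
        s = sigma[np.ix_(o, o)]
        sign, logdet = np.linalg.slogdet(s)
        if sign <= 0:
            return -np.inf
        r = resid[i][o]
        ll += -0.5 * (logdet + o.sum() * _LOG2PI + r @ np.linalg.solve(s, r))
    return float(ll)


def _profile_beta(theta: np.ndarray, data: _BivData, rho_zero: bool) -> np.ndarray:
    p2 = 2 * data.p
    a = np.zeros((p2, p2))
    b = np.zeros(p2)
    for zyg, idx in data.groups.items():
        if idx.size == 0:
            continue
        inv = np.linalg.inv(_build_sigma(theta, KINSHIP[zyg], rho_zero))
        ms, ys = data.m[idx], data.y[idx]
        mw = np.einsum("nif,ij->njf", ms, inv)
        a += np.einsum("njf,njg->fg", mw, ms)
        b += np.einsum("njf,nj->f", mw, ys)
    for i in np.flatnonzero(data.partial):
        sigma = _build_sigma(theta, KINSHIP[data.zygosity[i]], rho_zero)
        o = ~np.isnan(data.y[i])
        inv = np.linalg.inv(sigma[np.ix_(o, o)])
        mo = data.m[i][o]
        a += mo.T @ inv @ mo
        b += mo.T @ inv @ data.y[i][o]
    return np.linalg.lstsq(a, b, rcond=None)[0]


def _neg_profiled(theta: np.ndarray, data: _BivData, rho_zero: bool) -> float:
    beta = _profile_beta(theta, data, rho_zero)
    return -_loglik(theta, data, beta, rho_zero)


@dataclass
class BivariateResult:
    """Cross-trait ACE covariance decomposition at one anchor age."""

    trait_pair: tuple[str, str]
    anchor_ga: float
    sigma_a: np.ndarray
    sigma_c: np.ndarray
    sigma_e: np.ndarray
    rho_g: float
    rho_c: float
    rho_e: float
    rho_g_defined: bool
    loglik: float
    loglik_rho0: float
    p_rho_g: float
    n_mz_pairs: int
    n_dz_pairs: int
    converged: bool

    def to_dict(self) -> dict:
        d = dict(
            trait_pair=list(self.trait_pair), anchor_ga=self.anchor_ga,
            sigma_a=self.sigma_a.tolist(), sigma_c=self.sigma_c.tolist(),
            sigma_e=self.sigma_e.tolist(), rho_g=self.rho_g, rho_c=self.rho_c,
            rho_e=self.rho_e, rho_g_defined=self.rho_g_defined, loglik=self.loglik,
            p_rho_g=self.p_rho_g, n_mz_pairs=self.n_mz_pairs,
            n_dz_pairs=self.n_dz_pairs, converged=self.converged,
        )
        return d


def _corr_from(block: np.ndarray, floor: float) -> float:
    if block[0, 0] <= floor or block[1, 1] <= floor:
        return np.nan
    return float(block[0, 1] / np.sqrt(block[0, 0] * block[1, 1]))


def _starts(data: _BivData, v1: float, v2: float) -> list[np.ndarray]:
    """Starting Cholesky parameters built from univariate marginal fits."""
    def pack(h2_1, c2_1, h2_2, c2_2, rg, rc, re_):
        a11 = np.sqrt(max(h2_1 * v1, 1e-8))
        a22f = np.sqrt(max(h2_2 * v2, 1e-8))
        c11 = np.sqrt(max(c2_1 * v1, 1e-8))
        c22f = np.sqrt(max(c2_2 * v2, 1e-8))
        e1 = np.sqrt(max((1 - h2_1 - c2_1) * v1, 1e-6))
        e2 = np.sqrt(max((1 - h2_2 - c2_2) * v2, 1e-6))
        a21 = rg * a22f
        c21 = rc * c22f
        e21 = re_ * e2
        return np.array([
            a11, a21, np.sqrt(max(a22f**2 - a21**2, 1e-10)),
            c11, c21, np.sqrt(max(c22f**2 - c21**2, 1e-10)),
            e1, e21, np.sqrt(max(e2**2 - e21**2, 1e-8)),
        ])

    out = [
        pack(0.4, 0.3, 0.4, 0.3, 0.5, 0.5, 0.3),
        pack(0.33, 0.33, 0.33, 0.33, 0.0, 0.0, 0.0),
        pack(0.6, 0.1, 0.6, 0.1, 0.8, 0.3, 0.3),
    ]
    return out


def fit_bivariate_ace(values_trait1, values_trait2, zygosity, covariates=None, *,
                      trait_pair: tuple[str, str] = ("t1", "t2"),
                      anchor_ga: float = np.nan, compute_lrt: bool = True) -> BivariateResult:
    """Maximum-likelihood bivariate ACE fit for two traits at one anchor.

    ``values_trait1`` / ``values_trait2`` are (n_pairs, 2) co-twin arrays on
    the (transformed) analysis scale; ``covariates`` is an optional
    (n_pairs, 2, p) per-fetus design shared by both traits (an intercept is
    appended when absent).  Covariate coefficients, separate per trait, are
    profiled out by GLS.  Returns rho_G with a chi-square(1) LRT against the
    model with zero genetic covariance; when a trait's additive-genetic
    variance collapses to the boundary, rho_G is reported as undefined
    rather than fabricated.
    """
    y1 = np.asarray(values_trait1, dtype=float)
    y2 = np.asarray(values_trait2, dtype=float)
    if y1.shape != y2.shape or y1.shape[1] != 2:
        raise ValueError("trait value arrays must both be (n_pairs, 2)")
    # canonical internal trait order makes the fit exactly symmetric in the
    # order the caller passes the traits
    key1 = (float(np.nanvar(y1)), float(np.nansum(y1)))
    key2 = (float(np.nanvar(y2)), float(np.nansum(y2)))
    if key2 < key1:
        res = fit_bivariate_ace(values_trait2, values_trait1, zygosity, covariates,
                                trait_pair=(trait_pair[1], trait_pair[0]),
                                anchor_ga=anchor_ga, compute_lrt=compute_lrt)
        p = np.array([[0.0, 1.0], [1.0, 0.0]])
        return BivariateResult(
            trait_pair=tuple(trait_pair), anchor_ga=res.anchor_ga,
            sigma_a=p @ res.sigma_a @ p, sigma_c=p @ res.sigma_c @ p,
            sigma_e=p @ res.sigma_e @ p, rho_g=res.rho_g, rho_c=res.rho_c,
            rho_e=res.rho_e, rho_g_defined=res.rho_g_defined, loglik=res.loglik,
            loglik_rho0=res.loglik_rho0, p_rho_g=res.p_rho_g,
            n_mz_pairs=res.n_mz_pairs, n_dz_pairs=res.n_dz_pairs,
            converged=res.converged,
        )
    y = np.column_stack([y1[:, 0], y2[:, 0], y1[:, 1], y2[:, 1]])
    if covariates is None:
        x = np.ones((y1.shape[0], 2, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 2:
            covariates = np.repeat(covariates[:, None, :], 2, axis=1)
        flat = covariates.reshape(-1, covariates.shape[2])
        if np.any(np.ptp(flat, axis=0) == 0):
            x = covariates
        else:
            x = np.concatenate([np.ones((*covariates.shape[:2], 1)), covariates], axis=2)
    data = _BivData(y, x, zygosity)
    if data.n_complete("MZ") < 2 or data.n_complete("DZ") < 2:
        raise ValueError("need at least 2 complete MZ and 2 complete DZ pairs")

    v1 = float(np.nanvar(y1))
    v2 = float(np.nanvar(y2))
    scale = np.sqrt(max(v1, v2))
    bound = 10.0 * scale
    diag_idx_full = (0, 2, 3, 5, 6, 8)

    def bounds(rho_zero):
        n = 8 if rho_zero else 9
        diag = (0, 1, 2, 4, 5, 7) if rho_zero else diag_idx_full
        return [(0.0 if i in diag else -bound, bound) for i in range(n)]

    best = None
    for st in _starts(data, v1, v2):
        res = minimize(_neg_profiled, st, args=(data, False), method="L-BFGS-B",
                       bounds=bounds(False), options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 800})
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success)
    # polish from the winner with tight tolerances (convergence judged above)
    res = minimize(_neg_profiled, best.x, args=(data, False), method="L-BFGS-B",
                   bounds=bounds(False), options={"ftol": 1e-16, "gtol": 1e-11, "maxiter": 2000})
    if res.fun <= best.fun:
        best = res
    theta = best.x
    ll = -best.fun

    # constrained fit: SigmaA off-diagonal fixed at zero
    if compute_lrt:
        best0 = None
        for st in _starts(data, v1, v2):
            st0 = np.delete(st, 1)
            st0[0] = max(st0[0], 1e-4)
            res = minimize(_neg_profiled, st0, args=(data, True), method="L-BFGS-B",
                           bounds=bounds(True), options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 800})
            if best0 is None or res.fun < best0.fun:
                best0 = res
        ll0 = -best0.fun
    else:
        ll0 = np.nan

    sa, sc, se = _unpack(theta, False)
    floor = 1e-6 * max(v1, v2, 1e-12)
    rho_g = _corr_from(sa, floor)
    defined = np.isfinite(rho_g)
    if compute_lrt:
        t = max(0.0, 2.0 * (ll - ll0))
        p = float(chi2.sf(t, df=1)) if defined else np.nan
    else:
        p = np.nan
    return BivariateResult(
        trait_pair=tuple(trait_pair), anchor_ga=float(anchor_ga),
        sigma_a=sa, sigma_c=sc, sigma_e=se,
        rho_g=rho_g, rho_c=_corr_from(sc, floor), rho_e=_corr_from(se, 0.0),
        rho_g_defined=bool(defined), loglik=ll, loglik_rho0=ll0, p_rho_g=p,
        n_mz_pairs=data.n_complete("MZ"), n_dz_pairs=data.n_complete("DZ"),
        converged=converged,
    )


def rho_g_trend(results) -> dict:
    """Gestational trend of rho_G for one trait pair across anchors.

    Orders the estimates by anchor age, omits (and flags) anchors where
    rho_G is undefined, and reports the first-to-last difference and its
    sign; no smoothing is applied.  Requires at least two anchors with a
    defined estimate.
    """
    results = sorted(results, key=lambda r: r.anchor_ga)
    if len(results) < 2:
        raise ValueError("need results from at least two anchors")
    kept = [r for r in results if r.rho_g_defined]
    omitted = [r.anchor_ga for r in results if not r.rho_g_defined]
    if len(kept) < 2:
        raise ValueError("fewer than two anchors with a defined rho_G")
    seq = [(r.anchor_ga, r.rho_g) for r in kept]
    diff = kept[-1].rho_g - kept[0].rho_g
    return {
        "trait_pair": kept[0].trait_pair,
        "anchors": [a for a, _ in seq],
        "rho_g": [v for _, v in seq],
        "first_to_last_diff": float(diff),
        "sign": int(np.sign(diff)),
        "omitted_anchors": omitted,
    }
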