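"""Longitudinal growth trajectories: spline mixed model and anchor predictions.

Each trait is modelled across all visits pooled over zygosities as

    value = natural_spline(ga) * gamma + X * beta
            + pair-level (b0 + b1*ga' + b2*ga'^2 + b3*ga'^3)
            + fetus-within-pair intercept + residual,

with ``ga' = (ga - 26)/10`` centred and scaled to condition the cubic
random-effect terms, fitted by REML.  Best linear unbiased predictions of
the pair polynomial and the fetus intercept individualize each fetus's
trajectory; anchor-age predictions are fixed part + pair BLUP polynomial +
fetus BLUP intercept.  Estimated fetal weight is modelled on the log scale
(its SD grows proportionally with its mean); the skeletal traits are
modelled on the raw scale.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "SplineSpec",
    "natural_spline_basis",
    "TrajectoryFit",
    "fit_growth_lmm",
    "predict_at_anchor",
    "predict_anchor_dataset",
    "COVARIATE_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Covariate columns taken from the fetus-level covariate table into every
#: mean model (gravidity expands to two dummies).
COVARIATE_COLUMNS: tuple[str, ...] = (
    "maternal_age", "pre_pregnancy_bmi", "smoking", "alcohol", "race",
    "parity", "gravidity", "employment", "education", "marital", "sex",
)

_GA_CENTER, _GA_SCALE = 26.0, 10.0


@dataclass(frozen=True)
class SplineSpec:
    """Natural cubic spline specification for the mean growth curve."""

    interior_knots: tuple[float, ...] = (16.0, 22.0, 28.0, 34.0)
    boundary_knots: tuple[float, float] = (11.0, 41.0)
    degree: int = 3

    def __post_init__(self):
        lo, hi = self.boundary_knots
        ks = self.interior_knots
        if any(k2 <= k1 for k1, k2 in zip(ks, ks[1:])):
            raise ValueError("interior knots must be strictly increasing")
        if ks and (ks[0] <= lo or ks[-1] >= hi):
            raise ValueError("interior knots must lie inside the boundary knots")
        if self.degree != 3:
            raise ValueError("only cubic splines are supported")

    @property
    def all_knots(self) -> np.ndarray:
        return np.array([self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1]])

    @property
    def n_basis(self) -> int:
        """Number of non-intercept basis columns (interior knots + 1)."""
        return len(self.interior_knots) + 1


def natural_spline_basis(ga_weeks, spec: SplineSpec) -> np.ndarray:
    """Natural cubic spline basis (without intercept column).

    C2-continuous and linear beyond the boundary knots; with K total knots
    the spanned space has dimension K - 1 plus the intercept.  Valid for GA
    within [boundary_low - 1, boundary_high + 1].
    """
    x = np.atleast_1d(np.asarray(ga_weeks, dtype=float))
    lo, hi = spec.boundary_knots
    if np.any(x < lo - 1.0) or np.any(x > hi + 1.0):
        raise ValueError(f"gestational age outside [{lo - 1}, {hi + 1}]")
    knots = spec.all_knots
    kk = knots[-1]

    def d(k):
        return (np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - kk, 0, None) ** 3) / (kk - knots[k])

    cols = [x]
    d_last = d(len(knots) - 2)
    for k in range(len(knots) - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


@dataclass
class TrajectoryFit:
    """Fitted spline mixed model for one trait plus per-fetus BLUPs."""

    trait: str
    spec: SplineSpec
    log_scale: bool
    fixed_effects: "pd.Series"
    pair_re_cov: np.ndarray
    fetus_intercept_var: float
    residual_var: float
    loglik: float
    converged: bool
    pair_blups: Mapping[str, np.ndarray] = field(repr=False, default_factory=dict)
    fetus_blups: Mapping[tuple[str, int], float] = field(repr=False, default_factory=dict)
    fetus_info: "pd.DataFrame" = field(repr=False, default=None)  # per-fetus covariate row + last GA
    #: per fetus, (visit GA array, model residual array) for conditional prediction
    fetus_residuals: Mapping[tuple[str, int], tuple[np.ndarray, np.ndarray]] = field(
        repr=False, default_factory=dict
    )
    basis_names: tuple[str, ...] = ()
    covariate_names: tuple[str, ...] = ()
    dropped_columns: tuple[str, ...] = ()

    def summary_dict(self) -> dict:
        return {
            "trait": self.trait,
            "log_scale": self.log_scale,
            "fixed_effects": {k: float(v) for k, v in self.fixed_effects.items()},
            "pair_re_cov": np.asarray(self.pair_re_cov).tolist(),
            "fetus_intercept_var": float(self.fetus_intercept_var),
            "residual_var": float(self.residual_var),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "dropped_columns": list(self.dropped_columns),
        }


def _expand_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Fetus-level covariate design: gravidity -> two dummies, rest as-is."""
    out = pd.DataFrame(index=cov.index)
    for c in COVARIATE_COLUMNS:
        if c not in cov.columns:
            continue
        if c == "gravidity":
            out["gravidity_2"] = (cov[c] == 2).astype(float)
            out["gravidity_3"] = (cov[c] >= 3).astype(float)
        else:
            out[c] = cov[c].astype(float)
    return out


def _design_frame(measurements: pd.DataFrame, covariates: pd.DataFrame, trait: str,
                  spec: SplineSpec, log_scale: bool):
    sub = measurements.loc[measurements["trait"] == trait].copy()
    if sub.empty:
        raise ValueError(f"no measurements for trait {trait!r}")
    sub = sub.sort_values(["pair_id", "fetus_id", "ga_weeks"], kind="mergesort").reset_index(drop=True)
    cov = covariates.drop_duplicates(subset=["pair_id", "fetus_id"]).set_index(["pair_id", "fetus_id"])
    cov_design = _expand_covariates(cov)

    df = sub.merge(cov_design, left_on=["pair_id", "fetus_id"], right_index=True, how="left")
    missing = df[cov_design.columns].isna().any(axis=1)
    if missing.any():
        dropped = df.loc[missing, ["pair_id", "fetus_id"]].drop_duplicates()
        logger.info("%s: excluding %d fetuses without covariates", trait, len(dropped))
        df = df.loc[~missing].reset_index(drop=True)
    y = np.log(df["value"].to_numpy()) if log_scale else df["value"].to_numpy()
    df["y"] = y
    basis = natural_spline_basis(df["ga_weeks"].to_numpy(), spec)
    basis_names = tuple(f"ns{j + 1}" for j in range(basis.shape[1]))
    for j, name in enumerate(basis_names):
        df[name] = basis[:, j]
    gas = (df["ga_weeks"].to_numpy() - _GA_CENTER) / _GA_SCALE
    df["gas"], df["gas2"], df["gas3"] = gas, gas**2, gas**3
    df["fetus_uid"] = df["pair_id"].astype(str) + "_" + df["fetus_id"].astype(str)

    cov_names = []
    dropped_cols = []
    for c in cov_design.columns:
        if np.ptp(df[c].to_numpy()) == 0:
            logger.warning("%s: dropping constant covariate column %r", trait, c)
            dropped_cols.append(c)
        else:
            cov_names.append(c)
    return df, basis_names, tuple(cov_names), tuple(dropped_cols), cov_design


def fit_growth_lmm(measurements: pd.DataFrame, covariates: pd.DataFrame, trait: str,
                   spec: SplineSpec | None = None, log_scale: bool | None = None,
                   maxiter: int = 200) -> TrajectoryFit:
    """Fit the spline linear mixed model for one trait by REML.

    Random effects: a pair-level (intercept, linear, quadratic, cubic)
    polynomial in centred GA with unstructured 4x4 covariance, plus an iid
    fetus-within-pair intercept.  When the fixed-effect design already fits
    the data exactly (noise-free input), the degenerate REML problem is
    short-circuited to the least-squares solution with all variances zero.
    """
    spec = spec or SplineSpec()
    if log_scale is None:
        log_scale = trait == "EFW"
    df, basis_names, cov_names, dropped, cov_design = _design_frame(
        measurements, covariates, trait, spec, log_scale
    )

    fe_cols = list(basis_names) + list(cov_names)
    xmat = np.column_stack([np.ones(len(df))] + [df[c].to_numpy() for c in fe_cols])
    coef, *_ = np.linalg.lstsq(xmat, df["y"].to_numpy(), rcond=None)
    resid = df["y"].to_numpy() - xmat @ coef
    fe_index = ["Intercept"] + fe_cols

    fetus_info = _fetus_info(df, cov_design)

    if np.var(resid) < 1e-12 * max(np.var(df["y"].to_numpy()), 1e-300):
        # exact interpolation: all variance components vanish
        mse = float(np.mean(resid**2))
        ll = -0.5 * len(df) * (np.log(2 * np.pi * max(mse, 1e-300)) + 1.0)
        fit = TrajectoryFit(
            trait=trait, spec=spec, log_scale=log_scale,
            fixed_effects=pd.Series(coef, index=fe_index),
            pair_re_cov=np.zeros((4, 4)), fetus_intercept_var=0.0,
            residual_var=mse, loglik=ll, converged=True,
            pair_blups={p: np.zeros(4) for p in df["pair_id"].unique()},
            fetus_blups={k: 0.0 for k in fetus_info.index},
            fetus_info=fetus_info, basis_names=basis_names,
            covariate_names=cov_names, dropped_columns=dropped,
        )
        fit.fetus_residuals = _visit_residuals(fit, df)
        return fit

    formula = "y ~ " + " + ".join(fe_cols)
    model = smf.mixedlm(
        formula, df, groups=df["pair_id"],
        re_formula="~ 1 + gas + gas2 + gas3",
        vc_formula={"fetus": "0 + C(fetus_uid)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        attempts = []
        for method in ("lbfgs", None, "powell"):
            try:
                r = model.fit(reml=True, method=method, maxiter=maxiter)
            except Exception:
                continue
            if np.isfinite(r.llf):
                attempts.append(r)
            if attempts and attempts[-1].converged and method == "lbfgs":
                break
        if not attempts:
            raise RuntimeError(f"mixed-model fit failed for trait {trait!r}")
        # keep the best restricted likelihood; prefer a converged fit when
        # it is not materially worse
        attempts.sort(key=lambda r: r.llf, reverse=True)
        res = attempts[0]
        for r in attempts:
            if r.converged and r.llf >= res.llf - 1e-3 * max(1.0, abs(res.llf)):
                res = r
                break

    scale = float(res.scale)
    cov_re = np.asarray(res.cov_re)
    fetus_var = float(np.asarray(res.vcomp).ravel()[0])

    pair_blups: dict[str, np.ndarray] = {}
    fetus_blups: dict[tuple[str, int], float] = {}
    for group, series in res.random_effects.items():
        vals = series.to_numpy()
        pair_blups[str(group)] = vals[:4]
        for name, v in series.items():
            m = re.search(r"\[([^\[\]]+_\d+)\]\]$", str(name))
            if m:
                pid, fid = m.group(1).rsplit("_", 1)
                fetus_blups[(pid, int(fid))] = float(v)

    fit = TrajectoryFit(
        trait=trait, spec=spec, log_scale=log_scale,
        fixed_effects=pd.Series(res.fe_params.to_numpy(), index=fe_index),
        pair_re_cov=cov_re, fetus_intercept_var=fetus_var,
        residual_var=scale, loglik=float(res.llf), converged=bool(res.converged),
        pair_blups=pair_blups, fetus_blups=fetus_blups,
        fetus_info=fetus_info, basis_names=basis_names,
        covariate_names=cov_names, dropped_columns=dropped,
    )
    fit.fetus_residuals = _visit_residuals(fit, df)
    return fit


def _visit_residuals(fit: TrajectoryFit, df: pd.DataFrame) -> dict:
    """Per-fetus visit residuals around the individualized model trajectory."""
    out = {}
    for (pid, fid), g in df.groupby(["pair_id", "fetus_id"], sort=True):
        gv = g["ga_weeks"].to_numpy()
        basis = natural_spline_basis(gv, fit.spec)
        gs = (gv - _GA_CENTER) / _GA_SCALE
        mu = np.full(gv.shape, float(fit.fixed_effects["Intercept"]))
        for j, name in enumerate(fit.basis_names):
            mu += fit.fixed_effects[name] * basis[:, j]
        row = g.iloc[0]
        for name in fit.covariate_names:
            mu += fit.fixed_effects[name] * float(row[name])
        mu += np.column_stack([np.ones_like(gs), gs, gs**2, gs**3]) @ fit.pair_blups.get(str(pid), np.zeros(4))
        mu += fit.fetus_blups.get((pid, fid), 0.0)
        out[(pid, int(fid))] = (gv, g["y"].to_numpy() - mu)
    return out


def _fetus_info(df: pd.DataFrame, cov_design: pd.DataFrame) -> pd.DataFrame:
    grp = df.groupby(["pair_id", "fetus_id"], sort=True)
    info = grp.agg(last_ga=("ga_weeks", "max"), zygosity=("zygosity", "first"))
    return info.join(cov_design, how="left")


def _fixed_row(fit: TrajectoryFit, anchor_ga: float, cov_row: Mapping[str, float]) -> float:
    basis = natural_spline_basis(anchor_ga, fit.spec)[0]
    val = fit.fixed_effects["Intercept"]
    for j, name in enumerate(fit.basis_names):
        val += fit.fixed_effects[name] * basis[j]
    for name in fit.covariate_names:
        val += fit.fixed_effects[name] * float(cov_row[name])
    return float(val)


def predict_at_anchor(fit: TrajectoryFit, pair_id: str, fetus_id: int, anchor_ga: float,
                      covariates: Mapping[str, float] | None = None,
                      conditional: bool = True) -> tuple[float, bool]:
    """Predicted trait value for one fetus at one anchor age.

    Fixed part + pair BLUP polynomial + fetus BLUP intercept, back-transformed
    from the log scale where applicable.  With ``conditional=True`` (default)
    the prediction additionally conditions on the fetus's observed deviations
    around its individualized trajectory: within-fetus residuals are serially
    correlated in gestational age (growth deviations persist between visits),
    so the residual at the anchor is interpolated linearly between the
    bracketing visits and held constant beyond the observed range.  This
    keeps anchor values faithful to the fetus's local data instead of
    collapsing within-pair differences to a gestation-constant offset.
    ``extrapolated`` is True when the anchor lies beyond the fetus's last
    observed visit.
    """
    key = (pair_id, fetus_id)
    if key not in fit.fetus_info.index:
        raise KeyError(f"unknown fetus {key}")
    row = fit.fetus_info.loc[key]
    cov_row = covariates if covariates is not None else row
    pred = _fixed_row(fit, anchor_ga, cov_row)
    gs = (anchor_ga - _GA_CENTER) / _GA_SCALE
    pred += float(fit.pair_blups.get(str(pair_id), np.zeros(4)) @ np.array([1.0, gs, gs**2, gs**3]))
    pred += float(fit.fetus_blups.get(key, 0.0))
    if conditional and key in fit.fetus_residuals:
        gv, rv = fit.fetus_residuals[key]
        pred += float(np.interp(anchor_ga, gv, rv))
    if fit.log_scale:
        pred = float(np.exp(pred))
    return pred, bool(anchor_ga > row["last_ga"] + 1e-12)


def predict_anchor_dataset(fits: Mapping[str, TrajectoryFit] | Sequence[TrajectoryFit],
                           anchors: Sequence[float], conditional: bool = True) -> pd.DataFrame:
    """Anchor predictions for every fetus x anchor x trait as a tidy table."""
    if not isinstance(fits, Mapping):
        fits = {f.trait: f for f in fits}
    rows = []
    for trait, fit in fits.items():
        for (pair_id, fetus_id), info in fit.fetus_info.iterrows():
            for ga in anchors:
                pred, extrap = predict_at_anchor(fit, pair_id, fetus_id, float(ga),
                                                 conditional=conditional)
                rows.append((pair_id, fetus_id, info["zygosity"], float(ga), trait, pred, extrap))
    return pd.DataFrame(
        rows,
        columns=["pair_id", "fetus_id", "zygosity", "anchor_ga", "trait",
                 "predicted_value", "extrapolated"],
    )
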