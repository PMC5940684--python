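"""Seeded synthetic dichorionic-twin ultrasound cohorts.

The generator realizes the twin-design assumptions that the downstream
estimators rely on: MZ co-twins share their additive-genetic component A
entirely, DZ co-twins correlate 0.5 on A; the common environment C is shared
by both co-twins regardless of zygosity; the unique environment E is drawn
independently per fetus.  Variance fractions (h2, c2, e2) are defined on the
log scale of each trait at each anchor gestational age, so trait values are
log-normal and automatically positive, and the total log-scale SD is
calibrated to the anchor coefficients of variation.  Between anchors a
fetus's standardized latent score is linearly interpolated in gestational
age.

Estimated fetal weight is a first-class simulated trait with its own latent
ACE structure; head circumference is then derived per visit by inverting the
Hadlock formula, so that the EFW measurement rows satisfy the Hadlock
identity with the same visit's HC/AC/FL rows exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .config import (
    ANCHOR_GAS,
    ANCHOR_MEANS,
    ANCHOR_SDS,
    COVARIATE_DISTRIBUTIONS,
    INITIAL_VISIT_RANGE,
    SCHEDULE_A,
    SCHEDULE_B,
    TRAITS,
    CohortConfig,
    ConfigError,
)

__all__ = [
    "hadlock_efw",
    "hc_from_hadlock",
    "mean_growth_curve",
    "assign_visit_schedule",
    "simulate_cohort",
    "simulate_anchor_values",
    "TruthRecord",
    "HC_ANCHOR_MEANS",
]

GA_DOMAIN = (10.0, 42.0)

# Hadlock 3-parameter (HC, AC, FL) coefficients; inputs cm, output grams.
_H_INT, _H_ACFL, _H_HC, _H_AC, _H_FL = 1.326, -0.00326, 0.0107, 0.0438, 0.158


def hadlock_efw(hc_mm, ac_mm, fl_mm):
    """Estimated fetal weight in grams from HC, AC, FL in millimetres.

    log10(EFW) = 1.326 - 0.00326*AC*FL + 0.0107*HC + 0.0438*AC + 0.158*FL
    with biometrics in centimetres.
    """
    hc, ac, fl = (np.asarray(x, dtype=float) / 10.0 for x in (hc_mm, ac_mm, fl_mm))
    if np.any(hc <= 0) or np.any(ac <= 0) or np.any(fl <= 0):
        raise ValueError("HC, AC and FL must all be strictly positive")
    log10 = _H_INT + _H_ACFL * ac * fl + _H_HC * hc + _H_AC * ac + _H_FL * fl
    out = 10.0 ** log10
    return float(out) if out.ndim == 0 else out


def hc_from_hadlock(efw_g, ac_mm, fl_mm):
    """Head circumference (mm) solving the Hadlock identity for given EFW.

    The formula is linear in HC on the log10 scale, so the inversion is exact:
    ``hadlock_efw(hc_from_hadlock(w, ac, fl), ac, fl) == w``.
    """
    efw = np.asarray(efw_g, dtype=float)
    ac = np.asarray(ac_mm, dtype=float) / 10.0
    fl = np.asarray(fl_mm, dtype=float) / 10.0
    if np.any(efw <= 0) or np.any(ac <= 0) or np.any(fl <= 0):
        raise ValueError("EFW, AC and FL must all be strictly positive")
    hc = (np.log10(efw) - _H_INT - _H_ACFL * ac * fl - _H_AC * ac - _H_FL * fl) / _H_HC
    out = hc * 10.0
    return float(out) if out.ndim == 0 else out


#: HC anchor means (mm) derived so Hadlock EFW at the per-anchor trait means
#: reproduces the EFW anchor means exactly.
HC_ANCHOR_MEANS: tuple[float, ...] = tuple(
    hc_from_hadlock(ANCHOR_MEANS["EFW"][k], ANCHOR_MEANS["AC"][k], ANCHOR_MEANS["FL"][k])
    for k in range(4)
)

_CURVE_ANCHORS: dict[str, tuple[float, ...]] = {
    t: v for t, v in ANCHOR_MEANS.items() if t != "EFW"
}
_CURVE_ANCHORS["HC"] = HC_ANCHOR_MEANS


class _LogPchipCurve:
    """Monotone curve through anchor points, interpolated on the log scale.

    Inside the anchor range the curve is a monotone cubic (PCHIP) through
    log(mean); beyond it, linear continuation of the boundary log-slope.
    Log-scale interpolation keeps the curve strictly positive everywhere.
    """

    def __init__(self, gas: Sequence[float], values: Sequence[float]):
        self.x = np.asarray(gas, dtype=float)
        self.p = PchipInterpolator(self.x, np.log(np.asarray(values, dtype=float)))
        self.d = self.p.derivative()
        self.lo, self.hi = self.x[0], self.x[-1]

    def __call__(self, ga):
        ga = np.asarray(ga, dtype=float)
        g = np.clip(ga, self.lo, self.hi)
        logv = self.p(g)
        logv = logv + np.where(ga < self.lo, (ga - self.lo) * self.d(self.lo), 0.0)
        logv = logv + np.where(ga > self.hi, (ga - self.hi) * self.d(self.hi), 0.0)
        return np.exp(logv)


_MEAN_CURVES = {t: _LogPchipCurve(ANCHOR_GAS, v) for t, v in _CURVE_ANCHORS.items()}


def mean_growth_curve(trait: str, ga_weeks):
    """Expected trait value at gestational age ``ga_weeks`` (decimal weeks).

    Smooth, strictly increasing, and reproduces the anchor means exactly.
    The EFW curve is the Hadlock composition of the HC/AC/FL curves, which
    keeps the five mean curves mutually consistent at every GA (the HC
    anchors were derived from that same identity).  Valid for GA in
    [10, 42]; AC/HL/FL/HC in mm, EFW in grams.
    """
    ga = np.asarray(ga_weeks, dtype=float)
    if np.any(ga < GA_DOMAIN[0]) or np.any(ga > GA_DOMAIN[1]):
        raise ValueError(f"gestational age outside {GA_DOMAIN}")
    if trait == "EFW":
        out = np.asarray(
            hadlock_efw(_MEAN_CURVES["HC"](ga), _MEAN_CURVES["AC"](ga), _MEAN_CURVES["FL"](ga))
        )
    elif trait in _MEAN_CURVES:
        out = _MEAN_CURVES[trait](ga)
    else:
        raise ValueError(f"unknown trait {trait!r}")
    return float(out) if out.ndim == 0 else out


def assign_visit_schedule(pair_seed) -> np.ndarray:
    """Visit gestational ages for one pair: initial scan + schedule A or B.

    The initial sonogram GA is uniform on [11w0d, 13w6d]; schedules A
    (16,20,24,28,32,35) and B (18,22,26,30,34,36) are equally likely.
    ``pair_seed`` may be an integer seed or a numpy Generator.
    """
    rng = pair_seed if isinstance(pair_seed, np.random.Generator) else np.random.default_rng(pair_seed)
    initial = rng.uniform(*INITIAL_VISIT_RANGE)
    sched = SCHEDULE_A if rng.random() < 0.5 else SCHEDULE_B
    return np.array([initial, *sched], dtype=float)


@dataclass
class TruthRecord:
    """Realized generative parameters and latent draws of one cohort.

    Arrays are indexed [fetus, anchor, trait] (trait order ``TRAITS``);
    ``c_components`` is [pair, trait] since C is shared across anchors and
    co-twins.  ``anchor_values`` holds the noise-free latent trait values at
    the anchor ages — the ground truth that anchor predictions estimate.
    """

    seed: int
    anchor_gas: tuple[float, ...]
    traits: tuple[str, ...]
    variance_plan: Mapping[str, Sequence[tuple[float, float, float]]]
    rho_g_plan: Sequence[np.ndarray]
    covariate_effects: Mapping[str, float]
    pair_ids: list[str] = field(repr=False, default_factory=list)
    fetus_index: pd.DataFrame = field(repr=False, default=None)  # pair_id, fetus_id, zygosity
    a_components: np.ndarray = field(repr=False, default=None)
    c_components: np.ndarray = field(repr=False, default=None)
    e_components: np.ndarray = field(repr=False, default=None)
    latent_scores: np.ndarray = field(repr=False, default=None)
    anchor_values: np.ndarray = field(repr=False, default=None)

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "anchor_gas": list(self.anchor_gas),
            "traits": list(self.traits),
            "variance_plan": {t: [list(x) for x in v] for t, v in self.variance_plan.items()},
            "rho_g_plan": [np.asarray(m).tolist() for m in self.rho_g_plan],
            "covariate_effects": dict(self.covariate_effects),
            "pair_ids": list(self.pair_ids),
            "fetus_index": self.fetus_index.to_dict(orient="list"),
            "a_components": self.a_components.tolist(),
            "c_components": self.c_components.tolist(),
            "e_components": self.e_components.tolist(),
            "latent_scores": self.latent_scores.tolist(),
            "anchor_values": self.anchor_values.tolist(),
        }
        return json.dumps(d)


def _corr_sqrt(m: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root, tolerant of zero eigenvalues."""
    w, v = np.linalg.eigh(np.asarray(m, dtype=float))
    if w.min() < -1e-10:
        raise ConfigError("correlation matrix is not positive semidefinite")
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T


def _draw_trait_anchor(rng, roots: list[np.ndarray], rho_time: float) -> np.ndarray:
    """One (anchor, trait) latent draw with cross-trait correlation per anchor
    and cross-anchor persistence ``rho_time``.

    Per anchor k the trait vector is ``L_k u_k`` with ``u_k`` a unit-normal
    vector mixing a shared factor (weight sqrt(rho_time)) with an
    anchor-specific one, so marginals at each anchor follow the anchor's
    correlation matrix exactly.
    """
    n_k = len(roots)
    n_t = roots[0].shape[0]
    shared = rng.standard_normal(n_t)
    own = rng.standard_normal((n_k, n_t))
    u = np.sqrt(rho_time) * shared[None, :] + np.sqrt(1.0 - rho_time) * own
    return np.stack([roots[k] @ u[k] for k in range(n_k)])


def _draw_pair_covariates(rng, zygosity: str) -> dict:
    cd = COVARIATE_DISTRIBUTIONS
    age = rng.normal(*cd["maternal_age"])
    bmi = rng.normal(*cd["pre_pregnancy_bmi"])
    while bmi < 15.0:
        bmi = rng.normal(*cd["pre_pregnancy_bmi"])
    row = {
        "maternal_age": age,
        "pre_pregnancy_bmi": bmi,
        "smoking": int(rng.random() < cd["smoking"]),
        "alcohol": int(rng.random() < cd["alcohol"]),
        "race": int(rng.random() < cd["race"]),
        "parity": int(rng.random() < cd["parity"]),
        "gravidity": int(rng.choice(3, p=cd["gravidity"]) + 1),
        "employment": int(rng.random() < cd["employment"]),
        "education": int(rng.random() < cd["education"]),
        "marital": int(rng.random() < cd["marital"]),
    }
    if zygosity == "MZ":
        sex = int(rng.random() < 0.5)
        row["sexes"] = (sex, sex)
    else:
        row["sexes"] = (int(rng.random() < 0.5), int(rng.random() < 0.5))
    return row


def _standardized_covariates(cov_row: dict, sex: int) -> dict[str, float]:
    cd = COVARIATE_DISTRIBUTIONS
    p_race = cd["race"]
    return {
        "maternal_age": (cov_row["maternal_age"] - cd["maternal_age"][0]) / cd["maternal_age"][1],
        "fetal_sex": (sex - 0.5) / 0.5,
        "race": (cov_row["race"] - p_race) / np.sqrt(p_race * (1 - p_race)),
    }


def simulate_cohort(config: CohortConfig):
    """Simulate one cohort; returns (measurements, covariates, truth).

    ``measurements`` is a long-format table (pair_id, fetus_id, zygosity,
    ga_weeks, trait, value) over AC/HL/FL/HC/EFW; ``covariates`` has one row
    per fetus; ``truth`` is the :class:`TruthRecord` of latent draws.
    Deterministic given the config (including its seed).
    """
    config.validate()
    anchors = np.asarray(config.anchor_gas, dtype=float)
    n_k = len(anchors)
    traits = TRAITS
    n_t = len(traits)

    # Per-anchor log-scale SD calibrated to the anchor CVs (lognormal exact).
    s = np.empty((n_t, n_k))
    means = np.empty((n_t, n_k))
    for ti, t in enumerate(traits):
        cv = np.asarray(ANCHOR_SDS[t]) / np.asarray(ANCHOR_MEANS[t])
        s[ti] = np.sqrt(np.log1p(cv**2))
        means[ti] = np.asarray(ANCHOR_MEANS[t], dtype=float)

    sqrt_h = np.empty((n_t, n_k))
    sqrt_c = np.empty((n_t, n_k))
    sqrt_e = np.empty((n_t, n_k))
    for ti, t in enumerate(traits):
        plan = np.asarray(config.variance_plan[t], dtype=float)
        sqrt_h[ti], sqrt_c[ti], sqrt_e[ti] = np.sqrt(plan.T)

    roots = [_corr_sqrt(np.asarray(m)) for m in config.rho_g_plan]
    root_c = _corr_sqrt(np.asarray(config.rho_c))
    roots_e = [_corr_sqrt(np.asarray(config.rho_e))] * n_k
    beta = dict(config.covariate_effects)
    v_beta = float(sum(b * b for b in beta.values()))
    denom = np.sqrt(1.0 + v_beta)
    cv_m = {t: float(config.measurement_cv.get(t, 0.0)) for t in traits}

    n_pairs = config.n_mz + config.n_dz
    meas_rows: list[tuple] = []
    cov_rows: list[dict] = []
    fet_idx: list[tuple] = []
    a_all, c_all, e_all, g_all, v_all = [], [], [], [], []
    pair_ids = []

    for i in range(n_pairs):
        zyg = "MZ" if i < config.n_mz else "DZ"
        pair_id = f"P{i + 1:04d}"
        pair_ids.append(pair_id)
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, i)))

        cov = _draw_pair_covariates(rng, zyg)
        delivery = rng.normal(config.delivery_mean_ga, config.delivery_sd_ga)
        while not (config.delivery_range[0] <= delivery <= config.delivery_range[1]):
            delivery = rng.normal(config.delivery_mean_ga, config.delivery_sd_ga)
        visits = assign_visit_schedule(rng)

        r_a = 1.0 if zyg == "MZ" else 0.5
        a_pair = _draw_trait_anchor(rng, roots, config.rho_a_time)
        a_ind = [_draw_trait_anchor(rng, roots, config.rho_a_time) for _ in range(2)]
        c_pair = root_c @ rng.standard_normal(n_t)
        e_draws = [_draw_trait_anchor(rng, roots_e, config.rho_e_time) for _ in range(2)]

        kept = visits[visits <= delivery]
        for f in range(2):
            fetus_id = f + 1
            sex = cov["sexes"][f]
            a_f = np.sqrt(r_a) * a_pair + np.sqrt(1.0 - r_a) * a_ind[f]
            e_f = e_draws[f]
            z = _standardized_covariates(cov, sex)
            xb = float(sum(beta.get(name, 0.0) * z[name] for name in z))
            # latent standardized score per anchor per trait
            g = (sqrt_h.T * a_f + sqrt_c.T * c_pair[None, :] + sqrt_e.T * e_f + xb) / denom

            a_all.append(a_f)
            c_all.append(c_pair) if f == 0 else None
            e_all.append(e_f)
            g_all.append(g)
            fet_idx.append((pair_id, fetus_id, zyg))

            anchor_vals = means.T * np.exp(s.T * g - 0.5 * s.T**2)  # (n_k, n_t)
            v_all.append(anchor_vals)

            crow = {k: v for k, v in cov.items() if k != "sexes"}
            crow.update(pair_id=pair_id, fetus_id=fetus_id, zygosity=zyg,
                        sex=sex, delivery_ga=delivery)
            cov_rows.append(crow)

            if kept.size == 0:
                continue
            noise_z = rng.standard_normal((kept.size, n_t))
            obs = np.empty((kept.size, n_t))
            for ti, t in enumerate(traits):
                g_v = np.interp(kept, anchors, g[:, ti])
                s_v = np.interp(kept, anchors, s[ti])
                mu_v = mean_growth_curve(t, kept)
                vals = mu_v * np.exp(s_v * g_v - 0.5 * s_v**2)
                if cv_m[t] > 0:
                    sig = np.sqrt(np.log1p(cv_m[t] ** 2))
                    vals = vals * np.exp(sig * noise_z[:, ti] - 0.5 * sig**2)
                obs[:, ti] = vals
            # HC solves the Hadlock identity for the fetus's EFW given the
            # observed AC/FL (EFW is a derived measure, so its "noise" enters
            # only through the biometrics); a 5 mm floor guards against
            # extreme joint draws, with EFW recomputed to keep the identity.
            i_ac, i_fl, i_efw = traits.index("AC"), traits.index("FL"), traits.index("EFW")
            hc_obs = np.maximum(
                np.atleast_1d(hc_from_hadlock(obs[:, i_efw], obs[:, i_ac], obs[:, i_fl])), 5.0
            )
            obs[:, i_efw] = hadlock_efw(hc_obs, obs[:, i_ac], obs[:, i_fl])
            for vi, ga in enumerate(kept):
                for ti, t in enumerate(traits):
                    meas_rows.append((pair_id, fetus_id, zyg, ga, t, obs[vi, ti]))
                meas_rows.append((pair_id, fetus_id, zyg, ga, "HC", float(hc_obs[vi])))

    measurements = pd.DataFrame(
        meas_rows, columns=["pair_id", "fetus_id", "zygosity", "ga_weeks", "trait", "value"]
    )
    covariates = pd.DataFrame(cov_rows)[
        ["pair_id", "fetus_id", "zygosity", "sex", "maternal_age", "pre_pregnancy_bmi",
         "smoking", "alcohol", "race", "parity", "gravidity", "employment", "education",
         "marital", "delivery_ga"]
    ]
    truth = TruthRecord(
        seed=config.seed,
        anchor_gas=tuple(anchors),
        traits=traits,
        variance_plan=config.variance_plan,
        rho_g_plan=config.rho_g_plan,
        covariate_effects=beta,
        pair_ids=pair_ids,
        fetus_index=pd.DataFrame(fet_idx, columns=["pair_id", "fetus_id", "zygosity"]),
        a_components=np.stack(a_all),
        c_components=np.stack(c_all),
        e_components=np.stack(e_all),
        latent_scores=np.stack(g_all),
        anchor_values=np.stack(v_all),
    )
    return measurements, covariates, truth


def simulate_bivariate_anchor_values(n_mz: int, n_dz: int, plan1, plan2, rho_g: float,
                                     rng, rho_c: float = 0.0, rho_e: float = 0.0):
    """Two-trait single-anchor twin values on the standardized latent scale.

    ``plan1`` / ``plan2`` are (h2, c2) per trait; ``rho_g`` / ``rho_c`` /
    ``rho_e`` are the cross-trait correlations of the A / C / E components.
    Returns ``(values1, values2, zygosity)`` with each values array
    (n_pairs, 2); co-twin and cross-trait covariances follow the ACE twin
    structure exactly.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = n_mz + n_dz
    r = np.concatenate([np.ones(n_mz), np.full(n_dz, 0.5)])[:, None]

    def corr_pair(rho, shape):
        z0 = rng.standard_normal(shape)
        z1 = rng.standard_normal(shape)
        return z0, rho * z0 + np.sqrt(1.0 - rho**2) * z1

    a_p1, a_p2 = corr_pair(rho_g, (n, 1))
    a_i1, a_i2 = corr_pair(rho_g, (n, 2))
    a1 = np.sqrt(r) * a_p1 + np.sqrt(1 - r) * a_i1
    a2_ = np.sqrt(r) * a_p2 + np.sqrt(1 - r) * a_i2
    c1, c2_ = corr_pair(rho_c, (n, 1))
    e1, e2_ = corr_pair(rho_e, (n, 2))

    def mix(plan, a, c, e):
        h2, cc2 = plan
        e2 = 1.0 - h2 - cc2
        if e2 < 0 or min(h2, cc2) < 0:
            raise ConfigError("each plan needs h2, c2 >= 0 with h2 + c2 <= 1")
        return np.sqrt(h2) * a + np.sqrt(cc2) * c + np.sqrt(e2) * e

    y1 = mix(plan1, a1, c1, e1)
    y2 = mix(plan2, a2_, c2_, e2_)
    zyg = np.array(["MZ"] * n_mz + ["DZ"] * n_dz)
    return y1, y2, zyg


def simulate_anchor_values(n_mz: int, n_dz: int, h2: float, c2: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Single-trait single-anchor twin values on the standardized latent scale.

    Vectorized fast path used by the power simulator and the oracle tests:
    returns ``(values, zygosity)`` with values of shape (n_pairs, 2),
    unit marginal variance, co-twin correlation h2 + c2 for MZ and
    0.5*h2 + c2 for DZ.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    e2 = 1.0 - h2 - c2
    if e2 < 0 or min(h2, c2) < 0:
        raise ConfigError("h2 and c2 must be nonnegative with h2 + c2 <= 1")
    n = n_mz + n_dz
    r = np.concatenate([np.ones(n_mz), np.full(n_dz, 0.5)])
    a_pair = rng.standard_normal(n)
    a_ind = rng.standard_normal((n, 2))
    a = np.sqrt(r)[:, None] * a_pair[:, None] + np.sqrt(1 - r)[:, None] * a_ind
    c = rng.standard_normal(n)[:, None]
    e = rng.standard_normal((n, 2))
    y = np.sqrt(h2) * a + np.sqrt(c2) * c + np.sqrt(e2) * e
    zyg = np.array(["MZ"] * n_mz + ["DZ"] * n_dz)
    return y, zyg
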