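"""Study-design constants and cohort configuration.

The defaults encode the design of a prospective dichorionic-twin ultrasound
cohort: 15 monozygotic (MZ) and 133 dizygotic (DZ) pairs, up to seven
sonograms per pregnancy, and four anchor gestational ages (end of first
trimester 13w6d, mid-gestation 20w, late second trimester 27w6d, third
trimester 38w6d) at which growth trajectories are evaluated and the ACE
variance decomposition is performed.

Trait calibration anchors (means and SDs of abdominal circumference AC,
humerus length HL, femur length FL and estimated fetal weight EFW at the
four anchors) come from the cohort's DZ column; head circumference HC
anchors are derived in closed form from the Hadlock identity so that
EFW computed from the per-anchor HC/AC/FL means reproduces the EFW anchor
means exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "TRAITS",
    "ANCHOR_GAS",
    "ANCHOR_MEANS",
    "ANCHOR_SDS",
    "DEFAULT_VARIANCE_PLAN",
    "DEFAULT_RHO_G_PLAN",
    "CohortConfig",
    "ConfigError",
    "ga_from_weeks_days",
]


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def ga_from_weeks_days(weeks: int, days: int) -> float:
    """Gestational age in decimal weeks; 13w6d -> 13.857142857..."""
    return weeks + days / 7.0


#: Analyzed fetal growth traits (HC is simulated but not analyzed).
TRAITS: tuple[str, ...] = ("AC", "HL", "FL", "EFW")

#: Anchor gestational ages in decimal weeks: 13w6d, 20w0d, 27w6d, 38w6d.
ANCHOR_GAS: tuple[float, ...] = (
    ga_from_weeks_days(13, 6),
    20.0,
    ga_from_weeks_days(27, 6),
    ga_from_weeks_days(38, 6),
)

#: DZ trait means at the four anchors (mm for AC/HL/FL, grams for EFW).
ANCHOR_MEANS: dict[str, tuple[float, ...]] = {
    "AC": (77.0, 150.5, 235.8, 331.1),
    "HL": (13.0, 31.0, 46.9, 61.2),
    "FL": (12.4, 31.9, 51.3, 70.2),
    "EFW": (82.0, 335.5, 1157.8, 3046.8),
}

#: DZ trait SDs at the four anchors (same units as the means).
ANCHOR_SDS: dict[str, tuple[float, ...]] = {
    "AC": (5.0, 7.3, 9.5, 13.7),
    "HL": (1.4, 1.9, 1.4, 2.0),
    "FL": (1.4, 1.9, 1.3, 1.6),
    "EFW": (6.3, 28.3, 113.6, 382.1),
}

#: True (h2, c2, e2) per trait per anchor used as generator defaults.
#: h2 rises to a late-second-trimester peak while c2 declines from a
#: first-trimester maximum; e2 absorbs the remainder (incl. measurement error).
DEFAULT_VARIANCE_PLAN: dict[str, tuple[tuple[float, float, float], ...]] = {
    "AC": ((0.14, 0.50, 0.36), (0.23, 0.47, 0.30), (0.53, 0.19, 0.28), (0.45, 0.26, 0.29)),
    "HL": ((0.21, 0.54, 0.25), (0.22, 0.54, 0.24), (0.57, 0.20, 0.23), (0.56, 0.18, 0.26)),
    "FL": ((0.29, 0.47, 0.24), (0.30, 0.45, 0.25), (0.72, 0.00, 0.28), (0.39, 0.17, 0.44)),
    "EFW": ((0.17, 0.54, 0.29), (0.41, 0.39, 0.20), (0.71, 0.11, 0.18), (0.66, 0.07, 0.27)),
}


def _corr(ac_hl, ac_fl, hl_fl, efw_ac, efw_hl, efw_fl) -> np.ndarray:
    r = np.eye(4)
    pairs = {
        (0, 1): ac_hl, (0, 2): ac_fl, (1, 2): hl_fl,
        (0, 3): efw_ac, (1, 3): efw_hl, (2, 3): efw_fl,
    }
    for (i, j), v in pairs.items():
        r[i, j] = r[j, i] = v
    return r


#: Cross-trait additive-genetic correlation matrices per anchor, trait order
#: (AC, HL, FL, EFW).  Reported pair values are used verbatim except HL-FL,
#: which is softened from a boundary 1.00 to 0.95 (an exact unit off-diagonal
#: is incompatible with the unequal EFW-HL / EFW-FL correlations in the same
#: matrix); the unreported EFW-AC correlation declines 0.90 -> 0.75.  All four
#: matrices are positive definite.
DEFAULT_RHO_G_PLAN: tuple[np.ndarray, ...] = (
    _corr(0.67, 0.57, 0.95, 0.90, 0.85, 0.79),
    _corr(0.57, 0.40, 0.95, 0.85, 0.76, 0.73),
    _corr(0.46, 0.47, 0.90, 0.80, 0.70, 0.74),
    _corr(0.39, 0.35, 0.95, 0.75, 0.65, 0.67),
)

#: Cross-trait correlation of the shared-environment (C) and
#: unique-environment (E) latent components, trait order (AC, HL, FL, EFW).
#: Maternal/placental environments act on overall growth, so all traits
#: overlap substantially; EFW, a size composite, overlaps AC and FL most.
#: Both matrices are positive definite.
DEFAULT_RHO_C: np.ndarray = _corr(0.70, 0.70, 0.80, 0.90, 0.70, 0.80)
DEFAULT_RHO_E: np.ndarray = _corr(0.50, 0.70, 0.70, 0.90, 0.60, 0.85)

#: Per-SD covariate effects on every trait's standardized latent score.
#: Together they explain beta'beta / (1 + beta'beta) ~ 9.3% of phenotypic
#: variance, inside the 6.1-11.1% range the design targets.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "maternal_age": 0.20,
    "fetal_sex": 0.20,
    "race": 0.15,
}

#: Multiplicative ultrasound measurement noise (coefficient of variation)
#: added on top of the latent trait value at each visit.  Kept small because
#: the anchor SDs already include measurement error inside e2.  EFW carries
#: no noise of its own: it is a quantity computed from measured biometrics,
#: not an independently measured one.
DEFAULT_MEASUREMENT_CV: dict[str, float] = {"AC": 0.02, "HL": 0.02, "FL": 0.02, "EFW": 0.0}

#: Visit schedules: every pair gets one initial sonogram drawn uniformly in
#: [11w0d, 13w6d] followed by schedule A or B with equal probability.
SCHEDULE_A: tuple[float, ...] = (16.0, 20.0, 24.0, 28.0, 32.0, 35.0)
SCHEDULE_B: tuple[float, ...] = (18.0, 22.0, 26.0, 30.0, 34.0, 36.0)
INITIAL_VISIT_RANGE: tuple[float, float] = (11.0, ga_from_weeks_days(13, 6))

#: Maternal / fetal covariate generation parameters (DZ column of the cohort
#: composition table).
COVARIATE_DISTRIBUTIONS: dict[str, object] = {
    "maternal_age": (31.8, 6.1),        # Normal(mean, sd), years
    "pre_pregnancy_bmi": (26.7, 6.3),   # Normal truncated at 15, kg/m2
    "smoking": 0.150,
    "alcohol": 0.030,
    "race": 0.534,                      # White/non-Hispanic
    "parity": 0.444,                    # >= 1 prior birth
    "gravidity": (0.286, 0.361, 0.353), # 1 / 2 / >=3 pregnancies
    "employment": 0.917,
    "education": 0.812,                 # > high school
    "marital": 0.797,                   # married
}


@dataclass
class CohortConfig:
    """Full generative specification of a synthetic twin cohort.

    Parameters
    ----------
    n_mz, n_dz
        Monozygotic / dizygotic pair counts.
    seed
        Master seed; per-pair substreams are derived from (seed, pair index)
        so adding pairs never perturbs existing ones.
    anchor_gas
        Gestational ages (decimal weeks) at which the variance plan applies.
    variance_plan
        Per trait, one (h2, c2, e2) triple per anchor; each triple is
        nonnegative and sums to one.
    rho_g_plan
        Per anchor, a positive-semidefinite cross-trait genetic correlation
        matrix in trait order ``TRAITS``.
    covariate_effects
        Per-SD effects of standardized covariates on every trait's latent
        score.
    measurement_cv
        Per-trait multiplicative measurement noise CV.
    delivery_mean_ga, delivery_sd_ga
        Gestational age at delivery ~ Normal(mean, sd) truncated to
        ``delivery_range``; visits after delivery are dropped.
    rho_a_time, rho_e_time
        Cross-anchor correlation of the additive-genetic and
        unique-environment latent components (genes persist over gestation;
        E mixes persistent placental factors with transient error).
    """

    n_mz: int = 15
    n_dz: int = 133
    seed: int = 0
    anchor_gas: tuple[float, ...] = ANCHOR_GAS
    variance_plan: Mapping[str, Sequence[tuple[float, float, float]]] = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_VARIANCE_PLAN.items()}
    )
    rho_g_plan: Sequence[np.ndarray] = field(
        default_factory=lambda: tuple(m.copy() for m in DEFAULT_RHO_G_PLAN)
    )
    rho_c: np.ndarray = field(default_factory=lambda: DEFAULT_RHO_C.copy())
    rho_e: np.ndarray = field(default_factory=lambda: DEFAULT_RHO_E.copy())
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    measurement_cv: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEASUREMENT_CV)
    )
    delivery_mean_ga: float = 35.7
    delivery_sd_ga: float = 3.7
    delivery_range: tuple[float, float] = (28.0, 41.0)
    rho_a_time: float = 0.9
    rho_e_time: float = 0.5

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.n_mz < 0 or self.n_dz < 0:
            raise ConfigError("pair counts must be nonnegative")
        if self.n_mz + self.n_dz < 2:
            raise ConfigError("need at least two twin pairs in total")
        k = len(self.anchor_gas)
        for trait, triples in self.variance_plan.items():
            if len(triples) != k:
                raise ConfigError(f"variance_plan[{trait}] must have {k} triples")
            for h2, c2, e2 in triples:
                if min(h2, c2, e2) < 0:
                    raise ConfigError(f"negative variance fraction for {trait}")
                if abs(h2 + c2 + e2 - 1.0) > 1e-12:
                    raise ConfigError(f"variance fractions for {trait} do not sum to 1")
        if len(self.rho_g_plan) != k:
            raise ConfigError(f"rho_g_plan must have one matrix per anchor ({k})")
        for m in (*self.rho_g_plan, self.rho_c, self.rho_e):
            m = np.asarray(m, dtype=float)
            if m.shape[0] != m.shape[1]:
                raise ConfigError("rho_g_plan matrices must be square")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ConfigError("rho_g_plan matrices must be symmetric")
            if not np.allclose(np.diag(m), 1.0, atol=1e-10):
                raise ConfigError("rho_g_plan matrices must have unit diagonal")
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ConfigError("rho_g_plan matrix is not positive semidefinite")

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["anchor_gas"] = list(self.anchor_gas)
        d["variance_plan"] = {
            t: [list(tr) for tr in v] for t, v in self.variance_plan.items()
        }
        d["rho_g_plan"] = [np.asarray(m).tolist() for m in self.rho_g_plan]
        d["rho_c"] = np.asarray(self.rho_c).tolist()
        d["rho_e"] = np.asarray(self.rho_e).tolist()
        d["covariate_effects"] = dict(self.covariate_effects)
        d["measurement_cv"] = dict(self.measurement_cv)
        d["delivery_range"] = list(self.delivery_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "anchor_gas" in d:
            d["anchor_gas"] = tuple(float(x) for x in d["anchor_gas"])
        if "variance_plan" in d:
            d["variance_plan"] = {
                t: [tuple(float(x) for x in tr) for tr in v]
                for t, v in d["variance_plan"].items()
            }
        if "rho_g_plan" in d:
            d["rho_g_plan"] = tuple(np.asarray(m, dtype=float) for m in d["rho_g_plan"])
        for key in ("rho_c", "rho_e"):
            if key in d:
                d[key] = np.asarray(d[key], dtype=float)
        if "delivery_range" in d:
            d["delivery_range"] = tuple(float(x) for x in d["delivery_range"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)
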