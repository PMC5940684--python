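"""Statistical power of the classical twin design.

The non-centrality (NCP) route builds the model-implied standardized co-twin
covariance matrices under the true (a2, c2) fractions,

    Sigma_MZ = [[1, a2 + c2], [a2 + c2, 1]],
    Sigma_DZ = [[1, a2/2 + c2], [a2/2 + c2, 1]],

fits the null-constrained model to those population matrices by minimizing
the Gaussian ML discrepancy F = tr(S Sigma^-1) - ln|S Sigma^-1| - p per
zygosity group weighted by pair counts, and takes the minimized weighted
discrepancy as the expected likelihood-ratio non-centrality lambda.  Because
variance components are tested on their boundary, critical values come from
chi-square mixtures: 50:50 {chi2_0, chi2_1} for a single component, and
(1/4, 1/2, 1/4) over {chi2_0, chi2_1, chi2_2} for the joint familial test
(ACE vs E-only).  Power is the same mixture evaluated with non-central
components, which reduces exactly to the test size when lambda = 0.

A simulation route generates twin cohorts at a single anchor, fits full and
null models by maximum likelihood and counts rejections, cross-checking the
NCP approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import chi2, ncx2, norm

from .ace import ACEData, _fit_model
from .cohort import simulate_anchor_values

__all__ = ["PowerSpec", "PowerResult", "power_ncp", "power_sim", "mixture_critical_value"]

#: Mixture weights of the null distribution, by tested component.
_MIXTURES = {
    "A": ((0, 0.5), (1, 0.5)),
    "C": ((0, 0.5), (1, 0.5)),
    "AC-joint": ((0, 0.25), (1, 0.5), (2, 0.25)),
}


@dataclass
class PowerSpec:
    """Design and truth for a twin-power calculation.

    ``component`` selects the null hypothesis: "A" (drop additive genetics,
    ACE vs CE), "C" (drop shared environment, ACE vs AE) or "AC-joint"
    (drop both, ACE vs E-only).  ``e2 = 1 - a2 - c2`` implicitly.
    """

    n_mz: int
    n_dz: int
    a2: float
    c2: float
    alpha: float = 0.05
    component: str = "AC-joint"
    method: str = "ncp"
    n_reps: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.a2 < 0 or self.c2 < 0 or self.a2 + self.c2 > 1:
            raise ValueError("need a2, c2 >= 0 with a2 + c2 <= 1")
        if not (0 < self.alpha <= 0.5):
            raise ValueError("alpha must be in (0, 0.5]")
        if self.component not in _MIXTURES:
            raise ValueError(f"component must be one of {sorted(_MIXTURES)}")
        if self.method == "simulation" and self.n_reps < 100:
            raise ValueError("simulation needs n_reps >= 100")


@dataclass
class PowerResult:
    power: float
    ncp: float
    mixture: tuple
    critical_value: float
    alpha: float
    method: str
    n_dropped: int = 0
    flagged: bool = False
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["mixture"] = [list(m) for m in self.mixture]
        return d


def mixture_critical_value(mixture, alpha: float) -> float:
    """Upper-alpha point of a chi-square mixture (df=0 terms allowed)."""

    def tail(c):
        return sum(w * chi2.sf(c, df) for df, w in mixture if df > 0) - alpha

    return float(brentq(tail, 1e-12, 200.0))


def _mixture_power(mixture, crit: float, lam: float) -> float:
    """Alternative-hypothesis tail probability of the boundary LRT.

    For a single tested variance the exact one-sided asymptotics give
    ``T = max(0, Z + sqrt(lam))^2`` so power = Phi(sqrt(lam) - sqrt(crit)),
    which is continuous in lam and equals alpha at lam = 0.  For the joint
    2-df test the noncentral chi-square tail is used; with lam = 0 the null
    mixture applies and the tail is alpha by construction of the critical
    value.
    """
    max_df = max(df for df, _ in mixture)
    if max_df == 1:
        return float(norm.sf(np.sqrt(crit) - np.sqrt(lam)))
    if lam < 1e-12:
        return float(sum(w * chi2.sf(crit, df) for df, w in mixture if df > 0))
    return float(ncx2.sf(crit, max_df, lam))


def _implied_sigma(a2: float, c2: float) -> dict[str, np.ndarray]:
    out = {}
    for zyg, r in (("MZ", 1.0), ("DZ", 0.5)):
        cov = r * a2 + c2
        out[zyg] = np.array([[1.0, cov], [cov, 1.0]])
    return out


def _discrepancy(params, free, s_mats, weights) -> float:
    """n-weighted Gaussian ML discrepancy of the constrained ACE model."""
    vals = dict(zip(free, params))
    a2 = vals.get("a2", 0.0)
    c2 = vals.get("c2", 0.0)
    e2 = vals.get("e2", 1e-12)
    f = 0.0
    for zyg, s in s_mats.items():
        r = 1.0 if zyg == "MZ" else 0.5
        v = a2 + c2 + e2
        cz = r * a2 + c2
        det = v * v - cz * cz
        if v <= 0 or det <= 0:
            return np.inf
        # closed-form for 2x2: tr(S Sigma^-1) and ln|S Sigma^-1|
        tr = (v * (s[0, 0] + s[1, 1]) - 2 * cz * s[0, 1]) / det
        sdet = s[0, 0] * s[1, 1] - s[0, 1] ** 2
        f += weights[zyg] * (tr - (np.log(sdet) - np.log(det)) - 2.0)
    return float(f)


_NULL_FREE = {"A": ("c2", "e2"), "C": ("a2", "e2"), "AC-joint": ("e2",)}


def power_ncp(spec: PowerSpec) -> PowerResult:
    """Twin-design power by the expected-LRT non-centrality method.

    Deterministic; the full ACE model reproduces the population matrices
    exactly, so lambda equals the pair-count-weighted discrepancy of the
    best-fitting null model.
    """
    s_mats = _implied_sigma(spec.a2, spec.c2)
    weights = {"MZ": float(spec.n_mz), "DZ": float(spec.n_dz)}
    free = _NULL_FREE[spec.component]
    x0 = np.full(len(free), 1.0 / len(free))
    res = minimize(_discrepancy, x0, args=(free, s_mats, weights), method="L-BFGS-B",
                   bounds=[(1e-10, 10.0)] * len(free), options={"ftol": 1e-14})
    lam = max(0.0, float(res.fun))
    mixture = _MIXTURES[spec.component]
    crit = mixture_critical_value(mixture, spec.alpha)
    power = _mixture_power(mixture, crit, lam)
    return PowerResult(power=power, ncp=lam, mixture=mixture, critical_value=crit,
                       alpha=spec.alpha, method="ncp")


def power_sim(spec: PowerSpec) -> PowerResult:
    """Twin-design power by Monte-Carlo simulation.

    Each replicate simulates co-twin values at a single anchor on the
    standardized latent scale (no covariates), fits the full ACE and the
    component's null model by maximum likelihood, and rejects when the LRT
    statistic exceeds the boundary-mixture critical value.  Deterministic
    given ``spec.seed``; non-convergent replicates are dropped and counted,
    and the result is flagged if more than 5% drop.
    """
    mixture = _MIXTURES[spec.component]
    crit = mixture_critical_value(mixture, spec.alpha)
    rng = np.random.default_rng(spec.seed)
    free_null = {"A": (1, 2), "C": (0, 2), "AC-joint": (2,)}[spec.component]
    rejections = 0
    dropped = 0
    for _ in range(spec.n_reps):
        y, zyg = simulate_anchor_values(spec.n_mz, spec.n_dz, spec.a2, spec.c2, rng)
        data = ACEData(y, None, zyg)
        v = float(np.var(y))
        try:
            starts_full = [[v / 3, v / 3, v / 3], [0.6 * v, 0.1 * v, 0.3 * v],
                           [1e-4 * v, 1e-4 * v, v]]
            _, _, ll_full, ok_f = _fit_model(data, (0, 1, 2), starts_full, v)
            if len(free_null) == 1:
                starts_null = [[v]]
            else:
                starts_null = [[v / 2, v / 2], [1e-4 * v, v]]
            _, _, ll_null, ok_n = _fit_model(data, free_null, starts_null, v)
        except np.linalg.LinAlgError:
            dropped += 1
            continue
        if not np.isfinite(ll_full) or not np.isfinite(ll_null):
            dropped += 1
            continue
        t = max(0.0, 2.0 * (ll_full - ll_null))
        rejections += int(t > crit)
    n_eff = spec.n_reps - dropped
    power = rejections / n_eff if n_eff else np.nan
    return PowerResult(power=float(power), ncp=np.nan, mixture=mixture, critical_value=crit,
                       alpha=spec.alpha, method="simulation", n_dropped=dropped,
                       flagged=dropped > 0.05 * spec.n_reps)
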