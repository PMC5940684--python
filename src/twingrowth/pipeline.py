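"""End-to-end orchestration: simulate -> trajectories -> ACE -> rho_G -> report.

A run is fully determined by its :class:`RunConfig` (which embeds the cohort
generator's seed); re-running the same config reproduces every numeric
output.  Each stage writes tidy CSV/JSON artifacts into the output
directory, and a manifest records the config hash, seed and package
versions.  On a stage failure all partial outputs of the run are removed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .ace import ACEResult, fit_ace, inverse_normal_transform
from .bivariate import fit_bivariate_ace, rho_g_trend
from .cohort import simulate_cohort
from .config import ANCHOR_GAS, TRAITS, CohortConfig
from .io import write_covariates, write_measurements
from .trajectory import (
    SplineSpec,
    _expand_covariates,
    fit_growth_lmm,
    predict_anchor_dataset,
)

__all__ = ["RunConfig", "run_pipeline", "prepare_anchor_pairs", "ace_at_anchor"]

logger = logging.getLogger(__name__)

DEFAULT_TRAIT_PAIRS: tuple[tuple[str, str], ...] = (
    ("AC", "HL"), ("AC", "FL"), ("HL", "FL"), ("EFW", "FL"), ("EFW", "HL"),
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    spline: SplineSpec = field(default_factory=SplineSpec)
    traits: tuple[str, ...] = TRAITS
    trait_pairs: tuple[tuple[str, str], ...] = DEFAULT_TRAIT_PAIRS
    anchors: tuple[float, ...] = ANCHOR_GAS
    alpha: float = 0.05
    output_dir: str = "twingrowth_run"
    log_level: str = "INFO"
    include_extrapolated: bool = True
    conditional_predictions: bool = True
    make_plots: bool = True

    def __post_init__(self):
        unknown = set(self.traits) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown traits {sorted(unknown)}")
        for a, b in self.trait_pairs:
            if a == b:
                raise ValueError("trait_pairs must not contain self-pairs")
            if a not in self.traits or b not in self.traits:
                raise ValueError(f"trait pair ({a}, {b}) not a subset of traits")
        if list(self.anchors) != sorted(self.anchors) or not self.anchors:
            raise ValueError("anchors must be non-empty and ascending")

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "spline": dataclasses.asdict(self.spline),
            "traits": list(self.traits),
            "trait_pairs": [list(p) for p in self.trait_pairs],
            "anchors": list(self.anchors),
            "alpha": self.alpha,
            "output_dir": str(self.output_dir),
            "log_level": self.log_level,
            "include_extrapolated": self.include_extrapolated,
            "conditional_predictions": self.conditional_predictions,
            "make_plots": self.make_plots,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "spline" in d:
            sp = dict(d["spline"])
            sp["interior_knots"] = tuple(sp.get("interior_knots", (16, 22, 28, 34)))
            sp["boundary_knots"] = tuple(sp.get("boundary_knots", (11, 41)))
            d["spline"] = SplineSpec(**sp)
        for key in ("traits", "anchors"):
            if key in d:
                d[key] = tuple(d[key])
        if "trait_pairs" in d:
            d["trait_pairs"] = tuple(tuple(p) for p in d["trait_pairs"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def prepare_anchor_pairs(anchor_df: pd.DataFrame, covariates: pd.DataFrame, trait: str,
                         anchor_ga: float, include_extrapolated: bool = True):
    """Pairwise arrays for the ACE stage from an anchor-prediction table.

    Applies the rank-based inverse-normal transform to the trait's predicted
    values across all fetuses at the anchor, and assembles the per-pair value
    matrix, zygosity vector and per-fetus covariate design.
    Returns (values (n,2), zygosity (n,), design (n,2,p), names).
    """
    sub = anchor_df[
        (anchor_df["trait"] == trait) & np.isclose(anchor_df["anchor_ga"], anchor_ga)
    ].copy()
    if sub.empty:
        raise ValueError(f"no anchor predictions for {trait} at GA {anchor_ga}")
    if not include_extrapolated:
        sub = sub[~sub["extrapolated"]]
    sub = sub.sort_values(["pair_id", "fetus_id"], kind="mergesort")
    sub["y"] = inverse_normal_transform(sub["predicted_value"].to_numpy())

    cov = covariates.drop_duplicates(["pair_id", "fetus_id"]).set_index(["pair_id", "fetus_id"])
    design = _expand_covariates(cov)
    names = tuple(design.columns)

    pairs = []
    for pid, g in sub.groupby("pair_id", sort=True):
        g = g.set_index("fetus_id")
        y = [g["y"].get(1, np.nan), g["y"].get(2, np.nan)]
        x = []
        for fid in (1, 2):
            if (pid, fid) in design.index:
                x.append(design.loc[(pid, fid)].to_numpy())
            else:
                x.append(np.full(len(names), np.nan))
        pairs.append((pid, g["zygosity"].iloc[0], y, x))
    zyg = np.array([p[1] for p in pairs])
    values = np.array([p[2] for p in pairs])
    xmat = np.array([p[3] for p in pairs])
    # missing co-twin: NaN value is handled; its covariate row is irrelevant
    xmat = np.nan_to_num(xmat)
    return values, zyg, xmat, names


def ace_at_anchor(anchor_df: pd.DataFrame, covariates: pd.DataFrame, trait: str,
                  anchor_ga: float, include_extrapolated: bool = True) -> ACEResult:
    """Inverse-normal transform + covariate-adjusted ACE fit at one anchor."""
    values, zyg, xmat, names = prepare_anchor_pairs(
        anchor_df, covariates, trait, anchor_ga, include_extrapolated
    )
    return fit_ace(values, zyg, xmat, trait=trait, anchor_ga=anchor_ga, beta_names=names)


def _plot_variance_fractions(ace_df: pd.DataFrame, trait: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = ace_df[ace_df["trait"] == trait].sort_values("anchor_ga")
    fig, ax = plt.subplots(figsize=(5, 3.4))
    x = np.arange(len(sub))
    bottom = np.zeros(len(sub))
    for comp, color in (("h2", "#4C72B0"), ("c2", "#DD8452"), ("e2", "#55A868")):
        ax.bar(x, sub[comp], bottom=bottom, label={"h2": "h²", "c2": "c²", "e2": "e²"}[comp],
               color=color, width=0.6)
        bottom += sub[comp].to_numpy()
    ax.set_xticks(x)
    ax.set_xticklabels([f"{g:.1f}w" for g in sub["anchor_ga"]])
    ax.set_ylabel("variance fraction")
    ax.set_title(f"{trait}: ACE decomposition over gestation")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of artifact paths and key tables."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    def _write_text(name: str, text: str) -> Path:
        p = out / name
        p.write_text(text)
        created.append(p)
        return p

    try:
        # stage 1: cohort simulation
        measurements, covariates, truth = simulate_cohort(config.cohort)
        n_pairs = measurements["pair_id"].nunique()
        logger.info("simulate: %d pairs, %d measurement rows", n_pairs, len(measurements))
        write_measurements(measurements, out / "measurements.csv")
        created.append(out / "measurements.csv")
        write_covariates(covariates, out / "covariates.csv")
        created.append(out / "covariates.csv")
        _write_text("truth.json", truth.to_json())

        # stage 2: growth trajectories
        fits = {}
        for trait in config.traits:
            fits[trait] = fit_growth_lmm(measurements, covariates, trait, config.spline)
            logger.info("trajectories: %s converged=%s", trait, fits[trait].converged)
        anchor_df = predict_anchor_dataset(fits, config.anchors,
                                           conditional=config.conditional_predictions)
        anchor_df.to_csv(out / "anchor_predictions.csv", index=False, float_format="%.15g")
        created.append(out / "anchor_predictions.csv")
        _write_text("trajectory_fits.json",
                    json.dumps({t: f.summary_dict() for t, f in fits.items()}, indent=2))
        logger.info("trajectories: %d extrapolated anchor predictions",
                    int(anchor_df["extrapolated"].sum()))

        # stage 3: univariate ACE per trait x anchor
        ace_rows = []
        ace_records = []
        for trait in config.traits:
            for ga in config.anchors:
                r = ace_at_anchor(anchor_df, covariates, trait, ga,
                                  config.include_extrapolated)
                ace_records.append(r.to_dict())
                ace_rows.append({
                    "trait": trait, "anchor_ga": ga, "h2": r.h2, "c2": r.c2, "e2": r.e2,
                    "p_h2": r.p_h2, "p_c2": r.p_c2,
                    "covariate_var_explained": r.covariate_var_explained,
                    "converged": r.converged,
                })
        ace_df = pd.DataFrame(ace_rows)
        ace_df.to_csv(out / "ace_results.csv", index=False, float_format="%.10g")
        created.append(out / "ace_results.csv")
        _write_text("ace_results.json", json.dumps(ace_records, indent=2))

        # stage 4: bivariate ACE / genetic correlations
        rho_rows = []
        trends = []
        for t1, t2 in config.trait_pairs:
            pair_results = []
            for ga in config.anchors:
                v1, zyg, xmat, _ = prepare_anchor_pairs(
                    anchor_df, covariates, t1, ga, config.include_extrapolated)
                v2, _, _, _ = prepare_anchor_pairs(
                    anchor_df, covariates, t2, ga, config.include_extrapolated)
                br = fit_bivariate_ace(v1, v2, zyg, xmat, trait_pair=(t1, t2), anchor_ga=ga)
                pair_results.append(br)
                rho_rows.append({
                    "trait_1": t1, "trait_2": t2, "anchor_ga": ga, "rho_g": br.rho_g,
                    "p_rho_g": br.p_rho_g, "rho_g_defined": br.rho_g_defined,
                    "converged": br.converged,
                })
            if len(config.anchors) >= 2:
                try:
                    trends.append(rho_g_trend(pair_results))
                except ValueError:
                    pass
        if config.trait_pairs:
            pd.DataFrame(rho_rows).to_csv(out / "rho_g.csv", index=False, float_format="%.10g")
            created.append(out / "rho_g.csv")
            _write_text("rho_g_trends.json", json.dumps(trends, indent=2))

        # stage 5: truth-vs-estimate recovery report
        recovery = []
        for row in ace_rows:
            t, ga = row["trait"], row["anchor_ga"]
            if t in truth.variance_plan and ga in truth.anchor_gas:
                ki = list(truth.anchor_gas).index(ga)
                h2_t, c2_t, e2_t = truth.variance_plan[t][ki]
                recovery.append({
                    "trait": t, "anchor_ga": ga,
                    "h2_true": h2_t, "h2_est": row["h2"], "h2_err": row["h2"] - h2_t,
                    "c2_true": c2_t, "c2_est": row["c2"], "c2_err": row["c2"] - c2_t,
                })
        _write_text("recovery.json", json.dumps(recovery, indent=2))

        # stage 6: plots
        if config.make_plots:
            for trait in config.traits:
                p = out / f"variance_fractions_{trait}.png"
                _plot_variance_fractions(ace_df, trait, p)
                created.append(p)

        # stage 7: manifest
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.cohort.seed,
            "package_version": _pkg_version,
            "versions": _library_versions(),
            "n_pairs": int(n_pairs),
            "n_measurement_rows": int(len(measurements)),
            "n_extrapolated_predictions": int(anchor_df["extrapolated"].sum()),
            "trajectory_converged": {t: bool(f.converged) for t, f in fits.items()},
            "bivariate_skipped": not config.trait_pairs,
            "config": config.to_dict(),
        }
        _write_text("manifest.json", json.dumps(manifest, indent=2))
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        raise

    return {
        "output_dir": out,
        "measurements": measurements,
        "covariates": covariates,
        "truth": truth,
        "anchor_predictions": anchor_df,
        "ace": ace_df,
        "rho_g": pd.DataFrame(rho_rows) if config.trait_pairs else None,
        "recovery": recovery,
        "manifest": manifest,
    }


def _library_versions() -> dict:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }
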