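"""Parameter-file and run-configuration handling (YAML, strict schema)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .natural_history import (
    ConfigError,
    NaturalHistoryParams,
    VariantFParams,
    VariantPParams,
)
from .screening import Strategy
from .survival_benefit import SurvivalParams


def _check_keys(d: dict, allowed, where: str):
    extra = set(d) - set(allowed)
    if extra:
        raise ConfigError(f"unknown keys in {where}: {sorted(extra)}")


def nh_params_to_dict(params: NaturalHistoryParams) -> dict:
    out: dict = {
        "onset_edges": params.onset_edges.tolist(),
        "onset_hazard": params.onset_hazard.tolist(),
        "dx_mult": params.dx_mult.tolist(),
    }
    if params.variant_p is not None:
        p = params.variant_p
        out["variant_p"] = {
            "init_grade_probs": p.init_grade_probs.tolist(),
            "stage_rates": p.stage_rates.tolist(),
            "grade_rates": p.grade_rates.tolist(),
            "dx_rate": p.dx_rate.tolist(),
            "psa_log_median": p.psa_log_median.tolist(),
            "psa_sigma": p.psa_sigma,
            "benign_log_median_at_35": p.benign_log_median_at_35,
            "benign_log_slope": p.benign_log_slope,
            "benign_sigma": p.benign_sigma,
        }
    if params.variant_f is not None:
        f = params.variant_f
        out["variant_f"] = {
            "grade_mix_edges": f.grade_mix_edges.tolist(),
            "grade_mix": f.grade_mix.tolist(),
            "psa_log_intercept": f.psa_log_intercept,
            "psa_pre_slope": f.psa_pre_slope,
            "psa_post_slope": f.psa_post_slope.tolist(),
            "psa_sigma": f.psa_sigma,
            "dx_coef": f.dx_coef,
            "met_coef": f.met_coef,
        }
    return out


_NH_KEYS = ("onset_edges", "onset_hazard", "dx_mult", "variant_p", "variant_f")
_VP_KEYS = (
    "init_grade_probs", "stage_rates", "grade_rates", "dx_rate", "psa_log_median",
    "psa_sigma", "benign_log_median_at_35", "benign_log_slope", "benign_sigma",
)
_VF_KEYS = (
    "grade_mix_edges", "grade_mix", "psa_log_intercept", "psa_pre_slope",
    "psa_post_slope", "psa_sigma", "dx_coef", "met_coef",
)
_SURV_KEYS = (
    "median_localized", "median_metastatic", "hr_treat", "treat_grade_min",
    "cure_slope", "mechanism", "shift_scope", "mortality_scale",
)


def nh_params_from_dict(d: dict) -> NaturalHistoryParams:
    _check_keys(d, _NH_KEYS, "natural_history")
    vp = vf = None
    if "variant_p" in d:
        _check_keys(d["variant_p"], _VP_KEYS, "variant_p")
        vp = VariantPParams(**d["variant_p"])
    if "variant_f" in d:
        _check_keys(d["variant_f"], _VF_KEYS, "variant_f")
        vf = VariantFParams(**d["variant_f"])
    return NaturalHistoryParams(
        onset_edges=np.asarray(d["onset_edges"]),
        onset_hazard=np.asarray(d["onset_hazard"]),
        variant_p=vp,
        variant_f=vf,
        dx_mult=np.asarray(d.get("dx_mult", [1.0, 1.0, 1.0])),
    )


def survival_to_dict(s: SurvivalParams) -> dict:
    return {
        "median_localized": s.median_localized.tolist(),
        "median_metastatic": s.median_metastatic.tolist(),
        "hr_treat": s.hr_treat,
        "treat_grade_min": s.treat_grade_min,
        "cure_slope": s.cure_slope,
        "mechanism": s.mechanism,
        "shift_scope": s.shift_scope,
        "mortality_scale": s.mortality_scale,
    }


def survival_from_dict(d: dict) -> SurvivalParams:
    _check_keys(d, _SURV_KEYS, "survival")
    return SurvivalParams(**d)


def strategy_from_dict(d: dict) -> Strategy:
    _check_keys(d, ("ages", "start_year", "threshold", "sensitivity", "attendance"), "strategy")
    return Strategy(
        test_ages=tuple(d["ages"]),
        start_year=int(d.get("start_year", 2022)),
        threshold=float(d.get("threshold", 10.0)),
        sensitivity=float(d.get("sensitivity", 0.8)),
        attendance=float(d.get("attendance", 1.0)),
    )


def params_to_yaml(bundle, path) -> None:
    """Write the fixture bundle's model parameters as one YAML document."""
    doc = {
        "natural_history_p": nh_params_to_dict(bundle.nh_params_p),
        "natural_history_f": nh_params_to_dict(bundle.nh_params_f),
        "survival": survival_to_dict(bundle.survival),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def params_from_yaml(path):
    doc = yaml.safe_load(Path(path).read_text())
    _check_keys(doc, ("natural_history_p", "natural_history_f", "survival"), "parameter file")
    return (
        nh_params_from_dict(doc["natural_history_p"]),
        nh_params_from_dict(doc["natural_history_f"]),
        survival_from_dict(doc["survival"]),
    )


@dataclass
class RunConfig:
    """Configuration for the command-line pipeline."""

    variant: str = "F"
    mechanism: str = "cure_rate"
    seed: int | None = None
    multiplier: float = 1.0
    outdir: str = "prostasim_out"
    calibration_budget: int = 200_000
    strategies: list = field(default_factory=list)

    def __post_init__(self):
        if self.variant not in ("P", "F"):
            raise ConfigError("variant must be 'P' or 'F'")
        if self.multiplier <= 0:
            raise ConfigError("population multiplier must be positive")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ConfigError("a seed is required for simulation commands")
        return int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        _check_keys(
            doc,
            ("variant", "mechanism", "seed", "multiplier", "outdir",
             "calibration_budget", "strategies"),
            "run config",
        )
        return cls(**doc)
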