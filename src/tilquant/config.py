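"""Configuration objects for the synthetic slide and cohort generators.

All stochastic behaviour is controlled by an explicit integer seed carried in
the config; identical config + seed gives bit-identical output.  Intensities
are expressed per mm^2 (the conventional unit for nuclear densities in
histology) while coordinates and radii are in microns.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

from .errors import ConfigurationError

#: The three cell classes the classifier distinguishes.
CELL_CLASSES = ("cancer", "stromal", "lymphocyte")

#: Categorical covariate levels; the first listed level is the reference
#: category in every regression model.
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "er_status": ("Negative", "Positive"),
    "node_status": ("Negative", "Positive"),
    "tumour_size_cat": ("<=50 mm", ">50 mm"),
    "arm": ("BEV+D FEC", "D FEC"),
}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the marked-point-process slide generator.

    A slide is a rectangular field populated by three independent point
    processes (cancer, stromal, lymphocyte nuclei).  Lymphocytes may follow
    either a homogeneous Poisson process or a Thomas cluster process
    (Poisson parents with Gaussian-scattered offspring), mimicking the
    clustered appearance of real lymphocytic infiltrates.
    """

    field_width_um: float = 1000.0
    field_height_um: float = 1000.0
    lymphocyte_intensity: float = 500.0  # per mm^2
    cancer_intensity: float = 800.0  # per mm^2
    stromal_intensity: float = 600.0  # per mm^2
    cluster_mode: str = "poisson"  # "poisson" | "thomas"
    thomas_parent_intensity: float = 25.0  # parents per mm^2
    thomas_mean_offspring: float = 20.0  # mean offspring per parent
    thomas_sigma_um: float = 30.0  # Gaussian scatter of offspring
    #: per-class (mean, sd) of the equivalent nuclear radius, microns
    nucleus_radius_um_by_class: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "lymphocyte": (3.0, 0.25),
            "cancer": (6.5, 0.7),
            "stromal": (4.0, 0.4),
        }
    )
    render_pixel_size_um: float = 0.5
    noise_sd: float = 2.0  # additive 8-bit intensity noise at render time
    #: optional hard-core constraint: minimum centre-to-centre separation.
    #: 0 disables it; use > 2 * max radius to guarantee non-overlap.
    min_separation_um: float = 0.0
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        _require(
            math.isfinite(self.field_width_um) and self.field_width_um > 0,
            "field_width_um must be positive and finite",
        )
        _require(
            math.isfinite(self.field_height_um) and self.field_height_um > 0,
            "field_height_um must be positive and finite",
        )
        for name in ("lymphocyte_intensity", "cancer_intensity", "stromal_intensity"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0, f"{name} must be finite and >= 0")
        _require(
            self.cluster_mode in ("poisson", "thomas"),
            f"unknown cluster_mode {self.cluster_mode!r}",
        )
        if self.cluster_mode == "thomas":
            _require(self.thomas_sigma_um > 0, "thomas_sigma_um must be > 0")
            _require(self.thomas_parent_intensity >= 0, "thomas_parent_intensity must be >= 0")
            _require(self.thomas_mean_offspring >= 0, "thomas_mean_offspring must be >= 0")
        _require(self.render_pixel_size_um > 0, "render_pixel_size_um must be > 0")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.min_separation_um >= 0, "min_separation_um must be >= 0")
        for cls in CELL_CLASSES:
            _require(cls in self.nucleus_radius_um_by_class, f"missing radius spec for {cls}")
            mean, sd = self.nucleus_radius_um_by_class[cls]
            _require(mean > 0 and sd >= 0, f"radius spec for {cls} must have mean > 0, sd >= 0")
        return self


# A distribution spec is a tuple: ("normal", mu, sd), ("lognormal", mu_log,
# sd_log), ("bernoulli", p) or ("categorical", values, probs).
DistributionSpec = tuple


def validate_distribution(name: str, spec: DistributionSpec) -> None:
    _require(isinstance(spec, (tuple, list)) and len(spec) >= 2, f"{name}: malformed spec {spec!r}")
    kind = spec[0]
    if kind in ("normal", "lognormal"):
        _require(len(spec) == 3, f"{name}: {kind} spec needs (kind, mu, sd)")
        _require(math.isfinite(spec[1]), f"{name}: location must be finite")
        _require(math.isfinite(spec[2]) and spec[2] >= 0, f"{name}: scale must be finite and >= 0")
    elif kind == "bernoulli":
        _require(len(spec) == 2 and 0 <= spec[1] <= 1, f"{name}: bernoulli p must be in [0, 1]")
    elif kind == "categorical":
        _require(len(spec) == 3, f"{name}: categorical spec needs (kind, values, probs)")
        values, probs = spec[1], spec[2]
        _require(len(values) == len(probs) > 0, f"{name}: values/probs length mismatch")
        _require(all(p >= 0 for p in probs), f"{name}: probabilities must be >= 0")
        _require(abs(sum(probs) - 1.0) < 1e-9, f"{name}: probabilities must sum to 1")
    else:
        raise ConfigurationError(f"{name}: unknown distribution kind {kind!r}")


def _default_covariate_distributions() -> dict[str, DistributionSpec]:
    return {
        "age": ("normal", 50.0, 10.0),
        "grade": ("categorical", (1, 2, 3), (0.10, 0.45, 0.45)),
        "er_positive": ("bernoulli", 0.60),
        "node_positive": ("bernoulli", 0.45),
        "size_gt50": ("bernoulli", 0.15),
        "arm_dfec": ("bernoulli", 0.50),
    }


def _default_beta_covariates() -> dict[str, float]:
    # Log-odds per unit of each (numerically coded) covariate.
    return {
        "age": math.log(0.98),
        "grade": math.log(2.80),
        "er_positive": math.log(0.29),
        "node_positive": math.log(0.65),
        "size_gt50": math.log(1.05),
        "arm_dfec": math.log(0.60),
    }


def _default_survival_log_hazards() -> dict[str, float]:
    return {
        "er_positive": -0.5,
        "node_positive": 0.6,
        "grade": 0.3,
    }


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic trial-cohort generator.

    Pathological complete response (pCR) follows a logistic model in the
    pre-treatment lymphocyte density and the clinical covariates; survival
    times are exponential with covariate log-hazards; the pre-to-post
    density change is drawn from a two-component scheme in which patients
    with residual disease receive an upward shift with configurable
    probability, reproducing the inverse density-increase/pCR association
    the analysis is designed to detect.
    """

    n_patients: int = 609
    intercept: float = -2.45  # gives a marginal pCR prevalence near 20%
    beta_density: float = math.log(2.13)  # log-odds per density unit (a.u.)
    beta_covariates: Mapping[str, float] = field(default_factory=_default_beta_covariates)
    covariate_distributions: Mapping[str, DistributionSpec] = field(
        default_factory=_default_covariate_distributions
    )
    density_distribution: DistributionSpec = ("lognormal", math.log(0.5), 0.6)
    #: probability of a post-treatment density *increase* given residual
    #: disease / given pCR; the up/down components are log-normal shifts.
    p_increase_residual: float = 0.35
    p_increase_pcr: float = 0.05
    log_ratio_up_mean: float = 0.6
    log_ratio_down_mean: float = -0.7
    log_ratio_sd: float = 0.35
    survival_baseline_rate: float = 0.045  # OS events per year
    dfs_baseline_rate: float = 0.07  # DFS events per year
    censoring_rate: float = 0.25  # independent censoring, events per year
    survival_log_hazards: Mapping[str, float] = field(
        default_factory=_default_survival_log_hazards
    )
    #: fraction of patients with a digitised baseline slide, and fraction of
    #: those with a matched post-treatment slide (drives cohort accounting)
    p_baseline_slide: float = 0.78
    p_post_slide_given_baseline: float = 0.63
    seed: int = 0

    def validate(self) -> "CohortConfig":
        _require(self.n_patients >= 1, "n_patients must be >= 1")
        for name, spec in self.covariate_distributions.items():
            validate_distribution(name, spec)
        validate_distribution("density", self.density_distribution)
        for name, p in (
            ("p_increase_residual", self.p_increase_residual),
            ("p_increase_pcr", self.p_increase_pcr),
            ("p_baseline_slide", self.p_baseline_slide),
            ("p_post_slide_given_baseline", self.p_post_slide_given_baseline),
        ):
            _require(0 <= p <= 1, f"{name} must be in [0, 1]")
        for name in ("survival_baseline_rate", "dfs_baseline_rate", "censoring_rate"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(self.log_ratio_sd >= 0, "log_ratio_sd must be >= 0")
        unknown = set(self.beta_covariates) - set(self.covariate_distributions)
        _require(not unknown, f"beta_covariates refer to unknown covariates: {sorted(unknown)}")
        return self


def config_to_flat_dict(cfg: Any) -> dict[str, Any]:
    """Flatten a config dataclass to JSON-serialisable key/value pairs."""
    out: dict[str, Any] = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, Mapping):
            v = {str(k): list(x) if isinstance(x, (tuple, list)) else x for k, x in v.items()}
        elif isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


def config_hash(cfg: Any) -> str:
    """Stable SHA-256 over the flattened config, for provenance manifests."""
    payload = json.dumps(config_to_flat_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_flat_config(cfg: Any, path) -> None:
    """Echo a config as a flat TOML-style key = value file."""
    lines = []
    for key, value in config_to_flat_dict(cfg).items():
        lines.append(f"{key} = {json.dumps(value)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
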