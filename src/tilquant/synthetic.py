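"""Ground-truth slide and trial-cohort generators.

Slides are marked spatial point patterns: each of the three cell classes
(cancer, stromal, lymphocyte) is drawn from its own homogeneous Poisson
process, with an optional Thomas cluster process for lymphocytes.  Rendering
turns a pattern into an H&E-like RGB raster in which nuclei are filled
ellipses whose size, elongation and haematoxylin uptake depend on the class:
lymphocytes are small, round and darkly stained; cancer nuclei are large
with mottled chromatin; stromal nuclei are elongated and intermediate.

Cohorts are patient tables in which the pCR outcome follows a logistic
model in pre-treatment lymphocyte density and the clinical covariates, and
the post-treatment density change is tied to residual disease.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skimage.color import hed2rgb
from skimage.draw import ellipse as draw_ellipse

from .config import CELL_CLASSES, CohortConfig, SyntheticConfig
from .errors import ConfigurationError

# Haematoxylin optical density by class; the gap between classes is what
# makes the mean-OD feature informative for the classifier.
_CLASS_HAEMATOXYLIN_OD = {"lymphocyte": 1.0, "stromal": 0.70, "cancer": 0.45}
# Per-pixel OD mottling inside the nucleus (chromatin texture).
_CLASS_OD_TEXTURE_SD = {"lymphocyte": 0.02, "cancer": 0.10, "stromal": 0.04}
# Elongation (major/minor axis ratio) ranges.
_CLASS_ASPECT_RANGE = {"lymphocyte": (1.0, 1.15), "cancer": (1.1, 1.5), "stromal": (2.5, 3.5)}

_BACKGROUND_H_OD = 0.02
_BACKGROUND_E_OD = 0.25
_NUCLEUS_E_OD = 0.10

CELL_CSV_COLUMNS = ["cell_id", "x_um", "y_um", "class", "radius_um"]


@dataclass
class GroundTruthSlide:
    """A simulated slide: the true cell table and, optionally, its raster.

    ``cells`` has columns cell_id, x_um, y_um, class, radius_um plus the
    rendering nuisance parameters aspect and theta.  Coordinates are
    continuous microns with the origin at the top-left corner and y
    increasing downward, matching raster conventions.
    """

    cells: pd.DataFrame
    config: SyntheticConfig
    image: Optional[np.ndarray] = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def class_points(self, cls: str) -> np.ndarray:
        sub = self.cells[self.cells["class"] == cls]
        return sub[["x_um", "y_um"]].to_numpy(dtype=float)

    def write_cells_csv(self, path) -> None:
        self.cells[CELL_CSV_COLUMNS].to_csv(path, index=False)


def _thomas_lymphocytes(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    """Thomas cluster process: Poisson parents, Gaussian offspring.

    Parents are simulated on the field dilated by 4 sigma so that clusters
    centred just outside still contribute offspring inside (the standard
    edge treatment); offspring falling outside the field are discarded.
    """
    pad = 4.0 * cfg.thomas_sigma_um
    w, h = cfg.field_width_um + 2 * pad, cfg.field_height_um + 2 * pad
    n_parents = rng.poisson(cfg.thomas_parent_intensity * w * h / 1e6)
    parents = rng.uniform([-pad, -pad], [cfg.field_width_um + pad, cfg.field_height_um + pad],
                          size=(n_parents, 2))
    counts = rng.poisson(cfg.thomas_mean_offspring, size=n_parents)
    if counts.sum() == 0:
        return np.empty((0, 2))
    centres = np.repeat(parents, counts, axis=0)
    pts = centres + rng.normal(0.0, cfg.thomas_sigma_um, size=centres.shape)
    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] <= cfg.field_width_um)
        & (pts[:, 1] >= 0) & (pts[:, 1] <= cfg.field_height_um)
    )
    return pts[inside]


def _hardcore_thin(points: np.ndarray, min_sep: float, rng: np.random.Generator) -> np.ndarray:
    """Sequential rejection: keep points at least min_sep from all kept ones."""
    if len(points) == 0:
        return np.ones(0, dtype=bool)
    order = rng.permutation(len(points))
    kept: list[int] = []
    kept_xy = np.empty((0, 2))
    min_sep2 = min_sep * min_sep
    for i in order:
        p = points[i]
        if len(kept) == 0 or np.min(np.sum((kept_xy - p) ** 2, axis=1)) >= min_sep2:
            kept.append(i)
            kept_xy = np.vstack([kept_xy, p[None, :]])
    mask = np.zeros(len(points), dtype=bool)
    mask[kept] = True
    return mask


def simulate_point_pattern(config: SyntheticConfig) -> GroundTruthSlide:
    """Draw the marked point pattern of nuclei for one slide.

    Each class count is Poisson with mean intensity x area; positions are
    uniform over the field (Poisson mode) or Thomas-clustered for
    lymphocytes when ``cluster_mode == "thomas"``.  With
    ``min_separation_um > 0`` a hard-core thinning is applied across all
    classes, at the cost of a lower realised intensity.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    area_mm2 = config.field_width_um * config.field_height_um / 1e6

    xs, ys, classes = [], [], []
    for cls in CELL_CLASSES:
        if cls == "lymphocyte" and config.cluster_mode == "thomas":
            pts = _thomas_lymphocytes(rng, config)
        else:
            intensity = getattr(config, f"{cls}_intensity")
            n = rng.poisson(intensity * area_mm2)
            pts = rng.uniform([0.0, 0.0], [config.field_width_um, config.field_height_um],
                              size=(n, 2))
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
        classes.extend([cls] * len(pts))

    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    cls_arr = np.array(classes, dtype=object)

    radii = np.empty(len(x))
    aspects = np.empty(len(x))
    thetas = rng.uniform(0.0, math.pi, size=len(x))
    for cls in CELL_CLASSES:
        idx = np.flatnonzero(cls_arr == cls)
        mean, sd = config.nucleus_radius_um_by_class[cls]
        r = rng.normal(mean, sd, size=len(idx))
        radii[idx] = np.clip(r, 0.4 * mean, None)
        lo, hi = _CLASS_ASPECT_RANGE[cls]
        aspects[idx] = rng.uniform(lo, hi, size=len(idx))

    if config.min_separation_um > 0 and len(x) > 0:
        keep = _hardcore_thin(np.column_stack([x, y]), config.min_separation_um, rng)
        x, y, cls_arr = x[keep], y[keep], cls_arr[keep]
        radii, aspects, thetas = radii[keep], aspects[keep], thetas[keep]

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(len(x)),
            "x_um": x,
            "y_um": y,
            "class": cls_arr,
            "radius_um": radii,
            "aspect": aspects,
            "theta": thetas,
        }
    )
    return GroundTruthSlide(cells=cells, config=config)


def render_slide(slide: GroundTruthSlide, config: Optional[SyntheticConfig] = None) -> np.ndarray:
    """Render a point pattern as an 8-bit H&E-like RGB image.

    Nuclei are filled rotated ellipses drawn in optical-density (OD) space:
    each pixel accumulates a haematoxylin OD set by the cell class plus
    per-pixel chromatin texture, on top of a uniform eosin-pink background.
    OD is converted to RGB through the standard H&E stain matrix, so that
    colour deconvolution downstream recovers the haematoxylin channel.
    """
    if config is None:
        config = slide.config
    config.validate()
    if config.render_pixel_size_um <= 0:
        raise ConfigurationError("render_pixel_size_um must be > 0")

    px = config.render_pixel_size_um
    height = max(1, int(round(config.field_height_um / px)))
    width = max(1, int(round(config.field_width_um / px)))
    h_od = np.full((height, width), _BACKGROUND_H_OD)
    e_od = np.full((height, width), _BACKGROUND_E_OD)

    # Separate stream so rendering noise does not perturb the pattern draw.
    rng = np.random.default_rng([config.seed, 7])

    cols = slide.cells[["x_um", "y_um", "class", "radius_um", "aspect", "theta"]]
    for x_um, y_um, cls, radius_um, aspect, theta in cols.itertuples(index=False, name=None):
        r_px = radius_um / px
        a = r_px * math.sqrt(aspect)  # semi-major
        b = r_px / math.sqrt(aspect)  # semi-minor
        rr, cc = draw_ellipse(
            y_um / px, x_um / px, a, b,
            shape=(height, width), rotation=theta,
        )
        if len(rr) == 0:
            continue
        od = _CLASS_HAEMATOXYLIN_OD[cls]
        texture = rng.normal(0.0, _CLASS_OD_TEXTURE_SD[cls], size=len(rr))
        h_od[rr, cc] = np.maximum(h_od[rr, cc], od + texture)
        e_od[rr, cc] = _NUCLEUS_E_OD

    stains = np.stack([h_od, e_od, np.zeros_like(h_od)], axis=-1)
    rgb = hed2rgb(stains)
    img = rgb * 255.0
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def simulate_slide(config: SyntheticConfig, render: bool = True) -> GroundTruthSlide:
    """Convenience: point pattern plus (optionally) its rendered raster."""
    slide = simulate_point_pattern(config)
    if render:
        slide.image = render_slide(slide, config)
    return slide


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

COHORT_CSV_COLUMNS = [
    "patient_id", "age", "grade", "er_status", "node_status", "tumour_size_cat",
    "arm", "pre_density", "post_density", "delta_density", "pcr",
    "os_time", "os_event", "dfs_time", "dfs_event",
    "has_baseline_slide", "has_post_slide",
]


def _draw(rng: np.random.Generator, spec, n: int) -> np.ndarray:
    kind = spec[0]
    if kind == "normal":
        return rng.normal(spec[1], spec[2], size=n)
    if kind == "lognormal":
        return rng.lognormal(spec[1], spec[2], size=n)
    if kind == "bernoulli":
        return (rng.random(n) < spec[1]).astype(float)
    if kind == "categorical":
        values = np.asarray(spec[1], dtype=float)
        return rng.choice(values, size=n, p=np.asarray(spec[2], dtype=float))
    raise ConfigurationError(f"unknown distribution kind {kind!r}")


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a neoadjuvant-trial cohort as one row per patient.

    pCR ~ Bernoulli(logistic(intercept + beta_density * pre_density
    + sum beta_covariates * x)); OS and DFS times are exponential with the
    configured covariate log-hazards and independent exponential censoring.
    Post-treatment density is pre_density times a log-normal factor whose
    upward component is sampled with probability ``p_increase_residual``
    for patients with residual disease and ``p_increase_pcr`` otherwise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    cov = {name: _draw(rng, spec, n) for name, spec in config.covariate_distributions.items()}
    density = _draw(rng, config.density_distribution, n)

    eta = np.full(n, float(config.intercept))
    eta += config.beta_density * density
    for name, beta in config.beta_covariates.items():
        eta += beta * cov[name]
    pcr = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    log_hr = np.zeros(n)
    for name, beta in config.survival_log_hazards.items():
        if name == "pre_density":
            log_hr += beta * density
        else:
            log_hr += beta * cov[name]
    rel = np.exp(log_hr)

    def _survival(base_rate: float) -> tuple[np.ndarray, np.ndarray]:
        rate = np.maximum(base_rate * rel, 1e-12)
        event_t = rng.exponential(1.0 / rate)
        if config.censoring_rate > 0:
            cens_t = rng.exponential(1.0 / config.censoring_rate, size=n)
        else:
            cens_t = np.full(n, np.inf)
        t = np.minimum(event_t, cens_t)
        return t, (event_t <= cens_t).astype(int)

    os_time, os_event = _survival(config.survival_baseline_rate)
    dfs_time, dfs_event = _survival(config.dfs_baseline_rate)

    p_up = np.where(pcr == 1, config.p_increase_pcr, config.p_increase_residual)
    up = rng.random(n) < p_up
    mu = np.where(up, config.log_ratio_up_mean, config.log_ratio_down_mean)
    post = density * np.exp(rng.normal(mu, config.log_ratio_sd))

    has_baseline = rng.random(n) < config.p_baseline_slide
    has_post = has_baseline & (rng.random(n) < config.p_post_slide_given_baseline)

    er_levels = np.array(["Negative", "Positive"], dtype=object)
    size_levels = np.array(["<=50 mm", ">50 mm"], dtype=object)
    arm_levels = np.array(["BEV+D FEC", "D FEC"], dtype=object)

    frame = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age": cov["age"],
            "grade": cov["grade"],
            "er_status": er_levels[cov["er_positive"].astype(int)],
            "node_status": er_levels[cov["node_positive"].astype(int)],
            "tumour_size_cat": size_levels[cov["size_gt50"].astype(int)],
            "arm": arm_levels[cov["arm_dfec"].astype(int)],
            "pre_density": density,
            "post_density": post,
            "delta_density": post - density,
            "pcr": pcr,
            "os_time": os_time,
            "os_event": os_event,
            "dfs_time": dfs_time,
            "dfs_event": dfs_event,
            "has_baseline_slide": has_baseline,
            "has_post_slide": has_post,
        }
    )
    return frame[COHORT_CSV_COLUMNS]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(Path(path), index=False)
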