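"""Synthetic field data: canopy images, coverage series, yield tables.

The study data (nadir canopy photographs with panicle masks, per-plot
coverage time series, and post-harvest yield-component measurements) are
not publicly deposited, so this module generates stand-ins with the
statistical structure the analysis assumes:

* coverage series follow the piecewise sigmoid/quadratic model with
  additive Gaussian observation noise truncated to [0, 1];
* canopy images are background-colored canvases with randomly placed
  elliptical panicle-colored blobs and per-pixel color jitter — enough to
  exercise tiling, color-rule segmentation and coverage arithmetic,
  with no pretence of photorealism;
* yield tables draw each component as a stated linear combination of the
  standardized dynamic parameters plus Gaussian noise, with default
  coefficients reproducing the qualitative correlation pattern observed
  in the field: K strongly positive with Yield and grain number, the
  timing parameters d0/d1 negative with yield and filled-grain ratio, K
  mildly negative with 1000-grain weight.

The day axis convention is day 0 = first post-heading observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _ellipse

from . import piecewise_model
from .coverage_extraction import CoverageSeries
from .piecewise_model import PiecewiseParams
from .reference_params import parameter_envelope

__all__ = [
    "ScenarioConfig",
    "SyntheticImagePair",
    "YieldRecord",
    "DEFAULT_YIELD_COEFFS",
    "DEFAULT_YIELD_NOISE",
    "YIELD_SCALES",
    "generate_coverage_series",
    "generate_image_pair",
    "generate_yield_table",
    "table_to_records",
    "sample_params_envelope",
]

# Observation days: imaging every 3-7 days from heading through late
# senescence; 15 visits at 4-day spacing span days 0-56, covering every
# transition day in the published parameter envelope (max d1 ~ 40).
DEFAULT_SAMPLING_DAYS = tuple(float(d) for d in range(0, 60, 4))

PANICLE_COLOR = (205, 185, 95)  # ripening panicle, yellowish
BACKGROUND_COLOR = (45, 110, 50)  # leaf canopy, green


@dataclass
class ScenarioConfig:
    """Simulation settings for one synthetic experiment."""

    true_params: PiecewiseParams
    sampling_days: tuple[float, ...] = DEFAULT_SAMPLING_DAYS
    noise_sd: float = 0.01  # coverage units
    n_plots: int = 1
    seed: int = 0
    image_size: int = 1536
    panicle_color: tuple[int, int, int] = PANICLE_COLOR
    background_color: tuple[int, int, int] = BACKGROUND_COLOR
    color_jitter_sd: float = 8.0  # 0-255 intensity units

    def __post_init__(self) -> None:
        days = np.asarray(self.sampling_days, dtype=float)
        if days.size == 0:
            raise ValueError("sampling_days must be non-empty")
        if np.any(np.diff(days) <= 0):
            raise ValueError("sampling_days must be strictly increasing")
        if np.any(days < 0):
            raise ValueError("sampling_days must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")


@dataclass(frozen=True)
class SyntheticImagePair:
    image: np.ndarray  # H x W x 3, uint8
    mask: np.ndarray  # H x W, {0, 1}
    true_coverage: float

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        exact = np.count_nonzero(self.mask) / self.mask.size
        if abs(exact - self.true_coverage) > 1e-12:
            raise ValueError("true_coverage must equal the mask pixel fraction")


@dataclass(frozen=True)
class YieldRecord:
    """One plot's measured yield components."""

    plot_id: str
    Yield: float  # kg/ha
    GN: float  # grains per m^2
    PN: float  # panicles per m^2
    GNP: float  # grains per panicle
    TGW: float  # 1000-grain weight, g
    FGR: float  # filled-grain ratio, fraction

    def __post_init__(self) -> None:
        for name in ("Yield", "GN", "PN", "GNP", "TGW", "FGR"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.FGR > 1:
            raise ValueError("FGR is a fraction and must be <= 1")


def generate_coverage_series(config: ScenarioConfig) -> list[CoverageSeries]:
    """Noisy coverage observations for ``n_plots`` plots sharing one truth.

    coverage(day) = clip(f(day; true_params) + N(0, noise_sd), 0, 1),
    bit-identical for identical seed and config.
    """
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.sampling_days, dtype=float)
    clean = piecewise_model.evaluate(config.true_params, days)
    out = []
    for i in range(config.n_plots):
        noise = rng.normal(0.0, config.noise_sd, size=days.size) if config.noise_sd else 0.0
        cov = np.clip(clean + noise, 0.0, 1.0)
        out.append(CoverageSeries(f"plot{i:03d}", days.copy(), cov))
    return out


def generate_image_pair(
    config: ScenarioConfig,
    target_coverage: float,
    seed: int,
    tolerance: float = 0.01,
    max_attempts: int = 20000,
) -> SyntheticImagePair:
    """Draw elliptical panicle blobs until coverage hits the target +/- 0.01.

    Targets 0 and 1 are met exactly (empty / full mask). The returned
    ``true_coverage`` is the exact pixel fraction of the final mask.
    Raises RuntimeError if the target is not reached within
    ``max_attempts`` blob placements.
    """
    if not 0.0 <= target_coverage <= 1.0:
        raise ValueError(f"target_coverage must be in [0, 1], got {target_coverage}")
    rng = np.random.default_rng(seed)
    n = config.image_size
    mask = np.zeros((n, n), dtype=np.uint8)

    if target_coverage >= 1.0:
        mask[:] = 1
    elif target_coverage > 0.0:
        attempts = 0
        while True:
            cov = np.count_nonzero(mask) / mask.size
            deficit = target_coverage - cov
            if abs(deficit) <= tolerance or (deficit < 0):
                break
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not reach coverage {target_coverage} within "
                    f"{max_attempts} blob placements (at {cov:.4f})"
                )
            # scale blob area to the remaining deficit to avoid overshoot
            area = max(16.0, deficit * mask.size * 0.05)
            r_mean = np.sqrt(area / np.pi)
            ry = r_mean * rng.uniform(0.5, 1.5)
            rx = max(1.0, area / (np.pi * ry))
            cy, cx = rng.uniform(0, n, size=2)
            rr, cc = _ellipse(cy, cx, ry, rx, shape=mask.shape)
            mask[rr, cc] = 1
        cov = np.count_nonzero(mask) / mask.size
        if abs(cov - target_coverage) > tolerance:
            raise RuntimeError(
                f"overshot target coverage {target_coverage}: achieved {cov:.4f}"
            )

    image = np.empty((n, n, 3), dtype=float)
    image[:] = config.background_color
    image[mask.astype(bool)] = config.panicle_color
    if config.color_jitter_sd > 0:
        image += rng.normal(0.0, config.color_jitter_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return SyntheticImagePair(image, mask, np.count_nonzero(mask) / mask.size)


def sample_params_envelope(n: int, seed: int) -> list[PiecewiseParams]:
    """Sample plot parameters uniformly within the published envelope.

    Each of (K, g, d0, a, d1) is drawn independently and uniformly between
    its minimum and maximum across the published treatment table; draws
    with d1 <= d0 are rejected.
    """
    env = parameter_envelope()
    rng = np.random.default_rng(seed)
    out: list[PiecewiseParams] = []
    while len(out) < n:
        draw = {name: rng.uniform(lo, hi) for name, (lo, hi) in env.items()}
        if draw["d1"] <= draw["d0"]:
            continue
        out.append(PiecewiseParams(**draw))
    return out


# Linear attribution of each yield component to the standardized dynamic
# parameters (z-scores of K, g, d0, a, d1), chosen so that the sample
# correlation signs at n >= 100 plots reproduce the field pattern:
# K-Yield and K-GN strongly positive, d0/d1 negative with Yield and FGR,
# K mildly negative with TGW.
DEFAULT_YIELD_COEFFS: dict[str, dict[str, float]] = {
    "Yield": {"K": 0.90, "g": 0.05, "d0": -0.30, "a": 0.0, "d1": -0.25},
    "GN": {"K": 0.85, "g": 0.05, "d0": -0.30, "a": 0.0, "d1": -0.30},
    "PN": {"K": 0.70, "g": 0.10, "d0": -0.15, "a": 0.0, "d1": -0.15},
    "TGW": {"K": -0.50, "g": 0.0, "d0": 0.10, "a": 0.0, "d1": 0.15},
    "FGR": {"K": 0.25, "g": 0.05, "d0": -0.55, "a": 0.0, "d1": -0.50},
}

DEFAULT_YIELD_NOISE: dict[str, float] = {
    "Yield": 0.30,
    "GN": 0.30,
    "PN": 0.65,
    "TGW": 0.80,
    "FGR": 0.35,
}

# (mean, scale) in physical units applied to the standardized combination
YIELD_SCALES: dict[str, tuple[float, float]] = {
    "Yield": (6500.0, 800.0),  # kg/ha
    "GN": (32000.0, 4000.0),  # grains/m^2
    "PN": (380.0, 55.0),  # panicles/m^2
    "TGW": (21.5, 1.6),  # g
    "FGR": (0.85, 0.055),  # fraction
}

PARAM_NAMES = ("K", "g", "d0", "a", "d1")


def generate_yield_table(
    param_table: list[PiecewiseParams],
    coeffs: dict[str, dict[str, float]] | None = None,
    noise_sd_map: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Yield-component records from per-plot dynamic parameters.

    Each component c is scale_c * (sum_p coeffs[c][p] * z_p + N(0, sd_c))
    shifted to its physical mean, where z_p are z-scores of the parameter
    across plots (zero when the parameter is constant). GNP is derived as
    GN / PN. Values are clipped to their physical domain (non-negative;
    FGR <= 1).

    Returns a DataFrame with columns plot_id, K, g, d0, a, d1, Yield, GN,
    PN, GNP, TGW, FGR.
    """
    if not param_table:
        raise ValueError("param_table must be non-empty")
    coeffs = coeffs if coeffs is not None else DEFAULT_YIELD_COEFFS
    noise_sd_map = noise_sd_map if noise_sd_map is not None else DEFAULT_YIELD_NOISE
    rng = np.random.default_rng(seed)

    raw = np.array([[getattr(p, name) for name in PARAM_NAMES] for p in param_table])
    sd = raw.std(axis=0)
    z = np.where(sd > 0, (raw - raw.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    zcols = dict(zip(PARAM_NAMES, z.T))

    n = len(param_table)
    data: dict[str, np.ndarray] = {
        "plot_id": np.array([f"plot{i:03d}" for i in range(n)], dtype=object)
    }
    for name, col in zip(PARAM_NAMES, raw.T):
        data[name] = col
    for comp, cmap in coeffs.items():
        unknown = set(cmap) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters {unknown} in coefficients for {comp}")
        combo = sum(w * zcols[p] for p, w in cmap.items())
        combo = np.asarray(combo, dtype=float)
        if combo.shape == ():  # all-zero coefficient map
            combo = np.zeros(n)
        sd_c = noise_sd_map.get(comp, 0.0)
        if sd_c:
            combo = combo + rng.normal(0.0, sd_c, size=n)
        mean, scale = YIELD_SCALES[comp]
        vals = mean + scale * combo
        vals = np.clip(vals, 0.0, 1.0 if comp == "FGR" else np.inf)
        data[comp] = vals
    data["GNP"] = data["GN"] / np.where(data["PN"] > 0, data["PN"], np.nan)
    order = ["plot_id", *PARAM_NAMES, "Yield", "GN", "PN", "GNP", "TGW", "FGR"]
    return pd.DataFrame(data)[order]


def table_to_records(table: pd.DataFrame) -> list[YieldRecord]:
    """Validate a yield table row-wise into YieldRecord objects."""
    cols = ("Yield", "GN", "PN", "GNP", "TGW", "FGR")
    return [
        YieldRecord(plot_id=str(row["plot_id"]), **{c: float(row[c]) for c in cols})
        for _, row in table.iterrows()
    ]
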