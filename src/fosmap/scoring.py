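"""c-Fos scoring of GAD-positive interneurons against a resampled background.

GABAergic (GAD positive) cells are identified on high-magnification confocal
fields; the c-Fos channel intensity in a 20-pixel-radius disc around each
cell is compared with a background distribution built by placing the same
disc at 1000 random positions that avoid previously selected putative c-Fos
positive regions.  A cell is called c-Fos positive when its disc mean
exceeds the background mean plus twice the background standard deviation
(strict inequality; ties are negative).

Downstream tests: logistic regressions of the positive call on drug
treatment and on medio-lateral position, and a Poisson log-linear
homogeneity test of GAD-cell counts across the 3x3 grid of field locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage, stats

__all__ = [
    "FluorescenceField",
    "BackgroundDistribution",
    "roi_mean",
    "sample_background",
    "classify_gad_cfos",
    "gad_activation_summary",
    "logistic_effect_tests",
    "location_homogeneity_test",
]

ROI_RADIUS = 20
N_BACKGROUND = 1000

FIELD_COLUMNS = ("lateral", "central", "medial")
FIELD_ROWS = ("superior", "central", "inferior")


@dataclass
class FluorescenceField:
    """One confocal field: intensity raster plus annotated GAD-cell centers."""

    image: np.ndarray  # 2-D, non-negative intensities
    gad_centers: np.ndarray  # (n, 2) pixel coordinates as (row, col)
    exclusion_mask: np.ndarray | None = None  # True over putative c-Fos blobs
    pixel_size: float = 1.0
    field_location: tuple[str, str] = ("central", "central")
    field_id: str = "field"
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("image must be a 2-D raster")
        if np.any(self.image < 0):
            raise ValueError("intensities must be non-negative")
        self.gad_centers = np.atleast_2d(np.asarray(self.gad_centers, float))
        if self.exclusion_mask is not None:
            self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)
            if self.exclusion_mask.shape != self.image.shape:
                raise ValueError("exclusion mask shape must match the image")


@dataclass
class BackgroundDistribution:
    roi_means: np.ndarray
    mean: float
    sd: float
    threshold: float  # mean + 2·sd
    n_samples: int
    roi_radius: int
    seed: int


def _disc_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= radius * radius
    return dy[keep], dx[keep]


def roi_mean(
    field: FluorescenceField, center: tuple[int, int], radius: int = ROI_RADIUS
) -> float:
    """Mean intensity over the disc of pixels within ``radius`` of ``center``.

    Pixel membership is by pixel-center distance (no anti-aliasing), so the
    value is bit-reproducible.  The disc must lie fully inside the image.
    """
    row, col = int(round(center[0])), int(round(center[1]))
    h, w = field.image.shape
    if row - radius < 0 or col - radius < 0 or row + radius >= h or col + radius >= w:
        raise ValueError("ROI disc exceeds image bounds")
    dy, dx = _disc_offsets(radius)
    return float(field.image[row + dy, col + dx].mean())


def _valid_center_mask(field: FluorescenceField, radius: int) -> np.ndarray:
    h, w = field.image.shape
    valid = np.zeros((h, w), dtype=bool)
    valid[radius : h - radius, radius : w - radius] = True
    if h - 2 * radius <= 0 or w - 2 * radius <= 0:
        return np.zeros((h, w), dtype=bool)
    if field.exclusion_mask is not None and field.exclusion_mask.any():
        # centers whose disc would touch the mask = mask dilated by the disc
        disc = np.zeros((2 * radius + 1, 2 * radius + 1), dtype=bool)
        dy, dx = _disc_offsets(radius)
        disc[dy + radius, dx + radius] = True
        dilated = ndimage.binary_dilation(field.exclusion_mask, structure=disc)
        valid &= ~dilated
    return valid


def sample_background(
    field: FluorescenceField,
    n: int = N_BACKGROUND,
    radius: int = ROI_RADIUS,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 1_000_000,
) -> BackgroundDistribution:
    """Background ROI-mean distribution from random disc placements.

    Discs are placed uniformly at random (rejection sampling over pixel
    centers) subject to lying fully inside the image and not intersecting
    the exclusion mask; different discs may overlap each other.  Returns the
    sampled means with their mean, SD and the mean + 2·SD threshold.
    """
    if n < 1:
        raise ValueError("need at least one background sample")
    rng = np.random.default_rng(seed)
    valid = _valid_center_mask(field, radius)
    if not valid.any():
        raise ValueError("no valid background disc placement exists")
    h, w = field.image.shape
    dy, dx = _disc_offsets(radius)
    means = np.empty(n)
    got = 0
    attempts = 0
    while got < n:
        if attempts >= max_attempts:
            raise RuntimeError("background rejection sampling exceeded cap")
        row = int(rng.integers(radius, h - radius))
        col = int(rng.integers(radius, w - radius))
        attempts += 1
        if not valid[row, col]:
            continue
        means[got] = field.image[row + dy, col + dx].mean()
        got += 1
    mean = float(means.mean())
    sd = float(means.std(ddof=1)) if n > 1 else 0.0
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1
    return BackgroundDistribution(
        roi_means=means,
        mean=mean,
        sd=sd,
        threshold=mean + 2.0 * sd,
        n_samples=n,
        roi_radius=radius,
        seed=int(seed_val),
    )


def classify_gad_cfos(
    field: FluorescenceField,
    bg: BackgroundDistribution,
    treatment: str = "4AP",
) -> pd.DataFrame:
    """Score each GAD cell of the field against the background threshold.

    Positive iff the disc mean strictly exceeds background mean + 2·SD.
    Returns one row per cell with its disc mean and the boolean call.
    """
    rows = []
    for i, (r, c) in enumerate(field.gad_centers):
        m = roi_mean(field, (r, c), bg.roi_radius)
        rows.append(
            {
                "cell_id": f"{field.field_id}:{i}",
                "field_id": field.field_id,
                "treatment": treatment,
                "col_location": field.field_location[0],
                "row_location": field.field_location[1],
                "lateral_position": FIELD_COLUMNS.index(field.field_location[0]) + 1,
                "cfos_mean": m,
                "cfos_positive": bool(m > bg.threshold),
            }
        )
    return pd.DataFrame(rows)


def gad_activation_summary(
    double_positive_per_field: float, gad_per_field: float
) -> int:
    """Percent of GAD positive cells that are c-Fos positive, per field.

    100 · (GAD+/c-Fos+ per field) / (GAD+ per field), rounded to the nearest
    integer.  Because the per-field normalization cancels, the same value is
    obtained from total counts.
    """
    if gad_per_field <= 0:
        raise ValueError("GAD-positive count must be positive")
    return int(round(100.0 * double_positive_per_field / gad_per_field))


def _logit_wald_p(y: np.ndarray, x: np.ndarray) -> dict:
    """Wald p for a single-covariate logistic regression; flags separation."""
    xv = np.asarray(x, dtype=float)
    if len(np.unique(y)) < 2:
        return {"coef": np.nan, "p_value": np.nan, "separation": True}
    if len(np.unique(xv)) < 2:
        # constant covariate: effect not estimable
        return {"coef": np.nan, "p_value": np.nan, "separation": True}
    X = np.column_stack([np.ones(xv.size), xv])
    # complete separation: the covariate perfectly orders the outcomes
    if np.min(xv[y == 1]) > np.max(xv[y == 0]) or np.max(xv[y == 1]) < np.min(
        xv[y == 0]
    ):
        return {"coef": np.nan, "p_value": np.nan, "separation": True}
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception:
        return {"coef": np.nan, "p_value": np.nan, "separation": True}
    if not np.all(np.isfinite(fit.bse)) or np.any(fit.bse > 1e4):
        return {"coef": np.nan, "p_value": np.nan, "separation": True}
    return {
        "coef": float(fit.params[1]),
        "p_value": float(fit.pvalues[1]),
        "separation": False,
    }


def logistic_effect_tests(records: pd.DataFrame) -> dict:
    """Treatment and lateral-position effects on the c-Fos positive call.

    Two separate logistic regressions of ``cfos_positive``: on the 4-AP
    treatment indicator, and on the ordinal medio-lateral position (1 =
    lateral, 3 = medial).  A negative position coefficient means active GAD
    cells concentrate near the lateral edge.
    """
    y = records["cfos_positive"].astype(int).to_numpy()
    out = {}
    if "treatment" in records:
        t = (records["treatment"] == "4AP").astype(float).to_numpy()
        out["treatment"] = _logit_wald_p(y, t)
    if "lateral_position" in records:
        pos = records["lateral_position"].astype(float).to_numpy()
        out["lateral_position"] = _logit_wald_p(y, pos)
    return out


def location_homogeneity_test(counts: pd.DataFrame) -> dict:
    """Poisson log-linear test of homogeneous GAD counts across locations.

    ``counts`` has one row per field with columns ``location`` (any factor
    labeling, e.g. the 3x3 grid position) and ``count``.  The likelihood
    ratio of a location-factor Poisson model against the intercept-only
    model is referred to χ² with (#locations - 1) df.  All-zero counts are
    degenerate and return p = 1 with a flag.
    """
    locs = counts["location"].astype(str)
    k = locs.nunique()
    if k < 2:
        raise ValueError("need at least two field locations")
    y = counts["count"].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")
    if y.sum() == 0:
        return {"lrt": 0.0, "df": k - 1, "p_value": 1.0, "degenerate": True}
    X_full = pd.get_dummies(locs, drop_first=True, dtype=float)
    X_full = sm.add_constant(X_full.to_numpy())
    full = sm.GLM(y, X_full, family=sm.families.Poisson()).fit()
    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Poisson()).fit()
    lrt = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(stats.chi2.sf(lrt, k - 1))
    return {"lrt": float(lrt), "df": k - 1, "p_value": p, "degenerate": False}
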