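"""Seeded synthetic data: H&E-like patches and labelled feature cohorts.

Every generator is a pure function of its spec (which carries the seed), so
downstream stages — stain unmixing, segmentation, screening, tuning,
evaluation — can be exercised end to end with known ground truth and
bit-reproducible outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RUIFROK_HE",
    "CohortSpec",
    "PatchSpec",
    "SyntheticPatch",
    "ReplicateSet",
    "generate_feature_cohort",
    "generate_patch",
    "generate_replicate_set",
]

#: Ruifrok-Johnston hematoxylin / eosin optical-density unit vectors.
RUIFROK_HE = np.array(
    [
        [0.650, 0.704, 0.286],  # hematoxylin
        [0.072, 0.990, 0.105],  # eosin
    ]
)
RUIFROK_HE = RUIFROK_HE / np.linalg.norm(RUIFROK_HE, axis=1, keepdims=True)


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ValueError(f"invalid {field_name}: {message}")


# ---------------------------------------------------------------------------
# feature cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Design of a labelled synthetic feature cohort.

    Defaults mirror the study cohort this pipeline targets: 462 subjects at
    20.6% outcome prevalence, a small informative subset among
    block-correlated nuisance features.
    """

    n_subjects: int = 462
    prevalence: float = 0.206
    n_features: int = 120
    n_informative: int = 6
    effect_size: float = 1.0
    block_rho: float = 0.5
    block_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_subjects >= 2, "n_subjects", "need at least 2 subjects")
        _require(0 < self.prevalence < 1, "prevalence", "must lie in (0, 1)")
        _require(self.n_features >= 1, "n_features", "must be positive")
        _require(
            0 <= self.n_informative <= self.n_features,
            "n_informative",
            "must satisfy 0 <= n_informative <= n_features",
        )
        _require(self.effect_size >= 0, "effect_size", "must be nonnegative")
        _require(0 <= self.block_rho < 1, "block_rho", "must lie in [0, 1)")
        _require(self.block_size >= 1, "block_size", "must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


_NAME_TEMPLATES = (
    "Mean_IdentifyPrimaryObjects_AreaShape_CentralMoment_{a}_{b}",
    "Mean_IdentifyPrimaryObjects_Granularity_{i}_Hematoxylin",
    "Mean_IdentifySecondaryObjects_AreaShape_Zernike_{n}_{m}",
    "Granularity_{i}_Eosin",
    "Mean_IdentifyPrimaryObjects_Intensity_MeanIntensity_Hematoxylin_{i}",
    "Mean_IdentifySecondaryObjects_Intensity_IntegratedIntensity_Eosin_{i}",
)


def cellprofiler_style_names(n: int) -> list[str]:
    """Deterministic CellProfiler-convention column names for *n* features."""
    names: list[str] = []
    i = 0
    while len(names) < n:
        tpl = _NAME_TEMPLATES[i % len(_NAME_TEMPLATES)]
        k = i // len(_NAME_TEMPLATES)
        name = tpl.format(a=k % 5, b=(k + i) % 5, i=k + 1, n=k % 10, m=k % 10)
        if name in names:  # formatting collision — disambiguate
            name = f"{name}_{i}"
        names.append(name)
        i += 1
    return names[:n]


def generate_feature_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a labelled feature table with planted signal.

    Features are built from equicorrelated blocks (within-block correlation
    ``block_rho``), unit marginal variance, then the first ``n_informative``
    columns are shifted by ``effect_size`` standard deviations in class 1.
    Values are affinely squashed to [0, 1] (clipping at ±5 SD) so that they
    live on the min-max-normalisation scale used downstream; the mapping is
    monotone and preserves rank-based statistics.

    Returns a DataFrame indexed by ``subject_id`` whose first column is the
    binary ``label``, followed by CellProfiler-style feature columns.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_subjects, spec.n_features
    y = (rng.random(n) < spec.prevalence).astype(int)

    n_blocks = -(-p // spec.block_size)
    factors = rng.standard_normal((n, n_blocks))
    noise = rng.standard_normal((n, p))
    block_of = np.arange(p) // spec.block_size
    raw = (
        np.sqrt(spec.block_rho) * factors[:, block_of]
        + np.sqrt(1.0 - spec.block_rho) * noise
    )
    raw[:, : spec.n_informative] += spec.effect_size * y[:, None]

    bounded = np.clip(0.5 + raw / 10.0, 0.0, 1.0)

    names = cellprofiler_style_names(p)
    df = pd.DataFrame(bounded, columns=names)
    df.insert(0, "label", y)
    df.index = pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id")
    df.attrs["informative_features"] = names[: spec.n_informative]
    return df


# ---------------------------------------------------------------------------
# image patches
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchSpec:
    """Design of one synthetic H&E-like patch.

    Class 1 patches have more irregular nuclear outlines (radial Fourier
    perturbation of ellipses) and a coarser chromatin/speckle grain, the two
    axes the downstream shape and granularity features are sensitive to.
    ``nucleus_irregularity`` and ``grain_radius`` default per class when
    left as ``None``.
    """

    class_label: int = 0
    width: int = 512
    height: int = 512
    n_nuclei: int = 80
    nucleus_irregularity: float | None = None
    grain_radius: int | None = None
    stain_vectors: np.ndarray = field(default_factory=lambda: RUIFROK_HE.copy())
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.class_label in (0, 1), "class_label", "must be 0 or 1")
        _require(
            self.width >= 64 and self.height >= 64,
            "width/height",
            "must be >= 64 px (objects unresolvable below)",
        )
        _require(self.n_nuclei >= 0, "n_nuclei", "must be nonnegative")
        if self.nucleus_irregularity is not None:
            _require(
                self.nucleus_irregularity >= 0,
                "nucleus_irregularity",
                "must be nonnegative",
            )
        _require(self.noise_sd >= 0, "noise_sd", "must be nonnegative")
        sv = np.asarray(self.stain_vectors, dtype=float)
        _require(sv.shape == (2, 3), "stain_vectors", "must be 2x3")

    @property
    def irregularity(self) -> float:
        if self.nucleus_irregularity is not None:
            return self.nucleus_irregularity
        return 0.25 if self.class_label == 1 else 0.06

    @property
    def grain(self) -> int:
        if self.grain_radius is not None:
            return self.grain_radius
        return 6 if self.class_label == 1 else 3


@dataclass
class SyntheticPatch:
    """RGB patch plus the ground-truth stain densities used to render it."""

    pixels: np.ndarray  # (H, W, 3) uint8
    identifier: str
    h_truth: np.ndarray  # hematoxylin density map (arbitrary OD units)
    e_truth: np.ndarray  # eosin density map


def _nucleus_density(spec: PatchSpec, rng: np.random.Generator) -> np.ndarray:
    h = np.zeros((spec.height, spec.width))
    if spec.n_nuclei == 0:
        return h
    # rejection-sampled centres with a minimum spacing so nuclei stay
    # resolvable as separate connected components
    r_lo, r_hi = 8.0, 13.0
    min_dist = 2.2 * r_hi
    margin = int(r_hi * 2)
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < spec.n_nuclei and tries < spec.n_nuclei * 200:
        tries += 1
        cy = rng.uniform(margin, spec.height - margin)
        cx = rng.uniform(margin, spec.width - margin)
        if all((cy - y0) ** 2 + (cx - x0) ** 2 >= min_dist**2 for y0, x0 in centers):
            centers.append((cy, cx))
    for cy, cx in centers:
        r0 = rng.uniform(r_lo, r_hi)
        ecc = rng.uniform(0.7, 1.0)  # ellipse axis ratio
        phi0 = rng.uniform(0, 2 * np.pi)
        harmonics = np.arange(2, 6)
        amps = rng.normal(0.0, spec.irregularity / np.sqrt(len(harmonics)), len(harmonics))
        phases = rng.uniform(0, 2 * np.pi, len(harmonics))

        half = int(np.ceil(r0 * 2.2)) + 2
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
        ca, sa = np.cos(phi0), np.sin(phi0)
        u = ca * xx + sa * yy
        v = (-sa * xx + ca * yy) / ecc
        rho = np.hypot(u, v)
        theta = np.arctan2(v, u)
        pert = np.sum(
            amps[:, None, None]
            * np.cos(harmonics[:, None, None] * theta[None] + phases[:, None, None]),
            axis=0,
        )
        r_theta = r0 * np.clip(1.0 + pert, 0.3, 2.0)
        dens = np.clip(r_theta - rho, 0.0, 1.0)  # anti-aliased edge

        iy, ix = int(round(cy)), int(round(cx))
        y0, y1 = iy - half, iy + half + 1
        x0, x1 = ix - half, ix + half + 1
        sy0, sx0 = max(0, -y0), max(0, -x0)
        y0, x0 = max(0, y0), max(0, x0)
        y1, x1 = min(spec.height, y1), min(spec.width, x1)
        patch = dens[sy0 : sy0 + (y1 - y0), sx0 : sx0 + (x1 - x0)]
        np.maximum(h[y0:y1, x0:x1], patch, out=h[y0:y1, x0:x1])
    return h


def _grain_density(spec: PatchSpec, rng: np.random.Generator) -> np.ndarray:
    """Speckle field of disks at the class grain scale (chromatin-like dots)."""
    g = np.zeros((spec.height, spec.width))
    r = spec.grain
    # keep total speckle area roughly constant across grain scales
    n_dots = int(0.02 * spec.height * spec.width / (np.pi * r * r))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    disk = np.clip(r - np.hypot(yy, xx) + 0.5, 0.0, 1.0)
    for _ in range(n_dots):
        cy = rng.integers(r, spec.height - r)
        cx = rng.integers(r, spec.width - r)
        sl = g[cy - r : cy + r + 1, cx - r : cx + r + 1]
        np.maximum(sl, disk, out=sl)
    return g


def generate_patch(spec: PatchSpec) -> SyntheticPatch:
    """Render one synthetic patch by Beer-Lambert mixing of H&E densities.

    Hematoxylin density = irregular elliptical nuclei plus a speckle field
    at the class grain scale; eosin density = smoothly varying stroma.
    The RGB image is ``I = 255 · 10^(−OD)`` with
    ``OD = h·v_H + e·v_E`` and additive Gaussian read-out noise.
    """
    rng = np.random.default_rng(spec.seed)
    nuclei = _nucleus_density(spec, rng)
    if spec.n_nuclei > 0:
        # chromatin-like speckle accompanies cellular content only
        grain = _grain_density(spec, rng)
        h_density = 0.9 * nuclei + 0.45 * grain * (nuclei < 0.2)
    else:
        h_density = np.zeros((spec.height, spec.width))

    stroma = rng.standard_normal((spec.height, spec.width))
    stroma = ndimage.gaussian_filter(stroma, 25.0)
    stroma = (stroma - stroma.min()) / max(np.ptp(stroma), 1e-12)
    e_density = 0.22 + 0.12 * stroma

    sv = np.asarray(spec.stain_vectors, dtype=float)
    od = h_density[..., None] * sv[0] + e_density[..., None] * sv[1]
    img = 255.0 * np.power(10.0, -od)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    ident = f"synthetic_c{spec.class_label}_s{spec.seed}"
    return SyntheticPatch(pixels=pixels, identifier=ident, h_truth=h_density, e_truth=e_density)


# ---------------------------------------------------------------------------
# replicate sets (for ICC)
# ---------------------------------------------------------------------------


@dataclass
class ReplicateSet:
    """Repeated measurements: data[subject, replicate, feature]."""

    data: np.ndarray
    feature_names: list[str]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.data.shape[1]


def generate_replicate_set(
    base: pd.DataFrame,
    n_replicates: int,
    noise_sd: float | np.ndarray,
    seed: int = 0,
) -> ReplicateSet:
    """Replicate measurements: each replicate = base value + i.i.d. noise.

    ``noise_sd`` is a scalar or per-feature array of within-subject noise
    scales; with between-subject SD s_b the induced intraclass correlation
    is s_b² / (s_b² + noise_sd²).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    noise_sd = np.asarray(noise_sd, dtype=float)
    if np.any(noise_sd < 0):
        raise ValueError("noise_sd must be nonnegative")
    values = base.to_numpy(dtype=float)
    n, p = values.shape
    if noise_sd.ndim == 0:
        noise_sd = np.full(p, float(noise_sd))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n, n_replicates, p)) * noise_sd[None, None, :]
    data = values[:, None, :] + noise
    return ReplicateSet(data=data, feature_names=list(base.columns))
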