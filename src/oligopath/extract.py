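"""Patch-level pathomics feature extraction and slide-level aggregation.

Per patch: stain unmixing → primary (nucleus) and secondary (cell)
segmentation → per-object shape descriptors (area, central moments,
Zernike magnitudes), per-object intensity summaries, per-object and
image-level granularity spectra. Per-object values are averaged within the
patch (the ``Mean_Identify*Objects_`` prefix); a slide's vector is the
arithmetic mean of its patch vectors.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .granularity import granularity_spectrum, object_granularity
from .segment import NoObjectsError, ObjectLabelMap, identify_primary_objects, identify_secondary_objects
from .shapedesc import central_moments, zernike_indices, zernike_moments
from .stain import unmix_colors

__all__ = ["ExtractionConfig", "SlideFeatures", "extract_patch_features", "extract_slide_features", "resolve_zernike_label"]


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction settings; defaults are CellProfiler-like.

    ``requested_features``, when given, restricts the output to those
    columns (printed Zernike labels with out-of-lattice indices are
    resolved onto the standard (n, m) lattice, see
    :func:`resolve_zernike_label`).
    """

    min_diameter: float = 10.0
    max_diameter: float = 40.0
    max_expand: float = 10.0
    moment_max_order: int = 4
    zernike_max_degree: int = 9
    granularity_subsample: float = 0.25
    granularity_background_radius: int = 10
    granularity_length: int = 16
    stain_vectors: tuple | None = None
    requested_features: tuple[str, ...] | None = None

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return json.dumps(d, default=lambda o: list(o) if hasattr(o, "__iter__") else o)


_ZERNIKE_RE = re.compile(r"Zernike_(\d+)_(\d+)")


def resolve_zernike_label(a: int, b: int, max_degree: int = 9) -> tuple[int, int]:
    """Map a printed ``Zernike_a_b`` label onto the valid (n, m) lattice.

    Valid pairs satisfy 0 ≤ m ≤ n and n − m even. If (a, b) is valid it is
    used directly; if the swap (b, a) is valid it is used; otherwise
    n = max(a, b) and m is reduced to the largest parity-compatible value
    ≤ min(a, b). Published feature lists occasionally print out-of-lattice
    index pairs; this rule keeps their labels addressable.
    """

    def valid(n, m):
        return 0 <= m <= n <= max_degree and (n - m) % 2 == 0

    if valid(a, b):
        return a, b
    if valid(b, a):
        return b, a
    n, m = max(a, b), min(a, b)
    while m >= 0 and not valid(n, m):
        m -= 1
    if m < 0:
        raise ValueError(f"cannot resolve Zernike label ({a}, {b})")
    return n, m


def _object_features(
    labels: ObjectLabelMap,
    channel: np.ndarray,
    prefix: str,
    channel_name: str,
    config: ExtractionConfig,
) -> dict[str, float]:
    """Per-object descriptors averaged over the objects of one label map."""
    idx = np.arange(1, labels.object_count + 1)
    out: dict[str, list[float]] = {}

    objects = ndimage.find_objects(labels.labels)
    for i in idx:
        sl = objects[i - 1]
        if sl is None:
            continue
        mask = labels.labels[sl] == i
        cm = central_moments(mask, config.moment_max_order)
        zm = zernike_moments(mask, config.zernike_max_degree)
        feats = {f"AreaShape_CentralMoment_{p}_{q}": v for (p, q), v in cm.items()}
        feats.update({f"AreaShape_Zernike_{n}_{m}": v for (n, m), v in zm.items()})
        feats["AreaShape_Area"] = float(mask.sum())
        vals = channel[sl][mask]
        feats[f"Intensity_MeanIntensity_{channel_name}"] = float(vals.mean())
        feats[f"Intensity_IntegratedIntensity_{channel_name}"] = float(vals.sum())
        feats[f"Intensity_StdIntensity_{channel_name}"] = float(vals.std())
        for k, v in feats.items():
            out.setdefault(k, []).append(v)

    means = {f"Mean_{prefix}_{k}": float(np.mean(v)) for k, v in out.items()}

    gran = object_granularity(
        channel,
        labels.labels,
        subsample_factor=config.granularity_subsample,
        background_radius=config.granularity_background_radius,
        spectrum_length=config.granularity_length,
    )
    per_obj = gran.mean(axis=0)
    for i, v in enumerate(per_obj, start=1):
        means[f"Mean_{prefix}_Granularity_{i}_{channel_name}"] = float(v)
    return means


def extract_patch_features(pixels: np.ndarray, config: ExtractionConfig = ExtractionConfig()) -> dict[str, float]:
    """Full pathomics vector for one RGB patch.

    Raises :class:`NoObjectsError` when no nucleus can be identified.
    """
    stains = unmix_colors(pixels, config.stain_vectors)
    primary = identify_primary_objects(stains.hematoxylin, config.min_diameter, config.max_diameter)
    secondary = identify_secondary_objects(primary, stains.eosin, config.max_expand)

    feats: dict[str, float] = {}
    feats.update(
        _object_features(primary, stains.hematoxylin, "IdentifyPrimaryObjects", "Hematoxylin", config)
    )
    feats.update(
        _object_features(secondary, stains.eosin, "IdentifySecondaryObjects", "Eosin", config)
    )
    for name, channel in (("Hematoxylin", stains.hematoxylin), ("Eosin", stains.eosin)):
        spec = granularity_spectrum(
            channel,
            subsample_factor=config.granularity_subsample,
            background_radius=config.granularity_background_radius,
            spectrum_length=config.granularity_length,
        )
        for i, v in enumerate(spec, start=1):
            feats[f"Granularity_{i}_{name}"] = float(v)
        feats[f"Intensity_MeanIntensity_{name}"] = float(channel.mean())
        feats[f"Intensity_StdIntensity_{name}"] = float(channel.std())
    feats["Count_IdentifyPrimaryObjects"] = float(primary.object_count)
    return feats


@dataclass
class SlideFeatures:
    """Slide-level feature vector: mean over the slide's patch vectors."""

    values: dict[str, float]
    n_patches: int
    failed_patches: list[int] = field(default_factory=list)

    def to_series(self, name: str | None = None) -> pd.Series:
        return pd.Series(self.values, name=name)


def _select_requested(feats: dict[str, float], requested: tuple[str, ...]) -> dict[str, float]:
    out = {}
    for name in requested:
        if name in feats:
            out[name] = feats[name]
            continue
        m = _ZERNIKE_RE.search(name)
        if m:
            n, mm = resolve_zernike_label(int(m.group(1)), int(m.group(2)))
            resolved = name[: m.start()] + f"Zernike_{n}_{mm}" + name[m.end() :]
            if resolved in feats:
                out[name] = feats[resolved]
                continue
        raise KeyError(f"requested feature {name!r} is not produced by the extractor")
    return out


def extract_slide_features(
    patches: list[np.ndarray],
    config: ExtractionConfig = ExtractionConfig(),
) -> SlideFeatures:
    """Aggregate a slide's patches into one feature vector.

    Each patch is processed independently; a patch on which object
    identification fails is recorded as missing and the slide mean is taken
    over the remaining patches. All patches failing raises
    :class:`NoObjectsError`.
    """
    if len(patches) == 0:
        raise ValueError("need at least one patch")
    vectors: list[dict[str, float]] = []
    failed: list[int] = []
    for i, patch in enumerate(patches):
        pixels = getattr(patch, "pixels", patch)
        try:
            vectors.append(extract_patch_features(pixels, config))
        except NoObjectsError:
            failed.append(i)
    if not vectors:
        raise NoObjectsError("object identification failed on every patch")
    frame = pd.DataFrame(vectors)
    means = frame.mean(axis=0).to_dict()
    if config.requested_features is not None:
        means = _select_requested(means, tuple(config.requested_features))
    return SlideFeatures(values=means, n_patches=len(vectors), failed_patches=failed)
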