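"""Micrograph quantification: PI viability and eYFP expression fold changes.

Viability: image background is removed with one constant threshold shared by
all groups, suprathreshold PI fluorescence is summed per image, and group
means are normalised to the reference (untreated control) group to give fold
changes. When DAPI images are supplied, the dead-cell percentage is also
computed as PI-positive nuclei / DAPI nuclei (and, because the convention is
ambiguous, as a suprathreshold pixel fraction too — both are labelled).

Expression: for every retinal dose a matched non-expressing control image set
determines a noise threshold (an upper quantile of control green pixels)
below which green signal is attributed to autofluorescence; ChR2 images are
corrected by subtracting that threshold (floored at 0), summed, normalised by
the DAPI nucleus count, and expressed as fold change versus the zero-dose
ChR2 group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, filters, measure, morphology, segmentation

__all__ = [
    "QuantResult",
    "count_nuclei",
    "quantify_pi",
    "quantify_eyfp",
]

#: default upper quantile of control green pixels used as the eYFP noise threshold
EYFP_NOISE_QUANTILE = 0.995


@dataclass
class QuantResult:
    """Per-image and per-group quantification with fold changes.

    ``per_image`` has one row per image; ``group_stats`` one row per group
    with ``mean``, ``sem``, ``n`` and ``fold_change`` (reference group = 1 by
    construction). ``threshold`` records the constant background threshold
    (PI) or the per-condition noise thresholds (eYFP).
    """

    per_image: pd.DataFrame
    group_stats: pd.DataFrame
    reference: str
    threshold: float | dict[str, float]
    meta: dict = field(default_factory=dict)

    def fold(self, group: str) -> float:
        return float(self.group_stats.loc[group, "fold_change"])


def count_nuclei(
    dapi_image: np.ndarray, nucleus_radius: float = 5.0
) -> tuple[int, np.ndarray]:
    """Count nuclei in a DAPI image; returns (count, centers (N, 2) row/col).

    Otsu threshold -> small-object removal -> distance transform -> watershed
    split of touching nuclei. A blank image (no contrast above background
    noise) returns 0.
    """
    img = np.asarray(dapi_image, dtype=float)
    smoothed = ndimage.gaussian_filter(img, 1.0)
    lo, hi = smoothed.min(), smoothed.max()
    noise = 1.4826 * np.median(np.abs(img - smoothed))
    if hi - lo <= max(6.0 * noise, 1e-12):
        return 0, np.empty((0, 2))
    thr = filters.threshold_otsu(smoothed)
    mask = smoothed > thr
    min_size = max(4, int(0.3 * math.pi * nucleus_radius**2))
    mask = morphology.remove_small_objects(mask, max_size=min_size - 1)
    if not mask.any():
        return 0, np.empty((0, 2))
    distance = ndimage.distance_transform_edt(mask)
    min_dist = max(2, int(round(1.2 * nucleus_radius)))
    peaks = feature.peak_local_max(
        distance, min_distance=min_dist, labels=mask,
        threshold_abs=0.5 * nucleus_radius,
    )
    if len(peaks) == 0:
        return 0, np.empty((0, 2))
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-distance, markers, mask=mask)
    props = measure.regionprops(labels)
    centers = np.array([p.centroid for p in props]) if props else np.empty((0, 2))
    return len(props), centers


def _group_table(per_image: pd.DataFrame, value_col: str, reference: str) -> pd.DataFrame:
    rows = []
    for group, sub in per_image.groupby("group", sort=False):
        vals = sub[value_col].to_numpy(dtype=float)
        sem = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else math.nan
        rows.append({"group": group, "mean": float(np.mean(vals)), "sem": sem, "n": len(vals)})
    df = pd.DataFrame(rows).set_index("group")
    if reference not in df.index:
        raise ValueError(f"reference group {reference!r} not present")
    ref_mean = df.loc[reference, "mean"]
    if ref_mean == 0:
        warnings.warn("reference group mean is 0; fold changes undefined", stacklevel=3)
        df["fold_change"] = math.nan
    else:
        df["fold_change"] = df["mean"] / ref_mean
    return df


def pi_background_threshold(
    reference_images: Sequence[np.ndarray], n_sigma: float = 3.0
) -> float:
    """Constant PI threshold: mean + ``n_sigma`` SD of the reference background.

    Background pixels are those below the per-image Otsu level (or the whole
    image when it has no bimodal structure). The value is then frozen and
    shared by all groups.
    """
    bg: list[np.ndarray] = []
    for img in reference_images:
        img = np.asarray(img, dtype=float)
        try:
            thr = filters.threshold_otsu(img)
            px = img[img < thr]
        except ValueError:
            px = img.ravel()
        bg.append(px if px.size else img.ravel())
    pooled = np.concatenate(bg)
    return float(pooled.mean() + n_sigma * pooled.std())


def quantify_pi(
    images_by_group: Mapping[str, Sequence[np.ndarray]],
    reference_group: str,
    threshold: float | None = None,
    dapi_by_group: Mapping[str, Sequence[np.ndarray]] | None = None,
    nucleus_radius: float = 5.0,
) -> QuantResult:
    """Quantify cell death from PI micrographs.

    Per image the PI fluorescence of pixels above the single constant
    ``threshold`` is summed; group means are divided by the reference-group
    mean to give fold changes. If ``threshold`` is None it is derived from
    the reference group's background (mean + 3 SD). When matched DAPI images
    are provided, each nucleus is classified PI-positive if the mean PI
    signal in a half-radius disk around its centre exceeds the threshold,
    giving ``dead_fraction`` (cells) alongside ``dead_pixel_fraction``.
    """
    if reference_group not in images_by_group or not images_by_group[reference_group]:
        raise ValueError(f"reference group {reference_group!r} is empty or missing")
    if threshold is None:
        threshold = pi_background_threshold(images_by_group[reference_group])

    global_max = max(float(np.max(img)) for imgs in images_by_group.values() for img in imgs)
    if threshold > global_max:
        warnings.warn("PI threshold above global maximum; all sums are zero", stacklevel=2)

    rows = []
    for group, imgs in images_by_group.items():
        dapis = dapi_by_group.get(group) if dapi_by_group else None
        for i, img in enumerate(imgs):
            img = np.asarray(img, dtype=float)
            above = img > threshold
            row = {
                "group": group,
                "image": i,
                "pi_sum": float(img[above].sum()),
                "pi_pixels": int(above.sum()),
            }
            if dapis is not None:
                count, centers = count_nuclei(np.asarray(dapis[i], float), nucleus_radius)
                n_pos = 0
                rad = max(1, int(round(nucleus_radius / 2)))
                for r, c in centers:
                    r0, c0 = int(round(r)), int(round(c))
                    patch = img[max(0, r0 - rad):r0 + rad + 1, max(0, c0 - rad):c0 + rad + 1]
                    if patch.size and patch.mean() > threshold:
                        n_pos += 1
                dapi_arr = np.asarray(dapis[i], float)
                dapi_above = dapi_arr > threshold
                row["n_nuclei"] = count
                row["n_pi_positive"] = n_pos
                row["dead_fraction"] = n_pos / count if count else math.nan
                row["dead_pixel_fraction"] = (
                    above.sum() / dapi_above.sum() if dapi_above.any() else math.nan
                )
            rows.append(row)
    per_image = pd.DataFrame(rows)
    group_stats = _group_table(per_image, "pi_sum", reference_group)
    if dapi_by_group is not None:
        group_stats = group_stats.join(
            per_image.groupby("group", sort=False)["dead_fraction"].mean().rename("dead_fraction")
        )
    return QuantResult(
        per_image=per_image,
        group_stats=group_stats,
        reference=reference_group,
        threshold=float(threshold),
        meta={"mode": "pi", "nucleus_radius": nucleus_radius},
    )


def quantify_eyfp(
    chr2_by_condition: Mapping[str, Sequence[np.ndarray]],
    control_by_condition: Mapping[str, Sequence[np.ndarray]],
    dapi_by_condition: Mapping[str, Sequence[np.ndarray]],
    reference_condition: str,
    noise_quantile: float = EYFP_NOISE_QUANTILE,
    nucleus_radius: float = 5.0,
) -> QuantResult:
    """Quantify ChR2 expression from eYFP micrographs.

    For each condition the noise threshold is the ``noise_quantile`` of the
    pooled matched control (non-expressing) green pixels; ChR2 images are
    corrected by subtracting it (floored at 0), summed and divided by the
    DAPI nucleus count. Fold change is versus the reference (zero-dose)
    condition mean. A condition without a matched control raises an error
    naming it.
    """
    for cond in chr2_by_condition:
        if cond not in control_by_condition or not control_by_condition[cond]:
            raise ValueError(f"no matched control images for condition {cond!r}")
        if cond not in dapi_by_condition or not dapi_by_condition[cond]:
            raise ValueError(f"no DAPI images for condition {cond!r}")
    if reference_condition not in chr2_by_condition:
        raise ValueError(f"reference condition {reference_condition!r} missing")

    thresholds = {
        cond: float(np.quantile(
            np.concatenate([np.asarray(im, float).ravel() for im in imgs]),
            noise_quantile,
        ))
        for cond, imgs in control_by_condition.items()
    }

    rows = []
    for cond, imgs in chr2_by_condition.items():
        thr = thresholds[cond]
        dapis = dapi_by_condition[cond]
        for i, img in enumerate(imgs):
            corrected = np.clip(np.asarray(img, float) - thr, 0.0, None)
            total = float(corrected.sum())
            count, _ = count_nuclei(np.asarray(dapis[i], float), nucleus_radius)
            rows.append({
                "group": cond,
                "image": i,
                "eyfp_sum": total,
                "n_nuclei": count,
                "eyfp_per_cell": total / count if count else math.nan,
            })
    per_image = pd.DataFrame(rows)
    group_stats = _group_table(per_image, "eyfp_per_cell", reference_condition)
    return QuantResult(
        per_image=per_image,
        group_stats=group_stats,
        reference=reference_condition,
        threshold=thresholds,
        meta={"mode": "eyfp", "noise_quantile": noise_quantile,
              "nucleus_radius": nucleus_radius},
    )
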