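"""Tissue-section Golgi-area pipeline.

Segments marker-positive (e.g. GM130) regions in seminiferous-tubule
sections, measures their areas in square micrometres, classifies them
against a size threshold (default 5 um^2, strict ``>``), and aggregates
the fraction of large Golgi per tubule and per differentiation-stage
group.  Tubule membership and staging are supplied as annotations
(ground truth for synthetic images, or a user mask/stage map for real
sections); automated staging is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib import colormaps
from skimage.measure import label, regionprops

from .datatypes import STAGE_GROUPS, GolgiAreaRecord, StageSummary
from .golgi_density import binarize_golgi, compare_groups

__all__ = [
    "SegmentedRegions",
    "segment_regions",
    "classify_area",
    "summarize_by_stage",
    "pseudocolor",
    "DEFAULT_THRESHOLD_UM2",
]

DEFAULT_THRESHOLD_UM2 = 5.0


@dataclass
class SegmentedRegions:
    labels: np.ndarray            # 0 = background, 1..n regions
    region_ids: np.ndarray
    areas_um2: np.ndarray
    pixel_size_um: float


def segment_regions(
    channel: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 0.2,
) -> SegmentedRegions:
    """Otsu-binarize a marker channel and measure 8-connected region areas.

    Regions smaller than ``min_area_um2`` are removed from the label
    image.  An image with no surviving regions yields an empty table,
    not an error.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    mask = binarize_golgi(channel)
    labels = label(mask, connectivity=2)
    px2 = pixel_size_um**2
    ids, areas = [], []
    for p in regionprops(labels):
        area = p.area * px2
        if area < min_area_um2:
            labels[labels == p.label] = 0
            continue
        ids.append(p.label)
        areas.append(area)
    return SegmentedRegions(
        labels=labels,
        region_ids=np.asarray(ids, dtype=int),
        areas_um2=np.asarray(areas, dtype=float),
        pixel_size_um=pixel_size_um,
    )


def classify_area(area_um2: float, threshold_um2: float = DEFAULT_THRESHOLD_UM2) -> bool:
    """True iff the region is strictly larger than the threshold.

    A region exactly at the threshold counts as *not* above ("greater
    than" is strict).
    """
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    if threshold_um2 <= 0:
        raise ValueError("threshold must be positive")
    return area_um2 > threshold_um2


def records_from_segmentation(
    seg: SegmentedRegions,
    tubule_of_region: dict[int, int],
    stage_of_tubule: dict[int, str] | None = None,
    threshold_um2: float = DEFAULT_THRESHOLD_UM2,
) -> list[GolgiAreaRecord]:
    """Attach tubule/stage annotations and the size class to each region."""
    stage_of_tubule = stage_of_tubule or {}
    records = []
    for rid, area in zip(seg.region_ids, seg.areas_um2):
        tid = tubule_of_region.get(int(rid), -1)
        records.append(
            GolgiAreaRecord(
                region_id=int(rid),
                tubule_id=int(tid),
                stage_group=stage_of_tubule.get(tid, "unknown"),
                area_um2=float(area),
                above_threshold=classify_area(float(area), threshold_um2),
            )
        )
    return records


def summarize_by_stage(
    records: list[GolgiAreaRecord],
    expected_stages: tuple[str, ...] | None = None,
) -> list[StageSummary]:
    """Aggregate large-Golgi percentages per stage group.

    The per-tubule percentage of above-threshold regions is computed
    first; each stage group is then summarized as mean +/- SEM over its
    tubules.  A pooled percentage (all regions of the stage lumped) is
    emitted alongside.  A stage listed in ``expected_stages`` but backed
    by no tubules is omitted with a warning.
    """
    if not records:
        return []
    expected = set(expected_stages or ())
    df = pd.DataFrame(
        {
            "tubule_id": [r.tubule_id for r in records],
            "stage_group": [r.stage_group for r in records],
            "above": [r.above_threshold for r in records],
        }
    )
    summaries = []
    for stage in STAGE_GROUPS:
        sub = df[df.stage_group == stage]
        if sub.empty:
            if stage in expected:
                warnings.warn(f"stage group {stage} has no tubules; omitted", stacklevel=2)
            continue
        per_tubule = sub.groupby("tubule_id")["above"].mean() * 100.0
        n_tub = len(per_tubule)
        sem = float(per_tubule.std(ddof=1) / np.sqrt(n_tub)) if n_tub > 1 else 0.0
        summaries.append(
            StageSummary(
                stage_group=stage,
                n_tubules=n_tub,
                n_regions=int(len(sub)),
                percent_above=float(per_tubule.mean()),
                sem_percent_above=sem,
                per_tubule_percentages=per_tubule.tolist(),
                pooled_percent_above=float(sub["above"].mean() * 100.0),
            )
        )
    return summaries


def compare_stage_percentages(a: StageSummary, b: StageSummary) -> tuple[float, float]:
    """Unpaired t-test between two conditions' per-tubule percentages."""
    return compare_groups(a.per_tubule_percentages, b.per_tubule_percentages)


def pseudocolor(
    seg: SegmentedRegions,
    threshold_um2: float = DEFAULT_THRESHOLD_UM2,
    below_cmap: str = "viridis",
    above_color=(1.0, 0.1, 0.1),
) -> np.ndarray:
    """Render regions on a continuous area scale, large ones flagged red.

    Below-threshold regions are coloured along ``below_cmap`` by
    area / threshold; above-threshold regions are painted in the distinct
    ``above_color`` class.  Background is black.  Returns an RGB float
    image in [0, 1].
    """
    cmap = colormaps[below_cmap]
    rgb = np.zeros(seg.labels.shape + (3,), dtype=float)
    for rid, area in zip(seg.region_ids, seg.areas_um2):
        where = seg.labels == rid
        if classify_area(area, threshold_um2):
            rgb[where] = above_color
        else:
            rgb[where] = cmap(min(area / threshold_um2, 1.0))[:3]
    return rgb
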