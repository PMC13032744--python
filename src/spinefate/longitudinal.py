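"""Spine tracking across imaging days, survival and astrocyte proximity.

A dendrite imaged on Day 1 and Day 2 is re-aligned by a single rigid
translation; a Day-1 spine survives iff a Day-2 spine lies within its
radius after alignment.  Astrocyte proximity follows the tripartite-
synapse criterion: a spine is proximal if astrocyte signal overlaps its
ROI or lies within one spine radius of it — i.e. any astrocyte-positive
pixel within twice the spine-head radius of the centroid, boundary
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "MatchResult",
    "match_spines",
    "classify_proximity",
    "percent_spine_loss",
    "survival_by_proximity",
    "relative_change",
    "annotate_changes",
    "psvue_spine_intensity",
    "psvue_field_intensity",
]


@dataclass
class MatchResult:
    """Outcome of Day-1 → Day-2 spine matching on one dendrite."""

    shift: np.ndarray  # translation applied to day-2 coordinates (x, y)
    matches: dict[int, int]  # day-1 index -> day-2 index
    survived: np.ndarray  # per day-1 spine


def _nn_cost(day2: np.ndarray, day1: np.ndarray, shift: np.ndarray) -> float:
    tree = cKDTree(day1)
    d, _ = tree.query(day2 + shift)
    return float(np.sum(d))


def match_spines(
    day1_xy: np.ndarray,
    day2_xy: np.ndarray,
    radii: np.ndarray | float,
    max_shift_px: float = 20.0,
) -> MatchResult:
    """Rigid-translation alignment and one-to-one survival matching.

    The translation minimising the summed nearest-neighbour distance is
    searched over candidate shifts formed by all day-2→day-1 point pairs
    (bounded by ``max_shift_px``), then refined as the mean displacement
    of the implied mutual matches.  Matching is greedy nearest-first; ties
    break on the lower day-2 index.  A day-1 spine survives iff its
    matched day-2 spine lies within the spine radius.
    """
    day1 = np.atleast_2d(np.asarray(day1_xy, dtype=float))
    if day1.size == 0:
        raise ValueError("day-1 spine set is empty")
    day2 = np.asarray(day2_xy, dtype=float).reshape(-1, 2)
    n1 = day1.shape[0]
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (n1,))
    if np.any(radii <= 0):
        raise ValueError("spine radii must be positive")
    if day2.shape[0] == 0:
        return MatchResult(np.zeros(2), {}, np.zeros(n1, dtype=bool))

    candidates = [np.zeros(2)]
    for q in day2:
        for p in day1:
            s = p - q
            if np.hypot(*s) <= max_shift_px:
                candidates.append(s)
    shift = min(candidates, key=lambda s: _nn_cost(day2, day1, s))
    # refine: mean displacement over provisional within-radius matches
    tree = cKDTree(day1)
    d, idx = tree.query(day2 + shift)
    ok = d <= 2 * np.max(radii)
    if np.any(ok):
        shift = shift + np.mean(day1[idx[ok]] - (day2[ok] + shift), axis=0)

    aligned = day2 + shift
    # greedy nearest-first one-to-one assignment, deterministic tie-break
    pairs = sorted(
        ((np.hypot(*(day1[i] - aligned[j])), i, j)
         for i in range(n1) for j in range(aligned.shape[0])),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used1: set[int] = set()
    used2: set[int] = set()
    matches: dict[int, int] = {}
    survived = np.zeros(n1, dtype=bool)
    for dist, i, j in pairs:
        if i in used1 or j in used2:
            continue
        if dist <= radii[i]:
            matches[i] = j
            survived[i] = True
            used1.add(i)
            used2.add(j)
    return MatchResult(np.asarray(shift), matches, survived)


def classify_proximity(
    centroid_xy: tuple[float, float] | np.ndarray,
    radius_px: float,
    astro_mask: np.ndarray,
) -> bool:
    """True iff any astrocyte-positive pixel lies within ``2·radius`` of
    the spine centroid (ROI extent + one spine radius), boundary
    inclusive.  Pixel coordinates are (x=column, y=row) centres."""
    cx, cy = float(centroid_xy[0]), float(centroid_xy[1])
    h, w = astro_mask.shape
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("spine centroid outside mask bounds")
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    pts = np.argwhere(astro_mask)
    if pts.size == 0:
        return False
    tree = cKDTree(pts[:, ::-1])  # to (x, y)
    d, _ = tree.query([cx, cy])
    return bool(d <= 2.0 * radius_px)


def percent_spine_loss(survived: np.ndarray | pd.Series) -> float:
    """Spines lost between days as a percentage of Day-1 spines."""
    survived = np.asarray(survived, dtype=bool)
    if survived.size == 0:
        raise ValueError("no day-1 spines")
    return 100.0 * float((~survived).sum()) / survived.size


def survival_by_proximity(
    records: pd.DataFrame,
    survived_col: str = "survived",
    proximity_col: str = "proximity",
) -> pd.Series:
    """Per-dendrite survival fractions for proximal / non-proximal spines.

    Returns a Series indexed ``{"proximal", "non_proximal"}``; an empty
    group yields NaN (undefined, not zero).
    """
    out = {}
    for label, flag in (("proximal", True), ("non_proximal", False)):
        grp = records[records[proximity_col] == flag]
        out[label] = float(grp[survived_col].mean()) if len(grp) else np.nan
    return pd.Series(out)


def relative_change(pre: float, post: float) -> float:
    """(POST − PRE) / PRE; the ΔHz/Hz and ΔPsVue/PsVue statistic.

    A spine silent at PRE but active at POST yields +inf (reported
    separately, excluded from means); silent at both yields 0.
    """
    if pre < 0 or post < 0:
        raise ValueError("rates/intensities must be non-negative")
    if pre == 0:
        return 0.0 if post == 0 else np.inf
    return (post - pre) / pre


def annotate_changes(spines: pd.DataFrame) -> pd.DataFrame:
    """Add ``rel_change_hz`` and ``rel_change_psvue`` columns
    ((POST − PRE)/PRE) to a spine table; infinities are kept as values and
    handled downstream (excluded from means, reported separately)."""
    out = spines.copy()
    out["rel_change_hz"] = [
        relative_change(p, q) for p, q in zip(out["rate_pre"], out["rate_post"])
    ]
    out["rel_change_psvue"] = [
        relative_change(p, q) for p, q in zip(out["psvue_pre"], out["psvue_post"])
    ]
    return out


def _sum_project(stack: np.ndarray, background: float | np.ndarray = 0.0) -> np.ndarray:
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    proj = stack.sum(axis=0)
    return np.clip(proj - background, 0.0, None)


def psvue_spine_intensity(
    stack: np.ndarray,
    roi_mask: np.ndarray,
    background: float | np.ndarray = 0.0,
) -> float:
    """Mean PsVue intensity over an ROI of the background-subtracted sum
    projection of the stack."""
    proj = _sum_project(stack, background)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != proj.shape:
        raise ValueError("ROI mask shape does not match the projection")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    return float(proj[roi_mask].mean())


def psvue_field_intensity(
    stack: np.ndarray, background: float | np.ndarray = 0.0
) -> float:
    """Mean PsVue intensity over the whole field of the sum projection."""
    return float(_sum_project(stack, background).mean())
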