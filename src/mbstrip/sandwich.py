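"""Sandwich epitope-pair selection.

A sandwich lateral-flow strip is positive only when the analyte binds both
the gold-conjugated *detect* antibody and the immobilized *capture*
antibody (logical AND).  A pair of antigenic regions therefore
discriminates the target group perfectly when every target species binds
both region epitopes while every off-target species fails at least one.

The detect role goes to the region whose antibody binds more panel species
(the conjugate should capture as much antigen as possible); the narrower
antibody takes the test-line capture role, where it resolves the fine
differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .align import Alignment
from .binding import BindingModelParams, BindingScore, binding_score
from .panel import ReferencePanel, TARGET
from .regions import (
    AntigenicRegion,
    DEFAULT_FLANK_WIDTH,
    EpitopeWindow,
    consensus_window,
    extract_window,
)


@dataclass(frozen=True)
class DiscriminationResult:
    """AND-logic outcome of one (detect, capture) region pair over a panel."""

    pair: tuple[int, int]  # region indices (detect, capture)
    n_target_positive: int
    n_offtarget_negative: int
    perfect: bool
    calls: Mapping[str, tuple[bool, bool]]  # id -> (binds detect, binds capture)


@dataclass(frozen=True)
class SandwichDesign:
    """Chosen capture/detect regions plus per-species binding profiles."""

    detect_region: AntigenicRegion
    capture_region: AntigenicRegion
    detect_profile: Mapping[str, bool]
    capture_profile: Mapping[str, bool]
    margin: float


def enumerate_pairs(
    catalog: tuple[AntigenicRegion, ...]
) -> tuple[tuple[AntigenicRegion, AntigenicRegion], ...]:
    """All ordered (detect, capture) pairs of distinct regions, in index order."""
    if len(catalog) < 2:
        raise ValueError("need at least 2 regions to enumerate pairs")
    ordered = sorted(catalog, key=lambda r: r.index)
    return tuple(
        (d, c) for d in ordered for c in ordered if d.index != c.index
    )


def region_scores(
    region: AntigenicRegion,
    panel: ReferencePanel,
    msa: Alignment,
    params: BindingModelParams,
    flank_width: int = DEFAULT_FLANK_WIDTH,
) -> dict[str, BindingScore]:
    """Score every panel species against the target-consensus epitope of a region."""
    epitope = consensus_window(msa, panel, region, flank_width, group=TARGET)
    return {
        record.id: binding_score(
            epitope, extract_window(msa, record.id, region, flank_width), params
        )
        for record in panel.records
    }


def evaluate_pair(
    pair: tuple[AntigenicRegion, AntigenicRegion],
    panel: ReferencePanel,
    msa: Alignment,
    params: BindingModelParams,
    flank_width: int = DEFAULT_FLANK_WIDTH,
) -> DiscriminationResult:
    """AND-logic discrimination of one ordered (detect, capture) pair."""
    detect, capture = pair
    if detect.index == capture.index:
        raise ValueError("detect and capture regions must differ")
    panel.validate_for_design()
    scores_d = region_scores(detect, panel, msa, params, flank_width)
    scores_c = region_scores(capture, panel, msa, params, flank_width)

    calls = {
        rid: (scores_d[rid].binds, scores_c[rid].binds) for rid in panel.ids
    }
    n_target_positive = sum(
        1 for r in panel.records if r.group == TARGET and all(calls[r.id])
    )
    n_offtarget_negative = sum(
        1 for r in panel.records if r.group != TARGET and not all(calls[r.id])
    )
    from .panel import count_group

    perfect = (
        n_target_positive == count_group(panel, "target")
        and n_offtarget_negative == count_group(panel, "offtarget")
    )
    return DiscriminationResult(
        pair=(detect.index, capture.index),
        n_target_positive=n_target_positive,
        n_offtarget_negative=n_offtarget_negative,
        perfect=perfect,
        calls=calls,
    )


def _pair_margin(
    scores_d: Mapping[str, BindingScore],
    scores_c: Mapping[str, BindingScore],
    panel: ReferencePanel,
    threshold: float,
) -> float:
    """Minimum distance-to-misclassification over panel species.

    A positive species flips as soon as either region crosses the
    threshold, so its margin is the smaller headroom of the two regions.
    A negative species flips only when every failing region drops back
    under the threshold, so its margin is the largest excess among the
    failing regions.
    """
    margins = []
    for record in panel.records:
        t_d = scores_d[record.id].total
        t_c = scores_c[record.id].total
        failing = [t for t in (t_d, t_c) if t > threshold]
        if not failing:  # predicted positive
            margins.append(min(threshold - t_d, threshold - t_c))
        else:
            margins.append(max(t - threshold for t in failing))
    return min(margins) if margins else 0.0


def all_perfect_pairs(
    panel: ReferencePanel,
    msa: Alignment,
    params: BindingModelParams,
    flank_width: int = DEFAULT_FLANK_WIDTH,
    catalog: tuple[AntigenicRegion, ...] | None = None,
) -> list[DiscriminationResult]:
    """Every ordered pair whose AND-logic is perfect on this panel."""
    from .regions import load_region_catalog

    catalog = catalog or load_region_catalog()
    return [
        result
        for pair in enumerate_pairs(catalog)
        if (result := evaluate_pair(pair, panel, msa, params, flank_width)).perfect
    ]


def select_sandwich_pair(
    panel: ReferencePanel,
    msa: Alignment,
    params: BindingModelParams,
    flank_width: int = DEFAULT_FLANK_WIDTH,
    catalog: tuple[AntigenicRegion, ...] | None = None,
) -> SandwichDesign | None:
    """Best perfect pair, or ``None`` when no pair separates the groups.

    Among perfect pairs the one with maximal margin wins; ties break to the
    lowest (detect index, capture index).  Roles are then assigned by
    breadth: the region binding more panel species becomes the detect
    (conjugate) antibody, the narrower one the capture (test-line) antibody.
    """
    from .regions import get_region, load_region_catalog

    catalog = catalog or load_region_catalog()
    panel.validate_for_design()

    score_cache = {
        region.index: region_scores(region, panel, msa, params, flank_width)
        for region in catalog
    }

    best: tuple[float, tuple[int, int]] | None = None
    for detect, capture in enumerate_pairs(catalog):
        result = evaluate_pair((detect, capture), panel, msa, params, flank_width)
        if not result.perfect:
            continue
        margin = _pair_margin(
            score_cache[detect.index],
            score_cache[capture.index],
            panel,
            params.binding_threshold,
        )
        key = (margin, (detect.index, capture.index))
        if best is None or margin > best[0] or (
            margin == best[0] and key[1] < best[1]
        ):
            best = key
    if best is None:
        return None

    d_idx, c_idx = best[1]
    breadth = {
        idx: sum(1 for s in score_cache[idx].values() if s.binds)
        for idx in (d_idx, c_idx)
    }
    if breadth[c_idx] > breadth[d_idx]:
        d_idx, c_idx = c_idx, d_idx

    lookup = {r.index: r for r in catalog}
    detect_region, capture_region = lookup[d_idx], lookup[c_idx]
    return SandwichDesign(
        detect_region=detect_region,
        capture_region=capture_region,
        detect_profile={
            rid: s.binds for rid, s in score_cache[d_idx].items()
        },
        capture_profile={
            rid: s.binds for rid, s in score_cache[c_idx].items()
        },
        margin=best[0],
    )


def binding_matrix(
    panel: ReferencePanel,
    msa: Alignment,
    params: BindingModelParams,
    flank_width: int = DEFAULT_FLANK_WIDTH,
    catalog: tuple[AntigenicRegion, ...] | None = None,
) -> pd.DataFrame:
    """Species x region table of binding scores and boolean calls."""
    from .regions import load_region_catalog

    catalog = catalog or load_region_catalog()
    rows = []
    per_region = {
        region.index: region_scores(region, panel, msa, params, flank_width)
        for region in catalog
    }
    for record in panel.records:
        row: dict[str, object] = {
            "id": record.id,
            "species": record.species,
            "group": record.group,
        }
        for region in catalog:
            score = per_region[region.index][record.id]
            row[f"region{region.index}_total"] = score.total
            row[f"region{region.index}_binds"] = score.binds
        rows.append(row)
    return pd.DataFrame.from_records(rows)
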