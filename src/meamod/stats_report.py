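"""Group comparisons and end-to-end report assembly.

All group contrasts use the two-sided Mann-Whitney U test on medians, the
convention for these skewed, small-n electrophysiology summaries: exact
enumeration when the combined sample is small and tie-free, otherwise the
tie-corrected normal approximation with continuity correction.  P-values
are reported raw — no multiple-testing correction is applied, and the
report header says so.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .burst_analysis import (
    BurstCatalog,
    BurstDetectionParams,
    bursts_per_minute,
    detect_bursts,
    firing_rate,
)
from .burst_typing import ActivityTypeParams, ActivityTypeResult, classify_activity
from .connectivity import CFPParams, ConnectivityResult, connectivity_matrix
from .errors import ConsistencyError, InsufficientDataError, ValidationError
from .io_core import ElectrodeMap, SpikeTrainSet, register_report_type
from .propagation import PropagationParams, PropagationResult, propagation_probability

__all__ = [
    "GroupComparison",
    "ModuleSummary",
    "RecordingAnalysis",
    "Report",
    "mann_whitney",
    "analyze_recording",
    "build_report",
]

_EXACT_MAX_N = 20


@register_report_type
@dataclass
class GroupComparison:
    """Two-sided Mann-Whitney comparison of two labeled samples."""

    label_a: str
    label_b: str
    group_a: List[float]
    group_b: List[float]
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx_tie_corrected"


def mann_whitney(
    a: Sequence[float], b: Sequence[float], label_a: str = "a", label_b: str = "b"
) -> GroupComparison:
    """Two-sided Mann-Whitney U; exact when combined n <= 20 with no ties."""
    xa = np.asarray(list(a), dtype=float)
    xb = np.asarray(list(b), dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ValidationError("Mann-Whitney requires two non-empty samples")
    combined = np.concatenate([xa, xb])
    tie_free = np.unique(combined).size == combined.size
    if xa.size + xb.size <= _EXACT_MAX_N and tie_free:
        method = "exact"
        res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method="exact")
    else:
        method = "normal_approx_tie_corrected"
        res = sps.mannwhitneyu(
            xa, xb, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        group_a=[float(v) for v in xa],
        group_b=[float(v) for v in xb],
        median_a=float(np.median(xa)),
        median_b=float(np.median(xb)),
        u_statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method=method,
    )


@register_report_type
@dataclass
class ModuleSummary:
    """Per-module activity summary for one recording."""

    module: str
    firing_rate_hz: float
    n_bursts: int
    bursts_per_min: float
    median_sbe: Optional[float]
    median_bd_ms: Optional[float]
    activity_type: Optional[str]       # None when too few bursts to decide
    db_index: Optional[float]


@register_report_type
@dataclass
class RecordingAnalysis:
    """All per-recording stage outputs, bundled for pooling."""

    recording_id: str
    source: ModuleSummary
    target: ModuleSummary
    source_catalog: BurstCatalog
    target_catalog: BurstCatalog
    propagation: PropagationResult
    connectivity: Optional[ConnectivityResult]
    activity_type_disagreement: bool


@register_report_type
@dataclass
class Report:
    header: Dict[str, str]
    recordings: List[RecordingAnalysis]
    comparisons: Dict[str, GroupComparison]
    warnings: List[str]


def _summarize_module(
    sts: SpikeTrainSet,
    emap: ElectrodeMap,
    module: str,
    cat: BurstCatalog,
    typing_params: ActivityTypeParams,
) -> ModuleSummary:
    sbe = cat.sbe_values()
    bd = cat.duration_values_ms()
    try:
        typing: Optional[ActivityTypeResult] = classify_activity(cat, typing_params)
    except InsufficientDataError:
        typing = None
    return ModuleSummary(
        module=module,
        firing_rate_hz=firing_rate(sts, emap, module),
        n_bursts=len(cat),
        bursts_per_min=bursts_per_minute(cat),
        median_sbe=float(np.median(sbe)) if sbe.size else None,
        median_bd_ms=float(np.median(bd)) if bd.size else None,
        activity_type=typing.decided_type if typing else None,
        db_index=typing.db_index if typing else None,
    )


def analyze_recording(
    sts: SpikeTrainSet,
    emap: ElectrodeMap,
    recording_id: str = "recording",
    burst_params: Optional[BurstDetectionParams] = None,
    typing_params: Optional[ActivityTypeParams] = None,
    propagation_params: Optional[PropagationParams] = None,
    cfp_params: Optional[CFPParams] = None,
    with_connectivity: bool = True,
) -> RecordingAnalysis:
    """Run the full pipeline on one recording."""
    burst_params = burst_params or BurstDetectionParams()
    typing_params = typing_params or ActivityTypeParams()
    src_cat = detect_bursts(sts, emap, "source", burst_params)
    tgt_cat = detect_bursts(sts, emap, "target", burst_params)
    src_sum = _summarize_module(sts, emap, "source", src_cat, typing_params)
    tgt_sum = _summarize_module(sts, emap, "target", tgt_cat, typing_params)
    prop = propagation_probability(src_cat, tgt_cat, propagation_params)
    conn = connectivity_matrix(sts, emap, cfp_params) if with_connectivity else None
    disagree = (
        src_sum.activity_type is not None
        and tgt_sum.activity_type is not None
        and src_sum.activity_type != tgt_sum.activity_type
    )
    return RecordingAnalysis(
        recording_id=recording_id,
        source=src_sum,
        target=tgt_sum,
        source_catalog=src_cat,
        target_catalog=tgt_cat,
        propagation=prop,
        connectivity=conn,
        activity_type_disagreement=disagree,
    )


def _pool(recordings: List[RecordingAnalysis], metric) -> Dict[str, List[float]]:
    """Per-recording metric values keyed by the Source module's activity type."""
    groups: Dict[str, List[float]] = {"type1": [], "type2": []}
    for rec in recordings:
        t = rec.source.activity_type
        if t is None:
            continue
        v = metric(rec)
        if v is not None:
            groups[t].append(float(v))
    return groups


def build_report(recordings: List[RecordingAnalysis]) -> Report:
    """Assemble the pooled, activity-type-stratified report.

    Pools per-recording medians by the Source module's activity type and
    compares type 1 vs type 2 for SBE, BD, bursts/min and PPST; within each
    recording's connectivity, compares intra- vs inter-modular strength and
    latency pooled over recordings.
    """
    if not recordings:
        raise ValidationError("need at least one recording")
    ids = [r.recording_id for r in recordings]
    if len(set(ids)) != len(ids):
        raise ConsistencyError(f"duplicate recording identifiers: {ids}")

    warnings = [
        f"{r.recording_id}: Source and Target modules disagree on activity type"
        for r in recordings
        if r.activity_type_disagreement
    ]

    metrics = {
        "sbe_source": lambda r: r.source.median_sbe,
        "bd_ms_source": lambda r: r.source.median_bd_ms,
        "bursts_per_min_source": lambda r: r.source.bursts_per_min,
        "ppst": lambda r: r.propagation.ppst,
    }
    comparisons: Dict[str, GroupComparison] = {}
    for name, metric in metrics.items():
        groups = _pool(recordings, metric)
        if groups["type1"] and groups["type2"]:
            comparisons[f"{name}_type1_vs_type2"] = mann_whitney(
                groups["type1"], groups["type2"], "type1", "type2"
            )

    intra_strength: List[float] = []
    inter_strength: List[float] = []
    intra_latency: List[float] = []
    inter_latency: List[float] = []
    for rec in recordings:
        if rec.connectivity is None:
            continue
        for grp in (rec.connectivity.intra_source, rec.connectivity.intra_target):
            for c in grp:
                if c.connected:
                    intra_strength.append(c.strength)
                    intra_latency.append(c.latency_ms)
        for c in rec.connectivity.source_to_target:
            if c.connected:
                inter_strength.append(c.strength)
                inter_latency.append(c.latency_ms)
    if intra_strength and inter_strength:
        comparisons["strength_intra_vs_inter"] = mann_whitney(
            intra_strength, inter_strength, "intra", "inter"
        )
        comparisons["latency_intra_vs_inter"] = mann_whitney(
            intra_latency, inter_latency, "intra", "inter"
        )

    header = {
        "software": "meamod",
        "statistics": "two-sided Mann-Whitney U on medians",
        "multiple_testing": "none; p-values are raw",
    }
    return Report(header=header, recordings=recordings, comparisons=comparisons, warnings=warnings)
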