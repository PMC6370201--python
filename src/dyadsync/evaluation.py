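"""Concordance scoring of detected intervals against reference intervals.

Detected and reference intervals are rasterized to per-frame binary series
(1 = synchrony present), compared frame-wise with Cohen's kappa (sync
sequences) or summarized as the proportion of over-identified frames,
pr_out (no-sync sequences).  A configuration's identification rate (IR) is
an ordinal class per side:

    sync   — good: min kappa > .60; acceptable: min kappa in [.40, .60];
             poor: below .40
    nosync — good: max pr_out <= 5%; acceptable: in (5%, 10%]; poor: above

The combined IR is good only when both sides are good (the min of the two
classes in general).  The sequential gating of the validation study keeps
good configurations from the artificial condition, then good-or-acceptable
survivors from the isolated condition, before looking at the embedded one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np

__all__ = [
    "BinaryRating",
    "ConfigEvaluation",
    "intervals_to_binary",
    "cohens_kappa",
    "pr_out",
    "classify_ir",
    "sequential_selection",
    "IR_ORDER",
]

BinaryRating = np.ndarray  # values in {0, 1}

IR_ORDER = {"poor": 0, "acceptable": 1, "good": 2}
IR_LEVELS = ("poor", "acceptable", "good")

# classification boundaries, all in one place:
KAPPA_GOOD = 0.60  # strict: good requires min kappa > .60
KAPPA_ACCEPTABLE = 0.40  # inclusive: [.40, .60] is acceptable
PR_OUT_GOOD = 0.05  # inclusive: max pr_out <= 5% is good
PR_OUT_ACCEPTABLE = 0.10  # (5%, 10%] is acceptable


def intervals_to_binary(intervals: Iterable, n_frames: int) -> BinaryRating:
    """Union of half-open [start, end) intervals as a 0/1 frame series."""
    out = np.zeros(n_frames, dtype=np.int8)
    for iv in intervals:
        start, end = int(iv.start), int(iv.end)
        if start < 0 or end > n_frames:
            raise ValueError(
                f"interval [{start}, {end}) outside [0, {n_frames})"
            )
        out[start:end] = 1
    return out


def cohens_kappa(reference: BinaryRating, detected: BinaryRating) -> float:
    """Chance-corrected frame-level agreement of two binary series.

    kappa = (p_o - p_e) / (1 - p_e) from the 2x2 contingency table.  In the
    degenerate case p_e = 1 (both series constant with identical marginal),
    returns 1.0 if the series are identical and 0.0 otherwise.
    """
    ref = np.asarray(reference)
    det = np.asarray(detected)
    if ref.shape != det.shape or ref.size < 1:
        raise ValueError("ratings must have equal nonzero length")
    n = ref.size
    both1 = int(np.sum((ref == 1) & (det == 1)))
    both0 = int(np.sum((ref == 0) & (det == 0)))
    p_o = (both1 + both0) / n
    p1r = np.mean(ref == 1)
    p1d = np.mean(det == 1)
    p_e = p1r * p1d + (1 - p1r) * (1 - p1d)
    if p_e >= 1.0:
        return 1.0 if np.array_equal(ref, det) else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def pr_out(detected: BinaryRating) -> float:
    """Proportion of frames flagged synchronous (over-identification rate)."""
    det = np.asarray(detected)
    if det.size < 1:
        raise ValueError("rating must have nonzero length")
    return float(np.mean(det == 1))


@dataclass
class ConfigEvaluation:
    """Per-configuration concordance summaries and ordinal IR classes."""

    kappas: List[float]
    pr_outs: List[float]
    kappa_min: float
    kappa_max: float
    kappa_mean: float
    pr_out_min: float
    pr_out_max: float
    pr_out_mean: float
    ir_sync: str
    ir_nosync: str
    ir_combined: str


def _ir_sync(min_kappa: float) -> str:
    if min_kappa > KAPPA_GOOD:
        return "good"
    if min_kappa >= KAPPA_ACCEPTABLE:
        return "acceptable"
    return "poor"


def _ir_nosync(max_pr_out: float) -> str:
    if max_pr_out <= PR_OUT_GOOD:
        return "good"
    if max_pr_out <= PR_OUT_ACCEPTABLE:
        return "acceptable"
    return "poor"


def classify_ir(kappas: Sequence[float], pr_outs: Sequence[float]) -> ConfigEvaluation:
    """Ordinal identification rate from per-sequence kappas and pr_outs.

    The sync side is judged by the *minimum* kappa over sync sequences and
    the nosync side by the *maximum* pr_out over no-sync sequences — the
    criteria must hold for every sequence.
    """
    if len(kappas) == 0 or len(pr_outs) == 0:
        raise ValueError("need at least one sync and one nosync sequence")
    kappas = [float(k) for k in kappas]
    pr_outs = [float(p) for p in pr_outs]
    ir_sync = _ir_sync(min(kappas))
    ir_nosync = _ir_nosync(max(pr_outs))
    combined = IR_LEVELS[min(IR_ORDER[ir_sync], IR_ORDER[ir_nosync])]
    return ConfigEvaluation(
        kappas=kappas,
        pr_outs=pr_outs,
        kappa_min=min(kappas),
        kappa_max=max(kappas),
        kappa_mean=float(np.mean(kappas)),
        pr_out_min=min(pr_outs),
        pr_out_max=max(pr_outs),
        pr_out_mean=float(np.mean(pr_outs)),
        ir_sync=ir_sync,
        ir_nosync=ir_nosync,
        ir_combined=combined,
    )


def sequential_selection(
    results_by_condition: Mapping[str, Mapping[str, ConfigEvaluation]],
) -> Dict[str, List[str]]:
    """Stage-wise survivor sets across the three complexity conditions.

    Stage 1 keeps configurations with a good combined IR in the artificial
    condition; stage 2 keeps stage-1 survivors that are good or acceptable
    in the isolated condition; stage 3 lists stage-2 survivors that remain
    good or acceptable in the embedded condition (when available).
    """
    artificial = results_by_condition.get("artificial", {})
    stage1 = sorted(
        cid for cid, ev in artificial.items() if ev.ir_combined == "good"
    )
    isolated = results_by_condition.get("isolated", {})
    stage2 = [
        cid
        for cid in stage1
        if cid in isolated and IR_ORDER[isolated[cid].ir_combined] >= IR_ORDER["acceptable"]
    ]
    embedded = results_by_condition.get("embedded", {})
    stage3 = [
        cid
        for cid in stage2
        if cid in embedded and IR_ORDER[embedded[cid].ir_combined] >= IR_ORDER["acceptable"]
    ]
    return {"stage1": stage1, "stage2": stage2, "stage3": stage3}
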