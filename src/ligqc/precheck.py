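"""Stage-1 QC: per-electrode convergence and replicate-error diagnostics.

Fresh carbon electrodes need several CV sweeps to condition; the precheck
decides, per electrode, whether the output stabilized and which single curve
represents the electrode downstream.

Convergence is tracked by the ratio r_k = D(sweep_k, sweep_{k+1}) / ABC_k for
k = 1..K−1: the non-overlapping area between consecutive sweeps relative to
the area the earlier sweep encloses.  An electrode passes when the ratio has
converged to at most the convergence threshold (default 5%); the default
test point is the terminal ratio, optionally a trailing window.

The replicate-error check compares each of the last three sweeps against
their pointwise mean curve ȳ = (y_{K−2} + y_{K−1} + y_K)/3 via
D(y_k, ȳ)/ABC(ȳ).  If all three ratios stay within the replicate threshold
the last sweep alone represents the electrode; otherwise the mean of the
last three is used.  Non-convergent electrodes are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import BranchSplitError, DegenerateGeometryError, abc, \
    symmetric_difference_area
from .io_formats import BatchDataset, ElectrodeRecord, Voltammogram

logger = logging.getLogger("ligqc")

DEFAULT_CONVERGENCE_THRESHOLD = 0.05
DEFAULT_REPLICATE_THRESHOLD = 0.05
#: Stricter reporting threshold used alongside the pass threshold.
REPORT_REPLICATE_THRESHOLD = 0.02

RULE_LAST_SWEEP = "last_sweep"
RULE_MEAN_LAST_THREE = "mean_last_three"
RULE_REJECTED = "rejected"


@dataclass
class PrecheckResult:
    electrode_id: str
    ratios: np.ndarray                 # r_k, k = 1..K-1
    converged: bool
    replicate_ratios: np.ndarray       # 3 values, empty if rejected early
    replicate_ok: bool
    representative: Voltammogram | None
    representative_rule: str
    reason: str = ""                   # populated for rejections


@dataclass
class PrecheckReport:
    results: list[PrecheckResult]
    convergence_threshold: float = DEFAULT_CONVERGENCE_THRESHOLD
    replicate_threshold: float = DEFAULT_REPLICATE_THRESHOLD

    @property
    def passed(self) -> list[PrecheckResult]:
        return [r for r in self.results if r.representative_rule != RULE_REJECTED]

    @property
    def rejected(self) -> list[PrecheckResult]:
        return [r for r in self.results if r.representative_rule == RULE_REJECTED]

    def representatives(self) -> list[Voltammogram]:
        return [r.representative for r in self.passed]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        rows = []
        for r in self.results:
            rows.append({
                "id": r.electrode_id,
                "converged": r.converged,
                "r_final": float(r.ratios[-1]) if r.ratios.size else np.nan,
                "replicate_ok": r.replicate_ok,
                "max_replicate_ratio": (float(np.max(r.replicate_ratios))
                                        if r.replicate_ratios.size else np.nan),
                "representative_rule": r.representative_rule,
                "reason": r.reason,
            })
        ratio_rows = [
            {"id": r.electrode_id, "k": k + 1, "ratio": float(val)}
            for r in self.results for k, val in enumerate(r.ratios)
        ]
        return {"precheck": pd.DataFrame(rows),
                "convergence_ratios": pd.DataFrame(
                    ratio_rows, columns=["id", "k", "ratio"])}


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def convergence_ratios(e: ElectrodeRecord) -> np.ndarray:
    """r_k = D(sweep_k, sweep_{k+1}) / ABC(sweep_k) for k = 1..K−1."""
    if e.K < 2:
        raise ValueError(f"electrode {e.electrode_id!r}: need at least 2 sweeps")
    out = np.empty(e.K - 1)
    for k in range(e.K - 1):
        d = float(symmetric_difference_area(e.sweeps[k], e.sweeps[k + 1]))
        a = float(abc(e.sweeps[k]))
        out[k] = d / a
    return out


def convergence_pass(ratios: np.ndarray,
                     threshold: float = DEFAULT_CONVERGENCE_THRESHOLD,
                     window: int = 1) -> bool:
    """True iff all of the last ``window`` ratios are ≤ threshold."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("ratios must be non-empty")
    w = min(window, ratios.size)
    return bool(np.all(ratios[-w:] <= threshold))


def mean_last_sweeps(e: ElectrodeRecord, m: int = 3) -> Voltammogram:
    """Pointwise current mean of the last ``m`` sweeps on the shared grid."""
    if e.K < m:
        raise ValueError(f"electrode {e.electrode_id!r}: K={e.K} < m={m}")
    tail = e.sweeps[-m:]
    current = np.mean([s.current for s in tail], axis=0)
    return Voltammogram(potential=e.potential_grid.copy(), current=current,
                        sweep_index=e.K, electrode_id=e.electrode_id)


def replicate_error(e: ElectrodeRecord,
                    threshold: float = DEFAULT_REPLICATE_THRESHOLD
                    ) -> tuple[np.ndarray, bool]:
    """D(y_k, ȳ)/ABC(ȳ) for the last three sweeps vs their mean curve."""
    if e.K < 3:
        raise ValueError(f"electrode {e.electrode_id!r}: need K >= 3")
    mean_curve = mean_last_sweeps(e, 3)
    denom = float(abc(mean_curve))
    ratios = np.array([
        float(symmetric_difference_area(s, mean_curve)) / denom
        for s in e.sweeps[-3:]
    ])
    return ratios, bool(np.all(ratios <= threshold))


def representative_curve(e: ElectrodeRecord,
                         convergence_threshold: float = DEFAULT_CONVERGENCE_THRESHOLD,
                         replicate_threshold: float = DEFAULT_REPLICATE_THRESHOLD,
                         window: int = 1) -> tuple[Voltammogram | None, str]:
    """Select the curve representing a converged electrode.

    Last sweep when replicate error is within threshold, the mean of the last
    three otherwise; non-convergent electrodes yield (None, "rejected").
    """
    ratios = convergence_ratios(e)
    if not convergence_pass(ratios, convergence_threshold, window):
        return None, RULE_REJECTED
    _, ok = replicate_error(e, replicate_threshold)
    if ok:
        return e.sweeps[-1], RULE_LAST_SWEEP
    return mean_last_sweeps(e, 3), RULE_MEAN_LAST_THREE


def precheck_electrode(e: ElectrodeRecord,
                       convergence_threshold: float = DEFAULT_CONVERGENCE_THRESHOLD,
                       replicate_threshold: float = DEFAULT_REPLICATE_THRESHOLD,
                       window: int = 1) -> PrecheckResult:
    """Run the full stage-1 diagnostics on one electrode.

    Geometry failures (degenerate loops, missing turning point) reject the
    electrode with a reason instead of raising, so batch runs complete.
    """
    try:
        ratios = convergence_ratios(e)
        converged = convergence_pass(ratios, convergence_threshold, window)
        rep_ratios, rep_ok = replicate_error(e, replicate_threshold)
    except (DegenerateGeometryError, BranchSplitError, ValueError) as err:
        logger.warning("electrode %s rejected: %s", e.electrode_id, err)
        return PrecheckResult(
            electrode_id=e.electrode_id, ratios=np.array([]), converged=False,
            replicate_ratios=np.array([]), replicate_ok=False,
            representative=None, representative_rule=RULE_REJECTED,
            reason=f"geometry: {err}")
    if not converged:
        logger.info("electrode %s rejected: terminal ratio %.4f > %.4f",
                    e.electrode_id, ratios[-1], convergence_threshold)
        return PrecheckResult(
            electrode_id=e.electrode_id, ratios=ratios, converged=False,
            replicate_ratios=rep_ratios, replicate_ok=rep_ok,
            representative=None, representative_rule=RULE_REJECTED,
            reason="not converged")
    rep = e.sweeps[-1] if rep_ok else mean_last_sweeps(e, 3)
    rule = RULE_LAST_SWEEP if rep_ok else RULE_MEAN_LAST_THREE
    return PrecheckResult(
        electrode_id=e.electrode_id, ratios=ratios, converged=True,
        replicate_ratios=rep_ratios, replicate_ok=rep_ok,
        representative=rep, representative_rule=rule)


def precheck_batch(batch: BatchDataset,
                   convergence_threshold: float = DEFAULT_CONVERGENCE_THRESHOLD,
                   replicate_threshold: float = DEFAULT_REPLICATE_THRESHOLD,
                   window: int = 1) -> PrecheckReport:
    results = [precheck_electrode(e, convergence_threshold,
                                  replicate_threshold, window)
               for e in batch.electrodes]
    n_rej = sum(1 for r in results if r.representative_rule == RULE_REJECTED)
    logger.info("precheck: %d electrodes in, %d passed, %d rejected",
                len(results), len(results) - n_rej, n_rej)
    return PrecheckReport(results=results,
                          convergence_threshold=convergence_threshold,
                          replicate_threshold=replicate_threshold)
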