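"""Downstream validation: variability of sensor baselines via impedance PCA.

Biosensors built from QC-selected electrodes (treatment) are compared with
sensors built without QC (control).  The low-frequency imaginary impedance
Z'' — 0.01 to 0.1 Hz, closed interval — is extracted per sensor, the
sensor-by-frequency matrix is column mean-centered (no unit-variance
scaling: all columns are ohms), and the first principal component summarizes
each baseline.  The sample standard deviation (n−1) of PC1 scores per group
measures sensor-to-sensor variation; the headline statistic is

    percent_reduction = 100 · (SD_control − SD_treatment) / SD_control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ImpedanceDataset

logger = logging.getLogger("ligqc")

DEFAULT_BAND = (0.01, 0.1)   # Hz, closed interval


@dataclass
class ValidationReport:
    band: tuple[float, float]
    scores: dict[str, float]              # sensor_id -> PC1 score
    groups: dict[str, str]                # sensor_id -> group
    variance_explained: np.ndarray
    sd_by_group: dict[str, float]
    percent_reduction: float

    def to_frames(self) -> dict[str, pd.DataFrame]:
        score_rows = [{"sensor_id": sid, "group": self.groups[sid],
                       "pc1_score": s} for sid, s in self.scores.items()]
        summary = [{
            "band_min_Hz": self.band[0], "band_max_Hz": self.band[1],
            "pc1_variance_explained": float(self.variance_explained[0]),
            "sd_treatment": self.sd_by_group.get("treatment", np.nan),
            "sd_control": self.sd_by_group.get("control", np.nan),
            "percent_reduction": self.percent_reduction,
        }]
        return {"pc_scores": pd.DataFrame(score_rows),
                "validation_summary": pd.DataFrame(summary)}


def extract_band(sensors: list[ImpedanceDataset],
                 f_min: float = DEFAULT_BAND[0],
                 f_max: float = DEFAULT_BAND[1]) -> tuple[np.ndarray, list[str]]:
    """Restrict spectra to f_min ≤ f ≤ f_max on a shared grid.

    Returns the (n_sensors, n_band) Z'' matrix with columns in descending
    frequency, plus sensor ids in input order.  Grids must match exactly
    across sensors; validation data are never interpolated.
    """
    if not sensors:
        raise ValueError("no sensors")
    ref = sensors[0].frequency
    for s in sensors[1:]:
        if s.frequency.size != ref.size or np.abs(s.frequency - ref).max() > 1e-12 * ref.max():
            raise ValueError(f"sensor {s.sensor_id!r}: frequency grid differs "
                             "from the first sensor's grid")
    mask = (ref >= f_min) & (ref <= f_max)
    if not mask.any():
        raise ValueError(f"no frequencies inside [{f_min}, {f_max}] Hz")
    for s in sensors:
        covered = (s.frequency.min() <= f_min) and (s.frequency.max() >= f_max)
        if not covered:
            raise ValueError(f"sensor {s.sensor_id!r} does not cover the band "
                             f"[{f_min}, {f_max}] Hz")
    matrix = np.vstack([s.z_imag[mask] for s in sensors])
    return matrix, [s.sensor_id for s in sensors]


def pca_first_component(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PC1 scores and variance-explained fractions of a centered matrix.

    Columns are mean-centered (no scaling); components come from the SVD of
    the centered matrix.  The PC1 sign is fixed so the loading with the
    largest magnitude is positive.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least a 2x2 matrix")
    centered = matrix - matrix.mean(axis=0, keepdims=True)
    total = float(np.sum(centered ** 2))
    if total <= 0:
        raise ValueError("matrix has zero variance after centering")
    _, sing, vt = np.linalg.svd(centered, full_matrices=False)
    loading = vt[0]
    if loading[np.argmax(np.abs(loading))] < 0:
        loading = -loading
    scores = centered @ loading
    variance_explained = sing ** 2 / total
    return scores, variance_explained


def group_variation(scores: np.ndarray, groups: list[str]
                    ) -> tuple[dict[str, float], float]:
    """Per-group sample SD of PC1 scores and the percent reduction.

    percent_reduction = 100·(SD_control − SD_treatment)/SD_control.
    """
    scores = np.asarray(scores, dtype=float)
    labels = sorted(set(groups))
    sd_by_group: dict[str, float] = {}
    for g in labels:
        vals = scores[[i for i, lab in enumerate(groups) if lab == g]]
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 sensors")
        sd_by_group[g] = float(np.std(vals, ddof=1))
    if "treatment" in sd_by_group and "control" in sd_by_group:
        sd_c = sd_by_group["control"]
        if sd_c == 0:
            raise ZeroDivisionError("control-group SD is zero")
        pr = 100.0 * (sd_c - sd_by_group["treatment"]) / sd_c
    else:
        raise ValueError("need both 'treatment' and 'control' groups")
    return sd_by_group, pr


def validate_qc(sensors: list[ImpedanceDataset],
                f_min: float = DEFAULT_BAND[0],
                f_max: float = DEFAULT_BAND[1]) -> ValidationReport:
    """Full validation pipeline: band extraction → PCA → group SDs."""
    matrix, ids = extract_band(sensors, f_min, f_max)
    scores, var_exp = pca_first_component(matrix)
    group_of = {s.sensor_id: s.group for s in sensors}
    sd_by_group, pr = group_variation(scores, [group_of[i] for i in ids])
    logger.info("validation: PC1 explains %.1f%% of variance; SDs %s; "
                "reduction %.2f%%", 100 * var_exp[0],
                {g: round(v, 3) for g, v in sd_by_group.items()}, pr)
    return ValidationReport(band=(f_min, f_max),
                            scores=dict(zip(ids, scores.tolist())),
                            groups=group_of, variance_explained=var_exp,
                            sd_by_group=sd_by_group, percent_reduction=pr)
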