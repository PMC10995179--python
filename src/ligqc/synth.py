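"""Synthetic CV and EIS data with closed-form ground truth.

Pseudo-capacitive CV loops are modelled as a capacitive hysteresis band
(±halfwidth µA between the two passes of a triangular potential ramp) plus
Gaussian redox peaks on each branch — a shape, not an electrochemical
simulation: only the geometric properties (area between branches, peak
height, loop overlap) matter to the QC math, and Gaussians keep those in
closed form.

Electrode conditioning is emulated by a geometric drift of the loop scale,
``scale_k = 1 + (initial_scale − 1)·decay**(k−1)``, converging to 1 as the
surface stabilizes, plus i.i.d. Gaussian current noise per point.  Batches
derive electrodes from template loops with multiplicative current jitter, so
clustering tests have planted ground-truth labels.  EIS spectra are a shared
smooth Bode baseline plus a rank-1 perturbation whose per-sensor coefficient
is Gaussian with a group-specific SD — the planted PC1-score SD.

Defaults mirror the acquisition the workflow targets: 320 points per sweep
over −0.8…0.8 V, ten sweeps per electrode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .io_formats import BatchDataset, ElectrodeRecord, ImpedanceDataset, Voltammogram

DEFAULT_N_POINTS = 320
DEFAULT_WINDOW = (-0.8, 0.8)


@dataclass
class GaussianPeak:
    center: float      # V
    width: float       # V (Gaussian sigma)
    amplitude: float   # µA, >= 0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.width <= 0:
            raise ValueError("peak needs amplitude >= 0 and width > 0")

    def profile(self, v: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((v - self.center) / self.width) ** 2)

    def area(self, v_min: float, v_max: float) -> float:
        """Integral of the profile over [v_min, v_max] (truncated Gaussian)."""
        s = self.width * math.sqrt(2.0)
        return float(self.amplitude * self.width * math.sqrt(math.pi / 2.0)
                     * (erf((v_max - self.center) / s) - erf((v_min - self.center) / s)))


@dataclass
class LoopTemplate:
    """Parametric pseudo-capacitive CV loop."""

    vertex_potentials: tuple[float, float] = DEFAULT_WINDOW
    capacitive_halfwidth: float = 50.0          # µA
    anodic_peak: GaussianPeak | None = None
    cathodic_peak: GaussianPeak | None = None
    n_points: int = DEFAULT_N_POINTS

    def __post_init__(self) -> None:
        v_min, v_max = self.vertex_potentials
        if not v_min < v_max:
            raise ValueError(f"need V_min < V_max, got {self.vertex_potentials}")
        if self.n_points < 16:
            raise ValueError("n_points must be >= 16")
        if self.capacitive_halfwidth <= 0:
            raise ValueError("capacitive_halfwidth must be positive")

    @property
    def window(self) -> float:
        return self.vertex_potentials[1] - self.vertex_potentials[0]

    def abc_truth(self) -> float:
        """Closed-form area between branches, µA·V."""
        v_min, v_max = self.vertex_potentials
        area = 2.0 * self.capacitive_halfwidth * self.window
        for peak in (self.anodic_peak, self.cathodic_peak):
            if peak is not None:
                area += peak.area(v_min, v_max)
        return area

    def peak_truth(self, branch: str = "anodic") -> float:
        """Peak current magnitude at the peak center (µA), halfwidth included."""
        peak = self.anodic_peak if branch == "anodic" else self.cathodic_peak
        base = self.capacitive_halfwidth
        return base + (peak.amplitude if peak is not None else 0.0)


@dataclass
class DriftModel:
    """Geometric sweep-to-sweep drift plus additive current noise."""

    initial_scale: float = 1.5
    decay: float = 0.5
    noise_sd: float = 0.0     # µA
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def scale(self, k: int) -> float:
        """Loop scale for sweep k (1-based); converges to 1."""
        return 1.0 + (self.initial_scale - 1.0) * self.decay ** (k - 1)


def make_loop(t: LoopTemplate, electrode_id: str = "synthetic",
              sweep_index: int = 1, scale: float = 1.0,
              rng: np.random.Generator | None = None,
              noise_sd: float = 0.0) -> Voltammogram:
    """Generate one CV sweep from a template.

    Triangular potential ramp V_min→V_max→V_min over ``n_points``; current is
    +halfwidth plus the anodic Gaussian on the up-ramp and −halfwidth minus
    the cathodic Gaussian on the down-ramp, all multiplied by ``scale``.
    """
    v_min, v_max = t.vertex_potentials
    n_up = t.n_points // 2
    n_down = t.n_points - n_up
    # both ramps include their vertices: the branch jump at each vertex is a
    # vertical polygon edge, not a diagonal notch
    v_up = np.linspace(v_min, v_max, n_up)
    v_down = np.linspace(v_max, v_min, n_down)
    i_up = np.full(n_up, t.capacitive_halfwidth)
    if t.anodic_peak is not None:
        i_up = i_up + t.anodic_peak.profile(v_up)
    i_down = np.full(n_down, -t.capacitive_halfwidth)
    if t.cathodic_peak is not None:
        i_down = i_down - t.cathodic_peak.profile(v_down)
    current = scale * np.concatenate([i_up, i_down])
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        current = current + rng.normal(0.0, noise_sd, size=current.size)
    return Voltammogram(potential=np.concatenate([v_up, v_down]), current=current,
                        sweep_index=sweep_index, electrode_id=electrode_id)


def make_electrode(t: LoopTemplate, d: DriftModel | None = None, K: int = 10,
                   electrode_id: str = "synthetic") -> ElectrodeRecord:
    """Generate a conditioning run of K sweeps with drift and noise."""
    if K < 3:
        raise ValueError("K must be >= 3")
    d = d or DriftModel(initial_scale=1.0, noise_sd=0.0)
    rng = np.random.default_rng(d.seed)
    sweeps = [make_loop(t, electrode_id=electrode_id, sweep_index=k,
                        scale=d.scale(k), rng=rng, noise_sd=d.noise_sd)
              for k in range(1, K + 1)]
    return ElectrodeRecord(electrode_id=electrode_id, sweeps=sweeps)


def make_batch(templates: list[LoopTemplate], sizes: list[int],
               within_jitter: float = 0.02, d: DriftModel | None = None,
               K: int = 10, seed: int = 0,
               batch_id: str = "synthetic-batch") -> tuple[BatchDataset, list[int]]:
    """Generate a batch with planted cluster structure.

    Each electrode derives from its template with multiplicative current
    jitter ~ Normal(1, within_jitter).  Returns the batch and the planted
    template index per electrode (for adjusted-Rand scoring).
    """
    if len(templates) != len(sizes):
        raise ValueError("templates and sizes must have equal length")
    rng = np.random.default_rng(seed)
    d = d or DriftModel(initial_scale=1.2, decay=0.5, noise_sd=0.0)
    electrodes: list[ElectrodeRecord] = []
    labels: list[int] = []
    n = 0
    for g, (t, size) in enumerate(zip(templates, sizes)):
        for _ in range(size):
            n += 1
            jitter = float(rng.normal(1.0, within_jitter))
            jittered = LoopTemplate(
                vertex_potentials=t.vertex_potentials,
                capacitive_halfwidth=t.capacitive_halfwidth * jitter,
                anodic_peak=None if t.anodic_peak is None else GaussianPeak(
                    t.anodic_peak.center, t.anodic_peak.width,
                    t.anodic_peak.amplitude * jitter),
                cathodic_peak=None if t.cathodic_peak is None else GaussianPeak(
                    t.cathodic_peak.center, t.cathodic_peak.width,
                    t.cathodic_peak.amplitude * jitter),
                n_points=t.n_points,
            )
            ed = DriftModel(initial_scale=d.initial_scale, decay=d.decay,
                            noise_sd=d.noise_sd,
                            seed=int(rng.integers(0, 2**31 - 1)))
            electrodes.append(make_electrode(jittered, ed, K=K, electrode_id=f"E{n:02d}"))
            labels.append(g)
    return BatchDataset(batch_id=batch_id, electrodes=electrodes), labels


# ---------------------------------------------------------------------------
# EIS generator
# ---------------------------------------------------------------------------

def _base_spectrum(freq: np.ndarray) -> np.ndarray:
    """Smooth Bode-like |Z''| baseline rising toward low frequency (ohms)."""
    return -50.0 - 40.0 / (1.0 + (freq / 0.05))


def make_eis(n_per_group: int = 50,
             sd_by_group: dict[str, float] | None = None,
             seed: int = 0, n_freq: int = 31,
             f_max: float = 10.0, f_min: float = 0.01,
             band: tuple[float, float] = (0.01, 0.1),
             noise_sd: float = 1e-3) -> list[ImpedanceDataset]:
    """Generate two-group Bode Z'' spectra with planted PC1-score SDs.

    Spectra share a smooth base curve; a fixed rank-1 perturbation direction
    (unit-norm over the analysis band) is added with a per-sensor coefficient
    ~ Normal(0, sd_by_group[group]).  PCA restricted to the band therefore
    recovers per-group score SDs ≈ the planted values.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    sd_by_group = sd_by_group or {"treatment": 2.450, "control": 2.757}
    rng = np.random.default_rng(seed)
    freq = np.logspace(math.log10(f_max), math.log10(f_min), n_freq)
    base = _base_spectrum(freq)
    # smooth rank-1 direction, unit norm over the band so score SD == coef SD
    u = np.exp(-0.5 * ((np.log10(freq) - math.log10(0.05)) / 0.5) ** 2)
    in_band = (freq >= band[0]) & (freq <= band[1])
    u = u / np.linalg.norm(u[in_band])
    sensors: list[ImpedanceDataset] = []
    i = 0
    for group, sd in sd_by_group.items():
        coefs = rng.normal(0.0, sd, size=n_per_group)
        for c in coefs:
            i += 1
            z = base + c * u + rng.normal(0.0, noise_sd, size=n_freq)
            sensors.append(ImpedanceDataset(sensor_id=f"S{i:03d}", group=group,
                                            frequency=freq.copy(), z_imag=z))
    return sensors
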