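import numpy as np
import pytest

from ligqc import synth
from ligqc.io_formats import Voltammogram


def random_template(rng: np.random.Generator, n_points: int = 320) -> synth.LoopTemplate:
    """Random pseudo-capacitive template with peaks kept inside the window."""
    return synth.LoopTemplate(
        capacitive_halfwidth=float(rng.uniform(20.0, 90.0)),
        anodic_peak=synth.GaussianPeak(float(rng.uniform(-0.3, 0.4)),
                                       float(rng.uniform(0.08, 0.2)),
                                       float(rng.uniform(0.0, 320.0))),
        cathodic_peak=synth.GaussianPeak(float(rng.uniform(-0.4, 0.3)),
                                         float(rng.uniform(0.08, 0.2)),
                                         float(rng.uniform(0.0, 320.0))),
        n_points=n_points,
    )


def random_loop(rng: np.random.Generator, n_points: int = 320) -> Voltammogram:
    return synth.make_loop(random_template(rng, n_points))


def rectangle_loop(v0=0.0, v1=1.0, half=100.0, pts_per_branch=11) -> Voltammogram:
    """Rectangular loop: constant −half on the up pass, +half on the down pass."""
    up_v = np.linspace(v0, v1, pts_per_branch)
    down_v = np.linspace(v1, v0, pts_per_branch)
    potential = np.concatenate([up_v, down_v])
    current = np.concatenate([np.full(pts_per_branch, -half),
                              np.full(pts_per_branch, half)])
    return Voltammogram(potential, current, 1, "rect")


def ellipse_loop(a=0.5, b=100.0, center=0.0, n_points=320) -> Voltammogram:
    """Elliptic loop of semi-axes a (V) and b (µA); enclosed area = πab."""
    theta = np.linspace(np.pi, 3 * np.pi, n_points, endpoint=False)
    return Voltammogram(center + a * np.cos(theta), b * np.sin(theta), 1, "ellipse")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def separated_templates():
    """Three loop templates with well-separated sizes (between-D >> within-D)."""
    return [
        synth.LoopTemplate(capacitive_halfwidth=30.0,
                           anodic_peak=synth.GaussianPeak(0.2, 0.12, 180.0)),
        synth.LoopTemplate(capacitive_halfwidth=60.0,
                           anodic_peak=synth.GaussianPeak(0.2, 0.12, 300.0)),
        synth.LoopTemplate(capacitive_halfwidth=90.0,
                           anodic_peak=synth.GaussianPeak(0.2, 0.12, 420.0)),
    ]
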