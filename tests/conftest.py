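"""Shared fixtures: one fully processed synthetic specimen and the latent-
factor cohorts used by the shape-model and evaluation tests."""

from __future__ import annotations

import numpy as np
import pytest

from canalshape import preprocess as pp
from canalshape import ssm_core
from canalshape import synthetic_canals as syn

# study conditions for cohort-level experiments: three latent factors
# (r0, roundness, flare), realistic 0.3 mm in-plane point noise
THREE_FACTOR = dict(
    delta_phi=(15.0, 0.0), femur_length=(420.0, 0.0), noise_sd=0.3
)


@pytest.fixture(scope="session")
def default_params() -> syn.SyntheticParams:
    return syn.SyntheticParams()


@pytest.fixture(scope="session")
def pipeline_result(default_params):
    """Default synthetic specimen processed end-to-end, with its ground truth."""
    stack, truth = syn.generate_specimen(default_params)
    shape = pp.build_correspondence(stack)
    return stack, truth, shape


@pytest.fixture(scope="session")
def cohort3():
    """3-factor cohort (n=300) with noise: shapes, matrix, fitted model."""
    spec = syn.CohortSpec(n=300, seed=11, **THREE_FACTOR)
    shapes, truth = syn.generate_aligned_cohort(spec)
    matrix = ssm_core.build_shape_matrix(shapes)
    model = ssm_core.fit_ssm(matrix)
    return shapes, truth, matrix, model


@pytest.fixture(scope="session")
def cohort3_noiseless():
    spec = syn.CohortSpec(n=300, seed=11, delta_phi=(15.0, 0.0),
                          femur_length=(420.0, 0.0), noise_sd=0.0)
    shapes, _ = syn.generate_aligned_cohort(spec)
    matrix = ssm_core.build_shape_matrix(shapes)
    return matrix, ssm_core.fit_ssm(matrix)


def circle(r: float = 10.0, n: int = 50, center=(0.0, 0.0)) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + r * np.cos(th), center[1] + r * np.sin(th)]
    )


def ellipse(a, b, phi_deg, n=50, center=(0.0, 0.0)) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    phi = np.radians(phi_deg)
    u, v = a * np.cos(th), b * np.sin(th)
    return np.column_stack(
        [
            center[0] + u * np.cos(phi) - v * np.sin(phi),
            center[1] + u * np.sin(phi) + v * np.cos(phi),
        ]
    )
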