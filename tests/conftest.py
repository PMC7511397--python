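"""Shared fixtures: synthetic scenes and pooled angle samples.

Heavy scene batches are session-scoped so multiple tests can share one
rendering+tracing pass.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from afmbend import PipelineConfig, SceneSpec, generate_scene, measure_complex_angles

logging.disable(logging.WARNING)

# moment-ellipse elongation of strongly kinked filaments falls below the
# 0.75 default floor, so synthetic-scene analyses rely on the perimeter
# bound for blob/filament separation
SYNTH_CONFIG = PipelineConfig(elongation_range=(0.0, 1.0))

RECOVERY_CONDITIONS = (0.0, 20.0, 45.0, 70.0)


def collect_complex_angles(imposed_deg: float, seed_base: int,
                           n_target: int = 300, max_images: int = 60,
                           config: PipelineConfig = SYNTH_CONFIG):
    """Render scenes with a protein at the imposed-bend position and pool
    measured bend angles until ``n_target`` sites are reached."""
    angles = []
    truth_angles = []
    for k in range(max_images):
        spec = SceneSpec(image_size_px=(512, 512), n_molecules=8,
                         imposed_bend_deg=imposed_deg, place_protein=True,
                         rng_seed=seed_base + k)
        hm, truth = generate_scene(spec)
        df, _ = measure_complex_angles(hm, config, f"img{k}")
        ok = df[df.exclusion_reason == "none"]
        angles.extend(ok.bend_angle_deg.tolist())
        truth_angles.extend(m.bend_angle_deg for m in truth.molecules)
        if len(angles) >= n_target:
            break
    return np.asarray(angles), np.asarray(truth_angles)


@pytest.fixture(scope="session")
def recovery_samples():
    """Measured complex-site angles for imposed bends of 0/20/45/70 deg."""
    return {imposed: collect_complex_angles(imposed, 1000 * (i + 1))
            for i, imposed in enumerate(RECOVERY_CONDITIONS)}
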