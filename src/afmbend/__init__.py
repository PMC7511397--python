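"""afmbend: automated DNA bend-angle analysis for AFM topographs.

From a tapping-mode height image to conformational states: filament
tracing with sub-pixel refinement, tangent-geometry bend angles at protein
positions or at the DNA midpoint, folded-Gaussian state decomposition,
worm-like-chain persistence-length checks, and ensemble-FRET
cross-validation. A synthetic scene generator provides ground truth for
every stage.
"""

from .config import PipelineConfig, SceneSpec
from .image_ops import BinaryMask, HeightMap
from .tracing import FilamentTrace
from .angles import AngleQuery, ComplexSite, bend_angle_at
from .mixtures import (FoldedGaussianMixture, estimate_lp,
                       fit_folded_mixture, select_model,
                       weighted_mean_angle, wlc_msd)
from .fret import FretMeasurement, StatePopulation
from .pipeline import (measure_complex_angles, measure_lesion_angles,
                       run_pipeline)
from .scene import generate_scene, impose_bend, render_scene, sample_wlc_chain

BP_NM = 0.34  # helical rise of B-form DNA, nm per base pair


def duplex_contour_nm(n_bp: int) -> float:
    """Expected contour length of a B-form duplex (0.34 nm per bp)."""
    return n_bp * BP_NM


__version__ = "0.1.0"

__all__ = [
    "PipelineConfig", "SceneSpec", "HeightMap", "BinaryMask",
    "FilamentTrace", "AngleQuery", "ComplexSite", "bend_angle_at",
    "FoldedGaussianMixture", "fit_folded_mixture", "select_model",
    "weighted_mean_angle", "wlc_msd", "estimate_lp",
    "FretMeasurement", "StatePopulation",
    "measure_complex_angles", "measure_lesion_angles", "run_pipeline",
    "generate_scene", "render_scene", "sample_wlc_chain", "impose_bend",
    "BP_NM", "duplex_contour_nm",
]
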