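"""Validated configuration objects for simulation and analysis.

All physical quantities are in nanometres unless the field name says
otherwise; heights are in arbitrary (instrument) units.
"""

from __future__ import annotations

from typing import Literal, Optional, Tuple

from pydantic import BaseModel, Field, model_validator


class SceneSpec(BaseModel):
    """Parameters of a synthetic AFM scene with known ground truth.

    The defaults describe the imaging conditions of a typical
    glycosylase/DNA deposition: a 505 bp duplex (172 nm at 0.34 nm/bp)
    with persistence length 45 nm, imaged at 1.95 nm/pixel.
    """

    image_size_px: Tuple[int, int] = (512, 512)
    pixel_size_nm: float = Field(1.95, gt=0)
    n_molecules: int = Field(10, ge=0)
    contour_length_nm: float = Field(172.0, gt=0)
    persistence_length_nm: float = Field(45.0, gt=0)
    imposed_bend_deg: Optional[float] = Field(None, ge=0, le=180)
    bend_position_frac: float = Field(0.5, gt=0, lt=1)
    bend_sigma_deg: float = Field(0.0, ge=0)
    place_protein: bool = False          # protein disc at the bend position
    n_free_proteins: int = Field(0, ge=0)  # off-DNA blobs (non-specific)
    # true disc radius; tip convolution makes the apparent radius in the
    # rendered image ~6-7 nm, inside the 3-7 nm range observed for
    # glycosylase peaks, so an 8 nm query distance clears the protein
    protein_radius_nm: float = Field(2.5, gt=0)
    protein_height: float = Field(3.0, gt=0)
    dna_height: float = Field(1.0, gt=0)
    dna_sigma_nm: float = Field(1.0, gt=0)  # Gaussian half-width of the ridge
    tip_fwhm_nm: float = Field(6.0, gt=0)
    noise_sigma: float = Field(0.05, ge=0)
    step_nm: float = Field(1.0, gt=0)    # arc step of the sampled chain
    border_margin_nm: float = 15.0
    clearance_nm: float = 12.0           # min distance between molecules
    rng_seed: int = 0

    @model_validator(mode="after")
    def _invariants(self) -> "SceneSpec":
        if self.protein_height <= self.dna_height:
            raise ValueError(
                "protein_height must exceed dna_height so that protein "
                "peaks are separable by height thresholding"
            )
        if self.contour_length_nm < 10 * self.pixel_size_nm:
            raise ValueError("contour_length_nm must be >= 10 pixels")
        return self


class PipelineConfig(BaseModel):
    """Settings of the image-analysis pipeline (one object per run)."""

    pixel_size_nm: float = Field(1.95, gt=0)

    # pre-processing
    median_radius_px: int = Field(2, ge=1)
    blur_sigma_px: float = Field(2.0, ge=0)
    intermodes_offset: float = 0.0
    # floor for the protein threshold, as a multiple of the measured DNA
    # ridge height (automates the manual intermodes adjustment: protein
    # peaks must stand clear of the DNA by height)
    protein_height_factor: float = Field(1.5, gt=1.0)

    # shape filter for DNA filaments
    elongation_range: Tuple[float, float] = (0.75, 1.0)
    perimeter_min_px: float = 90.0
    # narrow each filament mask to half its own ridge height before
    # skeletonization (0 disables)
    ridge_rethreshold_frac: float = 0.5

    # tracing
    fwhm_nm: float = Field(6.0, gt=0)
    node_spacing_nm: float = Field(2.0, gt=0)
    spline_spacing_nm: float = Field(0.1, gt=0)
    min_skeleton_px: int = 10

    # protein assignment and angle query
    protein_radius_nm: float = Field(5.0, gt=0)   # glycosylases: ~3-7 nm
    dna_radius_nm: float = Field(3.0, gt=0)
    query_distance_nm: float = Field(8.0, gt=0)
    geometry: Literal["tangent", "secant"] = "tangent"
    spacing_min_nm: float = 50.0

    # lesion-mode length window (505 bp substrate: 172 nm nominal)
    length_min_nm: float = 150.0
    length_max_nm: float = 180.0

    # protein-peak area window, in um^2 (the conventional unit for these cutoffs)
    area_min_um2: float = 1e-7
    area_max_um2: float = 1e-4

    min_dna_coverage: float = 0.70

    # angle statistics
    bin_width_deg: float = 5.0
    r2_threshold_complexes: float = 0.94
    r2_threshold_lesions: float = 0.97
    kmax: int = 4
    fit_seed: int = 0

    @model_validator(mode="after")
    def _ordered(self) -> "PipelineConfig":
        lo, hi = self.elongation_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("elongation_range must be ordered within [0, 1]")
        if self.length_min_nm >= self.length_max_nm:
            raise ValueError("length window bounds must be ordered")
        if self.area_min_um2 >= self.area_max_um2:
            raise ValueError("area window bounds must be ordered")
        if self.query_distance_nm < 2 * self.pixel_size_nm:
            raise ValueError(
                "query_distance_nm below two pixels does not give a "
                "meaningful tangent"
            )
        return self
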