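"""End-to-end measurement pipelines.

Two modes share the pre-processing and tracing front end:

* complexes — locate protein peaks, assign them to DNA traces, and measure
  the bend angle at each bound protein position;
* lesions — filter traces to the expected substrate length and measure the
  bend angle at the 50% (midpoint) arc position, where the target site sits
  by construction.

Every candidate site appears in the output table, measured or excluded with
a reason; per-image QC records the fraction of selected DNA captured by
accepted traces, and images below the coverage floor are flagged and
excluded from aggregation.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from skimage import measure as _sk_measure

from . import image_ops, io, tracing
from .angles import AngleQuery, assign_proteins, bend_angle_at
from .config import PipelineConfig
from .image_ops import BinaryMask, HeightMap
from .mixtures import FoldedGaussianMixture, select_model
from .tracing import FilamentTrace

logger = logging.getLogger("afmbend")

__all__ = ["ImageQC", "trace_image", "measure_complex_angles",
           "measure_lesion_angles", "run_pipeline"]

_COLUMNS = ["image_id", "trace_id", "site_kind", "arc_position_nm",
            "bend_angle_deg", "exclusion_reason", "contour_length_nm",
            "distance_to_trace_nm", "site_x_nm", "site_y_nm"]


@dataclasses.dataclass
class ImageQC:
    image_id: str
    dna_coverage: float
    n_traces: int
    n_rejected_skeletons: int
    n_peaks: int
    n_aggregates: int
    excluded: bool


def trace_image(hm: HeightMap, config: PipelineConfig, image_id: str = "",
                ) -> Tuple[List[FilamentTrace], ImageQC, HeightMap, float]:
    """Shared front end: preprocess, select filaments, trace to 0.1 nm.

    Returns accepted traces, QC, the median-filtered image (used for
    sub-pixel refinement) and the Yen level.
    """
    med = image_ops.median_filter(hm, config.median_radius_px)
    yen_level, fg = image_ops.threshold_yen(med)
    dna_mask = image_ops.shape_filter(
        fg, config.elongation_range, config.perimeter_min_px)
    work_mask = dna_mask
    if config.ridge_rethreshold_frac > 0:
        work_mask = image_ops.ridge_rethreshold(
            work_mask, med, config.ridge_rethreshold_frac)
    if config.blur_sigma_px > 0:
        smooth = image_ops.gaussian_blur(
            HeightMap(work_mask.values.astype(float), hm.pixel_size_nm),
            config.blur_sigma_px)
        work_mask = BinaryMask(smooth.values > 0.5, hm.pixel_size_nm,
                               provenance=dna_mask.provenance + "+blur")

    polylines_px, rejects = tracing.skeletonize_and_order(
        work_mask, min_pixels=config.min_skeleton_px)

    traces: List[FilamentTrace] = []
    px = hm.pixel_size_nm
    for tid, poly in enumerate(polylines_px):
        try:
            t = tracing.resample(poly * px, config.node_spacing_nm,
                                 trace_id=tid, source_image_id=image_id)
            t, _ = tracing.refine_subpixel(t, med, config.fwhm_nm)
            t = tracing.spline_resample(t, config.spline_spacing_nm)
        except ValueError:
            continue
        traces.append(t)

    coverage = _dna_coverage(work_mask, traces, px)
    qc = ImageQC(image_id=image_id, dna_coverage=coverage,
                 n_traces=len(traces), n_rejected_skeletons=len(rejects),
                 n_peaks=0, n_aggregates=0,
                 excluded=coverage < config.min_dna_coverage)
    if qc.excluded:
        logger.warning("%s: DNA coverage %.2f below %.2f - image excluded",
                       image_id, coverage, config.min_dna_coverage)
    return traces, qc, med, yen_level


def _dna_coverage(mask: BinaryMask, traces: Sequence[FilamentTrace],
                  px: float) -> float:
    """Fraction of selected-DNA pixels belonging to a component that
    produced an accepted trace."""
    lab = _sk_measure.label(mask.values, connectivity=2)
    total = int(np.count_nonzero(lab))
    if total == 0:
        return 0.0
    covered_labels = set()
    for t in traces:
        mid = t.points[t.points.shape[0] // 2]
        r, c = int(round(mid[1] / px)), int(round(mid[0] / px))
        r = np.clip(r, 0, lab.shape[0] - 1)
        c = np.clip(c, 0, lab.shape[1] - 1)
        lbl = lab[r, c]
        if lbl == 0:                     # probe along the trace if off-mask
            for p in t.points[:: max(1, t.points.shape[0] // 50)]:
                rr, cc = int(round(p[1] / px)), int(round(p[0] / px))
                if (0 <= rr < lab.shape[0] and 0 <= cc < lab.shape[1]
                        and lab[rr, cc]):
                    lbl = lab[rr, cc]
                    break
        if lbl:
            covered_labels.add(int(lbl))
    covered = int(np.isin(lab, sorted(covered_labels)).sum()) \
        if covered_labels else 0
    return covered / total


def _dna_ridge_height(med: HeightMap, traces: Sequence[FilamentTrace],
                      ) -> Optional[float]:
    """Median image height along all trace backbones."""
    if not traces:
        return None
    px = med.pixel_size_nm
    vals = []
    for t in traces:
        pts = t.points[:: max(1, t.points.shape[0] // 200)]
        r = np.clip(np.round(pts[:, 1] / px).astype(int), 0,
                    med.values.shape[0] - 1)
        c = np.clip(np.round(pts[:, 0] / px).astype(int), 0,
                    med.values.shape[1] - 1)
        vals.append(med.values[r, c])
    return float(np.median(np.concatenate(vals)))


def _protein_mask(med: HeightMap, traces: Sequence[FilamentTrace],
                  yen_level: float, config: PipelineConfig) -> BinaryMask:
    """Protein-peak mask: intermodes threshold of the foreground histogram,
    floored at ``protein_height_factor`` times the DNA ridge height.

    The floor automates the manual threshold adjustment this step
    classically needs: when protein pixels are too few to form their own
    histogram mode, the intermodes level collapses into the DNA class, and
    only the height separation of proteins over DNA can rescue it.
    """
    level = None
    try:
        level, _ = image_ops.threshold_intermodes(
            med, manual_offset=config.intermodes_offset,
            foreground_min=yen_level)
    except ValueError:
        pass
    ridge = _dna_ridge_height(med, traces)
    if ridge is not None:
        floor = config.protein_height_factor * ridge
        level = floor if level is None else max(level, floor)
    if level is None:
        return BinaryMask(np.zeros_like(med.values, dtype=bool),
                          med.pixel_size_nm, provenance="protein:none")
    return BinaryMask(med.values > level, med.pixel_size_nm,
                      provenance=f"protein level={level:.6g}")


def measure_complex_angles(hm: HeightMap, config: PipelineConfig,
                           image_id: str = "",
                           ) -> Tuple[pd.DataFrame, ImageQC]:
    """Full protein-DNA complex chain on one image.

    One row per candidate protein peak (bound, excluded or aggregate).
    Deterministic for fixed input and config.
    """
    traces, qc, med, yen_level = trace_image(hm, config, image_id)
    protein_mask = _protein_mask(med, traces, yen_level, config)
    peaks, aggregates = image_ops.locate_protein_peaks(
        protein_mask, config.area_min_um2, config.area_max_um2)
    qc.n_peaks = len(peaks)
    qc.n_aggregates = len(aggregates)

    query = AngleQuery(config.query_distance_nm, config.geometry)
    sites = assign_proteins(peaks, traces, config.protein_radius_nm,
                            config.dna_radius_nm, query,
                            config.spacing_min_nm)
    rows = []
    contour_by_id = {t.trace_id: t.contour_length_nm for t in traces}
    for s in sites:
        rows.append((image_id, s.trace_id, "protein", s.arc_position_nm,
                     s.bend_angle_deg, s.exclusion_reason,
                     contour_by_id.get(s.trace_id, np.nan),
                     s.distance_to_trace_nm,
                     s.protein_centroid_nm[0], s.protein_centroid_nm[1]))
    for agg in aggregates:
        rows.append((image_id, -1, "protein", np.nan, np.nan, "aggregate",
                     np.nan, np.nan,
                     agg.centroid_nm[0], agg.centroid_nm[1]))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return df, qc


def measure_lesion_angles(hm: HeightMap, config: PipelineConfig,
                          image_id: str = "",
                          ) -> Tuple[pd.DataFrame, ImageQC]:
    """Midpoint bend angle of every length-filtered DNA trace.

    Traces outside [length_min_nm, length_max_nm] (broken or fused
    molecules) are recorded with reason 'bad_length'; the target site of an
    intact substrate sits at 50% of the contour by construction.
    """
    traces, qc, _, _ = trace_image(hm, config, image_id)
    query = AngleQuery(config.query_distance_nm, config.geometry)
    rows = []
    for t in traces:
        L = t.contour_length_nm
        if not config.length_min_nm <= L <= config.length_max_nm:
            rows.append((image_id, t.trace_id, "midpoint", np.nan, np.nan,
                         "bad_length", L, np.nan, np.nan, np.nan))
            continue
        theta = bend_angle_at(t, L / 2.0, query)
        mid = t.points[t.points.shape[0] // 2]
        rows.append((image_id, t.trace_id, "midpoint", L / 2.0, theta,
                     "none", L, np.nan, float(mid[0]), float(mid[1])))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return df, qc


def run_pipeline(images: Sequence[Union[str, Path, HeightMap]],
                 config: PipelineConfig, mode: str = "complexes",
                 outdir: Optional[Union[str, Path]] = None,
                 ) -> Tuple[pd.DataFrame, Optional[FoldedGaussianMixture],
                            List[ImageQC]]:
    """Run the measurement chain over a batch of images and fit the pooled
    bend-angle distribution.

    ``images`` may be TIFF paths or in-memory HeightMaps. Images flagged by
    QC (DNA coverage below the floor) contribute no angles; per-image
    failures are logged and collected, the run continues. When ``outdir``
    is given, the angle table, mixture fit and a config snapshot are
    written there.
    """
    if mode not in ("complexes", "lesions"):
        raise ValueError("mode must be 'complexes' or 'lesions'")
    fn = measure_complex_angles if mode == "complexes" else measure_lesion_angles
    tables: List[pd.DataFrame] = []
    qcs: List[ImageQC] = []
    for i, item in enumerate(images):
        if isinstance(item, HeightMap):
            hm, image_id = item, f"image{i:03d}"
        else:
            hm = io.read_height_map(item, config.pixel_size_nm)
            image_id = Path(item).stem
        try:
            df, qc = fn(hm, config, image_id)
        except Exception:
            logger.exception("%s: pipeline failure, image skipped", image_id)
            qcs.append(ImageQC(image_id, 0.0, 0, 0, 0, 0, excluded=True))
            continue
        qcs.append(qc)
        logger.info("%s: coverage=%.2f traces=%d peaks=%d excluded=%s",
                    image_id, qc.dna_coverage, qc.n_traces, qc.n_peaks,
                    qc.excluded)
        if not qc.excluded:
            tables.append(df)
    table = (pd.concat(tables, ignore_index=True) if tables
             else pd.DataFrame(columns=_COLUMNS))

    angles = table.loc[table.exclusion_reason == "none",
                       "bend_angle_deg"].to_numpy(dtype=float)
    mixture = None
    if angles.size >= 50:
        r2 = (config.r2_threshold_complexes if mode == "complexes"
              else config.r2_threshold_lesions)
        mixture = select_model(angles, r2, kmax=config.kmax,
                               bin_width_deg=config.bin_width_deg,
                               seed=config.fit_seed)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / f"angles_{mode}.csv", index=False)
        io.write_config_snapshot(outdir / "config_snapshot.json", config)
        if mixture is not None:
            import json
            (outdir / f"mixture_{mode}.json").write_text(json.dumps(dict(
                components=[dataclasses.asdict(c) for c in mixture.components],
                r_squared=mixture.r_squared,
                bin_width_deg=mixture.bin_width_deg,
                n_samples=mixture.n_samples,
                below_threshold=mixture.below_threshold), indent=2))
    return table, mixture, qcs
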