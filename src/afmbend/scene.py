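"""Synthetic AFM scene generator with known ground truth.

DNA molecules are sampled as discrete 2D worm-like chains (WLC): successive
turning angles are independent zero-mean Gaussians with variance
``step / L_P``, which gives the 2D tangent correlation ``exp(-s / (2 L_P))``
and hence the 2D mean squared end-to-end distance

    <R^2>_2D = 4 L_P L_c {1 - (2 L_P / L_c)(1 - e^(-L_c / 2 L_P))}.

Chains are equilibrated in the plane (no 3D projection), matching DNA
deposited on mica. A defined bend can be imposed at a chosen arc position,
and a protein blob can be placed on top of it; the renderer then emulates a
tapping-mode topograph: Gaussian-profile ridge for DNA, disc for protein,
tip convolution as Gaussian blur, additive Gaussian noise.

Heights are apparent (post-blur) heights in arbitrary units: the renderer
pre-compensates the amplitude loss that tip convolution inflicts on narrow
features, so `dna_height`/`protein_height` are what a cross-section through
the rendered image shows. Self-crossing chains are rendered as-is; rejecting
them is the tracer's job.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .config import SceneSpec
from .image_ops import HeightMap

__all__ = [
    "MoleculeTruth",
    "GroundTruth",
    "sample_wlc_chain",
    "impose_bend",
    "render_scene",
    "generate_scene",
    "write_scene",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclasses.dataclass
class MoleculeTruth:
    """Ground truth for one rendered molecule."""

    molecule_id: int
    path_nm: np.ndarray                 # (n, 2) x/y in nm
    bend_angle_deg: Optional[float]     # realized imposed angle, if any
    bend_position_frac: Optional[float]
    protein_xy_nm: Optional[Tuple[float, float]]


@dataclasses.dataclass
class GroundTruth:
    molecules: List[MoleculeTruth]
    free_protein_xy_nm: List[Tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.molecules:
            px, py = (m.protein_xy_nm if m.protein_xy_nm is not None
                      else (np.nan, np.nan))
            rows.append(dict(
                molecule_id=m.molecule_id,
                bend_angle_deg=m.bend_angle_deg,
                bend_position_frac=m.bend_position_frac,
                protein_x_nm=px, protein_y_nm=py,
            ))
        return pd.DataFrame(rows)


def sample_wlc_chain(contour_length_nm: float, persistence_length_nm: float,
                     step_nm: float, rng: np.random.Generator) -> np.ndarray:
    """Sample one discrete 2D worm-like chain.

    Returns an (n, 2) polyline with fixed arc spacing `step_nm`, starting at
    the origin with a random initial heading. Turning angles between
    successive segments are iid N(0, step_nm / persistence_length_nm).
    """
    if contour_length_nm <= 0 or persistence_length_nm <= 0 or step_nm <= 0:
        raise ValueError("lengths must be positive")
    if step_nm > persistence_length_nm / 10.0:
        raise ValueError("step_nm must be <= persistence_length_nm / 10")
    n_seg = max(1, int(round(contour_length_nm / step_nm)))
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    turns = rng.normal(0.0, np.sqrt(step_nm / persistence_length_nm), n_seg - 1)
    headings = theta0 + np.concatenate(([0.0], np.cumsum(turns)))
    steps = step_nm * np.column_stack((np.cos(headings), np.sin(headings)))
    pts = np.vstack((np.zeros(2), np.cumsum(steps, axis=0)))
    return pts


def _rotate(points: np.ndarray, angle_rad: float,
            center: np.ndarray) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rot = np.array([[c, -s], [s, c]])
    return (points - center) @ rot.T + center


def impose_bend(polyline: np.ndarray, angle_deg: float, position_frac: float,
                sigma_deg: float, rng: np.random.Generator,
                ) -> Tuple[np.ndarray, float]:
    """Insert a single kink of ``angle_deg + N(0, sigma_deg)`` (random sign).

    The kink is placed at the node nearest ``position_frac`` of the contour;
    the downstream part of the chain is rigidly rotated about that node, so
    contour length is unchanged. Returns the new polyline and the realized
    (unsigned) kink angle in degrees.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("polyline needs at least 3 points")
    if not 0.0 < position_frac < 1.0:
        raise ValueError("position_frac must lie in (0, 1)")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate(([0.0], np.cumsum(seg)))
    k = int(np.argmin(np.abs(arc - position_frac * arc[-1])))
    if k < 1 or k > pts.shape[0] - 2:
        raise ValueError("bend position too close to a chain end")
    applied = angle_deg + rng.normal(0.0, sigma_deg) if sigma_deg > 0 \
        else float(angle_deg)
    applied = abs(applied)
    sign = rng.choice((-1.0, 1.0))
    out = pts.copy()
    out[k + 1:] = _rotate(pts[k + 1:], sign * np.deg2rad(applied), pts[k])
    return out, applied


def _disc_attenuation(radius_nm: float, sigma_nm: float) -> float:
    # centre value of a unit disc after isotropic Gaussian blur
    return float(1.0 - np.exp(-radius_nm ** 2 / (2.0 * sigma_nm ** 2)))


def render_scene(spec: SceneSpec, molecules: Sequence[np.ndarray],
                 proteins: Sequence[Tuple[float, float]] = (),
                 rng: Optional[np.random.Generator] = None,
                 ) -> HeightMap:
    """Render molecules (nm polylines) and protein discs into a height map.

    Raises if any coordinate leaves the field of view. Deterministic for a
    fixed rng state (noise is the only stochastic element).
    """
    ny, nx = spec.image_size_px
    px = spec.pixel_size_nm
    img = np.zeros((ny, nx), dtype=float)
    sigma_tip = spec.tip_fwhm_nm * FWHM_TO_SIGMA
    sigma_dna = spec.dna_sigma_nm
    # amplitude compensation for tip convolution of a 1D Gaussian ridge
    ridge_gain = np.sqrt(sigma_dna ** 2 + sigma_tip ** 2) / sigma_dna

    xs = (np.arange(nx) + 0.0) * px
    ys = (np.arange(ny) + 0.0) * px

    for path in molecules:
        p = np.asarray(path, dtype=float)
        if (p < 0).any() or (p[:, 0] > xs[-1]).any() or (p[:, 1] > ys[-1]).any():
            raise ValueError("molecule extends beyond the field of view")
        dense = _densify(p, 0.5)
        pad = 4.0 * sigma_dna + 2.0 * px
        i0 = max(0, int((dense[:, 1].min() - pad) / px))
        i1 = min(ny, int((dense[:, 1].max() + pad) / px) + 2)
        j0 = max(0, int((dense[:, 0].min() - pad) / px))
        j1 = min(nx, int((dense[:, 0].max() + pad) / px) + 2)
        gx, gy = np.meshgrid(xs[j0:j1], ys[i0:i1])
        pix = np.column_stack((gx.ravel(), gy.ravel()))
        d, _ = cKDTree(dense).query(pix, k=1)
        ridge = (spec.dna_height * ridge_gain
                 * np.exp(-d ** 2 / (2.0 * sigma_dna ** 2)))
        block = img[i0:i1, j0:j1]
        np.maximum(block, ridge.reshape(block.shape), out=block)

    disc_gain = 1.0 / _disc_attenuation(spec.protein_radius_nm, sigma_tip)
    for (cx, cy) in proteins:
        if not (0 <= cx <= xs[-1] and 0 <= cy <= ys[-1]):
            raise ValueError("protein centre outside the field of view")
        pad = spec.protein_radius_nm + 2.0 * px
        i0 = max(0, int((cy - pad) / px)); i1 = min(ny, int((cy + pad) / px) + 2)
        j0 = max(0, int((cx - pad) / px)); j1 = min(nx, int((cx + pad) / px) + 2)
        gx, gy = np.meshgrid(xs[j0:j1], ys[i0:i1])
        disc = ((gx - cx) ** 2 + (gy - cy) ** 2
                <= spec.protein_radius_nm ** 2)
        block = img[i0:i1, j0:j1]
        np.maximum(block, disc * spec.protein_height * disc_gain, out=block)

    img = gaussian_filter(img, sigma_tip / px, mode="constant")
    if spec.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(spec.rng_seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return HeightMap(values=img, pixel_size_nm=px)


def _densify(polyline: np.ndarray, max_step_nm: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    arc = np.concatenate(([0.0], np.cumsum(seg)))
    n = max(2, int(np.ceil(arc[-1] / max_step_nm)) + 1)
    s = np.linspace(0.0, arc[-1], n)
    x = np.interp(s, arc, polyline[:, 0])
    y = np.interp(s, arc, polyline[:, 1])
    return np.column_stack((x, y))


def _place(path: np.ndarray, spec: SceneSpec, occupied: List[np.ndarray],
           rng: np.random.Generator, max_tries: int = 80,
           ) -> Optional[np.ndarray]:
    """Random rotation + translation avoiding other molecules and borders."""
    ny, nx = spec.image_size_px
    w = (nx - 1) * spec.pixel_size_nm
    h = (ny - 1) * spec.pixel_size_nm
    m = spec.border_margin_nm
    centred = path - path.mean(axis=0)
    tree = cKDTree(np.vstack(occupied)) if occupied else None
    for _ in range(max_tries):
        cand = _rotate(centred, rng.uniform(0, 2 * np.pi), np.zeros(2))
        lo, hi = cand.min(axis=0), cand.max(axis=0)
        if hi[0] - lo[0] > w - 2 * m or hi[1] - lo[1] > h - 2 * m:
            continue
        shift = np.array([rng.uniform(m - lo[0], w - m - hi[0]),
                          rng.uniform(m - lo[1], h - m - hi[1])])
        cand = cand + shift
        if tree is not None:
            d, _ = tree.query(cand[:: 4], k=1)
            if d.min() < spec.clearance_nm:
                continue
        return cand
    return None


def generate_scene(spec: SceneSpec,
                   rng: Optional[np.random.Generator] = None,
                   ) -> Tuple[HeightMap, GroundTruth]:
    """Sample, place and render a full scene from a SceneSpec.

    Molecules that cannot be placed without violating clearance or border
    margins after a bounded number of attempts are dropped (the ground truth
    only records rendered molecules). Identical spec + seed gives
    bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    molecules: List[MoleculeTruth] = []
    paths: List[np.ndarray] = []
    occupied: List[np.ndarray] = []
    mol_id = 0
    for _ in range(spec.n_molecules):
        path = sample_wlc_chain(spec.contour_length_nm,
                                spec.persistence_length_nm,
                                spec.step_nm, rng)
        bend_angle = None
        if spec.imposed_bend_deg is not None:
            path, bend_angle = impose_bend(
                path, spec.imposed_bend_deg, spec.bend_position_frac,
                spec.bend_sigma_deg, rng)
        placed = _place(path, spec, occupied, rng)
        if placed is None:
            continue
        occupied.append(_densify(placed, 2.0))
        protein_xy = None
        if spec.place_protein:
            seg = np.linalg.norm(np.diff(placed, axis=0), axis=1)
            arc = np.concatenate(([0.0], np.cumsum(seg)))
            k = int(np.argmin(np.abs(arc - spec.bend_position_frac * arc[-1])))
            protein_xy = (float(placed[k, 0]), float(placed[k, 1]))
        molecules.append(MoleculeTruth(
            molecule_id=mol_id, path_nm=placed,
            bend_angle_deg=bend_angle,
            bend_position_frac=(spec.bend_position_frac
                                if spec.imposed_bend_deg is not None else None),
            protein_xy_nm=protein_xy))
        mol_id += 1

    free: List[Tuple[float, float]] = []
    ny, nx = spec.image_size_px
    w = (nx - 1) * spec.pixel_size_nm
    h = (ny - 1) * spec.pixel_size_nm
    m = spec.border_margin_nm
    tree = cKDTree(np.vstack(occupied)) if occupied else None
    for _ in range(spec.n_free_proteins):
        for _ in range(80):
            cand = (rng.uniform(m, w - m), rng.uniform(m, h - m))
            far_dna = (tree is None
                       or tree.query(cand)[0] > 3 * spec.protein_radius_nm + 10)
            far_free = all(np.hypot(cand[0] - f[0], cand[1] - f[1])
                           > 3 * spec.protein_radius_nm for f in free)
            if far_dna and far_free:
                free.append(cand)
                break

    proteins = [m_.protein_xy_nm for m_ in molecules
                if m_.protein_xy_nm is not None] + free
    hm = render_scene(spec, [m_.path_nm for m_ in molecules], proteins,
                      rng=rng)
    return hm, GroundTruth(molecules=molecules, free_protein_xy_nm=free)


def write_scene(outdir: str | Path, spec: SceneSpec, hm: HeightMap,
                truth: GroundTruth) -> None:
    """Write TIFF (16-bit), ground-truth CSV and the SceneSpec as JSON."""
    from . import io as _io
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_height_map(outdir / "scene.tif", hm)
    truth.to_frame().to_csv(outdir / "ground_truth.csv", index=False)
    (outdir / "scene_spec.json").write_text(
        json.dumps(spec.model_dump(), indent=2))
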