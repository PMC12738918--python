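"""Synthetic labeled hyperspectral canopy scenes and calibration frames.

Real proximal canopy images of rice and paddy weeds are not redistributable,
so every stage of the pipeline is exercised on generated scenes that carry the
canonical vegetation reflectance structure:

* a *green peak* near 550 nm (low chlorophyll absorption in the green),
* a *red valley* near 680 nm (maximal chlorophyll absorption),
* a logistic *red edge* rising through 700-760 nm to a NIR *reflection
  plateau* (760-930 nm) governed by leaf/canopy structure,
* a water-related *absorption dip* near 935 nm.

Each species is a smooth base curve built from these features, with parameters
drawn per class from seeded distributions.  A scalar ``difficulty`` in [0, 1]
shrinks the between-class parameter spread (and widens within-class
variability), moving the task from trivially separable to hard.  Pixels of a
scene draw their species curve times a lognormal per-pixel factor plus
per-band Gaussian noise and a spectrally correlated noise component;
background pixels follow a flat soil-like ramp.

The generator emulates spectral structure, class layout and sensor noise; it
does not attempt radiative-transfer realism (leaf-angle, illumination or
mixed-pixel effects), so results on it bound what the classifier can do on
real canopies only qualitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .hsi_core import CalibrationFrames, HSICube, WavelengthGrid

__all__ = [
    "SpeciesSignature",
    "SceneSpec",
    "default_grid",
    "make_signatures",
    "make_scene",
    "make_calibration_frames",
    "soil_curve",
]


def default_grid(n_bands: int = 197, lo_nm: float = 397.0, hi_nm: float = 982.0) -> WavelengthGrid:
    """Evenly spaced working grid mirroring the post-trim camera range."""
    return WavelengthGrid(np.linspace(lo_nm, hi_nm, n_bands))


@dataclass
class SpeciesSignature:
    """A species-level base reflectance curve plus within-class variability."""

    species_id: int
    base: np.ndarray
    grid: WavelengthGrid
    green_peak: float
    red_valley_depth: float
    red_edge_nm: float
    nir_plateau: float
    dip935_depth: float
    lognormal_sd: float


def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def soil_curve(grid: WavelengthGrid) -> np.ndarray:
    """Featureless soil background: a gentle upward ramp, no pigment features."""
    w = grid.centers_nm
    return 0.08 + 0.17 * (w - w[0]) / (w[-1] - w[0])


def _vegetation_curve(
    grid: WavelengthGrid,
    visible_base: float,
    green_peak: float,
    red_valley_depth: float,
    red_edge_nm: float,
    red_edge_scale: float,
    nir_plateau: float,
    dip935_depth: float,
) -> np.ndarray:
    w = grid.centers_nm
    visible = (
        visible_base
        + green_peak * _gauss(w, 550.0, 35.0)
        - red_valley_depth * _gauss(w, 680.0, 25.0)
    )
    edge = 1.0 / (1.0 + np.exp(-(w - red_edge_nm) / red_edge_scale))
    curve = visible + (nir_plateau - visible) * edge
    curve = curve - dip935_depth * _gauss(w, 935.0, 20.0)
    return np.clip(curve, 1e-3, 0.999)


def make_signatures(
    K: int,
    grid: WavelengthGrid | None = None,
    difficulty: float = 0.0,
    seed: int = 0,
) -> list[SpeciesSignature]:
    """K species signatures sharing the canonical vegetation shape.

    ``difficulty`` in [0, 1] scales the between-class parameter offsets by
    ``(1 - 0.95 * difficulty)``, so the mean pairwise spectral distance
    decreases monotonically toward (but never reaching) zero, while the
    within-class lognormal spread grows from 0.02 to 0.12.
    """
    if K < 2:
        raise ParameterError("need at least 2 species")
    if not 0.0 <= difficulty <= 1.0:
        raise ParameterError("difficulty must lie in [0, 1]")
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(seed)
    scale = 1.0 - 0.95 * difficulty
    # centre of the species cloud; offsets shrink with difficulty
    center = {
        "visible_base": 0.07,
        "green_peak": 0.10,
        "red_valley_depth": 0.035,
        "red_edge_nm": 722.0,
        "red_edge_scale": 11.0,
        "nir_plateau": 0.45,
        "dip935_depth": 0.05,
    }
    spread = {
        "visible_base": 0.025,
        "green_peak": 0.05,
        "red_valley_depth": 0.015,
        "red_edge_nm": 16.0,
        "red_edge_scale": 3.0,
        "nir_plateau": 0.14,
        "dip935_depth": 0.03,
    }
    # stratified offsets: per parameter, classes occupy a shuffled even ladder
    # over [-1, 1], so any two classes differ in every feature (no accidental
    # near-duplicates among the K species)
    ladders = {
        k: rng.permutation(np.linspace(-1.0, 1.0, K)) for k in center
    }
    sigs = []
    for sid in range(1, K + 1):
        params = {k: center[k] + scale * spread[k] * ladders[k][sid - 1] for k in center}
        base = _vegetation_curve(grid, **params)
        sigs.append(
            SpeciesSignature(
                species_id=sid,
                base=base,
                grid=grid,
                green_peak=params["green_peak"],
                red_valley_depth=params["red_valley_depth"],
                red_edge_nm=params["red_edge_nm"],
                nir_plateau=params["nir_plateau"],
                dip935_depth=params["dip935_depth"],
                lognormal_sd=0.02 + 0.10 * difficulty,
            )
        )
    return sigs


@dataclass
class SceneSpec:
    """Layout and noise description of one synthetic scene."""

    M: int = 64
    N: int = 64
    K: int = 6
    layout: str = "voronoi"  # blobs | stripes | voronoi
    class_fractions: tuple[float, ...] | None = None  # default: equal, 0.7 total
    noise_sd: float = 0.01
    correlated_noise_sd: float = 0.005
    correlated_noise_bands: float = 15.0
    seed: int = 0

    def fractions(self) -> np.ndarray:
        if self.class_fractions is None:
            fr = np.full(self.K, 0.7 / self.K)
        else:
            fr = np.asarray(self.class_fractions, dtype=float)
        if fr.size != self.K:
            raise ParameterError("class_fractions must have K entries")
        if np.any(fr < 0) or fr.sum() > 1.0 + 1e-12:
            raise ParameterError("class fractions must be non-negative and sum <= 1")
        return fr


def _layout_labels(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Exact-count class layout: each class claims compact contiguous regions.

    Classes sequentially claim their quota of the unassigned pixels nearest
    their seed point, which yields clean compact patches (disks clipped by
    earlier claims) whose label histogram matches the requested fractions
    exactly; leftovers (far from every seed) become background.
    """
    m, n, k = spec.M, spec.N, spec.K
    fr = spec.fractions()
    caps = np.round(fr * m * n).astype(int)
    if spec.layout == "stripes":
        labels = np.zeros(m * n, dtype=int)
        start = 0
        for cls, cap in enumerate(caps, 1):
            labels[start : start + cap] = cls
            start += cap
        return labels.reshape(m, n)
    if spec.layout not in ("voronoi", "blobs"):
        raise ParameterError(f"unknown layout {spec.layout!r}")
    rr, cc = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    if spec.layout == "blobs":
        # seeds kept away from the border so patches read as whole plants
        centers = rng.uniform([m * 0.15, n * 0.15], [m * 0.85, n * 0.85], size=(k, 2))
    else:
        centers = rng.uniform([0, 0], [m, n], size=(k, 2))
    labels = np.zeros(m * n, dtype=int)
    for cls in range(1, k + 1):
        free = np.nonzero(labels == 0)[0]
        d = np.linalg.norm(pts[free] - centers[cls - 1], axis=1)
        take = free[np.argsort(d, kind="stable")[: caps[cls - 1]]]
        labels[take] = cls
    return labels.reshape(m, n)


def make_scene(
    spec: SceneSpec, signatures: list[SpeciesSignature]
) -> tuple[HSICube, np.ndarray]:
    """Render a labeled scene from species signatures; deterministic given seed."""
    if len(signatures) < spec.K:
        raise ParameterError("signatures do not cover K classes")
    grid = signatures[0].grid
    c = grid.count
    rng = np.random.default_rng(spec.seed)
    labels = _layout_labels(spec, rng)
    m, n = labels.shape
    values = np.empty((m, n, c))
    values[:] = soil_curve(grid)
    bg = labels == 0
    if np.any(bg):
        values[bg] *= np.exp(rng.normal(0.0, 0.05, size=int(bg.sum())))[:, None]
    for sig in signatures[: spec.K]:
        mask = labels == sig.species_id
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        factors = (
            np.exp(rng.normal(0.0, sig.lognormal_sd, size=cnt))
            if sig.lognormal_sd > 0
            else np.ones(cnt)
        )
        values[mask] = sig.base[None, :] * factors[:, None]
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=values.shape)
    if spec.correlated_noise_sd > 0:
        # low-rank smooth perturbations: random Gaussian bumps along the
        # spectral axis with per-pixel coefficients (drift/striping analogue)
        rank = 8
        centers = rng.uniform(grid.centers_nm[0], grid.centers_nm[-1], size=rank)
        basis = np.stack(
            [_gauss(grid.centers_nm, mu, spec.correlated_noise_bands) for mu in centers]
        )
        basis /= np.linalg.norm(basis, axis=1, keepdims=True)
        coeffs = rng.normal(0.0, 1.0, size=(m, n, rank))
        values += spec.correlated_noise_sd * (coeffs @ basis)
    values = np.clip(values, 0.0, 1.2)
    return HSICube(values=values, grid=grid), labels


def make_calibration_frames(
    cube: HSICube,
    dark_level: float = 100.0,
    white_level: float = 4000.0,
    shot_noise_sd: float = 0.0,
    seed: int = 0,
) -> CalibrationFrames:
    """Digital-number frames whose two-point calibration recovers the cube.

    ``raw = dark + reflectance * (white - dark) (+ shot noise)``, with the
    white frame standing in for the near-perfect (99 % nominal reflectance)
    diffuse reference panel.
    """
    if dark_level >= white_level:
        raise ParameterError("dark level must be below white level")
    c = cube.grid.count
    dark = np.full(c, float(dark_level))
    white = np.full(c, float(white_level))
    raw = dark_level + cube.values * (white_level - dark_level)
    if shot_noise_sd > 0:
        rng = np.random.default_rng(seed)
        raw = raw + rng.normal(0.0, shot_noise_sd, size=raw.shape)
    return CalibrationFrames(raw=raw, dark=dark, white=white, grid=cube.grid)
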