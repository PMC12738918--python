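"""Vegetation indices and principal-component exploration of reflectance spectra.

Three canopy indices are provided, each a normalized band combination:

* NDVI = (rho_NIR - rho_RED) / (rho_NIR + rho_RED) — greenness/biomass proxy.
* PRI  = (rho_531 - rho_570) / (rho_531 + rho_570) — xanthophyll-cycle /
  photosynthetic light-use-efficiency proxy.
* EVI  = 2.5 (rho_NIR - rho_RED) / (rho_NIR + 6 rho_RED - 7.5 rho_BLUE + 1) —
  chlorophyll-activity proxy with soil/aerosol resistance terms.

Bands are resolved by nearest wavelength; the camera never samples exactly at
the nominal index wavelengths.  PCA is mean-centered with no variance scaling
(all bands share reflectance units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .errors import ParameterError, ShapeMismatchError, UndefinedIndexError
from .hsi_core import HSICube, PixelMask, Spectrum, WavelengthGrid

__all__ = [
    "BandSelector",
    "IndexResult",
    "PCAResult",
    "band_value",
    "ndvi",
    "pri",
    "evi",
    "cube_indices",
    "pca_decompose",
]


@dataclass(frozen=True)
class BandSelector:
    """Nominal wavelengths (nm) realizing the index bands, resolved nearest-band."""

    nir_nm: float = 800.0
    red_nm: float = 680.0
    blue_nm: float = 470.0
    pri_a_nm: float = 531.0
    pri_b_nm: float = 570.0

    def check_span(self, grid: WavelengthGrid) -> None:
        lo, hi = grid.span
        for w in (self.nir_nm, self.red_nm, self.blue_nm, self.pri_a_nm, self.pri_b_nm):
            if not lo <= w <= hi:
                raise ParameterError(f"selector wavelength {w} nm outside grid span")


@dataclass
class IndexResult:
    """Per-pixel index maps (NaN where undefined) and optional ROI means."""

    ndvi: np.ndarray
    pri: np.ndarray
    evi: np.ndarray
    roi_means: dict = field(default_factory=dict)


def band_value(s: Spectrum, target_nm: float) -> float:
    """Reflectance at the band nearest ``target_nm`` (ties -> lower wavelength)."""
    return float(s.reflectance[s.grid.nearest_band(target_nm)])


def ndvi(nir: float, red: float) -> float:
    denom = nir + red
    if denom == 0:
        raise UndefinedIndexError("NDVI undefined: nir + red == 0")
    return (nir - red) / denom


def pri(r531: float, r570: float) -> float:
    denom = r531 + r570
    if denom == 0:
        raise UndefinedIndexError("PRI undefined: r531 + r570 == 0")
    return (r531 - r570) / denom


def evi(nir: float, red: float, blue: float) -> float:
    denom = nir + 6.0 * red - 7.5 * blue + 1.0
    if denom == 0:
        raise UndefinedIndexError("EVI undefined: zero denominator")
    return 2.5 * (nir - red) / denom


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    return out


def cube_indices(
    cube: HSICube, sel: BandSelector = BandSelector(), roi: PixelMask | None = None
) -> IndexResult:
    """Per-pixel NDVI/PRI/EVI maps; undefined pixels propagate as NaN.

    When ``roi`` is given, the result also carries the mean of each per-pixel
    index over the mask (NaN pixels excluded), the default summary convention
    for per-image markers.
    """
    sel.check_span(cube.grid)
    g = cube.grid
    v = cube.values
    nir = v[:, :, g.nearest_band(sel.nir_nm)]
    red = v[:, :, g.nearest_band(sel.red_nm)]
    blue = v[:, :, g.nearest_band(sel.blue_nm)]
    a = v[:, :, g.nearest_band(sel.pri_a_nm)]
    b = v[:, :, g.nearest_band(sel.pri_b_nm)]
    res = IndexResult(
        ndvi=_safe_ratio(nir - red, nir + red),
        pri=_safe_ratio(a - b, a + b),
        evi=_safe_ratio(2.5 * (nir - red), nir + 6.0 * red - 7.5 * blue + 1.0),
    )
    if roi is not None:
        if roi.flags.shape != v.shape[:2]:
            raise ShapeMismatchError("ROI shape does not match cube")
        for name in ("ndvi", "pri", "evi"):
            vals = getattr(res, name)[roi.flags]
            res.roi_means[name] = float(np.nanmean(vals)) if vals.size else float("nan")
    return res


@dataclass
class PCAResult:
    """Loadings (C x k, orthonormal columns), scores (samples x k), variance shares."""

    loadings: np.ndarray
    scores: np.ndarray
    explained_pct: np.ndarray
    mean: np.ndarray


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    # reproducible sign convention: largest-|.| element of each loading >= 0
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1


def pca_decompose(table, k: int) -> PCAResult:
    """Mean-centered PCA of a spectra table.

    Parameters
    ----------
    table
        Either a list of :class:`Spectrum` sharing one grid or a 2-D array
        (samples x bands).
    k
        Number of components, ``1 <= k <= min(samples - 1, bands)``.
    """
    if isinstance(table, np.ndarray):
        x = np.asarray(table, dtype=float)
    else:
        x = np.stack([s.reflectance for s in table])
    if x.ndim != 2 or x.shape[0] < 2:
        raise ParameterError("PCA needs a 2-D table with at least 2 samples")
    n, c = x.shape
    if not 1 <= k <= min(n - 1, c):
        raise ParameterError(f"k={k} outside [1, min(samples-1, bands)]")
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T.copy()
    _fix_signs(loadings, scores)
    explained = 100.0 * model.explained_variance_ratio_
    return PCAResult(
        loadings=loadings, scores=scores, explained_pct=explained, mean=model.mean_
    )
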