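"""Gray-level quantization, texture matrices, and the 53 textural features.

Matrices are built on the native voxel lattice (offset distance = 1 voxel):

* GLCM — accumulated over the 13 unique 3D directions, symmetrized and
  merged into a single matrix before features are computed;
* GLRLM — maximal constant-level runs along the same 13 directions;
* GLSZM — 26-connected constant-level zones.

Pairs, runs and zones never cross the mask boundary.  Degenerate matrices
(single nonzero cell, zero variance) use documented limits — correlation 0,
entropies 0 — so every feature value is always finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from immunorad.volumes import CTVolume, ROIMask

#: the 13 unique 3D lattice directions at Chebyshev distance 1
OFFSETS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


@dataclass(frozen=True)
class QuantizedVOI:
    """Integer gray levels 1..Ng over the foreground; 0 outside the mask."""

    levels: np.ndarray
    n_levels: int
    bin_edges: np.ndarray


@dataclass(frozen=True)
class TextureMatrices:
    """Merged GLCM, GLRLM and GLSZM counts plus bookkeeping totals."""

    glcm: np.ndarray   # Ng x Ng, symmetric
    glrlm: np.ndarray  # Ng x Nr
    glszm: np.ndarray  # Ng x Ns
    n_voxels: int
    n_directions: int


def quantize(voi: CTVolume, mask: ROIMask, n_bins: int = 64) -> QuantizedVOI:
    """Equal-width binning of in-mask HU into ``n_bins`` levels.

    Levels run 1..n_bins; the in-mask maximum maps to level n_bins and a
    constant-intensity VOI maps to level 1 everywhere.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    fg = mask.foreground
    x = voi.intensities[fg]
    lo, hi = float(x.min()), float(x.max())
    levels = np.zeros(voi.shape, dtype=np.int32)
    if hi <= lo:
        levels[fg] = 1
        edges = np.linspace(lo, lo + 1.0, n_bins + 1)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        width = (hi - lo) / n_bins
        levels[fg] = np.minimum(((x - lo) / width).astype(np.int64), n_bins - 1) + 1
    return QuantizedVOI(levels=levels, n_levels=n_bins, bin_edges=edges)


def _offset_slices(offset, shape):
    """Slices (a, b) such that arr[b] = arr[a] shifted by +offset."""
    a, b = [], []
    for o, dim in zip(offset, shape):
        a.append(slice(max(0, -o), dim - max(0, o)))
        b.append(slice(max(0, o), dim - max(0, -o)))
    return tuple(a), tuple(b)


def _glcm(levels, fg, n_levels, offsets):
    glcm = np.zeros((n_levels, n_levels), dtype=np.int64)
    for off in offsets:
        sl_a, sl_b = _offset_slices(off, fg.shape)
        valid = fg[sl_a] & fg[sl_b]
        a = levels[sl_a][valid] - 1
        b = levels[sl_b][valid] - 1
        np.add.at(glcm, (a, b), 1)
        np.add.at(glcm, (b, a), 1)
    return glcm


def _runs_along(levels, fg, offset):
    """(level, length) of every maximal constant-level in-mask run along offset."""
    shape = fg.shape
    prev_same = np.zeros(shape, dtype=bool)
    sl_p, sl_v = _offset_slices(offset, shape)
    prev_same[sl_v] = fg[sl_p] & fg[sl_v] & (levels[sl_p] == levels[sl_v])
    starts = np.argwhere(fg & ~prev_same)
    n = len(starts)
    run_len = np.ones(n, dtype=np.int64)
    run_lvl = levels[tuple(starts.T)]
    cur = starts.copy()
    active = np.arange(n)
    off = np.asarray(offset)
    while active.size:
        nxt = cur[active] + off
        inb = np.all((nxt >= 0) & (nxt < np.asarray(shape)), axis=1)
        ok = np.zeros(active.size, dtype=bool)
        if inb.any():
            pos = tuple(nxt[inb].T)
            ok[inb] = fg[pos] & (levels[pos] == run_lvl[active[inb]])
        cont = active[ok]
        run_len[cont] += 1
        cur[cont] = nxt[ok]
        active = cont
    return run_lvl, run_len


def _glrlm(levels, fg, n_levels, offsets):
    max_len = int(max(fg.shape))
    glrlm = np.zeros((n_levels, max_len), dtype=np.int64)
    for off in offsets:
        lvl, length = _runs_along(levels, fg, off)
        np.add.at(glrlm, (lvl - 1, length - 1), 1)
    nz = np.flatnonzero(glrlm.any(axis=0))
    return glrlm[:, : (nz[-1] + 1 if nz.size else 1)]


def _glszm(levels, fg, n_levels):
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    sizes_by_level: list[tuple[int, int]] = []
    max_size = 1
    for g in range(1, n_levels + 1):
        lab, n_zones = ndimage.label((levels == g) & fg, structure=structure)
        if n_zones == 0:
            continue
        counts = np.bincount(lab.ravel())[1:]
        for size in counts:
            sizes_by_level.append((g, int(size)))
            max_size = max(max_size, int(size))
    glszm = np.zeros((n_levels, max_size), dtype=np.int64)
    for g, size in sizes_by_level:
        glszm[g - 1, size - 1] += 1
    return glszm


def build_texture_matrices(
    q: QuantizedVOI,
    mask: ROIMask,
    offsets: Sequence[tuple[int, int, int]] | None = None,
) -> TextureMatrices:
    """Accumulate GLCM/GLRLM/GLSZM counts from a quantized VOI."""
    offs = tuple(tuple(o) for o in (offsets if offsets is not None else OFFSETS_3D))
    fg = mask.foreground
    return TextureMatrices(
        glcm=_glcm(q.levels, fg, q.n_levels, offs),
        glrlm=_glrlm(q.levels, fg, q.n_levels, offs),
        glszm=_glszm(q.levels, fg, q.n_levels),
        n_voxels=int(fg.sum()),
        n_directions=len(offs),
    )


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p))) if p.size else 0.0


def _glcm_features(glcm: np.ndarray) -> dict[str, float]:
    ng = glcm.shape[0]
    total = glcm.sum()
    out_zero = {name: 0.0 for name in GLCM_FEATURE_NAMES}
    if total == 0:
        return out_zero
    p = glcm / total
    i = np.arange(1, ng + 1)[:, None] * np.ones((1, ng))
    j = i.T
    px = p.sum(axis=1)
    mu = float(np.sum(i * p))  # symmetric: mu_x == mu_y
    sigma2 = float(np.sum((i - mu) ** 2 * p))
    sigma = np.sqrt(sigma2)
    diff = np.abs(i - j)
    # p_{x+y} over k = 2..2Ng and p_{x-y} over k = 0..Ng-1
    ksum = (i + j).astype(int)
    p_sum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    kdiff = diff.astype(int)
    p_diff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=ng)
    k_s = np.arange(2, 2 * ng + 1)
    k_d = np.arange(0, ng)
    diff_avg = float(np.sum(k_d * p_diff))
    hxy = _entropy2(p.ravel())
    px_py = px[:, None] * px[None, :]
    valid = (p > 0) & (px_py > 0)
    hxy1 = float(-np.sum(p[valid] * np.log2(px_py[valid])))
    pv = px_py[px_py > 0]
    hxy2 = float(-np.sum(pv * np.log2(pv)))
    hx = _entropy2(px)
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    off_diag = diff > 0
    return {
        "glcm_joint_maximum": float(p.max()),
        "glcm_joint_average": mu,
        "glcm_joint_energy": float(np.sum(p**2)),
        "glcm_joint_entropy": hxy,
        "glcm_contrast": float(np.sum(diff**2 * p)),
        "glcm_dissimilarity": float(np.sum(diff * p)),
        "glcm_inverse_difference": float(np.sum(p / (1.0 + diff))),
        "glcm_inverse_difference_moment": float(np.sum(p / (1.0 + diff**2))),
        "glcm_inverse_difference_normalized": float(np.sum(p / (1.0 + diff / ng))),
        "glcm_inverse_difference_moment_normalized": float(np.sum(p / (1.0 + diff**2 / ng**2))),
        "glcm_inverse_variance": float(np.sum(p[off_diag] / diff[off_diag] ** 2)),
        "glcm_correlation": (
            float((np.sum(i * j * p) - mu * mu) / sigma2) if sigma2 > 0 else 0.0
        ),
        "glcm_autocorrelation": float(np.sum(i * j * p)),
        "glcm_cluster_tendency": float(np.sum((i + j - 2 * mu) ** 2 * p)),
        "glcm_cluster_shade": float(np.sum((i + j - 2 * mu) ** 3 * p)),
        "glcm_cluster_prominence": float(np.sum((i + j - 2 * mu) ** 4 * p)),
        "glcm_sum_average": float(np.sum(k_s * p_sum)),
        "glcm_sum_entropy": _entropy2(p_sum),
        "glcm_sum_of_squares": sigma2,
        "glcm_difference_average": diff_avg,
        "glcm_difference_entropy": _entropy2(p_diff),
        "glcm_difference_variance": float(np.sum((k_d - diff_avg) ** 2 * p_diff)),
        "glcm_imc1": float(imc1),
        "glcm_imc2": imc2,
    }


def _glrlm_features(glrlm: np.ndarray, n_voxels: int, n_directions: int) -> dict[str, float]:
    total = glrlm.sum()
    if total == 0:
        return {name: 0.0 for name in GLRLM_FEATURE_NAMES}
    p = glrlm / total
    ng, nr = p.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nr + 1)[None, :]
    p_g = p.sum(axis=1)
    p_r = p.sum(axis=0)
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    return {
        "glrlm_short_run_emphasis": float(np.sum(p / j**2)),
        "glrlm_long_run_emphasis": float(np.sum(p * j**2)),
        "glrlm_gray_level_nonuniformity": float(total * np.sum(p_g**2)),
        "glrlm_gray_level_nonuniformity_normalized": float(np.sum(p_g**2)),
        "glrlm_run_length_nonuniformity": float(total * np.sum(p_r**2)),
        "glrlm_run_length_nonuniformity_normalized": float(np.sum(p_r**2)),
        "glrlm_run_percentage": float(total / (n_voxels * n_directions)),
        "glrlm_gray_level_variance": float(np.sum((i - mu_i) ** 2 * p)),
        "glrlm_run_length_variance": float(np.sum((j - mu_j) ** 2 * p)),
        "glrlm_run_entropy": _entropy2(p.ravel()),
        "glrlm_low_gray_level_run_emphasis": float(np.sum(p / i**2)),
        "glrlm_high_gray_level_run_emphasis": float(np.sum(p * i**2)),
        "glrlm_short_run_low_gray_level_emphasis": float(np.sum(p / (i**2 * j**2))),
        "glrlm_short_run_high_gray_level_emphasis": float(np.sum(p * i**2 / j**2)),
        "glrlm_long_run_low_gray_level_emphasis": float(np.sum(p * j**2 / i**2)),
        "glrlm_long_run_high_gray_level_emphasis": float(np.sum(p * i**2 * j**2)),
    }


def _glszm_features(glszm: np.ndarray, n_voxels: int) -> dict[str, float]:
    total = glszm.sum()
    if total == 0:
        return {name: 0.0 for name in GLSZM_FEATURE_NAMES}
    p = glszm / total
    ng, ns = p.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ns + 1)[None, :]
    p_g = p.sum(axis=1)
    p_s = p.sum(axis=0)
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    return {
        "glszm_small_area_emphasis": float(np.sum(p / j**2)),
        "glszm_large_area_emphasis": float(np.sum(p * j**2)),
        "glszm_gray_level_nonuniformity": float(total * np.sum(p_g**2)),
        "glszm_gray_level_nonuniformity_normalized": float(np.sum(p_g**2)),
        "glszm_size_zone_nonuniformity": float(total * np.sum(p_s**2)),
        "glszm_size_zone_nonuniformity_normalized": float(np.sum(p_s**2)),
        "glszm_zone_percentage": float(total / n_voxels),
        "glszm_gray_level_variance": float(np.sum((i - mu_i) ** 2 * p)),
        "glszm_zone_variance": float(np.sum((j - mu_j) ** 2 * p)),
        "glszm_zone_entropy": _entropy2(p.ravel()),
        "glszm_low_gray_level_zone_emphasis": float(np.sum(p / i**2)),
        "glszm_high_gray_level_zone_emphasis": float(np.sum(p * i**2)),
        "glszm_small_area_high_gray_level_emphasis": float(np.sum(p * i**2 / j**2)),
    }


def textural_features(m: TextureMatrices) -> dict[str, float]:
    """All 53 textural features (24 GLCM + 16 GLRLM + 13 GLSZM)."""
    out = _glcm_features(m.glcm)
    out.update(_glrlm_features(m.glrlm, m.n_voxels, m.n_directions))
    out.update(_glszm_features(m.glszm, m.n_voxels))
    return out


GLCM_FEATURE_NAMES = (
    "glcm_joint_maximum", "glcm_joint_average", "glcm_joint_energy",
    "glcm_joint_entropy", "glcm_contrast", "glcm_dissimilarity",
    "glcm_inverse_difference", "glcm_inverse_difference_moment",
    "glcm_inverse_difference_normalized",
    "glcm_inverse_difference_moment_normalized", "glcm_inverse_variance",
    "glcm_correlation", "glcm_autocorrelation", "glcm_cluster_tendency",
    "glcm_cluster_shade", "glcm_cluster_prominence", "glcm_sum_average",
    "glcm_sum_entropy", "glcm_sum_of_squares", "glcm_difference_average",
    "glcm_difference_entropy", "glcm_difference_variance", "glcm_imc1",
    "glcm_imc2",
)
GLRLM_FEATURE_NAMES = (
    "glrlm_short_run_emphasis", "glrlm_long_run_emphasis",
    "glrlm_gray_level_nonuniformity",
    "glrlm_gray_level_nonuniformity_normalized",
    "glrlm_run_length_nonuniformity",
    "glrlm_run_length_nonuniformity_normalized", "glrlm_run_percentage",
    "glrlm_gray_level_variance", "glrlm_run_length_variance",
    "glrlm_run_entropy", "glrlm_low_gray_level_run_emphasis",
    "glrlm_high_gray_level_run_emphasis",
    "glrlm_short_run_low_gray_level_emphasis",
    "glrlm_short_run_high_gray_level_emphasis",
    "glrlm_long_run_low_gray_level_emphasis",
    "glrlm_long_run_high_gray_level_emphasis",
)
GLSZM_FEATURE_NAMES = (
    "glszm_small_area_emphasis", "glszm_large_area_emphasis",
    "glszm_gray_level_nonuniformity",
    "glszm_gray_level_nonuniformity_normalized",
    "glszm_size_zone_nonuniformity",
    "glszm_size_zone_nonuniformity_normalized", "glszm_zone_percentage",
    "glszm_gray_level_variance", "glszm_zone_variance", "glszm_zone_entropy",
    "glszm_low_gray_level_zone_emphasis",
    "glszm_high_gray_level_zone_emphasis",
    "glszm_small_area_high_gray_level_emphasis",
)
TEXTURAL_FEATURE_NAMES = GLCM_FEATURE_NAMES + GLRLM_FEATURE_NAMES + GLSZM_FEATURE_NAMES
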