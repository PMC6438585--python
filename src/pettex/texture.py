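"""Gray-level discretization, the four 3D texture matrices (GLCM, GLRLM,
NGLDM, GLZLM) and the 31 textural indices computed from them.

Conventions
-----------
* Absolute resampling: SUVs are binned into 64 levels over the fixed range
  0-30 SUV, identically for every lesion (level ``1 + floor(64 * v / 30)``,
  clamped into ``1..64``).  Gray levels are 1-based so the low-gray-level
  emphases are always defined.
* GLCM: distance 1 voxel, the 13 unique 3D directions, both signs,
  accumulated into a single symmetric matrix and normalized.
* GLRLM: maximal equal-level runs along the same 13 directions, aggregated
  into one matrix.
* NGLDM: for each voxel, the number of its in-mask 26-neighbors sharing its
  level (no tolerance); boundary voxels simply have fewer neighbors.
  Coarseness / Contrast / Busyness follow the Amadasun-King functional
  forms, computed from the in-mask neighbor structure.
* GLZLM: 26-connected equal-level zones in 3D.
* Entropy is in bits (log2, with 0 log 0 = 0).
* Degenerate indices (GLCM Correlation and NGLDM Busyness on a constant
  VOI) are returned as NaN, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import label as nd_label

from .volumes import MIN_VOXELS, PETVolume, VOIMask, check_min_volume

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

#: The 13 unique voxel offsets (canonical sign: first non-zero positive).
OFFSETS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

GLCM_FEATURES = ["Homogeneity", "Energy", "Contrast_glcm", "Correlation",
                 "Entropy", "Dissimilarity"]
GLRLM_FEATURES = ["SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE",
                  "LRHGE", "GLNUr", "RLNU", "RP"]
NGLDM_FEATURES = ["Coarseness", "Contrast", "Busyness"]
GLZLM_FEATURES = ["SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE",
                  "LZHGE", "GLNUz", "ZLNU", "ZP"]

#: All 31 textural indices in table order.
TEXTURE_FEATURES = GLCM_FEATURES + GLRLM_FEATURES + NGLDM_FEATURES + GLZLM_FEATURES

#: Standard PET quantitative parameters reported alongside.
STANDARD_FEATURES = ["SUVmax", "MTV"]

ALL_FEATURES = TEXTURE_FEATURES + STANDARD_FEATURES


class IneligibleVOIError(ValueError):
    """Raised when a VOI is too small (< 64 voxels) for texture analysis."""


@dataclass(frozen=True)
class DiscretizationConfig:
    """Absolute resampling parameters: 64 levels over 0-30 SUV."""

    n_levels: int = 64
    lower_bound: float = 0.0
    upper_bound: float = 30.0

    def __post_init__(self) -> None:
        if self.upper_bound <= self.lower_bound:
            raise ValueError("upper_bound must exceed lower_bound")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


@dataclass
class DiscretizedVOI:
    """Masked voxels carrying gray levels 1..n_levels.

    ``levels`` is a dense int array over the (cropped) grid with 0 outside
    the mask; ``mask`` is the matching boolean array.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    spacing: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize_values(v: np.ndarray, config: DiscretizationConfig) -> np.ndarray:
    """Absolute-resample SUVs to integer levels in ``1..n_levels``."""
    lo, hi = config.lower_bound, config.upper_bound
    clamped = np.clip(np.asarray(v, dtype=np.float64), lo, hi)
    lvl = 1 + np.floor(config.n_levels * (clamped - lo) / (hi - lo)).astype(np.int64)
    return np.minimum(lvl, config.n_levels)


def discretize_absolute(
    volume: PETVolume, mask: VOIMask, config: DiscretizationConfig | None = None
) -> DiscretizedVOI:
    """Discretize the masked voxels of a volume; crops to the mask bounding
    box (texture matrices only see within-mask structure)."""
    config = config or DiscretizationConfig()
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    m = mask.mask
    idx = np.nonzero(m)
    box = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    sub_mask = m[box]
    sub_vals = volume.values[box]
    levels = np.zeros(sub_mask.shape, dtype=np.int64)
    levels[sub_mask] = discretize_values(sub_vals[sub_mask], config)
    return DiscretizedVOI(levels=levels, mask=sub_mask, n_levels=config.n_levels,
                          spacing=volume.spacing)


def _offset_slices(shape, offset):
    """Slice pair (src, dst) such that arr[src] aligns with arr[dst] shifted
    by ``offset``."""
    src, dst = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return tuple(src), tuple(dst)


def build_glcm(dvoi: DiscretizedVOI) -> np.ndarray:
    """Co-occurrence counts over the 26 ordered unit offsets (13 directions,
    both signs), as a symmetric ``n_levels x n_levels`` integer matrix."""
    n = dvoi.n_levels
    counts = np.zeros(n * n, dtype=np.int64)
    lv, m = dvoi.levels, dvoi.mask
    for off in OFFSETS_13:
        src, dst = _offset_slices(lv.shape, off)
        both = m[src] & m[dst]
        a = lv[src][both] - 1
        b = lv[dst][both] - 1
        pair = np.bincount(a * n + b, minlength=n * n)
        counts += pair
        counts += np.bincount(b * n + a, minlength=n * n)
    return counts.reshape(n, n)


def normalize_glcm(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    if total == 0:
        raise ValueError("degenerate co-occurrence matrix: no voxel pairs")
    return counts / total


def glcm_indices(p: np.ndarray) -> dict[str, float]:
    """The six co-occurrence indices from a normalized symmetric matrix.

    Correlation is NaN when the marginal SD is zero (constant VOI)."""
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    nz = p > 0
    homogeneity = float((p / (1.0 + np.abs(ii - jj))).sum())
    energy = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    dissimilarity = float((np.abs(ii - jj) * p).sum())
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    marg = p.sum(axis=1)
    mu = float((i * marg).sum())
    var = float(((i - mu) ** 2 * marg).sum())
    if var <= 0:
        correlation = float("nan")
    else:
        correlation = float((((ii - mu) * (jj - mu) * p).sum()) / var)
    return {
        "Homogeneity": homogeneity,
        "Energy": energy,
        "Contrast_glcm": contrast,
        "Correlation": correlation,
        "Entropy": entropy,
        "Dissimilarity": dissimilarity,
    }


def build_glrlm(dvoi: DiscretizedVOI) -> np.ndarray:
    """Run-length counts ``r[level-1, length-1]`` aggregated over the 13
    directions (each maximal in-mask collinear segment decomposed into
    maximal equal-level runs)."""
    lv, m = dvoi.levels, dvoi.mask
    n = dvoi.n_levels
    max_len = max(lv.shape)
    counts = np.zeros((n, max_len), dtype=np.int64)
    coords_all = np.argwhere(m)
    shape = np.asarray(lv.shape)
    for off in OFFSETS_13:
        d = np.asarray(off)
        # next voxel along the direction continues the run?
        src, dst = _offset_slices(lv.shape, off)
        nxt_same = np.zeros(lv.shape, dtype=bool)
        nxt_same[src] = m[src] & m[dst] & (lv[src] == lv[dst])
        # run starts: in mask and the predecessor does not continue the run
        prev_ok = np.zeros(lv.shape, dtype=bool)
        prev_ok[dst] = nxt_same[src]
        starts = coords_all[~prev_ok[m]]
        pos = starts.copy()
        length = 1
        while pos.shape[0]:
            cont = nxt_same[pos[:, 0], pos[:, 1], pos[:, 2]]
            ended = pos[~cont]
            if ended.shape[0]:
                levels_ended = lv[ended[:, 0], ended[:, 1], ended[:, 2]]
                np.add.at(counts, (levels_ended - 1, length - 1), 1)
            pos = pos[cont] + d
            length += 1
    return counts


def _run_zone_indices(counts: np.ndarray, prefix_short: str) -> dict[str, float]:
    """Shared emphasis formulas for run-length and zone matrices."""
    n_levels, max_len = counts.shape
    i = np.arange(1, n_levels + 1, dtype=np.float64)[:, None]
    l = np.arange(1, max_len + 1, dtype=np.float64)[None, :]
    r = counts.astype(np.float64)
    N = r.sum()
    if N == 0:
        raise ValueError("empty run/zone matrix")
    out = {}
    out["S_E"] = float((r / l**2).sum() / N)
    out["L_E"] = float((r * l**2).sum() / N)
    out["LG_E"] = float((r / i**2).sum() / N)
    out["HG_E"] = float((r * i**2).sum() / N)
    out["S_LG"] = float((r / (i**2 * l**2)).sum() / N)
    out["S_HG"] = float((r * i**2 / l**2).sum() / N)
    out["L_LG"] = float((r * l**2 / i**2).sum() / N)
    out["L_HG"] = float((r * i**2 * l**2).sum() / N)
    out["GLNU"] = float((r.sum(axis=1) ** 2).sum() / N)
    out["LNU"] = float((r.sum(axis=0) ** 2).sum() / N)
    out["N"] = float(N)
    return out


def glrlm_indices(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 11 run-length indices; RP uses the 13 x n_voxels denominator
    because the matrix aggregates all 13 directions."""
    c = _run_zone_indices(counts, "R")
    return {
        "SRE": c["S_E"], "LRE": c["L_E"], "LGRE": c["LG_E"], "HGRE": c["HG_E"],
        "SRLGE": c["S_LG"], "SRHGE": c["S_HG"], "LRLGE": c["L_LG"],
        "LRHGE": c["L_HG"], "GLNUr": c["GLNU"], "RLNU": c["LNU"],
        "RP": c["N"] / (len(OFFSETS_13) * n_voxels),
    }


@dataclass
class NGLDMResult:
    """Dependence matrix plus the per-level neighborhood summaries used by
    the Amadasun-King style indices.

    ``q[i-1, k]``: voxels of level i with k equal-level in-mask 26-neighbors.
    ``s[i-1]``: summed absolute difference between level i and the mean
    level of each voxel's in-mask neighborhood.
    ``n_i[i-1]``: voxels of level i with at least one in-mask neighbor.
    """

    q: np.ndarray
    s: np.ndarray
    n_i: np.ndarray


def build_ngldm(dvoi: DiscretizedVOI) -> NGLDMResult:
    lv, m = dvoi.levels, dvoi.mask
    n = dvoi.n_levels
    equal = np.zeros(lv.shape, dtype=np.int64)
    nb_sum = np.zeros(lv.shape, dtype=np.float64)
    nb_cnt = np.zeros(lv.shape, dtype=np.int64)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for off in offsets:
        src, dst = _offset_slices(lv.shape, off)
        both = m[src] & m[dst]
        equal[src] += both & (lv[src] == lv[dst])
        nb_sum[src][both] += lv[dst][both]
        nb_cnt[src] += both

    q = np.zeros((n, 27), dtype=np.int64)
    np.add.at(q, (lv[m] - 1, equal[m]), 1)

    has_nb = m & (nb_cnt > 0)
    diff = np.abs(lv[has_nb] - nb_sum[has_nb] / nb_cnt[has_nb])
    s = np.zeros(n, dtype=np.float64)
    np.add.at(s, lv[has_nb] - 1, diff)
    n_i = np.bincount(lv[has_nb] - 1, minlength=n)
    return NGLDMResult(q=q, s=s, n_i=n_i)


def ngldm_indices(ngldm: NGLDMResult) -> dict[str, float]:
    """Coarseness, Contrast and Busyness (Amadasun-King functional forms).

    Busyness is NaN on a single-level VOI (zero denominator); Contrast is 0
    when fewer than two levels are present."""
    n_total = ngldm.n_i.sum()
    if n_total == 0:
        raise ValueError("no voxel has an in-mask neighbor")
    p = ngldm.n_i / n_total
    s = ngldm.s
    i = np.arange(1, p.size + 1, dtype=np.float64)
    present = p > 0
    ng = int(present.sum())

    ps = float((p * s).sum())
    coarseness = 1.0 / (1e-8 + ps)

    if ng < 2:
        contrast = 0.0
    else:
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
        contrast = float(
            (pi * pj * (ii - jj) ** 2).sum() / (ng * (ng - 1)) * (s.sum() / n_total)
        )

    ipi = i[present] * p[present]
    denom = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    busyness = ps / denom if denom > 0 else float("nan")
    return {"Coarseness": coarseness, "Contrast": contrast, "Busyness": busyness}


def build_glzlm(dvoi: DiscretizedVOI) -> np.ndarray:
    """Zone counts ``z[level-1, size-1]``: 26-connected components of
    equal-level voxels within the mask."""
    lv, m = dvoi.levels, dvoi.mask
    n = dvoi.n_levels
    n_vox = int(m.sum())
    counts = np.zeros((n, n_vox), dtype=np.int64)
    for lvl in np.unique(lv[m]):
        comp, n_comp = nd_label(lv == lvl, structure=_STRUCT26)
        sizes = np.bincount(comp.ravel())[1:]
        for sz in sizes:
            counts[lvl - 1, sz - 1] += 1
    return counts


def glzlm_indices(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 11 zone indices; ZP is zones per voxel."""
    c = _run_zone_indices(counts, "Z")
    return {
        "SZE": c["S_E"], "LZE": c["L_E"], "LGZE": c["LG_E"], "HGZE": c["HG_E"],
        "SZLGE": c["S_LG"], "SZHGE": c["S_HG"], "LZLGE": c["L_LG"],
        "LZHGE": c["L_HG"], "GLNUz": c["GLNU"], "ZLNU": c["LNU"],
        "ZP": c["N"] / n_voxels,
    }


@dataclass
class FeatureVector:
    """All 31 textural indices plus SUVmax and MTV for one (patient,
    method, observer) VOI."""

    values: dict[str, float]
    patient: str = ""
    method: str = ""
    observer: str = ""

    def __post_init__(self) -> None:
        missing = [f for f in ALL_FEATURES if f not in self.values]
        if missing:
            raise ValueError(f"feature vector incomplete: missing {missing}")


def extract_features(
    volume: PETVolume,
    mask: VOIMask,
    disc_config: DiscretizationConfig | None = None,
    patient: str = "",
) -> FeatureVector:
    """Full per-VOI feature extraction.

    Raises :class:`IneligibleVOIError` for VOIs below the 64-voxel floor,
    mirroring the exclusion rule of the analysis; requires a single
    26-connected mask (run cluster selection first)."""
    elig = check_min_volume(mask)
    if not elig.eligible:
        raise IneligibleVOIError(
            f"VOI of {elig.n_voxels} voxels is below the {MIN_VOXELS}-voxel "
            f"floor ({elig.min_volume_ml:.2f} ml at this spacing)"
        )
    _, n_comp = nd_label(mask.mask, structure=_STRUCT26)
    if n_comp != 1:
        raise ValueError(f"mask must be one 26-connected component, got {n_comp}")

    dvoi = discretize_absolute(volume, mask, disc_config)
    n_vox = dvoi.n_voxels
    values: dict[str, float] = {}
    values.update(glcm_indices(normalize_glcm(build_glcm(dvoi))))
    values.update(glrlm_indices(build_glrlm(dvoi), n_vox))
    values.update(ngldm_indices(build_ngldm(dvoi)))
    values.update(glzlm_indices(build_glzlm(dvoi), n_vox))
    values["SUVmax"] = float(volume.values[mask.mask].max())
    values["MTV"] = mask.volume_ml
    return FeatureVector(values=values, patient=patient,
                         method=mask.method.value if mask.method else "",
                         observer=mask.observer)
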