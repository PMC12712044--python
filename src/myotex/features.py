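"""MaZda-style 2D texture features on a quantized ROI.

Six families are computed on the ``1..Ng`` level raster of a
:class:`~myotex.quantize.QuantizedRoi`:

* histogram (first-order moments and nearest-rank percentiles),
* absolute gradient (central-difference magnitude on interior pixels),
* run-length matrix (Galloway statistics, four directions),
* gray-level co-occurrence matrix (Haralick statistics at pixel offsets
  2 and 5, four directions),
* causal autoregressive model (four-neighbour least-squares fit),
* one-level orthonormal Haar wavelet subband energies.

Direction-dependent families (RLM, GLCM) are reduced by *feature-level*
averaging over the four lattice directions 0/45/90/135 deg, because the
in-plane rotation of a short-axis acquisition is not anatomically
meaningful.  The result is a fixed 50-feature catalog:
9 histogram + 5 gradient + 5 RLM + 22 GLCM (11 x 2 distances) + 5 AR +
4 wavelet.

All entropies use natural logarithms with the convention 0*log(0) = 0.
Undefined values (degenerate ROIs, empty co-occurrence sets, too few AR
pixels) are carried as NaN, never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .quantize import QuantizedRoi

__all__ = [
    "DIRECTIONS_DEG",
    "GLCM_DISTANCES",
    "NoCooccurrenceError",
    "GlcmMatrix",
    "RlmMatrix",
    "ArFit",
    "histogram_features",
    "gradient_features",
    "glcm",
    "glcm_features",
    "rlm",
    "rlm_features",
    "ar_fit",
    "wavelet_energies",
    "directional_average",
    "extract_all",
    "feature_catalog",
    "CATALOG_NAMES",
]

DIRECTIONS_DEG = (0, 45, 90, 135)
GLCM_DISTANCES = (2, 5)

# (row, col) unit offsets; angles counter-clockwise from +col with row down
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

HISTOGRAM_NAMES = (
    "Mean", "Variance", "Skewness", "Kurtosis",
    "Perc01", "Perc10", "Perc50", "Perc90", "Perc99",
)
GRADIENT_NAMES = ("GrMean", "GrVariance", "GrSkewness", "GrKurtosis", "GrNonZeros")
RLM_NAMES = ("ShrtREmp", "LngREmph", "GLevNonU", "RLNonUni", "Fraction")
GLCM_NAMES = (
    "AngScMom", "Contrast", "Correlat", "SumOfSqs", "InvDfMom",
    "SumAverg", "SumVarnc", "SumEntrp", "Entropy", "DifVarnc", "DifEntrp",
)
AR_NAMES = ("Teta1", "Teta2", "Teta3", "Teta4", "Sigma")
WAVELET_NAMES = ("WavEnLL", "WavEnLH", "WavEnHL", "WavEnHH")


class NoCooccurrenceError(ValueError):
    """No pixel pair exists at the requested offset inside the mask."""


def feature_catalog() -> pd.DataFrame:
    """Machine-readable manifest of the 50-feature catalog."""
    rows = []
    for n in HISTOGRAM_NAMES:
        rows.append((n, "histogram", False, None))
    for n in GRADIENT_NAMES:
        rows.append((n, "gradient", False, None))
    for n in RLM_NAMES:
        rows.append((f"Average_{n}", "rlm", True, None))
    for d in GLCM_DISTANCES:
        for n in GLCM_NAMES:
            rows.append((f"S{d}-Average_{n}", "glcm", True, d))
    for n in AR_NAMES:
        rows.append((n, "ar", False, None))
    for n in WAVELET_NAMES:
        rows.append((n, "wavelet", False, None))
    return pd.DataFrame(
        rows, columns=["name", "family", "direction_dependent", "distance"]
    )


CATALOG_NAMES: tuple[str, ...] = tuple(feature_catalog()["name"])


# ---------------------------------------------------------------------------
# first-order statistics

def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, population variance, skewness, excess kurtosis (NaN if var 0)."""
    x = np.asarray(x, dtype=np.float64)
    m = x.mean()
    c = x - m
    var = float(np.mean(c * c))
    if var == 0.0:
        return float(m), 0.0, np.nan, np.nan
    skew = float(np.mean(c**3) / var**1.5)
    kurt = float(np.mean(c**4) / var**2 - 3.0)
    return float(m), var, skew, kurt


def _nearest_rank(sorted_x: np.ndarray, q: float) -> float:
    n = sorted_x.size
    k = max(1, int(np.ceil(q * n)))
    return float(sorted_x[k - 1])


def histogram_features(q: QuantizedRoi) -> dict[str, float]:
    lev = q.levels
    if lev.size == 0:
        raise ValueError("empty ROI")
    mean, var, skew, kurt = _moments(lev)
    s = np.sort(lev)
    return {
        "Mean": mean,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Perc01": _nearest_rank(s, 0.01),
        "Perc10": _nearest_rank(s, 0.10),
        "Perc50": _nearest_rank(s, 0.50),
        "Perc90": _nearest_rank(s, 0.90),
        "Perc99": _nearest_rank(s, 0.99),
    }


def gradient_features(q: QuantizedRoi) -> dict[str, float]:
    """Moments of the central-difference gradient magnitude.

    g = sqrt((L(x+1,y)-L(x-1,y))^2 + (L(x,y+1)-L(x,y-1))^2) / 2 evaluated
    only where the pixel and its four axial neighbours are all in-mask.
    """
    L = q.levels_raster.astype(np.float64)
    m = q.mask
    valid = np.zeros_like(m)
    valid[1:-1, 1:-1] = (
        m[1:-1, 1:-1] & m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
    )
    if not valid.any():
        return dict.fromkeys(GRADIENT_NAMES, np.nan)
    dcol = np.zeros_like(L)
    drow = np.zeros_like(L)
    dcol[:, 1:-1] = L[:, 2:] - L[:, :-2]
    drow[1:-1, :] = L[2:, :] - L[:-2, :]
    g = np.hypot(dcol, drow)[valid] / 2.0
    mean, var, skew, kurt = _moments(g)
    return {
        "GrMean": mean,
        "GrVariance": var,
        "GrSkewness": skew,
        "GrKurtosis": kurt,
        "GrNonZeros": float(np.mean(g > 0)),
    }


# ---------------------------------------------------------------------------
# co-occurrence

@dataclass(frozen=True)
class GlcmMatrix:
    """Symmetric gray-level co-occurrence table at one (distance, direction)."""

    counts: np.ndarray  # Ng x Ng, both orderings accumulated
    distance: int
    direction_deg: int

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def prob(self) -> np.ndarray:
        tot = self.counts.sum()
        if tot == 0:
            raise NoCooccurrenceError("no co-occurrence at this offset")
        return self.counts / tot


def glcm(q: QuantizedRoi, d: int, direction_deg: int) -> GlcmMatrix:
    if d < 1:
        raise ValueError("distance must be >= 1")
    dr, dc = _OFFSETS[direction_deg]
    dr, dc = dr * d, dc * d
    L = q.levels_raster
    m = q.mask
    H, W = m.shape
    ng = q.n_levels

    r0s, r0e = max(0, -dr), min(H, H - dr)
    c0s, c0e = max(0, -dc), min(W, W - dc)
    counts = np.zeros((ng, ng), dtype=np.int64)
    if r0s < r0e and c0s < c0e:
        a_m = m[r0s:r0e, c0s:c0e]
        b_m = m[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        both = a_m & b_m
        a = L[r0s:r0e, c0s:c0e][both] - 1
        b = L[r0s + dr:r0e + dr, c0s + dc:c0e + dc][both] - 1
        np.add.at(counts, (a, b), 1)
        counts = counts + counts.T  # symmetric: both orderings
    if counts.sum() == 0:
        raise NoCooccurrenceError("no co-occurrence at this offset")
    return GlcmMatrix(counts, d, direction_deg)


def glcm_features(mat: GlcmMatrix) -> dict[str, float]:
    """The 11 Haralick statistics used by MaZda (natural log entropies)."""
    p = mat.prob
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)  # marginal (symmetric, so px == py)
    mu = float(np.sum(i * px))
    sd = float(np.sqrt(np.sum((i - mu) ** 2 * px)))

    # p_{x+y}(k), k = 2..2Ng   and   p_{x-y}(k), k = 0..Ng-1
    psum = np.zeros(2 * ng - 1)
    np.add.at(psum, (ii + jj).astype(np.int64).ravel() - 2, p.ravel())
    pdiff = np.zeros(ng)
    np.add.at(pdiff, np.abs(ii - jj).astype(np.int64).ravel(), p.ravel())
    ksum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    kdiff = np.arange(0, ng, dtype=np.float64)

    def ent(v: np.ndarray) -> float:
        nz = v[v > 0]
        return float(-np.sum(nz * np.log(nz)))

    sum_averg = float(np.sum(ksum * psum))
    dif_mean = float(np.sum(kdiff * pdiff))
    if sd > 0:
        correlat = float((np.sum(ii * jj * p) - mu * mu) / (sd * sd))
    else:
        correlat = np.nan
    return {
        "AngScMom": float(np.sum(p * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlat": correlat,
        "SumOfSqs": float(np.sum((ii - mu) ** 2 * p)),
        "InvDfMom": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "SumAverg": sum_averg,
        "SumVarnc": float(np.sum((ksum - sum_averg) ** 2 * psum)),
        "SumEntrp": ent(psum),
        "Entropy": ent(p.ravel()),
        "DifVarnc": float(np.sum((kdiff - dif_mean) ** 2 * pdiff)),
        "DifEntrp": ent(pdiff),
    }


# ---------------------------------------------------------------------------
# run-length

@dataclass(frozen=True)
class RlmMatrix:
    """Run counts by (gray level, run length) along one lattice direction."""

    counts: np.ndarray  # Ng x max_len; counts[i-1, j-1] = runs of level i, length j
    direction_deg: int
    n_pixels: int  # mask area

    @property
    def total_runs(self) -> int:
        return int(self.counts.sum())


def _mask_lines(m: np.ndarray, direction_deg: int):
    """Index arrays of the lattice lines of the raster along a direction."""
    H, W = m.shape
    if direction_deg == 0:
        for r in range(H):
            yield np.full(W, r), np.arange(W)
    elif direction_deg == 90:
        for c in range(W):
            yield np.arange(H), np.full(H, c)
    elif direction_deg == 135:  # constant col - row: main diagonals
        for off in range(-(H - 1), W):
            n = min(H, W, H + off, W - off)
            r = np.arange(max(0, -off), max(0, -off) + n)
            yield r, r + off
    elif direction_deg == 45:  # constant row + col: anti-diagonals
        for s in range(H + W - 1):
            r_lo, r_hi = max(0, s - W + 1), min(H - 1, s)
            r = np.arange(r_hi, r_lo - 1, -1)
            yield r, s - r
    else:
        raise ValueError("direction must be one of 0/45/90/135")


def rlm(q: QuantizedRoi, direction_deg: int) -> RlmMatrix:
    """Maximal equal-level runs along ``direction_deg``, broken at mask exits."""
    L = q.levels_raster
    m = q.mask
    levels: list[int] = []
    lengths: list[int] = []
    for rr, cc in _mask_lines(m, direction_deg):
        vals = np.where(m[rr, cc], L[rr, cc], 0)  # 0 breaks runs
        if not vals.any():
            continue
        change = np.flatnonzero(np.diff(vals)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [vals.size]))
        keep = vals[starts] > 0
        levels.extend(vals[starts[keep]])
        lengths.extend(ends[keep] - starts[keep])
    if not levels:
        return RlmMatrix(np.zeros((q.n_levels, 1), dtype=np.int64),
                         direction_deg, q.area)
    lev_a = np.asarray(levels)
    len_a = np.asarray(lengths)
    counts = np.zeros((q.n_levels, int(len_a.max())), dtype=np.int64)
    np.add.at(counts, (lev_a - 1, len_a - 1), 1)
    return RlmMatrix(counts, direction_deg, q.area)


def rlm_features(r: RlmMatrix) -> dict[str, float]:
    n = r.counts.astype(np.float64)
    C = n.sum()
    if C == 0:
        return dict.fromkeys(RLM_NAMES, np.nan)
    j = np.arange(1, n.shape[1] + 1, dtype=np.float64)
    covered = float(np.sum(n * j))
    return {
        "ShrtREmp": float(np.sum(n / j**2) / C),
        "LngREmph": float(np.sum(n * j**2) / C),
        "GLevNonU": float(np.sum(n.sum(axis=1) ** 2) / C),
        "RLNonUni": float(np.sum(n.sum(axis=0) ** 2) / C),
        "Fraction": float(C / covered),
    }


# ---------------------------------------------------------------------------
# autoregressive model

@dataclass(frozen=True)
class ArFit:
    """Causal four-neighbour AR fit: theta coefficients and residual SD."""

    teta1: float
    teta2: float
    teta3: float
    teta4: float
    sigma: float
    rank_deficient: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "Teta1": self.teta1, "Teta2": self.teta2,
            "Teta3": self.teta3, "Teta4": self.teta4, "Sigma": self.sigma,
        }


AR_MIN_PIXELS = 20

# causal neighbourhood, (row, col) offsets of L(x-1,y), L(x-1,y-1),
# L(x,y-1), L(x+1,y-1) with x = col, y = row
_AR_OFFSETS = ((0, -1), (-1, -1), (-1, 0), (-1, 1))


def ar_fit(q: QuantizedRoi) -> ArFit:
    """Least-squares fit of the causal AR model on mean-centred levels.

    L(x,y) = t1*L(x-1,y) + t2*L(x-1,y-1) + t3*L(x,y-1) + t4*L(x+1,y-1) + e,
    over pixels whose four causal neighbours are all in-mask; ``sigma`` is
    the RMS residual.
    """
    m = q.mask
    L = q.levels_raster.astype(np.float64)
    Lc = np.where(m, L - q.levels.mean(), 0.0)
    H, W = m.shape

    valid = m.copy()
    cols = []
    for dr, dc in _AR_OFFSETS:
        shifted_m = np.zeros_like(m)
        shifted_L = np.zeros_like(Lc)
        rs, re = max(0, dr), min(H, H + dr)
        cs, ce = max(0, dc), min(W, W + dc)
        shifted_m[rs:re, cs:ce] = m[rs - dr:re - dr, cs - dc:ce - dc]
        shifted_L[rs:re, cs:ce] = Lc[rs - dr:re - dr, cs - dc:ce - dc]
        valid &= shifted_m
        cols.append(shifted_L)
    if valid.sum() < AR_MIN_PIXELS:
        return ArFit(np.nan, np.nan, np.nan, np.nan, np.nan)

    X = np.stack([c[valid] for c in cols], axis=1)
    y = Lc[valid]
    theta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta
    sigma = float(np.sqrt(np.mean(resid**2)))
    return ArFit(*(float(t) for t in theta), sigma, rank_deficient=rank < 4)


# ---------------------------------------------------------------------------
# wavelet

def wavelet_energies(q: QuantizedRoi) -> dict[str, float]:
    """One-level orthonormal Haar subband energies over in-mask 2x2 blocks.

    The mask's bounding box is filled with the masked mean outside the ROI,
    edge-padded to even dimensions, and transformed with the orthonormal
    Haar filter; each subband energy is the mean squared coefficient over
    the 2x2 blocks that lie fully inside the mask.
    """
    m = q.mask
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    if rows.size == 0:
        return dict.fromkeys(WAVELET_NAMES, np.nan)
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    if (r1 - r0) < 4 or (c1 - c0) < 4:
        return dict.fromkeys(WAVELET_NAMES, np.nan)

    sub = q.levels_raster[r0:r1, c0:c1].astype(np.float64)
    subm = m[r0:r1, c0:c1]
    fill = q.levels.mean()
    img = np.where(subm, sub, fill)
    inmask = subm.copy()
    if img.shape[0] % 2:  # edge padding counts as outside the mask
        img = np.vstack([img, img[-1:]])
        inmask = np.vstack([inmask, np.zeros((1, inmask.shape[1]), bool)])
    if img.shape[1] % 2:
        img = np.hstack([img, img[:, -1:]])
        inmask = np.hstack([inmask, np.zeros((inmask.shape[0], 1), bool)])

    # LH = high-pass along columns (horizontal detail), HL = along rows
    ll, (hl, lh, hh) = pywt.dwt2(img, "haar", mode="periodization")
    blocks_in = (
        inmask[0::2, 0::2] & inmask[0::2, 1::2]
        & inmask[1::2, 0::2] & inmask[1::2, 1::2]
    )
    if not blocks_in.any():
        return dict.fromkeys(WAVELET_NAMES, np.nan)
    return {
        "WavEnLL": float(np.mean(ll[blocks_in] ** 2)),
        "WavEnLH": float(np.mean(lh[blocks_in] ** 2)),
        "WavEnHL": float(np.mean(hl[blocks_in] ** 2)),
        "WavEnHH": float(np.mean(hh[blocks_in] ** 2)),
    }


# ---------------------------------------------------------------------------
# directional averaging and full extraction

def directional_average(per_direction: dict[int, float] | list[float]) -> float:
    """Arithmetic mean over the four directions; NaN if any is undefined."""
    vals = (list(per_direction.values())
            if isinstance(per_direction, dict) else list(per_direction))
    if len(vals) != 4:
        raise ValueError("expected exactly 4 direction values")
    vals = np.asarray(vals, dtype=np.float64)
    if np.any(~np.isfinite(vals)):
        return np.nan
    return float(vals.mean())


def extract_all(q: QuantizedRoi) -> pd.Series:
    """The full 50-feature vector of a quantized ROI, in catalog order."""
    out: dict[str, float] = {}
    out.update(histogram_features(q))
    out.update(gradient_features(q))

    for name in RLM_NAMES:
        per_dir = []
        for th in DIRECTIONS_DEG:
            per_dir.append(rlm_features(rlm(q, th))[name])
        out[f"Average_{name}"] = directional_average(per_dir)

    for d in GLCM_DISTANCES:
        per_dir: dict[str, list[float]] = {n: [] for n in GLCM_NAMES}
        for th in DIRECTIONS_DEG:
            try:
                feats = glcm_features(glcm(q, d, th))
            except NoCooccurrenceError:
                feats = dict.fromkeys(GLCM_NAMES, np.nan)
            for n in GLCM_NAMES:
                per_dir[n].append(feats[n])
        for n in GLCM_NAMES:
            out[f"S{d}-Average_{n}"] = directional_average(per_dir[n])

    out.update(ar_fit(q).as_dict())
    out.update(wavelet_energies(q))
    return pd.Series(out, index=list(CATALOG_NAMES), dtype=np.float64)
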