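"""Feature robustness screens: ROI-size invariance and observer repeatability.

Two screens reduce the 50-feature catalog before population analysis:

* **size screen** — Spearman rank correlation of each feature against ROI
  pixel count across a cohort whose ROIs differ only in size; features with
  ``|r| >= r_threshold`` (default 0.80, the conventional "strong
  correlation" boundary) are excluded as ROI-size-dependent.
* **repeatability screen** — duplicate readings by one observer
  (intra-observer) and by two observers (inter-observer) summarised by the
  root-mean-square coefficient of variation; a feature passes if both RMS
  CoV values stay within ``cov_max`` (default 10%) and its cohort relative
  standard deviation stays within ``rsd_max`` (default 30%).

Both statistics are scale-free, so the screens are unaffected by positive
rescaling of any feature.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman",
    "size_screen",
    "rms_cov",
    "rsd",
    "repeatability_screen",
]

R_THRESHOLD_DEFAULT = 0.80
COV_MAX_DEFAULT = 10.0  # percent
RSD_MAX_DEFAULT = 30.0  # percent; the stricter 20% preset is also in use


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties, t-approximation p).

    Returns ``(nan, nan)`` when either variable has zero rank variance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return np.nan, np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def size_screen(
    table: pd.DataFrame,
    areas,
    r_threshold: float = R_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Spearman screen of every feature column against ROI area.

    ``table`` is a wide feature table (one row per subject, one column per
    feature); ``areas`` the matching ROI pixel counts.  Returns one row per
    feature with ``spearman_r``, ``p_value`` and ``excluded`` (:=
    ``|r| >= r_threshold``).  Features with undefined values or zero
    variance cannot be assessed and are retained with a warning.
    """
    areas = np.asarray(areas, dtype=np.float64)
    if len(table) != areas.size:
        raise ValueError("one area per subject required")
    if len(table) < 15:
        raise ValueError("size screen needs >= 15 subjects")
    if areas.max() < 2.0 * areas.min():
        warnings.warn("ROI areas span less than a 2x range", stacklevel=2)

    rows = []
    for name in table.columns:
        vals = table[name].to_numpy(dtype=np.float64)
        if np.any(~np.isfinite(vals)):
            warnings.warn(f"feature {name!r} has undefined values; skipped",
                          stacklevel=2)
            rows.append((name, np.nan, np.nan, False))
            continue
        r, p = spearman(vals, areas)
        if np.isnan(r):
            warnings.warn(f"feature {name!r} is constant; retained",
                          stacklevel=2)
            rows.append((name, np.nan, np.nan, False))
        else:
            rows.append((name, r, p, bool(abs(r) >= r_threshold)))
    rep = pd.DataFrame(rows,
                       columns=["feature", "spearman_r", "p_value", "excluded"])
    return rep.set_index("feature")


def rms_cov(pairs) -> float:
    """Root-mean-square coefficient of variation of duplicate readings, in %.

    Per subject the duplicate-measurement within-subject SD ``|x1-x2|/sqrt(2)``
    is divided by the subject mean; the subject CoVs are pooled as
    ``100 * sqrt(mean(cov_i^2))``.  Subjects with zero mean are excluded
    with a warning.
    """
    pairs = np.asarray(pairs, dtype=np.float64)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be (n_subjects, 2)")
    if pairs.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    means = pairs.mean(axis=1)
    ok = means != 0
    if not ok.all():
        warnings.warn("subjects with zero mean excluded from RMS CoV",
                      stacklevel=2)
    if not ok.any():
        return np.nan
    cov = (np.abs(pairs[ok, 0] - pairs[ok, 1]) / np.sqrt(2.0)) / np.abs(means[ok])
    return float(100.0 * np.sqrt(np.mean(cov**2)))


def rsd(values) -> float:
    """Relative standard deviation of cohort values: 100 * SD / |mean| (%).

    Sample SD (n-1 denominator); undefined (NaN) for a zero mean.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 3:
        raise ValueError("need at least 3 values")
    m = values.mean()
    if m == 0:
        return np.nan
    return float(100.0 * values.std(ddof=1) / abs(m))


def repeatability_screen(
    intra_pairs: pd.DataFrame,
    inter_pairs: pd.DataFrame,
    cov_max: float = COV_MAX_DEFAULT,
    rsd_max: float = RSD_MAX_DEFAULT,
) -> pd.DataFrame:
    """Per-feature repeatability report from intra- and inter-observer pairs.

    Both inputs are indexed by subject with a two-level column index
    ``(feature, reading)`` where reading is 0/1.  RSD is evaluated on the
    first intra-observer reading (the observer's primary measurement).
    Returns one row per feature with ``rms_cov_intra``, ``rms_cov_inter``,
    ``rsd``, ``pass`` and a failure ``reason``.
    """
    feats = list(dict.fromkeys(intra_pairs.columns.get_level_values(0)))
    if set(intra_pairs.index) != set(inter_pairs.index):
        raise ValueError("intra and inter pair sets must cover the same subjects")
    rows = []
    for f in feats:
        a = intra_pairs[f].to_numpy(dtype=np.float64)
        b = inter_pairs[f].to_numpy(dtype=np.float64)
        if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
            rows.append((f, np.nan, np.nan, np.nan, False, "undefined"))
            continue
        ci = rms_cov(a)
        ce = rms_cov(b)
        rv = rsd(a[:, 0])
        checks = [
            (not np.isnan(ci) and ci <= cov_max, "intra RMS CoV"),
            (not np.isnan(ce) and ce <= cov_max, "inter RMS CoV"),
            (not np.isnan(rv) and rv <= rsd_max, "RSD"),
        ]
        failed = [lab for ok, lab in checks if not ok]
        rows.append((f, ci, ce, rv, not failed, ";".join(failed)))
    rep = pd.DataFrame(rows, columns=[
        "feature", "rms_cov_intra", "rms_cov_inter", "rsd", "pass", "reason",
    ])
    return rep.set_index("feature")
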