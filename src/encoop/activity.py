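"""Count normalization and differential flagging.

Counts are turned into "synthesis levels" the way TT-seq pipelines do it:
size-factor normalization (DESeq2's median-of-ratios) followed by division by
unit length in kb. The resulting :class:`ActivityMatrix` is the single
in-memory container every downstream stage consumes.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_SAMPLE_RE = re.compile(r"^(?P<assay>[A-Za-z0-9]+)_(?P<time>[0-9.]+)_(?P<rep>\d+)$")


class NormalizationError(ValueError):
    pass


def parse_design(columns) -> pd.DataFrame:
    """Extract (assay, time_hr, replicate) from ``{assay}_{time}_{rep}`` names."""
    rows = []
    for col in columns:
        m = _SAMPLE_RE.match(col)
        if m is None:
            raise ValueError(f"cannot parse sample column name {col!r}; "
                             "expected '{assay}_{time}_{rep}'")
        rows.append((col, m["assay"], float(m["time"]), int(m["rep"])))
    return pd.DataFrame(rows, columns=["sample", "assay", "time_hr", "replicate"])


@dataclass
class ActivityMatrix:
    """Unit x sample matrix of per-kb, size-factor-normalized synthesis levels.

    Attributes
    ----------
    values : DataFrame, index unit id, one column per sample.
    design : DataFrame with columns sample/assay/time_hr/replicate.
    lengths : Series of unit lengths in bp.
    size_factors : Series of the per-sample factors used.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    lengths: pd.Series
    size_factors: pd.Series

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.design["sample"])
        if missing:
            raise ValueError(f"design does not cover samples: {sorted(missing)}")

    @property
    def time_points(self) -> np.ndarray:
        return np.sort(self.design["time_hr"].unique())

    def replicate_mean(self) -> pd.DataFrame:
        """Collapse replicates: one column per time point (ascending)."""
        groups = self.design.groupby("time_hr")["sample"]
        out = {t: self.values[list(cols)].mean(axis=1) for t, cols in groups}
        return pd.DataFrame(out)[self.time_points]

    def profile(self, unit_id: str) -> np.ndarray:
        """Replicate-mean trajectory of one unit over the time points."""
        if unit_id not in self.values.index:
            raise KeyError(unit_id)
        return self.replicate_mean().loc[unit_id].to_numpy()

    def is_active(self, floor: float = 1.0) -> pd.Series:
        """Transcribed at >= 1 time point: replicate-mean per-kb level above ``floor``."""
        return (self.replicate_mean() > floor).any(axis=1)

    def subset(self, unit_ids) -> "ActivityMatrix":
        return ActivityMatrix(self.values.loc[list(unit_ids)], self.design,
                              self.lengths.loc[list(unit_ids)], self.size_factors)


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq2 median-of-ratios size factors.

    factor_j = median over units of count_uj / geomean_u, restricted to units
    with nonzero counts in every sample.
    """
    arr = counts.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise NormalizationError("no unit has nonzero counts in every sample")
    sub = arr[all_nonzero]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, size_factors: pd.Series,
              lengths: pd.Series, design: pd.DataFrame | None = None) -> ActivityMatrix:
    """Size-factor and length normalization: count / factor / (length in kb)."""
    if (lengths.loc[counts.index] <= 0).any():
        raise ValueError("unit lengths must be positive")
    if (size_factors.loc[counts.columns] <= 0).any():
        raise ValueError("size factors must be positive")
    vals = counts.div(size_factors.loc[counts.columns], axis=1) \
                 .div(lengths.loc[counts.index] / 1000.0, axis=0)
    if design is None:
        design = parse_design(counts.columns)
    return ActivityMatrix(vals, design, lengths.loc[counts.index].astype(float),
                          size_factors.loc[counts.columns].astype(float))


def log2_fold_change(activity: ActivityMatrix, t: float, t0: float = 0.0,
                     pseudocount: float = 1.0) -> pd.Series:
    """log2((mean_t + pc) / (mean_t0 + pc)) on replicate means."""
    rm = activity.replicate_mean()
    for tp in (t, t0):
        if tp not in rm.columns:
            raise ValueError(f"time point {tp} not in design")
    return np.log2((rm[t] + pseudocount) / (rm[t0] + pseudocount))


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def differential_standin(activity: ActivityMatrix, t0: float = 0.0,
                         pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-contrast Welch tests on log2 activities, BH-adjusted per contrast.

    An approximation of the DESeq2 step used only when no external
    differential table is supplied: for each time point t > t0, a two-sample
    Welch t-test of log2(value + pseudocount) across replicates, adjusted over
    units within the contrast. Returns the long table expected by
    :func:`flag_differential`.
    """
    design = activity.design
    t0_cols = design.loc[design["time_hr"] == t0, "sample"]
    logv = np.log2(activity.values + pseudocount)
    frames = []
    for t in activity.time_points:
        if t == t0:
            continue
        t_cols = design.loc[design["time_hr"] == t, "sample"]
        a = logv[list(t_cols)].to_numpy()
        b = logv[list(t0_cols)].to_numpy()
        lfc = a.mean(axis=1) - b.mean(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant rows yield nan p
            _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.where(np.isfinite(p), p, 1.0)
        frames.append(pd.DataFrame({
            "unit_id": activity.values.index,
            "contrast": f"{t}_vs_{t0}",
            "log2fc": lfc,
            "fdr": benjamini_hochberg(p),
        }))
    return pd.concat(frames, ignore_index=True)


def flag_differential(de: pd.DataFrame, unit_ids=None,
                      lfc_thr: float = 1.0, fdr_thr: float = 0.05) -> pd.Series:
    """Differential iff some contrast has |log2fc| > lfc_thr AND fdr < fdr_thr.

    Both inequalities are strict. ``de`` is a long table with columns
    unit_id, contrast, log2fc, fdr.
    """
    need = {"unit_id", "log2fc", "fdr"}
    if not need <= set(de.columns):
        raise ValueError(f"differential table needs columns {sorted(need)}")
    hit = (de["log2fc"].abs() > lfc_thr) & (de["fdr"] < fdr_thr)
    flagged = de.loc[hit, "unit_id"].unique()
    if unit_ids is None:
        unit_ids = de["unit_id"].unique()
    else:
        missing = set(unit_ids) - set(de["unit_id"])
        if missing:
            raise KeyError(f"units absent from differential table: {sorted(missing)[:5]}")
    return pd.Series(np.isin(unit_ids, flagged), index=pd.Index(unit_ids, name="unit_id"),
                     name="is_differential")


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns nan (with a warning) for constant input, where the coefficient is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman needs two equal-length sequences of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("spearman undefined for constant input; returning nan")
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
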