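"""Robustness checks and the occupancy-based superenhancer caller.

These diagnostics probe whether a synergistic classification is an artifact:
cross-pairing-method overlap (Fisher), strongest-enhancer dominance,
dual-target concordance (binomial), global eRNA-signal inflation, and a
ROSE-style stitched superenhancer call to contrast occupancy-defined with
function-defined enhancer classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .activity import ActivityMatrix
from .annotation import Enhancer
from .config import Thresholds
from .intervals import merge_with_gap, min_gap_to_set
from .models import classify_all

log = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency table entries must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact(table: ContingencyTable, side: str = "greater"):
    """Fisher's exact test on a 2x2 table; returns (odds_ratio, p)."""
    if side not in ("greater", "two_sided"):
        raise ValueError("side must be 'greater' or 'two_sided'")
    alt = "greater" if side == "greater" else "two-sided"
    odds, p = stats.fisher_exact(table.as_array(), alternative=alt)
    return float(odds), float(p)


def class_overlap(classes_a: pd.Series, classes_b: pd.Series,
                  class_of_interest: str = "synergistic",
                  side: str = "greater"):
    """2x2 overlap of one class between two classifications of shared genes.

    Returns (table, odds_ratio, p) for the one-sided enrichment test over the
    genes classified by both methods.
    """
    shared = classes_a.index.intersection(classes_b.index)
    if len(shared) == 0:
        raise ValueError("no genes classified by both methods")
    ina = classes_a.loc[shared] == class_of_interest
    inb = classes_b.loc[shared] == class_of_interest
    t = ContingencyTable(int((ina & inb).sum()), int((ina & ~inb).sum()),
                         int((~ina & inb).sum()), int((~ina & ~inb).sum()))
    odds, p = fisher_exact(t, side)
    return t, odds, p


def strongest_fraction(gene_id: str, pairs: pd.DataFrame,
                       activity: ActivityMatrix) -> float:
    """Share of the summed-over-time eRNA signal carried by the strongest enhancer."""
    enh = pairs.loc[pairs["gene_id"] == gene_id, "enhancer_id"].unique()
    if len(enh) == 0:
        raise ValueError(f"gene {gene_id!r} has no paired enhancers")
    totals = activity.replicate_mean().loc[list(enh)].sum(axis=1)
    grand = float(totals.sum())
    if grand <= 0:
        log.warning("gene %s: zero total enhancer activity; dominance undefined", gene_id)
        return float("nan")
    return float(totals.max() / grand)


def dominance_summary(classes: pd.Series, pairs: pd.DataFrame,
                      activity: ActivityMatrix) -> pd.DataFrame:
    """Per-gene strongest-enhancer fraction plus the per-class median."""
    rows = []
    for g, cls in classes.items():
        try:
            frac = strongest_fraction(g, pairs, activity)
        except ValueError:
            continue
        rows.append((g, cls, frac))
    df = pd.DataFrame(rows, columns=["gene_id", "final_class", "strongest_fraction"])
    med = df.groupby("final_class")["strongest_fraction"].median()
    df.attrs["median_by_class"] = med.to_dict()
    return df


def dual_target_concordance(pairs: pd.DataFrame, classes: pd.Series,
                            null_p: Optional[float] = None):
    """Concordance of regulatory mode between the two targets of an enhancer.

    Over enhancers paired with exactly two genes classified additive or
    synergistic, counts those whose targets share a class and tests one-sided
    against a null concordance probability derived from the class marginals
    (sum of squared class frequencies) unless ``null_p`` is given.
    Returns (n_dual, n_concordant, p) — p is None when n_dual = 0.
    """
    keep = classes[classes.isin(["additive", "synergistic"])]
    sub = pairs[pairs["gene_id"].isin(keep.index)]
    per_enh = sub.groupby("enhancer_id")["gene_id"].unique()
    dual = per_enh[per_enh.map(len) == 2]
    n_dual = len(dual)
    if n_dual == 0:
        log.warning("no dual-target enhancers; concordance test undefined")
        return 0, 0, None
    n_conc = int(sum(keep[g1] == keep[g2] for g1, g2 in dual))
    if null_p is None:
        freqs = keep.value_counts(normalize=True).to_numpy()
        null_p = float((freqs ** 2).sum())
    p = stats.binomtest(n_conc, n_dual, null_p, alternative="greater").pvalue
    return n_dual, n_conc, float(p)


def inflation_robustness(pairs: pd.DataFrame, activity: ActivityMatrix,
                         enhancer_ids: Sequence[str], factor: float = 2.0,
                         thresholds: Thresholds | None = None, seed: int = 0,
                         per_enhancer_factors: Optional[pd.Series] = None):
    """Overlap of synergistic gene sets before vs after inflating eRNA signal.

    Multiplies every enhancer's activity by ``factor`` (or by per-enhancer
    factors), reruns the cohort classification, and returns
    |synergistic_before & synergistic_after| / |synergistic_before|
    (None when no gene was synergistic before).
    """
    if factor <= 0:
        raise ValueError("inflation factor must be positive")
    before = classify_all(pairs, activity, thresholds, seed=seed)
    vals = activity.values.copy()
    enh = [e for e in enhancer_ids if e in vals.index]
    if per_enhancer_factors is not None:
        vals.loc[enh] = vals.loc[enh].mul(per_enhancer_factors.loc[enh], axis=0)
    else:
        vals.loc[enh] = vals.loc[enh] * factor
    inflated = ActivityMatrix(vals, activity.design, activity.lengths,
                              activity.size_factors)
    after = classify_all(pairs, inflated, thresholds, seed=seed)
    syn_before = set(before.loc[before["final_class"] == "synergistic", "gene_id"])
    syn_after = set(after.loc[after["final_class"] == "synergistic", "gene_id"])
    if not syn_before:
        log.warning("no synergistic genes before inflation; overlap undefined")
        return None
    return len(syn_before & syn_after) / len(syn_before)


def stitch_regions(peaks: pd.DataFrame, enhancers: Sequence[Enhancer],
                   stitch_dist: int = 12_500,
                   proximity: int = 1000) -> pd.DataFrame:
    """ROSE-style stitching of occupancy peaks near enhancers.

    Keeps peaks within ``proximity`` of any enhancer, single-linkage merges
    them at a ``stitch_dist`` gap, and scores each region with
    sum(peak signals) / sum(peak widths).
    """
    need = {"chrom", "start", "end", "signal"}
    if not need <= set(peaks.columns):
        raise ValueError(f"peaks need columns {sorted(need)}")
    rows = []
    for chrom, sub in peaks.groupby("chrom"):
        echs = [e for e in enhancers if e.chrom == chrom]
        if not echs:
            continue
        es = np.array([e.start for e in echs])
        ee = np.array([e.end for e in echs])
        near = [min_gap_to_set(s, e, es, ee) <= proximity
                for s, e in zip(sub["start"], sub["end"])]
        kept = sub[np.asarray(near, dtype=bool)]
        if not len(kept):
            continue
        m_s, m_e, grp = merge_with_gap(kept["start"], kept["end"], stitch_dist)
        for gi in range(len(m_s)):
            members = kept.iloc[np.flatnonzero(grp == gi)]
            width = (members["end"] - members["start"]).sum()
            rows.append((chrom, int(m_s[gi]), int(m_e[gi]),
                         float(members["signal"].sum()) / float(width),
                         len(members)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "signal", "n_peaks"]) \
             .sort_values(["chrom", "start"]).reset_index(drop=True)


def elbow_cutoff(signals) -> tuple[float, np.ndarray]:
    """Rank-ordered elbow cutoff over width-normalized signals.

    Ascending rank and signal are min-max scaled to [0, 1]; the cutoff is the
    signal at the first rank where the discrete scaled slope exceeds 1;
    regions with signal strictly above the cutoff are flagged. A perfectly
    linear (or constant) curve flags nothing.
    """
    signals = np.asarray(signals, dtype=float)
    if len(signals) < 3:
        raise ValueError("elbow cutoff needs >= 3 regions")
    order = np.argsort(signals, kind="stable")
    s = signals[order]
    if np.ptp(s) == 0:
        log.warning("constant signals: no superenhancers")
        return float(s[0]), np.zeros(len(s), dtype=bool)[np.argsort(order)]
    x = np.arange(len(s)) / (len(s) - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    slope = np.diff(y) / np.diff(x)
    above = np.flatnonzero(slope > 1.0)
    if len(above) == 0:
        cutoff = float(s[-1])  # linear or concave: nothing flagged
    else:
        cutoff = float(s[above[0]])
    flags_sorted = s > cutoff
    flags = np.empty(len(s), dtype=bool)
    flags[order] = flags_sorted
    return cutoff, flags


def call_superenhancers(peaks: pd.DataFrame, enhancers: Sequence[Enhancer],
                        stitch_dist: int = 12_500,
                        proximity: int = 1000) -> pd.DataFrame:
    """Stitch, rank, and flag superenhancers above the elbow cutoff."""
    regions = stitch_regions(peaks, enhancers, stitch_dist, proximity)
    if len(regions) < 3:
        regions["rank"] = np.arange(1, len(regions) + 1)
        regions["is_super"] = False
        regions["cutoff_signal"] = np.nan
        return regions
    cutoff, flags = elbow_cutoff(regions["signal"].to_numpy())
    regions["rank"] = regions["signal"].rank(ascending=False, method="first").astype(int)
    regions["is_super"] = flags
    regions["cutoff_signal"] = cutoff
    return regions
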