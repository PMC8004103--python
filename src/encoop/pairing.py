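"""Enhancer-promoter pairing by the neighboring, 1 Mb window, and TAD methods.

* neighboring — an intragenic enhancer is paired with its host gene; an
  intergenic enhancer with the closest transcribed mRNA on each side; pairs
  whose gene is not differentially synthesized are dropped.
* window — every differential mRNA whose TSS lies within 1 Mb of the
  enhancer is a candidate; the enhancer must itself be differential and the
  Spearman correlation of the two time-course profiles must exceed 0.4.
* tad — as window, but candidates share a topologically associating domain
  with the enhancer instead of a linear window.

Merged enhancers are strandless, so the distance anchor is the enhancer
midpoint by default (configurable to the 5'-most constituent start).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .activity import ActivityMatrix, spearman
from .annotation import Enhancer, TranscriptionUnit
from .config import ConfigError, Thresholds
from .intervals import containing_interval, gap_distance

log = logging.getLogger(__name__)

PAIR_COLUMNS = ["enhancer_id", "gene_id", "method", "relation", "distance_bp", "rho"]


@dataclass
class TADSet:
    """Non-overlapping TAD intervals per chromosome, optionally per time point."""

    intervals: pd.DataFrame          # columns chrom, start, end
    time_hr: Optional[float] = None

    def __post_init__(self):
        df = self.intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, sub in df.groupby("chrom"):
            e = sub["end"].to_numpy()
            s = sub["start"].to_numpy()
            if (s[1:] < e[:-1]).any():
                raise ValueError(f"overlapping TADs on {chrom}")
        self.intervals = df

    def tad_index(self, chrom: str, pos: int) -> int:
        sub = self.intervals[self.intervals["chrom"] == chrom]
        idx = containing_interval(pos, sub["start"].to_numpy(), sub["end"].to_numpy())
        return -1 if idx < 0 else int(sub.index[idx])


def enhancer_anchor(enh: Enhancer, mode: str = "midpoint") -> int:
    if mode == "midpoint":
        return enh.midpoint
    return enh.start  # 5'-most constituent start after the strandless merge


def _gene_tss(gene: TranscriptionUnit) -> int:
    return gene.start if gene.strand == "+" else gene.end - 1


def pair_neighboring(enhancers: Sequence[Enhancer],
                     genes: Sequence[TranscriptionUnit],
                     gene_is_differential: pd.Series,
                     active_genes: Optional[pd.Series] = None) -> pd.DataFrame:
    """Nearest-gene pairing; keeps only pairs with a differential gene.

    ``genes`` should already be mRNAs; ``active_genes`` (boolean per gene id)
    further restricts to genes transcribed at >= 1 time point. "Closest" uses
    the gap between the gene body and the enhancer interval; ties go to the
    smaller gene start.
    """
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.id))
    if active_genes is not None:
        genes = [g for g in genes if bool(active_genes.get(g.id, False))]
    rows = []
    for enh in sorted(enhancers, key=lambda e: (e.chrom, e.start, e.id)):
        chrom_genes = [g for g in genes if g.chrom == enh.chrom]
        host = [g for g in chrom_genes
                if g.start <= enh.midpoint < g.end]
        if host:
            host.sort(key=lambda g: (g.start, g.id))
            rows.append((enh.id, host[0].id, "neighboring", "intragenic", 0))
            continue
        upstream = [g for g in chrom_genes if g.end <= enh.start]
        downstream = [g for g in chrom_genes if g.start >= enh.end]
        if upstream:
            best = min(upstream, key=lambda g: (enh.start - g.end, g.start))
            rows.append((enh.id, best.id, "neighboring", "upstream",
                         gap_distance(enh.start, enh.end, best.start, best.end)))
        if downstream:
            best = min(downstream, key=lambda g: (g.start - enh.end, g.start))
            rows.append((enh.id, best.id, "neighboring", "downstream",
                         gap_distance(enh.start, enh.end, best.start, best.end)))
    df = pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "method",
                                     "relation", "distance_bp"])
    df["rho"] = np.nan
    keep = df["gene_id"].map(lambda g: bool(gene_is_differential.get(g, False)))
    out = df[keep].drop_duplicates(["enhancer_id", "gene_id", "method"])
    return out.sort_values(["enhancer_id", "gene_id"]).reset_index(drop=True)


def pair_correlated(enhancers: Sequence[Enhancer],
                    genes: Sequence[TranscriptionUnit],
                    activity: ActivityMatrix,
                    gene_is_differential: pd.Series,
                    enhancer_is_differential: pd.Series,
                    scope: str = "window",
                    tads: Optional[TADSet] = None,
                    thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Window (1 Mb) or TAD pairing with a Spearman correlation gate.

    Both the gene and the enhancer must be differential, and the correlation
    of their replicate-mean activity profiles must exceed ``rho_min``.
    """
    thr = thresholds or Thresholds()
    if scope not in ("window", "tad"):
        raise ConfigError(f"unknown pairing scope {scope!r}")
    if scope == "tad" and tads is None:
        raise ConfigError("TAD pairing requested without a TADSet")
    rm = activity.replicate_mean()
    rows = []
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.id))
    for enh in sorted(enhancers, key=lambda e: (e.chrom, e.start, e.id)):
        if not bool(enhancer_is_differential.get(enh.id, False)):
            continue
        anchor = enhancer_anchor(enh, thr.enhancer_anchor)
        if scope == "tad":
            enh_tad = tads.tad_index(enh.chrom, anchor)
            if enh_tad < 0:
                continue
        for g in genes:
            if g.chrom != enh.chrom:
                continue
            if not bool(gene_is_differential.get(g.id, False)):
                continue
            tss = _gene_tss(g)
            if scope == "window":
                if abs(tss - anchor) > thr.window_bp:
                    continue
            else:
                if tads.tad_index(g.chrom, tss) != enh_tad:
                    continue
            if enh.id not in rm.index or g.id not in rm.index:
                continue
            rho = spearman(rm.loc[enh.id].to_numpy(), rm.loc[g.id].to_numpy())
            if np.isnan(rho) or rho <= thr.rho_min:
                continue
            rows.append((enh.id, g.id, scope if scope == "tad" else "window",
                         "scoped", abs(tss - anchor), rho))
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return df.sort_values(["enhancer_id", "gene_id"]).reset_index(drop=True)


def same_tad_fraction(pairs: pd.DataFrame,
                      enhancers: Dict[str, Enhancer],
                      genes: Dict[str, TranscriptionUnit],
                      tadsets: Sequence[TADSet]) -> float:
    """Fraction of pairs sharing a TAD (midpoint vs TSS) at >= 1 time point."""
    if not len(tadsets):
        raise ValueError("no TAD sets supplied")
    n_same = 0
    for _, row in pairs.iterrows():
        enh = enhancers[row["enhancer_id"]]
        gene = genes[row["gene_id"]]
        for ts in tadsets:
            ei = ts.tad_index(enh.chrom, enh.midpoint)
            gi = ts.tad_index(gene.chrom, _gene_tss(gene))
            if ei >= 0 and ei == gi and enh.chrom == gene.chrom:
                n_same += 1
                break
    return n_same / len(pairs) if len(pairs) else float("nan")
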