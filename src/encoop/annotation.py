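"""Transcription-unit classification and enhancer calling.

TUs segmented from nascent-RNA coverage are classified into positional RNA
classes against a reference gene annotation:

1. a TU inherits the reference gene type (mRNA, lincRNA, ...) when it covers
   more than 60% of a reference transcript (the best-covered transcript wins);
2. remaining TUs antisense to an mRNA with their 5' end within 1000 bp
   upstream / 500 bp downstream of that mRNA's TSS become uaRNA (body
   upstream of the TSS) or convRNA (body overlapping the TSS from inside the
   gene);
3. remaining same-strand TUs starting within 1 kb downstream of an mRNA 3'
   end (or within 10 kb with positionally decaying signal) become dsRNA;
4. remaining TUs covering more than 20% of any reference gene are discarded;
5. remaining ncRNAs within 1 kb of both an ATAC peak and an H3K4me1 peak at
   any (possibly different) time point become eRNA.

eRNAs within 1 kb of each other are merged strand-agnostically into
enhancers; enhancer activity is the sum of the constituents' per-kb,
size-factor-normalized counts (lengths taken before merging).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .activity import spearman
from .config import Thresholds
from .intervals import gap_distance, merge_with_gap, min_gap_to_set

log = logging.getLogger(__name__)

RNA_CLASSES = ("mRNA", "lincRNA", "dsRNA", "uaRNA", "convRNA", "eRNA",
               "unclassified", "discarded")


@dataclass
class TranscriptionUnit:
    """A stranded genomic interval (0-based half-open) with an RNA class."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    rna_class: str = "unclassified"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"TU {self.id}: start must be < end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"TU {self.id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ReferenceTranscript:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_type: str   # e.g. protein_coding -> mRNA, lincRNA, ...

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class PeakSet:
    """Sorted, within-set-disjoint peak intervals for one mark at one time."""

    mark: str
    time_hr: float
    intervals: pd.DataFrame  # columns chrom, start, end [, signal]

    def __post_init__(self):
        df = self.intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        merged = []
        for chrom, sub in df.groupby("chrom", sort=True):
            s, e, _ = merge_with_gap(sub["start"], sub["end"], max_gap=-1)
            part = pd.DataFrame({"chrom": chrom, "start": s, "end": e})
            if "signal" in df.columns and len(s) == len(sub):
                part["signal"] = sub["signal"].to_numpy()
            merged.append(part)
        self.intervals = pd.concat(merged, ignore_index=True) if merged else df


@dataclass
class Enhancer:
    """A strandless merged interval of >= 1 eRNA TUs."""

    id: str
    chrom: str
    start: int
    end: int
    constituent_tu_ids: List[str] = field(default_factory=list)
    activity: Optional[pd.Series] = None   # per-sample summed per-kb levels

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


def _overlap_len(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


_GENCODE_TO_CLASS = {"protein_coding": "mRNA", "lincRNA": "lincRNA"}


def assign_gencode_class(tu: TranscriptionUnit,
                         reference: Sequence[ReferenceTranscript],
                         min_frac: float = 0.60,
                         relative_to: str = "reference") -> Optional[str]:
    """Reference gene type of the best-covered transcript, if coverage > 60%.

    The fraction is overlap / reference-transcript length by default
    (``relative_to='tu'`` divides by the TU length instead); the transcript
    with the maximal fraction wins ties between gene types.
    """
    best_frac, best_type = min_frac, None
    for ref in reference:
        if ref.chrom != tu.chrom:
            continue
        ov = _overlap_len(tu.start, tu.end, ref.start, ref.end)
        if ov == 0:
            continue
        denom = ref.length if relative_to == "reference" else tu.length
        frac = ov / denom
        if frac > best_frac:
            best_frac = frac
            best_type = _GENCODE_TO_CLASS.get(ref.gene_type, ref.gene_type)
    return best_type


def classify_positional(tu: TranscriptionUnit,
                        mrnas: Sequence[TranscriptionUnit],
                        thresholds: Thresholds | None = None,
                        signal_fn=None) -> Optional[str]:
    """uaRNA / convRNA / dsRNA by position relative to classified mRNAs.

    ``signal_fn(tu) -> 1-D array`` supplies positional signal (5'->3') for the
    10 kb decaying-downstream-RNA rule; without it only the 1 kb rule applies.
    """
    thr = thresholds or Thresholds()
    for m in mrnas:
        if m.chrom != tu.chrom:
            continue
        if tu.strand in "+-" and m.strand in "+-" and tu.strand != m.strand:
            tss = m.start if m.strand == "+" else m.end - 1
            if m.strand == "+":
                lo, hi = tss - thr.ua_upstream_bp, tss + thr.ua_downstream_bp
                body_upstream = tu.midpoint < tss
            else:
                lo, hi = tss - thr.ua_downstream_bp, tss + thr.ua_upstream_bp
                body_upstream = tu.midpoint > tss
            if lo <= tu.five_prime <= hi:
                return "uaRNA" if body_upstream else "convRNA"
    for m in mrnas:
        if m.chrom != tu.chrom or tu.strand != m.strand or m.strand not in "+-":
            continue
        # gap from the mRNA 3' end to the TU, on the downstream side only
        if m.strand == "+":
            downstream = tu.start - m.end
        else:
            downstream = m.start - tu.end
        if 0 <= downstream <= thr.dsrna_near_bp:
            return "dsRNA"
        if thr.dsrna_near_bp < downstream <= thr.dsrna_far_bp and signal_fn is not None:
            sig = np.asarray(signal_fn(tu), dtype=float)
            nb = min(10, len(sig))
            bins = np.array_split(sig, nb)
            means = np.array([b.mean() for b in bins])
            if np.ptp(means) > 0:
                rho = spearman(np.arange(nb), means)
                if rho <= thr.dsrna_decay_rho:
                    return "dsRNA"
    return None


def discard_overlapping(tus: Sequence[TranscriptionUnit],
                        reference: Sequence[ReferenceTranscript],
                        max_frac: float = 0.20,
                        relative_to: str = "reference") -> None:
    """Mark still-unclassified TUs covering > 20% of a reference gene as discarded."""
    for tu in tus:
        if tu.rna_class != "unclassified":
            continue
        for ref in reference:
            if ref.chrom != tu.chrom:
                continue
            ov = _overlap_len(tu.start, tu.end, ref.start, ref.end)
            denom = ref.length if relative_to == "reference" else tu.length
            if ov / denom > max_frac:
                tu.rna_class = "discarded"
                break


def _near_any_peakset(tu: TranscriptionUnit, peaksets: Sequence[PeakSet],
                      max_dist: int) -> bool:
    for ps in peaksets:
        sub = ps.intervals[ps.intervals["chrom"] == tu.chrom]
        if len(sub) == 0:
            continue
        d = min_gap_to_set(tu.start, tu.end, sub["start"].to_numpy(),
                           sub["end"].to_numpy())
        if d <= max_dist:
            return True
    return False


def call_eRNAs(tus: Sequence[TranscriptionUnit], atac: Sequence[PeakSet],
               h3k4me1: Sequence[PeakSet], max_dist: int = 1000) -> List[TranscriptionUnit]:
    """Label retained unclassified ncRNAs as eRNA.

    A TU is an eRNA iff it lies within ``max_dist`` of an ATAC peak AND of an
    H3K4me1 peak, each condition satisfiable at any (possibly different) time
    point; distance 0 for overlap.
    """
    if not atac or not h3k4me1:
        log.warning("empty peak sets: no eRNAs can be called")
    called = []
    for tu in tus:
        if tu.rna_class != "unclassified":
            continue
        if (_near_any_peakset(tu, atac, max_dist)
                and _near_any_peakset(tu, h3k4me1, max_dist)):
            tu.rna_class = "eRNA"
            called.append(tu)
    return called


def classify_tus(tus: Sequence[TranscriptionUnit],
                 reference: Sequence[ReferenceTranscript],
                 atac: Sequence[PeakSet], h3k4me1: Sequence[PeakSet],
                 thresholds: Thresholds | None = None,
                 signal_fn=None) -> List[TranscriptionUnit]:
    """Full classification pass, in precedence order (see module docstring)."""
    thr = thresholds or Thresholds()
    for tu in tus:
        cls = assign_gencode_class(tu, reference, thr.gencode_overlap_frac,
                                   thr.overlap_relative_to)
        if cls is not None:
            tu.rna_class = cls
    mrnas = [t for t in tus if t.rna_class == "mRNA"]
    for tu in tus:
        if tu.rna_class != "unclassified":
            continue
        cls = classify_positional(tu, mrnas, thr, signal_fn)
        if cls is not None:
            tu.rna_class = cls
    discard_overlapping(tus, reference, thr.discard_overlap_frac,
                        thr.overlap_relative_to)
    call_eRNAs(tus, atac, h3k4me1, thr.erna_proximity)
    counts = pd.Series([t.rna_class for t in tus]).value_counts().to_dict()
    log.info("classified %d TUs: %s", len(tus), counts)
    return list(tus)


def merge_eRNAs(ernas: Sequence[TranscriptionUnit],
                merge_dist: int = 1000) -> List[Enhancer]:
    """Single-linkage, strand-agnostic merge of eRNAs with gap <= merge_dist."""
    enhancers: List[Enhancer] = []
    ernas = [t for t in ernas if t.rna_class == "eRNA"]
    by_chrom: dict = {}
    for tu in ernas:
        by_chrom.setdefault(tu.chrom, []).append(tu)
    for chrom in sorted(by_chrom):
        group_tus = by_chrom[chrom]
        starts = [t.start for t in group_tus]
        ends = [t.end for t in group_tus]
        m_starts, m_ends, grp = merge_with_gap(starts, ends, merge_dist)
        for gi in range(len(m_starts)):
            members = [group_tus[i] for i in np.flatnonzero(grp == gi)]
            enhancers.append(Enhancer(
                id=f"ENH_{chrom}_{m_starts[gi]}",
                chrom=chrom, start=int(m_starts[gi]), end=int(m_ends[gi]),
                constituent_tu_ids=sorted(t.id for t in members)))
    return enhancers


def enhancer_activity(enhancer: Enhancer, counts: pd.DataFrame,
                      size_factors: pd.Series,
                      tu_lengths: pd.Series) -> pd.Series:
    """Per-sample activity: sum over constituents of (count / size factor) / kb.

    Constituent lengths are the pre-merge eRNA TU lengths.
    """
    missing = [t for t in enhancer.constituent_tu_ids if t not in counts.index]
    if missing:
        raise KeyError(f"constituent TUs absent from counts: {missing}")
    sub = counts.loc[enhancer.constituent_tu_ids]
    norm = sub.div(size_factors.loc[sub.columns], axis=1) \
              .div(tu_lengths.loc[enhancer.constituent_tu_ids] / 1000.0, axis=0)
    act = norm.sum(axis=0)
    act.name = enhancer.id
    return act


def enhancer_activity_matrix(enhancers: Sequence[Enhancer], counts: pd.DataFrame,
                             size_factors: pd.Series, tu_lengths: pd.Series,
                             design: pd.DataFrame) -> "pd.DataFrame":
    """Stack per-enhancer activities into an enhancer x sample table."""
    rows = [enhancer_activity(e, counts, size_factors, tu_lengths)
            for e in enhancers]
    for e, r in zip(enhancers, rows):
        e.activity = r
    return pd.DataFrame(rows)
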