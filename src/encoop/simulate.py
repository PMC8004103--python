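"""Synthetic transdifferentiation fixtures with known regulatory ground truth.

The generator emulates the processed structure of a nascent-RNA time course:
stranded single-exon transcription units on a small genome, time-stamped
ATAC/H3K4me1 peak sets, TADs tiling each chromosome, and negative-binomially
sampled count tables whose promoter trajectories follow a known additive,
exponential, or logistic function of the summed activity of the gene's
enhancers. Enhancer time profiles are logistic-in-time ramps (up or down)
parameterized by onset hour and ramp width, sampled at the seven time points
of the time course; replicate noise is multiplicative log-normal.

Layout: each chromosome is split into equal gene territories; the gene sits
mid-territory with its enhancers placed intragenically or in the flanks,
closer to it than to any neighbor, and territory edges double as TAD
boundaries — so every ground-truth link is recoverable by the neighboring,
1 Mb, and TAD pairing methods alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .activity import ActivityMatrix, parse_design
from .annotation import Enhancer, PeakSet, ReferenceTranscript, TranscriptionUnit
from .config import ConfigError
from .models import predict
from .pairing import TADSet

log = logging.getLogger(__name__)

DEFAULT_TIME_POINTS = (0.0, 12.0, 24.0, 30.0, 36.0, 72.0, 96.0)


class CapacityError(ValueError):
    """Requested features do not fit on the configured genome."""


@dataclass
class SimConfig:
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 60
    n_enhancers: int = 200
    time_points_hr: Sequence[float] = DEFAULT_TIME_POINTS
    n_replicates: int = 2
    class_mix: Dict[str, float] = field(default_factory=lambda: {
        "additive": 1 / 3, "exponential": 1 / 3, "logistic": 1 / 3})
    noise_cv: float = 0.1
    nb_dispersion: float = 0.05
    read_depth: float = 20.0   # expected reads per unit of per-kb activity
    seed: int = 0
    # plumbing knobs
    background_per_gene: int = 3   # stable lincRNA-class TUs anchoring size factors
    n_decoys: int = 20
    decoy_single_mark_frac: float = 0.5
    enhancers_per_gene_min: int = 2
    enhancers_per_gene_max: int = 6
    split_frac: float = 0.2            # enhancers emitting two eRNA TUs
    frac_intragenic: float = 0.2
    frac_down_genes: float = 0.3       # genes whose enhancers ramp down

    def __post_init__(self):
        self.time_points_hr = tuple(float(t) for t in self.time_points_hr)
        if any(b - a <= 0 for a, b in zip(self.time_points_hr,
                                          self.time_points_hr[1:])):
            raise ConfigError("time_points_hr must be strictly increasing")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("class_mix must sum to 1")
        unknown = set(self.class_mix) - {"additive", "exponential", "logistic"}
        if unknown:
            raise ConfigError(f"unknown generating models: {sorted(unknown)}")
        for name in ("n_chromosomes", "chrom_length", "n_genes", "n_replicates"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_enhancers < 0 or self.noise_cv < 0 or self.nb_dispersion < 0:
            raise ConfigError("n_enhancers, noise_cv, nb_dispersion must be >= 0")
        if not (1 <= self.enhancers_per_gene_min <= self.enhancers_per_gene_max):
            raise ConfigError("invalid enhancers-per-gene range")


@dataclass
class Annotation:
    """Generated genome annotation plus regulatory layout."""

    chrom_sizes: Dict[str, int]
    genes: List[TranscriptionUnit]          # rna_class left unclassified
    reference: List[ReferenceTranscript]    # matching GENCODE-like transcripts
    enhancers: List[Enhancer]               # true enhancer loci w/ constituent TUs
    erna_tus: List[TranscriptionUnit]       # constituent eRNA TUs
    decoy_tus: List[TranscriptionUnit]
    background_tus: List[TranscriptionUnit]  # stably transcribed lincRNAs
    tads: TADSet
    enhancer_target: Dict[str, str]         # enhancer id -> gene id

    @property
    def all_tus(self) -> List[TranscriptionUnit]:
        return (list(self.genes) + list(self.erna_tus)
                + list(self.decoy_tus) + list(self.background_tus))

    @property
    def truth_pairs(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e, g) for e, g in sorted(self.enhancer_target.items())],
            columns=["enhancer_id", "gene_id"])


def _territories(config: SimConfig):
    """(chrom, start, end) per gene, tiling each chromosome."""
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    out = []
    for ci, n in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        if n == 0:
            continue
        width = config.chrom_length // n
        if width < 60_000:
            raise CapacityError(
                f"{n} genes on a {config.chrom_length} bp chromosome leave "
                f"{width} bp territories; need >= 60 kb each")
        for gi in range(n):
            end = config.chrom_length if gi == n - 1 else (gi + 1) * width
            out.append((chrom, gi * width, end))
    return out


def _enhancer_counts(config: SimConfig, rng) -> np.ndarray:
    lo, hi = config.enhancers_per_gene_min, config.enhancers_per_gene_max
    base = lo * config.n_genes
    if config.n_enhancers < base:
        raise ConfigError(
            f"n_enhancers={config.n_enhancers} cannot give every gene "
            f">= {lo} enhancers")
    if config.n_enhancers > hi * config.n_genes:
        raise ConfigError("n_enhancers exceeds the per-gene maximum capacity")
    counts = np.full(config.n_genes, lo)
    extra = config.n_enhancers - base
    while extra > 0:
        open_genes = np.flatnonzero(counts < hi)
        pick = rng.choice(open_genes)
        counts[pick] += 1
        extra -= 1
    return counts


def gen_annotation(config: SimConfig) -> Annotation:
    """Deterministic genome layout: genes, enhancer loci, decoys, TADs."""
    rng = np.random.default_rng(config.seed)
    terr = _territories(config)
    chrom_sizes = {f"chr{i + 1}": config.chrom_length
                   for i in range(config.n_chromosomes)}
    counts = _enhancer_counts(config, rng) if config.n_enhancers else \
        np.zeros(config.n_genes, dtype=int)

    genes, reference, enhancers, erna_tus, decoys = [], [], [], [], []
    background: List[TranscriptionUnit] = []
    enhancer_target: Dict[str, str] = {}
    tad_rows = []
    decoy_quota = np.zeros(config.n_genes, dtype=int)
    if config.n_decoys:
        for i in rng.choice(config.n_genes, size=config.n_decoys, replace=True):
            decoy_quota[i] += 1

    eid = did = 0
    for gi, (chrom, t_start, t_end) in enumerate(terr):
        tad_rows.append((chrom, t_start, t_end))
        width = t_end - t_start
        # genes are >= 12 kb so a 2 kb intragenic eRNA TU stays under the 20%
        # discard-filter overlap fraction
        gene_len = int(rng.integers(12_000, 24_000))
        center = t_start + width // 2 + int(rng.integers(-width // 10, width // 10))
        g_start = max(t_start + 5_000, center - gene_len // 2)
        g_end = g_start + gene_len
        if g_end > t_end - 5_000:
            g_end = t_end - 5_000
            g_start = g_end - gene_len
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"GENE_{gi:04d}"
        genes.append(TranscriptionUnit(gene_id, chrom, g_start, g_end, strand))
        reference.append(ReferenceTranscript(f"REF_{gi:04d}", chrom, g_start,
                                             g_end, strand, "protein_coding"))

        # candidate slots for regulatory loci: intragenic core + both flanks,
        # >= 2.5 kb from gene ends, >= 3 kb from TAD edges, 5 kb apart so that
        # loci never cross-merge and peaks of one locus stay > 1 kb from the
        # TUs of any other
        slots = []
        core_lo, core_hi = g_start + 2_500, g_end - 2_500
        for pos in range(core_lo, core_hi - 2_000, 5_000):
            slots.append(("intragenic", pos))
        left_lo, left_hi = t_start + 3_000, g_start - 3_000
        for pos in range(left_hi - 2_000, left_lo, -5_000):
            slots.append(("left", pos))
        right_lo, right_hi = g_end + 3_000, t_end - 3_000
        for pos in range(right_lo, right_hi - 2_000, 5_000):
            slots.append(("right", pos))
        n_needed = counts[gi] + decoy_quota[gi] + config.background_per_gene
        intr = [s for s in slots if s[0] == "intragenic"]
        flank = [s for s in slots if s[0] != "intragenic"]
        # interleave flanks by distance so loci stay closer to their own gene
        flank.sort(key=lambda s: abs(s[1] - (g_start + g_end) // 2))
        n_intr = min(len(intr), int(round(config.frac_intragenic * counts[gi])))
        chosen = ([intr[i] for i in
                   rng.choice(len(intr), size=n_intr, replace=False)]
                  if n_intr else [])
        chosen += flank[:n_needed - len(chosen)]
        if len(chosen) < n_needed:
            raise CapacityError(
                f"territory of {gene_id} ({width} bp) cannot host "
                f"{n_needed} regulatory loci")
        for k in range(counts[gi]):
            kind, pos = chosen[k]
            locus_len = int(rng.integers(800, 2_000))
            enh_id = f"ENH_{eid:04d}"
            split = rng.random() < config.split_frac and locus_len >= 1_200
            tu_ids = []
            if split:
                gap = int(rng.integers(100, 500))
                l1 = (locus_len - gap) // 2
                for j, (s, e) in enumerate([(pos, pos + l1),
                                            (pos + l1 + gap, pos + locus_len)]):
                    tu = TranscriptionUnit(f"eTU_{eid:04d}_{j}", chrom, s, e,
                                           "+" if rng.random() < 0.5 else "-")
                    erna_tus.append(tu)
                    tu_ids.append(tu.id)
            else:
                tu = TranscriptionUnit(f"eTU_{eid:04d}_0", chrom, pos,
                                       pos + locus_len,
                                       "+" if rng.random() < 0.5 else "-")
                erna_tus.append(tu)
                tu_ids.append(tu.id)
            enhancers.append(Enhancer(enh_id, chrom, pos, pos + locus_len,
                                      constituent_tu_ids=tu_ids))
            enhancer_target[enh_id] = gene_id
            eid += 1
        for k in range(counts[gi], counts[gi] + decoy_quota[gi]):
            kind, pos = chosen[k]
            locus_len = int(rng.integers(800, 1_500))
            decoys.append(TranscriptionUnit(f"DECOY_{did:04d}", chrom, pos,
                                            pos + locus_len,
                                            "+" if rng.random() < 0.5 else "-"))
            did += 1
        for k in range(counts[gi] + decoy_quota[gi], n_needed):
            kind, pos = chosen[k]
            locus_len = int(rng.integers(1_000, 2_000))
            bg_id = f"BG_{len(background):04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            background.append(TranscriptionUnit(bg_id, chrom, pos,
                                                pos + locus_len, strand))
            # matching reference entry so the TU classifies as lincRNA and
            # stays out of mRNA pairing while anchoring size factors
            reference.append(ReferenceTranscript(f"REF_{bg_id}", chrom, pos,
                                                 pos + locus_len, strand,
                                                 "lincRNA"))

    tads = TADSet(pd.DataFrame(tad_rows, columns=["chrom", "start", "end"]))
    return Annotation(chrom_sizes, genes, reference, enhancers, erna_tus,
                      decoys, background, tads, enhancer_target)


@dataclass
class GroundTruth:
    genes: pd.DataFrame       # gene_id, true_class, alpha, beta, delta, direction, paired ids
    enhancers: pd.DataFrame   # enhancer_id, target, base, amplitude, onset_hr, width_hr, direction

    def __post_init__(self):
        valid = set(self.enhancers["enhancer_id"])
        for ids in self.genes["paired_enhancer_ids"]:
            if not set(ids.split(",")) <= valid:
                raise ValueError("ground truth names unknown enhancer ids")
        logi = self.genes[self.genes["true_class"] == "logistic"]
        if (logi["delta"] <= 0).any():
            raise ValueError("logistic genes must have delta > 0")


def _ramp(t, base, amp, onset, width, direction):
    sig = 1.0 / (1.0 + np.exp(-(t - onset) / width))
    return base + amp * (sig if direction == "up" else 1.0 - sig)


def gen_activities(annotation: Annotation, config: SimConfig):
    """Per-sample activities (per-kb synthesis) plus the generating truth.

    Noiseless promoter trajectories are the gene's true model applied to the
    summed noiseless enhancer activities; log-normal multiplicative noise with
    sd = noise_cv x value is applied independently per replicate sample.
    """
    rng = np.random.default_rng(config.seed + 1)
    t = np.asarray(config.time_points_hr)
    by_gene: Dict[str, List[str]] = {}
    for e, g in annotation.enhancer_target.items():
        by_gene.setdefault(g, []).append(e)

    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    enh_rows, gene_rows = [], []
    noiseless: Dict[str, np.ndarray] = {}
    for gene in annotation.genes:
        gid = gene.id
        direction = "down" if rng.random() < config.frac_down_genes else "up"
        true_class = rng.choice(classes, p=probs) if len(classes) else "additive"
        S = np.zeros_like(t)
        for e in sorted(by_gene.get(gid, [])):
            # kinetics keep every enhancer > 2-fold induced (or repressed)
            # across the course, i.e. differential by construction
            base = rng.uniform(0.5, 2.0)
            amp = rng.uniform(10.0, 40.0)
            onset = rng.uniform(15.0, 60.0)
            width = rng.uniform(8.0, 20.0)
            a = _ramp(t, base, amp, onset, width, direction)
            noiseless[e] = a
            S += a
            enh_rows.append((e, gid, base, amp, onset, width, direction))
        smin, smax = float(S.min()), float(S.max())
        spread = max(smax - smin, 1e-9)
        delta = np.nan
        if true_class == "additive":
            alpha, beta = rng.uniform(1.0, 3.0), rng.uniform(0.0, 10.0)
            theta = (alpha, beta)
        elif true_class == "exponential":
            alpha = rng.uniform(2.0, 3.5) / spread
            beta = float(np.log(rng.uniform(50.0, 200.0)) - alpha * smax)
            theta = (alpha, beta)
        else:
            delta = rng.uniform(50.0, 200.0)
            alpha = rng.uniform(6.0, 10.0) / spread
            beta = -alpha * (smin + 0.5 * spread)
            theta = (alpha, beta, delta)
        noiseless[gid] = np.asarray(predict(true_class, theta, S))
        gene_rows.append((gid, true_class, alpha, beta, delta, direction,
                          ",".join(sorted(by_gene.get(gid, [])))))

    for tu in annotation.decoy_tus:   # weak, flat background transcription
        base = rng.uniform(0.5, 3.0)
        noiseless[tu.id] = np.full_like(t, base) * rng.uniform(0.8, 1.2, size=len(t))
    for tu in annotation.background_tus:  # stable lincRNA-class transcription
        base = rng.uniform(3.0, 15.0)
        noiseless[tu.id] = np.full_like(t, base)

    samples = [f"TTseq_{tp:g}_{r + 1}" for tp in t
               for r in range(config.n_replicates)]
    units = sorted(noiseless)
    values = np.empty((len(units), len(samples)))
    sigma = config.noise_cv
    for i, u in enumerate(units):
        clean = np.repeat(noiseless[u], config.n_replicates)
        if sigma > 0:
            noise = rng.normal(-0.5 * sigma ** 2, sigma, size=len(clean))
            values[i] = clean * np.exp(noise)
        else:
            values[i] = clean

    lengths = {}
    for gene in annotation.genes:
        lengths[gene.id] = gene.length
    for enh in annotation.enhancers:
        lengths[enh.id] = enh.length
    for tu in annotation.decoy_tus:
        lengths[tu.id] = tu.length
    for tu in annotation.background_tus:
        lengths[tu.id] = tu.length
    design = parse_design(samples)
    activity = ActivityMatrix(
        pd.DataFrame(values, index=pd.Index(units, name="unit_id"),
                     columns=samples),
        design,
        pd.Series({u: lengths[u] for u in units}, name="length"),
        pd.Series(1.0, index=pd.Index(samples), name="size_factor"))
    truth = GroundTruth(
        pd.DataFrame(gene_rows, columns=["gene_id", "true_class", "alpha",
                                         "beta", "delta", "direction",
                                         "paired_enhancer_ids"]),
        pd.DataFrame(enh_rows, columns=["enhancer_id", "target_gene", "base",
                                        "amplitude", "onset_hr", "width_hr",
                                        "direction"]))
    noiseless_df = pd.DataFrame({u: noiseless[u] for u in units}, index=t).T
    noiseless_df.index.name = "unit_id"
    activity.values.attrs["noiseless"] = noiseless_df
    return activity, truth


def gen_counts(activity: ActivityMatrix, annotation: Annotation,
               config: SimConfig):
    """Integer counts per TU: NB(mean = activity x kb x size factor x depth).

    ``read_depth`` emulates sequencing depth (reads per unit of per-kb
    activity); at depth 1 the expected count is exactly activity x length(kb)
    x size factor. Enhancer-level activity is distributed over constituent
    eRNA TUs (equal per-kb shares) so the downstream merge-and-normalize path
    can be tested end to end. Returns (counts, true per-sample size factors).
    """
    if (activity.values.to_numpy() < 0).any():
        raise ValueError("activities must be nonnegative")
    rng = np.random.default_rng(config.seed + 2)
    samples = list(activity.values.columns)
    size_factors = pd.Series(
        np.exp(rng.normal(0.0, 0.25, size=len(samples))),
        index=pd.Index(samples), name="size_factor")

    rows, index = [], []
    constituents: Dict[str, List[TranscriptionUnit]] = {}
    tu_by_id = {tu.id: tu for tu in annotation.erna_tus}
    for enh in annotation.enhancers:
        constituents[enh.id] = [tu_by_id[t] for t in enh.constituent_tu_ids]

    def sample_counts(mean):
        mean = np.maximum(mean, 0.0)
        if config.nb_dispersion == 0:
            return rng.poisson(mean)
        d = config.nb_dispersion
        n = 1.0 / d
        p = n / (n + np.where(mean > 0, mean, 1.0))
        out = rng.negative_binomial(n, p)
        return np.where(mean > 0, out, 0)

    depth = config.read_depth
    for gene in annotation.genes:
        mean = (activity.values.loc[gene.id].to_numpy()
                * (gene.length / 1000.0) * size_factors.to_numpy() * depth)
        rows.append(sample_counts(mean))
        index.append(gene.id)
    for enh in annotation.enhancers:
        act = activity.values.loc[enh.id].to_numpy()
        parts = constituents[enh.id]
        share = act / len(parts)          # per-kb activity split equally
        for tu in parts:
            mean = share * (tu.length / 1000.0) * size_factors.to_numpy() * depth
            rows.append(sample_counts(mean))
            index.append(tu.id)
    for tu in list(annotation.decoy_tus) + list(annotation.background_tus):
        mean = (activity.values.loc[tu.id].to_numpy()
                * (tu.length / 1000.0) * size_factors.to_numpy() * depth)
        rows.append(sample_counts(mean))
        index.append(tu.id)
    counts = pd.DataFrame(np.vstack(rows),
                          index=pd.Index(index, name="unit_id"),
                          columns=samples).astype(np.int64)
    return counts, size_factors


def gen_peaks(annotation: Annotation, config: SimConfig):
    """ATAC and H3K4me1 peak sets per time point.

    Every true enhancer locus gets both marks within 1 kb at >= 1 time point;
    a configurable fraction of decoy loci gets exactly one mark, the rest
    none, so no decoy can satisfy the two-mark eRNA predicate.
    """
    if not annotation.enhancers and not annotation.decoy_tus:
        log.warning("annotation has no regulatory loci; peak sets empty")
    rng = np.random.default_rng(config.seed + 3)
    times = list(config.time_points_hr)
    peaks: Dict[str, Dict[float, List[tuple]]] = {
        "ATAC": {tp: [] for tp in times},
        "H3K4me1": {tp: [] for tp in times}}

    def add_peak(mark, tp, chrom, lo, hi):
        off = int(rng.integers(-400, 400))
        half = int(rng.integers(200, 400))
        mid = (lo + hi) // 2 + off
        peaks[mark][tp].append((chrom, max(0, mid - half), mid + half))

    for enh in annotation.enhancers:
        for mark in ("ATAC", "H3K4me1"):
            k = int(rng.integers(1, 4))
            for tp in rng.choice(times, size=k, replace=False):
                add_peak(mark, float(tp), enh.chrom, enh.start, enh.end)
    for tu in annotation.decoy_tus:
        if rng.random() < config.decoy_single_mark_frac:
            mark = "ATAC" if rng.random() < 0.5 else "H3K4me1"
            add_peak(mark, float(rng.choice(times)), tu.chrom, tu.start, tu.end)

    out = {}
    for mark, per_time in peaks.items():
        sets = []
        for tp in times:
            df = pd.DataFrame(per_time[tp], columns=["chrom", "start", "end"])
            sets.append(PeakSet(mark, tp, df))
        out[mark] = sets
    return out


@dataclass
class Simulation:
    """Everything one synthetic study provides, in memory."""

    config: SimConfig
    annotation: Annotation
    activity: ActivityMatrix
    truth: GroundTruth
    counts: pd.DataFrame
    size_factors: pd.Series
    peaks: Dict[str, List[PeakSet]]

    @property
    def truth_pairs(self) -> pd.DataFrame:
        return self.annotation.truth_pairs

    def truth_differential(self, lfc: float = 1.0,
                           pseudocount: float = 1.0) -> pd.DataFrame:
        """Ground-truth differential table (synthetic stand-in for DESeq2 output).

        log2 fold changes come from the noiseless trajectories; units whose
        true |log2FC| from 0 hr exceeds ``lfc`` at some time point get a
        near-zero FDR, all others 0.5.
        """
        clean: pd.DataFrame = self.activity.values.attrs["noiseless"]
        t0 = clean.columns[0]
        rows = []
        constituents = {e.id: e.constituent_tu_ids
                        for e in self.annotation.enhancers}
        for t in clean.columns[1:]:
            lfc_t = np.log2((clean[t] + pseudocount) / (clean[t0] + pseudocount))
            for unit, v in lfc_t.items():
                fdr = 1e-6 if abs(v) > lfc else 0.5
                rows.append((unit, f"{t:g}_vs_{t0:g}", float(v), fdr))
                # constituent eRNA TUs share their enhancer's trajectory
                for tu_id in constituents.get(unit, ()):
                    rows.append((tu_id, f"{t:g}_vs_{t0:g}", float(v), fdr))
        return pd.DataFrame(rows, columns=["unit_id", "contrast", "log2fc", "fdr"])


def simulate(config: SimConfig | None = None) -> Simulation:
    """Full fixture generation; bit-reproducible under a fixed seed."""
    config = config or SimConfig()
    annotation = gen_annotation(config)
    activity, truth = gen_activities(annotation, config)
    counts, size_factors = gen_counts(activity, annotation, config)
    peaks = gen_peaks(annotation, config)
    return Simulation(config, annotation, activity, truth, counts,
                      size_factors, peaks)
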