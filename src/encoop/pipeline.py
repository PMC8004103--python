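"""End-to-end orchestration: classify -> merge -> normalize -> pair -> fit -> diagnose."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import annotation as ann
from . import diagnostics as diag
from . import io as eio
from .activity import (ActivityMatrix, compute_size_factors, differential_standin,
                       flag_differential, normalize)
from .config import ConfigError, PipelineConfig
from .models import classify_all
from .pairing import TADSet, pair_correlated, pair_neighboring, same_tad_fraction

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    """Everything a run produced, plus where it was written."""

    tus: List[ann.TranscriptionUnit]
    enhancers: List[ann.Enhancer]
    activity: ActivityMatrix
    differential: pd.Series
    pairs: Dict[str, pd.DataFrame]
    classifications: Dict[str, pd.DataFrame]
    diagnostics: Dict[str, object] = field(default_factory=dict)
    out_dir: Optional[str] = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on the files named in ``config``; write all tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds

    def stage(name, fn):
        try:
            result = fn()
        except (ConfigError, StageError):
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc
        return result

    config.require("tus", "reference", "counts")
    if "tad" in config.pairing_methods:
        config.require("tads")

    def load():
        tus = eio.read_tus(config.tus)
        reference = eio.read_gtf(config.reference)
        counts, design = eio.read_count_table(config.counts)
        atac = [eio.read_peaks(p, "ATAC", i) for i, p in
                enumerate(config.peaks_atac)]
        h3k4 = [eio.read_peaks(p, "H3K4me1", i) for i, p in
                enumerate(config.peaks_h3k4me1)]
        tads = eio.read_tads(config.tads) if config.tads else None
        return tus, reference, counts, design, atac, h3k4, tads

    tus, reference, counts, design, atac, h3k4, tads = stage("load", load)
    log.info("loaded %d TUs, %d reference transcripts, %d x %d counts",
             len(tus), len(reference), *counts.shape)

    def classify_stage():
        ann.classify_tus(tus, reference, atac, h3k4, thr)
        eio.write_tus(tus, out / "classified_tus.bed")
        return ann.merge_eRNAs([t for t in tus if t.rna_class == "eRNA"],
                               thr.merge_dist)

    enhancers = stage("classify", classify_stage)
    log.info("merged %d eRNAs into %d enhancers",
             sum(t.rna_class == "eRNA" for t in tus), len(enhancers))

    def normalize_stage():
        factors = compute_size_factors(counts)
        tu_lengths = pd.Series({t.id: t.length for t in tus})
        gene_like = [t for t in tus if t.rna_class not in ("eRNA", "discarded")]
        gene_counts = counts.loc[[t.id for t in gene_like
                                  if t.id in counts.index]]
        act = normalize(gene_counts, factors,
                        tu_lengths.loc[gene_counts.index], design)
        enh_vals = ann.enhancer_activity_matrix(enhancers, counts, factors,
                                                tu_lengths, design)
        enh_lengths = pd.Series({e.id: e.length for e in enhancers})
        full = ActivityMatrix(pd.concat([act.values, enh_vals]), design,
                              pd.concat([act.lengths, enh_lengths.astype(float)]),
                              factors)
        eio.write_enhancers(enhancers, out / "enhancers.bed",
                            out / "enhancer_activity.tsv")
        return full

    activity = stage("normalize", normalize_stage)

    def differential_stage():
        if config.de_table:
            de = eio.read_de_table(config.de_table)
        else:
            log.info("no differential table supplied; using Welch/BH stand-in")
            de = differential_standin(activity, pseudocount=thr.pseudocount)
        units = activity.values.index
        known = set(de["unit_id"].unique())
        flags = flag_differential(de, [u for u in units if u in known],
                                  thr.lfc, thr.fdr)
        flags = flags.reindex(units, fill_value=False)
        # a merged enhancer is differential if any constituent eRNA TU is
        tu_flags = flag_differential(de, sorted(known), thr.lfc, thr.fdr)
        for e in enhancers:
            if not flags.get(e.id, False):
                flags.loc[e.id] = any(bool(tu_flags.get(t, False))
                                      for t in e.constituent_tu_ids)
        return flags

    differential = stage("differential", differential_stage)
    log.info("%d of %d units differential", int(differential.sum()),
             len(differential))

    genes = [t for t in tus if t.rna_class == "mRNA"]
    active = activity.is_active(thr.activity_floor)
    pairs: Dict[str, pd.DataFrame] = {}

    def pairing_stage():
        for method in config.pairing_methods:
            if method == "neighboring":
                p = pair_neighboring(enhancers, genes, differential, active)
            else:
                p = pair_correlated(
                    enhancers, genes, activity, differential, differential,
                    scope="window" if method == "window" else "tad",
                    tads=tads, thresholds=thr)
            pairs[method] = p
            p.to_csv(out / f"pairs_{method}.tsv", sep="\t", index=False)
            log.info("%s pairing: %d pairs, %d genes, %d enhancers", method,
                     len(p), p["gene_id"].nunique(), p["enhancer_id"].nunique())
        return pairs

    stage("pairing", pairing_stage)

    classifications: Dict[str, pd.DataFrame] = {}

    def fit_stage():
        for method, p in pairs.items():
            cls = classify_all(p, activity, thr, seed=config.seed)
            classifications[method] = cls
            cls.to_csv(out / f"classifications_{method}.tsv", sep="\t",
                       index=False)
            if len(cls):
                log.info("%s cooperation classes: %s", method,
                         cls["final_class"].value_counts().to_dict())
        return classifications

    stage("fit", fit_stage)

    def diagnostics_stage():
        res: Dict[str, object] = {}
        enh_map = {e.id: e for e in enhancers}
        gene_map = {g.id: g for g in genes}
        if tads is not None and pairs:
            method = next(iter(pairs))
            if len(pairs[method]):
                res["same_tad_fraction"] = same_tad_fraction(
                    pairs[method], enh_map, gene_map, [tads])
        primary = config.pairing_methods[0]
        cls = classifications.get(primary, pd.DataFrame())
        if len(cls):
            classes = cls.set_index("gene_id")["final_class"]
            dom = diag.dominance_summary(classes, pairs[primary], activity)
            dom.to_csv(out / "dominance.tsv", sep="\t", index=False)
            res["dominance_median_by_class"] = dom.attrs["median_by_class"]
            n_dual, n_conc, p = diag.dual_target_concordance(
                pairs[primary], classes, thr.concordance_null)
            res["concordance"] = {"n_dual": n_dual, "n_concordant": n_conc,
                                  "p": p}
            pd.DataFrame([res["concordance"]]).to_csv(
                out / "concordance.tsv", sep="\t", index=False)
        second = [m for m in config.pairing_methods[1:]
                  if len(classifications.get(m, []))]
        if len(cls) and second:
            a = cls.set_index("gene_id")["final_class"]
            overlap_rows = []
            for m in second:
                b = classifications[m].set_index("gene_id")["final_class"]
                try:
                    t, odds, pv = diag.class_overlap(a, b, "synergistic")
                except ValueError:
                    continue
                overlap_rows.append((primary, m, t.a, t.b, t.c, t.d, odds, pv))
            if overlap_rows:
                ov = pd.DataFrame(overlap_rows, columns=[
                    "method_a", "method_b", "both", "a_only", "b_only",
                    "neither", "odds_ratio", "p"])
                ov.to_csv(out / "overlap_tables.tsv", sep="\t", index=False)
                res["overlap"] = ov
        return res

    diagnostics = stage("diagnostics", diagnostics_stage)

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(config.manifest(), fh, indent=2, sort_keys=True)
    return PipelineResult(tus, enhancers, activity, differential, pairs,
                          classifications, diagnostics, str(out))
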