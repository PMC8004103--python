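"""Readers and writers for the plain-text formats the pipeline speaks.

BED is parsed as 0-based half-open, GTF as 1-based inclusive and converted to
the internal half-open convention at the boundary. Count tables are TSV with
a ``unit_id`` index column and one column per sample named
``{assay}_{time}_{rep}``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .activity import parse_design
from .annotation import Enhancer, PeakSet, ReferenceTranscript, TranscriptionUnit
from .pairing import TADSet


class ParseError(ValueError):
    pass


def read_bed(path) -> pd.DataFrame:
    """BED(3-6) -> DataFrame chrom/start/end/name/score/strand (0-based half-open)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{ln}: BED needs >= 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
            if end <= start:
                raise ParseError(f"{path}:{ln}: end <= start")
            rows.append((f[0], start, end,
                         f[3] if len(f) > 3 else f"{f[0]}:{start}-{end}",
                         f[4] if len(f) > 4 else "0",
                         f[5] if len(f) > 5 else "."))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


def read_tus(path) -> List[TranscriptionUnit]:
    df = read_bed(path)
    return [TranscriptionUnit(r["name"], r["chrom"], r["start"], r["end"],
                              r["strand"],
                              rna_class=str(r["score"]) if str(r["score"]) in
                              ("mRNA", "lincRNA", "dsRNA", "uaRNA", "convRNA",
                               "eRNA", "discarded") else "unclassified")
            for _, r in df.iterrows()]


def write_tus(tus: Sequence[TranscriptionUnit], path) -> None:
    """BED6 with the RNA class carried in the score column."""
    with open(path, "w") as fh:
        for tu in sorted(tus, key=lambda t: (t.chrom, t.start, t.id)):
            fh.write(f"{tu.chrom}\t{tu.start}\t{tu.end}\t{tu.id}\t"
                     f"{tu.rna_class}\t{tu.strand}\n")


def _parse_gtf_attrs(field: str) -> Dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path) -> List[ReferenceTranscript]:
    """Minimal GTF reader: gene/transcript features with gene_id and gene_type."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}:{ln}: GTF needs 9 columns")
            try:
                start, end = int(f[3]), int(f[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
            if end < start:
                raise ParseError(f"{path}:{ln}: end < start")
            attrs = _parse_gtf_attrs(f[8])
            out.append(ReferenceTranscript(
                attrs.get("gene_id", f"line{ln}"), f[0],
                start - 1, end, f[6],          # 1-based inclusive -> half-open
                attrs.get("gene_type", "unknown")))
    return out


def write_gtf(reference: Sequence[ReferenceTranscript], path,
              source: str = "encoop") -> None:
    with open(path, "w") as fh:
        for ref in sorted(reference, key=lambda r: (r.chrom, r.start, r.id)):
            attrs = f'gene_id "{ref.id}"; gene_type "{ref.gene_type}";'
            fh.write(f"{ref.chrom}\t{source}\tgene\t{ref.start + 1}\t{ref.end}"
                     f"\t.\t{ref.strand}\t.\t{attrs}\n")


def read_peaks(path, mark: str, time_hr: float) -> PeakSet:
    df = read_bed(path)
    cols = df[["chrom", "start", "end"]].copy()
    score = pd.to_numeric(df["score"], errors="coerce")
    if score.notna().all():
        cols["signal"] = score
    return PeakSet(mark, time_hr, cols)


def write_peaks(ps: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for i, r in ps.intervals.iterrows():
            sig = r["signal"] if "signal" in ps.intervals.columns else 0
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t"
                     f"{ps.mark}_{ps.time_hr:g}_{i}\t{sig}\t.\n")


def read_tads(path, time_hr=None) -> TADSet:
    df = read_bed(path)
    return TADSet(df[["chrom", "start", "end"]], time_hr=time_hr)


def write_tads(tads: TADSet, path) -> None:
    with open(path, "w") as fh:
        for i, r in tads.intervals.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\tTAD_{i}\t0\t.\n")


def read_count_table(path):
    """TSV -> (counts DataFrame, design DataFrame). Validates cells and names."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated unit id {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ParseError(f"{path}: non-numeric value in column {col!r}")
        if (vals < 0).any():
            raise ParseError(f"{path}: negative count in column {col!r}")
        df[col] = vals.astype(np.int64)
    design = parse_design(df.columns)
    df.index.name = "unit_id"
    return df, design


def write_count_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="unit_id")


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"unit_id", "contrast", "log2fc", "fdr"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: differential table needs columns {sorted(need)}")
    return df


def write_enhancers(enhancers: Sequence[Enhancer], bed_path,
                    activity_path=None) -> None:
    """BED4 of merged enhancers, plus an optional per-sample activity TSV."""
    with open(bed_path, "w") as fh:
        for e in sorted(enhancers, key=lambda x: (x.chrom, x.start)):
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.id}\n")
    if activity_path is not None:
        rows = {e.id: e.activity for e in enhancers if e.activity is not None}
        pd.DataFrame(rows).T.to_csv(activity_path, sep="\t",
                                    index_label="enhancer_id")


def write_simulation(sim, out_dir) -> Dict[str, str]:
    """Write a full synthetic fixture; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_gtf(sim.annotation.reference, out / "genes.gtf")
    paths["reference"] = str(out / "genes.gtf")
    write_tus(sim.annotation.all_tus, out / "tus.bed")
    paths["tus"] = str(out / "tus.bed")
    with open(out / "enhancer_loci.bed", "w") as fh:
        for e in sim.annotation.enhancers:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.id}\n")
    paths["enhancer_loci"] = str(out / "enhancer_loci.bed")
    write_tads(sim.annotation.tads, out / "tads.bed")
    paths["tads"] = str(out / "tads.bed")
    for mark, sets in sim.peaks.items():
        for ps in sets:
            p = out / f"peaks_{mark}_{ps.time_hr:g}.bed"
            write_peaks(ps, p)
            paths[f"peaks_{mark}_{ps.time_hr:g}"] = str(p)
    write_count_table(sim.counts, out / "counts.tsv")
    paths["counts"] = str(out / "counts.tsv")
    sim.truth.genes.to_csv(out / "truth.tsv", sep="\t", index=False)
    paths["truth"] = str(out / "truth.tsv")
    sim.activity.design.to_csv(out / "design.tsv", sep="\t", index=False)
    paths["design"] = str(out / "design.tsv")
    sim.truth_differential().to_csv(out / "de.tsv", sep="\t", index=False)
    paths["de"] = str(out / "de.tsv")
    return paths
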