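"""Readers and writers for the standard formats the pipeline touches.

All in-memory coordinates are 0-based half-open.  Conversions to and from
1-based closed conventions (GFF3) happen only inside the readers/writers in
this module; everything downstream can do interval arithmetic without ±1
bookkeeping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

logger = logging.getLogger(__name__)

PFM_PSEUDOCOUNT = 0.25  # per-cell pseudocount when normalizing count matrices

ALPHABET = "ACGT"


class FormatError(ValueError):
    """Raised on malformed input files; carries the offending line number."""


@dataclass(frozen=True)
class Summit:
    """Single-base ChIP summit (point of maximal read pileup) for one replicate."""

    chrom: str
    pos: int
    replicate: str
    score: float | None = None

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"summit position must be >= 0, got {self.pos}")


@dataclass
class Gene:
    """One gene model with a single representative transcript.

    ``tx_start``/``tx_end`` bound the transcript, ``exons`` are sorted
    non-overlapping intervals within it, and ``cds_start``/``cds_end`` bound
    the coding region inside the exon union.  UTRs and introns are derived,
    never stored.
    """

    id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be + or -, got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.id}: tx_start must be < tx_end")
        prev_end = self.tx_start
        first = True
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.id}: empty exon [{s},{e})")
            if s < (self.tx_start if first else prev_end) or e > self.tx_end:
                raise ValueError(
                    f"{self.id}: exon [{s},{e}) outside gene bounds or overlapping"
                )
            prev_end = e
            first = False
        if not (self.cds_start < self.cds_end):
            raise ValueError(f"{self.id}: cds_start must be < cds_end")
        # CDS bounds must be exonic (the CDS interval may span introns; its
        # exonic pieces are what code for protein)
        if not (
            self._point_in_exons(self.cds_start)
            and self._point_in_exons(self.cds_end - 1)
        ):
            raise ValueError(f"{self.id}: CDS bounds not within exons")

    def _point_in_exons(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    # -- derived structure -------------------------------------------------

    @property
    def tss(self) -> int:
        """Transcription start site as a base position (strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tse(self) -> int:
        """Transcriptional end as a base position (strand-aware)."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 < s2:
                out.append((e1, s2))
        return out

    def _utr_intervals(self, five_prime: bool) -> list[tuple[int, int]]:
        # exonic sequence outside the CDS, split at the CDS into the 5' and
        # 3' sides according to strand
        left, right = [], []
        for s, e in self.exons:
            ls, le = s, min(e, self.cds_start)
            if ls < le:
                left.append((ls, le))
            rs, re = max(s, self.cds_end), e
            if rs < re:
                right.append((rs, re))
        if self.strand == "+":
            return left if five_prime else right
        return right if five_prime else left

    def five_prime_utrs(self) -> list[tuple[int, int]]:
        return self._utr_intervals(five_prime=True)

    def three_prime_utrs(self) -> list[tuple[int, int]]:
        return self._utr_intervals(five_prime=False)

    def coding_exon_intervals(self) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                out.append((cs, ce))
        return out


@dataclass
class GenomeAnnotation:
    """Gene models plus chromosome lengths, keyed by gene id."""

    genes: dict[str, Gene] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def add(self, gene: Gene) -> None:
        if gene.id in self.genes:
            raise ValueError(f"duplicate gene id {gene.id}")
        self.genes[gene.id] = gene

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes.values() if g.chrom == chrom]

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path: str, chrom_lengths: dict[str, int] | None = None) -> GenomeAnnotation:
    """Parse a GFF3 file into a :class:`GenomeAnnotation`.

    GFF3 columns 4-5 are 1-based closed and are converted to 0-based
    half-open here.  If a gene carries several mRNAs the first one wins (a
    log message records the choice).  Chromosome lengths are taken from
    ``##sequence-region`` pragmas unless supplied explicitly.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    ann = GenomeAnnotation(chrom_lengths=dict(chrom_lengths or {}))
    if not ann.chrom_lengths:
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, chrom, start, end = line.split()[:4]
                    ann.chrom_lengths[chrom] = int(end)
                elif not line.startswith("#"):
                    break
    for gene_feat in db.features_of_type("gene"):
        mrnas = list(db.children(gene_feat, featuretype="mRNA", order_by="start"))
        if not mrnas:
            raise FormatError(f"gene {gene_feat.id} has no mRNA child")
        if len(mrnas) > 1:
            logger.info(
                "gene %s has %d mRNAs; using the first (%s)",
                gene_feat.id, len(mrnas), mrnas[0].id,
            )
        mrna = mrnas[0]
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted(
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="CDS")
        )
        if not exons or not cds:
            raise FormatError(f"gene {gene_feat.id}: missing exon or CDS features")
        gene = Gene(
            id=gene_feat.id,
            chrom=gene_feat.seqid,
            strand=gene_feat.strand,
            tx_start=mrna.start - 1,
            tx_end=mrna.end,
            exons=exons,
            cds_start=cds[0][0],
            cds_end=cds[-1][1],
        )
        ann.add(gene)
    return ann


def write_gff3(ann: GenomeAnnotation, path: str) -> None:
    """Write the annotation as GFF3 (inverse of :func:`read_gff3`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(ann.chrom_lengths):
            fh.write(f"##sequence-region {chrom} 1 {ann.chrom_lengths[chrom]}\n")
        for g in sorted(ann.genes.values(), key=lambda g: (g.chrom, g.tx_start)):

            def row(ftype, s, e, fid, parent=None):
                attrs = f"ID={fid}" + (f";Parent={parent}" if parent else "")
                return (
                    f"{g.chrom}\t.\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )

            fh.write(row("gene", g.tx_start, g.tx_end, g.id))
            mrna_id = f"{g.id}.1"
            fh.write(row("mRNA", g.tx_start, g.tx_end, mrna_id, g.id))
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(row("exon", s, e, f"{mrna_id}.exon{i}", mrna_id))
            for i, (s, e) in enumerate(g.coding_exon_intervals(), 1):
                fh.write(row("CDS", s, e, f"{mrna_id}.cds{i}", mrna_id))


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED3+ file (0-based half-open) into a DataFrame.

    Columns: chrom, start, end, then name/score/strand when present.
    """
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype={0: str}
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names[:3])
    df.columns = names[: df.shape[1]]
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise FormatError(f"{path}: end <= start at line {bad[0] + 1}")
    return df


def write_bed(intervals: pd.DataFrame | Iterable, path: str) -> None:
    """Write intervals as BED (tab-separated, 0-based half-open, no header)."""
    if not isinstance(intervals, pd.DataFrame):
        intervals = pd.DataFrame(
            intervals, columns=["chrom", "start", "end", "name", "score", "strand"][: len(next(iter(intervals)))]
        )
    intervals.to_csv(path, sep="\t", header=False, index=False)


def read_summits_bed(path: str, replicate: str | None = None) -> list[Summit]:
    """Read point summits from BED; the summit is the interval midpoint.

    The replicate label defaults to the BED name column, falling back to the
    given ``replicate`` argument.
    """
    df = read_bed(path)
    out = []
    for i, row in df.iterrows():
        rep = str(row["name"]) if "name" in df.columns else replicate
        if rep is None:
            raise FormatError(f"{path}: line {i + 1} lacks a replicate name")
        pos = int((row["start"] + row["end"]) // 2)
        score = float(row["score"]) if "score" in df.columns else None
        out.append(Summit(str(row["chrom"]), pos, rep, score))
    return out


def write_summits_bed(summits: Sequence[Summit], path: str) -> None:
    rows = [
        (s.chrom, s.pos, s.pos + 1, s.replicate, s.score if s.score is not None else 0)
        for s in summits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# JASPAR position frequency matrices
# ---------------------------------------------------------------------------


def read_pfm(path: str, pseudocount: float = PFM_PSEUDOCOUNT) -> list["PWM"]:
    """Read a JASPAR-style PFM library into normalized :class:`PWM` records.

    Counts are normalized per column after adding ``pseudocount`` to each
    cell, which keeps log-odds finite for columns with zero counts.  The
    second header token (the JASPAR "name" slot) is used as the family
    label.  An empty file yields an empty list with a warning.
    """
    from .motifs import PWM  # local import to avoid a cycle

    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        warnings.warn(f"{path}: empty PFM file", stacklevel=2)
        return []
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for rec in records:
        counts = np.array([rec.counts[base] for base in ALPHABET], dtype=float).T
        if (counts < 0).any():
            raise FormatError(f"{path}: negative counts in motif {rec.matrix_id}")
        freqs = counts + pseudocount
        freqs /= freqs.sum(axis=1, keepdims=True)
        out.append(
            PWM(
                id=rec.matrix_id or rec.name,
                family=rec.name or "unknown",
                freqs=freqs,
            )
        )
    return out


def write_pfm(pwms: Sequence["PWM"], path: str, scale: int = 100) -> None:
    """Write PWMs as JASPAR-format count matrices (frequencies x ``scale``)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.id} {p.family}\n")
            for j, base in enumerate(ALPHABET):
                vals = " ".join(f"{v * scale:.2f}" for v in p.freqs[:, j])
                fh.write(f"{base}  [ {vals} ]\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    """Load a whole FASTA into memory (genomes here are small)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True, build_index=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}
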