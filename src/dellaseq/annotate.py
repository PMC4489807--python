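"""Assignment of binding sites to genes and genomic-location breakdown.

A gene is called bound when a site's anchor (the mean summit) lies within
``upstream_window`` bp upstream of its TSS or ``downstream_window`` bp
downstream of its transcriptional end with no intervening gene in between,
or when the anchor falls inside one of the gene's UTRs or introns.  One site
can annotate at most two genes, and then only on opposing strands.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io import Gene, GenomeAnnotation
from .merging import BindingSite

logger = logging.getLogger(__name__)

CATEGORIES = ("upstream", "downstream", "five_prime_UTR", "three_prime_UTR", "intron")


@dataclass(frozen=True)
class AnnotationParams:
    """Promoter and downstream search windows (bp)."""

    upstream_window: int = 2500
    downstream_window: int = 500

    def __post_init__(self):
        if self.upstream_window < 0 or self.downstream_window < 0:
            raise ValueError("windows must be >= 0")


@dataclass(frozen=True)
class PeakGeneAssignment:
    site_id: str
    gene_id: str | None
    category: str | None
    signed_distance_to_tss: int | None


def _signed_tss_distance(anchor: int, gene: Gene) -> int:
    """Distance from anchor to TSS in transcription direction (negative =
    upstream of the TSS)."""
    return anchor - gene.tss if gene.strand == "+" else gene.tss - anchor


def _downstream_distance(anchor: int, gene: Gene) -> int:
    """Distance past the transcriptional end in transcription direction."""
    return anchor - gene.tse if gene.strand == "+" else gene.tse - anchor


def _point_in(anchor: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(s <= anchor < e for s, e in intervals)


def classify_location(anchor: int, gene: Gene, params: AnnotationParams) -> str | None:
    """Category of ``anchor`` relative to one gene, or None if ineligible.

    Structural membership (UTR/intron) takes precedence over the distance
    windows; anchors in coding exons are ineligible for this gene.
    """
    if gene.tx_start <= anchor < gene.tx_end:
        if _point_in(anchor, gene.five_prime_utrs()):
            return "five_prime_UTR"
        if _point_in(anchor, gene.three_prime_utrs()):
            return "three_prime_UTR"
        if _point_in(anchor, gene.introns()):
            return "intron"
        return None  # coding exon
    d_tss = _signed_tss_distance(anchor, gene)
    if -params.upstream_window <= d_tss < 0:
        return "upstream"
    if 0 < _downstream_distance(anchor, gene) <= params.downstream_window:
        return "downstream"
    return None


def _blocked_by_intervening(
    anchor: int, endpoint: int, gene: Gene, genes_sorted: list[Gene], starts: list[int]
) -> bool:
    """True if any other gene's transcript body overlaps the open span
    between the anchor and the endpoint (TSS or TSE)."""
    lo, hi = min(anchor, endpoint), max(anchor, endpoint)
    # bases strictly between anchor and endpoint: [lo+1, hi)
    span_s, span_e = lo + 1, hi
    if span_s >= span_e:
        return False
    i = bisect_left(starts, span_e)
    for other in genes_sorted[:i]:
        if other.id != gene.id and other.tx_end > span_s and other.tx_start < span_e:
            return True
    return False


def assign_sites_to_genes(
    sites: Sequence[BindingSite],
    annotation: GenomeAnnotation,
    params: AnnotationParams = AnnotationParams(),
) -> list[PeakGeneAssignment]:
    """Assign each binding site to at most one gene per strand.

    Structural (UTR/intron) eligibility needs no intervening-gene check;
    upstream/downstream assignments are blocked when another gene's body
    intersects the span between the anchor and the TSS/TSE.  Among eligible
    genes on one strand the nearest wins (absolute TSS distance for window
    assignments, distance 0 for structural ones); distance ties go to the
    lexicographically smaller gene id, which is logged.  Sites with no
    eligible gene are reported with ``gene_id=None``.
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in annotation.genes.values():
        by_chrom.setdefault(g.chrom, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: g.tx_start)
    starts_by_chrom = {c: [g.tx_start for g in gs] for c, gs in by_chrom.items()}

    out: list[PeakGeneAssignment] = []
    for site in sites:
        anchor = site.mean_summit
        genes_sorted = by_chrom.get(site.chrom, [])
        starts = starts_by_chrom.get(site.chrom, [])
        best: dict[str, tuple[int, str, Gene, str]] = {}  # strand -> (dist, id, gene, cat)
        for gene in genes_sorted:
            cat = classify_location(anchor, gene, params)
            if cat is None:
                continue
            if cat == "upstream":
                if _blocked_by_intervening(anchor, gene.tss, gene, genes_sorted, starts):
                    continue
                dist = abs(_signed_tss_distance(anchor, gene))
            elif cat == "downstream":
                if _blocked_by_intervening(anchor, gene.tse, gene, genes_sorted, starts):
                    continue
                dist = abs(_downstream_distance(anchor, gene))
            else:
                dist = 0
            key = (dist, gene.id)
            if gene.strand not in best or key < (best[gene.strand][0], best[gene.strand][1]):
                if gene.strand in best and dist == best[gene.strand][0]:
                    logger.info(
                        "site %s: tie at distance %d between %s and %s; "
                        "smaller id wins", site.site_id, dist, gene.id,
                        best[gene.strand][1],
                    )
                best[gene.strand] = (dist, gene.id, gene, cat)
        if not best:
            out.append(PeakGeneAssignment(site.site_id, None, None, None))
            continue
        for strand in sorted(best):
            dist, gid, gene, cat = best[strand]
            out.append(
                PeakGeneAssignment(
                    site.site_id, gid, cat, _signed_tss_distance(anchor, gene)
                )
            )
    return out


def summarize_locations(assignments: Sequence[PeakGeneAssignment]) -> pd.DataFrame:
    """Count assignments per genomic category (unassigned counted apart)."""
    counts = {c: 0 for c in CATEGORIES}
    unassigned = 0
    for a in assignments:
        if a.gene_id is None:
            unassigned += 1
        else:
            counts[a.category] += 1
    rows = [(c, n) for c, n in counts.items()] + [("unassigned", unassigned)]
    return pd.DataFrame(rows, columns=["category", "count"])


def assignments_to_frame(assignments: Sequence[PeakGeneAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.site_id, a.gene_id, a.category, a.signed_distance_to_tss)
            for a in assignments
        ],
        columns=["site_id", "gene_id", "category", "signed_distance_to_tss"],
    )
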