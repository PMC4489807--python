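"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives its answer by exhaustive enumeration or exact
arithmetic, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from dellaseq.annotate import AnnotationParams
from dellaseq.io import Gene, GenomeAnnotation, Summit


def binom_upper_tail_exact(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Bin(n, p) by exact rational term summation."""
    pf = Fraction(p)
    qf = 1 - pf
    total = Fraction(0)
    term_p = pf ** k
    term_q = qf ** (n - k)
    for i in range(k, n + 1):
        total += comb(n, i) * term_p * term_q
        term_p *= pf
        if qf:
            term_q /= qf
    return float(total)


def optimal_cluster_partitions(
    summits: list[Summit], max_distance: int, min_replicates: int
):
    """All valid-cluster sets achievable by partitions maximizing the number
    of reproducible clusters.

    Enumerates contiguous partitions of the position-sorted summits (for a
    span constraint on points of a line some optimal partition is always
    contiguous) by dynamic programming with full backtracking.  Returns
    (max_count, set of frozensets of clusters), a cluster being a sorted
    tuple of (pos, replicate).
    """
    summits = sorted(summits, key=lambda s: (s.pos, s.replicate))
    n = len(summits)

    def feasible(i, j):
        return summits[j - 1].pos - summits[i].pos <= max_distance

    def reproducible(i, j):
        return int(len({s.replicate for s in summits[i:j]}) >= min_replicates)

    NEG = -(10 ** 9)
    dp = [NEG] * (n + 1)
    dp[0] = 0
    for j in range(1, n + 1):
        for i in range(j):
            if feasible(i, j) and dp[i] != NEG:
                dp[j] = max(dp[j], dp[i] + reproducible(i, j))
    partitions: set[frozenset] = set()

    def back(j, acc):
        if j == 0:
            partitions.add(frozenset(acc))
            return
        for i in range(j):
            if feasible(i, j) and dp[i] != NEG and dp[i] + reproducible(i, j) == dp[j]:
                block = tuple(sorted((s.pos, s.replicate) for s in summits[i:j]))
                back(i, acc + ([block] if reproducible(i, j) else []))

    back(n, [])
    return dp[n], partitions


# ---------------------------------------------------------------------------
# gene assignment, evaluated gene by gene with no shared helpers
# ---------------------------------------------------------------------------


def _intervals_intersect(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _naive_category(anchor: int, g: Gene, params: AnnotationParams):
    """(category, |distance|) for one gene or None, by direct rule reading."""
    if g.strand == "+":
        tss, tse = g.tx_start, g.tx_end - 1
        upstream = (tss - params.upstream_window, tss)          # half-open
        downstream = (tse + 1, tse + 1 + params.downstream_window)
    else:
        tss, tse = g.tx_end - 1, g.tx_start
        upstream = (tss + 1, tss + 1 + params.upstream_window)
        downstream = (tse - params.downstream_window, tse)

    if g.tx_start <= anchor < g.tx_end:
        introns = [
            (e1, s2) for (_, e1), (s2, _) in zip(g.exons, g.exons[1:]) if e1 < s2
        ]
        exonic = [(s, e) for s, e in g.exons]
        left = [(s, min(e, g.cds_start)) for s, e in exonic if s < g.cds_start]
        right = [(max(s, g.cds_end), e) for s, e in exonic if e > g.cds_end]
        utr5, utr3 = (left, right) if g.strand == "+" else (right, left)
        if any(s <= anchor < e for s, e in utr5):
            return "five_prime_UTR", 0
        if any(s <= anchor < e for s, e in utr3):
            return "three_prime_UTR", 0
        if any(s <= anchor < e for s, e in introns):
            return "intron", 0
        return None
    if upstream[0] <= anchor < upstream[1]:
        return "upstream", abs(anchor - tss)
    if downstream[0] <= anchor < downstream[1]:
        return "downstream", abs(anchor - tse)
    return None


def oracle_assign(sites, annotation: GenomeAnnotation, params: AnnotationParams):
    """Exhaustive per-site x per-gene evaluation of the assignment rules.

    Returns, per site, a dict strand -> (gene_id, category) for comparison
    with the implementation (unassigned sites map to an empty dict).
    """
    out = {}
    genes = list(annotation.genes.values())
    for site in sites:
        anchor = site.mean_summit
        per_strand: dict[str, tuple[int, str, str]] = {}
        for g in genes:
            if g.chrom != site.chrom:
                continue
            res = _naive_category(anchor, g, params)
            if res is None:
                continue
            cat, dist = res
            if cat in ("upstream", "downstream"):
                endpoint = (
                    (g.tx_start if g.strand == "+" else g.tx_end - 1)
                    if cat == "upstream"
                    else (g.tx_end - 1 if g.strand == "+" else g.tx_start)
                )
                lo, hi = sorted((anchor, endpoint))
                between = (lo + 1, hi)  # bases strictly between
                blocked = between[0] < between[1] and any(
                    o.id != g.id
                    and o.chrom == g.chrom
                    and _intervals_intersect((o.tx_start, o.tx_end), between)
                    for o in genes
                )
                if blocked:
                    continue
            key = (dist, g.id)
            if g.strand not in per_strand or key < per_strand[g.strand][:2]:
                per_strand[g.strand] = (dist, g.id, cat)
        out[site.site_id] = {
            strand: (gid, cat) for strand, (dist, gid, cat) in per_strand.items()
        }
    return out
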