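"""Replicate-reproducible binding-site definition from ChIP summits.

Summits from independent biological replicates are considered reproducible
when they lie within ``max_distance`` bp of each other.  Reproducible groups
are reduced to a mean summit position and extended equally on both sides to
a fixed-width binding site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .io import Summit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MergeParams:
    """Clustering and site-definition parameters.

    max_distance
        Maximum pairwise distance (bp) between summits of one reproducible
        group.  Default 200.
    min_replicates
        Distinct replicates required per group; ``None`` means all
        replicates present in the input.
    site_width
        Width (bp) of the final binding site centered on the mean summit.
        Must be even.
    """

    max_distance: int = 200
    min_replicates: int | None = None
    site_width: int = 200

    def __post_init__(self):
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        if self.site_width <= 0 or self.site_width % 2:
            raise ValueError("site_width must be even and > 0")
        if self.min_replicates is not None and self.min_replicates < 2:
            raise ValueError("min_replicates must be >= 2")


@dataclass
class BindingSite:
    """Fixed-width reproducible binding site anchored at the mean summit."""

    chrom: str
    mean_summit: int
    start: int
    end: int
    member_summits: list[Summit] = field(default_factory=list)
    site_id: str = ""

    @property
    def n_replicates(self) -> int:
        return len({s.replicate for s in self.member_summits})


def _split_chain(positions: list[int], max_distance: int) -> list[list[int]]:
    """Greedy left-to-right split of a sorted chain into clusters whose span
    (= max pairwise distance for points on a line) is <= max_distance."""
    clusters: list[list[int]] = []
    current: list[int] = []
    for p in positions:
        if current and p - current[0] > max_distance:
            clusters.append(current)
            current = []
        current.append(p)
    if current:
        clusters.append(current)
    return clusters


def cluster_summits(
    summit_sets: Sequence[Sequence[Summit]],
    params: MergeParams = MergeParams(),
    chrom_lengths: dict[str, int] | None = None,
) -> list[list[Summit]]:
    """Group summits that are reproducible across replicates.

    All replicates' summits are pooled and sorted per chromosome.
    Single-linkage chains (adjacent gap <= ``max_distance``) are formed
    first, then each chain is split greedily left-to-right so every emitted
    cluster has pairwise span <= ``max_distance``.  Clusters represented by
    fewer than ``min_replicates`` distinct replicates are discarded.

    Output is sorted by (chrom, mean position) and is invariant to the order
    of the input summits and replicate sets.
    """
    if len(summit_sets) < 2:
        raise ValueError("need summit sets from at least 2 replicates")
    all_summits = [s for reps in summit_sets for s in reps]
    if not all_summits:
        return []
    replicates = sorted({s.replicate for s in all_summits})
    min_reps = params.min_replicates if params.min_replicates is not None else len(replicates)

    if chrom_lengths is not None:
        for s in all_summits:
            if s.chrom not in chrom_lengths:
                raise ValueError(f"summit on unknown chromosome {s.chrom!r}")
            if s.pos >= chrom_lengths[s.chrom]:
                raise ValueError(f"summit at {s.chrom}:{s.pos} beyond chromosome end")

    by_chrom: dict[str, list[Summit]] = {}
    for s in all_summits:
        by_chrom.setdefault(s.chrom, []).append(s)

    clusters: list[list[Summit]] = []
    n_discarded = 0
    for chrom in sorted(by_chrom):
        # stable sort by (pos, replicate) makes tie-breaking deterministic
        summits = sorted(by_chrom[chrom], key=lambda s: (s.pos, s.replicate))
        chain: list[Summit] = []
        chains: list[list[Summit]] = []
        for s in summits:
            if chain and s.pos - chain[-1].pos > params.max_distance:
                chains.append(chain)
                chain = []
            chain.append(s)
        if chain:
            chains.append(chain)
        for chain in chains:
            idx = 0
            for group_positions in _split_chain([s.pos for s in chain], params.max_distance):
                members = chain[idx : idx + len(group_positions)]
                idx += len(group_positions)
                if len({m.replicate for m in members}) >= min_reps:
                    clusters.append(members)
                else:
                    n_discarded += 1
    logger.info(
        "clustered %d summits into %d reproducible groups (%d discarded, "
        "min_replicates=%d)", len(all_summits), len(clusters), n_discarded, min_reps,
    )
    clusters.sort(key=lambda c: (c[0].chrom, sum(s.pos for s in c) / len(c)))
    return clusters


def define_binding_sites(
    clusters: Sequence[Sequence[Summit]],
    params: MergeParams,
    chrom_lengths: dict[str, int],
) -> list[BindingSite]:
    """Reduce each cluster to a fixed-width site at its mean summit.

    The mean summit is the floor of the arithmetic mean of member positions;
    the site extends ``site_width/2`` to each side.  At chromosome edges the
    site is shifted inward so its width is preserved.
    """
    half = params.site_width // 2
    sites = []
    for i, members in enumerate(clusters):
        chrom = members[0].chrom
        length = chrom_lengths[chrom]
        if length < params.site_width:
            raise ValueError(
                f"chromosome {chrom} ({length} bp) shorter than site width "
                f"{params.site_width}"
            )
        mean = sum(s.pos for s in members) // len(members)
        start = mean - half
        if start < 0:
            start = 0
        if start + params.site_width > length:
            start = length - params.site_width
        sites.append(
            BindingSite(
                chrom=chrom,
                mean_summit=mean,
                start=start,
                end=start + params.site_width,
                member_summits=list(members),
                site_id=f"site_{i + 1:05d}",
            )
        )
    return sites


def sites_to_frame(sites: Sequence[BindingSite]) -> pd.DataFrame:
    """BED-compatible table of binding sites (score = replicate support)."""
    return pd.DataFrame(
        [
            (s.chrom, s.start, s.end, s.site_id, s.n_replicates, ".", s.mean_summit)
            for s in sites
        ],
        columns=["chrom", "start", "end", "name", "score", "strand", "mean_summit"],
    )


def members_to_frame(sites: Sequence[BindingSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        for m in s.member_summits:
            rows.append((s.site_id, m.chrom, m.pos, m.replicate))
    return pd.DataFrame(rows, columns=["site_id", "chrom", "pos", "replicate"])
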