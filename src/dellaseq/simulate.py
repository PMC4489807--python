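"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study design end to end: a small multi-
chromosome genome with non-overlapping intron-containing gene models, three
biological-replicate summit sets jittered around true binding sites plus
replicate-specific decoys, motif consensus sequences planted into the
central windows of true sites at controlled per-site probabilities, a
factorial DEX x PAC expression experiment with planted DELLA-dependence
classes, and ChIP-qPCR Ct tables whose noiseless double-normalized
enrichment equals a chosen truth.

A single run seed drives everything; each stage derives its own generator
from a fixed offset so stages can be regenerated independently and
reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Gene, GenomeAnnotation, Summit
from .motifs import PWM, ALPHABET

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# fixed sub-stream offsets (stage independence under one run seed)
_STREAM = {"genome": 0, "sites": 1, "summits": 2, "motifs": 3, "expression": 4, "qpcr": 5}

# fixed gene architecture: 2 exons, 1 intron, 100 bp UTRs at both ends
GENE_LENGTH = 1000
_EXON1 = (0, 450)
_INTRON = (450, 650)
_EXON2 = (650, 1000)
_UTR_LEN = 100
MIN_GENE_GAP = 200

#: planted expression classes and the classifier label that recovers each
TRUE_CLASSES = ("arr1_della_dependent", "arr1_independent", "arr1_repressed_with_della", "null")
TRUE_TO_CALLED = {
    "arr1_della_dependent": "arr1_induced_della_dependent",
    "arr1_independent": "arr1_induced_both",
    "arr1_repressed_with_della": "arr1_repressed_della_dependent",
    "null": "null",
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with study-like defaults.

    Three replicates mirror the three independent ChIP sequencing
    libraries; jitter of 30 bp keeps replicate summits well inside the
    200 bp reproducibility distance; expression effects of 2 log2 units
    with 0.25 SD noise represent a strong, clearly resolvable hormone
    response on arrays.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 200_000
    n_genes: int = 200
    n_true_sites: int = 40
    n_replicates: int = 3
    summit_jitter_sd: float = 30.0
    false_summits_per_replicate: int = 10
    planted_motif_probs: dict[str, float] = field(default_factory=dict)
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    de_effect_size: float = 2.0
    de_noise_sd: float = 0.25
    class_counts: dict[str, int] = field(default_factory=dict)
    # secondary knobs
    site_width: int = 200
    merge_distance: int = 200
    true_site_placement: str = "uniform"  # or "promoter"
    n_reps_per_cell: int = 3
    include_ba: bool = False
    qpcr_efficiency: float = 2.0
    qpcr_ct_noise_sd: float = 0.0
    qpcr_n_technical: int = 3

    def __post_init__(self):
        if abs(sum(self.background_freqs) - 1.0) > 1e-9:
            raise ValueError("background_freqs must sum to 1")
        for name in ("n_chroms", "chrom_len", "n_genes", "n_true_sites", "site_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        for motif, p in self.planted_motif_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"planting probability for {motif} outside [0,1]")
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if sum(self.class_counts.values()) > self.n_genes:
            raise ValueError("sum of class_counts exceeds n_genes")
        if not 1 < self.qpcr_efficiency <= 2:
            raise ValueError("qpcr_efficiency must be in (1, 2]")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([_STREAM[stage], self.seed])


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery downstream."""

    true_site_positions: list[tuple[str, int]] = field(default_factory=list)
    planted_motif_flags: dict[str, dict[str, bool]] = field(default_factory=dict)
    gene_classes: dict[str, str] = field(default_factory=dict)
    true_qpcr_enrichments: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "true_site_positions": self.true_site_positions,
                    "planted_motif_flags": self.planted_motif_flags,
                    "gene_classes": self.gene_classes,
                    "true_qpcr_enrichments": self.true_qpcr_enrichments,
                },
                fh, indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["true_site_positions"] = [tuple(x) for x in d["true_site_positions"]]
        return cls(**d)


class CapacityError(ValueError):
    """Genes cannot be placed without overlap in the requested genome."""


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], GenomeAnnotation]:
    """Random genome sequence plus non-overlapping gene models.

    Genes all share a fixed architecture (two exons flanking one intron,
    100 bp UTRs at both transcript ends) so structural assignment rules are
    easy to reason about in tests.  Strands are random; gaps between genes
    are at least MIN_GENE_GAP with the remaining slack spread randomly.
    """
    rng = config.rng("genome")
    footprint = GENE_LENGTH + MIN_GENE_GAP
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    for n in per_chrom:
        if n * footprint + MIN_GENE_GAP > config.chrom_len:
            raise CapacityError(
                f"cannot place {n} genes of footprint {footprint} bp on a "
                f"{config.chrom_len} bp chromosome"
            )
    ann = GenomeAnnotation()
    genome: dict[str, str] = {}
    bases = np.array(list(ALPHABET))
    gene_no = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        ann.chrom_lengths[chrom] = config.chrom_len
        seq = rng.choice(4, size=config.chrom_len, p=config.background_freqs)
        genome[chrom] = "".join(bases[seq])
        n = per_chrom[c]
        slack = config.chrom_len - n * footprint - MIN_GENE_GAP
        # sorted uniform cuts distribute the slack among the n+1 gaps
        cuts = np.sort(rng.integers(0, slack + 1, size=n)) if n else np.array([], int)
        for i in range(n):
            gene_no += 1
            start = int(MIN_GENE_GAP + i * footprint + cuts[i])
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"SYNG{gene_no:04d}"
            ann.add(
                Gene(
                    id=gid, chrom=chrom, strand=strand,
                    tx_start=start, tx_end=start + GENE_LENGTH,
                    exons=[
                        (start + _EXON1[0], start + _EXON1[1]),
                        (start + _EXON2[0], start + _EXON2[1]),
                    ],
                    cds_start=start + _UTR_LEN,
                    cds_end=start + GENE_LENGTH - _UTR_LEN,
                )
            )
    return genome, ann


# ---------------------------------------------------------------------------
# true sites and replicate summits
# ---------------------------------------------------------------------------


def generate_true_sites(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> list[tuple[str, int]]:
    """Ground-truth binding positions.

    ``uniform`` placement scatters sites anywhere (kept a site width away
    from chromosome ends and well separated from each other); ``promoter``
    placement drops every site upstream of a random gene's TSS, inside the
    2.5 kb promoter window.
    """
    rng = config.rng("sites")
    min_sep = 2 * config.merge_distance + config.site_width
    sites: list[tuple[str, int]] = []
    chroms = sorted(annotation.chrom_lengths)
    if config.true_site_placement == "promoter":
        # a promoter site must stay > 500 bp from the flanking neighbour's
        # body so it cannot pick up a downstream (TSE-side) assignment
        clearance = 501
        by_chrom: dict[str, list[Gene]] = {}
        for g in annotation.genes.values():
            by_chrom.setdefault(g.chrom, []).append(g)
        candidates: list[tuple[str, int, int]] = []  # (chrom, lo, hi) inclusive
        for chrom, genes in by_chrom.items():
            genes.sort(key=lambda g: g.tx_start)
            for i, g in enumerate(genes):
                if g.strand == "+":
                    prev_end = genes[i - 1].tx_end if i else 0
                    lo = max(g.tss - (MIN_GENE_GAP - 1), prev_end + clearance)
                    hi = g.tss - 1
                else:
                    next_start = (
                        genes[i + 1].tx_start if i + 1 < len(genes)
                        else annotation.chrom_lengths[chrom]
                    )
                    lo = g.tss + 1
                    hi = min(g.tss + (MIN_GENE_GAP - 1), next_start - clearance)
                if lo <= hi:
                    candidates.append((chrom, lo, hi))
        if len(candidates) < config.n_true_sites:
            raise CapacityError(
                f"only {len(candidates)} promoters can host a clear site; "
                f"{config.n_true_sites} requested"
            )
        chosen = rng.choice(len(candidates), size=config.n_true_sites, replace=False)
        for ci in chosen:
            chrom, lo, hi = candidates[int(ci)]
            sites.append((chrom, int(rng.integers(lo, hi + 1))))
    elif config.true_site_placement == "uniform":
        for _ in range(config.n_true_sites):
            for _attempt in range(10_000):
                chrom = chroms[int(rng.integers(len(chroms)))]
                length = annotation.chrom_lengths[chrom]
                pos = int(rng.integers(config.site_width, length - config.site_width))
                if all(c != chrom or abs(p - pos) >= min_sep for c, p in sites):
                    sites.append((chrom, pos))
                    break
            else:
                raise CapacityError("could not place well-separated true sites")
    else:
        raise ValueError(f"unknown placement {config.true_site_placement!r}")
    sites.sort()
    return sites


def generate_summit_replicates(
    truth_sites: list[tuple[str, int]],
    config: SimulationConfig,
    chrom_lengths: dict[str, int],
) -> list[list[Summit]]:
    """Per-replicate summit lists: jittered truth plus replicate decoys.

    Every replicate gets one summit per true site displaced by Gaussian
    jitter (clamped to the chromosome) and ``false_summits_per_replicate``
    uniform decoys kept at least twice the merge distance away from every
    true site and every other decoy, so decoys can never merge into a
    reproducible cluster.
    """
    if config.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = config.rng("summits")
    exclusion = 2 * config.merge_distance
    replicates: list[list[Summit]] = []
    placed_decoys: list[tuple[str, int]] = []
    chroms = sorted(chrom_lengths)
    for r in range(config.n_replicates):
        name = f"rep{r + 1}"
        summits = []
        for chrom, pos in truth_sites:
            jitter = rng.normal(0.0, config.summit_jitter_sd) if config.summit_jitter_sd > 0 else 0.0
            p = int(round(pos + jitter))
            p = min(max(p, 0), chrom_lengths[chrom] - 1)
            summits.append(Summit(chrom, p, name))
        for _ in range(config.false_summits_per_replicate):
            for _attempt in range(10_000):
                chrom = chroms[int(rng.integers(len(chroms)))]
                pos = int(rng.integers(0, chrom_lengths[chrom]))
                near_true = any(
                    c == chrom and abs(p - pos) < exclusion for c, p in truth_sites
                )
                near_decoy = any(
                    c == chrom and abs(p - pos) < exclusion for c, p in placed_decoys
                )
                if not near_true and not near_decoy:
                    summits.append(Summit(chrom, pos, name))
                    placed_decoys.append((chrom, pos))
                    break
            else:
                raise CapacityError("could not place well-separated decoy summits")
        replicates.append(summits)
    return replicates


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------


def plant_motif_instances(
    genome: dict[str, str],
    sites: list[tuple[str, int]],
    pwms: list[PWM],
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, dict[str, bool]]]:
    """Write motif consensus sequences into the central windows of sites.

    For each (site, motif) pair, with the configured probability the
    consensus (per-column argmax, so any sensible score threshold fires) is
    written at a uniform offset on a uniform strand inside the site's
    central window.  Overlaps between two planted instances at one site are
    re-drawn a bounded number of times, then reported by raising.
    Returns the mutated genome and per-site planting flags.
    """
    rng = config.rng("motifs")
    half = config.site_width // 2
    mutable = {c: bytearray(s, "ascii") for c, s in genome.items()}
    flags: dict[str, dict[str, bool]] = {}
    for si, (chrom, pos) in enumerate(sites):
        site_key = f"{chrom}:{pos}"
        flags[site_key] = {}
        length = len(genome[chrom])
        w_start = min(max(pos - half, 0), length - config.site_width)
        occupied: list[tuple[int, int]] = []
        for pwm in pwms:
            p = config.planted_motif_probs.get(pwm.id, 0.0)
            planted = False
            if p > 0 and rng.random() < p:
                cons = pwm.consensus
                if len(cons) > config.site_width:
                    raise ValueError(
                        f"motif {pwm.id} longer than the central window"
                    )
                for _attempt in range(50):
                    off = int(rng.integers(0, config.site_width - len(cons) + 1))
                    start = w_start + off
                    end = start + len(cons)
                    if any(s < end and start < e for s, e in occupied):
                        continue
                    strand = "+" if rng.random() < 0.5 else "-"
                    written = cons if strand == "+" else cons.translate(_COMPLEMENT)[::-1]
                    mutable[chrom][start:end] = written.encode()
                    occupied.append((start, end))
                    planted = True
                    break
                else:
                    raise ValueError(
                        f"could not place motif {pwm.id} without overlap at {site_key}"
                    )
            flags[site_key][pwm.id] = planted
    return {c: b.decode() for c, b in mutable.items()}, flags


# ---------------------------------------------------------------------------
# expression experiment
# ---------------------------------------------------------------------------


def generate_expression_dataset(
    gene_ids: list[str], config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Factorial DEX x PAC log-intensity matrix with planted classes.

    Returns (matrix, design, gene_classes).  Class effects on the log2
    scale: DELLA-dependent induction acts only in the DEX+PAC cell,
    DELLA-independent induction in every DEX cell, DELLA-dependent
    repression only in DEX+PAC; null genes carry no effect.  Gaussian noise
    of SD ``de_noise_sd`` is added throughout.
    """
    counts = dict(config.class_counts)
    if sum(counts.values()) > len(gene_ids):
        raise ValueError("class_counts exceed the number of genes")
    unknown = set(counts) - set(TRUE_CLASSES)
    if unknown:
        raise ValueError(f"unknown class label(s): {sorted(unknown)}")
    rng = config.rng("expression")
    order = list(gene_ids)
    perm = rng.permutation(len(order))
    classes: dict[str, str] = {}
    cursor = 0
    for cls in TRUE_CLASSES:
        if cls == "null":
            continue
        for _ in range(counts.get(cls, 0)):
            classes[order[perm[cursor]]] = cls
            cursor += 1
    for g in order:
        classes.setdefault(g, "null")

    cells = [("mock", "-"), ("mock", "+"), ("dex", "-"), ("dex", "+")]
    if config.include_ba:
        cells += [("ba", "-"), ("ba", "+")]
    samples, design_rows = [], []
    for dex, pac in cells:
        for r in range(config.n_reps_per_cell):
            sid = f"{dex}_PAC{pac}_{r + 1}"
            samples.append(sid)
            design_rows.append((sid, dex, pac))
    design = pd.DataFrame(design_rows, columns=["sample", "DEX", "PAC"]).set_index("sample")

    baseline = rng.normal(8.0, 1.5, size=len(order))
    eff = config.de_effect_size
    matrix = np.zeros((len(order), len(samples)))
    for j, sid in enumerate(samples):
        dex = design.loc[sid, "DEX"]
        pac = design.loc[sid, "PAC"]
        for i, g in enumerate(order):
            cls = classes[g]
            effect = 0.0
            if cls == "arr1_della_dependent" and dex == "dex" and pac == "+":
                effect = eff
            elif cls == "arr1_independent" and dex == "dex":
                effect = eff
            elif cls == "arr1_repressed_with_della" and dex == "dex" and pac == "+":
                effect = -eff
            matrix[i, j] = baseline[i] + effect
    if config.de_noise_sd > 0:
        matrix += rng.normal(0.0, config.de_noise_sd, size=matrix.shape)
    return pd.DataFrame(matrix, index=order, columns=samples), design, classes


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def generate_qpcr_dataset(
    truth_enrichments: dict[str, float] | dict[str, dict[str, float]],
    config: SimulationConfig,
    conditions: tuple[str, ...] = ("mock",),
    control_amplicon: str = "HSF",
) -> pd.DataFrame:
    """Ct table whose noiseless double-normalized enrichment equals truth.

    ``truth_enrichments`` maps amplicon to a positive enrichment, or to a
    per-condition mapping.  The control amplicon is appended with truth 1.
    Technical replicates share the same mean Ct plus independent Gaussian
    noise of SD ``qpcr_ct_noise_sd``.
    """
    rng = config.rng("qpcr")
    eff = config.qpcr_efficiency
    log_eff = np.log(eff)

    def truth(amp: str, cond: str) -> float:
        v = truth_enrichments[amp]
        val = v[cond] if isinstance(v, dict) else v
        if val <= 0:
            raise ValueError(f"true enrichment for {amp} must be positive")
        return float(val)

    amps = sorted(truth_enrichments)
    ctrl_input, ctrl_ip = 24.0, 28.0
    input_offsets = {amp: float(rng.uniform(-1.0, 1.0)) for amp in amps}
    rows = []
    for cond in conditions:
        for amp in [control_amplicon] + amps:
            if amp == control_amplicon:
                ct_in, enr = ctrl_input, 1.0
            else:
                ct_in, enr = ctrl_input + input_offsets[amp], truth(amp, cond)
            # IP Ct chosen so the double-normalized ratio inverts to `enr`
            ct_ip = ctrl_ip + (ct_in - ctrl_input) - np.log(enr) / log_eff
            for fraction, ct in (("IP", ct_ip), ("input", ct_in)):
                for r in range(config.qpcr_n_technical):
                    noisy = ct + (
                        rng.normal(0.0, config.qpcr_ct_noise_sd)
                        if config.qpcr_ct_noise_sd > 0 else 0.0
                    )
                    rows.append((amp, fraction, cond, r + 1, noisy, eff))
    return pd.DataFrame(
        rows, columns=["amplicon", "fraction", "condition", "replicate", "Ct", "efficiency"]
    )


# ---------------------------------------------------------------------------
# default motif library
# ---------------------------------------------------------------------------


def default_motif_library(
    n_motifs: int = 12, length: int = 10, seed: int = 12345,
    information: float = 0.9,
) -> list[PWM]:
    """Small synthetic PWM library with distinct consensus sequences.

    Each column puts weight ``information`` on one base and spreads the
    rest; families group motifs in pairs, mimicking TF-family structure.
    """
    rng = np.random.default_rng(seed)
    pwms = []
    for m in range(n_motifs):
        cons = rng.integers(0, 4, size=length)
        freqs = np.full((length, 4), (1 - information) / 3)
        freqs[np.arange(length), cons] = information
        pwms.append(
            PWM(id=f"SYNM{m + 1:03d}", family=f"FAM{m // 2 + 1}", freqs=freqs)
        )
    return pwms


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
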