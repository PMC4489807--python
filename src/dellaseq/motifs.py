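"""PWM scanning and cis-element over-representation testing.

Binding-site sequences are reduced to their central window (most relevant
cis elements concentrate there), scanned with log-odds position weight
matrices on both strands, and each motif's count of hit sequences is tested
for over-representation against an empirical background expectation with an
exact one-sided binomial test under Bonferroni control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import floor, log10
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass
class PWM:
    """Position weight matrix: per-position nucleotide frequencies.

    ``freqs`` is L x 4 (columns A, C, G, T); each row sums to 1.
    """

    id: str
    family: str
    freqs: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise ValueError(f"{self.id}: freqs must be L x 4")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.id}: each position must sum to 1")

    def __len__(self) -> int:
        return self.freqs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.freqs.argmax(axis=1))

    def log_odds(self, background: Sequence[float]) -> np.ndarray:
        bg = np.asarray(background, dtype=float)
        return np.log2(self.freqs / bg)

    def reverse_complement(self) -> "PWM":
        return PWM(self.id, self.family, self.freqs[::-1, ::-1])


@dataclass(frozen=True)
class ScanParams:
    """Scanner settings.

    window_width
        Central window (bp) extracted from each binding site; default 200.
    background_freqs
        Nucleotide composition (A, C, G, T) of the null model.
    score_threshold_fraction
        A position is a hit when its log-odds score reaches this fraction of
        the motif's maximum attainable score.
    both_strands
        Scan the reverse complement as well.
    """

    window_width: int = 200
    background_freqs: tuple[float, float, float, float] = DEFAULT_BACKGROUND
    score_threshold_fraction: float = 0.8
    both_strands: bool = True

    def __post_init__(self):
        if not np.isclose(sum(self.background_freqs), 1.0, atol=1e-9):
            raise ValueError("background_freqs must sum to 1")
        if not 0 < self.score_threshold_fraction <= 1:
            raise ValueError("score_threshold_fraction must be in (0, 1]")


@dataclass
class EnrichmentResult:
    motif_id: str
    family: str
    n_sequences: int
    k_hits: int
    p_expected: float
    p_value: float
    significant: bool
    bonferroni_threshold: float


def extract_central_windows(
    sites, genome: dict[str, str], params: ScanParams
) -> list[str]:
    """Uppercase central ``window_width`` sequence of each site.

    Windows are centered on the mean summit and shifted inward at
    chromosome edges, mirroring the site-definition clamping.
    """
    half = params.window_width // 2
    out = []
    for site in sites:
        seq = genome.get(site.chrom)
        if seq is None:
            raise ValueError(f"site {site.site_id} on unknown chromosome {site.chrom}")
        if len(seq) < params.window_width:
            raise ValueError(
                f"chromosome {site.chrom} shorter than window ({params.window_width} bp)"
            )
        start = min(max(site.mean_summit - half, 0), len(seq) - params.window_width)
        out.append(seq[start : start + params.window_width].upper())
    return out


def _encode(sequence: str) -> np.ndarray:
    """Map ACGTN to 0..4 (N=4); reject anything else."""
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    lut[ord("N")] = 4
    enc = lut[arr]
    if (enc == 255).any():
        bad = sequence[int(np.argmax(enc == 255))]
        raise ValueError(f"invalid nucleotide {bad!r} in sequence")
    return enc


def max_attainable_score(pwm: PWM, params: ScanParams) -> float:
    return float(pwm.log_odds(params.background_freqs).max(axis=1).sum())


def pwm_log_odds_scan(
    sequence: str, pwm: PWM, params: ScanParams
) -> list[tuple[int, str, float]]:
    """All hits of ``pwm`` in ``sequence`` as (offset, strand, score).

    score(w) = sum_j log2(freqs[j, w_j] / background[w_j]); N contributes 0
    (background-neutral).  A hit requires score >= threshold fraction of the
    maximum attainable score.  Offsets are on the forward strand; minus-
    strand hits are found by scanning the reverse-complemented matrix and
    reported at the forward-strand offset of the matched window.
    """
    L = len(pwm)
    if len(sequence) < L:
        raise ValueError("sequence shorter than motif")
    max_score = max_attainable_score(pwm, params)
    if max_score <= 0:
        raise DegenerateMotifError(pwm.id)
    threshold = params.score_threshold_fraction * max_score
    enc = _encode(sequence.upper())
    hits = []
    mats = [("+", pwm)]
    if params.both_strands:
        mats.append(("-", pwm.reverse_complement()))
    for strand, mat in mats:
        lo = np.hstack([mat.log_odds(params.background_freqs), np.zeros((L, 1))])
        # rolling windows over the encoded sequence, one row per offset
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        scores = lo[np.arange(L), windows].sum(axis=1)
        for off in np.nonzero(scores >= threshold)[0]:
            hits.append((int(off), strand, float(scores[off])))
    hits.sort()
    return hits


class DegenerateMotifError(ValueError):
    """Motif whose maximum attainable log-odds is <= 0 (indistinguishable
    from background); such motifs are skipped with a warning."""

    def __init__(self, motif_id: str):
        super().__init__(f"motif {motif_id} is degenerate (max log-odds <= 0)")
        self.motif_id = motif_id


def _has_hit(enc: np.ndarray, lo_fwd: np.ndarray, lo_rev: np.ndarray | None,
             threshold: float, L: int) -> bool:
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    idx = np.arange(L)
    if (lo_fwd[idx, windows].sum(axis=1) >= threshold).any():
        return True
    if lo_rev is not None and (lo_rev[idx, windows].sum(axis=1) >= threshold).any():
        return True
    return False


def _prepared(pwm: PWM, params: ScanParams):
    max_score = max_attainable_score(pwm, params)
    if max_score <= 0:
        raise DegenerateMotifError(pwm.id)
    threshold = params.score_threshold_fraction * max_score
    lo_fwd = np.hstack([pwm.log_odds(params.background_freqs), np.zeros((len(pwm), 1))])
    lo_rev = None
    if params.both_strands:
        rc = pwm.reverse_complement()
        lo_rev = np.hstack([rc.log_odds(params.background_freqs), np.zeros((len(pwm), 1))])
    return lo_fwd, lo_rev, threshold


def count_hit_sequences(windows: Sequence[str], pwm: PWM, params: ScanParams) -> int:
    """Number of windows with at least one hit (not the total hit count).

    Equal-length windows are scanned as one batched array operation.
    """
    if len(windows) == 0:
        return 0
    lo_fwd, lo_rev, threshold = _prepared(pwm, params)
    L = len(pwm)
    if isinstance(windows, np.ndarray) and windows.ndim == 2:
        enc = windows
    else:
        lengths = {len(w) for w in windows}
        enc = (
            np.stack([_encode(w.upper()) for w in windows])
            if len(lengths) == 1 and min(lengths) >= L
            else None
        )
    if enc is not None and enc.shape[1] >= L:
        sub = np.lib.stride_tricks.sliding_window_view(enc, L, axis=1)
        idx = np.arange(L)
        hit = (lo_fwd[idx, sub].sum(axis=2) >= threshold).any(axis=1)
        if lo_rev is not None:
            hit |= (lo_rev[idx, sub].sum(axis=2) >= threshold).any(axis=1)
        return int(hit.sum())
    k = 0
    for w in windows:
        enc = _encode(w.upper())
        if len(enc) >= L and _has_hit(enc, lo_fwd, lo_rev, threshold, L):
            k += 1
    return k


def encode_windows(windows: Sequence[str]) -> np.ndarray:
    """Pre-encode equal-length windows for repeated batched scans."""
    return np.stack([_encode(w.upper()) for w in windows])


def generate_background_sequences(
    n: int, params: ScanParams, rng: np.random.Generator
) -> list[str]:
    """Random window-width sequences drawn from the background model."""
    draws = rng.choice(4, size=(n, params.window_width), p=params.background_freqs)
    bases = np.array(list(ALPHABET))
    return ["".join(bases[row]) for row in draws]


def estimate_expected_frequency(
    pwm: PWM, params: ScanParams, background_sequences: Sequence[str]
) -> float:
    """Fraction of background windows with >= 1 hit, floored at 1/(2n).

    The floor keeps the binomial test defined for motifs never seen in the
    background sample.
    """
    n = len(background_sequences)
    if n < 100:
        raise ValueError("need at least 100 background sequences")
    k = count_hit_sequences(background_sequences, pwm, params)
    return max(k / n, 1.0 / (2 * n))


def binomial_enrichment_test(k: int, n: int, p_expected: float) -> float:
    """Upper-tail exact binomial p-value P(X >= k), X ~ Bin(n, p_expected)."""
    if not 0 < p_expected < 1:
        raise ValueError("p_expected must be in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binom.sf(k - 1, n, p_expected))


def bonferroni_threshold(alpha: float, n_motifs: int) -> float:
    """Per-motif significance threshold alpha / n_motifs."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    return alpha / n_motifs


def format_threshold(threshold: float) -> str:
    """Display form truncated (not rounded) to 2 significant figures,
    e.g. 1.9685e-4 -> '1.9E-4'."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    exponent = floor(log10(threshold))
    mantissa = threshold / 10 ** exponent
    truncated = floor(mantissa * 10) / 10
    return f"{truncated:.1f}E{exponent:+d}"


def run_enrichment(
    windows: Sequence[str],
    pwms: Sequence[PWM],
    params: ScanParams,
    alpha: float = 0.05,
    n_background: int = 1000,
    rng: np.random.Generator | None = None,
    background_sequences: Sequence[str] | None = None,
    p_expected_cache: dict[str, float] | None = None,
) -> list[EnrichmentResult]:
    """Per-motif over-representation test over all (non-degenerate) motifs.

    The Bonferroni denominator is the number of motifs actually tested,
    i.e. after excluding degenerate ones; both counts are logged.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if background_sequences is None:
        background_sequences = generate_background_sequences(n_background, params, rng)
    testable = []
    for pwm in pwms:
        try:
            _prepared(pwm, params)
        except DegenerateMotifError:
            warnings.warn(f"skipping degenerate motif {pwm.id}", stacklevel=2)
            continue
        testable.append(pwm)
    logger.info("testing %d of %d motifs (degenerate excluded)", len(testable), len(pwms))
    if not testable:
        return []
    thr = bonferroni_threshold(alpha, len(testable))
    n = len(windows)
    results = []
    for pwm in testable:
        if p_expected_cache is not None and pwm.id in p_expected_cache:
            p_exp = p_expected_cache[pwm.id]
        else:
            p_exp = estimate_expected_frequency(pwm, params, background_sequences)
            if p_expected_cache is not None:
                p_expected_cache[pwm.id] = p_exp
        k = count_hit_sequences(windows, pwm, params)
        p = binomial_enrichment_test(k, n, p_exp) if n else 1.0
        results.append(
            EnrichmentResult(
                motif_id=pwm.id, family=pwm.family, n_sequences=n, k_hits=k,
                p_expected=p_exp, p_value=p, significant=p < thr,
                bonferroni_threshold=thr,
            )
        )
    return results


def aggregate_by_family(
    results: Sequence[EnrichmentResult],
    windows: Sequence[str] | None = None,
    pwms: Sequence[PWM] | None = None,
    params: ScanParams | None = None,
) -> pd.DataFrame:
    """Family-level summary: best member p-value and union hit count.

    A family is reported iff at least one member motif is significant.  When
    ``windows``/``pwms``/``params`` are given, the union count is the number
    of windows hit by any member motif (each window counted once);
    otherwise the max member k is reported as a lower bound.
    """
    by_family: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        by_family.setdefault(r.family, []).append(r)
    pwm_index = {p.id: p for p in (pwms or [])}
    rows = []
    for family in sorted(by_family):
        members = by_family[family]
        if not any(m.significant for m in members):
            continue
        best = min(members, key=lambda m: m.p_value)
        if windows is not None and pwms is not None and params is not None:
            prepared = []
            for m in members:
                if m.motif_id in pwm_index:
                    pwm = pwm_index[m.motif_id]
                    prepared.append((len(pwm),) + _prepared(pwm, params))
            union = 0
            for w in windows:
                enc = _encode(w.upper())
                if any(
                    len(enc) >= L and _has_hit(enc, lo_f, lo_r, thr, L)
                    for L, lo_f, lo_r, thr in prepared
                ):
                    union += 1
        else:
            union = max(m.k_hits for m in members)
        rows.append((family, best.motif_id, best.p_value, union, len(members)))
    return pd.DataFrame(
        rows, columns=["family", "best_motif", "best_p_value", "n_windows_hit", "n_motifs"]
    )


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.motif_id, r.family, r.n_sequences, r.k_hits, r.p_expected,
             r.p_value, r.significant, r.bonferroni_threshold)
            for r in results
        ],
        columns=["motif", "family", "n", "k", "p_expected", "p_value",
                 "significant", "bonferroni_threshold"],
    )
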