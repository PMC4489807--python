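"""Z-score / Z-ratio differential expression and DELLA-dependence classes.

Log-intensity arrays are standardized per sample (each array gets mean 0,
SD 1 across genes), per-gene between-condition z-differences are scaled by
their SD across genes into Z-ratios, and two-sided normal p-values call
genes up/down at p < alpha.  Crossing the DEX-effect contrast computed under
high (PAC+) and low (PAC-) DELLA levels classifies each gene's dependence
of its ARR1 response on DELLA accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: exhaustive, disjoint DELLA-dependence classes
CLASSES = (
    "arr1_induced_both",
    "arr1_induced_della_dependent",
    "arr1_repressed_both",
    "arr1_repressed_della_dependent",
    "arr1_induced_della_independent_only",
    "arr1_repressed_della_independent_only",
    "discordant",
    "null",
)


@dataclass
class ZRatioResult:
    """Per-contrast differential expression table.

    ``table`` has one row per gene with columns z_diff, z_ratio, p_value,
    call (up / down / ns).
    """

    contrast: str
    table: pd.DataFrame
    alpha: float


def zscore_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each sample (column) to mean 0, SD 1 across genes.

    Uses the n-1 sample SD.  A zero-variance sample is an error because its
    z-scores would be undefined.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes per sample")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    zero = sds.index[sds == 0]
    if len(zero):
        raise ValueError(f"zero-variance sample(s): {', '.join(map(str, zero))}")
    return (matrix - means) / sds


def _cell_samples(design: pd.DataFrame, cell: dict[str, str]) -> list[str]:
    mask = np.ones(len(design), dtype=bool)
    for factor, level in cell.items():
        mask &= design[factor].astype(str) == str(level)
    return list(design.index[mask])


def zratio_contrast(
    zmatrix: pd.DataFrame,
    design: pd.DataFrame,
    cell_a: dict[str, str],
    cell_b: dict[str, str],
    alpha: float = 0.05,
    name: str | None = None,
) -> ZRatioResult:
    """Z-ratio contrast between two design cells.

    For each gene, z_diff = mean z over cell A samples - mean z over cell B
    samples; z_ratio = z_diff / SD(z_diff across genes); two-sided p-values
    come from the standard normal.  ``design`` maps sample id (index) to
    factor levels; a cell is a factor -> level mapping.
    """
    samples_a = _cell_samples(design, cell_a)
    samples_b = _cell_samples(design, cell_b)
    if not samples_a or not samples_b:
        raise ValueError(f"empty design cell: {cell_a if not samples_a else cell_b}")
    zdiff = zmatrix[samples_a].mean(axis=1) - zmatrix[samples_b].mean(axis=1)
    sd = float(zdiff.std(ddof=1))
    if sd == 0:
        raise ValueError("SD of z-differences across genes is 0")
    zratio = zdiff / sd
    pvals = 2 * stats.norm.sf(np.abs(zratio))
    call = np.where(pvals >= alpha, "ns", np.where(zratio > 0, "up", "down"))
    table = pd.DataFrame(
        {"z_diff": zdiff, "z_ratio": zratio, "p_value": pvals, "call": call},
        index=zmatrix.index,
    )
    if name is None:
        name = f"{cell_a} vs {cell_b}"
    return ZRatioResult(contrast=name, table=table, alpha=alpha)


def classify_arr1_della_targets(
    high_della: ZRatioResult, low_della: ZRatioResult
) -> pd.Series:
    """DELLA-dependence class per gene from the two DEX-effect contrasts.

    ``high_della`` is the DEX-vs-mock contrast under PAC (DELLAs
    accumulate); ``low_della`` the same contrast without PAC.  The mapping
    of (call under high DELLA, call under low DELLA) to classes is
    exhaustive and disjoint.
    """
    a, b = high_della.table, low_della.table
    if not a.index.equals(b.index):
        missing = a.index.symmetric_difference(b.index)
        raise ValueError(f"contrasts computed on different gene sets: {list(missing)[:5]}")
    mapping = {
        ("up", "up"): "arr1_induced_both",
        ("up", "ns"): "arr1_induced_della_dependent",
        ("down", "down"): "arr1_repressed_both",
        ("down", "ns"): "arr1_repressed_della_dependent",
        ("ns", "up"): "arr1_induced_della_independent_only",
        ("ns", "down"): "arr1_repressed_della_independent_only",
        ("up", "down"): "discordant",
        ("down", "up"): "discordant",
        ("ns", "ns"): "null",
    }
    classes = [
        mapping[(a.loc[g, "call"], b.loc[g, "call"])] for g in a.index
    ]
    return pd.Series(classes, index=a.index, name="class")


def class_counts(classes: pd.Series) -> pd.DataFrame:
    counts = classes.value_counts()
    return pd.DataFrame(
        [(c, int(counts.get(c, 0))) for c in CLASSES], columns=["class", "count"]
    )


def intersect_with_binding(
    classes: pd.Series, chip_gene_ids: set[str]
) -> pd.DataFrame:
    """Per class, the genes also in the ChIP-bound set (count and list)."""
    rows = []
    for cls in CLASSES:
        members = set(classes.index[classes == cls])
        overlap = sorted(members & set(chip_gene_ids))
        rows.append((cls, len(members), len(overlap), ",".join(overlap)))
    return pd.DataFrame(rows, columns=["class", "n_genes", "n_bound", "bound_genes"])


def heatmap_matrix(
    zmatrix: pd.DataFrame, classes: pd.Series, keep: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Z-score matrix restricted to regulated genes, ordered by class (for a
    heat-map style export)."""
    if keep is None:
        keep = tuple(c for c in CLASSES if c != "null")
    order = [g for c in keep for g in classes.index[classes == c]]
    out = zmatrix.loc[order].copy()
    out.insert(0, "class", classes.loc[order])
    return out
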