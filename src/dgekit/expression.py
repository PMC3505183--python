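"""TPM quantification, detection calls, library correlation, saturation.

Expression is quantified in TPM — transcripts per million clean tags:
``count * 1e6 / total_clean``, with the library's *total clean tags* (not
its mapped tags) as the denominator. A gene with zero unambiguous tags is
"not detected" and its TPM is floored at 0.01 so that ratios against it
remain finite.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from ._util import round_half_up, rng_from
from .mapping import TagIndex, TagCategory, map_tag
from .types import ExpressionMatrix, TagLibrary

TPM_FLOOR = 0.01


def tpm_normalize(counts: dict[str, int], total_clean: int) -> dict[str, float]:
    """Per-gene TPM; undetected (zero-count) genes are floored at 0.01."""
    if total_clean <= 0:
        raise ValueError("total_clean must be positive")
    out = {}
    for gene, c in counts.items():
        if c < 0:
            raise ValueError(f"negative count for {gene}")
        out[gene] = c * 1e6 / total_clean if c > 0 else TPM_FLOOR
    return out


def format_tpm(tpm: float) -> str:
    """Display convention: two decimals, half away from zero (e.g. 0.266 -> '0.27')."""
    return f"{round_half_up(tpm, 2):.2f}"


def detect_stage_specific(
    matrix: ExpressionMatrix, library_subset: Optional[Sequence[str]] = None
) -> dict[str, str]:
    """Genes detected (count > 0) in exactly one of the subset libraries.

    Returns ``gene -> library_id`` for those genes; genes detected in zero
    or in two or more libraries are excluded.
    """
    libs = list(library_subset) if library_subset is not None else matrix.libraries
    if len(libs) < 2:
        raise ValueError("need at least two libraries to call specificity")
    missing = set(libs) - set(matrix.libraries)
    if missing:
        raise ValueError(f"unknown libraries: {sorted(missing)}")
    sub = matrix.counts[libs]
    detected = sub > 0
    single = detected.sum(axis=1) == 1
    out: dict[str, str] = {}
    for gene in sub.index[single]:
        out[gene] = detected.columns[detected.loc[gene].to_numpy().argmax()]
    return out


def pearson_correlation(
    matrix: ExpressionMatrix, lib_a: str, lib_b: str
) -> float:
    """Pearson r of log10(TPM) between two libraries.

    Genes detected in at least one of the pair enter; the undetected partner
    contributes its 0.01 floor. Fewer than three usable genes is an error.
    """
    for lib in (lib_a, lib_b):
        if lib not in matrix.libraries:
            raise ValueError(f"unknown library {lib!r}")
    use = (matrix.counts[lib_a] > 0) | (matrix.counts[lib_b] > 0)
    if int(use.sum()) < 3:
        raise ValueError("fewer than 3 genes detected in the pair")
    x = np.log10(matrix.tpm.loc[use, lib_a].to_numpy())
    y = np.log10(matrix.tpm.loc[use, lib_b].to_numpy())
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 1.0 if np.allclose(x - x.mean(), y - y.mean()) else float("nan")
    return float(sps.pearsonr(x, y).statistic)


def saturation_curve(
    clean_library: TagLibrary,
    index: TagIndex,
    grid: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Detected-gene counts at nested subsamples of the clean tag pool.

    Tags are expanded to individual copies, shuffled once, and each grid size
    takes a prefix — nested subsampling without replacement, so the curve is
    non-decreasing by construction. A gene counts as detected when at least
    one of its unambiguous tags is present. Default grid: ten equal steps up
    to the full library.
    """
    total = clean_library.total_clean
    if grid is None:
        grid = [round(total * k / 10) for k in range(1, 11)]
    grid = sorted(int(g) for g in grid)
    if grid and grid[-1] > total:
        raise ValueError("grid sizes must not exceed total clean tags")

    tags = list(clean_library.clean)
    gene_of = np.full(len(tags), -1, dtype=np.int64)
    gene_ids: dict[str, int] = {}
    for k, t in enumerate(tags):
        ann = map_tag(t, index)
        if ann.category is TagCategory.UNAMBIGUOUS_GENE:
            (gid,) = ann.gene_hits
            gene_of[k] = gene_ids.setdefault(gid, len(gene_ids))

    counts = np.fromiter((clean_library.clean[t] for t in tags), dtype=np.int64)
    pool = np.repeat(np.arange(len(tags)), counts)
    rng_from(seed).shuffle(pool)

    genes = gene_of[pool]
    seen = np.zeros(len(gene_ids), dtype=bool)
    out: list[tuple[int, int]] = []
    prev = 0
    n_seen = 0
    for size in grid:
        chunk = genes[prev:size]
        u = np.unique(chunk[chunk >= 0])
        new = u[~seen[u]]
        seen[new] = True
        n_seen += len(new)
        prev = size
        out.append((size, n_seen))
    return out
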