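"""Tissue specificity (SPM) and contribution (CTM) classification.

SPM of a gene for tissue i is the cosine between its expression vector and
the i-th basis vector, x_i / ||x||; CTM of a tissue subset S is
||x_S|| / ||x||.  A gene is tissue-specific when some SPM exceeds 0.9 and
tissue-selective when 2-4 tissues have SPM > 0.3 with a joint CTM > 0.9.

Before scoring, zero-expression tissues are dropped per gene and, within
each group of similar tissues, only the member with the highest expression
is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SpecificityResult:
    gene_id: str
    retained_tissues: list[str]
    spm: dict[str, float]
    ctm: float
    label: str  # "specific", "selective", "unassigned"
    tissues: tuple[str, ...]  # tagged tissue(s) for specific/selective genes


def reduce_tissues(
    expression: Mapping[str, float],
    groups: Optional[Sequence[Sequence[str]]] = None,
) -> dict[str, float]:
    """Per-gene tissue reduction.

    Tissues with zero expression are excluded; within each similarity group
    only the tissue with the highest expression for this gene is kept.
    Ties inside a group break toward the first listed tissue.
    """
    kept = {t: x for t, x in expression.items() if x > 0}
    if groups:
        for group in groups:
            members = [t for t in group if t in kept]
            if len(members) > 1:
                best = max(members, key=lambda t: (kept[t], -group.index(t)))
                for t in members:
                    if t != best:
                        del kept[t]
    return kept


def compute_spm_ctm(
    expression: Mapping[str, float], subset: Sequence[str]
) -> tuple[dict[str, float], float]:
    """SPM per tissue and CTM of ``subset`` for one reduced expression row."""
    tissues = list(expression)
    x = np.array([expression[t] for t in tissues], dtype=float)
    norm = float(np.linalg.norm(x))
    if norm == 0:
        raise ValueError("zero expression vector")
    spm = {t: float(v) / norm for t, v in zip(tissues, x)}
    sub = np.array([expression.get(t, 0.0) for t in subset], dtype=float)
    ctm = float(np.linalg.norm(sub)) / norm
    return spm, ctm


def classify_restriction(
    gene_id: str,
    expression: Mapping[str, float],
    groups: Optional[Sequence[Sequence[str]]] = None,
    spm_specific: float = 0.9,
    spm_selective: float = 0.3,
    ctm_selective: float = 0.9,
    max_selective: int = 4,
) -> SpecificityResult:
    """Classify one gene as tissue-specific / selective / unassigned."""
    kept = reduce_tissues(expression, groups)
    if not kept:
        return SpecificityResult(gene_id, [], {}, 0.0, "unassigned", ())
    spm, _ = compute_spm_ctm(kept, [])
    top = max(spm, key=lambda t: (spm[t], t))
    if spm[top] > spm_specific:
        return SpecificityResult(
            gene_id, list(kept), spm, spm[top], "specific", (top,)
        )
    tagged = sorted(t for t, v in spm.items() if v > spm_selective)
    if 2 <= len(tagged) <= max_selective:
        _, ctm = compute_spm_ctm(kept, tagged)
        if ctm > ctm_selective:
            return SpecificityResult(
                gene_id, list(kept), spm, ctm, "selective", tuple(tagged)
            )
    return SpecificityResult(gene_id, list(kept), spm, 0.0, "unassigned", ())


def classify_matrix(
    matrix: pd.DataFrame,
    groups: Optional[Sequence[Sequence[str]]] = None,
    **thresholds,
) -> list[SpecificityResult]:
    """Classify every row of a genes x tissues expression matrix."""
    results = []
    for gene_id, row in matrix.iterrows():
        results.append(
            classify_restriction(str(gene_id), row.to_dict(), groups, **thresholds)
        )
    return results


def pick_peripheral_tissue(result: SpecificityResult, rng: np.random.Generator) -> str:
    """Tissue used for ratio comparison: the single tagged tissue for a
    specific gene, one drawn uniformly among tagged tissues otherwise."""
    if not result.tissues:
        raise ValueError(f"gene {result.gene_id} has no tagged tissue")
    if len(result.tissues) == 1:
        return result.tissues[0]
    return result.tissues[int(rng.integers(len(result.tissues)))]


def correlate_ratio_expression(
    regulator_expression: Sequence[float],
    median_ratios: Sequence[float],
) -> tuple[float, float]:
    """Pearson correlation of log10 regulator expression vs per-tissue
    median d3'UTR ratios; two-sided p."""
    x = np.log10(np.asarray(regulator_expression, dtype=float))
    y = np.asarray(median_ratios, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired tissues")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no defined correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def write_labels_table(results: Sequence[SpecificityResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlabel\ttissues\tmax_spm\tctm\n")
        for r in sorted(results, key=lambda r: r.gene_id):
            max_spm = max(r.spm.values()) if r.spm else 0.0
            fh.write(
                f"{r.gene_id}\t{r.label}\t{','.join(r.tissues) or 'NA'}\t"
                f"{max_spm:.6g}\t{r.ctm:.6g}\n"
            )
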