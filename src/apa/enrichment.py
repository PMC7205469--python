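"""Classic-scheme gene-set enrichment analysis and d3'UTR miRNA-site filtering.

The classic (unweighted) Kolmogorov-Smirnov running score adds 1/N_hit at
each set member and subtracts 1/(N - N_hit) elsewhere; the enrichment score
is the signed maximal deviation from zero (ties toward the positive
extreme).  Significance comes from gene-set permutations; the FDR follows
the standard NES-based procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import D3UTR, SplitFeature

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedList:
    """Gene ids ordered by a descending real-valued metric.

    Ties in the metric are broken by gene_id (lexicographic) so the order
    is deterministic.
    """

    genes: tuple[str, ...]
    metric: tuple[float, ...]

    @classmethod
    def from_scores(cls, scores: Mapping[str, float]) -> "RankedList":
        items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(tuple(g for g, _ in items), tuple(v for _, v in items))

    def __len__(self) -> int:
        return len(self.genes)

    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class GeneSetResult:
    set_id: str
    size: int
    es: float
    nes: float
    p: float
    fdr_q: float
    leading_edge: tuple[str, ...]


def _es_from_hits(hit_idx: np.ndarray, n: int) -> tuple[float, int]:
    """Signed maximal running-sum deviation and the hit index attaining it.

    ``hit_idx`` must be sorted ranked positions of the set members.
    Returns (es, j) where j is the index into hit_idx of the extreme hit
    (the peak hit for positive es, the trough hit for negative es).
    """
    nh = len(hit_idx)
    nm = n - nh
    if nh == 0 or nm == 0:
        raise ValueError("set must be a proper nonempty subset of the universe")
    j = np.arange(nh)
    after = (j + 1) / nh - (hit_idx - j) / nm  # running sum at each hit
    before = j / nh - (hit_idx - j) / nm  # running sum just before each hit
    pos_j = int(np.argmax(after))
    neg_j = int(np.argmin(before))
    pos, neg = float(after[pos_j]), float(before[neg_j])
    # exact ties resolve toward the positive extreme; true non-tie gaps are
    # multiples of 1/(nh*nm), far above the float tolerance
    if pos >= -neg - 1e-12:
        return pos, pos_j
    return neg, neg_j


def enrichment_score(
    ranked: RankedList, gene_set: Iterable[str]
) -> tuple[float, tuple[str, ...]]:
    """Classic ES of a set plus its leading-edge genes."""
    idx = ranked.index()
    hit_idx = np.array(sorted(idx[g] for g in gene_set if g in idx), dtype=np.int64)
    es, j = _es_from_hits(hit_idx, len(ranked))
    if es >= 0:
        le = hit_idx[: j + 1]
    else:
        le = hit_idx[j:]
    return es, tuple(ranked.genes[i] for i in le)


def gsea_classic(
    ranked: RankedList,
    sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 5000,
) -> list[GeneSetResult]:
    """Classic GSEA over a collection of gene sets.

    Sets are filtered to ``min_size``..``max_size`` members present in the
    ranked universe; p and FDR q come from gene-set permutations (random
    same-size sets drawn from the universe) with the given seed.
    """
    rng = np.random.default_rng(seed)
    n = len(ranked)
    universe = set(ranked.genes)

    kept: dict[str, list[str]] = {}
    for sid in sorted(sets):
        members = sorted(set(sets[sid]) & universe)
        if not members:
            log.warning("set %s has no member in the ranked universe; skipped", sid)
            continue
        if min_size <= len(members) <= max_size and len(members) < n:
            kept[sid] = members
    if not kept:
        return []

    observed: dict[str, tuple[float, tuple[str, ...]]] = {
        sid: enrichment_score(ranked, members) for sid, members in kept.items()
    }

    # permutation null per distinct set size
    sizes = sorted({len(m) for m in kept.values()})
    null_es: dict[int, np.ndarray] = {}
    for k in sizes:
        es_perm = np.empty(n_perm)
        for i in range(n_perm):
            hit = np.sort(rng.choice(n, size=k, replace=False))
            es_perm[i], _ = _es_from_hits(hit, n)
        null_es[k] = es_perm

    def normalize(es: float, null: np.ndarray) -> float:
        same = null[null >= 0] if es >= 0 else null[null < 0]
        denom = float(np.mean(np.abs(same))) if len(same) else float("nan")
        return es / denom if denom and denom > 0 else float("nan")

    results = []
    all_null_nes: list[float] = []
    for sid, members in kept.items():
        es, le = observed[sid]
        null = null_es[len(members)]
        if es >= 0:
            pool = null[null >= 0]
            p = float(np.mean(pool >= es)) if len(pool) else 1.0
        else:
            pool = null[null < 0]
            p = float(np.mean(pool <= es)) if len(pool) else 1.0
        nes = normalize(es, null)
        results.append(GeneSetResult(sid, len(members), es, nes, p, 1.0, le))
    for k in sizes:
        all_null_nes.extend(normalize(e, null_es[k]) for e in null_es[k])

    null_nes = np.array([v for v in all_null_nes if np.isfinite(v)])
    obs_nes = np.array([r.nes for r in results])
    for r in results:
        if not np.isfinite(r.nes):
            r.fdr_q = 1.0
            continue
        if r.nes >= 0:
            num_pool = null_nes[null_nes >= 0]
            obs_pool = obs_nes[obs_nes >= 0]
            num = np.mean(num_pool >= r.nes) if len(num_pool) else 1.0
            den = np.mean(obs_pool >= r.nes) if len(obs_pool) else 1.0
        else:
            num_pool = null_nes[null_nes < 0]
            obs_pool = obs_nes[obs_nes < 0]
            num = np.mean(num_pool <= r.nes) if len(num_pool) else 1.0
            den = np.mean(obs_pool <= r.nes) if len(obs_pool) else 1.0
        r.fdr_q = float(min(1.0, num / den)) if den > 0 else 1.0
    return results


def leading_edge_summary(
    results: Sequence[GeneSetResult],
    fdr_threshold: float = 0.05,
    min_count: int = 5,
) -> tuple[dict[str, int], list[str]]:
    """Per-gene count of significant sets holding it in their leading edge,
    and the genes appearing in at least ``min_count`` of them."""
    counts: dict[str, int] = {}
    for r in results:
        if r.fdr_q < fdr_threshold:
            for g in r.leading_edge:
                counts[g] = counts.get(g, 0) + 1
    selected = sorted(g for g, c in counts.items() if c >= min_count)
    return counts, selected


def top_fraction_genes(scores: Mapping[str, float], fraction: float = 0.3) -> list[str]:
    """The top fraction of genes by descending score (ties by gene_id)."""
    ranked = RankedList.from_scores(dict(scores))
    k = int(round(fraction * len(ranked)))
    return list(ranked.genes[:k])


# ---------------------------------------------------------------------------
# miRNA conserved-site filtering


def filter_d3utr_mirna_sites(
    sites: pd.DataFrame,
    features: Sequence[SplitFeature],
    gene_subset: Sequence[str],
) -> tuple[set[str], float]:
    """Genes of the subset with >= 1 conserved miRNA site inside their d3'UTR.

    ``sites`` columns: mirna_family, gene_id, chrom, start, end (0-based
    half-open).  A site counts only when fully inside the gene's d3utr
    feature.  Returns the qualifying genes and their proportion over the
    whole subset (genes without a d3utr feature stay in the denominator).
    """
    d3 = {f.gene_id: f for f in features if f.kind == D3UTR}
    subset = list(gene_subset)
    hit: set[str] = set()
    for row in sites.itertuples(index=False):
        f = d3.get(row.gene_id)
        if f is None or row.chrom != f.chrom:
            continue
        if f.interval[0] <= row.start and row.end <= f.interval[1]:
            hit.add(row.gene_id)
    qualifying = hit & set(subset)
    proportion = len(qualifying) / len(subset) if subset else 0.0
    return qualifying, proportion


# ---------------------------------------------------------------------------
# I/O


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for sid in sorted(sets):
            fh.write("\t".join([sid, description, *sets[sid]]) + "\n")


def read_site_table(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"mirna_family": str, "gene_id": str, "chrom": str, "start": int, "end": int},
    )


def write_results_table(results: Sequence[GeneSetResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("set_id\tsize\tes\tnes\tp\tfdr_q\tleading_edge_size\n")
        for r in sorted(results, key=lambda r: (r.fdr_q, r.set_id)):
            fh.write(
                f"{r.set_id}\t{r.size}\t{r.es:.6g}\t{r.nes:.6g}\t{r.p:.6g}\t"
                f"{r.fdr_q:.6g}\t{len(r.leading_edge)}\n"
            )
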