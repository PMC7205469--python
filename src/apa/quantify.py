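"""Read counting, RPKM, d3'UTR ratios, and two-condition sensitivity calls.

A read counts toward a feature only when strictly contained in it
(read interval a subset of the feature interval, same chromosome;
strand-agnostic because the library prep is unstranded).  The d3'UTR ratio
of a gene is the RPKM of its d3utr feature divided by the RPKM of its
upstream_last_exon feature; it is NA when no read maps to the upstream
region.

The two-condition comparison normalizes with median-of-ratios size factors
and assigns a standard score to each gene's log2 fold-change within
equal-occupancy expression bins (robust location/scale), a documented
stand-in for the negative-binomial test used historically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .annotation import D3UTR, UPSTREAM, SplitFeature

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignedRead:
    chrom: str
    strand: str
    interval: tuple[int, int]

    def __post_init__(self) -> None:
        if self.interval[1] <= self.interval[0]:
            raise ValueError(f"degenerate read interval {self.interval}")


class ReadSet:
    """Aligned reads stored as per-chromosome coordinate arrays."""

    def __init__(self, per_chrom: dict[str, dict[str, np.ndarray]]):
        # per_chrom[chrom] = {"start": int64[], "end": int64[], "fwd": bool[]}
        self._per_chrom = per_chrom

    @classmethod
    def from_reads(cls, reads: Iterable[AlignedRead]) -> "ReadSet":
        buckets: dict[str, list[tuple[int, int, bool]]] = {}
        for r in reads:
            buckets.setdefault(r.chrom, []).append(
                (r.interval[0], r.interval[1], r.strand == "+")
            )
        per_chrom = {}
        for chrom, rows in buckets.items():
            arr = np.asarray(rows, dtype=np.int64)
            per_chrom[chrom] = {
                "start": arr[:, 0],
                "end": arr[:, 1],
                "fwd": arr[:, 2].astype(bool),
            }
        return cls(per_chrom)

    @classmethod
    def from_arrays(
        cls, chrom: str, start: np.ndarray, end: np.ndarray, fwd: np.ndarray
    ) -> "ReadSet":
        return cls(
            {
                chrom: {
                    "start": np.asarray(start, dtype=np.int64),
                    "end": np.asarray(end, dtype=np.int64),
                    "fwd": np.asarray(fwd, dtype=bool),
                }
            }
        )

    @classmethod
    def from_sam(cls, path) -> "ReadSet":
        import pysam

        buckets: dict[str, list[tuple[int, int, bool]]] = {}
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped:
                    continue
                buckets.setdefault(rec.reference_name, []).append(
                    (rec.reference_start, rec.reference_end, not rec.is_reverse)
                )
        per_chrom = {}
        for chrom, rows in buckets.items():
            arr = np.asarray(rows, dtype=np.int64)
            per_chrom[chrom] = {
                "start": arr[:, 0],
                "end": arr[:, 1],
                "fwd": arr[:, 2].astype(bool),
            }
        return cls(per_chrom)

    @classmethod
    def from_bed(cls, path) -> "ReadSet":
        buckets: dict[str, list[tuple[int, int, bool]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.rstrip("\n").split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                strand = parts[5] if len(parts) > 5 else "+"
                buckets.setdefault(chrom, []).append((start, end, strand == "+"))
        per_chrom = {}
        for chrom, rows in buckets.items():
            arr = np.asarray(rows, dtype=np.int64)
            per_chrom[chrom] = {
                "start": arr[:, 0],
                "end": arr[:, 1],
                "fwd": arr[:, 2].astype(bool),
            }
        return cls(per_chrom)

    @property
    def n_reads(self) -> int:
        return sum(len(v["start"]) for v in self._per_chrom.values())

    def chroms(self) -> list[str]:
        return sorted(self._per_chrom)

    def arrays(self, chrom: str) -> Optional[dict[str, np.ndarray]]:
        return self._per_chrom.get(chrom)

    def dedup(self) -> "ReadSet":
        """Collapse reads identical in (chrom, 5' start, strand) to one.

        The 5' start is the leftmost coordinate on +, the rightmost on -,
        matching rmdup semantics on single-end data.  Idempotent.
        """
        per_chrom = {}
        for chrom, a in self._per_chrom.items():
            five = np.where(a["fwd"], a["start"], a["end"] - 1)
            key = np.stack([five, a["fwd"].astype(np.int64)], axis=1)
            _, idx = np.unique(key, axis=0, return_index=True)
            idx.sort()
            per_chrom[chrom] = {
                "start": a["start"][idx],
                "end": a["end"][idx],
                "fwd": a["fwd"][idx],
            }
        return ReadSet(per_chrom)

    def iter_reads(self) -> Iterable[AlignedRead]:
        for chrom in self.chroms():
            a = self._per_chrom[chrom]
            for s, e, f in zip(a["start"], a["end"], a["fwd"]):
                yield AlignedRead(chrom, "+" if f else "-", (int(s), int(e)))


@dataclass
class CountTable:
    counts: dict[str, int]
    library_size: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative count")
        if any(c > self.library_size for c in self.counts.values()):
            raise ValueError("count exceeds library size")


def count_contained_reads(
    reads: "ReadSet | Iterable[AlignedRead]",
    features: Sequence[SplitFeature],
    dedup: bool = False,
    sample_id: str = "",
) -> CountTable:
    """Count reads strictly contained in each feature.

    Containment is strand-agnostic.  With ``dedup`` duplicate reads
    (same chrom, 5' start, strand) collapse to one before counting;
    ``library_size`` is the total number of (deduplicated) mapped reads.
    """
    for f in features:
        if f.length <= 0:  # pragma: no cover - SplitFeature already rejects
            raise ValueError(f"zero-length feature {f.feature_id}")
    if not isinstance(reads, ReadSet):
        reads = ReadSet.from_reads(reads)
    if dedup:
        reads = reads.dedup()
    counts: dict[str, int] = {}
    sorted_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in reads.chroms():
        a = reads.arrays(chrom)
        order = np.argsort(a["start"], kind="stable")
        sorted_chrom[chrom] = (a["start"][order], a["end"][order])
    for f in features:
        got = sorted_chrom.get(f.chrom)
        if got is None:
            counts[f.feature_id] = 0
            continue
        starts, ends = got
        lo = np.searchsorted(starts, f.interval[0], side="left")
        hi = np.searchsorted(starts, f.interval[1], side="left")
        counts[f.feature_id] = int((ends[lo:hi] <= f.interval[1]).sum())
    return CountTable(counts=counts, library_size=reads.n_reads, sample_id=sample_id)


def compute_rpkm(
    table: CountTable, features: Sequence[SplitFeature]
) -> dict[str, float]:
    """Reads per kilobase of feature per million mapped reads."""
    if table.library_size <= 0:
        raise ValueError("library_size must be positive for RPKM")
    scale = table.library_size / 1e6
    out = {}
    for f in features:
        c = table.counts.get(f.feature_id, 0)
        out[f.feature_id] = c / ((f.length / 1e3) * scale)
    return out


@dataclass
class RatioRecord:
    gene_id: str
    d3utr_count: int
    upstream_count: int
    d3utr_rpkm: float
    upstream_rpkm: float
    ratio: float  # NaN = NA (no upstream reads)

    @property
    def is_na(self) -> bool:
        return math.isnan(self.ratio)


def pair_features(
    features: Sequence[SplitFeature],
) -> dict[str, tuple[SplitFeature, SplitFeature]]:
    """gene_id -> (upstream_last_exon, d3utr) for genes carrying both."""
    ups: dict[str, SplitFeature] = {}
    d3s: dict[str, SplitFeature] = {}
    for f in features:
        if f.kind == UPSTREAM:
            ups[f.gene_id] = f
        elif f.kind == D3UTR:
            d3s[f.gene_id] = f
    pairs = {}
    for gid in sorted(set(ups) | set(d3s)):
        if gid in ups and gid in d3s:
            pairs[gid] = (ups[gid], d3s[gid])
        else:
            log.warning("gene %s lacks its upstream/d3utr partner; skipped", gid)
    return pairs


def compute_d3utr_ratios(
    rpkm: Mapping[str, float],
    features: Sequence[SplitFeature],
    counts: Mapping[str, int],
) -> list[RatioRecord]:
    """Per-gene d3'UTR ratio records; NA (NaN) when upstream count is zero."""
    records = []
    for gid, (up, d3) in pair_features(features).items():
        uc = int(counts.get(up.feature_id, 0))
        dc = int(counts.get(d3.feature_id, 0))
        ur = float(rpkm.get(up.feature_id, 0.0))
        dr = float(rpkm.get(d3.feature_id, 0.0))
        ratio = dr / ur if uc > 0 else float("nan")
        records.append(RatioRecord(gid, dc, uc, dr, ur, ratio))
    return records


def ratios_from_counts(
    table: CountTable, features: Sequence[SplitFeature]
) -> list[RatioRecord]:
    """Convenience: RPKM then ratios from one count table."""
    rpkm = compute_rpkm(table, features)
    return compute_d3utr_ratios(rpkm, features, table.counts)


# ---------------------------------------------------------------------------
# Two-condition comparison


@dataclass
class DiffExprRecord:
    gene_id: str
    mean_a: float
    mean_b: float
    fc: float
    z: float
    p: float
    label: str = "unassigned"


def median_of_ratios_size_factors(
    ka: np.ndarray, kb: np.ndarray, min_genes: int = 50
) -> tuple[float, float]:
    """Size factors from the median ratio to the per-gene geometric mean."""
    both = (ka > 0) & (kb > 0)
    if int(both.sum()) < min_genes:
        raise ValueError(
            f"only {int(both.sum())} genes nonzero in both samples "
            f"(need >= {min_genes}); size factors unstable"
        )
    gm = np.sqrt(ka[both].astype(float) * kb[both].astype(float))
    return float(np.median(ka[both] / gm)), float(np.median(kb[both] / gm))


def differential_expression(
    a: CountTable,
    b: CountTable,
    genes: Optional[Sequence[str]] = None,
    pseudocount: float = 0.5,
    n_bins: int = 20,
    min_genes: int = 50,
) -> list[DiffExprRecord]:
    """Normalized fold-changes b/a with binned robust standard scores.

    Genes are binned into ``n_bins`` equal-occupancy bins by normalized
    count in the reference sample ``a``; within a bin
    z = (log2 fc - median) / (1.4826 * MAD) and p is the one-sided upper
    normal tail.  Binning on the reference rather than the cross-condition
    mean keeps genes with genuine effects from migrating into shared bins
    whose robust location would absorb the effect.
    """
    if genes is None:
        genes = sorted(set(a.counts) | set(b.counts))
    ka = np.array([a.counts.get(g, 0) for g in genes], dtype=float)
    kb = np.array([b.counts.get(g, 0) for g in genes], dtype=float)
    sa, sb = median_of_ratios_size_factors(ka, kb, min_genes=min_genes)
    na, nb = ka / sa, kb / sb
    fc = (nb + pseudocount) / (na + pseudocount)
    log2fc = np.log2(fc)

    order = np.argsort(na, kind="stable")
    z = np.zeros(len(genes))
    for bin_idx in np.array_split(order, n_bins):
        if len(bin_idx) == 0:
            continue
        vals = log2fc[bin_idx]
        med = np.median(vals)
        sigma = 1.4826 * np.median(np.abs(vals - med))
        diff = vals - med
        if sigma == 0:
            zb = np.zeros(len(diff))
            zb[diff > 0] = np.inf
            zb[diff < 0] = -np.inf
            z[bin_idx] = zb
        else:
            z[bin_idx] = diff / sigma
    p = stats.norm.sf(z)

    records = [
        DiffExprRecord(g, float(na[i]), float(nb[i]), float(fc[i]), float(z[i]), float(p[i]))
        for i, g in enumerate(genes)
    ]
    return classify_aire_sensitivity(records)


def classify_aire_sensitivity(
    records: Sequence[DiffExprRecord],
    fc_sensitive: float = 3.0,
    p_sensitive: float = 0.01,
    fc_neutral: float = 2.0,
) -> list[DiffExprRecord]:
    """sensitive iff fc >= 3 and p < 0.01; neutral iff 0.5 < fc < 2."""
    for r in records:
        if r.fc >= fc_sensitive and r.p < p_sensitive:
            r.label = "sensitive"
        elif 1.0 / fc_neutral < r.fc < fc_neutral:
            r.label = "neutral"
        else:
            r.label = "unassigned"
    return list(records)


# ---------------------------------------------------------------------------
# Tab-delimited I/O (NA literal for missing ratios)


def write_count_table(table: CountTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# library_size={table.library_size}\tsample_id={table.sample_id}\n")
        fh.write("feature_id\tcount\n")
        for fid in sorted(table.counts):
            fh.write(f"{fid}\t{table.counts[fid]}\n")


def read_count_table(path) -> CountTable:
    counts = {}
    library_size = 0
    sample_id = ""
    with open(path) as fh:
        header = fh.readline()
        if header.startswith("#"):
            for part in header[1:].strip().split("\t"):
                k, _, v = part.partition("=")
                if k == "library_size":
                    library_size = int(v)
                elif k == "sample_id":
                    sample_id = v
            fh.readline()  # column header
        for line in fh:
            fid, c = line.rstrip("\n").split("\t")
            counts[fid] = int(c)
    if library_size == 0:
        library_size = sum(counts.values())
    return CountTable(counts=counts, library_size=library_size, sample_id=sample_id)


def write_ratio_table(records: Sequence[RatioRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\td3utr_count\tupstream_count\td3utr_rpkm\tupstream_rpkm\tratio\n"
        )
        for r in sorted(records, key=lambda r: r.gene_id):
            ratio = "NA" if r.is_na else f"{r.ratio:.6g}"
            fh.write(
                f"{r.gene_id}\t{r.d3utr_count}\t{r.upstream_count}\t"
                f"{r.d3utr_rpkm:.6g}\t{r.upstream_rpkm:.6g}\t{ratio}\n"
            )


def read_ratio_table(path) -> list[RatioRecord]:
    records = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            gid, dc, uc, dr, ur, ratio = line.rstrip("\n").split("\t")
            records.append(
                RatioRecord(
                    gid,
                    int(dc),
                    int(uc),
                    float(dr),
                    float(ur),
                    float("nan") if ratio == "NA" else float(ratio),
                )
            )
    return records


def write_diffexpr_table(records: Sequence[DiffExprRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tmean_a\tmean_b\tfc\tz\tp\tlabel\n")
        for r in sorted(records, key=lambda r: r.gene_id):
            fh.write(
                f"{r.gene_id}\t{r.mean_a:.6g}\t{r.mean_b:.6g}\t{r.fc:.6g}\t"
                f"{r.z:.6g}\t{r.p:.6g}\t{r.label}\n"
            )


def read_diffexpr_table(path) -> list[DiffExprRecord]:
    records = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            gid, ma, mb, fc, z, p, label = line.rstrip("\n").split("\t")
            records.append(
                DiffExprRecord(gid, float(ma), float(mb), float(fc), float(z), float(p), label)
            )
    return records
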