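"""Split 3'UTR annotation at proximal polyA sites.

Builds, from gene models and a polyA-site (pA) table, the two regions whose
expression ratio defines distal-3'UTR (d3'UTR) usage: the portion of the
last 3' exon upstream of the proximal pA (last coding-exon segment fused
with the proximal 3'UTR) and the d3'UTR segment from the pA to the distal
3'UTR boundary.

Coordinates are 0-based half-open internally; GTF input/output uses the
standard 1-based inclusive dialect.  A pA position marks the first base of
the d3'UTR in transcript orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

log = logging.getLogger(__name__)

Interval = tuple[int, int]

UPSTREAM = "upstream_last_exon"
D3UTR = "d3utr"
OTHER = "other_exon"


@dataclass(frozen=True)
class GeneModel:
    """One transcript's exon/CDS/3'UTR structure.

    ``exons`` are sorted, non-overlapping half-open genomic intervals;
    ``utr3`` intervals are subsets of exons and lie 3' of the CDS end in
    transcript orientation.
    """

    gene_id: str
    tx_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds: Optional[Interval] = None
    utr3: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.tx_id}")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "utr3", tuple(sorted(tuple(u) for u in self.utr3)))
        prev_end = None
        for s, e in exons:
            if e <= s:
                raise ValueError(f"degenerate exon [{s},{e}) in {self.tx_id}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"overlapping exons in {self.tx_id}")
            prev_end = e
        for u in self.utr3:
            if not any(s <= u[0] and u[1] <= e for s, e in exons):
                raise ValueError(f"utr3 {u} not inside an exon of {self.tx_id}")

    @property
    def last_exon(self) -> Interval:
        """Exon at the transcript 3' end (rightmost on +, leftmost on -)."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    @property
    def terminal_utr3(self) -> Optional[Interval]:
        """3'UTR interval lying in the last exon, or None."""
        if not self.utr3:
            return None
        term = self.utr3[-1] if self.strand == "+" else self.utr3[0]
        le = self.last_exon
        if not (le[0] <= term[0] and term[1] <= le[1]):
            return None
        return term

    @property
    def utr3_length(self) -> int:
        return sum(e - s for s, e in self.utr3)


@dataclass(frozen=True)
class PASite:
    """A cleavage/polyadenylation site tied to a gene."""

    chrom: str
    strand: str
    position: int
    gene_id: str


@dataclass(frozen=True)
class SplitFeature:
    """A quantifiable region of a gene."""

    gene_id: str
    kind: str
    chrom: str
    strand: str
    interval: Interval

    def __post_init__(self) -> None:
        if self.kind not in (UPSTREAM, D3UTR, OTHER):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.interval[1] <= self.interval[0]:
            raise ValueError(f"degenerate feature {self.interval} ({self.gene_id})")

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def feature_id(self) -> str:
        return f"{self.gene_id}:{self.kind}:{self.interval[0]}"


def _distal_distance(gene: GeneModel, pos: int, term: Interval) -> int:
    """Bases from the pA to the distal 3'UTR boundary, transcript orientation."""
    if gene.strand == "+":
        return term[1] - pos
    return pos + 1 - term[0]


def select_proximal_pa(
    gene: GeneModel, sites: Iterable[PASite], min_distance: int = 20
) -> Optional[PASite]:
    """Pick the validated proximal pA for a gene, or None.

    A site is valid when it lies inside the terminal 3'UTR interval and its
    distance to the distal 3'UTR boundary is at least ``min_distance`` bases.
    Among valid sites the most proximal one (closest to the stop codon in
    transcript orientation) is returned.
    """
    term = gene.terminal_utr3
    if term is None:
        return None
    valid = []
    for s in sites:
        if s.chrom != gene.chrom or s.strand != gene.strand:
            continue
        if not (term[0] <= s.position < term[1]):
            continue
        if _distal_distance(gene, s.position, term) < min_distance:
            continue
        valid.append(s)
    if not valid:
        return None
    if gene.strand == "+":
        return min(valid, key=lambda s: s.position)
    return max(valid, key=lambda s: s.position)


def pick_representative_transcripts(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """One transcript per gene_id: the longest annotated 3'UTR wins, ties by tx_id."""
    best: dict[str, GeneModel] = {}
    for g in genes:
        cur = best.get(g.gene_id)
        if (
            cur is None
            or g.utr3_length > cur.utr3_length
            or (g.utr3_length == cur.utr3_length and g.tx_id < cur.tx_id)
        ):
            best[g.gene_id] = g
    return [best[k] for k in sorted(best)]


def split_gene(
    gene: GeneModel, pa: Optional[PASite]
) -> list[SplitFeature]:
    """Features for one gene: the upstream/d3utr pair when a pA is given,
    all exons as ``other_exon`` otherwise."""
    mk = lambda kind, iv: SplitFeature(gene.gene_id, kind, gene.chrom, gene.strand, iv)
    if pa is None:
        return [mk(OTHER, e) for e in gene.exons]
    term = gene.terminal_utr3
    assert term is not None
    le = gene.last_exon
    if gene.strand == "+":
        upstream = (le[0], pa.position)
        d3 = (pa.position, term[1])
    else:
        upstream = (pa.position + 1, le[1])
        d3 = (term[0], pa.position + 1)
    if upstream[1] <= upstream[0] or d3[1] <= d3[0]:
        # degenerate split: treat as no valid pA
        return [mk(OTHER, e) for e in gene.exons]
    out = [mk(UPSTREAM, upstream), mk(D3UTR, d3)]
    for e in gene.exons:
        if e != le:
            out.append(mk(OTHER, e))
    return out


def build_split_annotation(
    genes: Sequence[GeneModel],
    sites: Sequence[PASite],
    min_distance: int = 20,
) -> list[SplitFeature]:
    """Split annotation over all genes.

    Genes without a validated proximal pA contribute only ``other_exon``
    features (single-pA genes); genes with one contribute an
    ``upstream_last_exon``/``d3utr`` pair abutting at the pA plus their
    remaining exons unchanged.  One transcript per gene_id is used
    (longest 3'UTR).
    """
    reps = pick_representative_transcripts(genes)
    by_gene: dict[str, list[PASite]] = {}
    for s in sites:
        by_gene.setdefault(s.gene_id, []).append(s)
    features: list[SplitFeature] = []
    for g in reps:
        pa = select_proximal_pa(g, by_gene.get(g.gene_id, ()), min_distance)
        features.extend(split_gene(g, pa))
    return features


def single_pa_genes(features: Sequence[SplitFeature]) -> set[str]:
    """Gene ids that carry no d3utr feature (no validated proximal pA)."""
    with_d3 = {f.gene_id for f in features if f.kind == D3UTR}
    return {f.gene_id for f in features} - with_d3


# ---------------------------------------------------------------------------
# I/O: GTF and tab-delimited tables


def write_split_gtf(features: Sequence[SplitFeature], path) -> None:
    """Write split features as GTF (1-based inclusive), deterministic order."""
    order = {UPSTREAM: 0, D3UTR: 1, OTHER: 2}
    feats = sorted(
        features, key=lambda f: (f.chrom, f.interval[0], order[f.kind], f.gene_id)
    )
    with open(path, "w") as fh:
        for f in feats:
            attrs = f'gene_id "{f.gene_id}"; feature_kind "{f.kind}";'
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        "apa",
                        f.kind,
                        str(f.interval[0] + 1),
                        str(f.interval[1]),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def _parse_gtf_attrs(field: str) -> dict[str, str]:
    out = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_split_gtf(path) -> list[SplitFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, kind, start, end, _sc, strand, _fr, attrs = line.rstrip(
                "\n"
            ).split("\t")
            a = _parse_gtf_attrs(attrs)
            feats.append(
                SplitFeature(
                    a["gene_id"], kind, chrom, strand, (int(start) - 1, int(end))
                )
            )
    return feats


def read_gene_models_gtf(path) -> list[GeneModel]:
    """Gene models from a GTF with exon / CDS / 3UTR feature lines.

    Feature names accepted for the 3'UTR: ``3UTR``, ``three_prime_utr``,
    ``three_prime_UTR``, ``UTR3``.
    """
    utr_names = {"3UTR", "three_prime_utr", "three_prime_UTR", "UTR3"}
    acc: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, kind, start, end, _sc, strand, _fr, attrs = line.rstrip(
                "\n"
            ).split("\t")
            if kind not in {"exon", "CDS"} | utr_names:
                continue
            a = _parse_gtf_attrs(attrs)
            tx = a.get("transcript_id", a["gene_id"])
            rec = acc.setdefault(
                tx,
                {
                    "gene_id": a["gene_id"],
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                    "utr3": [],
                },
            )
            iv = (int(start) - 1, int(end))
            if kind == "exon":
                rec["exons"].append(iv)
            elif kind == "CDS":
                rec["cds"].append(iv)
            else:
                rec["utr3"].append(iv)
    genes = []
    for tx, rec in sorted(acc.items()):
        cds = None
        if rec["cds"]:
            cds = (min(s for s, _ in rec["cds"]), max(e for _, e in rec["cds"]))
        genes.append(
            GeneModel(
                gene_id=rec["gene_id"],
                tx_id=tx,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(rec["exons"]),
                cds=cds,
                utr3=tuple(rec["utr3"]),
            )
        )
    return genes


def read_gene_models_refseq(path) -> list[GeneModel]:
    """Gene models from a refGene-style tab table.

    Columns (with header): tx_id, chrom, strand, tx_start, tx_end,
    cds_start, cds_end, exon_starts, exon_ends, gene_id.  Exon start/end
    lists are comma-separated, 0-based half-open.  The 3'UTR is derived as
    the exonic region 3' of the CDS end in transcript orientation.
    """
    import csv

    genes = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            starts = [int(x) for x in row["exon_starts"].rstrip(",").split(",")]
            ends = [int(x) for x in row["exon_ends"].rstrip(",").split(",")]
            exons = list(zip(starts, ends))
            cs, ce = int(row["cds_start"]), int(row["cds_end"])
            strand = row["strand"]
            utr3 = []
            if ce > cs:  # coding
                for s, e in exons:
                    if strand == "+":
                        lo, hi = max(s, ce), e
                    else:
                        lo, hi = s, min(e, cs)
                    if hi > lo:
                        utr3.append((lo, hi))
                cds = (cs, ce)
            else:
                cds = None
            genes.append(
                GeneModel(
                    gene_id=row["gene_id"],
                    tx_id=row["tx_id"],
                    chrom=row["chrom"],
                    strand=strand,
                    exons=tuple(exons),
                    cds=cds,
                    utr3=tuple(utr3),
                )
            )
    return genes


def read_pa_table(path) -> list[PASite]:
    """pA sites from a tab table with header chrom, strand, position, gene_id."""
    import csv

    sites = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sites.append(
                PASite(row["chrom"], row["strand"], int(row["position"]), row["gene_id"])
            )
    return sites


def write_pa_table(sites: Sequence[PASite], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstrand\tposition\tgene_id\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.strand}\t{s.position}\t{s.gene_id}\n")
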