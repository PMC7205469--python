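"""Synthetic inputs with planted ground truth for every pipeline stage.

Gene models carry a last exon whose 3'UTR can host a proximal pA; reads are
drawn uniformly within isoform bodies with the long-isoform fraction pi per
gene, so the estimated d3'UTR ratio converges to pi.  Additional generators
emit multi-tissue expression matrices, probe intensity tables, first-order
decay time courses, and coverage tracks with peaks planted at pA positions.

All outputs are fully determined by the config and its seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    D3UTR,
    UPSTREAM,
    GeneModel,
    PASite,
    SplitFeature,
    build_split_annotation,
)
from .profiles_stability import CoverageTrack
from .quantify import CountTable, ReadSet


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 200
    n_chroms: int = 4
    pa_fraction: float = 0.8
    read_length: int = 50
    # gene geometry (bases)
    other_exon_range: tuple[int, int] = (200, 400)
    last_cds_range: tuple[int, int] = (300, 500)
    utr3_range: tuple[int, int] = (2000, 3000)
    pa_utr_fraction: tuple[float, float] = (0.40, 0.60)
    intergenic_gap: int = 500
    # expression and two-condition effects
    pi_range: tuple[float, float] = (0.05, 0.95)
    mean_reads_per_gene: float = 2000.0
    log_expr_sd: float = 0.6
    sensitive_fraction: float = 0.1
    effect_fc_range: tuple[float, float] = (3.0, 8.0)
    sensitive_pi_delta: float = 0.0
    # tissue design
    n_tissues: int = 22
    n_specific: int = 20
    n_selective: int = 20
    n_flat: int = 60
    tissue_signal: float = 100.0
    tissue_background: float = 1.0
    tissue_noise_sd: float = 0.0
    # probe design
    probes_upstream: int = 3
    probes_d3utr: int = 2
    probe_noise_sd: float = 0.05
    probe_expr_sd: float = 1.5  # per-gene log2 expression spread
    n_replicates: int = 2
    probe_shift_fraction: float = 0.2
    # decay design
    half_lives: tuple[float, ...] = (2.0, 6.0, math.inf)
    genes_per_class: int = 200
    timepoints: tuple[float, ...] = (3.0, 6.0, 12.0)
    anchor_weight: float = 10.0
    decay_mean_count: float = 200.0
    # clip design
    clip_background: float = 1.0
    clip_peak_height: float = 20.0
    clip_peak_sd: float = 25.0

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SimulatedAnnotation:
    genes: list[GeneModel]
    sites: list[PASite]
    chrom_sizes: dict[str, int]
    truth: pd.DataFrame  # indexed by gene_id


def simulate_annotation(config: SimulationConfig) -> SimulatedAnnotation:
    """Gene models plus proximal pA sites and a per-gene truth table.

    Truth columns: has_pa, pi, base_expr, sensitive, effect_fc, strand,
    pa_position.  A configured fraction of genes carries one proximal pA
    at least 20 bases from the distal 3'UTR boundary.
    """
    if config.utr3_range[0] < 40 and config.pa_fraction > 0:
        raise ValueError("3'UTR shorter than 40 b cannot host a proximal pA")
    rng = np.random.default_rng(config.seed)
    genes: list[GeneModel] = []
    sites: list[PASite] = []
    rows = []
    cursor = {f"chr{i + 1}": 1000 for i in range(config.n_chroms)}
    n_sensitive = int(round(config.sensitive_fraction * config.n_genes))
    sensitive_ids = set(rng.choice(config.n_genes, size=n_sensitive, replace=False))
    for i in range(config.n_genes):
        gid = f"G{i:05d}"
        chrom = f"chr{i % config.n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        has_pa = rng.random() < config.pa_fraction
        other_len = int(rng.integers(*config.other_exon_range))
        cds_len = int(rng.integers(*config.last_cds_range))
        utr_len = int(rng.integers(*config.utr3_range))
        start = cursor[chrom]
        intron = 200
        if strand == "+":
            exon1 = (start, start + other_len)
            le_start = exon1[1] + intron
            last_exon = (le_start, le_start + cds_len + utr_len)
            utr = (le_start + cds_len, last_exon[1])
            cds = (exon1[0], le_start + cds_len)
        else:
            last_exon = (start, start + cds_len + utr_len)
            utr = (start, start + utr_len)
            e2_start = last_exon[1] + intron
            exon1 = (e2_start, e2_start + other_len)
            cds = (start + utr_len, exon1[1])
        exons = (exon1, last_exon) if strand == "+" else (last_exon, exon1)
        gene = GeneModel(gid, f"{gid}.t1", chrom, strand, exons, cds, (utr,))
        genes.append(gene)
        cursor[chrom] = max(exon1[1], last_exon[1]) + config.intergenic_gap

        pa_pos = -1
        if has_pa:
            frac = rng.uniform(*config.pa_utr_fraction)
            offset = int(round(frac * utr_len))
            offset = min(max(offset, 1), utr_len - 20)  # keep >=20 b to distal end
            if strand == "+":
                pa_pos = utr[0] + offset
            else:
                pa_pos = utr[1] - 1 - offset
            sites.append(PASite(chrom, strand, pa_pos, gid))

        pi = float(rng.uniform(*config.pi_range))
        sensitive = i in sensitive_ids
        if sensitive and config.sensitive_pi_delta:
            pi = max(0.02, pi - config.sensitive_pi_delta)
        effect = float(rng.uniform(*config.effect_fc_range)) if sensitive else 1.0
        base_expr = float(rng.lognormal(0.0, config.log_expr_sd))
        rows.append(
            {
                "gene_id": gid,
                "has_pa": has_pa,
                "pi": pi,
                "base_expr": base_expr,
                "sensitive": sensitive,
                "effect_fc": effect,
                "strand": strand,
                "pa_position": pa_pos,
            }
        )
    chrom_sizes = {c: cursor[c] + 2000 for c in cursor}
    truth = pd.DataFrame(rows).set_index("gene_id")
    return SimulatedAnnotation(genes, sites, chrom_sizes, truth)


def _isoform_segments(
    gene: GeneModel, pa_pos: int, read_length: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(short, long) isoform segment lists in genomic coordinates."""
    le = gene.last_exon
    others = [e for e in gene.exons if e != le]
    term = gene.terminal_utr3
    assert term is not None
    if gene.strand == "+":
        short_last = (le[0], pa_pos)
        long_last = (le[0], term[1])
    else:
        short_last = (pa_pos + 1, le[1])
        long_last = (term[0], le[1])
    return others + [short_last], others + [long_last]


def simulate_reads(
    config: SimulationConfig,
    annotation: SimulatedAnnotation,
    condition: str = "a",
    seed_offset: int = 0,
) -> ReadSet:
    """Uniform reads within isoform bodies at planted mixture proportions.

    A read is assigned to the long isoform with probability proportional to
    pi times the isoform's effective length (reads scale with transcript
    length), giving equal per-base start density across isoforms so the
    d3'UTR ratio estimates pi.  Condition "b" scales planted sensitive
    genes by their effect fold-change.
    """
    if condition not in ("a", "b"):
        raise ValueError("condition must be 'a' or 'b'")
    rng = np.random.default_rng((config.seed, 1, seed_offset))
    L = config.read_length
    buckets: dict[str, list[np.ndarray]] = {}
    strands: dict[str, list[np.ndarray]] = {}
    for gene in annotation.genes:
        t = annotation.truth.loc[gene.gene_id]
        expr = t["base_expr"]
        if condition == "b" and t["sensitive"]:
            expr = expr * t["effect_fc"]
        n = int(rng.poisson(expr * config.mean_reads_per_gene))
        if n == 0:
            continue
        if t["has_pa"]:
            short_segs, long_segs = _isoform_segments(gene, int(t["pa_position"]), L)
            pi = float(t["pi"])
        else:
            full = [e for e in gene.exons]
            short_segs, long_segs = full, full
            pi = 1.0
        w_short = sum(max(0, e - s - L + 1) for s, e in short_segs)
        w_long = sum(max(0, e - s - L + 1) for s, e in long_segs)
        p_long = pi * w_long / (pi * w_long + (1 - pi) * w_short) if w_short else 1.0
        n_long = int(rng.binomial(n, p_long))
        starts = []
        for segs, count in ((long_segs, n_long), (short_segs, n - n_long)):
            if count == 0:
                continue
            weights = np.array([max(0, e - s - L + 1) for s, e in segs], dtype=float)
            if weights.sum() == 0:
                continue
            seg_idx = rng.choice(len(segs), size=count, p=weights / weights.sum())
            for k, (s, e) in enumerate(segs):
                m = int((seg_idx == k).sum())
                if m:
                    starts.append(rng.integers(s, e - L + 1, size=m))
        if starts:
            st = np.concatenate(starts)
            buckets.setdefault(gene.chrom, []).append(st)
            fwd = rng.random(len(st)) < 0.5  # unstranded library
            strands.setdefault(gene.chrom, []).append(fwd)
    per_chrom = {}
    for chrom, lst in buckets.items():
        st = np.concatenate(lst)
        fwd = np.concatenate(strands[chrom])
        order = np.argsort(st, kind="stable")
        per_chrom[chrom] = {
            "start": st[order],
            "end": st[order] + L,
            "fwd": fwd[order],
        }
    return ReadSet(per_chrom)


def write_sam(reads: ReadSet, chrom_sizes: Mapping[str, int], path) -> None:
    """Plain-text single-end SAM with minimal header."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom in sorted(chrom_sizes):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{chrom_sizes[chrom]}\n")
        i = 0
        for chrom in reads.chroms():
            a = reads.arrays(chrom)
            for s, e, f in zip(a["start"], a["end"], a["fwd"]):
                flag = 0 if f else 16
                fh.write(
                    f"r{i:08d}\t{flag}\t{chrom}\t{s + 1}\t255\t{e - s}M\t*\t0\t0\t*\t*\n"
                )
                i += 1


def simulate_tissue_matrix(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multi-tissue expression matrix with planted specificity labels.

    Returns (matrix, truth) where truth has columns label
    (specific/selective/flat) and tissues (comma-joined planted tissues).
    """
    rng = np.random.default_rng((config.seed, 2))
    tissues = [f"T{i + 1:02d}" for i in range(config.n_tissues)]
    rows, trows = [], []
    idx = []

    def noisy(values: np.ndarray) -> np.ndarray:
        if config.tissue_noise_sd > 0:
            return values * rng.lognormal(0.0, config.tissue_noise_sd, size=len(values))
        return values

    for i in range(config.n_specific):
        gid = f"SP{i:04d}"
        x = np.full(config.n_tissues, config.tissue_background)
        j = int(rng.integers(config.n_tissues))
        x[j] = config.tissue_signal
        rows.append(noisy(x))
        idx.append(gid)
        trows.append({"gene_id": gid, "label": "specific", "tissues": tissues[j]})
    for i in range(config.n_selective):
        gid = f"SE{i:04d}"
        k = int(rng.integers(2, 5))
        js = rng.choice(config.n_tissues, size=k, replace=False)
        x = np.full(config.n_tissues, config.tissue_background)
        x[js] = config.tissue_signal
        rows.append(noisy(x))
        idx.append(gid)
        trows.append(
            {
                "gene_id": gid,
                "label": "selective",
                "tissues": ",".join(sorted(tissues[j] for j in js)),
            }
        )
    for i in range(config.n_flat):
        gid = f"FL{i:04d}"
        x = np.full(config.n_tissues, config.tissue_signal / 4)
        rows.append(noisy(x))
        idx.append(gid)
        trows.append({"gene_id": gid, "label": "flat", "tissues": ""})
    matrix = pd.DataFrame(np.array(rows), index=idx, columns=tissues)
    truth = pd.DataFrame(trows).set_index("gene_id")
    return matrix, truth


def simulate_probes(
    config: SimulationConfig,
    annotation: SimulatedAnnotation,
    features: Optional[Sequence[SplitFeature]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe intensity table consistent with planted d3'UTR ratio shifts.

    Returns (probes, truth).  Probe columns: probe_id, gene_id, chrom,
    start, end, then log2 intensities a1..aN, b1..bN.  A configured
    fraction of genes with a d3utr gets its d3'UTR level doubled in
    condition b (planted increase); truth records the planted direction.
    """
    rng = np.random.default_rng((config.seed, 3))
    if features is None:
        features = build_split_annotation(annotation.genes, annotation.sites)
    ups = {f.gene_id: f for f in features if f.kind == UPSTREAM}
    d3s = {f.gene_id: f for f in features if f.kind == D3UTR}
    samples = [f"a{r + 1}" for r in range(config.n_replicates)] + [
        f"b{r + 1}" for r in range(config.n_replicates)
    ]
    rows, trows = [], []
    for gid in sorted(d3s):
        up, d3 = ups[gid], d3s[gid]
        shifted = rng.random() < config.probe_shift_fraction
        # per-gene expression spread keeps the background filter from
        # preferentially trimming the (dimmer) d3utr probes of typical genes
        level_up = 100.0 * 2.0 ** rng.normal(0, config.probe_expr_sd)
        d3_a = level_up * 0.4
        d3_b = d3_a * (2.0 if shifted else 1.0)
        trows.append(
            {
                "gene_id": gid,
                "planted_direction": "increase" if shifted else "none",
                "n_d3_probes": config.probes_d3utr,
            }
        )

        def place(feature, n):
            span = feature.length
            return [
                (
                    feature.interval[0] + int(k * span / (n + 1)),
                    feature.interval[0] + int(k * span / (n + 1)) + 25,
                )
                for k in range(1, n + 1)
            ]

        for k, (s, e) in enumerate(place(up, config.probes_upstream)):
            intens = {
                smp: float(np.log2(level_up) + rng.normal(0, config.probe_noise_sd))
                for smp in samples
            }
            rows.append(
                {
                    "probe_id": f"{gid}_u{k}",
                    "gene_id": gid,
                    "chrom": up.chrom,
                    "start": s,
                    "end": e,
                    **intens,
                }
            )
        for k, (s, e) in enumerate(place(d3, config.probes_d3utr)):
            intens = {}
            for smp in samples:
                level = d3_b if smp.startswith("b") else d3_a
                intens[smp] = float(np.log2(level) + rng.normal(0, config.probe_noise_sd))
            rows.append(
                {
                    "probe_id": f"{gid}_d{k}",
                    "gene_id": gid,
                    "chrom": d3.chrom,
                    "start": s,
                    "end": e,
                    **intens,
                }
            )
    probes = pd.DataFrame(rows)
    truth = pd.DataFrame(trows).set_index("gene_id")
    return probes, truth


def simulate_decay(
    config: SimulationConfig,
) -> tuple[dict[float, CountTable], CountTable, pd.DataFrame]:
    """First-order decay time courses with class-dependent half-lives.

    Returns (treated tables by timepoint, control table, truth).  Counts
    are Poisson around expression * 2^(-t / half_life); a heavy stable
    anchor gene set keeps total-count normalization meaningful; library
    sizes are whatever the Poisson draws sum to.
    """
    rng = np.random.default_rng((config.seed, 4))
    classes = list(config.half_lives)
    genes, expr, hl = [], [], []
    for ci, h in enumerate(classes):
        for i in range(config.genes_per_class):
            genes.append(f"D{ci}_{i:04d}")
            expr.append(rng.lognormal(0.0, config.log_expr_sd))
            hl.append(h)
    # stable anchors dominating the library so totals barely move
    n_anchor = max(10, config.genes_per_class // 4)
    for i in range(n_anchor):
        genes.append(f"ANCHOR_{i:04d}")
        expr.append(
            config.anchor_weight
            * config.genes_per_class
            * len(classes)
            / n_anchor
        )
        hl.append(math.inf)
    expr = np.asarray(expr)
    hl = np.asarray(hl)

    def table(scale: np.ndarray, sample_id: str) -> CountTable:
        lam = expr * scale * config.decay_mean_count
        counts = rng.poisson(lam)
        return CountTable(
            counts={g: int(c) for g, c in zip(genes, counts)},
            library_size=int(counts.sum()),
            sample_id=sample_id,
        )

    control = table(np.ones_like(expr), "control")
    treated = {}
    for t in config.timepoints:
        decay = np.where(np.isinf(hl), 1.0, 2.0 ** (-t / hl))
        treated[float(t)] = table(decay, f"actd_{t:g}h")
    truth = pd.DataFrame(
        {"gene_id": genes, "half_life": hl, "base_expr": expr}
    ).set_index("gene_id")
    return treated, control, truth


def simulate_clip(
    config: SimulationConfig,
    annotation: SimulatedAnnotation,
    peak_at: str = "proximal",
) -> CoverageTrack:
    """Coverage with Gaussian peaks at pA positions over uniform background.

    ``peak_at``: "proximal" puts peaks at planted proximal pAs, "distal" at
    distal 3'UTR boundaries, "none" leaves a flat track.
    """
    per_chrom = {
        c: np.full(n, config.clip_background, dtype=float)
        for c, n in annotation.chrom_sizes.items()
    }
    positions: list[tuple[str, int]] = []
    if peak_at == "proximal":
        positions = [(s.chrom, s.position) for s in annotation.sites]
    elif peak_at == "distal":
        for g in annotation.genes:
            term = g.terminal_utr3
            if term is None:
                continue
            pos = term[1] - 1 if g.strand == "+" else term[0]
            positions.append((g.chrom, pos))
    elif peak_at != "none":
        raise ValueError("peak_at must be proximal, distal, or none")
    half_span = int(4 * config.clip_peak_sd)
    kernel = config.clip_peak_height * np.exp(
        -0.5 * (np.arange(-half_span, half_span + 1) / config.clip_peak_sd) ** 2
    )
    for chrom, pos in positions:
        v = per_chrom[chrom]
        lo, hi = pos - half_span, pos + half_span + 1
        klo, khi = max(0, -lo), len(kernel) - max(0, hi - len(v))
        v[max(0, lo) : min(len(v), hi)] += kernel[klo:khi]
    return CoverageTrack(per_chrom)


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")
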