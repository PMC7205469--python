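"""Probe-level microarray d3'UTR analysis.

For each gene with at least two probes in its d3'UTR, the probe-level
d3'UTR ratio is mean d3'UTR probe intensity over mean intensity of all the
gene's probes (linear scale).  Per-gene increase/decrease calls between two
conditions come from a Welch t-test on replicate-level ratios, and a 2x2
chi-squared test compares the genome-wide increase/decrease balance of a
candidate knockdown against a control comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import D3UTR, SplitFeature

log = logging.getLogger(__name__)

EXCLUDED = "excluded"
INCREASE = "increase"
DECREASE = "decrease"
NOT_SIGNIFICANT = "not_significant"


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    gene_id: str
    chrom: str
    interval: tuple[int, int]
    log2_intensity: Mapping[str, float]  # sample -> value


@dataclass
class GeneRatioChange:
    gene_id: str
    ratio_a: float
    ratio_b: float
    direction: str
    p: float = float("nan")
    fallback: bool = False  # True when called on fold-change only


def read_probe_table(path) -> list[ProbeRecord]:
    """Probes from a tab table: probe_id, gene_id, chrom, start, end, then
    one log2-intensity column per sample."""
    return read_probe_table_df(pd.read_csv(path, sep="\t"))


def read_probe_table_df(df: pd.DataFrame) -> list[ProbeRecord]:
    fixed = ["probe_id", "gene_id", "chrom", "start", "end"]
    samples = [c for c in df.columns if c not in fixed]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            ProbeRecord(
                str(d["probe_id"]),
                str(d["gene_id"]),
                str(d["chrom"]),
                (int(d["start"]), int(d["end"])),
                {s: float(d[s]) for s in samples},
            )
        )
    return records


def filter_background(
    probes: Sequence[ProbeRecord],
    samples: Sequence[str],
    quantile: float = 0.05,
) -> list[ProbeRecord]:
    """Keep probes above background in every compared sample.

    Background is the given quantile of all probe intensities per sample;
    a non-positive quantile disables the filter.
    """
    if not probes:
        return []
    if quantile <= 0:
        return list(probes)
    thresholds = {
        s: float(np.quantile([p.log2_intensity[s] for p in probes], quantile))
        for s in samples
    }
    return [
        p
        for p in probes
        if all(p.log2_intensity[s] > thresholds[s] for s in samples)
    ]


def _in_d3utr(probe: ProbeRecord, d3: Optional[SplitFeature]) -> bool:
    if d3 is None or probe.chrom != d3.chrom:
        return False
    return d3.interval[0] <= probe.interval[0] and probe.interval[1] <= d3.interval[1]


def probe_d3utr_ratio(
    probes: Sequence[ProbeRecord],
    d3_feature: Optional[SplitFeature],
    sample: str,
    min_d3_probes: int = 2,
) -> Optional[float]:
    """Probe-level d3'UTR ratio of one gene in one sample, or None (excluded).

    Linear-scale mean of d3'UTR probes over linear-scale mean of all probes.
    Excluded when fewer than ``min_d3_probes`` probes fall inside the d3'UTR.
    """
    if not probes:
        return None
    d3_vals = [
        2.0 ** p.log2_intensity[sample] for p in probes if _in_d3utr(p, d3_feature)
    ]
    if len(d3_vals) < min_d3_probes:
        return None
    all_vals = [2.0 ** p.log2_intensity[sample] for p in probes]
    return float(np.mean(d3_vals) / np.mean(all_vals))


def per_gene_ratio_change(
    probes: Sequence[ProbeRecord],
    d3_feature: Optional[SplitFeature],
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    gene_id: str = "",
    alpha: float = 0.05,
    fc_fallback: float = 1.5,
) -> GeneRatioChange:
    """Direction of the d3'UTR ratio change of one gene between conditions.

    Replicate-level ratios feed a pooled two-sample t-test at ``alpha``
    (exact under the null with the duplicate arrays available here, where
    Welch's approximation is badly conservative); the sign comes from
    mean(ratio_b) - mean(ratio_a).  Without replicates (one sample per
    condition) a fold-change-only call (|log2 change| > log2 1.5) is made
    and flagged.
    """
    gene_id = gene_id or (probes[0].gene_id if probes else "")
    ra = [probe_d3utr_ratio(probes, d3_feature, s) for s in samples_a]
    rb = [probe_d3utr_ratio(probes, d3_feature, s) for s in samples_b]
    if any(r is None for r in ra + rb):
        return GeneRatioChange(gene_id, float("nan"), float("nan"), EXCLUDED)
    mean_a, mean_b = float(np.mean(ra)), float(np.mean(rb))
    if len(ra) < 2 or len(rb) < 2:
        delta = np.log2(mean_b) - np.log2(mean_a)
        if abs(delta) > np.log2(fc_fallback):
            direction = INCREASE if delta > 0 else DECREASE
        else:
            direction = NOT_SIGNIFICANT
        return GeneRatioChange(gene_id, mean_a, mean_b, direction, fallback=True)
    t, p = stats.ttest_ind(rb, ra, equal_var=True)
    if p < alpha:
        direction = INCREASE if mean_b > mean_a else DECREASE
    else:
        direction = NOT_SIGNIFICANT
    return GeneRatioChange(gene_id, mean_a, mean_b, direction, p=float(p))


def screen_genes(
    probes: Sequence[ProbeRecord],
    d3_features: Mapping[str, SplitFeature],
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    background_quantile: float = 0.05,
    alpha: float = 0.05,
) -> list[GeneRatioChange]:
    """Per-gene direction calls across a whole probe table."""
    kept = filter_background(probes, list(samples_a) + list(samples_b), background_quantile)
    by_gene: dict[str, list[ProbeRecord]] = {}
    for p in kept:
        by_gene.setdefault(p.gene_id, []).append(p)
    return [
        per_gene_ratio_change(
            by_gene[g], d3_features.get(g), samples_a, samples_b, gene_id=g, alpha=alpha
        )
        for g in sorted(by_gene)
    ]


@dataclass
class ImbalanceResult:
    statistic: float
    p: float
    stars: str  # "" / "*" / "**"
    table: tuple[tuple[int, int], tuple[int, int]]  # (cand up/down, ctrl up/down)
    exact_fallback: bool = False


def ratio_imbalance_test(
    candidate: Sequence[GeneRatioChange],
    control: Sequence[GeneRatioChange],
) -> ImbalanceResult:
    """2x2 chi-squared on increase/decrease counts, candidate vs control.

    Star labels: "*" for p < 1e-4, "**" for p < 1e-9.  When any margin is
    zero the chi-squared is undefined and Fisher's exact test is used,
    flagged in the result.
    """

    def updown(changes):
        up = sum(1 for c in changes if c.direction == INCREASE)
        down = sum(1 for c in changes if c.direction == DECREASE)
        return up, down

    cu, cd = updown(candidate)
    ku, kd = updown(control)
    table = np.array([[cu, cd], [ku, kd]], dtype=float)
    exact = False
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        _, p = stats.fisher_exact([[cu, cd], [ku, kd]])
        statistic = float("nan")
        exact = True
    else:
        statistic, p, _, _ = stats.chi2_contingency(table, correction=False)
        statistic = float(statistic)
    stars = "**" if p < 1e-9 else "*" if p < 1e-4 else ""
    return ImbalanceResult(statistic, float(p), stars, ((cu, cd), (ku, kd)), exact)


def write_screen_table(changes: Sequence[GeneRatioChange], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tratio_a\tratio_b\tdirection\tp\tfallback\n")
        for c in sorted(changes, key=lambda c: c.gene_id):
            ra = "NA" if np.isnan(c.ratio_a) else f"{c.ratio_a:.6g}"
            rb = "NA" if np.isnan(c.ratio_b) else f"{c.ratio_b:.6g}"
            p = "NA" if np.isnan(c.p) else f"{c.p:.6g}"
            fh.write(f"{c.gene_id}\t{ra}\t{rb}\t{c.direction}\t{p}\t{int(c.fallback)}\n")
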