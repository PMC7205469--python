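"""pA-centred coverage metaprofiles and transcript-stability analysis.

Metaprofiles average read density in fixed windows around polyA sites,
with minus-strand windows reversed so bins run 5'->3' in transcript
orientation.  Decay analysis normalizes each timepoint to total read counts
and expresses every gene relative to the untreated control; genes are
classified by the change of their d3'UTR ratio between conditions
(decreased < 0.5x, steady within 1.2-fold) and the decreased/steady groups
are compared per timepoint with a two-sided rank-sum test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .annotation import PASite
from .quantify import CountTable

log = logging.getLogger(__name__)

DECREASED = "decreased"
STEADY = "steady"
OTHER = "other"


class CoverageTrack:
    """Per-chromosome dense vectors of non-negative read density."""

    def __init__(self, per_chrom: Mapping[str, np.ndarray]):
        self._per_chrom = {c: np.asarray(v, dtype=float) for c, v in per_chrom.items()}
        for c, v in self._per_chrom.items():
            if (v < 0).any():
                raise ValueError(f"negative density on {c}")

    @classmethod
    def from_bedgraph(cls, path, chrom_sizes: Optional[Mapping[str, int]] = None):
        intervals: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, start, end, value = line.rstrip("\n").split("\t")
                intervals.setdefault(chrom, []).append(
                    (int(start), int(end), float(value))
                )
        per_chrom = {}
        for chrom, ivs in intervals.items():
            size = (
                chrom_sizes[chrom]
                if chrom_sizes and chrom in chrom_sizes
                else max(e for _, e, _ in ivs)
            )
            v = np.zeros(size)
            for s, e, val in ivs:
                v[s:e] = val
            per_chrom[chrom] = v
        return cls(per_chrom)

    def to_bedgraph(self, path) -> None:
        """Run-length-encoded bedGraph; zero runs are omitted."""
        with open(path, "w") as fh:
            for chrom in sorted(self._per_chrom):
                v = self._per_chrom[chrom]
                if len(v) == 0:
                    continue
                breaks = np.flatnonzero(np.diff(v)) + 1
                starts = np.concatenate([[0], breaks])
                ends = np.concatenate([breaks, [len(v)]])
                for s, e in zip(starts, ends):
                    val = v[s]
                    if val != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{val:.6g}\n")

    def chrom(self, name: str) -> Optional[np.ndarray]:
        return self._per_chrom.get(name)


@dataclass
class MetaProfile:
    window: int
    binsize: int
    bins: np.ndarray  # mean density per offset, 5'->3' in transcript direction
    n_sites: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1, self.binsize)


def site_metaprofile(
    track: CoverageTrack,
    sites: Sequence[PASite],
    window: int = 1000,
    binsize: int = 10,
) -> MetaProfile:
    """Average density profile around sites, oriented 5'->3'.

    Bin centres sit at offsets -window..window in steps of ``binsize``;
    each bin averages density over ``binsize`` bases centred on its offset.
    Minus-strand windows are reversed before averaging.  Sites whose window
    would leave the chromosome are skipped with a warning.
    """
    if window % binsize != 0:
        raise ValueError("window must be a multiple of binsize")
    n_bins = 2 * window // binsize + 1
    half = binsize // 2
    lo_off = -window - half
    hi_off = window + (binsize - half)
    acc = np.zeros(n_bins)
    used = 0
    for s in sites:
        v = track.chrom(s.chrom)
        if v is None:
            log.warning("site %s: chromosome %s absent from track", s.gene_id, s.chrom)
            continue
        # displacement d (5'->3' in transcript orientation) maps to genomic
        # position pos+d on + and pos-d on -, keeping reflection exact
        if s.strand == "+":
            a, b = s.position + lo_off, s.position + hi_off
            if a < 0 or b > len(v):
                log.warning("site %s@%d too close to chromosome edge; skipped", s.gene_id, s.position)
                continue
            win = v[a:b]
        else:
            a, b = s.position - hi_off + 1, s.position - lo_off + 1
            if a < 0 or b > len(v):
                log.warning("site %s@%d too close to chromosome edge; skipped", s.gene_id, s.position)
                continue
            win = v[a:b][::-1]
        acc += win.reshape(n_bins, binsize).mean(axis=1)
        used += 1
    if used == 0:
        raise ValueError("no usable site")
    return MetaProfile(window=window, binsize=binsize, bins=acc / used, n_sites=used)


# ---------------------------------------------------------------------------
# Decay / stability


@dataclass
class DecayRecord:
    gene_id: str
    timepoints: tuple[float, ...]
    rel_expr: tuple[float, ...]
    shortening_class: str = OTHER


def decay_relative_expression(
    treated: Mapping[float, CountTable],
    control: CountTable,
    pseudocount: float = 0.5,
) -> list[DecayRecord]:
    """Total-count-normalized treated/control expression ratio per timepoint."""
    if control.library_size <= 0:
        raise ValueError("control library is empty")
    times = tuple(sorted(treated))
    genes = sorted(control.counts)
    records = []
    for g in genes:
        ctrl = (control.counts.get(g, 0) + pseudocount) / control.library_size
        rel = []
        for t in times:
            tab = treated[t]
            if tab.library_size <= 0:
                raise ValueError(f"treated library at t={t} is empty")
            rel.append(
                ((tab.counts.get(g, 0) + pseudocount) / tab.library_size) / ctrl
            )
        records.append(DecayRecord(g, times, tuple(rel)))
    return records


def classify_shortening(
    ratio_ctr: float, ratio_kd: float, steady_fold: float = 1.2
) -> str:
    """decreased iff ratio_ctr/ratio_kd < 0.5 (strict); steady within
    ``steady_fold``; other in between.  NaN input is undefined."""
    if math.isnan(ratio_ctr) or math.isnan(ratio_kd):
        raise ValueError("NA ratio: gene must be excluded upstream")
    r = ratio_ctr / ratio_kd
    if r < 0.5:
        return DECREASED
    if abs(math.log2(r)) <= math.log2(steady_fold):
        return STEADY
    return OTHER


def label_decay_records(
    records: Sequence[DecayRecord],
    ratios_ctr: Mapping[str, float],
    ratios_kd: Mapping[str, float],
) -> list[DecayRecord]:
    """Attach shortening classes; genes with NA ratios are dropped."""
    out = []
    for r in records:
        rc = ratios_ctr.get(r.gene_id, float("nan"))
        rk = ratios_kd.get(r.gene_id, float("nan"))
        if math.isnan(rc) or math.isnan(rk):
            continue
        r.shortening_class = classify_shortening(rc, rk)
        out.append(r)
    return out


def compare_decay_groups(
    records: Sequence[DecayRecord],
    group_a: str = DECREASED,
    group_b: str = STEADY,
    min_group: int = 3,
) -> dict[float, float]:
    """Two-sided rank-sum p per timepoint between two shortening classes.

    Returns {timepoint: p}; NaN when either group has fewer than
    ``min_group`` members.
    """
    if not records:
        return {}
    times = records[0].timepoints
    a = [r for r in records if r.shortening_class == group_a]
    b = [r for r in records if r.shortening_class == group_b]
    out = {}
    for i, t in enumerate(times):
        xa = [r.rel_expr[i] for r in a]
        xb = [r.rel_expr[i] for r in b]
        if len(xa) < min_group or len(xb) < min_group:
            out[t] = float("nan")
            continue
        _, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        out[t] = float(p)
    return out


def loess_curve(
    x: Sequence[float], y: Sequence[float], frac: float = 0.75
) -> np.ndarray:
    """Lowess fit for descriptive plotting only (never used in tests of
    significance).  Returns an (n, 2) array of (x, fitted y) sorted by x."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    return lowess(np.asarray(y, float), np.asarray(x, float), frac=frac)


def write_profile_table(profile: MetaProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tmean_density\n")
        for off, val in zip(profile.offsets, profile.bins):
            fh.write(f"{off}\t{val:.6g}\n")


def write_decay_table(records: Sequence[DecayRecord], path) -> None:
    if not records:
        with open(path, "w") as fh:
            fh.write("gene_id\tshortening_class\n")
        return
    times = records[0].timepoints
    with open(path, "w") as fh:
        cols = "\t".join(f"rel_expr_{t:g}h" for t in times)
        fh.write(f"gene_id\tshortening_class\t{cols}\n")
        for r in sorted(records, key=lambda r: r.gene_id):
            vals = "\t".join(f"{v:.6g}" for v in r.rel_expr)
            fh.write(f"{r.gene_id}\t{r.shortening_class}\t{vals}\n")
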