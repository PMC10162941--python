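"""Genomic interval algebra and file I/O.

All coordinates are 0-based half-open ``[start, end)`` — the native BED
convention — everywhere inside the package.  Overlap is strict half-open:
touching intervals (``a.end == b.start``) do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval on one chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class Gene:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    interval: GenomicInterval
    alt_tss: tuple = ()   # additional annotated TSSs (isoforms)

    @property
    def all_tss(self) -> tuple:
        return (self.tss, *self.alt_tss)


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus a gene table with TSS coordinates."""

    chrom_sizes: dict[str, int]
    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene_ids must be unique")
        for g in self.genes:
            size = self.chrom_sizes.get(g.chrom)
            if size is None or g.interval.end > size:
                raise ValueError(f"gene {g.gene_id} outside chromosome {g.chrom}")

    @property
    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "tss": [g.tss for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "start": [g.interval.start for g in self.genes],
                "end": [g.interval.end for g in self.genes],
            }
        )

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def merge_intervals(
    intervals: Sequence[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose inner distance is at most ``gap``.

    Two intervals merge when ``next.start - current.end <= gap`` (non-strict:
    with the ROSE default gap of 12 500 bp, peaks exactly 12 500 bp apart are
    stitched).  Merging is transitive and per-chromosome; output is sorted.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if (
            merged
            and iv.chrom == merged[-1].chrom
            and iv.start - merged[-1].end <= gap
        ):
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def union_partition(
    interval_sets: Mapping[str, Sequence[tuple[GenomicInterval, str]]],
    exclude_sex_chroms: bool = True,
) -> tuple[list[GenomicInterval], pd.DataFrame]:
    """Finest common partition of labelled segmentations across samples.

    Emulates ``bedtools unionbed`` on per-sample segmentations: all interval
    breakpoints define atomic regions, and each matrix cell holds the label of
    the covering interval of that sample.  Only regions covered by *every*
    sample are returned.  Within one sample the intervals must not overlap.
    """
    samples = list(interval_sets)
    chroms: set[str] = set()
    for sample, ivs in interval_sets.items():
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv, _label in ivs:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping intervals in sample {sample} on {chrom}"
                    )
            chroms.add(chrom)
    if exclude_sex_chroms:
        chroms -= SEX_CHROMS

    regions: list[GenomicInterval] = []
    blocks: list[np.ndarray] = []
    for chrom in sorted(chroms):
        cuts: set[int] = set()
        per_sample: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for sample in samples:
            segs = sorted(
                (iv.start, iv.end, lab)
                for iv, lab in interval_sets[sample]
                if iv.chrom == chrom
            )
            starts = np.array([s for s, _, _ in segs], dtype=np.int64)
            ends = np.array([e for _, e, _ in segs], dtype=np.int64)
            labs = np.array([l for _, _, l in segs], dtype=object)
            per_sample[sample] = (starts, ends, labs)
            cuts.update(starts.tolist())
            cuts.update(ends.tolist())
        bounds = np.array(sorted(cuts), dtype=np.int64)
        if len(bounds) < 2:
            continue
        lows, highs = bounds[:-1], bounds[1:]
        covered = np.ones(len(lows), dtype=bool)
        cols = []
        for sample in samples:
            starts, ends, labs = per_sample[sample]
            if len(starts) == 0:
                covered[:] = False
                cols.append(np.full(len(lows), "", dtype=object))
                continue
            idx = np.searchsorted(starts, lows, side="right") - 1
            ok = (idx >= 0) & (highs <= ends[np.clip(idx, 0, None)])
            covered &= ok
            col = np.full(len(lows), "", dtype=object)
            col[ok] = labs[idx[ok]]
            cols.append(col)
        for lo, hi in zip(lows[covered], highs[covered]):
            regions.append(GenomicInterval(chrom, int(lo), int(hi)))
        blocks.append(np.column_stack(cols)[covered])
    index = [f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    data = np.vstack(blocks) if blocks else np.empty((0, len(samples)), object)
    matrix = pd.DataFrame(data, index=index, columns=samples)
    return regions, matrix


def overlaps(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """Index pairs ``(i, j)`` where ``a[i]`` overlaps ``b[j]`` (half-open)."""
    order_b = sorted(range(len(b)), key=lambda j: (b[j].chrom, b[j].start))
    pairs: list[tuple[int, int]] = []
    # sweep per chromosome over b sorted by start
    by_chrom: dict[str, list[int]] = {}
    for j in order_b:
        by_chrom.setdefault(b[j].chrom, []).append(j)
    for i, iv in enumerate(a):
        for j in by_chrom.get(iv.chrom, ()):
            bj = b[j]
            if bj.start >= iv.end:
                break
            if bj.end > iv.start:
                pairs.append((i, j))
    return sorted(pairs)


def nearest_tss(
    interval: GenomicInterval, genome: GenomeAnnotation
) -> tuple[str, int]:
    """Gene with the TSS closest to the interval midpoint; ties by gene_id."""
    candidates = genome.genes_on(interval.chrom)
    if not candidates:
        raise ValueError(f"no genes on {interval.chrom}")
    mid = interval.midpoint
    best = min(candidates, key=lambda g: (abs(g.tss - mid), g.gene_id))
    return best.gene_id, int(abs(best.tss - mid))


# ---------------------------------------------------------------------------
# file I/O — BED (tab-delimited, headerless, 0-based half-open) and TSV tables
# ---------------------------------------------------------------------------


def read_bed(path) -> pd.DataFrame:
    """Read BED3/4/6 into a DataFrame with canonical column names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    return df


def write_bed(df: pd.DataFrame, path, columns: Sequence[str] | None = None) -> None:
    cols = list(columns) if columns else [c for c in
            ("chrom", "start", "end", "name", "score", "strand") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def intervals_from_bed(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(str(c), int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]


def read_signal_table(path) -> pd.DataFrame:
    """Signal TSV with header: sample, chrom, start, end, ip, input."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "chrom", "start", "end", "ip", "input"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"signal table missing columns: {sorted(missing)}")
    return df


def write_signal_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_bed(path) -> GenomeAnnotation:
    """Gene annotation as BED6 with gene_id in the name column.

    The TSS is the strand-aware 5' end.  Chromosome sizes are taken as the
    maximal annotated coordinate (callers with real assemblies should build
    :class:`GenomeAnnotation` directly).
    """
    df = read_bed(path)
    genes = []
    for row in df.itertuples(index=False):
        strand = getattr(row, "strand", "+")
        tss = int(row.start) if strand == "+" else int(row.end) - 1
        genes.append(
            Gene(
                gene_id=str(row.name),
                chrom=str(row.chrom),
                tss=tss,
                strand=strand,
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
            )
        )
    sizes: dict[str, int] = {}
    for g in genes:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.interval.end)
    return GenomeAnnotation(chrom_sizes=sizes, genes=genes)


def write_gene_bed(genome: GenomeAnnotation, path) -> None:
    df = genome.gene_table
    out = df.assign(score=0)[["chrom", "start", "end", "gene_id", "score", "strand"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_segmentation_bed(path) -> list[tuple[GenomicInterval, str]]:
    """BED4 with the chromatin-state label (E1..E6) in the name column."""
    df = read_bed(path)
    return [
        (GenomicInterval(str(c), int(s), int(e)), str(n))
        for c, s, e, n in zip(df["chrom"], df["start"], df["end"], df["name"])
    ]


def write_segmentation_bed(
    segments: Iterable[tuple[GenomicInterval, str]], path
) -> None:
    rows = [(iv.chrom, iv.start, iv.end, lab) for iv, lab in segments]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
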