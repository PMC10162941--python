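"""SE-to-gene assignment.

Candidate genes for each consensus super-enhancer come from three sources —
gene-body overlap, nearest TSS, and a GREAT-style "basal plus extension"
regulatory domain (5 kb upstream / 1 kb downstream of the TSS, extended up
to 1 Mb until the neighbouring gene's basal region).  The SE is then
assigned to the candidate whose expression best tracks SE activity
(Spearman correlation across tumour samples), the field's standard
proximity-plus-correlation heuristic for cis-regulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomeAnnotation, GenomicInterval
from .se_calling import SERepertoire


@dataclass
class LinkParams:
    basal_up: int = 5_000
    basal_down: int = 1_000
    extension: int = 1_000_000
    top_pair_fraction: float = 0.01
    pair_size_guard: int = 2_000_000

    def __post_init__(self) -> None:
        if min(self.basal_up, self.basal_down, self.extension) <= 0:
            raise ValueError("domain sizes must be positive")
        if not 0 < self.top_pair_fraction <= 1:
            raise ValueError("top_pair_fraction must be in (0, 1]")


@dataclass
class SEGeneLink:
    se_region: GenomicInterval
    gene_id: str
    spearman_rho: float
    candidate_source: str  # overlap | proximal | basal_extension
    is_best: bool = False


def _basal_domain(tss: int, strand: str, p: LinkParams) -> tuple[int, int]:
    if strand == "-":
        return tss - p.basal_down + 1, tss + p.basal_up + 1
    return tss - p.basal_up, tss + p.basal_down


def regulatory_domains(
    genome: GenomeAnnotation, params: LinkParams | None = None
) -> dict[str, tuple[int, int]]:
    """GREAT basal-plus-extension domain per gene.

    The basal region is strand-oriented around the TSS; each side is then
    extended up to ``extension`` bp, stopping at the nearest neighbouring
    gene's basal region (domains never shrink below the basal region).
    """
    params = params or LinkParams()
    basal = {
        g.gene_id: _basal_domain(g.tss, g.strand, params) for g in genome.genes
    }
    domains: dict[str, tuple[int, int]] = {}
    for chrom, size in genome.chrom_sizes.items():
        genes = sorted(genome.genes_on(chrom), key=lambda g: basal[g.gene_id][0])
        for i, g in enumerate(genes):
            b_lo, b_hi = basal[g.gene_id]
            lo = max(b_lo - params.extension, 0)
            hi = min(b_hi + params.extension, size)
            left_ends = [
                basal[o.gene_id][1] for o in genes if basal[o.gene_id][1] <= b_lo
                and o.gene_id != g.gene_id
            ]
            if left_ends:
                lo = max(lo, max(left_ends))
            right_starts = [
                basal[o.gene_id][0] for o in genes if basal[o.gene_id][0] >= b_hi
                and o.gene_id != g.gene_id
            ]
            if right_starts:
                hi = min(hi, min(right_starts))
            domains[g.gene_id] = (min(lo, b_lo), max(hi, b_hi))
    return domains


def candidate_genes(
    se: GenomicInterval,
    genome: GenomeAnnotation,
    params: LinkParams | None = None,
    domains: dict[str, tuple[int, int]] | None = None,
) -> list[tuple[str, str]]:
    """Candidate (gene_id, source) pairs for one SE.

    Sources in decreasing specificity: ``overlap`` (gene body overlaps the
    SE), ``proximal`` (nearest TSS to the SE midpoint), ``basal_extension``
    (GREAT-style domain intersects the SE).  A gene reached by several routes
    keeps the most specific source.
    """
    params = params or LinkParams()
    if domains is None:
        domains = regulatory_domains(genome, params)
    found: dict[str, str] = {}
    chrom_genes = genome.genes_on(se.chrom)
    for g in chrom_genes:
        lo, hi = domains[g.gene_id]
        if lo < se.end and se.start < hi:
            found[g.gene_id] = "basal_extension"
    if chrom_genes:
        mid = se.midpoint
        nearest = min(chrom_genes, key=lambda g: (abs(g.tss - mid), g.gene_id))
        found[nearest.gene_id] = "proximal"
    for g in chrom_genes:
        if g.interval.overlaps(se):
            found[g.gene_id] = "overlap"
    return sorted(found.items())


def assign_gene(
    se: GenomicInterval,
    se_activity: pd.Series,
    candidates: Sequence[tuple[str, str]],
    expression: pd.DataFrame,
    genome: GenomeAnnotation,
) -> list[SEGeneLink]:
    """Spearman-correlate SE activity with each candidate's expression and
    flag the best link (ties broken by TSS distance to the SE midpoint)."""
    if not candidates:
        raise ValueError("no candidate genes")
    shared = [s for s in se_activity.index if s in expression.columns]
    if len(shared) < 4:
        raise ValueError("need >= 4 shared samples")
    act = se_activity[shared].to_numpy(float)
    if np.all(act == act[0]):
        return [
            SEGeneLink(se, g, np.nan, src, is_best=False) for g, src in candidates
        ]
    tss = {g.gene_id: g.tss for g in genome.genes}
    links = []
    for gene, src in candidates:
        if gene not in expression.index:
            continue
        expr = expression.loc[gene, shared].to_numpy(float)
        if np.all(expr == expr[0]):
            rho = np.nan
        else:
            rho = float(stats.spearmanr(act, expr).statistic)
        links.append(SEGeneLink(se, gene, rho, src))
    valid = [l for l in links if np.isfinite(l.spearman_rho)]
    if valid:
        best = min(
            valid,
            key=lambda l: (
                -l.spearman_rho,
                abs(tss.get(l.gene_id, 0) - se.midpoint),
                l.gene_id,
            ),
        )
        best.is_best = True
    return links


def link_repertoire(
    repertoire: SERepertoire,
    genome: GenomeAnnotation,
    expression: pd.DataFrame,
    params: LinkParams | None = None,
    tumour_samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Best-candidate links for every consensus SE.

    Correlations use ``tumour_samples`` when given (default: all shared
    samples).  SEs with no valid correlation are retained with
    ``is_best = False`` rows, never dropped silently.
    """
    params = params or LinkParams()
    domains = regulatory_domains(genome, params)
    cols = (
        [s for s in repertoire.activity.columns if s in set(tumour_samples)]
        if tumour_samples is not None
        else list(repertoire.activity.columns)
    )
    rows = []
    for key, region in zip(repertoire.activity.index, repertoire.consensus_regions):
        cands = candidate_genes(region, genome, params, domains)
        if not cands:
            continue
        links = assign_gene(
            region, repertoire.activity.loc[key, cols], cands, expression, genome
        )
        for l in links:
            rows.append(
                (
                    key,
                    region.chrom,
                    region.start,
                    region.end,
                    l.gene_id,
                    l.spearman_rho,
                    l.candidate_source,
                    l.is_best,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["region", "chrom", "start", "end", "gene", "rho", "source",
                 "is_best"],
    )


def top_pairs(
    repertoire: SERepertoire,
    expression: pd.DataFrame,
    params: LinkParams | None = None,
    restrict_to_candidates: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Genome-wide SE x gene Spearman pairs in the top fraction by rho.

    With ``restrict_to_candidates`` (region key -> genes) only those pairs
    are scored; without it the full cross product is used, guarded by
    ``pair_size_guard``.
    """
    params = params or LinkParams()
    shared = [s for s in repertoire.activity.columns if s in expression.columns]
    if len(shared) < 4:
        raise ValueError("need >= 4 shared samples")
    act = repertoire.activity[shared]
    expr = expression[shared]
    if restrict_to_candidates is None:
        n_pairs = act.shape[0] * expr.shape[0]
        if n_pairs > params.pair_size_guard:
            raise ValueError(
                f"{n_pairs} SE x gene pairs exceed the size guard; pass "
                "restrict_to_candidates"
            )
        ra = act.rank(axis=1).to_numpy()
        re = expr.rank(axis=1).to_numpy()
        ra = (ra - ra.mean(1, keepdims=True)) / (ra.std(1, keepdims=True) + 1e-30)
        re = (re - re.mean(1, keepdims=True)) / (re.std(1, keepdims=True) + 1e-30)
        rho = ra @ re.T / len(shared)
        frame = pd.DataFrame(rho, index=act.index, columns=expr.index)
        long = frame.stack().rename("rho").reset_index()
        long.columns = ["region", "gene", "rho"]
    else:
        rows = []
        for region, genes in restrict_to_candidates.items():
            for gene in genes:
                r = stats.spearmanr(
                    act.loc[region], expr.loc[gene]
                ).statistic
                rows.append((region, gene, float(r)))
        long = pd.DataFrame(rows, columns=["region", "gene", "rho"])
    long = long.dropna().sort_values("rho", ascending=False, ignore_index=True)
    n_top = max(1, int(np.ceil(len(long) * params.top_pair_fraction)))
    return long.head(n_top)
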