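"""Synthetic cohort generator.

Generates a bladder-cancer-like multi-omic cohort with the statistical
structure the downstream analyses assume: subtype-specific super-enhancer
(SE) signal, chromatin states coupled to that signal, SE-to-gene expression
coupling, regulon-driven transcription-factor programs, and a two-population
single-cell matrix.  Every quantity flows from one seed through a
hierarchical ``numpy`` generator, so identical configs give bit-identical
cohorts.

The default configuration emulates a 24-sample design — 9 Luminal, 9 Ba/Sq
("Basal"), 4 Stroma-rich and 2 normal urothelium samples, of which 15 are
tumours and 9 cultured lines — with a 2x in-group versus out-of-group mean
IP signal at planted group-specific SEs, negative-binomial read counts, and
a 10% chromatin-state randomisation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import Gene, GenomeAnnotation, GenomicInterval

STATES = ("E1", "E2", "E3", "E4", "E5", "E6")
STATE_SIGN = {"E1": 1, "E2": 3, "E3": 2, "E4": -3, "E5": -1, "E6": -2}

#: active state planted at SE regions; repressed state planted elsewhere
ACTIVE_STATE = "E2"
REPRESSED_STATE = "E4"

DEFAULT_GROUPS = {"Luminal": 9, "Basal": 9, "StromaRich": 4, "Normal": 2}

#: groups in which a planted SE of a given home group is active.  The
#: differentiation programme (luminal SEs) is shared by Luminal and
#: Stroma-rich samples; the basal programme by Ba/Sq and normal urothelium,
#: whose cultured, proliferative state is basal-like — so all planted state
#: differences align on one basal-versus-non-basal axis, the dominant
#: chromatin split in bladder cohorts.
ACTIVE_PARTNERS = {
    "Luminal": frozenset({"Luminal", "StromaRich"}),
    "Basal": frozenset({"Basal", "Normal"}),
    "StromaRich": frozenset({"StromaRich"}),
    "Normal": frozenset({"Normal"}),
}
BASAL_LIKE = frozenset({"Basal", "Normal"})


def se_is_active(se_group: str, sample_group: str) -> bool:
    """Whether a planted SE with home group ``se_group`` is active in a
    sample of ``sample_group``."""
    if se_group == "shared":
        return True
    return sample_group in ACTIVE_PARTNERS.get(se_group, {se_group})


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Counts, lengths and rates mirror a small multi-sample ChIP-seq study;
    effect sizes are calibration choices (2x signal gap at planted SEs),
    not measured values.
    """

    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 360
    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    n_planted_SEs: int = 20          # per group, plus the same number shared
    peak_density: float = 30.0       # background peaks per Mb per sample
    signal_noise_sd: float = 1.0     # scales NB dispersion (r = 10 / sd^2)
    state_noise_rate: float = 0.1
    expression_noise_sd: float = 0.5
    n_TFs: int = 12
    regulon_size: int = 20
    se_effect: float = 2.0           # in-group / out-of-group mean IP ratio
    se_width: int = 20_000
    bin_size: int = 2_000            # segmentation resolution
    batch_effect_rate: float = 0.2   # fraction of bins altered by culture
    n_cell_lines: int = 9            # samples flagged as cultured (batch axis)
    amplified_sample: str | None = None  # give this sample one 100x region
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.chrom_length <= 0:
            raise ValueError("n_chromosomes and chrom_length must be > 0")
        if self.chrom_length <= 10 * 12_500:
            raise ValueError("chrom_length must exceed 10x the stitching distance")
        if not 0 <= self.state_noise_rate < 1:
            raise ValueError("state_noise_rate must be in [0, 1)")
        if any(n <= 0 for n in self.n_samples_per_group.values()):
            raise ValueError("all group sizes must be > 0")
        if self.n_planted_SEs <= 0 or self.n_genes < 0:
            raise ValueError("n_planted_SEs must be > 0 and n_genes >= 0")

    @property
    def samples(self) -> list[str]:
        out = []
        for group, n in self.n_samples_per_group.items():
            out.extend(f"{group}_{i + 1}" for i in range(n))
        return out

    @property
    def sample_groups(self) -> pd.Series:
        groups = []
        for group, n in self.n_samples_per_group.items():
            groups.extend([group] * n)
        return pd.Series(groups, index=self.samples, name="group")

    @property
    def sample_batches(self) -> pd.Series:
        """Tumour / cell-line flag: the last samples of each group are
        cultured, filling ``n_cell_lines`` slots round-robin."""
        batch = pd.Series("tumour", index=self.samples, name="batch")
        remaining = self.n_cell_lines
        while remaining > 0:
            assigned = 0
            for group, n in self.n_samples_per_group.items():
                members = [s for s in self.samples if s.startswith(f"{group}_")]
                for s in reversed(members):
                    if batch[s] == "tumour":
                        batch[s] = "cell_line"
                        remaining -= 1
                        assigned += 1
                        break
                if remaining == 0:
                    break
            if assigned == 0:
                break
        return batch


@dataclass
class PlantedSE:
    region: GenomicInterval
    group: str               # group name or "shared"
    target_gene: str
    peak_starts: list[int]


@dataclass
class SyntheticCohort:
    config: CohortConfig
    genome: GenomeAnnotation
    peaks: dict[str, pd.DataFrame]            # sample -> BED6-style frame
    signal: pd.DataFrame                      # sample, chrom, start, end, ip, input
    segmentations: dict[str, list[tuple[GenomicInterval, str]]]
    bulk_expression: pd.DataFrame             # genes x samples, log2 scale
    sample_groups: pd.Series
    sample_batches: pd.Series
    planted_ses: list[PlantedSE]
    tf_table: pd.DataFrame                    # TF, subtype, is_driver
    regulons: dict[str, list[tuple[str, int]]]
    true_tf_activity: pd.DataFrame            # TFs x samples

    @property
    def state_clusters(self) -> pd.Series:
        """Planted chromatin supercluster per sample: 'basal-like'
        (Ba/Sq + normal urothelium) vs 'non-basal' (Luminal + Stroma)."""
        return self.sample_groups.map(
            lambda g: "basal-like" if g in BASAL_LIKE else "non-basal"
        ).rename("state_cluster")


# ---------------------------------------------------------------------------


def make_genome(config: CohortConfig) -> GenomeAnnotation:
    """Place ``n_genes`` genes with collision-free TSSs on a toy genome."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sizes = {c: config.chrom_length for c in chroms}
    gene_len = 5_000
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chromosomes)
    genes: list[Gene] = []
    for chrom, idx in zip(chroms, per_chrom):
        n = len(idx)
        if n == 0:
            continue
        max_start = config.chrom_length - gene_len
        n_slots = max_start // (2 * gene_len)
        if n > n_slots:
            raise ValueError(
                f"chrom_length {config.chrom_length} too small for {n} genes"
            )
        slots = rng.choice(n_slots, size=n, replace=False)
        slots.sort()
        for g, slot in zip(idx, slots):
            start = int(slot) * 2 * gene_len + gene_len // 2
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else start + gene_len - 1
            genes.append(
                Gene(
                    gene_id=f"G{g:04d}",
                    chrom=chrom,
                    tss=tss,
                    strand=strand,
                    interval=GenomicInterval(chrom, start, start + gene_len),
                )
            )
    return GenomeAnnotation(chrom_sizes=sizes, genes=genes)


def _nb_counts(rng: np.random.Generator, mean, r: float, size=None) -> np.ndarray:
    """Negative binomial with mean ``mean`` and dispersion ``r``
    (variance = mean + mean^2 / r)."""
    mean = np.asarray(mean, dtype=float)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size if size is not None else mean.shape)


def _plant_ses(
    config: CohortConfig, genome: GenomeAnnotation, rng: np.random.Generator
) -> list[PlantedSE]:
    """Choose non-overlapping SE windows, each tied to a distinct target gene.

    The SE is placed 30-80 kb downstream of its target's gene body so that
    constituent peaks escape the promoter-exclusion window.
    """
    groups = list(config.n_samples_per_group) + ["shared"]
    n_total = config.n_planted_SEs * len(groups)
    genes = list(genome.genes)
    if n_total > len(genes):
        raise ValueError("not enough genes to anchor planted SEs")
    # anchors are kept non-adjacent in genomic order so each SE's candidate
    # window contains at most one planted target, and the SE sits 5-15 kb
    # from its target so the target is always a proximity candidate
    order = sorted(range(len(genes)), key=lambda i: (genes[i].chrom,
                                                     genes[i].interval.start))
    rank_of = {i: r for r, i in enumerate(order)}
    chosen = rng.permutation(len(genes))
    blocked_ranks: set[int] = set()
    planted: list[PlantedSE] = []
    taken: list[GenomicInterval] = []
    stitch_margin = 13_000  # planted SEs must not stitch into one another
    gi = 0
    for group in groups:
        for _ in range(config.n_planted_SEs):
            placed = False
            while gi < len(chosen) and not placed:
                gene = genes[chosen[gi]]
                rk = rank_of[int(chosen[gi])]
                gi += 1
                if rk in blocked_ranks:
                    continue
                offset = int(rng.integers(5_000, 10_000))
                start = gene.interval.end + offset
                end = start + config.se_width
                if end > genome.chrom_sizes[gene.chrom]:
                    continue
                # the target's regulatory domain is truncated at the next
                # gene's basal region: require it to reach past the SE
                # midpoint so the target is always a candidate
                if rk + 1 < len(order):
                    nxt = genes[order[rk + 1]]
                    if nxt.chrom == gene.chrom and (
                        nxt.interval.start - 6_000 < end + config.bin_size
                    ):
                        continue
                region = GenomicInterval(gene.chrom, start, end)
                probe = GenomicInterval(
                    gene.chrom, max(0, start - stitch_margin), end + stitch_margin
                )
                if any(probe.overlaps(t) for t in taken):
                    continue
                n_peaks = 4
                span = config.se_width // n_peaks
                peak_starts = [start + k * span + span // 4 for k in range(n_peaks)]
                planted.append(PlantedSE(region, group, gene.gene_id, peak_starts))
                taken.append(region)
                blocked_ranks.update(range(rk - 1, rk + 2))
                placed = True
            if not placed:
                raise ValueError("could not place all planted SEs; enlarge genome")
    return planted


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Full synthetic cohort: peaks + signal, segmentations, expression, truth."""
    if sum(g in config.n_samples_per_group for g in ("Luminal", "Basal")) < 2:
        raise ValueError("cohort must include both Luminal and Basal groups")
    root = np.random.SeedSequence([config.seed, 2])
    ss = root.spawn(6)
    rng_peaks = np.random.default_rng(ss[0])
    rng_signal = np.random.default_rng(ss[1])
    rng_states = np.random.default_rng(ss[2])
    rng_expr = np.random.default_rng(ss[3])
    rng_reg = np.random.default_rng(ss[4])

    genome = make_genome(config)
    planted = _plant_ses(config, genome, np.random.default_rng(ss[5]))
    samples = config.samples
    groups = config.sample_groups
    batches = config.sample_batches
    r_disp = 10.0 / max(config.signal_noise_sd, 1e-9) ** 2

    # --- peaks and signal -------------------------------------------------
    # One shared background peak set (consensus peak geometry is common
    # across samples of one tissue); enrichment ~4x input, as called
    # H3K27ac peaks are.
    peak_width = 1_000
    base_mean, planted_out, input_mean = 60.0, 60.0, 15.0
    planted_in = planted_out * config.se_effect
    peaks: dict[str, pd.DataFrame] = {}
    signal_rows: list[tuple] = []
    n_bg = int(config.peak_density * config.chrom_length / 1e6)
    bg_starts = {
        chrom: np.sort(
            rng_peaks.choice((size - peak_width) // peak_width, n_bg, replace=False)
        )
        * peak_width
        for chrom, size in genome.chrom_sizes.items()
    }
    for sample in samples:
        group = groups[sample]
        rows = []
        for chrom, size in genome.chrom_sizes.items():
            for s in bg_starts[chrom]:
                rows.append((chrom, int(s), int(s) + peak_width, base_mean))
        for se in planted:
            mean = planted_in if se_is_active(se.group, group) else planted_out
            for ps in se.peak_starts:
                rows.append((se.region.chrom, ps, ps + peak_width, mean))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_ip"])
        df = df.sort_values(["chrom", "start"], ignore_index=True)
        ip = _nb_counts(rng_signal, df["mean_ip"].to_numpy(), r_disp)
        inp = _nb_counts(rng_signal, np.full(len(df), input_mean), r_disp)
        if config.amplified_sample == sample:
            # copy-number amplification: 100x IP at the first planted SE
            amp = planted[0].region
            hit = (df["chrom"] == amp.chrom) & (df["start"] >= amp.start) & (
                df["end"] <= amp.end
            )
            ip = np.where(hit, ip * 100, ip)
        out = df.assign(ip=ip, input=inp, name=".", score=ip, strand=".")
        peaks[sample] = out[
            ["chrom", "start", "end", "name", "score", "strand", "ip", "input"]
        ]
        for row in out.itertuples(index=False):
            signal_rows.append(
                (sample, row.chrom, row.start, row.end, int(row.ip), int(row.input))
            )
    signal = pd.DataFrame(
        signal_rows, columns=["sample", "chrom", "start", "end", "ip", "input"]
    )

    # --- chromatin-state segmentations ------------------------------------
    # A shared background state per bin, group-dependent states at planted SEs,
    # and a cultured-sample batch stripe; per-sample randomisation at
    # state_noise_rate.
    nbins = config.chrom_length // config.bin_size
    bg_states = {
        chrom: rng_states.choice(
            STATES, size=nbins, p=[0.55, 0.05, 0.05, 0.1, 0.15, 0.1]
        )
        for chrom in genome.chrom_sizes
    }
    # batch stripe: bins whose state flips to the opposite-signed extreme in
    # cultured samples — the strong in-vitro effect that dominates Dim 1 of
    # the landscape embedding (tumours vs lines), as in real cohorts
    batch_bins = {
        chrom: rng_states.random(nbins) < config.batch_effect_rate
        for chrom in genome.chrom_sizes
    }
    flip = {s: ("E4" if STATE_SIGN[s] > 0 else "E2") for s in STATES}
    planted_by_chrom: dict[str, list[PlantedSE]] = {}
    for se in planted:
        planted_by_chrom.setdefault(se.region.chrom, []).append(se)
    # each planted target's promoter bin follows its SE's programme (states
    # are generated consistently with signal and expression)
    tss_bin = {
        se.target_gene: (g.chrom, min(g.tss // config.bin_size, nbins - 1))
        for se in planted
        for g in genome.genes
        if g.gene_id == se.target_gene
    }
    segmentations: dict[str, list[tuple[GenomicInterval, str]]] = {}
    states_by_sample: dict[str, dict[str, np.ndarray]] = {}
    for sample in samples:
        group = groups[sample]
        cultured = batches[sample] == "cell_line"
        segs: list[tuple[GenomicInterval, str]] = []
        states_by_sample[sample] = {}
        for chrom, size in genome.chrom_sizes.items():
            states = bg_states[chrom].copy()
            if cultured:
                flipped = np.array([flip[s] for s in states], dtype=object)
                states = np.where(batch_bins[chrom], flipped, states)
            for se in planted_by_chrom.get(chrom, []):
                b0 = se.region.start // config.bin_size
                b1 = -(-se.region.end // config.bin_size)
                st = (
                    ACTIVE_STATE
                    if se_is_active(se.group, group)
                    else REPRESSED_STATE
                )
                states[b0:b1] = st
                tchrom, tb = tss_bin[se.target_gene]
                if tchrom == chrom:
                    states[tb] = st
            noise = rng_states.random(nbins) < config.state_noise_rate
            if noise.any():
                states = np.where(
                    noise, rng_states.choice(STATES, size=nbins), states
                )
            states_by_sample[sample][chrom] = states
            for b in range(nbins):
                lo = b * config.bin_size
                hi = min(size, lo + config.bin_size)
                segs.append((GenomicInterval(chrom, lo, hi), str(states[b])))
        segmentations[sample] = segs

    # --- regulons ----------------------------------------------------------
    gene_ids = [g.gene_id for g in genome.genes]
    se_targets = {se.target_gene for se in planted}
    # genes bordering a planted anchor are kept programme-free so that the
    # SE-target correlation has no same-pattern competitor in its window
    order = sorted(genome.genes, key=lambda g: (g.chrom, g.interval.start))
    near_anchor: set[str] = set()
    for i, g in enumerate(order):
        if g.gene_id in se_targets:
            for j in (i - 1, i, i + 1):
                if 0 <= j < len(order):
                    near_anchor.add(order[j].gene_id)
    free_genes = [g for g in gene_ids if g not in near_anchor]
    driver_pool = [se for se in planted if se.group in ("Luminal", "Basal")]
    n_drivers = min(6, len(driver_pool))
    tf_rows, regulons = [], {}
    activity = np.zeros((config.n_TFs, len(samples)))
    grp_arr = groups.to_numpy()
    for t in range(config.n_TFs):
        if t < n_drivers:
            se = driver_pool[t * len(driver_pool) // n_drivers]
            tf_gene, subtype, driver = se.target_gene, se.group, True
            act = np.where(grp_arr == subtype, 3.0, -1.0)
        else:
            tf_gene = free_genes[t]
            subtype, driver = "none", False
            act = np.zeros(len(samples))
        act = act + rng_reg.normal(0, 0.3, len(samples))
        activity[t] = act
        targets = rng_reg.choice(
            [g for g in free_genes[config.n_TFs:] if g != tf_gene],
            size=config.regulon_size,
            replace=False,
        )
        modes = rng_reg.choice([1, -1], size=config.regulon_size)
        regulons[tf_gene] = list(zip(targets.tolist(), modes.tolist()))
        tf_rows.append((tf_gene, subtype, driver))
    tf_table = pd.DataFrame(tf_rows, columns=["TF", "subtype", "is_driver"])
    true_activity = pd.DataFrame(
        activity, index=tf_table["TF"].tolist(), columns=samples
    )

    # --- bulk expression ----------------------------------------------------
    expr = pd.DataFrame(
        rng_expr.normal(8.0, 1.0, size=(len(gene_ids), 1)).repeat(len(samples), 1),
        index=gene_ids,
        columns=samples,
    )
    # TSS-state coupling: promoter chromatin state modulates expression
    # (active E2 up, repressed E4 down), the ordering the landscape analysis
    # presumes
    for sample in samples:
        bonus = np.empty(len(gene_ids))
        for gi, g in enumerate(genome.genes):
            b = min(g.tss // config.bin_size, nbins - 1)
            bonus[gi] = 0.4 * STATE_SIGN[str(states_by_sample[sample][g.chrom][b])]
        expr[sample] = expr[sample].to_numpy() + bonus

    # SE -> target coupling: expression follows the (latent) mean IP signal
    for se in planted:
        for sample in samples:
            group = groups[sample]
            mean = planted_in if se_is_active(se.group, group) else planted_out
            expr.loc[se.target_gene, sample] += 2.0 * np.log2(mean / planted_out)
    # regulon coupling
    for (tf_gene, _subtype, _driver), act in zip(tf_rows, activity):
        expr.loc[tf_gene] += act
        for target, mode in regulons[tf_gene]:
            expr.loc[target] = expr.loc[target] + 0.8 * mode * act
    expr += rng_expr.normal(0, config.expression_noise_sd, expr.shape)

    return SyntheticCohort(
        config=config,
        genome=genome,
        peaks=peaks,
        signal=signal,
        segmentations=segmentations,
        bulk_expression=expr,
        sample_groups=groups,
        sample_batches=batches,
        planted_ses=planted,
        tf_table=tf_table,
        regulons=regulons,
        true_tf_activity=true_activity,
    )


# ---------------------------------------------------------------------------


def simulate_single_cell(
    n_cells_per_pop: int = 200,
    markers_per_pop: int = 50,
    n_genes: int = 1000,
    noise_sd: float = 1.0,
    dropout: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Two-population (luminal-like / basal-like) single-cell matrix.

    Returns ``(matrix cells x genes in log2(TPM-like) scale, cluster labels,
    planted marker dict)``.  Marker genes get a +2 log2 mean shift in their
    population; ``dropout`` zeroes entries at random, mimicking sparse
    droplet data.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    genes = [f"SC{g:04d}" for g in range(n_genes)]
    lum_markers = genes[:markers_per_pop]
    bas_markers = genes[markers_per_pop: 2 * markers_per_pop]
    cells = [f"L{i}" for i in range(n_cells_per_pop)] + [
        f"B{i}" for i in range(n_cells_per_pop)
    ]
    labels = pd.Series(
        ["luminal-like"] * n_cells_per_pop + ["basal-like"] * n_cells_per_pop,
        index=cells,
        name="cluster",
    )
    base = rng.normal(2.0, 0.5, size=n_genes)
    mean = np.tile(base, (len(cells), 1))
    mean[: n_cells_per_pop, :markers_per_pop] += 2.0
    mean[n_cells_per_pop:, markers_per_pop: 2 * markers_per_pop] += 2.0
    x = mean + rng.normal(0, noise_sd, mean.shape)
    x = np.clip(x, 0, None)
    if dropout > 0:
        x = np.where(rng.random(x.shape) < dropout, 0.0, x)
    matrix = pd.DataFrame(x, index=cells, columns=genes)
    markers = {"luminal-like": lum_markers, "basal-like": bas_markers}
    return matrix, labels, markers


def simulate_expression_classes(
    n_per_class: int = 20,
    n_queries_per_class: int = 4,
    n_genes: int = 2_000,
    n_informative: int = 200,
    class_names: tuple[str, ...] = ("Luminal", "Basal", "StromaRich"),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """Labelled reference + held-out query expression from one generative
    model, for testing reference-similarity subtype transfer.

    Each class has a centroid shift on ``n_informative`` genes; queries are
    drawn from the same centroids and then passed through a monotone
    'platform' distortion (exponentiation to a TPM-like scale), which a
    rank-based normalisation must undo.  Returns
    ``(reference genes x samples, reference labels, query, query labels)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    genes = [f"g{i:04d}" for i in range(n_genes)]
    base = rng.normal(6.0, 1.0, n_genes)
    centroids = {}
    for k, c in enumerate(class_names):
        shift = np.zeros(n_genes)
        idx = rng.choice(n_informative, n_informative // len(class_names),
                         replace=False)
        shift[idx] = rng.choice([-2.0, 2.0], size=len(idx))
        centroids[c] = base + shift
    def _draw(n, distort):
        cols, labs = {}, {}
        for c in class_names:
            for i in range(n):
                name = f"{c}_{'q' if distort else 'r'}{i}"
                x = centroids[c] + rng.normal(0, noise_sd, n_genes)
                if distort:
                    x = np.power(2.0, x / 2.0)  # monotone platform change
                cols[name], labs[name] = x, c
        m = pd.DataFrame(cols, index=genes)
        return m, pd.Series(labs, name="class")
    ref, ref_labels = _draw(n_per_class, distort=False)
    qry, qry_labels = _draw(n_queries_per_class, distort=True)
    return ref, ref_labels, qry, qry_labels


def simulate_regulons(
    n_TFs: int = 10,
    regulon_size: int = 30,
    n_samples: int = 100,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, list[tuple[str, int]]], pd.DataFrame, pd.DataFrame]:
    """Regulon-driven expression with known TF activities.

    Each target's expression is ``mode * activity + noise`` with modes in
    {+1, -1}; a TF's own expression tracks its activity.  Returns
    ``(network, expression genes x samples, true activity TFs x samples)``.
    """
    if regulon_size < 5:
        raise ValueError("regulon_size must be >= 5")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    samples = [f"S{i:03d}" for i in range(n_samples)]
    tfs = [f"TF{i:02d}" for i in range(n_TFs)]
    activity = rng.normal(0, 1, size=(n_TFs, n_samples))
    network: dict[str, list[tuple[str, int]]] = {}
    rows, index = [], []
    for i, tf in enumerate(tfs):
        rows.append(activity[i] + rng.normal(0, max(noise_sd, 1e-12) / 2, n_samples))
        index.append(tf)
    for i, tf in enumerate(tfs):
        targets = [f"{tf}_T{j:02d}" for j in range(regulon_size)]
        modes = rng.choice([1, -1], size=regulon_size)
        network[tf] = list(zip(targets, modes.tolist()))
        for target, mode in zip(targets, modes):
            rows.append(mode * activity[i] + rng.normal(0, noise_sd, n_samples))
            index.append(target)
    expression = pd.DataFrame(rows, index=index, columns=samples)
    true_activity = pd.DataFrame(activity, index=tfs, columns=samples)
    return network, expression, true_activity


# ---------------------------------------------------------------------------
# cohort file output (round-trippable through episenet.intervals readers)
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write the cohort to plain-text files; returns a name -> path manifest."""
    from pathlib import Path

    from .intervals import write_gene_bed, write_segmentation_bed, write_signal_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    write_gene_bed(cohort.genome, out / "genes.bed")
    manifest["genes"] = str(out / "genes.bed")
    write_signal_table(cohort.signal, out / "signal.tsv")
    manifest["signal"] = str(out / "signal.tsv")
    for sample, df in cohort.peaks.items():
        p = out / f"peaks_{sample}.bed"
        df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            p, sep="\t", header=False, index=False
        )
        manifest[f"peaks/{sample}"] = str(p)
    for sample, segs in cohort.segmentations.items():
        p = out / f"segments_{sample}.bed"
        write_segmentation_bed(segs, p)
        manifest[f"segments/{sample}"] = str(p)
    cohort.bulk_expression.to_csv(out / "expression.tsv", sep="\t")
    manifest["expression"] = str(out / "expression.tsv")
    meta = pd.DataFrame(
        {"group": cohort.sample_groups, "batch": cohort.sample_batches}
    )
    meta.to_csv(out / "samples.tsv", sep="\t", index_label="sample")
    manifest["samples"] = str(out / "samples.tsv")
    truth = pd.DataFrame(
        [
            (se.region.chrom, se.region.start, se.region.end, se.group, se.target_gene)
            for se in cohort.planted_ses
        ],
        columns=["chrom", "start", "end", "group", "target_gene"],
    )
    truth.to_csv(out / "truth_ses.tsv", sep="\t", index=False)
    manifest["truth_ses"] = str(out / "truth_ses.tsv")
    return manifest
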