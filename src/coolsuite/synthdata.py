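"""Synthetic single-cell NOMe-seq data with planted ground truth.

The generator builds a genome with a requested GC content, plants genes,
promoter/distal nucleosome-depleted regions (NDRs), nucleosome cores
tiling the remaining chromatin at the repeat length, CpG islands,
heterozygous SNPs, and per-stage / per-allele WCG methylation levels.
Per-cell call tables then reflect the assay's statistical structure:
GpC methyltransferase marks accessible GCH sites at ``p_gch_open`` and
nucleosome-core GCH sites at ``p_gch_closed``; WCG sites follow the
allele-averaged endogenous level; bisulfite errors are applied
symmetrically to both channels; sites are recovered sparsely
(``site_detection_prob``); lambda spike-in and genomic read counts scale
with ploidy.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from coolsuite import context as ctx_mod
from coolsuite import ioformats
from coolsuite.intervals import GenomicInterval

BASES = np.array(list("ACGT"))

DEFAULT_WCG_LEVELS: dict[str, dict[str, tuple[float, float]]] = {
    "ES": {"intragenic": (0.7, 0.7), "intergenic": (0.5, 0.5), "CGI": (0.1, 0.1)}
}


@dataclass
class SimulationConfig:
    n_chromosomes: int = 1
    chrom_length: int = 200_000
    gc_fraction: float = 0.42
    nucleosome_core: int = 147
    nucleosome_repeat: int = 180
    n_genes: int = 20
    gene_length: int = 2_000
    ndr_fraction_of_promoters: float = 0.5
    ndr_width_range: tuple[int, int] = (200, 400)
    n_distal_ndrs: int | None = None
    n_cgis: int = 5
    cgi_length: int = 500
    p_gch_open: float = 0.8
    p_gch_closed: float = 0.05
    # the assay cannot tell linker from NDR at a single site, so linkers
    # default to accessible; False makes all non-NDR chromatin closed,
    # which isolates planted NDRs for boundary-accuracy checks
    linker_accessible: bool = True
    wcg_level_by_stage_and_allele: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_WCG_LEVELS.items()}
    )
    region_meth_overrides: list = field(default_factory=list)  # (chrom,start,end,mat,pat)
    denovo_site_fraction: float = 0.0
    denovo_low_level: float = 0.1
    denovo_high_level: float = 0.6
    bisulfite_failure_rate: float = 0.005
    inappropriate_conversion_rate: float = 0.005
    site_detection_prob: float = 0.10
    depth_mean: float = 2.0  # depth = 1 + Poisson(depth_mean)
    fixed_depth: int | None = None
    snp_density: float = 0.001
    cells_per_stage: dict = field(default_factory=lambda: {"ES": 8})
    ploidy_by_cell: dict = field(default_factory=dict)
    divergent_promoter_fraction: float = 0.0
    reads_per_haploid: float = 25_000.0
    lambda_spike_reads: float = 1_000.0
    n_reads_per_cell: int = 2_000
    read_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.gc_fraction,
            self.ndr_fraction_of_promoters,
            self.p_gch_open,
            self.p_gch_closed,
            self.bisulfite_failure_rate,
            self.inappropriate_conversion_rate,
            self.site_detection_prob,
            self.snp_density,
            self.divergent_promoter_fraction,
            self.denovo_site_fraction,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.nucleosome_core >= self.nucleosome_repeat:
            raise ValueError("nucleosome_core must be < nucleosome_repeat")
        lo, hi = self.ndr_width_range
        if not (0 < lo <= hi):
            raise ValueError("bad ndr_width_range")
        for stage, classes in self.wcg_level_by_stage_and_allele.items():
            for cls, (mat, pat) in classes.items():
                if not (0 <= mat <= 1 and 0 <= pat <= 1):
                    raise ValueError(f"bad WCG level for {stage}/{cls}")
        # stages without configured WCG levels inherit the defaults
        for stage in self.cells_per_stage:
            if stage not in self.wcg_level_by_stage_and_allele:
                self.wcg_level_by_stage_and_allele[stage] = dict(
                    DEFAULT_WCG_LEVELS["ES"]
                )

    @property
    def stages(self) -> list[str]:
        return list(self.cells_per_stage)


@dataclass
class GroundTruth:
    genome: dict[str, str]
    tss_table: pd.DataFrame
    gene_bodies: list[GenomicInterval]
    cgis: list[GenomicInterval]
    planted_ndrs: list[GenomicInterval]       # name: gene id for promoter NDRs
    nucleosome_cores: list[GenomicInterval]
    snp_table: pd.DataFrame                   # chrom, pos, maternal, paternal
    contexts: pd.DataFrame                    # chrom, pos, strand, tri, context
    cell_table: pd.DataFrame                  # cell, stage, ploidy
    true_promoter_state: pd.DataFrame         # genes x cells of open/closed
    denovo_sites: pd.DataFrame                # chrom, pos, strand (WCG sites)

    @property
    def true_ploidy(self) -> dict[str, float]:
        return dict(zip(self.cell_table["cell"], self.cell_table["ploidy"]))

    def promoter_ndrs(self) -> list[GenomicInterval]:
        return [iv for iv in self.planted_ndrs if iv.name is not None]


@dataclass
class CellData:
    cell: str
    stage: str
    calls: pd.DataFrame       # cytosine call table (WCG/GCH sites only)
    reads: pd.DataFrame       # simplified read records
    genomic_reads: int
    lambda_reads: int


# ---------------------------------------------------------------------------
# genome + ground truth
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> GroundTruth:
    """Build a synthetic genome and every piece of planted ground truth."""
    rng = np.random.default_rng(config.seed)
    p = np.array(
        [
            (1 - config.gc_fraction) / 2,
            config.gc_fraction / 2,
            config.gc_fraction / 2,
            (1 - config.gc_fraction) / 2,
        ]
    )
    genome: dict[str, str] = {}
    for i in range(config.n_chromosomes):
        seq = rng.choice(BASES, size=config.chrom_length, p=p)
        genome[f"chr{i + 1}"] = "".join(seq)

    # genes: evenly spaced TSSs, round-robin over chromosomes
    chroms = list(genome)
    per_chrom = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        per_chrom[i] += 1
    margin = 3_000
    tss_rows = []
    gene_bodies = []
    gidx = 0
    for chrom, n_genes in zip(chroms, per_chrom):
        if n_genes == 0:
            continue
        usable = config.chrom_length - 2 * margin - config.gene_length
        if usable <= 0 or usable // max(n_genes, 1) < config.gene_length + 1_000:
            raise ValueError(
                f"{chrom} too short ({config.chrom_length} bp) for {n_genes} genes"
            )
        spacing = usable // n_genes
        for j in range(n_genes):
            tss = margin + j * spacing
            strand = "+" if rng.random() < 0.5 else "-"
            gene = f"g{gidx:04d}"
            if strand == "+":
                body = GenomicInterval(chrom, tss, tss + config.gene_length, strand, gene)
            else:
                body = GenomicInterval(
                    chrom, tss - config.gene_length + 1, tss + 1, strand, gene
                )
            tss_rows.append((gene, chrom, tss, strand))
            gene_bodies.append(body)
            gidx += 1
    tss_table = pd.DataFrame(tss_rows, columns=["gene", "chrom", "tss", "strand"])

    # promoter NDRs at a configured fraction of promoters
    n_promoter_ndrs = int(round(config.ndr_fraction_of_promoters * len(tss_table)))
    ndr_genes = sorted(
        rng.choice(len(tss_table), size=n_promoter_ndrs, replace=False).tolist()
    )
    planted: list[GenomicInterval] = []
    for gi in ndr_genes:
        row = tss_table.iloc[gi]
        width = int(rng.integers(config.ndr_width_range[0], config.ndr_width_range[1] + 1))
        start = max(0, row.tss - width // 2)
        planted.append(GenomicInterval(row.chrom, start, start + width, name=row.gene))

    # distal NDRs: random, >= 2 kb from every TSS, non-overlapping
    n_distal = (
        config.n_distal_ndrs if config.n_distal_ndrs is not None else n_promoter_ndrs
    )
    attempts = 0
    while n_distal > 0 and attempts < 10_000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        width = int(rng.integers(config.ndr_width_range[0], config.ndr_width_range[1] + 1))
        start = int(rng.integers(0, config.chrom_length - width))
        iv = GenomicInterval(chrom, start, start + width)
        tss_here = tss_table[tss_table["chrom"] == chrom]["tss"].to_numpy()
        if len(tss_here) and np.min(
            np.minimum(np.abs(tss_here - iv.start), np.abs(tss_here - (iv.end - 1)))
        ) <= 2_000:
            continue
        if any(iv.overlaps(o) for o in planted):
            continue
        planted.append(iv)
        n_distal -= 1

    # nucleosome cores tile non-NDR chromatin at the repeat length
    cores: list[GenomicInterval] = []
    for chrom in chroms:
        ndrs_here = sorted(
            [iv for iv in planted if iv.chrom == chrom], key=lambda x: x.start
        )
        starts = np.array([iv.start for iv in ndrs_here], dtype=int)
        ends = np.array([iv.end for iv in ndrs_here], dtype=int)
        for s in range(0, config.chrom_length - config.nucleosome_core + 1,
                       config.nucleosome_repeat):
            e = s + config.nucleosome_core
            if len(starts):
                k = np.searchsorted(ends, s, side="right")
                if k < len(starts) and starts[k] < e:
                    continue
            cores.append(GenomicInterval(chrom, s, e))

    # CpG islands around the first n_cgis TSSs
    cgis = []
    for _, row in tss_table.head(config.n_cgis).iterrows():
        half = config.cgi_length // 2
        cgis.append(
            GenomicInterval(row.chrom, max(0, row.tss - half), row.tss + half,
                            name=row.gene)
        )

    # heterozygous SNPs: maternal = reference, paternal = random other base
    snp_rows = []
    for chrom, seq in genome.items():
        n_snps = rng.binomial(len(seq), config.snp_density)
        positions = np.sort(
            rng.choice(len(seq), size=n_snps, replace=False)
        )
        for pos in positions:
            ref = seq[pos]
            if ref not in "ACGT":
                continue
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[int(rng.integers(3))]
            snp_rows.append((chrom, int(pos), ref, alt))
    snp_table = pd.DataFrame(snp_rows, columns=["chrom", "pos", "maternal", "paternal"])

    contexts = ctx_mod.classify_cytosines(genome)

    # cells and ploidies
    cell_rows = []
    for stage, n_cells in config.cells_per_stage.items():
        for j in range(n_cells):
            name = f"{stage}_c{j:02d}"
            cell_rows.append((name, stage, float(config.ploidy_by_cell.get(name, 2.0))))
    cell_table = pd.DataFrame(cell_rows, columns=["cell", "stage", "ploidy"])

    # per-cell true promoter state: open iff a promoter NDR was planted;
    # a configured fraction of NDR promoters is made divergent (per-cell coin)
    ndr_gene_names = {iv.name for iv in planted if iv.name is not None}
    divergent_genes: set[str] = set()
    if config.divergent_promoter_fraction > 0 and ndr_gene_names:
        names = sorted(ndr_gene_names)
        n_div = int(round(config.divergent_promoter_fraction * len(names)))
        divergent_genes = set(
            np.array(names)[rng.choice(len(names), size=n_div, replace=False)]
        )
    state = {}
    for cell in cell_table["cell"]:
        col = {}
        for gene in tss_table["gene"]:
            if gene in divergent_genes:
                col[gene] = "open" if rng.random() < 0.5 else "closed"
            elif gene in ndr_gene_names:
                col[gene] = "open"
            else:
                col[gene] = "closed"
        state[cell] = col
    true_promoter_state = pd.DataFrame(state)

    # planted de novo methylation events between the first two stages
    wcg_plus = contexts[(contexts["context"] == "WCG")]
    if config.denovo_site_fraction > 0 and len(config.stages) >= 2 and len(wcg_plus):
        take = rng.random(len(wcg_plus)) < config.denovo_site_fraction
        denovo_sites = wcg_plus.loc[take, ["chrom", "pos", "strand"]].reset_index(
            drop=True
        )
    else:
        denovo_sites = pd.DataFrame(columns=["chrom", "pos", "strand"])

    return GroundTruth(
        genome=genome,
        tss_table=tss_table,
        gene_bodies=gene_bodies,
        cgis=cgis,
        planted_ndrs=planted,
        nucleosome_cores=cores,
        snp_table=snp_table,
        contexts=contexts,
        cell_table=cell_table,
        true_promoter_state=true_promoter_state,
        denovo_sites=denovo_sites,
    )


# ---------------------------------------------------------------------------
# per-cell simulation
# ---------------------------------------------------------------------------

def _interval_mask(
    chrom: np.ndarray, pos: np.ndarray, intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Membership of (chrom, pos) points in non-overlapping intervals."""
    mask = np.zeros(len(pos), dtype=bool)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for c, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda x: x.start)
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        sel = chrom == c
        if not sel.any():
            continue
        p = pos[sel]
        k = np.searchsorted(starts, p, side="right") - 1
        ok = (k >= 0) & (p < ends[np.clip(k, 0, None)])
        sub = mask[sel]
        sub[ok] = True
        mask[sel] = sub
    return mask


def _observed_prob(p_true: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Apply symmetric bisulfite error to a true methylation probability."""
    return (
        p_true * (1.0 - config.inappropriate_conversion_rate)
        + (1.0 - p_true) * config.bisulfite_failure_rate
    )


def _wcg_allele_levels(
    truth: GroundTruth, config: SimulationConfig, stage: str,
    chrom: np.ndarray, pos: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """True (maternal, paternal) WCG level per site for one stage."""
    levels = config.wcg_level_by_stage_and_allele[stage]
    mat = np.full(len(pos), levels.get("intergenic", (0.5, 0.5))[0])
    pat = np.full(len(pos), levels.get("intergenic", (0.5, 0.5))[1])
    if "intragenic" in levels:
        m = _interval_mask(chrom, pos, truth.gene_bodies)
        mat[m], pat[m] = levels["intragenic"]
    if "CGI" in levels:
        m = _interval_mask(chrom, pos, truth.cgis)
        mat[m], pat[m] = levels["CGI"]
    for chrom_o, start, end, m_lvl, p_lvl in config.region_meth_overrides:
        m = (chrom == chrom_o) & (pos >= start) & (pos < end)
        mat[m], pat[m] = m_lvl, p_lvl
    if len(truth.denovo_sites):
        stage_idx = config.stages.index(stage)
        lvl = config.denovo_low_level if stage_idx == 0 else config.denovo_high_level
        key = set(zip(truth.denovo_sites["chrom"], truth.denovo_sites["pos"]))
        m = np.fromiter(
            ((c, int(q)) in key for c, q in zip(chrom, pos)), dtype=bool, count=len(pos)
        )
        mat[m] = pat[m] = lvl
    return mat, pat


def _gch_open_prob(
    truth: GroundTruth, config: SimulationConfig, cell: str,
    chrom: np.ndarray, pos: np.ndarray,
) -> np.ndarray:
    """True GCH methylation probability per site for one cell.

    Linkers and NDRs are accessible (p_gch_open); nucleosome cores are
    protected; promoters truly closed in this cell behave like cores.
    """
    if config.linker_accessible:
        p = np.full(len(pos), config.p_gch_open)
        in_core = _interval_mask(chrom, pos, truth.nucleosome_cores)
        p[in_core] = config.p_gch_closed
    else:
        p = np.full(len(pos), config.p_gch_closed)
        in_ndr = _interval_mask(chrom, pos, truth.planted_ndrs)
        p[in_ndr] = config.p_gch_open
    state_col = truth.true_promoter_state[cell]
    closed_ndrs = [
        iv
        for iv in truth.planted_ndrs
        if iv.name is not None and state_col.get(iv.name) == "closed"
    ]
    if closed_ndrs:
        m = _interval_mask(chrom, pos, closed_ndrs)
        p[m] = config.p_gch_closed
    return p


def simulate_cells(
    truth: GroundTruth, config: SimulationConfig
) -> dict[str, CellData]:
    """Simulate every cell's call table, read records and read counts."""
    rng = np.random.default_rng([config.seed, 1])
    sites = truth.contexts[truth.contexts["context"].isin(["WCG", "GCH"])]
    sites = sites.sort_values(["chrom", "pos", "strand"], ignore_index=True)
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    is_gch = (sites["context"] == "GCH").to_numpy()

    out: dict[str, CellData] = {}
    for row in truth.cell_table.itertuples(index=False):
        cell, stage, ploidy = row.cell, row.stage, row.ploidy
        covered = rng.random(len(sites)) < config.site_detection_prob
        n_cov = int(covered.sum())
        if config.fixed_depth is not None:
            depth = np.full(n_cov, config.fixed_depth, dtype=int)
        else:
            depth = 1 + rng.poisson(config.depth_mean, size=n_cov)

        c_chrom = chrom_arr[covered]
        c_pos = pos_arr[covered]
        c_gch = is_gch[covered]

        p_true = np.empty(n_cov)
        p_true[c_gch] = _gch_open_prob(
            truth, config, cell, c_chrom[c_gch], c_pos[c_gch]
        )
        mat, pat = _wcg_allele_levels(
            truth, config, stage, c_chrom[~c_gch], c_pos[~c_gch]
        )
        p_true[~c_gch] = 0.5 * (mat + pat)

        p_obs = _observed_prob(p_true, config)
        meth = rng.binomial(depth, p_obs)
        calls = sites.loc[covered, ["chrom", "pos", "strand", "context", "tri"]].copy()
        calls["meth"] = meth
        calls["unmeth"] = depth - meth
        calls = calls[["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]]
        calls = calls.reset_index(drop=True)

        reads = _simulate_reads(truth, config, cell, stage, rng)
        genomic = int(rng.poisson(ploidy * config.reads_per_haploid))
        lam = int(rng.poisson(config.lambda_spike_reads))
        out[cell] = CellData(cell, stage, calls, reads, genomic, lam)
    return out


def _simulate_reads(
    truth: GroundTruth,
    config: SimulationConfig,
    cell: str,
    stage: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    chroms = list(truth.genome)
    lengths = np.array([len(truth.genome[c]) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    snp = truth.snp_table
    snp_by_chrom = {
        c: g.sort_values("pos").reset_index(drop=True) for c, g in snp.groupby("chrom")
    }
    site_tab = truth.contexts[truth.contexts["context"].isin(["WCG", "GCH"])]
    sites_by = {
        (c, s): g.sort_values("pos").reset_index(drop=True)
        for (c, s), g in site_tab.groupby(["chrom", "strand"])
    }

    rows = []
    which = rng.integers(0, len(chroms), size=config.n_reads_per_cell)
    for i in range(config.n_reads_per_cell):
        chrom = chroms[int(which[i])]
        length = int(lengths[which[i]])
        start = int(rng.integers(0, max(length - config.read_length, 1)))
        end = start + config.read_length
        strand = "+" if rng.random() < 0.5 else "-"
        allele = "maternal" if rng.random() < 0.5 else "paternal"

        snp_obs = []
        sg = snp_by_chrom.get(chrom)
        if sg is not None:
            pos = sg["pos"].to_numpy()
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            for k in range(lo, hi):
                base = sg.iloc[k]["maternal" if allele == "maternal" else "paternal"]
                # SNP-position cytosines are treated as unmethylated, so
                # conversion is deterministic on the read's strand
                if strand == "+" and base == "C":
                    base = "T"
                elif strand == "-" and base == "G":
                    base = "A"
                snp_obs.append((int(pos[k]), base))

        meth_obs = []
        st = sites_by.get((chrom, strand))
        if st is not None:
            pos = st["pos"].to_numpy()
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            sub_pos = pos[lo:hi]
            sub_ctx = st["context"].to_numpy()[lo:hi]
            if len(sub_pos):
                gch_sel = sub_ctx == "GCH"
                p = np.empty(len(sub_pos))
                if gch_sel.any():
                    p[gch_sel] = _gch_open_prob(
                        truth, config, cell,
                        np.full(gch_sel.sum(), chrom), sub_pos[gch_sel],
                    )
                if (~gch_sel).any():
                    mat, pat = _wcg_allele_levels(
                        truth, config, stage,
                        np.full((~gch_sel).sum(), chrom), sub_pos[~gch_sel],
                    )
                    p[~gch_sel] = mat if allele == "maternal" else pat
                p = _observed_prob(p, config)
                m = rng.random(len(sub_pos)) < p
                meth_obs = [
                    (int(q), c, int(v)) for q, c, v in zip(sub_pos, sub_ctx, m)
                ]

        rows.append(
            {
                "read_id": f"{cell}_r{i:06d}",
                "cell": cell,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "true_allele": allele,
                "snp_obs": snp_obs,
                "meth_obs": meth_obs,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk output
# ---------------------------------------------------------------------------

def write_outputs(
    truth: GroundTruth, cells: Mapping[str, CellData], outdir: str | Path
) -> None:
    """Write FASTA, annotations, per-cell reports, reads and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ioformats.write_fasta(truth.genome, outdir / "genome.fa")
    ioformats.write_tss_table(truth.tss_table, outdir / "tss.tsv")
    ioformats.write_snp_table(truth.snp_table, outdir / "snps.tsv")
    ioformats.write_bed(truth.planted_ndrs, outdir / "planted_ndrs.bed")
    ioformats.write_bed(truth.nucleosome_cores, outdir / "nucleosome_cores.bed")
    if truth.cgis:
        ioformats.write_bed(truth.cgis, outdir / "cgis.bed")

    counts_rows = []
    for cell, data in cells.items():
        ioformats.write_cytosine_report(data.calls, outdir / f"{cell}.cx.tsv")
        write_read_records(data.reads, outdir / f"{cell}.reads.tsv")
        counts_rows.append((cell, data.stage, data.genomic_reads, data.lambda_reads))
    pd.DataFrame(
        counts_rows, columns=["cell", "stage", "genomic_reads", "lambda_reads"]
    ).to_csv(outdir / "read_counts.tsv", sep="\t", index=False)

    truth_json = {
        "tss": truth.tss_table.to_dict(orient="list"),
        "planted_ndrs": [
            [iv.chrom, iv.start, iv.end, iv.name] for iv in truth.planted_ndrs
        ],
        "nucleosome_cores": [
            [iv.chrom, iv.start, iv.end] for iv in truth.nucleosome_cores
        ],
        "true_ploidy": truth.true_ploidy,
        "true_promoter_state": truth.true_promoter_state.to_dict(orient="dict"),
        "denovo_sites": truth.denovo_sites.to_dict(orient="list"),
    }
    ioformats.dump_json(truth_json, outdir / "ground_truth.json")


def write_read_records(reads: pd.DataFrame, path: str | Path) -> None:
    out = reads.copy()
    out["snp_obs"] = out["snp_obs"].apply(
        lambda obs: ";".join(f"{p}:{b}" for p, b in obs)
    )
    out["meth_obs"] = out["meth_obs"].apply(
        lambda obs: ";".join(f"{p}:{c}:{m}" for p, c, m in obs)
    )
    out.to_csv(path, sep="\t", index=False)


def read_read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)

    def parse_snp(s: str):
        if not s:
            return []
        return [
            (int(p), b) for p, b in (item.split(":") for item in s.split(";"))
        ]

    def parse_meth(s: str):
        if not s:
            return []
        return [
            (int(p), c, int(m))
            for p, c, m in (item.split(":") for item in s.split(";"))
        ]

    df["snp_obs"] = df["snp_obs"].astype(str).replace("nan", "").apply(parse_snp)
    df["meth_obs"] = df["meth_obs"].astype(str).replace("nan", "").apply(parse_meth)
    return df
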