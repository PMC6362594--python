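"""Seeded synthetic CRISPR screen generator with known ground truth.

The generator emulates the data structure the correction targets: a
segmented genome in which copy-number amplification arises either from
whole-chromosome duplication (copy-number ratio stays 1, no fitness bias) or
from focal events such as tandem duplications (ratio > 1, ratio-dependent
depletion bias), guides tiled over genes, a plasmid library, and replicate
counts carrying a ratio-dependent bias plus true essential-gene depletion.

Layout (defaults): 8 chromosomes of 10 Mb.  Four carry focal events — six
short (20 kb) focal segments each (one focal deletion at 0.5x the base
ploidy plus five amplifications whose multipliers densely cover ~1.3-4.6x
across the chromosomes), every focal event matched by a tandem-duplication
or deletion SV call with breakpoints jittered within the matching tolerance.
Two chromosomes are cleanly diploid and two wholly duplicated (the ratio-1
negative control at copy number 4).  Focal segments are kept short relative
to the chromosome so the size-weighted chromosome copy number stays close to
the base ploidy and segment ratios land near their intended multipliers;
focal passenger genes are a small share (~2%) of the genome, as focal
amplicons are in real screens, and focal segments carry enough genes that
the essential-gene load per segment matches the genome-wide rate.

Every segment hosts enough guides (>= 36) to be eligible for GP training, so
the default genome yields 80 eligible segments spanning ratios ~0.5 to ~4.5.

The injected bias is piecewise linear in the copy-number ratio and saturates:
b(r) = -beta * min(max(r - 1, 0), saturation - 1); counts are Poisson draws
around plasmid abundance times 2^(true fc + bias + Gaussian guide noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import copy_number
from .io_formats import (
    CopyNumberSegment,
    CountMatrix,
    GuideRecord,
    SvRecord,
    SvType,
    group_segments,
)

__all__ = [
    "SimulationConfig",
    "SimulatedGenome",
    "SimulatedScreen",
    "default_bias",
    "simulate_genome",
    "simulate_screen",
    "simulate_dataset",
    "write_simulation",
]


def default_bias(ratio: float, beta: float = 1.0, saturation: float = 4.0) -> float:
    """Piecewise-linear depletion bias: 0 at ratio <= 1, saturating at *saturation*."""
    return -beta * min(max(ratio - 1.0, 0.0), saturation - 1.0)


@dataclass
class SimulationConfig:
    n_chromosomes: int = 8
    chrom_length: int = 10_000_000
    segments_per_chromosome: int = 7
    genes_per_background_segment: int = 200
    genes_per_focal_segment: int = 9
    guides_per_gene: int = 4
    base_ploidy: int = 2
    # chromosome indices (1-based) carrying focal events / whole-chromosome dups
    focal_chromosomes: Tuple[int, ...] = (1, 2, 3, 4)
    whole_chrom_dup_chromosomes: Tuple[int, ...] = (7, 8)
    # per focal chromosome: focal segment copy number = base_ploidy * multiplier;
    # one focal deletion each, amplification ratios densely covering ~1.3-4.5
    focal_multipliers: Tuple[Tuple[float, ...], ...] = (
        (0.5, 1.30, 1.95, 2.60, 3.25, 3.90),
        (0.5, 1.45, 2.10, 2.75, 3.40, 4.10),
        (0.5, 1.60, 2.25, 2.90, 3.55, 4.35),
        (0.5, 1.75, 2.40, 3.05, 3.70, 4.60),
    )
    focal_segment_length: int = 20_000
    essential_fraction: float = 0.05
    nonexpressed_fraction: float = 0.4
    beta: float = 1.0
    bias_saturation: float = 4.0
    count_depth: int = 500
    noise_sd: float = 0.3
    low_abundance_fraction: float = 0.01
    n_replicates: int = 2
    cell_line: str = "CL1"
    sv_jitter_bp: int = 4_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("essential_fraction", "nonexpressed_fraction",
                     "low_abundance_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.count_depth <= 0:
            raise ValueError("count_depth must be > 0")
        if len(self.focal_multipliers) != len(self.focal_chromosomes):
            raise ValueError(
                "focal_multipliers needs one tuple per focal chromosome"
            )
        n_slots = max((len(m) for m in self.focal_multipliers), default=0)
        focal_span = n_slots * self.focal_segment_length
        background_span = self.chrom_length - focal_span
        min_gene_room = self.genes_per_background_segment * 100
        if background_span // self.segments_per_chromosome < min_gene_room:
            raise ValueError("chromosomes too short for the requested gene layout")
        if n_slots >= self.segments_per_chromosome:
            raise ValueError(
                "need fewer focal slots than background segments per chromosome"
            )
        if set(self.focal_chromosomes) & set(self.whole_chrom_dup_chromosomes):
            raise ValueError("a chromosome cannot be both focal and wholly duplicated")

    def bias(self, ratio: float) -> float:
        return default_bias(ratio, self.beta, self.bias_saturation)


@dataclass
class SimulatedGenome:
    segments: Dict[str, List[CopyNumberSegment]]
    library: List[GuideRecord]
    gene_annotation: pd.DataFrame
    svs: List[SvRecord]
    gene_segment: Dict[str, CopyNumberSegment]


@dataclass
class SimulatedScreen:
    counts: CountMatrix
    expression: pd.DataFrame
    ground_truth: pd.DataFrame
    config: SimulationConfig = field(repr=False)

    @property
    def sample_columns(self) -> List[str]:
        return [c for c in self.counts.samples if c != self.counts.plasmid_id]


def _tile_genes(
    seg: CopyNumberSegment, n_genes: int, guides_per_gene: int,
    chrom: str, gene_prefix: str, start_index: int,
):
    """Evenly tile *n_genes* genes (with guides) inside a segment, clear of its edges."""
    genes, guides = [], []
    margin = max(seg.length // 20, 200)
    usable = seg.length - 2 * margin
    slot = usable // n_genes
    gene_len = max(slot // 2, 120)
    for j in range(n_genes):
        gstart = seg.start + margin + j * slot
        gend = gstart + gene_len
        name = f"{gene_prefix}{start_index + j:04d}"
        genes.append({"gene": name, "chrom": chrom, "start": gstart, "end": gend})
        for k in range(guides_per_gene):
            pos = gstart + int((k + 0.5) * gene_len / guides_per_gene)
            guides.append(GuideRecord(f"{name}_sg{k + 1}", name, chrom, pos, pos + 20))
    return genes, guides


def simulate_genome(cfg: SimulationConfig) -> SimulatedGenome:
    """Build segments, guide library, gene annotation and matching SV calls."""
    rng = np.random.default_rng(cfg.seed)
    segments: List[CopyNumberSegment] = []
    genes: List[dict] = []
    library: List[GuideRecord] = []
    svs: List[SvRecord] = []
    gene_segment: Dict[str, CopyNumberSegment] = {}

    gene_counter = 0
    for ci in range(1, cfg.n_chromosomes + 1):
        chrom = f"chr{ci}"
        base_cn = float(cfg.base_ploidy)
        if ci in cfg.whole_chrom_dup_chromosomes:
            base_cn *= 2.0
        is_focal = ci in cfg.focal_chromosomes

        chrom_segs: List[CopyNumberSegment] = []
        if is_focal:
            mults = cfg.focal_multipliers[cfg.focal_chromosomes.index(ci)]
            n_focal = len(mults)
            bg_total = cfg.chrom_length - n_focal * cfg.focal_segment_length
            bg_len = bg_total // cfg.segments_per_chromosome
            # alternate background / focal; focal slots spread over the first
            # n_focal background boundaries
            pos = 0
            focal_iter = iter(mults)
            for si in range(cfg.segments_per_chromosome):
                last = si == cfg.segments_per_chromosome - 1
                end = cfg.chrom_length if last else pos + bg_len
                chrom_segs.append(CopyNumberSegment(chrom, pos, end, base_cn))
                pos = end
                if si < n_focal:
                    mult = next(focal_iter)
                    fseg = CopyNumberSegment(
                        chrom, pos, pos + cfg.focal_segment_length, base_cn * mult
                    )
                    chrom_segs.append(fseg)
                    pos = fseg.end
                    sv_type = (
                        SvType.TANDEM_DUPLICATION if mult > 1 else SvType.DELETION
                    )
                    j1 = int(rng.integers(-cfg.sv_jitter_bp, cfg.sv_jitter_bp + 1))
                    j2 = int(rng.integers(-cfg.sv_jitter_bp, cfg.sv_jitter_bp + 1))
                    svs.append(
                        SvRecord(sv_type, chrom, fseg.start + j1, chrom,
                                 fseg.end + j2, float(rng.uniform(60, 100)))
                    )
        else:
            bg_len = cfg.chrom_length // cfg.segments_per_chromosome
            for si in range(cfg.segments_per_chromosome):
                start = si * bg_len
                end = cfg.chrom_length if si == cfg.segments_per_chromosome - 1 else start + bg_len
                chrom_segs.append(CopyNumberSegment(chrom, start, end, base_cn))

        for seg in chrom_segs:
            n_genes = (
                cfg.genes_per_focal_segment
                if seg.length == cfg.focal_segment_length and is_focal
                else cfg.genes_per_background_segment
            )
            g, gu = _tile_genes(seg, n_genes, cfg.guides_per_gene, chrom, "GENE",
                                gene_counter)
            gene_counter += n_genes
            genes.extend(g)
            library.extend(gu)
            for rec in g:
                gene_segment[rec["gene"]] = seg
        segments.extend(chrom_segs)

    # decoy SV calls: filtered out by type or missing score, or far from any edge
    clean = [c for c in range(1, cfg.n_chromosomes + 1)
             if c not in cfg.focal_chromosomes][0]
    svs.append(SvRecord(SvType.INVERSION, f"chr{clean}", 1_000_000, f"chr{clean}",
                        2_000_000, 75.0))
    svs.append(SvRecord(SvType.TANDEM_DUPLICATION, f"chr{clean}", 900_000,
                        f"chr{clean}", 2_100_000, None))
    svs.append(SvRecord(SvType.TRANSLOCATION, "chr1", 5_000_000,
                        f"chr{clean}", 5_000_000, 80.0))

    ann = pd.DataFrame(genes).set_index("gene")
    return SimulatedGenome(group_segments(segments), library, ann, svs, gene_segment)


def simulate_screen(genome: SimulatedGenome, cfg: SimulationConfig) -> SimulatedScreen:
    """Draw plasmid and replicate counts with injected bias and essential depletion."""
    rng = np.random.default_rng(cfg.seed + 1)
    genes = list(genome.gene_annotation.index)
    n_genes = len(genes)

    essential = rng.random(n_genes) < cfg.essential_fraction
    nonexpr = (~essential) & (rng.random(n_genes) < cfg.nonexpressed_fraction)

    all_segs = [s for lst in genome.segments.values() for s in lst]
    est = copy_number.ploidy(all_segs, cfg.cell_line)

    rows = []
    for i, gene in enumerate(genes):
        seg = genome.gene_segment[gene]
        chrom_cn = est.chrom_cn[seg.chrom]
        ratio = seg.copy_number / chrom_cn
        rows.append(
            {
                "gene": gene,
                "chrom": seg.chrom,
                "essential": bool(essential[i]),
                "nonexpressed": bool(nonexpr[i]),
                "true_fc": -1.0 if essential[i] else 0.0,
                "gene_cn": seg.copy_number,
                "chrom_cn": chrom_cn,
                "ratio": ratio,
                "injected_bias": cfg.bias(ratio),
            }
        )
    truth = pd.DataFrame(rows).set_index("gene")

    guide_ids = [g.guide_id for g in genome.library]
    n_guides = len(guide_ids)
    abundance = rng.lognormal(mean=np.log(cfg.count_depth), sigma=0.3, size=n_guides)
    low = rng.random(n_guides) < cfg.low_abundance_fraction
    abundance[low] = rng.uniform(1, 15, size=int(low.sum()))

    guide_gene = np.array([g.gene for g in genome.library])
    guide_bias = truth["injected_bias"].loc[guide_gene].to_numpy()
    guide_true = truth["true_fc"].loc[guide_gene].to_numpy()

    cols = {"plasmid": rng.poisson(abundance)}
    for rep in range(1, cfg.n_replicates + 1):
        noise = rng.normal(0.0, cfg.noise_sd, size=n_guides)
        expected = abundance * np.exp2(guide_true + guide_bias + noise)
        cols[f"{cfg.cell_line}_rep{rep}"] = rng.poisson(expected)
    counts = pd.DataFrame(cols, index=pd.Index(guide_ids, name="guide_id"),
                          dtype=np.int64)

    rpkm = np.where(
        nonexpr,
        rng.uniform(0.0, 0.99, size=n_genes),
        np.exp2(rng.uniform(1.0, 8.0, size=n_genes)),
    )
    expression = pd.DataFrame({cfg.cell_line: rpkm}, index=truth.index)

    return SimulatedScreen(CountMatrix(counts, "plasmid"), expression, truth, cfg)


def simulate_dataset(cfg: SimulationConfig | None = None) -> Tuple[SimulatedGenome, SimulatedScreen]:
    cfg = cfg or SimulationConfig()
    genome = simulate_genome(cfg)
    return genome, simulate_screen(genome, cfg)


def write_simulation(genome: SimulatedGenome, screen: SimulatedScreen, outdir: str) -> Dict[str, str]:
    """Write all standard input files plus ground_truth.tsv to *outdir*."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    lib = pd.DataFrame(
        [
            {"guide_id": g.guide_id, "gene": g.gene, "chrom": g.chrom,
             "start": g.start, "end": g.end}
            for g in genome.library
        ]
    )
    paths["library"] = os.path.join(outdir, "library.tsv")
    lib.to_csv(paths["library"], sep="\t", index=False)

    segs = pd.DataFrame(
        [
            {"chrom": s.chrom, "start": s.start, "end": s.end,
             "copy_number": s.copy_number}
            for lst in genome.segments.values()
            for s in lst
        ]
    )
    paths["segments"] = os.path.join(outdir, "segments.tsv")
    segs.to_csv(paths["segments"], sep="\t", index=False)

    paths["counts"] = os.path.join(outdir, "counts.tsv")
    screen.counts.counts.to_csv(paths["counts"], sep="\t")

    paths["expression"] = os.path.join(outdir, "expression.tsv")
    screen.expression.to_csv(paths["expression"], sep="\t", index_label="gene")

    sv_rows = []
    for sv in genome.svs:
        sv_rows.append(
            {"sv_type": sv.sv_type.value, "chrom1": sv.chrom1, "pos1": sv.pos1,
             "chrom2": sv.chrom2, "pos2": sv.pos2,
             "assembly_score": "" if sv.assembly_score is None else sv.assembly_score}
        )
    paths["svs"] = os.path.join(outdir, "svs.bedpe.tsv")
    pd.DataFrame(sv_rows).to_csv(paths["svs"], sep="\t", index=False)

    paths["annotation"] = os.path.join(outdir, "gene_annotation.tsv")
    genome.gene_annotation.to_csv(paths["annotation"], sep="\t", index_label="gene")

    ess = screen.ground_truth.index[screen.ground_truth["essential"]]
    paths["essential"] = os.path.join(outdir, "essential_genes.txt")
    with open(paths["essential"], "w") as fh:
        fh.write("\n".join(ess) + "\n")

    paths["ground_truth"] = os.path.join(outdir, "ground_truth.tsv")
    screen.ground_truth.to_csv(paths["ground_truth"], sep="\t", index_label="gene")
    return paths
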