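"""Synthetic chilling-accumulation experiments with known ground truth.

Generates, from one seed, a complete desk-scale experiment: a random genome
with realistic cytosine-context composition, non-overlapping gene models,
per-sample cytosine reports for a 2-genotype x 4-condition x 3-replicate
design, negative-binomial gene counts, and truth tables for every planted
differentially methylated region (DMR), differentially expressed gene (DEG)
and anti-correlated DMR-gene pair.  Every downstream stage of the pipeline
is testable against these truth tables without any external data.

Planted effects
---------------
The windowed methylation statistic is a log2 density enrichment, gated at a
3-log2-unit between-condition difference; only order-of-magnitude changes in
methylated-call density can pass that gate.  Planted DMR loci therefore model
de-novo (RdDM-like) gain at near-unmethylated loci (locus baseline 0.05
rising by the planted effect, default +0.5, from the onset condition) and the
mirror-image loss at methylated loci (0.55 falling by the effect).  Ordinary
planted DMRs switch on as a step at the onset condition; DMRs that belong to
an anti-correlated gene pair ramp monotonically across conditions while
their partner gene's expression ramps the opposite way.

Methylation baselines per context default to CpG 0.60, CHG 0.35, CHH 0.10 —
typical plant-methylome per-context rates.  Coverage is negative binomial
(mean 20, size 5); counts are NB with dispersion 0.1 around log-normal
baseline means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CONTEXTS, write_cytosine_report, write_gene_models

__all__ = [
    "SimulationDesign",
    "SimulatedExperiment",
    "simulate_genome",
    "cytosine_sites",
    "simulate_methylome",
    "simulate_counts",
    "simulate_experiment",
    "write_experiment",
]

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class SimulationDesign:
    """Parameters of a synthetic experiment.

    Defaults are the desk-scale preset: 2 genotypes x 4 chilling conditions x
    3 replicates on one 200 kb chromosome with 500 genes, 40 planted DMRs, 50
    planted DEGs and 10 planted anti-correlated pairs.
    """

    seed: int = 0
    conditions: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "royal_dawn": (0, 173, 348, 516),
            "kordia": (0, 443, 1295, 1637),
        }
    )
    replicates: int = 3
    chrom_sizes: Mapping[str, int] = field(default_factory=lambda: {"chr1": 200_000})
    gc_content: float = 0.38
    n_genes: int = 500
    gene_length: tuple[int, int] = (150, 400)
    baselines: Mapping[str, float] = field(
        default_factory=lambda: {"CpG": 0.60, "CHG": 0.35, "CHH": 0.10}
    )
    coverage_mean: float = 20.0
    coverage_size: float = 5.0
    # planted DMRs
    n_dmrs: int = 40
    dmr_width: int = 200
    dmr_effect: float = 0.5
    dmr_low_baseline: float = 0.05
    dmr_high_baseline: float = 0.55
    dmr_context: str = "all"        # 'all' or one of CONTEXTS
    dmr_onset_index: int = 1
    # planted DEGs
    n_degs: int = 50
    deg_log2fc: float = 2.0
    deg_onset_index: int = 1
    nb_dispersion: float = 0.1
    expr_log_mean: float = 5.0      # natural-log scale of baseline means
    expr_log_sd: float = 1.0
    depth_log_sd: float = 0.1       # sample depth-factor spread
    # planted anti-correlated DMR-gene pairs
    n_pairs: int = 10
    pair_drop_log2: float = 2.5
    pair_offset: int = 500          # bp between gene end and pair DMR
    window: int = 100               # analysis window the planting aligns to

    def __post_init__(self) -> None:
        for ctx, p in self.baselines.items():
            if not 0 <= p <= 1:
                raise ValueError(f"baseline for {ctx} outside [0,1]")
        for g, conds in self.conditions.items():
            if not 0 <= self.dmr_onset_index < len(conds):
                raise ValueError("dmr_onset_index outside the condition range")
        if self.dmr_context not in ("all", *CONTEXTS):
            raise ValueError(f"unknown dmr_context {self.dmr_context!r}")

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def condition_label(self, genotype: str, ch: int) -> str:
        return f"{ch}CH"

    def sample_id(self, genotype: str, ch: int, rep: int) -> str:
        return f"{genotype}_{ch}CH_r{rep}"


@dataclass
class SimulatedExperiment:
    """All artefacts of one simulated experiment."""

    design: SimulationDesign
    genome: dict[str, str]
    genes: pd.DataFrame
    sites: pd.DataFrame
    calls: dict[str, dict[str, pd.DataFrame]]      # genotype -> sample -> calls
    counts: dict[str, pd.DataFrame]                # genotype -> genes x samples
    sample_sheets: dict[str, pd.DataFrame]
    truth_dmrs: pd.DataFrame
    truth_degs: pd.DataFrame
    truth_pairs: pd.DataFrame

    def sample_design(self, genotype: str) -> dict[str, str]:
        sheet = self.sample_sheets[genotype]
        return dict(zip(sheet["sample_id"], sheet["condition"]))


# ---------------------------------------------------------------------------
# genome

def simulate_genome(
    design: SimulationDesign, rng: np.random.Generator
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome plus non-overlapping gene models.

    Sequence bases are i.i.d. with the configured GC content, which yields a
    realistic mix of CpG/CHG/CHH cytosine contexts.  Genes are placed without
    overlap by distributing the slack between consecutive genes at random;
    an error is raised if they cannot fit.
    """
    bases = np.array(list("ACGT"))
    p_gc = design.gc_content / 2
    probs = [(1 - design.gc_content) / 2, p_gc, p_gc, (1 - design.gc_content) / 2]
    genome = {
        chrom: "".join(rng.choice(bases, size=size, p=probs))
        for chrom, size in design.chrom_sizes.items()
    }

    lo, hi = design.gene_length
    lengths = rng.integers(lo, hi + 1, size=design.n_genes)
    # spread genes over chromosomes proportionally to size
    chroms = list(design.chrom_sizes)
    sizes = np.array([design.chrom_sizes[c] for c in chroms], dtype=float)
    assign = rng.choice(len(chroms), size=design.n_genes, p=sizes / sizes.sum())
    rows = []
    gi = 0
    for ci, chrom in enumerate(chroms):
        glens = lengths[assign == ci]
        slack = design.chrom_sizes[chrom] - int(glens.sum())
        if slack < 0:
            raise ValueError(f"genes do not fit on {chrom}")
        # random gaps before each gene and after the last one
        cuts = np.sort(rng.integers(0, slack + 1, size=len(glens)))
        gaps = np.diff(np.concatenate([[0], cuts]))
        pos = 1
        for L, gap in zip(glens, gaps):
            start = pos + int(gap)
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"g{gi:04d}", chrom, start, start + int(L) - 1, strand))
            pos = start + int(L)
            gi += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return genome, genes


def cytosine_sites(genome: Mapping[str, str]) -> pd.DataFrame:
    """All cytosine positions (both strands) with their sequence context.

    A ``C`` on the forward strand at i (1-based) is CpG if followed by G, CHG
    if the base after next is G, else CHH; a ``G`` on the forward strand is a
    cytosine on the reverse strand and is classified from the reverse
    complement.  Sites within 2 bp of a chromosome end are skipped.
    """
    frames = []
    for chrom, seq in genome.items():
        a = np.frombuffer(seq.encode(), dtype="S1")
        n = len(a)
        is_c = a == b"C"
        is_g = a == b"G"
        idx_c = np.flatnonzero(is_c)
        idx_c = idx_c[(idx_c >= 2) & (idx_c < n - 2)]
        nxt1 = a[idx_c + 1] == b"G"
        nxt2 = a[idx_c + 2] == b"G"
        ctx_c = np.where(nxt1, "CpG", np.where(nxt2, "CHG", "CHH"))
        idx_g = np.flatnonzero(is_g)
        idx_g = idx_g[(idx_g >= 2) & (idx_g < n - 2)]
        prv1 = a[idx_g - 1] == b"C"
        prv2 = a[idx_g - 2] == b"C"
        ctx_g = np.where(prv1, "CpG", np.where(prv2, "CHG", "CHH"))
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": np.concatenate([idx_c, idx_g]) + 1,
                "strand": np.concatenate(
                    [np.full(len(idx_c), "+"), np.full(len(idx_g), "-")]
                ),
                "context": np.concatenate([ctx_c, ctx_g]),
            }
        )
        frames.append(df.sort_values("pos", kind="stable"))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# planting

def _plant_truth(
    design: SimulationDesign, genes: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Choose planted DMR windows, DEG genes and anti-correlated pairs.

    Planted elements are shared across genotypes (same loci, same
    directions), which is what makes cross-genotype conservation testable;
    the noise realisations differ per genotype.
    """
    w = design.window
    chrom = max(design.chrom_sizes, key=design.chrom_sizes.get)
    chrom_len = design.chrom_sizes[chrom]
    n_slots = chrom_len // w
    width_w = max(1, design.dmr_width // w)
    used: set[int] = set()

    def claim(slot: int) -> bool:
        span = set(range(slot - 1, slot + width_w + 1))  # keep a buffer slot
        if span & used or slot < 0 or slot + width_w > n_slots:
            return False
        used.update(span)
        return True

    # pair DMRs first: place just downstream of their partner gene
    gene_pool = genes[genes["chrom"] == chrom].reset_index(drop=True)
    pair_rows, dmr_rows = [], []
    order = rng.permutation(len(gene_pool))
    n_half = design.n_pairs // 2
    placed = 0
    for oi in order:
        if placed >= design.n_pairs:
            break
        g = gene_pool.iloc[oi]
        slot = (int(g.end) + design.pair_offset) // w
        if not claim(slot):
            continue
        start = slot * w + 1
        end = start + width_w * w - 1
        direction = "hyper" if placed < design.n_pairs - n_half else "hypo"
        dmr_id = f"pdmr{placed:03d}"
        dmr_rows.append(
            (dmr_id, chrom, start, end, direction, design.dmr_context,
             design.dmr_onset_index, design.dmr_effect, "ramp", "pair", g.gene_id)
        )
        pair_rows.append(
            (g.gene_id, dmr_id, direction,
             "down" if direction == "hyper" else "up", design.pair_drop_log2)
        )
        placed += 1
    if placed < design.n_pairs:
        raise ValueError("could not place all anti-correlated pairs")

    # ordinary planted DMRs
    n_hyper = design.n_dmrs // 2
    for i in range(design.n_dmrs):
        for _ in range(1000):
            slot = int(rng.integers(0, n_slots - width_w))
            if claim(slot):
                break
        else:
            raise ValueError("could not place all planted DMRs")
        start = slot * w + 1
        end = start + width_w * w - 1
        direction = "hyper" if i < n_hyper else "hypo"
        dmr_rows.append(
            (f"dmr{i:03d}", chrom, start, end, direction, design.dmr_context,
             design.dmr_onset_index, design.dmr_effect, "step", "dmr", "")
        )
    truth_dmrs = pd.DataFrame(
        dmr_rows,
        columns=["dmr_id", "chrom", "start", "end", "direction", "context",
                 "onset_index", "effect", "profile", "kind", "pair_gene"],
    )
    truth_pairs = pd.DataFrame(
        pair_rows,
        columns=["gene_id", "dmr_id", "dmr_direction", "expr_direction",
                 "drop_log2"],
    )

    # planted DEGs among genes not used by pairs
    candidates = [g for g in genes["gene_id"] if g not in set(truth_pairs["gene_id"])]
    deg_genes = rng.choice(candidates, size=design.n_degs, replace=False)
    signs = np.where(np.arange(design.n_degs) < design.n_degs // 2, 1, -1)
    truth_degs = pd.DataFrame(
        {
            "gene_id": deg_genes,
            "sign": signs,
            "log2fc": design.deg_log2fc,
            "onset_index": design.deg_onset_index,
        }
    )
    return truth_dmrs, truth_degs, truth_pairs


# ---------------------------------------------------------------------------
# methylome

def _site_probabilities(
    design: SimulationDesign,
    sites: pd.DataFrame,
    truth_dmrs: pd.DataFrame,
    n_conds: int,
) -> np.ndarray:
    """(n_conds, n_sites) methylation probabilities including planted effects."""
    ctx = sites["context"].to_numpy()
    base = np.zeros(len(sites))
    for c, p in design.baselines.items():
        base[ctx == c] = p
    P = np.tile(base, (n_conds, 1))
    chrom_arr = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    for d in truth_dmrs.itertuples(index=False):
        in_win = (chrom_arr == d.chrom) & (pos >= d.start) & (pos <= d.end)
        locus_base = (
            design.dmr_low_baseline if d.direction == "hyper"
            else design.dmr_high_baseline
        )
        P[:, in_win] = locus_base
        shift_mask = in_win if d.context == "all" else in_win & (ctx == d.context)
        sign = 1.0 if d.direction == "hyper" else -1.0
        for c in range(n_conds):
            if d.profile == "step":
                frac = 1.0 if c >= d.onset_index else 0.0
            else:  # monotone ramp across conditions
                frac = c / (n_conds - 1) if n_conds > 1 else 0.0
            P[c, shift_mask] = locus_base + sign * d.effect * frac
    return np.clip(P, 0.01, 0.99)


def simulate_methylome(
    design: SimulationDesign,
    sites: pd.DataFrame,
    truth_dmrs: pd.DataFrame,
    genotype: str,
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Per-sample cytosine calls for one genotype.

    Coverage per site is NB(mean, size); methylated calls are binomial with
    the site's condition-specific probability.  Sites drawing zero coverage
    produce no call line for that sample.
    """
    conds = design.conditions[genotype]
    P = _site_probabilities(design, sites, truth_dmrs, len(conds))
    size = design.coverage_size
    p_nb = size / (size + design.coverage_mean)
    out: dict[str, pd.DataFrame] = {}
    n_sites = len(sites)
    for ci, ch in enumerate(conds):
        for rep in range(1, design.replicates + 1):
            cov = rng.negative_binomial(size, p_nb, size=n_sites)
            meth = rng.binomial(cov, P[ci])
            keep = cov > 0
            df = pd.DataFrame(
                {
                    "chrom": sites["chrom"].to_numpy()[keep],
                    "pos": sites["pos"].to_numpy()[keep],
                    "strand": sites["strand"].to_numpy()[keep],
                    "n_meth": meth[keep],
                    "n_unmeth": (cov - meth)[keep],
                    "context": sites["context"].to_numpy()[keep],
                }
            )
            out[design.sample_id(genotype, ch, rep)] = df
    return out


# ---------------------------------------------------------------------------
# counts

def simulate_counts(
    design: SimulationDesign,
    genes: pd.DataFrame,
    truth_degs: pd.DataFrame,
    truth_pairs: pd.DataFrame,
    genotype: str,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB gene counts and a sample sheet for one genotype.

    Baseline means are log-normal across genes; planted DEGs multiply their
    mean by 2**(sign*log2fc) from the onset condition onward; pair genes ramp
    monotonically by ``drop_log2`` log2 units across conditions, opposite in
    sign to their partner DMR.
    """
    conds = design.conditions[genotype]
    n_conds = len(conds)
    gene_ids = genes["gene_id"].to_numpy()
    base = rng.lognormal(design.expr_log_mean, design.expr_log_sd, size=len(gene_ids))
    means = np.tile(base[:, None], (1, n_conds))
    gidx = {g: i for i, g in enumerate(gene_ids)}
    for t in truth_degs.itertuples(index=False):
        i = gidx[t.gene_id]
        for c in range(t.onset_index, n_conds):
            means[i, c] *= 2.0 ** (t.sign * t.log2fc)
    for t in truth_pairs.itertuples(index=False):
        i = gidx[t.gene_id]
        sign = -1.0 if t.expr_direction == "down" else 1.0
        for c in range(n_conds):
            frac = c / (n_conds - 1) if n_conds > 1 else 0.0
            means[i, c] = base[i] * 2.0 ** (sign * t.drop_log2 * frac)

    disp = design.nb_dispersion
    cols, data, sheet_rows = [], [], []
    for ci, ch in enumerate(conds):
        for rep in range(1, design.replicates + 1):
            depth = rng.lognormal(0.0, design.depth_log_sd)
            mu = means[:, ci] * depth
            if disp > 0:
                counts = rng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * mu))
            else:
                counts = rng.poisson(mu)
            sid = design.sample_id(genotype, ch, rep)
            cols.append(sid)
            data.append(counts)
            sheet_rows.append((sid, genotype, f"{ch}CH", ch, rep))
    counts = pd.DataFrame(
        np.column_stack(data), index=pd.Index(gene_ids, name="gene_id"), columns=cols
    )
    sheet = pd.DataFrame(
        sheet_rows,
        columns=["sample_id", "genotype", "condition", "condition_CH", "replicate"],
    )
    return counts, sheet


# ---------------------------------------------------------------------------
# full experiment

def simulate_experiment(design: SimulationDesign) -> SimulatedExperiment:
    """Generate the whole experiment; fully deterministic under the seed."""
    ss = np.random.SeedSequence(design.seed)
    keys = ["genome", "plant"] + [
        f"{assay}:{g}" for g in design.conditions for assay in ("meth", "rna")
    ]
    children = dict(zip(keys, ss.spawn(len(keys))))
    rng_genome = np.random.default_rng(children["genome"])
    genome, genes = simulate_genome(design, rng_genome)
    sites = cytosine_sites(genome)
    truth_dmrs, truth_degs, truth_pairs = _plant_truth(
        design, genes, np.random.default_rng(children["plant"])
    )
    calls, counts, sheets = {}, {}, {}
    for g in design.conditions:
        calls[g] = simulate_methylome(
            design, sites, truth_dmrs, g, np.random.default_rng(children[f"meth:{g}"])
        )
        counts[g], sheets[g] = simulate_counts(
            design, genes, truth_degs, truth_pairs, g,
            np.random.default_rng(children[f"rna:{g}"]),
        )
    return SimulatedExperiment(
        design=design,
        genome=genome,
        genes=genes,
        sites=sites,
        calls=calls,
        counts=counts,
        sample_sheets=sheets,
        truth_dmrs=truth_dmrs,
        truth_degs=truth_degs,
        truth_pairs=truth_pairs,
    )


def write_experiment(exp: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write every artefact as plain text; returns the path map."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = outdir / "genome.fa"
    SeqIO.write(
        [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in exp.genome.items()],
        fasta, "fasta",
    )
    paths["genome"] = fasta

    gff = outdir / "genes.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in exp.genes.itertuples(index=False):
            fh.write(
                f"{g.chrom}\tchillmeth\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
    paths["genes"] = gff
    bed = outdir / "genes.bed"
    write_gene_models(exp.genes, bed)
    paths["genes_bed"] = bed

    for genotype, samples in exp.calls.items():
        d = outdir / "methylome" / genotype
        d.mkdir(parents=True, exist_ok=True)
        for sid, df in samples.items():
            write_cytosine_report(df, d / f"{sid}.cx.tsv")
        paths[f"methylome:{genotype}"] = d
    for genotype, cm in exp.counts.items():
        p = outdir / f"counts_{genotype}.tsv"
        cm.to_csv(p, sep="\t")
        paths[f"counts:{genotype}"] = p
        p = outdir / f"samples_{genotype}.tsv"
        exp.sample_sheets[genotype].to_csv(p, sep="\t", index=False)
        paths[f"samples:{genotype}"] = p

    for name, df in (
        ("truth_dmrs", exp.truth_dmrs),
        ("truth_degs", exp.truth_degs),
        ("truth_pairs", exp.truth_pairs),
    ):
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p

    design_dict = asdict(exp.design)
    design_dict["conditions"] = {k: list(v) for k, v in exp.design.conditions.items()}
    design_dict["chrom_sizes"] = dict(exp.design.chrom_sizes)
    design_dict["baselines"] = dict(exp.design.baselines)
    design_dict["gene_length"] = list(exp.design.gene_length)
    p = outdir / "design.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(design_dict, fh, sort_keys=True)
    paths["design"] = p
    return paths
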