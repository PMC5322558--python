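"""Synthetic data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: multi
species alignments evolved on a fixed tree with planted rate-decelerated
elements, site frequency spectra drawn from per-class Normal distributions
of 2Ns under the PRF model, sequences with controlled dinucleotide
composition, and toy gene annotations with a matching genome. All
generators are bit-reproducible under a fixed seed. Sites evolve
independently (no indels, no rate autocorrelation), matching the analysis
model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import AnnotationSet
from .maf import MafBlock, MafRow
from .phylo import PhyloModel, Tree, parse_newick, transition_matrix
from .rna import dinucleotide_shuffle
from .selection import SfsObservation, ascertainment_weight

__all__ = [
    "DEFAULT_TREE_NEWICK",
    "default_tree",
    "default_model",
    "SimulationConfig",
    "SfsClassConfig",
    "simulate_alignment",
    "simulate_sfs",
    "random_seq_with_dinucleotides",
    "ToyGenome",
    "toy_annotation_generator",
]

# Twelve Drosophila-clade assemblies on a plausible topology; branch lengths
# in expected substitutions/site sum to ~3.2, comparable to genome-wide
# divergence across the clade.
DEFAULT_TREE_NEWICK = (
    "((((((dm3:0.06,(droSim1:0.05,droSec1:0.05):0.03):0.06,"
    "(droYak2:0.10,droEre2:0.09):0.04):0.11,droAna3:0.26):0.09,"
    "(dp4:0.03,droPer1:0.03):0.29):0.11,droWil1:0.40):0.13,"
    "((droVir3:0.31,droMoj3:0.33):0.09,droGri2:0.36):0.16);"
)


def default_tree(scale: float = 1.0) -> Tree:
    tree = parse_newick(DEFAULT_TREE_NEWICK)
    tree.blen[tree.root] = 0.0
    return tree.scaled(scale) if scale != 1.0 else tree


def default_model(kind: str = "HKY", kappa: float = 2.0, tree_scale: float = 1.0) -> PhyloModel:
    pi = np.array([0.29, 0.21, 0.21, 0.29])  # fly-like, slightly A+T rich
    if kind.upper() == "JC":
        pi = np.full(4, 0.25)
    return PhyloModel(tree=default_tree(tree_scale), kind=kind, kappa=kappa, pi=pi)


@dataclass
class SimulationConfig:
    """Ground-truth configuration for the alignment simulator.

    ``planted`` lists (start, length, rate_scale) triples on the reference;
    a rate scale of 0 copies the root base to every leaf (a perfect
    element), values in (0, 1) decelerate, 1 is background.
    """

    seed: int = 0
    model: PhyloModel | None = None
    genome_length: int = 50_000
    planted: Sequence[tuple[int, int, float]] = ()
    chrom: str = "chrSim"
    ref_species: str = "dm3"
    block_width: int = 1000
    # the scan never stitches runs across block boundaries, so planted
    # intervals must not straddle one unless explicitly testing that case
    allow_block_straddle: bool = False

    def __post_init__(self):
        if self.model is None:
            self.model = default_model()
        ivs = sorted((s, s + l) for s, l, _ in self.planted)
        for (s, e), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e:
                raise ValueError(f"planted intervals overlap: {(s, e)} and {(s2, e2)}")
        for s, e in ivs:
            if s < 0 or e > self.genome_length:
                raise ValueError(f"planted interval {(s, e)} outside genome bounds")
            if not self.allow_block_straddle and (
                s // self.block_width != (e - 1) // self.block_width
            ):
                raise ValueError(
                    f"planted interval {(s, e)} straddles a {self.block_width}-column "
                    "block boundary; move it or set allow_block_straddle=True"
                )


def _sample_states(P: np.ndarray, parent_states: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw of child states given parent states and uniforms."""
    cum = np.cumsum(P, axis=1)
    return (u[:, None] > cum[parent_states]).sum(axis=1).astype(np.int8)


def simulate_alignment(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[MafBlock], list[tuple[str, int, int]]]:
    """Evolve a genome down the tree and emit MAF blocks plus truth intervals.

    The root sequence is drawn from the model's equilibrium frequencies;
    each site evolves independently along every branch with transition
    matrix expm(Q * lambda * t), where lambda is the planted rate scale of
    the site (1 for background, 0 copying the root base to all leaves).
    Blocks of ``block_width`` columns are emitted; truth intervals are
    returned as (chrom, start, end).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    model = config.model
    tree = model.tree
    L = config.genome_length
    lam = np.ones(L)
    for s, length, scale in config.planted:
        lam[s : s + length] = scale
    scales = np.unique(lam)
    root_states = rng.choice(4, size=L, p=model.pi).astype(np.int8)
    states = {tree.root: root_states}
    preorder = list(reversed(tree.postorder))
    for node in preorder:
        if node == tree.root:
            continue
        parent_states = states[tree.parent[node]]
        child = np.empty(L, dtype=np.int8)
        u = rng.random(L)
        for sc in scales:
            mask = lam == sc
            if sc == 0.0:
                child[mask] = parent_states[mask]
            else:
                P = transition_matrix(model, tree.blen[node] * sc)
                child[mask] = _sample_states(P, parent_states[mask], u[mask])
        states[node] = child
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    leaf_seqs = {
        tree.names[leaf]: base_arr[states[leaf]].tobytes().decode()
        for leaf in tree.leaves
    }
    blocks = []
    for start in range(0, L, config.block_width):
        end = min(start + config.block_width, L)
        block = MafBlock(ref_species=config.ref_species)
        for sp in [config.ref_species] + [
            n for n in tree.leaf_names if n != config.ref_species
        ]:
            text = leaf_seqs[sp][start:end]
            chrom = config.chrom if sp == config.ref_species else f"scf_{sp}"
            block.rows[sp] = MafRow(
                species=sp, chrom=chrom, start=start, size=end - start,
                strand="+", src_size=L, text=text,
            )
        blocks.append(block)
    truth = [(config.chrom, s, s + l) for s, l, _ in sorted(config.planted)]
    return blocks, truth


@dataclass
class SfsClassConfig:
    """Generative regime of one site class's frequency spectrum."""

    label: str
    mu: float
    sigma2: float
    n_sites: int
    sample_size: int
    ascertained: bool = False
    div_intensity: float = 0.0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2")


def simulate_sfs(
    class_configs: Sequence[SfsClassConfig], rng: np.random.Generator
) -> tuple[dict[str, list[SfsObservation]], dict[str, tuple[float, float]]]:
    """Draw derived-allele counts per class under the hierarchical PRF model.

    Per site: gamma ~ Normal(mu_c, sigma2_c); ascertained classes
    accept/reject each site with probability exp(-div_intensity * v(gamma));
    the derived count is drawn from the PRF sampling distribution by
    inverse CDF. Returns the observation table and the truth parameters.
    """
    data: dict[str, list[SfsObservation]] = {}
    truth: dict[str, tuple[float, float]] = {}
    for cfg in class_configs:
        truth[cfg.label] = (cfg.mu, cfg.sigma2)
        gammas = np.empty(cfg.n_sites)
        filled = 0
        attempts = 0
        while filled < cfg.n_sites:
            draw = rng.normal(cfg.mu, np.sqrt(cfg.sigma2), size=cfg.n_sites)
            attempts += len(draw)
            if cfg.ascertained and cfg.div_intensity > 0:
                keep = rng.random(len(draw)) < ascertainment_weight(
                    draw, cfg.div_intensity
                )
                draw = draw[keep]
            take = min(len(draw), cfg.n_sites - filled)
            gammas[filled : filled + take] = draw[:take]
            filled += take
            if attempts > 1000 * cfg.n_sites:
                raise RuntimeError(
                    f"class {cfg.label}: ascertainment rejection rate > 99.9%; "
                    "reduce div_intensity"
                )
        n = cfg.sample_size
        counts = np.empty(cfg.n_sites, dtype=int)
        u = rng.random(cfg.n_sites)
        from .selection import _binomial_kernel, _density_matrix, _gl_nodes

        x_nodes = _gl_nodes(50)[0]
        B = _binomial_kernel(n, 50)  # (n-1, K), weights included
        for lo in range(0, cfg.n_sites, 4000):
            hi = min(lo + 4000, cfg.n_sites)
            F = _density_matrix(gammas[lo:hi], x_nodes)  # (m, K)
            P = F @ B.T  # (m, n-1)
            cdf = np.cumsum(P / P.sum(axis=1, keepdims=True), axis=1)
            counts[lo:hi] = (u[lo:hi, None] > cdf).sum(axis=1) + 1
        counts = np.clip(counts, 1, n - 1)
        data[cfg.label] = [
            SfsObservation(cfg.label, int(i), n) for i in counts
        ]
    return data, truth


def random_seq_with_dinucleotides(
    template: str | None = None,
    counts: Mapping[tuple[str, str], int] | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """A random sequence realizing exact dinucleotide counts.

    Give either a template sequence (its counts are used) or an explicit
    count matrix. The counts must admit an Eulerian path in the
    dinucleotide transition multigraph (degree and connectivity
    conditions); otherwise a ValueError names the violated condition.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if template is not None:
        if len(template) < 2:
            raise ValueError("template must have length >= 2")
        return dinucleotide_shuffle(template, rng)
    if not counts:
        raise ValueError("provide a template or a non-empty count matrix")
    # degree condition: at most one vertex with out-in = +1 (start) and one
    # with in-out = +1 (end); all others balanced
    outdeg: dict[str, int] = {}
    indeg: dict[str, int] = {}
    succ: dict[str, list[str]] = {}
    for (a, b), c in counts.items():
        if c < 0:
            raise ValueError("counts must be non-negative")
        if c:
            outdeg[a] = outdeg.get(a, 0) + c
            indeg[b] = indeg.get(b, 0) + c
            succ.setdefault(a, []).extend([b] * c)
    vertices = set(outdeg) | set(indeg)
    starts = [v for v in vertices if outdeg.get(v, 0) - indeg.get(v, 0) == 1]
    ends = [v for v in vertices if indeg.get(v, 0) - outdeg.get(v, 0) == 1]
    balanced = all(
        abs(outdeg.get(v, 0) - indeg.get(v, 0)) <= 1 for v in vertices
    )
    if not balanced or len(starts) > 1 or len(ends) > 1 or (len(starts) != len(ends)):
        raise ValueError(
            "counts violate the Eulerian-path degree condition "
            f"(start candidates {starts}, end candidates {ends})"
        )
    start = starts[0] if starts else sorted(vertices)[0]
    # Hierholzer construction of one Eulerian path
    pools = {v: list(s) for v, s in succ.items()}
    stack, path = [start], []
    while stack:
        v = stack[-1]
        if pools.get(v):
            stack.append(pools[v].pop())
        else:
            path.append(stack.pop())
    path.reverse()
    if len(path) != sum(counts.values()) + 1:
        raise ValueError(
            "counts violate the connectivity condition: transition graph "
            "is not a single connected Eulerian component"
        )
    return dinucleotide_shuffle("".join(path), rng)


@dataclass
class ToyGenome:
    """A toy genome with consistent gene models for annotation tests."""

    genome: str
    annotations: AnnotationSet
    genes: pd.DataFrame  # chromosome/start/end/symbol/fbid rows, CDS intervals
    gff3: str
    chrom: str = "chrSim"


def toy_annotation_generator(
    n_genes: int,
    rng: np.random.Generator,
    exons_per_gene: int = 2,
    exon_len: int = 200,
    intron_len: int = 100,
    utr_len: int = 50,
    intergenic_len: int = 300,
    chrom: str = "chrSim",
) -> ToyGenome:
    """Deterministic toy gene models: UTR - CDS (- intron - CDS)* - UTR.

    Lengths are jittered around the given geometry; coordinates are 0-based
    half-open and consistent (features nest within gene bounds, introns sit
    between consecutive CDS exons). Returns the genome sequence, an
    :class:`AnnotationSet`, a per-CDS gene table, and GFF3 text.
    """
    if min(exons_per_gene, exon_len, intron_len, utr_len, intergenic_len) <= 0:
        raise ValueError("geometry parameters must be positive")
    intervals: list[tuple[str, int, int, str]] = []
    gff_lines = ["##gff-version 3"]
    gene_rows = []
    pos = 0

    def jitter(mean):
        return max(10, int(rng.integers(int(mean * 0.7), int(mean * 1.3) + 1)))

    for g in range(n_genes):
        pos += jitter(intergenic_len)
        gene_start = pos
        symbol = f"gene{g + 1}"
        fbid = f"TOY{g + 1:07d}"
        utr5 = (pos, pos + jitter(utr_len))
        pos = utr5[1]
        cds_list = []
        introns = []
        for e in range(exons_per_gene):
            if e > 0:
                iv = (pos, pos + jitter(intron_len))
                introns.append(iv)
                pos = iv[1]
            cds = (pos, pos + jitter(exon_len))
            cds_list.append(cds)
            pos = cds[1]
        utr3 = (pos, pos + jitter(utr_len))
        pos = utr3[1]
        gene_end = pos
        gff_lines.append(
            f"{chrom}\ttoy\tgene\t{gene_start + 1}\t{gene_end}\t.\t+\t."
            f"\tID={fbid};Name={symbol}"
        )
        for s, e in (utr5,):
            intervals.append((chrom, s, e, "utr"))
            gff_lines.append(
                f"{chrom}\ttoy\tfive_prime_UTR\t{s + 1}\t{e}\t.\t+\t.\tParent={fbid}"
            )
        for s, e in cds_list:
            intervals.append((chrom, s, e, "cds"))
            gff_lines.append(f"{chrom}\ttoy\tCDS\t{s + 1}\t{e}\t.\t+\t0\tParent={fbid}")
            gene_rows.append(
                {"chromosome": chrom, "start": s, "end": e, "symbol": symbol, "fbid": fbid}
            )
        for s, e in introns:
            intervals.append((chrom, s, e, "intron"))
            gff_lines.append(
                f"{chrom}\ttoy\tintron\t{s + 1}\t{e}\t.\t+\t.\tParent={fbid}"
            )
        intervals.append((chrom, utr3[0], utr3[1], "utr"))
        gff_lines.append(
            f"{chrom}\ttoy\tthree_prime_UTR\t{utr3[0] + 1}\t{utr3[1]}\t.\t+\t."
            f"\tParent={fbid}"
        )
    genome_len = pos + jitter(intergenic_len)
    genome = "".join(
        np.array(list("ACGT"))[rng.integers(0, 4, size=genome_len)]
    )
    return ToyGenome(
        genome=genome,
        annotations=AnnotationSet(intervals),
        genes=pd.DataFrame(
            gene_rows, columns=["chromosome", "start", "end", "symbol", "fbid"]
        ),
        gff3="\n".join(gff_lines) + "\n",
        chrom=chrom,
    )
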