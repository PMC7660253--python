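"""Seeded generators for every pipeline input, with planted recoverable signal.

The generators emulate the statistical structure the analysis assumes: a
16-chromosome budding-yeast genome, strain panels whose small chromosomes
are aneuploid more often than large ones (with gains twice as likely as
losses), signed genetic-interaction tables with per-chromosome-pair score
blocks, binary stress up-regulation flags with planted enriched
chromosomes, and Poisson (optionally gamma-overdispersed) window depths
from a population in which each chromosome is carried by a fraction
``phi`` of cells.

Every generator is a pure function of (inputs, seed): repeated calls with
the same config return identical objects. Distinct generators draw from
distinct, deterministically derived substreams of ``config.seed`` so the
tables are mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    EXPRESSION_CONDITIONS,
    ComplexMembership,
    CopyNumberMatrix,
    DepthProfile,
    ExpressionFlags,
    GenomeMap,
    InteractionTable,
)

# S288C nuclear chromosome lengths (bp), chromosomes I..XVI.
S288C_CHROM_LENGTHS: dict[str, int] = {
    "chrI": 230218,
    "chrII": 813184,
    "chrIII": 316620,
    "chrIV": 1531933,
    "chrV": 576874,
    "chrVI": 270161,
    "chrVII": 1090940,
    "chrVIII": 562643,
    "chrIX": 439888,
    "chrX": 745751,
    "chrXI": 666816,
    "chrXII": 1078177,
    "chrXIII": 924431,
    "chrXIV": 784333,
    "chrXV": 1091291,
    "chrXVI": 948066,
}

# substream labels so each generator gets an independent deterministic rng
_STREAMS = {
    "genome": 1,
    "copies": 2,
    "interactions_genetic": 3,
    "interactions_physical": 4,
    "expression": 5,
    "depth": 6,
    "complexes": 7,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study conditions.

    Defaults describe an S288C-like genome (16 chromosomes, ~50 genes per
    100 kb, matching the ~6000 genes / 12 Mb density of the reference) and
    an aneuploidy process whose per-chromosome rate is inversely
    proportional to length, scaled to 0.30 at the smallest chromosome —
    the same 0.05–0.33 range observed across real strain panels.
    """

    seed: int = 0
    n_chromosomes: int = 16
    chromosome_lengths: Sequence[int] | None = None
    genes_per_100kb: float = 50.0
    gene_length: int = 1000
    n_strains: int = 100
    baseline_ploidies: Sequence[int] = (2,)
    aneuploidy_prob: Sequence[float] | float | None = None
    gain_loss_odds: float = 2.0
    interaction_rate: float = 2.0
    score_sigma: float = 0.1
    score_mu_blocks: Mapping[tuple[str, str], float] = field(default_factory=dict)
    complex_prob: float = 0.3
    expression_base_prob: float = 0.1
    planted_enriched_chromosomes: Mapping[str, tuple[Sequence[str], float]] = field(
        default_factory=dict
    )
    depth_lambda: float = 100.0
    depth_baseline_copies: int = 1
    phi: Mapping[str, float] | float = 1.0
    overdispersion: float = 0.0
    window_size: int = 1000

    def __post_init__(self) -> None:
        if self.chromosome_lengths is not None:
            self.chromosome_lengths = [int(x) for x in self.chromosome_lengths]
            if any(x <= 0 for x in self.chromosome_lengths):
                raise ValueError("chromosome lengths must be positive")
            self.n_chromosomes = len(self.chromosome_lengths)
        if self.genes_per_100kb < 0 or self.interaction_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.expression_base_prob <= 1:
            raise ValueError("expression_base_prob must be in [0, 1]")
        if not 0 <= self.complex_prob <= 1:
            raise ValueError("complex_prob must be in [0, 1]")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        for p in np.atleast_1d(self.phi_vector_check()):
            if not 0 <= p <= 1:
                raise ValueError("phi must be in [0, 1]")
        if self.aneuploidy_prob is not None:
            for p in np.atleast_1d(self.aneuploidy_prob):
                if not 0 <= p <= 1:
                    raise ValueError("aneuploidy_prob must be in [0, 1]")

    def phi_vector_check(self) -> np.ndarray:
        if isinstance(self.phi, Mapping):
            return np.array(list(self.phi.values()) or [1.0], dtype=float)
        return np.array([self.phi], dtype=float)

    # -- resolved parameter vectors ------------------------------------
    def chrom_ids(self) -> list[str]:
        if self.chromosome_lengths is None and self.n_chromosomes == 16:
            return list(S288C_CHROM_LENGTHS)
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]

    def lengths(self) -> np.ndarray:
        if self.chromosome_lengths is not None:
            return np.asarray(self.chromosome_lengths, dtype=int)
        if self.n_chromosomes == 16:
            return np.array(list(S288C_CHROM_LENGTHS.values()), dtype=int)
        # evenly spread 200 kb .. 1.5 Mb for non-16 chromosome counts
        return np.linspace(200_000, 1_500_000, self.n_chromosomes).astype(int)

    def aneuploidy_probs(self) -> np.ndarray:
        if self.aneuploidy_prob is None:
            lengths = self.lengths().astype(float)
            return 0.30 * lengths.min() / lengths
        p = np.asarray(self.aneuploidy_prob, dtype=float)
        if p.ndim == 0:
            p = np.full(self.n_chromosomes, float(p))
        if len(p) != self.n_chromosomes:
            raise ValueError("aneuploidy_prob length mismatch")
        return p

    def phi_for(self, chrom_ids: Sequence[str]) -> np.ndarray:
        if isinstance(self.phi, Mapping):
            return np.array([float(self.phi.get(c, 1.0)) for c in chrom_ids])
        return np.full(len(chrom_ids), float(self.phi))

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


def simulate_genome_map(config: SimulationConfig) -> GenomeMap:
    """Draw a genome map: per-chromosome gene counts are Poisson with mean
    length x genes_per_100kb / 1e5, genes placed uniformly."""
    rng = config.rng("genome")
    chrom_ids = config.chrom_ids()
    lengths = config.lengths()
    chroms = pd.DataFrame({"chrom": chrom_ids, "length": lengths})
    rows = []
    for cid, length in zip(chrom_ids, lengths):
        n = int(rng.poisson(length * config.genes_per_100kb / 1e5))
        glen = min(config.gene_length, int(length))
        starts = np.sort(rng.integers(1, length - glen + 2, size=n))
        strands = rng.choice(["+", "-"], size=n)
        for i, (s, st) in enumerate(zip(starts, strands)):
            rows.append((f"{cid}_g{i:04d}", cid, int(s), int(s) + glen - 1, st))
    genes = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])
    return GenomeMap(chromosomes=chroms, genes=genes)


def simulate_copy_number_matrix(
    genome_map: GenomeMap, config: SimulationConfig
) -> CopyNumberMatrix:
    """Draw a strain panel; each strain-chromosome cell deviates from the
    strain's baseline ploidy with its chromosome's probability, gains being
    ``gain_loss_odds`` times as likely as losses (losses floor at 0)."""
    rng = config.rng("copies")
    chrom_ids = genome_map.chrom_ids
    probs = config.aneuploidy_probs()
    if len(probs) != len(chrom_ids):
        raise ValueError("aneuploidy_prob length does not match genome map")
    n, m = config.n_strains, len(chrom_ids)
    baselines = np.array(
        [config.baseline_ploidies[i % len(config.baseline_ploidies)] for i in range(n)]
    )
    aneuploid = rng.random((n, m)) < probs[None, :]
    p_gain = config.gain_loss_odds / (1.0 + config.gain_loss_odds)
    gain = rng.random((n, m)) < p_gain
    delta = np.where(aneuploid, np.where(gain, 1, -1), 0)
    copies = np.maximum(baselines[:, None] + delta, 0)
    strains = [f"S{i:04d}" for i in range(n)]
    df = pd.DataFrame(copies, index=pd.Index(strains, name="strain"), columns=chrom_ids)
    return CopyNumberMatrix(
        copies=df, baseline_ploidy=pd.Series(baselines, index=df.index)
    )


def simulate_interaction_table(
    genome_map: GenomeMap, config: SimulationConfig, kind: str = "genetic"
) -> InteractionTable:
    """Draw gene pairs uniformly at ``interaction_rate`` expected pairs per
    gene; genetic scores are Normal(mu_block, sigma) where mu_block is the
    planted mean for the unordered chromosome pair (0 when unplanted)."""
    rng = config.rng(f"interactions_{kind}")
    genes = genome_map.genes["gene"].to_numpy()
    chroms = genome_map.genes["chrom"].to_numpy()
    n_genes = len(genes)
    if n_genes < 2 or config.interaction_rate == 0:
        cols = ["gene_a", "gene_b"] + (["score"] if kind == "genetic" else [])
        return InteractionTable(rows=pd.DataFrame(columns=cols), kind=kind)
    n_pairs = int(rng.poisson(config.interaction_rate * n_genes / 2))
    ia = rng.integers(0, n_genes, size=n_pairs)
    ib = rng.integers(0, n_genes, size=n_pairs)
    keep = ia != ib
    ia, ib = ia[keep], ib[keep]
    df = pd.DataFrame({"gene_a": genes[ia], "gene_b": genes[ib]})
    if kind == "genetic":
        mu = np.zeros(len(ia))
        if config.score_mu_blocks:
            blocks = {
                tuple(sorted(k)): v for k, v in config.score_mu_blocks.items()
            }
            pair_keys = [
                tuple(sorted((ca, cb))) for ca, cb in zip(chroms[ia], chroms[ib])
            ]
            mu = np.array([blocks.get(k, 0.0) for k in pair_keys])
        df["score"] = rng.normal(mu, config.score_sigma)
    return InteractionTable(rows=df, kind=kind)


def simulate_complex_membership(
    genome_map: GenomeMap, config: SimulationConfig
) -> ComplexMembership:
    """Assign each gene to a pseudo-complex with probability ``complex_prob``."""
    rng = config.rng("complexes")
    genes = genome_map.genes["gene"].to_numpy()
    member = rng.random(len(genes)) < config.complex_prob
    chosen = genes[member]
    cplx = [f"CPX{rng.integers(0, max(1, len(chosen) // 5 + 1)):04d}" for _ in chosen]
    return ComplexMembership(rows=pd.DataFrame({"gene": chosen, "complex": cplx}))


def simulate_expression_flags(
    genome_map: GenomeMap, config: SimulationConfig
) -> ExpressionFlags:
    """Bernoulli(base_prob) up-regulation per gene and condition; on planted
    chromosomes the probability is multiplied by the enrichment factor and
    clipped to 1."""
    rng = config.rng("expression")
    genes = genome_map.genes["gene"].to_numpy()
    chroms = genome_map.genes["chrom"].to_numpy()
    frames = []
    for cond in EXPRESSION_CONDITIONS:
        p = np.full(len(genes), config.expression_base_prob)
        if cond in config.planted_enriched_chromosomes:
            planted, factor = config.planted_enriched_chromosomes[cond]
            mask = np.isin(chroms, list(planted))
            p[mask] = np.clip(p[mask] * factor, 0.0, 1.0)
        flags = (rng.random(len(genes)) < p).astype(int)
        frames.append(pd.DataFrame({"gene": genes, "condition": cond, "flag": flags}))
    return ExpressionFlags(rows=pd.concat(frames, ignore_index=True))


def simulate_depth(genome_map: GenomeMap, config: SimulationConfig) -> DepthProfile:
    """Draw windowed depths from a mixed population.

    A fraction ``phi`` of cells carries the chromosome at
    ``depth_baseline_copies`` copies, the rest at 0, so the expected depth is
    lambda x copies x phi. Base counts per window are Poisson; with
    ``overdispersion`` a > 0 the rate is gamma-jittered (negative-binomial
    mixture with Var = mu + a mu^2).
    """
    rng = config.rng("depth")
    chrom_ids = genome_map.chrom_ids
    lengths = genome_map.chrom_lengths
    phis = config.phi_for(chrom_ids)
    ws = config.window_size
    frames = []
    for cid, phi in zip(chrom_ids, phis):
        length = int(lengths[cid])
        n_win = -(-length // ws)
        starts = np.arange(n_win) * ws
        ends = np.minimum(starts + ws, length)
        wlen = ends - starts
        mu = config.depth_lambda * config.depth_baseline_copies * phi * wlen
        if config.overdispersion > 0:
            a = config.overdispersion
            mu = np.where(mu > 0, rng.gamma(1.0 / a, a * np.maximum(mu, 1e-12)), 0.0)
        counts = rng.poisson(mu)
        frames.append(
            pd.DataFrame(
                {"chrom": cid, "start": starts, "end": ends,
                 "mean_depth": counts / wlen}
            )
        )
    return DepthProfile(records=pd.concat(frames, ignore_index=True))
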