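"""Coverage summaries, expected-coverage baselines, and chromosome
population-frequency estimation.

The central quantity is the chromosome population frequency ``phi``: the
fraction of cells in a (possibly heterogeneous) strain population that
carry a given chromosome. For a chromosome sequenced in a pool, observed
mean depth scales linearly with the fraction of carrying cells, so

    phi_hat = observed mean depth / expected depth per haploid copy,

where the expected depth per copy comes from the sequencing arithmetic
total_bases / model_genome_size. A chromosome fully present in every cell
has phi near 1; one lost from the whole population has phi near 0; small
but clearly non-zero values indicate carriage at low frequency in the
population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import DepthProfile, FormatError, GenomeMap

DEFAULT_LOST_BELOW = 0.002
DEFAULT_PRESENT_ABOVE = 0.5


@dataclass
class CoverageSummary:
    """Per-chromosome depth summary: (chrom, mean_depth, median_depth, n_windows).

    ``mean_depth`` is the window-length-weighted mean, so it is invariant to
    re-partitioning of the same per-base depth field. Chromosomes absent
    from the depth profile are reported with n_windows=0 and NaN depths.
    """

    table: pd.DataFrame

    @property
    def missing_chromosomes(self) -> list[str]:
        return list(self.table.loc[self.table["n_windows"] == 0, "chrom"])


@dataclass
class ExpectedCoverage:
    """Expected fold-coverage per haploid genome copy from raw read counts."""

    total_bases: int
    model_genome_size: int

    @property
    def expected_per_copy(self) -> float:
        return self.total_bases / self.model_genome_size


def chromosome_depth_summary(
    depth: DepthProfile, genome_map: GenomeMap
) -> CoverageSummary:
    """Length-weighted mean and median window depth per chromosome."""
    lengths = genome_map.chrom_lengths
    df = depth.records
    unknown = set(df["chrom"]) - set(lengths.index)
    if unknown:
        raise FormatError(f"depth cites unknown chromosome(s): {sorted(unknown)}")
    beyond = df["end"] > df["chrom"].map(lengths)
    if beyond.any():
        row = df[beyond].iloc[0]
        raise FormatError(
            f"window [{row['start']}, {row['end']}) beyond end of {row['chrom']}"
        )
    rows = []
    for cid in genome_map.chrom_ids:
        sub = df[df["chrom"] == cid]
        if len(sub) == 0:
            rows.append((cid, np.nan, np.nan, 0))
            continue
        wlen = (sub["end"] - sub["start"]).to_numpy()
        mean = float(np.average(sub["mean_depth"], weights=wlen))
        rows.append((cid, mean, float(sub["mean_depth"].median()), len(sub)))
    return CoverageSummary(
        table=pd.DataFrame(
            rows, columns=["chrom", "mean_depth", "median_depth", "n_windows"]
        )
    )


def expected_subgenome_coverage(
    read_pairs: int, read_length: int, subgenome_sizes: list[int]
) -> ExpectedCoverage:
    """Expected per-haploid-copy coverage from the sequencing arithmetic.

    total_bases = read_pairs x 2 x read_length; the model genome is the sum
    of the haploid sub-genome sizes (one entry per haploid copy, so a
    triploid hybrid model lists three sizes).
    """
    if read_pairs <= 0 or read_length <= 0:
        raise ValueError("read counts and lengths must be positive")
    if not subgenome_sizes:
        raise ValueError("at least one sub-genome size is required")
    if any(s <= 0 for s in subgenome_sizes):
        raise ValueError("sub-genome sizes must be positive")
    return ExpectedCoverage(
        total_bases=int(read_pairs) * 2 * int(read_length),
        model_genome_size=int(sum(subgenome_sizes)),
    )


def estimate_chromosome_frequency(
    summary: CoverageSummary,
    expected: ExpectedCoverage,
    thresholds: tuple[float, float] = (DEFAULT_LOST_BELOW, DEFAULT_PRESENT_ABOVE),
    *,
    depth: DepthProfile | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    max_copies: float = 1.0,
) -> pd.DataFrame:
    """Estimate phi per chromosome with a bootstrap CI and a state label.

    Returns columns (chrom, mean_depth, n_windows, phi_hat, phi_hat_clipped,
    ci_low, ci_high, state). ``phi_hat`` is reported unclipped (sampling
    noise can push it slightly above ``max_copies``); the clipped companion
    lies in [0, max_copies]. States: ``lost`` below ``thresholds[0]``,
    ``present`` above ``thresholds[1]``, ``low_frequency`` between, and
    ``no_data`` for chromosomes with no windows. The CI is a seeded
    nonparametric bootstrap over windows and requires ``depth``; without it
    the CI columns are NaN.
    """
    lost_below, present_above = thresholds
    per_copy = expected.expected_per_copy
    if per_copy <= 0:
        raise ValueError("expected coverage per copy must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in summary.table.itertuples(index=False):
        if rec.n_windows == 0:
            rows.append((rec.chrom, np.nan, 0, np.nan, np.nan, np.nan, np.nan, "no_data"))
            continue
        phi = rec.mean_depth / per_copy
        ci_low = ci_high = np.nan
        if depth is not None and n_boot > 0:
            sub = depth.records[depth.records["chrom"] == rec.chrom]
            d = sub["mean_depth"].to_numpy()
            w = (sub["end"] - sub["start"]).to_numpy().astype(float)
            idx = rng.integers(0, len(d), size=(n_boot, len(d)))
            boots = (d[idx] * w[idx]).sum(axis=1) / w[idx].sum(axis=1) / per_copy
            ci_low, ci_high = np.quantile(boots, [0.025, 0.975])
        if phi < lost_below:
            state = "lost"
        elif phi > present_above:
            state = "present"
        else:
            state = "low_frequency"
        rows.append(
            (rec.chrom, rec.mean_depth, rec.n_windows, phi,
             float(np.clip(phi, 0.0, max_copies)), ci_low, ci_high, state)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "mean_depth", "n_windows", "phi_hat",
                 "phi_hat_clipped", "ci_low", "ci_high", "state"],
    )
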