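"""Bootstrap enrichment of gene-level features per chromosome.

For every chromosome and feature, the observed statistic is the mean
feature value over the chromosome's genes. The null distribution is built
by repeatedly (default 10,000 times) drawing, without replacement, a
random gene set of the same size n_c from the whole genome and recording
its mean. The reported value is the CDF of the observed mean under that
null — Phi((actual - null_mean) / null_sd) with the normal method, or the
tie-corrected empirical proportion of resampled means below the observed
one. Values near 0 mean the chromosome is depleted for the feature, near
1 enriched.

Because every chromosome statistic is a per-gene mean and the null set has
exactly n_c genes, CDFs computed from per-chromosome sums and from means
are identical draw-for-draw (the sum is the mean scaled by the constant
n_c, and both the normal z-score and the empirical rank are scale
invariant).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_model import (
    ComplexMembership,
    ExpressionFlags,
    GenomeMap,
    InteractionTable,
)

logger = logging.getLogger(__name__)

# resampled means per window of vectorized sampling; bounds peak memory
_CHUNK = 512


@dataclass(frozen=True)
class FeatureSpec:
    """One column of the enrichment heatmap.

    ``source`` names the input table ('physical', 'genetic', 'complex',
    'expression'); ``partition`` restricts interaction partners to the same
    ('intra') or a different ('inter') chromosome; ``sign`` filters genetic
    scores; ``condition`` selects the stress condition for expression flags.
    """

    feature_id: str
    source: str
    partition: str = "all"
    sign: str = "all"
    condition: str | None = None


#: The seventeen heatmap features: physical-interaction counts (mean/intra/
#: inter), genetic-interaction counts by sign and partner partition,
#: complex membership, and the four stress up-regulation flags.
DEFAULT_FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec("PI_mean", "physical"),
    FeatureSpec("PI_intra", "physical", partition="intra"),
    FeatureSpec("PI_inter", "physical", partition="inter"),
    FeatureSpec("GI", "genetic"),
    FeatureSpec("GI_pos", "genetic", sign="pos"),
    FeatureSpec("GI_neg", "genetic", sign="neg"),
    FeatureSpec("GI_intra", "genetic", partition="intra"),
    FeatureSpec("GI_intra_pos", "genetic", partition="intra", sign="pos"),
    FeatureSpec("GI_intra_neg", "genetic", partition="intra", sign="neg"),
    FeatureSpec("GI_inter", "genetic", partition="inter"),
    FeatureSpec("GI_inter_pos", "genetic", partition="inter", sign="pos"),
    FeatureSpec("GI_inter_neg", "genetic", partition="inter", sign="neg"),
    FeatureSpec("Complex_member", "complex"),
    FeatureSpec("Expr_GLY", "expression", condition="GLY"),
    FeatureSpec("Expr_LAC", "expression", condition="LAC"),
    FeatureSpec("Expr_ETOH", "expression", condition="ETOH"),
    FeatureSpec("Expr_OXD", "expression", condition="OXD"),
)


@dataclass
class NullDistribution:
    reps: int
    set_size: int
    null_mean: float
    null_sd: float
    seed: int | None = None
    samples: np.ndarray | None = None


def gene_feature_vector(
    genome_map: GenomeMap,
    source: InteractionTable | ExpressionFlags | ComplexMembership,
    spec: FeatureSpec,
) -> pd.Series:
    """Per-gene feature values over the full genome-map gene universe.

    Interaction features count retained pairs per gene, filtered by the
    partner partition (intra/inter relative to the gene's own chromosome)
    and score sign; complex membership and expression flags are 0/1. Genes
    appearing in the source but absent from the genome map are logged and
    ignored; map genes absent from the source get 0.
    """
    universe = genome_map.genes["gene"]
    values = pd.Series(0.0, index=pd.Index(universe, name="gene"))
    gene_chrom = genome_map.gene_chrom
    if isinstance(source, InteractionTable):
        if spec.source not in ("physical", "genetic"):
            raise ValueError(f"{spec.feature_id}: source mismatch")
        df = source.rows
        if spec.sign != "all":
            if source.kind != "genetic":
                raise ValueError("sign filtering requires a genetic table")
            df = df[df["score"] > 0] if spec.sign == "pos" else df[df["score"] < 0]
        known_a = df["gene_a"].isin(gene_chrom.index)
        known_b = df["gene_b"].isin(gene_chrom.index)
        n_unknown = int((~known_a | ~known_b).sum())
        if n_unknown:
            logger.info(
                "%s: ignored %d pair(s) with gene(s) absent from the genome map",
                spec.feature_id, n_unknown,
            )
        df = df[known_a & known_b]
        if len(df):
            ca = df["gene_a"].map(gene_chrom)
            cb = df["gene_b"].map(gene_chrom)
            if spec.partition == "intra":
                df = df[(ca == cb).to_numpy()]
            elif spec.partition == "inter":
                df = df[(ca != cb).to_numpy()]
        counts = pd.concat([df["gene_a"], df["gene_b"]]).value_counts()
        values = values.add(counts.reindex(values.index, fill_value=0), fill_value=0)
    elif isinstance(source, ComplexMembership):
        members = source.members
        unknown = members - set(universe)
        if unknown:
            logger.info(
                "%s: ignored %d complex member(s) absent from the genome map",
                spec.feature_id, len(unknown),
            )
        values[:] = universe.isin(members).astype(float).to_numpy()
    elif isinstance(source, ExpressionFlags):
        if spec.condition is None:
            raise ValueError(f"{spec.feature_id}: expression feature needs a condition")
        sub = source.rows[source.rows["condition"] == spec.condition]
        unknown = set(sub["gene"]) - set(universe)
        if unknown:
            logger.info(
                "%s: ignored %d flagged gene(s) absent from the genome map",
                spec.feature_id, len(unknown),
            )
        flags = sub.set_index("gene")["flag"].reindex(values.index, fill_value=0)
        values[:] = flags.astype(float).to_numpy()
    else:
        raise TypeError(f"unsupported source type {type(source).__name__}")
    return values


def _sample_means(
    values: np.ndarray, set_size: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of ``reps`` without-replacement draws of ``set_size`` genes.

    Vectorized: random keys per rep, argpartition picks the set. Chunked so
    the reps x universe key matrix never exceeds a few MB.
    """
    n = len(values)
    if set_size > n:
        raise ValueError(f"set_size {set_size} exceeds gene universe {n}")
    if set_size == n:
        return np.full(reps, values.mean())
    out = np.empty(reps)
    done = 0
    while done < reps:
        m = min(_CHUNK, reps - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, set_size, axis=1)[:, :set_size]
        # argpartition of distinct uniforms: each row is a uniform
        # without-replacement draw of set_size distinct indices
        out[done:done + m] = values[idx].mean(axis=1)
        done += m
    return out


def bootstrap_null(
    values: pd.Series | np.ndarray,
    set_size: int,
    reps: int = 10_000,
    seed: int | np.random.Generator = 0,
    keep_samples: bool = True,
) -> NullDistribution:
    """Null distribution of the mean of a random same-size gene set.

    Each rep draws ``set_size`` genes without replacement from the full
    universe and records their mean feature value.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    vals = np.asarray(values, dtype=float)
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    samples = _sample_means(vals, set_size, reps, rng)
    return NullDistribution(
        reps=reps,
        set_size=set_size,
        null_mean=float(samples.mean()),
        null_sd=float(samples.std(ddof=1)) if reps > 1 else 0.0,
        seed=seed if isinstance(seed, int) else None,
        samples=samples if keep_samples else None,
    )


def cdf_value(
    actual_mean: float, null: NullDistribution, method: str = "normal"
) -> float:
    """CDF of the observed mean under the resampling null.

    ``normal``: Phi((actual - null_mean)/null_sd). ``empirical``:
    proportion of rep means below the observed one, counting ties at half
    weight. A degenerate null (sd = 0) maps to 0.5 at the null mean and to
    0/1 by sign otherwise.
    """
    if method == "normal":
        if null.null_sd == 0:
            if actual_mean == null.null_mean:
                return 0.5
            return 1.0 if actual_mean > null.null_mean else 0.0
        return float(stats.norm.cdf((actual_mean - null.null_mean) / null.null_sd))
    if method == "empirical":
        if null.samples is None:
            raise ValueError("empirical method requires retained samples")
        below = np.count_nonzero(null.samples < actual_mean)
        ties = np.count_nonzero(null.samples == actual_mean)
        return float((below + 0.5 * ties) / len(null.samples))
    raise ValueError(f"unknown method {method!r}")


def enrichment_matrix(
    genome_map: GenomeMap,
    sources: Mapping[str, object],
    specs: Sequence[FeatureSpec] = DEFAULT_FEATURES,
    reps: int = 10_000,
    seed: int = 0,
    method: str = "normal",
    statistic: str = "mean",
    aneuploidy_f: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One CDF per (chromosome, feature) plus a long-format detail table.

    ``sources`` maps source names ('physical', 'genetic', 'complex',
    'expression') to loaded tables; features whose source is missing are
    skipped with a warning. One shared seed governs the whole matrix, with
    a deterministic substream per (chromosome, feature) so any single cell
    can be recomputed in isolation. ``statistic='sum'`` runs the engine on
    per-chromosome sums instead of means; the resulting CDFs are identical
    draw-for-draw. Feature values are computed once per gene with respect
    to its true chromosome and then resampled — a random gene set does not
    redefine intra/inter for its members.

    Returns (wide chromosome x feature CDF matrix, long detail table with
    actual/null statistics). Chromosomes with zero genes get NaN rows and a
    warning rather than being dropped. When ``aneuploidy_f`` is given it is
    appended to the wide matrix as an ``Aneuploidy_f`` column (not a CDF).
    """
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    usable = []
    for spec in specs:
        if spec.source in sources:
            usable.append(spec)
        else:
            warnings.warn(
                f"feature {spec.feature_id}: source {spec.source!r} not supplied; "
                "skipped",
                stacklevel=2,
            )
    n_c = genome_map.n_genes_per_chromosome()
    empty = [c for c in genome_map.chrom_ids if n_c[c] == 0]
    if empty:
        warnings.warn(f"chromosome(s) with zero genes flagged: {empty}", stacklevel=2)
    gene_chrom = genome_map.gene_chrom
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(genome_map.chrom_ids) * len(usable)))
    long_rows = []
    wide = pd.DataFrame(
        index=pd.Index(genome_map.chrom_ids, name="chrom"),
        columns=[s.feature_id for s in usable],
        dtype=float,
    )
    for spec in usable:
        values = gene_feature_vector(genome_map, sources[spec.source], spec)
        arr = values.to_numpy()
        chrom_of = gene_chrom.reindex(values.index).to_numpy()
        for cid in genome_map.chrom_ids:
            child = next(children)
            k = int(n_c[cid])
            if k == 0:
                long_rows.append((cid, spec.feature_id, np.nan, np.nan, np.nan, np.nan))
                continue
            scale = k if statistic == "sum" else 1
            actual = float(arr[chrom_of == cid].mean()) * scale
            rng = np.random.default_rng(child)
            null = bootstrap_null(
                arr, k, reps=reps, seed=rng,
                keep_samples=(method == "empirical"),
            )
            if statistic == "sum":
                null = NullDistribution(
                    reps=null.reps,
                    set_size=null.set_size,
                    null_mean=null.null_mean * k,
                    null_sd=null.null_sd * k,
                    samples=None if null.samples is None else null.samples * k,
                )
            cdf = cdf_value(actual, null, method=method)
            wide.loc[cid, spec.feature_id] = cdf
            long_rows.append(
                (cid, spec.feature_id, actual, null.null_mean, null.null_sd, cdf)
            )
    long = pd.DataFrame(
        long_rows,
        columns=["chrom", "feature", "actual", "null_mean", "null_sd", "cdf"],
    )
    if aneuploidy_f is not None:
        wide["Aneuploidy_f"] = aneuploidy_f.reindex(wide.index)
    return wide, long


def correlation_distance_matrix(matrix: pd.DataFrame, axis: int = 0) -> np.ndarray:
    """Pairwise 1 - Pearson distance between rows (axis=0) or columns (axis=1).

    Zero-variance vectors have undefined correlation; they are assigned the
    maximal distance 2 (with a warning) so they cluster last.
    """
    data = matrix.to_numpy(dtype=float)
    if axis == 1:
        data = data.T
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    if np.isnan(corr).any():
        warnings.warn(
            "zero-variance row/column assigned maximal correlation distance",
            stacklevel=2,
        )
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 2.0
    np.fill_diagonal(dist, 0.0)
    # exact symmetry for squareform
    return (dist + dist.T) / 2.0


def cluster_heatmap_order(matrix: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Row and column display order by average-linkage correlation clustering.

    Distance is 1 - Pearson correlation; leaves are ordered by the standard
    left-to-right dendrogram traversal, which is deterministic for a given
    matrix (ties resolved by merge order, earliest-formed cluster first).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("clustering needs >= 2 rows and >= 2 columns")
    orders = []
    for axis, labels in ((0, matrix.index), (1, matrix.columns)):
        dist = correlation_distance_matrix(matrix, axis=axis)
        Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
        leaves = hierarchy.leaves_list(Z)
        orders.append([labels[i] for i in leaves])
    return orders[0], orders[1]
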