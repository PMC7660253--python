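"""Domain types and tab-delimited readers/writers for every pipeline input.

All files are UTF-8 TSV with a header row; lines starting with ``#`` are
comments, except the ``#chromosomes`` / ``#genes`` section markers of the
genome-map dialect. Coordinates follow the usual mixed convention: gene
coordinates are 1-based inclusive, depth windows are 0-based half-open
(BED), and samtools-depth positions are 1-based.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPRESSION_CONDITIONS = ("GLY", "LAC", "ETOH", "OXD")


class FormatError(ValueError):
    """Raised when an input file violates the dialect or a type invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeMap:
    """Chromosome lengths plus gene coordinates.

    ``chromosomes`` has columns (chrom, length); ``genes`` has columns
    (gene, chrom, start, end, strand) with 1-based inclusive coordinates.
    This is the denominator universe for resampling: every statistic that
    samples "random genes from the genome" draws from ``genes``.
    """

    chromosomes: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.chromosomes = self.chromosomes.reset_index(drop=True)
        self.genes = self.genes.reset_index(drop=True)
        chroms = self.chromosomes["chrom"]
        if chroms.duplicated().any():
            dup = chroms[chroms.duplicated()].iloc[0]
            raise FormatError(f"duplicate chromosome id {dup!r}")
        if (self.chromosomes["length"] <= 0).any():
            raise FormatError("chromosome lengths must be positive")
        if len(self.genes):
            if self.genes["gene"].duplicated().any():
                dup = self.genes["gene"][self.genes["gene"].duplicated()].iloc[0]
                raise FormatError(f"duplicate gene id {dup!r}")
            known = set(chroms)
            bad = self.genes.loc[~self.genes["chrom"].isin(known), "chrom"]
            if len(bad):
                raise FormatError(
                    f"gene row cites unknown chromosome {bad.iloc[0]!r}"
                )
            lengths = self.genes["chrom"].map(self.chrom_lengths)
            ok = (
                (self.genes["start"] >= 1)
                & (self.genes["start"] <= self.genes["end"])
                & (self.genes["end"] <= lengths)
            )
            if not ok.all():
                row = self.genes[~ok].iloc[0]
                raise FormatError(
                    f"gene {row['gene']!r} coordinates outside chromosome bounds"
                )
        self.genes = self.genes.sort_values(
            ["chrom", "start", "gene"], kind="mergesort"
        ).reset_index(drop=True)

    @property
    def chrom_ids(self) -> list[str]:
        return list(self.chromosomes["chrom"])

    @property
    def chrom_lengths(self) -> pd.Series:
        return self.chromosomes.set_index("chrom")["length"]

    @property
    def gene_chrom(self) -> pd.Series:
        """gene id -> chromosome id."""
        return self.genes.set_index("gene")["chrom"]

    def n_genes_per_chromosome(self) -> pd.Series:
        """Gene counts n_c per chromosome, zero-filled for empty chromosomes."""
        counts = self.genes["chrom"].value_counts()
        return counts.reindex(self.chrom_ids, fill_value=0).astype(int)


@dataclass
class CopyNumberMatrix:
    """Strain x chromosome integer copy numbers with per-strain baseline ploidy.

    ``copies`` is indexed by strain with one column per chromosome; missing
    calls are NA and are excluded from both sides of downstream frequency
    statistics.
    """

    copies: pd.DataFrame
    baseline_ploidy: pd.Series

    def __post_init__(self) -> None:
        self.copies = self.copies.astype("Int64")
        if (self.copies.to_numpy(dtype=float, na_value=np.nan) < 0).any():
            raise FormatError("copy numbers must be >= 0")
        self.baseline_ploidy = self.baseline_ploidy.astype(int)
        if not self.baseline_ploidy.index.equals(self.copies.index):
            self.baseline_ploidy = self.baseline_ploidy.reindex(self.copies.index)
            if self.baseline_ploidy.isna().any():
                raise FormatError("baseline ploidy missing for some strains")
            self.baseline_ploidy = self.baseline_ploidy.astype(int)
        if (self.baseline_ploidy < 1).any():
            raise FormatError("baseline ploidy must be >= 1")
        self.baseline_ploidy.name = "ploidy"

    @property
    def strains(self) -> list[str]:
        return list(self.copies.index)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.copies.columns)


@dataclass
class DepthProfile:
    """Windowed mean read depth: columns (chrom, start, end, mean_depth).

    Windows are 0-based half-open and must not overlap within a chromosome.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True)
        if (df["mean_depth"] < 0).any():
            raise FormatError("mean_depth must be >= 0")
        if (df["start"] >= df["end"]).any():
            raise FormatError("depth windows must satisfy start < end")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        overlap = (df["chrom"] == df["chrom"].shift()) & (
            df["start"] < df["end"].shift()
        )
        if overlap.any():
            row = df[overlap].iloc[0]
            raise FormatError(
                f"overlapping depth windows on {row['chrom']} at {row['start']}"
            )
        self.records = df

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.records["chrom"]))


@dataclass
class InteractionTable:
    """Gene-gene interaction pairs.

    ``kind='genetic'`` rows carry a signed epistasis score; ``kind='physical'``
    rows are unsigned pairs. Self-pairs are dropped and duplicate unordered
    pairs collapsed (mean score for genetic, unique for physical); drop
    counts are logged, never silent.
    """

    rows: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("genetic", "physical"):
            raise FormatError(f"unknown interaction kind {self.kind!r}")
        self.rows = _collapse_pairs(self.rows, self.kind)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class ExpressionFlags:
    """Binary up-regulation flags: columns (gene, condition, flag)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows.reset_index(drop=True)
        bad = set(df["condition"]) - set(EXPRESSION_CONDITIONS)
        if bad:
            raise FormatError(f"unknown expression condition(s): {sorted(bad)}")
        if not df["flag"].isin([0, 1]).all():
            raise FormatError("expression flags must be 0 or 1")
        if df.duplicated(["gene", "condition"]).any():
            raise FormatError("one row per gene x condition required")
        df["flag"] = df["flag"].astype(int)
        self.rows = df


@dataclass
class ComplexMembership:
    """Protein-complex membership: columns (gene, complex)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        self.rows = self.rows.drop_duplicates().reset_index(drop=True)

    @property
    def members(self) -> set[str]:
        return set(self.rows["gene"])


def _collapse_pairs(rows: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Drop self-pairs, orient pairs canonically, collapse duplicates.

    Genetic duplicates collapse to the arithmetic mean score (symmetric and
    order-independent, so the downstream pairwise sums stay well defined).
    """
    df = rows.reset_index(drop=True).copy()
    n0 = len(df)
    df = df[df["gene_a"] != df["gene_b"]].reset_index(drop=True)
    n_self = n0 - len(df)
    if n_self:
        logger.info("dropped %d self-pair row(s)", n_self)
    a = df["gene_a"].to_numpy(dtype=object)
    b = df["gene_b"].to_numpy(dtype=object)
    swap = a > b
    a[swap], b[swap] = b[swap].copy(), a[swap].copy()
    oriented = pd.DataFrame({"gene_a": a, "gene_b": b})
    if kind == "genetic":
        oriented["score"] = pd.to_numeric(df["score"]).to_numpy()
        collapsed = (
            oriented.groupby(["gene_a", "gene_b"], sort=True, as_index=False)[
                "score"
            ].mean()
        )
    else:
        collapsed = oriented.drop_duplicates(["gene_a", "gene_b"]).sort_values(
            ["gene_a", "gene_b"]
        ).reset_index(drop=True)
    n_dup = len(df) - len(collapsed)
    if n_dup:
        logger.info("collapsed %d duplicate unordered pair row(s)", n_dup)
    return collapsed.reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kw)


def load_genome_map(path: str | Path) -> GenomeMap:
    """Read the two-section genome-map TSV (``#chromosomes`` then ``#genes``)."""
    chrom_lines: list[str] = []
    gene_lines: list[str] = []
    section = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if line.strip() == "#chromosomes":
            section = chrom_lines
            continue
        if line.strip() == "#genes":
            section = gene_lines
            continue
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if section is None:
            raise FormatError(
                f"{path}: line {lineno} before any #chromosomes/#genes marker"
            )
        section.append(line)
    if not chrom_lines:
        raise FormatError(f"{path}: missing #chromosomes section")
    chroms = pd.read_csv(io.StringIO("\n".join(chrom_lines)), sep="\t", dtype=str)
    try:
        chroms["length"] = chroms["length"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer chromosome length: {exc}") from exc
    if gene_lines:
        genes = pd.read_csv(io.StringIO("\n".join(gene_lines)), sep="\t", dtype=str)
    else:
        genes = pd.DataFrame(columns=["gene", "chrom", "start", "end", "strand"])
    for col in ("start", "end"):
        try:
            genes[col] = genes[col].astype(int)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer gene coordinate: {exc}") from exc
    try:
        return GenomeMap(chromosomes=chroms, genes=genes)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_genome_map(gm: GenomeMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chromosomes\n")
        gm.chromosomes.to_csv(fh, sep="\t", index=False)
        fh.write("#genes\n")
        gm.genes.to_csv(fh, sep="\t", index=False)


def load_copy_number_matrix(path: str | Path) -> CopyNumberMatrix:
    """Read a strain x chromosome copy-number TSV.

    First column is the strain id; a ``ploidy`` column, when present, gives
    the baseline; otherwise the baseline is inferred per strain as the mode
    of its chromosome copies (ties toward the smaller value).
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str,
        keep_default_na=False, na_values=[],
    )
    if df.isna().any(axis=None) or (df == "").any(axis=None):
        raise FormatError(f"{path}: ragged row (missing fields)")
    strain_col = df.columns[0]
    df = df.set_index(strain_col)
    ploidy = None
    if "ploidy" in df.columns:
        ploidy = df.pop("ploidy").astype(int)
    df = df.replace({"NA": None})
    copies = df.apply(pd.to_numeric).astype("Int64")
    if (copies.to_numpy(dtype=float, na_value=np.nan) < 0).any():
        raise FormatError(f"{path}: negative copy number")
    if ploidy is None:
        ploidy = copies.apply(infer_baseline_ploidy, axis=1)
        logger.info("ploidy column absent; baseline inferred by per-strain mode")
    return CopyNumberMatrix(copies=copies, baseline_ploidy=ploidy)


def infer_baseline_ploidy(copies: pd.Series) -> int:
    """Per-strain mode of chromosome copies; ties broken toward the smaller."""
    vals = copies.dropna().astype(int)
    if vals.empty:
        raise FormatError("cannot infer ploidy from an all-missing strain row")
    counts = vals.value_counts()
    best = counts[counts == counts.max()]
    return int(min(best.index))


def write_copy_number_matrix(m: CopyNumberMatrix, path: str | Path) -> None:
    out = m.copies.copy()
    out.insert(0, "ploidy", m.baseline_ploidy)
    out.index.name = "strain"
    out.to_csv(path, sep="\t")


def load_depth_profile(
    path: str | Path,
    *,
    dialect: str = "bed",
    genome_map: GenomeMap | None = None,
    window_size: int = 1000,
) -> DepthProfile:
    """Read a depth file.

    ``dialect='bed'``: windowed TSV (chrom, start, end, mean_depth), header
    optional, 0-based half-open. ``dialect='depth'``: samtools-depth style
    (chrom, pos, depth), headerless, 1-based positions; converted to windows
    of ``window_size`` with absent positions counted as depth 0 (``-a``
    semantics), which requires ``genome_map`` for chromosome lengths.
    """
    if dialect == "bed":
        first = pd.read_csv(path, sep="\t", comment="#", nrows=1, header=None)
        has_header = not str(first.iloc[0, 1]).lstrip("-").isdigit()
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=0 if has_header else None,
            names=["chrom", "start", "end", "mean_depth"],
        )
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["mean_depth"] = df["mean_depth"].astype(float)
        return DepthProfile(records=df)
    if dialect == "depth":
        if genome_map is None:
            raise ValueError("samtools-depth conversion requires a genome map")
        raw = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "pos", "depth"],
        )
        return positions_to_windows(raw, genome_map, window_size)
    raise ValueError(f"unknown depth dialect {dialect!r}")


def positions_to_windows(
    positions: pd.DataFrame, genome_map: GenomeMap, window_size: int
) -> DepthProfile:
    """Bin per-base depths into fixed windows, zero-filling absent positions."""
    lengths = genome_map.chrom_lengths
    out = []
    for chrom, grp in positions.groupby("chrom", sort=False):
        if chrom not in lengths.index:
            raise FormatError(f"depth cites unknown chromosome {chrom!r}")
        length = int(lengths[chrom])
        pos = grp["pos"].astype(int).to_numpy()
        if (pos < 1).any() or (pos > length).any():
            raise FormatError(f"depth position outside {chrom} bounds")
        dep = grp["depth"].astype(float).to_numpy()
        win = (pos - 1) // window_size
        n_win = -(-length // window_size)
        sums = np.bincount(win, weights=dep, minlength=n_win)
        starts = np.arange(n_win) * window_size
        ends = np.minimum(starts + window_size, length)
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "mean_depth": sums / (ends - starts),
                }
            )
        )
    frames = pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["chrom", "start", "end", "mean_depth"]
    )
    return DepthProfile(records=frames)


def write_depth_profile(dp: DepthProfile, path: str | Path) -> None:
    dp.records.to_csv(path, sep="\t", index=False)


def load_interaction_table(path: str | Path, kind: str) -> InteractionTable:
    """Read an interaction TSV (gene_a, gene_b[, score]).

    The score column is required and numeric for ``kind='genetic'`` and
    ignored for ``kind='physical'``.
    """
    df = _read_tsv(path)
    if kind == "genetic":
        if "score" not in df.columns:
            raise FormatError(f"{path}: genetic table requires a score column")
        try:
            df["score"] = df["score"].astype(float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric score: {exc}") from exc
        df = df[["gene_a", "gene_b", "score"]]
    else:
        df = df[["gene_a", "gene_b"]]
    return InteractionTable(rows=df, kind=kind)


def write_interaction_table(t: InteractionTable, path: str | Path) -> None:
    t.rows.to_csv(path, sep="\t", index=False)


def load_expression_flags(path: str | Path) -> ExpressionFlags:
    df = _read_tsv(path)
    df["flag"] = df["flag"].astype(int)
    return ExpressionFlags(rows=df[["gene", "condition", "flag"]])


def write_expression_flags(e: ExpressionFlags, path: str | Path) -> None:
    e.rows.to_csv(path, sep="\t", index=False)


def load_complex_membership(path: str | Path) -> ComplexMembership:
    """Read a CYC2008-like TSV with columns (gene, complex) (aka ORF, complex)."""
    df = _read_tsv(path)
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene", cols.get("orf"))
    cplx_col = cols.get("complex")
    if gene_col is None or cplx_col is None:
        raise FormatError(f"{path}: expected columns gene/ORF and complex")
    df = df[[gene_col, cplx_col]].rename(
        columns={gene_col: "gene", cplx_col: "complex"}
    )
    return ComplexMembership(rows=df)


def write_complex_membership(c: ComplexMembership, path: str | Path) -> None:
    c.rows.to_csv(path, sep="\t", index=False)
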