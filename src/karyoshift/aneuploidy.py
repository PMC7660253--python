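"""Per-chromosome aneuploidy-frequency statistics over a strain panel.

For each chromosome the statistic f is the count of strains with an
abnormal copy number (gain or loss alike) divided by the count of strains
with the normal (baseline-ploidy) copy number, computed within the subset
of strains that are aneuploid for at least one chromosome. f is an
abnormal:normal odds, not a proportion — it is >= 0 and can exceed 1.
Alternative denominators (all strains in the subset, or the abnormal count
over the whole panel) are available for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import CopyNumberMatrix, GenomeMap

DENOMINATORS = ("normal", "aneuploid", "all")


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


class NoAneuploidStrainsError(ValueError):
    """The panel contains no strain deviating from its baseline ploidy."""


def _abnormal_mask(matrix: CopyNumberMatrix) -> pd.DataFrame:
    """Boolean strain x chromosome: copy differs from baseline; NA cells False."""
    base = matrix.baseline_ploidy
    diff = matrix.copies.ne(base, axis=0)
    return diff.where(matrix.copies.notna(), other=False).astype(bool)


def detect_aneuploid_strains(matrix: CopyNumberMatrix) -> list[str]:
    """Strains with at least one chromosome deviating from their baseline."""
    mask = _abnormal_mask(matrix)
    return list(matrix.copies.index[mask.any(axis=1)])


def aneuploidy_frequency(
    matrix: CopyNumberMatrix, denominator: str = "normal"
) -> pd.DataFrame:
    """Per-chromosome aneuploidy frequency within the aneuploid strain subset.

    Returns columns (chrom, n_abnormal, n_normal, f). With the default
    ``denominator='normal'``, f = n_abnormal / n_normal and is NaN where no
    strain has a normal copy (degenerate denominator). ``'aneuploid'``
    divides by the aneuploid-subset size with a defined cell;
    ``'all'`` divides by the whole panel's defined-cell count.
    """
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    aneuploid = detect_aneuploid_strains(matrix)
    if not aneuploid:
        raise NoAneuploidStrainsError("no aneuploid strains in the panel")
    full_mask = _abnormal_mask(matrix)
    sub = matrix.copies.loc[aneuploid]
    sub_mask = full_mask.loc[aneuploid]
    defined = sub.notna()
    n_abnormal = (sub_mask & defined).sum()
    n_normal = (~sub_mask & defined).sum()
    if denominator == "normal":
        denom = n_normal.astype(float)
    elif denominator == "aneuploid":
        denom = defined.sum().astype(float)
    else:
        denom = matrix.copies.notna().sum().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = n_abnormal / denom.replace(0, np.nan)
    return pd.DataFrame(
        {
            "chrom": matrix.chromosomes,
            "n_abnormal": n_abnormal.to_numpy(dtype=int),
            "n_normal": n_normal.to_numpy(dtype=int),
            "f": f.to_numpy(dtype=float),
        }
    )


def size_frequency_correlation(
    freqs: pd.DataFrame, genome_map: GenomeMap
) -> CorrelationResult:
    """Pearson correlation between chromosome length and aneuploidy frequency.

    Uses chromosomes with a defined f; the p-value is the two-sided t-test
    with n-2 degrees of freedom. Needs >= 3 defined chromosomes and
    non-constant f and size.
    """
    merged = freqs.merge(
        genome_map.chromosomes, on="chrom", how="inner"
    ).dropna(subset=["f"])
    n = len(merged)
    if n < 3:
        raise ValueError("need >= 3 chromosomes with a defined frequency")
    size = merged["length"].to_numpy(dtype=float)
    f = merged["f"].to_numpy(dtype=float)
    if np.ptp(size) == 0 or np.ptp(f) == 0:
        raise ValueError("correlation undefined for constant size or frequency")
    res = stats.pearsonr(size, f)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=n)
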