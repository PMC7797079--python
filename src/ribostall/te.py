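"""Translation efficiency (RPF / mRNA), codon-content binning, and gene-list
overlap statistics.

TE is the simple count-ratio estimator log2((rpf + pc) / (rna + pc)); an
increase under stress reflects more ribosomes per transcript, which for
stall-codon-rich genes indicates slower elongation rather than more protein
output. Ratios are median-centred for comparison across conditions, mirroring
standard practice for relative TE displays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Set

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import GeneCounts, TranscriptSet, ValidationError
from .codons import is_sense

logger = logging.getLogger(__name__)


def compute_te(counts: Iterable[GeneCounts], pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-gene log2 TE table, indexed by gene_id.

    Columns: rpf_count, rna_count, log2_te, flagged (True where rna_count is
    zero, i.e. the ratio rests on the pseudocount alone).
    """
    counts = list(counts)
    if not counts:
        raise ValidationError("compute_te: empty counts")
    if pseudocount <= 0 and any(c.rpf_count == 0 or c.rna_count == 0 for c in counts):
        raise ValidationError("pseudocount <= 0 with zero counts present")
    df = pd.DataFrame(
        {
            "rpf_count": [c.rpf_count for c in counts],
            "rna_count": [c.rna_count for c in counts],
        },
        index=pd.Index([c.gene_id for c in counts], name="gene_id"),
    )
    df["log2_te"] = np.log2((df.rpf_count + pseudocount) / (df.rna_count + pseudocount))
    df["flagged"] = df.rna_count == 0
    return df


def median_center(values: pd.Series) -> pd.Series:
    """Subtract the column median (mean-of-middle-two for even n); missing
    values pass through."""
    finite = values.dropna()
    finite = finite[np.isfinite(finite)]
    if finite.empty:
        raise ValidationError("median_center: no finite values")
    return values - float(finite.median())


def te_change(te_stress: pd.DataFrame, te_control: pd.DataFrame) -> pd.Series:
    """Median-centred per-gene log2 TE change (stress - control).

    Genes missing in either condition are dropped (count logged). Before
    centring the statistic is antisymmetric in the two conditions.
    """
    common = te_stress.index.intersection(te_control.index)
    if common.empty:
        raise ValidationError("te_change: no shared genes")
    dropped = len(te_stress.index.union(te_control.index)) - len(common)
    if dropped:
        logger.info("te_change: dropped %d genes missing in one condition", dropped)
    delta = te_stress.loc[common, "log2_te"] - te_control.loc[common, "log2_te"]
    return median_center(delta.sort_index())


@dataclass
class CodonContentBins:
    """Partition of genes by target-codon content.

    bin 0 = genes with zero occurrences of the target codon; bins 1..n-1 are
    ascending-content groups of the remainder, as equal in size as possible
    (sizes differ by at most one). Content fraction = occurrences / sense
    codons of the gene (start included, stop excluded). Ties in content are
    broken by gene_id, so the partition is deterministic.
    """

    target_codon: str
    table: pd.DataFrame  # gene_id index; columns content_fraction, bin_id

    @property
    def n_bins(self) -> int:
        return int(self.table["bin_id"].max()) + 1

    def genes_in_bin(self, bin_id: int) -> list[str]:
        return sorted(self.table.index[self.table["bin_id"] == bin_id])


def bin_by_content(
    transcripts: TranscriptSet, target_codon: str, n_bins: int = 11
) -> CodonContentBins:
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if not is_sense(target_codon):
        raise ValidationError(f"{target_codon!r} is not a sense codon")
    rows = []
    for tid, t in sorted(transcripts.items()):
        sense = t.codons[:-1]  # start included, stop excluded
        frac = sense.count(target_codon) / len(sense)
        rows.append((tid, frac))
    df = pd.DataFrame(rows, columns=["gene_id", "content_fraction"]).set_index("gene_id")

    zero = df[df.content_fraction == 0]
    nonzero = df[df.content_fraction > 0].sort_values(
        ["content_fraction"], kind="mergesort"
    )
    # stable sort + sorted gene_id index gives the (content, gene_id) order
    if len(nonzero) < n_bins - 1:
        raise ValidationError(
            f"only {len(nonzero)} genes with nonzero {target_codon} content; "
            f"need at least {n_bins - 1}"
        )
    df["bin_id"] = 0
    for k, chunk in enumerate(np.array_split(np.arange(len(nonzero)), n_bins - 1)):
        df.loc[nonzero.index[chunk], "bin_id"] = k + 1
    assert len(zero) + len(nonzero) == len(df)
    return CodonContentBins(target_codon, df)


@dataclass
class BinTrendResult:
    per_bin: pd.DataFrame       # bin_id, n, median, q1, q3, min, max
    trend_rho: float            # Spearman of bin index (1..k) vs bin median
    p_value: float              # one-sided permutation p for a positive trend
    n_permutations: int


def bin_trend(
    bins: CodonContentBins,
    changes: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> BinTrendResult:
    """Per-bin summaries of TE change plus a content-trend statistic.

    The trend is the Spearman correlation between bin index (1..k, bin 0
    excluded) and bin median change; its one-sided p-value comes from
    permuting gene-to-change assignments within the binned gene set
    (>= ``n_permutations`` permutations, seeded). Bin 0 may be empty (a
    simulated transcriptome rarely has zero-content genes); any empty bin
    among 1..k is an error.
    """
    table = bins.table.join(changes.rename("change"), how="inner")
    if table.empty:
        raise ValidationError("bin_trend: bins and changes share no genes")
    ks = range(1, bins.n_bins)
    for k in ks:
        if not (table.bin_id == k).any():
            raise ValidationError(f"bin {k} has no genes after intersection")

    def summarize(t: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for k in sorted(t.bin_id.unique()):
            v = t.loc[t.bin_id == k, "change"].to_numpy()
            rows.append(
                (k, len(v), float(np.median(v)),
                 float(np.percentile(v, 25)), float(np.percentile(v, 75)),
                 float(v.min()), float(v.max()))
            )
        return pd.DataFrame(rows, columns=["bin_id", "n", "median", "q1", "q3", "min", "max"])

    per_bin = summarize(table)

    nz = table[table.bin_id >= 1]
    medians = nz.groupby("bin_id")["change"].median()
    rho = float(stats.spearmanr(medians.index.to_numpy(), medians.to_numpy()).statistic)

    rng = np.random.default_rng(seed)
    bin_ids = nz.bin_id.to_numpy()
    vals = nz.change.to_numpy()
    idx = medians.index.to_numpy()
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(vals)
        m = pd.Series(perm).groupby(bin_ids).median()
        r = float(stats.spearmanr(idx, m.loc[idx].to_numpy()).statistic)
        if r >= rho:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return BinTrendResult(per_bin, rho, p, n_permutations)


@dataclass(frozen=True)
class OverlapResult:
    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    p_value: float  # one-sided (enrichment) hypergeometric upper tail


def overlap_test(
    list_a: Set[str], list_b: Set[str], universe: Set[str]
) -> OverlapResult:
    """Significance of the overlap of two gene lists drawn from a universe
    (one-sided Fisher's exact / hypergeometric upper tail,
    P[overlap >= observed])."""
    a, b, u = set(list_a), set(list_b), set(universe)
    if not a <= u or not b <= u:
        raise ValidationError("gene lists must be subsets of the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    p = min(p, 1.0)
    return OverlapResult(len(u), len(a), len(b), k, p)
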