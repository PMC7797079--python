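"""Normalized per-codon ribosome occupancy.

For each coding sequence, over the eligible region (codon positions strictly
after the cutoff, stop codon excluded):

    f(c) = fraction of the gene's eligible A-site footprints on codon c
    a(c) = fraction of the gene's eligible codon positions with identity c
    o(c) = f(c) / a(c)            (defined only where a(c) > 0)

so Σ_c a(c)·o(c) = 1 exactly per gene. Occupancy ~1 means average dwell;
o(c) > 1 means the ribosome decodes c slowly. Profiles average o unweighted
across genes (read-pooled averaging is available behind a flag for
sensitivity analysis). The cutoff (default: only codons after 90, 1-based)
removes the initiation ramp from the statistic.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation_io import TranscriptModel, TranscriptSet, ValidationError
from .codons import CODON_TO_AA, SENSE_CODONS
from .psite import CodonCountTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OccupancyConfig:
    #: 1-based codon index; positions <= cutoff are excluded (start codon = 1).
    codon_cutoff: int = 90
    #: minimum eligible-region footprints for a gene to contribute.
    min_gene_rpf: int = 64

    def __post_init__(self) -> None:
        if self.codon_cutoff < 0:
            raise ValidationError("codon_cutoff must be >= 0")
        if self.min_gene_rpf < 1:
            raise ValidationError("min_gene_rpf must be >= 1")


@dataclass
class GeneOccupancy:
    gene_id: str
    f: dict[str, float]
    a: dict[str, float]
    o: dict[str, float]
    n_eligible_reads: int
    n_eligible_positions: int


@dataclass
class OccupancyProfile:
    """61-row mean occupancy table (codon, amino_acid, mean_occupancy,
    n_genes, stderr). Codons present in no contributing gene are NaN —
    flagged missing, never zero."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.table["codon"]) != list(SENSE_CODONS):
            raise ValidationError("occupancy profile must have exactly the 61 sense codons, sorted")

    def occupancy(self, codon: str) -> float:
        return float(self.table.set_index("codon").loc[codon, "mean_occupancy"])


def eligible_slice(transcript: TranscriptModel, cfg: OccupancyConfig) -> slice:
    """0-based slice of eligible codon positions: 1-based index > cutoff,
    stop codon excluded."""
    return slice(cfg.codon_cutoff, transcript.n_codons - 1)


def gene_occupancy(
    track: CodonCountTrack,
    transcript: TranscriptModel,
    cfg: OccupancyConfig = OccupancyConfig(),
) -> GeneOccupancy | None:
    """Per-gene occupancy, or None if the gene is excluded (too few eligible
    reads, or no eligible positions)."""
    if len(track.counts) != transcript.n_codons:
        raise ValidationError(
            f"{transcript.transcript_id}: track length {len(track.counts)} != "
            f"n_codons {transcript.n_codons}"
        )
    sl = eligible_slice(transcript, cfg)
    codons = transcript.codons[sl]
    counts = track.counts[sl]
    if len(codons) == 0:
        logger.debug("%s excluded: no eligible positions", transcript.transcript_id)
        return None
    total_reads = int(counts.sum())
    if total_reads < cfg.min_gene_rpf:
        logger.debug(
            "%s excluded: %d eligible reads < %d",
            transcript.transcript_id, total_reads, cfg.min_gene_rpf,
        )
        return None

    pos_by_codon: Counter[str] = Counter(codons)
    reads_by_codon: dict[str, int] = {}
    for codon, n in zip(codons, counts):
        reads_by_codon[codon] = reads_by_codon.get(codon, 0) + int(n)

    n_pos = len(codons)
    f = {c: reads_by_codon.get(c, 0) / total_reads for c in pos_by_codon}
    a = {c: pos_by_codon[c] / n_pos for c in pos_by_codon}
    o = {c: f[c] / a[c] for c in pos_by_codon}
    return GeneOccupancy(transcript.transcript_id, f, a, o, total_reads, n_pos)


def occupancy_by_gene(
    tracks: Mapping[str, CodonCountTrack],
    transcripts: TranscriptSet,
    cfg: OccupancyConfig = OccupancyConfig(),
) -> list[GeneOccupancy]:
    out = []
    for tid, track in sorted(tracks.items()):
        res = gene_occupancy(track, transcripts[tid], cfg)
        if res is not None:
            out.append(res)
    return out


def average_occupancy(
    genes: Iterable[GeneOccupancy], weighted_by_reads: bool = False
) -> OccupancyProfile:
    """Average per-gene occupancies into a 61-codon profile.

    Default is the unweighted mean of o over genes where o is defined.
    ``weighted_by_reads=True`` pools by eligible read counts instead
    (sensitivity mode).
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("average_occupancy: no contributing genes")
    rows = []
    for codon in SENSE_CODONS:
        vals = np.array([g.o[codon] for g in genes if codon in g.o])
        if len(vals) == 0:
            rows.append((codon, CODON_TO_AA[codon], np.nan, 0, np.nan))
            continue
        if weighted_by_reads:
            w = np.array([g.n_eligible_reads for g in genes if codon in g.o], dtype=float)
            mean = float(np.average(vals, weights=w))
        else:
            mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        rows.append((codon, CODON_TO_AA[codon], mean, len(vals), se))
    table = pd.DataFrame(
        rows, columns=["codon", "amino_acid", "mean_occupancy", "n_genes", "stderr"]
    )
    return OccupancyProfile(table)


def occupancy_ratio(
    profile_stress: OccupancyProfile, profile_control: OccupancyProfile
) -> pd.DataFrame:
    """Per-codon log2(stress / control) occupancy ratios, ranked.

    Codons missing (or non-positive) in either profile are NaN with a
    warning; rank 1 is the largest ratio.
    """
    s = profile_stress.table.set_index("codon")["mean_occupancy"]
    c = profile_control.table.set_index("codon")["mean_occupancy"]
    bad = (s <= 0) | (c <= 0)
    if bad.any():
        logger.warning("non-positive occupancy for %s; ratio set missing", list(s.index[bad.fillna(False)]))
    ratio = np.log2(s.where(~bad) / c.where(~bad))
    out = pd.DataFrame(
        {
            "codon": ratio.index,
            "amino_acid": [CODON_TO_AA[x] for x in ratio.index],
            "log2_ratio": ratio.values,
        }
    )
    out["rank"] = out["log2_ratio"].rank(ascending=False, method="min")
    return out.reset_index(drop=True)
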