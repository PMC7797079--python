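"""A-site assignment: map footprint 5' ends to the codon being decoded.

The ribosome protects ~30 nt with the A-site codon beginning ~15 nt from the
5' end (12-nt P-site offset + 3). Occupancies downstream are reported in the
A-site frame; the P-site index is simply A-site - 1.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .annotation_io import (
    FootprintAlignment,
    TranscriptModel,
    TranscriptSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_A_SITE_OFFSET = 15
CALIBRATION_MIN_READS = 500


@dataclass(frozen=True)
class OffsetTable:
    """read length (nt) -> A-site offset (nt from the 5' end).

    ``default_offset`` is applied to unlisted lengths when it is valid for
    that length (0 < offset < length); otherwise the read is unassigned.
    """

    offsets: Mapping[int, int]
    default_offset: int | None = DEFAULT_A_SITE_OFFSET

    def __post_init__(self) -> None:
        for length, off in self.offsets.items():
            if not (0 < off < length):
                raise ValidationError(
                    f"offset {off} invalid for read length {length} (need 0 < offset < length)"
                )

    def get(self, read_length: int) -> int | None:
        """A-site offset for this read length, or None (unassigned)."""
        off = self.offsets.get(read_length)
        if off is None:
            off = self.default_offset
        if off is None or not (0 < off < read_length):
            return None
        return off

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_length\ta_site_offset\n")
            for length in sorted(self.offsets):
                fh.write(f"{length}\t{self.offsets[length]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, default_offset: int | None = DEFAULT_A_SITE_OFFSET):
        offsets: dict[int, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("read_length"):
                raise ValidationError(f"{path}: expected read_length/a_site_offset header")
            for line in fh:
                length, off = line.split("\t")
                offsets[int(length)] = int(off)
        return cls(offsets, default_offset)


def default_offsets() -> OffsetTable:
    """The documented default: 15-nt A-site offset for 27-31-nt reads, and the
    same 15 nt for other lengths whenever it is geometrically valid."""
    return OffsetTable(
        {length: DEFAULT_A_SITE_OFFSET for length in range(27, 32)},
        default_offset=DEFAULT_A_SITE_OFFSET,
    )


@dataclass
class CodonCountTrack:
    """Per-transcript vector of A-site footprint counts per codon position."""

    transcript_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValidationError(f"{self.transcript_id}: negative codon counts")


def calibrate_offsets(
    footprints: Iterable[FootprintAlignment | tuple[str, int, int]],
    transcripts: TranscriptSet,
    min_reads: int = CALIBRATION_MIN_READS,
    fallback: OffsetTable | None = None,
) -> OffsetTable:
    """Estimate per-length A-site offsets from a start-codon metagene.

    Initiating ribosomes place their P-site on codon 0, so their 5' ends sit a
    fixed distance upstream of the ATG. For each read-length class the modal
    upstream 5'-end distance d gives P-site offset d and A-site offset d + 3.
    Reads are accepted as raw (transcript_id, start, length) tuples so that
    negative CDS-relative starts — which the BED reader rejects — can be used
    here. Classes with fewer than ``min_reads`` total reads, or no upstream
    reads, fall back to the default table. Ties between modes take the lower
    offset (deterministic).
    """
    fallback = fallback or default_offsets()
    by_length: dict[int, list[int]] = {}
    n_total = 0
    for fp in footprints:
        if isinstance(fp, FootprintAlignment):
            tid, start, length = fp.transcript_id, fp.start, fp.length
        else:
            tid, start, length = fp
        if tid not in transcripts:
            continue
        n_total += 1
        by_length.setdefault(length, []).append(start)

    calibrated: dict[int, int] = {}
    for length, starts in sorted(by_length.items()):
        if len(starts) < min_reads:
            off = fallback.get(length)
            if off is not None:
                calibrated[length] = off
            logger.info(
                "length %d: %d reads < %d, falling back to default offset %s",
                length, len(starts), min_reads, off,
            )
            continue
        upstream = Counter(-s for s in starts if -length < s < 0)
        if not upstream:
            off = fallback.get(length)
            if off is not None:
                calibrated[length] = off
            logger.info("length %d: no upstream 5' ends; using default %s", length, off)
            continue
        top = max(upstream.values())
        modes = sorted(d for d, n in upstream.items() if n == top)
        if len(modes) > 1:
            logger.warning(
                "length %d: tied modal 5' distances %s; taking the lower offset",
                length, modes,
            )
        a_offset = modes[0] + 3  # P-site offset + one codon
        if 0 < a_offset < length:
            calibrated[length] = a_offset
        else:
            off = fallback.get(length)
            if off is not None:
                calibrated[length] = off

    if not by_length or not any(
        len(s) >= min_reads for s in by_length.values()
    ):
        raise ValidationError(
            "no read-length class had enough reads to calibrate; "
            "use default_offsets() instead"
        )
    return OffsetTable(calibrated, default_offset=fallback.default_offset)


def assign_asite(
    fp: FootprintAlignment, offsets: OffsetTable, transcript: TranscriptModel
) -> int | None:
    """Codon index decoded in the A-site, or None (unassigned).

    Unassigned when the length has no valid offset, or the index falls on the
    stop codon or outside the CDS. Reads landing in the start codon are kept
    (codon 0); the downstream >90-codon occupancy cutoff removes them.
    """
    off = offsets.get(fp.length)
    if off is None:
        return None
    idx = (fp.start + off) // 3
    if idx < 0 or idx >= transcript.n_codons - 1:
        return None
    return idx


def p_site_index(a_site: int | None) -> int | None:
    """P-site codon index for a given A-site index (exposed for completeness)."""
    if a_site is None:
        return None
    return a_site - 1


@dataclass
class TrackBuildResult:
    tracks: dict[str, CodonCountTrack]
    n_assigned: int
    n_unassigned: int


def build_count_tracks(
    footprints: Iterable[FootprintAlignment],
    offsets: OffsetTable,
    transcripts: TranscriptSet,
) -> TrackBuildResult:
    """Tally A-site assignments into per-transcript codon count tracks.

    Conservation: n_assigned + n_unassigned equals the number of input
    footprints, and n_assigned equals the sum over all tracks.
    """
    fps = list(footprints)
    tracks = {
        tid: CodonCountTrack(tid, np.zeros(t.n_codons, dtype=np.int64))
        for tid, t in transcripts.items()
    }
    if not fps:
        return TrackBuildResult(tracks, 0, 0)

    # vectorised: per-length offset lookup, then bincount per transcript
    tids = np.array([fp.transcript_id for fp in fps])
    starts = np.fromiter((fp.start for fp in fps), dtype=np.int64, count=len(fps))
    lengths = np.fromiter((fp.length for fp in fps), dtype=np.int64, count=len(fps))

    off_by_len = {int(l): offsets.get(int(l)) for l in np.unique(lengths)}
    off = np.array([-1 if off_by_len[int(l)] is None else off_by_len[int(l)] for l in lengths])
    has_offset = off >= 0
    idx = np.where(has_offset, (starts + off) // 3, -1)

    n_unassigned = 0
    order = np.argsort(tids, kind="stable")
    tids_s, idx_s = tids[order], idx[order]
    bounds = np.searchsorted(tids_s, np.unique(tids_s))
    uniq = np.unique(tids_s)
    for k, tid in enumerate(uniq):
        a = bounds[k]
        b = bounds[k + 1] if k + 1 < len(bounds) else len(tids_s)
        sub = idx_s[a:b]
        if tid not in tracks:
            n_unassigned += len(sub)
            continue
        n = transcripts[tid].n_codons
        ok = (sub >= 0) & (sub < n - 1)
        n_unassigned += int((~ok).sum())
        if ok.any():
            tracks[tid].counts += np.bincount(sub[ok], minlength=n)

    n_assigned = len(fps) - n_unassigned
    return TrackBuildResult(tracks, n_assigned, n_unassigned)
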