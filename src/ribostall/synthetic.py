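"""Synthetic transcriptomes, dwell-weighted ribosome footprints and matched
RNA-seq counts.

The simulator is an occupancy sampler, not a kinetic (TASEP) model: each
footprint's A-site codon is drawn with probability proportional to the
relative dwell time of the codon identity at that position, and a gene's
share of footprints is proportional to expression x total ribosome transit
time (the sum of dwell over its placeable codons). Under uniform dwell that
reduces to expression x length; under a stall it makes stall-codon-rich
genes accumulate proportionally more footprints, which is the density
signature the downstream TE analysis looks for. Queuing is injected by an
explicit emission rule: a footprint whose A-site is the stall codon seeds a
queued footprint one ribosome width (10 codons at 30-nt protection) upstream
with probability q, and a second, two widths up, with probability q^2.
Expectations therefore stay in closed form and every downstream statistic
can be checked against them.

Scenario presets mirror the study conditions: ``control`` (uniform dwell, no
queuing), ``h2o2`` (oxidative stress: TGG dwell x8, queue probability 0.3,
up to two queued ribosomes), and ``h2o2_trp`` (stress plus tryptophan
supplementation, which restores control dwell — the rescue condition).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .annotation_io import (
    FootprintAlignment,
    GeneCounts,
    TranscriptModel,
    TranscriptSet,
    ValidationError,
    write_cds_fasta,
)
from .codons import SENSE_CODONS, STOP_CODONS
from .psite import default_offsets

logger = logging.getLogger(__name__)

# per-stage child-seed tags (one master seed per scenario)
_STAGE_TRANSCRIPTOME = 0
_STAGE_FOOTPRINTS = 1
_STAGE_RNASEQ = 2

MIN_CDS_CODONS = 121  # occupancy cutoff (90) + metagene window (30) + 1


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage child generator from one master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


# ---------------------------------------------------------------------------
# Dwell / queue / scenario types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DwellModel:
    """Relative dwell time per sense codon (dimensionless, mean ~1)."""

    dwell: dict[str, float]
    stall_codon: str | None = None
    stall_factor: float = 1.0

    def __post_init__(self) -> None:
        if set(self.dwell) != set(SENSE_CODONS):
            raise ValidationError("dwell model must cover exactly the 61 sense codons")
        if any(v <= 0 for v in self.dwell.values()):
            raise ValidationError("dwell values must be positive")
        if self.stall_factor < 1:
            raise ValidationError("stall_factor must be >= 1")
        if self.stall_codon is not None and self.stall_codon not in self.dwell:
            raise ValidationError(f"stall codon {self.stall_codon!r} is not a sense codon")

    @classmethod
    def uniform(cls, stall_codon: str | None = None, stall_factor: float = 1.0) -> "DwellModel":
        return cls({c: 1.0 for c in SENSE_CODONS}, stall_codon, stall_factor)

    @classmethod
    def random(cls, seed: int, sigma: float = 0.5) -> "DwellModel":
        """Heterogeneous lognormal dwell model (geometric mean 1)."""
        rng = np.random.default_rng(seed)
        vals = np.exp(rng.normal(0.0, sigma, size=len(SENSE_CODONS)))
        return cls(dict(zip(SENSE_CODONS, vals.tolist())))

    def effective(self) -> dict[str, float]:
        """Dwell with the stall multiplier applied."""
        out = dict(self.dwell)
        if self.stall_codon is not None and self.stall_factor != 1.0:
            out[self.stall_codon] = out[self.stall_codon] * self.stall_factor
        return out


@dataclass(frozen=True)
class QueueParams:
    """Queued-footprint emission: occurrence probability q^k at k ribosome
    widths upstream of a stalled A-site, k <= max_queue_depth."""

    queue_prob: float = 0.0
    max_queue_depth: int = 2
    ribosome_width_codons: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.queue_prob < 1):
            raise ValidationError("queue_prob must be in [0, 1)")
        if self.max_queue_depth < 0:
            raise ValidationError("max_queue_depth must be >= 0")
        if self.ribosome_width_codons < 1:
            raise ValidationError("ribosome_width_codons must be >= 1")


@dataclass(frozen=True)
class FootprintLengthDist:
    """Discrete distribution on footprint lengths 17..30 nt.

    Default: a triangular component on 26-30 peaking at 30 (90% of mass —
    the canonical ~30-nt protected fragment) plus a uniform 17-25 minor tail
    (10% of mass) for the shorter gel-range fragments.
    """

    lengths: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.lengths) != len(self.probs):
            raise ValidationError("lengths and probs must align")
        if abs(sum(self.probs) - 1.0) > 1e-9 or any(p < 0 for p in self.probs):
            raise ValidationError("probs must be a probability vector")

    @classmethod
    def default(cls) -> "FootprintLengthDist":
        lengths = tuple(range(17, 31))
        tail = [0.10 / 9] * 9                       # 17..25
        tri = np.arange(1, 6, dtype=float)          # 26..30, peak at 30
        tri = (0.90 * tri / tri.sum()).tolist()
        return cls(lengths, tuple(tail + tri))

    @classmethod
    def fixed(cls, length: int) -> "FootprintLengthDist":
        return cls((length,), (1.0,))

    @property
    def mode(self) -> int:
        return self.lengths[int(np.argmax(self.probs))]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(np.array(self.lengths), size=size, p=np.array(self.probs))


SCENARIO_NAMES = ("control", "h2o2", "h2o2_trp")


@dataclass(frozen=True)
class SimScenario:
    name: str
    dwell: DwellModel
    queue: QueueParams
    expression: dict[str, float] | None = None  # None -> uniform over genes
    n_footprints: int = 1_000_000
    n_rna_reads: int = 1_000_000
    length_dist: FootprintLengthDist = field(default_factory=FootprintLengthDist.default)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_footprints < 1:
            raise ValidationError("n_footprints must be >= 1")
        if self.expression is not None:
            total = sum(self.expression.values())
            if total <= 0 or any(v < 0 for v in self.expression.values()):
                raise ValidationError("expression values must be non-negative with positive sum")

    def expression_for(self, transcripts: TranscriptSet) -> np.ndarray:
        ids = sorted(transcripts)
        if self.expression is None:
            expr = np.ones(len(ids))
        else:
            missing = [t for t in ids if t not in self.expression]
            if missing:
                raise ValidationError(f"expression missing for genes {missing[:3]}...")
            expr = np.array([self.expression[t] for t in ids], dtype=float)
        return expr / expr.sum()


def make_scenario(name: str, **overrides) -> SimScenario:
    """Build a named scenario preset, then apply and re-validate overrides.

    Presets: ``control`` and ``h2o2_trp`` (uniform dwell, stall factor 1, no
    queuing — the tryptophan rescue restores control elongation) and
    ``h2o2`` (TGG stall x8, queue probability 0.3, up to 2 queued ribosomes).
    """
    if name == "control":
        base = SimScenario(name, DwellModel.uniform(), QueueParams(queue_prob=0.0))
    elif name == "h2o2":
        base = SimScenario(
            name,
            DwellModel.uniform(stall_codon="TGG", stall_factor=8.0),
            QueueParams(queue_prob=0.3, max_queue_depth=2),
        )
    elif name == "h2o2_trp":
        base = SimScenario(name, DwellModel.uniform(), QueueParams(queue_prob=0.0))
    else:
        raise ValidationError(f"unknown scenario {name!r}; presets: {SCENARIO_NAMES}")

    dwell_keys = {"stall_codon", "stall_factor", "dwell"}
    queue_keys = {"queue_prob", "max_queue_depth", "ribosome_width_codons"}
    dw = {k: overrides.pop(k) for k in list(overrides) if k in dwell_keys}
    qu = {k: overrides.pop(k) for k in list(overrides) if k in queue_keys}
    if dw:
        base = replace(base, dwell=replace(base.dwell, **dw))
    if qu:
        base = replace(base, queue=replace(base.queue, **qu))
    if overrides:
        base = replace(base, **overrides)
    return base


def load_scenario_yaml(path: str | Path) -> tuple[SimScenario, dict]:
    """Load a scenario from YAML. Returns (scenario, generator_keys) where
    generator_keys holds transcriptome parameters (n_genes, length_range)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    name = raw.pop("scenario")
    gen = {k: raw.pop(k) for k in ("n_genes", "length_range") if k in raw}
    return make_scenario(name, **raw), gen


# ---------------------------------------------------------------------------
# Transcriptome generation
# ---------------------------------------------------------------------------

def default_codon_weights(tgg_fraction: float = 0.02) -> dict[str, float]:
    """Uniform sense-codon weights, with TGG re-weighted to the requested
    internal fraction (~2% by default, the Trp-content regime of interest)."""
    if not (0 < tgg_fraction < 1):
        raise ValidationError("tgg_fraction must be in (0, 1)")
    w = {c: 1.0 for c in SENSE_CODONS}
    w["TGG"] = tgg_fraction * 60 / (1 - tgg_fraction)
    return w


def generate_transcriptome(
    n_genes: int,
    length_range_codons: tuple[int, int] = (250, 600),
    codon_weights: dict[str, float] | None = None,
    seed: int = 0,
    fasta_path: str | Path | None = None,
    id_prefix: str = "g",
) -> TranscriptSet:
    """Generate a multi-gene CDS set with internal codons drawn from
    ``codon_weights`` (sense codons only), ATG first and a random stop last.

    The minimum length must exceed the occupancy cutoff plus the metagene
    window so every gene can contribute to every analysis stage.
    """
    lo, hi = length_range_codons
    if lo < MIN_CDS_CODONS:
        raise ValidationError(
            f"minimum CDS length {lo} codons is below {MIN_CDS_CODONS} "
            "(occupancy cutoff + metagene window); downstream stages would see no data"
        )
    if lo > hi:
        raise ValidationError("length range must be (min, max) with min <= max")
    weights = codon_weights or default_codon_weights()
    if set(weights) - set(SENSE_CODONS):
        raise ValidationError("codon_weights may only cover sense codons")
    if any(v < 0 for v in weights.values()) or sum(weights.values()) <= 0:
        raise ValidationError("codon_weights must be non-negative with positive sum")

    codon_pool = np.array([c for c in SENSE_CODONS if weights.get(c, 0) > 0])
    p = np.array([weights[c] for c in codon_pool], dtype=float)
    p /= p.sum()
    stops = np.array(sorted(STOP_CODONS))

    rng = _stage_rng(seed, _STAGE_TRANSCRIPTOME)
    width = len(str(n_genes))
    transcripts = TranscriptSet()
    for i in range(n_genes):
        n = int(rng.integers(lo, hi + 1))
        internal = rng.choice(codon_pool, size=n - 2, p=p)
        stop = str(rng.choice(stops))
        seq = "ATG" + "".join(internal) + stop
        transcripts.add(TranscriptModel(f"{id_prefix}{i + 1:0{width}d}", seq))
    if fasta_path is not None:
        write_cds_fasta(transcripts, fasta_path)
    return transcripts


# ---------------------------------------------------------------------------
# Footprint simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedFootprints:
    footprints: list[FootprintAlignment]
    n_primary: int
    n_primary_skipped: int     # boundary-skipped primary occurrences
    n_queued: int
    n_queued_skipped: int      # queued emissions lost to transcript bounds

    def __iter__(self):
        return iter(self.footprints)

    def __len__(self) -> int:
        return len(self.footprints)

    def per_gene_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for fp in self.footprints:
            totals[fp.transcript_id] = totals.get(fp.transcript_id, 0) + 1
        return totals


def simulate_footprints(
    transcripts: TranscriptSet, scenario: SimScenario
) -> SimulatedFootprints:
    """Sample dwell-weighted footprints, with queued emissions under a
    queuing scenario.

    Each footprint's 5' end is placed so its A-site, under the default
    offset table, falls on the intended codon. A-site codons are restricted
    to positions where a maximum-length read fits inside the CDS (and the
    stop codon is never an A-site); intended placements that still fall
    outside bounds are skipped and counted.
    """
    rng = _stage_rng(scenario.seed, _STAGE_FOOTPRINTS)
    offsets = default_offsets()
    ids = sorted(transcripts)
    expr = scenario.expression_for(transcripts)
    eff = scenario.dwell.effective()
    max_len = max(scenario.length_dist.lengths)
    nominal_off = offsets.get(scenario.length_dist.mode)
    if nominal_off is None:
        raise ValidationError("no valid A-site offset for the modal footprint length")
    j_min = math.ceil(nominal_off / 3)

    # flat per-(gene, codon) sampling weights: expression_g * dwell(codon_gj)
    dwell_vec = np.array([eff[c] for c in SENSE_CODONS])
    codon_index = {c: k for k, c in enumerate(SENSE_CODONS)}
    gene_arrays = []
    gene_of = []
    pos_of = []
    n_codons_arr = np.array([transcripts[t].n_codons for t in ids])
    for g, tid in enumerate(ids):
        t = transcripts[tid]
        n = t.n_codons
        w = np.zeros(n)
        idx = np.fromiter((codon_index[c] for c in t.codons[:-1]), dtype=np.int64, count=n - 1)
        w[: n - 1] = dwell_vec[idx]
        j_max = min(n - 2, (3 * n - max_len + nominal_off) // 3)
        w[:j_min] = 0.0
        w[j_max + 1 :] = 0.0
        gene_arrays.append(w * expr[g])
        gene_of.append(np.full(n, g))
        pos_of.append(np.arange(n))
    W = np.concatenate(gene_arrays)
    gene_flat = np.concatenate(gene_of)
    pos_flat = np.concatenate(pos_of)
    if W.sum() <= 0:
        raise ValidationError("no placeable codon positions under this scenario")

    probs = W / W.sum()
    draws = rng.choice(len(W), size=scenario.n_footprints, p=probs)
    genes = gene_flat[draws]
    jpos = pos_flat[draws]
    lengths = scenario.length_dist.sample(rng, scenario.n_footprints)
    off_by_len = {l: offsets.get(l) for l in scenario.length_dist.lengths}
    offs = np.array([off_by_len[l] for l in lengths])
    starts = 3 * jpos - offs
    nc = n_codons_arr[genes]
    ok = (starts >= 0) & (starts + lengths <= 3 * nc)
    n_primary_skipped = int((~ok).sum())

    all_genes = [genes[ok]]
    all_starts = [starts[ok]]
    all_lengths = [lengths[ok]]
    n_primary = int(ok.sum())

    n_queued = 0
    n_queued_skipped = 0
    q = scenario.queue.queue_prob
    stall = scenario.dwell.stall_codon
    if q > 0 and stall is not None and scenario.queue.max_queue_depth > 0:
        wcod = scenario.queue.ribosome_width_codons
        # which primary draws have the stall codon in the A-site
        stall_mask_flat = np.zeros(len(W), dtype=bool)
        cursor = 0
        for tid in ids:
            t = transcripts[tid]
            arr = np.array(t.codons) == stall
            stall_mask_flat[cursor : cursor + t.n_codons] = arr
            cursor += t.n_codons
        stalled = stall_mask_flat[draws] & ok
        for k in range(1, scenario.queue.max_queue_depth + 1):
            emit = stalled & (rng.random(scenario.n_footprints) < q**k)
            if not emit.any():
                continue
            jq = jpos[emit] - k * wcod
            gq = genes[emit]
            lq = scenario.length_dist.sample(rng, int(emit.sum()))
            oq = np.array([off_by_len[l] for l in lq])
            sq = 3 * jq - oq
            okq = (jq >= 0) & (sq >= 0) & (sq + lq <= 3 * n_codons_arr[gq])
            n_queued_skipped += int((~okq).sum())
            n_queued += int(okq.sum())
            all_genes.append(gq[okq])
            all_starts.append(sq[okq])
            all_lengths.append(lq[okq])

    genes_cat = np.concatenate(all_genes)
    starts_cat = np.concatenate(all_starts)
    lengths_cat = np.concatenate(all_lengths)
    footprints = [
        FootprintAlignment(ids[g], int(s), int(l))
        for g, s, l in zip(genes_cat, starts_cat, lengths_cat)
    ]
    logger.info(
        "simulated %d footprints (%d primary, %d skipped; %d queued, %d queue-skipped)",
        len(footprints), n_primary, n_primary_skipped, n_queued, n_queued_skipped,
    )
    return SimulatedFootprints(
        footprints, n_primary, n_primary_skipped, n_queued, n_queued_skipped
    )


def simulate_rnaseq_counts(
    transcripts: TranscriptSet,
    scenario: SimScenario,
    footprints: SimulatedFootprints | None = None,
) -> list[GeneCounts]:
    """Matched RNA-seq counts: multinomial over genes with probability
    proportional to expression x CDS length; RPF counts are the per-gene
    footprint totals (simulated here if not supplied)."""
    if scenario.n_rna_reads < 1:
        raise ValidationError("n_rna_reads must be >= 1")
    if footprints is None:
        footprints = simulate_footprints(transcripts, scenario)
    rng = _stage_rng(scenario.seed, _STAGE_RNASEQ)
    ids = sorted(transcripts)
    expr = scenario.expression_for(transcripts)
    lengths = np.array([3 * transcripts[t].n_codons for t in ids], dtype=float)
    p = expr * lengths
    p /= p.sum()
    rna = rng.multinomial(scenario.n_rna_reads, p)
    rpf = footprints.per_gene_totals()
    return [
        GeneCounts(tid, rpf.get(tid, 0), int(rna[i])) for i, tid in enumerate(ids)
    ]
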