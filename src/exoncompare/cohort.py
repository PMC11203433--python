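"""Cohort-level aggregation of per-sample, per-exon variant calls.

Each sample supplies one nucleotide sequence per exon.  Every exon is
globally aligned to the reference exon, variants are called and
3'-normalized, and events are accumulated into per-exon counts, a
per-position recurrence table, the altered/unaltered sample split, and
sliding-window mutation hotspots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .align import DEFAULT_SCHEME, ScoringScheme, global_align
from .gene_model import GeneModel
from .variant_call import Variant, call_variants, to_name

__all__ = [
    "SampleRecord",
    "CohortSummary",
    "HotspotWindow",
    "compare_cohort",
    "recurrent_positions",
    "hotspot_windows",
    "exon_histogram",
    "read_cohort_dir",
    "write_sample_fasta",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleRecord:
    """One sample: an id, a group label, and one sequence per exon.

    An exon absent from ``exon_seqs`` (or mapped to an empty string) is
    treated as missing and excluded from counting.
    """

    sample_id: str
    group: str  # "healthy" or "tumor"
    exon_seqs: dict[int, str] = field(default_factory=dict)


@dataclass
class CohortSummary:
    """Aggregated calls: counts per exon and per position, sample split."""

    n_samples: int
    n_altered: int
    n_unaltered: int
    exon_counts: dict[int, int]
    position_counts: dict[int, int]
    variants: list[tuple[str, Variant]]  # (sample_id, event)
    scheme: ScoringScheme = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        assert self.n_altered + self.n_unaltered == self.n_samples
        total = len(self.variants)
        assert sum(self.exon_counts.values()) == total
        assert sum(self.position_counts.values()) == total

    def variants_frame(self, dialect: str = "paper") -> pd.DataFrame:
        rows = [
            {
                "sample_id": sid,
                "exon_id": v.exon_id,
                "name": to_name(v, dialect),
                "kind": v.kind,
                "cdna_start": v.cdna_start,
                "cdna_end": v.cdna_end,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
            }
            for sid, v in self.variants
        ]
        cols = [
            "sample_id", "exon_id", "name", "kind",
            "cdna_start", "cdna_end", "ref", "alt",
        ]
        return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class HotspotWindow:
    """A maximal merged run of qualifying sliding windows.

    ``cdna_start``/``cdna_end`` span the mutated positions the run contains;
    ``exon_id`` is the exon of the peak position (highest event count,
    leftmost on ties).
    """

    cdna_start: int
    cdna_end: int
    exon_id: int
    event_count: int
    recurrent_positions: tuple[tuple[int, int], ...]
    width: int


def compare_cohort(
    samples: list[SampleRecord],
    model: GeneModel,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> CohortSummary:
    """Align, call and normalize every sample exon; accumulate the summary."""
    if not samples:
        raise ValueError("cohort is empty")
    exon_counts = {e.exon_id: 0 for e in model.exons}
    position_counts: dict[int, int] = {}
    all_variants: list[tuple[str, Variant]] = []
    n_altered = 0

    for sample in samples:
        sample_events = 0
        for span in model.exons:
            seq = sample.exon_seqs.get(span.exon_id, "")
            if not seq:
                logger.warning(
                    "sample %s: exon %d missing, excluded from counts",
                    sample.sample_id, span.exon_id,
                )
                continue
            aln = global_align(model.exon_sequence(span.exon_id), seq, scheme)
            for v in call_variants(aln, model, span.exon_id):
                exon_counts[v.exon_id] += 1
                position_counts[v.cdna_start] = (
                    position_counts.get(v.cdna_start, 0) + 1
                )
                all_variants.append((sample.sample_id, v))
                sample_events += 1
        if sample_events:
            n_altered += 1

    return CohortSummary(
        n_samples=len(samples),
        n_altered=n_altered,
        n_unaltered=len(samples) - n_altered,
        exon_counts=exon_counts,
        position_counts=dict(sorted(position_counts.items())),
        variants=all_variants,
        scheme=scheme,
    )


def recurrent_positions(
    summary: CohortSummary, min_count: int = 2
) -> list[tuple[int, int]]:
    """Positions hit in >= ``min_count`` events, by count desc then position."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    hits = [
        (pos, n) for pos, n in summary.position_counts.items() if n >= min_count
    ]
    return sorted(hits, key=lambda pn: (-pn[1], pn[0]))


def hotspot_windows(
    summary: CohortSummary,
    model: GeneModel,
    width: int = 50,
    min_events: int = 4,
) -> list[HotspotWindow]:
    """Sliding-window hotspot scan over the cDNA.

    A window of ``width`` nt steps by 1 across the reference; windows holding
    >= ``min_events`` events qualify, and overlapping qualifying windows merge
    into one maximal interval, reported as the span of the mutated positions
    it contains.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if min_events < 1:
        raise ValueError("min_events must be >= 1")

    positions = sorted(summary.position_counts)
    if not positions:
        return []
    counts = summary.position_counts

    def events_in(lo: int, hi: int) -> int:
        return sum(counts[p] for p in positions if lo <= p <= hi)

    qualifying = [
        s
        for s in range(1, model.length - width + 2)
        if events_in(s, s + width - 1) >= min_events
    ]
    if not qualifying:
        return []

    # merge qualifying window starts whose windows overlap (gap < width)
    runs: list[tuple[int, int]] = []
    run_start = prev = qualifying[0]
    for s in qualifying[1:]:
        if s - prev <= width - 1:
            prev = s
        else:
            runs.append((run_start, prev + width - 1))
            run_start = prev = s
    runs.append((run_start, prev + width - 1))

    out = []
    for lo, hi in runs:
        inside = [p for p in positions if lo <= p <= hi]
        if not inside:
            continue
        start, end = min(inside), max(inside)
        peak = max(inside, key=lambda p: (counts[p], -p))
        recurrent = tuple(
            (p, counts[p]) for p in inside if counts[p] >= 2
        )
        out.append(
            HotspotWindow(
                cdna_start=start,
                cdna_end=end,
                exon_id=model.exon_of(peak),
                event_count=sum(counts[p] for p in inside),
                recurrent_positions=recurrent,
                width=width,
            )
        )
    return out


def exon_histogram(summary: CohortSummary, model: GeneModel) -> pd.DataFrame:
    """Mutation-event count per exon, in model order, zero rows included."""
    rows = [
        {"exon_id": e.exon_id, "count": summary.exon_counts.get(e.exon_id, 0)}
        for e in model.exons
    ]
    return pd.DataFrame(rows, columns=["exon_id", "count"])


# -- cohort I/O (per-sample multi-FASTA, record ids "sampleID|exonID") -----

def write_sample_fasta(sample: SampleRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        for exon_id in sorted(sample.exon_seqs):
            seq = sample.exon_seqs[exon_id]
            fh.write(f">{sample.sample_id}|{exon_id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_cohort_dir(path: str | Path, group: str = "tumor") -> list[SampleRecord]:
    """Read every ``*.fasta``/``*.fa``/``*.txt`` file in a directory.

    Each file is one sample; record ids are ``sampleID|exonID``.
    """
    path = Path(path)
    files = sorted(
        p for p in path.iterdir()
        if p.suffix.lower() in (".fasta", ".fa", ".txt")
    )
    if not files:
        raise FileNotFoundError(f"no FASTA files found in {path}")
    samples = []
    for f in files:
        exon_seqs: dict[int, str] = {}
        sample_id = f.stem
        for rec in SeqIO.parse(str(f), "fasta"):
            if "|" not in rec.id:
                raise ValueError(
                    f"{f.name}: record id {rec.id!r} is not 'sampleID|exonID'"
                )
            sid, exon = rec.id.rsplit("|", 1)
            sample_id = sid
            exon_seqs[int(exon)] = str(rec.seq).upper()
        samples.append(SampleRecord(sample_id, group, exon_seqs))
    return samples
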