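"""Gene model: exon structure of a coding sequence and cDNA coordinate mapping.

All coordinates are 1-based inclusive cDNA (c.) positions, with c.1 the first
base of the model's reference coding sequence.  Samples are supplied per exon,
so the model also maps between exon-local offsets and cDNA positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "ExonSpan",
    "GeneModel",
    "GeneModelError",
    "DEFAULT_TP53_EXONS",
    "load_gene_model",
]

VALID_BASES = frozenset("ACGT")

#: Coding exons 2-11 of a TP53-like gene model (1182-nt CDS).  Exon 1 is
#: non-coding and intentionally absent; intronic positions are not modeled.
DEFAULT_TP53_EXONS: tuple[tuple[int, int, int], ...] = (
    (2, 1, 74),
    (3, 75, 96),
    (4, 97, 375),
    (5, 376, 560),
    (6, 561, 672),
    (7, 673, 782),
    (8, 783, 919),
    (9, 920, 993),
    (10, 994, 1100),
    (11, 1101, 1182),
)


class GeneModelError(ValueError):
    """Structured validation failure in a gene model or coordinate lookup."""


@dataclass(frozen=True)
class ExonSpan:
    """One exon's 1-based inclusive span on the coding sequence."""

    exon_id: int
    cdna_start: int
    cdna_end: int

    def __post_init__(self) -> None:
        if self.cdna_start < 1 or self.cdna_start > self.cdna_end:
            raise GeneModelError(
                f"exon {self.exon_id}: invalid span "
                f"{self.cdna_start}..{self.cdna_end}"
            )

    @property
    def length(self) -> int:
        return self.cdna_end - self.cdna_start + 1

    def __contains__(self, cdna_pos: int) -> bool:
        return self.cdna_start <= cdna_pos <= self.cdna_end


@dataclass(frozen=True)
class GeneModel:
    """Exon spans plus the reference coding sequence they tile.

    Invariants enforced at construction: spans sorted ascending, contiguous
    (each starts where the previous ended +1), first starts at c.1, and the
    union covers the reference sequence exactly.
    """

    gene_name: str
    reference_cdna: str
    exons: tuple[ExonSpan, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        bad = [
            (i + 1, b)
            for i, b in enumerate(self.reference_cdna)
            if b not in VALID_BASES
        ]
        if bad:
            pos, b = bad[0]
            raise GeneModelError(
                f"reference contains non-ACGT character {b!r} at c.{pos}"
            )
        if not self.exons:
            raise GeneModelError("gene model has no exons")
        prev_end = 0
        for span in self.exons:
            if span.cdna_start != prev_end + 1:
                raise GeneModelError(
                    f"exon {span.exon_id}: span {span.cdna_start}.."
                    f"{span.cdna_end} is not contiguous with previous end "
                    f"{prev_end} (overlap or gap)"
                )
            prev_end = span.cdna_end
        if prev_end != len(self.reference_cdna):
            raise GeneModelError(
                f"exon spans cover 1..{prev_end} but reference is "
                f"{len(self.reference_cdna)} nt"
            )

    # -- lookups -----------------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.reference_cdna)

    @property
    def exon_ids(self) -> list[int]:
        return [e.exon_id for e in self.exons]

    def exon_span(self, exon_id: int) -> ExonSpan:
        for span in self.exons:
            if span.exon_id == exon_id:
                return span
        raise GeneModelError(f"unknown exon id {exon_id}")

    def exon_of(self, cdna_pos: int) -> int:
        """Exon id whose span contains the 1-based cDNA position."""
        for span in self.exons:
            if cdna_pos in span:
                return span.exon_id
        raise GeneModelError(
            f"c.{cdna_pos} is outside the model (valid range 1..{self.length})"
        )

    def exon_local_to_cdna(self, exon_id: int, local_pos: int) -> int:
        """Map a 1-based offset within an exon to its cDNA position."""
        span = self.exon_span(exon_id)
        if not 1 <= local_pos <= span.length:
            raise GeneModelError(
                f"local position {local_pos} exceeds exon {exon_id} "
                f"length {span.length}"
            )
        return span.cdna_start + local_pos - 1

    def cdna_to_exon_local(self, cdna_pos: int) -> tuple[int, int]:
        """Inverse of :meth:`exon_local_to_cdna`: (exon_id, local 1-based)."""
        exon_id = self.exon_of(cdna_pos)
        span = self.exon_span(exon_id)
        return exon_id, cdna_pos - span.cdna_start + 1

    def exon_sequence(self, exon_id: int) -> str:
        span = self.exon_span(exon_id)
        return self.reference_cdna[span.cdna_start - 1 : span.cdna_end]

    def base_at(self, cdna_pos: int) -> str:
        if not 1 <= cdna_pos <= self.length:
            raise GeneModelError(f"c.{cdna_pos} outside reference")
        return self.reference_cdna[cdna_pos - 1]

    # -- serialisation -----------------------------------------------------

    def to_files(self, model_tsv: str | Path, reference_fasta: str | Path) -> None:
        """Write the gene-model TSV and single-record reference FASTA."""
        with open(model_tsv, "w") as fh:
            fh.write("exon_id\tcdna_start\tcdna_end\n")
            for e in self.exons:
                fh.write(f"{e.exon_id}\t{e.cdna_start}\t{e.cdna_end}\n")
        with open(reference_fasta, "w") as fh:
            fh.write(f">{self.gene_name} reference coding sequence\n")
            for i in range(0, self.length, 60):
                fh.write(self.reference_cdna[i : i + 60] + "\n")


def load_gene_model(
    model_tsv: str | Path,
    reference_fasta: str | Path,
    gene_name: str | None = None,
) -> GeneModel:
    """Load and validate a gene model from a TSV of exon spans + FASTA.

    The TSV must carry a header line with columns ``exon_id``, ``cdna_start``
    and ``cdna_end``; the FASTA must contain exactly one record whose sequence
    is the reference coding sequence.
    """
    model_tsv = Path(model_tsv)
    reference_fasta = Path(reference_fasta)
    if not model_tsv.exists():
        raise GeneModelError(f"gene-model TSV not found: {model_tsv}")
    if not reference_fasta.exists():
        raise GeneModelError(f"reference FASTA not found: {reference_fasta}")

    with open(model_tsv) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["exon_id", "cdna_start", "cdna_end"]
        if [c.strip() for c in header[:3]] != required:
            raise GeneModelError(
                f"gene-model TSV header must be {required!r}, got {header!r}"
            )
        spans = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                spans.append(
                    ExonSpan(int(parts[0]), int(parts[1]), int(parts[2]))
                )
            except (IndexError, ValueError) as exc:
                raise GeneModelError(
                    f"malformed gene-model row {line.rstrip()!r}: {exc}"
                ) from exc
    spans.sort(key=lambda s: s.cdna_start)

    records = list(SeqIO.parse(str(reference_fasta), "fasta"))
    if len(records) != 1:
        raise GeneModelError(
            f"reference FASTA must hold exactly one record, found {len(records)}"
        )
    name = gene_name or records[0].id
    return GeneModel(
        gene_name=name,
        reference_cdna=str(records[0].seq).upper(),
        exons=tuple(spans),
    )
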