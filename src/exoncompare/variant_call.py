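"""Variant extraction and naming from an exon alignment.

Converts alignment columns into substitution / deletion / insertion events in
1-based cDNA (c.) coordinates, shifts indels to their 3'-most equivalent
placement within the exon (the HGVS convention), and formats/parses variant
names in two dialects:

``paper``
    substitution ``c.404G>T``; single-base deletion ``c.80delC``; multi-base
    deletion with a length suffix ``c.450_478del29``; insertion
    ``c.622_623insGATA``.
``hgvs-strict``
    deletions drop the allele/length suffix (``c.80del``, ``c.450_478del``);
    substitutions and insertions are unchanged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

from .align import Alignment
from .gene_model import GeneModel

__all__ = [
    "Variant",
    "VariantError",
    "call_variants",
    "normalize_3prime",
    "to_name",
    "parse_name",
]

logger = logging.getLogger(__name__)

SUBSTITUTION = "substitution"
DELETION = "deletion"
INSERTION = "insertion"


class VariantError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Variant:
    """One mutation event in cDNA coordinates.

    For substitutions and single-base deletions ``cdna_start == cdna_end``;
    for insertions the coordinates are the two flanking anchor bases, so
    ``cdna_end == cdna_start + 1`` and ``ref_allele`` is empty; deletions
    carry the deleted bases in ``ref_allele`` and an empty ``alt_allele``.
    """

    cdna_start: int
    cdna_end: int
    kind: str
    ref_allele: str
    alt_allele: str
    exon_id: int | None = None

    def __post_init__(self) -> None:
        if self.cdna_start > self.cdna_end:
            raise VariantError(f"cdna_start > cdna_end in {self}")
        if self.kind == SUBSTITUTION:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise VariantError("substitution alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise VariantError("substitution ref and alt are identical")
            if self.cdna_start != self.cdna_end:
                raise VariantError("substitution spans one position")
        elif self.kind == DELETION:
            if self.alt_allele or not self.ref_allele:
                raise VariantError("deletion needs ref bases and empty alt")
            if self.cdna_end - self.cdna_start + 1 != len(self.ref_allele):
                raise VariantError("deletion span does not match ref allele")
        elif self.kind == INSERTION:
            if self.ref_allele or not self.alt_allele:
                raise VariantError("insertion needs alt bases and empty ref")
            if self.cdna_end != self.cdna_start + 1:
                raise VariantError("insertion anchors must be adjacent")
        else:
            raise VariantError(f"unknown variant kind {self.kind!r}")

    @property
    def name(self) -> str:
        return to_name(self)


def call_variants(
    aln: Alignment, model: GeneModel, exon_id: int
) -> list[Variant]:
    """All variant events in an exon alignment, 3'-normalized and sorted.

    The degapped reference row must equal the model's sequence for
    ``exon_id``.  Columns involving 'N' are skipped with a warning.  Adjacent
    gap columns in the same row merge into one multi-base indel event.
    """
    exon_seq = model.exon_sequence(exon_id)
    if aln.ref_seq != exon_seq:
        raise VariantError(
            f"alignment reference row does not match model exon {exon_id}"
        )
    span = model.exon_span(exon_id)

    raw: list[Variant] = []
    local = 0  # ref bases consumed so far
    del_start_local: int | None = None
    del_bases: list[str] = []
    ins_anchor_local: int | None = None
    ins_bases: list[str] = []

    def flush_del() -> None:
        nonlocal del_start_local, del_bases
        if del_start_local is not None:
            raw.append(
                Variant(
                    cdna_start=span.cdna_start + del_start_local - 1,
                    cdna_end=span.cdna_start + del_start_local - 2 + len(del_bases),
                    kind=DELETION,
                    ref_allele="".join(del_bases),
                    alt_allele="",
                    exon_id=exon_id,
                )
            )
            del_start_local, del_bases = None, []

    def flush_ins() -> None:
        # an anchor of 0 (gap before the first reference base) is kept
        # provisionally; 3' normalization either slides it into the exon or
        # the final check below rejects it
        nonlocal ins_anchor_local, ins_bases
        if ins_anchor_local is not None:
            anchor = span.cdna_start + ins_anchor_local - 1
            raw.append(
                Variant(
                    cdna_start=anchor,
                    cdna_end=anchor + 1,
                    kind=INSERTION,
                    ref_allele="",
                    alt_allele="".join(ins_bases),
                    exon_id=exon_id,
                )
            )
            ins_anchor_local, ins_bases = None, []

    for a, b in zip(aln.ref_row, aln.sample_row):
        if b == "-":  # base missing from sample
            flush_ins()
            local += 1
            if del_start_local is None:
                del_start_local = local
            del_bases.append(a)
            continue
        if a == "-":  # extra base in sample
            flush_del()
            if ins_anchor_local is None:
                ins_anchor_local = local
            ins_bases.append(b)
            continue
        flush_del()
        flush_ins()
        local += 1
        if a == "N" or b == "N":
            logger.warning(
                "skipping no-call column at c.%d (exon %s)",
                span.cdna_start + local - 1,
                exon_id,
            )
            continue
        if a != b:
            raw.append(
                Variant(
                    cdna_start=span.cdna_start + local - 1,
                    cdna_end=span.cdna_start + local - 1,
                    kind=SUBSTITUTION,
                    ref_allele=a,
                    alt_allele=b,
                    exon_id=exon_id,
                )
            )
    flush_del()
    flush_ins()

    # 3'-shift each indel, but never across the next called event: the
    # shift equivalence assumes the sample matches the reference in the
    # shifted-through region, which a neighbouring variant violates
    raw.sort(key=lambda v: v.cdna_start)
    normalized = []
    for i, v in enumerate(raw):
        limit = span.cdna_end
        if i + 1 < len(raw):
            limit = min(limit, raw[i + 1].cdna_start - 1)
        normalized.append(_normalize_up_to(v, model, limit))
    normalized.sort()
    for v in normalized:
        if v.cdna_start < span.cdna_start:
            raise VariantError(
                f"insertion before the first base of exon {exon_id} "
                "cannot be anchored within the exon"
            )
    return normalized


def normalize_3prime(v: Variant, model: GeneModel) -> Variant:
    """Shift an indel to its 3'-most equivalent position within its exon.

    Substitutions are returned unchanged.  Idempotent: the 3'-most placement
    is a fixed point of the shift.  Raises if the variant's stated reference
    allele disagrees with the model sequence.
    """
    exon_id = v.exon_id if v.exon_id is not None else model.exon_of(v.cdna_start)
    return _normalize_up_to(v, model, model.exon_span(exon_id).cdna_end)


def _normalize_up_to(v: Variant, model: GeneModel, limit: int) -> Variant:
    """3'-shift ``v`` without letting it extend past cDNA position ``limit``."""
    exon_id = v.exon_id if v.exon_id is not None else model.exon_of(v.cdna_start)
    span = model.exon_span(exon_id)
    limit = min(limit, span.cdna_end)

    if v.kind == SUBSTITUTION:
        if model.base_at(v.cdna_start) != v.ref_allele:
            raise VariantError(
                f"reference mismatch at c.{v.cdna_start}: model has "
                f"{model.base_at(v.cdna_start)}, variant states {v.ref_allele}"
            )
        return replace(v, exon_id=exon_id)

    if v.kind == DELETION:
        s, e = v.cdna_start, v.cdna_end
        ref_span = model.reference_cdna[s - 1 : e]
        if ref_span != v.ref_allele:
            raise VariantError(
                f"reference mismatch for deletion at c.{s}_{e}: model has "
                f"{ref_span}, variant states {v.ref_allele}"
            )
        # deleting [s..e] == deleting [s+1..e+1] iff base at e+1 equals base at s
        while e < limit and model.base_at(e + 1) == model.base_at(s):
            s += 1
            e += 1
        return Variant(
            cdna_start=s,
            cdna_end=e,
            kind=DELETION,
            ref_allele=model.reference_cdna[s - 1 : e],
            alt_allele="",
            exon_id=exon_id,
        )

    # insertion: rotate the inserted string while it can slide 3'-wards
    p = v.cdna_start
    ins = v.alt_allele
    while p + 1 <= limit and model.base_at(p + 1) == ins[0]:
        ins = ins[1:] + ins[0]
        p += 1
    return Variant(
        cdna_start=p,
        cdna_end=p + 1,
        kind=INSERTION,
        ref_allele="",
        alt_allele=ins,
        exon_id=exon_id,
    )


def to_name(v: Variant, dialect: str = "paper") -> str:
    """Format a variant name; see module docstring for the two dialects."""
    if dialect not in ("paper", "hgvs-strict"):
        raise VariantError(f"unknown name dialect {dialect!r}")
    if v.kind == SUBSTITUTION:
        return f"c.{v.cdna_start}{v.ref_allele}>{v.alt_allele}"
    if v.kind == DELETION:
        if len(v.ref_allele) == 1:
            suffix = v.ref_allele if dialect == "paper" else ""
            return f"c.{v.cdna_start}del{suffix}"
        suffix = str(len(v.ref_allele)) if dialect == "paper" else ""
        return f"c.{v.cdna_start}_{v.cdna_end}del{suffix}"
    return f"c.{v.cdna_start}_{v.cdna_end}ins{v.alt_allele}"


_SUB_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_DEL1_RE = re.compile(r"^c\.(\d+)del([ACGT])?$")
_DELN_RE = re.compile(r"^c\.(\d+)_(\d+)del(\d+|[ACGT]+)?$")
_INS_RE = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")


def parse_name(name: str, model: GeneModel | None = None) -> Variant:
    """Parse a variant name (either dialect) back into a :class:`Variant`.

    Deletion names that omit the deleted bases (``c.5del``,
    ``c.450_478del29``) need ``model`` to recover the reference allele;
    without it they raise.  With ``model`` the stated alleles are checked
    against the reference and the exon is assigned.
    """
    name = name.strip()

    def _finish(v: Variant) -> Variant:
        if model is not None:
            return normalize_3prime(v, model)  # validates ref + fills exon
        return v

    if m := _SUB_RE.match(name):
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
        if ref == alt:
            raise VariantError(f"substitution with identical alleles: {name!r}")
        return _finish(Variant(pos, pos, SUBSTITUTION, ref, alt))

    if m := _DEL1_RE.match(name):
        pos, base = int(m.group(1)), m.group(2)
        if base is None:
            if model is None:
                raise VariantError(
                    f"{name!r} omits the deleted base; a gene model is "
                    "required to resolve it"
                )
            base = model.base_at(pos)
        return _finish(Variant(pos, pos, DELETION, base, ""))

    if m := _DELN_RE.match(name):
        start, end, suffix = int(m.group(1)), int(m.group(2)), m.group(3)
        length = end - start + 1
        if length < 1:
            raise VariantError(f"bad deletion span in {name!r}")
        if suffix and suffix.isdigit():
            if int(suffix) != length:
                raise VariantError(
                    f"length suffix {suffix} contradicts span "
                    f"{start}_{end} in {name!r}"
                )
            suffix = None
        if suffix is None:
            if model is None:
                raise VariantError(
                    f"{name!r} omits the deleted bases; a gene model is "
                    "required to resolve them"
                )
            ref = model.reference_cdna[start - 1 : end]
        else:
            if len(suffix) != length:
                raise VariantError(
                    f"deleted bases {suffix!r} contradict span "
                    f"{start}_{end} in {name!r}"
                )
            ref = suffix
        return _finish(Variant(start, end, DELETION, ref, ""))

    if m := _INS_RE.match(name):
        start, end, ins = int(m.group(1)), int(m.group(2)), m.group(3)
        if end != start + 1:
            raise VariantError(
                f"insertion anchors must be adjacent, got {start}_{end} "
                f"in {name!r}"
            )
        return _finish(Variant(start, end, INSERTION, "", ins))

    raise VariantError(f"cannot parse variant name {name!r}")
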