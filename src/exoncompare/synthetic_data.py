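"""Synthetic references and cohorts with planted (spiked-in) variants.

The centrepiece is the *fixture cohort*: a 50-sample tumor cohort plus a
50-sample healthy cohort carrying a fixed variant catalogue on a synthetic
TP53-like coding sequence.  The reference sequence is random but seeded,
except at *constrained sites* whose bases are pinned so that every
catalogued variant name is consistent with the reference and is already in
its 3'-normal form (e.g., the homopolymer run at c.453-455 ends at 455, so a
single-C loss there is named c.455delC).

The catalogue content (sample assignment, positions, kinds, constrained
alleles) is seed-independent; the seed only varies the reference composition
at unconstrained sites, and with it the alleles of events whose reference
base is unconstrained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SampleRecord, write_sample_fasta
from .gene_model import DEFAULT_TP53_EXONS, ExonSpan, GeneModel
from .variant_call import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    Variant,
    VariantError,
    normalize_3prime,
    parse_name,
    to_name,
)

__all__ = [
    "VariantSpec",
    "VariantCatalogue",
    "FixtureCohort",
    "apply_variant",
    "fixture_gene_model",
    "build_fixture_cohort",
    "random_cohort",
]

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

# Reference bases pinned by the catalogue: printed ref alleles, homopolymer
# context for 3'-normal deletion names, and flanks that stop indel sliding.
_FIXED_REF_BASES: dict[int, str] = {
    80: "C", 81: "A",          # c.80delC; run of C ends at 80
    254: "C", 255: "A",        # c.254delC
    404: "G",                  # c.404G>T
    447: "C", 465: "C", 483: "C",   # healthy synonymous substitutions
    450: "G", 479: "A",        # c.450_478del29 cannot slide 3'
    453: "C", 454: "C", 455: "C", 456: "A",  # c.455delC run ends at 455
    475: "G",                  # c.475G>A
    487: "T",                  # c.487T>A
    524: "G",                  # c.524G>A
    623: "T",                  # c.622_623insGATA cannot slide 3'
    637: "C",                  # c.637C>T
    742: "C",                  # c.742C>T
    818: "G",                  # c.818G>A / c.818G>C
    822: "T",                  # healthy c.822T>A
    844: "C",                  # c.844C>T
    1024: "C",                 # c.1024C>T
}

# Tumor catalogue: named variants at printed position and multiplicity.
# A bare integer is a substitution whose alleles are unstated; it becomes a
# transition of the (seeded) reference base at that position.
_TUMOR_NAMED: tuple[tuple[int, str | int], ...] = (
    (2, 69),
    (3, "c.80delC"), (3, 96),
    (4, 108), (4, 108), (4, "c.254delC"),
    (5, "c.404G>T"), (5, "c.404G>T"), (5, "c.450_478del29"),
    (5, "c.455delC"), (5, "c.475G>A"), (5, "c.487T>A"), (5, "c.524G>A"),
    (6, "c.622_623insGATA"), (6, "c.637C>T"), (6, 639),
    (7, "c.742C>T"),
    (8, "c.818G>A"), (8, "c.818G>A"), (8, "c.818G>C"), (8, "c.818G>C"),
    (8, "c.844C>T"), (8, "c.844C>T"),
    (10, 994), (10, 994), (10, "c.1024C>T"),
    (11, 1169),
)

# Filler substitutions completing the per-exon totals
# {e2:1, e3:2, e4:6, e5:12, e6:6, e7:4, e8:12, e9:0, e10:4, e11:1}.
# Positions are fixture decisions: inside the narrative per-exon ranges,
# distinct from the named positions so no extra recurrence arises.
FILLER_POSITIONS: dict[int, tuple[int, ...]] = {
    4: (260, 275, 290),
    5: (412, 423, 431, 440, 466),
    6: (575, 590, 605),
    7: (685, 700, 715),
    8: (821, 827, 833, 839, 851, 857),
    10: (1010,),
}

# Healthy cohort: three synonymous-style substitutions per exon; positions
# named in the source catalogue keep their printed alt allele, invented
# ones take the transition of the reference base.
_HEALTHY_SITES: dict[int, tuple[tuple[int, str | None], ...]] = {
    2: ((20, None), (40, None), (60, None)),
    3: ((78, None), (85, None), (92, None)),
    4: ((150, None), (200, None), (300, None)),
    5: ((447, "G"), (465, "G"), (483, "G")),
    6: ((580, None), (600, None), (660, None)),
    7: ((690, None), (720, None), (760, None)),
    8: ((807, None), (822, "A"), (873, None)),
    9: ((930, None), (950, None), (970, None)),
    10: ((1030, None), (1060, None), (1090, None)),
    11: ((1120, None), (1140, None), (1160, None)),
}


@dataclass(frozen=True)
class VariantSpec:
    """A planted variant: the event plus the sample that carries it."""

    sample_id: str
    variant: Variant


@dataclass
class VariantCatalogue:
    """The plant list for a simulated cohort."""

    specs: list[VariantSpec]
    n_samples: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s.sample_id,
                "exon_id": s.variant.exon_id,
                "name": to_name(s.variant),
                "kind": s.variant.kind,
                "start": s.variant.cdna_start,
                "end": s.variant.cdna_end,
                "ref": s.variant.ref_allele,
                "alt": s.variant.alt_allele,
            }
            for s in self.specs
        ]
        cols = ["sample_id", "exon_id", "name", "kind", "start", "end", "ref", "alt"]
        return pd.DataFrame(rows, columns=cols)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class FixtureCohort:
    model: GeneModel
    tumor: list[SampleRecord]
    healthy: list[SampleRecord]
    tumor_catalogue: VariantCatalogue
    healthy_catalogue: VariantCatalogue

    def write(self, outdir: str | Path) -> None:
        """Write gene model, reference, per-sample FASTAs and catalogues."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.model.to_files(outdir / "model.tsv", outdir / "reference.fasta")
        for group, samples in (("tumor", self.tumor), ("healthy", self.healthy)):
            gdir = outdir / group
            gdir.mkdir(exist_ok=True)
            for s in samples:
                write_sample_fasta(s, gdir / f"{s.sample_id}.fasta")
        self.tumor_catalogue.write_tsv(outdir / "catalogue_tumor.tsv")
        self.healthy_catalogue.write_tsv(outdir / "catalogue_healthy.tsv")


def apply_variant(seq: str, variant: Variant, model: GeneModel) -> str:
    """Apply one variant to an exon sequence (the inverse of calling).

    ``seq`` must be the unmutated exon sequence of ``variant.exon_id``; the
    stated reference allele is checked against it before editing.
    """
    exon_id = variant.exon_id
    if exon_id is None:
        exon_id = model.exon_of(variant.cdna_start)
    span = model.exon_span(exon_id)
    s_loc = variant.cdna_start - span.cdna_start + 1

    if variant.kind == SUBSTITUTION:
        if seq[s_loc - 1] != variant.ref_allele:
            raise VariantError(
                f"ref mismatch applying {to_name(variant)}: sequence has "
                f"{seq[s_loc - 1]} at c.{variant.cdna_start}"
            )
        return seq[: s_loc - 1] + variant.alt_allele + seq[s_loc:]

    if variant.kind == DELETION:
        e_loc = variant.cdna_end - span.cdna_start + 1
        if seq[s_loc - 1 : e_loc] != variant.ref_allele:
            raise VariantError(
                f"ref mismatch applying {to_name(variant)}: sequence has "
                f"{seq[s_loc - 1:e_loc]}"
            )
        return seq[: s_loc - 1] + seq[e_loc:]

    # insertion between the anchor base and the next
    return seq[:s_loc] + variant.alt_allele + seq[s_loc:]


def _reference_sequence(seed: int, length: int = 1182) -> str:
    rng = np.random.default_rng(seed)
    bases = rng.choice(list(_BASES), size=length)
    for pos, base in _FIXED_REF_BASES.items():
        bases[pos - 1] = base
    return "".join(bases)


def fixture_gene_model(seed: int = 1, gene_name: str = "TP53") -> GeneModel:
    """The default TP53-like model: coding exons 2-11 on a 1182-nt CDS.

    The reference is seeded-random except at the constrained sites pinned by
    the fixture catalogue.
    """
    return GeneModel(
        gene_name=gene_name,
        reference_cdna=_reference_sequence(seed),
        exons=tuple(ExonSpan(*row) for row in DEFAULT_TP53_EXONS),
    )


def _resolve_event(model: GeneModel, exon_id: int, item: str | int) -> Variant:
    """Turn a catalogue entry (name or bare position) into a Variant."""
    if isinstance(item, int):
        ref = model.base_at(item)
        v = Variant(item, item, SUBSTITUTION, ref, _TRANSITION[ref], exon_id)
    else:
        v = parse_name(item, model)
    if v.exon_id != exon_id:
        raise VariantError(
            f"catalogue entry {item!r} maps to exon {v.exon_id}, "
            f"expected {exon_id}"
        )
    return v


def _tumor_events(model: GeneModel) -> list[Variant]:
    events = [_resolve_event(model, e, item) for e, item in _TUMOR_NAMED]
    for exon_id, positions in FILLER_POSITIONS.items():
        for pos in positions:
            events.append(_resolve_event(model, exon_id, pos))
    events.sort(key=lambda v: (v.exon_id, v.cdna_start, v.alt_allele))
    return events


def build_fixture_cohort(seed: int = 1) -> FixtureCohort:
    """Build the canonical 50 + 50 sample fixture cohort.

    Tumor side: 48 events over 42 altered samples (six samples carry two
    events in different exons, assigned deterministically by sample index);
    8 samples are identical to the reference.  Healthy side: 30 samples each
    carry one synonymous-style substitution (three per exon); 20 are
    identical to the reference.
    """
    model = fixture_gene_model(seed)
    events = _tumor_events(model)
    assert len(events) == 48

    n_altered = 42
    specs: list[VariantSpec] = []
    for i, v in enumerate(events):
        idx = i if i < n_altered else i - n_altered
        specs.append(VariantSpec(f"T{idx + 1:02d}", v))

    tumor = _materialize("T", 50, specs, model)
    tumor_cat = VariantCatalogue(specs, n_samples=50, seed=seed)

    healthy_specs: list[VariantSpec] = []
    k = 0
    for span in model.exons:
        for pos, alt in _HEALTHY_SITES[span.exon_id]:
            ref = model.base_at(pos)
            alt = alt if alt is not None else _TRANSITION[ref]
            if alt == ref:
                raise VariantError(f"healthy site c.{pos}: alt equals ref")
            k += 1
            healthy_specs.append(
                VariantSpec(
                    f"H{k:02d}",
                    Variant(pos, pos, SUBSTITUTION, ref, alt, span.exon_id),
                )
            )
    healthy = _materialize("H", 50, healthy_specs, model)
    healthy_cat = VariantCatalogue(healthy_specs, n_samples=50, seed=seed)

    return FixtureCohort(model, tumor, healthy, tumor_cat, healthy_cat)


def _materialize(
    prefix: str, n: int, specs: list[VariantSpec], model: GeneModel
) -> list[SampleRecord]:
    by_sample: dict[str, list[Variant]] = {}
    for s in specs:
        by_sample.setdefault(s.sample_id, []).append(s.variant)
    group = "tumor" if prefix == "T" else "healthy"
    samples = []
    for i in range(1, n + 1):
        sid = f"{prefix}{i:02d}"
        exon_seqs = {}
        for span in model.exons:
            seq = model.exon_sequence(span.exon_id)
            for v in by_sample.get(sid, []):
                if v.exon_id == span.exon_id:
                    seq = apply_variant(seq, v, model)
            exon_seqs[span.exon_id] = seq
        samples.append(SampleRecord(sid, group, exon_seqs))
    return samples


def random_cohort(
    n_samples: int,
    per_exon_rate: float = 0.05,
    indel_fraction: float = 0.2,
    seed: int = 0,
    model: GeneModel | None = None,
) -> tuple[list[SampleRecord], VariantCatalogue]:
    """Random cohort with at most one planted variant per sample per exon.

    Variants are placed uniformly in the exon interior (two bases clear of
    each boundary); ``indel_fraction`` of events are indels (half deletions
    of 1-3 nt, half insertions of 1-4 nt), the rest substitutions.  The
    returned catalogue holds the 3'-normalized specs for round-trip checks.
    """
    if not 0 <= per_exon_rate <= 1 or not 0 <= indel_fraction <= 1:
        raise ValueError("rates must lie in [0, 1]")
    if per_exon_rate > 0.5:
        warnings.warn(
            "high per-exon rate: dense planting risks ambiguous "
            "normalization when events interact",
            stacklevel=2,
        )
    if model is None:
        model = fixture_gene_model(seed)
    rng = np.random.default_rng(seed)

    specs: list[VariantSpec] = []
    samples: list[SampleRecord] = []
    for i in range(1, n_samples + 1):
        sid = f"R{i:03d}"
        exon_seqs = {}
        for span in model.exons:
            seq = model.exon_sequence(span.exon_id)
            if rng.random() < per_exon_rate and span.length >= 8:
                v = _random_variant(rng, model, span, indel_fraction)
                seq = apply_variant(seq, v, model)
                specs.append(VariantSpec(sid, normalize_3prime(v, model)))
            exon_seqs[span.exon_id] = seq
        samples.append(SampleRecord(sid, "tumor", exon_seqs))
    return samples, VariantCatalogue(specs, n_samples=n_samples, seed=seed)


def _random_variant(
    rng: np.random.Generator,
    model: GeneModel,
    span: ExonSpan,
    indel_fraction: float,
) -> Variant:
    lo, hi = span.cdna_start + 2, span.cdna_end - 2
    r = rng.random()
    if r >= indel_fraction:  # substitution
        pos = int(rng.integers(lo, hi + 1))
        ref = model.base_at(pos)
        alt = rng.choice([b for b in _BASES if b != ref])
        return Variant(pos, pos, SUBSTITUTION, ref, str(alt), span.exon_id)
    if r < indel_fraction / 2:  # deletion of 1-3 nt
        length = int(rng.integers(1, 4))
        pos = int(rng.integers(lo, hi - length + 2))
        ref = model.reference_cdna[pos - 1 : pos - 1 + length]
        return Variant(pos, pos + length - 1, DELETION, ref, "", span.exon_id)
    # insertion of 1-4 nt after an anchor base
    anchor = int(rng.integers(lo, hi))
    ins = "".join(rng.choice(list(_BASES), size=int(rng.integers(1, 5))))
    return Variant(anchor, anchor + 1, INSERTION, "", ins, span.exon_id)
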