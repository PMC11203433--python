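"""Synthetic reference/cohort generator: determinism, constraints, spike-ins."""

import pytest

from exoncompare import (
    Variant,
    VariantError,
    apply_variant,
    build_fixture_cohort,
    compare_cohort,
    fixture_gene_model,
    parse_name,
    random_cohort,
)


def test_reference_respects_constrained_sites(model):
    # printed ref alleles
    for pos, base in [(404, "G"), (475, "G"), (487, "T"), (524, "G"),
                      (637, "C"), (742, "C"), (818, "G"), (822, "T"),
                      (844, "C"), (1024, "C"), (80, "C"), (254, "C")]:
        assert model.base_at(pos) == base, pos
    # homopolymer context making c.455delC the 3'-normal single-C loss
    assert model.reference_cdna[452:456] == "CCCA"
    # the 29-nt deletion and the GATA insertion cannot slide 3'
    assert model.base_at(479) != model.base_at(450)
    assert model.base_at(623) != "G"


def test_constrained_sites_are_seed_independent():
    m1, m2 = fixture_gene_model(1), fixture_gene_model(2)
    for pos in (80, 254, 404, 447, 465, 475, 483, 487, 524, 637, 742,
                818, 822, 844, 1024):
        assert m1.base_at(pos) == m2.base_at(pos)
    assert m1.reference_cdna != m2.reference_cdna  # free sites do vary


def test_apply_substitution_changes_exactly_one_base(model):
    v = parse_name("c.404G>T", model)
    ref = model.exon_sequence(5)
    mut = apply_variant(ref, v, model)
    assert len(mut) == len(ref)
    diffs = [i for i, (a, b) in enumerate(zip(ref, mut)) if a != b]
    assert diffs == [404 - 376]  # local 0-based offset of c.404


def test_apply_indels_change_length(model):
    ref = model.exon_sequence(5)
    d = parse_name("c.450_478del29", model)
    assert len(apply_variant(ref, d, model)) == len(ref) - 29
    ins = parse_name("c.622_623insGATA", model)
    ref6 = model.exon_sequence(6)
    assert len(apply_variant(ref6, ins, model)) == len(ref6) + 4


def test_apply_rejects_reference_mismatch(model):
    wrong = Variant(404, 404, "substitution", "A", "T", 5)
    with pytest.raises(VariantError, match="mismatch"):
        apply_variant(model.exon_sequence(5), wrong, model)


def test_fixture_build_is_deterministic():
    a = build_fixture_cohort(seed=3)
    b = build_fixture_cohort(seed=3)
    assert a.model.reference_cdna == b.model.reference_cdna
    for sa, sb in zip(a.tumor + a.healthy, b.tumor + b.healthy):
        assert sa.exon_seqs == sb.exon_seqs
    assert a.tumor_catalogue.to_frame().equals(b.tumor_catalogue.to_frame())


def test_catalogue_layout_is_seed_independent():
    """Changing the seed moves unconstrained bases only: sample assignment,
    positions and kinds are fixed; printed alleles are fixed too."""
    f1 = build_fixture_cohort(seed=1).tumor_catalogue.to_frame()
    f2 = build_fixture_cohort(seed=2).tumor_catalogue.to_frame()
    cols = ["sample_id", "exon_id", "kind", "start", "end"]
    assert f1[cols].equals(f2[cols])
    fixed = f1["name"].isin(["c.404G>T", "c.818G>A", "c.818G>C", "c.844C>T"])
    assert f1.loc[fixed, "name"].equals(f2.loc[fixed, "name"])


def test_fixture_cohort_shape(fixture_cohort):
    assert len(fixture_cohort.tumor) == 50
    assert len(fixture_cohort.healthy) == 50
    assert len(fixture_cohort.tumor_catalogue.specs) == 48
    per_sample_exon = {
        (s.sample_id, s.variant.exon_id)
        for s in fixture_cohort.tumor_catalogue.specs
    }
    assert len(per_sample_exon) == 48  # at most one event per sample per exon
    doubles = {
        sid
        for sid in {s.sample_id for s in fixture_cohort.tumor_catalogue.specs}
        if sum(1 for s in fixture_cohort.tumor_catalogue.specs
               if s.sample_id == sid) == 2
    }
    assert len(doubles) == 6


def test_healthy_side_three_synonymous_sites_per_exon(fixture_cohort, model):
    cat = fixture_cohort.healthy_catalogue
    by_exon: dict[int, int] = {}
    for s in cat.specs:
        assert s.variant.kind == "substitution"
        by_exon[s.variant.exon_id] = by_exon.get(s.variant.exon_id, 0) + 1
    assert by_exon == {e.exon_id: 3 for e in model.exons}
    names = {s.variant.name for s in cat.specs}
    assert {"c.447C>G", "c.465C>G", "c.483C>G", "c.822T>A"} <= names


def test_healthy_calls_recover_planted_synonymous_set(
    fixture_cohort, healthy_summary
):
    called = sorted((sid, v) for sid, v in healthy_summary.variants)
    planted = sorted(
        (s.sample_id, s.variant) for s in fixture_cohort.healthy_catalogue.specs
    )
    assert called == planted
    assert healthy_summary.n_altered == 30


def test_fixture_write_layout(tmp_path, fixture_cohort):
    fixture_cohort.write(tmp_path / "fx")
    tumor_files = sorted((tmp_path / "fx" / "tumor").glob("*.fasta"))
    healthy_files = sorted((tmp_path / "fx" / "healthy").glob("*.fasta"))
    assert len(tumor_files) == 50 and len(healthy_files) == 50
    assert (tmp_path / "fx" / "model.tsv").exists()
    assert (tmp_path / "fx" / "catalogue_tumor.tsv").exists()


def test_random_cohort_empty_and_all_substitutions(model):
    samples, cat = random_cohort(0, seed=5, model=model)
    assert samples == [] and cat.specs == []
    samples, cat = random_cohort(15, per_exon_rate=0.3, indel_fraction=0.0,
                                 seed=5, model=model)
    assert cat.specs and all(s.variant.kind == "substitution" for s in cat.specs)


def test_random_cohort_rate_validation_and_warning(model):
    with pytest.raises(ValueError):
        random_cohort(2, per_exon_rate=1.5, model=model)
    with pytest.warns(UserWarning, match="per-exon rate"):
        random_cohort(1, per_exon_rate=0.9, seed=2, model=model)


def test_random_cohort_with_indels_round_trips(model):
    samples, cat = random_cohort(
        15, per_exon_rate=0.25, indel_fraction=0.5, seed=13, model=model
    )
    summary = compare_cohort(samples, model)
    called = sorted((sid, v) for sid, v in summary.variants)
    planted = sorted((s.sample_id, s.variant) for s in cat.specs)
    assert called == planted
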