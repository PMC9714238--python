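"""Data model, panels, genotype-table parsing, and serialization."""

import io

import pytest

from ystrkit.io import (
    GenotypeFormatError,
    TableDialect,
    load_genotype_table,
    read_distance_matrix,
    samples_from_json,
    samples_to_json,
    write_distance_matrix,
    write_genotype_table,
)
from ystrkit.markers import (
    AlleleValidationError,
    BUILTIN_PANELS,
    DYS389_DELTA,
    Haplotype,
    MH9,
    NETWORK_LOCI_14,
    PanelError,
    PPY12,
    restrict_to_panel,
    SWGDAM11,
    to_repeat_vector,
    YFILER17,
)
from ystrkit.stats import haplotype_frequencies

from conftest import make_hap, make_sample


class TestPanels:
    def test_builtin_panels_nest(self):
        assert MH9.issubset(SWGDAM11)
        assert SWGDAM11.issubset(PPY12)
        assert PPY12.issubset(YFILER17)

    def test_slot_counts(self):
        # DYS385 contributes two allele slots at every level
        assert [p.n_slots for p in (MH9, SWGDAM11, PPY12, YFILER17)] == [9, 11, 12, 17]

    def test_only_dys385_is_duplicated(self):
        for panel in BUILTIN_PANELS.values():
            for locus in panel.loci:
                assert (locus.copy_number == 2) == (locus.name == "DYS385")


class TestHaplotype:
    def test_dys385_pair_canonicalized(self):
        h1 = make_hap("s1", DYS385=(17.0, 14.0))
        h2 = make_hap("s2", DYS385=(14.0, 17.0))
        assert h1.alleles["DYS385"] == h2.alleles["DYS385"] == (14.0, 17.0)

    def test_dys385_single_peak_duplicated(self):
        h = make_hap("s1", DYS385=14.0)
        assert h.alleles["DYS385"] == (14.0, 14.0)

    def test_dys389_order_enforced(self):
        with pytest.raises(AlleleValidationError):
            make_hap("bad", DYS389I=30.0, DYS389II=13.0)

    @pytest.mark.parametrize("value", [4.0, 61.0, 17.5, "x"])
    def test_invalid_alleles_rejected(self, value):
        with pytest.raises(AlleleValidationError):
            make_hap("bad", DYS19=value)

    def test_microvariant_kept_exact(self):
        h = make_hap("s1", DYS458=17.2)
        assert h.alleles["DYS458"] == 17.2


class TestRestriction:
    def test_projection_to_mh9(self):
        s = make_sample("P", [make_hap("a"), make_hap("b")])
        r = restrict_to_panel(s, MH9)
        assert r.n == s.n
        assert set(r.haplotypes[0].alleles) == set(MH9.locus_names)

    def test_identity_restriction(self):
        s = make_sample("P", [make_hap("a")])
        r = restrict_to_panel(s, YFILER17)
        assert r.haplotypes[0].alleles == s.haplotypes[0].alleles

    def test_missing_target_locus_named(self):
        s = make_sample("P", [make_hap("a")])
        mh9_only = restrict_to_panel(s, MH9)
        with pytest.raises(PanelError, match="DYS448"):
            restrict_to_panel(mh9_only, YFILER17)

    def test_resolution_collapses_dys458_difference(self):
        # distinct at Yfiler-17, identical after restriction to PPY-12/MH-9
        s = make_sample("P", [make_hap("a", DYS458=16.0), make_hap("b", DYS458=17.0)])
        assert len(haplotype_frequencies(s, YFILER17)) == 2
        assert len(haplotype_frequencies(s, MH9)) == 1

    def test_restriction_never_splits_haplotypes(self, small_cohort):
        for s in small_cohort:
            th = [
                len(haplotype_frequencies(s, p))
                for p in (MH9, SWGDAM11, PPY12, YFILER17)
            ]
            assert th == sorted(th)


class TestRepeatVector:
    def test_dys389_difference_slot(self):
        h = make_hap("s1", DYS389I=13.0, DYS389II=30.0)
        vec = to_repeat_vector(h)
        assert vec[NETWORK_LOCI_14.index(DYS389_DELTA)] == 17.0

    def test_vector_length_is_14(self):
        assert len(to_repeat_vector(make_hap("s1"))) == 14

    def test_equal_haplotypes_equal_vectors(self):
        assert to_repeat_vector(make_hap("a")) == to_repeat_vector(make_hap("b"))

    def test_null_allele_reported_by_locus(self):
        h = make_hap("s1", DYS392=None)
        with pytest.raises(AlleleValidationError, match="DYS392"):
            to_repeat_vector(h)


GENOTYPE_CSV = """SampleID,Population,DYS19,DYS385,DYS389I,DYS389II,DYS390,DYS391,DYS392,DYS393,DYS437,DYS438,DYS439,DYS448,DYS456,DYS458,DYS635,Y_GATA_H4
s1,North,14,"11,14",13,29,24,10,11,12,15,10,12,19,15,16,23,12
s2,North,15,"11,14",13,29,24,10,11,12,15,10,12,19,15,17.2,23,12
s3,South,14,"17,14",13,29,24,10,11,12,15,10,12,19,15,16,23,12
s4,South,14,"14,17",13,29,24,10,11,12,15,10,12,19,15,16,23,12
"""


class TestGenotypeTable:
    def test_partition_by_population_label(self):
        samples = load_genotype_table(io.StringIO(GENOTYPE_CSV))
        assert {s.label: s.n for s in samples} == {"North": 2, "South": 2}

    def test_dys385_order_canonical_on_load(self):
        samples = load_genotype_table(io.StringIO(GENOTYPE_CSV))
        south = next(s for s in samples if s.label == "South")
        pairs = {h.alleles["DYS385"] for h in south.haplotypes}
        assert pairs == {(14.0, 17.0)}

    def test_microvariant_parsed_decimal(self):
        samples = load_genotype_table(io.StringIO(GENOTYPE_CSV))
        north = next(s for s in samples if s.label == "North")
        assert any(h.alleles["DYS458"] == 17.2 for h in north.haplotypes)

    def test_custom_dys385_separator(self):
        text = GENOTYPE_CSV.replace('"11,14"', '"11-14"').replace(
            '"17,14"', '"17-14"'
        ).replace('"14,17"', '"14-17"')
        samples = load_genotype_table(
            io.StringIO(text), dialect=TableDialect(dys385_sep="-")
        )
        south = next(s for s in samples if s.label == "South")
        assert {h.alleles["DYS385"] for h in south.haplotypes} == {(14.0, 17.0)}

    def test_missing_column_named(self):
        import pandas as pd

        df = pd.read_csv(io.StringIO(GENOTYPE_CSV)).drop(columns=["DYS392"])
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        with pytest.raises(GenotypeFormatError, match="DYS392"):
            load_genotype_table(buf)

    def test_out_of_range_allele_names_row(self):
        text = GENOTYPE_CSV.replace("s2,North,15", "s2,North,99")
        with pytest.raises(AlleleValidationError, match="s2"):
            load_genotype_table(io.StringIO(text))

    def test_bad_rows_reported_not_dropped_silently(self):
        text = GENOTYPE_CSV.replace("s2,North,15", "s2,North,99")
        samples = load_genotype_table(io.StringIO(text), errors="report")
        assert [sid for sid, _ in samples.problems] == ["s2"]
        assert sum(s.n for s in samples) == 3

    def test_round_trip_table_model_table(self, small_cohort):
        buf = io.StringIO()
        write_genotype_table(small_cohort, buf)
        buf.seek(0)
        reloaded = load_genotype_table(buf)
        assert samples_to_json(sorted(reloaded, key=lambda s: s.label)) == \
            samples_to_json(sorted(small_cohort, key=lambda s: s.label))

    def test_study_scale_partition(self):
        from ystrkit.simulate import make_study_like_dataset

        samples = make_study_like_dataset(5)
        buf = io.StringIO()
        write_genotype_table(samples, buf)
        buf.seek(0)
        reloaded = load_genotype_table(buf)
        assert sorted(s.n for s in reloaded) == [108, 122, 128, 135]


class TestMatrixAndJson:
    def test_distance_matrix_round_trip(self):
        import numpy as np

        labels = ["A", "B", "C"]
        m = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        buf = io.StringIO()
        write_distance_matrix(labels, m, buf)
        buf.seek(0)
        l2, m2 = read_distance_matrix(buf)
        assert l2 == labels
        assert np.allclose(m, m2)

    def test_empty_matrix_round_trip(self):
        import numpy as np

        buf = io.StringIO()
        write_distance_matrix([], np.zeros((0, 0)), buf)
        buf.seek(0)
        labels, m = read_distance_matrix(buf)
        assert labels == [] and m.shape == (0, 0)

    def test_json_round_trip(self, small_cohort):
        text = samples_to_json(small_cohort)
        back = samples_from_json(text)
        assert samples_to_json(back) == text
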