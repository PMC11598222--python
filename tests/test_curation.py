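"""Structure standardization, duplicate resolution and dataset assembly."""

import math

import pytest

import skinsens as ss
from skinsens.curation import RejectReason


class TestStandardization:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("CC(=O)[O-].[Na+]", "CC(=O)O"),  # counterion stripped, acid neutralized
            ("c1ccccc1C(=O)O.Cl", "O=C(O)c1ccccc1"),  # HCl salt stripped
            ("OCC(O)CO", "OCC(O)CO"),  # already clean
        ],
    )
    def test_salt_stripping_and_neutralization(self, raw, expected):
        out = ss.standardize_structure(raw)
        assert out.ok and out.std_smiles == expected

    @pytest.mark.parametrize(
        "raw, reason",
        [
            ("CCO.CCC", RejectReason.MIXTURE),  # two substantial organic fragments
            ("[Na+].[Cl-]", RejectReason.INORGANIC),
            ("O", RejectReason.INORGANIC),  # no carbon
            ("not a smiles", RejectReason.UNPARSABLE),
            ("", RejectReason.UNPARSABLE),
        ],
    )
    def test_rejections(self, raw, reason):
        out = ss.standardize_structure(raw)
        assert not out.ok and out.reason == reason

    def test_large_organic_cap(self):
        polymer = "C" * 120
        assert ss.standardize_structure(polymer).reason == RejectReason.LARGE_ORGANIC
        assert ss.standardize_structure(polymer, max_heavy_atoms=200).ok

    def test_quaternary_nitrogen_stays_charged(self):
        out = ss.standardize_structure("C[N+](C)(C)C.[Cl-]")
        assert out.ok and "+" in out.std_smiles

    def test_idempotent(self):
        for raw in ("CC(=O)[O-].[Na+]", "c1ccc(C=O)cc1", "CCN.Cl"):
            first = ss.standardize_structure(raw)
            again = ss.standardize_structure(first.std_smiles)
            assert again.std_smiles == first.std_smiles

    def test_smiles_order_invariance(self):
        assert (
            ss.standardize_structure("CCO").std_smiles
            == ss.standardize_structure("OCC").std_smiles
        )


def _rec(casrn, smiles, outcome, scheme="WES"):
    rec = ss.CompoundRecord(casrn=casrn, raw_smiles=smiles, outcomes={scheme: outcome})
    rec.std_smiles = ss.standardize_structure(smiles).std_smiles
    return rec


class TestDuplicateResolution:
    def test_concordant_collapsed(self):
        recs = [_rec("1", "CCO", "sensitizer"), _rec("2", "OCC", "sensitizer")]
        kept, log = ss.resolve_duplicates(recs, "WES")
        assert len(kept) == 1
        assert log == [("2", "merged", "concordant_duplicate")]

    def test_discordant_removed_entirely(self):
        recs = [_rec("1", "CCO", "sensitizer"), _rec("2", "OCC", "NC")]
        kept, log = ss.resolve_duplicates(recs, "WES")
        assert kept == []
        assert {r for _, _, r in log} == {"discordant"}

    def test_distinct_structures_untouched(self):
        recs = [_rec("1", "CCO", "NC"), _rec("2", "CCCO", "sensitizer")]
        kept, _ = ss.resolve_duplicates(recs, "WES")
        assert {r.casrn for r in kept} == {"1", "2"}

    def test_potency_level_distinguishes_1a_1b(self):
        recs = [_rec("1", "CCO", "1A"), _rec("2", "OCC", "1B")]
        hazard_kept, _ = ss.resolve_duplicates(recs, "WES", level="hazard")
        potency_kept, _ = ss.resolve_duplicates(recs, "WES", level="potency")
        assert len(hazard_kept) == 1  # both sensitizers from a hazard view
        assert potency_kept == []  # conflicting potency classes

    def test_unknown_scheme_named_in_error(self):
        with pytest.raises(ValueError, match="BOGUS"):
            ss.resolve_duplicates([_rec("1", "CCO", "NC")], "BOGUS")


class TestAssembly:
    def test_binary_mapping_and_drops(self):
        recs = [
            _rec("A", "CCO", "sensitizer"),
            _rec("B", "CCCO", "NC"),
            _rec("C", "CCCCO", "unavailable"),
            _rec("D", "CCCCCO", "1A"),
            _rec("E", "CCCCCCO", "1B"),
        ]
        ds = ss.assemble_binary(recs, "WES")
        labels = dict(ds.items)
        assert labels[ss.standardize_structure("CCO").std_smiles] == 1
        assert labels[ss.standardize_structure("CCCO").std_smiles] == 0
        # potency labels 1A and 1B are both hazards
        assert labels[ss.standardize_structure("CCCCCO").std_smiles] == 1
        assert labels[ss.standardize_structure("CCCCCCO").std_smiles] == 1
        assert ("C", "dropped", "no_outcome") in ds.log

    def test_empty_dataset_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            ss.assemble_binary([_rec("A", "CCO", "unavailable")], "WES")

    def test_multiclass_mapping(self):
        recs = [_rec("A", "CCO", "1A"), _rec("B", "CCCO", "1B"), _rec("C", "CCCCO", "NC")]
        ds = ss.assemble_multiclass(recs, "WES")
        assert sorted(ds.labels) == [0, 1, 2]
        assert sum(ds.class_counts().values()) == len(ds.items)

    def test_multiclass_drops_hazard_only_outcome(self):
        recs = [_rec("A", "CCO", "sensitizer"), _rec("B", "CCCO", "NC")]
        ds = ss.assemble_multiclass(recs, "WES")
        assert len(ds.items) == 1 and ds.log[0][0] == "A"

    def test_conservation_and_order_invariance(self):
        recs = [
            _rec(str(i), smi, out)
            for i, (smi, out) in enumerate(
                [("CCO", "1A"), ("CCCO", "NC"), ("CCCCO", "unavailable"),
                 ("CCCCCO", "1B"), ("CCCCCCO", "NC")]
            )
        ]
        ds = ss.assemble_binary(recs, "WES")
        assert len(recs) == len(ds.items) + len(ds.log)
        ds_rev = ss.assemble_binary(recs[::-1], "WES")
        assert ds.items == ds_rev.items


class TestContinuous:
    def _dose_rec(self, casrn, smiles, dsa):
        rec = ss.CompoundRecord(casrn=casrn, raw_smiles=smiles, dsa=dsa)
        rec.std_smiles = ss.standardize_structure(smiles).std_smiles
        return rec

    def test_median_then_log10(self):
        recs = [self._dose_rec(str(i), "CCO", v) for i, v in enumerate([10, 100, 1000])]
        ds = ss.assemble_continuous(recs, "DSA")
        assert ds.items[0][1] == pytest.approx(2.0)

    def test_log10_of_unit_dose_is_zero(self):
        ds = ss.assemble_continuous([self._dose_rec("1", "CCO", 1.0)], "DSA")
        assert ds.items[0][1] == 0.0

    def test_even_count_median_is_midpoint(self):
        # median of [10, 1000] is 505; log10(505) computed independently
        recs = [self._dose_rec("1", "CCO", 10.0), self._dose_rec("2", "CCO", 1000.0)]
        ds = ss.assemble_continuous(recs, "DSA")
        assert ds.items[0][1] == pytest.approx(math.log10(505), abs=1e-12)

    def test_nonpositive_dose_dropped(self):
        recs = [self._dose_rec("1", "CCO", -5.0), self._dose_rec("2", "CCCO", 10.0)]
        ds = ss.assemble_continuous(recs, "DSA")
        assert len(ds.items) == 1
        assert ("1", "dropped", "nonpositive_dose") in ds.log

    def test_conservation(self):
        recs = [
            self._dose_rec("1", "CCO", 10.0),
            self._dose_rec("2", "CCO", 20.0),  # merged into the same structure
            self._dose_rec("3", "CCCO", None),
        ]
        ds = ss.assemble_continuous(recs, "DSA")
        assert len(ds.items) == 1 and len(ds.log) == 1


def test_full_curation_idempotent(study_records):
    """Running curation twice on the same raw table gives identical output."""
    records, _ = study_records
    def run():
        kept, _ = ss.standardize_records(records)
        deduped, _ = ss.resolve_duplicates(kept, "WES")
        return ss.assemble_binary(deduped, "WES")
    a, b = run(), run()
    assert a.items == b.items and a.log == b.log
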