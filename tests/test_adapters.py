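import json
import random

import pytest

from morbidgenes.adapters import (
    ClinvarVariantRecord,
    GenccSubmission,
    HgmdVariantRecord,
    OmimAssociation,
    PanelAppGeneEntry,
    PanelAppInstance,
    Source,
    SysnddEntry,
    clinvar_criterion,
    gencc_criterion,
    hgmd_criterion,
    omim_criterion,
    panelapp_criterion,
    parse_clinvar,
    parse_gencc,
    parse_hgmd,
    parse_omim,
    parse_panelapp,
    parse_sysndd,
    sysndd_criterion,
)
from morbidgenes.errors import FormatError

from _bruteforce import all_verdicts


def _clinvar(n, sig="Pathogenic", vtype="single nucleotide variant", origin="germline", start=1):
    return [
        ClinvarVariantRecord(start + i, "G1", vtype, sig, origin, "GRCh38") for i in range(n)
    ]


def _hgmd(n, klass="DM"):
    return [HgmdVariantRecord("G1", klass, f"CM{i:06d}") for i in range(n)]


# ---------------------------------------------------------------------------
# OMIM


class TestOmim:
    def test_parse_single_entry(self, tmp_path):
        p = tmp_path / "omim.tsv"
        p.write_text(
            "Gene Symbols\tMIM Number\tPhenotypes\n"
            "SHH\t600725\tHoloprosencephaly 5, 609637 (3)\n"
        )
        (assoc,) = parse_omim(p)
        assert assoc == OmimAssociation("SHH", 600725, "Holoprosencephaly 5", 3)

    def test_parse_empty_cell_and_split(self, tmp_path):
        p = tmp_path / "omim.tsv"
        p.write_text(
            "Gene Symbols\tMIM Number\tPhenotypes\n"
            "A1\t600001\t\n"
            "B1\t600002\tDisease 1, 610001 (3); Disease 2, 610002 (4)\n"
        )
        out = parse_omim(p)
        assert [a.gene_symbol for a in out] == ["B1", "B1"]
        assert [a.mapping_key for a in out] == [3, 4]

    def test_malformed_mapping_key_kept_with_null(self, tmp_path):
        p = tmp_path / "omim.tsv"
        p.write_text("Gene Symbols\tMIM Number\tPhenotypes\nA1\t600001\tOdd entry no key\n")
        (assoc,) = parse_omim(p)
        assert assoc.mapping_key is None
        assert assoc.phenotype_label == "Odd entry no key"

    @pytest.mark.parametrize(
        "label, key, met",
        [
            ("Holoprosencephaly 5", 3, True),
            ("Some disorder", 4, True),
            ("{Asthma, susceptibility to}", 3, False),  # susceptibility
            ("?Neurodevelopmental disorder", 3, False),  # provisional
            ("[Blood group, Junior system]", 3, False),  # nondisease trait
            ("Linkage-only phenotype", 2, False),  # mapping key below 3
            ("No key at all", None, False),
        ],
    )
    def test_criterion(self, label, key, met):
        ev = omim_criterion([OmimAssociation("G1", 600001, label, key)])
        assert ev.source is Source.OMIM
        assert ev.met is met
        assert ev.count == (1 if met else 0)

    def test_empty_associations(self):
        ev = omim_criterion([])
        assert (ev.met, ev.count) == (False, 0)

    def test_mapping_keys_configurable(self):
        assoc = OmimAssociation("G1", 600001, "Linkage phenotype", 2)
        assert omim_criterion([assoc], mapping_keys=frozenset({2, 3, 4})).met is True


# ---------------------------------------------------------------------------
# ClinVar


class TestClinvar:
    def test_parse_dedups_assemblies(self, tmp_path):
        p = tmp_path / "cv.tsv"
        p.write_text(
            "VariationID\tType\tGeneSymbol\tClinicalSignificance\tOriginSimple\tAssembly\n"
            "7\tsingle nucleotide variant\tG1\tPathogenic\tgermline\tGRCh37\n"
            "7\tsingle nucleotide variant\tG1\tPathogenic\tgermline\tGRCh38\n"
        )
        assert len(parse_clinvar(p)) == 1

    def test_parse_expands_multigene_cells(self, tmp_path):
        p = tmp_path / "cv.tsv"
        p.write_text(
            "VariationID\tType\tGeneSymbol\tClinicalSignificance\tOriginSimple\tAssembly\n"
            "8\tsingle nucleotide variant\tA;B\tPathogenic\tgermline\tGRCh38\n"
        )
        out = parse_clinvar(p)
        assert sorted(r.gene_symbol for r in out) == ["A", "B"]

    def test_parse_skips_non_integer_id(self, tmp_path):
        p = tmp_path / "cv.tsv"
        p.write_text(
            "VariationID\tType\tGeneSymbol\tClinicalSignificance\tOriginSimple\tAssembly\n"
            "oops\tsingle nucleotide variant\tG1\tPathogenic\tgermline\tGRCh38\n"
        )
        assert parse_clinvar(p) == []

    def test_parse_empty_file(self, tmp_path):
        p = tmp_path / "cv.tsv"
        p.write_text("VariationID\tType\tGeneSymbol\tClinicalSignificance\tOriginSimple\tAssembly\n")
        assert parse_clinvar(p) == []

    def test_four_pathogenic_snvs_met(self):
        ev = clinvar_criterion(_clinvar(4))
        assert (ev.met, ev.count) == (True, 4)

    def test_cnv_excluded_from_count(self):
        records = _clinvar(3) + _clinvar(1, vtype="copy number loss", start=100)
        ev = clinvar_criterion(records)
        assert (ev.met, ev.count) == (False, 3)

    def test_somatic_likely_pathogenic_counts(self):
        ev = clinvar_criterion(_clinvar(4, sig="Likely pathogenic", origin="somatic"))
        assert ev.met is True

    def test_conflicting_never_counts(self):
        ev = clinvar_criterion(_clinvar(4, sig="Conflicting interpretations of pathogenicity"))
        assert (ev.met, ev.count) == (False, 0)

    def test_combined_significance_counts(self):
        ev = clinvar_criterion(_clinvar(4, sig="Pathogenic/Likely pathogenic"))
        assert ev.met is True

    def test_benign_does_not_count(self):
        assert clinvar_criterion(_clinvar(5, sig="Benign")).count == 0

    def test_threshold_sharp_at_four(self):
        assert clinvar_criterion(_clinvar(4)).met is True
        assert clinvar_criterion(_clinvar(3)).met is False


# ---------------------------------------------------------------------------
# HGMD


class TestHgmd:
    def test_parse_and_skip_unknown_class(self, tmp_path):
        p = tmp_path / "hgmd.tsv"
        p.write_text(
            "gene\tvariant_id\tvariant_class\n"
            "G1\tCM000001\tDM\nG1\tCM000002\tXX\nG1\tCM000003\tDM?\n"
        )
        out = parse_hgmd(p)
        assert [r.variant_class for r in out] == ["DM", "DM?"]

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "hgmd.tsv"
        p.write_text("gene\tvariant_class\nG1\tDM\n")
        with pytest.raises(FormatError, match="variant_id"):
            parse_hgmd(p)

    def test_dm_questionable_excluded_by_default(self):
        ev = hgmd_criterion(_hgmd(3) + _hgmd(2, "DM?"))
        assert (ev.met, ev.count) == (False, 3)

    def test_dm_questionable_admissible_via_config(self):
        ev = hgmd_criterion(_hgmd(3) + _hgmd(2, "DM?"), pathogenic_classes=frozenset({"DM", "DM?"}))
        assert (ev.met, ev.count) == (True, 5)

    def test_threshold_sharp_at_four(self):
        assert hgmd_criterion(_hgmd(4)).met is True
        assert hgmd_criterion(_hgmd(3)).met is False

    def test_empty(self):
        assert hgmd_criterion([]) == hgmd_criterion([])
        assert hgmd_criterion([]).count == 0


# ---------------------------------------------------------------------------
# PanelApp


class TestPanelApp:
    def test_parse_panel_dir(self, tmp_path):
        d = tmp_path / "pa"
        d.mkdir()
        (d / "panel_1.json").write_text(
            json.dumps(
                {
                    "id": 1,
                    "name": "Demo panel",
                    "genes": [
                        {"entity_name": "A", "confidence_level": "3"},
                        {"entity_name": "B", "confidence_level": "1"},
                    ],
                }
            )
        )
        out = parse_panelapp(d, PanelAppInstance.GENOMICS_ENGLAND)
        assert len(out) == 2
        assert out[0].confidence_level == 3  # coerced from string

    def test_empty_dir(self, tmp_path):
        d = tmp_path / "pa"
        d.mkdir()
        assert parse_panelapp(d, PanelAppInstance.AUSTRALIA) == []

    def test_bad_json_names_file(self, tmp_path):
        d = tmp_path / "pa"
        d.mkdir()
        (d / "broken.json").write_text("{not json")
        with pytest.raises(FormatError, match="broken.json"):
            parse_panelapp(d, PanelAppInstance.AUSTRALIA)

    @pytest.mark.parametrize(
        "levels, instances, met",
        [
            ([3], [PanelAppInstance.GENOMICS_ENGLAND], True),
            ([1, 2], [PanelAppInstance.GENOMICS_ENGLAND] * 2, False),
            ([4], [PanelAppInstance.AUSTRALIA], True),  # green only in Australia
            ([2], [PanelAppInstance.AUSTRALIA], False),
        ],
    )
    def test_criterion(self, levels, instances, met):
        entries = [
            PanelAppGeneEntry(inst, 1, "P", "G1", lvl) for lvl, inst in zip(levels, instances)
        ]
        ev = panelapp_criterion(entries)
        assert ev.met is met

    def test_level_threshold_sharp_at_three(self):
        e2 = PanelAppGeneEntry(PanelAppInstance.GENOMICS_ENGLAND, 1, "P", "G1", 2)
        e3 = PanelAppGeneEntry(PanelAppInstance.GENOMICS_ENGLAND, 1, "P", "G1", 3)
        assert panelapp_criterion([e2]).met is False
        assert panelapp_criterion([e3]).met is True


# ---------------------------------------------------------------------------
# GenCC / SysNDD


class TestGenccSysndd:
    def test_gencc_definitive_met(self):
        ev = gencc_criterion([GenccSubmission("G1", "HGNC:1", "dis", "Definitive", "lab")])
        assert (ev.met, ev.count) == (True, 1)

    def test_gencc_lower_tiers_not_met(self):
        subs = [
            GenccSubmission("G1", "HGNC:1", "dis", "Strong", "lab"),
            GenccSubmission("G1", "HGNC:1", "dis", "Moderate", "lab"),
        ]
        assert gencc_criterion(subs).met is False

    def test_gencc_parse_missing_column(self, tmp_path):
        p = tmp_path / "gencc.tsv"
        p.write_text("gene_symbol\thgnc_id\tdisease\tsubmitter\nG1\tHGNC:1\td\tlab\n")
        with pytest.raises(FormatError, match="classification"):
            parse_gencc(p)

    def test_gencc_parse_roundtrip(self, tmp_path):
        p = tmp_path / "gencc.tsv"
        p.write_text(
            "gene_symbol\thgnc_id\tdisease\tclassification\tsubmitter\n"
            "G1\t\tdis\tDefinitive\tlab\n"
        )
        (sub,) = parse_gencc(p)
        assert sub.hgnc_id is None  # empty cell

    @pytest.mark.parametrize(
        "status, met", [("Definitive", True), ("definite", True), ("Limited", False)]
    )
    def test_sysndd_status(self, status, met):
        assert sysndd_criterion([SysnddEntry("G1", status, "NDD")]).met is met

    def test_sysndd_parse(self, tmp_path):
        p = tmp_path / "sysndd.tsv"
        p.write_text("symbol\tstatus\tdisease\nG1\tDefinitive\tNDD\n")
        (entry,) = parse_sysndd(p)
        assert entry.status == "Definitive"

    def test_absent_gene_not_met(self):
        assert sysndd_criterion([]).met is False
        assert gencc_criterion([]).met is False


# ---------------------------------------------------------------------------
# cross-cutting properties


class TestCriterionProperties:
    def test_order_invariance(self):
        """Criteria are pure functions of the record multiset."""
        rng = random.Random(0)
        records = _clinvar(3) + _clinvar(2, vtype="copy number gain", start=50) + _clinvar(2, start=60)
        base = clinvar_criterion(records)
        hgmd_records = _hgmd(4) + _hgmd(3, "DM?")
        hgmd_base = hgmd_criterion(hgmd_records)
        for _ in range(10):
            rng.shuffle(records)
            rng.shuffle(hgmd_records)
            assert clinvar_criterion(records) == base
            assert hgmd_criterion(hgmd_records) == hgmd_base

    def test_bruteforce_oracle_matches_adapters(self, universe):
        """Independent row-filtering over the snapshot files reproduces every
        adapter verdict on a full universe."""
        from morbidgenes.build import harmonize_records, _parse_all
        from morbidgenes.adapters import criterion_for
        from morbidgenes.harmonizer import load_symbol_table
        from morbidgenes.scoring import ALL_SOURCES

        table = load_symbol_table(universe["dir"] / "hgnc.tsv")
        grouped = harmonize_records(_parse_all(universe["config"]), table)
        expected = all_verdicts(universe["dir"])
        for hgnc_id, by_source in grouped.items():
            for source in ALL_SOURCES:
                ev = criterion_for(source, by_source[source])
                want = expected[source].get(hgnc_id, (False, 0))
                assert (ev.met, ev.count) == want, (hgnc_id, source)
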