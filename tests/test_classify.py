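"""Two-peptide rule, presence partition, BMSP architecture and categories."""

from __future__ import annotations

import pytest

from conftest import record
from shellome.classify import (
    CATEGORY_CONSERVED,
    CATEGORY_LCR,
    CATEGORY_UNCHARACTERIZED,
    DEFAULT_CATALOG,
    PRESENCE_CLASSES,
    SUB_ENZYME,
    SUB_NONE,
    SUB_POLYSACCHARIDE,
    SUB_PROTEASE_INHIBITOR,
    apply_peptide_rule,
    category_counts,
    classify_protein,
    detect_bmsp_architecture,
    presence_class,
    presence_partition,
)
from shellome.lcr import LCRegion
from shellome.model import DomainHit, EvidenceTable, ShellomeError

E = ("ASM_2bl", "ASM_3bl", "AIM_2bl", "AIM_3bl")


def evidence(entries: dict) -> EvidenceTable:
    return EvidenceTable(entries=entries, extract_ids=E)


def region(pid="p", start=1, end=20, kind="single", residues="T"):
    label = "".join(sorted(residues)) + "-rich"
    return LCRegion(pid, start, end, kind, residues, label)


def hit(accession, start=1, end=60, pid="p"):
    return DomainHit(pid, "Pfam", accession, accession, start, end)


class TestPeptideRule:
    def test_accepts_multi_peptide_protein(self):
        assert apply_peptide_rule(evidence({("p1", "ASM_2bl"): 3})) == {"p1"}

    def test_single_peptide_rejected(self):
        # "more than one" means at least two
        assert apply_peptide_rule(evidence({("p2", "ASM_2bl"): 1})) == set()

    def test_counts_totalled_across_extracts(self):
        table = evidence({("p3", "ASM_2bl"): 1, ("p3", "AIM_3bl"): 1})
        assert apply_peptide_rule(table) == {"p3"}
        assert table.presence("p3") == {"ASM_2bl", "AIM_3bl"}


class TestPresencePartition:
    @pytest.mark.parametrize("present, expected", [
        (set(E), "common_to_four"),
        ({"ASM_2bl", "ASM_3bl", "AIM_2bl"}, "in_three"),
        ({"ASM_2bl"}, "ASM_specific"),
        ({"ASM_2bl", "ASM_3bl"}, "ASM_specific"),
        ({"AIM_2bl", "AIM_3bl"}, "AIM_specific"),
        ({"ASM_2bl", "AIM_2bl"}, "other"),
        (set(), "other"),
    ])
    def test_class_assignment(self, present, expected):
        assert presence_class(present, E) == expected

    def test_unknown_extract_rejected(self):
        with pytest.raises(ShellomeError, match="unknown extract"):
            presence_class({"XYZ"}, E)

    def test_cohort_counts_match_hand_enumeration_and_sum(self):
        presences = {
            "a": set(E), "b": set(E),                       # 2 common
            "c": {"ASM_2bl", "ASM_3bl", "AIM_2bl"},          # 1 in_three
            "d": {"ASM_2bl"}, "e": {"ASM_3bl"},              # 2 ASM-specific
            "f": {"AIM_2bl", "AIM_3bl"}, "g": {"AIM_3bl"},   # 2 AIM-specific
            "h": {"AIM_2bl"},                                # 1 AIM-specific
            "i": {"ASM_2bl", "AIM_3bl"},                     # 1 other
            "j": {"ASM_3bl", "AIM_2bl"},                     # 1 other
        }
        counts = presence_partition(presences, E)
        assert counts == {"common_to_four": 2, "in_three": 1, "ASM_specific": 2,
                          "AIM_specific": 3, "other": 2}
        assert sum(counts.values()) == len(presences)
        assert set(counts) == set(PRESENCE_CLASSES)


VWA, CHBD, OTHER = "PF00092", "PF01607", "PF00150"


class TestBmspArchitecture:
    @pytest.mark.parametrize("accessions, expected", [
        ([VWA, VWA, VWA, VWA, CHBD], (4, 1, True)),
        ([VWA, VWA, CHBD, CHBD], (2, 2, True)),
        ([CHBD, VWA, VWA], (0, 1, False)),       # wrong order
        ([VWA, CHBD], (1, 1, False)),            # "more than one" VWA required
        ([VWA, VWA, OTHER, CHBD], (2, 0, False)),  # intervening catalogued domain
        ([VWA, VWA], (2, 0, False)),             # no ChBD at all
        ([], (0, 0, False)),
    ])
    def test_architecture_sweep(self, accessions, expected):
        domains = [hit(a, start=10 + 100 * i, end=70 + 100 * i)
                   for i, a in enumerate(accessions)]
        assert detect_bmsp_architecture(domains) == expected

    def test_uncatalogued_domains_are_transparent(self):
        domains = [hit(VWA, 10, 70), hit("PF99999", 80, 120),
                   hit(VWA, 130, 190), hit(CHBD, 200, 260)]
        assert detect_bmsp_architecture(domains) == (2, 1, True)

    def test_order_comes_from_coordinates_not_input_order(self):
        domains = [hit(CHBD, 300, 360), hit(VWA, 10, 70), hit(VWA, 100, 160)]
        assert detect_bmsp_architecture(domains)[2] is True


class TestClassifyProtein:
    REC = record("A" * 50, "p")

    def test_domain_protein_keeps_lcr_labels(self):
        c = classify_protein(self.REC, [hit("PF01607")], [region()])
        assert c.category == CATEGORY_CONSERVED
        assert c.subcategory == SUB_POLYSACCHARIDE
        assert c.lcr_labels_single == ("T-rich",)

    def test_lcr_only_protein(self):
        c = classify_protein(self.REC, [], [region(residues="G")])
        assert (c.category, c.subcategory) == (CATEGORY_LCR, SUB_NONE)

    def test_uncharacterized(self):
        c = classify_protein(self.REC, [], [])
        assert c.category == CATEGORY_UNCHARACTERIZED

    def test_uncatalogued_domain_does_not_make_conserved(self):
        c = classify_protein(self.REC, [hit("PF99999")], [])
        assert c.category == CATEGORY_UNCHARACTERIZED

    def test_subcategory_precedence(self):
        c = classify_protein(self.REC, [hit("PF00014"), hit("PF00150", 100, 160)], [])
        assert c.subcategory == SUB_ENZYME
        c2 = classify_protein(self.REC, [hit("PF00014"), hit("PF01607", 100, 160)], [])
        assert c2.subcategory == SUB_POLYSACCHARIDE

    def test_invariant_to_input_order(self):
        domains = [hit("PF00092", 10, 70), hit("PF01607", 100, 160)]
        lcrs = [region(start=1, end=20), region(start=30, end=50, residues="G")]
        a = classify_protein(self.REC, domains, lcrs)
        b = classify_protein(self.REC, list(reversed(domains)), list(reversed(lcrs)))
        assert a == b

    def test_category_counts_sum_and_exhaust(self):
        recs = [record("A" * 30, f"p{i}") for i in range(6)]
        cls = [
            classify_protein(recs[0], [hit("PF01607", pid="p0")], []),
            classify_protein(recs[1], [hit("PF00264", pid="p1")], [region("p1")]),
            classify_protein(recs[2], [], [region("p2")]),
            classify_protein(recs[3], [], [region("p3", kind="pair", residues="GS")]),
            classify_protein(recs[4], [], []),
            classify_protein(recs[5], [hit("PF99999", pid="p5")], []),
        ]
        counts = category_counts(cls)
        assert counts == {CATEGORY_CONSERVED: 2, CATEGORY_LCR: 2,
                          CATEGORY_UNCHARACTERIZED: 2}
        assert sum(counts.values()) == len(cls)

    def test_catalog_is_configuration(self):
        custom = dict(DEFAULT_CATALOG)
        custom["PF99999"] = SUB_PROTEASE_INHIBITOR
        c = classify_protein(self.REC, [hit("PF99999")], [], catalog=custom)
        assert (c.category, c.subcategory) == (CATEGORY_CONSERVED, SUB_PROTEASE_INHIBITOR)
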