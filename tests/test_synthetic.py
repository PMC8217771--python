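"""Generator determinism, clean-background guarantee and planted truth."""

from __future__ import annotations

import pytest

from shellome import io as sio
from shellome.classify import apply_peptide_rule, presence_class
from shellome.ella import normalize_plate
from shellome.lcr import detect_lcrs, find_homopolymer_runs
from shellome.model import ShellomeError
from shellome.phospho import overlay_track
from shellome.synthetic import (
    EVIDENCE_TEMPLATES,
    PlantedLCR,
    SynthSpec,
    gen_evidence,
    gen_phospho,
    gen_plate,
    gen_protein_set,
)


def fasta_bytes(records) -> bytes:
    import tempfile, pathlib
    with tempfile.TemporaryDirectory() as d:
        p = pathlib.Path(d) / "x.faa"
        sio.write_fasta(records, p)
        return p.read_bytes()


class TestProteinSet:
    def test_purity_one_plant_is_literal(self):
        spec = SynthSpec(n_proteins=3, planted_lcrs=(PlantedLCR("single", "T", 20),), seed=1)
        records, truth = gen_protein_set(spec)
        for rec in records:
            span = truth[rec.id].lcr_spans[0]
            assert rec.sequence[span.start - 1: span.end] == "T" * 20

    def test_same_seed_gives_identical_fasta_bytes(self):
        spec = SynthSpec(n_proteins=5, planted_lcrs=(PlantedLCR("pair", "GS", 24),), seed=7)
        a, _ = gen_protein_set(spec)
        b, _ = gen_protein_set(spec)
        assert fasta_bytes(a) == fasta_bytes(b)

    def test_clean_background_has_no_detections(self):
        spec = SynthSpec(n_proteins=20, seed=11)
        records, _ = gen_protein_set(spec)
        assert all(detect_lcrs(rec) == [] for rec in records)

    def test_planted_recovery_in_clean_mode(self):
        spec = SynthSpec(
            n_proteins=25,
            planted_lcrs=(PlantedLCR("single", "T", 18), PlantedLCR("pair", "GS", 24)),
            seed=13,
        )
        records, truth = gen_protein_set(spec)
        for rec in records:
            regions = detect_lcrs(rec)
            for span in truth[rec.id].lcr_spans:
                match = [r for r in regions
                         if r.kind == span.kind and r.residues == span.residues]
                assert len(match) == 1
                assert match[0].start <= span.start and match[0].end >= span.end

    def test_polyd_tail_planted_at_c_terminus(self):
        spec = SynthSpec(n_proteins=4, planted_polyd_tail=8, seed=17)
        records, truth = gen_protein_set(spec)
        for rec in records:
            start, end = truth[rec.id].polyd_tail
            assert end == len(rec.sequence)
            runs = find_homopolymer_runs(rec, "D", 5)
            assert runs and (runs[-1].start, runs[-1].end) == (start, end)

    def test_plant_longer_than_protein_rejected(self):
        with pytest.raises(ShellomeError, match="planted features"):
            gen_protein_set(SynthSpec(
                n_proteins=1, length_range=(30, 40),
                planted_lcrs=(PlantedLCR("single", "T", 35),)))

    def test_impure_plants_marked_approximate(self):
        spec = SynthSpec(n_proteins=3,
                         planted_lcrs=(PlantedLCR("single", "T", 30, purity=0.8),),
                         seed=19)
        _, truth = gen_protein_set(spec)
        assert all(not t.lcr_spans[0].exact for t in truth.values())

    def test_planted_domains_recorded(self):
        spec = SynthSpec(n_proteins=2, planted_domains=(("PF00092", 10), ("PF01607", 80)),
                         seed=23)
        _, truth = gen_protein_set(spec)
        for t in truth.values():
            assert [d.accession for d in t.domains] == ["PF00092", "PF01607"]


class TestEvidence:
    def test_template_accepted_and_classed(self):
        table = gen_evidence({"p1": "common_to_four"})
        assert apply_peptide_rule(table) == {"p1"}
        assert presence_class(table.presence("p1")) == "common_to_four"

    def test_rejected_template_fails_rule(self):
        table = gen_evidence({"p1": "rejected"})
        assert apply_peptide_rule(table) == set()

    def test_all_templates_produce_their_class(self):
        for name in ("common_to_four", "in_three", "ASM_specific", "AIM_specific"):
            table = gen_evidence({"p": name})
            assert presence_class(table.presence("p")) == name

    def test_explicit_counts(self):
        table = gen_evidence({"p": (0, 0, 3, 0)})
        assert table.entries == {("p", "AIM_2bl"): 3}


class TestPhospho:
    def test_zero_outside_rate_forces_full_overlap(self):
        spec = SynthSpec(
            n_proteins=15, planted_lcrs=(PlantedLCR("single", "S", 20),),
            phospho_rate_in_lcr=0.9, phospho_rate_outside=0.0, seed=29,
        )
        records, truth = gen_protein_set(spec)
        tracks = {t.protein_id: t for t in gen_phospho(spec, records, truth)}
        saw_likely = 0
        for rec in records:
            summary = overlay_track(tracks[rec.id], detect_lcrs(rec), protein_length=len(rec))
            if summary.n_likely:
                saw_likely += 1
                assert summary.frac_in_lcr == 1.0
        assert saw_likely > 0

    def test_probabilities_respect_threshold_sides(self):
        spec = SynthSpec(n_proteins=5, planted_lcrs=(PlantedLCR("single", "S", 20),),
                         phospho_rate_in_lcr=1.0, phospho_rate_outside=0.0, seed=31)
        records, truth = gen_protein_set(spec)
        for t in gen_phospho(spec, records, truth):
            spans = truth[t.protein_id].lcr_spans
            inside = set()
            for s in spans:
                inside.update(range(s.start, s.end + 1))
            for site in t.sites:
                if site.position in inside:
                    assert site.probability > 0.5
                else:
                    assert site.probability < 0.5

    def test_tracks_cross_check_against_sequences(self):
        spec = SynthSpec(n_proteins=5, planted_lcrs=(PlantedLCR("single", "T", 16),), seed=37)
        records, truth = gen_protein_set(spec)
        for rec, track in zip(records, gen_phospho(spec, records, truth)):
            track.cross_check(rec)  # raises on mismatch


class TestPlate:
    def test_noiseless_plate_roundtrips_exactly(self):
        true = {"Jacalin": 1.0, "DSL": 0.5, "WGA": 0.25}
        spec = SynthSpec(plate_true=true, plate_noise_sd=0.0, seed=41)
        r = normalize_plate(gen_plate(spec))
        assert r.mean_percent("Jacalin") == pytest.approx(100.0)
        assert r.mean_percent("DSL") == pytest.approx(50.0)
        assert r.mean_percent("WGA") == pytest.approx(25.0)
        assert all(r.sd_percent(l) == pytest.approx(0.0) for l in true)

    def test_default_plate_has_21_lectins_and_jacalin_max(self):
        r = normalize_plate(gen_plate(SynthSpec(seed=43)))
        assert len(r.values) == 21
        assert r.max_lectins() == ["Jacalin"]

    def test_determinism_under_seed(self):
        a = gen_plate(SynthSpec(seed=47))
        b = gen_plate(SynthSpec(seed=47))
        assert a == b
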