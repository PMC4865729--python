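import math

import numpy as np
import pytest

from ptmtransfer import cpe
from ptmtransfer.alignment import SearchParams, SequenceDatabase
from ptmtransfer.cpe import (
    CPEError,
    ReciprocalResult,
    blast1_find_hit,
    blast2_reciprocal,
    blast3_reciprocal,
    cpe_verdict,
    evalue_verdict,
    make_evidence,
)
from ptmtransfer.seq_io import ProteinRecord
from ptmtransfer.windowing import (
    build_known_peptides,
    extract_window,
    windows_to_records,
)
from ptmtransfer.seq_io import SiteAnnotation

AA = list("ACDEFGHIKLMNPQRSTWYV")
PARAMS = SearchParams()


def rand_seq(rng, n):
    return "".join(rng.choice(AA, size=n))


def peptide_db(proteome, annotations, w):
    wins = build_known_peptides(proteome, annotations, w)
    return SequenceDatabase.from_records("known_peptides", windows_to_records(wins))


class TestBlast1:
    def test_identical_window_is_the_hit_and_center_aligns(self):
        rng = np.random.default_rng(10)
        seq = rand_seq(rng, 40)
        seq = seq[:19] + "S" + seq[20:]
        known = ProteinRecord("H1", "", seq)
        ann = [SiteAnnotation("H1", 20, "S", "phosphorylation")]
        db = peptide_db([known], ann, w=7)
        query = ProteinRecord("Q1", "", seq)
        window = extract_window(query, 20, 7, "phosphorylation")
        hit = blast1_find_hit(window, db, PARAMS)
        assert hit is not None
        assert hit.hit_protein_id == "H1"
        assert hit.hit_site_position == 20
        assert hit.center_aligned
        assert hit.peptide_evalue < 1e-3

    def test_offset_match_fails_strict_center_mode(self):
        # the known window's center is W; the candidate is the same peptide
        # shifted by one, so the candidate center aligns to a non-central
        # residue of the known window
        known = ProteinRecord("H1", "", "CCAAAWKKKCC")
        ann = [SiteAnnotation("H1", 6, "W", "phosphorylation")]
        db = peptide_db([known], ann, w=3)  # window AAWKKK + flank = "AAAWKKK"
        query = ProteinRecord("Q1", "", "CAAWKKKC")
        window = extract_window(query, 5, 3, "phosphorylation")  # "AAWKKKC"
        assert window.center_residue == "K"
        assert blast1_find_hit(window, db, PARAMS, strict_center=True) is None
        relaxed = blast1_find_hit(window, db, PARAMS, strict_center=False)
        assert relaxed is not None and not relaxed.center_aligned

    def test_hit_above_cutoff_is_dropped(self):
        rng = np.random.default_rng(11)
        seq = rand_seq(rng, 40)
        seq = seq[:19] + "S" + seq[20:]
        known = ProteinRecord("H1", "", seq)
        ann = [SiteAnnotation("H1", 20, "S", "phosphorylation")]
        db = peptide_db([known], ann, w=7)
        window = extract_window(ProteinRecord("Q1", "", seq), 20, 7, "phosphorylation")
        strict = SearchParams(evalue_cutoff=1e-30)
        assert blast1_find_hit(window, db, strict) is None


class TestReciprocalSearches:
    def setup_method(self):
        rng = np.random.default_rng(12)
        self.shared = rand_seq(rng, 80)
        self.query = ProteinRecord("Q1", "", self.shared)
        self.decoy = ProteinRecord("D1", "", rand_seq(rng, 80))
        self.query_db = SequenceDatabase.from_records("qp", [self.query, self.decoy])

    def test_identical_hit_protein_is_reciprocal(self):
        hit_protein = ProteinRecord("H1", "", self.shared)
        res = blast2_reciprocal(hit_protein, "Q1", self.query_db, PARAMS)
        assert res.best_subject == "Q1"
        assert res.reciprocal
        assert res.best_evalue == res.partner_evalue

    def test_closer_paralog_breaks_reciprocity(self):
        rng = np.random.default_rng(13)
        paralog_seq = rand_seq(rng, 80)
        db = SequenceDatabase.from_records(
            "qp", [self.query, ProteinRecord("PARA", "", paralog_seq)]
        )
        hit_protein = ProteinRecord("H1", "", paralog_seq)  # identical to PARA
        res = blast2_reciprocal(hit_protein, "Q1", db, PARAMS)
        assert res.best_subject == "PARA"
        assert not res.reciprocal
        assert res.best_evalue < res.partner_evalue

    def test_no_alignment_to_partner_gives_infinite_evalue(self):
        hit_protein = ProteinRecord("H1", "", "W" * 40)
        db = SequenceDatabase.from_records(
            "qp",
            [ProteinRecord("Q1", "", "G" * 40), ProteinRecord("D1", "", "W" * 40)],
        )
        res = blast2_reciprocal(hit_protein, "Q1", db, PARAMS)
        assert math.isinf(res.partner_evalue)
        assert not res.reciprocal

    def test_query_absent_from_query_proteome_is_fatal(self):
        with pytest.raises(CPEError):
            blast2_reciprocal(self.query, "NOT_THERE", self.query_db, PARAMS)

    def test_blast3_mirrors_blast2(self):
        known_db = SequenceDatabase.from_records(
            "kp", [ProteinRecord("H1", "", self.shared), self.decoy]
        )
        res = blast3_reciprocal(self.query, "H1", known_db, PARAMS)
        assert res.best_subject == "H1"
        assert res.reciprocal


def _recip(reciprocal: bool, best=1e-20, partner=1e-20) -> ReciprocalResult:
    return ReciprocalResult(best, partner, "x", 100, 100, reciprocal)


class TestVerdicts:
    def test_cpe_yes_requires_both_directions(self):
        assert cpe_verdict(make_evidence(_recip(True), _recip(True)))
        assert not cpe_verdict(make_evidence(_recip(True), _recip(False)))
        assert not cpe_verdict(make_evidence(_recip(False), _recip(True)))
        assert not cpe_verdict(make_evidence(_recip(False), _recip(False)))

    def test_evalue_verdict_thresholds(self):
        rng = np.random.default_rng(14)
        seq = rand_seq(rng, 40)
        known = ProteinRecord("H1", "", seq[:19] + "S" + seq[20:])
        ann = [SiteAnnotation("H1", 20, "S", "phosphorylation")]
        db = peptide_db([known], ann, w=7)
        window = extract_window(known, 20, 7, "phosphorylation")
        hit = blast1_find_hit(window, db, PARAMS)
        assert evalue_verdict(hit, threshold=1e-3)
        assert not evalue_verdict(hit, threshold=hit.peptide_evalue / 10)
        with pytest.raises(CPEError):
            evalue_verdict(hit, threshold=0)


class TestParalogTrapShape:
    """The benchmark-comparison case: a site accepted by the plain E-value
    benchmark but rejected by the reciprocal check because the parent
    proteins are not each other's best whole-protein match."""

    def test_local_identity_without_whole_protein_reciprocity(self):
        rng = np.random.default_rng(15)
        w = 5
        host_seq = rand_seq(rng, 60)
        host_seq = host_seq[:29] + "S" + host_seq[30:]
        host = ProteinRecord("H1", "", host_seq)
        ann = [SiteAnnotation("H1", 30, "S", "phosphorylation")]
        window = host_seq[30 - 1 - w: 30 + w]

        backbone = rand_seq(rng, 60)
        trap_seq = backbone[:20] + window + backbone[20 + 2 * w + 1:]
        trap_query = ProteinRecord("QT", "", trap_seq)
        paralog = ProteinRecord(
            "PP", "", trap_seq[:20] + rand_seq(rng, 2 * w + 1) + trap_seq[20 + 2 * w + 1:]
        )

        peptides = peptide_db([host], ann, w)
        known_db = SequenceDatabase.from_records("kp", [host, paralog])
        query_db = SequenceDatabase.from_records(
            "qp", [trap_query, ProteinRecord("D1", "", rand_seq(rng, 60))]
        )

        cand_window = extract_window(trap_query, 26, w, "phosphorylation")
        hit = blast1_find_hit(cand_window, peptides, PARAMS)
        assert hit is not None and hit.hit_protein_id == "H1"
        assert evalue_verdict(hit, threshold=PARAMS.evalue_cutoff)

        fwd = blast2_reciprocal(host, "QT", query_db, PARAMS)
        rev = blast3_reciprocal(trap_query, "H1", known_db, PARAMS)
        assert rev.best_subject == "PP"  # the paralog wins whole-protein
        assert not cpe_verdict(make_evidence(fwd, rev))
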