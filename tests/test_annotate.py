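import numpy as np
import pytest

from ighclone.annotate import (
    annotate_sequence,
    assign_segment,
    enumerate_mutations,
    extract_cdr3,
    kabat_view,
)
from ighclone.simulate import parse_truth_mutations


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class TestAssignSegment:
    def test_identity_query(self, germline_db):
        gene = germline_db.get("V", "V5-17")
        hit = assign_segment(gene.nt_seq, germline_db, "V")
        assert hit.call == "V5-17"
        assert hit.identity_pct == 100.0

    def test_two_substitutions_identity(self, germline_db):
        gene = germline_db.get("V", "V5-17")
        seq = list(gene.nt_seq)
        seq[10] = "A" if seq[10] != "A" else "C"
        seq[50] = "A" if seq[50] != "A" else "C"
        hit = assign_segment("".join(seq), germline_db, "V")
        n = len(gene.nt_seq)
        assert hit.call == "V5-17"
        assert hit.identity_pct == round(100.0 * (n - 2) / n, 2)

    def test_short_query_rejected(self, germline_db):
        with pytest.raises(ValueError):
            assign_segment("ACGT" * 7, germline_db, "V")

    def test_mutated_queries_recover_donor_vs_bruteforce_oracle(self, germline_db):
        """50 queries mutated at 2%/site from known donors map back to the
        donor, in agreement with an exhaustive hamming-distance oracle
        (mutated copies are gapless, so minimal hamming = true donor)."""
        rng = np.random.default_rng(42)
        v_genes = germline_db.by_segment("V")
        for _ in range(50):
            donor = v_genes[rng.integers(len(v_genes))]
            seq = list(donor.nt_seq)
            for i in range(len(seq)):
                if rng.random() < 0.02:
                    seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
            query = "".join(seq)
            oracle = min(v_genes, key=lambda g: (_hamming(query, g.nt_seq), g.name))
            assert oracle.name == donor.name  # donors differ pairwise far beyond 2%
            assert assign_segment(query, germline_db, "V").call == donor.name


class TestExtractCdr3:
    def test_planted_insert_recovered(self, germline_db):
        """V-through-Cys + insert + J-from-Trp yields the insert as CDR3."""
        v = germline_db.get("V", "V1-7")
        j = germline_db.get("J", "J2")
        insert = "GCTAGAAAACGTCGTTGGGATTAT"  # ARKRRWDY
        query = v.nt_seq + insert + j.nt_seq[3 * j.trp118_codon_offset :]
        v_hit = assign_segment(query, germline_db, "V")
        j_hit = assign_segment(query, germline_db, "J")
        cdr3_nt, cdr3_aa, flags = extract_cdr3(query, v_hit, j_hit)
        assert cdr3_nt == insert
        assert cdr3_aa == "ARKRRWDY"
        assert "junction_unresolved" not in flags

    def test_stop_codon_flags_nonproductive(self, germline_db):
        v = germline_db.get("V", "V1-7")
        j = germline_db.get("J", "J2")
        insert = "GCTAGATAACGTCGTTGGGATTAT"  # contains TAA stop
        query = v.nt_seq + insert + j.nt_seq
        v_hit = assign_segment(query, germline_db, "V")
        j_hit = assign_segment(query, germline_db, "J")
        _, cdr3_aa, flags = extract_cdr3(query, v_hit, j_hit)
        assert "*" in cdr3_aa
        assert "nonproductive" in flags

    def test_simulated_junction_identity(self, germline_db, sim_default, sim_annotated):
        """extract_cdr3 of a simulated record returns the planted CDR3."""
        for row in sim_default.truth.itertuples():
            ann = sim_annotated[row.record_id]
            assert ann.cdr3_nt == row.cdr3_nt_true
            assert ann.cdr3_aa_imgt == row.cdr3_aa_true

    def test_panel_row_3f12(self, panel_records):
        rec = next(r for r in panel_records if r.record_id == "3F12")
        assert rec.cdr3_aa_imgt == "TRKGWDDAY"
        assert len(rec.cdr3_aa_imgt) == 9


class TestKabatView:
    @pytest.mark.parametrize(
        "imgt,expected",
        [
            ("ARRKLRNYYAMDY", "RKLRNYYAMDY"),
            ("TSRQLRLRRVAY", "RQLRLRRVAY"),
            ("AR", ""),
        ],
    )
    def test_examples(self, imgt, expected):
        if expected == "":
            assert kabat_view(imgt) == ""
        else:
            assert kabat_view(imgt) == expected

    def test_short_input_warns(self):
        with pytest.warns(UserWarning):
            assert kabat_view("A") == ""

    def test_length_invariant(self, panel_records):
        for rec in panel_records:
            assert len(kabat_view(rec.cdr3_aa_imgt)) == len(rec.cdr3_aa_imgt) - 2


class TestEnumerateMutations:
    def test_germline_itself_is_mutation_free(self, germline_db):
        for gene in germline_db.by_segment("V"):
            hit = assign_segment(gene.nt_seq, germline_db, "V")
            muts, total, nonsilent = enumerate_mutations(gene.nt_seq, hit, None)
            assert (muts, total, nonsilent) == ([], 0, 0)

    def test_silent_third_position_change(self, germline_db):
        """TGT -> TGC keeps Cys: 1 total / 0 non-silent."""
        gene = germline_db.get("V", "V5-17")
        pos = 3 * gene.cys104_codon_index + 2
        assert gene.nt_seq[pos] == "T"
        seq = gene.nt_seq[:pos] + "C" + gene.nt_seq[pos + 1 :]
        hit = assign_segment(seq, germline_db, "V")
        muts, total, nonsilent = enumerate_mutations(seq, hit, None)
        assert total == 1 and nonsilent == 0
        assert muts[0].key == ("V", pos, "C")

    def test_double_hit_codon_shares_joint_effect(self, germline_db):
        gene = germline_db.get("V", "V5-17")
        codon = gene.nt_seq[0:3]
        # replace the first codon entirely with a codon for a different residue
        new = "GGG" if codon != "GGG" else "CCC"
        seq = new + gene.nt_seq[3:]
        hit = assign_segment(seq, germline_db, "V")
        muts, total, nonsilent = enumerate_mutations(seq, hit, None)
        changed = sum(a != b for a, b in zip(codon, new))
        assert total == changed
        assert all(m.effect == muts[0].effect for m in muts)

    def test_simulated_mutations_recovered_exactly(self, germline_db, sim_default, sim_annotated):
        """Planted mutation lists are recovered position-by-position."""
        for row in sim_default.truth.itertuples():
            ann = sim_annotated[row.record_id]
            assert {m.key for m in ann.mutations} == set(parse_truth_mutations(row.mutations_true))
            assert ann.n_mut_total == row.n_mut_true
            assert ann.n_mut_nonsilent <= ann.n_mut_total


def test_annotation_invariants(sim_annotated):
    for ann in sim_annotated.values():
        assert ann.v_call is not None and ann.j_call is not None
        assert len(ann.cdr3_aa_kabat) == len(ann.cdr3_aa_imgt) - 2
        assert 3 * len(ann.cdr3_aa_imgt) == len(ann.cdr3_nt)
        assert ann.n_mut_total == len(ann.mutations)


def test_junk_sequence_yields_no_junction(germline_db):
    """A random sequence may still align a short overlap to some germline,
    but no CDR3 junction can resolve from it."""
    rng = np.random.default_rng(7)
    junk = "".join(rng.choice(list("ACGT"), size=400))
    ann = annotate_sequence("junk", junk, germline_db)
    assert ann.cdr3_nt is None
    assert set(ann.flags) & {"unassignable_v", "unassignable_j", "junction_unresolved"}
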