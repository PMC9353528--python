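import numpy as np
import pytest

from igmrep.annotate import (
    AnnotationParams,
    annotate_read,
    annotate_repertoire,
    assign_vdj,
    decompose_junction,
    extract_cdr3,
)
from igmrep.simulate import preset_model, simulate_repertoire

from .oracles import min_np_partition


def _seqs(germline, v="IGHV12-3*01", d="IGHD2*01", j="IGHJ1*01"):
    return germline[v], germline[d], germline[j]


class TestAssignVdj:
    def test_exact_concatenation_recovers_all_calls(self, germline, params):
        v, d, j = _seqs(germline)
        read = v.sequence + d.sequence + j.sequence
        a = assign_vdj(read, germline, params)
        assert a.ok
        assert (a.v_call, a.d_call, a.j_call) == (v.name, d.name, j.name)

    def test_short_random_insert_yields_no_d_call(self, germline, params):
        v, _, j = _seqs(germline)
        read = v.sequence + "ACGT" + j.sequence  # 4 nt < min_d_match=5
        a = assign_vdj(read, germline, params)
        assert a.ok
        assert a.d_call is None

    def test_garbage_read_flagged_not_raised(self, germline, params):
        rng = np.random.default_rng(0)
        read = "".join(rng.choice(list("ACGT"), 200))
        a = assign_vdj(read, germline, params)
        assert not a.ok
        assert a.fail_reason == "no_v_call"

    def test_invalid_characters_flagged(self, germline, params):
        a = assign_vdj("ACGTNNNACGT", germline, params)
        assert not a.ok and a.fail_reason == "invalid_sequence"

    def test_reverse_complement_rescue(self, germline, params):
        v, d, j = _seqs(germline)
        read = v.sequence + d.sequence + j.sequence
        rc = read.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        a = assign_vdj(rc, germline, params)
        assert a.ok and a.rev_comp
        assert a.v_call == v.name and a.j_call == j.name

    def test_call_agreement_on_simulated_reads(self, germline, params, preset_runs):
        sims, anns = preset_runs["perc_b1b"]
        truth = {s.sequence_id: s for s in sims}
        ok = [r for r in anns if r.annotation_ok]
        v_agree = np.mean([r.v_call == truth[r.sequence_id].v_call for r in ok])
        j_agree = np.mean([r.j_call == truth[r.sequence_id].j_call for r in ok])
        assert v_agree >= 0.95
        assert j_agree >= 0.95


class TestDecomposition:
    def test_constructed_junction_recovers_n_regions(self, germline, params):
        v, d, j = _seqs(germline)
        # v untrimmed + CC + a 10 nt DH2 core (unique among the D segments) + G
        d_core = d.sequence[2:12]
        read = v.sequence + "CC" + d_core + "G" + j.sequence
        r = annotate_read("x", read, germline, params)
        assert r.annotation_ok
        assert r.d_call == d.name
        assert r.decomposition.n1 == "CC"
        assert r.decomposition.d_core == d_core
        assert r.decomposition.n2 == "G"
        assert (r.np1_length, r.np2_length) == (2, 1)
        assert r.decomposition.concatenation() == r.junction

    def test_zero_insert_read_has_zero_n_additions(self, germline, params):
        v, d, j = _seqs(germline)
        r = annotate_read("x", v.sequence + d.sequence + j.sequence, germline, params)
        assert (r.np1_length, r.np2_length) == (0, 0)
        assert r.decomposition.p_v == "" and r.decomposition.p_j == ""

    def test_no_d_call_puts_whole_insert_in_n1(self, germline, params):
        v, _, j = _seqs(germline)
        r = annotate_read("x", v.sequence + "ACGT" + j.sequence, germline, params)
        assert r.annotation_ok and r.d_call is None
        assert r.decomposition.n1 == "ACGT"
        assert r.np2_length is None

    def test_conservation_on_simulated_corpus(self, preset_runs):
        for _, anns in preset_runs.values():
            for r in anns:
                if r.annotation_ok:
                    assert r.decomposition.concatenation() == r.junction

    def test_maximal_templated_minimizes_n_total(self, germline, params, preset_runs):
        """Greedy anchor walks + longest exact D match reach the brute-force
        minimum over all exact-templated partitions (inserts <= 12 nt)."""
        d_seqs = {s.name: s.sequence for s in germline.of_type("D")}
        checked = 0
        for _, anns in preset_runs.values():
            for r in anns:
                if not (r.annotation_ok and r.has_d):
                    continue
                dec = r.decomposition
                insert_len = dec.np1 + (dec.np2 or 0) + len(dec.d_core or "")
                if insert_len > 12:
                    continue
                v = germline[r.v_call]
                j = germline[r.j_call]
                best = min_np_partition(
                    r.junction,
                    v.sequence[v.anchor :],
                    j.sequence[: j.anchor + 3],
                    d_seqs,
                    params.min_d_match,
                )
                assert best is not None
                assert dec.np1 + dec.np2 == best
                checked += 1
                if checked >= 150:
                    return
        assert checked > 20


class TestCdr3:
    def test_germline_join_yields_canonical_b1a_clonotype(self, germline, params):
        """The untrimmed VH12+DH2+JH1 join is fully germline-encoded and
        translates to the canonical B-1a CDR-H3."""
        v, d, j = _seqs(germline)
        r = annotate_read("x", v.sequence + d.sequence + j.sequence, germline, params)
        assert r.productive
        assert r.junction_aa.startswith("C") and r.junction_aa.endswith("W")
        assert r.cdr3_aa == "AGDYDGYWYFDV"
        assert len(r.cdr3_aa) == len(r.junction_aa) - 2

    def test_in_frame_stop_codon_is_unproductive(self, germline, params):
        v, _, j = _seqs(germline)
        r = annotate_read("x", v.sequence + "TAG" + j.sequence, germline, params)
        assert r.annotation_ok
        assert "*" in r.junction_aa
        assert not r.productive

    def test_out_of_frame_junction_unproductive_but_reported(self, germline, params):
        v, _, j = _seqs(germline)
        r = annotate_read("x", v.sequence + "TA" + j.sequence, germline, params)
        assert r.annotation_ok
        assert not r.productive
        assert len(r.junction) % 3 != 0
        assert r.cdr3_aa  # still translated in the V frame

    def test_simulated_cdr3_matches_generative_truth(self, preset_runs):
        sims, anns = preset_runs["perc_b1a"]
        truth = {s.sequence_id: s for s in sims}
        ok = [r for r in anns if r.annotation_ok]
        agree = np.mean([r.cdr3_aa == truth[r.sequence_id].cdr3_aa for r in ok])
        assert agree >= 0.95


class TestBatch:
    def test_empty_fasta_gives_empty_list(self, germline, params, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert annotate_repertoire(p, germline, params) == []

    def test_mixed_valid_and_garbage_reads(self, germline, params):
        v, d, j = _seqs(germline)
        good = v.sequence + d.sequence + j.sequence
        rng = np.random.default_rng(1)
        bad = "".join(rng.choice(list("ACGT"), 150))
        out = annotate_repertoire([("good", good), ("bad", bad)], germline, params)
        assert [r.sequence_id for r in out] == ["good", "bad"]
        assert out[0].annotation_ok
        assert not out[1].annotation_ok and out[1].fail_reason == "no_v_call"

    def test_determinism_across_runs(self, germline, params):
        model = preset_model("spleen_b1a", germline)
        sims = simulate_repertoire(model, 40, seed=5)
        reads = [(s.sequence_id, s.read) for s in sims]
        a = annotate_repertoire(reads, germline, params)
        b = annotate_repertoire(reads, germline, params)
        for x, y in zip(a, b):
            assert (x.v_call, x.d_call, x.j_call) == (y.v_call, y.d_call, y.j_call)
            assert (x.np1_length, x.np2_length) == (y.np1_length, y.np2_length)
            assert x.junction == y.junction
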