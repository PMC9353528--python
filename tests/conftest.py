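from __future__ import annotations

import pytest

from igmrep import AnnotationParams, annotate_repertoire, builtin_germline
from igmrep.simulate import PRESET_NAMES, preset_model, simulate_repertoire, truth_table


@pytest.fixture(scope="session")
def germline():
    return builtin_germline()


@pytest.fixture(scope="session")
def params():
    return AnnotationParams()


@pytest.fixture(scope="session")
def preset_runs(germline, params):
    """One 500-cell simulated + annotated repertoire per condition preset (seed 7)."""
    runs = {}
    for preset in PRESET_NAMES:
        model = preset_model(preset, germline)
        sims = simulate_repertoire(model, 500, seed=7)
        anns = annotate_repertoire(
            [(s.sequence_id, s.read) for s in sims], germline, params
        )
        runs[preset] = (sims, anns)
    return runs


@pytest.fixture
def tiny_germline_files(tmp_path):
    """A 3-record V/D/J reference (FASTA + anchors) for loader tests."""
    fasta = tmp_path / "ref.fasta"
    anchors = tmp_path / "anchors.tsv"
    fasta.write_text(
        ">IGHV1-5*01\nACGTACGTACGTACGTACGTTGTGCAAGAGAT\n"
        ">IGHD2*01\nTACGACGGCTAC\n"
        ">IGHJ1*01\nTACTTCGATGTCTGGGGCGCAGGG\n"
    )
    anchors.write_text("name\tanchor_0based\nIGHV1-5*01\t20\nIGHJ1*01\t12\n")
    return fasta, anchors
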