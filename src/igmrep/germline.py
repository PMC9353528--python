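"""Germline V/D/J segment references.

A germline reference is a plain FASTA of ungapped V, D and J nucleotide
segments plus a tab-separated anchor file giving, for every V segment, the
0-based offset of the conserved Cys codon near the segment's 3' end and,
for every J segment, the offset of the conserved Trp/Phe codon of the
W/F-G-x-G motif.  D segments carry no anchor.

Family labels (the granularity at which usage is tabulated, e.g. ``VH12``,
``DH1-1``, ``JH1``) are derived from IMGT-style allele names.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

__all__ = [
    "GermlineSegment",
    "GermlineSet",
    "load_germline",
    "builtin_germline",
    "family_of",
]

SegmentType = Literal["V", "D", "J"]

_NT = set("ACGT")

_CALL_RE = re.compile(r"^IGH([VDJ])([^*]+)(?:\*.*)?$")


def family_of(call: str) -> str:
    """Family label for an IMGT-style heavy-chain allele call.

    V and J families keep the token between the locus prefix and the first
    hyphen or asterisk (``"IGHV12-3*01"`` -> ``"VH12"``); D families keep
    the whole gene token up to the asterisk (``"IGHD1-1*01"`` -> ``"DH1-1"``)
    because D genes within one numeric family are tabulated separately.
    """
    m = _CALL_RE.match(call)
    if m is None:
        raise ValueError(f"unparseable allele call: {call!r}")
    locus, token = m.group(1), m.group(2)
    if locus == "D":
        return f"DH{token}"
    token = token.split("-", 1)[0]
    return f"{locus}H{token}"


@dataclass(frozen=True)
class GermlineSegment:
    """One germline reference segment.

    ``anchor`` is the 0-based codon start of the conserved Cys (V) or the
    conserved Trp/Phe (J); it is ``None`` for D segments.
    """

    name: str
    segment_type: SegmentType
    sequence: str
    anchor: int | None = None

    def __post_init__(self) -> None:
        if self.segment_type not in ("V", "D", "J"):
            raise ValueError(f"bad segment_type {self.segment_type!r}")
        if not self.sequence:
            raise ValueError(f"segment {self.name}: empty sequence")
        bad = set(self.sequence) - _NT
        if bad:
            raise ValueError(
                f"segment {self.name}: non-ACGT characters {sorted(bad)}"
            )
        if self.segment_type == "D":
            if self.anchor is not None:
                raise ValueError(f"segment {self.name}: D segments carry no anchor")
        else:
            if self.anchor is None:
                raise ValueError(
                    f"segment {self.name}: {self.segment_type} segment requires an anchor"
                )
            if not (0 <= self.anchor and self.anchor + 3 <= len(self.sequence)):
                raise ValueError(
                    f"segment {self.name}: anchor {self.anchor} does not fit a codon "
                    f"in a sequence of length {len(self.sequence)}"
                )

    @property
    def family(self) -> str:
        return family_of(self.name)


@dataclass
class GermlineSet:
    """A validated collection of V, D and J germline segments."""

    segments: list[GermlineSegment]
    provenance: str = ""
    _by_name: dict[str, GermlineSegment] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate segment names: {sorted(dupes)}")
        for st in ("V", "D", "J"):
            if not any(s.segment_type == st for s in self.segments):
                raise ValueError(f"germline set has no {st} segments")
        # order-independent canonical storage
        self.segments = sorted(self.segments, key=lambda s: (s.segment_type, s.name))
        self._by_name = {s.name: s for s in self.segments}

    def of_type(self, segment_type: SegmentType) -> list[GermlineSegment]:
        return [s for s in self.segments if s.segment_type == segment_type]

    def __getitem__(self, name: str) -> GermlineSegment:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self.segments)

    def families(self, segment_type: SegmentType) -> list[str]:
        """Sorted unique family vocabulary for one segment type."""
        return sorted({s.family for s in self.of_type(segment_type)})


def _strip_gaps(seq: str, anchor: int | None) -> tuple[str, int | None]:
    """Remove IMGT gap dots, recomputing the anchor offset."""
    if "." not in seq:
        return seq, anchor
    if anchor is not None:
        anchor = anchor - seq[:anchor].count(".")
    return seq.replace(".", ""), anchor


def _read_anchor_table(anchors_path: str | Path) -> dict[str, int]:
    anchors: dict[str, int] = {}
    with open(anchors_path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if i == 0 and parts[0] == "name":
                continue
            if len(parts) < 2:
                raise ValueError(f"{anchors_path}: malformed line {i + 1}: {line!r}")
            anchors[parts[0]] = int(parts[1])
    return anchors


def load_germline(
    fasta_path: str | Path,
    anchors_path: str | Path,
    provenance: str | None = None,
) -> GermlineSet:
    """Load a germline reference from FASTA + anchor TSV.

    Segment type is inferred from the IMGT-style record name (IGHV/IGHD/IGHJ
    prefix).  Every V and J record must have a row in the anchor file; D
    records must not.  IMGT gap dots are stripped with anchors recomputed.
    """
    anchors = _read_anchor_table(anchors_path)
    segments: list[GermlineSegment] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        name = rec.id
        if name in seen:
            raise ValueError(f"duplicate record name in {fasta_path}: {name}")
        seen.add(name)
        m = _CALL_RE.match(name)
        if m is None:
            raise ValueError(f"record {name!r}: cannot infer segment type from name")
        st: SegmentType = m.group(1)  # type: ignore[assignment]
        seq = str(rec.seq).upper()
        anchor = anchors.get(name)
        if st in ("V", "J") and anchor is None:
            raise ValueError(f"record {name}: missing from anchor file {anchors_path}")
        if st == "D":
            anchor = None
        seq, anchor = _strip_gaps(seq, anchor)
        segments.append(GermlineSegment(name, st, seq, anchor))
    return GermlineSet(
        segments,
        provenance=provenance or f"{fasta_path}",
    )


def builtin_germline() -> GermlineSet:
    """The small synthetic mouse-like reference bundled with the package.

    10 V, 4 D and 4 J segments whose family vocabulary (VH1..VH14, DH1-1,
    DH1-2, DH2, DH3, JH1..JH4) matches the families tabulated for murine
    B-1 cell heavy chains.  Segment bodies are synthetic; only the anchor
    regions and junction-facing termini are designed.
    """
    data = resources.files("igmrep") / "data"
    with resources.as_file(data / "germline.fasta") as fa, resources.as_file(
        data / "anchors.tsv"
    ) as an:
        return load_germline(fa, an, provenance="igmrep builtin synthetic reference")
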