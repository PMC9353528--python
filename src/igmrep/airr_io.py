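"""AIRR Rearrangement TSV reader/writer.

Follows the AIRR Community Rearrangement schema conventions: tab-separated,
empty string for missing values, ``T``/``F`` booleans, 1-based closed
alignment coordinates on disk (0-based half-open in memory).  A few vendor
columns (``np1_sequence`` is not part of the schema; N/P lengths and the
annotation failure reason are written under ``np{1,2}_length``,
``p{v,j}_length`` and ``fail_reason``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .align import SegmentAlignment
from .annotate import Rearrangement

__all__ = ["read_airr", "write_airr", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = (
    "sequence_id",
    "sequence",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "np1_length",
    "np2_length",
    "productive",
)

_COLUMNS = [
    "sequence_id",
    "sequence",
    "rev_comp",
    "productive",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "cdr3_aa",
    "np1_length",
    "np2_length",
    "v_sequence_start",
    "v_sequence_end",
    "v_germline_start",
    "v_germline_end",
    "d_sequence_start",
    "d_sequence_end",
    "d_germline_start",
    "d_germline_end",
    "j_sequence_start",
    "j_sequence_end",
    "j_germline_start",
    "j_germline_end",
    "v_score",
    "v_identity",
    "j_score",
    "j_identity",
    "p_v_length",
    "p_j_length",
    "annotation_ok",
    "fail_reason",
]


def _bool(v: bool | None) -> str:
    if v is None:
        return ""
    return "T" if v else "F"


def _span_cols(aln: SegmentAlignment | None) -> tuple:
    """0-based half-open spans -> 1-based closed AIRR coordinates."""
    if aln is None:
        return "", "", "", ""
    q0, q1 = aln.query_span
    s0, s1 = aln.segment_span
    return q0 + 1, q1, s0 + 1, s1


def write_airr(rearrangements: Sequence[Rearrangement], path: str | Path) -> Path:
    rows = []
    for r in rearrangements:
        row = {
            "sequence_id": r.sequence_id,
            "sequence": r.sequence,
            "rev_comp": _bool(r.rev_comp),
            "productive": _bool(r.productive),
            "v_call": r.v_call or "",
            "d_call": r.d_call or "",
            "j_call": r.j_call or "",
            "junction": r.junction or "",
            "junction_aa": r.junction_aa or "",
            "cdr3_aa": r.cdr3_aa or "",
            "np1_length": "" if r.np1_length is None else r.np1_length,
            "np2_length": "" if r.np2_length is None else r.np2_length,
            "p_v_length": "" if r.p_v_length is None else r.p_v_length,
            "p_j_length": "" if r.p_j_length is None else r.p_j_length,
            "annotation_ok": _bool(r.annotation_ok),
            "fail_reason": r.fail_reason or "",
        }
        for prefix, aln in (("v", r.v_alignment), ("d", r.d_alignment), ("j", r.j_alignment)):
            qs, qe, gs, ge = _span_cols(aln)
            row[f"{prefix}_sequence_start"] = qs
            row[f"{prefix}_sequence_end"] = qe
            row[f"{prefix}_germline_start"] = gs
            row[f"{prefix}_germline_end"] = ge
        row["v_score"] = r.v_alignment.score if r.v_alignment else ""
        row["v_identity"] = round(r.v_alignment.identity, 6) if r.v_alignment else ""
        row["j_score"] = r.j_alignment.score if r.j_alignment else ""
        row["j_identity"] = round(r.j_alignment.identity, 6) if r.j_alignment else ""
        rows.append(row)
    df = pd.DataFrame(rows, columns=_COLUMNS)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def _opt_str(v) -> str | None:
    if pd.isna(v) or v == "":
        return None
    return str(v)


def _opt_int(v) -> int | None:
    if pd.isna(v) or v == "":
        return None
    return int(v)


def _opt_bool(v) -> bool:
    return str(v).strip() in ("T", "true", "True", "1")


def _read_alignment(row: pd.Series, prefix: str, name: str | None) -> SegmentAlignment | None:
    qs = _opt_int(row.get(f"{prefix}_sequence_start"))
    qe = _opt_int(row.get(f"{prefix}_sequence_end"))
    gs = _opt_int(row.get(f"{prefix}_germline_start"))
    ge = _opt_int(row.get(f"{prefix}_germline_end"))
    if name is None or qs is None or qe is None or gs is None or ge is None:
        return None
    score = _opt_int(row.get(f"{prefix}_score"))
    ident = row.get(f"{prefix}_identity")
    identity = 1.0 if (ident is None or pd.isna(ident) or ident == "") else float(ident)
    return SegmentAlignment(
        segment_name=name,
        query_span=(qs - 1, qe),
        segment_span=(gs - 1, ge),
        score=score if score is not None else 0,
        identity=identity,
    )


def read_airr(path: str | Path) -> list[Rearrangement]:
    """Read an AIRR Rearrangement TSV into in-memory rearrangements.

    Unknown columns are tolerated; missing required columns raise a
    ValueError naming them.  Junction decompositions are not serialised, so
    ``decomposition`` is None on round-tripped records; the N/P lengths,
    calls, junction strings and coordinates are preserved exactly.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required AIRR columns: {missing}")
    out: list[Rearrangement] = []
    for _, row in df.iterrows():
        v_call = _opt_str(row["v_call"])
        d_call = _opt_str(row["d_call"])
        j_call = _opt_str(row["j_call"])
        out.append(
            Rearrangement(
                sequence_id=str(row["sequence_id"]),
                sequence=str(row["sequence"]),
                rev_comp=_opt_bool(row.get("rev_comp", "F")),
                v_call=v_call,
                d_call=d_call,
                j_call=j_call,
                v_alignment=_read_alignment(row, "v", v_call),
                d_alignment=_read_alignment(row, "d", d_call),
                j_alignment=_read_alignment(row, "j", j_call),
                junction=_opt_str(row["junction"]),
                junction_aa=_opt_str(row["junction_aa"]),
                cdr3_aa=_opt_str(row.get("cdr3_aa", "")),
                np1_length=_opt_int(row["np1_length"]),
                np2_length=_opt_int(row["np2_length"]),
                p_v_length=_opt_int(row.get("p_v_length", "")),
                p_j_length=_opt_int(row.get("p_j_length", "")),
                productive=_opt_bool(row["productive"]),
                annotation_ok=_opt_bool(row.get("annotation_ok", "T")),
                fail_reason=_opt_str(row.get("fail_reason", "")),
            )
        )
    return out
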