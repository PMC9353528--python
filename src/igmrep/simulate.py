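"""Generative V(D)J recombination simulator with ground truth.

The generative model mirrors the mechanism of heavy-chain rearrangement:
segment choice (categorical usage vectors), exonucleolytic trimming of the
junction-facing ends (capped geometric), optional P-nucleotides at untrimmed
ends (hairpin-derived palindromes), TdT N-additions of length drawn from an
explicit distribution and uniform base composition, clonal expansion
(geometric clone sizes), and optional per-base substitution noise.

Four presets emulate four murine B-1 cell IgM repertoire conditions — peritoneal (PerC) B-1a, PerC B-1b, splenic B-1a and splenic
B-1b — which differ in N-addition burden, V/D/J usage skew and clonality:
junctional heterogeneity increases and clonality decreases in the order
PerC B-1a < PerC B-1b < spleen B-1a < spleen B-1b.

Every simulated read carries its full generative record, so annotation
accuracy is measurable exactly (:func:`recovery_report`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import Rearrangement, _longest_common_substring, _revcomp, _translate
from .germline import GermlineSet, builtin_germline

__all__ = [
    "RecombinationModel",
    "SimulatedRearrangement",
    "RecoveryReport",
    "simulate_rearrangement",
    "simulate_repertoire",
    "recovery_report",
    "preset_model",
    "PRESET_NAMES",
    "truth_table",
    "write_reads_fasta",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class RecombinationModel:
    """Parameters of the generative rearrangement model.

    ``v_usage``/``d_usage``/``j_usage`` map segment names to probabilities
    (each summing to 1).  ``trim_p`` is the success parameter of the
    geometric trimming distribution (P(t) ∝ (1-p)^t), truncated at the
    per-end caps.  ``n_len_dist[k]`` is the probability of k N-additions,
    applied independently at the V-D and D-J junctions.  ``clone_p`` is the
    geometric clone-size parameter (mean clone size 1/clone_p).  When
    ``require_inframe`` is set, junction-forming draws are resampled until
    the junction is in-frame and stop-free, emulating productively
    rearranged, surface-IgM-selected cells.
    """

    germline: GermlineSet
    v_usage: dict[str, float]
    d_usage: dict[str, float]
    j_usage: dict[str, float]
    n_len_dist: tuple[float, ...] = (1.0,)
    trim_p: float = 0.45
    trim_cap_v: int = 4
    trim_cap_d5: int = 3
    trim_cap_d3: int = 3
    trim_cap_j: int = 4
    p_prob: float = 0.0
    clone_p: float = 1.0
    mutation_rate: float = 0.0
    max_p_len: int = 2
    require_inframe: bool = False
    name: str = "custom"
    seed: int = 0

    def __post_init__(self) -> None:
        for label, usage, st in (
            ("v_usage", self.v_usage, "V"),
            ("d_usage", self.d_usage, "D"),
            ("j_usage", self.j_usage, "J"),
        ):
            if abs(sum(usage.values()) - 1.0) > 1e-9:
                raise ValueError(f"{label} does not sum to 1")
            for name in usage:
                if name not in self.germline:
                    raise ValueError(f"{label}: unknown segment {name!r}")
                if self.germline[name].segment_type != st:
                    raise ValueError(f"{label}: {name!r} is not a {st} segment")
        if abs(sum(self.n_len_dist) - 1.0) > 1e-9:
            raise ValueError("n_len_dist does not sum to 1")
        if not 0 < self.clone_p <= 1:
            raise ValueError("clone_p must lie in (0, 1]")


@dataclass
class SimulatedRearrangement:
    """A simulated read plus its generative ground truth."""

    sequence_id: str
    read: str
    clone_id: str
    v_call: str
    d_call: str
    j_call: str
    trim_v: int
    trim_d5: int
    trim_d3: int
    trim_j: int
    p_v: str
    n1: str
    n2: str
    p_j: str
    d_core: str
    junction: str
    junction_aa: str
    cdr3_aa: str
    productive: bool
    mutated_positions: tuple[int, ...] = ()

    @property
    def np1(self) -> int:
        return len(self.n1)

    @property
    def np2(self) -> int:
        return len(self.n2)

    def reconstruct(self, germline: GermlineSet) -> str:
        """Reassemble the read from the generative record (pre-mutation)."""
        v = germline[self.v_call].sequence
        d = germline[self.d_call].sequence
        j = germline[self.j_call].sequence
        read = (
            v[: len(v) - self.trim_v]
            + self.p_v
            + self.n1
            + d[self.trim_d5 : len(d) - self.trim_d3]
            + self.n2
            + self.p_j
            + j[self.trim_j :]
        )
        read = list(read)
        for pos in self.mutated_positions:
            read[pos] = self._mut_base_at(pos)
        return "".join(read)

    # mutated bases are stored in the read itself; reconstruct() uses them
    def _mut_base_at(self, pos: int) -> str:
        return self.read[pos]


def _draw_trim(rng: np.random.Generator, p: float, cap: int) -> int:
    if cap <= 0:
        return 0
    t = int(rng.geometric(p)) - 1
    return min(t, cap)


def _draw_usage(rng: np.random.Generator, usage: dict[str, float]) -> str:
    names = sorted(usage)
    probs = np.array([usage[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    return names[int(rng.choice(len(names), p=probs))]


def _draw_n(rng: np.random.Generator, dist: tuple[float, ...]) -> str:
    k = int(rng.choice(len(dist), p=np.asarray(dist) / sum(dist)))
    if k == 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, size=k)])


def _recombine(
    model: RecombinationModel, rng: np.random.Generator
) -> SimulatedRearrangement:
    """One recombination event (no mutations, no id/clone labels yet)."""
    g = model.germline
    v = g[_draw_usage(rng, model.v_usage)]
    d = g[_draw_usage(rng, model.d_usage)]
    j = g[_draw_usage(rng, model.j_usage)]
    assert v.anchor is not None and j.anchor is not None

    cap_v = min(model.trim_cap_v, len(v.sequence) - (v.anchor + 3))
    cap_j = min(model.trim_cap_j, j.anchor)
    for attempt in range(200):
        trim_v = _draw_trim(rng, model.trim_p, cap_v)
        trim_j = _draw_trim(rng, model.trim_p, cap_j)
        trim_d5 = _draw_trim(rng, model.trim_p, model.trim_cap_d5)
        trim_d3 = _draw_trim(rng, model.trim_p, model.trim_cap_d3)
        if trim_d5 + trim_d3 >= len(d.sequence):
            continue  # exhausted D: redraw
        p_v = p_j = ""
        if trim_v == 0 and rng.random() < model.p_prob:
            k = int(rng.integers(1, model.max_p_len + 1))
            p_v = _revcomp(v.sequence[-k:])
        if trim_j == 0 and rng.random() < model.p_prob:
            k = int(rng.integers(1, model.max_p_len + 1))
            p_j = _revcomp(j.sequence[:k])
        n1 = _draw_n(rng, model.n_len_dist)
        n2 = _draw_n(rng, model.n_len_dist)

        d_core = d.sequence[trim_d5 : len(d.sequence) - trim_d3]
        v_kept = len(v.sequence) - trim_v
        junction = (
            v.sequence[v.anchor : v_kept]
            + p_v + n1 + d_core + n2 + p_j
            + j.sequence[trim_j : j.anchor + 3]
        )
        junction_aa = _translate(junction)
        productive = (len(junction) % 3 == 0) and ("*" not in junction_aa)
        if model.require_inframe and not productive:
            continue
        read = (
            v.sequence[:v_kept] + p_v + n1 + d_core + n2 + p_j + j.sequence[trim_j:]
        )
        cdr3_aa = junction_aa[1:-1] if len(junction_aa) >= 2 else ""
        return SimulatedRearrangement(
            sequence_id="", read=read, clone_id="",
            v_call=v.name, d_call=d.name, j_call=j.name,
            trim_v=trim_v, trim_d5=trim_d5, trim_d3=trim_d3, trim_j=trim_j,
            p_v=p_v, n1=n1, n2=n2, p_j=p_j, d_core=d_core,
            junction=junction, junction_aa=junction_aa, cdr3_aa=cdr3_aa,
            productive=productive,
        )
    raise RuntimeError(
        "simulation failed: no viable trim/N draw after 200 attempts "
        f"(V={v.name}, D={d.name}, J={j.name})"
    )


def _mutate(
    sim: SimulatedRearrangement, rate: float, rng: np.random.Generator
) -> SimulatedRearrangement:
    if rate <= 0:
        return sim
    read = np.array(list(sim.read))
    hits = np.nonzero(rng.random(len(read)) < rate)[0]
    for pos in hits:
        choices = [b for b in "ACGT" if b != read[pos]]
        read[pos] = choices[int(rng.integers(0, 3))]
    if hits.size == 0:
        return sim
    return dataclasses.replace(
        sim, read="".join(read), mutated_positions=tuple(int(h) for h in hits)
    )


def simulate_rearrangement(
    model: RecombinationModel, rng: np.random.Generator | int | None = None
) -> SimulatedRearrangement:
    """Draw one rearranged read (with mutations) and its ground truth."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(model.seed if rng is None else rng)
    return _mutate(_recombine(model, rng), model.mutation_rate, rng)


def simulate_repertoire(
    model: RecombinationModel,
    n_cells: int,
    seed: int | None = None,
    id_prefix: str | None = None,
) -> list[SimulatedRearrangement]:
    """Simulate a clonally structured repertoire of ``n_cells`` reads.

    Clone sizes are drawn geometrically (parameter ``model.clone_p``) until
    the requested cell count is reached (the last clone is truncated); all
    cells of a clone share one recombination event, with substitution noise
    applied per cell.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    prefix = id_prefix or model.name
    out: list[SimulatedRearrangement] = []
    clone_idx = 0
    while len(out) < n_cells:
        size = int(rng.geometric(model.clone_p))
        size = min(size, n_cells - len(out))
        event = _recombine(model, rng)
        for _ in range(size):
            cell = _mutate(event, model.mutation_rate, rng)
            cell = dataclasses.replace(
                cell,
                sequence_id=f"{prefix}_{len(out):05d}",
                clone_id=f"{prefix}_clone{clone_idx:05d}",
            )
            out.append(cell)
        clone_idx += 1
    return out


_TRUTH_COLUMNS = [
    "sequence_id", "clone_id", "v_call", "d_call", "j_call",
    "trim_v", "trim_d5", "trim_d3", "trim_j",
    "p_v", "n1", "d_core", "n2", "p_j", "np1", "np2",
    "junction", "junction_aa", "cdr3_aa", "productive",
    "n_mutations", "read",
]


def truth_table(sims: Sequence[SimulatedRearrangement]) -> pd.DataFrame:
    """Ground-truth table, one row per simulated cell (columns truth_*)."""
    rows = []
    for s in sims:
        rows.append(
            {
                "sequence_id": s.sequence_id,
                "clone_id": s.clone_id,
                "v_call": s.v_call,
                "d_call": s.d_call,
                "j_call": s.j_call,
                "trim_v": s.trim_v,
                "trim_d5": s.trim_d5,
                "trim_d3": s.trim_d3,
                "trim_j": s.trim_j,
                "p_v": s.p_v,
                "n1": s.n1,
                "d_core": s.d_core,
                "n2": s.n2,
                "p_j": s.p_j,
                "np1": s.np1,
                "np2": s.np2,
                "junction": s.junction,
                "junction_aa": s.junction_aa,
                "cdr3_aa": s.cdr3_aa,
                "productive": s.productive,
                "n_mutations": len(s.mutated_positions),
                "read": s.read,
            }
        )
    df = pd.DataFrame(rows, columns=_TRUTH_COLUMNS)
    return df.rename(columns={c: f"truth_{c}" for c in df.columns if c != "sequence_id"})


def write_reads_fasta(sims: Sequence[SimulatedRearrangement], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for s in sims:
            fh.write(f">{s.sequence_id}\n{s.read}\n")
    return path


# ---------------------------------------------------------------------------
# Presets: the four B-1 compartment x subset conditions
# ---------------------------------------------------------------------------

PRESET_NAMES = ("perc_b1a", "perc_b1b", "spleen_b1a", "spleen_b1b")

_V = {
    "VH1": "IGHV1-1*01", "VH2": "IGHV2-1*01", "VH3": "IGHV3-1*01",
    "VH4": "IGHV4-1*01", "VH5": "IGHV5-1*01", "VH6": "IGHV6-1*01",
    "VH10": "IGHV10-1*01", "VH11": "IGHV11-2*01", "VH12": "IGHV12-3*01",
    "VH14": "IGHV14-1*01",
}
_D = {"DH1-1": "IGHD1-1*01", "DH1-2": "IGHD1-2*01", "DH2": "IGHD2*01", "DH3": "IGHD3*01"}
_J = {"JH1": "IGHJ1*01", "JH2": "IGHJ2*01", "JH3": "IGHJ3*01", "JH4": "IGHJ4*01"}


def _usage(mapping: dict[str, str], weights: dict[str, float]) -> dict[str, float]:
    return {mapping[k]: w for k, w in weights.items()}


_PRESETS: dict[str, dict] = {
    # Dominant VH12/DH2/JH1, near-zero N burden, heavy clonality.
    "perc_b1a": dict(
        v=_usage(_V, {"VH12": 0.82, "VH11": 0.05, "VH1": 0.04, "VH2": 0.02,
                      "VH3": 0.02, "VH5": 0.02, "VH6": 0.01, "VH10": 0.01,
                      "VH4": 0.005, "VH14": 0.005}),
        d=_usage(_D, {"DH2": 0.80, "DH1-1": 0.08, "DH3": 0.07, "DH1-2": 0.05}),
        j=_usage(_J, {"JH1": 0.82, "JH2": 0.08, "JH3": 0.06, "JH4": 0.04}),
        n_len_dist=(0.95, 0.02, 0.015, 0.01, 0.005),
        clone_p=0.42,
    ),
    # Spread V usage (VH1/2/3/6/14), moderate N burden.
    "perc_b1b": dict(
        v=_usage(_V, {"VH1": 0.22, "VH2": 0.13, "VH3": 0.13, "VH6": 0.12,
                      "VH14": 0.12, "VH12": 0.08, "VH4": 0.05, "VH5": 0.05,
                      "VH10": 0.05, "VH11": 0.05}),
        d=_usage(_D, {"DH2": 0.45, "DH1-1": 0.25, "DH3": 0.20, "DH1-2": 0.10}),
        j=_usage(_J, {"JH1": 0.30, "JH2": 0.25, "JH4": 0.25, "JH3": 0.20}),
        n_len_dist=(0.55, 0.15, 0.12, 0.08, 0.05, 0.03, 0.02),
        clone_p=0.63,
    ),
    # VH1-dominant with residual VH12, heavier N burden.
    "spleen_b1a": dict(
        v=_usage(_V, {"VH1": 0.40, "VH12": 0.15, "VH2": 0.07, "VH5": 0.07,
                      "VH14": 0.07, "VH6": 0.06, "VH11": 0.06, "VH10": 0.05,
                      "VH3": 0.04, "VH4": 0.03}),
        d=_usage(_D, {"DH2": 0.35, "DH1-1": 0.30, "DH3": 0.20, "DH1-2": 0.15}),
        j=_usage(_J, {"JH1": 0.35, "JH4": 0.25, "JH2": 0.20, "JH3": 0.20}),
        n_len_dist=(0.45, 0.15, 0.13, 0.10, 0.07, 0.05, 0.05),
        clone_p=0.68,
    ),
    # VH1/VH14, balanced DH1-1/DH2, JH4-shifted, heaviest N burden, least clonal.
    "spleen_b1b": dict(
        v=_usage(_V, {"VH1": 0.45, "VH14": 0.15, "VH4": 0.08, "VH5": 0.08,
                      "VH11": 0.08, "VH2": 0.04, "VH3": 0.04, "VH6": 0.03,
                      "VH10": 0.03, "VH12": 0.02}),
        d=_usage(_D, {"DH1-1": 0.40, "DH2": 0.40, "DH3": 0.12, "DH1-2": 0.08}),
        j=_usage(_J, {"JH4": 0.35, "JH3": 0.25, "JH2": 0.20, "JH1": 0.20}),
        n_len_dist=(0.22, 0.08, 0.10, 0.12, 0.12, 0.12, 0.10, 0.08, 0.06),
        clone_p=0.79,
    ),
}


def preset_model(
    name: str, germline: GermlineSet | None = None, seed: int = 0, **overrides
) -> RecombinationModel:
    """One of the four B-1 condition presets over the bundled reference."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    cfg = _PRESETS[name]
    kwargs = dict(
        germline=germline or builtin_germline(),
        v_usage=cfg["v"],
        d_usage=cfg["d"],
        j_usage=cfg["j"],
        n_len_dist=cfg["n_len_dist"],
        clone_p=cfg["clone_p"],
        require_inframe=True,
        name=name,
        seed=seed,
    )
    kwargs.update(overrides)
    return RecombinationModel(**kwargs)


# ---------------------------------------------------------------------------
# Recovery reporting
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """Per-field agreement between generative truth and annotation."""

    n: int
    n_ok: int
    v_agreement: float
    d_agreement: float
    j_agreement: float
    np1_agreement: float
    np2_agreement: float
    cdr3_agreement: float
    accidental_extension_ids: frozenset[str]
    clean_np_agreement: float
    n_clean: int
    np_le_generated_violations: int


def _accidental_extension(
    sim_row: pd.Series, germline: GermlineSet, min_d_match: int
) -> bool:
    """Whether annotation is expected to deviate from the generated N counts.

    Conservatively flags every read where the maximal-templated convention
    can reassign generated junction bases to a templated region: generated
    P-nucleotides (counted as N by the default annotation), N/D bases that
    happen to continue a trimmed germline terminus, a D core shorter than
    the call threshold, or an insert whose best exact D placement differs
    from the generative one.
    """
    v = germline[sim_row["truth_v_call"]].sequence
    d = germline[sim_row["truth_d_call"]].sequence
    j = germline[sim_row["truth_j_call"]].sequence
    trim_v, trim_j = int(sim_row["truth_trim_v"]), int(sim_row["truth_trim_j"])
    trim_d5, trim_d3 = int(sim_row["truth_trim_d5"]), int(sim_row["truth_trim_d3"])
    p_v = sim_row["truth_p_v"] or ""
    p_j = sim_row["truth_p_j"] or ""
    n1 = sim_row["truth_n1"] or ""
    n2 = sim_row["truth_n2"] or ""
    d_core = sim_row["truth_d_core"] or ""
    if sim_row["truth_n_mutations"]:
        return True
    if p_v or p_j:
        return True
    if len(d_core) < min_d_match:
        return True
    insert = n1 + d_core + n2
    # V terminus continuation
    if trim_v > 0:
        rest = insert + j[trim_j:]
        if rest and rest[0] == v[len(v) - trim_v]:
            return True
    # J terminus continuation
    if trim_j > 0:
        before = v[: len(v) - trim_v] + insert
        if before and before[-1] == j[trim_j - 1]:
            return True
    # D terminus continuation into the N regions
    if trim_d5 > 0 and n1 and n1[-1] == d[trim_d5 - 1]:
        return True
    if trim_d3 > 0 and n2 and n2[0] == d[len(d) - trim_d3]:
        return True
    # alternative exact D placements in the insert
    best = None
    for seg in sorted(germline.of_type("D"), key=lambda s: s.name):
        hit = _longest_common_substring(insert, seg.sequence)
        if hit is None or hit[0] < min_d_match:
            continue
        L, ins_start, _ = hit
        cand = (-L, seg.name, ins_start)
        if best is None or cand < best:
            best = cand
    if best is None:
        return True
    L, ins_start = -best[0], best[2]
    return not (L == len(d_core) and ins_start == len(n1))


def recovery_report(
    truth: pd.DataFrame,
    annotations: Sequence[Rearrangement],
    germline: GermlineSet,
    min_d_match: int = 5,
) -> RecoveryReport:
    """Compare annotations against simulator ground truth, id by id."""
    ann = {r.sequence_id: r for r in annotations}
    truth_ids = list(truth["sequence_id"])
    if set(truth_ids) != set(ann):
        raise ValueError("sequence_id mismatch between truth table and annotations")

    n = len(truth_ids)
    agree = {k: 0 for k in ("v", "d", "j", "np1", "np2", "cdr3")}
    n_ok = 0
    dirty_ids: set[str] = set()
    clean_np_ok = 0
    n_clean = 0
    np_violations = 0
    for _, row in truth.iterrows():
        r = ann[row["sequence_id"]]
        dirty = _accidental_extension(row, germline, min_d_match)
        if dirty:
            dirty_ids.add(row["sequence_id"])
        if not r.annotation_ok:
            continue
        n_ok += 1
        agree["v"] += r.v_call == row["truth_v_call"]
        agree["d"] += r.d_call == row["truth_d_call"]
        agree["j"] += r.j_call == row["truth_j_call"]
        np1_match = r.np1_length == int(row["truth_np1"])
        np2_match = r.np2_length == int(row["truth_np2"])
        agree["np1"] += np1_match
        agree["np2"] += np2_match
        agree["cdr3"] += r.cdr3_aa == row["truth_cdr3_aa"]
        if r.np1_length is not None and r.np1_length > int(row["truth_np1"]):
            np_violations += 1
        if r.np2_length is not None and r.np2_length > int(row["truth_np2"]):
            np_violations += 1
        if not dirty:
            n_clean += 1
            clean_np_ok += np1_match and np2_match
    denom = max(n_ok, 1)
    return RecoveryReport(
        n=n,
        n_ok=n_ok,
        v_agreement=agree["v"] / denom,
        d_agreement=agree["d"] / denom,
        j_agreement=agree["j"] / denom,
        np1_agreement=agree["np1"] / denom,
        np2_agreement=agree["np2"] / denom,
        cdr3_agreement=agree["cdr3"] / denom,
        accidental_extension_ids=frozenset(dirty_ids),
        clean_np_agreement=clean_np_ok / max(n_clean, 1),
        n_clean=n_clean,
        np_le_generated_violations=np_violations,
    )
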