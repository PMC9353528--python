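"""End-to-end pipeline: simulate/load -> annotate -> summarize -> compare.

A :class:`PipelineConfig` declares the germline reference, a set of named
repertoires (simulated from a preset, or loaded from FASTA/AIRR), and the
between-repertoire comparisons to run.  :func:`run_pipeline` writes, per
repertoire, an AIRR Rearrangement TSV (plus reads FASTA and ground-truth
TSV for simulated input), a summary JSON + tidy CSV, a comparisons CSV +
JSON, and a run manifest (config hash, seed, versions).  Outputs are
byte-identical for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .airr_io import read_airr, write_airr
from .annotate import AnnotationParams, annotate_repertoire
from .compare import (
    category_counts_vector,
    chi2_contingency,
    compare_family_usage,
    mann_whitney,
    n_addition_sums,
)
from .germline import GermlineSet, builtin_germline, load_germline
from .simulate import (
    PRESET_NAMES,
    preset_model,
    simulate_repertoire,
    truth_table,
    write_reads_fasta,
)
from .stats import summarize_repertoire

logger = logging.getLogger("igmrep")

__all__ = ["RepertoireSpec", "PipelineConfig", "run_pipeline"]

_WHATS = ("categories", "n_additions", "usage")


@dataclass
class RepertoireSpec:
    name: str
    mode: str = "simulate"  # simulate | fasta | airr
    preset: str | None = None
    n: int = 500
    path: str | None = None


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    germline_fasta: str | None = None  # None -> bundled reference
    germline_anchors: str | None = None
    repertoires: list[RepertoireSpec] = field(default_factory=list)
    comparisons: list[dict] = field(default_factory=list)
    annotation: dict = field(default_factory=dict)
    include_unproductive: bool = False
    include_no_d: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        reps = [RepertoireSpec(**r) for r in data.pop("repertoires", [])]
        return cls(repertoires=reps, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def validate(self) -> None:
        if not self.repertoires:
            raise ValueError("no repertoires declared")
        names = [r.name for r in self.repertoires]
        if len(set(names)) != len(names):
            raise ValueError("repertoire names must be unique")
        if (self.germline_fasta is None) != (self.germline_anchors is None):
            raise ValueError("germline_fasta and germline_anchors must be given together")
        for p in (self.germline_fasta, self.germline_anchors):
            if p is not None and not Path(p).exists():
                raise ValueError(f"germline file not found: {p}")
        for r in self.repertoires:
            if r.mode not in ("simulate", "fasta", "airr"):
                raise ValueError(f"repertoire {r.name}: unknown mode {r.mode!r}")
            if r.mode == "simulate":
                if r.preset not in PRESET_NAMES:
                    raise ValueError(
                        f"repertoire {r.name}: preset must be one of {PRESET_NAMES}"
                    )
            elif r.path is None or not Path(r.path).exists():
                raise ValueError(f"repertoire {r.name}: input path not found: {r.path}")
        for c in self.comparisons:
            if c.get("a") not in names or c.get("b") not in names:
                raise ValueError(f"comparison references undeclared repertoire: {c}")
            if c.get("what", "categories") not in _WHATS:
                raise ValueError(f"comparison 'what' must be one of {_WHATS}: {c}")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _tidy_rows(summary) -> list[dict]:
    rows = []

    def add(stat, key, value):
        rows.append(
            {"repertoire": summary.name, "statistic": stat, "key": key, "value": value}
        )

    for k in ("n_total", "n_annotated", "n_productive", "n_no_d", "n_eligible"):
        add(k, "", getattr(summary, k))
    for cat, v in summary.category_freqs.items():
        add("category_freq_pct", cat, round(v, 1))
    for cat, v in summary.category_counts.items():
        add("category_count", cat, v)
    for stat in ("mean_np1", "mean_np2", "mean_sum"):
        v = getattr(summary, stat)
        add(stat, "", "" if v is None else round(v, 3))
    for st, table in summary.usage.items():
        for fam, freq in table.items():
            add(f"usage_{st}", fam, round(freq, 4))
    rf = summary.replicate_fraction
    add("replicate_fraction", "", "" if rf is None else round(rf, 4))
    return rows


def _run_comparison(c: dict, rearr_by_name: dict, germline: GermlineSet,
                    include_unproductive: bool) -> list[dict]:
    a, b = c["a"], c["b"]
    what = c.get("what", "categories")
    pair = f"{a}_vs_{b}"
    ra, rb = rearr_by_name[a], rearr_by_name[b]
    rows = []
    if what == "categories":
        res = chi2_contingency(
            category_counts_vector(ra, include_unproductive),
            category_counts_vector(rb, include_unproductive),
        )
        rows.append(
            {"pair": pair, "what": what, "segment_type": "", "family": "",
             "statistic": res.statistic, "df_or_u": res.df,
             "p_raw": res.p_value, "p_adjusted": "", "method": "chi2_2xK"}
        )
    elif what == "n_additions":
        res = mann_whitney(
            n_addition_sums(ra, include_unproductive),
            n_addition_sums(rb, include_unproductive),
        )
        rows.append(
            {"pair": pair, "what": what, "segment_type": "", "family": "",
             "statistic": res.u_statistic, "df_or_u": res.u_statistic,
             "p_raw": res.p_value, "p_adjusted": "",
             "method": f"mann_whitney_{res.method}"}
        )
    else:  # usage
        st = c.get("segment_type", "V")
        for fc in compare_family_usage(ra, rb, st, germline, include_unproductive):
            rows.append(
                {"pair": pair, "what": what, "segment_type": st, "family": fc.family,
                 "statistic": "", "df_or_u": "",
                 "p_raw": fc.p_raw, "p_adjusted": fc.p_adjusted,
                 "method": "fisher_exact+bh"}
            )
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a dict of output paths and summaries."""
    config.validate()  # no outputs written on validation failure
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.germline_fasta is not None:
        germline = load_germline(config.germline_fasta, config.germline_anchors)
    else:
        germline = builtin_germline()
    params = AnnotationParams(**config.annotation)

    manifest: dict = {
        "package": "igmrep",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "config": config.to_dict(),
        "stages": {},
    }
    outputs: dict = {"manifest": out_dir / "manifest.json"}
    rearr_by_name: dict = {}
    summaries: dict = {}

    try:
        for i, spec in enumerate(config.repertoires):
            logger.info("repertoire %s (%s)", spec.name, spec.mode)
            if spec.mode == "simulate":
                model = preset_model(spec.preset, germline)
                sims = simulate_repertoire(
                    model, spec.n, seed=int(1_000_003 * (config.seed + 1) + i) % (2**31),
                    id_prefix=spec.name,
                )
                write_reads_fasta(sims, out_dir / f"{spec.name}.reads.fasta")
                truth_table(sims).to_csv(
                    out_dir / f"{spec.name}.truth.tsv", sep="\t", index=False
                )
                reads = [(s.sequence_id, s.read) for s in sims]
                rearr = annotate_repertoire(reads, germline, params)
            elif spec.mode == "fasta":
                rearr = annotate_repertoire(spec.path, germline, params)
            else:
                rearr = read_airr(spec.path)
            write_airr(rearr, out_dir / f"{spec.name}.airr.tsv")
            rearr_by_name[spec.name] = rearr
            manifest["stages"][f"annotate:{spec.name}"] = {"n": len(rearr)}
        outputs["airr"] = {
            n: out_dir / f"{n}.airr.tsv" for n in rearr_by_name
        }

        for name, rearr in rearr_by_name.items():
            summaries[name] = summarize_repertoire(
                rearr,
                name=name,
                germline=germline,
                include_unproductive=config.include_unproductive,
                include_no_d=config.include_no_d,
            )
        summary_json = out_dir / "summary.json"
        with open(summary_json, "w") as fh:
            json.dump({n: s.to_dict() for n, s in summaries.items()}, fh, indent=2)
        tidy = pd.DataFrame(
            [row for s in summaries.values() for row in _tidy_rows(s)]
        )
        summary_csv = out_dir / "summary.csv"
        tidy.to_csv(summary_csv, index=False)
        outputs["summary_json"] = summary_json
        outputs["summary_csv"] = summary_csv
        manifest["stages"]["summarize"] = {"n_repertoires": len(summaries)}

        comp_rows = []
        for c in config.comparisons:
            comp_rows.extend(
                _run_comparison(c, rearr_by_name, germline, config.include_unproductive)
            )
        if config.comparisons:
            comp_csv = out_dir / "comparisons.csv"
            pd.DataFrame(comp_rows).to_csv(comp_csv, index=False)
            with open(out_dir / "comparisons.json", "w") as fh:
                json.dump(comp_rows, fh, indent=2)
            outputs["comparisons_csv"] = comp_csv
            manifest["stages"]["compare"] = {"n_tests": len(comp_rows)}
    except Exception as exc:
        manifest["failed_stage"] = repr(exc)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    outputs["summaries"] = summaries
    return outputs
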