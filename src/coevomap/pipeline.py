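"""End-to-end run orchestration with a declarative configuration.

A :class:`RunConfig` carries every threshold of the analysis (coverage,
gene separation, identity, gap ratio, distance cutoff, score floor,
selection rule) plus input/output paths.  :func:`run_pipeline` executes
pair → MSA → score → map, persists every intermediate artifact, and writes
a JSON report plus a JSON-lines log of the parameters used.  Identical
configuration and seed yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import tomllib
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .errors import ConfigError, CoevomapError
from .hits import (
    ITERATIVE_SEARCH_EVALUES,
    filter_hits,
    pair_by_locus,
    read_hit_table,
    write_paired_records,
)
from .msa import build_paired_msa, gap_filter, redundancy_filter, write_msa
from .scoring import (
    aggregate_contact_probability,
    mi_apc_scores,
    rank_inter_pairs,
    read_distogram,
    write_score_matrix,
)
from .structure import (
    annotate_pairs,
    interface_precision,
    load_structure,
    select_pairs,
    summarize_selection,
    write_selected_pairs,
    write_selection_summary,
)


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    # inputs
    hits_a: str = ""
    hits_b: str = ""
    family_a: str = "famA"
    family_b: str = "famB"
    profile_length_a: int = 0
    profile_length_b: int = 0
    structure: str = ""
    chain_map: str = ""
    distogram: str = ""
    out_dir: str = "run_out"
    # thresholds (defaults are the study's printed parameters)
    min_coverage: float = 0.60
    max_evalue: float = 1e-3
    max_separation: int = 20
    pairing: str = "closest"
    max_gap_ratio: float = 0.25
    max_identity: float = 0.90
    backend: str = "mi_apc"
    pseudocount: float = 1.0
    distance_cutoff: float = 12.0
    min_score: float = 0.05
    selection: str = "threshold70"
    contact_cutoff: float = 12.0
    scope: str = "hetero"
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (0.0 <= self.min_coverage <= 1.0, "min_coverage must be in [0, 1]"),
            (self.max_evalue >= 0, "max_evalue must be >= 0"),
            (self.max_separation >= 1, "max_separation must be >= 1"),
            (self.pairing in ("closest", "all"), "pairing must be closest|all"),
            (0.0 <= self.max_gap_ratio <= 1.0, "max_gap_ratio must be in [0, 1]"),
            (0.0 < self.max_identity <= 1.0, "max_identity must be in (0, 1]"),
            (
                self.backend in ("mi_apc", "distogram"),
                "backend must be mi_apc|distogram",
            ),
            (self.pseudocount >= 0, "pseudocount must be >= 0"),
            (self.distance_cutoff > 0, "distance_cutoff must be > 0"),
            (self.contact_cutoff > 0, "contact_cutoff must be > 0"),
            (self.scope == "hetero", "only scope=hetero is implemented"),
            (self.profile_length_a > 0, "profile_length_a must be > 0"),
            (self.profile_length_b > 0, "profile_length_b must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        if self.selection not in ("threshold70",) and not (
            self.selection.startswith("top:")
            or self.selection.startswith("min_score:")
        ):
            raise ConfigError(f"unknown selection mode {self.selection!r}")
        for name in ("hits_a", "hits_b", "structure", "chain_map"):
            value = getattr(self, name)
            if not value:
                raise ConfigError(f"missing required path {name!r}")
            if not Path(value).exists():
                raise ConfigError(f"{name}: no such file {value!r}")
        if self.backend == "distogram":
            if not self.distogram:
                raise ConfigError("backend=distogram requires a distogram path")
            if not Path(self.distogram).exists():
                raise ConfigError(f"distogram: no such file {self.distogram!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("rb") as fh:
            data = tomllib.load(fh)
        flat: dict = {}
        for key, value in data.items():
            if isinstance(value, dict):  # allow [inputs]/[params] grouping
                flat.update(value)
            else:
                flat[key] = value
        return cls.from_dict(flat)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the JSON report.

    Stages: read + filter hit tables, pair by genomic locus, build and
    curate the paired MSA, score inter-protein pairs (MI/APC or distogram
    aggregation), rank, select, map onto the structure, and measure
    interface precision.  Every intermediate is written under
    ``config.out_dir``; any stage failure aborts with the stage named.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run_log.jsonl"
    log_fh = log_path.open("w")

    def log(stage: str, **fields) -> None:
        log_fh.write(
            json.dumps({"stage": stage, **fields}, sort_keys=True) + "\n"
        )

    log(
        "config",
        version=__version__,
        config=dataclasses.asdict(config),
        upstream_search_evalue_schedule=list(ITERATIVE_SEARCH_EVALUES),
    )
    report: dict = {"version": __version__}

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except CoevomapError as exc:
            log_fh.close()
            raise CoevomapError(f"stage {name!r} failed: {exc}") from exc

    hits_a = stage(
        "read_hits_a",
        read_hit_table,
        config.hits_a,
        config.family_a,
        config.profile_length_a,
    )
    hits_b = stage(
        "read_hits_b",
        read_hit_table,
        config.hits_b,
        config.family_b,
        config.profile_length_b,
    )
    report["n_hits_a"] = len(hits_a)
    report["n_hits_b"] = len(hits_b)

    hits_a = stage(
        "filter_hits_a", filter_hits, hits_a, config.min_coverage, config.max_evalue
    )
    hits_b = stage(
        "filter_hits_b", filter_hits, hits_b, config.min_coverage, config.max_evalue
    )
    report["n_hits_a_filtered"] = len(hits_a)
    report["n_hits_b_filtered"] = len(hits_b)
    log("filter", n_a=len(hits_a), n_b=len(hits_b))

    pairs = stage(
        "pair_by_locus",
        pair_by_locus,
        hits_a,
        hits_b,
        config.max_separation,
        config.pairing,
    )
    report["n_paired_records"] = len(pairs)
    write_paired_records(pairs, out / "paired_records.tsv")
    log("pair", n_pairs=len(pairs))

    msa = stage(
        "build_msa",
        build_paired_msa,
        pairs,
        config.profile_length_a,
        config.profile_length_b,
    )
    msa = stage("gap_filter", gap_filter, msa, config.max_gap_ratio)
    report["n_rows_after_gap_filter"] = msa.n_rows
    msa = stage("redundancy_filter", redundancy_filter, msa, config.max_identity)
    report["n_rows_after_redundancy_filter"] = msa.n_rows
    write_msa(msa, out / "paired_msa.fasta")
    log("msa", n_rows=msa.n_rows, len_a=msa.len_a, len_b=msa.len_b)

    if config.backend == "mi_apc":
        inter, intra_a, intra_b = stage(
            "mi_apc_scores", mi_apc_scores, msa, config.pseudocount
        )
        write_score_matrix(intra_a, out / "scores_intra_a.tsv")
        write_score_matrix(intra_b, out / "scores_intra_b.tsv")
    else:
        disto = stage("read_distogram", read_distogram, config.distogram)
        inter = stage(
            "aggregate",
            aggregate_contact_probability,
            disto,
            config.distance_cutoff,
        )
    write_score_matrix(inter, out / "scores_inter.tsv")

    ranked = stage("rank", rank_inter_pairs, inter, config.min_score)
    report["n_ranked_pairs"] = len(ranked)
    log("score", backend=config.backend, n_ranked=len(ranked))

    selected = stage("select", select_pairs, ranked, config.selection)
    report["n_selected"] = len(selected)

    chain_map = json.loads(Path(config.chain_map).read_text())
    model = stage("load_structure", load_structure, config.structure, chain_map)
    selected = stage(
        "annotate",
        annotate_pairs,
        selected,
        model,
        config.family_a,
        config.family_b,
        config.contact_cutoff,
    )
    write_selected_pairs(selected, out / "selected_pairs.tsv")
    summary = summarize_selection(selected, config.contact_cutoff)
    write_selection_summary(summary, out / "selection_summary.json")
    report.update(
        {
            "selection_mode": config.selection,
            "categories": summary["categories"],
            "n_unresolved": summary["n_unresolved"],
        }
    )
    if "interface_precision" in summary:
        report["interface_precision"] = summary["interface_precision"]
    log("map", **{k: v for k, v in summary.items() if k != "categories"})

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    log("done")
    log_fh.close()
    return report
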