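"""End-to-end orchestration: simulate -> demux -> search -> LCA -> stats.

A run is driven by a YAML config (see :func:`load_config` for the schema
defaults) and a single top-level seed that is split per stage.  Every stage
writes its outputs under the run directory, and a manifest records the
config hash, the thresholds actually applied, and per-stage read
conservation counts, so a run is auditable end to end.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from .demux import DemuxConfigError, demux_pool, validate_windows
from .io_formats import read_fastx, read_lineages, write_fastx
from .simulator import (
    KINGDOM_OF_MARKER,
    simulate_community,
    simulate_reads,
    simulate_references,
    write_truth,
)
from .tag_design import DesignConfig, expand_design, read_primer_sheet, write_primer_sheet
from .taxonomy_lca import assign_all, blast_search, write_assignments

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "simulate": {
        "enabled": True,
        "n_taxa": {"16S": 24, "ITS": 18},
        "tree_depth": 6,
        "reads_per_library": 200,
        "error_rates": {"sub": 0.03, "ins": 0.03, "del": 0.03},
        "chimera_rate": 0.0,
        "profile_kinds": {},  # sample_id -> raw|sterilized|post_treatment
        "default_profile_kind": "raw",
        "design": {},  # DesignConfig overrides
    },
    "inputs": {  # used when simulate.enabled is false
        "reads": None,
        "primer_sheet": None,
        "references": {},  # marker -> fasta
        "lineages": {},  # marker -> tsv
    },
    "demux": {
        "min_coverage": 0.90,
        "windows": {"16S": [1200, 1700], "ITS": [600, 900]},
        "end_zone": 150,
        "score_floor": 18.0,
    },
    "taxonomy": {"min_top_bitscore": 100.0, "t": 0.995},
    "community": {"min_reads": 2, "kingdoms": dict(KINGDOM_OF_MARKER)},
}


class PipelineConfigError(ValueError):
    pass


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: Mapping) -> None:
    windows = {m: tuple(w) for m, w in cfg["demux"]["windows"].items()}
    try:
        validate_windows(windows)
    except DemuxConfigError as exc:
        raise PipelineConfigError(str(exc)) from exc
    for m in windows:
        if m not in ("16S", "ITS"):
            raise PipelineConfigError(f"unknown marker {m!r} in windows")
    if not cfg["simulate"]["enabled"]:
        inp = cfg["inputs"]
        if not inp.get("reads") or not inp.get("primer_sheet"):
            raise PipelineConfigError(
                "simulation disabled but inputs.reads/primer_sheet missing"
            )
        if inp.get("references") and not inp.get("lineages"):
            raise PipelineConfigError(
                "taxonomy requested (references given) but lineages missing"
            )
    t = cfg["taxonomy"]["t"]
    if not 0 < t <= 1:
        raise PipelineConfigError("taxonomy.t must be in (0, 1]")


def config_hash(cfg: Mapping) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    thresholds: dict[str, Any]
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def record(self, stage: str, **counts: Any) -> None:
        self.stages[stage] = counts

    def check_conservation(self) -> None:
        d = self.stages.get("demux")
        if d is not None:
            if sum(d["status_counts"].values()) != d["n_reads"]:
                raise AssertionError("demux status counts do not conserve reads")
        t = self.stages.get("taxonomy")
        if d is not None and t is not None:
            if t["n_assigned"] + t["n_unassigned"] != d["status_counts"]["assigned"]:
                raise AssertionError("taxonomy counts do not conserve reads")

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "thresholds": self.thresholds,
                "stages": self.stages,
            },
            indent=2,
            sort_keys=True,
        )


def run_pipeline(cfg: Mapping, out_dir: str | Path) -> RunManifest:
    """Execute all stages in fixed order under ``out_dir``.

    Reruns with an identical config (including seed) reproduce identical
    outputs.  Config errors surface before any compute.
    """
    _validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(
        config_hash=config_hash(cfg),
        seed=seed,
        thresholds={
            "min_coverage": cfg["demux"]["min_coverage"],
            "windows": cfg["demux"]["windows"],
            "min_top_bitscore": cfg["taxonomy"]["min_top_bitscore"],
            "t": cfg["taxonomy"]["t"],
            "min_reads": cfg["community"]["min_reads"],
        },
    )
    stage_seeds = np.random.SeedSequence(seed).spawn(4)

    # --- stage 1: obtain reads, primers, references -----------------------
    if cfg["simulate"]["enabled"]:
        plans, reads, ref_sets = _simulate_stage(cfg, out, stage_seeds)
        references = {
            m: out / f"references_{m}.fasta" for m in ref_sets
        }
        lineage_maps = {m: ref_sets[m].lineages for m in ref_sets}
    else:
        plans = read_primer_sheet(cfg["inputs"]["primer_sheet"])
        reads = list(read_fastx(cfg["inputs"]["reads"], "fastq"))
        references = {
            m: Path(p) for m, p in cfg["inputs"]["references"].items()
        }
        lineage_maps = {
            m: read_lineages(p) for m, p in cfg["inputs"]["lineages"].items()
        }
        manifest.record("input", n_reads=len(reads), n_libraries=len(plans))

    # --- stage 2: demultiplex --------------------------------------------
    windows = {m: tuple(w) for m, w in cfg["demux"]["windows"].items()}
    records, summary = demux_pool(
        reads,
        plans,
        windows,
        min_coverage=cfg["demux"]["min_coverage"],
        end_zone=cfg["demux"]["end_zone"],
        score_floor=cfg["demux"]["score_floor"],
        out_dir=out / "demux",
    )
    manifest.record(
        "demux",
        n_reads=summary.n_reads,
        status_counts=summary.status_counts,
        per_library_N=summary.per_library,
    )

    # --- stage 3: taxonomy per marker -------------------------------------
    lib_of_read = {
        r.read_id: r.library_id for r in records if r.status == "assigned"
    }
    marker_of_lib = {p.library_id: p.marker for p in plans}
    all_assignments = []
    all_unassigned: dict[str, str] = {}
    n_searched = 0
    for marker, ref_fasta in references.items():
        marker_reads = [
            r for r in records
            if r.status == "assigned" and marker_of_lib[r.library_id] == marker
        ]
        if not marker_reads:
            continue
        n_searched += len(marker_reads)
        query = out / f"trimmed_{marker}.fasta"
        from .io_formats import Read as _Read

        write_fastx(
            query,
            (_Read(r.read_id, r.trimmed_sequence) for r in marker_reads),
            "fasta",
        )
        hits = blast_search(
            query, ref_fasta, out / f"hits_{marker}.tsv"
        )
        assignments, unassigned = assign_all(
            hits,
            lineage_maps[marker],
            read_ids=[r.read_id for r in marker_reads],
            min_top_bitscore=cfg["taxonomy"]["min_top_bitscore"],
            t=cfg["taxonomy"]["t"],
        )
        all_assignments.extend(assignments)
        all_unassigned.update(unassigned)
    write_assignments(
        out / "assignments.tsv", all_assignments, all_unassigned, lib_of_read
    )
    manifest.record(
        "taxonomy",
        n_searched=n_searched,
        n_assigned=len(all_assignments),
        n_unassigned=len(all_unassigned)
        + (summary.status_counts["assigned"] - n_searched),
    )

    # --- stage 4: community tables and stats ------------------------------
    stats_frames = []
    mass_of_lib = {p.library_id: p.input_mass_ng for p in plans}
    for marker in references:
        marker_libs = [
            p.library_id for p in plans if p.marker == marker
        ]
        marker_assignments = [
            a for a in all_assignments
            if marker_of_lib[lib_of_read[a.read_id]] == marker
        ]
        if not marker_assignments:
            continue
        table = comm.build_otu_table(
            marker_assignments, lib_of_read, samples=marker_libs
        )
        table.write_tsv(out / f"otu_table_{marker}.tsv")
        kingdom = cfg["community"]["kingdoms"][marker]
        filtered = comm.min_count_filter(
            comm.kingdom_filter(table, kingdom),
            cfg["community"]["min_reads"],
        )
        filtered.write_tsv(out / f"otu_table_{marker}.filtered.tsv")
        stats = comm.sample_stats(
            filtered, summary.per_library, mass_of_lib
        )
        stats.insert(0, "marker", marker)
        stats_frames.append(stats)
        if len(filtered.samples) >= 2 and filtered.counts.size:
            comm.bray_curtis_matrix(filtered).to_csv(
                out / f"bray_curtis_{marker}.tsv", sep="\t"
            )
        comm.phylum_rollup(filtered).to_csv(
            out / f"phylum_{marker}.tsv", sep="\t", index_label="phylum"
        )
        manifest.record(
            f"community_{marker}",
            n_taxa=len(table.taxa),
            n_taxa_filtered=len(filtered.taxa),
            total_reads=int(table.counts.values.sum()),
            total_reads_filtered=int(filtered.counts.values.sum()),
        )
    if stats_frames:
        pd.concat(stats_frames).to_csv(out / "sample_stats.tsv", sep="\t")

    manifest.check_conservation()
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _simulate_stage(cfg: Mapping, out: Path, stage_seeds) -> tuple:
    sim = cfg["simulate"]
    design = DesignConfig(**sim.get("design", {}))
    plans = expand_design(design)
    write_primer_sheet(out / "primer_sheet.tsv", plans)

    markers = sorted({p.marker for p in plans})
    ref_rng = np.random.default_rng(stage_seeds[0])
    ref_sets = {}
    for m in markers:
        ref_sets[m] = simulate_references(
            sim["n_taxa"][m], m, sim["tree_depth"],
            seed=int(ref_rng.integers(2**31)),
        )
        ref_sets[m].write(
            out / f"references_{m}.fasta", out / f"lineages_{m}.tsv"
        )

    prof_rng = np.random.default_rng(stage_seeds[1])
    profiles = {}  # (marker, sample) -> profile
    kinds = sim.get("profile_kinds", {})
    default_kind = sim.get("default_profile_kind", "raw")
    for m in markers:
        for sample in {p.sample_id for p in plans if p.marker == m}:
            profiles[(m, sample)] = simulate_community(
                ref_sets[m],
                kinds.get(sample, default_kind),
                seed=int(prof_rng.integers(2**31)),
                sample_id=sample,
            )

    reads = []
    truth_frames = []
    read_rng = np.random.default_rng(stage_seeds[2])
    for m in markers:
        m_plans = [p for p in plans if p.marker == m]
        m_profiles = {
            s: profiles[(m, s)] for s in {p.sample_id for p in m_plans}
        }
        r, t = simulate_reads(
            {m: ref_sets[m]},
            m_profiles,
            m_plans,
            sim["reads_per_library"],
            sim["error_rates"],
            sim["chimera_rate"],
            seed=int(read_rng.integers(2**31)),
        )
        # re-key read ids so markers do not collide
        renamed = []
        for rd in r:
            renamed.append(
                type(rd)(f"{m}_{rd.read_id}", rd.sequence, rd.quality)
            )
        t["read_id"] = m + "_" + t["read_id"]
        reads.extend(renamed)
        truth_frames.append(t)
    truth = pd.concat(truth_frames, ignore_index=True)
    write_fastx(out / "reads.fastq", reads, "fastq")
    write_truth(out / "truth.tsv", truth)
    return plans, reads, ref_sets


def summarize(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Load the per-sample stats and per-phylum tables of a completed run."""
    run_dir = Path(run_dir)
    missing = [
        name
        for name in ("manifest.json", "sample_stats.tsv")
        if not (run_dir / name).exists()
    ]
    if missing:
        raise PipelineConfigError(
            f"incomplete run in {run_dir}: missing {', '.join(missing)}"
        )
    out: dict[str, pd.DataFrame] = {
        "sample_stats": pd.read_csv(run_dir / "sample_stats.tsv", sep="\t",
                                    index_col=0)
    }
    for p in sorted(run_dir.glob("phylum_*.tsv")):
        marker = p.stem.split("_", 1)[1]
        out[f"phylum_{marker}"] = pd.read_csv(p, sep="\t", index_col=0)
    return out
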