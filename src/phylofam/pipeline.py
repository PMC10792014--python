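"""End-to-end orchestration: simulate -> cluster -> reconcile -> complements
-> support -> motifs, with a JSON manifest recording every output file,
its checksum, and the per-stage derived seed.

All randomness flows from the single top-level seed; per-stage seeds are
derived deterministically, so identical config + seed gives byte-identical
outputs for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from . import clustering, complements, filters, reconcile, simulate, support
from .datasets import EXAMPLE_SPECIES_NEWICK
from .treeio import (
    SpeciesTree,
    leaf_species_map,
    parse_newick,
    parse_newick_file,
    write_newick,
)

log = logging.getLogger("phylofam")

ALL_STAGES = ["simulate", "cluster", "reconcile", "complements", "support", "motifs"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # inputs (paths); None means "use the previous stage's output"
    species_tree: str | None = None
    gene_trees: str | None = None
    pairs: str | None = None
    ref_tree: str | None = None
    replicates: str | None = None
    fasta: str | None = None
    annotations: str | None = None
    # simulation
    n_families: int = 5
    dup_rate: float = 0.5
    loss_rate: float = 0.2
    n_replicates: int = 20
    nni_per_replicate: int = 1
    # clustering
    thresholds: list[float] = field(
        default_factory=lambda: [1e-35, 1e-15, 1e-6]
    )
    dedup_policy: str = "min"
    # reconciliation
    separator: str = "_"
    position: str = "prefix"
    dup_cost: float = 1.0
    loss_cost: float = 1.0
    # filtering
    motif_window: int = 60
    motif_offset: int = 0
    min_tm: int = 5
    max_tm: int = 8
    unknown_keys: list[str] = field(default_factory=list)

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        """Flat ``key = value`` config format; '#' starts a comment."""
        raw: dict[str, str] = {}
        with open(path) as handle:
            for line in handle:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = value.strip()
        known = {f.name for f in fields(cls)} - {"unknown_keys"}
        kwargs: dict = {"unknown_keys": sorted(set(raw) - known)}
        for key, value in raw.items():
            if key not in known:
                continue
            if key == "stages":
                kwargs[key] = [s.strip() for s in value.split(",") if s.strip()]
            elif key == "thresholds":
                kwargs[key] = [float(x) for x in value.split(",") if x.strip()]
            elif key in ("seed", "n_families", "n_replicates",
                         "nni_per_replicate", "motif_window", "motif_offset",
                         "min_tm", "max_tm"):
                kwargs[key] = int(value)
            elif key in ("dup_rate", "loss_rate", "dup_cost", "loss_cost"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        kwargs.update(overrides)
        if "out_dir" not in kwargs:
            raise ValueError("config must set out_dir")
        return cls(**kwargs)


def validate_config(config: RunConfig) -> list[str]:
    """Report-only validation: missing paths, inconsistent options,
    unknown keys. An empty list means the config looks runnable."""
    problems = []
    for key in config.unknown_keys:
        problems.append(f"unknown config key: {key}")
    for stage in config.stages:
        if stage not in ALL_STAGES:
            problems.append(f"unknown stage: {stage}")
    for name in ("species_tree", "gene_trees", "pairs", "ref_tree",
                 "replicates", "fasta", "annotations"):
        path = getattr(config, name)
        if path is not None and not os.path.exists(path):
            problems.append(f"missing path for {name}: {path}")
    if any(
        b <= a for a, b in zip(config.thresholds, config.thresholds[1:])
    ):
        problems.append("unsorted ladder: thresholds must be strictly increasing")
    if config.dedup_policy not in ("min", "max", "mean"):
        problems.append(f"unknown dedup_policy: {config.dedup_policy}")
    if "cluster" in config.stages and "simulate" not in config.stages \
            and config.pairs is None:
        problems.append("cluster stage needs pairs= when simulate is not run")
    if "reconcile" in config.stages and "simulate" not in config.stages \
            and config.gene_trees is None:
        problems.append("reconcile stage needs gene_trees= when simulate is not run")
    # motifs is auto-skipped in an all-stages run without sequences; only an
    # explicit narrower stage selection makes the missing input an error
    if ("motifs" in config.stages and config.fasta is None
            and set(config.stages) != set(ALL_STAGES)):
        problems.append("motifs stage needs fasta=")
    return problems


def _stage_seed(base_seed: int, stage: str) -> int:
    idx = ALL_STAGES.index(stage)
    return int(
        np.random.SeedSequence(entropy=[base_seed, idx]).generate_state(1)[0]
    )


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _load_species_tree(config: RunConfig) -> SpeciesTree:
    if config.species_tree is not None:
        with open(config.species_tree) as handle:
            return SpeciesTree.from_newick(handle.read())
    return SpeciesTree.from_newick(EXAMPLE_SPECIES_NEWICK)


# ---------------------------------------------------------------------------
# Stages. Each returns {relative filename: params-dict-free note}; outputs
# are written under config.out_dir and recorded by the driver.
# ---------------------------------------------------------------------------


def _stage_simulate(config: RunConfig, ctx: dict, seed: int) -> list[str]:
    st = ctx["species_tree"]
    params = simulate.SimParams(config.dup_rate, config.loss_rate, seed=seed)
    fams = simulate.simulate_families(
        st, config.n_families, params, separator=config.separator
    )
    ctx["families"] = [t for t, _ in fams if t is not None]
    ctx["event_logs"] = [log_ for _, log_ in fams]

    out = config.out_dir
    files = []
    with open(os.path.join(out, "species.nwk"), "w") as handle:
        handle.write(write_newick(st.tree) + "\n")
    files.append("species.nwk")
    with open(os.path.join(out, "families.nwk"), "w") as handle:
        for tree in ctx["families"]:
            handle.write(write_newick(tree) + "\n")
    files.append("families.nwk")
    with open(os.path.join(out, "events.json"), "w") as handle:
        json.dump(
            [log_.to_dict() for log_ in ctx["event_logs"]],
            handle, sort_keys=True, indent=1,
        )
    files.append("events.json")

    graph = simulate.simulate_similarity(
        ctx["families"], seed=_stage_seed(seed, "cluster")
    )
    ctx["graph"] = graph
    clustering.write_blast_tsv(graph, os.path.join(out, "pairs.tsv"))
    files.append("pairs.tsv")

    ref = next((t for t in ctx["families"] if len(t.leaves()) >= 4), None)
    if ref is not None:
        ctx["ref_tree"] = ref
        reps = [
            simulate.perturb_tree(ref, config.nni_per_replicate, seed=seed + k)
            for k in range(config.n_replicates)
        ]
        ctx["replicates"] = reps
        with open(os.path.join(out, "replicates.nwk"), "w") as handle:
            for rep in reps:
                handle.write(write_newick(rep) + "\n")
        files.append("replicates.nwk")
    return files


def _stage_cluster(config: RunConfig, ctx: dict, seed: int) -> list[str]:
    if config.pairs is not None:
        graph = clustering.build_graph(config.pairs, config.dedup_policy)
    elif "graph" in ctx:
        graph = clustering.build_graph(
            os.path.join(config.out_dir, "pairs.tsv"), config.dedup_policy
        )
    else:
        raise ValueError("no pairs input available")
    partitions = clustering.threshold_profile(graph, config.thresholds)
    rows = []
    for part in partitions:
        for vid, cid in sorted(part.assignment.items()):
            rows.append(
                {"vertex": vid, "threshold": part.threshold, "component": cid}
            )
    pd.DataFrame(rows).to_csv(
        os.path.join(config.out_dir, "partitions.tsv"), sep="\t", index=False
    )
    ctx["partitions"] = partitions
    return ["partitions.tsv"]


def _load_gene_trees(config: RunConfig, ctx: dict):
    if config.gene_trees is not None:
        return parse_newick_file(config.gene_trees)
    if "families" in ctx:
        return ctx["families"]
    raise ValueError("no gene trees available")


def _stage_reconcile(config: RunConfig, ctx: dict, seed: int) -> list[str]:
    st = ctx["species_tree"]
    weights = reconcile.CostWeights(config.dup_cost, config.loss_cost)
    trees = _load_gene_trees(config, ctx)
    recons = []
    summaries = []
    nhx_lines = []
    for k, tree in enumerate(trees):
        binary = reconcile.resolve_polytomies(tree, seed=seed + k)
        lmap = leaf_species_map(
            binary, st, separator=config.separator, position=config.position
        )
        if binary.rooted:
            recon = reconcile.reconcile(binary, st, lmap)
        else:
            recon = reconcile.root_by_dl(binary, st, lmap, weights).reconciliation
        recons.append(recon)
        summary = recon.to_dict()
        summary["family"] = f"fam{k}"
        summary["cost"] = recon.cost(weights)
        summaries.append(summary)
        nhx_lines.append(reconcile.reconciliation_to_nhx(recon))
    ctx["reconciliations"] = recons
    with open(os.path.join(config.out_dir, "reconciled.nhx"), "w") as handle:
        handle.write("\n".join(nhx_lines) + "\n")
    with open(os.path.join(config.out_dir, "reconcile_summary.json"), "w") as handle:
        json.dump(summaries, handle, sort_keys=True, indent=1)
    return ["reconciled.nhx", "reconcile_summary.json"]


def _stage_complements(config: RunConfig, ctx: dict, seed: int) -> list[str]:
    st = ctx["species_tree"]
    recons = ctx.get("reconciliations")
    if recons is None:
        raise ValueError("complements stage requires the reconcile stage")
    columns = {
        f"fam{k}": complements.copy_numbers(r) for k, r in enumerate(recons)
    }
    table = pd.DataFrame(columns)
    table.index.name = "node"
    table.to_csv(os.path.join(config.out_dir, "complements.tsv"), sep="\t")

    assignments = []
    reference = [st.leaf_labels()[0]]
    for k, recon in enumerate(recons):
        lmap = leaf_species_map(
            recon.gene_tree, st,
            separator=config.separator, position=config.position,
        )
        assignments.append(
            complements.orthogroups(
                recon, lmap, reference, family=f"fam{k}",
                separator=config.separator, position=config.position,
            )
        )
    presence = complements.presence_matrix(assignments, st.leaf_labels())
    presence.to_csv(os.path.join(config.out_dir, "presence.tsv"), sep="\t")
    bursts = complements.duplication_bursts(recons, st)
    bursts.index.name = "node"
    bursts.to_csv(os.path.join(config.out_dir, "bursts.tsv"), sep="\t")
    return ["complements.tsv", "presence.tsv", "bursts.tsv"]


def _stage_support(config: RunConfig, ctx: dict, seed: int) -> list[str]:
    if config.ref_tree is not None:
        ref = parse_newick_file(config.ref_tree)[0]
    else:
        ref = ctx.get("ref_tree")
    if config.replicates is not None:
        reps = parse_newick_file(config.replicates, expect_rooted=False)
    else:
        reps = ctx.get("replicates")
    if ref is None or not reps:
        raise ValueError("support stage needs a reference tree and replicates")
    table = support.evaluate_support(ref, reps)
    rows = [
        {
            "branch": "|".join(sorted(b.bipartition)),
            "p": b.p,
            "tbe": b.tbe,
            "fbp": b.fbp,
            "tbe_class": support.classify_support(b.tbe),
            "fbp_class": support.classify_support(b.fbp),
        }
        for b in table
    ]
    pd.DataFrame(rows).to_csv(
        os.path.join(config.out_dir, "supports.tsv"), sep="\t", index=False
    )
    annotated = support.annotate_tree(ref, table)
    with open(os.path.join(config.out_dir, "supports.nwk"), "w") as handle:
        handle.write(write_newick(annotated) + "\n")
    return ["supports.tsv", "supports.nwk"]


def _stage_motifs(config: RunConfig, ctx: dict, seed: int) -> list[str]:
    if config.fasta is None:
        raise ValueError("motifs stage needs fasta=")
    records = filters.read_candidates(config.fasta, config.annotations)
    report = filters.candidate_report(
        records,
        window=config.motif_window,
        offset=config.motif_offset,
        min_tm=config.min_tm,
        max_tm=config.max_tm,
    )
    report.to_csv(os.path.join(config.out_dir, "candidates.tsv"), sep="\t")
    return ["candidates.tsv"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "cluster": _stage_cluster,
    "reconcile": _stage_reconcile,
    "complements": _stage_complements,
    "support": _stage_support,
    "motifs": _stage_motifs,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; returns (and
    writes) the manifest. A stage failure aborts the run with the failing
    stage named; outputs of completed stages stay on disk and are marked
    complete in the partial manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    os.makedirs(config.out_dir, exist_ok=True)
    ctx: dict = {"species_tree": _load_species_tree(config)}
    manifest: dict = {"seed": config.seed, "stages": {}}
    stages = [s for s in ALL_STAGES if s in config.stages]
    if "motifs" in stages and config.fasta is None:
        stages.remove("motifs")
    for stage in stages:
        seed = _stage_seed(config.seed, stage)
        started = time.perf_counter()
        try:
            files = _STAGE_FN[stage](config, ctx, seed)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(config, manifest)
            raise PipelineError(stage, exc) from exc
        elapsed = time.perf_counter() - started
        log.info("stage %s finished in %.2fs", stage, elapsed)
        manifest["stages"][stage] = {
            "status": "complete",
            "seed": seed,
            "outputs": {
                name: _sha256(os.path.join(config.out_dir, name))
                for name in files
            },
        }
    _write_manifest(config, manifest)
    return manifest


def _write_manifest(config: RunConfig, manifest: dict) -> None:
    path = os.path.join(config.out_dir, "manifest.json")
    with open(path, "w") as handle:
        json.dump(manifest, handle, sort_keys=True, indent=1)
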