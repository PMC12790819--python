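"""End-to-end simulation pipeline.

``run_simulate`` executes plate -> graph -> pattern -> assignment ->
expression -> (optional) spot aggregation from a resolved configuration,
writes every artifact to the output directory, and returns a manifest.
Randomness flows from the single top-level seed through named
SeedSequence spawns, so identical configs reproduce outputs byte for
byte.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as stio
from .aggregate import aggregate_to_spots, make_spot_lattice
from .assign import assign_celltypes, epoch_schedule
from .config import dump_config, resolve_config
from .errors import ConfigError, SchemaError, StforgeError
from .expression import SingleCellST, sample_expression, simulate_reference
from .patterns import LayerLayout, PatternSpec, predefined_pattern
from .plate import build_graph, generate_plate


def _pattern_from_config(cfg: dict) -> PatternSpec:
    p = cfg["pattern"]
    if p["mode"] == "custom":
        if p["transition"] is None or p["proportions"] is None:
            raise ConfigError("custom pattern requires proportions and transition")
        return PatternSpec(
            proportions=np.asarray(p["proportions"], float),
            transition=np.asarray(p["transition"], float),
            mode="custom",
            type_names=p["type_names"],
        )
    return predefined_pattern(
        p["mode"],
        p["n_types"],
        group_assignment=p["group_assignment"],
        dominant_prob=p["dominant_prob"],
        proportions=p["proportions"],
        type_names=p["type_names"],
    )


def run_simulate(config: dict | None = None, **overrides) -> dict:
    """Run the full simulation described by ``config``.

    Returns the output manifest (also written as ``manifest.json``).  Any
    stage failure is re-raised with the stage name prefixed and the
    partial output directory marked incomplete.
    """
    cfg = resolve_config({**(config or {}), **overrides})
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    incomplete = outdir / "INCOMPLETE"
    incomplete.write_text("run in progress\n")
    log_lines: list[str] = [f"seed: {cfg['seed']}"]
    manifest: dict = {"outdir": str(outdir)}
    seeds = np.random.SeedSequence(cfg["seed"]).generate_state(8, dtype=np.uint64)
    seeds = [int(s % (2**31 - 1)) for s in seeds]

    stage = "plate"
    try:
        pc = cfg["plate"]
        plate = generate_plate(
            pc["n"], mode=pc["mode"], bounds=pc["bounds"], dim=pc["dim"], seed=seeds[0]
        )

        stage = "graph"
        gc = cfg["graph"]
        graph = build_graph(plate, method=gc["method"], param=gc["param"], metric=gc["metric"])
        log_lines.append(
            f"graph: {gc['method']} param={gc['param']} edges={graph.n_edges}"
        )

        stage = "pattern"
        spec = _pattern_from_config(cfg)
        manifest["pattern"] = spec.to_dict()

        stage = "assign"
        ac = cfg["anneal"]
        schedule = epoch_schedule(
            plate.n_cells,
            bounds=plate.bounds[:2],
            alpha=ac["alpha"],
            tmin_frac=ac["tmin_frac"],
            stall_limit=ac["stall_limit"],
            max_temps=ac["max_temps"],
        )
        log_lines.append(f"schedule: {schedule.describe()}")
        if spec.mode in ("layered", "gyrus"):
            # layered fields are sampled geometrically, then logged against
            # the implied transition matrix
            from .patterns import layered_labels

            layout = LayerLayout.equal_strata(
                plate,
                cfg["pattern"]["n_layers"] or spec.n_types,
                dominant_prob=cfg["pattern"]["dominant_prob"],
                amplitude=0.15 * plate.extents[1] if spec.mode == "gyrus" else 0.0,
            )
            labels = layered_labels(
                plate, layout, n_types=spec.n_types, seed=seeds[1]
            )
            from .assign import Assignment, objective

            assignment = Assignment(
                labels=labels,
                n_types=spec.n_types,
                target_counts=np.bincount(labels, minlength=spec.n_types),
                objective_value=objective(labels, graph.adjacency, spec.transition),
                trace=np.zeros(1),
                method=spec.mode,
            )
        else:
            assignment = assign_celltypes(
                graph, plate, spec, method=ac["method"], schedule=schedule, seed=seeds[2]
            )
        log_lines.append(f"final objective: {assignment.objective_value:.6f}")
        trace_path = outdir / "objective_trace.csv"
        pd.DataFrame(
            {"iteration": np.arange(assignment.trace.size), "objective": assignment.trace}
        ).to_csv(trace_path, index=False)
        manifest["objective_trace"] = str(trace_path)
        manifest["objective"] = assignment.objective_value

        stage = "expression"
        ec = cfg["expression"]
        names = spec.type_names
        str_labels = np.asarray([names[i] for i in assignment.labels])
        if ec["source"] == "none":
            import scipy.sparse as sp

            counts = sp.csr_matrix((plate.n_cells, 0))
            gene_ids: list[str] = []
            provenance = None
        else:
            if ec["source"] == "reference":
                ref = stio.read_labeled_reference(
                    matrix=ec["reference_matrix"],
                    genes=ec["reference_genes"],
                    labels=ec["reference_labels"],
                )
            elif ec["source"] == "simulate":
                ref = simulate_reference(
                    n_types=spec.n_types,
                    n_genes=ec["n_genes"],
                    n_cells_per_type=ec["n_cells_per_type"],
                    baseline_mean=ec["baseline_mean"],
                    dispersion=ec["dispersion"],
                    marker_fold=ec["marker_fold"],
                    n_markers_per_type=ec["n_markers_per_type"],
                    type_names=names,
                    seed=seeds[3],
                )
            else:
                raise ConfigError(f"unknown expression source {ec['source']!r}")
            counts, provenance = sample_expression(str_labels, ref, seed=seeds[4])
            gene_ids = list(ref.gene_ids)

        sc = SingleCellST(
            plate=plate,
            labels=str_labels,
            counts=counts,
            gene_ids=gene_ids,
            provenance=provenance,
        )
        manifest["dataset"] = stio.write_dataset(sc, outdir)

        stage = "aggregate"
        if cfg["spots"]["enabled"]:
            scfg = cfg["spots"]
            grid = make_spot_lattice(
                plate.bounds, shape=scfg["shape"], size=scfg["size"], lattice=scfg["lattice"]
            )
            spots = aggregate_to_spots(sc, grid)
            manifest["spots"] = stio.write_spots(spots, outdir)
            manifest["spots"]["uncaptured"] = spots.uncaptured
            log_lines.append(
                f"spots: {grid.n_spots} spots, {spots.uncaptured} uncaptured cells"
            )

        stage = "finalize"
        dump_config(cfg, outdir / "config.yaml")
        manifest["config"] = str(outdir / "config.yaml")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        manifest["log"] = str(outdir / "run.log")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        incomplete.unlink(missing_ok=True)
        return manifest
    except ConfigError as exc:
        raise ConfigError(f"[stage: {stage}] {exc}") from exc
    except SchemaError as exc:
        raise SchemaError(f"[stage: {stage}] {exc}") from exc
    except StforgeError as exc:
        raise StforgeError(f"[stage: {stage}] {exc}") from exc
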