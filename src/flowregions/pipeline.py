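"""End-to-end orchestration: records in, report bundle out.

Stage order mirrors the analysis: read -> validate -> OD build -> origin
filter -> sufficiency table -> successive enlargement (per micro-region and
for the designated region) -> flow network and hub-excluded network ->
catchments and displacement statistics.  Every stage logs its in/out counts
so the conservation identity (records = matrix total = edges + self-flows +
dropped) can be audited from the log alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .io import (
    StudyConfig,
    UnitTable,
    read_admissions,
    read_units,
    validate_dataset,
)
from .od import (
    ODMatrix,
    apply_origin_filter,
    build_od_matrix,
    cross_border_summary,
    delineate_functional_region,
)
from .sufficiency import frech_enlarge, sufficiency_table, sufficiency_table_to_csv
from .network import (
    build_flow_graph,
    edge_weight_sum,
    graph_to_edge_csv,
    graph_to_graphml,
    identify_hubs,
    node_metrics_to_csv,
    origin_entropy,
    remove_node_subnetwork,
    weak_components,
)
from .geo import catchment_quartiles, displacement_stats

log = logging.getLogger("flowregions")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ReportBundle:
    """Paths and metadata of a completed pipeline run."""

    out_dir: Path
    sufficiency_csv: Path
    enlargement_json: Path
    edges_csv: Path
    graphml: Path
    node_metrics_csv: Path
    entropy_csv: Path
    catchments_csv: Path
    catchments_geojson: Path
    cross_border_json: Path
    od_long_csv: Path
    metadata_json: Path
    summary: dict = field(default_factory=dict)


def run_pipeline(
    config: StudyConfig,
    admissions_path: str | Path,
    units_path: str | Path,
    out_dir: str | Path,
) -> ReportBundle:
    """Run the whole analysis and write the report bundle to ``out_dir``.

    Deterministic for fixed inputs and config; a stage failure removes any
    partial outputs and raises :class:`PipelineError` naming the stage.
    """
    out_dir = Path(out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, Path(admissions_path), Path(units_path), out_dir)
    except PipelineError:
        _cleanup(out_dir, created)
        raise
    except Exception as exc:  # pragma: no cover - defensive
        _cleanup(out_dir, created)
        raise PipelineError("unknown", exc) from exc


def _cleanup(out_dir: Path, created: bool) -> None:
    if created:
        shutil.rmtree(out_dir, ignore_errors=True)
    else:
        for child in out_dir.glob("*"):
            if child.is_file():
                child.unlink()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    return wrap


def _run(
    config: StudyConfig, admissions_path: Path, units_path: Path, out_dir: Path
) -> ReportBundle:
    units: UnitTable = _stage("read-units")(read_units, units_path)
    records = _stage("read-admissions")(read_admissions, admissions_path, config)
    report = _stage("validate")(
        validate_dataset, records, units, config.unknown_unit_mode
    )
    report.to_json(out_dir / "validation.json")
    records = report.clean_records
    log.info("pipeline: %d record(s) enter the OD build", len(records))

    od: ODMatrix = _stage("od-build")(build_od_matrix, records, units)
    hospital_set = units.hospital_units or od.hospital_units
    od = _stage("origin-filter")(
        apply_origin_filter,
        od,
        hospital_set,
        config.min_sent_patients,
        config.origin_filter_mode,
    )

    designated = units.designated_units or set(od.unit_ids)
    functional = _stage("functional-region")(
        delineate_functional_region, od, designated, config.min_sent_patients
    )
    summary = _stage("cross-border")(cross_border_summary, od, designated)

    results = _stage("sufficiency")(
        sufficiency_table, od, units, config.sufficiency_threshold
    )
    sufficiency_table_to_csv(results, out_dir / "sufficiency.csv")

    traces = {}
    seeds = dict(sorted(units.micro_region_members().items()))
    seeds["designated-region"] = designated
    for name, seed_set in seeds.items():
        seed_set = set(seed_set) & set(od.unit_ids)
        if not seed_set:
            continue
        res = _stage(f"frech-enlarge[{name}]")(
            frech_enlarge,
            od,
            seed_set,
            config.sufficiency_threshold,
            config.enlargement_rank,
            units,
        )
        traces[name] = {
            "final_set": sorted(res.final_set),
            "label": res.label,
            "steps": [
                {
                    "added_unit": s.added_unit,
                    "set_size": s.set_size,
                    "lifo_pct": s.lifo_pct,
                    "lofi_pct": s.lofi_pct,
                    "label": s.label,
                }
                for s in res.trace
            ],
        }
    (out_dir / "enlargement_traces.json").write_text(json.dumps(traces, indent=2))

    graph = _stage("network")(build_flow_graph, od)
    graph_to_edge_csv(graph, out_dir / "edges.csv")
    graph_to_graphml(graph, out_dir / "network.graphml")
    node_metrics_to_csv(graph, out_dir / "node_metrics.csv")
    entropy = _stage("entropy")(origin_entropy, od)
    entropy.to_csv(out_dir / "origin_entropy.csv")

    hubs = identify_hubs(graph, k=1)
    hub = hubs[0] if hubs else None
    hub_excluded_components = []
    if hub is not None:
        reduced = _stage("hub-excluded")(remove_node_subnetwork, graph, hub)
        graph_to_edge_csv(reduced, out_dir / "edges_without_hub.csv")
        hub_excluded_components = [sorted(c) for c in weak_components(reduced)]

    # catchments for every destination with in-flow
    catch_frames = []
    geo_features = []
    for dest in sorted(od.hospital_units):
        cm = _stage(f"catchment[{dest}]")(catchment_quartiles, od, dest)
        t = cm.table.reset_index()
        t.insert(0, "destination", dest)
        catch_frames.append(t)
        for origin, row in cm.table.iterrows():
            u = units.frame.loc[origin]
            geo_features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [float(u["lon"]), float(u["lat"])],
                    },
                    "properties": {
                        "origin": origin,
                        "destination": dest,
                        "intensity": float(row["intensity"]),
                        "quartile": row["quartile"],
                    },
                }
            )
    import pandas as pd

    if catch_frames:
        catch = pd.concat(catch_frames, ignore_index=True)
    else:
        catch = pd.DataFrame(columns=["destination", "origin", "intensity", "quartile"])
    catch.to_csv(out_dir / "catchments.csv", index=False)
    (out_dir / "catchments.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": geo_features}, indent=2)
    )

    disp = None
    if hub is not None:
        disp = _stage("displacement")(
            displacement_stats, od, units, hub, config.earth_radius_km
        )

    od.to_long_csv(out_dir / "od_long.csv")
    od.to_square_csv(out_dir / "od_matrix.csv")

    summary_payload = {
        "records_analyzed": od.total,
        "records_dropped_by_filter": od.dropped_records,
        "designated_units": sorted(designated),
        "functional_region": sorted(functional),
        "functional_region_size": len(functional),
        "cross_border": {
            "total": summary.total,
            "cross_border": summary.cross_border,
            "proportion_pct": summary.proportion_pct,
        },
        "hub": hub,
        "displacement_km": None
        if disp is None
        else {"to_hub_mean": disp.hub_mean_km, "other_mean": disp.other_mean_km},
        "hub_excluded_components": hub_excluded_components,
    }
    (out_dir / "cross_border.json").write_text(json.dumps(summary_payload, indent=2))

    metadata = {
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "seed": config.random_seed,
        "version": __version__,
        "inputs": {"admissions": str(admissions_path), "units": str(units_path)},
    }
    (out_dir / "metadata.json").write_text(json.dumps(metadata, indent=2))

    return ReportBundle(
        out_dir=out_dir,
        sufficiency_csv=out_dir / "sufficiency.csv",
        enlargement_json=out_dir / "enlargement_traces.json",
        edges_csv=out_dir / "edges.csv",
        graphml=out_dir / "network.graphml",
        node_metrics_csv=out_dir / "node_metrics.csv",
        entropy_csv=out_dir / "origin_entropy.csv",
        catchments_csv=out_dir / "catchments.csv",
        catchments_geojson=out_dir / "catchments.geojson",
        cross_border_json=out_dir / "cross_border.json",
        od_long_csv=out_dir / "od_long.csv",
        metadata_json=out_dir / "metadata.json",
        summary=summary_payload,
    )
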