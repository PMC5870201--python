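"""End-to-end pipeline: claims -> graph -> communities -> profiles -> trade.

Stage order: ingest, collapse to visits, provider filter, graph build, edge
prune, community detection, small-community exclusion, patient attribution,
community profiles, trade/RCA. Every stage's output is persisted under the
run's output directory and its row counts are logged and recorded in a
machine-readable JSON report, so any downstream table can be regenerated
from the saved intermediates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from contextlib import contextmanager
from pathlib import Path

import pandas as pd

from carenet import graph as graphmod
from carenet.attribution import assign_by_pcp, assign_by_plurality, impute_pcp
from carenet.bookkeeping import cohort_bookkeeping
from carenet.communities import detect_communities, filter_small_communities
from carenet.config import RunConfig, synth_config_to_dict
from carenet.ingest import collapse_to_visits, filter_providers, load_dataset
from carenet.profiles import build_profiles, org_community_concentration
from carenet.synthetic import generate_dataset, write_dataset
from carenet.trade import (
    net_trade_report,
    rca_table,
    top_traded_specialties,
    trade_flow_edges,
    trade_tensor,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@contextmanager
def _stage(name: str):
    logger.info("stage: %s", name)
    try:
        yield
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the stage name
        raise StageError(f"stage '{name}' failed: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the JSON-serializable report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "config": _config_dict(config)}

    with _stage("ingest"):
        if config.synth is not None:
            dataset = generate_dataset(config.synth)
            write_dataset(dataset, outdir / "synth")
            claims, providers, patients = (
                dataset.claims,
                dataset.providers,
                dataset.patients,
            )
            report["stages"]["ingest"] = {
                "source": "synthetic",
                "claim_lines": len(claims),
                "providers": len(providers),
                "patients": len(patients),
                "true_visits": dataset.truth.n_visits,
            }
        else:
            ds = load_dataset(
                config.claims_path, config.providers_path, config.patients_path
            )
            claims, providers, patients = ds.claims, ds.providers, ds.patients
            report["stages"]["ingest"] = {
                "source": "files",
                **dataclasses.asdict(ds.report),
            }

    with _stage("visits"):
        visits = collapse_to_visits(claims)
        filtered_visits, retained_npis = filter_providers(visits, config.min_patients)
        visits.to_csv(outdir / "visits.csv", index=False)
        report["stages"]["visits"] = {
            "claim_lines": len(claims),
            "visits": len(visits),
            "providers_before_filter": int(visits["npi"].nunique()),
            "providers_after_filter": len(retained_npis),
            "visits_after_filter": len(filtered_visits),
        }

    with _stage("graph"):
        g = graphmod.build_shared_patient_graph(filtered_visits)
        pruned, isolates = graphmod.prune_edges(g, config.min_shared)
        graphmod.write_graphml(pruned, outdir / "network.graphml")
        graphmod.write_edge_list(pruned, outdir / "edges.csv")
        report["stages"]["graph"] = {
            "nodes_before_prune": g.number_of_nodes(),
            "edges_before_prune": g.number_of_edges(),
            "nodes": pruned.number_of_nodes(),
            "edges": pruned.number_of_edges(),
            "isolates_removed": len(isolates),
            "total_weight": float(graphmod.total_weight(pruned)),
        }

    with _stage("communities"):
        detected = detect_communities(pruned)
        partition = filter_small_communities(detected, config.min_community_size)
        excl = partition.exclusion_summary()
        pd.Series(partition.assignment, name="community").rename_axis("npi").sort_index().to_csv(
            outdir / "partition.csv"
        )
        graph_providers = pruned.number_of_nodes()
        report["stages"]["communities"] = {
            "modularity": detected.modularity,
            "n_detected": len(detected.sizes),
            "n_retained": len(partition.sizes),
            "sizes": {str(k): v for k, v in partition.sizes.items()},
            "excluded_communities": excl.n_communities,
            "excluded_providers": excl.n_providers,
            "excluded_mean_size": excl.mean_size,
            "excluded_provider_pct": (
                100.0 * excl.n_providers / graph_providers if graph_providers else 0.0
            ),
        }

    with _stage("attribution"):
        if config.attribution == "pcp":
            imputed = impute_pcp(visits, providers, list(config.pcp_specialties))
            assignment = assign_by_pcp(visits, imputed, partition)
        else:
            assignment = assign_by_plurality(visits, partition)
        assignment.table.assign(method=assignment.method).to_csv(
            outdir / "assignments.csv"
        )
        cohort = int(visits["patient_id"].nunique())
        report["stages"]["attribution"] = {
            "method": assignment.method,
            "patients": cohort,
            "assigned": cohort - assignment.n_unassigned,
            "unassigned": assignment.n_unassigned,
            "unassigned_patient_pct": (
                100.0 * assignment.n_unassigned / cohort if cohort else 0.0
            ),
        }

    with _stage("profiles"):
        profiles, county_shares = build_profiles(
            partition, assignment, providers, patients, config.pcp_specialties
        )
        profiles.to_csv(outdir / "profiles.csv")
        county_shares.to_csv(outdir / "county_shares.csv", index=False)
        org_count, org_k = org_community_concentration(providers, partition)
        display = profiles.copy()
        display["pmpm"] = display["pmpm"].round(0)
        report["stages"]["profiles"] = {
            "table": json.loads(display.reset_index().to_json(orient="records")),
            "org_concentration": {"aligned": org_count, "top_k": org_k},
        }

    with _stage("trade"):
        tensor = trade_tensor(visits, assignment, partition, providers)
        tensor.to_csv(outdir / "trade_tensor.csv", index=False)
        rca = rca_table(tensor)
        rca.to_csv(outdir / "rca.csv", index=False)
        top = top_traded_specialties(tensor, config.rca_top_k)
        flows = (
            pd.concat(
                [
                    trade_flow_edges(tensor, s, config.flow_threshold).assign(
                        specialty=s
                    )
                    for s in top
                ],
                ignore_index=True,
            )
            if top
            else pd.DataFrame(
                columns=["importer", "exporter", "proportion", "specialty"]
            )
        )
        flows.to_csv(outdir / "trade_flows.csv", index=False)
        report["stages"]["trade"] = {
            "cross_community_visits": (
                int(tensor["visits"].sum()) if len(tensor) else 0
            ),
            "top_specialties": top,
            "net_trade": net_trade_report(
                tensor, balance_threshold=config.balance_threshold
            ),
        }

    with _stage("bookkeeping"):
        books = cohort_bookkeeping(
            total_providers=graph_providers,
            total_patients=cohort,
            retained_provider_counts=list(partition.sizes.values()),
            retained_patient_counts=[
                int((assignment.assigned["community"] == c).sum())
                for c in partition.labels
            ],
            n_excluded_communities=excl.n_communities or None,
        )
        report["bookkeeping"] = dataclasses.asdict(books)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    logger.info("pipeline complete: report at %s", outdir / "report.json")
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.synth is not None:
        d["synth"] = synth_config_to_dict(config.synth)
    d["pcp_specialties"] = list(d["pcp_specialties"])
    return d


def _jsonable(obj):
    if isinstance(obj, pd.Timestamp):
        return obj.isoformat()
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
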