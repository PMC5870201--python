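"""Inter-community service trade and Revealed Comparative Advantage.

A visit by a patient of community c to a provider of a different community
c' is an *import* of the provider's servicing specialty by c and an *export*
by c'. Cross-community flows are tallied in a tensor x(importer, exporter,
specialty); the Revealed Comparative Advantage index for a community c and
specialty i (per trade direction) is

    RCA(c, i) = [x(c,i) / sum_i x(c,i)] / [sum_c x(c,i) / sum_{c,i} x(c,i)]

i.e. the specialty's share of the community's trade relative to its share of
all trade. RCA > 1 on the export side flags a surplus (the community is an
efficient exporter); on the import side it flags a deficit (a service the
community particularly needs from outside).
"""

from __future__ import annotations

import logging
import pandas as pd

from carenet.attribution import UNASSIGNED, PatientAssignment
from carenet.communities import Partition

logger = logging.getLogger(__name__)

#: Exporter label for visits to providers outside every retained community;
#: tallied for leakage accounting but excluded from RCA (which requires a
#: community on both sides of the trade).
EXTERNAL = "external"


def trade_tensor(
    visits: pd.DataFrame,
    assignment: PatientAssignment,
    partition: Partition,
    providers: pd.DataFrame,
) -> pd.DataFrame:
    """Count cross-community visits by (importer, exporter, specialty).

    One row per non-zero cell: columns importer (the patient's community),
    exporter (the provider's community, or ``EXTERNAL``), specialty (the
    provider's servicing specialty), visits. In-community visits and
    unassigned patients do not trade.
    """
    tagged = visits.copy()
    tagged["exporter"] = tagged["npi"].map(partition.assignment)
    tagged["importer"] = tagged["patient_id"].map(assignment.table["community"])
    tagged["specialty"] = tagged["npi"].map(providers.set_index("npi")["specialty"])
    tagged = tagged[
        tagged["importer"].notna() & (tagged["importer"] != UNASSIGNED)
    ].copy()
    tagged["exporter"] = tagged["exporter"].fillna(EXTERNAL)
    cross = tagged[tagged["importer"] != tagged["exporter"]]
    tensor = (
        cross.groupby(["importer", "exporter", "specialty"])
        .size()
        .rename("visits")
        .reset_index()
    )
    tensor["importer"] = tensor["importer"].astype(int)
    return tensor.sort_values(["importer", "exporter", "specialty"]).reset_index(
        drop=True
    )


def _marginals(tensor: pd.DataFrame, direction: str) -> pd.DataFrame:
    """x(c, i) summed over the opposite side; external trade excluded."""
    internal = tensor[tensor["exporter"] != EXTERNAL].copy()
    internal["exporter"] = internal["exporter"].astype(int)
    key = "importer" if direction == "import" else "exporter"
    out = (
        internal.groupby([key, "specialty"])["visits"].sum().rename("x").reset_index()
    )
    return out.rename(columns={key: "community"})


def rca(marginals: pd.DataFrame, community: int, specialty: str) -> float:
    """RCA for one community-specialty cell of a directional marginal table.

    ``marginals`` has columns (community, specialty, x). Returns NaN when
    the community has no trade or the specialty is untraded (undefined,
    reported as missing — never 0).
    """
    total = marginals["x"].sum()
    comm_total = marginals.loc[marginals["community"] == community, "x"].sum()
    spec_total = marginals.loc[marginals["specialty"] == specialty, "x"].sum()
    if total == 0 or comm_total == 0 or spec_total == 0:
        return float("nan")
    x_ci = marginals.loc[
        (marginals["community"] == community) & (marginals["specialty"] == specialty),
        "x",
    ].sum()
    return (x_ci / comm_total) / (spec_total / total)


def rca_table(tensor: pd.DataFrame) -> pd.DataFrame:
    """RCA for every (community, specialty, direction) with any trade.

    Long table with columns community, specialty, direction, x, rca.
    External imports are excluded (no exporting community exists for them).
    """
    frames = []
    for direction in ("import", "export"):
        marg = _marginals(tensor, direction)
        if marg.empty:
            continue
        total = marg["x"].sum()
        comm_tot = marg.groupby("community")["x"].sum()
        spec_tot = marg.groupby("specialty")["x"].sum()
        marg = marg.assign(
            direction=direction,
            rca=lambda df: (df["x"] / df["community"].map(comm_tot))
            / (df["specialty"].map(spec_tot) / total),
        )
        frames.append(marg)
    if not frames:
        return pd.DataFrame(columns=["community", "specialty", "direction", "x", "rca"])
    return pd.concat(frames, ignore_index=True)[
        ["community", "specialty", "direction", "x", "rca"]
    ]


def top_traded_specialties(tensor: pd.DataFrame, k: int = 4) -> list[str]:
    """Specialties ranked by total cross-community visit volume (top k).

    Ties are broken alphabetically. An all-zero tensor yields an empty list.
    """
    if tensor.empty or tensor["visits"].sum() == 0:
        logger.warning("no cross-community trade to rank")
        return []
    volume = tensor.groupby("specialty")["visits"].sum()
    ranked = volume.reset_index().sort_values(
        ["visits", "specialty"], ascending=[False, True], kind="mergesort"
    )
    return ranked["specialty"].head(k).tolist()


def trade_flow_edges(
    tensor: pd.DataFrame, specialty: str, threshold: float = 0.05
) -> pd.DataFrame:
    """Community-pair flows carrying more than ``threshold`` of a specialty.

    The proportion is each (importer, exporter) pair's share of the
    specialty's total cross-community volume; only strictly-greater-than-
    threshold edges are returned, sorted by descending proportion.
    """
    spec = tensor[tensor["specialty"] == specialty]
    total = spec["visits"].sum()
    if total == 0:
        return pd.DataFrame(columns=["importer", "exporter", "proportion"])
    flows = (
        spec.groupby(["importer", "exporter"])["visits"].sum().reset_index()
    )
    flows["proportion"] = flows["visits"] / total
    flows = flows[flows["proportion"] > threshold]
    return (
        flows.sort_values(
            ["proportion", "importer"], ascending=[False, True], kind="mergesort"
        )[["importer", "exporter", "proportion"]]
        .reset_index(drop=True)
    )


def net_trade_report(
    tensor: pd.DataFrame,
    top_n: int = 2,
    balance_threshold: float = 0.2,
) -> dict:
    """Per-community top imports/exports by RCA plus balanced-trade flags.

    A community-specialty pair is flagged as an internalization opportunity
    when its import and export volumes are within ``balance_threshold``
    relative gap: |imports - exports| / max(imports, exports) <
    balance_threshold — comparable demand and supply already exist, so the
    leakage could be served in-community.
    """
    table = rca_table(tensor)
    report: dict = {"communities": {}, "balanced": []}
    if table.empty:
        return report
    for community in sorted(table["community"].unique()):
        sub = table[table["community"] == community]
        entry = {}
        for direction in ("import", "export"):
            ranked = sub[sub["direction"] == direction].sort_values(
                ["rca", "specialty"], ascending=[False, True], kind="mergesort"
            )
            entry[f"top_{direction}s"] = [
                {"specialty": r.specialty, "rca": round(float(r.rca), 2)}
                for r in ranked.head(top_n).itertuples()
            ]
        report["communities"][int(community)] = entry

    imports = table[table["direction"] == "import"].set_index(
        ["community", "specialty"]
    )["x"]
    exports = table[table["direction"] == "export"].set_index(
        ["community", "specialty"]
    )["x"]
    for key in imports.index.intersection(exports.index):
        xi, xe = float(imports[key]), float(exports[key])
        if max(xi, xe) > 0 and abs(xi - xe) / max(xi, xe) < balance_threshold:
            report["balanced"].append(
                {
                    "community": int(key[0]),
                    "specialty": key[1],
                    "imports": xi,
                    "exports": xe,
                }
            )
    return report
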