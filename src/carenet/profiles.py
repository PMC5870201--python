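"""Per-community profiles: composition, leakage, concentration, cost, risk.

For each retained community the profile reports provider and patient counts,
the PCP share of providers, pooled within-community utilization and spending
percentages, the Herfindahl index of organization market shares (share =
fraction of the community's providers affiliated with the organization),
per-member-per-month cost (PMPM), mean risk score, risk-adjusted PMPM
(PMPM / mean risk), and the home-county distribution of assigned patients.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from carenet.attribution import PatientAssignment
from carenet.communities import Partition
from carenet.config import DEFAULT_PCP_SPECIALTIES

logger = logging.getLogger(__name__)


def pcp_specialist_ratio(
    specialties: Iterable[str],
    pcp_specialties: Sequence[str] = DEFAULT_PCP_SPECIALTIES,
    as_quotient: bool = False,
) -> float:
    """PCP-specialist ratio of a community, as a percentage.

    Default definition: 100 * (PCP count) / (total provider count) — the PCP
    share of the community. ``as_quotient=True`` instead returns
    100 * PCP / specialist (undefined for an all-PCP community).
    """
    specialties = list(specialties)
    if not specialties:
        raise ValueError("community has no providers")
    pcp = sum(s in set(pcp_specialties) for s in specialties)
    if as_quotient:
        n_spec = len(specialties) - pcp
        if n_spec == 0:
            return float("inf")
        return 100.0 * pcp / n_spec
    return 100.0 * pcp / len(specialties)


def herfindahl(org_ids: Iterable[str | None]) -> float:
    """Sum of squared organization market shares within a community.

    Shares are each organization's fraction of the community's providers.
    Providers without an organization each count as a singleton
    organization. 1 = a single monopolistic organization; near 0 = many
    small ones.
    """
    org_ids = list(org_ids)
    if not org_ids:
        raise ValueError("community has no providers")
    counts: dict[object, int] = {}
    singletons = 0
    for o in org_ids:
        if o is None or pd.isna(o):
            singletons += 1
        else:
            counts[o] = counts.get(o, 0) + 1
    n = len(org_ids)
    return sum((c / n) ** 2 for c in counts.values()) + singletons * (1 / n) ** 2


def pmpm(total_spend: float, total_member_months: float) -> float:
    """Per-member-per-month cost: total allowed spend / member-months."""
    if total_member_months <= 0:
        raise ValueError("member-months must be positive")
    return total_spend / total_member_months


def risk_adjusted_pmpm(pmpm_value: float, mean_risk: float) -> float:
    """PMPM divided by the mean risk score, rounded to cents."""
    if mean_risk <= 0:
        raise ValueError("mean risk score must be positive")
    return round(pmpm_value / mean_risk, 2)


def community_utilization_spend(
    assignment: PatientAssignment,
) -> pd.DataFrame:
    """Pooled within-community utilization and spending percent per community.

    Pooled: sum of assigned patients' within-community visits over the sum
    of their total visits (x100); spend analogue on dollars. Patient-mean
    variants are also returned. Communities with zero visits are reported
    as missing rather than 0.
    """
    assigned = assignment.assigned
    rows = []
    for label, grp in assigned.groupby("community"):
        tv, ts = grp["total_visits"].sum(), grp["total_spend"].sum()
        rows.append(
            {
                "community": int(label),
                "pct_within_utilization": (
                    100.0 * grp["within_visits"].sum() / tv if tv > 0 else np.nan
                ),
                "pct_within_spend": (
                    100.0 * grp["within_dollars"].sum() / ts if ts > 0 else np.nan
                ),
                "pct_within_utilization_patient_mean": (
                    100.0 * grp["within_utilization"].mean() if len(grp) else np.nan
                ),
                "pct_within_spend_patient_mean": (
                    100.0 * grp["within_spend"].mean() if len(grp) else np.nan
                ),
            }
        )
    return pd.DataFrame(rows).set_index("community")


def county_distribution(
    assignment: PatientAssignment, patients: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Home-county shares of assigned patients per community, plus anchors.

    Returns a long table (community, county, share) and a Series mapping
    community -> anchor county (the argmax share; ties resolved
    alphabetically and logged).
    """
    assigned = assignment.assigned.merge(
        patients[["patient_id", "county"]], left_index=True, right_on="patient_id"
    )
    shares = (
        assigned.groupby(["community", "county"]).size()
        / assigned.groupby("community").size()
    ).rename("share").reset_index()
    anchors = {}
    for label, grp in shares.groupby("community"):
        top = grp["share"].max()
        tied = sorted(grp.loc[grp["share"] == top, "county"])
        if len(tied) > 1:
            logger.warning(
                "community %s anchor county tied among %s; taking %s",
                label, tied, tied[0],
            )
        anchors[int(label)] = tied[0]
    return shares, pd.Series(anchors, name="anchor_county").rename_axis("community")


def org_community_concentration(
    providers: pd.DataFrame,
    partition: Partition,
    top_k: int = 20,
    threshold: float = 0.75,
) -> tuple[int, int]:
    """How many of the top-k organizations sit mostly inside one community.

    Organizations are ranked by the number of affiliated providers retained
    in the partition; an organization counts if at least ``threshold`` of
    those providers share a single community. Returns (count, k_used);
    k_used < top_k when fewer organizations exist (warned).
    """
    retained = providers[providers["npi"].isin(partition.assignment)].copy()
    retained = retained.dropna(subset=["org_id"])
    sizes = retained.groupby("org_id").size().sort_values(ascending=False)
    if len(sizes) < top_k:
        logger.warning("only %d organizations available (top_k=%d)", len(sizes), top_k)
    top = sizes.index[:top_k]
    count = 0
    retained["community"] = retained["npi"].map(partition.assignment)
    for org in top:
        comms = retained.loc[retained["org_id"] == org, "community"]
        if comms.value_counts().iloc[0] / len(comms) >= threshold:
            count += 1
    return count, len(top)


def build_profiles(
    partition: Partition,
    assignment: PatientAssignment,
    providers: pd.DataFrame,
    patients: pd.DataFrame,
    pcp_specialties: Sequence[str] = DEFAULT_PCP_SPECIALTIES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-community profile table.

    Returns (profiles, county_shares): one profile row per retained
    community with n_providers, n_patients, pcp_specialist_ratio,
    pct_within_utilization, pct_within_spend, herfindahl, pmpm (whole
    dollars in reports; full precision here), mean_risk, risk_adjusted_pmpm
    (cents), and anchor_county.
    """
    prov = providers.set_index("npi")
    pat = patients.set_index("patient_id")
    util = community_utilization_spend(assignment)
    county_shares, anchors = county_distribution(assignment, patients)
    assigned = assignment.assigned

    rows = []
    for label in partition.labels:
        members = partition.members(label)
        specialties = prov.loc[prov.index.intersection(members), "specialty"]
        orgs = prov.loc[prov.index.intersection(members), "org_id"]
        grp = assigned[assigned["community"] == label]
        pat_grp = pat.loc[pat.index.intersection(grp.index)]
        mm = float(pat_grp["member_months"].sum())
        spend = float(grp["total_spend"].sum())
        mean_risk = float(pat_grp["risk_score"].mean()) if len(pat_grp) else np.nan
        pm = pmpm(spend, mm) if mm > 0 else np.nan
        rows.append(
            {
                "community": label,
                "n_providers": len(members),
                "n_patients": len(grp),
                "pcp_specialist_ratio": pcp_specialist_ratio(
                    specialties, pcp_specialties
                ),
                "pct_within_utilization": util["pct_within_utilization"].get(
                    label, np.nan
                ),
                "pct_within_spend": util["pct_within_spend"].get(label, np.nan),
                "herfindahl": herfindahl(orgs),
                "pmpm": pm,
                "mean_risk": mean_risk,
                "risk_adjusted_pmpm": (
                    risk_adjusted_pmpm(pm, mean_risk)
                    if np.isfinite(pm) and mean_risk > 0
                    else np.nan
                ),
                "anchor_county": anchors.get(label, None),
            }
        )
    return pd.DataFrame(rows).set_index("community"), county_shares
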