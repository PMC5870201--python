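"""Attribute patients to provider communities and measure their leakage.

Two attribution rules are supported:

* plurality — a patient belongs to the retained community holding the most
  of their visits (ties by greater spend in the tied communities, then by
  the smaller community label). Plurality maximizes each patient's
  within-community utilization by construction.
* pcp — a patient inherits the community of their imputed primary care
  provider (the PCP-specialty provider with the most of their visits).

Within-community utilization (and spending) uses ALL of a patient's visits
in the denominator — including visits to providers that fell to the
minimum-patient filter or to excluded small communities — so leakage is
never hidden by upstream filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from carenet.communities import Partition
from carenet.config import ConfigurationError

logger = logging.getLogger(__name__)

UNASSIGNED = -1


@dataclass(frozen=True)
class PatientAssignment:
    """Per-patient community assignment plus leakage fractions.

    ``table`` is indexed by patient_id with columns ``community`` (int,
    ``UNASSIGNED`` = -1 for patients with no visit to any retained
    community), ``within_utilization``, ``within_spend``, ``total_visits``,
    ``total_spend``. ``visit_counts`` is the patient x community visit-count
    matrix over retained communities.
    """

    table: pd.DataFrame
    visit_counts: pd.DataFrame
    method: str

    @property
    def assigned(self) -> pd.DataFrame:
        return self.table[self.table["community"] != UNASSIGNED]

    @property
    def n_unassigned(self) -> int:
        return int((self.table["community"] == UNASSIGNED).sum())


def _visits_with_community(visits: pd.DataFrame, partition: Partition) -> pd.DataFrame:
    out = visits.copy()
    out["community"] = out["npi"].map(partition.assignment).fillna(UNASSIGNED).astype(int)
    return out


def _community_visit_counts(tagged: pd.DataFrame, partition: Partition) -> pd.DataFrame:
    retained = tagged[tagged["community"] != UNASSIGNED]
    counts = (
        retained.groupby(["patient_id", "community"]).size().unstack(fill_value=0)
    )
    for label in partition.labels:
        if label not in counts.columns:
            counts[label] = 0
    return counts[sorted(counts.columns)]


def assign_by_plurality(visits: pd.DataFrame, partition: Partition) -> PatientAssignment:
    """Assign each patient to the retained community with most of their visits.

    Ties are broken by greater spend within the tied communities, then by
    the smaller community label. Patients with no visit to any retained
    community are unassigned (and excluded from community profiles
    downstream, but reported).
    """
    tagged = _visits_with_community(visits, partition)
    retained = tagged[tagged["community"] != UNASSIGNED]
    per = (
        retained.groupby(["patient_id", "community"])
        .agg(n_visits=("npi", "size"), spend=("spend", "sum"))
        .reset_index()
        .sort_values(
            ["patient_id", "n_visits", "spend", "community"],
            ascending=[True, False, False, True],
            kind="mergesort",
        )
    )
    winner = per.groupby("patient_id", sort=True).first()["community"].astype(int)
    assignment = _finalize(tagged, winner, partition, method="plurality")
    return assignment


def impute_pcp(
    visits: pd.DataFrame,
    providers: pd.DataFrame,
    pcp_specialties: list[str] | tuple[str, ...],
) -> pd.Series:
    """Impute each patient's primary care provider by visit plurality.

    The imputed PCP is the PCP-specialty provider the patient visited most
    during the study window; ties by most recent visit date, then smaller
    NPI. Patients with no PCP visit map to NA (counted and logged).
    """
    if not pcp_specialties:
        raise ConfigurationError("pcp_specialties must be non-empty")
    pcp_npis = set(providers.loc[providers["specialty"].isin(pcp_specialties), "npi"])
    pcp_visits = visits[visits["npi"].isin(pcp_npis)]
    if pcp_visits.empty:
        logger.warning("no primary-care visits found; every patient lacks a PCP")
        return pd.Series(dtype=object, name="imputed_pcp_npi")
    per = (
        pcp_visits.groupby(["patient_id", "npi"])
        .agg(n_visits=("start_date", "size"), last_seen=("start_date", "max"))
        .reset_index()
        .sort_values(
            ["patient_id", "n_visits", "last_seen", "npi"],
            ascending=[True, False, False, True],
            kind="mergesort",
        )
    )
    imputed = per.groupby("patient_id", sort=True).first()["npi"]
    n_without = visits["patient_id"].nunique() - len(imputed)
    if n_without:
        logger.info("%d patients have no imputed PCP (no primary-care visits)", n_without)
    return imputed.rename("imputed_pcp_npi")


def assign_by_pcp(
    visits: pd.DataFrame,
    imputed: pd.Series,
    partition: Partition,
) -> PatientAssignment:
    """Assign each patient to their imputed PCP's retained community.

    A missing PCP, or a PCP outside every retained community, leaves the
    patient unassigned.
    """
    tagged = _visits_with_community(visits, partition)
    winner = (
        imputed.map(partition.assignment).dropna().astype(int)
    )
    winner.index.name = "patient_id"
    return _finalize(tagged, winner, partition, method="pcp")


def _finalize(
    tagged: pd.DataFrame,
    winner: pd.Series,
    partition: Partition,
    method: str,
) -> PatientAssignment:
    all_patients = pd.Index(sorted(tagged["patient_id"].unique()), name="patient_id")
    community = winner.reindex(all_patients).fillna(UNASSIGNED).astype(int)
    totals = tagged.groupby("patient_id").agg(
        total_visits=("npi", "size"), total_spend=("spend", "sum")
    )
    table = totals.reindex(all_patients).fillna(0)
    table["community"] = community
    table = _within_stats(tagged, table)
    counts = _community_visit_counts(tagged, partition).reindex(
        all_patients, fill_value=0
    )
    n_unassigned = int((table["community"] == UNASSIGNED).sum())
    if n_unassigned:
        logger.info("%d patients unassigned under %s attribution", n_unassigned, method)
    cols = [
        "community",
        "within_utilization",
        "within_spend",
        "total_visits",
        "total_spend",
        "within_visits",
        "within_dollars",
    ]
    return PatientAssignment(table=table[cols], visit_counts=counts, method=method)


def patient_within_stats(
    visits: pd.DataFrame,
    community: pd.Series,
    partition: Partition,
) -> pd.DataFrame:
    """Within-community utilization and spending under a given assignment.

    ``community`` maps patient_id -> community label (use ``UNASSIGNED``
    for unattributed patients). ``within_utilization`` = visits to providers
    of the patient's own community / all of the patient's visits;
    ``within_spend`` is the dollar analogue. Providers outside every
    retained community contribute to the denominator only. Useful for
    evaluating forced alternative assignments against plurality.
    """
    tagged = _visits_with_community(visits, partition)
    all_patients = pd.Index(sorted(tagged["patient_id"].unique()), name="patient_id")
    table = tagged.groupby("patient_id").agg(
        total_visits=("npi", "size"), total_spend=("spend", "sum")
    ).reindex(all_patients).fillna(0)
    table["community"] = (
        community.reindex(all_patients).fillna(UNASSIGNED).astype(int)
    )
    return _within_stats(tagged, table)


def _within_stats(tagged: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Attach within-community visit/spend fractions to a patient table.

    Unassigned patients get 0.
    """
    table = table.copy()
    own = tagged.merge(
        table[["community"]].rename(columns={"community": "assigned"}),
        left_on="patient_id",
        right_index=True,
        how="left",
    )
    inside = own[(own["community"] == own["assigned"]) & (own["assigned"] != UNASSIGNED)]
    win = inside.groupby("patient_id").agg(
        within_visits=("npi", "size"), within_dollars=("spend", "sum")
    )
    table["within_visits"] = win["within_visits"].reindex(table.index).fillna(0)
    table["within_dollars"] = win["within_dollars"].reindex(table.index).fillna(0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        table["within_utilization"] = np.where(
            table["total_visits"] > 0,
            table["within_visits"] / table["total_visits"],
            0.0,
        )
        table["within_spend"] = np.where(
            table["total_spend"] > 0,
            table["within_dollars"] / table["total_spend"],
            0.0,
        )
    return table
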