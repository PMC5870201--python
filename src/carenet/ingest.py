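"""Load the claims, provider, and patient tables and collapse lines to visits.

A "visit" is one distinct (patient, provider, start date) triple: a single
provider encounter can be billed as several claim lines, all sharing the
claim's start date, so lines are collapsed on that key and their allowed
amounts summed. Providers are then required to serve a minimum number of
distinct patients (default 5) to enter the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from carenet.config import ConfigurationError

logger = logging.getLogger(__name__)

CLAIMS_COLUMNS = ("patient_id", "npi", "start_date", "allowed_amount")
PROVIDER_COLUMNS = ("npi", "specialty")
PATIENT_COLUMNS = ("patient_id", "county", "risk_score", "member_months")


class SchemaError(ValueError):
    """A required input column is missing."""


@dataclass
class IngestReport:
    """Row-level accounting of what loading dropped or flagged."""

    claims_rows_read: int = 0
    claims_rows_dropped_missing: int = 0
    providers_read: int = 0
    providers_dropped_organizational: int = 0
    providers_dropped_missing: int = 0
    patients_read: int = 0
    patients_dropped_missing: int = 0
    #: claim rows whose npi/patient_id is absent from the profile tables;
    #: retained in the claims, flagged here.
    claims_unknown_npi: int = 0
    claims_unknown_patient: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Dataset:
    claims: pd.DataFrame
    providers: pd.DataFrame
    patients: pd.DataFrame
    report: IngestReport


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing required column(s): {missing}")


def load_dataset(
    claims_path: str | Path,
    providers_path: str | Path,
    patients_path: str | Path,
) -> Dataset:
    """Read and type the three CSV tables.

    Rows missing a key field are dropped and counted; providers with an
    organizational NPI type are dropped (the analysis covers individual
    practitioners only); claims referencing unknown NPIs or patients are
    retained but flagged in the referential-integrity report.
    """
    report = IngestReport()

    claims = pd.read_csv(claims_path, dtype={"patient_id": str, "npi": str})
    _require_columns(claims, CLAIMS_COLUMNS, "claims")
    report.claims_rows_read = len(claims)
    key_ok = claims[["patient_id", "npi", "start_date"]].notna().all(axis=1)
    report.claims_rows_dropped_missing = int((~key_ok).sum())
    claims = claims.loc[key_ok].copy()
    claims["start_date"] = pd.to_datetime(claims["start_date"]).dt.normalize()
    claims["allowed_amount"] = (
        pd.to_numeric(claims["allowed_amount"], errors="coerce").fillna(0.0)
    )
    if claims.empty:
        msg = "claims table is empty after cleaning"
        report.warnings.append(msg)
        logger.warning(msg)

    providers = pd.read_csv(providers_path, dtype={"npi": str, "org_id": str})
    _require_columns(providers, PROVIDER_COLUMNS, "providers")
    report.providers_read = len(providers)
    ok = providers["npi"].notna() & providers["specialty"].notna()
    report.providers_dropped_missing = int((~ok).sum())
    providers = providers.loc[ok].copy()
    if "npi_type" in providers.columns:
        organizational = providers["npi_type"].astype(str).str.lower().eq(
            "organizational"
        )
        report.providers_dropped_organizational = int(organizational.sum())
        providers = providers.loc[~organizational].copy()
    else:
        providers["npi_type"] = "individual"
    for col in ("org_id", "county"):
        if col not in providers.columns:
            providers[col] = pd.NA
    providers = providers.drop_duplicates(subset="npi", keep="first")

    patients = pd.read_csv(patients_path, dtype={"patient_id": str})
    _require_columns(patients, PATIENT_COLUMNS, "patients")
    report.patients_read = len(patients)
    ok = patients["patient_id"].notna()
    report.patients_dropped_missing = int((~ok).sum())
    patients = patients.loc[ok].drop_duplicates(subset="patient_id", keep="first").copy()
    if "imputed_pcp_npi" not in patients.columns:
        patients["imputed_pcp_npi"] = pd.NA

    report.claims_unknown_npi = int(
        (~claims["npi"].isin(providers["npi"])).sum()
    )
    report.claims_unknown_patient = int(
        (~claims["patient_id"].isin(patients["patient_id"])).sum()
    )
    if report.claims_unknown_npi:
        logger.warning(
            "%d claim rows reference NPIs absent from the provider table",
            report.claims_unknown_npi,
        )
    return Dataset(claims=claims, providers=providers, patients=patients, report=report)


def collapse_to_visits(claims: pd.DataFrame) -> pd.DataFrame:
    """Collapse claim lines to visits on (patient_id, npi, start_date).

    Spend is the sum of the collapsed lines' allowed amounts, so total spend
    is conserved; the operation is idempotent.
    """
    visits = (
        claims.groupby(["patient_id", "npi", "start_date"], as_index=False, sort=True)
        .agg(spend=("allowed_amount", "sum"))
    )
    return visits


def filter_providers(
    visits: pd.DataFrame, min_patients: int = 5
) -> tuple[pd.DataFrame, set[str]]:
    """Keep only providers serving at least ``min_patients`` distinct patients.

    A single pass suffices: removing one provider's visits cannot reduce any
    other provider's distinct-patient count. Returns the filtered visit
    table and the retained NPI set.
    """
    if min_patients < 1:
        raise ConfigurationError("min_patients must be >= 1")
    counts = visits.groupby("npi")["patient_id"].nunique()
    retained = set(counts.index[counts >= min_patients])
    filtered = visits[visits["npi"].isin(retained)].reset_index(drop=True)
    return filtered, retained
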