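"""Cohort bookkeeping: exclusion arithmetic for the run report.

Given the post-filter cohort totals and the per-retained-community provider
and patient counts, derives the exclusion accounting a network designer
checks first: how many providers and patients the small-community exclusion
removed, what fraction of the cohort that is, and the mean sizes involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class CohortBookkeeping:
    total_providers: int
    total_patients: int
    n_retained_communities: int
    mean_retained_community_size: float
    excluded_providers: int
    excluded_patients: int
    n_excluded_communities: int | None
    mean_excluded_community_size: float | None
    excluded_provider_pct: float
    excluded_patient_pct: float


def cohort_bookkeeping(
    total_providers: int,
    total_patients: int,
    retained_provider_counts: Sequence[int],
    retained_patient_counts: Sequence[int],
    n_excluded_communities: int | None = None,
) -> CohortBookkeeping:
    """Derive exclusion accounting from totals and retained-community counts.

    ``total_providers``/``total_patients`` are the cohort after the
    provider-level and edge-level filters (the population the community
    detection saw); the retained counts are per major community. Excluded
    counts are the complements; the mean excluded community size needs
    ``n_excluded_communities``.
    """
    retained_p = sum(retained_provider_counts)
    retained_pat = sum(retained_patient_counts)
    if retained_p > total_providers or retained_pat > total_patients:
        raise ValueError("retained counts exceed cohort totals")
    k = len(retained_provider_counts)
    excluded_providers = total_providers - retained_p
    excluded_patients = total_patients - retained_pat
    return CohortBookkeeping(
        total_providers=total_providers,
        total_patients=total_patients,
        n_retained_communities=k,
        mean_retained_community_size=retained_p / k if k else 0.0,
        excluded_providers=excluded_providers,
        excluded_patients=excluded_patients,
        n_excluded_communities=n_excluded_communities,
        mean_excluded_community_size=(
            excluded_providers / n_excluded_communities
            if n_excluded_communities
            else None
        ),
        excluded_provider_pct=100.0 * excluded_providers / total_providers,
        excluded_patient_pct=100.0 * excluded_patients / total_patients,
    )
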