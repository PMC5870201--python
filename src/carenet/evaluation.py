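"""Recovery metrics against the synthetic generator's planted truth."""

from __future__ import annotations

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from carenet.attribution import PatientAssignment
from carenet.communities import Partition


def community_recovery_ari(partition: Partition, provider_truth: pd.Series) -> float:
    """Adjusted Rand index between a detected partition and the planted one.

    Evaluated over the providers present in the partition (providers removed
    by filters carry no detected label to compare).
    """
    npis = sorted(partition.assignment)
    detected = [partition.assignment[n] for n in npis]
    truth = [int(provider_truth.loc[n]) for n in npis]
    return float(adjusted_rand_score(truth, detected))


def map_labels_to_truth(partition: Partition, provider_truth: pd.Series) -> dict[int, int]:
    """Map each detected community to its majority planted community."""
    mapping: dict[int, int] = {}
    for label in partition.labels:
        members = partition.members(label)
        counts = provider_truth.loc[provider_truth.index.intersection(members)]
        mapping[label] = int(counts.value_counts().idxmax())
    return mapping


def attribution_accuracy(
    assignment: PatientAssignment,
    partition: Partition,
    provider_truth: pd.Series,
    patient_truth: pd.Series,
) -> float:
    """Fraction of assigned patients attributed to their planted home community.

    Detected community labels are first mapped to planted labels by provider
    majority; unassigned patients are excluded from the denominator.
    """
    mapping = map_labels_to_truth(partition, provider_truth)
    assigned = assignment.assigned
    if assigned.empty:
        return float("nan")
    planted = assigned["community"].map(mapping)
    truth = patient_truth.reindex(assigned.index)
    return float((planted.values == truth.values).mean())
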