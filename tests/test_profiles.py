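"""Community profiles: composition, concentration, cost and risk measures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from carenet.attribution import assign_by_plurality
from carenet.communities import Partition, detect_communities, filter_small_communities
from carenet.config import SynthConfig
from carenet.graph import build_shared_patient_graph, prune_edges
from carenet.ingest import collapse_to_visits
from carenet.profiles import (
    build_profiles,
    community_utilization_spend,
    county_distribution,
    herfindahl,
    org_community_concentration,
    pcp_specialist_ratio,
    pmpm,
    risk_adjusted_pmpm,
)
from carenet.synthetic import generate_dataset


def test_pcp_share_definitional():
    specs = ["Family Medicine"] * 2 + ["Cardiovascular Disease"] * 8
    assert pcp_specialist_ratio(specs) == pytest.approx(20.0)
    assert pcp_specialist_ratio(["Internal Medicine"] * 4) == pytest.approx(100.0)
    # the PCP/specialist quotient variant
    assert pcp_specialist_ratio(specs, as_quotient=True) == pytest.approx(25.0)
    with pytest.raises(ValueError):
        pcp_specialist_ratio([])


def test_pcp_share_recovers_generator_fraction():
    cfg = SynthConfig(n_communities=1, providers_per_community=200,
                      patients_per_community=1, pcp_fraction=0.45, seed=31)
    ds = generate_dataset(cfg)
    ratio = pcp_specialist_ratio(ds.providers["specialty"], cfg.pcp_specialties)
    se = 100 * np.sqrt(0.45 * 0.55 / 200)
    assert abs(ratio - 45.0) <= 3 * se


def test_herfindahl_worked_examples():
    assert herfindahl(["O1"] * 7) == pytest.approx(1.0)
    assert herfindahl(["O1", "O1", "O2", "O2"]) == pytest.approx(0.5)
    orgs = ["A"] * 4 + ["B"] * 3 + ["C"] * 2 + ["D"]
    assert herfindahl(orgs) == pytest.approx(0.30)


def test_herfindahl_nulls_are_singletons_and_label_invariance():
    assert herfindahl(["O1", "O1", None, None]) == pytest.approx(
        0.25 + 2 * 0.0625
    )
    orgs = ["A"] * 5 + ["B"] * 5
    relabeled = ["X"] * 5 + ["Y"] * 5
    assert herfindahl(orgs) == pytest.approx(herfindahl(relabeled))


@given(st.lists(st.sampled_from(["A", "B", "C"]), min_size=2, max_size=20))
def test_herfindahl_decreases_when_provider_leaves_largest_org(orgs):
    biggest = max(set(orgs), key=orgs.count)
    if orgs.count(biggest) < 2:
        return
    idx = orgs.index(biggest)
    moved = orgs[:idx] + ["__new_singleton__"] + orgs[idx + 1:]
    assert herfindahl(moved) < herfindahl(orgs)


def test_pmpm_definitional():
    assert pmpm(12_000.0, 10 * 12) == pytest.approx(100.0)
    assert pmpm(0.0, 24) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        pmpm(100.0, 0)


def test_risk_adjusted_pmpm_worked_examples():
    assert risk_adjusted_pmpm(1536, 5.4) == pytest.approx(284.44)
    assert risk_adjusted_pmpm(3586, 10.2) == pytest.approx(351.57)
    assert risk_adjusted_pmpm(123.45, 1.0) == pytest.approx(123.45)
    with pytest.raises(ValueError):
        risk_adjusted_pmpm(100.0, 0.0)


def _pipeline_pieces(ds, min_size=5):
    visits = collapse_to_visits(ds.claims)
    g, _ = prune_edges(build_shared_patient_graph(visits))
    part = filter_small_communities(detect_communities(g), min_size=min_size)
    assignment = assign_by_plurality(visits, part)
    return visits, part, assignment


def test_pmpm_matches_per_patient_brute_force(small_dataset):
    visits, part, assignment = _pipeline_pieces(small_dataset)
    profiles, _ = build_profiles(
        part, assignment, small_dataset.providers, small_dataset.patients
    )
    pat = small_dataset.patients.set_index("patient_id")
    for label in part.labels:
        ids = assignment.assigned.index[assignment.assigned["community"] == label]
        spend = sum(
            visits.loc[visits["patient_id"] == pid, "spend"].sum() for pid in ids
        )
        months = sum(pat.loc[pid, "member_months"] for pid in ids)
        assert profiles.loc[label, "pmpm"] == pytest.approx(spend / months, abs=0.01)


def test_profile_risk_identity(small_dataset):
    visits, part, assignment = _pipeline_pieces(small_dataset)
    profiles, _ = build_profiles(
        part, assignment, small_dataset.providers, small_dataset.patients
    )
    for _, row in profiles.iterrows():
        assert row["risk_adjusted_pmpm"] * row["mean_risk"] == pytest.approx(
            row["pmpm"], abs=0.01 * row["mean_risk"]
        )
    assert profiles["n_patients"].sum() == len(assignment.assigned)


def test_pooled_utilization_aggregation():
    table = pd.DataFrame(
        {
            "community": [1, 1, 1, 1],
            "within_utilization": [0.75] * 4,
            "within_spend": [0.75] * 4,
            "total_visits": [4] * 4,
            "total_spend": [100.0] * 4,
            "within_visits": [3] * 4,
            "within_dollars": [75.0] * 4,
        },
        index=pd.Index([f"p{i}" for i in range(4)], name="patient_id"),
    )
    from carenet.attribution import PatientAssignment

    assignment = PatientAssignment(table=table, visit_counts=pd.DataFrame(),
                                   method="plurality")
    util = community_utilization_spend(assignment)
    assert util.loc[1, "pct_within_utilization"] == pytest.approx(75.0)
    assert util.loc[1, "pct_within_spend"] == pytest.approx(75.0)


def test_fully_in_community_cohort_scores_100():
    ds = generate_dataset(
        SynthConfig(n_communities=2, providers_per_community=8,
                    patients_per_community=40, leakage_rate=0.0, seed=41)
    )
    visits, part, assignment = _pipeline_pieces(ds)
    util = community_utilization_spend(assignment)
    assert np.allclose(util["pct_within_utilization"], 100.0)


def test_county_shares_and_anchor(small_dataset):
    visits, part, assignment = _pipeline_pieces(small_dataset)
    shares, anchors = county_distribution(assignment, small_dataset.patients)
    sums = shares.groupby("community")["share"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)
    for label in part.labels:
        grp = shares[shares["community"] == label]
        assert anchors[label] == grp.loc[grp["share"].idxmax(), "county"]


def test_anchor_county_recovered_within_three_se():
    cfg = SynthConfig(n_communities=4, providers_per_community=15,
                      patients_per_community=150, leakage_rate=0.05,
                      anchor_county_prob=0.8, seed=43)
    ds = generate_dataset(cfg)
    visits, part, assignment = _pipeline_pieces(ds, min_size=10)
    shares, anchors = county_distribution(assignment, ds.patients)
    se = np.sqrt(0.8 * 0.2 / cfg.patients_per_community)
    planted = {c: cfg.counties[c % 4] for c in range(4)}
    from carenet.evaluation import map_labels_to_truth

    mapping = map_labels_to_truth(part, ds.truth.provider_community)
    for label in part.labels:
        assert anchors[label] == planted[mapping[label]]
        top = shares[
            (shares["community"] == label) & (shares["county"] == anchors[label])
        ]["share"].iloc[0]
        assert abs(top - 0.8) <= 3 * se


def _org_partition(providers, mapping):
    sizes = {}
    for c in mapping.values():
        sizes[c] = sizes.get(c, 0) + 1
    return Partition(assignment=mapping, modularity=0.0, sizes=sizes)


def test_org_concentration_degenerate_and_split_cases():
    providers = pd.DataFrame(
        {
            "npi": [f"n{i}" for i in range(8)],
            "specialty": ["Family Medicine"] * 8,
            "org_id": ["O1"] * 4 + ["O2"] * 4,
        }
    )
    whole = _org_partition(providers, {f"n{i}": 1 if i < 4 else 2 for i in range(8)})
    count, k = org_community_concentration(providers, whole, top_k=2, threshold=0.75)
    assert (count, k) == (2, 2)
    # one org split 50/50 across communities fails a 75% threshold
    split = _org_partition(providers, {f"n{i}": 1 if i % 2 else 2 for i in range(8)})
    count, _ = org_community_concentration(providers, split, top_k=2, threshold=0.75)
    assert count == 0


def test_org_alignment_on_concentrated_synthetic_run():
    cfg = SynthConfig(n_communities=4, providers_per_community=25,
                      patients_per_community=100, leakage_rate=0.05,
                      org_concentration=0.9, orgs_per_community=3, seed=47)
    ds = generate_dataset(cfg)
    visits, part, assignment = _pipeline_pieces(ds, min_size=15)
    count, k = org_community_concentration(ds.providers, part, top_k=10)
    assert k >= 1
    assert count / k >= 0.8
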