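"""Synthetic claims generator with planted provider communities.

Emulates one study year of administrative claims for a pre-filtered chronic
cohort: every patient belongs to a home community of providers, each visit
goes to a home-community provider unless it "leaks" (probability
``leakage_rate``) to a provider elsewhere, and every visit is emitted as one
or more claim lines sharing the visit's start date. Provider specialties are
tilted per community so that planted import/export roles are recoverable
downstream; organizations are planted with a configurable concentration so
the Herfindahl and organization-alignment statistics have known truth.

The ground truth (provider -> community, patient -> home community, true
visit count) is carried alongside the tables so every pipeline stage can be
tested against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from carenet.config import ConfigurationError, SynthConfig


@dataclass(frozen=True)
class Truth:
    """Planted assignments and visit-level ground truth."""

    provider_community: pd.Series  # index npi -> community label (0-based)
    patient_community: pd.Series  # index patient_id -> community label
    #: one row per true visit: patient_id, npi, start_date, home_community,
    #: provider_community, leaked
    visits: pd.DataFrame | None = None

    @property
    def n_visits(self) -> int:
        return 0 if self.visits is None else len(self.visits)


@dataclass(frozen=True)
class Population:
    providers: pd.DataFrame
    patients: pd.DataFrame
    truth: Truth


@dataclass(frozen=True)
class SynthDataset:
    claims: pd.DataFrame
    providers: pd.DataFrame
    patients: pd.DataFrame
    truth: Truth


def _community_weights(config: SynthConfig, community: int) -> tuple[list[str], np.ndarray]:
    names = list(config.specialty_catalog)
    w = np.array(
        [
            config.specialty_catalog[s][community % len(config.specialty_catalog[s])]
            for s in names
        ],
        dtype=float,
    )
    if w.sum() <= 0:
        raise ConfigurationError(f"specialty weights for community {community} sum to 0")
    return names, w / w.sum()


def generate_population(config: SynthConfig) -> Population:
    """Draw the provider and patient tables with planted community labels.

    Providers are PCPs with probability ``pcp_fraction`` (uniform over the
    configured PCP specialties), otherwise specialists drawn from the
    community's tilted specialty weights. Each provider joins its
    community's largest organization with probability ``org_concentration``,
    else a uniformly chosen smaller one, and sits in the community's anchor
    county. Patients get their community's anchor county with probability
    ``anchor_county_prob``, else a uniform other county; risk scores are
    truncated-normal above zero.
    """
    rng = np.random.default_rng([config.seed % (2**31), 11])
    K = config.n_communities
    counties = list(config.counties)
    anchor = {c: counties[c % len(counties)] for c in range(K)}

    provider_rows = []
    npi_counter = 1000000000
    for c in range(K):
        names, weights = _community_weights(config, c)
        for _ in range(config.providers_per_community):
            npi_counter += 1
            if rng.random() < config.pcp_fraction:
                specialty = config.pcp_specialties[
                    rng.integers(len(config.pcp_specialties))
                ]
            else:
                specialty = names[rng.choice(len(names), p=weights)]
            if config.orgs_per_community == 1 or rng.random() < config.org_concentration:
                org_idx = 0
            else:
                org_idx = int(rng.integers(1, config.orgs_per_community))
            provider_rows.append(
                {
                    "npi": str(npi_counter),
                    "specialty": specialty,
                    "org_id": f"ORG-C{c}-{org_idx}",
                    "county": anchor[c],
                    "npi_type": "individual",
                    "_community": c,
                }
            )
    providers = pd.DataFrame(provider_rows)

    patient_rows = []
    a = (0.0 - config.risk_mean) / config.risk_sd
    for c in range(K):
        n = config.patients_per_community
        risks = stats.truncnorm.rvs(
            a, np.inf, loc=config.risk_mean, scale=config.risk_sd, size=n,
            random_state=np.random.default_rng([config.seed % (2**31), 13, c]),
        )
        for j in range(n):
            if rng.random() < config.anchor_county_prob or len(counties) == 1:
                county = anchor[c]
            else:
                others = [x for x in counties if x != anchor[c]]
                county = others[rng.integers(len(others))]
            patient_rows.append(
                {
                    "patient_id": f"P{c:02d}-{j:05d}",
                    "county": county,
                    "risk_score": float(risks[j]),
                    "member_months": config.member_months_per_patient,
                    "imputed_pcp_npi": "",
                    "_community": c,
                }
            )
    patients = pd.DataFrame(patient_rows)

    truth = Truth(
        provider_community=providers.set_index("npi")["_community"].rename("community"),
        patient_community=patients.set_index("patient_id")["_community"].rename(
            "community"
        ),
    )
    return Population(
        providers=providers.drop(columns="_community"),
        patients=patients.drop(columns="_community"),
        truth=truth,
    )


def generate_visits(population: Population, config: SynthConfig) -> SynthDataset:
    """Simulate visits and expand them into claim lines.

    Per patient: Poisson(``visits_per_patient_mean``) visits, i.i.d. Each
    visit leaks to a uniformly chosen out-of-home-community provider with
    probability ``leakage_rate``, else goes to a uniform home-community
    provider; the visit date is uniform within the study year and resampled
    on (provider, date) collision so every true visit survives the
    start-date collapse. Each visit emits ``1 + Poisson(mean - 1)`` claim
    lines sharing the start date, with independent lognormal allowed
    amounts.
    """
    if len(population.providers) == 0 or len(population.patients) == 0:
        raise ValueError("population is empty")
    rng = np.random.default_rng([config.seed % (2**31), 17])
    K = config.n_communities
    prov_comm = population.truth.provider_community
    by_comm = {
        c: prov_comm.index[prov_comm.values == c].to_numpy() for c in range(K)
    }
    all_npis = prov_comm.index.to_numpy()
    year_start = pd.Timestamp(config.study_year, 1, 1)
    n_days = 366 if year_start.is_leap_year else 365

    visit_rows = []
    line_rows = []
    for patient_id, home in population.truth.patient_community.items():
        n_visits = int(rng.poisson(config.visits_per_patient_mean))
        seen: set[tuple[str, int]] = set()
        home_pool = by_comm[home]
        away_pool = all_npis[prov_comm.values != home] if K > 1 else home_pool
        for _ in range(n_visits):
            leaked = K > 1 and rng.random() < config.leakage_rate
            pool = away_pool if leaked else home_pool
            npi = pool[rng.integers(len(pool))]
            day = int(rng.integers(n_days))
            while (npi, day) in seen:
                day = int(rng.integers(n_days))
            seen.add((npi, day))
            date = (year_start + pd.Timedelta(days=day)).date().isoformat()
            visit_rows.append(
                {
                    "patient_id": patient_id,
                    "npi": npi,
                    "start_date": date,
                    "home_community": home,
                    "provider_community": int(prov_comm.loc[npi]),
                    "leaked": leaked,
                }
            )
            n_lines = 1 + int(rng.poisson(config.duplicate_lines_per_visit_mean - 1.0))
            amounts = rng.lognormal(config.cost_log_mean, config.cost_log_sd, n_lines)
            for amt in amounts:
                line_rows.append(
                    {
                        "patient_id": patient_id,
                        "npi": npi,
                        "start_date": date,
                        "allowed_amount": round(float(amt), 2),
                    }
                )

    claims = pd.DataFrame(
        line_rows, columns=["patient_id", "npi", "start_date", "allowed_amount"]
    )
    visits_truth = pd.DataFrame(
        visit_rows,
        columns=[
            "patient_id",
            "npi",
            "start_date",
            "home_community",
            "provider_community",
            "leaked",
        ],
    )
    truth = Truth(
        provider_community=population.truth.provider_community,
        patient_community=population.truth.patient_community,
        visits=visits_truth,
    )
    return SynthDataset(
        claims=claims,
        providers=population.providers,
        patients=population.patients,
        truth=truth,
    )


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Generate population and visits in one step."""
    return generate_visits(generate_population(config), config)


def write_dataset(dataset: SynthDataset, outdir: str | Path) -> dict[str, Path]:
    """Write claims.csv, providers.csv, patients.csv and truth.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "claims": outdir / "claims.csv",
        "providers": outdir / "providers.csv",
        "patients": outdir / "patients.csv",
        "truth": outdir / "truth.csv",
    }
    dataset.claims.to_csv(paths["claims"], index=False)
    dataset.providers.to_csv(paths["providers"], index=False)
    dataset.patients.to_csv(paths["patients"], index=False)
    truth = pd.concat(
        [
            dataset.truth.provider_community.rename_axis("id")
            .reset_index()
            .assign(kind="provider"),
            dataset.truth.patient_community.rename_axis("id")
            .reset_index()
            .assign(kind="patient"),
        ],
        ignore_index=True,
    )[["kind", "id", "community"]]
    truth.to_csv(paths["truth"], index=False)
    return paths
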