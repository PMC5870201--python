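"""Configuration objects for the synthetic generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its contract."""


#: Default PCP specialty set used for the PCP-specialist ratio and PCP
#: imputation. Configurable everywhere it is consumed.
DEFAULT_PCP_SPECIALTIES: tuple[str, ...] = (
    "Family Medicine",
    "Internal Medicine",
    "General Practice",
)

#: Specialist specialties with per-community multinomial weight tilts.
#: A community with a large weight for a specialty holds a surplus of it
#: (an exporter role); a small weight plants a deficit (an importer role).
#: Weights are cycled when there are more communities than weight entries.
DEFAULT_SPECIALTY_CATALOG: Mapping[str, Sequence[float]] = {
    "Cardiovascular Disease": (0.5, 0.5, 0.5, 3.0),
    "Endocrinology": (3.0, 0.5, 1.0, 0.5),
    "Ophthalmology": (1.0, 3.0, 0.5, 0.5),
    "Dermatology": (0.5, 1.0, 3.0, 1.0),
    "Gastroenterology": (1.0, 1.0, 1.0, 0.5),
    "Vascular Surgery": (0.5, 0.5, 0.5, 2.0),
}

#: The four study counties; each planted community is anchored to one
#: (cycled if there are more communities than counties).
DEFAULT_COUNTIES: tuple[str, ...] = (
    "Albany",
    "Rensselaer",
    "Saratoga",
    "Schenectady",
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the planted-community claims generator.

    Defaults emulate a single-payer, single-year diabetic cohort spread over
    four adjacent counties: one provider community anchored per county, a
    ~45% PCP share, twelve member-months per patient, and a 15% chance that
    any visit leaks outside the patient's home community.
    """

    n_communities: int = 4
    providers_per_community: int = 50
    patients_per_community: int = 200
    #: Probability that a visit goes to a provider outside the patient's
    #: home community. Planted-regime tests require < 0.5.
    leakage_rate: float = 0.15
    pcp_fraction: float = 0.45
    specialty_catalog: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_SPECIALTY_CATALOG)
    )
    pcp_specialties: Sequence[str] = DEFAULT_PCP_SPECIALTIES
    orgs_per_community: int = 8
    #: Probability a provider joins its community's largest organization.
    org_concentration: float = 0.3
    visits_per_patient_mean: float = 8.0
    #: Mean claim lines emitted per visit (>= 1); lines share the visit date.
    duplicate_lines_per_visit_mean: float = 1.5
    cost_log_mean: float = 6.6
    cost_log_sd: float = 1.0
    risk_mean: float = 5.0
    risk_sd: float = 2.0
    member_months_per_patient: int = 12
    counties: Sequence[str] = DEFAULT_COUNTIES
    #: Probability a patient resides in their community's anchor county.
    anchor_county_prob: float = 0.8
    study_year: int = 2014
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_communities": self.n_communities,
            "providers_per_community": self.providers_per_community,
            "patients_per_community": self.patients_per_community,
            "orgs_per_community": self.orgs_per_community,
            "member_months_per_patient": self.member_months_per_patient,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a count >= 1, got {value!r}")
        probs = {
            "leakage_rate": self.leakage_rate,
            "pcp_fraction": self.pcp_fraction,
            "org_concentration": self.org_concentration,
            "anchor_county_prob": self.anchor_county_prob,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
        if self.visits_per_patient_mean <= 0:
            raise ConfigurationError("visits_per_patient_mean must be positive")
        if self.duplicate_lines_per_visit_mean < 1:
            raise ConfigurationError("duplicate_lines_per_visit_mean must be >= 1")
        if self.risk_mean <= 0 or self.risk_sd <= 0:
            raise ConfigurationError("risk_mean and risk_sd must be positive")
        if self.cost_log_sd < 0:
            raise ConfigurationError("cost_log_sd must be non-negative")
        if not self.counties:
            raise ConfigurationError("counties must be non-empty")
        if not self.specialty_catalog:
            raise ConfigurationError("specialty_catalog must be non-empty")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline run configuration.

    Exactly one of ``claims_path``/``providers_path``/``patients_path`` (all
    three) or ``synth`` must be provided.
    """

    claims_path: str | None = None
    providers_path: str | None = None
    patients_path: str | None = None
    synth: SynthConfig | None = None
    min_patients: int = 5
    min_shared: int = 2
    min_community_size: int = 50
    attribution: str = "plurality"
    pcp_specialties: Sequence[str] = DEFAULT_PCP_SPECIALTIES
    rca_top_k: int = 4
    flow_threshold: float = 0.05
    balance_threshold: float = 0.2
    output_dir: str = "carenet_out"
    seed: int = 0

    def __post_init__(self) -> None:
        paths = (self.claims_path, self.providers_path, self.patients_path)
        has_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if some_paths and not has_paths:
            raise ConfigurationError(
                "claims_path, providers_path and patients_path must be given together"
            )
        if has_paths == (self.synth is not None):
            raise ConfigurationError(
                "exactly one of input paths or a synth block must be configured"
            )
        if self.attribution not in ("plurality", "pcp"):
            raise ConfigurationError(
                f"attribution must be 'plurality' or 'pcp', got {self.attribution!r}"
            )
        for name in ("min_patients", "min_shared", "min_community_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    synth = raw.pop("synth", None)
    if synth is not None:
        synth = SynthConfig(**synth)
    return RunConfig(synth=synth, **raw)


def synth_config_to_dict(config: SynthConfig) -> dict:
    d = asdict(config)
    d["specialty_catalog"] = {k: list(v) for k, v in d["specialty_catalog"].items()}
    d["pcp_specialties"] = list(d["pcp_specialties"])
    d["counties"] = list(d["counties"])
    return d
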