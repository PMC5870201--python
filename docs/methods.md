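# Methods

carenet reconstructs "naturally occurring" provider networks from one year
of medical insurance claims and characterizes their service leakage. This
note documents the model, the numerical and design choices, and what the
synthetic benchmark does and does not establish.

## From claim lines to a patient-sharing graph

A provider encounter is typically billed as several claim lines; all lines
of one encounter share the claim's start date. We therefore define a
**visit** as a distinct (patient, provider NPI, start date) triple and sum
the lines' allowed amounts into the visit's spend, which conserves total
dollars. Day resolution is deliberate: two same-day lines are one visit even
if they cover distinct procedures.

Only individual (Type 1) NPIs are analyzed; organizational NPIs are dropped
at load. A provider must serve at least `min_patients` (default 5) distinct
cohort patients to enter the network. One filtering pass suffices because
removing a provider cannot reduce another provider's distinct-patient count.

Nodes are providers; the edge weight between two providers is the number of
**distinct patients** who visited both during the study period — a patient
contributes at most one unit per provider pair regardless of how often they
co-visited. Edges carried by a single shared patient are pruned
(`min_shared`, default 2). Nodes isolated by pruning are removed and
reported: community detection on singletons is vacuous, while the leakage
denominators downstream still see visits to those providers.

## Community detection

Communities maximize the weighted Newman–Girvan modularity

    Q = (1/2m) Σ_ij [A_ij − k_i k_j / (2m)] δ(c_i, c_j)

with A the shared-patient weights, k the node strengths, and m the total
edge weight. We implement the fast-greedy agglomerative maximizer
(Clauset–Newman–Moore): start from singletons, repeatedly merge the
connected community pair with the largest gain ΔQ = 2(e_ij − a_i a_j), and
stop when no merge improves Q. Two numerical choices make runs reproducible
without a seed:

* **tie-break** — among equal-gain merges (tolerance 1e-15) the pair whose
  community representatives (minimum member NPI) sort lexicographically
  smallest is merged first;
* **stability** — retained communities are always relabeled 1..K by
  descending size, ties by smallest member NPI.

Greedy agglomeration is a heuristic; correctness is gated on an exhaustive
oracle (`brute_force_max_modularity`, all set partitions of graphs with ≤ 10
nodes) that the greedy result never exceeds and matches exactly on
disconnected-clique graphs. Detected communities smaller than
`min_community_size` (default 50 providers) are excluded from profiling and
reported (count, providers removed, mean size).

## Patient attribution and leakage

Patients are attributed by **plurality**: the retained community holding the
most of the patient's visits, with ties broken by greater spend in the tied
communities, then by the smaller community label (spend is the natural
secondary plurality signal; the label rule makes attribution total and
deterministic). An alternative **pcp** rule assigns a patient to the
community of their imputed primary care provider — the PCP-specialty
provider with the most of their visits (ties: most recent visit, then
smaller NPI). The default PCP specialty set is {Family Medicine, Internal
Medicine, General Practice}, configurable.

Within-community utilization is the share of a patient's visits inside
their assigned community; within-community spending is the dollar analogue.
The denominator includes visits to providers removed by the
minimum-patient filter and to excluded small communities — the conservative
choice, so upstream filters never hide leakage. Plurality maximizes
within-community utilization per patient by construction, and the test
suite verifies no forced single-community alternative beats it.

Community-level percentages are **pooled** (community total within-visits
over community total visits) rather than means of patient fractions; the
patient-mean variant is also computed and reported alongside.

## Community profiles

Per retained community: provider and patient counts; the PCP-specialist
ratio as the PCP **share** of providers (a PCP/specialist quotient is
available behind `as_quotient=True`, but the share is the primary
definition since it remains bounded for PCP-dominated communities); the
Herfindahl index Σ s_o² over organizations' shares of the community's
providers (unaffiliated providers count as singleton organizations; 1 =
monopoly); PMPM = assigned patients' total allowed spend (all their visits,
in- and out-of-community) divided by their summed member-months, displayed
in whole dollars; the unweighted mean risk score of assigned patients; and
risk-adjusted PMPM = PMPM / mean risk, reported to cents — the identity
risk_adjusted × mean_risk = PMPM holds to the cent before display rounding.
County shares of assigned patients identify each community's anchor county
(argmax share; alphabetical on ties, which are flagged). A separate
statistic counts how many of the top-k organizations by affiliated
retained-provider count have at least 75% of those providers in a single
community.

## Import/export trade and RCA

A visit by a patient of community c to a provider of community c′ ≠ c is an
import of the provider's **servicing specialty** by c and an export by c′.
Trade is counted in visits, not dollars (a dollar-weighted tensor is a
one-line variant users can build from the saved long-format tensor). Visits
to providers outside every retained community are tallied under an
`external` exporter bucket: they are leakage, but RCA requires a community
on both sides, so they are excluded from RCA marginals.

    RCA(c, i) = [x(c,i) / Σ_i x(c,i)] / [Σ_c x(c,i) / Σ_{c,i} x(c,i)]

computed separately on import and export marginals. Undefined cells (a
community or specialty with zero directional trade) are reported missing,
never 0. Invariants enforced by tests: per-specialty import/export
conservation; the trade-share-weighted mean of RCA over communities equals
1 per specialty and direction (to 1e-9); scale invariance. Flow edges for a
specialty normalize each community pair's volume by the specialty's total
cross-community volume and keep pairs strictly above the threshold
(default 5%). The net-trade report flags community-specialty pairs whose
import and export volumes differ by less than 20% relative gap as
internalization opportunities: demand and supply both exist in-community.

## Synthetic benchmark

The generator plants K communities, each anchored to a county. Providers
are PCPs with probability `pcp_fraction` (default 0.45, the observed
low-leakage "sweet spot") or specialists drawn from per-community tilted
specialty weights, which plants recoverable importer/exporter roles. Each
provider joins its community's largest organization with probability
`org_concentration` (default 0.3 of 8 organizations, giving Herfindahl
values in the 0.05–0.3 range typical of mixed provider markets). Patients
live in the anchor county with probability 0.8; risk scores are
truncated-normal above zero (mean 5, sd 2, matching a chronic-cohort HCC
scale); member-months default to 12 (full-year enrollment).

Visits are i.i.d. per patient, Poisson(8) per year within a single study
year (2014): the downstream measures use only visit counts, so temporal
dynamics would add nothing testable. Each visit leaks to a uniformly chosen
out-of-community provider with probability `leakage_rate` (default 0.15,
consistent with ~85% within-community utilization in mature networks), and
is emitted as 1 + Poisson(0.5) claim lines sharing the start date, with
lognormal line amounts (log-mean 6.6, log-sd 1.0, putting PMPM near the
$1,000–3,500 range seen in high-morbidity commercial cohorts). Visit dates
are resampled on (provider, date) collision so the true visit count
survives the start-date collapse exactly.

What passing the planted-recovery suite shows: the pipeline correctly
recovers block structure, attribution, leakage level, anchor counties, and
planted trade roles under a well-separated regime (leakage < 0.5, ample
patients per provider). What it does not show: robustness to the messiness
of real claims — enrollment churn, specialty miscoding, shared NPIs,
out-of-state care, or communities of very different sizes and densities.

Problem sizes in the default test and acceptance runs (hundreds of
providers, up to ~10⁴ visits) were chosen as the smallest scales at which
the binomial oracles have power; all statistical assertions use 3-standard-
error bands derived from the generator's own parameters, fixed in advance.

## Known limitations

* Greedy modularity has a resolution limit and no optimality guarantee on
  large graphs; the oracle gate covers small graphs only.
* Modularity values depend on the variant of maximizer; other maximizers
  (leading-eigenvector, Louvain) may partition real data differently.
* Risk scores are consumed as given numbers; no risk model is fitted.
* Single-year, non-longitudinal: network change over time is out of scope.
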