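"""Synthetic data emulating the structure of the empirical study.

The study template mirrors the sampling design: eleven locations in three
regions (Western Indian Ocean, Western Pacific, Western Atlantic), 25
microsatellite loci and a 2,516-bp concatenated mtDNA fragment, with the
per-location genotype and sequence sample sizes of the source sampling
campaign. :func:`generate_study_like` simulates multi-location datasets
under three qualitative regimes, including a mito-nuclear-discordant one in
which nuclear differentiation between the two Indo-Pacific regions stays
near zero while mitochondrial differentiation is strong — the pattern that
motivates the scenario comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import msprime
import numpy as np

from .coalsim import (
    MarkerConfig,
    PriorSpec,
    ScenarioSpec,
    msat_from_demography,
    mtdna_from_demography,
    sample_prior,
    simulate_joint,
)
from .data import GenotypeTable, HaplotypeAlignment, PopulationMap

#: (location, n genotyped, n sequenced, region)
STUDY_LOCATIONS: tuple[tuple[str, int, int, str], ...] = (
    ("ZAN", 13, 13, "WIO"),
    ("SEY", 39, 36, "WIO"),
    ("MOZ", 18, 18, "WIO"),
    ("SAF", 32, 25, "WIO"),
    ("MAD", 12, 8, "WIO"),
    ("RUN", 126, 38, "WIO"),
    ("ROD", 6, 6, "WIO"),
    ("AUS1", 44, 23, "WP"),
    ("AUS2", 26, 14, "WP"),
    ("NCA", 10, 7, "WP"),
    ("FLO", 31, 30, "WA"),
)

#: per-gene fragment lengths of the concatenated mtDNA sequence
GENE_FRAGMENTS: dict[str, int] = {"CR": 923, "nd4": 672, "cytb": 921}

REGIMES = ("discordant", "panmictic", "three-isolates")


@dataclass
class StudyTemplate:
    """Sampling design: locations, per-marker sample sizes, regions."""

    locations: tuple[tuple[str, int, int, str], ...] = STUDY_LOCATIONS
    n_sat_loci: int = 25
    gene_fragments: dict[str, int] = field(default_factory=lambda: dict(GENE_FRAGMENTS))

    def __post_init__(self) -> None:
        for name, n_sat, n_seq, _region in self.locations:
            if n_sat < 1 or n_seq < 1:
                raise ValueError(f"location {name}: sample sizes must be >= 1")

    @property
    def seq_length(self) -> int:
        return sum(self.gene_fragments.values())

    @property
    def regions(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for name, _, _, region in self.locations:
            out.setdefault(region, []).append(name)
        return out

    @property
    def msat_samples(self) -> dict[str, int]:
        return {name: n for name, n, _, _ in self.locations}

    @property
    def seq_samples(self) -> dict[str, int]:
        return {name: n for name, _, n, _ in self.locations}

    def population_map(self) -> PopulationMap:
        loc_to_group = {name: region for name, _, _, region in self.locations}
        return PopulationMap({}, loc_to_group)


@dataclass
class RegimeParams:
    """Demographic knobs behind one study-like regime (sizes in gene
    copies, times in generations)."""

    n_loc_sat: float
    n_loc_mt: float
    m_within: float  # island-model rate among locations of a region
    t_locations: float  # split of locations from their regional ancestor
    t_wio_wp: float  # divergence of the two Indo-Pacific regions
    t_wa: float  # divergence of the Atlantic from the rest
    mu_sat: float = 5e-4
    p_gsm: float = 0.22
    mu_mt: float = 2e-8
    kappa_like: float = 0.7


#: regime presets; the discordant one reproduces the qualitative pattern of
#: weak nuclear / strong mitochondrial structure between WIO and WP
REGIME_PRESETS: dict[str, RegimeParams] = {
    "discordant": RegimeParams(
        n_loc_sat=2e5, n_loc_mt=2e3, m_within=1e-3,
        t_locations=200.0, t_wio_wp=2e4, t_wa=4e5,
    ),
    "panmictic": RegimeParams(
        n_loc_sat=2e4, n_loc_mt=5e3, m_within=5e-2,
        t_locations=50.0, t_wio_wp=50.0, t_wa=50.0,
    ),
    "three-isolates": RegimeParams(
        n_loc_sat=2e3, n_loc_mt=5e2, m_within=1e-2,
        t_locations=100.0, t_wio_wp=5e4, t_wa=5e4,
    ),
}


def _study_demography(
    template: StudyTemplate, rp: RegimeParams, ploidy: int, n_copies: float
) -> msprime.Demography:
    d = msprime.Demography()
    regions = template.regions
    size = n_copies / ploidy
    for name, _, _, _region in template.locations:
        d.add_population(name=name, initial_size=size)
    for region, locs in regions.items():
        d.add_population(name=f"ANC_{region}", initial_size=size)
        d.add_population_split(
            time=rp.t_locations, derived=locs, ancestral=f"ANC_{region}"
        )
        if rp.m_within > 0:
            for a in locs:
                for b in locs:
                    if a != b:
                        d.set_migration_rate(source=a, dest=b, rate=rp.m_within)
    d.add_population(name="ANC_IP", initial_size=size)
    d.add_population_split(
        time=max(rp.t_wio_wp, rp.t_locations),
        derived=["ANC_WIO", "ANC_WP"],
        ancestral="ANC_IP",
    )
    d.add_population(name="ROOT", initial_size=size)
    d.add_population_split(
        time=max(rp.t_wa, rp.t_wio_wp, rp.t_locations),
        derived=["ANC_IP", "ANC_WA"],
        ancestral="ROOT",
    )
    d.sort_events()
    return d


@dataclass
class TruthRecord:
    """Provenance of one synthetic dataset, sufficient for exact replay."""

    scenario_id: int | None
    params: dict[str, float]
    seed: int
    regime: str | None = None

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(**d)


def generate_study_like(
    template: StudyTemplate,
    regime: str,
    rng: np.random.Generator,
    regime_params: RegimeParams | None = None,
) -> tuple[GenotypeTable, HaplotypeAlignment, TruthRecord]:
    """Simulate a full multi-location study dataset under one regime.

    Regions are internally connected island models; the regimes differ in
    effective sizes and between-region divergence times. Returns the
    genotype table, the alignment and a truth record holding the seed and
    the regime parameters used.
    """
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}")
    rp = regime_params or REGIME_PRESETS[regime]
    seed = int(rng.integers(1, 2**31 - 1))
    local = np.random.default_rng(seed)
    d_sat = _study_demography(template, rp, ploidy=2, n_copies=rp.n_loc_sat)
    table = msat_from_demography(
        d_sat, template.msat_samples, template.n_sat_loci, rp.mu_sat, rp.p_gsm, local
    )
    d_mt = _study_demography(template, rp, ploidy=1, n_copies=rp.n_loc_mt)
    alignment = mtdna_from_demography(
        d_mt, template.seq_samples, template.seq_length, rp.mu_mt, rp.kappa_like, local
    )
    truth = TruthRecord(None, asdict(rp), seed, regime=regime)
    return table, alignment, truth


def make_pods(
    prior: PriorSpec,
    scenario: ScenarioSpec,
    n: int,
    config: MarkerConfig,
    rng: np.random.Generator,
) -> list[tuple[GenotypeTable, HaplotypeAlignment, TruthRecord]]:
    """Independent pseudo-observed datasets with recorded truth.

    Each POD stores its own seed so it can be re-simulated exactly from the
    truth record alone.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    out = []
    for _ in range(n):
        seed = int(rng.integers(1, 2**31 - 1))
        local = np.random.default_rng(seed)
        params = sample_prior(prior, local)
        table, alignment = simulate_joint(scenario, params, config, local)
        out.append(
            (table, alignment, TruthRecord(scenario.scenario_id, params.as_dict(), seed))
        )
    return out


def replay_pod(
    truth: TruthRecord, config: MarkerConfig, prior: PriorSpec
) -> tuple[GenotypeTable, HaplotypeAlignment]:
    """Re-simulate a POD exactly from its truth record."""
    local = np.random.default_rng(truth.seed)
    params = sample_prior(prior, local)
    if {k: float(v) for k, v in params.as_dict().items()} != truth.params:
        raise ValueError("truth record does not match the supplied prior")
    return simulate_joint(ScenarioSpec(truth.scenario_id), params, config, local)
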