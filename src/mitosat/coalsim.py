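"""Two-deme coalescent simulation of four divergence scenarios.

An ancestral population of size ``N_anc`` splits ``t_2`` generations ago
into populations 1 and 2. The scenarios differ only in when bidirectional
(not necessarily symmetric) migration is active, expressed backward in time
from sampling (time 0):

* scenario 1 - recurrent migration over the whole divergence, ``[0, t_2)``;
* scenario 2 - migration after the split, then recent isolation: ``[t_1, t_2)``;
* scenario 3 - divergence in complete isolation (no window);
* scenario 4 - isolation after the split, then recent migration: ``[0, t_1)``.

Each parameter draw produces a *paired* dataset: microsatellites (diploid
sampling, generalized stepwise mutation) and mtDNA (haploid sampling,
finite-sites HKY-like mutation) share t_1, t_2 and the scenario but have
their own effective sizes, migration and mutation rates, mirroring the
four-fold smaller, maternally inherited mitochondrial genome.

All effective sizes are expressed in gene copies; ancestry and mutations are
delegated to msprime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import msprime
import numpy as np

from .data import GenotypeTable, HaplotypeAlignment

SCENARIO_DESCRIPTIONS = {
    1: "constant recurrent migration from the split to present",
    2: "migration after the split followed by recent isolation",
    3: "divergence in complete isolation",
    4: "isolation after the split followed by recent migration",
}


@dataclass(frozen=True)
class ScenarioSpec:
    scenario_id: int

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIO_DESCRIPTIONS:
            raise ValueError("scenario_id must be 1, 2, 3 or 4")

    @property
    def description(self) -> str:
        return SCENARIO_DESCRIPTIONS[self.scenario_id]

    @property
    def uses_t1(self) -> bool:
        return self.scenario_id in (2, 4)


@dataclass
class DemographicParams:
    """Scenario parameter vector; sizes in gene copies, times in generations.

    Migration rates are backward per-generation probabilities: ``m12`` is
    the probability that a lineage currently in population 1 traces back to
    population 2 in the previous generation. ``mu_sat`` is per locus per
    generation; ``mu_mt`` per site per generation. ``p_gsm`` is the
    geometric parameter of the generalized stepwise model (0 = strict
    single-step); ``kappa_like`` is the probability a substitution is a
    transition.
    """

    n1_sat: float
    n2_sat: float
    nanc_sat: float
    n1_mt: float
    n2_mt: float
    nanc_mt: float
    t2: float
    t1: float = 0.0
    m12_sat: float = 0.0
    m21_sat: float = 0.0
    m12_mt: float = 0.0
    m21_mt: float = 0.0
    mu_sat: float = 5e-4
    p_gsm: float = 0.22
    mu_mt: float = 1e-8
    kappa_like: float = 0.7

    def __post_init__(self) -> None:
        for name in ("n1_sat", "n2_sat", "nanc_sat", "n1_mt", "n2_mt", "nanc_mt"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 gene copy")
        if not 0 <= self.t1 <= self.t2:
            raise ValueError("need 0 <= t1 <= t2")
        for name in ("m12_sat", "m21_sat", "m12_mt", "m21_mt"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.p_gsm < 1:
            raise ValueError("p_gsm must be in [0, 1)")
        if not 0 <= self.kappa_like < 1:
            raise ValueError("kappa_like must be in [0, 1)")
        if self.mu_sat < 0 or self.mu_mt < 0:
            raise ValueError("mutation rates must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in dc_fields(self)}


PARAM_NAMES = tuple(f.name for f in dc_fields(DemographicParams))


@dataclass
class MarkerConfig:
    """Sampling layout and marker geometry for a paired simulation."""

    n_sat_loci: int = 25
    seq_length: int = 2516
    n_diploid: tuple[int, int] = (30, 30)
    n_haploid: tuple[int, int] = (20, 20)
    pop_labels: tuple[str, str] = ("P1", "P2")
    # bounded microsatellite state space (repeat units)
    allele_lo: int = 1
    allele_hi: int = 100
    ancestral_size: int = 50

    def __post_init__(self) -> None:
        if min(self.n_diploid) < 1 or min(self.n_haploid) < 1:
            raise ValueError("sample sizes must be >= 1")
        if self.n_sat_loci < 1 or self.seq_length < 1:
            raise ValueError("need >= 1 locus and >= 1 site")
        if not self.allele_lo <= self.ancestral_size <= self.allele_hi:
            raise ValueError("ancestral allele size outside [lo, hi]")


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Independent priors for each parameter.

    Each entry maps a :class:`DemographicParams` field to
    ``("uniform" | "loguniform" | "fixed", low, high)``. ``t1`` is special:
    it is drawn as ``u * t2`` with ``u ~ Uniform(low, high)`` so the
    constraint ``t1 <= t2`` holds by construction.
    """

    entries: dict[str, tuple[str, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (kind, lo, hi) in self.entries.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            if kind not in ("uniform", "loguniform", "fixed"):
                raise ValueError(f"unknown prior kind {kind!r}")
            if kind == "fixed":
                continue
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"{name}: need finite low < high")
            if kind == "loguniform" and lo <= 0:
                raise ValueError(f"{name}: log-uniform needs low > 0")

    def with_overrides(self, **overrides: tuple[str, float, float]) -> "PriorSpec":
        merged = dict(self.entries)
        merged.update(overrides)
        return PriorSpec(merged)


def default_prior() -> PriorSpec:
    """Broad reference priors: effective sizes and divergence time
    log-uniform over four orders of magnitude, the migration window boundary
    a uniform fraction of t2, and literature-scale mutation rates."""
    return PriorSpec(
        {
            "n1_sat": ("loguniform", 1e2, 1e6),
            "n2_sat": ("loguniform", 1e2, 1e6),
            "nanc_sat": ("loguniform", 1e2, 1e6),
            "n1_mt": ("loguniform", 1e2, 1e6),
            "n2_mt": ("loguniform", 1e2, 1e6),
            "nanc_mt": ("loguniform", 1e2, 1e6),
            "t2": ("loguniform", 1e2, 1e6),
            "t1": ("uniform", 0.0, 1.0),  # fraction of t2
            "m12_sat": ("loguniform", 1e-6, 1e-2),
            "m21_sat": ("loguniform", 1e-6, 1e-2),
            "m12_mt": ("loguniform", 1e-6, 1e-2),
            "m21_mt": ("loguniform", 1e-6, 1e-2),
            "mu_sat": ("loguniform", 1e-4, 1e-3),
            "p_gsm": ("fixed", 0.22, 0.22),
            "mu_mt": ("loguniform", 1e-9, 1e-7),
            "kappa_like": ("fixed", 0.7, 0.7),
        }
    )


def _draw(kind: str, lo: float, hi: float, rng: np.random.Generator) -> float:
    if kind == "fixed":
        return lo
    if kind == "uniform":
        return float(rng.uniform(lo, hi))
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_prior(prior: PriorSpec, rng: np.random.Generator) -> DemographicParams:
    """Draw one parameter vector; reproducible for a given generator state."""
    vals: dict[str, float] = {}
    # fixed draw order = declared parameter order, for reproducibility
    for name in PARAM_NAMES:
        kind, lo, hi = prior.entries.get(name, ("fixed", 0.0, 0.0))
        if name not in prior.entries:
            continue
        vals[name] = _draw(kind, lo, hi, rng)
    if "t1" in vals and "t2" in vals:
        vals["t1"] = vals["t1"] * vals["t2"]
    return DemographicParams(**vals)


# ---------------------------------------------------------------------------
# demography
# ---------------------------------------------------------------------------

def migration_window(spec: ScenarioSpec, t1: float, t2: float) -> tuple[float, float] | None:
    """Backward-time interval ``[a, b)`` during which migration is active,
    or ``None`` for isolation throughout (scenario 3)."""
    if not 0 <= t1 <= t2:
        raise ValueError("need 0 <= t1 <= t2")
    sid = spec.scenario_id
    if sid == 1:
        return (0.0, t2)
    if sid == 2:
        return (t1, t2)
    if sid == 3:
        return None
    return (0.0, t1)


def build_demography(
    spec: ScenarioSpec,
    params: DemographicParams,
    marker_class: str,
    ploidy: int,
) -> msprime.Demography:
    """msprime demography for one marker class ('sat' or 'mt').

    Sizes are converted from gene copies to msprime population sizes
    (coalescence rate ``1/(ploidy * size)``); migration is switched on and
    off by rate-change events delimiting the scenario's window.
    """
    if marker_class not in ("sat", "mt"):
        raise ValueError("marker_class must be 'sat' or 'mt'")
    n1 = getattr(params, f"n1_{marker_class}") / ploidy
    n2 = getattr(params, f"n2_{marker_class}") / ploidy
    nanc = getattr(params, f"nanc_{marker_class}") / ploidy
    m12 = getattr(params, f"m12_{marker_class}")
    m21 = getattr(params, f"m21_{marker_class}")

    d = msprime.Demography()
    d.add_population(name="P1", initial_size=n1)
    d.add_population(name="P2", initial_size=n2)
    d.add_population(name="ANC", initial_size=nanc)
    d.add_population_split(time=params.t2, derived=["P1", "P2"], ancestral="ANC")

    window = migration_window(spec, params.t1, params.t2)
    if window is not None and window[0] < window[1] and (m12 > 0 or m21 > 0):
        a, b = window
        if a == 0.0:
            d.set_migration_rate(source="P1", dest="P2", rate=m12)
            d.set_migration_rate(source="P2", dest="P1", rate=m21)
        else:
            d.add_migration_rate_change(time=a, source="P1", dest="P2", rate=m12)
            d.add_migration_rate_change(time=a, source="P2", dest="P1", rate=m21)
        if b < params.t2:
            d.add_migration_rate_change(time=b, source="P1", dest="P2", rate=0.0)
            d.add_migration_rate_change(time=b, source="P2", dest="P1", rate=0.0)
    d.sort_events()
    return d


def active_migration_rates(demography: msprime.Demography) -> list[float]:
    """All nonzero migration rates configured in a demography (initial
    matrix plus rate-change events); empty when the class migrates nowhere."""
    rates = [r for r in np.asarray(demography.migration_matrix).ravel() if r > 0]
    for ev in demography.events:
        rate = getattr(ev, "rate", 0.0)
        if getattr(ev, "source", None) is not None and rate and rate > 0:
            rates.append(rate)
    return rates


# ---------------------------------------------------------------------------
# mutation models
# ---------------------------------------------------------------------------

def gsm_mutation_model(
    p_gsm: float, lo: int, hi: int, ancestral: int
) -> msprime.MatrixMutationModel:
    """Generalized stepwise model on the bounded state space [lo, hi].

    A mutation shifts the repeat count by ±k with k geometric(p_gsm)
    (p_gsm = 0 degenerates to the strict single-step model). Steps that
    would leave the state space are redistributed by renormalising the row,
    which makes the lower bound a reflecting floor.
    """
    k = hi - lo + 1
    idx = np.arange(k, dtype=float)
    dist = np.abs(idx[:, None] - idx[None, :])
    if p_gsm == 0.0:
        w = (dist == 1.0).astype(float)
    else:
        with np.errstate(divide="ignore"):
            w = np.where(dist >= 1.0, (1 - p_gsm) * p_gsm ** (dist - 1.0), 0.0)
    w /= w.sum(axis=1, keepdims=True)
    root = np.zeros(k)
    root[ancestral - lo] = 1.0
    alleles = [str(i) for i in range(lo, hi + 1)]
    return msprime.MatrixMutationModel(alleles, root_distribution=root, transition_matrix=w)


def hky_mutation_model(kappa_like: float) -> msprime.HKY:
    """Finite-sites nucleotide model with transition probability
    ``kappa_like`` per substitution (kappa = 2 w / (1 - w) under equal base
    frequencies)."""
    kappa = 2.0 * kappa_like / (1.0 - kappa_like) if kappa_like > 0 else 1e-9
    return msprime.HKY(kappa=kappa)


def _seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _concat_locus_trees(replicates, n_loci: int):
    """Pack independent single-locus tree sequences into one tree sequence.

    Locus ``l`` occupies the unit interval ``[l, l+1)`` with its own node
    block, so one mutation call covers all loci while genealogies stay
    independent. Sample nodes of each locus form a contiguous id block.
    """
    import tskit

    times, flags, pops = [], [], []
    lefts, rights, parents, children = [], [], [], []
    offset = 0
    first_tables = None
    for l, ts in enumerate(replicates):
        t = ts.tables
        if first_tables is None:
            first_tables = t
        nn = len(t.nodes)
        times.append(t.nodes.time)
        flags.append(t.nodes.flags)
        pops.append(t.nodes.population)
        lefts.append(np.full(len(t.edges), float(l)))
        rights.append(np.full(len(t.edges), float(l + 1)))
        parents.append(t.edges.parent + offset)
        children.append(t.edges.child + offset)
        offset += nn
    tables = tskit.TableCollection(sequence_length=float(n_loci))
    for _ in range(len(first_tables.populations)):
        tables.populations.add_row()
    tables.nodes.set_columns(
        time=np.concatenate(times),
        flags=np.concatenate(flags),
        population=np.concatenate(pops),
    )
    tables.edges.set_columns(
        left=np.concatenate(lefts),
        right=np.concatenate(rights),
        parent=np.concatenate(parents).astype(np.int32),
        child=np.concatenate(children).astype(np.int32),
    )
    tables.sort()
    return tables.tree_sequence()


def msat_from_demography(
    demog: msprime.Demography,
    samples: dict[str, int],
    n_loci: int,
    mu: float,
    p_gsm: float,
    rng: np.random.Generator,
    allele_lo: int = 1,
    allele_hi: int = 100,
    ancestral_size: int = 50,
) -> GenotypeTable:
    """Simulate unlinked microsatellite loci under an arbitrary demography.

    ``samples`` maps population name to diploid individual count; sample
    order in the returned table follows the dict order.
    """
    anc_seed, mut_seed = _seed(rng), _seed(rng)
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=demog,
        sequence_length=1,
        ploidy=2,
        num_replicates=n_loci,
        random_seed=anc_seed,
        record_provenance=False,
    )
    n_ind = sum(samples.values())
    n_samp = 2 * n_ind
    calls = np.full((n_ind, n_loci, 2), ancestral_size, dtype=np.int32)
    if mu > 0:
        ts_all = _concat_locus_trees(reps, n_loci)
        model = gsm_mutation_model(p_gsm, allele_lo, allele_hi, ancestral_size)
        mts = msprime.sim_mutations(
            ts_all,
            rate=mu,
            model=model,
            random_seed=mut_seed,
            record_provenance=False,
        )
        # sample nodes of locus l are the contiguous genotype columns
        # [l*n_samp, (l+1)*n_samp); samples of other loci decode as missing
        positions = mts.tables.sites.position
        for site_id, var in enumerate(mts.variants(isolated_as_missing=True)):
            l = int(positions[site_id])
            g = var.genotypes[l * n_samp : (l + 1) * n_samp]
            sizes = np.fromiter(
                (int(a) if a is not None else 0 for a in var.alleles),
                dtype=np.int32,
            )
            calls[:, l, :] = sizes[g].reshape(n_ind, 2)
    labels = [lab for lab, n in samples.items() for _ in range(n)]
    ids = [f"{lab}_{i:03d}" for i, lab in enumerate(labels)]
    loci = [f"L{l + 1:02d}" for l in range(n_loci)]
    return GenotypeTable(ids, labels, loci, calls)


def simulate_msat(
    spec: ScenarioSpec,
    params: DemographicParams,
    config: MarkerConfig,
    rng: np.random.Generator,
) -> GenotypeTable:
    """Simulate ``n_sat_loci`` independent microsatellite loci.

    Returns a diploid genotype table with individuals labelled by
    population; with ``mu_sat = 0`` every allele equals the configured
    ancestral repeat count.
    """
    demog = build_demography(spec, params, "sat", ploidy=2)
    n1, n2 = config.n_diploid
    table = msat_from_demography(
        demog,
        {"P1": n1, "P2": n2},
        config.n_sat_loci,
        params.mu_sat,
        params.p_gsm,
        rng,
        allele_lo=config.allele_lo,
        allele_hi=config.allele_hi,
        ancestral_size=config.ancestral_size,
    )
    if config.pop_labels != ("P1", "P2"):
        table = table.relabel(
            {"P1": config.pop_labels[0], "P2": config.pop_labels[1]}
        )
    return table


_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


def mtdna_from_demography(
    demog: msprime.Demography,
    samples: dict[str, int],
    seq_length: int,
    mu: float,
    kappa_like: float,
    rng: np.random.Generator,
) -> HaplotypeAlignment:
    """Simulate one non-recombining haploid locus under an arbitrary
    demography. Invariant sites receive i.i.d. random bases; variant
    columns come from the finite-sites mutation process on the genealogy."""
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=demog,
        sequence_length=seq_length,
        ploidy=1,
        random_seed=_seed(rng),
        record_provenance=False,
    )
    mut_seed = _seed(rng)
    n = sum(samples.values())
    # background (ancestral) bases for every site, then overwrite variants
    base_idx = rng.integers(0, 4, size=seq_length)
    mat = np.tile(_BASES[base_idx], (n, 1))
    if mu > 0:
        mts = msprime.sim_mutations(
            ts,
            rate=mu,
            model=hky_mutation_model(kappa_like),
            random_seed=mut_seed,
            record_provenance=False,
        )
        positions = mts.tables.sites.position
        for site_id, var in enumerate(mts.variants()):
            col = np.array([a.encode() for a in var.alleles], dtype="S1")
            mat[:, int(positions[site_id])] = col[var.genotypes]
    seqs = [row.tobytes().decode() for row in mat]
    labels = [lab for lab, k in samples.items() for _ in range(k)]
    ids = [f"{lab}_mt_{i:03d}" for i, lab in enumerate(labels)]
    return HaplotypeAlignment(ids, labels, seqs)


def simulate_mtdna(
    spec: ScenarioSpec,
    params: DemographicParams,
    config: MarkerConfig,
    rng: np.random.Generator,
) -> HaplotypeAlignment:
    """Simulate the mtDNA locus for the two-population scenario."""
    demog = build_demography(spec, params, "mt", ploidy=1)
    n1, n2 = config.n_haploid
    aln = mtdna_from_demography(
        demog,
        {"P1": n1, "P2": n2},
        config.seq_length,
        params.mu_mt,
        params.kappa_like,
        rng,
    )
    if config.pop_labels != ("P1", "P2"):
        aln = aln.relabel({"P1": config.pop_labels[0], "P2": config.pop_labels[1]})
    return aln


def simulate_joint(
    spec: ScenarioSpec,
    params: DemographicParams,
    config: MarkerConfig,
    rng: np.random.Generator,
) -> tuple[GenotypeTable, HaplotypeAlignment]:
    """Paired simulation: both marker classes share t_1, t_2 and the
    scenario but use their class-specific sizes, migration and mutation
    rates; genealogies are independent given that shared history."""
    table = simulate_msat(spec, params, config, rng)
    alignment = simulate_mtdna(spec, params, config, rng)
    return table, alignment
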