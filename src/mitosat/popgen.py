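"""Descriptive diversity and differentiation statistics with permutation
tests and FDR control.

This module covers the classical side of the analysis: per-location
diversity tables (allele numbers, rarefied allelic richness, observed and
expected heterozygosity, F_IS with a Hardy-Weinberg permutation test,
haplotype and nucleotide diversity), pairwise differentiation (Weir-
Cockerham F_ST, Jost's D_est, Phi_ST) with permutation p-values and
Benjamini-Hochberg correction, hierarchical AMOVA, coalescent-null
neutrality tests for Tajima's D and Fu's Fs, and a likelihood-ratio scan
for linkage disequilibrium between locus pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .data import DataError, GenotypeTable, HaplotypeAlignment, PopulationMap
from . import sumstats


def benjamini_hochberg(pvalues: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """BH-adjusted p-values and significance flags at the given FDR level."""
    p = np.asarray(pvalues, dtype=float)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# rarefied allelic richness
# ---------------------------------------------------------------------------

def _log_comb(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(np.asarray(n, dtype=float) + 1) - gammaln(k + 1) - gammaln(
        np.asarray(n, dtype=float) - k + 1
    )


def _prob_absent(n_total: int, n_allele: np.ndarray, g: int) -> np.ndarray:
    """P(allele absent from a random subsample of g gene copies)."""
    n_allele = np.asarray(n_allele)
    out = np.zeros(len(n_allele))
    ok = n_total - n_allele >= g
    if ok.any():
        out[ok] = np.exp(_log_comb(n_total - n_allele[ok], g) - _log_comb(n_total, g))
    return out


def rarefied_richness(table: GenotypeTable, g: int = 12) -> pd.DataFrame:
    """Rarefied allelic richness ``A_r`` and private allelic richness
    ``A_rp`` per location, standardised to ``g`` gene copies.

    ``A_r`` is the expected allele count in a subsample of g gene copies;
    ``A_rp`` follows Kalinowski's construction: the probability an allele
    appears in the focal rarefied sample times the probability it is absent
    from every other location's rarefied sample, summed over alleles.
    """
    locations = table.location_set
    subs = {loc: table.population(loc) for loc in locations}
    ar = {loc: [] for loc in locations}
    arp = {loc: [] for loc in locations}
    for l in range(table.n_loci):
        copies = {loc: subs[loc].allele_array(l) for loc in locations}
        for loc in locations:
            if copies[loc].size < g:
                raise DataError(
                    f"location {loc!r} has only {copies[loc].size} gene copies "
                    f"at locus {table.loci[l]!r}; cannot rarefy to g={g}"
                )
        alleles = np.unique(np.concatenate(list(copies.values())))
        counts = {
            loc: np.array([(copies[loc] == a).sum() for a in alleles])
            for loc in locations
        }
        q_absent = {
            loc: _prob_absent(copies[loc].size, counts[loc], g) for loc in locations
        }
        for loc in locations:
            present = 1.0 - q_absent[loc]
            ar[loc].append(present.sum())
            others = np.ones(len(alleles))
            for other in locations:
                if other != loc:
                    others *= q_absent[other]
            arp[loc].append((present * others).sum())
    return pd.DataFrame(
        {
            "location": locations,
            "A_r": [float(np.mean(ar[loc])) for loc in locations],
            "A_rp": [float(np.mean(arp[loc])) for loc in locations],
        }
    ).set_index("location")


# ---------------------------------------------------------------------------
# Hardy-Weinberg / F_IS
# ---------------------------------------------------------------------------

@dataclass
class HweResult:
    per_locus: pd.DataFrame  # locus, F_IS, p_value (NaN where monomorphic)
    multilocus_fis: float
    multilocus_p: float


def _fis_components(calls: np.ndarray) -> tuple[float, float]:
    """Summed (c, b+c) Weir-Cockerham components for one locus, one pop."""
    calls = calls[calls[:, 0] > 0]
    n = calls.shape[0]
    if n < 2:
        return 0.0, 0.0
    alleles = np.unique(calls)
    if alleles.size < 2:
        return 0.0, 0.0
    eq0 = calls[:, 0][:, None] == alleles[None, :]
    eq1 = calls[:, 1][:, None] == alleles[None, :]
    p = (eq0.sum(0) + eq1.sum(0)) / (2 * n)
    h = (eq0 ^ eq1).mean(0)
    b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
    c = h / 2
    return float(c.sum()), float((b + c).sum())


def hwe_test(
    table: GenotypeTable,
    pop: str,
    n_perm: int = 5000,
    rng: np.random.Generator | None = None,
) -> HweResult:
    """F_IS per locus and multilocus, with a permutation test of HWE.

    The null distribution shuffles gene copies among individuals within the
    population (random union of gametes); the two-sided p-value is the
    proportion of permuted ``|F_IS|`` at least as large as observed.
    Monomorphic loci have undefined F_IS and are excluded from the
    multilocus aggregate.
    """
    rng = np.random.default_rng() if rng is None else rng
    sub = table.population(pop)
    obs_c = np.zeros(sub.n_loci)
    obs_bc = np.zeros(sub.n_loci)
    for l in range(sub.n_loci):
        obs_c[l], obs_bc[l] = _fis_components(sub.calls[:, l, :])
    poly = obs_bc != 0.0

    def fis(c: float, bc: float) -> float:
        return 1.0 - c / bc

    obs_fis = np.full(sub.n_loci, np.nan)
    obs_fis[poly] = 1.0 - obs_c[poly] / obs_bc[poly]
    obs_multi = fis(obs_c[poly].sum(), obs_bc[poly].sum()) if poly.any() else np.nan

    exceed = np.zeros(sub.n_loci)
    exceed_multi = 0
    for _ in range(n_perm):
        perm_c = np.zeros(sub.n_loci)
        perm_bc = np.zeros(sub.n_loci)
        for l in np.flatnonzero(poly):
            calls = sub.calls[:, l, :]
            genotyped = calls[calls[:, 0] > 0]
            copies = genotyped.ravel().copy()
            rng.shuffle(copies)
            perm_calls = np.sort(copies.reshape(-1, 2), axis=1)
            perm_c[l], perm_bc[l] = _fis_components(perm_calls)
        for l in np.flatnonzero(poly):
            if perm_bc[l] != 0 and abs(fis(perm_c[l], perm_bc[l])) >= abs(obs_fis[l]) - 1e-12:
                exceed[l] += 1
        pc, pbc = perm_c[poly].sum(), perm_bc[poly].sum()
        if pbc != 0 and abs(fis(pc, pbc)) >= abs(obs_multi) - 1e-12:
            exceed_multi += 1
    pvals = np.full(sub.n_loci, np.nan)
    if n_perm > 0:
        pvals[poly] = (exceed[poly] + 1) / (n_perm + 1)
    per_locus = pd.DataFrame(
        {"locus": sub.loci, "F_IS": obs_fis, "p_value": pvals}
    ).set_index("locus")
    multi_p = (exceed_multi + 1) / (n_perm + 1) if n_perm > 0 else np.nan
    return HweResult(per_locus, float(obs_multi), float(multi_p))


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

def jost_d(table: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Jost's D_est between two populations, averaged over loci.

    Per locus, with harmonic-mean sample size correction (Nei & Chesser
    estimators of H_S and H_T):

    ``D = 2 * (H_T_hat - H_S_hat) / (1 - H_S_hat)``.
    """
    sub_a, sub_b = table.population(pop_a), table.population(pop_b)
    vals = []
    for l in range(table.n_loci):
        pair = []
        for sub in (sub_a, sub_b):
            c = sub.calls[:, l, :]
            c = c[c[:, 0] > 0]
            pair.append(c)
        na, nb = pair[0].shape[0], pair[1].shape[0]
        if na < 1 or nb < 1:
            continue
        alleles = np.unique(np.concatenate([c.ravel() for c in pair]))
        if alleles.size < 2:
            vals.append(0.0)
            continue
        freqs = np.stack(
            [
                np.array([(c == a).mean() for a in alleles])
                for c in pair
            ]
        )
        n_harm = 2.0 / (1.0 / na + 1.0 / nb)
        hs = float(np.mean(1.0 - (freqs**2).sum(axis=1)))
        pbar = freqs.mean(axis=0)
        ht = float(1.0 - (pbar**2).sum())
        hs_hat = (2 * n_harm / (2 * n_harm - 1)) * hs
        ht_hat = ht + hs_hat / (4 * n_harm)
        if hs_hat >= 1.0:
            vals.append(0.0)
        else:
            vals.append(2.0 * (ht_hat - hs_hat) / (1.0 - hs_hat))
    if not vals:
        raise DataError("no locus genotyped in both populations")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Hierarchical variance decomposition.

    ``components`` holds sigma^2 for (among groups, among locations within
    groups, within locations); two-level decompositions have no group term.
    Percentages may contain negative entries but always sum to 100.
    """

    components: dict[str, float]
    percentages: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    df: dict[str, int] = field(default_factory=dict)


def _ss_pairs(d: np.ndarray, idx: np.ndarray) -> float:
    """Sum over within-set pairs of squared distances, divided by set size."""
    if len(idx) < 2:
        return 0.0
    block = d[np.ix_(idx, idx)]
    return float(block.sum() / 2.0 / len(idx))


def _amova_from_distances(
    d: np.ndarray,
    pops: np.ndarray,
    groups: np.ndarray | None,
) -> AmovaResult:
    """Variance decomposition of squared distances among hierarchy levels."""
    n = d.shape[0]
    pop_ids, pop_labels = pd.factorize(pops)
    n_pops = len(pop_labels)
    pop_sizes = np.bincount(pop_ids).astype(float)
    ss_total = d.sum() / 2.0 / n
    ss_wp = sum(_ss_pairs(d, np.flatnonzero(pop_ids == p)) for p in range(n_pops))

    if groups is None:
        df_ap, df_wp = n_pops - 1, n - n_pops
        ss_ap = ss_total - ss_wp
        ms_wp = ss_wp / df_wp if df_wp else 0.0
        ms_ap = ss_ap / df_ap if df_ap else 0.0
        n_prime = (n - (pop_sizes**2).sum() / n) / df_ap
        sig_c = ms_wp
        sig_b = (ms_ap - ms_wp) / n_prime
        total = sig_b + sig_c
        phi_st = sig_b / total if total != 0 else 0.0
        comps = {"among_locations": sig_b, "within_locations": sig_c}
        pcts = {k: 100.0 * v / total if total != 0 else 0.0 for k, v in comps.items()}
        return AmovaResult(
            comps, pcts, {"phi_ST": float(phi_st)},
            df={"among_locations": df_ap, "within_locations": df_wp},
        )

    grp_ids, grp_labels = pd.factorize(groups)
    n_grp = len(grp_labels)
    if n_grp < 2:
        return _amova_from_distances(d, pops, None)
    # group membership of each population
    pop_group = np.array([grp_ids[pop_ids == p][0] for p in range(n_pops)])
    ss_grp_tot = sum(
        _ss_pairs(d, np.flatnonzero(grp_ids == g)) for g in range(n_grp)
    )
    ss_ag = ss_total - ss_grp_tot
    ss_apwg = ss_grp_tot - ss_wp
    df_ag = n_grp - 1
    df_apwg = n_pops - n_grp
    df_wp = n - n_pops
    ms_ag = ss_ag / df_ag
    ms_apwg = ss_apwg / df_apwg if df_apwg else 0.0
    ms_wp = ss_wp / df_wp if df_wp else 0.0
    grp_sizes = np.bincount(grp_ids).astype(float)
    sum_n2_by_group = np.array(
        [(pop_sizes[pop_group == g] ** 2).sum() for g in range(n_grp)]
    )
    n_prime = (n - (sum_n2_by_group / grp_sizes).sum()) / df_apwg if df_apwg else 1.0
    n_dprime = (
        ((sum_n2_by_group / grp_sizes).sum() - (pop_sizes**2).sum() / n) / df_ag
    )
    n_tprime = (n - (grp_sizes**2).sum() / n) / df_ag
    sig_c = ms_wp
    sig_b = (ms_apwg - sig_c) / n_prime if df_apwg else 0.0
    sig_a = (ms_ag - sig_c - n_dprime * sig_b) / n_tprime
    total = sig_a + sig_b + sig_c
    comps = {
        "among_groups": sig_a,
        "among_locations_within_groups": sig_b,
        "within_locations": sig_c,
    }
    pcts = {k: 100.0 * v / total if total != 0 else 0.0 for k, v in comps.items()}
    phi = {
        "phi_CT": sig_a / total if total != 0 else 0.0,
        "phi_SC": sig_b / (sig_b + sig_c) if (sig_b + sig_c) != 0 else 0.0,
        "phi_ST": (sig_a + sig_b) / total if total != 0 else 0.0,
    }
    return AmovaResult(
        comps, pcts, {k: float(v) for k, v in phi.items()},
        df={
            "among_groups": df_ag,
            "among_locations_within_groups": df_apwg,
            "within_locations": df_wp,
        },
    )


def _msat_distance_matrix(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Gene-copy level allele-identity distances (0/1) and pop labels.

    Each diploid individual contributes its two gene copies as separate
    units; missing calls are dropped.
    """
    # one unit per gene copy, vector of allele sizes across loci (0=missing)
    labels: list[str] = []
    units = []
    for i in range(table.n_individuals):
        a = table.calls[i, :, 0]
        b = table.calls[i, :, 1]
        units.append(a)
        units.append(b)
        labels.extend([table.locations[i]] * 2)
    u = np.stack(units)
    valid = u > 0
    diff = (u[:, None, :] != u[None, :, :]) & valid[:, None, :] & valid[None, :, :]
    return diff.sum(axis=2).astype(float), np.array(labels)


def _seq_distance_matrix(alignment: HaplotypeAlignment) -> np.ndarray:
    from scipy.spatial.distance import squareform

    return squareform(sumstats._pair_diffs(alignment))


def phi_st(alignment: HaplotypeAlignment, pop_a: str, pop_b: str) -> float:
    """Phi_ST between two populations: AMOVA on raw pairwise difference
    counts (no substitution-model correction)."""
    keep = [loc in (pop_a, pop_b) for loc in alignment.locations]
    sub = alignment.subset(np.array(keep))
    d = _seq_distance_matrix(sub)
    res = _amova_from_distances(d, np.array(sub.locations), None)
    return res.phi["phi_ST"]


def amova(
    data: GenotypeTable | HaplotypeAlignment,
    pmap: PopulationMap,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA (groups / locations / within locations).

    Microsatellites use allele-identity distances between gene copies;
    sequences use pairwise difference counts. Permutation schemes: units
    among locations (within groups) for phi_SC / two-level phi_ST, whole
    locations among groups for phi_CT.
    """
    rng = np.random.default_rng() if rng is None else rng
    if isinstance(data, GenotypeTable):
        d, unit_pops = _msat_distance_matrix(data)
    else:
        d = _seq_distance_matrix(data)
        unit_pops = np.array(data.locations)
    if pmap.location_to_group is not None:
        unit_groups = np.array([pmap.group_of(p) for p in unit_pops])
        if len(set(unit_groups)) < 2:
            unit_groups = None
    else:
        unit_groups = None
    obs = _amova_from_distances(d, unit_pops, unit_groups)

    p_values: dict[str, float] = {}
    if n_perm > 0:
        if unit_groups is None:
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(unit_pops)
                r = _amova_from_distances(d, perm, None)
                if r.phi["phi_ST"] >= obs.phi["phi_ST"] - 1e-12:
                    count += 1
            p_values["phi_ST"] = (count + 1) / (n_perm + 1)
        else:
            # phi_SC: units among locations within their group
            count_sc = 0
            for _ in range(n_perm):
                perm = unit_pops.copy()
                for g in np.unique(unit_groups):
                    idx = np.flatnonzero(unit_groups == g)
                    perm[idx] = perm[idx][rng.permutation(len(idx))]
                r = _amova_from_distances(d, perm, unit_groups)
                if r.phi["phi_SC"] >= obs.phi["phi_SC"] - 1e-12:
                    count_sc += 1
            p_values["phi_SC"] = (count_sc + 1) / (n_perm + 1)
            # phi_CT: whole locations among groups
            pops = pd.unique(unit_pops)
            pop_grp = {p: unit_groups[unit_pops == p][0] for p in pops}
            count_ct = 0
            for _ in range(n_perm):
                shuffled = rng.permutation([pop_grp[p] for p in pops])
                lookup = dict(zip(pops, shuffled))
                perm_groups = np.array([lookup[p] for p in unit_pops])
                r = _amova_from_distances(d, unit_pops, perm_groups)
                if r.phi["phi_CT"] >= obs.phi["phi_CT"] - 1e-12:
                    count_ct += 1
            p_values["phi_CT"] = (count_ct + 1) / (n_perm + 1)
    obs.p_values = p_values
    return obs


# ---------------------------------------------------------------------------
# pairwise differentiation with permutations + FDR
# ---------------------------------------------------------------------------

@dataclass
class DifferentiationResult:
    fst: pd.DataFrame | None
    dest: pd.DataFrame | None
    phist: pd.DataFrame | None
    p_values: dict[str, pd.DataFrame]
    significant: dict[str, pd.DataFrame]


def _permutation_p(
    stat_fn, observed: float, labels: list[str], relabel_fn, n_perm: int, rng
) -> float:
    count = 0
    labels_arr = np.array(labels)
    for _ in range(n_perm):
        perm = labels_arr[rng.permutation(len(labels_arr))]
        if stat_fn(relabel_fn(perm)) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def pairwise_differentiation(
    msat: GenotypeTable | None = None,
    alignment: HaplotypeAlignment | None = None,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> DifferentiationResult:
    """All pairwise F_ST / D_est (microsatellites) and Phi_ST (sequences)
    with permutation p-values and BH-FDR flags per statistic.

    P-values permute individuals between the two locations of each pair;
    locations with fewer than two samples are excluded with a warning.
    """
    import warnings

    rng = np.random.default_rng() if rng is None else rng
    matrices: dict[str, pd.DataFrame] = {}
    pvals: dict[str, pd.DataFrame] = {}

    def run(dataset, stats: dict[str, callable]) -> None:
        locs = [
            loc
            for loc in dataset.location_set
            if sum(x == loc for x in dataset.locations) >= 2
        ]
        dropped = set(dataset.location_set) - set(locs)
        if dropped:
            warnings.warn(f"locations with n<2 excluded: {sorted(dropped)}")
        for name in stats:
            matrices[name] = pd.DataFrame(0.0, index=locs, columns=locs)
            pvals[name] = pd.DataFrame(np.nan, index=locs, columns=locs)
        for a, b in itertools.combinations(locs, 2):
            keep = np.array([loc in (a, b) for loc in dataset.locations])
            sub = dataset.subset(keep)
            for name, fn in stats.items():
                obs = fn(sub, a, b)
                matrices[name].loc[a, b] = matrices[name].loc[b, a] = obs
                if n_perm > 0:
                    count = 0
                    for _ in range(n_perm):
                        perm_labels = list(
                            np.array(sub.locations)[
                                rng.permutation(len(sub.locations))
                            ]
                        )
                        shuffled = sub.relabel({})  # copy
                        shuffled.locations = perm_labels
                        if fn(shuffled, a, b) >= obs - 1e-12:
                            count += 1
                    p = (count + 1) / (n_perm + 1)
                    pvals[name].loc[a, b] = pvals[name].loc[b, a] = p

    if msat is not None:
        run(msat, {"fst": sumstats.wc_fst, "dest": jost_d})
    if alignment is not None:
        run(alignment, {"phist": phi_st})

    significant: dict[str, pd.DataFrame] = {}
    for name, pm in pvals.items():
        flags = pd.DataFrame(False, index=pm.index, columns=pm.columns)
        locs = list(pm.index)
        pairs = list(itertools.combinations(locs, 2))
        ps = [pm.loc[a, b] for a, b in pairs]
        if pairs and not np.isnan(ps).any():
            _, rej = benjamini_hochberg(np.array(ps), alpha=alpha)
            for (a, b), r in zip(pairs, rej):
                flags.loc[a, b] = flags.loc[b, a] = bool(r)
        significant[name] = flags
    return DifferentiationResult(
        matrices.get("fst"), matrices.get("dest"), matrices.get("phist"),
        pvals, significant,
    )


# ---------------------------------------------------------------------------
# neutrality tests with a simulated null
# ---------------------------------------------------------------------------

@dataclass
class NeutralityResult:
    tajimas_d: float
    fus_fs: float
    p_d: float
    p_fs: float
    theta_pi: float
    skipped: bool = False


def _null_stats(n: int, length: int, theta_locus: float, n_sim: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Neutral constant-size coalescent null for (D, Fs), conditioned on the
    observed theta_pi (per locus)."""
    n_sim_pop = 1000.0
    mu_site = theta_locus / (2 * n_sim_pop * length)
    ds = np.empty(n_sim)
    fss = np.empty(n_sim)
    reps = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=n_sim_pop,
        sequence_length=length,
        num_replicates=n_sim,
        random_seed=int(rng.integers(1, 2**31 - 1)),
        record_provenance=False,
    )
    mut_seeds = rng.integers(1, 2**31 - 1, size=n_sim)
    for i, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts,
            rate=mu_site,
            model=msprime.JC69(),
            random_seed=int(mut_seeds[i]),
            record_provenance=False,
        )
        g = mts.genotype_matrix()
        if g.shape[0] == 0:
            ds[i] = 0.0
            fss[i] = 0.0
            continue
        counts = np.stack(
            [(g == al).sum(axis=1) for al in range(int(g.max()) + 1)], axis=1
        )
        poly = (counts > 0).sum(axis=1) > 1
        s = int(poly.sum())
        pairs = n * (n - 1) / 2
        pi = float(((n**2 - (counts**2).sum(axis=1)) / 2.0).sum() / pairs)
        k = len(np.unique(g.T.copy().view([("", g.dtype)] * g.shape[0])))
        ds[i] = sumstats._d_from(n, s, pi)
        fss[i] = sumstats._fs_from(n, pi, k)
    return ds, fss


def neutrality_tests(
    alignment: HaplotypeAlignment,
    pop: str | None = None,
    n_sim: int = 100000,
    rng: np.random.Generator | None = None,
) -> NeutralityResult:
    """Tajima's D and Fu's Fs with p-values from neutral constant-size
    coalescent simulations conditioned on the observed theta_pi.

    The Fs p-value is one-tailed (proportion of simulated values <=
    observed, small values indicating haplotype excess); D is two-tailed.
    A sample with no segregating sites is skipped.
    """
    rng = np.random.default_rng() if rng is None else rng
    sub = alignment if pop is None else alignment.population(pop)
    d_obs, d_degen = sumstats.tajimas_d(sub)
    fs_obs, _ = sumstats.fus_fs(sub)
    theta = sumstats.mean_pairwise_diff(sub)
    if d_degen and theta == 0.0:
        return NeutralityResult(0.0, 0.0, np.nan, np.nan, 0.0, skipped=True)
    ds, fss = _null_stats(sub.n_sequences, sub.length, theta, n_sim, rng)
    p_low = (np.sum(ds <= d_obs + 1e-12) + 1) / (n_sim + 1)
    p_high = (np.sum(ds >= d_obs - 1e-12) + 1) / (n_sim + 1)
    p_d = min(1.0, 2.0 * min(p_low, p_high))
    p_fs = (np.sum(fss <= fs_obs + 1e-12) + 1) / (n_sim + 1)
    return NeutralityResult(
        float(d_obs), float(fs_obs), float(p_d), float(p_fs), float(theta)
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium scan
# ---------------------------------------------------------------------------

def ld_test_count(n_loci: int, n_locations: int) -> int:
    """Number of LD tests scheduled when every locus is polymorphic in
    every location: C(n_loci, 2) * n_locations."""
    return n_loci * (n_loci - 1) // 2 * n_locations


def _em_haplotype_ll(ga: np.ndarray, gb: np.ndarray, n_iter: int = 40) -> tuple[float, float]:
    """Log-likelihoods (alternative EM haplotype fit, null = allele-frequency
    product) for two unphased diploid loci.

    ``ga``/``gb`` are (n, 2) sorted allele arrays without missing data.
    Phase-count constants cancel in the likelihood ratio and are omitted.
    """
    als_a, inv_a = np.unique(ga, return_inverse=True)
    als_b, inv_b = np.unique(gb, return_inverse=True)
    ka, kb = len(als_a), len(als_b)
    ia = inv_a.reshape(-1, 2)
    ib = inv_b.reshape(-1, 2)
    pa = np.bincount(ia.ravel(), minlength=ka) / ia.size
    pb = np.bincount(ib.ravel(), minlength=kb) / ib.size
    h = np.outer(pa, pb)  # start at linkage equilibrium
    n = ia.shape[0]
    # the two possible phasings of each individual
    ph1 = (ia[:, 0], ib[:, 0], ia[:, 1], ib[:, 1])
    ph2 = (ia[:, 0], ib[:, 1], ia[:, 1], ib[:, 0])
    same_phase = (ia[:, 0] == ia[:, 1]) | (ib[:, 0] == ib[:, 1])
    for _ in range(n_iter):
        w1 = h[ph1[0], ph1[1]] * h[ph1[2], ph1[3]]
        w2 = h[ph2[0], ph2[1]] * h[ph2[2], ph2[3]]
        w2 = np.where(same_phase, 0.0, w2)
        tot = w1 + w2
        tot[tot == 0] = 1.0
        r1 = w1 / tot
        r2 = w2 / tot
        new = np.zeros((ka, kb))
        np.add.at(new, (ph1[0], ph1[1]), r1)
        np.add.at(new, (ph1[2], ph1[3]), r1)
        np.add.at(new, (ph2[0], ph2[1]), r2)
        np.add.at(new, (ph2[2], ph2[3]), r2)
        h = new / (2 * n)
    w1 = h[ph1[0], ph1[1]] * h[ph1[2], ph1[3]]
    w2 = np.where(same_phase, 0.0, h[ph2[0], ph2[1]] * h[ph2[2], ph2[3]])
    lik = w1 + w2
    h0 = np.outer(pa, pb)
    w1_0 = h0[ph1[0], ph1[1]] * h0[ph1[2], ph1[3]]
    w2_0 = np.where(same_phase, 0.0, h0[ph2[0], ph2[1]] * h0[ph2[2], ph2[3]])
    lik0 = w1_0 + w2_0
    tiny = 1e-300
    return float(np.log(np.maximum(lik, tiny)).sum()), float(
        np.log(np.maximum(lik0, tiny)).sum()
    )


def ld_pair_stat(table: GenotypeTable, locus_a: int, locus_b: int) -> float | None:
    """Likelihood-ratio statistic for association between two loci, or None
    when either locus lacks polymorphism or shared genotyped individuals."""
    ca = table.calls[:, locus_a, :]
    cb = table.calls[:, locus_b, :]
    ok = (ca[:, 0] > 0) & (cb[:, 0] > 0)
    ga, gb = ca[ok], cb[ok]
    if ga.shape[0] < 2:
        return None
    if np.unique(ga).size < 2 or np.unique(gb).size < 2:
        return None
    ll1, ll0 = _em_haplotype_ll(ga, gb)
    return max(0.0, 2.0 * (ll1 - ll0))


def ld_scan(
    table: GenotypeTable,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Likelihood-ratio LD test for every locus pair in every location.

    Returns one row per performed test (location, locus_a, locus_b, LR, p,
    significant-after-BH); pairs lacking polymorphism are skipped and
    excluded from the count. The total scheduled count for a fully
    polymorphic dataset is :func:`ld_test_count`. ``n_perm = 0`` computes
    statistics only (p-values NaN, no FDR flags).
    """
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    for loc in table.location_set:
        sub = table.population(loc)
        for a, b in itertools.combinations(range(sub.n_loci), 2):
            obs = ld_pair_stat(sub, a, b)
            if obs is None:
                continue
            p = np.nan
            if n_perm > 0:
                count = 0
                ca = sub.calls[:, a, :]
                cb = sub.calls[:, b, :]
                ok = (ca[:, 0] > 0) & (cb[:, 0] > 0)
                ga, gb = ca[ok], cb[ok]
                for _ in range(n_perm):
                    perm = rng.permutation(ga.shape[0])
                    ll1, ll0 = _em_haplotype_ll(ga[perm], gb)
                    if max(0.0, 2.0 * (ll1 - ll0)) >= obs - 1e-12:
                        count += 1
                p = (count + 1) / (n_perm + 1)
            rows.append(
                {
                    "location": loc,
                    "locus_a": sub.loci[a],
                    "locus_b": sub.loci[b],
                    "lr_stat": obs,
                    "p_value": p,
                }
            )
    df = pd.DataFrame(rows)
    if len(df) and n_perm > 0:
        _, rej = benjamini_hochberg(df["p_value"].to_numpy(), alpha=alpha)
        df["significant"] = rej
    elif len(df):
        df["significant"] = False
    return df


# ---------------------------------------------------------------------------
# the per-location diversity table
# ---------------------------------------------------------------------------

def diversity_table(
    msat: GenotypeTable | None = None,
    alignment: HaplotypeAlignment | None = None,
    rarefaction_g: int | None = None,
    hwe_permutations: int = 5000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-location summary: sample sizes, allele numbers, rarefied
    richness, heterozygosities, F_IS with HWE p-value, and for sequences
    haplotype count/diversity, segregating sites and per-site nucleotide
    diversity."""
    rng = np.random.default_rng() if rng is None else rng
    locations: list[str] = []
    if msat is not None:
        locations = msat.location_set
    elif alignment is not None:
        locations = alignment.location_set
    rows = {}
    for loc in locations:
        rows[loc] = {}
    if msat is not None:
        if rarefaction_g is None:
            # rarefy to the smallest fully genotyped sample (gene copies)
            rarefaction_g = min(
                int(
                    min(
                        msat.population(loc).allele_array(l).size
                        for l in range(msat.n_loci)
                    )
                )
                for loc in locations
            )
        rich = rarefied_richness(msat, g=rarefaction_g)
        for loc in locations:
            sub = msat.population(loc)
            het_obs = []
            het_exp = []
            for l in range(sub.n_loci):
                c = sub.calls[:, l, :]
                c = c[c[:, 0] > 0]
                if c.shape[0] < 2:
                    continue
                het_obs.append((c[:, 0] != c[:, 1]).mean())
                flat = c.ravel()
                _, counts = np.unique(flat, return_counts=True)
                p = counts / flat.size
                n = flat.size
                het_exp.append(n / (n - 1) * (1 - (p**2).sum()))
            hwe = hwe_test(msat, loc, n_perm=hwe_permutations, rng=rng)
            rows[loc].update(
                N=sub.n_individuals,
                N_a=sumstats.mean_num_alleles(msat, loc),
                A_r=rich.loc[loc, "A_r"],
                A_rp=rich.loc[loc, "A_rp"],
                H_O=float(np.mean(het_obs)),
                H_E=float(np.mean(het_exp)),
                F_IS=hwe.multilocus_fis,
                HWE_p=hwe.multilocus_p,
            )
    if alignment is not None:
        for loc in locations:
            if loc not in alignment.location_set:
                continue
            sub = alignment.population(loc)
            rows[loc].update(
                N_s=sub.n_sequences,
                H=sumstats.haplotype_count(sub),
                h=sumstats.nei_gene_diversity(sub) if sub.n_sequences > 1 else np.nan,
                S=sumstats.segregating_sites(sub),
                pi=sumstats.nucleotide_diversity(sub) if sub.n_sequences > 1 else np.nan,
            )
    return pd.DataFrame.from_dict(rows, orient="index")
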