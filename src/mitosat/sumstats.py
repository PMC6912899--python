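"""The 19 summary statistics describing a paired two-population dataset.

Eight microsatellite statistics (mean allele number K, mean Nei gene
diversity H, the modified Garza-Williamson index per population, pairwise
Weir-Cockerham F_ST and the squared difference in mean allele length
delta-mu^2) and eleven mtDNA statistics (haplotype count K, haplotype
diversity H, mean pairwise differences pi, Tajima's D and Fu's Fs per
population, plus a haplotype-frequency F_ST) jointly summarise one paired
(microsatellite, mtDNA) dataset for ABC.

Degenerate statistics (no segregating sites, monomorphic samples) are mapped
to 0 rather than NaN so reference-table rows are never dropped; the flags
are available from the low-level functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DataError, GenotypeTable, HaplotypeAlignment

#: canonical field order of the 19-statistic vector; suffix 1/2 indexes the
#: two populations in sorted label order.
STAT_NAMES: tuple[str, ...] = (
    "sat_K_1", "sat_K_2",
    "sat_H_1", "sat_H_2",
    "sat_FST",
    "sat_MGW_1", "sat_MGW_2",
    "sat_dmu2",
    "mt_K_1", "mt_K_2",
    "mt_H_1", "mt_H_2",
    "mt_FST",
    "mt_pi_1", "mt_pi_2",
    "mt_D_1", "mt_D_2",
    "mt_Fs_1", "mt_Fs_2",
)

N_STATS = len(STAT_NAMES)


@dataclass
class SummaryStatVector:
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_STATS,):
            raise ValueError(f"expected {N_STATS} statistics")
        if not np.isfinite(self.values).all():
            raise ValueError("summary statistics must be finite")

    @property
    def names(self) -> tuple[str, ...]:
        return STAT_NAMES

    def as_dict(self) -> dict[str, float]:
        return dict(zip(STAT_NAMES, self.values))

    def __getitem__(self, name: str) -> float:
        return float(self.values[STAT_NAMES.index(name)])


# ---------------------------------------------------------------------------
# microsatellite statistics
# ---------------------------------------------------------------------------

def _pop_table(table: GenotypeTable, pop: str | None) -> GenotypeTable:
    return table if pop is None else table.population(pop)


def mean_num_alleles(table: GenotypeTable, pop: str | None = None) -> float:
    """Mean number of distinct alleles per locus (loci with no data skipped)."""
    sub = _pop_table(table, pop)
    counts = []
    for l in range(sub.n_loci):
        alleles = sub.allele_array(l)
        if alleles.size:
            counts.append(np.unique(alleles).size)
    if not counts:
        raise DataError("population has no genotyped locus")
    return float(np.mean(counts))


def nei_gene_diversity(data: GenotypeTable | HaplotypeAlignment, pop: str | None = None) -> float:
    """Unbiased Nei gene diversity, averaged over loci.

    Per locus ``H = n/(n-1) * (1 - sum p_i^2)`` over ``n`` gene copies. For
    an alignment the single locus is the haplotype, giving haplotype
    diversity h.
    """
    if isinstance(data, HaplotypeAlignment):
        sub = data if pop is None else data.population(pop)
        n = sub.n_sequences
        if n < 2:
            raise DataError("need >= 2 sequences")
        _, counts = np.unique(sub.sequences, return_counts=True)
        p = counts / n
        return float(n / (n - 1) * (1.0 - np.sum(p**2)))
    sub = _pop_table(data, pop)
    vals = []
    for l in range(sub.n_loci):
        alleles = sub.allele_array(l)
        n = alleles.size
        if n < 2:
            continue
        _, counts = np.unique(alleles, return_counts=True)
        p = counts / n
        vals.append(n / (n - 1) * (1.0 - np.sum(p**2)))
    if not vals:
        raise DataError("population has no locus with >= 2 gene copies")
    return float(np.mean(vals))


def mgw(table: GenotypeTable, pop: str | None = None) -> float:
    """Modified Garza-Williamson index, mean over loci of k / (R + 1).

    ``k`` is the allele count and ``R`` the allele-size range in repeat
    units; values near 1 indicate alleles filling their size range, low
    values signal a bottleneck having thinned intermediate alleles.
    """
    sub = _pop_table(table, pop)
    vals = []
    for l in range(sub.n_loci):
        alleles = sub.allele_array(l)
        if not alleles.size:
            continue
        k = np.unique(alleles).size
        r = int(alleles.max() - alleles.min())
        vals.append(k / (r + 1))
    if not vals:
        raise DataError("population has no genotyped locus")
    return float(np.mean(vals))


def delta_mu_sq(table: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Goldstein's delta-mu^2: mean over loci of squared difference in mean
    allele size between the two populations. Grows ~ linearly with divergence
    time under stepwise mutation."""
    sub_a, sub_b = table.population(pop_a), table.population(pop_b)
    vals = []
    for l in range(table.n_loci):
        xa, xb = sub_a.allele_array(l), sub_b.allele_array(l)
        if xa.size and xb.size:
            vals.append((xa.mean() - xb.mean()) ** 2)
    if not vals:
        raise DataError("no locus genotyped in both populations")
    return float(np.mean(vals))


def _wc_components(table: GenotypeTable, pops: list[str]) -> tuple[float, float, float]:
    """Weir-Cockerham variance components (a, b, c) summed over alleles and
    loci for diploid genotype data in ``r`` populations."""
    subs = [table.population(p) for p in pops]
    r = len(subs)
    A = B = C = 0.0
    for l in range(table.n_loci):
        # per-pop sample sizes (genotyped individuals), allele freqs, het freqs
        ns, freqs, hets = [], [], []
        for sub in subs:
            calls = sub.calls[:, l, :]
            ok = calls[:, 0] > 0
            calls = calls[ok]
            if calls.shape[0] == 0:
                break
            ns.append(calls.shape[0])
            freqs.append(calls)
            hets.append(calls)
        else:
            alleles = np.unique(np.concatenate([c[c > 0] for c in freqs]))
            if alleles.size < 2:
                continue
            ns_arr = np.asarray(ns, dtype=float)
            nbar = ns_arr.mean()
            if nbar <= 1 or r < 2:
                continue
            nc = (r * nbar - (ns_arr**2).sum() / (r * nbar)) / (r - 1)
            for al in alleles:
                p = np.array([(c == al).mean() for c in freqs])
                h = np.array(
                    [((c[:, 0] == al) ^ (c[:, 1] == al)).mean() for c in hets]
                )
                pbar = (ns_arr * p).sum() / (r * nbar)
                s2 = (ns_arr * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
                hbar = (ns_arr * h).sum() / (r * nbar)
                a = (nbar / nc) * (
                    s2
                    - 1.0
                    / (nbar - 1)
                    * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                )
                b = (nbar / (nbar - 1)) * (
                    pbar * (1 - pbar)
                    - (r - 1) / r * s2
                    - (2 * nbar - 1) / (4 * nbar) * hbar
                )
                c = hbar / 2
                A += a
                B += b
                C += c
    return A, B, C


def wc_fst(table: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir-Cockerham theta (ratio of summed components).

    A monomorphic combined sample is defined as 0; slightly negative values
    are kept (truncation is a display concern only).
    """
    a, b, c = _wc_components(table, [pop_a, pop_b])
    denom = a + b + c
    if denom == 0.0:
        return 0.0
    return float(a / denom)


def wc_fis(table: GenotypeTable, pop: str) -> float:
    """Weir-Cockerham inbreeding coefficient f = 1 - sum(c)/sum(b+c),
    components aggregated over loci (single population)."""
    sub = table.population(pop)
    num = den = 0.0
    for l in range(sub.n_loci):
        calls = sub.calls[:, l, :]
        calls = calls[calls[:, 0] > 0]
        n = calls.shape[0]
        if n < 2:
            continue
        alleles = np.unique(calls)
        if alleles.size < 2:
            continue
        for al in alleles:
            p = (calls == al).mean()
            h = ((calls[:, 0] == al) ^ (calls[:, 1] == al)).mean()
            b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            c = h / 2
            num += c
            den += b + c
    if den == 0.0:
        raise DataError("F_IS undefined: no polymorphic locus")
    return float(1.0 - num / den)


# ---------------------------------------------------------------------------
# sequence statistics
# ---------------------------------------------------------------------------

def haplotype_count(alignment: HaplotypeAlignment, pop: str | None = None) -> int:
    sub = alignment if pop is None else alignment.population(pop)
    return int(np.unique(sub.sequences).size)


def _pair_diffs(sub: HaplotypeAlignment) -> np.ndarray:
    """Condensed vector of pairwise difference counts (pairwise deletion)."""
    m = sub.matrix()
    obs = sub.observed_mask()
    n = m.shape[0]
    # restrict to candidate sites: observed somewhere and not constant
    if obs.all():
        seg = (m != m[0]).any(axis=0)
        m2, obs2 = m[:, seg], None
    else:
        m2, obs2 = m, obs
    out = np.empty(n * (n - 1) // 2, dtype=float)
    k = 0
    for i in range(n - 1):
        diff = m2[i + 1 :] != m2[i]
        if obs2 is not None:
            diff &= obs2[i + 1 :] & obs2[i]
        out[k : k + n - 1 - i] = diff.sum(axis=1)
        k += n - 1 - i
    return out


def mean_pairwise_diff(alignment: HaplotypeAlignment, pop: str | None = None) -> float:
    """Mean number of differing sites over all sequence pairs (absolute
    count, not per site; N and - removed pairwise)."""
    sub = alignment if pop is None else alignment.population(pop)
    if sub.n_sequences < 2:
        raise DataError("need >= 2 sequences")
    return float(_pair_diffs(sub).mean())


def segregating_sites(alignment: HaplotypeAlignment, pop: str | None = None) -> int:
    """Number of sites with >= 2 distinct observed bases."""
    sub = alignment if pop is None else alignment.population(pop)
    m = sub.matrix().view(np.uint8)
    obs = sub.observed_mask()
    # >= 2 distinct observed values iff masked max > masked min
    colmax = np.where(obs, m, 0).max(axis=0)
    colmin = np.where(obs, m, 255).min(axis=0)
    return int(((colmax > colmin) & (obs.sum(axis=0) >= 2)).sum())


def nucleotide_diversity(alignment: HaplotypeAlignment, pop: str | None = None) -> float:
    """Per-site nucleotide diversity: mean pairwise differences / length."""
    sub = alignment if pop is None else alignment.population(pop)
    return mean_pairwise_diff(sub) / sub.length


def tajimas_d(alignment: HaplotypeAlignment, pop: str | None = None) -> tuple[float, bool]:
    """Tajima's D from pi and S with the standard normalising constants.

    Returns ``(D, degenerate)``; ``S = 0`` yields ``(0.0, True)``.
    """
    sub = alignment if pop is None else alignment.population(pop)
    n = sub.n_sequences
    if n < 2:
        raise DataError("need >= 2 sequences")
    s = segregating_sites(sub)
    if s == 0:
        return 0.0, True
    pi = mean_pairwise_diff(sub)
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return 0.0, True
    return float((pi - s / a1) / np.sqrt(var)), False


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k) for k = 1..n under the Ewens sampling formula.

    The allele count K is a sum of independent Bernoulli(theta/(theta+i))
    indicators for i = 0..n-1, so the distribution follows from a stable
    Poisson-binomial convolution (no Stirling numbers needed).
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    probs = np.zeros(n + 1)
    probs[0] = 1.0
    for i in range(n):
        q = theta / (theta + i)
        probs[1 : i + 2] = probs[1 : i + 2] * (1 - q) + probs[: i + 1] * q
        probs[0] *= 1 - q
    return probs[1:]


def fus_fs(alignment: HaplotypeAlignment, pop: str | None = None) -> tuple[float, bool]:
    """Fu's Fs: ``ln(S'/(1-S'))`` with ``S' = P(K >= k_obs | theta_pi, n)``
    under the Ewens sampling distribution. Large negative values indicate an
    excess of haplotypes relative to the neutral constant-size expectation.

    Returns ``(Fs, degenerate)``; a monomorphic sample yields ``(0.0, True)``.
    """
    sub = alignment if pop is None else alignment.population(pop)
    n = sub.n_sequences
    if n < 2:
        raise DataError("need >= 2 sequences")
    theta = mean_pairwise_diff(sub)
    k_obs = haplotype_count(sub)
    if theta <= 0.0 or k_obs <= 1:
        return 0.0, True
    pk = ewens_k_distribution(n, theta)
    s_prime = float(pk[k_obs - 1 :].sum())
    tiny = 1e-300
    clamped = not (tiny < s_prime < 1 - 1e-16)
    s_prime = min(max(s_prime, tiny), 1 - 1e-16)
    return float(np.log(s_prime / (1.0 - s_prime))), clamped


def haplotype_fst(alignment: HaplotypeAlignment, pop_a: str, pop_b: str) -> float:
    """Haplotype-frequency F_ST (distance-free) between two populations.

    Weir-Cockerham variance components for haploid data, treating each
    distinct sequence as an allele; equivalent to an AMOVA with simple
    identity distances between haplotypes.
    """
    subs = [alignment.population(pop_a), alignment.population(pop_b)]
    ns = np.array([s.n_sequences for s in subs], dtype=float)
    if (ns < 1).any():
        raise DataError("both populations must be non-empty")
    r = 2
    haps = np.unique(np.concatenate([s.sequences for s in subs]))
    if haps.size < 2:
        return 0.0
    n_tot = ns.sum()
    nc = (n_tot - (ns**2).sum() / n_tot) / (r - 1)
    num = den = 0.0
    for h in haps:
        p = np.array([np.mean(np.asarray(s.sequences) == h) for s in subs])
        pbar = (ns * p).sum() / n_tot
        msp = (ns * (p - pbar) ** 2).sum() / (r - 1)
        msg = (ns * p * (1 - p)).sum() / (n_tot - r)
        sa = (msp - msg) / nc
        num += sa
        den += sa + msg
    if den == 0.0:
        return 0.0
    return float(num / den)


# ---------------------------------------------------------------------------
# the 19-statistic vector
# ---------------------------------------------------------------------------

def _msat_block(msat: GenotypeTable, p1: str, p2: str) -> list[float]:
    """K, H, MGW per population plus F_ST and delta-mu^2 in one pass."""
    idx1 = np.array([loc == p1 for loc in msat.locations])
    idx2 = np.array([loc == p2 for loc in msat.locations])
    k_ = [[], []]
    h_ = [[], []]
    m_ = [[], []]
    dmu = []
    fst_num = fst_den = 0.0
    r = 2
    for l in range(msat.n_loci):
        cols = []
        for idx in (idx1, idx2):
            c = msat.calls[idx, l, :]
            cols.append(c[c[:, 0] > 0])
        means = []
        for j, c in enumerate(cols):
            flat = c.ravel()
            if flat.size == 0:
                means.append(None)
                continue
            uniq = np.unique(flat)
            k_[j].append(uniq.size)
            m_[j].append(uniq.size / (flat.max() - flat.min() + 1))
            means.append(flat.mean())
            n = flat.size
            if n >= 2:
                counts = np.bincount(np.searchsorted(uniq, flat))
                p = counts / n
                h_[j].append(n / (n - 1) * (1.0 - np.sum(p**2)))
        if means[0] is not None and means[1] is not None:
            dmu.append((means[0] - means[1]) ** 2)
        # Weir-Cockerham components, vectorised over alleles
        if cols[0].shape[0] == 0 or cols[1].shape[0] == 0:
            continue
        alleles = np.unique(np.concatenate([c.ravel() for c in cols]))
        if alleles.size < 2:
            continue
        ns = np.array([c.shape[0] for c in cols], dtype=float)
        nbar = ns.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        p_mat = np.empty((r, alleles.size))
        h_mat = np.empty((r, alleles.size))
        for j, c in enumerate(cols):
            eq0 = c[:, 0][:, None] == alleles[None, :]
            eq1 = c[:, 1][:, None] == alleles[None, :]
            p_mat[j] = (eq0.sum(0) + eq1.sum(0)) / (2 * c.shape[0])
            h_mat[j] = (eq0 ^ eq1).mean(0)
        pbar = (ns[:, None] * p_mat).sum(0) / (r * nbar)
        s2 = (ns[:, None] * (p_mat - pbar) ** 2).sum(0) / ((r - 1) * nbar)
        hbar = (ns[:, None] * h_mat).sum(0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c_comp = hbar / 2
        fst_num += a.sum()
        fst_den += (a + b + c_comp).sum()
    fst = fst_num / fst_den if fst_den != 0.0 else 0.0
    return [
        float(np.mean(k_[0])), float(np.mean(k_[1])),
        float(np.mean(h_[0])), float(np.mean(h_[1])),
        float(fst),
        float(np.mean(m_[0])), float(np.mean(m_[1])),
        float(np.mean(dmu)),
    ]


def _seq_summary(sub: HaplotypeAlignment) -> tuple[int, int, float, int]:
    """(n, S, pi, K) for one population's alignment."""
    n = sub.n_sequences
    s = segregating_sites(sub)
    pi = float(_pair_diffs(sub).mean()) if n >= 2 else 0.0
    k = int(np.unique(sub.sequences).size)
    return n, s, pi, k


def _d_from(n: int, s: int, pi: float) -> float:
    if s == 0 or n < 2:
        return 0.0
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    var = (c1 / a1) * s + (c2 / (a1**2 + a2)) * s * (s - 1)
    if var <= 0:
        return 0.0
    return float((pi - s / a1) / np.sqrt(var))


def _fs_from(n: int, pi: float, k_obs: int) -> float:
    if pi <= 0.0 or k_obs <= 1 or n < 2:
        return 0.0
    pk = ewens_k_distribution(n, pi)
    s_prime = float(pk[k_obs - 1 :].sum())
    s_prime = min(max(s_prime, 1e-300), 1 - 1e-16)
    return float(np.log(s_prime / (1.0 - s_prime)))


def summarize_pair(msat: GenotypeTable, mt: HaplotypeAlignment) -> SummaryStatVector:
    """Compute the full 19-statistic vector for a paired dataset.

    Both datasets must contain exactly the same two population labels; the
    1/2 suffixes follow sorted label order.
    """
    pops = sorted(msat.location_set)
    if len(pops) != 2 or sorted(mt.location_set) != pops:
        raise DataError(
            f"expected the same two populations in both datasets, got "
            f"{msat.location_set} and {mt.location_set}"
        )
    p1, p2 = pops
    sat = _msat_block(msat, p1, p2)
    mt1, mt2 = mt.population(p1), mt.population(p2)
    mt_vals = []
    per_pop = [_seq_summary(mt1), _seq_summary(mt2)]
    ks = [v[3] for v in per_pop]
    hs = [
        nei_gene_diversity(sub) if sub.n_sequences >= 2 else 0.0
        for sub in (mt1, mt2)
    ]
    mt_vals = [
        ks[0], ks[1],
        hs[0], hs[1],
        haplotype_fst(mt, p1, p2),
        per_pop[0][2], per_pop[1][2],
        _d_from(*[per_pop[0][i] for i in (0, 1, 2)]),
        _d_from(*[per_pop[1][i] for i in (0, 1, 2)]),
        _fs_from(per_pop[0][0], per_pop[0][2], per_pop[0][3]),
        _fs_from(per_pop[1][0], per_pop[1][2], per_pop[1][3]),
    ]
    return SummaryStatVector(np.array(sat + mt_vals, dtype=float))
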