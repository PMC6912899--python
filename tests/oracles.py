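"""Independent brute-force reference implementations used as oracles.

Everything here is written directly from published formulas or as explicit
enumeration, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, log, sqrt

import numpy as np


def wc_fst_oracle(pops: list[list[tuple[int, int]]]) -> float:
    """Weir & Cockerham (1984) theta for diploid genotype lists.

    ``pops[i]`` is a list of (allele, allele) genotypes for population i at
    one locus. Scalar transcription of the published estimator.
    """
    r = len(pops)
    ns = [len(p) for p in pops]
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    alleles = sorted({a for p in pops for g in p for a in g})
    A = B = C = 0.0
    for allele in alleles:
        p_i = []
        h_i = []
        for pop in pops:
            copies = [a for g in pop for a in g]
            p_i.append(copies.count(allele) / len(copies))
            h_i.append(
                sum(1 for g in pop if (g[0] == allele) != (g[1] == allele))
                / len(pop)
            )
        pbar = sum(n * p for n, p in zip(ns, p_i)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, h_i)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        A += a
        B += b
        C += c
    return A / (A + B + C)


def jost_d_oracle(pop_a: list[tuple[int, int]], pop_b: list[tuple[int, int]]) -> float:
    """Jost's D for one locus, two populations, with the Nei & Chesser
    sample-size-corrected gene diversities and harmonic-mean n."""
    na, nb = len(pop_a), len(pop_b)
    alleles = sorted({a for g in pop_a + pop_b for a in g})
    pa = [sum(g.count(al) for g in pop_a) / (2 * na) for al in alleles]
    pb = [sum(g.count(al) for g in pop_b) / (2 * nb) for al in alleles]
    n_harm = 2.0 / (1.0 / na + 1.0 / nb)
    hs = 0.5 * ((1 - sum(p * p for p in pa)) + (1 - sum(p * p for p in pb)))
    ht = 1 - sum(((x + y) / 2) ** 2 for x, y in zip(pa, pb))
    hs_hat = (2 * n_harm / (2 * n_harm - 1)) * hs
    ht_hat = ht + hs_hat / (4 * n_harm)
    if hs_hat >= 1.0:
        return 0.0
    return 2.0 * (ht_hat - hs_hat) / (1.0 - hs_hat)


def tajimas_d_oracle(seqs: list[str]) -> float:
    """Tajima's D by explicit pairwise counting and literal coefficients."""
    n = len(seqs)
    length = len(seqs[0])
    s = 0
    for j in range(length):
        column = {seq[j] for seq in seqs if seq[j] not in "N-"}
        if len(column) > 1:
            s += 1
    if s == 0:
        return 0.0
    diffs = []
    for x, y in itertools.combinations(seqs, 2):
        diffs.append(
            sum(
                1
                for cx, cy in zip(x, y)
                if cx not in "N-" and cy not in "N-" and cx != cy
            )
        )
    pi = sum(diffs) / len(diffs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / sqrt(e1 * s + e2 * s * (s - 1))


def _stirling_unsigned(n: int, k: int) -> int:
    """Unsigned Stirling numbers of the first kind by recursion."""
    table = [[0] * (n + 1) for _ in range(n + 1)]
    table[0][0] = 1
    for i in range(1, n + 1):
        for j in range(1, i + 1):
            table[i][j] = table[i - 1][j - 1] + (i - 1) * table[i - 1][j]
    return table[n][k]


def fus_fs_oracle(n: int, k_obs: int, theta: float) -> float:
    """Fu's Fs via the Ewens sampling formula with explicit Stirling
    numbers: P(K = k) = |S(n, k)| theta^k / (theta)_n."""
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    s_prime = sum(
        _stirling_unsigned(n, k) * theta**k / rising for k in range(k_obs, n + 1)
    )
    return log(s_prime / (1.0 - s_prime))


def rarefaction_oracle(
    pop_copies: dict[str, list[int]], g: int
) -> tuple[dict[str, float], dict[str, float]]:
    """Exhaustive rarefaction for one locus: expected allele count and
    expected private allele count when drawing g copies per location."""
    presence: dict[str, dict[int, Fraction]] = {}
    alleles = sorted({a for copies in pop_copies.values() for a in copies})
    for loc, copies in pop_copies.items():
        total = comb(len(copies), g)
        pres = {}
        for allele in alleles:
            hits = sum(
                1
                for subset in itertools.combinations(range(len(copies)), g)
                if any(copies[i] == allele for i in subset)
            )
            pres[allele] = Fraction(hits, total)
        presence[loc] = pres
    ar = {loc: float(sum(presence[loc].values())) for loc in pop_copies}
    arp = {}
    for loc in pop_copies:
        total = Fraction(0)
        for allele in alleles:
            term = presence[loc][allele]
            for other in pop_copies:
                if other != loc:
                    term *= 1 - presence[other][allele]
            total += term
        arp[loc] = float(total)
    return ar, arp


def amova_two_level_oracle(d2: np.ndarray, pops: list[str]) -> tuple[float, float, float]:
    """Two-level AMOVA components (sigma_among, sigma_within, phi_ST) from
    a squared-distance matrix, via explicit sums of squares."""
    n = len(pops)
    labels = sorted(set(pops))
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    sizes = {}
    for lab in labels:
        idx = [i for i, p in enumerate(pops) if p == lab]
        sizes[lab] = len(idx)
        ss_within += sum(
            d2[i, j] for i in idx for j in idx if i < j
        ) / len(idx)
    ss_among = ss_total - ss_within
    df_among = len(labels) - 1
    df_within = n - len(labels)
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n_prime = (n - sum(v * v for v in sizes.values()) / n) / df_among
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n_prime
    phi = sigma_a / (sigma_a + sigma_w)
    return sigma_a, sigma_w, phi


def amova_three_level_oracle(
    d2: np.ndarray, pops: list[str], groups: list[str]
) -> tuple[float, float, float]:
    """Three-level AMOVA variance components from explicit sums of squares
    (among groups, among populations within groups, within populations)."""
    n = len(pops)
    pop_labels = sorted(set(pops))
    grp_labels = sorted(set(groups))
    pop_group = {p: groups[pops.index(p)] for p in pop_labels}

    def ss_sets(sets: list[list[int]]) -> float:
        total = 0.0
        for idx in sets:
            if len(idx) > 1:
                total += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
        return total

    all_idx = [list(range(n))]
    grp_idx = [
        [i for i in range(n) if groups[i] == g] for g in grp_labels
    ]
    pop_idx = [[i for i in range(n) if pops[i] == p] for p in pop_labels]
    ss_total = ss_sets(all_idx)
    ss_g = ss_sets(grp_idx)
    ss_p = ss_sets(pop_idx)
    ss_ag = ss_total - ss_g
    ss_apwg = ss_g - ss_p
    ss_wp = ss_p
    df_ag = len(grp_labels) - 1
    df_apwg = len(pop_labels) - len(grp_labels)
    df_wp = n - len(pop_labels)
    pop_sizes = {p: len(idx) for p, idx in zip(pop_labels, pop_idx)}
    grp_sizes = {g: len(idx) for g, idx in zip(grp_labels, grp_idx)}
    sum_n2_by_grp = {
        g: sum(pop_sizes[p] ** 2 for p in pop_labels if pop_group[p] == g)
        for g in grp_labels
    }
    n_prime = (
        (n - sum(sum_n2_by_grp[g] / grp_sizes[g] for g in grp_labels)) / df_apwg
        if df_apwg
        else 1.0
    )
    n_dprime = (
        sum(sum_n2_by_grp[g] / grp_sizes[g] for g in grp_labels)
        - sum(v * v for v in pop_sizes.values()) / n
    ) / df_ag
    n_tprime = (n - sum(v * v for v in grp_sizes.values()) / n) / df_ag
    sigma_c = ss_wp / df_wp if df_wp else 0.0
    sigma_b = (ss_apwg / df_apwg - sigma_c) / n_prime if df_apwg else 0.0
    sigma_a = (ss_ag / df_ag - sigma_c - n_dprime * sigma_b) / n_tprime
    return sigma_a, sigma_b, sigma_c


def pairwise_diff_matrix(seqs: list[str]) -> np.ndarray:
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sum(
                1
                for a, b in zip(seqs[i], seqs[j])
                if a not in "N-" and b not in "N-" and a != b
            )
    return d


def kingman_smm_sample(
    n: int, big_n: float, mu: float, rng: np.random.Generator, ancestral: int = 50
) -> np.ndarray:
    """Single-deme coalescent with strict stepwise mutation, simulated from
    first principles (exponential coalescence times, Poisson mutations on
    branches, +-1 steps). Returns the sampled allele sizes."""
    # lineages: (node_id); record branch intervals then drop mutations
    times = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    active = list(range(n))
    next_id = n
    t = 0.0
    while len(active) > 1:
        k = len(active)
        rate = k * (k - 1) / 2.0 / big_n
        t += rng.exponential(1.0 / rate)
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        active = [x for x in active if x not in (a, b)]
        times[next_id] = t
        children[next_id] = (a, b)
        active.append(next_id)
        next_id += 1
    root = active[0]
    sizes = {root: ancestral}
    stack = [root]
    while stack:
        node = stack.pop()
        for child in children.get(node, ()):
            branch = times[node] - times[child]
            n_mut = rng.poisson(mu * branch)
            state = sizes[node]
            for _ in range(n_mut):
                state += rng.choice([-1, 1])
                state = max(state, 1)
            sizes[child] = state
            stack.append(child)
    return np.array([sizes[i] for i in range(n)])
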