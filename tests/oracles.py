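"""Independent brute-force oracles, written separately from the package.

These deliberately use naive per-site, per-fragment Python loops so they
share no code path with the vectorised implementations they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_fdss(fragments, populations, population_order, cap):
    """Per-site classification + per-fragment tallying, the slow way.

    ``fragments``: list of (sites x chromosomes) allele matrices with -1
    for missing.  Returns an array (n_pairs, 4, cap + 1) in the order
    private1, private2, shared, fixed.
    """
    pops = list(populations)
    cols = {p: [i for i, q in enumerate(pops) if q == p] for p in population_order}
    pairs = []
    for i in range(len(population_order)):
        for j in range(i + 1, len(population_order)):
            pairs.append((population_order[i], population_order[j]))
    out = np.zeros((len(pairs), 4, cap + 1), dtype=np.int64)
    for k, (pa, pb) in enumerate(pairs):
        for f, frag in enumerate(fragments):
            tallies = [0, 0, 0, 0]
            for site in np.asarray(frag):
                site = list(site)
                if any(a < 0 for a in site):
                    continue  # missing call: drop the site
                if len(set(site)) > 2:
                    continue  # multi-allelic: drop the site
                a = [site[c] for c in cols[pa]]
                b = [site[c] for c in cols[pb]]
                poly_a = len(set(a)) > 1
                poly_b = len(set(b)) > 1
                if poly_a and not poly_b:
                    tallies[0] += 1
                elif poly_b and not poly_a:
                    tallies[1] += 1
                elif poly_a and poly_b:
                    tallies[2] += 1
                elif a[0] != b[0]:
                    tallies[3] += 1
            for c, t in enumerate(tallies):
                out[k, c, min(t, cap)] += 1
    return out


def random_fragment_instance(rng, n_pops=2, n_fragments=20, max_sites=8,
                             missing_rate=0.0, multiallelic_rate=0.0):
    """A random FDSS input: populations of one diploid each."""
    pop_names = [f"pop{i}" for i in range(n_pops)]
    populations = [p for p in pop_names for _ in range(2)]
    frags = []
    for _ in range(n_fragments):
        s = int(rng.integers(0, max_sites + 1))
        alleles = rng.integers(0, 2, size=(s, 2 * n_pops))
        if multiallelic_rate and s:
            hit = rng.random(s) < multiallelic_rate
            extra = rng.integers(0, 2 * n_pops, size=s)
            for i in np.flatnonzero(hit):
                alleles[i, extra[i]] = 2
        if missing_rate and s:
            mask = rng.random((s, 2 * n_pops)) < missing_rate
            alleles = np.where(mask, -1, alleles)
        frags.append(alleles.astype(np.int64))
    return frags, populations, tuple(pop_names)
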