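"""Independent oracles shared by the unit and acceptance suites.

These deliberately re-derive quantities by the dumbest correct route
(enumeration, direct tallies) and never call the code paths they check.
"""

import itertools

import numpy as np


def brute_force_pvalue(test_genes, term, universe, bins):
    """P(control count >= test count) by full enumeration of control sets.

    Enumerates every combination of per-test-gene bin members with equal
    probability (draws are uniform and independent), so it is exact for any
    instance small enough to enumerate.
    """
    test = list(test_genes)
    pools = [sorted(bins.index[bins == bins.loc[g]]) for g in test]
    k = sum(1 for g in test if universe.has_term(g, term))
    total = hits = 0
    for combo in itertools.product(*pools):
        total += 1
        count = sum(1 for g in combo if universe.has_term(g, term))
        if count >= k:
            hits += 1
    return hits / total


def random_tiny_instance(rng, max_genes=8, max_terms=4):
    """A random small universe + test set for oracle cross-checks."""
    from conftest import make_universe

    n_genes = int(rng.integers(4, max_genes + 1))
    genes = [f"g{i}" for i in range(n_genes)]
    lengths = {g: int(rng.integers(100, 10_000)) for g in genes}
    n_terms = int(rng.integers(1, max_terms + 1))
    term_members = {}
    for j in range(n_terms):
        size = int(rng.integers(1, n_genes + 1))
        members = rng.choice(genes, size=size, replace=False)
        term_members[f"GO:{j + 1:07d}"] = sorted(members.tolist())
    universe = make_universe(lengths, term_members)
    test = sorted(rng.choice(genes, size=int(rng.integers(1, 4)), replace=False).tolist())
    return universe, test


def mc_standard_error(p, n_draws):
    return np.sqrt(p * (1.0 - p) / n_draws)
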