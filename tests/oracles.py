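"""Independent brute-force oracles the implementation is checked against.

These deliberately take the slow, direct route: exhaustive pairwise scans
over alleles and genotypes, never reusing the package's EAG/partition
machinery beyond raw region-sequence access.
"""

from __future__ import annotations

import itertools

import numpy as np

from abotype.refdb import ReferenceDB


def observation_of_pair(db: ReferenceDB, a1: str, a2: str) -> tuple:
    """Per-amplicon sorted sequence multiset produced by an allele pair."""
    return tuple(
        tuple(sorted((db.region_seq(a1, amp), db.region_seq(a2, amp))))
        for amp in db.amplicon_ids
    )


def consistent_allele_pairs(db: ReferenceDB, observation: tuple) -> set[frozenset]:
    """All unordered allele pairs whose sequences reproduce the observation."""
    alleles = sorted(db.alleles)
    out = set()
    for a1, a2 in itertools.combinations_with_replacement(alleles, 2):
        if observation_of_pair(db, a1, a2) == observation:
            out.add(frozenset((a1, a2)))
    return out


def genotype_pairs_of_call(call) -> set[frozenset]:
    """Unordered allele pairs spanned by a call's phasing alternatives."""
    out = set()
    for alt in call.alternatives:
        for x in alt.candidates[0]:
            for y in alt.candidates[1]:
                out.add(frozenset((x, y)))
    return out


def brute_force_ambiguous_classes(db: ReferenceDB) -> set[frozenset]:
    """Sets of allele-group genotypes sharing one observation, via full scan.

    Enumerates every unordered allele pair, maps it to its observation, and
    collapses observationally-equivalent pairs to group-level genotypes.
    Returns the genotype sets of classes containing > 1 group genotype.
    """
    group_of = db.group_table.group_of
    by_obs: dict[tuple, set[tuple]] = {}
    alleles = sorted(db.alleles)
    for a1, a2 in itertools.combinations_with_replacement(alleles, 2):
        obs = observation_of_pair(db, a1, a2)
        pair = tuple(sorted((group_of[a1], group_of[a2])))
        by_obs.setdefault(obs, set()).add(pair)
    return {frozenset(pairs) for pairs in by_obs.values() if len(pairs) > 1}


def grid_search_mle(counts, genotype_sets, step_coarse=0.01, step_fine=1e-4):
    """Brute-force multinomial MLE on the 2-simplex (K=3) by two-stage grid.

    ``genotype_sets`` is a list parallel to ``counts``: each entry the set of
    (i, j) index genotypes the category comprises.
    """

    def loglik(theta):
        ll = 0.0
        for n_c, genos in zip(counts, genotype_sets):
            p = 0.0
            for i, j in genos:
                p += theta[i] ** 2 if i == j else 2 * theta[i] * theta[j]
            if n_c > 0:
                if p <= 0:
                    return -np.inf
                ll += n_c * np.log(p)
        return ll

    def scan(t1_range, t2_range):
        best, best_ll = None, -np.inf
        for t1 in t1_range:
            for t2 in t2_range:
                t3 = 1.0 - t1 - t2
                if t3 < -1e-12:
                    continue
                theta = (t1, t2, max(t3, 0.0))
                ll = loglik(theta)
                if ll > best_ll:
                    best, best_ll = theta, ll
        return best

    coarse = scan(np.arange(0, 1 + step_coarse, step_coarse),
                  np.arange(0, 1 + step_coarse, step_coarse))
    lo1, lo2 = max(0, coarse[0] - 2 * step_coarse), max(0, coarse[1] - 2 * step_coarse)
    fine = scan(np.arange(lo1, min(1, coarse[0] + 2 * step_coarse) + step_fine, step_fine),
                np.arange(lo2, min(1, coarse[1] + 2 * step_coarse) + step_fine, step_fine))
    return np.asarray(fine)
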