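"""Shared fixtures: synthetic references at several scales."""

from __future__ import annotations

import pytest

from abotype.refdb import AmpliconDef, ReferenceDB
from abotype.simulate import SimConfig, fig2_collision, german_config, make_allele_db


@pytest.fixture(scope="session")
def small_db() -> ReferenceDB:
    """Tiny random reference: 6 alleles, no collisions, singleton EAGs."""
    config = SimConfig(
        n_alleles={"A": 2, "B": 2, "O": 2},
        amplicons=[AmpliconDef("ex6", "6", 0, 30), AmpliconDef("ex7", "7", 0, 40)],
        n_samples=0,
        seed=11,
    )
    return make_allele_db(config)


@pytest.fixture(scope="session")
def trap_db() -> ReferenceDB:
    """Reference with the canonical cross-amplicon phasing trap.

    The four alleles B1.01.01, O.02.01, Ax.02.01 and O.02.14 share exon 6,
    while exon-7a and exon-7b sharing is crossed, so B1.01.01/O.02.01 and
    Ax.02.01/O.02.14 are observationally identical.
    """
    return make_allele_db(german_config(seed=7))


@pytest.fixture(scope="session")
def trap_freqs() -> dict[str, float]:
    """Published German frequencies keyed by bare allele name (fractions)."""
    from abotype.frequencies import GERMAN_GROUP_FREQUENCIES_PCT

    return {k.rstrip("*"): v / 100.0 for k, v in GERMAN_GROUP_FREQUENCIES_PCT.items()}


def random_sim_config(rng, n_min=12, n_max=60, seed=0) -> SimConfig:
    """Random small reference config with random EAG collisions.

    Collisions merge disjoint random subsets of alleles per amplicon,
    occasionally wiring a full cross-amplicon trap.
    """
    from abotype.simulate import _synthetic_names

    n = int(rng.integers(n_min, n_max + 1))
    n_a = max(1, n // 3)
    n_b = max(1, n // 4)
    n_o = n - n_a - n_b
    names = _synthetic_names({"A": n_a, "B": n_b, "O": n_o})
    amps = [
        AmpliconDef("ex6", "6", 0, 140),
        AmpliconDef("ex7a", "7", 0, 160),
        AmpliconDef("ex7b", "7", 140, 300),
    ]
    collisions: dict[str, list[list[str]]] = {}
    if rng.random() < 0.5 and len(names) >= 4:
        p, q, r, s = [names[i] for i in rng.choice(len(names), size=4, replace=False)]
        collisions = {k: [list(c) for c in v] for k, v in fig2_collision(p, q, r, s).items()}
    for amp in amps:
        cells = collisions.setdefault(amp.id, [])
        used = {a for cell in cells for a in cell}
        free = [x for x in names if x not in used]
        n_merges = int(rng.integers(0, 3))
        for _ in range(n_merges):
            if len(free) < 2:
                break
            size = int(rng.integers(2, min(4, len(free)) + 1))
            idx = rng.choice(len(free), size=size, replace=False)
            cell = [free[i] for i in sorted(idx)]
            cells.append(cell)
            free = [x for x in free if x not in cell]
    return SimConfig(
        allele_names=names, amplicons=amps, collisions=collisions, n_samples=0, seed=seed
    )
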