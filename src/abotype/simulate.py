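"""Synthetic allele databases, HWE population samples, and error-bearing reads.

The generator emulates the structures the genotyper must cope with: a
reference whose alleles share amplicon-window sequences in controlled ways
(EAG collisions, including the cross-amplicon phasing trap where exon-6
sharing plus crossed exon-7 sharing yields two valid genotypes), diploid
populations in Hardy-Weinberg equilibrium at configurable allele-group
frequencies, and amplicon reads with i.i.d. substitution errors.

By default the allele census (108 A, 68 B, 73 O), the sample size (113,367),
the frequency spectrum (the published German estimates) and the depth scale
(1,000 reads per amplicon) follow the population survey this package is
modeled on; sequence content is random but fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np

from .frequencies import german_theta
from .nomenclature import parse_allele_name
from .refdb import AlleleRecord, AmpliconDef, ReferenceDB

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_amplicons() -> list[AmpliconDef]:
    """Three-amplicon assay: exon 6 (192 bp) plus two overlapping exon-7 windows."""
    return [
        AmpliconDef("ex6", "6", 0, 192),
        AmpliconDef("ex7a", "7", 0, 460),
        AmpliconDef("ex7b", "7", 363, 691),
    ]


def assay2_amplicons() -> list[AmpliconDef]:
    """Two-amplicon assay: exon 6 plus the central 507 bp of exon 7."""
    return [
        AmpliconDef("ex6", "6", 0, 192),
        AmpliconDef("ex7c", "7", 92, 599),
    ]


def fig2_collision(p: str, q: str, r: str, s: str) -> dict[str, list[list[str]]]:
    """Cross-amplicon phasing trap over four alleles.

    All four share exon 6; at exon 7a the pairs {p,r} and {q,s} share, at
    exon 7b the pairs {p,s} and {q,r}.  A p/q sample is then observationally
    identical to an r/s sample, with the two chain pairings giving exactly
    those two genotypes.
    """
    return {
        "ex6": [[p, q, r, s]],
        "ex7a": [[p, r], [q, s]],
        "ex7b": [[p, s], [q, r]],
    }


def german_allele_names() -> list[str]:
    """The 82 published German allele/allele-group identifiers, asterisks stripped."""
    return sorted(k.rstrip("*") for k in german_theta())


def german_theta_by_allele() -> dict[str, float]:
    return {k.rstrip("*"): v for k, v in german_theta().items()}


@dataclass
class SimConfig:
    """Study conditions for synthetic data generation."""

    n_alleles: Mapping[str, int] = dc_field(
        default_factory=lambda: {"A": 108, "B": 68, "O": 73}
    )
    allele_names: Sequence[str] | None = None      # explicit names override n_alleles
    amplicons: Sequence[AmpliconDef] = dc_field(default_factory=default_amplicons)
    collisions: Mapping[str, Sequence[Sequence[str]]] = dc_field(default_factory=dict)
    theta: Mapping[str, float] | None = None       # allele-group simplex (fractions)
    n_samples: int = 113_367
    depth: int = 1000
    error_rate: float = 0.001
    novel_rate: float = 0.0
    seed: int = 0


class CollisionSpecError(ValueError):
    """Contradictory or infeasible EAG collision specification."""


def german_config(seed: int = 0, n_samples: int = 113_367) -> SimConfig:
    """Study-condition config: the 82 published German allele groups as the
    allele set, published frequencies as θ, and the canonical cross-amplicon
    phasing trap (B1.01.01/O.02.01 vs Ax.02.01/O.02.14) wired in."""
    return SimConfig(
        allele_names=german_allele_names(),
        collisions=fig2_collision("B1.01.01", "O.02.01", "Ax.02.01", "O.02.14"),
        theta=german_theta_by_allele(),
        n_samples=n_samples,
        seed=seed,
    )


def _synthetic_names(n_alleles: Mapping[str, int]) -> list[str]:
    subgroup_pools = {"A": ["A1", "A2", "A3", "Ax", "Aw", "Ael"], "B": ["B1", "Ba", "Bw", "Bel"]}
    names: list[str] = []
    for bg in ("A", "B", "O"):
        n = int(n_alleles.get(bg, 0))
        for i in range(n):
            if bg == "O":
                names.append(f"O.{i % 3 + 1:02d}.{i // 3 + 1:02d}")
            else:
                pool = subgroup_pools[bg]
                sg = pool[i % len(pool)]
                names.append(f"{sg}.{i // len(pool) + 1:02d}.01")
    return names


def _exclusive_positions(amp: AmpliconDef, all_amps: Sequence[AmpliconDef]) -> list[int]:
    """Exon positions inside amp's window covered by no other amplicon."""
    covered = set()
    for other in all_amps:
        if other.id != amp.id and other.exon == amp.exon:
            covered.update(range(other.start, other.end))
    return [p for p in range(amp.start, amp.end) if p not in covered]


def make_allele_db(config: SimConfig) -> ReferenceDB:
    """Generate a reference realizing the requested EAG collision structure.

    Every allele's exon sequences derive from one random base sequence per
    exon; each non-base EAG class mutates two dedicated positions in its
    amplicon's exclusive zone, so distinct window sequences differ at >= 2
    positions (a single read error never converts one reference sequence
    into another) and collision classes on different amplicons never
    interact.  Raises :class:`CollisionSpecError` on contradictory specs.
    """
    rng = np.random.default_rng(config.seed)
    names = list(config.allele_names) if config.allele_names else _synthetic_names(config.n_alleles)
    if len(set(names)) != len(names):
        raise CollisionSpecError("duplicate allele names")
    name_set = set(names)
    amps = list(config.amplicons)
    exon_len = {a.exon: 0 for a in amps}
    for a in amps:
        exon_len[a.exon] = max(exon_len[a.exon], a.end)
    base = {
        exon: _BASES[rng.integers(0, 4, size=ln)].copy() for exon, ln in sorted(exon_len.items())
    }

    # per-amplicon partition: collision cells plus singletons
    exon_seqs: dict[str, dict[str, np.ndarray]] = {
        n: {exon: b.copy() for exon, b in base.items()} for n in names
    }
    for amp in amps:
        cells = [list(cell) for cell in config.collisions.get(amp.id, [])]
        assigned: set[str] = set()
        for cell in cells:
            for a in cell:
                if a not in name_set:
                    raise CollisionSpecError(f"unknown allele {a!r} in collision spec for {amp.id}")
                if a in assigned:
                    raise CollisionSpecError(
                        f"allele {a!r} appears in two collision cells for amplicon {amp.id}"
                    )
                assigned.add(a)
        cells.extend([[n] for n in names if n not in assigned])
        cells.sort(key=lambda c: min(c))
        exclusive = _exclusive_positions(amp, amps)
        needed = 2 * (len(cells) - 1)
        if needed > len(exclusive):
            raise CollisionSpecError(
                f"amplicon {amp.id}: {len(cells)} EAG classes need {needed} exclusive "
                f"positions, only {len(exclusive)} available"
            )
        pos = rng.permutation(np.asarray(exclusive))[:needed] if needed else np.empty(0, int)
        for k, cell in enumerate(cells):
            if k == 0:
                continue  # base class keeps the unmutated sequence
            p1, p2 = int(pos[2 * (k - 1)]), int(pos[2 * k - 1])
            for a in cell:
                for p in (p1, p2):
                    exon_seqs[a][amp.exon][p] = _mutate(base[amp.exon][p])

    records = []
    for n in names:
        parsed = parse_allele_name(n)
        seqs = {exon: arr.tobytes().decode() for exon, arr in exon_seqs[n].items()}
        records.append(
            AlleleRecord(
                name=n,
                blood_group=parsed.blood_group,
                subgroup=parsed.subgroup,
                fields=parsed.fields,
                exon_seqs=seqs,
                phenotype_known=True,
                phenotype_uncertain=False,
                seq_complete={exon: True for exon in seqs},
            )
        )
    db = ReferenceDB(records, amps)
    _check_partition(db, config, names)
    return db


def _mutate(b: int) -> int:
    idx = int(np.where(_BASES == b)[0][0])
    return int(_BASES[(idx + 1) % 4])


def _check_partition(db: ReferenceDB, config: SimConfig, names: list[str]) -> None:
    for amp_id, cells in config.collisions.items():
        realized = {frozenset(e.members) for e in db.eags[amp_id]}
        merged: set[str] = set()
        for cell in cells:
            if frozenset(cell) not in realized:
                raise CollisionSpecError(
                    f"requested collision cell {sorted(cell)} not realized on {amp_id}"
                )
            merged.update(cell)
        for n in names:
            if n not in merged and frozenset([n]) not in realized:
                raise CollisionSpecError(f"allele {n!r} unexpectedly merged on {amp_id}")


# --- population and reads ----------------------------------------------------

def representative_allele(db: ReferenceDB, group_or_allele: str) -> str:
    """Resolve a group identifier or allele name to a concrete allele in the DB."""
    if group_or_allele in db.alleles:
        return group_or_allele
    if group_or_allele in db.group_table.groups:
        return min(db.group_table.groups[group_or_allele])
    raise KeyError(f"{group_or_allele!r} is neither an allele nor a group in the DB")


def sample_population(
    db: ReferenceDB, theta: Mapping[str, float], n: int, seed: int
) -> list[tuple[str, str]]:
    """Draw n unordered diploid genotypes under HWE: two i.i.d. draws from θ."""
    groups = sorted(theta)
    p = np.asarray([theta[g] for g in groups], dtype=float)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    a1 = rng.choice(len(groups), size=n, p=p)
    a2 = rng.choice(len(groups), size=n, p=p)
    out = []
    for i, j in zip(a1, a2):
        g1, g2 = groups[int(i)], groups[int(j)]
        out.append((g1, g2) if g1 <= g2 else (g2, g1))
    return out


def simulate_reads(
    genotype: tuple[str, str],
    db: ReferenceDB,
    depth: int,
    error_rate: float,
    seed: int,
) -> dict[str, list[str]]:
    """Amplicon reads for one diploid sample with i.i.d. substitution errors.

    Reads split between the two haplotypes as Binomial(depth, 1/2); each base
    flips to one of the three alternatives with probability ``error_rate``.
    Byte-identical output for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    a1 = representative_allele(db, genotype[0])
    a2 = representative_allele(db, genotype[1])
    out: dict[str, list[str]] = {}
    for amp in db.amplicons:
        seqs = [db.region_seq(a1, amp.id), db.region_seq(a2, amp.id)]
        n1 = int(rng.binomial(depth, 0.5))
        reads: list[str] = []
        for hap_seq, count in zip(seqs, (n1, depth - n1)):
            if count == 0:
                continue
            arr = np.tile(np.frombuffer(hap_seq.encode(), dtype=np.uint8), (count, 1))
            if error_rate > 0:
                # sparse error placement: draw the number of errors for the
                # block, then flat positions (collisions at realistic rates
                # are vanishingly rare and collapse to a single substitution)
                n_err = rng.binomial(arr.size, error_rate)
                if n_err:
                    flat = rng.integers(0, arr.size, size=n_err)
                    shifts = rng.integers(1, 4, size=n_err)
                    view = arr.reshape(-1)
                    idx = np.searchsorted(_BASES, view[flat])
                    view[flat] = _BASES[(idx + shifts) % 4]
            reads.extend(row.tobytes().decode() for row in arr)
        out[amp.id] = reads
    return out
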