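"""Read collapsing, exact EAG matching, intersection calling, resolution."""

from __future__ import annotations

import numpy as np
import pytest

from abotype.genotyper import (
    NovelHit,
    Resolution,
    SampleObservation,
    Status,
    call_genotype,
    classify_resolution,
    collapse_reads,
    match_sequence,
    phenotype_of,
)
from abotype.refdb import AmpliconDef
from abotype.simulate import SimConfig, make_allele_db, simulate_reads

from .conftest import random_sim_config
from .oracles import consistent_allele_pairs, genotype_pairs_of_call, observation_of_pair


def observation_for(db, genotype, depth=200):
    reads = simulate_reads(genotype, db, depth=depth, error_rate=0.0, seed=99)
    return collapse_reads(reads, db.amplicons, sample_id="t")


# --- collapse_reads ----------------------------------------------------------

def test_collapse_identical_reads(small_db):
    amp = small_db.amplicons[0]
    seq = small_db.region_seq(sorted(small_db.alleles)[0], amp.id)
    obs = collapse_reads({amp.id: [seq] * 100}, [amp])
    assert obs.seqs[amp.id] == [(seq, 100)]
    assert obs.total_reads[amp.id] == 100


def test_collapse_keeps_balanced_heterozygote(small_db):
    amp = small_db.amplicons[0]
    names = sorted(small_db.alleles)
    s1, s2 = (small_db.region_seq(n, amp.id) for n in names[:2])
    obs = collapse_reads({amp.id: [s1] * 60 + [s2] * 40}, [amp], min_fraction=0.25)
    assert {s for s, _ in obs.seqs[amp.id]} == {s1, s2}


def test_collapse_empty_input_yields_zero_totals(small_db):
    obs = collapse_reads({}, small_db.amplicons)
    assert all(t == 0 for t in obs.total_reads.values())


def test_error_variants_fall_below_fraction_threshold():
    """At 1% substitution error and depth 200, the true (<=2) sequences
    survive collapsing and every error variant is dropped, over 100 seeds.

    Windows of 20 bp keep the error-free read fraction (0.99^20 = 0.82) far
    above the 0.25 cutoff while error variants stay individually rare.
    """
    db = make_allele_db(
        SimConfig(
            n_alleles={"A": 2, "B": 2, "O": 2},
            amplicons=[AmpliconDef("ex6", "6", 0, 20), AmpliconDef("ex7", "7", 0, 20)],
            n_samples=0,
            seed=21,
        )
    )
    names = sorted(db.alleles)
    genotype = (names[0], names[3])
    truth = {
        amp.id: {db.region_seq(genotype[0], amp.id), db.region_seq(genotype[1], amp.id)}
        for amp in db.amplicons
    }
    for seed in range(100):
        reads = simulate_reads(genotype, db, depth=200, error_rate=0.01, seed=seed)
        obs = collapse_reads(reads, db.amplicons, min_fraction=0.25)
        for amp in db.amplicons:
            kept = {s for s, _ in obs.seqs[amp.id]}
            assert kept == truth[amp.id]


# --- match_sequence ----------------------------------------------------------

def test_exact_match_returns_eag(small_db):
    amp = small_db.amplicons[0]
    eag = small_db.eags[amp.id][0]
    assert match_sequence(amp.id, eag.sequence, small_db) is eag


def test_single_substitution_yields_novel_hit_with_position(small_db):
    amp = small_db.amplicons[0]
    name = sorted(small_db.alleles)[0]
    seq = small_db.region_seq(name, amp.id)
    pos = 7
    mutated = seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1 :]
    hit = match_sequence(amp.id, mutated, small_db)
    assert isinstance(hit, NovelHit)
    assert hit.mismatch_positions == (pos,)
    assert name in hit.closest


def test_equidistant_novel_hit_lists_all_ties():
    """A query one substitution from two distinct references reports both."""
    amps = [AmpliconDef("ex6", "6", 0, 30)]
    db = make_allele_db(
        SimConfig(allele_names=["A1.01.01", "B1.01.01"], amplicons=amps, n_samples=0, seed=13)
    )
    s1 = db.region_seq("A1.01.01", "ex6")
    s2 = db.region_seq("B1.01.01", "ex6")
    diff = [i for i in range(len(s1)) if s1[i] != s2[i]]
    assert len(diff) == 2  # synthetic construction guarantees distance 2
    # mutate s1 at one differing position to the s2 base -> distance 1 from both
    i = diff[0]
    query = s1[:i] + s2[i] + s1[i + 1 :]
    hit = match_sequence("ex6", query, db)
    assert isinstance(hit, NovelHit)
    assert set(hit.closest) == {"A1.01.01", "B1.01.01"}
    assert len(hit.mismatch_positions) == 1


def test_length_mismatch_and_unknown_amplicon(small_db):
    amp = small_db.amplicons[0]
    hit = match_sequence(amp.id, "ACGT", small_db)
    assert isinstance(hit, NovelHit) and "length" in hit.note
    with pytest.raises(KeyError):
        match_sequence("nope", "ACGT", small_db)


# --- call_genotype -----------------------------------------------------------

def test_unique_homozygous_full_resolution(small_db):
    name = sorted(small_db.alleles)[0]
    call = call_genotype(observation_for(small_db, (name, name)), small_db)
    assert call.status == Status.OK
    assert len(call.alternatives) == 1
    assert call.alternatives[0].candidates == (frozenset([name]), frozenset([name]))
    assert classify_resolution(call, small_db.group_table) == Resolution.full


def test_trap_genotype_yields_both_printed_alternatives(trap_db):
    """The cross-amplicon trap produces exactly the two published genotypes:
    B1.01.01/O.02.01 and Ax.02.01/O.02.14."""
    call = call_genotype(observation_for(trap_db, ("B1.01.01", "O.02.01")), trap_db)
    assert call.status == Status.OK
    pairs = {
        frozenset((min(a.candidates[0]), min(a.candidates[1]))) for a in call.alternatives
    }
    assert pairs == {
        frozenset(("B1.01.01", "O.02.01")),
        frozenset(("Ax.02.01", "O.02.14")),
    }
    assert all(len(s) == 1 for a in call.alternatives for s in a.candidates)
    # alternatives disagree on the carried blood group -> phenotype undetermined
    assert call.phenotype is None
    assert classify_resolution(call, trap_db.group_table) is None


def test_failure_statuses(small_db):
    names = sorted(small_db.alleles)
    obs = observation_for(small_db, (names[0], names[1]), depth=200)
    # low reads
    low = SampleObservation("s", obs.seqs, {a: 10 for a in obs.total_reads})
    assert call_genotype(low, small_db).status == Status.FAIL_LOW_READS
    # three sequences at one amplicon
    amp = small_db.amplicons[0].id
    seqs3 = dict(obs.seqs)
    extra = small_db.region_seq(names[2], amp)
    seqs3[amp] = seqs3[amp] + [(extra, 50)]
    tri = SampleObservation("s", seqs3, obs.total_reads)
    call = call_genotype(tri, small_db)
    assert call.status == Status.FAIL_NO_INTERSECTION
    # unmatched sequence -> novel candidate
    seqs_novel = dict(obs.seqs)
    s0 = seqs_novel[amp][0][0]
    mutated = ("A" if s0[0] != "A" else "C") + s0[1:]
    seqs_novel[amp] = [(mutated, 100), seqs_novel[amp][1]] if len(seqs_novel[amp]) > 1 else [(mutated, 100)]
    call = call_genotype(SampleObservation("s", seqs_novel, obs.total_reads), small_db)
    assert call.status == Status.NOVEL_CANDIDATE
    assert call.novel_hits


def test_no_intersection_when_chains_conflict():
    """EAG member sets that cannot be joined into two haplotypes fail."""
    amps = [AmpliconDef("ex6", "6", 0, 30), AmpliconDef("ex7", "7", 0, 40)]
    db = make_allele_db(
        SimConfig(
            allele_names=["A1.01.01", "B1.01.01", "O.01.01"],
            amplicons=amps, n_samples=0, seed=3,
        )
    )
    # exon-6 sequences of alleles 1+2, exon-7 sequences of alleles 1+3: the
    # second chain would need an allele with B's exon 6 and O's exon 7
    seqs = {
        "ex6": [(db.region_seq("A1.01.01", "ex6"), 100), (db.region_seq("B1.01.01", "ex6"), 100)],
        "ex7": [(db.region_seq("A1.01.01", "ex7"), 100), (db.region_seq("O.01.01", "ex7"), 100)],
    }
    obs = SampleObservation("s", seqs, {"ex6": 200, "ex7": 200})
    assert call_genotype(obs, db).status == Status.FAIL_NO_INTERSECTION


@pytest.mark.parametrize("seed", range(8))
def test_alternatives_match_exhaustive_pair_oracle(seed):
    """On random small references, the union of phasing alternatives equals
    the brute-force scan over all unordered allele pairs, and always contains
    the true genotype (error-free reads)."""
    rng = np.random.default_rng(1000 + seed)
    db = make_allele_db(random_sim_config(rng, n_min=12, n_max=30, seed=2000 + seed))
    names = sorted(db.alleles)
    for _ in range(5):
        g = tuple(names[i] for i in rng.integers(0, len(names), 2))
        call = call_genotype(observation_for(db, g), db)
        assert call.status == Status.OK
        assert frozenset(g) in genotype_pairs_of_call(call)
        oracle = consistent_allele_pairs(db, observation_of_pair(db, *g))
        assert genotype_pairs_of_call(call) == oracle


def test_call_invariant_to_haplotype_and_amplicon_order(trap_db):
    """Swapping haplotypes or permuting amplicon arrival order leaves the
    candidate sets unchanged."""
    g = ("B1.01.01", "O.02.01")
    obs = observation_for(trap_db, g)
    base = call_genotype(obs, trap_db)
    swapped = SampleObservation(
        "t",
        {amp: list(reversed(v)) for amp, v in obs.seqs.items()},
        obs.total_reads,
    )
    alt = call_genotype(swapped, trap_db)
    key = lambda c: sorted(tuple(sorted(map(sorted, a.candidates))) for a in c.alternatives)
    assert key(base) == key(alt)


def test_adding_amplicon_never_increases_alternatives():
    rng = np.random.default_rng(77)
    config = random_sim_config(rng, n_min=15, n_max=25, seed=88)
    db_full = make_allele_db(config)
    config2 = SimConfig(
        allele_names=config.allele_names,
        amplicons=config.amplicons[:2],
        collisions={k: v for k, v in config.collisions.items() if k in ("ex6", "ex7a")},
        n_samples=0,
        seed=config.seed,
    )
    db_part = make_allele_db(config2)
    names = sorted(db_full.alleles)
    for i in range(6):
        g = (names[(3 * i) % len(names)], names[(5 * i + 1) % len(names)])
        full = call_genotype(observation_for(db_full, g), db_full)
        part = call_genotype(observation_for(db_part, g), db_part)
        if full.status == Status.OK and part.status == Status.OK:
            assert len(full.alternatives) <= len(part.alternatives)


# --- resolution & phenotype --------------------------------------------------

@pytest.mark.parametrize(
    "pair,expected",
    [
        (("A1.01.01", "O.01.01"), "A"),
        (("A1.01.01", "B1.01.01"), "AB"),
        (("B1.01.01", "B1.01.05"), "B"),
        (("O.01.01", "O.02.01"), "O"),
    ],
)
def test_phenotype_dominance(pair, expected):
    assert phenotype_of(pair) == expected


def test_allele_group_resolution_for_cross_subgroup_group():
    """Candidates collapsing to one cross-subgroup allele group resolve at the
    allele_group level, not field-level."""
    members = ["A1.01.01", "Ael.04.01", "Aw.13.01", "Ax.15.01"]
    amps = [AmpliconDef("ex6", "6", 0, 30), AmpliconDef("ex7", "7", 0, 40)]
    db = make_allele_db(
        SimConfig(
            allele_names=members + ["O.01.01"],
            amplicons=amps,
            collisions={"ex6": [members], "ex7": [members]},
            n_samples=0,
            seed=5,
        )
    )
    call = call_genotype(observation_for(db, ("A1.01.01", "O.01.01")), db)
    assert call.status == Status.OK
    assert classify_resolution(call, db.group_table) == Resolution.allele_group
    assert call.phenotype == "A"
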