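"""Per-sample genotype calling by exact EAG matching and cross-amplicon intersection.

A diploid sample yields one or two distinct sequences per amplicon.  Each
observed sequence is matched exactly against the reference EAGs of its
amplicon; the genotype is obtained by distributing the per-amplicon sequences
onto two haplotype chains and intersecting each chain's EAG member sets.
When two heterozygous amplicons can be joined in more than one way, several
phasing alternatives remain and the call is ambiguous.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .nomenclature import blood_group_of, field2_of, field3_of, subgroup_of
from .refdb import AlleleGroupTable, ExonAlleleGroup, ReferenceDB


class Status(str, Enum):
    OK = "OK"
    FAIL_LOW_READS = "FAIL_LOW_READS"
    FAIL_NO_INTERSECTION = "FAIL_NO_INTERSECTION"
    NOVEL_CANDIDATE = "NOVEL_CANDIDATE"


class Resolution(str, Enum):
    """Granularity of a resolved call, low to high."""

    blood_group = "blood_group"
    subgroup = "subgroup"
    allele_group = "allele_group"
    field2 = "field2"
    field3 = "field3"
    full = "full"


DEFAULT_MIN_DEPTH = 50
DEFAULT_MIN_FRACTION = 0.25


@dataclass
class SampleObservation:
    """Collapsed per-amplicon sequences with read counts for one sample."""

    sample_id: str
    seqs: dict[str, list[tuple[str, int]]]   # amplicon -> [(sequence, count)]
    total_reads: dict[str, int]


@dataclass(frozen=True)
class PhasingAlternative:
    """One way of joining per-amplicon sequences into two haplotype chains.

    Each slot carries the chain (amplicon -> sequence) and the candidate
    alleles consistent with the whole chain (intersection of EAG members).
    """

    chains: tuple[tuple[tuple[str, str], ...], tuple[tuple[str, str], ...]]
    candidates: tuple[frozenset[str], frozenset[str]]

    def candidate_pair(self) -> tuple[frozenset[str], frozenset[str]]:
        return self.candidates


@dataclass(frozen=True)
class NovelHit:
    """An observed sequence with no exact reference match."""

    amplicon_id: str
    sequence: str
    closest: tuple[str, ...]            # minimal-Hamming-distance allele(s)
    mismatch_positions: tuple[int, ...]  # 0-based positions vs closest
    note: str = ""


@dataclass
class GenotypeCall:
    sample_id: str
    status: Status
    alternatives: list[PhasingAlternative] = field(default_factory=list)
    resolution: Resolution | None = None
    phenotype: str | None = None         # A, B, AB, O, or None = undetermined
    novel_hits: list[NovelHit] = field(default_factory=list)
    reason: str = ""
    discarded: list[tuple[PhasingAlternative, float]] = field(default_factory=list)


def collapse_reads(
    fastq_records: Mapping[str, Iterable[str]],
    amplicon_defs: Sequence,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    sample_id: str = "",
) -> SampleObservation:
    """Collapse raw reads into distinct per-amplicon sequences with counts.

    A sequence is kept only when supported by at least ``min_fraction`` of
    the amplicon's *modal* (most abundant) sequence count — the standard
    diploid minor-vs-major rule: with exact-identity collapsing each
    sequencing-error read is a (near-)unique variant, so thresholding against
    the modal count separates the one or two true haplotype sequences from
    the error background regardless of the per-read error-free fraction.
    Depth failures are not raised here; ``call_genotype`` applies
    ``min_depth`` downstream.
    """
    seqs: dict[str, list[tuple[str, int]]] = {}
    totals: dict[str, int] = {}
    for amp in amplicon_defs:
        reads = [str(r).upper() for r in fastq_records.get(amp.id, [])]
        totals[amp.id] = len(reads)
        counts: dict[str, int] = {}
        for r in reads:
            counts[r] = counts.get(r, 0) + 1
        modal = max(counts.values(), default=0)
        cutoff = min_fraction * modal
        kept = [(s, c) for s, c in counts.items() if c >= cutoff and c > 0]
        kept.sort(key=lambda sc: (-sc[1], sc[0]))
        seqs[amp.id] = kept
    return SampleObservation(sample_id=sample_id, seqs=seqs, total_reads=totals)


def match_sequence(
    amplicon_id: str, sequence: str, db: ReferenceDB
) -> ExonAlleleGroup | NovelHit:
    """Exact full-length match of a query against the amplicon's EAGs.

    Returns the unique matching EAG, or a :class:`NovelHit` carrying the
    minimal-Hamming-distance allele(s) and differing positions (all tied
    alleles listed).  Length mismatches short-circuit with a note.
    """
    if amplicon_id not in db.eags:
        raise KeyError(f"unknown amplicon {amplicon_id!r}")
    sequence = sequence.upper()
    hit = db.eag_by_seq.get((amplicon_id, sequence))
    if hit is not None:
        return hit
    amp = db.amplicon(amplicon_id)
    if len(sequence) != amp.expected_length:
        return NovelHit(
            amplicon_id,
            sequence,
            closest=(),
            mismatch_positions=(),
            note=f"length {len(sequence)} != expected {amp.expected_length}",
        )
    best_d = None
    best: list[tuple[str, tuple[int, ...]]] = []
    for eag in db.eags[amplicon_id]:
        positions = tuple(i for i, (a, b) in enumerate(zip(sequence, eag.sequence)) if a != b)
        d = len(positions)
        if best_d is None or d < best_d:
            best_d, best = d, [(min(eag.members), positions)]
        elif d == best_d:
            best.append((min(eag.members), positions))
    closest = tuple(sorted(name for name, _ in best))
    return NovelHit(amplicon_id, sequence, closest=closest, mismatch_positions=best[0][1])


def _enumerate_pairings(per_amp_seqs: Sequence[list[str]]):
    """All unordered ways to place 1-2 sequences per amplicon onto two chains."""
    options = []
    for seqs in per_amp_seqs:
        if len(seqs) == 1:
            options.append([(seqs[0], seqs[0])])
        else:
            s1, s2 = seqs
            options.append([(s1, s2), (s2, s1)])
    seen = set()
    for combo in itertools.product(*options):
        chain_a = tuple(c[0] for c in combo)
        chain_b = tuple(c[1] for c in combo)
        key = frozenset((chain_a, chain_b))
        if key in seen:
            continue
        seen.add(key)
        yield chain_a, chain_b


def call_genotype(
    observation: SampleObservation,
    db: ReferenceDB,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> GenotypeCall:
    """Intersect EAG memberships across amplicons into phasing alternatives.

    Every valid distribution of the observed sequences onto two haplotype
    chains with non-empty candidate intersections is kept; unordered duplicate
    pairings are deduplicated.  Failure modes: low read counts, a sequence
    with no reference match (novel candidate), more than two sequences at an
    amplicon, or no pairing with consistent intersections.
    """
    call = GenotypeCall(sample_id=observation.sample_id, status=Status.OK)
    amp_ids = db.amplicon_ids
    low = [a for a in amp_ids if observation.total_reads.get(a, 0) < min_depth]
    if low:
        call.status = Status.FAIL_LOW_READS
        call.reason = f"amplicons under {min_depth} reads: {','.join(low)}"
        return call

    per_amp_eags: list[list[ExonAlleleGroup]] = []
    for amp_id in amp_ids:
        entries = observation.seqs.get(amp_id, [])
        if not entries:
            call.status = Status.FAIL_LOW_READS
            call.reason = f"no surviving sequence at amplicon {amp_id}"
            return call
        if len(entries) > 2:
            call.status = Status.FAIL_NO_INTERSECTION
            call.reason = f"{len(entries)} sequences at amplicon {amp_id}; diploid expects <= 2"
            return call
        matched = []
        for seq, _count in entries:
            hit = match_sequence(amp_id, seq, db)
            if isinstance(hit, NovelHit):
                call.novel_hits.append(hit)
            else:
                matched.append(hit)
        if call.novel_hits:
            continue
        per_amp_eags.append(matched)
    if call.novel_hits:
        call.status = Status.NOVEL_CANDIDATE
        call.reason = "unmatched sequence(s): " + ",".join(
            h.amplicon_id for h in call.novel_hits
        )
        return call

    eag_members = [
        {eag.sequence: eag.members for eag in eags} for eags in per_amp_eags
    ]
    per_amp_seqs = [[eag.sequence for eag in eags] for eags in per_amp_eags]
    alts: list[PhasingAlternative] = []
    seen: set[frozenset] = set()
    for chain_a, chain_b in _enumerate_pairings(per_amp_seqs):
        cand_a = frozenset.intersection(
            *[frozenset(eag_members[i][s]) for i, s in enumerate(chain_a)]
        )
        if not cand_a:
            continue
        cand_b = frozenset.intersection(
            *[frozenset(eag_members[i][s]) for i, s in enumerate(chain_b)]
        )
        if not cand_b:
            continue
        key = frozenset((cand_a, cand_b))
        if key in seen:
            continue
        seen.add(key)
        chains = (
            tuple(zip(amp_ids, chain_a)),
            tuple(zip(amp_ids, chain_b)),
        )
        # canonical slot order for symmetry
        if sorted(cand_b) < sorted(cand_a):
            chains = (chains[1], chains[0])
            cand_a, cand_b = cand_b, cand_a
        alts.append(PhasingAlternative(chains=chains, candidates=(cand_a, cand_b)))

    if not alts:
        call.status = Status.FAIL_NO_INTERSECTION
        call.reason = "EAG member sets do not intersect under any pairing"
        return call
    alts.sort(key=lambda alt: tuple(sorted(map(sorted, alt.candidates))))
    call.alternatives = alts
    call.phenotype = _call_phenotype(alts)
    return call


# --- resolution and phenotype -----------------------------------------------

def phenotype_of(pair: tuple[str, str]) -> str:
    """ABO phenotype of an allele pair: A and B are codominant, O recessive."""
    bgs = {blood_group_of(pair[0]), blood_group_of(pair[1])}
    if bgs == {"A", "B"}:
        return "AB"
    if "A" in bgs:
        return "A"
    if "B" in bgs:
        return "B"
    return "O"


def _alt_phenotype(alt: PhasingAlternative) -> str | None:
    bg_sets = [{blood_group_of(a) for a in slot} for slot in alt.candidates]
    if any(len(s) != 1 for s in bg_sets):
        return None
    return phenotype_of((next(iter(alt.candidates[0])), next(iter(alt.candidates[1]))))

def _call_phenotype(alts: Sequence[PhasingAlternative]) -> str | None:
    phenos = {_alt_phenotype(a) for a in alts}
    if len(phenos) == 1 and None not in phenos:
        return phenos.pop()
    return None


_LEVELS_HIGH_TO_LOW: list[Resolution] = [
    Resolution.full,
    Resolution.field3,
    Resolution.field2,
    Resolution.allele_group,
    Resolution.subgroup,
    Resolution.blood_group,
]


def classify_resolution(
    call: GenotypeCall, group_table: AlleleGroupTable
) -> Resolution | None:
    """Highest level at which the call is single-valued and consistent.

    A level is achieved when, projecting every candidate allele to that level
    (full name, third/second field, allele group, subgroup, blood group),
    each slot collapses to one label and all phasing alternatives agree on
    the same unordered label pair.  Returns ``None`` when even the blood
    group is undetermined.
    """
    if call.status != Status.OK or not call.alternatives:
        return None

    projections = {
        Resolution.full: lambda a: a,
        Resolution.field3: field3_of,
        Resolution.field2: field2_of,
        Resolution.allele_group: lambda a: group_table.group_of.get(a, a),
        Resolution.subgroup: subgroup_of,
        Resolution.blood_group: blood_group_of,
    }
    for level in _LEVELS_HIGH_TO_LOW:
        proj = projections[level]
        pairs = set()
        ok = True
        for alt in call.alternatives:
            labels = []
            for slot in alt.candidates:
                projected = {proj(a) for a in slot}
                if len(projected) != 1:
                    ok = False
                    break
                labels.append(projected.pop())
            if not ok:
                break
            pairs.add(frozenset((labels[0], labels[1])) if labels[0] != labels[1] else frozenset((labels[0],)))
        if ok and len(pairs) == 1:
            return level
    return None
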