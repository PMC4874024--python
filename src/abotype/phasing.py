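"""Hardy-Weinberg scoring and disambiguation of phasing alternatives.

When a call admits more than one phasing alternative, each alternative is a
candidate genotype whose population probability follows Hardy-Weinberg
proportions (2·θi·θj for heterozygotes, θi² for homozygotes) under the
allele-group frequencies θ.  The ratio of these probabilities — the relative
likelihood — quantifies how safely the rarer alternative can be discarded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

from .genotyper import GenotypeCall, PhasingAlternative, Status
from .nomenclature import subgroup_of
from .refdb import ReferenceDB

Pair = tuple[str, str]


@dataclass(frozen=True)
class AmbiguityCase:
    """One EAG-composition pattern explained by more than one genotype.

    ``genotypes`` is ordered by decreasing HWE probability; ``pair_a`` is the
    most likely genotype and ``pair_b`` the runner-up.  ``case_frequency`` is
    the HWE-expected population frequency of encountering this ambiguous
    pattern (sum over all constituent genotype probabilities).
    """

    genotypes: tuple[Pair, ...]
    case_frequency: float
    relative_likelihood: float
    subgroup_relevant: bool

    @property
    def pair_a(self) -> Pair:
        return self.genotypes[0]

    @property
    def pair_b(self) -> Pair:
        return self.genotypes[1]


def hwe_genotype_prob(pair: Pair, freqs: Mapping[str, float]) -> float:
    """Hardy-Weinberg probability of an unordered genotype: 2θiθj or θi²."""
    g1, g2 = pair
    try:
        t1, t2 = freqs[g1], freqs[g2]
    except KeyError as exc:
        raise KeyError(f"no frequency for allele group {exc.args[0]!r}") from None
    return t1 * t1 if g1 == g2 else 2.0 * t1 * t2


def relative_likelihood(pair_a: Pair, pair_b: Pair, freqs: Mapping[str, float]) -> float:
    """P(pair_a)/P(pair_b) under HWE.  Scale-invariant in the frequencies.

    The factor 2 cancels when both genotypes are heterozygous; homozygous
    alternatives keep their θ² form.  A zero-probability denominator yields
    ``+inf`` with a warning.
    """
    pa = hwe_genotype_prob(pair_a, freqs)
    pb = hwe_genotype_prob(pair_b, freqs)
    if pb == 0.0:
        warnings.warn("zero-probability denominator in relative likelihood", stacklevel=2)
        return math.inf
    return pa / pb


def rounded_relative_likelihood(pair_a: Pair, pair_b: Pair, freqs: Mapping[str, float]) -> int:
    """Reporting helper: relative likelihood rounded to the nearest integer."""
    return round(relative_likelihood(pair_a, pair_b, freqs))


# --- call resolution ---------------------------------------------------------

def _alternative_prob(
    alt: PhasingAlternative, db: ReferenceDB, freqs: Mapping[str, float]
) -> float | None:
    """HWE probability of an alternative at allele-group granularity.

    Each slot's candidate set is a union of complete allele groups (groups
    are indistinguishable across all amplicons); the slot frequency is the
    sum of its groups' frequencies.  Returns None when a group has no
    frequency, meaning the alternative cannot be scored.
    """
    group_of = db.group_table.group_of
    slot_groups = [sorted({group_of.get(a, a) for a in slot}) for slot in alt.candidates]
    try:
        t = [sum(freqs[g] for g in gs) for gs in slot_groups]
    except KeyError:
        return None
    if slot_groups[0] == slot_groups[1]:
        return t[0] * t[0]
    return 2.0 * t[0] * t[1]


def resolve_call(
    call: GenotypeCall,
    db: ReferenceDB,
    freqs: Mapping[str, float],
    ratio_threshold: float = 1000.0,
) -> GenotypeCall:
    """Discard phasing alternatives that are implausible under HWE.

    When the most likely alternative is at least ``ratio_threshold`` times
    more probable than another, the latter is dropped and recorded in
    ``discarded`` with its ratio.  Ties are never discarded, and an
    alternative that cannot be scored (missing frequency) is always kept.
    Resolution and phenotype are recomputed on the survivors.
    """
    from .genotyper import _call_phenotype, classify_resolution

    if call.status != Status.OK or len(call.alternatives) < 2:
        return call
    probs = [_alternative_prob(alt, db, freqs) for alt in call.alternatives]
    scored = [p for p in probs if p is not None]
    if not scored:
        return call
    best = max(scored)
    kept: list[PhasingAlternative] = []
    discarded: list[tuple[PhasingAlternative, float]] = []
    for alt, p in zip(call.alternatives, probs):
        if p is None or p == best:
            kept.append(alt)
        elif p > 0 and best / p < ratio_threshold:
            kept.append(alt)
        else:
            discarded.append((alt, math.inf if p == 0 else best / p))
    out = GenotypeCall(
        sample_id=call.sample_id,
        status=call.status,
        alternatives=kept,
        novel_hits=call.novel_hits,
        reason=call.reason,
        discarded=call.discarded + discarded,
    )
    out.phenotype = _call_phenotype(kept)
    out.resolution = classify_resolution(out, db.group_table)
    return out


# --- ambiguity census --------------------------------------------------------

def _genotype_signature(db: ReferenceDB, g1: str, g2: str) -> tuple:
    """Observed per-amplicon sequence multiset for an allele-group genotype."""
    return tuple(
        tuple(sorted((db.group_region_seq(g1, amp), db.group_region_seq(g2, amp))))
        for amp in db.amplicon_ids
    )


def ambiguity_census(
    db: ReferenceDB, freqs: Mapping[str, float] | None = None
) -> list[AmbiguityCase]:
    """Enumerate every EAG-composition pattern with more than one genotype.

    All unordered allele-group pairs are mapped to their observed sequence
    multisets; patterns explained by > 1 genotype become ambiguity cases.
    With frequencies given, cases carry their HWE-expected frequency and the
    best-vs-runner-up relative likelihood, and are sorted by case frequency
    descending; genotypes containing a group without a frequency score 0.
    """
    groups = sorted(db.group_table.groups)
    by_sig: dict[tuple, list[Pair]] = {}
    for i, g1 in enumerate(groups):
        for g2 in groups[i:]:
            by_sig.setdefault(_genotype_signature(db, g1, g2), []).append((g1, g2))

    def prob(pair: Pair) -> float:
        if freqs is None:
            return 0.0
        try:
            return hwe_genotype_prob(pair, freqs)
        except KeyError:
            return 0.0

    cases: list[AmbiguityCase] = []
    for sig, genos in by_sig.items():
        if len(genos) < 2:
            continue
        genos = sorted(genos, key=lambda p: (-prob(p), p))
        probs = [prob(p) for p in genos]
        case_freq = float(sum(probs))
        rl = probs[0] / probs[1] if probs[1] > 0 else math.inf
        subgroup_sets = {
            frozenset(subgroup_of(g.rstrip("*")) for g in pair) for pair in genos
        }
        cases.append(
            AmbiguityCase(
                genotypes=tuple(genos),
                case_frequency=case_freq,
                relative_likelihood=rl,
                subgroup_relevant=len(subgroup_sets) > 1,
            )
        )
    cases.sort(key=lambda c: (-c.case_frequency, c.genotypes))
    return cases


def projected_error_rate(case_frequency: float, rel_likelihood: float) -> float:
    """Theoretical mistyping rate from always discarding the rarer alternative.

    Approximately case_frequency / relative_likelihood: the population
    frequency of the ambiguous pattern divided by the odds against the
    discarded genotype.
    """
    if not math.isfinite(rel_likelihood) or rel_likelihood <= 0:
        return 0.0
    return case_frequency / rel_likelihood
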