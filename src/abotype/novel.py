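"""Novel-allele candidate tracking, replicate confirmation, and rate projection.

An amplicon sequence with no exact reference match flags the sample as a
novel-allele candidate.  A candidate is *confirmed* only when an independent
replicate run yields the identical sequence at the same amplicon — PCR or
sequencing artifacts are overwhelmingly unlikely to recur identically.
Population-level incidence is projected by transferring the confirmation
rate of the replicated subset onto all flagged samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

ReplicateStatus = str  # "unconfirmed" | "confirmed" | "refuted"


@dataclass
class NovelCandidate:
    sample_id: str
    amplicon_id: str
    sequence: str
    closest: tuple[str, ...] = ()
    mismatch_positions: tuple[int, ...] = ()
    replicate_status: ReplicateStatus = "unconfirmed"


def confirm_candidates(
    first_run: Iterable[NovelCandidate],
    replicate_run: Iterable[NovelCandidate],
) -> list[NovelCandidate]:
    """Classify first-run candidates against an independent replicate.

    confirmed: the replicate shows the identical sequence at the same
    amplicon of the same sample; refuted: the sample was replicated at that
    amplicon but the sequence differs (or no novel sequence recurred);
    unconfirmed: no replicate data for that sample/amplicon.
    """
    rep_seqs: dict[tuple[str, str], set[str]] = {}
    for cand in replicate_run:
        rep_seqs.setdefault((cand.sample_id, cand.amplicon_id), set()).add(cand.sequence)
    rep_samples = {key for key in rep_seqs}
    rep_sample_ids = {sid for sid, _ in rep_samples}
    out = []
    for cand in first_run:
        key = (cand.sample_id, cand.amplicon_id)
        if key in rep_seqs and cand.sequence in rep_seqs[key]:
            status = "confirmed"
        elif cand.sample_id in rep_sample_ids:
            status = "refuted"
        else:
            status = "unconfirmed"
        out.append(
            NovelCandidate(
                sample_id=cand.sample_id,
                amplicon_id=cand.amplicon_id,
                sequence=cand.sequence,
                closest=cand.closest,
                mismatch_positions=cand.mismatch_positions,
                replicate_status=status,
            )
        )
    return out


def unique_novel_sequences(candidates: Iterable[NovelCandidate]) -> dict[str, int]:
    """Census of distinct novel sequences with sample support (order-invariant)."""
    seen: dict[str, set[str]] = {}
    for cand in candidates:
        seen.setdefault(cand.sequence, set()).add(cand.sample_id)
    return {seq: len(samples) for seq, samples in sorted(seen.items())}


def project_novel_rate(
    n_flagged: int, n_tested: int, n_confirmed: int, n_total_typed: int
) -> dict[str, float]:
    """Project the population novel-allele rate from a replicated subset.

    The confirmation rate of the replicated subset (confirmed/tested) is
    applied to all flagged samples; the projected count over all typed
    samples gives the population rate.  Assumes the replicated subset is
    representative of the flagged samples (caveat flag on the output).

    Returns raw and presentation-rounded values: the confirmation rate and
    population rate in percent (1 and 2 decimals respectively), the
    projected count to the nearest integer.
    """
    if n_tested == 0:
        raise ZeroDivisionError("confirmation rate undefined: no samples tested")
    if not (n_confirmed <= n_tested <= n_flagged):
        raise ValueError("expected n_confirmed <= n_tested <= n_flagged")
    if n_total_typed <= 0:
        raise ValueError("n_total_typed must be positive")
    rate = n_confirmed / n_tested
    projected = round(n_flagged * rate)
    pop_rate = projected / n_total_typed
    return {
        "confirmation_rate": rate,
        "confirmation_rate_pct": round(100.0 * rate, 1),
        "projected_count": projected,
        "population_rate": pop_rate,
        "population_rate_pct": round(100.0 * pop_rate, 2),
        "subset_not_systematic": True,  # caveat: transfer assumes representativeness
    }
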