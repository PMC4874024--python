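"""Allele-group frequency estimation from (possibly ambiguous) genotype calls.

Samples are tallied by *ambiguity category* — the distinct EAG composition
they present.  An unambiguous category maps to a single allele-group genotype;
an ambiguous one maps to the set G(c) of genotypes that produce the same
observed sequences.  Under Hardy-Weinberg proportions the category
probability is the sum of its constituent genotype probabilities, giving a
multinomial likelihood over categories in the allele-group frequencies θ.

Two estimators share this likelihood:

* ``em_estimate`` — maximum likelihood via expectation-maximization, where
  the E-step distributes each ambiguous count over G(c) proportionally to
  current genotype probabilities and the M-step re-counts allele copies;
* ``gibbs_estimate`` — a data-augmentation Gibbs sampler alternating latent
  genotype assignment for ambiguous observations with conjugate
  Dirichlet draws of θ, reporting the posterior mean and SD per group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotyper import GenotypeCall, Status
from .nomenclature import blood_group_of, subgroup_of
from .phasing import Pair, _genotype_signature
from .refdb import ReferenceDB


@dataclass(frozen=True)
class Category:
    """One ambiguity category: a distinct EAG composition and its genotype set."""

    id: str
    genotypes: tuple[Pair, ...]   # unordered allele-group pairs
    count: int


@dataclass
class ObservationTable:
    """Counts per ambiguity category; categories partition genotype space."""

    categories: list[Category]
    groups: list[str]             # all allele-group identifiers, sorted

    @property
    def n_samples(self) -> int:
        return sum(c.count for c in self.categories)


@dataclass
class FrequencyVector:
    """Allele-group frequency estimates on the simplex."""

    groups: list[str]
    theta: np.ndarray                      # point estimate (MLE or posterior mean)
    posterior_sd: np.ndarray | None = None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.groups, map(float, self.theta)))

    def sd_dict(self) -> dict[str, float]:
        if self.posterior_sd is None:
            return {g: 0.0 for g in self.groups}
        return dict(zip(self.groups, map(float, self.posterior_sd)))


@dataclass
class EstimatorConfig:
    dirichlet_alpha: float = 1.0
    burn_in: int = 10_000
    samples: int = 10_000
    seed: int = 0
    em_tol: float = 1e-10
    em_max_iter: int = 10_000

    def __post_init__(self):
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if self.burn_in <= 0 or self.samples <= 0:
            raise ValueError("burn_in and samples must be positive")


# --- category partition ------------------------------------------------------

def category_partition(db: ReferenceDB) -> list[tuple[tuple, tuple[Pair, ...]]]:
    """All (signature, G(c)) pairs: genotype space partitioned by EAG composition.

    Cached on the DB instance (the partition is a pure function of the
    reference).
    """
    cached = getattr(db, "_category_partition", None)
    if cached is not None:
        return cached
    groups = sorted(db.group_table.groups)
    by_sig: dict[tuple, list[Pair]] = {}
    for i, g1 in enumerate(groups):
        for g2 in groups[i:]:
            by_sig.setdefault(_genotype_signature(db, g1, g2), []).append((g1, g2))
    result = sorted(
        ((sig, tuple(sorted(genos))) for sig, genos in by_sig.items()),
        key=lambda item: item[1],
    )
    db._category_partition = result
    return result


def _category_id(genotypes: Sequence[Pair]) -> str:
    head = min(genotypes)
    tag = f"{head[0]}/{head[1]}"
    return tag if len(genotypes) == 1 else tag + f"+{len(genotypes) - 1}"


def _call_signature(call: GenotypeCall, db: ReferenceDB) -> tuple:
    alt = call.alternatives[0]
    seq_by_amp = {0: dict(alt.chains[0]), 1: dict(alt.chains[1])}
    return tuple(
        tuple(sorted((seq_by_amp[0][amp], seq_by_amp[1][amp])))
        for amp in db.amplicon_ids
    )


def build_observation_table(calls: Iterable[GenotypeCall], db: ReferenceDB) -> ObservationTable:
    """Aggregate OK calls into category counts over the full DB partition.

    Zero-count categories are retained so the categories cover genotype space;
    a call whose observed sequences match no category indicates an
    inconsistent DB/call combination and raises.
    """
    partition = category_partition(db)
    index = {sig: i for i, (sig, _) in enumerate(partition)}
    counts = np.zeros(len(partition), dtype=np.int64)
    for call in calls:
        if call.status != Status.OK:
            continue
        sig = _call_signature(call, db)
        if sig not in index:
            raise AssertionError(
                f"call {call.sample_id!r}: observed sequences match no DB category"
            )
        counts[index[sig]] += 1
    categories = [
        Category(id=_category_id(genos), genotypes=genos, count=int(counts[i]))
        for i, (_, genos) in enumerate(partition)
    ]
    return ObservationTable(categories=categories, groups=sorted(db.group_table.groups))


def sample_category_counts(
    db: ReferenceDB, theta: Mapping[str, float], n: int, seed: int
) -> ObservationTable:
    """Draw an HWE population of size n directly at category resolution.

    Statistically identical to sampling n diploid genotypes from θ and
    tallying each into its ambiguity category, but via a single multinomial
    over category probabilities — the fast path for estimator validation at
    large n.
    """
    partition = category_partition(db)
    z = sum(theta.get(g, 0.0) for g in db.group_table.groups)
    if z <= 0:
        raise ValueError("θ has no mass on the DB's allele groups")
    t = np.zeros(len(partition))
    for i, (_, genos) in enumerate(partition):
        for g1, g2 in genos:
            p1, p2 = theta.get(g1, 0.0) / z, theta.get(g2, 0.0) / z
            t[i] += p1 * p1 if g1 == g2 else 2.0 * p1 * p2
    total = t.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"θ-induced category probabilities sum to {total}, expected 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, t / total)
    categories = [
        Category(id=_category_id(genos), genotypes=genos, count=int(counts[i]))
        for i, (_, genos) in enumerate(partition)
    ]
    return ObservationTable(categories=categories, groups=sorted(db.group_table.groups))


def table_from_genotypes(genotypes: Iterable[Pair], db: ReferenceDB) -> ObservationTable:
    """Tally true allele-group genotypes directly into their categories.

    Equivalent to genotyping error-free reads for each sample: a genotype is
    counted under the category whose EAG composition it produces.
    """
    partition = category_partition(db)
    index: dict[Pair, int] = {}
    for i, (_, genos) in enumerate(partition):
        for g in genos:
            index[g] = i
    counts = np.zeros(len(partition), dtype=np.int64)
    for g1, g2 in genotypes:
        pair = (g1, g2) if g1 <= g2 else (g2, g1)
        counts[index[pair]] += 1
    categories = [
        Category(id=_category_id(genos), genotypes=genos, count=int(counts[i]))
        for i, (_, genos) in enumerate(partition)
    ]
    return ObservationTable(categories=categories, groups=sorted(db.group_table.groups))


# --- shared likelihood machinery ---------------------------------------------

class _Arrays:
    """Flattened genotype arrays for vectorized likelihood computations."""

    def __init__(self, table: ObservationTable):
        gidx = {g: i for i, g in enumerate(table.groups)}
        gi, gj, cat, factor = [], [], [], []
        counts = []
        for c_i, cat_ in enumerate(table.categories):
            counts.append(cat_.count)
            for g1, g2 in cat_.genotypes:
                gi.append(gidx[g1])
                gj.append(gidx[g2])
                cat.append(c_i)
                factor.append(1.0 if g1 == g2 else 2.0)
        self.gi = np.asarray(gi, dtype=np.int64)
        self.gj = np.asarray(gj, dtype=np.int64)
        self.cat = np.asarray(cat, dtype=np.int64)
        self.factor = np.asarray(factor)
        self.counts = np.asarray(counts, dtype=np.float64)
        self.n_cat = len(table.categories)
        self.n_groups = len(table.groups)

    def genotype_probs(self, theta: np.ndarray) -> np.ndarray:
        return self.factor * theta[self.gi] * theta[self.gj]

    def category_probs(self, theta: np.ndarray) -> np.ndarray:
        return np.bincount(self.cat, weights=self.genotype_probs(theta), minlength=self.n_cat)

    def expected_copies(self, theta: np.ndarray) -> np.ndarray:
        """E-step: expected allele copies per group given θ."""
        pg = self.genotype_probs(theta)
        pc = np.bincount(self.cat, weights=pg, minlength=self.n_cat)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = pg / pc[self.cat] * self.counts[self.cat]
        w = np.nan_to_num(w)
        copies = np.bincount(self.gi, weights=w, minlength=self.n_groups)
        copies += np.bincount(self.gj, weights=w, minlength=self.n_groups)
        return copies


def _log_likelihood(arr: _Arrays, theta: np.ndarray) -> float:
    pc = arr.category_probs(theta)
    observed = arr.counts > 0
    if np.any(pc[observed] <= 0):
        return -np.inf
    return float(np.sum(arr.counts[observed] * np.log(pc[observed])))


# --- EM ----------------------------------------------------------------------

def em_estimate(table: ObservationTable, config: EstimatorConfig | None = None) -> FrequencyVector:
    """Maximum-likelihood θ via EM over the category multinomial.

    Ambiguous counts are split across G(c) proportionally to current genotype
    probabilities, then onto allele copies; θ is re-set to copies/2N.  The
    log-likelihood is non-decreasing; convergence on its relative change.
    """
    config = config or EstimatorConfig()
    arr = _Arrays(table)
    n = table.n_samples
    if n <= 0:
        raise ValueError("observation table holds no samples")
    theta = np.full(arr.n_groups, 1.0 / arr.n_groups)
    prev_ll = _log_likelihood(arr, theta)
    for _ in range(config.em_max_iter):
        pc = arr.category_probs(theta)
        if np.any((arr.counts > 0) & (pc <= 0)):
            warnings.warn("observed category with zero probability; restarting from uniform")
            theta = np.full(arr.n_groups, 1.0 / arr.n_groups)
            prev_ll = _log_likelihood(arr, theta)
            continue
        copies = arr.expected_copies(theta)
        theta = copies / (2.0 * n)
        ll = _log_likelihood(arr, theta)
        if ll + 1e-9 < prev_ll:
            raise AssertionError("EM log-likelihood decreased")
        if prev_ll != -np.inf and abs(ll - prev_ll) <= config.em_tol * max(1.0, abs(prev_ll)):
            prev_ll = ll
            break
        prev_ll = ll
    return FrequencyVector(groups=list(table.groups), theta=theta)


# --- Gibbs -------------------------------------------------------------------

def gibbs_estimate(table: ObservationTable, config: EstimatorConfig | None = None) -> FrequencyVector:
    """Posterior mean/SD of θ via data-augmentation Gibbs sampling.

    Each sweep (i) assigns every ambiguous observation a latent genotype drawn
    from G(c) with probability proportional to its HWE probability under the
    current θ, and (ii) draws θ from the conjugate
    Dirichlet(alpha + allele copy counts).  Draws after burn-in are summarized
    by their mean and standard deviation; a fixed seed reproduces the chain
    bit-for-bit.
    """
    config = config or EstimatorConfig()
    arr = _Arrays(table)
    n = table.n_samples
    if n <= 0:
        raise ValueError("observation table holds no samples")
    rng = np.random.default_rng(config.seed)
    k = arr.n_groups

    # copies fixed by unambiguous categories; ambiguous ones resampled per sweep
    base_copies = np.zeros(k)
    ambiguous: list[tuple[float, np.ndarray, np.ndarray, np.ndarray]] = []
    for c_i in range(arr.n_cat):
        mask = arr.cat == c_i
        count = arr.counts[c_i]
        if count == 0:
            continue
        gi, gj, factor = arr.gi[mask], arr.gj[mask], arr.factor[mask]
        if mask.sum() == 1:
            base_copies[gi[0]] += count
            base_copies[gj[0]] += count
        else:
            ambiguous.append((count, gi, gj, factor))

    theta = rng.dirichlet(np.full(k, config.dirichlet_alpha))
    total = config.burn_in + config.samples
    mean_acc = np.zeros(k)
    m2_acc = np.zeros(k)
    kept = 0
    for it in range(total):
        copies = base_copies.copy()
        for count, gi, gj, factor in ambiguous:
            w = factor * theta[gi] * theta[gj]
            s = w.sum()
            if s <= 0:
                w = np.full(len(w), 1.0 / len(w))
            else:
                w = w / s
            split = rng.multinomial(int(count), w)
            np.add.at(copies, gi, split)
            np.add.at(copies, gj, split)
        theta = rng.dirichlet(config.dirichlet_alpha + copies)
        if it >= config.burn_in:
            kept += 1
            delta = theta - mean_acc
            mean_acc += delta / kept
            m2_acc += delta * (theta - mean_acc)
    sd = np.sqrt(m2_acc / kept) if kept > 1 else np.zeros(k)
    return FrequencyVector(groups=list(table.groups), theta=mean_acc, posterior_sd=sd)


# --- hierarchical summaries --------------------------------------------------

def _subgroup_key(identifier: str) -> str:
    return subgroup_of(identifier.rstrip("*"))


def aggregate_to_subgroups(group_values: Mapping[str, float]) -> dict[str, float]:
    """Sum allele/allele-group values into serological subgroup totals."""
    out: dict[str, float] = {}
    for gid, v in group_values.items():
        out[_subgroup_key(gid)] = out.get(_subgroup_key(gid), 0.0) + v
    return dict(sorted(out.items()))


def aggregate_to_blood_groups(subgroup_values: Mapping[str, float]) -> dict[str, float]:
    """Sum subgroup values into A/B/O blood-group totals."""
    out: dict[str, float] = {}
    for sub, v in subgroup_values.items():
        bg = sub[0].upper()
        out[bg] = out.get(bg, 0.0) + v
    return dict(sorted(out.items()))


def summarize_frequencies(
    freqs: FrequencyVector | Mapping[str, float], db: ReferenceDB | None = None
) -> pd.DataFrame:
    """Hierarchical report: group, subgroup and blood-group frequencies.

    Returns a tidy frame with columns (level, id, subgroup, blood_group,
    frequency, sd).  Subgroup rows sum their member groups; blood-group rows
    sum their subgroups; the grand total equals the sum of the input.
    """
    if isinstance(freqs, FrequencyVector):
        values = freqs.as_dict()
        sds = freqs.sd_dict()
    else:
        values = dict(freqs)
        sds = {g: float("nan") for g in values}
    rows = []
    for gid, v in sorted(values.items()):
        rows.append(
            {
                "level": "group",
                "id": gid,
                "subgroup": _subgroup_key(gid),
                "blood_group": blood_group_of(gid.rstrip("*")),
                "frequency": v,
                "sd": sds.get(gid, float("nan")),
            }
        )
    sub = aggregate_to_subgroups(values)
    for sid, v in sub.items():
        rows.append(
            {
                "level": "subgroup",
                "id": sid,
                "subgroup": sid,
                "blood_group": sid[0].upper(),
                "frequency": v,
                "sd": float("nan"),
            }
        )
    for bid, v in aggregate_to_blood_groups(sub).items():
        rows.append(
            {
                "level": "blood_group",
                "id": bid,
                "subgroup": "",
                "blood_group": bid,
                "frequency": v,
                "sd": float("nan"),
            }
        )
    return pd.DataFrame(rows)
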