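"""Allele reference database: loading, filtering, EAG and allele-group construction.

The reference is a set of ABO alleles with per-exon sequences (exons 6 and 7
in the standard assays).  For each amplicon — a coordinate window within an
exon — alleles sharing an identical window sequence form an Exon Allele Group
(EAG), the unit of per-amplicon matching.  Alleles indistinguishable across
*all* configured amplicons are collapsed into allele groups whose identifier
is the lexicographically smallest member name with a trailing asterisk.
"""

from __future__ import annotations

import hashlib
import json
import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from Bio import SeqIO

from .nomenclature import parse_allele_name

_DNA = set("ACGT")


class ReferenceError(ValueError):
    """Malformed reference input (names, duplicates, incomplete sequences)."""


@dataclass
class AlleleRecord:
    """One reference allele: parsed name, per-exon sequence, phenotype metadata."""

    name: str
    blood_group: str
    subgroup: str
    fields: tuple[str, ...]
    exon_seqs: dict[str, str] = field(default_factory=dict)
    phenotype_known: bool = True
    phenotype_uncertain: bool = False
    seq_complete: dict[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class AmpliconDef:
    """Amplicon window within an exon; internal coordinates 0-based half-open."""

    id: str
    exon: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"amplicon {self.id}: end must exceed start")

    @property
    def expected_length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_config(cls, id: str, exon: str, start_1based: int, end_inclusive: int) -> "AmpliconDef":
        """Build from the 1-based inclusive coordinates used in config files."""
        return cls(id=id, exon=str(exon), start=start_1based - 1, end=end_inclusive)


@dataclass(frozen=True)
class ExonAlleleGroup:
    """Alleles sharing one amplicon-window sequence."""

    amplicon_id: str
    sequence: str
    members: frozenset[str]


@dataclass
class AlleleGroupTable:
    """Partition of retained alleles into cross-amplicon indistinguishability groups."""

    groups: dict[str, frozenset[str]]            # identifier -> member allele names
    spans_subgroups: dict[str, bool]
    group_of: dict[str, str] = field(default_factory=dict)  # allele -> identifier

    def __post_init__(self):
        if not self.group_of:
            self.group_of = {a: gid for gid, mem in self.groups.items() for a in mem}

    def __len__(self) -> int:
        return len(self.groups)


def load_reference(fasta_path, metadata_path) -> list[AlleleRecord]:
    """Load allele records from a multi-FASTA plus a metadata table.

    FASTA headers are ``>ALLELE|EXON`` (e.g. ``>A1.01.01|6``).  The metadata
    CSV/TSV has columns ``allele``, ``phenotype_known``, ``phenotype_uncertain``
    and optional ``incomplete_exons`` (semicolon-separated exon ids whose
    sequence is present but truncated).  Every allele in the metadata appears
    in the output; a missing exon sequence is recorded as
    ``seq_complete[exon] = False``, not treated as an error.
    """
    seqs: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        header = rec.description.split()[0]
        if "|" not in header:
            raise ReferenceError(f"FASTA header {header!r} lacks '|exon' suffix")
        allele, exon = header.rsplit("|", 1)
        seq = str(rec.seq).upper()
        bad = set(seq) - _DNA
        if bad:
            raise ReferenceError(f"allele {allele!r} exon {exon}: non-ACGT characters {sorted(bad)}")
        if allele in seqs and exon in seqs[allele]:
            raise ReferenceError(f"duplicate sequence entry for ({allele!r}, exon {exon})")
        seqs.setdefault(allele, {})[exon] = seq

    path = Path(metadata_path)
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    records: list[AlleleRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter=delim):
            name = row["allele"].strip()
            if name in seen:
                raise ReferenceError(f"duplicate metadata row for allele {name!r}")
            seen.add(name)
            try:
                parsed = parse_allele_name(name)
            except ValueError as exc:
                raise ReferenceError(f"malformed allele name in metadata: {name!r}") from exc
            exon_seqs = seqs.get(name, {})
            incomplete = {
                e.strip() for e in (row.get("incomplete_exons") or "").split(";") if e.strip()
            }
            seq_complete = {
                exon: (exon in exon_seqs and exon not in incomplete)
                for exon in set(exon_seqs) | incomplete
            }
            records.append(
                AlleleRecord(
                    name=name,
                    blood_group=parsed.blood_group,
                    subgroup=parsed.subgroup,
                    fields=parsed.fields,
                    exon_seqs=exon_seqs,
                    phenotype_known=_truthy(row.get("phenotype_known", "1")),
                    phenotype_uncertain=_truthy(row.get("phenotype_uncertain", "0")),
                    seq_complete=seq_complete,
                )
            )
    orphans = set(seqs) - seen
    if orphans:
        raise ReferenceError(f"FASTA alleles missing from metadata: {sorted(orphans)[:5]}")
    return records


def _truthy(value) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes", "y"}


# --- filtering ---------------------------------------------------------------

FilterRule = tuple[str, Callable[[AlleleRecord], bool]]


def standard_filter_rules(required_exons: Sequence[str] = ("6", "7")) -> list[FilterRule]:
    """Exclusion predicates applied in order; the first match is recorded.

    Mirrors the reference-curation policy: drop alleles missing exon 6/7
    sequence, alleles with a truncated exon 7, alleles of unknown phenotype
    and alleles of uncertain phenotype.
    """
    required = tuple(required_exons)

    def missing_seq(rec: AlleleRecord) -> bool:
        return any(exon not in rec.exon_seqs for exon in required)

    def exon7_gap(rec: AlleleRecord) -> bool:
        return not rec.seq_complete.get("7", "7" not in required)

    return [
        ("missing_exon_6_7", missing_seq),
        ("exon7_incomplete", exon7_gap),
        ("phenotype_unknown", lambda rec: not rec.phenotype_known),
        ("phenotype_uncertain", lambda rec: rec.phenotype_uncertain),
    ]


def filter_reference(
    alleles: Iterable[AlleleRecord], rules: Sequence[FilterRule]
) -> tuple[list[AlleleRecord], list[tuple[AlleleRecord, str]]]:
    """Split alleles into (retained, excluded-with-reason).

    Each excluded record carries the first matching rule's reason code;
    retained + excluded always partition the input.
    """
    retained: list[AlleleRecord] = []
    excluded: list[tuple[AlleleRecord, str]] = []
    for rec in alleles:
        for code, pred in rules:
            if pred(rec):
                excluded.append((rec, code))
                break
        else:
            retained.append(rec)
    return retained, excluded


# --- EAGs and allele groups --------------------------------------------------

def region_sequence(rec: AlleleRecord, amp: AmpliconDef) -> str:
    """Amplicon-window substring of the allele's exon sequence."""
    seq = rec.exon_seqs.get(amp.exon)
    if seq is None or not rec.seq_complete.get(amp.exon, False):
        raise ReferenceError(
            f"allele {rec.name!r} lacks complete exon {amp.exon} sequence for amplicon {amp.id}"
        )
    if len(seq) < amp.end:
        raise ReferenceError(
            f"allele {rec.name!r}: exon {amp.exon} sequence shorter than amplicon {amp.id} window"
        )
    return seq[amp.start : amp.end]


def build_eags(
    retained: Sequence[AlleleRecord], amplicon_defs: Sequence[AmpliconDef]
) -> dict[str, list[ExonAlleleGroup]]:
    """Group alleles by identical amplicon-window sequence, per amplicon.

    The EAGs of one amplicon partition the retained alleles; two alleles share
    an EAG iff their window substrings are equal.
    """
    out: dict[str, list[ExonAlleleGroup]] = {}
    for amp in amplicon_defs:
        by_seq: dict[str, set[str]] = {}
        for rec in retained:
            by_seq.setdefault(region_sequence(rec, amp), set()).add(rec.name)
        out[amp.id] = [
            ExonAlleleGroup(amp.id, seq, frozenset(members))
            for seq, members in sorted(by_seq.items())
        ]
    return out


def collapse_allele_groups(
    retained: Sequence[AlleleRecord], amplicon_defs: Sequence[AmpliconDef]
) -> AlleleGroupTable:
    """Merge alleles identical across ALL amplicon windows into allele groups.

    The group identifier is the lexicographically smallest member name, with a
    trailing asterisk when the group has more than one member.
    ``spans_subgroups`` is set when members belong to different subgroups.
    """
    by_sig: dict[tuple[str, ...], list[AlleleRecord]] = {}
    for rec in retained:
        sig = tuple(region_sequence(rec, amp) for amp in amplicon_defs)
        by_sig.setdefault(sig, []).append(rec)
    groups: dict[str, frozenset[str]] = {}
    spans: dict[str, bool] = {}
    for members in by_sig.values():
        names = sorted(m.name for m in members)
        gid = names[0] + ("*" if len(names) > 1 else "")
        groups[gid] = frozenset(names)
        spans[gid] = len({m.subgroup for m in members}) > 1
    return AlleleGroupTable(groups=groups, spans_subgroups=spans)


# --- indexed bundle ----------------------------------------------------------

class ReferenceDB:
    """Frozen, indexed reference: retained alleles, amplicons, EAGs, allele groups."""

    def __init__(self, retained: Sequence[AlleleRecord], amplicon_defs: Sequence[AmpliconDef]):
        self.alleles: dict[str, AlleleRecord] = {r.name: r for r in retained}
        self.amplicons: list[AmpliconDef] = sorted(amplicon_defs, key=lambda a: a.id)
        self.eags = build_eags(retained, self.amplicons)
        self.eag_by_seq: dict[tuple[str, str], ExonAlleleGroup] = {
            (amp_id, eag.sequence): eag for amp_id, lst in self.eags.items() for eag in lst
        }
        self.group_table = collapse_allele_groups(retained, self.amplicons)
        self._region_cache: dict[tuple[str, str], str] = {}

    @property
    def amplicon_ids(self) -> list[str]:
        return [a.id for a in self.amplicons]

    def amplicon(self, amp_id: str) -> AmpliconDef:
        for a in self.amplicons:
            if a.id == amp_id:
                return a
        raise KeyError(f"unknown amplicon {amp_id!r}")

    def region_seq(self, allele: str, amp_id: str) -> str:
        key = (allele, amp_id)
        if key not in self._region_cache:
            self._region_cache[key] = region_sequence(self.alleles[allele], self.amplicon(amp_id))
        return self._region_cache[key]

    def group_region_seq(self, group_id: str, amp_id: str) -> str:
        """Window sequence of an allele group (identical for all members)."""
        member = min(self.group_table.groups[group_id])
        return self.region_seq(member, amp_id)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    # serialization — JSON bundle keyed by content so calls are traceable
    def to_dict(self) -> dict:
        return {
            "amplicons": [
                {"id": a.id, "exon": a.exon, "start": a.start, "end": a.end}
                for a in self.amplicons
            ],
            "alleles": [
                {
                    "name": r.name,
                    "exon_seqs": r.exon_seqs,
                    "phenotype_known": r.phenotype_known,
                    "phenotype_uncertain": r.phenotype_uncertain,
                    "seq_complete": r.seq_complete,
                }
                for r in sorted(self.alleles.values(), key=lambda r: r.name)
            ],
        }

    def save(self, path) -> None:
        doc = self.to_dict()
        doc["content_hash"] = self.content_hash()
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ReferenceDB":
        amps = [AmpliconDef(a["id"], a["exon"], a["start"], a["end"]) for a in doc["amplicons"]]
        recs = []
        for r in doc["alleles"]:
            parsed = parse_allele_name(r["name"])
            recs.append(
                AlleleRecord(
                    name=r["name"],
                    blood_group=parsed.blood_group,
                    subgroup=parsed.subgroup,
                    fields=parsed.fields,
                    exon_seqs=dict(r["exon_seqs"]),
                    phenotype_known=r.get("phenotype_known", True),
                    phenotype_uncertain=r.get("phenotype_uncertain", False),
                    seq_complete=dict(r["seq_complete"]),
                )
            )
        return cls(recs, amps)

    @classmethod
    def load(cls, path) -> "ReferenceDB":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_amplicon_config(path) -> list[AmpliconDef]:
    """Read amplicon definitions from JSON: [{id, exon, start, end}] 1-based inclusive."""
    doc = json.loads(Path(path).read_text())
    return [AmpliconDef.from_config(a["id"], a["exon"], a["start"], a["end"]) for a in doc]
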