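"""Parsing and projection of dbRBC-style ABO allele names.

An allele name such as ``ABO*A1.01.01.1`` carries, in order: an optional
``ABO*`` locus prefix, a subgroup token (``A1``, ``Ax``, ``B1``, ``O`` ...),
and up to three further numeric name fields separated by dots.  The blood
group (A, B or O) is the leading letter of the subgroup token.  For O alleles
the subgroup token is the bare letter ``O`` and the serological subgroup
(O1, O2, O48, ...) is derived from the second name field.

Allele-group identifiers use the same grammar with a trailing asterisk
(``A1.01.01*``) marking a group that collapses several indistinguishable
alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

BLOOD_GROUPS = ("A", "B", "O")


class AlleleNameError(ValueError):
    """Raised when an allele identifier does not follow the ABO grammar."""


@dataclass(frozen=True)
class AlleleName:
    """Parsed ABO allele (or allele-group) identifier."""

    raw: str
    blood_group: str          # A, B or O
    subgroup: str             # e.g. A1, Ax, B1, O1, O2, O48
    fields: tuple[str, ...]   # ordered name fields, subgroup token included
    is_group: bool            # trailing-asterisk group identifier

    @property
    def name(self) -> str:
        """Identifier without locus prefix, asterisk preserved for groups."""
        return ".".join(self.fields) + ("*" if self.is_group else "")

    def field_prefix(self, n: int) -> str:
        """Join of the first *n* name fields (resolution projections)."""
        return ".".join(self.fields[:n])


@lru_cache(maxsize=4096)
def parse_allele_name(name: str) -> AlleleName:
    """Parse a dbRBC-style ABO allele name.

    The ``ABO*`` prefix is optional; a single trailing ``*`` marks an
    allele-group identifier.  Raises :class:`AlleleNameError` on names that
    do not start with an A/B/O subgroup token.
    """
    raw = name
    body = name.strip()
    if body.upper().startswith("ABO*"):
        body = body[4:]
    is_group = body.endswith("*")
    if is_group:
        body = body[:-1]
    if not body:
        raise AlleleNameError(f"empty allele name: {raw!r}")
    fields = tuple(body.split("."))
    token = fields[0]
    bg = token[0].upper()
    if bg not in BLOOD_GROUPS:
        raise AlleleNameError(
            f"allele name {raw!r}: subgroup token {token!r} does not start with A, B or O"
        )
    if bg == "O" and token.upper() == "O":
        # O.02.14 -> subgroup O2; O.48.01 -> O48
        if len(fields) < 2:
            raise AlleleNameError(f"O allele {raw!r} lacks a subgroup name field")
        sub_field = fields[1]
        try:
            subgroup = "O" + str(int(sub_field))
        except ValueError:
            subgroup = "O" + sub_field
    else:
        subgroup = token
    return AlleleName(raw=raw, blood_group=bg, subgroup=subgroup, fields=fields, is_group=is_group)


def blood_group_of(name: str) -> str:
    return parse_allele_name(name).blood_group


def subgroup_of(name: str) -> str:
    return parse_allele_name(name).subgroup


def field2_of(name: str) -> str:
    """Second-field projection, e.g. A1.01.01.1 -> A1.01, O.02.14 -> O.02."""
    return parse_allele_name(name).field_prefix(2)


def field3_of(name: str) -> str:
    """Third-field projection, e.g. A1.01.01.1 -> A1.01.01."""
    return parse_allele_name(name).field_prefix(3)
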