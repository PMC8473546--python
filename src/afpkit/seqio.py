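"""Protein FASTA input/output and sequence validation.

Sequences are validated against the 20-letter standard amino-acid
alphabet before any descriptor is computed.  Two sanitization policies
are supported: ``strict`` (any nonstandard character is an error) and
``tolerant`` (the common ambiguity/nonstandard codes B, Z, X, U, O, J
plus ``*`` and ``-`` are stripped with a warning, but a record losing
more than 5% of its residues is rejected so composition features cannot
be silently corrupted).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
#: Characters silently removable under the tolerant policy.
REMOVABLE = set("BZXUOJ*-")
#: Maximum fraction of residues the tolerant policy may remove.
MAX_REMOVED_FRACTION = 0.05
#: Minimum sequence length accepted at load time (AA-x-AA needs 3).
MIN_LENGTH = 3

POSITIVE, NEGATIVE = 1, 0

_OS_TAG = re.compile(r"\bOS=(.+?)(?=\s+[A-Z]{2}=|$)")
_BRACKET = re.compile(r"\[([^\[\]]+)\]\s*$")


class SeqIOError(ValueError):
    """Base class for sequence I/O errors."""


class EmptyInputError(SeqIOError):
    """A FASTA file contained no entries."""


class InvalidResidueError(SeqIOError):
    """A sequence contains characters outside the accepted alphabet."""


class RecordRejectedError(SeqIOError):
    """Tolerant sanitization removed more than the allowed fraction."""


class DuplicateIdError(SeqIOError):
    """Two records in one collection share an id."""


@dataclass
class SequenceRecord:
    """One protein sequence with identity metadata."""

    id: str
    sequence: str
    species: str = ""
    label: Optional[int] = None       # POSITIVE, NEGATIVE or None
    reviewed: Optional[bool] = None

    def __len__(self) -> int:
        return len(self.sequence)

    def with_label(self, label: Optional[int]) -> "SequenceRecord":
        return replace(self, label=label)


def sanitize_sequence(raw: str, policy: str = "tolerant") -> str:
    """Uppercase and validate a raw sequence string.

    strict: any character outside the 20-letter alphabet raises
    :class:`InvalidResidueError`.  tolerant: characters in
    ``{B,Z,X,U,O,J,*,-}`` are removed (warned); anything else nonstandard
    still raises; removing more than 5% of residues raises
    :class:`RecordRejectedError`.
    """
    if not raw:
        raise InvalidResidueError("empty sequence")
    if policy not in ("strict", "tolerant"):
        raise ValueError(f"unknown policy {policy!r}")
    seq = raw.upper().replace(" ", "").replace("\n", "")
    bad = set(seq) - ALPHABET
    if policy == "strict":
        if bad:
            raise InvalidResidueError(f"nonstandard residues {sorted(bad)}")
        return seq
    unexpected = bad - REMOVABLE
    if unexpected:
        raise InvalidResidueError(f"unrecognized characters {sorted(unexpected)}")
    cleaned = "".join(c for c in seq if c in ALPHABET)
    removed = len(seq) - len(cleaned)
    if removed:
        if removed > MAX_REMOVED_FRACTION * len(seq):
            raise RecordRejectedError(
                f"{removed}/{len(seq)} residues nonstandard (> "
                f"{MAX_REMOVED_FRACTION:.0%}); record rejected"
            )
        logger.warning("removed %d nonstandard residue(s)", removed)
    return cleaned


def parse_species(description: str) -> str:
    """Extract an organism name from a FASTA description line.

    Supports UniProt ``OS=...`` tags and a trailing ``[Species name]``
    bracket; returns "" when neither is present.
    """
    m = _OS_TAG.search(description)
    if m:
        return m.group(1).strip()
    m = _BRACKET.search(description.strip())
    if m:
        return m.group(1).strip()
    return ""


def _parse_reviewed(header_id: str) -> Optional[bool]:
    if header_id.startswith("sp|"):
        return True
    if header_id.startswith("tr|"):
        return False
    return None


def read_fasta(
    path: str | Path,
    label: Optional[int] = None,
    policy: str = "tolerant",
    min_length: int = MIN_LENGTH,
) -> list[SequenceRecord]:
    """Read a protein FASTA file into validated records.

    The header token before the first whitespace becomes the record id;
    species is parsed from an ``OS=`` tag or bracketed suffix when
    present.  ``label``, if given, is applied to every record.  Records
    failing sanitization or shorter than ``min_length`` are skipped with
    a warning.  A file with zero FASTA entries raises
    :class:`EmptyInputError`; duplicate ids raise
    :class:`DuplicateIdError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    n_entries = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        n_entries += 1
        try:
            seq = sanitize_sequence(str(entry.seq), policy=policy)
        except RecordRejectedError as exc:
            logger.warning("skipping %s: %s", entry.id, exc)
            continue
        if len(seq) < min_length:
            logger.warning("skipping %s: length %d < %d", entry.id, len(seq), min_length)
            continue
        if entry.id in seen:
            raise DuplicateIdError(f"duplicate id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(SequenceRecord(
            id=entry.id,
            sequence=seq,
            species=parse_species(entry.description),
            label=label,
            reviewed=_parse_reviewed(entry.id),
        ))
    if n_entries == 0:
        raise EmptyInputError(f"no FASTA entries in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as wrapped FASTA, preserving ids and order."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.species:
                header += f" OS={rec.species}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_sidecar_tsv(path: str | Path) -> dict[str, dict]:
    """Read a metadata sidecar TSV with columns id, species[, reviewed]."""
    meta: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        if "id" not in cols:
            raise SeqIOError(f"sidecar {path} lacks an 'id' column")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            entry: dict = {}
            if "species" in cols and len(parts) > cols["species"]:
                entry["species"] = parts[cols["species"]]
            if "reviewed" in cols and len(parts) > cols["reviewed"]:
                entry["reviewed"] = parts[cols["reviewed"]].strip().lower() in (
                    "1", "true", "yes")
            meta[parts[cols["id"]]] = entry
    return meta


def apply_sidecar(records: list[SequenceRecord],
                  meta: dict[str, dict]) -> list[SequenceRecord]:
    """Fill species/reviewed fields from a sidecar table (id-matched)."""
    out = []
    for rec in records:
        extra = meta.get(rec.id)
        if extra:
            rec = replace(rec,
                          species=extra.get("species", rec.species),
                          reviewed=extra.get("reviewed", rec.reviewed))
        out.append(rec)
    return out
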