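"""Global protein sequence descriptors: AAC, DC, AA-x-AA and CTD.

The feature vector used throughout this package concatenates four
descriptor families computed on the primary sequence alone:

* **AAC** — amino-acid composition, the frequency of each of the 20
  standard residues (20 dimensions).
* **DC** — dipeptide composition, the frequency of each ordered pair of
  adjacent residues among the ``L - 1`` adjacent windows (400 dimensions).
* **AA-x-AA** — gapped-pair composition, the frequency of each ordered
  residue pair separated by exactly one arbitrary residue among the
  ``L - 2`` windows (400 dimensions).  Several antifreeze-protein
  families (notably the Ala-rich type-1 AFPs and the Ala-Ala-Thr repeat
  glycoproteins) carry this pattern on their ice-binding faces, which is
  why it is included alongside the plain dipeptide composition.
* **CTD** — composition/transition/distribution encoding.  For each of
  eight physicochemical properties every residue is mapped to one of
  three classes (Group 1/2/3); the sequence becomes a digit string over
  ``{1,2,3}`` from which three summaries are computed: class frequencies
  (composition, 3 values), frequencies of adjacent cross-class pairs
  (transition, 3 values: 1/2, 1/3, 2/3) and the sequence-relative
  positions of the first, 25%, 50%, 75% and 100% occurrences of each
  class (distribution, 15 values).  Eight properties give
  ``8 * (3 + 3 + 15) = 168`` dimensions.

Total: ``20 + 400 + 400 + 168 = 988`` named features in a fixed block
order, so vectors are comparable across runs and trained models are
portable.

Feature names follow the field's conventions: three-letter residue codes
for AAC (``"Cys"``), ``"Ala-Ala"`` for dipeptides, ``"Ala-x-Ala"`` for
gapped pairs, and ``"<Property> Composition; Group 2"`` /
``"<Property> Transition; Group 1/2"`` /
``"<Property> Distribution; Group 1 (50%)"`` for the CTD block.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "THREE_LETTER",
    "PropertyGrouping",
    "FeatureVector",
    "DEFAULT_GROUPINGS",
    "load_groupings",
    "save_groupings",
    "compute_aac",
    "compute_dc",
    "compute_gapped",
    "encode_property_string",
    "ctd_composition",
    "ctd_transition",
    "ctd_distribution",
    "compute_ctd",
    "feature_names",
    "assemble_feature_vector",
    "extract_features",
    "GroupingError",
]

#: Canonical (alphabetical one-letter) residue order used by every block.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_LETTER = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
}

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Distribution anchor fractions and their display labels.
_DISTRIBUTION_FRACTIONS = (
    ("first", None),
    ("25%", 0.25),
    ("50%", 0.50),
    ("75%", 0.75),
    ("100%", 1.00),
)


class GroupingError(ValueError):
    """A property grouping does not partition the 20 standard residues."""


@dataclass(frozen=True)
class PropertyGrouping:
    """A named 3-way partition of the 20 standard amino acids.

    Parameters
    ----------
    property_name
        Machine identifier, e.g. ``"polarizability"``.
    display_name
        Human-readable name used in feature labels, e.g. ``"Polarizability"``.
    groups
        Ordered triple of residue strings (Group 1, Group 2, Group 3).
        Together they must cover each of the 20 standard residues exactly
        once; order within a group is irrelevant.
    """

    property_name: str
    display_name: str
    groups: tuple[str, str, str]
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for gi, members in enumerate(self.groups, start=1):
            for aa in members:
                if aa not in _AA_INDEX:
                    raise GroupingError(
                        f"{self.property_name}: non-standard residue {aa!r}"
                    )
                if aa in seen:
                    raise GroupingError(
                        f"{self.property_name}: residue {aa} assigned to both "
                        f"group {seen[aa]} and group {gi}"
                    )
                seen[aa] = gi
        missing = set(AMINO_ACIDS) - set(seen)
        if missing:
            raise GroupingError(
                f"{self.property_name}: residues not covered: {sorted(missing)}"
            )
        object.__setattr__(self, "_index", dict(seen))

    def group_of(self, residue: str) -> int:
        """1-based group index of a residue."""
        return self._index[residue]


def _g(name: str, display: str, g1: str, g2: str, g3: str) -> PropertyGrouping:
    return PropertyGrouping(name, display, (g1, g2, g3))


#: The eight default property groupings, in the fixed property order used
#: for the CTD block.  The seven classical properties use the standard
#: Dubchak-style three-class partitions; the polarizability partition is
#: additionally pinned down by the worked example in the test suite.
#: Disorder propensity splits residues into disorder-promoting,
#: order-promoting and neutral sets.  Alternative groupings can be loaded
#: from a JSON file with :func:`load_groupings`.
DEFAULT_GROUPINGS: tuple[PropertyGrouping, ...] = (
    _g("hydrophobicity", "Hydrophobicity", "RKEDQN", "GASTPHY", "CLVIMFW"),
    _g("normalized_vdwv", "Normalized VDWV", "GASTPDC", "NVEQIL", "MHKFRYW"),
    _g("polarity", "Polarity", "LIFWCMVY", "PATGS", "HQRKNED"),
    _g("charge", "Charge", "KR", "ANCQGHILMFPSTWYV", "DE"),
    _g("secondary_structure", "Secondary Structure", "EALMQKRH", "VIYCWFT", "GNPSD"),
    _g("solvent_accessibility", "Solvent Accessibility", "ALFCGIVW", "RKQEND", "MSPTHY"),
    _g("polarizability", "Polarizability", "GASDT", "CPNVEQIL", "KMHFRYW"),
    _g("disorder_propensity", "Disorder Propensity", "ARSQEGKP", "WCFIYVLN", "HMTD"),
)


def load_groupings(path: str | Path) -> tuple[PropertyGrouping, ...]:
    """Load property groupings from a JSON config.

    The file maps property name to ``{"display_name": str, "groups":
    [str, str, str]}``; property order in the file fixes the CTD block
    order.  Each grouping is validated as a partition on load.
    """
    with open(path) as fh:
        raw = json.load(fh)
    return tuple(
        PropertyGrouping(name, entry.get("display_name", name.title()),
                         tuple(entry["groups"]))
        for name, entry in raw.items()
    )


def save_groupings(groupings: Iterable[PropertyGrouping], path: str | Path) -> None:
    """Write groupings to the JSON format read by :func:`load_groupings`."""
    payload = {
        g.property_name: {"display_name": g.display_name, "groups": list(g.groups)}
        for g in groupings
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def _check_sequence(seq: str, min_length: int, op: str) -> None:
    if len(seq) < min_length:
        raise ValueError(f"{op} requires length >= {min_length}, got {len(seq)}")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"{op}: non-standard residues {sorted(bad)}; sanitize first")


def compute_aac(seq: str) -> np.ndarray:
    """Amino-acid composition: ``count(a) / L`` in canonical residue order."""
    _check_sequence(seq, 1, "AAC")
    vec = np.zeros(20)
    for aa in seq:
        vec[_AA_INDEX[aa]] += 1.0
    return vec / len(seq)


def compute_dc(seq: str) -> np.ndarray:
    """Dipeptide composition: adjacent ordered-pair counts over ``L - 1``."""
    _check_sequence(seq, 2, "DC")
    vec = np.zeros(400)
    for a, b in zip(seq, seq[1:]):
        vec[20 * _AA_INDEX[a] + _AA_INDEX[b]] += 1.0
    return vec / (len(seq) - 1)


def compute_gapped(seq: str) -> np.ndarray:
    """AA-x-AA composition: ordered pairs one residue apart, over ``L - 2``."""
    _check_sequence(seq, 3, "AA-x-AA")
    vec = np.zeros(400)
    for a, b in zip(seq, seq[2:]):
        vec[20 * _AA_INDEX[a] + _AA_INDEX[b]] += 1.0
    return vec / (len(seq) - 2)


def encode_property_string(seq: str, grouping: PropertyGrouping) -> str:
    """Map each residue to its group digit, e.g. ``"MAG..." -> "311..."``."""
    _check_sequence(seq, 1, "property encoding")
    return "".join(str(grouping.group_of(aa)) for aa in seq)


def ctd_composition(encoded: str) -> np.ndarray:
    """Class frequencies of the digit string: ``count(g) / L`` for g=1,2,3."""
    if not encoded:
        raise ValueError("composition requires a non-empty encoding")
    L = len(encoded)
    return np.array([encoded.count(d) for d in "123"]) / L


def ctd_transition(encoded: str) -> np.ndarray:
    """Cross-class adjacent-pair frequencies, ordered (1/2, 1/3, 2/3).

    Transition a/b counts pairs ``ab`` and ``ba`` alike, normalized by the
    number of adjacent pairs ``L - 1``.
    """
    if len(encoded) < 2:
        raise ValueError("transition requires length >= 2")
    counts = {frozenset(p): 0 for p in (("1", "2"), ("1", "3"), ("2", "3"))}
    for a, b in zip(encoded, encoded[1:]):
        if a != b:
            counts[frozenset((a, b))] += 1
    denom = len(encoded) - 1
    return np.array([
        counts[frozenset(("1", "2"))],
        counts[frozenset(("1", "3"))],
        counts[frozenset(("2", "3"))],
    ]) / denom


def _anchor_index(fraction: float | None, n: int) -> int:
    """1-based occurrence index for a distribution anchor.

    ``None`` (the "first" anchor) maps to occurrence 1; a fraction ``f``
    maps to ``max(1, round(f * n))`` with half rounded away from zero, so
    for 8 occurrences the 25/50/75/100% anchors hit occurrences 2/4/6/8.
    """
    if fraction is None:
        return 1
    return max(1, int(math.floor(fraction * n + 0.5)))


def ctd_distribution(encoded: str) -> np.ndarray:
    """Sequence-relative positions of class-occurrence anchors.

    For each class g with occurrences at 1-based positions
    ``p_1 < ... < p_n`` the five values are ``p_k / L`` for the anchor
    occurrences k of the first, 25%, 50%, 75% and 100% anchors.  A class
    absent from the string contributes five zeros.  Output is
    group-major: 5 values for Group 1, then Group 2, then Group 3.
    """
    if not encoded:
        raise ValueError("distribution requires a non-empty encoding")
    L = len(encoded)
    out = np.zeros(15)
    for gi, digit in enumerate("123"):
        positions = [i + 1 for i, d in enumerate(encoded) if d == digit]
        if not positions:
            continue
        for fi, (_, frac) in enumerate(_DISTRIBUTION_FRACTIONS):
            k = _anchor_index(frac, len(positions))
            out[5 * gi + fi] = positions[k - 1] / L
    return out


def compute_ctd(
    seq: str, groupings: Sequence[PropertyGrouping] = DEFAULT_GROUPINGS
) -> np.ndarray:
    """Full CTD block: per property, composition(3) + transition(3) +
    distribution(15), concatenated over the properties in order."""
    _check_sequence(seq, 2, "CTD")
    parts = []
    for grouping in groupings:
        enc = encode_property_string(seq, grouping)
        parts.append(ctd_composition(enc))
        parts.append(ctd_transition(enc))
        parts.append(ctd_distribution(enc))
    return np.concatenate(parts)


def feature_names(
    groupings: Sequence[PropertyGrouping] = DEFAULT_GROUPINGS,
) -> list[str]:
    """The 988 feature names in fixed block order AAC + DC + AA-x-AA + CTD."""
    names = [THREE_LETTER[a] for a in AMINO_ACIDS]
    names += [f"{THREE_LETTER[a]}-{THREE_LETTER[b]}"
              for a in AMINO_ACIDS for b in AMINO_ACIDS]
    names += [f"{THREE_LETTER[a]}-x-{THREE_LETTER[b]}"
              for a in AMINO_ACIDS for b in AMINO_ACIDS]
    for grouping in groupings:
        disp = grouping.display_name
        names += [f"{disp} Composition; Group {g}" for g in (1, 2, 3)]
        names += [f"{disp} Transition; Group {ab}" for ab in ("1/2", "1/3", "2/3")]
        for g in (1, 2, 3):
            names += [f"{disp} Distribution; Group {g} ({label})"
                      for label, _ in _DISTRIBUTION_FRACTIONS]
    return names


@dataclass
class FeatureVector:
    """A 988-dimensional descriptor vector with parallel feature names."""

    values: np.ndarray
    names: list[str]

    #: Block layout (name, width) in concatenation order.
    LAYOUT = (("AAC", 20), ("DC", 400), ("AA-x-AA", 400), ("CTD", 168))

    def __post_init__(self) -> None:
        expected = sum(w for _, w in self.LAYOUT)
        if len(self.values) != expected or len(self.names) != expected:
            raise ValueError(
                f"feature vector must have {expected} values and names, got "
                f"{len(self.values)}/{len(self.names)}"
            )

    def block(self, name: str) -> np.ndarray:
        """Return one descriptor block by name ("AAC", "DC", "AA-x-AA", "CTD")."""
        start = 0
        for block_name, width in self.LAYOUT:
            if block_name == name:
                return self.values[start:start + width]
            start += width
        raise KeyError(name)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def assemble_feature_vector(
    seq: str, groupings: Sequence[PropertyGrouping] = DEFAULT_GROUPINGS
) -> FeatureVector:
    """Compute the full named 988-d vector for one validated sequence.

    Requires length >= 3 (the AA-x-AA block is undefined below that).
    """
    _check_sequence(seq, 3, "feature assembly")
    values = np.concatenate([
        compute_aac(seq),
        compute_dc(seq),
        compute_gapped(seq),
        compute_ctd(seq, groupings),
    ])
    return FeatureVector(values=values, names=feature_names(groupings))


def extract_features(
    records,
    groupings: Sequence[PropertyGrouping] = DEFAULT_GROUPINGS,
) -> pd.DataFrame:
    """Feature matrix for a collection of records.

    ``records`` is an iterable of objects with ``.id`` and ``.sequence``
    (see :class:`afpkit.seqio.SequenceRecord`).  Returns a DataFrame
    indexed by record id with the 988 named feature columns.
    """
    names = feature_names(groupings)
    rows, ids = [], []
    for rec in records:
        rows.append(assemble_feature_vector(rec.sequence, groupings).values)
        ids.append(rec.id)
    return pd.DataFrame(np.asarray(rows).reshape(len(rows), -1) if rows else
                        np.empty((0, len(names))), index=ids, columns=names)
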