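"""Dataset curation, splitting and synthetic sequence generation.

Mirrors the curation style used to build antifreeze-protein benchmark
sets from UniProtKB: pick one representative sequence per species to
remove taxonomic bias, remove redundancy by greedy identity clustering
(CD-HIT style), draw an equal-sized random negative set so training is
always balanced, and split either 64/16/20 into train/validation/test or
into stratified cross-validation folds.

The synthetic generator produces positive sequences that caricature the
three classical AFP composition signatures — Ala-rich (type-1 AFPs),
Cys-rich (type-2 AFPs) and Ala-Ala-Thr repeats (antifreeze
glycoproteins) — against negatives drawn from background amino-acid
frequencies, so the whole pipeline is testable without any database
download.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from sklearn.model_selection import StratifiedKFold

from . import features as _features
from .seqio import NEGATIVE, POSITIVE, SequenceRecord, write_fasta

__all__ = [
    "LabeledDataset",
    "Cluster",
    "CurationError",
    "select_species_representatives",
    "pairwise_identity",
    "greedy_identity_cluster",
    "run_cdhit",
    "sample_balanced_negatives",
    "split_train_valid_test",
    "make_cv_folds",
    "generate_synthetic_dataset",
    "write_manifest",
    "write_clusters",
    "BACKGROUND_FREQUENCIES",
]


class CurationError(ValueError):
    """A curation precondition was violated."""


@dataclass
class LabeledDataset:
    """Records + binary labels, with an optional extracted feature matrix."""

    records: list[SequenceRecord]
    labels: np.ndarray
    features: Optional[pd.DataFrame] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.records):
            raise CurationError("labels length must equal records length")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise CurationError("record ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord],
                     provenance: str = "") -> "LabeledDataset":
        labels = np.array([r.label if r.label is not None else -1 for r in records])
        if (labels < 0).any():
            raise CurationError("all records must carry a binary label")
        return cls(list(records), labels, provenance=provenance)

    def extract_features(self, groupings=_features.DEFAULT_GROUPINGS) -> pd.DataFrame:
        """Compute (and cache) the 988-column feature matrix."""
        if self.features is None:
            self.features = _features.extract_features(self.records, groupings)
        return self.features

    def subset(self, indices: Sequence[int], note: str = "") -> "LabeledDataset":
        indices = list(indices)
        feats = self.features.iloc[indices] if self.features is not None else None
        return LabeledDataset(
            records=[self.records[i] for i in indices],
            labels=self.labels[indices],
            features=feats,
            provenance=(self.provenance + ("; " + note if note else "")).strip("; "),
        )


# ---------------------------------------------------------------------------
# curation

def select_species_representatives(
    records: Sequence[SequenceRecord], rule: str = "longest"
) -> list[SequenceRecord]:
    """One representative record per distinct species.

    ``longest`` keeps the longest sequence per species (ties broken by
    lexicographically smallest id); ``first`` keeps the first in input
    order.  Output preserves the order in which species first appear.
    Idempotent: applying it twice is a no-op.
    """
    if rule not in ("longest", "first"):
        raise ValueError(f"unknown rule {rule!r}")
    by_species: dict[str, SequenceRecord] = {}
    for rec in records:
        if not rec.species:
            raise CurationError(f"record {rec.id} has no species annotation")
        best = by_species.get(rec.species)
        if best is None:
            by_species[rec.species] = rec
        elif rule == "longest" and (
            len(rec) > len(best) or (len(rec) == len(best) and rec.id < best.id)
        ):
            by_species[rec.species] = rec
    return list(by_species.values())


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = 0
_aligner.open_gap_score = 0
_aligner.extend_gap_score = 0


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matched residues / shorter length.

    The alignment maximizes exact matches without penalizing gaps, which
    makes the score a deterministic upper envelope of match count; at
    fixture scale this emulates CD-HIT's identity well enough for
    redundancy removal.
    """
    if not a or not b:
        raise ValueError("identity of an empty sequence is undefined")
    matches = _aligner.score(a, b)
    return matches / min(len(a), len(b))


@dataclass
class Cluster:
    representative: str
    members: list[str] = field(default_factory=list)


def greedy_identity_cluster(
    records: Sequence[SequenceRecord], identity_cutoff: float
) -> list[Cluster]:
    """CD-HIT-style greedy incremental clustering.

    Sequences are visited in order of decreasing length (ties by id); a
    sequence joins the first cluster whose founding representative it
    matches at >= ``identity_cutoff``, else founds a new cluster.
    """
    if not records:
        raise CurationError("clustering requires at least one record")
    if not (0 < identity_cutoff <= 1):
        raise ValueError(f"identity cutoff must lie in (0, 1], got {identity_cutoff}")
    order = sorted(records, key=lambda r: (-len(r), r.id))
    clusters: list[Cluster] = []
    seqs: dict[str, str] = {r.id: r.sequence for r in records}
    for rec in order:
        for cl in clusters:
            if pairwise_identity(rec.sequence, seqs[cl.representative]) >= identity_cutoff:
                cl.members.append(rec.id)
                break
        else:
            clusters.append(Cluster(representative=rec.id, members=[rec.id]))
    return clusters


def run_cdhit(fasta_in: str | Path, fasta_out: str | Path,
              identity_cutoff: float, binary: str = "cd-hit") -> None:
    """Optional hook to an external CD-HIT binary (never required)."""
    subprocess.run(
        [binary, "-i", str(fasta_in), "-o", str(fasta_out),
         "-c", str(identity_cutoff)],
        check=True,
    )


def sample_balanced_negatives(
    negative_pool: Sequence[SequenceRecord], n: int, seed: int
) -> list[SequenceRecord]:
    """Uniform sample without replacement of ``n`` negatives, seeded.

    Matches the balanced-training convention: as many negatives as there
    are positives.  Pool order of the chosen records is preserved.
    """
    if len(negative_pool) < n:
        raise CurationError(
            f"negative pool has {len(negative_pool)} < {n} requested")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(negative_pool), size=n, replace=False))
    return [negative_pool[i].with_label(NEGATIVE) for i in idx]


# ---------------------------------------------------------------------------
# splitting

def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    exact = [f * n for f in fractions]
    counts = [int(x) for x in exact]
    remainders = sorted(range(len(fractions)),
                        key=lambda i: (-(exact[i] - counts[i]), i))
    for i in range(n - sum(counts)):
        counts[remainders[i]] += 1
    return counts


def split_train_valid_test(
    dataset: LabeledDataset,
    fractions: tuple[float, float, float] = (0.64, 0.16, 0.20),
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Stratified random train/validation/test partition.

    Sizes follow ``fractions`` by largest-remainder rounding within each
    class, so a balanced n=100 gives exactly 64/16/20.  Reproducible
    under ``seed``; raises if any split ends up empty.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if any(f <= 0 for f in fractions):
        raise ValueError("all fractions must be positive")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(dataset.labels):
        idx = np.flatnonzero(dataset.labels == cls)
        rng.shuffle(idx)
        counts = _largest_remainder(len(idx), fractions)
        start = 0
        for p, c in enumerate(counts):
            parts[p].extend(idx[start:start + c].tolist())
            start += c
    if any(len(p) == 0 for p in parts):
        raise CurationError(
            f"split of n={len(dataset)} leaves an empty part under {fractions}")
    names = ("train", "valid", "test")
    return tuple(
        dataset.subset(sorted(p), note=f"{name} split {frac:.0%} seed={seed}")
        for p, name, frac in zip(parts, names, fractions)
    )


def make_cv_folds(
    dataset: LabeledDataset, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold index pairs; test blocks partition the dataset."""
    if len(dataset) < k:
        raise CurationError(f"need at least k={k} records, got {len(dataset)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train, test)
            for train, test in skf.split(np.zeros(len(dataset)), dataset.labels)]


# ---------------------------------------------------------------------------
# synthetic fixtures

#: Swiss-Prot-style background amino-acid frequencies (renormalized).
BACKGROUND_FREQUENCIES = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0687,
}

_PROFILES = ("ala_rich", "cys_rich", "thr_repeat", "mixed")
#: Multiplier applied to the boosted residue's background weight.
_ALA_BOOST = 6.0
_CYS_BOOST = 8.0
#: Probability of emitting an Ala-Ala-Thr repeat unit in thr_repeat mode.
_AAT_UNIT_PROB = 0.65


def _freq_vector(boost: dict[str, float] | None = None) -> np.ndarray:
    aas = _features.AMINO_ACIDS
    w = np.array([BACKGROUND_FREQUENCIES[a] for a in aas])
    if boost:
        for aa, mult in boost.items():
            w[aas.index(aa)] *= mult
    return w / w.sum()


def _draw_background(rng: np.random.Generator, length: int,
                     probs: np.ndarray) -> str:
    aas = np.frombuffer(_features.AMINO_ACIDS.encode(), dtype="S1")
    return b"".join(rng.choice(aas, size=length, p=probs)).decode()


def _draw_thr_repeat(rng: np.random.Generator, length: int,
                     probs: np.ndarray) -> str:
    # interleave AAT repeat units with background residues
    out: list[str] = []
    n = 0
    while n < length:
        if rng.random() < _AAT_UNIT_PROB:
            out.append("AAT")
            n += 3
        else:
            out.append(_draw_background(rng, 1, probs))
            n += 1
    return "".join(out)[:length]


def generate_synthetic_dataset(
    n_pos: int,
    n_neg: int,
    motif_profile: str = "mixed",
    length_range: tuple[int, int] = (60, 300),
    label_noise: float = 0.0,
    seed: int = 0,
) -> LabeledDataset:
    """Generate a labeled fixture dataset with planted AFP-like signal.

    Positives are drawn from one of three composition caricatures —
    ``ala_rich`` (6x Ala weight), ``cys_rich`` (8x Cys weight) or
    ``thr_repeat`` (Ala-Ala-Thr repeat units interleaved with background
    residues); ``mixed`` picks a profile per sequence uniformly.
    Negatives follow background frequencies.  ``label_noise`` flips that
    fraction of labels (rounded), chosen uniformly.  Fully reproducible
    under ``seed``.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    if motif_profile not in _PROFILES:
        raise ValueError(f"profile must be one of {_PROFILES}")
    if not (0 <= label_noise < 1):
        raise ValueError("label_noise must lie in [0, 1)")
    lo, hi = length_range
    if lo < 3 or hi < lo:
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    background = _freq_vector()
    emitters = {
        "ala_rich": lambda L: _draw_background(rng, L, _freq_vector({"A": _ALA_BOOST})),
        "cys_rich": lambda L: _draw_background(rng, L, _freq_vector({"C": _CYS_BOOST})),
        "thr_repeat": lambda L: _draw_thr_repeat(rng, L, background),
    }
    base_profiles = [p for p in _PROFILES if p != "mixed"]

    records: list[SequenceRecord] = []
    for i in range(n_pos):
        profile = (motif_profile if motif_profile != "mixed"
                   else base_profiles[rng.integers(len(base_profiles))])
        L = int(rng.integers(lo, hi + 1))
        records.append(SequenceRecord(
            id=f"POS{i + 1:04d}",
            sequence=emitters[profile](L),
            species=f"Synthospecies positivus {i + 1}",
            label=POSITIVE,
        ))
    for i in range(n_neg):
        L = int(rng.integers(lo, hi + 1))
        records.append(SequenceRecord(
            id=f"NEG{i + 1:04d}",
            sequence=_draw_background(rng, L, background),
            species=f"Synthospecies negativus {i + 1}",
            label=NEGATIVE,
        ))

    n_flip = int(round(label_noise * len(records)))
    if n_flip:
        flip = rng.choice(len(records), size=n_flip, replace=False)
        for i in flip:
            records[i] = records[i].with_label(1 - records[i].label)

    return LabeledDataset.from_records(
        records,
        provenance=(f"synthetic profile={motif_profile} n_pos={n_pos} "
                    f"n_neg={n_neg} lengths={length_range} "
                    f"noise={label_noise} seed={seed}"),
    )


# ---------------------------------------------------------------------------
# tabular output

def write_manifest(dataset: LabeledDataset, path: str | Path,
                   splits: Optional[dict[str, str]] = None) -> None:
    """Write a TSV manifest (id, label, species[, split])."""
    rows = []
    for rec, lab in zip(dataset.records, dataset.labels):
        row = {"id": rec.id, "label": int(lab), "species": rec.species}
        if splits is not None:
            row["split"] = splits.get(rec.id, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_clusters(clusters: Sequence[Cluster], path: str | Path) -> None:
    """Write clustering output as TSV (cluster_id, member_id, is_representative)."""
    rows = [
        {"cluster_id": ci, "member_id": m,
         "is_representative": int(m == cl.representative)}
        for ci, cl in enumerate(clusters) for m in cl.members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_dataset_fasta(dataset: LabeledDataset, path: str | Path) -> None:
    write_fasta(dataset.records, path)
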