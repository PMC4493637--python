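"""Sequence and site-table IO, 25-mer fragment extraction, splitting, sampling.

Coordinates are 1-based inclusive in all user-facing tables (FASTA positions,
site TSVs, prediction output); 0-based indices are used internally.

A *fragment* is the 25-residue window spanning offsets -12..+12 around a
candidate serine/threonine/tyrosine.  Window positions falling outside the
protein are filled with the pad symbol ``-``, which is reserved for
truncation and excluded from every encoding computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from oryzaphos.errors import ConfigError, DataError

logger = logging.getLogger(__name__)

WINDOW = 25
HALF_WINDOW = 12
PAD = "-"
WILDCARD = "X"
CENTER_RESIDUES = ("S", "T", "Y")

#: residues outside the 20-letter standard alphabet; collapsed to the wildcard
_NONSTANDARD = set("BJOUZ*")

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SiteAnnotation:
    """One annotated candidate site: protein, 1-based position, residue, label."""

    protein_id: str
    position: int
    residue: str
    label: str
    accessible: bool | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DataError(
                f"site position must be >= 1, got {self.position} for {self.protein_id}"
            )
        if self.residue not in CENTER_RESIDUES:
            raise DataError(
                f"site residue must be one of S/T/Y, got {self.residue!r} "
                f"at {self.protein_id}:{self.position}"
            )
        if self.label not in ("positive", "negative"):
            raise DataError(f"label must be 'positive' or 'negative', got {self.label!r}")


@dataclass(frozen=True)
class Fragment:
    """A 25-mer window centered on a candidate S/T/Y with provenance and label."""

    sequence: str
    center_residue: str
    protein_id: str
    position: int
    label: str

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW:
            raise DataError(
                f"fragment must be {WINDOW} characters, got {len(self.sequence)} "
                f"({self.protein_id}:{self.position})"
            )
        if self.sequence[HALF_WINDOW] != self.center_residue:
            raise DataError(
                f"fragment center mismatch at {self.protein_id}:{self.position}: "
                f"window has {self.sequence[HALF_WINDOW]!r}, expected {self.center_residue!r}"
            )
        if self.center_residue not in CENTER_RESIDUES:
            raise DataError(
                f"center residue must be S/T/Y, got {self.center_residue!r} "
                f"at {self.protein_id}:{self.position}"
            )
        core = self.sequence.strip(PAD)
        if PAD in core:
            raise DataError(
                f"pad symbols must be a contiguous prefix/suffix "
                f"({self.protein_id}:{self.position})"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, self.position)


@dataclass(frozen=True)
class SplitSpec:
    """Independent-test split and training class-ratio configuration.

    ``ratio`` is the requested (+):(-) proportion of the training set; the
    class in excess is downsampled, positives are never upsampled.
    """

    test_fraction: float = 1.0 / 3.0
    ratio: tuple[int, int] = (1, 1)
    seed: int = 0
    by_protein: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError(f"test_fraction must be in (0,1), got {self.test_fraction}")
        if min(self.ratio) < 1:
            raise ConfigError(f"ratio components must be >= 1, got {self.ratio}")


def _normalize_sequence(raw: str) -> str:
    seq = raw.upper()
    return "".join(WILDCARD if c in _NONSTANDARD else c for c in seq)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{protein_id: sequence}``.

    Ids are the first whitespace-delimited header token.  Sequences are
    upper-cased and non-standard residues (B, J, O, U, Z, *) are mapped to
    the wildcard ``X``.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA file not found: {path}")
    text = path.read_text()
    if not text.strip():
        raise DataError(f"empty FASTA file: {path}")
    if not text.lstrip().startswith(">"):
        raise DataError(f"not FASTA content (no leading '>'): {path}")
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise DataError(f"duplicate protein id {record.id!r} in {path}")
        sequences[record.id] = _normalize_sequence(str(record.seq))
    if not sequences:
        raise DataError(f"no FASTA records parsed from {path}")
    return sequences


def read_site_annotations(path: str | Path) -> list[SiteAnnotation]:
    """Read the tab-delimited site table (protein_id, position, residue, label)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str})
    required = {"protein_id", "position", "residue", "label"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"site table {path} missing columns: {sorted(missing)}")
    return [
        SiteAnnotation(
            protein_id=row.protein_id,
            position=int(row.position),
            residue=str(row.residue),
            label=str(row.label),
        )
        for row in df.itertuples()
    ]


def read_accessibility(path: str | Path) -> dict[tuple[str, int], bool]:
    """Read per-site solvent-accessibility flags keyed by (protein_id, position)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str})
    required = {"protein_id", "position", "accessible"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"accessibility table {path} missing columns: {sorted(missing)}")
    return {
        (row.protein_id, int(row.position)): bool(int(row.accessible))
        for row in df.itertuples()
    }


def extract_fragment(
    sequence: str,
    position: int,
    pad_symbol: str = PAD,
    protein_id: str = "?",
) -> str:
    """Extract the 25-character window centered at a 1-based position.

    Positions outside the protein are filled with ``pad_symbol``.  The
    center residue must be S, T or Y.
    """
    if not 1 <= position <= len(sequence):
        raise DataError(
            f"position {position} outside protein {protein_id} (length {len(sequence)})"
        )
    center = sequence[position - 1]
    if center not in CENTER_RESIDUES:
        raise DataError(
            f"residue at {protein_id}:{position} is {center!r}, not a candidate S/T/Y"
        )
    i = position - 1
    lo, hi = i - HALF_WINDOW, i + HALF_WINDOW + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(sequence))
    core = sequence[max(0, lo) : min(len(sequence), hi)]
    return pad_symbol * left_pad + core + pad_symbol * right_pad


def _dedup(fragments: list[Fragment]) -> list[Fragment]:
    """Drop exact 25-mer duplicates, keeping first by (protein_id, position)."""
    ordered = sorted(fragments, key=lambda f: f.key)
    seen: set[str] = set()
    kept = []
    for frag in ordered:
        if frag.sequence in seen:
            continue
        seen.add(frag.sequence)
        kept.append(frag)
    return kept


def build_datasets(
    sequences: Mapping[str, str],
    annotations: Sequence[SiteAnnotation],
    auto_negatives: bool = True,
    pad_symbol: str = PAD,
) -> tuple[list[Fragment], list[Fragment]]:
    """Compile positive and negative fragment datasets.

    Positives are the annotated phosphosites.  Negatives are annotated
    negative sites plus, when ``auto_negatives``, every S/T/Y residue not
    annotated positive.  Within each class exact duplicate 25-mers are
    removed (first occurrence by (protein_id, position) kept); duplicates
    across classes are kept but logged as conflicts.
    """
    missing = sorted({a.protein_id for a in annotations} - set(sequences))
    if missing:
        raise DataError(f"annotations reference missing proteins: {missing}")

    for ann in annotations:
        actual = sequences[ann.protein_id][ann.position - 1]
        if actual != ann.residue:
            raise DataError(
                f"annotation residue mismatch at {ann.protein_id}:{ann.position}: "
                f"sequence has {actual!r}, annotation says {ann.residue!r}"
            )

    positive_keys = {(a.protein_id, a.position) for a in annotations if a.label == "positive"}
    explicit_negative_keys = {
        (a.protein_id, a.position) for a in annotations if a.label == "negative"
    }

    def make(pid: str, pos: int, label: str) -> Fragment:
        window = extract_fragment(sequences[pid], pos, pad_symbol, protein_id=pid)
        return Fragment(window, sequences[pid][pos - 1], pid, pos, label)

    positives = [make(pid, pos, "positive") for pid, pos in sorted(positive_keys)]

    negative_keys = set(explicit_negative_keys)
    if auto_negatives:
        for pid, seq in sequences.items():
            for i, residue in enumerate(seq):
                if residue in CENTER_RESIDUES and (pid, i + 1) not in positive_keys:
                    negative_keys.add((pid, i + 1))
    negatives = [make(pid, pos, "negative") for pid, pos in sorted(negative_keys)]

    positives = _dedup(positives)
    negatives = _dedup(negatives)

    pos_seqs = {f.sequence for f in positives}
    conflicts = sum(1 for f in negatives if f.sequence in pos_seqs)
    if conflicts:
        logger.warning("%d negative 25-mers identical to a positive 25-mer (kept)", conflicts)
    return positives, negatives


def filter_inaccessible_negatives(
    negatives: Sequence[Fragment],
    accessibility: Mapping[tuple[str, int], bool],
) -> list[Fragment]:
    """Keep only negatives flagged solvent-inaccessible.

    Kinases cannot reach residues buried in the protein core, so buried
    unannotated sites are the most trustworthy negatives.  Negatives with
    no accessibility flag are dropped (counted in a log message).
    """
    kept = []
    unflagged = 0
    for frag in negatives:
        flag = accessibility.get(frag.key)
        if flag is None:
            unflagged += 1
        elif flag is False:
            kept.append(frag)
    if unflagged:
        logger.warning("%d negatives lacked an accessibility flag and were dropped", unflagged)
    return kept


def _split_class(
    fragments: list[Fragment], test_fraction: float, rng: np.random.Generator
) -> tuple[list[Fragment], list[Fragment]]:
    n = len(fragments)
    n_test = int(round(test_fraction * n))
    order = rng.permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [fragments[i] for i in range(n) if i not in test_idx]
    test = [fragments[i] for i in range(n) if i in test_idx]
    return train, test


def _split_class_by_protein(
    fragments: list[Fragment], test_fraction: float, test_proteins: set[str]
) -> tuple[list[Fragment], list[Fragment]]:
    train = [f for f in fragments if f.protein_id not in test_proteins]
    test = [f for f in fragments if f.protein_id in test_proteins]
    return train, test


def split_and_sample(
    positives: Sequence[Fragment],
    negatives: Sequence[Fragment],
    spec: SplitSpec,
) -> tuple[list[Fragment], list[Fragment]]:
    """Hold out an independent test fraction per class, then subsample the
    training pool to the requested (+):(-) ratio.

    Returns ``(train, test)``.  Sampling is uniform without replacement and
    reproducible given ``spec.seed``.  Only the class in excess of the
    requested ratio is downsampled.
    """
    if not positives or not negatives:
        raise DataError("both classes must be non-empty to split")
    positives = list(positives)
    negatives = list(negatives)
    rng = np.random.default_rng(spec.seed)

    if spec.by_protein:
        proteins = sorted({f.protein_id for f in positives} | {f.protein_id for f in negatives})
        n_test_prot = max(1, int(round(spec.test_fraction * len(proteins))))
        order = rng.permutation(len(proteins))
        test_proteins = {proteins[i] for i in order[:n_test_prot]}
        pos_train, pos_test = _split_class_by_protein(positives, spec.test_fraction, test_proteins)
        neg_train, neg_test = _split_class_by_protein(negatives, spec.test_fraction, test_proteins)
        if not pos_train or not neg_train:
            raise DataError("protein-level split left a training class empty; adjust fraction")
    else:
        pos_train, pos_test = _split_class(positives, spec.test_fraction, rng)
        neg_train, neg_test = _split_class(negatives, spec.test_fraction, rng)

    rp, rn = spec.ratio
    scale = min(len(pos_train) / rp, len(neg_train) / rn)
    n_pos_keep = int(scale * rp)
    n_neg_keep = int(scale * rn)
    if n_pos_keep < 1 or n_neg_keep < 1:
        raise DataError(
            f"ratio {rp}:{rn} unsatisfiable from {len(pos_train)} (+) / "
            f"{len(neg_train)} (-) training fragments; "
            f"maximum achievable ratio is {len(pos_train)}:{len(neg_train)}"
        )
    pos_kept = [pos_train[i] for i in sorted(rng.choice(len(pos_train), n_pos_keep, replace=False))]
    neg_kept = [neg_train[i] for i in sorted(rng.choice(len(neg_train), n_neg_keep, replace=False))]

    train = pos_kept + neg_kept
    test = pos_test + neg_test
    return train, test


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_site_annotations(annotations: Iterable[SiteAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(a.protein_id, a.position, a.residue, a.label) for a in annotations],
        columns=["protein_id", "position", "residue", "label"],
    )
    df.to_csv(path, sep="\t", index=False)
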