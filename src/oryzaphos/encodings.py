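"""Fragment encodings: AF, CKSAAP, KNN, and their pairwise combinations.

Three views of the sequence context around a candidate phosphosite:

* **AF** — amino-acid occurrence frequency: 20 values, the fraction of the
  fragment made up by each standard residue.
* **CKSAAP** — composition of k-spaced amino-acid pairs: for each spacing
  k = 0..k_max, the normalized count of each of the 400 ordered residue
  pairs separated by k intervening residues (2400 features at k_max = 5).
* **KNN** — for each of several neighbor fractions, the ratio of the mean
  distance to the nearest negative reference fragments over the mean
  distance to the nearest positive reference fragments, under a
  min-max-normalized BLOSUM62 similarity distance.  Larger values mean the
  query sits closer to the positive class.

Pad (``-``) and wildcard (``X``) characters are excluded from all counts,
denominators and distance positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from oryzaphos.dataset import Fragment, STANDARD_AA
from oryzaphos.errors import ConfigError, DataError

logger = logging.getLogger(__name__)

AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

DEFAULT_K_MAX = 5
DEFAULT_KNN_FRACTIONS = (0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.10)

SCHEMES = ("AF", "KNN", "CKSAAP", "AF-KNN", "AF-CKSAAP", "CKSAAP-KNN")

#: default ratio value when the mean nearest-positive distance is exactly 0
DEFAULT_RATIO_CAP = 100.0


def _sequence_of(fragment: Fragment | str) -> str:
    return fragment.sequence if isinstance(fragment, Fragment) else str(fragment)


def seq_to_codes(sequence: str) -> np.ndarray:
    """Integer codes over the 20-letter alphabet; pad/X/nonstandard -> -1."""
    return np.array([AA_INDEX.get(c, -1) for c in sequence], dtype=np.int64)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Min-max-normalized 20x20 amino-acid similarity lookup in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (20, 20):
            raise ConfigError(f"similarity matrix must be 20x20, got {v.shape}")
        if not np.allclose(v, v.T):
            raise ConfigError("similarity matrix must be symmetric")
        if v.min() < 0 or v.max() > 1:
            raise ConfigError("similarity values must lie in [0, 1]")

    def lookup(self, a: str, b: str) -> float:
        return float(self.values[AA_INDEX[a], AA_INDEX[b]])


def normalize_blosum62() -> SimilarityMatrix:
    """BLOSUM62 over the 20 standard residues, min-max scaled to [0, 1]."""
    blosum = substitution_matrices.load("BLOSUM62")
    raw = np.empty((20, 20))
    for i, a in enumerate(STANDARD_AA):
        for j, b in enumerate(STANDARD_AA):
            raw[i, j] = blosum[a, b]
    lo, hi = raw.min(), raw.max()
    return SimilarityMatrix((raw - lo) / (hi - lo))


def af_layout() -> list[str]:
    return [f"AF:{aa}" for aa in STANDARD_AA]


def cksaap_layout(k_max: int = DEFAULT_K_MAX) -> list[str]:
    return [
        f"CK:{a}{b}:k{k}"
        for k in range(k_max + 1)
        for a in STANDARD_AA
        for b in STANDARD_AA
    ]


def knn_layout(fractions: Sequence[float] = DEFAULT_KNN_FRACTIONS) -> list[str]:
    return [f"KNN:f{f:g}" for f in fractions]


@dataclass(frozen=True)
class EncodingSpec:
    """Which encoding scheme to use, its parameters, and its feature layout."""

    scheme: str = "AF-CKSAAP"
    k_max: int = DEFAULT_K_MAX
    knn_fractions: tuple[float, ...] = DEFAULT_KNN_FRACTIONS
    ratio_cap: float = DEFAULT_RATIO_CAP

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ConfigError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        if self.k_max < 0:
            raise ConfigError("k_max must be >= 0")

    @property
    def components(self) -> tuple[str, ...]:
        return tuple(self.scheme.split("-"))

    @property
    def uses_knn(self) -> bool:
        return "KNN" in self.components

    def feature_layout(self) -> list[str]:
        """Ordered feature identifiers: AF block, then CKSAAP, then KNN."""
        layout: list[str] = []
        if "AF" in self.components:
            layout += af_layout()
        if "CKSAAP" in self.components:
            layout += cksaap_layout(self.k_max)
        if "KNN" in self.components:
            layout += knn_layout(self.knn_fractions)
        return layout

    @property
    def dimension(self) -> int:
        return len(self.feature_layout())

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "k_max": self.k_max,
            "knn_fractions": list(self.knn_fractions),
            "ratio_cap": self.ratio_cap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingSpec":
        return cls(
            scheme=d["scheme"],
            k_max=int(d["k_max"]),
            knn_fractions=tuple(d["knn_fractions"]),
            ratio_cap=float(d.get("ratio_cap", DEFAULT_RATIO_CAP)),
        )


def encode_af(fragment: Fragment | str) -> np.ndarray:
    """Amino-acid occurrence frequencies (20 values, alphabetical order).

    The denominator is the number of standard residues in the fragment
    (pads and wildcards excluded), so a pad-free fragment sums to 1.
    """
    codes = seq_to_codes(_sequence_of(fragment))
    valid = codes[codes >= 0]
    if valid.size == 0:
        raise DataError("cannot AF-encode a fragment with no standard residues")
    counts = np.bincount(valid, minlength=20).astype(float)
    return counts / valid.size


def encode_cksaap(fragment: Fragment | str, k_max: int = DEFAULT_K_MAX) -> np.ndarray:
    """Composition of k-spaced amino-acid pairs for k = 0..k_max.

    For spacing k, every position pair (i, i+k+1) with both members being
    standard residues contributes; the feature value is the pair count over
    the total count at that spacing.  A spacing with no valid pairs yields
    an all-zero block (logged).
    """
    if k_max < 0:
        raise ConfigError("k_max must be >= 0")
    codes = seq_to_codes(_sequence_of(fragment))
    out = np.zeros(400 * (k_max + 1))
    for k in range(k_max + 1):
        gap = k + 1
        if codes.size <= gap:
            logger.warning("fragment too short for spacing k=%d; block left zero", k)
            continue
        first = codes[:-gap]
        second = codes[gap:]
        mask = (first >= 0) & (second >= 0)
        n_total = int(mask.sum())
        if n_total == 0:
            logger.warning("no valid pairs at spacing k=%d; block left zero", k)
            continue
        flat = first[mask] * 20 + second[mask]
        block = np.bincount(flat, minlength=400).astype(float) / n_total
        out[400 * k : 400 * (k + 1)] = block
    return out


def knn_distance(
    fragment1: Fragment | str,
    fragment2: Fragment | str,
    sim: SimilarityMatrix,
) -> float:
    """Distance between two aligned 25-mers under normalized similarity.

    One minus the mean similarity over aligned positions, skipping
    positions where either fragment has a pad or wildcard.
    """
    c1 = seq_to_codes(_sequence_of(fragment1))
    c2 = seq_to_codes(_sequence_of(fragment2))
    if c1.size != c2.size:
        raise DataError("fragments must have equal length for distance computation")
    mask = (c1 >= 0) & (c2 >= 0)
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise DataError("incomparable fragments: no aligned standard-residue positions")
    total = sim.values[c1[mask], c2[mask]].sum()
    return float(1.0 - total / n_valid)


def _codes_matrix(fragments: Sequence[Fragment | str]) -> np.ndarray:
    return np.stack([seq_to_codes(_sequence_of(f)) for f in fragments])


def _distance_block(
    q_codes: np.ndarray, r_codes: np.ndarray, sim: np.ndarray, chunk: int = 256
) -> np.ndarray:
    """All query-vs-reference distances; (n_q, n_r), pads/X skipped per pair."""
    n_q, n_r = q_codes.shape[0], r_codes.shape[0]
    out = np.empty((n_q, n_r))
    # pad/X entries routed to a sacrificial zero row/col in an augmented matrix
    aug = np.zeros((21, 21))
    aug[:20, :20] = sim
    q_safe = np.where(q_codes >= 0, q_codes, 20)
    r_safe = np.where(r_codes >= 0, r_codes, 20)
    q_valid = q_codes >= 0
    r_valid = r_codes >= 0
    for start in range(0, n_q, chunk):
        stop = min(start + chunk, n_q)
        sims = aug[q_safe[start:stop, None, :], r_safe[None, :, :]]
        pair_valid = q_valid[start:stop, None, :] & r_valid[None, :, :]
        n_valid = pair_valid.sum(axis=2)
        if np.any(n_valid == 0):
            raise DataError("incomparable fragments: no aligned standard-residue positions")
        out[start:stop] = 1.0 - (sims * pair_valid).sum(axis=2) / n_valid
    return out


def k_from_fraction(fraction: float, n_refs: int) -> int:
    """Neighbor count from a fraction: round half away from zero, floor 1."""
    return max(1, int(np.floor(fraction * n_refs + 0.5)))


def _knn_features_from_distances(
    d_pos: np.ndarray,
    d_neg: np.ndarray,
    fractions: Sequence[float],
    ratio_cap: float,
) -> np.ndarray:
    """KNN ratio features for one query given its sorted-unsorted distance rows."""
    d_pos_sorted = np.sort(d_pos, kind="stable")
    d_neg_sorted = np.sort(d_neg, kind="stable")
    feats = np.empty(len(fractions))
    for j, f in enumerate(fractions):
        k_pos = k_from_fraction(f, d_pos.size)
        k_neg = k_from_fraction(f, d_neg.size)
        mean_pos = d_pos_sorted[:k_pos].mean()
        mean_neg = d_neg_sorted[:k_neg].mean()
        if mean_pos == 0.0:
            if mean_neg == 0.0:
                logger.warning("query equidistant (0) from both reference classes; ratio set to 1")
                feats[j] = 1.0
            else:
                logger.warning("zero mean nearest-positive distance; ratio capped at %g", ratio_cap)
                feats[j] = ratio_cap
        else:
            feats[j] = mean_neg / mean_pos
    return feats


def _reference_mask(
    queries: Sequence[Fragment], refs: Sequence[Fragment]
) -> np.ndarray:
    """Boolean (n_q, n_r): True where the reference is the query itself."""
    ref_keys = [(r.protein_id, r.position) for r in refs]
    mask = np.zeros((len(queries), len(refs)), dtype=bool)
    key_to_cols: dict[tuple[str, int], list[int]] = {}
    for j, key in enumerate(ref_keys):
        key_to_cols.setdefault(key, []).append(j)
    for i, q in enumerate(queries):
        if isinstance(q, Fragment):
            for j in key_to_cols.get((q.protein_id, q.position), []):
                mask[i, j] = True
    return mask


def encode_knn_matrix(
    queries: Sequence[Fragment],
    positive_refs: Sequence[Fragment],
    negative_refs: Sequence[Fragment],
    fractions: Sequence[float] = DEFAULT_KNN_FRACTIONS,
    sim: SimilarityMatrix | None = None,
    exclude_self: bool = False,
    ratio_cap: float = DEFAULT_RATIO_CAP,
) -> np.ndarray:
    """KNN ratio features for a batch of queries; (n_queries, len(fractions)).

    For each fraction f the k nearest reference distances per class are
    averaged (k = max(1, round(f * class size))); the feature is the mean
    negative distance over the mean positive distance.  With
    ``exclude_self`` a query matched by (protein_id, position) is removed
    from its own reference class before the neighbor search.
    """
    if not positive_refs or not negative_refs:
        raise DataError("both reference sets must be non-empty for KNN encoding")
    if sim is None:
        sim = normalize_blosum62()
    q_codes = _codes_matrix(queries)
    d_pos = _distance_block(q_codes, _codes_matrix(positive_refs), sim.values)
    d_neg = _distance_block(q_codes, _codes_matrix(negative_refs), sim.values)

    if exclude_self:
        pos_mask = _reference_mask(queries, positive_refs)
        neg_mask = _reference_mask(queries, negative_refs)
    else:
        pos_mask = neg_mask = None

    out = np.empty((len(queries), len(fractions)))
    for i in range(len(queries)):
        dp = d_pos[i][~pos_mask[i]] if pos_mask is not None else d_pos[i]
        dn = d_neg[i][~neg_mask[i]] if neg_mask is not None else d_neg[i]
        if dp.size == 0 or dn.size == 0:
            raise DataError("exclude_self emptied a reference set")
        out[i] = _knn_features_from_distances(dp, dn, fractions, ratio_cap)
    return out


def encode_knn(
    fragment: Fragment,
    positive_refs: Sequence[Fragment],
    negative_refs: Sequence[Fragment],
    fractions: Sequence[float] = DEFAULT_KNN_FRACTIONS,
    sim: SimilarityMatrix | None = None,
    exclude_self: bool = False,
    ratio_cap: float = DEFAULT_RATIO_CAP,
) -> np.ndarray:
    """KNN ratio features for a single query fragment."""
    return encode_knn_matrix(
        [fragment], positive_refs, negative_refs, fractions, sim, exclude_self, ratio_cap
    )[0]


def encode_fragments(
    fragments: Sequence[Fragment],
    spec: EncodingSpec,
    positive_refs: Sequence[Fragment] | None = None,
    negative_refs: Sequence[Fragment] | None = None,
    sim: SimilarityMatrix | None = None,
    exclude_self: bool = False,
) -> np.ndarray:
    """Encode fragments under ``spec``; blocks concatenated AF, CKSAAP, KNN."""
    blocks: list[np.ndarray] = []
    if "AF" in spec.components:
        blocks.append(np.stack([encode_af(f) for f in fragments]))
    if "CKSAAP" in spec.components:
        blocks.append(np.stack([encode_cksaap(f, spec.k_max) for f in fragments]))
    if spec.uses_knn:
        if positive_refs is None or negative_refs is None:
            raise ConfigError(f"scheme {spec.scheme} requires positive and negative references")
        blocks.append(
            encode_knn_matrix(
                fragments,
                positive_refs,
                negative_refs,
                spec.knn_fractions,
                sim,
                exclude_self,
                spec.ratio_cap,
            )
        )
    return np.hstack(blocks)


def encode_combined(
    fragment: Fragment,
    spec: EncodingSpec,
    positive_refs: Sequence[Fragment] | None = None,
    negative_refs: Sequence[Fragment] | None = None,
    sim: SimilarityMatrix | None = None,
    exclude_self: bool = False,
) -> np.ndarray:
    """Single-fragment convenience wrapper around :func:`encode_fragments`."""
    return encode_fragments(
        [fragment], spec, positive_refs, negative_refs, sim, exclude_self
    )[0]
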