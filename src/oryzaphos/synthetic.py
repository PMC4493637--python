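"""Synthetic fragment and protein generators with plantable phosphosite signal.

Negatives are 25-mers drawn i.i.d. from a background residue composition
with the center sampled from an S/T/Y distribution.  Positives are drawn
the same way and then given signal in two forms that mirror what the
encodings are designed to detect:

* *positional motifs* — (offset, residue, probability): with the stated
  probability the residue is written at that window offset, emulating
  position-specific kinase preferences (e.g. proline-directed +1 P,
  basophilic -3 R);
* *pair motifs* — (a, b, spacing, multiplier): candidate positives are
  rejection-tilted so fragments containing more (a, b) pairs at that
  spacing are over-accepted, enriching the pair roughly by the multiplier
  when the background pair probability is small.

The default S/T/Y center distribution (0.85, 0.12, 0.03) approximates the
relative abundance of experimentally observed phospho-serine, -threonine
and -tyrosine substrates in rice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from oryzaphos.dataset import (
    Fragment,
    HALF_WINDOW,
    SiteAnnotation,
    STANDARD_AA,
    WINDOW,
)
from oryzaphos.encodings import AA_INDEX
from oryzaphos.errors import ConfigError

logger = logging.getLogger(__name__)

#: count at which the rejection tilt saturates (fragments with this many
#: motif pairs are always accepted)
_TILT_SATURATION = 2

#: minimum tolerated expected acceptance rate for the rejection sampler
_MIN_ACCEPTANCE = 1e-3


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for synthetic fragment datasets."""

    n_pos: int = 500
    n_neg: int = 500
    background: tuple[float, ...] | None = None  # uniform over 20 when None
    positional_motifs: tuple[tuple[int, str, float], ...] = ()
    pair_motifs: tuple[tuple[str, str, int, float], ...] = ()
    center_distribution: tuple[float, float, float] = (0.85, 0.12, 0.03)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ConfigError("n_pos and n_neg must be >= 1")
        bg = self.background_array()
        if bg.size != 20 or not np.isclose(bg.sum(), 1.0) or (bg < 0).any():
            raise ConfigError("background must be 20 non-negative frequencies summing to 1")
        if not np.isclose(sum(self.center_distribution), 1.0):
            raise ConfigError("center_distribution must sum to 1")
        for offset, residue, prob in self.positional_motifs:
            if offset == 0 or not -HALF_WINDOW <= offset <= HALF_WINDOW:
                raise ConfigError(f"motif offset must be in -12..+12 excluding 0, got {offset}")
            if residue not in AA_INDEX:
                raise ConfigError(f"motif residue {residue!r} not a standard amino acid")
            if not 0.0 <= prob <= 1.0:
                raise ConfigError(f"motif probability must be in [0,1], got {prob}")
        for a, b, k, mult in self.pair_motifs:
            if a not in AA_INDEX or b not in AA_INDEX:
                raise ConfigError(f"pair motif residues {a!r},{b!r} must be standard")
            if k < 0 or k > WINDOW - 2:
                raise ConfigError(f"pair spacing must be in 0..{WINDOW - 2}, got {k}")
            if mult < 1.0:
                raise ConfigError("pair enrichment multiplier must be >= 1")

    def background_array(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 1.0 / 20.0)
        return np.asarray(self.background, dtype=float)


def strong_signal_spec(n_pos: int = 500, n_neg: int = 500, seed: int = 0) -> GeneratorSpec:
    """The package's standard strong-signal benchmark conditions.

    Emulates a proline-directed motif (P at +1) combined with basophilic
    context (R at -3, K at +3) and an enriched center-adjacent S-P pair.
    """
    return GeneratorSpec(
        n_pos=n_pos,
        n_neg=n_neg,
        positional_motifs=((1, "P", 0.95), (-3, "R", 0.8), (3, "K", 0.8)),
        pair_motifs=(("S", "P", 0, 3.0),),
        seed=seed,
    )


def _pair_count(codes: np.ndarray, a_idx: int, b_idx: int, k: int) -> np.ndarray:
    """Occurrences of the ordered pair (a, b) at spacing k per fragment row."""
    gap = k + 1
    first = codes[:, :-gap]
    second = codes[:, gap:]
    return np.sum((first == a_idx) & (second == b_idx), axis=1)


def _tilt_weights(codes: np.ndarray, spec: GeneratorSpec) -> np.ndarray:
    """Per-fragment acceptance probability under the pair-motif tilt."""
    accept = np.ones(codes.shape[0])
    for a, b, k, mult in spec.pair_motifs:
        counts = _pair_count(codes, AA_INDEX[a], AA_INDEX[b], k)
        accept *= np.minimum(1.0, mult ** (counts.astype(float) - _TILT_SATURATION))
    return accept


def _check_feasible(spec: GeneratorSpec) -> None:
    """Poisson-approximation feasibility of each requested pair enrichment.

    The tilt saturates: fragments with >= ``_TILT_SATURATION`` motif pairs
    are always accepted, so the achievable enrichment is bounded by the
    conditional mean count in that tail.  A multiplier beyond the bound (or
    one driving the expected acceptance rate too low) cannot be realized by
    rejection and is rejected up front with the bound in the message.
    """
    bg = spec.background_array()
    expected_acc = 1.0
    for a, b, k, mult in spec.pair_motifs:
        mu = (WINDOW - 1 - k) * bg[AA_INDEX[a]] * bg[AA_INDEX[b]]
        pois = [np.exp(-mu)]
        for c in range(1, 12):
            pois.append(pois[-1] * mu / c)
        acc = sum(p * min(1.0, mult ** (c - _TILT_SATURATION)) for c, p in enumerate(pois))
        expected_acc *= acc
        tail_p = sum(pois[_TILT_SATURATION:])
        tail_mean = sum(c * p for c, p in enumerate(pois) if c >= _TILT_SATURATION)
        max_enrich = (tail_mean / tail_p) / mu if tail_p > 0 else 1.0
        if mult > 0.95 * max_enrich:
            raise ConfigError(
                f"pair enrichment multiplier {mult:g} for ({a},{b},k={k}) exceeds "
                f"what rejection tilting can achieve; keep it below about "
                f"{0.95 * max_enrich:.0f}"
            )
    if expected_acc < _MIN_ACCEPTANCE:
        raise ConfigError(
            f"pair enrichment infeasible for rejection sampling (expected "
            f"acceptance {expected_acc:.2e} < {_MIN_ACCEPTANCE}); lower the multipliers"
        )


def _sample_codes(
    n: int, spec: GeneratorSpec, rng: np.random.Generator, positive: bool
) -> np.ndarray:
    bg = spec.background_array()
    codes = rng.choice(20, size=(n, WINDOW), p=bg)
    centers = rng.choice([AA_INDEX["S"], AA_INDEX["T"], AA_INDEX["Y"]],
                         size=n, p=np.asarray(spec.center_distribution))
    codes[:, HALF_WINDOW] = centers
    if positive:
        for offset, residue, prob in spec.positional_motifs:
            hit = rng.random(n) < prob
            codes[hit, HALF_WINDOW + offset] = AA_INDEX[residue]
    return codes


def _codes_to_fragments(codes: np.ndarray, label: str, prefix: str) -> list[Fragment]:
    frags = []
    for i, row in enumerate(codes):
        seq = "".join(STANDARD_AA[c] for c in row)
        frags.append(
            Fragment(seq, seq[HALF_WINDOW], f"{prefix}{i:05d}", HALF_WINDOW + 1, label)
        )
    return frags


def generate(spec: GeneratorSpec) -> tuple[list[Fragment], list[Fragment]]:
    """Generate (positives, negatives) under the spec's study conditions.

    Negatives come straight from the background; positives get positional
    motifs by overwrite and pair motifs by rejection tilting.  The achieved
    pair enrichment relative to the negatives is logged.
    """
    if spec.pair_motifs:
        _check_feasible(spec)
    rng = np.random.default_rng(spec.seed)

    neg_codes = _sample_codes(spec.n_neg, spec, rng, positive=False)

    if spec.pair_motifs:
        accepted: list[np.ndarray] = []
        n_have = 0
        tries = 0
        max_tries = 400
        while n_have < spec.n_pos and tries < max_tries:
            batch = _sample_codes(max(spec.n_pos, 256), spec, rng, positive=True)
            keep = rng.random(batch.shape[0]) < _tilt_weights(batch, spec)
            accepted.append(batch[keep])
            n_have += int(keep.sum())
            tries += 1
        if n_have < spec.n_pos:
            raise ConfigError(
                "rejection sampling failed to reach n_pos; lower the pair multipliers"
            )
        pos_codes = np.concatenate(accepted)[: spec.n_pos]
        for a, b, k, mult in spec.pair_motifs:
            got = _pair_count(pos_codes, AA_INDEX[a], AA_INDEX[b], k).mean()
            base = _pair_count(neg_codes, AA_INDEX[a], AA_INDEX[b], k).mean()
            logger.info(
                "pair motif (%s,%s,k=%d): achieved enrichment %.2f (target %g)",
                a, b, k, got / base if base else float("inf"), mult,
            )
    else:
        pos_codes = _sample_codes(spec.n_pos, spec, rng, positive=True)

    return (
        _codes_to_fragments(pos_codes, "positive", "sp"),
        _codes_to_fragments(neg_codes, "negative", "sn"),
    )


def generate_proteins(
    spec: GeneratorSpec,
    n_proteins: int = 20,
    length_range: tuple[int, int] = (80, 160),
    edge_sites: int = 0,
    id_prefix: str = "synthprot",
) -> tuple[dict[str, str], list[SiteAnnotation]]:
    """Embed generated fragments into random background proteins.

    Each fragment's 25-mer window is written into a background protein at a
    recorded center position; windows are spaced so they never overlap.
    ``edge_sites`` fragments are deliberately placed so close to the
    N-terminus that their windows truncate, exercising pad handling
    downstream.  Returns sequences plus site annotations consumable by the
    dataset module.
    """
    positives, negatives = generate(spec)
    fragments = positives + negatives
    rng = np.random.default_rng(spec.seed + 1)
    bg = spec.background_array()

    lo, hi = length_range
    if lo < WINDOW:
        lo = WINDOW
    per_protein = int(np.ceil(len(fragments) / n_proteins))
    stride = WINDOW + 5

    sequences: dict[str, str] = {}
    annotations: list[SiteAnnotation] = []
    frag_iter = iter(fragments)
    edge_remaining = edge_sites
    done = False
    for p in range(n_proteins):
        if done:
            break
        length = max(int(rng.integers(lo, hi + 1)), per_protein * stride + WINDOW)
        chars = [STANDARD_AA[c] for c in rng.choice(20, size=length, p=bg)]
        for s in range(per_protein):
            frag = next(frag_iter, None)
            if frag is None:
                done = True
                break
            if edge_remaining > 0 and s == 0:
                # truncated placement: center at position 3 (1-based)
                center0 = 2
                edge_remaining -= 1
            else:
                center0 = HALF_WINDOW + s * stride
            for w, ch in enumerate(frag.sequence):
                pos0 = center0 - HALF_WINDOW + w
                if 0 <= pos0 < length:
                    chars[pos0] = ch
            pid = f"{id_prefix}{p:03d}"
            annotations.append(
                SiteAnnotation(pid, center0 + 1, frag.center_residue, frag.label)
            )
        sequences[f"{id_prefix}{p:03d}"] = "".join(chars)
    return sequences, annotations
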