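"""Per-residue stickiness energy landscapes.

A chain is described by a continuous well-depth profile delta-E in [0, 1]
(units of the Lennard-Jones energy scale epsilon) rather than an explicit
amino-acid alphabet.  Residues whose well depth exceeds a classification
threshold (default 0.1) are "stickers"; the rest are purely repulsive
"spacers".  The canonical ordered profile is the periodic modulation

    delta_E[i] = sin^2(2 pi i / k)

with residue index i (0-based) and formula parameter k, giving the pattern
family P_k.  Controlled-disorder variants are derived from it:

    P_kA : sticker values shuffled among sticker positions (spacers fixed)
    P_kB : within each sticker domain, strengths re-ordered to alternate
           high/low position by position
    R_k  : full uniform permutation of the profile (random heteropolymer)

All variants conserve the total stickiness of the base pattern exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import wasserstein_distance

__all__ = [
    "StickerPattern",
    "PairInteractionMatrix",
    "SequenceDescriptor",
    "build_periodic_profile",
    "apply_spacer_threshold",
    "randomize_full",
    "shuffle_stickers_fix_spacers",
    "alternate_sticker_strengths",
    "pair_matrix",
    "wasserstein_to_random",
    "hydropathy_profile",
    "kappa_and_descriptor",
    "KYTE_DOOLITTLE",
]

DEFAULT_SPACER_THRESHOLD = 0.1


@dataclass(frozen=True)
class StickerPattern:
    """A per-residue well-depth profile with sticker/spacer classification."""

    label: str
    period_k: int
    n_residues: int
    well_depth: np.ndarray  # shape (Np,), values in [0, 1], units of epsilon
    is_sticker: np.ndarray  # shape (Np,), bool
    spacer_threshold: float = 0.0

    def __post_init__(self) -> None:
        wd = np.ascontiguousarray(np.asarray(self.well_depth, dtype=float))
        st = np.ascontiguousarray(np.asarray(self.is_sticker, dtype=bool))
        if wd.ndim != 1 or wd.shape[0] != self.n_residues:
            raise ValueError("well_depth must be a 1-D array of length n_residues")
        if st.shape != wd.shape:
            raise ValueError("is_sticker must match well_depth in shape")
        if np.any(wd < 0.0) or np.any(wd > 1.0):
            raise ValueError("well depths must lie in [0, 1]")
        object.__setattr__(self, "well_depth", wd)
        object.__setattr__(self, "is_sticker", st)

    @property
    def n_stickers(self) -> int:
        return int(self.is_sticker.sum())

    @property
    def total_stickiness(self) -> float:
        return float(self.well_depth.sum())

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "period_k": self.period_k,
                "n_residues": self.n_residues,
                "spacer_threshold": self.spacer_threshold,
                "well_depth": self.well_depth.tolist(),
                "is_sticker": self.is_sticker.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StickerPattern":
        d = json.loads(text)
        return cls(
            label=d["label"],
            period_k=int(d["period_k"]),
            n_residues=int(d["n_residues"]),
            well_depth=np.asarray(d["well_depth"], dtype=float),
            is_sticker=np.asarray(d["is_sticker"], dtype=bool),
            spacer_threshold=float(d["spacer_threshold"]),
        )


@dataclass(frozen=True)
class PairInteractionMatrix:
    """Symmetric per-residue well-depth matrix eps[i, j] = sqrt(eps_ii eps_jj)."""

    eps: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.eps, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("eps must be a square matrix")
        object.__setattr__(self, "eps", e)


@dataclass
class SequenceDescriptor:
    """Periodicity/energy descriptors of a real or synthetic sequence profile."""

    lambda_profile: np.ndarray
    lambda_max: float
    kappa: float = np.nan
    x_descriptor: float = np.nan
    w1: float = np.nan
    degenerate: bool = False


def build_periodic_profile(period_k: int, n_residues: int) -> StickerPattern:
    """Construct the un-thresholded periodic profile sin^2(2 pi i / period_k).

    Residue indices are 0-based, so residue 0 is always an exact spacer.
    The profile repeats every ``period_k / 2`` residues; the family label
    P<k> follows the formula parameter.
    """
    if period_k < 2:
        raise ValueError("period_k must be >= 2")
    if n_residues < 1 or n_residues < period_k / 2:
        raise ValueError("n_residues must cover at least half a period")
    i = np.arange(n_residues)
    wd = np.sin(2.0 * np.pi * i / period_k) ** 2
    return StickerPattern(
        label=f"P{period_k}",
        period_k=period_k,
        n_residues=n_residues,
        well_depth=wd,
        is_sticker=wd > 0.0,
        spacer_threshold=0.0,
    )


def apply_spacer_threshold(
    pattern: StickerPattern, threshold: float = DEFAULT_SPACER_THRESHOLD
) -> StickerPattern:
    """Zero all well depths <= threshold and classify the rest as stickers."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    wd = pattern.well_depth.copy()
    spacer = wd <= threshold
    wd[spacer] = 0.0
    return replace(
        pattern, well_depth=wd, is_sticker=~spacer, spacer_threshold=threshold
    )


def randomize_full(pattern: StickerPattern, seed: int) -> StickerPattern:
    """Uniform random permutation of the whole profile (R_k heteropolymer)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pattern.n_residues)
    wd = pattern.well_depth[perm]
    return replace(
        pattern,
        label=f"R{pattern.period_k}",
        well_depth=wd,
        is_sticker=wd > pattern.spacer_threshold,
    )


def shuffle_stickers_fix_spacers(pattern: StickerPattern, seed: int) -> StickerPattern:
    """Permute sticker values among sticker positions; spacers stay put (P_kA)."""
    if pattern.n_stickers == 0:
        raise ValueError("pattern has no stickers to shuffle")
    rng = np.random.default_rng(seed)
    wd = pattern.well_depth.copy()
    idx = np.flatnonzero(pattern.is_sticker)
    wd[idx] = wd[idx[rng.permutation(idx.size)]]
    return replace(pattern, label=pattern.label + "A", well_depth=wd)


def _alternate(values: np.ndarray) -> np.ndarray:
    """Sort descending, put top half at even positions, bottom half at odd."""
    s = np.sort(values)[::-1]
    out = np.empty_like(s)
    n_even = out[0::2].size
    out[0::2] = s[:n_even]
    out[1::2] = s[n_even:]
    return out


def alternate_sticker_strengths(pattern: StickerPattern) -> StickerPattern:
    """Re-order each contiguous sticker domain to alternate high/low (P_kB).

    Total stickiness is conserved exactly: only positions within a domain
    change, never the multiset of values.
    """
    wd = pattern.well_depth.copy()
    st = pattern.is_sticker
    n = pattern.n_residues
    i = 0
    while i < n:
        if st[i]:
            j = i
            while j < n and st[j]:
                j += 1
            wd[i:j] = _alternate(wd[i:j])
            i = j
        else:
            i += 1
    return replace(pattern, label=pattern.label + "B", well_depth=wd)


def pair_matrix(pattern: StickerPattern) -> PairInteractionMatrix:
    """Geometric-mean combining rule eps[i, j] = sqrt(eps_ii eps_jj).

    Cross-motif attractions are therefore never stronger than the stronger
    partner's self-affinity, and any pairing with a spacer is zero.
    """
    root = np.sqrt(pattern.well_depth)
    return PairInteractionMatrix(eps=np.outer(root, root))


def wasserstein_to_random(
    pattern: StickerPattern, n_shuffles: int = 200, seed: int = 0
) -> float:
    """W1 distance of the positional energy profile to its shuffled ensemble.

    The profile is treated as a probability distribution over scaled residue
    position x_i = i / Np with mass well_depth[i] / sum(well_depth); the
    reference is the same construction averaged over ``n_shuffles`` uniform
    permutations.  Computed by 1-D optimal transport (integrated CDF
    difference).  Higher-frequency patterns spread their mass more evenly
    and hence lie closer to the random reference.
    """
    total = pattern.total_stickiness
    if total <= 0.0:
        raise ValueError("zero-mass profile has no transport distance")
    rng = np.random.default_rng(seed)
    wd = pattern.well_depth
    ref = np.zeros_like(wd)
    for _ in range(n_shuffles):
        ref += wd[rng.permutation(wd.size)]
    ref /= n_shuffles
    x = np.arange(pattern.n_residues) / pattern.n_residues
    return float(wasserstein_distance(x, x, u_weights=wd, v_weights=ref))


# Kyte-Doolittle hydropathy index, max-rescaled to [0, 1] at lookup time.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}
_KD_MIN = min(KYTE_DOOLITTLE.values())
_KD_MAX = max(KYTE_DOOLITTLE.values())


def hydropathy_profile(sequence: str) -> SequenceDescriptor:
    """Per-residue energy amplitudes lambda_i from the hydropathy index.

    Raw Kyte-Doolittle values are min-max rescaled to [0, 1] so they live on
    the same scale as the landscape well depths.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    lam = np.empty(len(seq))
    for pos, aa in enumerate(seq):
        try:
            raw = KYTE_DOOLITTLE[aa]
        except KeyError:
            raise ValueError(
                f"unknown amino-acid letter {aa!r} at position {pos}"
            ) from None
        lam[pos] = (raw - _KD_MIN) / (_KD_MAX - _KD_MIN)
    return SequenceDescriptor(lambda_profile=lam, lambda_max=float(lam.max()))


def autocorrelation_half_decay(profile: np.ndarray) -> tuple[float, bool]:
    """Smallest lag at which the normalized autocorrelation falls to 1/2.

    The mean-removed autocorrelation c(s) = <(x_i - xbar)(x_{i+s} - xbar)>
    is normalized by c(0); the half-decay lag is located by linear
    interpolation between integer lags.  A zero-variance profile is
    degenerate and returns (1.0, True).
    """
    x = np.asarray(profile, dtype=float)
    n = x.size
    xc = x - x.mean()
    c0 = float(np.dot(xc, xc) / n)
    if c0 <= 0.0 or not np.isfinite(c0):
        return 1.0, True
    prev = 1.0
    for s in range(1, n):
        cs = float(np.dot(xc[:-s], xc[s:]) / (n - s)) / c0
        if cs <= 0.5:
            # linear interpolation between (s-1, prev) and (s, cs)
            frac = (prev - 0.5) / (prev - cs)
            return (s - 1) + frac, False
        prev = cs
    return float(n), False


def kappa_and_descriptor(descriptor: SequenceDescriptor) -> SequenceDescriptor:
    """Fill the correlation length <kappa> and the combined x descriptor.

    x = <kappa> * (sum_i lambda_i / lambda_max) / Np couples patterning
    periodicity with total interaction strength; for an all-equal profile
    it degenerates to 1 (kappa defined as 1).
    """
    lam = descriptor.lambda_profile
    if lam.size == 0:
        raise ValueError("empty lambda profile")
    kappa, degenerate = autocorrelation_half_decay(lam)
    descriptor.kappa = kappa
    descriptor.degenerate = degenerate
    if descriptor.lambda_max <= 0:
        raise ValueError("lambda_max must be positive")
    descriptor.x_descriptor = float(
        kappa * (lam.sum() / descriptor.lambda_max) / lam.size
    )
    return descriptor


def build_variant(
    variant: str,
    period_k: int,
    n_residues: int,
    threshold: float = DEFAULT_SPACER_THRESHOLD,
    seed: int = 0,
) -> StickerPattern:
    """Convenience constructor: one of the P/PA/PB/R families, thresholded."""
    base = apply_spacer_threshold(
        build_periodic_profile(period_k, n_residues), threshold
    )
    v = variant.upper()
    if v == "P":
        return base
    if v == "PA":
        return shuffle_stickers_fix_spacers(base, seed)
    if v == "PB":
        return alternate_sticker_strengths(base)
    if v == "R":
        return randomize_full(base, seed)
    raise ValueError(f"unknown variant {variant!r}; expected P, PA, PB or R")
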