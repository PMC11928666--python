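"""Sequence-derived protein descriptors and the fixed 466-slot feature vector.

The vector concatenates, in pinned order:

========  =====  =================================================
block     size   content
========  =====  =================================================
AAC       20     amino-acid composition (relative frequencies)
DPC       400    overlapping dipeptide composition
pQSO      20     partial quasi-sequence-order coupling terms, lags 1..20
pPAAC     20     partial pseudo-amino-acid-composition terms, lags 1..20
pI        1      isoelectric point (Henderson–Hasselbalch bisection)
SLR       1      amalgam log-ratio of membrane vs non-membrane regions
SP        4      signal-peptide probabilities (any, Sec/SPI, SPII, Tat)
========  =====  =================================================

"Partial" means the classical quasi-sequence-order / pseudo-amino-acid
descriptors stripped of their 20 composition slots (those duplicate the AAC
block); the classical normalising denominator is retained so the coupling
terms keep the scale they would have in the full descriptor.

Ambiguity letters (X, B, Z, U, O) are excluded from descriptor computation:
composition counts ignore them, dipeptide windows containing one are skipped,
and the sequence-order descriptors operate on the canonical-only subsequence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import (AA_INDEX, AMINO_ACIDS, EMBOSS_PKA,
                        default_distance_matrix, standardized_scales)
from .seq_io import AnnotationBundle, ProteinRecord

log = logging.getLogger(__name__)

# (name, size) of the pinned blocks; offsets 0, 20, 420, 440, 460, 461, 462.
BLOCKS: tuple[tuple[str, int], ...] = (
    ("AAC", 20), ("DPC", 400), ("pQSO", 20), ("pPAAC", 20),
    ("pI", 1), ("SLR", 1), ("SP", 4),
)
N_FEATURES = sum(size for _, size in BLOCKS)  # 466


def block_slices() -> dict[str, slice]:
    """Named slices of the feature vector, in layout order."""
    out, offset = {}, 0
    for name, size in BLOCKS:
        out[name] = slice(offset, offset + size)
        offset += size
    return out


def feature_names() -> list[str]:
    names = [f"AAC_{a}" for a in AMINO_ACIDS]
    names += [f"DPC_{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS]
    names += [f"pQSO_{d}" for d in range(1, 21)]
    names += [f"pPAAC_{d}" for d in range(1, 21)]
    names += ["pI", "SLR", "SP_any", "SP_spi", "SP_spii", "SP_tat"]
    return names


class DescriptorError(ValueError):
    pass


def canonical_indices(seq: str) -> np.ndarray:
    """Indices into AMINO_ACIDS of the canonical residues, in order."""
    return np.array([AA_INDEX[c] for c in seq if c in AA_INDEX], dtype=np.intp)


# ---------------------------------------------------------------------------
# Composition blocks

def aac(seq: str) -> np.ndarray:
    """Amino-acid composition over the 20 canonical letters (sums to 1)."""
    idx = canonical_indices(seq)
    if idx.size == 0:
        raise DescriptorError("no canonical residues in sequence")
    return np.bincount(idx, minlength=20) / idx.size


def dpc(seq: str) -> np.ndarray:
    """Overlapping dipeptide composition (400 ordered pairs, sums to 1).

    Windows containing an ambiguity letter are skipped, so the counts are
    taken over the original sequence, not the canonical-only subsequence.
    """
    counts = np.zeros((20, 20))
    for a, b in zip(seq, seq[1:]):
        if a in AA_INDEX and b in AA_INDEX:
            counts[AA_INDEX[a], AA_INDEX[b]] += 1
    total = counts.sum()
    if total == 0:
        raise DescriptorError("no valid dipeptide window in sequence")
    return counts.ravel() / total


# ---------------------------------------------------------------------------
# Sequence-order blocks

def pqso(seq: str, maxlag: int = 20, w: float = 0.1,
         matrix: np.ndarray | None = None) -> np.ndarray:
    """Partial quasi-sequence-order coupling terms.

    tau_d = sum_i d(R_i, R_{i+d})^2 over the canonical subsequence for
    d = 1..maxlag; the emitted feature is w*tau_d / (1 + w*sum_d tau_d).
    Lags d >= sequence length are 0.
    """
    if matrix is None:
        matrix = default_distance_matrix()
    idx = canonical_indices(seq)
    if idx.size < 2:
        raise DescriptorError("need >= 2 canonical residues for pQSO")
    tau = np.zeros(maxlag)
    for d in range(1, min(maxlag, idx.size - 1) + 1):
        tau[d - 1] = (matrix[idx[:-d], idx[d:]] ** 2).sum()
    return w * tau / (1.0 + w * tau.sum())


def ppaac(seq: str, lam: int = 20, w: float = 0.05,
          scales: np.ndarray | None = None) -> np.ndarray:
    """Partial pseudo-amino-acid-composition coupling terms.

    Theta(a, b) is the mean over three standardized propensity scales
    (hydrophobicity, hydrophilicity, residue mass) of the squared scale
    difference; theta_d averages Theta over all lag-d pairs; the emitted
    feature is w*theta_d / (1 + w*sum theta).  Lags d >= length are 0.
    """
    if scales is None:
        scales = standardized_scales()
    idx = canonical_indices(seq)
    if idx.size < 2:
        raise DescriptorError("need >= 2 canonical residues for pPAAC")
    diff = scales[:, :, None] - scales[:, None, :]
    big_theta = (diff ** 2).mean(axis=0)          # (20, 20)
    theta = np.zeros(lam)
    for d in range(1, min(lam, idx.size - 1) + 1):
        theta[d - 1] = big_theta[idx[:-d], idx[d:]].mean()
    return w * theta / (1.0 + w * theta.sum())


# ---------------------------------------------------------------------------
# Scalar blocks

SLR_EPS = 1e-6


def slr(region_props) -> float:
    """Amalgam log-ratio of membrane-type to non-membrane-type region
    proportions: ln((pH + pB + eps) / (pS + po + pi + eps)), eps = 1e-6."""
    ph, pb, ps, po, pi_ = region_props
    for p in region_props:
        if p < 0:
            raise DescriptorError(f"negative region proportion {p}")
    return math.log((ph + pb + SLR_EPS) / (ps + po + pi_ + SLR_EPS))


def isoelectric_point(seq: str, pka: dict[str, float] | None = None) -> float:
    """Isoelectric point by bisection of the Henderson–Hasselbalch net charge.

    Positive groups: N-terminus, K, R, H; negative: C-terminus, D, E, C, Y.
    The net charge is monotone decreasing in pH, so the root on [0, 14] is
    unique; bisection runs to interval width < 1e-6, which puts |Q| far
    below 1e-4 for desk-scale proteins.  Composition-only model: permuting
    the sequence does not change the value.
    """
    if pka is None:
        pka = EMBOSS_PKA
    counts = {a: 0 for a in "KRHDECY"}
    n_canonical = 0
    for c in seq:
        if c in AA_INDEX:
            n_canonical += 1
            if c in counts:
                counts[c] += 1
    if n_canonical == 0:
        raise DescriptorError("no canonical residues in sequence")

    def charge(ph: float) -> float:
        pos = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
        for a in "KRH":
            pos += counts[a] / (1.0 + 10 ** (ph - pka[a]))
        neg = 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
        for a in "DECY":
            neg += counts[a] / (1.0 + 10 ** (pka[a] - ph))
        return pos - neg

    lo, hi = 0.0, 14.0
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if charge(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Signal-peptide heuristic fallback

SP_FALLBACK_WINDOW = 8
SP_FALLBACK_SPAN = 30


def sp_heuristic(seq: str) -> tuple[float, float, float, float]:
    """Crude signal-peptide score for use when no annotation table is given:
    the best mean Kyte–Doolittle hydropathy over 8-residue windows within the
    first 30 residues, squashed to [0, 1].  NOT equivalent to a trained
    signal-peptide predictor; type probabilities are left at 0."""
    from .constants import KYTE_DOOLITTLE
    head = [KYTE_DOOLITTLE[c] for c in seq[:SP_FALLBACK_SPAN] if c in AA_INDEX]
    if len(head) < SP_FALLBACK_WINDOW:
        return (0.0, 0.0, 0.0, 0.0)
    h = np.array(head)
    means = np.convolve(h, np.ones(SP_FALLBACK_WINDOW) / SP_FALLBACK_WINDOW,
                        mode="valid")
    best = float(means.max())
    p_any = 1.0 / (1.0 + math.exp(-2.0 * (best - 2.25)))
    return (p_any, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Assembly

@dataclass
class FeatureConfig:
    """Tunable knobs of the descriptor set."""

    maxlag: int = 20
    w_qso: float = 0.1
    w_paac: float = 0.05
    distance_matrix: np.ndarray = field(default_factory=default_distance_matrix)
    scales: np.ndarray = field(default_factory=standardized_scales)
    pka: dict[str, float] = field(default_factory=lambda: dict(EMBOSS_PKA))


def assemble_features(record: ProteinRecord, bundle: AnnotationBundle,
                      config: FeatureConfig | None = None) -> np.ndarray:
    """Assemble the 466-vector AAC‖DPC‖pQSO‖pPAAC‖pI‖SLR‖SP for one protein.

    Pure function of its inputs; any sub-descriptor failure is re-raised with
    the offending block named.
    """
    if config is None:
        config = FeatureConfig()
    parts: list[np.ndarray] = []
    steps = [
        ("AAC", lambda: aac(record.seq)),
        ("DPC", lambda: dpc(record.seq)),
        ("pQSO", lambda: pqso(record.seq, config.maxlag, config.w_qso,
                              config.distance_matrix)),
        ("pPAAC", lambda: ppaac(record.seq, config.maxlag, config.w_paac,
                                config.scales)),
        ("pI", lambda: np.array([isoelectric_point(record.seq, config.pka)])),
        ("SLR", lambda: np.array([slr(bundle.region_props)])),
        ("SP", lambda: np.asarray(bundle.sp_probs, dtype=float)),
    ]
    for name, fn in steps:
        try:
            parts.append(np.atleast_1d(np.asarray(fn(), dtype=float)))
        except Exception as exc:
            raise DescriptorError(
                f"[{name}] failed for {record.id!r}: {exc}") from exc
    vec = np.concatenate(parts)
    if vec.size != N_FEATURES or not np.all(np.isfinite(vec)):
        raise DescriptorError(
            f"feature vector for {record.id!r} is malformed")
    return vec


def feature_matrix(records, bundles, config: FeatureConfig | None = None
                   ) -> np.ndarray:
    """Stack assemble_features over a record collection (rows in order)."""
    return np.vstack([
        assemble_features(r, bundles[r.id], config) for r in records])
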