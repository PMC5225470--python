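"""Soft-mode decomposition of the LRT response.

Modes of a C4-symmetric tetramer split into those that move all four
subunits identically ("non-degenerate"; they describe cooperative
transitions of the assembly) and the rest.  The symmetry check follows
the magnitude-correlation recipe: per mode, compute the N-vector of
per-residue displacement magnitudes, split it into the four chain
quarters, and require every pairwise Pearson correlation to exceed the
threshold (default 0.95, strict) for the mode to count as
non-degenerate.  Modes whose eigenvalues coincide to numerical
precision (relative gap < 1e-9 to a neighbour) are always classified
degenerate: within an exactly degenerate eigenspace the individual
eigenvectors returned by the solver are an arbitrary rotation of the
pair, so a single member's magnitude pattern is not well defined and
can pass the correlation test by accident.

The LRT displacement is then decomposed over the non-degenerate modes:
the overlap between two vectors is the absolute cosine of their angle,
and because eigenvectors are orthonormal the best k-mode combination is
obtained by projecting the normalised target onto each candidate mode
(coefficients a_i = v_i . d_hat) and keeping the k largest projections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enm import Spectrum
from .structure import Structure

logger = logging.getLogger("perturbnet")

DEGENERACY_THRESHOLD = 0.95
#: relative eigenvalue gap below which two modes count as an exactly
#: degenerate pair (their eigenvectors are then solver-arbitrary)
EIGENVALUE_PAIR_TOL = 1e-9


@dataclass
class ModeInfo:
    global_index: int        # 1-based rank by ascending eigenvalue, null modes excluded
    eigenvalue: float
    min_quarter_corr: float  # smallest of the 6 pairwise quarter correlations
    non_degenerate: bool


@dataclass
class ModeClassification:
    modes: list[ModeInfo]
    threshold: float

    @property
    def non_degenerate_indices(self) -> list[int]:
        return [m.global_index for m in self.modes if m.non_degenerate]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mode": [m.global_index for m in self.modes],
            "eigenvalue": [m.eigenvalue for m in self.modes],
            "min_quarter_corr": [m.min_quarter_corr for m in self.modes],
            "label": ["non-degenerate" if m.non_degenerate else "degenerate"
                      for m in self.modes],
        })


@dataclass
class ModeCombination:
    mode_indices: list[int]   # global indices of the included modes
    coefficients: np.ndarray  # a_i = v_i . d_hat
    combined: np.ndarray      # sum_i a_i v_i
    overlap: float            # overlap(combined, target)


def _quarter_correlations(mags: np.ndarray) -> float:
    """Minimum pairwise Pearson r between the four quarters of a magnitude vector."""
    quarters = np.array_split(mags, 4)
    rmin = 1.0
    for a in range(4):
        for b in range(a + 1, 4):
            qa, qb = quarters[a], quarters[b]
            if np.std(qa) < 1e-14 or np.std(qb) < 1e-14:
                logger.warning("zero-variance quarter; correlation treated as 0")
                r = 0.0
            else:
                r = float(np.corrcoef(qa, qb)[0, 1])
            rmin = min(rmin, r)
    return rmin


def classify_degeneracy(spectrum: Spectrum, structure: Structure,
                        threshold: float = DEGENERACY_THRESHOLD) -> ModeClassification:
    """Label every non-null mode by its four-fold magnitude symmetry."""
    lengths = set(structure.chain_lengths().values())
    if len(structure.chains) != 4 or len(lengths) != 1:
        raise ValueError("degeneracy classification requires 4 equal-length chains")
    infos = []
    vals = spectrum.eigenvalues
    for k in range(spectrum.null_count, vals.shape[0]):
        mags = np.linalg.norm(spectrum.eigenvectors[:, k].reshape(-1, 3), axis=1)
        rmin = _quarter_correlations(mags)
        # an exactly degenerate eigenvalue pair has solver-arbitrary
        # eigenvectors; classify its members degenerate regardless of rmin
        paired = any(
            spectrum.null_count <= j < vals.shape[0]
            and abs(vals[j] - vals[k]) <= EIGENVALUE_PAIR_TOL * abs(vals[k])
            for j in (k - 1, k + 1)
        )
        infos.append(ModeInfo(
            global_index=k - spectrum.null_count + 1,
            eigenvalue=float(vals[k]),
            min_quarter_corr=rmin,
            non_degenerate=(rmin > threshold) and not paired,  # strictly greater
        ))
    return ModeClassification(infos, threshold)


def overlap(v, d) -> float:
    """Absolute cosine of the angle between two 3N vectors, in [0, 1]."""
    v = np.asarray(v, dtype=float).ravel()
    d = np.asarray(d, dtype=float).ravel()
    nv, nd = np.linalg.norm(v), np.linalg.norm(d)
    if nv < 1e-300 or nd < 1e-300:
        raise ValueError("overlap undefined for a zero vector")
    return min(1.0, abs(float(v @ d)) / (nv * nd))


def _mode_vector(spectrum: Spectrum, global_index: int) -> np.ndarray:
    return spectrum.eigenvectors[:, spectrum.null_count + global_index - 1]


def best_linear_combination(spectrum: Spectrum, classification: ModeClassification,
                            d, k: int) -> ModeCombination:
    """Best k-term combination of non-degenerate modes describing ``d``.

    Modes are ranked by individual overlap with ``d`` (descending; ties
    broken by global index); for orthonormal modes this greedy choice
    is the exact best subset.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    candidates = classification.non_degenerate_indices
    if len(candidates) < k:
        raise ValueError(
            f"only {len(candidates)} non-degenerate modes available, need {k}"
        )
    d = np.asarray(d, dtype=float).ravel()
    d_hat = d / np.linalg.norm(d)
    scored = sorted(
        ((overlap(_mode_vector(spectrum, g), d), -g) for g in candidates),
        reverse=True,
    )
    chosen = sorted(-neg_g for _, neg_g in scored[:k])
    coeffs = np.array([float(_mode_vector(spectrum, g) @ d_hat) for g in chosen])
    combined = np.sum(
        [a * _mode_vector(spectrum, g) for a, g in zip(coeffs, chosen)], axis=0
    )
    return ModeCombination(chosen, coeffs, combined, overlap(combined, d))


def cumulative_overlap_report(spectrum: Spectrum, classification: ModeClassification,
                              d, k_max: int) -> pd.DataFrame:
    """Overlap of the best k-mode combination for k = 1..k_max."""
    rows = []
    k_max = min(k_max, len(classification.non_degenerate_indices))
    for k in range(1, k_max + 1):
        combo = best_linear_combination(spectrum, classification, d, k)
        rows.append({
            "k": k,
            "modes": ",".join(str(g) for g in combo.mode_indices),
            "overlap": combo.overlap,
        })
    return pd.DataFrame(rows)
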