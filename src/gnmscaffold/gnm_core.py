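"""Gaussian Network Model core: Kirchhoff matrix, eigensystem, fast-mode profile.

The GNM treats a protein chain as an elastic network over its Cα atoms: two
residues are connected when their Cα–Cα distance is at most 7 Å.  The network's
Kirchhoff (graph Laplacian) matrix Γ has eigenpairs (λ_k, u_k); large-λ "fast"
modes are spatially localized and identify tightly packed, kinetically hot
residues.  The per-residue mean-square fluctuation restricted to a mode set F is

    ⟨ΔR_i²⟩_F  ∝  Σ_{k∈F} λ_k⁻¹ [u_k]_i²  /  Σ_{k∈F} λ_k⁻¹

The physical prefactor k_B·T/γ is set to 1: the profile is normalized to unit
sum, so the prefactor cancels and the hot-residue threshold (0.05 of the total)
is scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .structure_io import ChainModel

__all__ = [
    "KirchhoffMatrix",
    "ModeSpectrum",
    "FluctuationProfile",
    "build_kirchhoff",
    "eigendecompose",
    "top_decile_mode_count",
    "fast_mode_profile",
    "hot_residues",
    "KIRCHHOFF_CUTOFF",
    "HOT_THRESHOLD",
]

#: Default Cα–Cα contact cutoff of the elastic network, Å.
KIRCHHOFF_CUTOFF = 7.0
#: Normalized-amplitude threshold above which a residue is kinetically hot.
HOT_THRESHOLD = 0.05

# Relative tolerance for treating an eigenvalue as zero.
_ZERO_TOL = 1e-8


@dataclass
class KirchhoffMatrix:
    """Laplacian of the Cα contact graph.

    ``residue_map[r]`` gives the chain seq_index of matrix row ``r`` (rows
    cover only residues with a resolved Cα).
    """

    matrix: np.ndarray
    cutoff: float
    residue_map: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ModeSpectrum:
    """Sorted eigensystem of a Kirchhoff matrix.

    ``eigenvalues`` ascending; ``eigenvectors[:, k]`` is the orthonormal
    eigenvector of ``eigenvalues[k]`` with a deterministic sign (largest-
    magnitude component positive).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    residue_map: np.ndarray

    @property
    def n(self) -> int:
        return len(self.eigenvalues)

    def zero_tolerance(self) -> float:
        scale = max(1.0, float(self.eigenvalues[-1]))
        return _ZERO_TOL * scale

    def n_zero_modes(self) -> int:
        """Number of (numerically) zero eigenvalues = connected components."""
        return int(np.sum(self.eigenvalues <= self.zero_tolerance()))


@dataclass
class FluctuationProfile:
    """Normalized fast-mode mean-square-fluctuation profile.

    ``values[r]`` is the kinetic weight of matrix row ``r``; when
    ``normalized`` the values sum to 1.
    """

    values: np.ndarray
    mode_count: int
    normalized: bool
    residue_map: np.ndarray


def build_kirchhoff(chain: ChainModel, cutoff: float = KIRCHHOFF_CUTOFF) -> KirchhoffMatrix:
    """Kirchhoff contact matrix over the chain's resolved Cα atoms.

    Γ_ij = −1 iff i ≠ j and d(Cα_i, Cα_j) ≤ cutoff; Γ_ii = contact degree.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if chain.length < 2:
        raise ValueError("chain must have at least 2 residues with resolved Cα")
    coords = chain.ca_array()
    diff = coords[:, None, :] - coords[None, :, :]
    dist2 = (diff ** 2).sum(axis=-1)
    adj = (dist2 <= cutoff ** 2).astype(float)
    np.fill_diagonal(adj, 0.0)
    gamma = np.diag(adj.sum(axis=1)) - adj
    return KirchhoffMatrix(matrix=gamma, cutoff=cutoff, residue_map=chain.ca_indices())


def eigendecompose(k: KirchhoffMatrix) -> ModeSpectrum:
    """Full ascending eigensystem with a deterministic sign convention."""
    gamma = np.asarray(k.matrix, dtype=float)
    if gamma.ndim != 2 or gamma.shape[0] != gamma.shape[1]:
        raise ValueError("Kirchhoff matrix must be square")
    if not np.allclose(gamma, gamma.T, atol=1e-10):
        raise ValueError("Kirchhoff matrix must be symmetric")
    evals, evecs = scipy.linalg.eigh(gamma)
    evals = np.clip(evals, 0.0, None)  # remove tiny negative round-off
    # sign convention: largest-magnitude component of each eigenvector positive
    pivot = np.argmax(np.abs(evecs), axis=0)
    signs = np.sign(evecs[pivot, np.arange(evecs.shape[1])])
    signs[signs == 0] = 1.0
    evecs = evecs * signs
    return ModeSpectrum(eigenvalues=evals, eigenvectors=evecs, residue_map=k.residue_map)


def top_decile_mode_count(spec: ModeSpectrum) -> int:
    """Number of fast modes covering the top 10% of the eigenvalue range.

    m = |{k : λ_k ≥ λ_max − 0.1·(λ_max − λ_min)}|, with λ_min the smallest
    eigenvalue (the trivial ≈0 mode included).
    """
    lam = spec.eigenvalues
    lam_min, lam_max = float(lam[0]), float(lam[-1])
    if lam_max - lam_min <= spec.zero_tolerance():
        raise ValueError("degenerate spectrum: all eigenvalues equal")
    threshold = lam_max - 0.1 * (lam_max - lam_min)
    return int(np.sum(lam >= threshold))


def fast_mode_profile(spec: ModeSpectrum, m: int) -> FluctuationProfile:
    """Normalized λ⁻¹-weighted fluctuation profile of the m fastest modes.

    values_i = Σ_{k∈F} λ_k⁻¹ [u_k]_i² / Σ_{k∈F} λ_k⁻¹ with F the m largest-λ
    modes (ties broken by descending eigenvalue then ascending mode index, the
    natural order of the sorted spectrum taken from the top).
    """
    n = spec.n
    if not 1 <= m <= n - 1:
        raise ValueError(f"mode count m={m} out of range [1, {n - 1}]")
    lam = spec.eigenvalues[n - m:]
    if np.any(lam <= spec.zero_tolerance()):
        raise ValueError("selected mode set includes a zero eigenvalue")
    vecs = spec.eigenvectors[:, n - m:]
    inv = 1.0 / lam
    values = (vecs ** 2) @ inv / inv.sum()
    total = values.sum()
    values = values / total  # unit sum (analytically already 1 for orthonormal u)
    return FluctuationProfile(
        values=values, mode_count=m, normalized=True, residue_map=spec.residue_map
    )


def hot_residues(profile: FluctuationProfile, threshold: float = HOT_THRESHOLD) -> set[int]:
    """Chain seq_index of residues with normalized amplitude strictly above
    ``threshold``; may be empty."""
    if not profile.normalized:
        raise ValueError("profile must be normalized")
    rows = np.nonzero(profile.values > threshold)[0]
    return {int(profile.residue_map[r]) for r in rows}
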