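"""Gaussian network model: Kirchhoff matrix, mode mobilities, hinges.

The GNM represents a folded protein as a network of residue nodes
(Cα atoms) connected by uniform harmonic springs within a cutoff
distance r_c (default 7.3 Å).  The network topology is encoded by the
Kirchhoff (graph Laplacian) matrix Γ; its eigenmodes describe the
isotropic fluctuation spectrum.  Low-frequency ("global") modes carry
large-amplitude collective domain motions, and residues with minimal
mobility in those modes act as hinges anchoring the interdomain motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure import StructureModel

__all__ = [
    "ElasticNetworkG",
    "ModeSet",
    "MobilityProfile",
    "build_gnm",
    "decompose_gnm",
    "mode_mobility",
    "cumulative_mobility",
    "dynamics_fraction",
    "find_hinges",
]


@dataclass
class ElasticNetworkG:
    """Kirchhoff matrix of a Cα contact network (spring constant factored out)."""

    kirchhoff: np.ndarray
    cutoff: float
    gamma: float
    residue_ids: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.kirchhoff.shape[0]

    @property
    def is_connected(self) -> bool:
        # Laplacian of a connected graph has exactly one (numerically) zero mode
        vals = np.linalg.eigvalsh(self.kirchhoff)
        tol = max(vals[-1], 1.0) * 1e-10
        return int(np.sum(vals < tol)) == 1


@dataclass
class ModeSet:
    """Eigen-decomposition of an elastic network with zero-mode bookkeeping.

    ``eigenvalues`` ascend; ``eigenvectors[:, k]`` is the k-th mode.
    Nonzero modes are indexed 1, 2, ... from the lowest nonzero
    eigenvalue, matching the usual "mode 1 = slowest internal mode"
    convention.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero: int
    residue_ids: np.ndarray

    @property
    def n_nonzero(self) -> int:
        return len(self.eigenvalues) - self.n_zero

    def mode(self, k: int) -> tuple[float, np.ndarray]:
        """Eigenvalue and eigenvector of nonzero mode ``k`` (1-based)."""
        if not 1 <= k <= self.n_nonzero:
            raise ValueError(f"mode index {k} outside 1..{self.n_nonzero}")
        idx = self.n_zero + k - 1
        return float(self.eigenvalues[idx]), self.eigenvectors[:, idx]


@dataclass
class MobilityProfile:
    """Per-residue mobility, from a single mode or a cumulative sum of modes."""

    values: np.ndarray
    residue_ids: np.ndarray
    mode_range: tuple[int, int]
    normalized: bool = False

    def normalized_copy(self) -> "MobilityProfile":
        """Max-normalised to [0, 1], for plotting/reporting."""
        top = self.values.max()
        vals = self.values / top if top > 0 else self.values.copy()
        return MobilityProfile(vals, self.residue_ids, self.mode_range, True)


def build_gnm(
    model: StructureModel, cutoff: float = 7.3, gamma: float = 1.0
) -> ElasticNetworkG:
    """Build the Kirchhoff matrix from Cα contacts within ``cutoff`` Å.

    Γ_ij = -1 for contacting pairs (i ≠ j), 0 otherwise; the diagonal
    holds the node degree so each row sums to zero.
    """
    if len(model) < 2:
        raise ValueError("a network needs at least 2 residues")
    coords = model.ca_coords
    d = squareform(pdist(coords))
    contact = (d <= cutoff) & ~np.eye(len(model), dtype=bool)
    k = -contact.astype(float)
    np.fill_diagonal(k, contact.sum(axis=1))
    net = ElasticNetworkG(k, cutoff, gamma, model.residue_ids)
    if not net.is_connected:
        warnings.warn(
            f"GNM network is disconnected at cutoff {cutoff} Å; "
            "decomposition will report more than one zero mode"
        )
    return net


def decompose_gnm(net: ElasticNetworkG, zero_tol: float = 1e-8) -> ModeSet:
    """Full eigen-decomposition of Γ with zero modes identified.

    Modes with λ < zero_tol · λ_max are classified as zero modes (one
    per connected component).  Degenerate nonzero eigenvalues are
    ordered by (λ, index of largest-magnitude eigenvector component)
    for determinism.
    """
    vals, vecs = np.linalg.eigh(net.kirchhoff)
    lam_max = max(vals[-1], 1.0)
    n_zero = int(np.sum(vals < zero_tol * lam_max))
    if n_zero < 1:
        raise RuntimeError("Laplacian lost its zero mode; numerical failure")
    # deterministic ordering within degenerate groups + sign convention
    order = sorted(
        range(len(vals)), key=lambda i: (round(vals[i] / (zero_tol * lam_max)), int(np.argmax(np.abs(vecs[:, i]))))
    )
    vals = vals[order]
    vecs = vecs[:, order]
    signs = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    if n_zero > 1:
        warnings.warn(f"{n_zero} zero modes: network has {n_zero} connected components")
    return ModeSet(vals, vecs, n_zero, net.residue_ids)


def mode_mobility(ms: ModeSet, k: int) -> MobilityProfile:
    """Mobility of residue i in nonzero mode k: M_i^(k) = (u_k)_i² / λ_k."""
    lam, u = ms.mode(k)
    return MobilityProfile(u**2 / lam, ms.residue_ids, (k, k))


def cumulative_mobility(ms: ModeSet, m: int = 10) -> MobilityProfile:
    """Cumulative mobility over the ``m`` lowest nonzero modes.

    ⟨M_i⟩|_m = Σ_{k=1..m} (u_k)_i² / λ_k.  Zero modes carry no internal
    motion and are not counted.
    """
    if m < 1 or m > ms.n_nonzero:
        raise ValueError(f"m={m} outside 1..{ms.n_nonzero} nonzero modes")
    vals = np.zeros(len(ms.residue_ids))
    for k in range(1, m + 1):
        vals += mode_mobility(ms, k).values
    return MobilityProfile(vals, ms.residue_ids, (1, m))


def dynamics_fraction(ms: ModeSet, m: int) -> float:
    """Fraction of the overall dynamics captured by the m slowest modes.

    Mode k contributes fluctuation amplitude ∝ 1/λ_k, so the captured
    fraction is Σ_{k≤m} λ_k⁻¹ / Σ_all λ_k⁻¹ over nonzero modes.
    """
    if m == 0:
        return 0.0
    if m < 0 or m > ms.n_nonzero:
        raise ValueError(f"m={m} outside 0..{ms.n_nonzero}")
    inv = 1.0 / ms.eigenvalues[ms.n_zero :]
    return float(inv[:m].sum() / inv.sum())


def find_hinges(
    profile: MobilityProfile, window: int = 5, percentile: float = 20.0
) -> list[int]:
    """Hinge residues: strict local minima of the mobility profile.

    A residue qualifies if it is the strict minimum within ±``window``
    positions and its mobility lies below the given ``percentile`` of
    the whole profile.  Returned sorted by mobility (deepest minimum
    first).  The low-percentile gate suppresses shallow ripples in
    already-mobile regions.
    """
    v = profile.values
    n = len(v)
    if n < 2 * window + 1:
        raise ValueError("profile too short for the requested window")
    if np.allclose(v, v[0]):
        return []
    thresh = np.percentile(v, percentile)
    hinges: list[tuple[float, int]] = []
    for i in range(n):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        neighbours = np.r_[v[lo:i], v[i + 1 : hi]]
        if v[i] <= thresh and neighbours.size and np.all(v[i] < neighbours):
            hinges.append((v[i], int(profile.residue_ids[i])))
    hinges.sort()
    return [rid for _, rid in hinges]
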