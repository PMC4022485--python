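"""Perturbation-response scanning (PRS) on an anisotropic elastic network.

PRS probes how a force applied at one residue propagates through the
structure: with the 3N×3N Hessian H of an anisotropic network model
(ANM), linear response gives the displacement field ΔR = H⁺ F for a
force F localised at residue i.  Averaging the squared displacement of
residue k over isotropically random unit forces at i yields the
response s_ik; the N×N map of these responses is asymmetric, which is
what lets PRS separate *effectors* (high row average: perturbing them
moves everything) from *sensors* (high column average: they move when
anything is perturbed) — a distinction a symmetric fluctuation
covariance matrix cannot make.

The isotropic average has a closed form: s_ik = ‖G_ki‖²_F / 3, where
G_ki is the 3×3 super-element of the Hessian pseudoinverse.  The
closed form is the default compute path; the Monte-Carlo protocol
(random unit forces) is retained as a seeded validation mode with the
same expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure import StructureModel

__all__ = [
    "ElasticNetworkA",
    "PRSMap",
    "build_anm",
    "prs_response",
    "prs_map",
    "influence_profile",
    "response_profile",
    "rank_effectors_sensors",
]

_N_RIGID_MODES = 6  # translations + rotations of a 3-D connected network


@dataclass
class ElasticNetworkA:
    """3N×3N ANM Hessian (spring constant factored out) plus bookkeeping."""

    hessian: np.ndarray
    cutoff: float
    gamma: float
    residue_ids: np.ndarray
    _pinv: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.residue_ids)

    def pseudoinverse(self, zero_tol: float = 1e-8) -> np.ndarray:
        """H⁺ with the six rigid-body modes removed (cached)."""
        if self._pinv is None:
            vals, vecs = np.linalg.eigh(self.hessian)
            lam_max = max(vals[-1], 1.0)
            n_zero = int(np.sum(vals < zero_tol * lam_max))
            if n_zero != _N_RIGID_MODES:
                raise ValueError(
                    f"expected {_N_RIGID_MODES} rigid-body modes, found {n_zero}: "
                    "network is disconnected or geometrically degenerate"
                )
            inv = np.zeros_like(vals)
            inv[n_zero:] = 1.0 / vals[n_zero:]
            self._pinv = (vecs * inv) @ vecs.T
        return self._pinv


@dataclass
class PRSMap:
    """N×N perturbation-response map with effector/sensor marginals.

    ``response[i, k]`` is the response of residue k to a perturbation at
    residue i.  ``effectiveness`` holds row means and ``sensitivity``
    column means, both excluding the diagonal (self-response is not
    signal propagation).
    """

    response: np.ndarray
    residue_ids: np.ndarray
    effectiveness: np.ndarray
    sensitivity: np.ndarray
    mode: str
    row_normalized: bool

    def _pos(self, residue_id: int) -> int:
        hits = np.nonzero(self.residue_ids == residue_id)[0]
        if len(hits) == 0:
            raise KeyError(f"residue {residue_id} not in PRS map")
        return int(hits[0])


def build_anm(
    model: StructureModel, cutoff: float = 13.0, gamma: float = 1.0
) -> ElasticNetworkA:
    """Standard pairwise ANM Hessian from Cα contacts within ``cutoff`` Å.

    Each contacting pair contributes the rank-1 super-element
    -γ (d d^T)/|d|² built from the inter-residue direction vector d.
    """
    n = len(model)
    if n < 3:
        raise ValueError("an ANM needs at least 3 residues")
    coords = model.ca_coords
    d = squareform(pdist(coords))
    contact = (d <= cutoff) & ~np.eye(n, dtype=bool)
    h = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in np.nonzero(contact[i])[0]:
            if j <= i:
                continue
            dv = coords[j] - coords[i]
            r2 = dv @ dv
            block = -gamma * np.outer(dv, dv) / r2
            h[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            h[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
            h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            h[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    net = ElasticNetworkA(h, cutoff, gamma, model.residue_ids)
    try:
        net.pseudoinverse()
    except ValueError as err:
        raise ValueError(f"degenerate ANM geometry: {err}") from None
    return net


def prs_response(
    net: ElasticNetworkA,
    i: int,
    mode: str = "closed_form",
    m_trials: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Response of every residue to an isotropic unit perturbation at ``i``.

    ``i`` is a residue id.  In ``closed_form`` mode the exact isotropic
    average s_ik = ‖G_ki‖²_F / 3 is returned; ``stochastic`` mode
    averages |ΔR_k|² over ``m_trials`` uniformly random unit forces.
    """
    pos = int(np.nonzero(net.residue_ids == i)[0][0]) if i in net.residue_ids else None
    if pos is None:
        raise KeyError(f"residue {i} not in network")
    g = net.pseudoinverse()
    cols = g[:, 3 * pos : 3 * pos + 3]  # G_ki stacked over k
    if mode == "closed_form":
        blocks = cols.reshape(net.n_nodes, 3, 3)
        return np.einsum("kab,kab->k", blocks, blocks) / 3.0
    if mode == "stochastic":
        if m_trials < 1:
            raise ValueError("m_trials must be >= 1")
        rng = np.random.default_rng(seed)
        f = rng.standard_normal((3, m_trials))
        f /= np.linalg.norm(f, axis=0, keepdims=True)
        dr = cols @ f  # (3N, m_trials)
        sq = dr.reshape(net.n_nodes, 3, m_trials) ** 2
        return sq.sum(axis=1).mean(axis=1)
    raise ValueError(f"unknown PRS mode {mode!r}")


def prs_map(
    net: ElasticNetworkA,
    mode: str = "closed_form",
    normalize_rows: bool = True,
    m_trials: int = 1000,
    seed: int | None = None,
) -> PRSMap:
    """Full N×N PRS map with effector/sensor marginals.

    Row i holds the responses to perturbing residue i.  With
    ``normalize_rows`` each row is divided by its self-response so
    entries are responses relative to the perturbation site, removing
    the trivial scaling by local flexibility.
    """
    n = net.n_nodes
    resp = np.empty((n, n))
    rng = np.random.default_rng(seed)
    for pos, rid in enumerate(net.residue_ids):
        sub_seed = int(rng.integers(2**31)) if mode == "stochastic" else None
        resp[pos] = prs_response(net, int(rid), mode, m_trials, sub_seed)
    if normalize_rows:
        diag = np.diag(resp).copy()
        if np.any(diag <= 0):
            bad = net.residue_ids[diag <= 0]
            raise ValueError(f"zero self-response at residues {bad}: isolated node?")
        resp = resp / diag[:, None]
    off = ~np.eye(n, dtype=bool)
    effectiveness = np.where(off, resp, 0.0).sum(axis=1) / (n - 1)
    sensitivity = np.where(off, resp, 0.0).sum(axis=0) / (n - 1)
    label = mode if mode == "closed_form" else f"stochastic(m={m_trials})"
    return PRSMap(resp, net.residue_ids, effectiveness, sensitivity, label, normalize_rows)


def influence_profile(prs: PRSMap, target: int) -> np.ndarray:
    """How strongly each residue, when perturbed, moves ``target``.

    This is the column of ``target``: peaks mark the residues with the
    greatest influence on (effectiveness with respect to) the target.
    """
    return prs.response[:, prs._pos(target)].copy()


def response_profile(prs: PRSMap, source: int) -> np.ndarray:
    """Response of the whole structure to perturbing ``source`` (its row)."""
    return prs.response[prs._pos(source)].copy()


def rank_effectors_sensors(
    prs: PRSMap, top_n: int = 10
) -> tuple[list[int], list[int], list[int]]:
    """Top-``top_n`` residues by effectiveness and by sensitivity.

    Returns (effectors, sensors, overlap).  Ties are broken by residue
    id for determinism.  In well-packed heterogeneous structures the
    two sets are largely disjoint: being easy to move and being able to
    move others are different structural roles.
    """
    def top(values: np.ndarray) -> list[int]:
        order = sorted(
            range(len(values)), key=lambda p: (-values[p], prs.residue_ids[p])
        )
        return [int(prs.residue_ids[p]) for p in order[:top_n]]

    effectors = top(prs.effectiveness)
    sensors = top(prs.sensitivity)
    overlap = sorted(set(effectors) & set(sensors))
    return effectors, sensors, overlap
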