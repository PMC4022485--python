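"""Ground-truth generators for every stage of the analysis.

Two families of synthetic fixtures, both pure functions of their
arguments plus a seed:

* **Structures** — two compact bead lobes (jittered cubic lattice,
  3.8 Å nearest-neighbour spacing, grown for compactness) joined by an
  extended linker whose beads have at most two contacts at the GNM
  cutoff.  This emulates the architecture of a two-domain protein such
  as Hsp70 (NBD–linker–SBD) with a *known* hinge, so hinge-detection
  can be scored against planted truth.

* **Alignments** — independent background columns drawn from
  Dirichlet-sampled profiles, optionally with conserved columns,
  phylogenetically redundant duplicate sequences, and *planted*
  pairwise-coupled column pairs of controlled strength.  Coupling is
  planted copula-style: with probability equal to the coupling
  parameter the second column's state is a fixed permutation image of
  the first, otherwise it is drawn independently — giving exact control
  of the target mutual information without Potts sampling.

Truth records (planted hinges, planted pairs with their realised MI)
are returned alongside the fixtures and can be serialised to JSON so
tests never re-derive truth from the fixture itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .msa import ALPHABET, AlignmentSet
from .structure import Residue, StructureModel, write_ca_pdb

__all__ = [
    "SyntheticStructureTruth",
    "SyntheticMSATruth",
    "make_two_domain_structure",
    "make_coupled_msa",
    "null_msa",
]

_SPACING = 3.8  # Å, Cα virtual-bond length
_MIN_SEPARATION = 2.5  # Å, steric clash bound

# 26-neighbourhood offsets on the cubic lattice
_NEIGHBOURS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)
_FACE_NEIGHBOURS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
)


@dataclass
class SyntheticStructureTruth:
    """A two-domain bead structure plus its planted ground truth.

    ``planted_hinge_ids`` spans the whole flexible bridge — the linker
    chain plus the two lobe attachment beads it hangs from — because
    the mobility node of a two-lobe system sits anywhere along the
    bridge depending on the lobe mass ratio.  ``linker_ids`` is the
    strict chain-linker subset (the beads guaranteed to have at most
    two contacts at the GNM cutoff).
    """

    model: StructureModel
    planted_hinge_ids: list[int]
    linker_ids: list[int]
    lobe_sizes: tuple[int, int]
    linker_len: int
    seed: int

    def truth_json(self) -> str:
        return json.dumps(
            {
                "planted_hinge_ids": self.planted_hinge_ids,
                "linker_ids": self.linker_ids,
                "lobe_sizes": list(self.lobe_sizes),
                "linker_len": self.linker_len,
                "seed": self.seed,
            },
            indent=2,
        )

    def write(self, pdb_path: str, truth_path: str | None = None) -> None:
        write_ca_pdb(self.model, pdb_path)
        if truth_path:
            with open(truth_path, "w") as fh:
                fh.write(self.truth_json())


@dataclass
class SyntheticMSATruth:
    """A synthetic alignment plus planted coupling/conservation truth."""

    msa: AlignmentSet
    planted_pairs: list[dict]
    conserved_cols: list[dict]
    redundancy_groups: list[list[int]]
    seed: int

    def planted_column_pairs(self) -> list[tuple[int, int]]:
        return [(p["col_a"], p["col_b"]) for p in self.planted_pairs]

    def truth_json(self) -> str:
        return json.dumps(
            {
                "planted_pairs": self.planted_pairs,
                "conserved_cols": self.conserved_cols,
                "redundancy_groups": self.redundancy_groups,
                "seed": self.seed,
            },
            indent=2,
        )


def _grow_lobe(n: int, rng: np.random.Generator) -> np.ndarray:
    """Compact connected cluster of n sites on the unit cubic lattice.

    Random sequential packing biased toward the candidate with the most
    occupied neighbours, which guarantees connectivity and produces
    globular lobes (interior mean degree well above 6 at the GNM
    cutoff once scaled to 3.8 Å spacing).
    """
    occupied = {(0, 0, 0)}
    frontier = {tuple(d) for d in _FACE_NEIGHBOURS}
    while len(occupied) < n:
        cands = list(frontier)
        scores = np.array(
            [
                sum((tuple(np.add(c, d)) in occupied) for d in _NEIGHBOURS)
                for c in cands
            ]
        )
        best = np.nonzero(scores == scores.max())[0]
        pick = cands[int(rng.choice(best))]
        occupied.add(pick)
        frontier.discard(pick)
        for d in _FACE_NEIGHBOURS:
            site = tuple(np.add(pick, d))
            if site not in occupied:
                frontier.add(site)
    return np.array(sorted(occupied), dtype=float)


def make_two_domain_structure(
    n_lobe1: int = 30,
    n_lobe2: int = 30,
    linker_len: int = 4,
    seed: int = 0,
    jitter: float = 0.25,
    max_retries: int = 5,
) -> SyntheticStructureTruth:
    """Two compact bead lobes joined by an extended linker.

    Residue ids run 1..n1 (lobe1), n1+1..n1+linker_len (linker, the
    planted hinge), then the second lobe.  Nodes are labelled
    ``lobe1`` / ``linker`` / ``lobe2``.  Deterministic under ``seed``.
    """
    if n_lobe1 < 20 or n_lobe2 < 20:
        raise ValueError("lobes need at least 20 beads each to be meaningfully dense")
    rng = np.random.default_rng(seed)
    for _attempt in range(max_retries):
        # each lobe = compact cluster + one protruding "stalk" bead that
        # carries the linker attachment, so linker beads see exactly one
        # lobe contact at the GNM cutoff
        lobe1 = _grow_lobe(n_lobe1 - 1, rng) * _SPACING
        lobe2 = _grow_lobe(n_lobe2 - 1, rng) * _SPACING
        lobe1 += rng.uniform(-jitter, jitter, lobe1.shape)
        lobe2 += rng.uniform(-jitter, jitter, lobe2.shape)
        tip1 = lobe1[int(np.argmax(lobe1[:, 0]))] + np.array([_SPACING, 0, 0])
        lobe1 = np.vstack([lobe1, tip1])
        lobe1 -= tip1  # stalk bead at origin
        # gently helical linker: exact 3.8 Å consecutive spacing with an
        # off-axis sweep — a collinear chain would leave the anisotropic
        # network with zero-energy bending/torsion mechanisms
        amp, phase0, dphase, gap = 1.5, 0.0, 1.0, 4.2
        lateral = amp * np.column_stack(
            [
                np.cos(phase0 + dphase * np.arange(linker_len)),
                np.sin(phase0 + dphase * np.arange(linker_len)),
            ]
        )
        step = np.sqrt(
            _SPACING**2
            - np.sum(np.diff(lateral, axis=0) ** 2, axis=1)
        )
        x = gap + np.concatenate([[0.0], np.cumsum(step)])
        linker = np.column_stack([x, lateral[:, 0], lateral[:, 1]])
        tip2_target = linker[-1] + np.array([gap, -linker[-1, 1], -linker[-1, 2]])
        a2 = int(np.argmin(lobe2[:, 0]))
        tip2 = lobe2[a2] - np.array([_SPACING, 0, 0])
        lobe2 = np.vstack([tip2, lobe2]) + (tip2_target - tip2)
        coords = np.vstack([lobe1, linker, lobe2])
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() >= _MIN_SEPARATION:
            break
    else:
        raise RuntimeError(
            f"could not build a clash-free structure in {max_retries} attempts"
        )
    labels = (
        ["lobe1"] * n_lobe1 + ["linker"] * linker_len + ["lobe2"] * n_lobe2
    )
    residues = [
        Residue(
            residue_id=i + 1,
            chain_id="A",
            aa="A",
            ca_xyz=tuple(coords[i]),
            label=labels[i],
        )
        for i in range(len(coords))
    ]
    model = StructureModel(residues, source_id=f"synthetic-two-domain-seed{seed}")
    linker_ids = list(range(n_lobe1 + 1, n_lobe1 + linker_len + 1))
    # bridge = attachment stalk of lobe1, the linker chain, stalk of lobe2
    hinge_ids = list(range(n_lobe1, n_lobe1 + linker_len + 2))
    return SyntheticStructureTruth(
        model, hinge_ids, linker_ids, (n_lobe1, n_lobe2), linker_len, seed
    )


def _realized_mi(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """MI in nats of two sampled columns, by direct count enumeration."""
    joint = np.zeros((21, 21))
    for a, b in zip(col_a, col_b):
        joint[a, b] += 1
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    mi = 0.0
    for a in range(21):
        for b in range(21):
            if joint[a, b] > 0:
                mi += joint[a, b] * np.log(joint[a, b] / (pa[a] * pb[b]))
    return float(mi)


def make_coupled_msa(
    L: int = 100,
    N: int = 2000,
    planted: list[tuple[tuple[int, int], float]] | None = None,
    conserved: list[tuple[int, float]] | None = None,
    n_duplicate_groups: int = 0,
    n_pair_states: int = 4,
    dirichlet_alpha: float = 0.5,
    seed: int = 0,
) -> SyntheticMSATruth:
    """Synthetic alignment with planted couplings and conservation.

    ``planted`` lists ((col_a, col_b), coupling) with 0-based column
    indices and coupling ∈ [0, 1]; each planted pair uses
    ``n_pair_states`` equiprobable amino-acid states and a random
    permutation as the coupled map, so coupling 1 yields MI =
    ln(n_pair_states) in the infinite-sample limit.  ``conserved``
    lists (col, dominant_freq).  ``n_duplicate_groups`` exact duplicate
    sequences are appended to exercise redundancy weighting.  Columns
    are mapped to reference residue ids 1..L.
    """
    planted = list(planted or [])
    conserved = list(conserved or [])
    used: set[int] = set()
    for (ca, cb), coup in planted:
        if not 0 <= coup <= 1:
            raise ValueError(f"coupling {coup} outside [0, 1]")
        if ca in used or cb in used or ca == cb:
            raise ValueError("planted pairs must use disjoint columns")
        used.update((ca, cb))
    for col, freq in conserved:
        if col in used:
            raise ValueError(f"column {col} already used by a planted pair")
        used.add(col)
    if any(c >= L for c in used):
        raise ValueError("planted/conserved column index outside alignment")
    if n_pair_states > 20:
        raise ValueError("planted pairs are restricted to the 20 amino acids")

    rng = np.random.default_rng(seed)
    matrix = np.empty((N, L), dtype=np.int8)
    # independent background columns from Dirichlet-sampled profiles
    for col in range(L):
        if col in used:
            continue
        profile = rng.dirichlet(np.full(20, dirichlet_alpha))
        matrix[:, col] = rng.choice(20, size=N, p=profile)
    conserved_truth = []
    for col, freq in conserved:
        dominant = int(rng.integers(20))
        rest = (1.0 - freq) / 19.0
        profile = np.full(20, rest)
        profile[dominant] = freq
        matrix[:, col] = rng.choice(20, size=N, p=profile)
        conserved_truth.append(
            {"col": col, "dominant_aa": ALPHABET[dominant], "dominant_freq": freq}
        )
    planted_truth = []
    for (ca, cb), coup in planted:
        states = rng.choice(20, size=n_pair_states, replace=False)
        perm = rng.permutation(n_pair_states)
        a_idx = rng.integers(n_pair_states, size=N)
        coupled = rng.random(N) < coup
        b_idx = np.where(coupled, perm[a_idx], rng.integers(n_pair_states, size=N))
        matrix[:, ca] = states[a_idx]
        matrix[:, cb] = states[b_idx]
        planted_truth.append(
            {
                "col_a": int(ca),
                "col_b": int(cb),
                "coupling": float(coup),
                "states": [ALPHABET[s] for s in states],
                "permutation": perm.tolist(),
                "realized_mi_nats": _realized_mi(matrix[:, ca], matrix[:, cb]),
            }
        )
    redundancy_groups: list[list[int]] = []
    if n_duplicate_groups:
        originals = rng.choice(N, size=n_duplicate_groups, replace=False)
        dup_rows = matrix[originals]
        matrix = np.vstack([matrix, dup_rows])
        redundancy_groups = [
            [int(orig), N + k] for k, orig in enumerate(originals)
        ]
    ids = [f"seq{i}" for i in range(matrix.shape[0])]
    column_map = np.arange(1, L + 1)
    msa = AlignmentSet(ids, matrix, column_map=column_map)
    return SyntheticMSATruth(msa, planted_truth, conserved_truth, redundancy_groups, seed)


def null_msa(L: int = 50, N: int = 1000, seed: int = 0) -> AlignmentSet:
    """Fully independent columns: the null model for score calibration."""
    return make_coupled_msa(L=L, N=N, seed=seed).msa
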