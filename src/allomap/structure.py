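"""Residue-level structure handling for two-domain allostery analysis.

A :class:`StructureModel` is an ordered list of residue nodes (one per
residue with a resolved Cα), each carrying the author-assigned residue
number, one-letter amino-acid code, the Cα coordinate, optionally the
full set of heavy-atom coordinates, and a domain label.  Author residue
numbering (as deposited) is the coordinate system everywhere in this
package; residues are never re-indexed, so residue names like T417 or
D481 in the Hsp70/DnaK literature map directly onto node identifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
import biotite.structure.io.pdbx as pdbx
from biotite.sequence import ProteinSequence

__all__ = [
    "Residue",
    "StructureModel",
    "DomainMap",
    "DNAK_DOMAIN_MAP",
    "DNAK_NBD_RANGE",
    "DNAK_SBD_RANGE",
    "read_structure",
    "annotate_domains",
    "residue_distance",
    "write_residue_table",
    "write_ca_pdb",
]


@dataclass(frozen=True)
class Residue:
    """One residue node: author id, chain, amino acid, coordinates."""

    residue_id: int
    chain_id: str
    aa: str
    ca_xyz: tuple[float, float, float]
    heavy_atoms: tuple[tuple[float, float, float], ...] = ()
    label: str = "other"


@dataclass
class StructureModel:
    """Ordered residue nodes extracted from one chain of a structure."""

    residues: list[Residue]
    source_id: str = ""

    def __post_init__(self) -> None:
        coords = self.ca_coords
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("non-finite Cα coordinates")
        ids = [r.residue_id for r in self.residues]
        by_chain: dict[str, int] = {}
        for r in self.residues:
            prev = by_chain.get(r.chain_id)
            if prev is not None and r.residue_id <= prev:
                raise ValueError(
                    f"residue ids not strictly increasing in chain {r.chain_id!r}: "
                    f"{prev} then {r.residue_id}"
                )
            by_chain[r.chain_id] = r.residue_id
        self._index = {i: pos for pos, i in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def residue_ids(self) -> np.ndarray:
        return np.array([r.residue_id for r in self.residues], dtype=int)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca_xyz for r in self.residues], dtype=float).reshape(-1, 3)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.residues]

    def index_of(self, residue_id: int) -> int:
        """Position of a residue id in the node ordering."""
        try:
            return self._index[residue_id]
        except KeyError:
            raise KeyError(f"residue {residue_id} not in structure") from None

    def __contains__(self, residue_id: int) -> bool:
        return residue_id in self._index

    def get(self, residue_id: int) -> Residue:
        return self.residues[self.index_of(residue_id)]


@dataclass(frozen=True)
class DomainMap:
    """Named, closed residue-id intervals labelling domains/subdomains.

    ``segments`` maps a label to a tuple of ``(first, last)`` inclusive
    intervals in author numbering.  Lookup is total: ids outside every
    interval get the sentinel label ``"other"``.
    """

    segments: dict[str, tuple[tuple[int, int], ...]]

    def __post_init__(self) -> None:
        seen: list[tuple[int, int, str]] = []
        for label, ranges in self.segments.items():
            for lo, hi in ranges:
                if lo > hi:
                    raise ValueError(f"{label}: empty interval {lo}-{hi}")
                for plo, phi, plabel in seen:
                    if lo <= phi and plo <= hi and plabel != label:
                        raise ValueError(
                            f"overlapping intervals: {label} {lo}-{hi} vs "
                            f"{plabel} {plo}-{phi}"
                        )
                seen.append((lo, hi, label))

    def lookup(self, residue_id: int) -> str:
        for label, ranges in self.segments.items():
            for lo, hi in ranges:
                if lo <= residue_id <= hi:
                    return label
        return "other"

    def residues_of(self, *labels: str) -> list[int]:
        """All residue ids covered by the given labels, ascending."""
        out: set[int] = set()
        for label in labels:
            for lo, hi in self.segments.get(label, ()):
                out.update(range(lo, hi + 1))
        return sorted(out)


#: Default DnaK (E. coli Hsp70) domain partition.  NBD subdomains IA, IB,
#: IIA, IIB; the interdomain linker; and the substrate-binding domain.
DNAK_DOMAIN_MAP = DomainMap(
    {
        "IA": ((3, 38), (112, 184)),
        "IB": ((39, 111),),
        "IIA": ((185, 228), (310, 388)),
        "IIB": ((229, 309),),
        "linker": ((389, 392),),
        "SBD": ((393, 604),),
    }
)

#: Whole-domain residue ranges used when enumerating NBD x SBD pairs.
#: The NBD is counted as residues 1-388 (388 residues) and the SBD as
#: 393-604 (212 residues), so the interdomain pair space has
#: 388 * 212 = 82,256 candidate pairs.
DNAK_NBD_RANGE = (1, 388)
DNAK_SBD_RANGE = (393, 604)


def _load_atoms(path: str, model_index: int) -> struc.AtomArray:
    path = str(path)
    if path.endswith((".cif", ".mmcif", ".pdbx")):
        f = pdbx.CIFFile.read(path)
        atoms = pdbx.get_structure(f, model=model_index, altloc="occupancy")
    else:
        f = pdb.PDBFile.read(path)
        atoms = pdb.get_structure(f, model=model_index, altloc="occupancy")
    return atoms


def read_structure(
    path: str,
    chain: str | None = None,
    model_index: int = 1,
    include_hetero: bool = False,
    max_skip_fraction: float = 0.10,
) -> StructureModel:
    """Read a PDB or mmCIF file into a residue-node model.

    One node is created per residue possessing a Cα atom.  Alternate
    locations are resolved to the highest-occupancy conformer (ties fall
    to the first conformer in file order, i.e. alphabetically for
    conventionally written files).  Residues lacking a Cα are skipped
    with a warning; if more than ``max_skip_fraction`` of the chain is
    skipped, an error is raised.

    Parameters
    ----------
    chain:
        Chain identifier.  ``None`` selects the first chain in the file.
    include_hetero:
        If False (default) only standard amino-acid residues enter the
        node set; bound nucleotides, ions and waters are excluded.
    """
    atoms = _load_atoms(path, model_index)
    chains = sorted(set(atoms.chain_id))
    if chain is None:
        chain = atoms.chain_id[0]
    if chain not in chains:
        raise ValueError(f"chain {chain!r} not found; available chains: {chains}")
    atoms = atoms[atoms.chain_id == chain]
    if not include_hetero:
        atoms = atoms[struc.filter_amino_acids(atoms)]
    # drop hydrogens; nodes are built from heavy atoms only
    atoms = atoms[atoms.element != "H"]

    residues: list[Residue] = []
    n_skipped = 0
    n_total = 0
    for res in struc.residue_iter(atoms):
        n_total += 1
        ca = res[res.atom_name == "CA"]
        if len(ca) == 0:
            warnings.warn(
                f"residue {res.res_name[0]} {res.res_id[0]} lacks a Cα atom; skipped"
            )
            n_skipped += 1
            continue
        try:
            one = ProteinSequence.convert_letter_3to1(res.res_name[0])
        except KeyError:
            one = "X"
        residues.append(
            Residue(
                residue_id=int(res.res_id[0]),
                chain_id=chain,
                aa=one,
                ca_xyz=tuple(float(x) for x in ca.coord[0]),
                heavy_atoms=tuple(tuple(float(x) for x in c) for c in res.coord),
            )
        )
    if n_total == 0:
        raise ValueError(f"no residues found in chain {chain!r} of {path}")
    if n_skipped > max_skip_fraction * n_total:
        raise ValueError(
            f"{n_skipped}/{n_total} residues lack a Cα atom "
            f"(exceeds {max_skip_fraction:.0%})"
        )
    return StructureModel(residues, source_id=str(path))


def annotate_domains(model: StructureModel, domain_map: DomainMap) -> StructureModel:
    """Return a copy of the model with every residue carrying a domain label."""
    labelled = [replace(r, label=domain_map.lookup(r.residue_id)) for r in model.residues]
    return StructureModel(labelled, source_id=model.source_id)


def residue_distance(
    model: StructureModel, i: int, j: int, convention: str = "ca"
) -> float:
    """Distance in Å between residues ``i`` and ``j``.

    ``convention="ca"`` measures Cα–Cα; ``convention="heavy_min"``
    measures the minimum over all heavy-atom pairs and requires heavy
    atoms to have been loaded.
    """
    ri, rj = model.get(i), model.get(j)
    if convention == "ca":
        return float(np.linalg.norm(np.subtract(ri.ca_xyz, rj.ca_xyz)))
    if convention == "heavy_min":
        if not ri.heavy_atoms or not rj.heavy_atoms:
            raise ValueError("heavy_min distance requires heavy atoms to be loaded")
        a = np.asarray(ri.heavy_atoms)
        b = np.asarray(rj.heavy_atoms)
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        return float(d.min())
    raise ValueError(f"unknown distance convention {convention!r}")


def write_residue_table(model: StructureModel, path: str) -> None:
    """Per-residue annotation table (TSV: residue_id, chain, aa, label)."""
    with open(path, "w") as fh:
        fh.write("residue_id\tchain\taa\tlabel\n")
        for r in model.residues:
            fh.write(f"{r.residue_id}\t{r.chain_id}\t{r.aa}\t{r.label}\n")


def write_ca_pdb(
    model: StructureModel, path: str, bfactor: np.ndarray | None = None
) -> None:
    """Write the Cα trace as a PDB file.

    ``bfactor`` (length N) is written into the B-factor column, which is
    the conventional channel for painting a per-residue profile onto a
    structure in molecular-graphics tools.
    """
    n = len(model)
    atoms = struc.AtomArray(n)
    atoms.coord = model.ca_coords
    atoms.chain_id = np.array([r.chain_id or "A" for r in model.residues])
    atoms.res_id = model.residue_ids
    atoms.res_name = np.array(
        [
            ProteinSequence.convert_letter_1to3(r.aa) if r.aa != "X" else "UNK"
            for r in model.residues
        ]
    )
    atoms.atom_name = np.array(["CA"] * n)
    atoms.element = np.array(["C"] * n)
    atoms.hetero = np.zeros(n, dtype=bool)
    if bfactor is not None:
        if len(bfactor) != n:
            raise ValueError("bfactor length does not match residue count")
        atoms.set_annotation("b_factor", np.asarray(bfactor, dtype=float))
    f = pdb.PDBFile()
    pdb.set_structure(f, atoms)
    f.write(str(path))
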