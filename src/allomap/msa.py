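"""Alignment handling: I/O, reference mapping, weighting, conservation.

Sequences are stored column-aligned and integer-encoded over a 21-letter
alphabet (20 amino acids + gap).  Redundancy is handled by the standard
identity-based weighting scheme (a sequence's weight is the reciprocal
of the number of alignment members within an identity threshold of it),
and conservation is measured by per-column Shannon entropy.  Alignment
columns can be mapped to the residue numbering of a named reference
sequence so that column-level statistics can be reported against
structure residue ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALPHABET",
    "GAP_STATE",
    "AlignmentSet",
    "FrequencyTables",
    "read_msa",
    "write_msa",
    "map_to_reference",
    "sequence_weights",
    "filter_columns",
    "frequencies",
    "shannon_entropy",
]

#: Canonical state order: 20 amino acids then the gap state.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
GAP_STATE = 20
N_STATES = 21
_CODE = {c: i for i, c in enumerate(ALPHABET)}


def encode(seq: str) -> np.ndarray:
    """Integer-encode an aligned sequence; unknown letters become gaps."""
    return np.array([_CODE.get(c, GAP_STATE) for c in seq.upper().replace(".", "-")], dtype=np.int8)


def decode(row: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in row)


@dataclass
class AlignmentSet:
    """A multiple sequence alignment with weights and a column→residue map.

    ``matrix`` is (n_sequences, n_columns) int8 over `ALPHABET` codes.
    ``column_map`` holds, per column, the reference residue id or -1 for
    unmapped columns.  ``weights`` default to 1 per sequence until
    :func:`sequence_weights` is applied.
    """

    ids: list[str]
    matrix: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    column_map: np.ndarray = field(default=None)  # type: ignore[assignment]
    ref_annotation: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("id count does not match row count")
        if self.weights is None:
            self.weights = np.ones(self.matrix.shape[0])
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("sequence weights must be positive")
        if self.column_map is None:
            self.column_map = np.full(self.matrix.shape[1], -1, dtype=int)
        self.column_map = np.asarray(self.column_map, dtype=int)
        mapped = self.column_map[self.column_map >= 0]
        if len(mapped) != len(np.unique(mapped)):
            raise ValueError("column_map must be injective on mapped columns")

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def m_eff(self) -> float:
        """Effective number of sequences after redundancy weighting."""
        return float(self.weights.sum())

    def sequence(self, idx: int) -> str:
        return decode(self.matrix[idx])

    def column_residue_ids(self) -> np.ndarray:
        return self.column_map.copy()


@dataclass
class FrequencyTables:
    """Weighted single- and pairwise-column state frequencies.

    With additive pseudocount λ distributed uniformly over the q = 21
    states: f_i(a) = (λ/q + c_i(a)) / (λ + M_eff) where c_i(a) is the
    weighted count; pairwise analogously with λ/q².  ``f_ij`` is stored
    as an (L·q, L·q) matrix of q×q blocks.
    """

    f_i: np.ndarray
    f_ij: np.ndarray
    pseudocount: float
    m_eff: float
    column_map: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.f_i.shape[0]

    def pair_block(self, i: int, j: int) -> np.ndarray:
        """The q×q joint table of columns i, j."""
        q = N_STATES
        return self.f_ij[i * q : (i + 1) * q, j * q : (j + 1) * q]


def read_msa(path: str, fmt: str = "fasta") -> AlignmentSet:
    """Read a FASTA or Stockholm alignment.

    Ragged alignments raise with the offending row id.  A Stockholm
    ``#=GC RF`` reference-annotation line, if present, is preserved.
    """
    if fmt not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    try:
        aln = AlignIO.read(path, fmt)
    except ValueError as err:
        # biopython folds ragged-length problems into a generic ValueError;
        # re-check row lengths ourselves to name the culprit
        from Bio import SeqIO

        lengths = {}
        try:
            for rec in SeqIO.parse(path, fmt):
                lengths[rec.id] = len(rec.seq)
        except Exception:
            raise ValueError(f"could not parse {path} as {fmt}: {err}") from None
        if len(set(lengths.values())) > 1:
            ref_len = next(iter(lengths.values()))
            bad = [i for i, n in lengths.items() if n != ref_len]
            raise ValueError(f"ragged alignment: rows {bad} differ in length") from None
        raise ValueError(f"could not parse {path} as {fmt}: {err}") from None
    ids = [rec.id for rec in aln]
    matrix = np.vstack([encode(str(rec.seq)) for rec in aln])
    rf = aln.column_annotations.get("reference_annotation") if aln.column_annotations else None
    return AlignmentSet(ids, matrix, ref_annotation=rf)


def write_msa(msa: AlignmentSet, path: str, fmt: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(msa.sequence(i)), id=msa.ids[i], description="")
        for i in range(msa.n_sequences)
    ]
    aln = MultipleSeqAlignment(records)
    if msa.ref_annotation is not None and fmt == "stockholm":
        aln.column_annotations["reference_annotation"] = msa.ref_annotation
    AlignIO.write(aln, path, fmt)


def map_to_reference(msa: AlignmentSet, ref_id: str, ref_start: int) -> AlignmentSet:
    """Assign reference residue ids to the columns.

    Columns where the reference row is non-gap get consecutive ids
    ``ref_start``, ``ref_start``+1, …; reference-gap columns stay
    unmapped (-1).
    """
    try:
        row = msa.ids.index(ref_id)
    except ValueError:
        raise KeyError(f"reference id {ref_id!r} not in alignment") from None
    ref = msa.matrix[row]
    non_gap = ref != GAP_STATE
    if not non_gap.any():
        raise ValueError(f"reference row {ref_id!r} is all gaps")
    cmap = np.full(msa.n_columns, -1, dtype=int)
    cmap[non_gap] = ref_start + np.arange(non_gap.sum())
    return AlignmentSet(msa.ids, msa.matrix, msa.weights, cmap, msa.ref_annotation)


def sequence_weights(msa: AlignmentSet, identity_threshold: float = 0.8) -> AlignmentSet:
    """Down-weight phylogenetically redundant sequences.

    Sequence s gets weight 1 / |{t : identity(s, t) ≥ threshold}|, where
    identity is the fraction of matching alignment positions (gap
    counted as a state).  M_eff = Σ weights.  Computed blockwise with a
    one-hot product so large alignments stay tractable.
    """
    x = msa.matrix
    n, length = x.shape
    onehot = np.zeros((n, length * N_STATES), dtype=np.float32)
    onehot[np.arange(n)[:, None], np.arange(length) * N_STATES + x] = 1.0
    counts = np.zeros(n)
    block = max(1, int(2e8 / max(onehot.shape[1], 1) / 8))
    for lo in range(0, n, block):
        sim = onehot[lo : lo + block] @ onehot.T  # match counts
        counts[lo : lo + block] = (sim / length >= identity_threshold - 1e-12).sum(axis=1)
    weights = 1.0 / counts
    return AlignmentSet(msa.ids, msa.matrix, weights, msa.column_map, msa.ref_annotation)


def filter_columns(
    msa: AlignmentSet, max_gap_fraction: float = 0.5, mapped_only: bool = False
) -> AlignmentSet:
    """Drop columns with too many gaps (and, optionally, unmapped columns)."""
    gap_frac = (msa.matrix == GAP_STATE).mean(axis=0)
    keep = gap_frac <= max_gap_fraction
    if mapped_only:
        keep &= msa.column_map >= 0
    return AlignmentSet(
        msa.ids, msa.matrix[:, keep], msa.weights, msa.column_map[keep], None
    )


def frequencies(
    msa: AlignmentSet, pseudocount: float = 0.0, weighted: bool = True
) -> FrequencyTables:
    """Weighted (or raw) single and pairwise state frequencies.

    λ = 0 gives the raw weighted frequencies; λ → ∞ approaches the
    uniform distribution over the 21 states.
    """
    w = msa.weights if weighted else np.ones(msa.n_sequences)
    m_eff = w.sum()
    n, length = msa.matrix.shape
    onehot = np.zeros((n, length * N_STATES))
    onehot[np.arange(n)[:, None], np.arange(length) * N_STATES + msa.matrix] = 1.0
    counts_i = (w[:, None] * onehot).sum(axis=0).reshape(length, N_STATES)
    counts_ij = (onehot * w[:, None]).T @ onehot
    lam = float(pseudocount)
    f_i = (lam / N_STATES + counts_i) / (lam + m_eff)
    f_ij = (lam / N_STATES**2 + counts_ij) / (lam + m_eff)
    return FrequencyTables(f_i, f_ij, lam, m_eff, msa.column_map.copy())


def shannon_entropy(msa: AlignmentSet, weighted: bool = False, base: float = np.e) -> np.ndarray:
    """Per-column Shannon entropy over the 20 amino acids (gaps excluded).

    Frequencies are renormalised over the amino-acid states before the
    entropy H_i = −Σ_a f_i(a) log f_i(a) is taken, so a column's score
    reflects the diversity of the residues actually present: 0 for a
    fully conserved column, ln 20 for a uniform one.  Default unit is
    nats; pass ``base=2`` for bits.
    """
    ft = frequencies(msa, pseudocount=0.0, weighted=weighted)
    aa = ft.f_i[:, :GAP_STATE]
    totals = aa.sum(axis=1, keepdims=True)
    h = np.zeros(msa.n_columns)
    ok = totals[:, 0] > 0
    p = np.where(totals > 0, aa / np.where(totals > 0, totals, 1.0), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h[ok] = -terms[ok].sum(axis=1)
    return h / np.log(base)
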