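"""Pairwise whole-genome identity, per-region variability, and an NJ tree.

Identity is computed from a global pairwise alignment: matching columns over
total alignment columns, with gap columns counting in the denominator (the
simplest defensible convention for untrimmed whole-genome comparisons).
Alignment uses exact edit-distance dynamic programming (edlib); sequences
longer than the built-in cap must arrive as a precomputed alignment.
Ambiguity codes and N are treated as missing - never a match, never a
variable state.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from Bio import SeqIO

from .errors import CapabilityError, ContractError, CoordinateError, FormatError
from .records import GenomeInterval, PlastomeRecord

GAP = "-"


@dataclass
class SimilarityMatrix:
    taxa: list[str]
    values: np.ndarray  # symmetric, unit diagonal, fractions in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ContractError("matrix shape does not match taxa")
        self.values = v

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


@dataclass
class RegionVariability:
    name: str
    kind: str                 # 'coding' | 'non-coding'
    columns: int
    variable_columns: int

    @property
    def percent_variable(self) -> float:
        return self.variable_columns / self.columns if self.columns else 0.0


def pairwise_identity(a: str, b: str, max_builtin_len: int = 50000) -> float:
    """Global-alignment identity of two sequences (gaps in the denominator).

    With substitution-only divergence this equals 1 - k/L exactly, because
    the optimal unit-cost alignment is the ungapped diagonal.
    """
    if not a or not b:
        raise ContractError("pairwise_identity requires non-empty sequences")
    if len(a) > max_builtin_len or len(b) > max_builtin_len:
        raise CapabilityError(
            f"built-in aligner capped at {max_builtin_len} bp per sequence; "
            "supply a precomputed alignment for longer genomes"
        )
    a, b = a.upper(), b.upper()
    if (len(b), b) < (len(a), a):
        a, b = b, a  # canonical order: identity is symmetric by construction
    if len(a) == len(b):
        # among equal-cost alignments, prefer the ungapped diagonal: when the
        # Hamming distance already attains the edit distance, identity is
        # exactly 1 - k/L
        arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
        arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
        hamming = int(np.count_nonzero(arr_a != arr_b))
        dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
        if hamming == dist:
            return 1.0 - hamming / len(a)
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    matched = nice["matched_aligned"]
    return matched.count("|") / len(matched)


def aligned_pair_identity(row_a: str, row_b: str) -> float:
    """Identity of two rows of an existing alignment.

    Columns where both rows are gaps are dropped; N/ambiguity columns are
    treated as missing; remaining gap columns count as differences.
    """
    num = den = 0
    for x, y in zip(row_a.upper(), row_b.upper()):
        if x == GAP and y == GAP:
            continue
        if x == "N" or y == "N":
            continue
        den += 1
        if x == y and x != GAP:
            num += 1
    if den == 0:
        raise ContractError("no comparable columns between rows")
    return num / den


def similarity_matrix(records_or_alignment, max_builtin_len: int = 50000) -> SimilarityMatrix:
    """All-pairs identity matrix from records or from an aligned FASTA path."""
    if isinstance(records_or_alignment, (str,)) or hasattr(records_or_alignment, "__fspath__"):
        rows = read_alignment(records_or_alignment)
        taxa = [t for t, _ in rows]
        seqs = [s for _, s in rows]
        pair = aligned_pair_identity
    else:
        records: list[PlastomeRecord] = list(records_or_alignment)
        taxa = [r.identifier for r in records]
        seqs = [r.sequence for r in records]
        pair = lambda x, y: pairwise_identity(x, y, max_builtin_len)  # noqa: E731
    if len(taxa) < 2:
        raise ContractError("similarity matrix needs at least two taxa")
    n = len(taxa)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pair(seqs[i], seqs[j])
    return SimilarityMatrix(taxa=taxa, values=vals)


def read_alignment(path) -> list[tuple[str, str]]:
    rows = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise FormatError(f"no alignment rows in {path}")
    widths = {len(s) for _, s in rows}
    if len(widths) != 1:
        raise FormatError(f"ragged alignment in {path}: row lengths {sorted(widths)}")
    return rows


def variable_percentage(
    alignment: list[tuple[str, str]],
    regions: list[tuple[str, str, GenomeInterval]],
    reference_taxon: str,
) -> list[RegionVariability]:
    """Percent variable columns per region of the ungapped reference.

    Reference intervals are projected through the reference row's gap
    structure onto alignment columns. A column is variable iff >= 2 distinct
    non-gap, non-N characters occur and >= 2 rows are non-gap.
    """
    rows = dict(alignment)
    if reference_taxon not in rows:
        raise ContractError(f"reference taxon {reference_taxon} not in alignment")
    ref = rows[reference_taxon]
    # map ungapped reference offset -> alignment column
    col_of = [i for i, c in enumerate(ref) if c != GAP]
    ref_len = len(col_of)
    variable = _variable_columns(list(rows.values()))
    out = []
    for name, kind, iv in regions:
        if iv.end > ref_len or iv.start >= ref_len:
            raise CoordinateError(
                f"region {name} [{iv.start},{iv.end}) beyond reference length {ref_len}"
            )
        cols = [col_of[o] for o in range(iv.start, iv.end)]
        var = sum(1 for c in cols if variable[c])
        out.append(RegionVariability(name=name, kind=kind, columns=len(cols), variable_columns=var))
    return out


def _variable_columns(rows: list[str]) -> list[bool]:
    width = len(rows[0])
    flags = []
    for c in range(width):
        states = [r[c] for r in rows]
        bases = {s for s in states if s not in (GAP, "N")}
        nongap = sum(1 for s in states if s != GAP)
        flags.append(len(bases) >= 2 and nongap >= 2)
    return flags


def nj_tree(matrix: SimilarityMatrix) -> str:
    """Neighbor-joining tree (Newick, with branch lengths) on 1 - identity.

    Taxa are sorted lexicographically before construction so ties break
    deterministically.
    """
    if len(matrix.taxa) < 3:
        raise ContractError("neighbor joining needs at least three taxa")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    order = sorted(range(len(matrix.taxa)), key=lambda i: matrix.taxa[i])
    ids = [matrix.taxa[i] for i in order]
    dist = 1.0 - matrix.values[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    tree = nj(DistanceMatrix(dist, ids))
    return str(tree).strip()
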