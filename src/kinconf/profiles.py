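"""Curated profile alignment handling and chain-to-column mapping.

Every feature in the pipeline is indexed by a column of a curated kinase
domain profile alignment (241 columns for the default ePK profile), with a
reference row — conventionally the PKA catalytic subunit — whose ungapped
author numbering translates columns into the community PKA numbering frame.
Chains are mapped onto profile columns by pairwise alignment against each
profile row (BLOSUM62, affine gaps, free end gaps so a full-length protein
can carry its kinase domain anywhere in the chain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .structure import Chain

__all__ = ["Profile", "ColumnMap", "ProfileError", "load_profile", "align_chain", "pka_positions"]

GAP_CHARS = set("-.")

DEFAULT_REFERENCE_ROW = "PKA"
DEFAULT_MIN_IDENTITY = 0.30
MIN_CHAIN_LENGTH = 50


class ProfileError(ValueError):
    """Malformed or incomplete profile alignment."""


@dataclass
class Profile:
    """A gapped multiple alignment over a fixed number of columns."""

    rows: dict[str, str]  # row id -> gapped sequence, all of equal length
    reference_row: str = DEFAULT_REFERENCE_ROW
    reference_start: int = 1  # author number of the reference row's first residue

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ProfileError(f"ragged alignment: row lengths {sorted(lengths)}")
        if self.reference_row not in self.rows:
            raise ProfileError(f"reference row {self.reference_row!r} absent from profile")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def ungapped(self, row_id: str) -> str:
        return "".join(c for c in self.rows[row_id] if c not in GAP_CHARS)

    def row_columns(self, row_id: str) -> list[int]:
        """1-based profile columns occupied by each ungapped residue of a row."""
        return [i + 1 for i, c in enumerate(self.rows[row_id]) if c not in GAP_CHARS]


@dataclass
class ColumnMap:
    """Mapping of one chain's residues onto profile columns."""

    chain_ref: tuple[str, str]  # (structure_id, chain_id)
    col_to_res: dict[int, int] = field(default_factory=dict)  # 1-based column -> residue index
    identity: float = 0.0
    best_row: str = ""

    @property
    def res_to_col(self) -> dict[int, int]:
        return {r: c for c, r in self.col_to_res.items()}

    def residue_at(self, column: int) -> int | None:
        return self.col_to_res.get(column)


def load_profile(path, reference_row: str = DEFAULT_REFERENCE_ROW,
                 reference_start: int = 1) -> Profile:
    """Load a gapped FASTA or Stockholm alignment as a Profile.

    Format is sniffed from the first line; rows must be of equal length and
    the reference row id must be present.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    fmt = "stockholm" if first.startswith("# STOCKHOLM") else "fasta"
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ProfileError(f"cannot parse alignment {path}: {exc}") from exc
    rows = {rec.id: str(rec.seq).upper() for rec in aln}
    return Profile(rows=rows, reference_row=reference_row, reference_start=reference_start)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # free end gaps: the kinase domain may sit anywhere in the chain, and a
    # chain may cover only part of the domain
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


def _sanitize(seq: str) -> str:
    """Restrict to the BLOSUM62 alphabet; unknowns become X."""
    alphabet = set("ARNDCQEGHILKMFPSTWYVBZX")
    return "".join(c if c in alphabet else "X" for c in seq.upper())


def align_chain(chain: Chain, profile: Profile,
                min_identity: float = DEFAULT_MIN_IDENTITY,
                structure_id: str = "") -> ColumnMap | None:
    """Map a chain's residues to profile columns via its best-matching row.

    The chain sequence is aligned against every profile row; the best row is
    chosen by raw score (identity, then row order, break ties). Returns None
    (rejection) when the best identity over aligned positions falls below
    ``min_identity`` — the chain is then considered not to be a kinase domain.
    """
    seq = chain.sequence
    if len(seq) < MIN_CHAIN_LENGTH:
        return None
    query = _sanitize(seq)
    aligner = _make_aligner()

    best = None  # (score, identity, row_id, alignment)
    for row_id in profile.rows:
        target = _sanitize(profile.ungapped(row_id))
        if not target:
            continue
        alignments = aligner.align(target, query)
        aln = alignments[0]
        score = aln.score
        pairs = _aligned_pairs(aln)
        if not pairs:
            continue
        n_match = sum(1 for t, q in pairs if target[t] == query[q])
        # identity relative to the profile row length, so a tiny local match
        # of a non-kinase sequence cannot score highly
        identity = n_match / len(target)
        key = (score, identity)
        if best is None or key > (best[0], best[1]):
            best = (score, identity, row_id, pairs)

    if best is None or best[1] < min_identity:
        return None

    _, identity, row_id, pairs = best
    row_cols = profile.row_columns(row_id)
    col_to_res = {row_cols[t]: q for t, q in pairs}
    return ColumnMap(
        chain_ref=(structure_id, chain.chain_id),
        col_to_res=col_to_res,
        identity=identity,
        best_row=row_id,
    )


def _aligned_pairs(aln) -> list[tuple[int, int]]:
    pairs = []
    t_blocks, q_blocks = aln.aligned
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        pairs.extend(zip(range(ts, te), range(qs, qe)))
    return pairs


def pka_positions(profile: Profile, columns) -> list[int | None]:
    """Translate profile columns to reference-row (PKA) residue numbers.

    Returns the ungapped author number of the reference row at each column,
    or None where the reference row is gapped.
    """
    ref = profile.rows[profile.reference_row]
    n = profile.n_columns
    out: list[int | None] = []
    # cumulative count of reference residues up to each column
    counts = []
    c = 0
    for ch in ref:
        if ch not in GAP_CHARS:
            c += 1
            counts.append(c)
        else:
            counts.append(None)
    for col in columns:
        if not 1 <= col <= n:
            raise IndexError(f"column {col} outside [1, {n}]")
        k = counts[col - 1]
        out.append(None if k is None else profile.reference_start + k - 1)
    return out
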