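"""Identity/conservation statistics, deletion blocks, and the column-level
residue correspondence (AlignmentMap) that downstream superposition and
equivalence mapping are driven by.

"Identity" is same-letter at an aligned column. "Conserved" is identity or
co-membership in one similarity group of a :class:`ConservationScheme`; the
scheme is configuration, not a constant, because rendering tools that colour
"conserved" columns do not agree on a single definition. Reference numbering
is the ungapped position in the reference row (1-based), which for UniProt
sequences coincides with author numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align

from tklscan.structure_io import Alignment, ResiduePointer, Structure, chain_to_sequence

__all__ = [
    "ConservationScheme",
    "DEFAULT_SCHEME",
    "ConservationStats",
    "DeletionBlock",
    "AlignmentMap",
    "pairwise_stats",
    "find_deletion_blocks",
    "build_alignment_map",
]

GAP_CHARS = "-."


@dataclass(frozen=True)
class ConservationScheme:
    """Named similarity groups; two distinct letters are 'conserved' iff they
    share a group."""

    name: str
    groups: tuple[str, ...]

    def conserved(self, a: str, b: str) -> bool:
        if a == b:
            return True
        return any(a in g and b in g for g in self.groups)


#: hydrophobic / basic / acidic / amide / hydroxyl / small / proline groups,
#: in the style of alignment-rendering conventions
DEFAULT_SCHEME = ConservationScheme(
    name="default",
    groups=("ILMVFWYC", "KRH", "DE", "NQ", "ST", "AG", "P"),
)


@dataclass
class ConservationStats:
    n_columns: int
    n_identical: int
    n_conserved: int
    pct_identity: float
    pct_conserved: float
    region: Optional[tuple[int, int]] = None
    denominator: str = "ref_length"

    def __post_init__(self) -> None:
        if not (self.n_identical <= self.n_conserved <= self.n_columns):
            raise ValueError(
                f"inconsistent counts: identical {self.n_identical} <= "
                f"conserved {self.n_conserved} <= columns {self.n_columns} violated"
            )


@dataclass
class DeletionBlock:
    """A maximal run of reference residues aligned to gaps in the query."""

    ref_start: int
    ref_end: int
    start_name: str
    end_name: str
    length: int

    def __str__(self) -> str:
        return (
            f"{self.start_name}{self.ref_start}-{self.end_name}{self.ref_end} "
            f"({self.length} residues)"
        )


def _ref_positions(row: str) -> list[Optional[int]]:
    """Per column: 1-based ungapped position in this row, or None at gaps."""
    out: list[Optional[int]] = []
    pos = 0
    for ch in row:
        if ch in GAP_CHARS:
            out.append(None)
        else:
            pos += 1
            out.append(pos)
    return out


def pairwise_stats(
    aln: Alignment,
    ref: str,
    query: str,
    region: Optional[tuple[int, int]] = None,
    scheme: ConservationScheme = DEFAULT_SCHEME,
    denominator: str = "ref_length",
) -> ConservationStats:
    """Identity and conservation of ``query`` relative to ``ref``.

    Parameters
    ----------
    region
        Closed interval ``(start, end)`` in reference numbering; only columns
        whose reference position falls inside it are counted.
    denominator
        ``"ref_length"`` — percentages over the number of reference residues
        (in the region); ``"aligned_columns"`` — over columns where both rows
        have a residue (symmetric in ref/query).
    """
    if denominator not in ("ref_length", "aligned_columns"):
        raise ValueError(f"unknown denominator {denominator!r}")
    rrow, qrow = aln.row(ref), aln.row(query)
    rpos = _ref_positions(rrow)

    def in_region(col: int) -> bool:
        if region is None:
            return True
        p = rpos[col]
        return p is not None and region[0] <= p <= region[1]

    n_ref = n_both = n_id = n_cons = 0
    for col in range(aln.length):
        if not in_region(col):
            continue
        r, q = rrow[col], qrow[col]
        r_gap, q_gap = r in GAP_CHARS, q in GAP_CHARS
        if not r_gap:
            n_ref += 1
        if r_gap or q_gap:
            continue
        n_both += 1
        if r == q:
            n_id += 1
            n_cons += 1
        elif scheme.conserved(r, q):
            n_cons += 1
    denom = n_ref if denominator == "ref_length" else n_both
    if denom == 0:
        raise ValueError(
            f"empty region: no reference columns for {ref!r} in {region!r}"
        )
    return ConservationStats(
        n_columns=denom,
        n_identical=n_id,
        n_conserved=n_cons,
        pct_identity=100.0 * n_id / denom,
        pct_conserved=100.0 * n_cons / denom,
        region=region,
        denominator=denominator,
    )


def find_deletion_blocks(
    aln: Alignment,
    ref: str,
    query: str,
    min_length: int = 1,
) -> list[DeletionBlock]:
    """Maximal runs of reference-residue-vs-gap columns, in ref numbering."""
    rrow, qrow = aln.row(ref), aln.row(query)
    blocks: list[DeletionBlock] = []
    run: list[tuple[int, str]] = []  # (ref position, letter)
    pos = 0
    for col in range(aln.length):
        r, q = rrow[col], qrow[col]
        if r not in GAP_CHARS:
            pos += 1
        if r not in GAP_CHARS and q in GAP_CHARS:
            run.append((pos, r))
        elif run and r not in GAP_CHARS:
            # a ref residue aligned to a query residue ends the run; pure-gap
            # columns (both gapped) do not interrupt it
            blocks.append(_close_run(run))
            run = []
    if run:
        blocks.append(_close_run(run))
    return [b for b in blocks if b.length >= min_length]


def _close_run(run: list[tuple[int, str]]) -> DeletionBlock:
    return DeletionBlock(
        ref_start=run[0][0],
        ref_end=run[-1][0],
        start_name=run[0][1],
        end_name=run[-1][1],
        length=len(run),
    )


# ---------------------------------------------------------------------------
# alignment map

@dataclass
class AlignmentMap:
    """Per-column residue pointers for every structure-bound sequence."""

    alignment: Alignment
    pointers: dict[str, list[Optional[ResiduePointer]]] = field(default_factory=dict)
    residue_names: dict[str, list[Optional[str]]] = field(default_factory=dict)
    unmatched: dict[str, list[ResiduePointer]] = field(default_factory=dict)

    def column_of(self, seq_id: str, ptr: ResiduePointer) -> Optional[int]:
        cols = self.pointers.get(seq_id)
        if cols is None:
            raise KeyError(f"sequence {seq_id!r} is not structure-bound")
        for i, p in enumerate(cols):
            if p == ptr:
                return i
        return None

    def pointer_at(self, seq_id: str, column: int) -> Optional[ResiduePointer]:
        return self.pointers[seq_id][column]

    def equivalent(
        self, from_id: str, ptr: ResiduePointer, to_id: str
    ) -> Optional[ResiduePointer]:
        """Residue of ``to_id`` in the same alignment column, or None."""
        col = self.column_of(from_id, ptr)
        if col is None:
            return None
        return self.pointers[to_id][col]

    def to_dict(self) -> dict:
        return {
            "columns": self.alignment.length,
            "sequences": {
                sid: [str(p) if p else None for p in cols]
                for sid, cols in self.pointers.items()
            },
        }


class BindingError(ValueError):
    """Structure chain does not match its alignment row well enough."""


def _align_row_to_chain(row_seq: str, chain_seq: str) -> list[Optional[int]]:
    """Map each position of ``row_seq`` to an index in ``chain_seq``.

    Exact equality short-circuits; otherwise a global pairwise alignment
    bridges gaps from unmodelled residues or sequence-version differences.
    """
    if row_seq == chain_seq:
        return list(range(len(row_seq)))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(row_seq, chain_seq)[0]
    mapping: list[Optional[int]] = [None] * len(row_seq)
    n_match = 0
    for (r0, r1), (c0, c1) in zip(*alignment.aligned):
        for off in range(r1 - r0):
            mapping[r0 + off] = c0 + off
            if row_seq[r0 + off] == chain_seq[c0 + off]:
                n_match += 1
    identity = n_match / max(len(row_seq), 1)
    if identity < 0.95:
        mismatches = [
            f"{i + 1}:{row_seq[i]}->{chain_seq[j]}"
            for i, j in enumerate(mapping)
            if j is not None and row_seq[i] != chain_seq[j]
        ]
        raise BindingError(
            f"sequence/structure identity {100 * identity:.1f}% below 95% "
            f"(first mismatches: {', '.join(mismatches[:10])})"
        )
    return mapping


def build_alignment_map(
    aln: Alignment,
    bindings: Sequence[tuple[str, Structure, str]],
) -> AlignmentMap:
    """Bind alignment rows to structure chains.

    Each binding ``(seq_id, structure, chain_id)`` attaches author-numbered
    residue pointers to the non-gap columns of that row. Structure residues
    that match no alignment position are reported in ``unmatched``.
    """
    amap = AlignmentMap(alignment=aln)
    for seq_id, structure, chain_id in bindings:
        row = aln.row(seq_id)
        row_seq = aln.ungapped(seq_id)
        chain_seq, numbering = chain_to_sequence(structure, chain_id)
        try:
            mapping = _align_row_to_chain(row_seq, chain_seq)
        except BindingError as exc:
            raise BindingError(f"binding {seq_id!r} to chain {chain_id!r}: {exc}")
        ptrs: list[Optional[ResiduePointer]] = []
        names: list[Optional[str]] = []
        ungapped = -1
        used: set[int] = set()
        for ch in row:
            if ch in GAP_CHARS:
                ptrs.append(None)
                names.append(None)
                continue
            ungapped += 1
            j = mapping[ungapped]
            if j is None:
                ptrs.append(None)
                names.append(None)
            else:
                used.add(j)
                num, icode = numbering[j]
                ptrs.append(ResiduePointer(chain_id, num, icode))
                names.append(chain_seq[j])
        amap.pointers[seq_id] = ptrs
        amap.residue_names[seq_id] = names
        amap.unmatched[seq_id] = [
            ResiduePointer(chain_id, numbering[j][0], numbering[j][1])
            for j in range(len(chain_seq))
            if j not in used
        ]
    return amap
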