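"""Reference-anchored codon alignment.

Every downstream statistic in the pipeline is reported in the coordinate
system of one reference ortholog (in the motivating use case, the human
protein, numbered 1..L on the full protein).  Instead of a progressive
multiple alignment, each query ORF is aligned pairwise to the reference at
the protein level and the alignment is back-threaded onto codons — a star
alignment.  Query codons inserted relative to the reference carry no
reference coordinate and are dropped (counted per sequence); reference
positions deleted in a query become the gap codon ``---``.  The resulting
matrix has exactly one column per reference codon position, so indels in
any query never shift the numbering.
"""

from __future__ import annotations

import logging
from typing import Iterable
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import GAP_CODON, OrfRecord, write_fasta

log = logging.getLogger(__name__)


def make_protein_aligner(
    matrix: str = "BLOSUM62", gap_open: float = -11.0, gap_extend: float = -1.0
) -> Align.PairwiseAligner:
    """Global protein aligner with affine gaps (BLOSUM62, -11/-1 defaults)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def pairwise_codon_align(
    query: OrfRecord, ref: OrfRecord, aligner: Align.PairwiseAligner | None = None
) -> tuple[list[str], list[str]]:
    """Align one query ORF to the reference ORF at codon resolution.

    The two translated proteins are globally aligned with affine gaps, and
    each aligned residue pair / gap is mapped back to the underlying codon
    triplet, so reading frame is preserved by construction.

    Returns
    -------
    (ref_codons, query_codons) : two equal-length lists of 3-mers or '---'.
    """
    if not query.seq or not ref.seq:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_protein_aligner()
    alignment = aligner.align(ref.protein(), query.protein())[0]
    ref_gapped, query_gapped = str(alignment[0]), str(alignment[1])
    ref_codons_src, query_codons_src = ref.codons(), query.codons()
    ri = qi = 0
    ref_out: list[str] = []
    query_out: list[str] = []
    for rc, qc in zip(ref_gapped, query_gapped):
        if rc == "-":
            ref_out.append(GAP_CODON)
        else:
            ref_out.append(ref_codons_src[ri])
            ri += 1
        if qc == "-":
            query_out.append(GAP_CODON)
        else:
            query_out.append(query_codons_src[qi])
            qi += 1
    return ref_out, query_out


@dataclass(frozen=True)
class CodonAlignment:
    """Reference-indexed codon matrix.

    Attributes
    ----------
    ref_id : id of the reference row (never gapped).
    aa_start, aa_end : 1-based inclusive codon positions on the reference
        full protein covered by the columns.
    ids : row identifiers (reference first).
    codons : (n_rows, n_positions) array of 3-mers or '---'.
    dropped_insertions : per-row count of query codons without a reference
        coordinate, discarded during star assembly.
    """

    ref_id: str
    aa_start: int
    aa_end: int
    ids: tuple[str, ...]
    codons: np.ndarray
    dropped_insertions: dict[str, int] | None = None

    @property
    def n_rows(self) -> int:
        return self.codons.shape[0]

    @property
    def n_positions(self) -> int:
        return self.codons.shape[1]

    @property
    def positions(self) -> np.ndarray:
        """Human-numbered (reference) codon positions of the columns."""
        return np.arange(self.aa_start, self.aa_end + 1)

    def column(self, position: int) -> np.ndarray:
        """Codon column at a reference position (1-based, human numbering)."""
        if not self.aa_start <= position <= self.aa_end:
            raise IndexError(f"position {position} outside [{self.aa_start}, {self.aa_end}]")
        return self.codons[:, position - self.aa_start]

    def aa_matrix(self) -> np.ndarray:
        """Residue view of the matrix ('-' for gap cells)."""
        from .seqio import translate_codon

        out = np.empty(self.codons.shape, dtype="<U1")
        it = np.nditer(self.codons, flags=["multi_index"])
        for codon in it:
            c = str(codon)
            out[it.multi_index] = "-" if c == GAP_CODON else translate_codon(c)
        return out

    def nucleotide_rows(self) -> list[str]:
        """Each row as one gapped nucleotide string (codons concatenated)."""
        return ["".join(row) for row in self.codons]

    def protein_rows(self) -> list[str]:
        return ["".join(row) for row in self.aa_matrix()]

    def write_codon_fasta(self, path: str | Path) -> None:
        write_fasta(self.ids, self.nucleotide_rows(), path)

    def write_protein_fasta(self, path: str | Path) -> None:
        write_fasta(self.ids, self.protein_rows(), path)


def build_reference_alignment(
    orfs: Iterable[OrfRecord],
    ref_id: str,
    aa_start: int | None = None,
    aa_end: int | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> CodonAlignment:
    """Star-align a set of ORFs against one reference ORF.

    Parameters
    ----------
    orfs : the sequence set, containing the reference.
    ref_id : id of the reference (anchor) sequence.
    aa_start, aa_end : 1-based inclusive window of reference codon positions
        to keep (defaults: the whole reference protein).

    Notes
    -----
    Rows are ordered reference first, then lexicographically by id, so the
    result is independent of input order.
    """
    records = {r.id: r for r in orfs}
    if ref_id not in records:
        raise KeyError(f"reference id {ref_id!r} not found among {len(records)} records")
    ref = records[ref_id]
    n_ref = ref.n_codons
    if aa_start is None:
        aa_start = 1
    if aa_end is None:
        aa_end = n_ref
    if not 1 <= aa_start <= aa_end <= n_ref:
        raise ValueError(
            f"invalid window [{aa_start}, {aa_end}] for a {n_ref}-codon reference"
        )
    if aligner is None:
        aligner = make_protein_aligner()

    other_ids = sorted(i for i in records if i != ref_id)
    ids = [ref_id] + other_ids
    rows = [ref.codons()]
    dropped: dict[str, int] = {}
    for qid in other_ids:
        ref_gapped, q_gapped = pairwise_codon_align(records[qid], ref, aligner)
        row: list[str] = []
        n_dropped = 0
        for rc, qc in zip(ref_gapped, q_gapped):
            if rc == GAP_CODON:
                n_dropped += 1  # insertion relative to reference: no coordinate
            else:
                row.append(qc)
        if n_dropped:
            dropped[qid] = n_dropped
            log.info("row %s: %d inserted codon(s) dropped (no reference coordinate)", qid, n_dropped)
        rows.append(row)

    matrix = np.array(rows, dtype="<U3")[:, aa_start - 1 : aa_end]
    return CodonAlignment(
        ref_id=ref_id,
        aa_start=aa_start,
        aa_end=aa_end,
        ids=tuple(ids),
        codons=matrix,
        dropped_insertions=dropped or None,
    )


def codons_analyzed(aln: CodonAlignment) -> int:
    """Total codon-column cells examined: n_rows x n_positions (gaps included)."""
    return aln.n_rows * aln.n_positions
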