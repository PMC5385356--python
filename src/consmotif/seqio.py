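"""Reading, validating and writing the formats the pipeline touches.

The central currency is the :class:`OrfRecord`: one in-frame coding
nucleotide sequence (an ORF as deposited in sequence databases), optionally
tagged with an organism-group label.  Validation is strict — the downstream
codon arithmetic assumes unambiguous, stop-free, frame-0 sequences — but
record-level problems reject the record with a warning rather than aborting
a whole multi-FASTA.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

log = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: The three stop codons of the standard genetic code.
STOP_CODONS = frozenset(_STANDARD.stop_codons)

#: The 61 sense codons of the standard genetic code, sorted.
SENSE_CODONS = tuple(sorted(_STANDARD.forward_table))

#: Gap symbol used for a whole codon column cell.
GAP_CODON = "---"

_VALID_NT = frozenset("ACGT")


class OrfValidationError(ValueError):
    """A sequence failed ORF validation (frame, alphabet or stop codons)."""


def translate_codon(codon: str) -> str:
    """One codon -> one amino acid letter ('*' for a stop codon)."""
    if codon in STOP_CODONS:
        return "*"
    return _STANDARD.forward_table[codon]


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide sequence with the standard code.

    Raises
    ------
    OrfValidationError
        If the length is not a multiple of 3, the sequence contains
        ambiguity codes, or any codon is a stop (the error names the
        0-based codon index).
    """
    if len(seq) % 3:
        raise OrfValidationError(f"length {len(seq)} is not a multiple of 3")
    aa = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            raise OrfValidationError(f"stop codon {codon} at codon index {i // 3}")
        try:
            aa.append(_STANDARD.forward_table[codon])
        except KeyError:
            raise OrfValidationError(f"invalid codon {codon!r} at codon index {i // 3}") from None
    return "".join(aa)


@dataclass(frozen=True)
class OrfRecord:
    """One validated in-frame coding sequence.

    Attributes
    ----------
    id : str
        Unique identifier within a set.
    seq : str
        Upper-case nucleotides over {A,C,G,T}; length a multiple of 3; no
        in-frame stop codons (a trailing stop is stripped at ingest).
    group : str or None
        Optional organism-group label used by the cross-group analysis.
    """

    id: str
    seq: str
    group: str | None = None

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    def protein(self) -> str:
        return translate(self.seq)


def _clean_and_validate(rec_id: str, raw: str) -> str:
    """Normalise a raw sequence string and enforce the ORF invariants."""
    seq = raw.upper().replace("U", "T")
    if not seq:
        raise OrfValidationError("empty sequence")
    bad = set(seq) - _VALID_NT
    if bad:
        raise OrfValidationError(f"ambiguous/invalid characters {sorted(bad)}")
    if len(seq) % 3:
        raise OrfValidationError(f"length {len(seq)} not a multiple of 3")
    if seq[-3:] in STOP_CODONS:
        log.info("record %s: trailing stop codon %s stripped", rec_id, seq[-3:])
        seq = seq[:-3]
        if not seq:
            raise OrfValidationError("sequence is a lone stop codon")
    for i in range(0, len(seq), 3):
        if seq[i : i + 3] in STOP_CODONS:
            raise OrfValidationError(
                f"internal stop codon {seq[i:i+3]} at codon index {i // 3}"
            )
    return seq


def read_orfs(path: str | Path, groups: Mapping[str, str] | None = None) -> list[OrfRecord]:
    """Read and validate ORFs from a (multi-)FASTA file.

    Records failing validation (ambiguity codes, frame, internal stops) are
    rejected with a logged warning and the run continues.  A duplicate id or
    an empty/unparseable file is a hard error.

    Parameters
    ----------
    path : path to a FASTA file
    groups : optional id -> group-label mapping attached to the records

    Returns
    -------
    list of OrfRecord, in file order.
    """
    path = Path(path)
    records: list[OrfRecord] = []
    seen: set[str] = set()
    n_parsed = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_parsed += 1
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            seq = _clean_and_validate(rec.id, str(rec.seq))
        except OrfValidationError as exc:
            log.warning("record %s rejected: %s", rec.id, exc)
            continue
        records.append(OrfRecord(rec.id, seq, groups.get(rec.id) if groups else None))
    if n_parsed == 0:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_orfs(records: Iterable[OrfRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA (byte-identical round trip)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def write_fasta(ids: Sequence[str], rows: Sequence[str], path: str | Path) -> None:
    """Write parallel id/sequence lists as unwrapped FASTA (gaps allowed)."""
    with open(path, "w") as fh:
        for rid, row in zip(ids, rows):
            fh.write(f">{rid}\n{row}\n")


def read_alignment_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA (gap '-' allowed); returns (ids, rows).

    All rows must have equal length.
    """
    recs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(Path(path)), "fasta")]
    if not recs:
        raise ValueError(f"no FASTA records found in {path}")
    lengths = {len(s) for _, s in recs}
    if len(lengths) != 1:
        raise ValueError(f"alignment rows have unequal lengths {sorted(lengths)}")
    return [r for r, _ in recs], [s for _, s in recs]


@dataclass(frozen=True)
class GroupTable:
    """Mapping of sequence id -> organism-group label."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        """Distinct group labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g)
        return list(seen)

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def members(self, label: str) -> list[str]:
        return [i for i, g in self.mapping.items() if g == label]

    def summary(self) -> "pd.DataFrame":  # noqa: F821 - lazy pandas
        """Per-group sequence counts plus a 'total' row."""
        import pandas as pd

        counts = [(g, len(self.members(g))) for g in self.labels]
        counts.append(("total", len(self.mapping)))
        return pd.DataFrame(counts, columns=["group", "n_sequences"])

    def __len__(self) -> int:
        return len(self.mapping)


def _looks_like_header(rows: list[list[str]]) -> bool:
    # Header heuristic: an obvious id/group header, or a first row whose
    # group field never recurs while later group fields do repeat.
    first = rows[0]
    if [c.strip().lower() for c in first] in (["id", "group"], ["sequence", "group"]):
        return True
    if len(rows) > 2:
        later = [r[1] for r in rows[1:]]
        if first[1] not in later and len(set(later)) < len(later):
            return True
    return False


def read_groups(path: str | Path, orf_ids: Iterable[str] | None = None) -> GroupTable:
    """Read a two-column ``id<TAB>group`` table (header auto-detected).

    A row with the wrong number of columns is a hard error naming the line;
    an id absent from `orf_ids` (when given) only warns.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not raw or (len(raw) == 1 and not raw[0].strip()):
                continue
            if raw[0].startswith("#"):
                continue
            if len(raw) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(raw)}")
            if not raw[0].strip() or not raw[1].strip():
                raise ValueError(f"{path}:{lineno}: empty id or group label")
            rows.append([raw[0].strip(), raw[1].strip()])
    if not rows:
        raise ValueError(f"no data rows in {path}")
    if _looks_like_header(rows):
        rows = rows[1:]
        if not rows:
            raise ValueError(f"only a header row in {path}")
    mapping: dict[str, str] = {}
    for rid, grp in rows:
        if rid in mapping and mapping[rid] != grp:
            raise ValueError(f"id {rid!r} mapped to two groups ({mapping[rid]!r}, {grp!r})")
        mapping[rid] = grp
    if orf_ids is not None:
        known = set(orf_ids)
        for rid in mapping:
            if rid not in known:
                log.warning("group table id %s not present in the ORF set", rid)
    return GroupTable(mapping)


def write_groups(table: GroupTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#id\tgroup\n")
        for rid, grp in table.mapping.items():
            fh.write(f"{rid}\t{grp}\n")
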