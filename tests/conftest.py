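import numpy as np
import pytest

from consmotif.codon_align import CodonAlignment
from consmotif.seqio import OrfRecord


def make_alignment(rows: list[str], ids: list[str] | None = None, aa_start: int = 1) -> CodonAlignment:
    """Build a CodonAlignment directly from equal-length codon strings."""
    if ids is None:
        ids = [f"s{i}" for i in range(len(rows))]
    n_pos = len(rows[0]) // 3
    codons = np.array(
        [[r[i : i + 3] for i in range(0, len(r), 3)] for r in rows], dtype="<U3"
    )
    return CodonAlignment(
        ref_id=ids[0], aa_start=aa_start, aa_end=aa_start + n_pos - 1,
        ids=tuple(ids), codons=codons,
    )


@pytest.fixture
def toy_orfs() -> list[OrfRecord]:
    """Four short, gap-free ORFs differing by point substitutions."""
    base = "ATGAAACCCGGGTTTGCTGACCATTGGCTGAAG"[:30]
    return [
        OrfRecord("ref", base),
        OrfRecord("q1", base[:14] + "C" + base[15:]),          # third-position change
        OrfRecord("q2", base[:3] + "AGA" + base[6:]),          # K2R nonsynonymous
        OrfRecord("q3", base),
    ]


def write_fasta(tmp_path, name: str, entries: list[tuple[str, str]]):
    path = tmp_path / name
    path.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in entries))
    return path
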