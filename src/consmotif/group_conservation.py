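"""Cross-group conservation categorization of a protein alignment.

Sequences are partitioned into G organism groups (for the motivating
endospanin analysis: vertebrate orthologs of the two paralogs,
invertebrates, fungi and plants, G = 5).  A group is *conserved* at a
position when all of its non-gap residues are identical and at least a
configurable fraction of the group is non-gap.  Each position is then
binned by how many groups conserve it — the "conserved in all / in at
least 4 / 3 / 2 groups" coloring — and band percentages are computed over
the total alignment length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .seqio import GroupTable

log = logging.getLogger(__name__)

#: Band colors used by the motivating 5-group figure, most-conserved first.
BAND_COLORS = ("red", "green", "cyan", "gray")


def group_conserved(
    column: Sequence[str],
    ids: Sequence[str],
    groups: GroupTable,
    min_group_coverage: float = 0.5,
) -> dict[str, bool]:
    """Per-group conservation flags for one residue column.

    A group's flag is True iff all its non-gap residues are identical and
    the non-gap fraction of the group is >= `min_group_coverage`.  An
    entirely gapped group is flagged False (logged).
    """
    by_group: dict[str, list[str]] = {g: [] for g in groups.labels}
    sizes: dict[str, int] = {g: 0 for g in groups.labels}
    for rid, res in zip(ids, column):
        g = groups.mapping.get(rid)
        if g is None:
            continue
        sizes[g] += 1
        if res != "-":
            by_group[g].append(res)
    flags: dict[str, bool] = {}
    for g in groups.labels:
        residues = by_group[g]
        if not residues:
            log.debug("group %s entirely gapped at a position", g)
            flags[g] = False
            continue
        coverage = len(residues) / sizes[g] if sizes[g] else 0.0
        flags[g] = coverage >= min_group_coverage and len(set(residues)) == 1
    return flags


def _category(n_conserved: int, G: int) -> str:
    if n_conserved == G:
        return "all"
    if n_conserved >= 2:
        return f"ge{n_conserved}"
    return "none"


@dataclass(frozen=True)
class GroupConservationProfile:
    """Per-position cross-group conservation.

    `table` columns: position (1-based alignment column), one boolean column
    per group label, n_groups_conserved, category.  Bands used for the
    summary are *exclusive* ("exactly k groups conserved") so they are
    disjoint and union to the positions with >= 2 conserved groups.
    """

    table: pd.DataFrame
    group_labels: tuple[str, ...]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def n_positions(self) -> int:
        return len(self.table)

    def band_counts(self) -> dict[int, int]:
        """count of positions with exactly k conserved groups, k = G..2."""
        n = self.table["n_groups_conserved"]
        return {k: int((n == k).sum()) for k in range(self.n_groups, 1, -1)}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(self.table.columns) + "\n")
            self.table.to_csv(fh, sep="\t", header=False, index=False)


def group_conservation_profile(
    ids: Sequence[str],
    rows: Sequence[str],
    groups: GroupTable,
    min_group_coverage: float = 0.5,
) -> GroupConservationProfile:
    """Classify every column of a protein alignment by group conservation."""
    if not rows:
        raise ValueError("empty alignment")
    unmapped = [i for i in ids if i not in groups.mapping]
    if unmapped:
        log.warning("%d sequence(s) without a group label are ignored", len(unmapped))
    G = groups.n_groups
    n_cols = len(rows[0])
    recs = []
    for j in range(n_cols):
        column = [row[j] for row in rows]
        flags = group_conserved(column, ids, groups, min_group_coverage)
        n_cons = sum(flags.values())
        recs.append((j + 1, *[flags[g] for g in groups.labels], n_cons, _category(n_cons, G)))
    table = pd.DataFrame(
        recs, columns=["position", *groups.labels, "n_groups_conserved", "category"]
    )
    return GroupConservationProfile(table=table, group_labels=tuple(groups.labels))


def category_percentages(band_counts: dict[int, int], n_positions: int) -> pd.DataFrame:
    """Band percentage accounting over the total alignment length.

    Per-band percent = 100 * count / n_positions rounded to one decimal.
    Two totals are appended: ``any_rounded_sum`` (the sum of the rounded
    band percents, the arithmetic used in the motivating report) and
    ``any_exact`` (the unrounded union percentage).

    Bands are keyed "exactly k conserved groups", most conserved first;
    for G = 5 the conventional colors red/green/cyan/gray are attached.
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    ks = sorted(band_counts, reverse=True)
    colors = dict(zip(ks, BAND_COLORS)) if len(ks) == len(BAND_COLORS) else {}
    recs = []
    rounded_total = 0.0
    exact_total = 0
    for k in ks:
        count = band_counts[k]
        pct = round(100.0 * count / n_positions, 1)
        rounded_total += pct
        exact_total += count
        recs.append((f"exactly_{k}", colors.get(k, ""), count, pct))
    recs.append(
        ("any_rounded_sum", "", exact_total, round(rounded_total, 1))
    )
    recs.append(
        ("any_exact", "", exact_total, round(100.0 * exact_total / n_positions, 1))
    )
    return pd.DataFrame(recs, columns=["band", "color", "count", "percent"])
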