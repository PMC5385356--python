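"""The combined 0-2 conservation score and sliding-window motif discovery.

Each reference position gets two additive components:

* ``c`` in [0, 1] — residue conservation, ``(m - 1) / (n - 1)`` where m is
  the modal residue count among the n non-gap residues: 1 at 100% identity,
  0 when all residues differ.
* ``p`` in [0, 1] — selection, ``clamp(z / 2, 0, 1)`` of the standardized
  dN - dS: 1 when the site is more than 2 SDs above the gene mean for
  purifying selection, 0 at or below the mean.

``score = c + p`` is 2 exactly when the residue is 100% conserved *and*
z >= 2, and 0 exactly when the residues are all distinct and z <= 0.  The
per-site scores are averaged over a 21-codon sliding window and the
top-scoring mutually non-overlapping windows are reported as candidate
linear motifs, in reference (human) numbering.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_align import CodonAlignment
from .selection import SiteSelectionProfile

log = logging.getLogger(__name__)

#: Window width from the motivating analysis: 21 codons.
DEFAULT_WINDOW = 21


def conservation_component(column: "np.ndarray | list[str]") -> tuple[float, float] | None:
    """(modal frequency f, conservation c) of a residue column.

    Gap cells ('-') are ignored.  Returns None (position unscored) with
    fewer than 2 non-gap residues.
    """
    residues = [r for r in column if r != "-"]
    n = len(residues)
    if n < 2:
        return None
    m = Counter(residues).most_common(1)[0][1]
    return m / n, (m - 1) / (n - 1)


def selection_component(z: float) -> float:
    """clamp(z/2, 0, 1); an unscored (NaN) z contributes 0 (conservative)."""
    if z is None or np.isnan(z):
        return 0.0
    return float(min(max(z / 2.0, 0.0), 1.0))


@dataclass(frozen=True)
class ConservationProfile:
    """Per-position combined scores.

    `table` columns: position, n_residues, f (modal frequency), c, p, score,
    low_support (True where more than half the rows are gapped).  Unscored
    positions (fewer than 2 residues) carry score 0 and low_support True.
    """

    table: pd.DataFrame

    @property
    def positions(self) -> np.ndarray:
        return self.table["position"].to_numpy()

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#position\tn_residues\tf\tc\tp\tscore\tlow_support\n")
            self.table.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")


def site_scores(
    aln: CodonAlignment,
    sel: SiteSelectionProfile,
    categorical: bool = False,
    low_support_gap_frac: float = 0.5,
) -> ConservationProfile:
    """Combine residue conservation with standardized selection per position.

    With ``categorical=True`` the score is the integer {0, 1, 2} count of
    endpoint conditions met (100% identity; z >= 2) instead of the
    continuous sum.
    """
    if not np.array_equal(aln.positions, sel.positions):
        raise ValueError("alignment and selection profile cover different positions")
    aa = aln.aa_matrix()
    z_arr = sel.z
    recs = []
    for k, pos in enumerate(aln.positions):
        col = aa[:, k]
        n_gaps = int((col == "-").sum())
        comp = conservation_component(col)
        z = z_arr[k]
        p = selection_component(z)
        if comp is None:
            recs.append((pos, aln.n_rows - n_gaps, np.nan, np.nan, p, 0.0, True))
            continue
        f, c = comp
        if categorical:
            score = float((f == 1.0) + (not np.isnan(z) and z >= 2.0))
        else:
            score = c + p
        low = n_gaps > low_support_gap_frac * aln.n_rows
        recs.append((pos, aln.n_rows - n_gaps, f, c, p, score, low))
    table = pd.DataFrame(
        recs, columns=["position", "n_residues", "f", "c", "p", "score", "low_support"]
    )
    return ConservationProfile(table=table)


def window_scores(profile: ConservationProfile, w: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Mean score over every full w-codon window (step 1, no edge windows).

    Returns a DataFrame with columns start, end (inclusive, reference
    numbering) and window_mean_score.
    """
    scores = profile.scores
    if len(scores) < w:
        raise ValueError(f"profile has {len(scores)} positions, fewer than window width {w}")
    means = np.convolve(scores, np.ones(w) / w, mode="valid")
    starts = profile.positions[: len(means)]
    return pd.DataFrame(
        {"start": starts, "end": starts + w - 1, "window_mean_score": means}
    )


@dataclass(frozen=True)
class MotifTable:
    """Ranked non-overlapping top windows; columns rank, start, end,
    window_mean_score."""

    table: pd.DataFrame
    window: int

    def intervals(self) -> list[tuple[int, int]]:
        return list(zip(self.table["start"], self.table["end"]))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#rank\tstart\tend\twindow_mean_score\n")
            self.table.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")


def top_motifs(windows: pd.DataFrame, k: int, allow_overlap: bool = False) -> MotifTable:
    """Greedy selection of the k highest-mean windows.

    Windows overlapping an already-selected window are skipped (unless
    ``allow_overlap``); ties in the mean are broken leftmost.  Fewer than k
    motifs are returned (and logged) when disjoint windows run out.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    w = int(windows["end"].iloc[0] - windows["start"].iloc[0] + 1)
    order = windows.sort_values(
        ["window_mean_score", "start"], ascending=[False, True], kind="mergesort"
    )
    chosen: list[tuple[int, int, float]] = []
    for _, row in order.iterrows():
        s, e, m = int(row["start"]), int(row["end"]), float(row["window_mean_score"])
        if not allow_overlap and any(s <= ce and e >= cs for cs, ce, _ in chosen):
            continue
        chosen.append((s, e, m))
        if len(chosen) == k:
            break
    if len(chosen) < k:
        log.info("only %d non-overlapping motif(s) available (asked for %d)", len(chosen), k)
    table = pd.DataFrame(
        [(i + 1, s, e, m) for i, (s, e, m) in enumerate(chosen)],
        columns=["rank", "start", "end", "window_mean_score"],
    )
    return MotifTable(table=table, window=w)


def plot_profile(
    profile: ConservationProfile, motifs: MotifTable | None, path: str | Path
) -> None:
    """Bar graph of per-site scores with motif windows boxed (optional extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, len(profile.positions) / 20), 3))
    ax.bar(profile.positions, profile.scores, width=1.0, color="steelblue")
    if motifs is not None:
        for s, e in motifs.intervals():
            ax.axvspan(s - 0.5, e + 0.5, color="orange", alpha=0.3)
    ax.set_xlabel("reference codon position")
    ax.set_ylabel("conservation score (0-2)")
    ax.set_ylim(0, 2.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
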