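"""Per-site synonymous/nonsynonymous substitution estimation by counting.

A Nei-Gojobori-style estimator applied column by column: for every unordered
pair of non-gap codons at a reference position, synonymous and nonsynonymous
differences are tallied by averaging over all mutational pathways between
the two codons (pathways through stop codons excluded), and expected
synonymous/nonsynonymous site counts come from single-base neighbor
enumeration.  Per-pair proportions are averaged into per-site dN and dS, and
d = dN - dS is standardized across the scored positions of a gene.

Sign convention: z = (mean(d) - d_i) / sd(d), so a site under strong
purifying selection (very negative d) gets a large *positive* z.  No
multiple-hit correction is applied at single-codon scale — raw proportions
are used, clamped into [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_align import CodonAlignment
from .seqio import GAP_CODON, STOP_CODONS, translate_codon

log = logging.getLogger(__name__)

_NT = "ACGT"


@lru_cache(maxsize=None)
def ng86_expected_sites(codon: str) -> tuple[float, float]:
    """Expected synonymous (S) and nonsynonymous (N) sites of a sense codon.

    At each of the three positions, each of the three single-nucleotide
    changes contributes 1/3 site, classed as synonymous or nonsynonymous by
    the standard genetic code; changes creating a stop codon are excluded
    from both counts (hence S + N <= 3).
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = translate_codon(codon)
    S = N = 0.0
    for pos in range(3):
        for nt in _NT:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            if translate_codon(mutant) == aa:
                S += 1.0 / 3.0
            else:
                N += 1.0 / 3.0
    return S, N


@lru_cache(maxsize=None)
def ng86_pair_counts(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous (sd) and nonsynonymous (nd) differences between two codons.

    If the codons differ at k positions, the k! orderings of the single-base
    steps are enumerated and sd/nd averaged over them.  Pathways passing
    through a stop codon are excluded; if every pathway is excluded the
    average falls back to all pathways, counting steps into/out of stops as
    nonsynonymous (logged).
    """
    for c in (c1, c2):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c} cannot be scored")
    if c1 == c2:
        return 0.0, 0.0
    diff = [i for i in range(3) if c1[i] != c2[i]]

    def walk(order: tuple[int, ...]) -> tuple[float, float, bool]:
        cur = c1
        sd = nd = 0.0
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                hits_stop = True
            if translate_codon(cur) == translate_codon(nxt):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd, hits_stop

    paths = [walk(order) for order in permutations(diff)]
    valid = [(sd, nd) for sd, nd, stop in paths if not stop]
    if not valid:
        log.debug("all pathways %s->%s pass through a stop; falling back to all paths", c1, c2)
        valid = [(sd, nd) for sd, nd, _ in paths]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


@dataclass(frozen=True)
class SiteSelectionProfile:
    """Per-reference-position selection summary.

    `table` columns: position (human numbering), n_pairs, dN, dS, d, z.
    z is NaN at positions with fewer than `min_pairs` comparable pairs.
    """

    table: pd.DataFrame
    min_pairs: int

    @property
    def positions(self) -> np.ndarray:
        return self.table["position"].to_numpy()

    @property
    def z(self) -> np.ndarray:
        return self.table["z"].to_numpy()

    @property
    def d(self) -> np.ndarray:
        return self.table["d"].to_numpy()

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#position\tn_pairs\tdN\tdS\td\tz\n")
            self.table.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")


def site_selection_profile(aln: CodonAlignment, min_pairs: int = 3) -> SiteSelectionProfile:
    """Column-wise pairwise NG86 counting over a codon alignment.

    For each position, every unordered pair of non-gap codons contributes
    pN = nd/Nbar and pS = sd/Sbar (Nbar, Sbar: the pair-averaged expected
    sites), clamped into [0, 1]; dN and dS are the means over pairs.
    z standardizes d = dN - dS across the scored positions (population SD),
    flipped so stronger purifying selection gives larger positive z.
    """
    if aln.n_rows < 2:
        raise ValueError("selection profile needs at least 2 rows")
    recs = []
    for pos in aln.positions:
        col = [c for c in aln.column(pos) if c != GAP_CODON]
        n_pairs = 0
        pn_sum = ps_sum = 0.0
        for c1, c2 in combinations(col, 2):
            sd, nd = ng86_pair_counts(c1, c2)
            s1, n1 = ng86_expected_sites(c1)
            s2, n2 = ng86_expected_sites(c2)
            sbar, nbar = 0.5 * (s1 + s2), 0.5 * (n1 + n2)
            ps = min(sd / sbar, 1.0) if sbar > 0 else 0.0
            pn = min(nd / nbar, 1.0) if nbar > 0 else 0.0
            ps_sum += ps
            pn_sum += pn
            n_pairs += 1
        if n_pairs:
            dN, dS = pn_sum / n_pairs, ps_sum / n_pairs
            recs.append((pos, n_pairs, dN, dS, dN - dS))
        else:
            recs.append((pos, 0, np.nan, np.nan, np.nan))
    table = pd.DataFrame(recs, columns=["position", "n_pairs", "dN", "dS", "d"])

    scored = table["n_pairs"] >= min_pairs
    z = np.full(len(table), np.nan)
    if scored.sum() >= 2:
        d = table.loc[scored, "d"].to_numpy()
        sd_d = d.std(ddof=0)
        if sd_d > 0:
            z[scored.to_numpy()] = (d.mean() - d) / sd_d
        else:
            z[scored.to_numpy()] = 0.0  # degenerate: every scored site identical
    elif scored.any():
        z[scored.to_numpy()] = 0.0
    table["z"] = z
    return SiteSelectionProfile(table=table, min_pairs=min_pairs)
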