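# consmotif

Conserved linear-motif discovery from ortholog codon alignments.

`consmotif` is a desk-scale molecular-evolution pipeline for a single
gene's ortholog set (e.g. the leptin-pathway genes *LEP*, *LEPR* and
*LEPROT*/endospanin across vertebrates, or endospanin orthologs across
eukaryote kingdoms).  From a multi-FASTA of in-frame coding sequences it
produces:

* a **reference-anchored codon alignment** — every query star-aligned to
  one reference ortholog (protein-level affine-gap alignment, back-threaded
  to codons), so all positions carry reference (human) numbering;
* a **per-site selection profile** — Nei–Gojobori-style counting of
  synonymous/nonsynonymous differences over all sequence pairs per codon
  column, giving dN, dS, d = dN − dS and its across-site z-score;
* a **combined 0–2 conservation score** per position,
  `score = c + clamp(z/2, 0, 1)` with `c = (m−1)/(n−1)` the modal-residue
  conservation: score 2 ⇔ 100% residue identity *and* selection more than
  2 SDs above the gene mean; score 0 ⇔ all residues distinct and
  at-or-below-mean selection;
* **top linear motifs** — the highest-scoring mutually non-overlapping
  21-codon sliding windows;
* **phylogenies** — TN93 distances, neighbor-joining trees, and supports
  from a seeded 500-replicate nonparametric bootstrap;
* **cross-group conservation categories** — for sequences partitioned
  into G organism groups, each position binned by how many groups conserve
  it, with band-percentage accounting;
* a **codon-evolution simulator** (site-specific ω, planted conserved
  blocks, clade-structured groups) so the whole pipeline is testable with
  no downloads.

See `docs/methods.md` for the models, conventions and their limits.

## Worked example

Simulate a 12-taxon, 60-codon ortholog set with one planted conserved
block at codons 20–40 and three organism groups, then run the full
pipeline anchored on taxon `t01`:

```sh
cat > sim.yaml <<EOF
n_taxa: 12
n_codons: 60
motifs: [[20, 40]]
n_groups: 3
seed: 9
EOF
consmotif simulate --config sim.yaml --out sim
consmotif all --fasta sim/orfs.fasta --ref t01 -k 1 --boot 100 --seed 3 \
              --groups sim/groups.tsv --out run
```

`run/motifs.tsv` — the rank-1 window recovers the planted block (19–39 vs
planted 20–40; window mean score 1.13 on the 0–2 scale):

```
#rank	start	end	window_mean_score
1	19	39	1.13141
```

`run/scores.tsv` (first positions) — position 2 is 100% conserved *and*
more than 2 SDs above the gene mean for purifying selection, so it reaches
the score-2 endpoint; positions 1 and 3 have modal-residue frequency 0.45
(c = 0.4) and at-or-below-mean selection (p = 0):

```
#position	n_residues	f	c	p	score	low_support
1	11	0.454545	0.4	0	0.4	False
2	11	1	1	1	2	False
3	11	0.454545	0.4	0	0.4	False
```

`run/group_summary.tsv` — 24/60 positions are conserved within all three
groups, 5 more in exactly two; 48.3% of positions are conserved in at
least two groupings:

```
#band	color	count	percent
exactly_3		24	40.0
exactly_2		5	8.3
any_rounded_sum		29	48.3
any_exact		29	48.3
```

`run/tree.nwk` holds the NJ tree with bootstrap percentages as internal
node labels, e.g. `((t04:0.0399,t05:0.0303)100:0.0584,t06:0.0419)92:...`.

The same stages are available individually (`align`, `tree`, `selection`,
`score`, `motifs`, `groups`, `simulate`, `recover`) and as library
functions (`consmotif.build_reference_alignment`,
`consmotif.site_selection_profile`, `consmotif.site_scores`, ...).

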