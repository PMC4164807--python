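# Methods

## The trace model

The unit of analysis is a multiple sequence alignment of orthologs that
spans two paralog groups, together with a partition assigning every
sequence to one group. For each group g and column c the *group
consensus* is

* the single letter shared by all non-gap residues of the group at c,
* `VARIABLE` if at least two distinct letters occur, or
* `ALL_GAP` if the group has no residue at c.

Columns are then classified: **conserved** when every group shows the
same single letter; **group-specific** when every group shows a single
letter but the letters differ; **neutral** otherwise. The three classes
partition the columns, so their counts always sum to the alignment length
and, after mapping onto a query row, to the query's residue count.

Two decisions here were genuinely open:

* A column invariant in one group but variable in the other is classified
  **neutral**. Requiring invariance in *every* group is what makes
  group-specific columns clean selectivity candidates and keeps the three
  classes a partition.
* Gaps are ignored inside a group (the consensus is taken over the
  non-gap residues), but an all-gap group column forces neutral; this is
  the least destructive convention for ragged alignment ends.

Strict invariance is the default (`min_group_identity = 1.0`). The knob
can be lowered to accept a majority letter (frequency among non-gap
residues ≥ threshold), which trades robustness to sequencing noise against
the crispness of "conserved"; nothing in the shipped analyses uses it.

The classification renders to the ET sequence — the conserved letter,
`X` for group-specific, `-` for neutral. A column conserved as the
unknown residue X would collide with the group-specific marker on
re-parsing; the rendering is a report format, not the data model, so the
collision is accepted and documented on `parse_et_sequence`.

## Sequence identity and the selection filter

Ortholog selection keeps candidates with *strictly more than* a threshold
(default 80%) identity to the query. Identity is defined over a global
Needleman–Wunsch alignment (match 1, mismatch −1, linear gap −2;
traceback ties resolved diagonal → up → left, so runs are reproducible)
as identical pairs divided by columns where neither row is a gap. Any
monotone similarity measure would do for a threshold filter; global
alignment keeps the package dependency-light and deterministic. `X`
counts as a mismatch; exact duplicates of the query (identity 100) are
always retained.

## Tree and partition

Distances are uncorrected p-distances — mismatch fraction over gap-free
column pairs. At the >80% identity the selection filter enforces,
multiple-hit corrections change distances by well under the branch-length
noise, so a correction model would add a parameter without information.

Neighbor joining follows Saitou–Nei: join the pair minimising
Q(i,j) = (n−2)d(i,j) − Σd(i,·) − Σd(j,·); limb lengths
lᵢ = d(i,j)/2 + (rᵢ − rⱼ)/(2(n−2)); the new node's distances are
(d(i,k)+d(j,k)−d(i,j))/2. Negative limb lengths are clamped to zero with
the deficit moved to the sister limb, preserving the joined path length.
Ties in Q are broken by the lexicographically smallest pair of subtree
keys (each active node keyed by its smallest leaf label), so the topology
is a pure function of the input matrix. The unrooted tree is represented
with a degree-3 root and serialises to Newick with 10 significant digits,
which round-trips branch lengths well below the 1e-9 tolerance the tests
assert.

The two-group partition removes one edge. The automatic rule picks the
edge maximising the minimum inter-group leaf-to-leaf path length — the
deepest split — with ties broken by balance and then by a canonical edge
order (preorder, children visited by smallest contained leaf). For two
paralog families this is the long internal edge between them; for a star
with one divergent leaf it isolates that leaf, which is the correct
reading of "deepest". The cut is also addressable manually by edge id or
leaf label, and that manual path is authoritative when reproducing a
published partition whose placement is only shown graphically.

## Structures

PDB files are parsed through gemmi behind light containers (chain →
residue → atom, Å). Policy: first altloc conformer, first MODEL (with a
warning), waters flagged and never counted as protein, hydrogens used for
distances if present (crystal structures typically lack them; a
`heavy_only` flag exists). Residue numbering follows the ATOM records
verbatim — the trace-to-structure join relies on it.

*Ligand selection.* Default: every non-water HETATM residue. Because
peptidomimetic inhibitors are often deposited as their own polymer chain
rather than as HETATMs, a chain override and a residue-name override
exist, and the chain override is the intended path for inhibitor
complexes such as 1FKN.

*Binding site.* A protein residue is in the site iff its minimum
atom-to-ligand-atom Euclidean distance is ≤ the cutoff (5.0 Å default,
inclusive — "within 5 Å" read as closed). Distances are computed as an
exact all-pairs scan (`scipy.spatial.distance.cdist` per residue); no
spatial index, so there is no pruning bug to have, and the tests still
compare against an independent pure-Python double loop.

*Superposition.* Chains are paired by globally aligning their one-letter
sequences (non-standard residues map to `X`) and keeping aligned residue
pairs where both carry a Cα. The Kabsch fit is the SVD of the 3×3
covariance with the determinant correction forcing a proper rotation;
RMSD is reported after applying the optimal transform. Because the pair
count depends on the matching rule, RMSDs against published values are
compared with a tolerance and the pair count approximately.

*Annotation.* Trace statuses joined onto a structure are written into the
B-factor column (0 neutral, 50 group-specific, 99.99 conserved, 25
unmapped) so any molecular viewer can colour by status.

## Synthetic data

`simulate_family` plants column statuses by construction: conserved
columns one letter everywhere, group-specific columns two distinct
letters, neutral columns a small per-column alphabet
(`neutral_alphabet_size`, default 4) with per-sequence substitution at
rate `within_group_noise` (default 0.1) *and* one forced disagreeing pair
in a randomly chosen group — so neutral columns are genuinely variable
even at zero noise and planted-status recovery is exact for every noise
level, which the suite exploits. The forced pair is drawn per column so
no sequence becomes a long-branch outlier. Defaults (two groups of 7,
length 200, 40% / 25% / 35% status fractions) mirror a two-paralog
mammalian ortholog family in the regime the worked example reports.
The noise model is i.i.d. per sequence with no phylogenetic
autocorrelation and no indels, so passing tests demonstrate correctness
of the classification and partition machinery, not robustness to real
alignment error; trees inferred from these families are star-like within
groups, which is exactly the regime where the deepest-split rule must
still find the inter-group edge.

`simulate_complex` builds a single backbone-only chain (N, CA, C, O) on
an ideal helix (1.5 Å rise, 100° twist, 2.3 Å radius) or a straight
3.8 Å-spaced chain, and places each ligand atom at an exact requested
distance from a target residue's Cα along a given direction. The true
binding site is then *measured* from the emitted coordinates by an
exhaustive scan, so the truth is consistent whatever the backbone does
around the planted contacts; requested distances are exact to 1e-6 Å in
memory and to the 3-decimal precision of the PDB format on disk. No
side chains: the 5 Å rule is atom-set agnostic, so backbone-only
fixtures exercise it fully.

The packaged reference table (`table1_fixture`) lists the 28 BACE1 and
24 BACE2 binding-site residues with trace statuses and the BACE1↔BACE2
correspondence; it is the oracle for the worked-example counts (flap
intersection 69–73, four group-specific pairs, conserved dyad
Asp32/Asp228).

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run on alignments of length
60–200 with 8–14 sequences, toy complexes of 40–390 residues, and 100
simulation seeds per recovery rate — sizes at which every oracle
(exhaustive alignment enumeration, 15-topology least-squares search,
all-pairs distance scans, 20 000-rotation grids) is exact or dense while
the whole suite stays in the seconds range. All randomness flows from
explicit integer seeds; identical seeds give byte-identical FASTA/PDB
outputs, and a pipeline re-run writes a byte-identical MANIFEST.

## Known limitations

* Only two-group partitions; the original ET rank sweep over nested
  partitions is out of scope.
* The >80% ortholog selection assumes the candidate set is supplied;
  database search is external.
* p-distances without correction are only appropriate for the
  high-identity families the method targets.
* The Cα pairing rule is sequence-based; structure-based alignment of
  remote homologs is out of scope.
* Real-structure checks (binding-site counts, chain-A RMSD) need the
  crystal structure files locally; they are not redistributable with the
  package.
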