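# Methods

## Scope and model

pocketbench treats "pocket similarity" operationally: two binding sites are
similar when (i) their typed ligand–protein contact environments overlap,
(ii) a residue correspondence between them places the two bound ligands on
top of each other, or (iii) they induce correlated compound rankings in
structure-based virtual screening. The package computes these three signals
and the machinery to benchmark any external pocket-matching score against
labelled pairs. It deliberately does **not** compute global structure
similarity: TM-scores are consumed from an external lookup (a structural
alignment tool or the fixture generator), because the benchmark's defining
constraint — pairs must be globally *dissimilar* (TM-score < 0.4) — is an
input to curation, not an output.

## Contacts and the binding environment (structures)

A contact is any ligand-heavy-atom / residue-heavy-atom pair at ≤ 4.5 Å
(`CONTACT_CUTOFF`, configurable). This distance surrogate replaces
surface-complementarity contact definitions whose internals are not
reproducible; it shifts absolute contact counts but not the comparative
statistics built on them, since both pockets of a pair are profiled
identically. Binding residues are residues with at least one contact at the
same cutoff. Contacts are typed by the residue group
I (LVIMC), II (AG), III (ST), IV (P), V (FYW), VI (EDNQ), VII (KR),
VIII (H); modified residues map to their parent amino acid through a small
alias table (MSE→MET etc.) and otherwise drop out of profiles with a log
entry.

Parsing conventions: first MODEL only; per (residue, atom-name) group the
highest-occupancy alternate location wins, ties broken by the lowest altloc
character; author residue numbering and insertion codes are preserved;
chain length is counted over polymer residues with at least one atom, not
over the deposited sequence record. A hetero group is a candidate ligand if
its code is off the solvent/ion/cryoprotectant exclusion list, it has heavy
atoms, and no heavy atom lies within 1.9 Å of the protein (covalent-link
threshold).

## Ligand chemistry (chem)

Ligands come from HETATM records where bond orders, protonation and
aromaticity are unreliable, so all chemistry runs on element-labelled
heavy-atom graphs:

* **Bond perception**: bond iff distance ≤ 1.15 × (sum of covalent radii).
  Atoms closer than 0.5 Å are treated as corrupt input.
* **Fingerprint**: all simple linear paths of 1–7 atoms, the element
  sequence canonicalized to the lexicographically smaller read direction,
  hashed by CRC-32 into 1024 bits. The dialect is fixed and deterministic
  across platforms; absolute Tanimoto values differ between fingerprint
  dialects, which only shifts thresholds, so the curation thresholds below
  are interpreted *in this dialect*.
* **Atom equivalence**: maximum connected *induced* common subgraph under
  element matching, by backtracking search with a per-element-count bound;
  induced matching was chosen over edge-subset matching for symmetry and
  because it admits a clean exhaustive oracle. A wall-clock budget
  (default 30 s) returns the best-so-far mapping with a truncation flag;
  in practice drug-sized molecules (≤ ~35 heavy atoms) solve in
  milliseconds because the element-count upper bound is usually attained.
* **Leader clustering**: molecules in descending heavy-atom order join the
  first representative with TC ≥ threshold. This deterministic rule stands
  in for unspecified published orderings; its output is order-invariant
  whenever pairwise similarities are cleanly above/below threshold.

## Superposition and reference alignments (geometry)

Rigid superposition is the SVD Kabsch solution with the determinant sign
correction (never a reflection). Point sets of fewer than 3 points, or
collinear within 1e-9, are rejected rather than silently under-determined.

The **reference alignment** of a pocket pair superposes complex B onto A
over chemically equivalent ligand atoms, then pairs binding residues
one-to-one by minimum-total-cost Hungarian assignment on Cα–Cα distances,
admitting pairs within 5.0 Å (`PAIR_CUTOFF`). Assignment-plus-cutoff is a
design choice where the literature procedure is underspecified; the cutoff
and the assignment rule are configuration values. For chemically different
ligands the ligand RMSD is computed over equivalent atoms only (an
ATP/ADP-style comparison forces a common-atom convention).

## Statistics (metrics, benchmark)

* **SSC** = |A∩B| / min(|A|,|B|); the intersection is a *maximum* bipartite
  one-to-one matching of contacts (greedy matching undercounts when one
  ligand atom touches several residues of the same group).
* **Kendall τ** is the τ-a form, (n_C − n_D)/(n(n−1)/2), with no tie
  correction: sequence positions are unique within a chain, so ties cannot
  arise in well-formed alignments.
* **Spearman ρ** is the classical 1 − 6Σd²/(n(n²−1)) without ties and the
  Pearson correlation of midranks with ties — the formula is the no-ties
  special case of the midrank form, and docking scores do tie. Rank 1 is
  the best (most negative) predicted affinity.
* **MCC** returns 0 when any marginal is empty; alignment MCC treats every
  possible residue pair as a classification unit with TN over the
  n_A × n_B universe.
* **ROC/AUC** uses the Mann–Whitney rank identity with half-credit for
  ties, which equals the trapezoidal integral of the step curve (asserted
  to 1e-10 in tests). Sensitivity at an FPR level is the TPR at the largest
  achieved FPR ≤ level. Pairs missing a method's score are excluded for
  that method and counted, not imputed: tool failures should be visible.
* **Meta-predictor** = direct score × ρ; monotone in each factor over
  positive ranges.

## Curation pipeline (curation)

Stages, with defaults in `CurationConfig` (all published operating points):
chain length 50–999 residues; best Tanimoto to a drug library ≥ 0.5; one
qualifying ligand per chain; greedy longest-first sequence clustering at
40% identity (global alignment, BLOSUM62, gap open/extend −11/−1, identity
= exact matches / alignment columns); within a sequence cluster, records
are kept when their ligands differ chemically (TC < 0.5) *or* their sites
are ≥ 8 Å apart (ligand-centroid distance; the conjunctive reading is
available via `representative_rule="and"`); predicted pockets must match
ligand-derived pockets at MCC ≥ 0.4; ligand leader clustering at TC 0.7;
and all pairs require TM-score < 0.4. Positives are within-ligand-cluster
pairs; negatives pair per-cluster representatives (the record with the most
binding residues) across clusters. Every record ends up either in the
survivor set or in the filter log with the rule that removed it, and
`verify_manifest` re-audits every constraint of the finished manifest.

## Synthetic data (fixtures)

The generators emulate the *structure* of the benchmark's inputs, not the
physics:

* Chains are self-avoiding Cα walks with exact 3.8 Å steps, no
  non-consecutive pair closer than 3.5 Å, and one side-chain pseudo-atom
  1.5 Å from each Cα. Very long chains (> a few hundred residues) use a
  regular helix with the same spacing guarantees. The ligand is a short
  zigzag heavy-atom chain (1.45 Å bonds) laid along the backbone ~3.6–4 Å
  out, which yields pockets of ~4–10 residues.
* A **positive pair** copies the pocket micro-environment (binding residues
  + ligand) into an independently folded decoy chain under a random rigid
  motion with optional Gaussian coordinate noise, renumbered in shuffled
  order. The planted residue mapping and identity ligand equivalence are
  exact ground truth: at zero noise the reference alignment must recover
  the mapping with ligand RMSD 0. A **negative pair** plants a pocket with
  disjoint contact types (different ligand elements, different residue
  groups), guaranteeing near-zero SSC.
* **Alignments with controlled order**: the B-side permutation is a
  Bernoulli mixture — with probability |level| the fully ordered (or
  reversed) correspondence, otherwise a uniform shuffle — so the expected
  τ equals the level exactly, the ±1 levels are deterministic, and the
  mixture variance is realised across seeds.
* **Rank matrices** come from a Gaussian copula; the latent Pearson
  correlation is back-transformed from the requested Spearman value via
  r = 2 sin(πρ/6) (the exact bivariate-normal relation), so planted ρ is
  recovered without bias. A synthetic molecular-weight covariate is coupled
  to all targets the same way, mimicking the weight-driven component of
  docking-score correlations.

What passing tests on these fixtures shows: the algorithms are correct on
inputs whose ground truth is known by construction. What it does not show:
robustness to real crystallographic pathology (disorder, split occupancies
beyond simple altlocs, lattice contacts), to real docking-score error
structure, or to the contact definitions of any specific published tool.

## Numerical choices

Distances compare with ≤ at cutoffs; Kabsch degeneracy is a second singular
value < 1e-9 of the centered coordinates; Hungarian-inadmissible residue
pairs carry a large finite cost and are filtered after assignment (keeps
the assignment solvable when no full matching exists); clustering and
representative selection break ties by input order and record id so every
pipeline stage is deterministic; fingerprints hash with CRC-32, not
Python's salted `hash`. Spearman and τ raise on degenerate input (constant
vectors, alignments shorter than 2) instead of returning NaN.

## Known limitations

* The contact surrogate will not reproduce any specific tool's contact
  lists atom-for-atom; worked-example SSC/τ/RMSD values on deposited
  structures are therefore expected to land within ~0.1 of published
  values rather than exactly on them.
* The connected-MCS search is exact but exponential in the worst case; the
  time budget makes it an anytime algorithm on adversarial graphs.
* mmCIF input, biological assemblies, hydrogens, and resolution-based
  filtering are out of scope; external aligner/docking tools are consumed
  through parsers, never invoked.
* Printed dataset sizes of any published compilation are snapshot-dependent
  and are not reproduction targets; the pipeline reproduces the *rules*,
  audited per record, not the counts.
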