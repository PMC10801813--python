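# Methods

## Scope and model of the data

`afscreen` analyses the *outputs* of AlphaFold-Multimer-style structure
prediction; it never runs prediction itself. Its unit of input is a
prediction ensemble for one candidate pair: M coordinate files (PDB or
mmCIF, per-residue pLDDT stored in the temperature-factor field by the
AlphaFold convention) and M PAE matrices (JSON, either the ColabFold
`"pae"` dialect or the AFDB `"predicted_aligned_error"` dialect, optionally
wrapped in a one-element list). Models of one pair are assumed
residue-identical; no sequence alignment between models is attempted.
Run provenance (weights version, recycles, dropout, templates) is carried
as free-text metadata only — it never influences scoring.

## Contact definition

A contact is an inter-chain residue pair passing three filters, all strict:

| filter | default | units |
| --- | --- | --- |
| pair-mean pLDDT | > 50 | 0–100 scale |
| best-direction pAE, min(pae[i,j], pae[j,i]) | < 15 | Å |
| minimum inter-residue heavy-atom distance | < 8 | Å |

Interpretation choices, where the plain-language definition is ambiguous:
"average pLDDT" of a pair is the arithmetic mean of the two residues'
values (the only reading consistent with a per-pair filter); "minimum pAE"
takes the better of the two directions, since PAE is directional; and "two
non-hydrogen atoms closer than 8 Å" is read as at least one heavy-atom pair
— one atom from each residue — within 8 Å, i.e. a minimum-distance
criterion over all heavy-atom pairs. Hydrogens (and deuterium/tritium) are
parsed and retained but can never affect detection.

The neighbour search uses a k-d tree (`scipy.spatial.cKDTree`) pruned at
the distance cutoff; an all-pairs brute-force path is kept in the module
and the test suite additionally checks the tree search against an
independent brute-force oracle written in the tests themselves. Correctness
is anchored to that oracle; the tree is only an optimisation.

## Interface statistics and pDockQ

Per prediction and chain pair, the interface summary holds the contact
count n, the mean over contacts of the per-contact minimum pAE, the mean
over contacts of the per-contact mean pLDDT, and pDockQ with the standard
published sigmoid constants (L = 0.724, x0 = 152.611, k = 0.052,
b = 0.018, natural logarithm). Empty interfaces report their averages as
absent and pDockQ as exactly 0 rather than the sigmoid floor b: an
interface that was never predicted should not outrank any predicted one.

pDockQ's x is computed from *this pipeline's* contact set. The originally
published recipe instead counts Cβ–Cβ (Cα for glycine) pairs within 8 Å
and averages pLDDT over the unique interface residues; that variant is
available as `pdockq_reference_cb` for comparison, with the own-contacts
definition as the default.

## Cross-model aggregation

Unique contacts are keyed exactly by (chain, residue number) pairs — no
clustering of near-identical contacts. For a pair predicted by M models,
each unique contact's count is the number of models containing it;
`avg_n_models` is the mean of the counts and `max_n_models` their maximum.
Models with empty interfaces contribute no counts but still count toward
M (the counts are "how many models predicted this contact", not a
renormalisation). Both metrics are absent when no model found any contact.

The ranked screen table needs one representative `pdockq` /
`avg_interface_pae` / `avg_interface_plddt` value per pair. The default
reduction is "best" (maximum pDockQ and pLDDT, minimum pAE over models —
the most confident model as representative); a "mean" reduction over the
models with non-empty interfaces is selectable. Ties in per-model optima
break deterministically to the lowest model id.

## Ranking protocol

Candidates sort lexicographically by `avg_n_models` (descending), `pdockq`
(descending), `avg_interface_pae` (ascending), with any remaining tie
broken by partner identifier ascending, so the order is total and
independent of input order; ranks are assigned 1..N without gaps. Rows with
no metrics (no contacts in any model) sink below all scored rows — their
missing pDockQ is treated as −∞ and missing pAE as +∞ — and order among
themselves by identifier. Annotation re-ranking sets a 0/1 flag from a
supplied identifier set and re-sorts with the flag as the primary
descending key followed by the same metric keys; the same sinking rule
applies within the flagged and unflagged blocks.

Proteome input filtering keeps sequences of 15–3034 residues inclusive and
removes exact duplicates after uppercase normalisation (first occurrence
kept) — no similarity threshold, since redundancy here means identical
strings.

## Synthetic fixtures

The generator emulates the file-level contract of real predictions —
multi-chain coordinates with pLDDT tracks, square PAE matrices over the
concatenated residue index, M-model ensembles — while keeping the ground
truth analytic. Chains sit on lattices separated by `background_min_dist`
(default 20 Å, required > 8 Å); each planted contact moves one designated
residue purely along +z to its target heavy-atom distance (< 8 Å, realised
to 0.01 Å through the file round trip). Because the offset is orthogonal
to the lattice plane and rows are far apart, a moved residue approaches
only its partner, so the residue pairs within the cutoff are exactly the
planted ones and a fixture's expected contact set can be stated in its
manifest without running any search. Residue placement conflicts (one
residue in two planted contacts) are rejected before writing. Background
residues carry pLDDT 40 (must be ≤ 50, so unplanted pairs also fail the
pLDDT filter) and pairwise PAE 30 Å; planted contacts carry their own
pLDDT/PAE values, which may deliberately fail a filter — the manifest then
lists them as planted-but-filtered. Residues default to a single Cα atom;
a three-atom (N, Cα, C) variant exercises the minimum-over-atoms rule, the
extra atoms being offset in-plane so the Cα–Cα separation remains the
pairwise minimum. Ensembles realise each planted contact only in the
models of its membership set, and the manifest's `avg_n_models` /
`max_n_models` are the mean/max of the membership sizes over
filter-passing contacts.

What the fixtures do *not* emulate: realistic backbone geometry, secondary
structure, sequence plausibility, spatially correlated PAE, or pLDDT
smoothness along the chain. Passing tests therefore demonstrate that the
bookkeeping — parsing, indexing, filtering, counting, ranking — is exact,
not that the confidence metrics are biologically calibrated.

## Numerical and I/O choices

- pLDDT is kept on the 0–100 scale; files whose B-factors are all ≤ 1 are
  auto-rescaled ×100 with a warning (both conventions occur in the wild,
  and the 50 threshold assumes 0–100). All-zero B-factors are an error
  (pLDDT missing), as is a file with fewer than two chains.
- Atoms of one residue are expected to share the residue's pLDDT; spreads
  above 0.01 warn and the first atom's value is used. Altloc duplicates
  keep the highest occupancy, ties by file order. HETATM ligands/waters
  are skipped; only the first MODEL block of a multi-model PDB is read.
- The PAE matrix maps to residues by concatenated chain order as written
  in the coordinate file; a size mismatch with the structure is an error
  reporting both counts. PAE is never symmetrised.
- Relaxed and unrelaxed coordinates are both accepted; the reader makes no
  distinction.
- TSV output formats real metrics with 3 decimals and integers unpadded,
  and every ordering is deterministic, so re-running a command on the same
  inputs is byte-identical. Logging goes to stderr, results to
  stdout/files.

## Problem sizes in the shipped suites

The test and acceptance suites run on desk-scale synthetic data: random
fixtures of up to 50 residues per chain for oracle-equivalence checks (100
fixtures), 100 random 5-model ensembles for end-to-end planted-truth
recovery through the file formats, a 200-fixture suite for the pDockQ
bound claim, and 50 random 5-model ensembles for the agreement-metric
bounds. These sizes make every check exhaustive or exactly verifiable
against an independent oracle while completing in seconds.

## Known limitations

- Contacts are matched across models by exact residue key only; a
  one-residue register shift between models would count as two different
  contacts.
- pDockQ constants are taken as published; no recalibration against DockQ
  on reference complexes is performed, and ipTM/pTM are not extracted.
- STRING membership is consumed as a plain identifier list; no REST
  retrieval or identifier mapping is included.
- The screen assumes one bait–partner chain pair per prediction; higher-
  order complexes are scored one chain pair at a time.
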