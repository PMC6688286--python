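# Methods

This note documents the model, the operational definitions, the numerical
choices and the known limitations of the `nplikeness` toolkit. It states no
empirical result that the test suite or `scripts/acceptance.py` do not
themselves compute.

## Model

The NP-likeness of a molecule is the average log odds of its fragments
between a natural-product corpus and a synthetic-molecule corpus.
Fragments are height-*h* atom signatures (default *h* = 2): the canonical
form of the subgraph induced by all atoms within graph distance *h* of a
root atom. Height 2 balances structural specificity against over-training;
height 1 environments are too generic, height 3 fragments become so rare
that counts are dominated by noise. The model assumes that the two training
corpora differ in fragment composition and that per-fragment frequencies,
normalised per molecule, carry the class signal; it makes no use of global
molecular properties.

Training counts fragment occurrences with multiplicity (a fragment present
three times in a molecule adds 3 to its class count), while the corpus
totals `NP_t` / `SM_t` count molecules, so the `SM_t/NP_t` factor corrects
for corpus-size imbalance and nothing else.

## Curation pipeline

Order: parse → strip stereochemistry → keep largest connected component →
element/size filter → stereo-free InChI key → merge duplicates.

* Stereochemistry is stripped because source databases disagree wildly on
  its presence and encoding, and stereo descriptors would split otherwise
  identical fragments.
* The size filter drops molecules with fewer than 6 atoms. "Atoms" are
  counted as **heavy atoms** by default: hydrogen counts depend on how a
  given file encodes them (implicit vs explicit), heavy-atom counts do
  not. Both the floor (`--min-atoms`) and the counting mode
  (`--count-hydrogens`) are configurable.
* Allowed elements: C, H, N, O, P, S, Cl, F, As, Se, Br, I, B, Na, Si, K,
  Fe. Anything else rejects the record.
* Duplicate structures across sources merge on standard InChI of the
  stereo-free largest component. A merged molecule is labelled NP if any
  source labels it NP — public databases are known to mislabel — and every
  conflict is logged for audit. Records labelled *biogenic* are curated and
  stored but excluded from both training classes.
* No explicit charge/protonation standardisation and no tautomer
  canonicalisation are attempted: counter-ions disappear with
  largest-component selection, and anything further would be an
  underdetermined design choice better left to the caller's preprocessing.

## Sugar removal

There is no single community definition of a "sugar moiety"; the
definitions here are the package's own, deliberately simple, and exposed as
tunable thresholds (`sugar_rules.json`, `SugarRules`):

* **Circular**: a non-aromatic 5- or 6-ring with exactly one ring oxygen,
  otherwise carbons, not fused to another ring, whose ring carbons carry at
  least (ring size − 2) exocyclic single-bonded oxygens. This captures
  pyranoses/furanoses and their glycosides while sparing plain cyclic
  ethers (THF, THP, morpholine) and fused-ring ethers.
* **Linear**: a maximal acyclic component of 3–7 carbons, none in a ring,
  each bearing exactly one oxygen substituent (hydroxyl, carbonyl or
  bridging). Polyols and open-chain aldoses qualify; alkyl chains and
  esters (two oxygens on the acyl carbon) do not.
* Removal deletes the sugar atoms plus their oxygen substituents; a
  bridging oxygen survives only if it connects two non-sugar heavy atoms.
  Circular sugars are removed before linear ones so ring sugars cannot be
  partially consumed by the chain pattern; the largest remaining component
  is the aglycone, and a remainder below 6 heavy atoms yields no aglycone
  (the molecule was essentially all sugar). Sugar-free molecules are exact
  fixed points and removal is idempotent on aglycones — both are asserted
  in the tests.

These rules intentionally do not special-case deoxy-, amino- or acid
sugars; on glycoside-rich real corpora they will classify somewhat
differently than more elaborate detectors, which is why they are
configuration, not code.

## Atom signatures

Hydrogens are made explicit and are signature centres in their own right
(H-centred fragments exist in the trained tables; a flag excludes them if
unwanted). Aromaticity is perceived after curation and aromatic bonds
carry their own bond token — Kekulé alternation would split equivalent
aromatic atoms into artificial classes.

Canonicality is the load-bearing property: two atoms must receive the same
string exactly when their rooted height-*h* neighbourhood subgraphs are
isomorphic. Tree-serialisation schemes with locally sorted branches are
not exactly canonical on ring-containing neighbourhoods, so the
neighbourhood graph (root distinguished, atom tokens as vertex colours,
bond tokens as colours on subdivision vertices) is canonically labelled
with BLISS (via `igraph`), and the string is serialised from the canonical
order. Colour integers are derived from the sorted label set because BLISS
canonical forms depend on colour values, not just the partition. The test
suite checks the result against an independent brute-force VF2
rooted-isomorphism oracle (networkx) over every atom pair of a panel of
small molecules, and checks permutation invariance over the fixture
corpora.

The string grammar is versioned (`sig1/...`) and must never change meaning,
since trained stores persist these strings.

## Score computation

* `Frag_i` is evaluated as one sign-canonical logarithm of the integer
  products `(NP_i+p)·SM_t` and `(SM_i+p)·NP_t`. This makes two properties
  hold bit-exactly in floating point: swapping the corpora negates every
  score, and scaling all counts and totals by a common factor (pseudocount
  0) changes nothing.
* Log base: natural, configurable (`--log-base 10`); the base is a pure
  rescaling and is recorded in every table and store.
* Pseudocount: 1 on `NP_i` and `SM_i` only (not the totals), default on.
  At pseudocount 0 a fragment absent from one class scores ±∞ rather than
  erroring; absent from both classes it has no score at all.
* `N` in the molecule score counts only fragments found in the table.
  Excluding unknown fragments from the denominator as well as the numerator
  keeps the score a weighted mean of known fragment scores, hence always
  within [min, max] of the fragments used; a molecule with no known
  fragment has a null score plus an alert, never a fabricated 0.
* Class imbalance is tolerated (the totals ratio corrects it); the CLI
  warns above 10×.

## Store

A single-file SQLite database (stdlib `sqlite3`) with the five content
tables (`ori_molecule`, `molecule`, `fragment_with_sugar`,
`fragment_without_sugar`, `molecule_fragment_cpd`) plus `meta` for the run
configuration; the DDL ships as `schema.sql`. Raw submissions accumulate
redundantly with provenance; curated molecules are unique by structural
key, and re-ingesting a file can therefore never double-count fragments.
All counts and totals are derivable from the rows, which is what makes
`rescore` possible without the original input files. "Byte-stable" in the
tests means byte-identical TSV dumps of every table (the dump has a
deterministic row order and lossless float formatting); the SQLite file
itself is not a stable byte representation. The per-molecule
"repeated fragments" column counts *distinct* non-H-centred signatures
with multiplicity ≥ 2 (zero means every fragment occurs once).

## Synthetic fixtures

The fixture generator emulates the statistical contrast the scorer relies
on, at desk scale: NP-like molecules from an oxygen-rich grammar
(polyol-substituted carbocycles, lactones, a terpenoid chain, a flavanone),
with a configurable fraction (default 0.4) decorated with a glycosylated
pyranose or furanose; SM-like molecules from halogenated-aromatic,
sulfonamide, urea and nitroarene templates. Benzene cores appear in both
grammars on purpose, so scoring exercises shared and unknown fragments.
Template assembly guarantees chemical validity; exact decorated/plain
counts are generated per class so deduplication cannot skew the sugar
fraction; the same spec yields byte-identical files.

What the fixtures do **not** model: the structural breadth, ring diversity,
tautomers, charge states and label noise of real corpora. Passing the
separation test (≥ 95% of held-out molecules on the correct side of zero,
trained at 200 molecules per class, scored on 100 held-out per class)
demonstrates that curation, fragmentation, training and scoring compose
correctly — not that the score transfers with that accuracy to real
chemical space. Published full-scale corpora are hundreds of thousands of
molecules per class; all problem sizes here (200/100 per class, the
300-molecule sugar-rate check) were chosen as the smallest sizes at which
the statistical properties are stable.

## Numerical details and degenerate inputs

* Largest-component ties break by heavy atoms, then total atoms, then
  lexicographically smallest canonical SMILES — order-independent.
* Fragment ids are assigned in sorted signature order at training, so
  identical corpora always produce identical tables.
* Molecule score summation uses exact float summation (`math.fsum`) before
  a single division.
* Unparseable records, InChI failures, all-sugar molecules and empty
  classes are all non-fatal where the contract allows (logged and counted);
  empty training classes and empty stores are fatal.

## Limitations

* The sugar definitions are heuristic (see above).
* Fragment scores from small corpora carry large pseudocount bias; scores
  are comparable only between runs with the same height, base and
  pseudocount (all recorded in table/store metadata).
* No similarity fallback for unknown fragments: a molecule far outside the
  training space is flagged, not extrapolated.
* The store is single-writer; concurrent deployment is out of scope.
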