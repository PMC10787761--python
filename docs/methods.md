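# Methods

## The meta-pathway model

A pathway knowledge base records biochemical events as reactions: a set of
substrates is converted into a set of products, optionally under one or more
controllers (enzymes, transporters, modulators) and cofactors.  Signaling
events are a special case — in a post-translational modification (PTM) the
substrate and product are the same protein, and the interesting actor is the
controlling kinase — while metabolic events rename their participants.  The
meta-pathway construction maps both onto one directed-graph shape by
materialising, per reaction, an *intermediate node* that stands for the
transient state in which substrates and enzyme are bound together:

* substrate → intermediate (`sub`),
* controller → intermediate (`ctrl+` activating, `ctrl-` inhibiting,
  `ctrl` unknown sign or cofactor),
* intermediate → product (`pro`).

Because every molecular participant connects only through intermediates, the
merged multi-database graph (the global integrative network, GIN) stays a
faithful hypergraph encoding: grouping a reaction's edges by its
intermediate recovers (substrates, controllers ∪ cofactors, products)
exactly, a property the test suite asserts over randomly generated
reactions.

Assumptions and simplifications: stoichiometry, compartments and kinetics
are discarded (participants are sets); reversible conversions are emitted
once in their stated direction unless `expand_reversible` is set, in which
case the mirror reaction gets its own intermediate; protein–protein binding
interactions outside the ComplexAssembly reaction class are out of scope, as
are template (expression) reactions.

## Naming rules

Determinism of names is what makes cross-database merging work, so every
rule is fixed byte-exactly:

* **Intermediates**: sorted unique substrate names, then sorted unique
  controller names, joined by `;`.  Cofactors receive `ctrl` edges but are
  not part of the name — the name describes the substrate–enzyme encounter.
  Names are assigned **after** identifier unification.  When distinct
  reactions share substrates+controllers but differ in products, every
  colliding intermediate gets a `;#k` suffix, k ranking the sorted product
  sets, so each intermediate denotes exactly one reaction.  (A suffix is
  applied only on true collision; a collision present in one database but
  not another therefore yields differing names — accepted, since such
  collisions are rare and the alternative, always suffixing, would make all
  names depend on corpus composition.)
* **Degenerate reactions**: an uncontrolled single-substrate reaction (e.g.
  a bare degradation) produces an intermediate whose name *is* its member.
  The node keeps the member's kind, the self-shaped edge is kept, and the
  case is counted in diagnostics.
* **Complexes**: recursively flattened; leaves are unified names (non-protein
  members are kept — dropping them would silently lose interactions);
  duplicates collapse (homodimers contribute one token); sorted ascending in
  plain byte order (locale-independent) and joined by `_`.
* **Genes**: a direct gene-symbol xref wins over a UniProt table mapping,
  which wins over any other mapped source; remaining ties break on sorted
  (source, id).  Conflicts are logged, never fatal; unmappable entities
  become `UNMAPPED:<id>`.
* **Chemicals**: one of six unified chemical ID types — default precedence
  CID > SID > CAS > KEGG > HMDB > ChEBI, configurable
  (`chemical_precedence`) because different corpora favour different
  sources; ties within a type break on the smallest external id.  The
  chosen type is recoverable from the prefix (`CID…`, `SID…`, `CAS:…`,
  `KEGG:…`, `HMDB…`, `CHEBI:…`).  Entities that are neither protein/gene
  nor small molecule fall back to `NAME:<display name>` and are treated as
  gene-side nodes (the node-kind vocabulary is gene / chemical / complex /
  intermediate).

## Parsing and unification inputs

Only the BioPAX level-3 vocabulary is interpreted; other RDF content is
counted and ignored.  Internal entity IDs are the URI fragment.  Property
order and literal bytes are preserved, and parse errors name the offending
line — the reason parsing is built on `lxml` rather than a triple store,
which would normalise both away.  Cross-references attached to an entity
reference (ProteinReference, SmallMoleculeReference) are inherited by every
physical entity pointing to it, matching how PathwayCommons exports attach
unification xrefs.  Xref source spellings are case-folded through a
configurable alias table (e.g. `pubchem-compound` → `CID`).  Gene-symbol
mapping is file-driven — a (source, external id, symbol) TSV — so runs are
reproducible offline.

Controllers come from Catalysis, Control and Modulation individuals whose
`controlled` is an extracted reaction; `ACTIVATION*`/`INHIBITION*` control
types map to signs, a Catalysis without a control type is activating (its
definition), a bare Control/Modulation is unknown.  Controls that target
other controls are logged and not chained.

## Merging and the non-human filter

Merging is set union on (source, edge type, target) triples with provenance
tags unioning — idempotent and order-independent, verified by permutation
tests.  A node reported with different kinds by different inputs is a hard
error rather than a silent guess.  Humanness of a gene node is decided from
its organism annotation when the source provides one, else by membership in
the supplied human gene table; every edge incident to a non-human gene, and
every edge of an intermediate whose name embeds one (that intermediate's
reaction involves the gene), is removed, then orphaned nodes are dropped.
The whole reaction is removed rather than the single offending edge because
the intermediate's identity already contains the non-human participant.

## Network analysis

Degree is in+out over unique edges, ties broken by node id.  Community
detection runs Leiden (python-igraph / leidenalg) on the directed graph with
parallel edge types collapsed to single arcs; the default objective is
directed modularity (RB configuration null model) at resolution 1.0, both
configurable, and the partition is deterministic given (graph, resolution,
seed).  On components too small for modularity to distinguish any split,
every candidate partition scores zero and Leiden's tie-breaking is
arbitrary; a deterministic post-pass therefore merges edge-connected cluster
pairs whose merge does not decrease the objective.  Only zero-gain merges
can fire (Leiden is locally optimal), component separation is preserved, and
planted-community benchmarks are unaffected.  Clusters are relabelled by
descending size.

Database contribution assigns an edge to a cluster when both endpoints are
inside it; a cluster's per-database percentages may sum above 100 because a
shared edge counts once per contributing source.

Subnetwork extraction collects the seeds, the intermediates adjacent to
them, and those intermediates' participants; with regulator expansion, for
every enzyme in that core (gene or complex with a control edge into a core
intermediate) the intermediates producing the enzyme and their controllers
are added — the pattern that pulls in the kinases whose PTM reactions
modify a metabolic pathway's enzymes.  The result is the induced edge set,
patched so no intermediate is left without its member side.

## Synthetic data: what it emulates and what it does not

The generator (`ginkit.synthetic`) is the oracle for the whole pipeline.
Its defaults define the desk-scale study conditions used throughout the
tests and the acceptance script: 3 databases × 50 reactions, 30 genes, 40
chemicals, 40% signaling reactions, 20% of reactions planted into every
database, 15% complex-controlled reactions, 8% reactions involving a
non-human gene, 1–3 xref sources per chemical.  These sizes keep a full
end-to-end run under a second while exercising every branch: all six
reaction classes, all three control classes with and without explicit
control types, nested complexes, a planted chemical synonym table, and
distractors (a participant-less reaction, a template reaction, a chained
control) that must be dropped or ignored *and counted*.

Two deliberate design constraints make the planted truth well-posed:

* every chemical has one *anchor* xref source present wherever the chemical
  appears, with extra synonyms drawn only from strictly lower-precedence
  sources — otherwise two databases could legitimately unify the same
  molecule to different IDs and "planted overlap" would be ambiguous;
* reactions are sampled so that no two share both substrate set and
  controller set, so intermediate names are collision-free and the expected
  edge set follows from the naming rule alone (collision handling is
  covered by dedicated unit tests instead).

Shared reactions are planted into *all* databases (keeping per-database
reaction counts exact); pairwise-only overlaps are exercised by unit tests.
The generator's bookkeeping — expected edges, node kinds, overlap tables,
non-human removals — is computed with plain set logic, independent of the
conversion modules it judges.

What the synthetic corpus does **not** emulate: heavy-tailed degree
distributions and hub metabolites (water, ATP) of real knowledge bases,
database-specific naming quirks and special characters, compartments,
stoichiometry, and corpus sizes in the tens of thousands of reactions.
Passing tests therefore demonstrate correctness of the conversion algebra
and analyses, not fidelity of any particular real-world curation; runs on
real PathwayCommons-style archives will additionally exercise the alias
table and the `NAME:` fallbacks far more heavily.

Two further fixtures are built directly at the network level: a planted
3-community graph (45 intra-community reactions over 8 genes + 10 chemicals
per community, 2 bridges) whose labels Leiden must recover, and a
glycolysis-like chain (10 conversions, each with its own enzyme, 7 enzymes
carrying a planted kinase PTM, plus disconnected background reactions)
whose regulators extraction must recover exactly.

## Numerical and degenerate-input choices

* All randomness is seeded: the generator from its spec seed, Leiden from
  the run config.  Reruns are byte-identical, including file output (edges
  sorted by triple, nodes by id).
* SIFI files always carry the provenance column (singleton for per-database
  files), so the write/read round-trip is lossless in one uniform layout;
  the 3-column Cytoscape SIF export drops it.
* Empty inputs yield empty outputs (never errors): empty documents, empty
  reaction lists, empty networks, zero-element databases (excluded from that
  element kind's overlap table, logged).
* Reactions with no participants, controls targeting non-reactions, xrefs
  missing a `db` or `id`, unmapped entities and removed non-human edges are
  all counted in per-run diagnostics so input and output reconcile.

## Known limitations

* The `;#k` collision suffix is corpus-local (see above).
* Two distinct proteins mapping to one gene symbol merge; participant
  counts can shrink under such non-injective maps.
* Organism filtering needs either organism annotations or a complete human
  gene table; symbols absent from both are treated as non-human.
* The zero-gain cluster merge is a tie resolution, not an optimiser; at
  resolutions far from 1.0 or under CPM it is skipped.
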