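# Methods

This note documents the models, conventions and design choices behind
`brushscreen`, in the order the pipeline runs them.

## Molecular graphs and the valence model

Molecules are labelled undirected graphs over heavy atoms
({C, N, O, S, P, F, Cl, Br}); hydrogens are implicit only. The SMILES
dialect is the organic subset plus bracket atoms with explicit hydrogen
counts and formal charges, branches, ring closures and single / double /
triple / aromatic bonds. Stereochemistry and isotopes are rejected: all
descriptors here are 1D/2D and no computation depends on configuration.

Implicit hydrogens fill the smallest allowed valence state (C 4, N 3,
O 2, S 2/4/6, P 3/5, halogens 1). Cationic N/P gain one bonding slot per
positive charge (quaternary ammonium N⁺ carries no H); anionic O/S/C
lose one per negative charge (carboxylate / sulfonate O⁻ carry none).
These rules are what make the zwitterionic monomers (CBAA, CBMA, SBMA,
MPC, VPPS) parse with net charge zero.

Aromaticity is trusted from the input (lowercase atoms), not perceived:
a molecule entered in Kekulé form stays aliphatic. Every aromatic system
is kekulized to alternating single/double bonds by a backtracking
perfect matching over the atoms that must carry a double bond (aromatic
C always; pyridine-type N; substituted pyridinium N⁺; not pyrrole-type N
or aromatic O/S). The kekulized integer orders drive the valence model,
the descriptor tables and the "exact" bond-match mode of the MCS. For
symmetric rings the choice of alternation does not affect any result;
for asymmetric ones the matching is deterministic (sorted adjacency), so
results are reproducible.

Ring membership of bonds is decided by bridge detection (exact); the
ring list itself is a minimum cycle basis (networkx).

## Descriptors

The ten-column descriptor vector mirrors a SwissADME-style
physicochemical panel:

| descriptor | definition | units / default |
|---|---|---|
| molecular_weight | IUPAC standard atomic weights, incl. implicit H | g/mol |
| heavy_atoms | non-hydrogen atom count | — |
| fraction_csp3 | carbons with only single bonds, non-aromatic / all carbons | [0,1] |
| hba | N+O atoms, excluding amide-type N, pyrrole-type N, N⁺ | count |
| hbd | N/O atoms bearing ≥1 H | count |
| rotatable_bonds | acyclic single bonds between non-terminal heavy atoms, amide C–N excluded | count |
| tpsa | Ertl group contributions over N/O/S/P environments | Å² |
| wlogp | Wildman–Crippen atom-type contributions | log units |
| molar_refractivity | Wildman–Crippen MR table | — |
| esol_logs | Delaney linear model (below) | log mol/L |

The Ertl (2000) and Wildman–Crippen (1999) contribution tables are
transcribed from the publications into the versioned
`data/constants.json`; only the atom types reachable from the panel and
the synthetic generator's feature space are packaged, and an atom
environment outside the tables raises an error naming the atom rather
than guessing. The TPSA table is extended with the published S and P
environments, since sulfonate (SBMA, VPPS) and phosphate (MPC) monomers
are otherwise uncomputable. The implementation was validated atom-by-atom
against an independent reference implementation on a ~1000-molecule
battery during development.

Lipophilicity is the single table-driven WLOGP model; multi-predictor
consensus logP is deliberately out of scope (the other predictors are
not reproducible from published constants). Solubility is the Delaney
ESOL refit as used downstream of WLOGP:

log S = 0.16 − 0.63·WLOGP − 0.0062·MW + 0.066·RB − 0.74·AP,

with RB the rotatable-bond count and AP the aromatic-atom proportion.

HBA/HBD have no universal definition; the pinned rules above are an
approximation of SwissADME's and are applied uniformly, which is what
matters for the rule filters. Rule thresholds (Lipinski ≤1 violation
allowed; Ghose, Veber, Egan, Muegge, lead-likeness strict) and the
Abbott bioavailability score (anion → TPSA bins 0.85/0.56/0.11, else
0.55/0.17 by Lipinski) live in the constants file.

## BOILED-Egg

Gut absorption and BBB permeation are two independent ellipse-membership
tests in the (TPSA, WLOGP) plane. The published model is available only
graphically, so the packaged constants are the standard digitized
parameterization (white: centre (71.051, 2.292), semi-axes
(71.04, 4.37); yolk: centre (38.117, 3.481), semi-axes (41.03, 2.78);
axis-aligned). Zwitterions are classified by the same geometry but
flagged, because the model was calibrated on neutral drug-like species.

Known limitation: the panel's small hydrophilic monomers sit *below* the
yolk's WLOGP range (≈0.7–6.3), so this geometry classifies all 14
monomers as BBB-non-permeant. Published reference predictions that mark
such molecules permeant cannot be produced by the egg geometry alone and
presumably involve auxiliary models; the gut-absorption column, in
contrast, reproduces exactly (sialic acid the unique low absorber).

## MCS similarity

The similarity of a pair is T = c/(a+b+c) with features counted on the
**connected induced maximum common subgraph**: the largest set of atoms
whose induced subgraphs in both molecules are isomorphic under the
active match semantics, and connected. The search is exact: vertices of
the modular product graph are compatible atom pairs, edges are *c*-edges
(bond present in both, orders compatible) or *d*-edges (bond absent in
both), and a Koch-style branch-and-bound enumerates cliques whose c-edge
subgraph is connected. A hard 40-heavy-atom guard replaces any timeout
heuristic, and ties between maximum mappings break to the
lexicographically smallest mapping, so every coefficient is
deterministic. On the panel (≤21 heavy atoms) the full 14×14 matrix
takes well under a second.

Match semantics has three axes: feature unit (atoms | atoms+bonds),
charge sensitivity (blind | sensitive) and bond order (any | exact on
kekulized orders). `calibrate_semantics` grid-searches the eight
variants against a set of printed reference coefficients and returns the
variant with the smallest maximum absolute deviation (ties to the
earlier grid entry: atoms before atoms+bonds, charge-blind before
sensitive, exact before any). On the packaged references the winner is
**atoms, charge-blind, exact bond order**, with residuals
(HPMA/HEMA −0.02, AA/DMA −0.066, CBMA/VPPS −0.018, SBMA/CBMA −0.03).

Two reference values are not reachable by any variant, and we report
them as computed rather than force them:

* AA/DMA is structurally pinned at 5/7 ≈ 0.714 — acrylamide's entire
  graph embeds in dimethylacrylamide, so c=5, a=0, b=2 under every
  semantics. A printed value of 0.78 (or >0.8) cannot arise from an
  MCS-atom-count Tanimoto for these structures.
* VP/VPPS is capped at 8/15 ≈ 0.533 by the size ratio alone
  (computed: 0.353), so a ≥0.6 claim for that pair is likewise
  unreachable. Fingerprint-based (atom-pair) Tanimoto coefficients,
  which are out of scope here, plausibly explain both printed values.

The induced-subgraph convention is pinned by the package contract; the
edge-subgraph (non-induced) convention used by some MCS tools agrees on
all of the reference pairs above but can differ elsewhere (e.g. OZ/VP:
0.667 induced vs 0.875 edge-subgraph).

## Clustering

The descriptor table is z-scored per column (population SD; constant
columns dropped with a warning) before Euclidean distances, because the
raw columns span three orders of magnitude (MW ~70–310 vs counts 0–10)
and would otherwise reduce the clustering to a molecular-weight sort. A
`--no-standardize` variant keeps the raw scales; both variants are
first-class and the acceptance checks examine both.

Agglomeration is group-average (UPGMA): merge the closest pair of
clusters, with inter-cluster distance the unweighted mean of all
cross-cluster leaf distances, recomputed from the base leaf-distance
matrix at every step. Ties break to the smallest node-index pair; clustroids break
ties lexicographically. Heights are checked to be non-decreasing (true
for metric inputs; a warning flags inversions). The Newick export writes
branch length = parent height − child height with leaves at height 0
(heights are *not* halved: root-to-leaf path length equals the root
merge height), children ordered by smallest leaf identifier; the same
ordering defines the heatmap leaf order. Internal nodes are numbered by
merge order — clade numbers in any drawing are presentation artifacts,
and only co-membership claims are meaningful.

On the panel, the standardized variant isolates sialic acid (the only
ringed, high-TPSA monomer) at the top split and divides the remaining 13
monomers 8 (neutral/hydrophilic) vs 5 (zwitterionic), with HPMA+HEMA and
SBMA+MPC as sibling pairs; the raw variant additionally pairs OZ+DMA and
AA+Gly but puts SA inside the charged cluster. No single variant
reproduces all five published sibling pairs (CBMA+VPPS appears in
neither), which is the expected sensitivity of average-linkage trees to
unknown upstream descriptor-column and scaling choices.

## Panel fixture

The published structure table exists only as an image, so the shipped
`monomers.smi` reconstructs the 14 structures from the monomer names
using standard literature chemistry, with a provenance note per entry.
Three entries deserve mention: OZ is the *linear* N-acylated repeating
block of poly(2-methyl-2-oxazoline) (the study describes OZ as linear,
and its high printed OZ/VP similarity is only reachable with the linear
form); HEMA is hydroxyethyl methacryl**amide**, following the study's
own expansion of the abbreviation (conventionally HEMA names the
methacrylate); CBAA/CBMA use the 2-carbon carboxybetaine arm common in
betaine-monomer chemistry. Sialic acid is entered without stereocentres
(no descriptor here is stereo-aware). The fixture is checksummed and
`load_panel` refuses a modified file.

## Synthetic generator

`generate_molecules` produces seeded random molecules emulating the
panel's feature space: 4–18 heavy atoms over {C, N, O, S} (P only via
phosphate arms), acyclic chains, at most one aliphatic or aromatic ring,
C=C/C=O/C=N double bonds, polar decorations (carboxyl, amide, sulfonic,
phosphate) and optional zwitterion pairs (quaternary ammonium +
carboxylate/sulfonate, always net-neutral). Heteroatoms bond only to
carbon, which keeps every generated environment inside the packaged
contribution tables. The generator is a test instrument: it exercises
the valence model, parser round-trips and the graph algorithms. It does
not sample realistic fragment distributions, so passing property tests
demonstrate algorithmic correctness, not chemical coverage of drug
space.

## Determinism and problem sizes

Everything in the package is deterministic given the inputs and seeds:
parser, kekulization, MCS tie-breaks, clustering tie-breaks, CLI outputs
(byte-identical manifests). The test suite's stochastic checks use fixed
seeds: the MCS clique search is compared against an exhaustive
enumeration oracle on 200 random pairs of ≤10-atom molecules, the UPGMA
implementation against a naïve O(n³) recomputation on 100 random ≤8-leaf
matrices and against scipy's average linkage, and parser round-trips run
on 1000 generated molecules — sizes at which the independent oracles are
themselves exact and fast. The acceptance script runs the full panel
pipeline (calibration, 91 MCS pairs, dendrogram) in about one second.
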