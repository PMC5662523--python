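# Methods

This note records the package's model of the data it handles, the choices
made where the formats and procedures were genuinely open, and the limits of
what the synthetic fixtures demonstrate.

## Data model

A molecule is an element list (atomic numbers 1–118), a flat Cartesian
coordinate array of length 3N in ångström (atom *i* at offset 3i), and an
optional bond list with 0-based endpoint indices and positive integer
orders. All codecs convert into this model on ingest and out of it on
write; nothing downstream handles more than one length unit or index base.
Physical values elsewhere are `Quantity` objects with a closed unit
vocabulary (hartree, eV, cm-1, angstrom, bohr, amu, debye, dimensionless);
the bohr→Å factor is CODATA 2018, 0.529177210903 Å.

Masses come from an embedded table of IUPAC 2021 conventional (abridged)
standard atomic weights, three decimals where a conventional value exists,
longest-lived-isotope mass numbers for elements without stable isotopes.
Embedding the table keeps `molecular_mass` reproducible with no runtime
dependency; the trade-off is that the table is frozen until manually
updated, and isotopic composition is ignored.

InChI and InChIKey are stored metadata, never computed internally. When no
key is supplied, deduplication uses a structure key: the molecular graph
(nodes colored by atomic number, edges by bond order) hashed with
networkx's Weisfeiler–Lehman graph hash, combined with the sorted element
multiset and digested with SHA-1. The key is invariant under atom
reordering (property-tested over random permutations). Its known
limitation is inherited from WL: rare non-isomorphic graphs that WL cannot
distinguish would collide, and the key identifies a graph, not a conformer
— geometrically distinct conformers of one graph deduplicate to one record,
which is the intended store semantics ("a molecular graph is unique"). An
optional provider hook (`chemstore.identifiers`) lets a toolkit such as
RDKit supply real InChIKeys, which then take precedence.

## Format dialects

The exact key spellings of both JSON dialects are package decisions,
documented here and treated as the format definition for this codebase.

Chemical JSON: top-level `chemicalJson` (integer version, currently 1),
`atoms.elements.number`, `atoms.coords.3d`, `bonds.connections.index`
(flat pairs) with `bonds.order`, `vibrations.{frequencies, intensities,
eigenVectors}`, and a `volume` block (`origin`, `spacing`, `dimensions`,
`values`, z fastest-varying as in cube files). Unknown top-level keys are
preserved verbatim through a read/write cycle so that documents written by
newer dialect revisions survive. Numbers are serialized with Python's
shortest round-trip float representation, so parse∘write is exact on
coordinates, not merely close. The validator returns violations as data
(path + message, all of them at once) rather than failing on the first.

ChemLog JSON: `simulation` metadata, a `calculations` array, each entry
with `calculationSetup` (`theory`, `task`, `basisSet`), `molecule`
(per-atom objects: `element`, `coordinates` as `{value, units}`, ids like
`Atom.1.Mol.2`), and `calculationResults`. The key spelling inside
`calculationSetup` beyond `basisSet` is provisional. Reference semantics
are deliberately strict: a string is a reference only under the linking
keys `molecule`, `basisSet`, `calculationSetup`, `atom` (a global
"any string that matches an id" rule would misfire on names), an id may be
defined once, and references must resolve to an id defined earlier in
document order — forward references are rejected, keeping single-pass
streaming parses possible. The writer deduplicates: the first mention of an
id-tagged object is inlined, later occurrences become the id string.
JSON-pointer/RFC-style referencing was considered and not adopted; the
id-tag convention is the format.

## Log ingestion

The parser is a single forward pass with a table of recognized energy
labels (`Total SCF energy`, `Total DFT energy` → theory tags) and module
headers (SCF, DFT, frequency analysis); both tables are module constants so
labels for other codes can be registered. Association rule: each task
section's molecule is the last geometry block printed before it. Geometry
values are stored in ChemLog with the units the log declared (angstroms or
a.u.) — conversion to Å happens only when a core molecule is extracted, so
no precision is lost by converting twice. Geometries identical in units,
elements, and printed coordinates deduplicate into one molecule block; the
frequency table is parsed in column blocks of up to six modes.

The synthetic log generator emulates this structure — banner, per-task
geometry echo, labeled final-energy lines, frequency/eigenvector tables —
with a seed that jitters only inter-token whitespace. That gives a
parameter-recovery oracle: generated energies (printed to 8 decimals, and
drawn pre-rounded to 8 decimals) round-trip bit-exactly, and coordinates
round-trip within ~3·10⁻⁹ Å (the worst case through a bohr-unit geometry
echo). What the fixtures do **not** emulate: real NWChem basis tables, MO
vector dumps, optimization traces, restarts, or the many formatting
variants across versions — the parser targets the structure above, not
production logs in all their variety.

## Query engine

Hand-written tokenizer and recursive-descent parser for
`expr := term (OR term)*`, `term := factor (AND factor)*`,
`factor := '(' expr ')' | comparison | bareword`, so AND binds tighter than
OR; keywords are case-insensitive and a bareword desugars to `name ~ word`.
Numeric comparisons are exact float comparisons by design — predictable
semantics, with ranges as the documented idiom — and a comparison against
a missing optional field (e.g. no stored InChIKey) is false rather than an
error. There is no NOT operator. Correctness is established by oracle
equivalence: the engine's results over seeded random molecule collections
are compared against naive per-molecule evaluation for seeded random ASTs,
plus intersection/union algebra checks and a parse∘print fixpoint on the
canonical printer.

## Service

The service is a pure-WSGI application (standard library only) over an
in-memory store; `serve` runs it with `wsgiref`, and the test client calls
the WSGI callable directly so the contract suite needs no sockets.
Persistence is a newline-delimited JSON journal replayed at startup —
deliberately primitive, sufficient for a single-writer store of this
scale. Record ids are 24-hex-character strings derived from a seeded
counter + SHA-1, so test runs are reproducible while ids stay opaque.
Upload extracts each calculation's molecule, deduplicates it through the
uniqueness index (InChIKey, else structure key), and stores one calculation
record per entry with provenance (code, theory, calculation types, file
id). All endpoints are public; authentication, chunked upload, and database
backends are out of scope.

## Animation and volumetric output

Normal-mode animation frames follow the standard looping convention:
frame k displaces equilibrium coordinates by `A·sin(2πk/n)` along the mode
vector, max-norm-normalized to 1 before scaling so `A` is the peak
per-coordinate excursion in Å. Frame 0 is the equilibrium geometry; at
n = 4 the displacement factors are exactly (0, +A, 0, −A) up to float
rounding of sin(π) (~10⁻¹⁶). A degenerate all-zero mode vector animates as
the identity rather than dividing by zero. Volumetric data serializes in
the Gaussian cube text layout, converting Å to bohr as cube files are
atomic-unit by convention.

## Fixtures and problem sizes

Random molecules draw 1–12 atoms from an organic-chemistry element pool
with coordinates uniform in ±8 Å rounded to 10⁻⁶ (matching XYZ's printed
precision), and bonds on a spanning-tree-plus-extras scheme so bond graphs
are connected without geometric perception; they are plausible as data
structures, not as chemistry — no valence rules, no realistic geometry.
The default suites use 100 molecules per codec round trip, 50 synthetic
logs for ingestion recovery, 200 molecules × 100 queries for the oracle
equivalence, and 25 molecules over all 9 format pairs for the conversion
lattice; the full test suite and the acceptance script each complete in a
few seconds on one core.

## Known limitations

- XYZ carries no bonds; conversion paths through it lose bond data (the
  dispatcher flags this but cannot recover the bonds).
- The CML subset covers `atomArray`/`bondArray` attribute form only.
- The Hill formula and mass ignore charge and isotopes.
- ChemLog → Chemical JSON conversion as a *conversion source* always uses
  calculation 0; other calculations are reachable through the service's
  per-calculation resources.
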