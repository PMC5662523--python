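# chemstore

Structured chemical data tooling for computational chemistry: two JSON
dialects, format converters, a quantum-chemistry log parser, a molecule
query language, and a REST data service.

## The problem

Quantum-chemistry codes such as NWChem still communicate through plain-text
log files: multi-megabyte streams in which geometries, energies, and
vibrational analyses are printed with no machine-readable structure. At the
other end of the pipeline, web and desktop visualization tools want compact,
array-shaped documents they can render directly. `chemstore` serves both
needs with two complementary JSON formats and the plumbing between them:

- **Chemical JSON** (`.cjson`) — array-oriented and visualization-focused.
  Atomic numbers live in one array, Cartesian coordinates in a flat array of
  length 3N (atom *i* occupies slots 3i, 3i+1, 3i+2, in Å), bonds as a flat
  index-pair array plus an order array, with optional vibrational
  (frequencies in cm⁻¹, per-mode 3N displacement eigenvectors) and
  volumetric blocks. One self-contained document per molecule.
- **ChemLog JSON** (`.chemlog.json`) — object-oriented and semantically
  annotated; a structured replacement for the log file. A run is a
  `calculations` array; every physical value is a `{value, units}` object
  (hartree, bohr, cm-1, ...); every atom is a single object holding its
  element, coordinates, and properties. Objects that recur across
  calculations (a molecule, a basis set) are written once with an `id` tag
  — `"Molecule.2"`, `"Atom.1.Mol.2"` — and later uses are just that string,
  a pointer to the first mention. References must point backwards in
  document order; dangling, forward, and duplicate tags are rejected.

Around the two formats:

- **Converters** — XYZ and a CML subset (`atomArray`/`bondArray`), a
  ChemLog→Chemical JSON mapping, and a dispatcher that routes any supported
  pair through the core molecule model (XYZ drops bonds; the result is
  flagged lossy).
- **NWChem-style log ingestion** — a table-driven parser that walks a log,
  associates each task section with the last printed geometry, extracts
  final energies and frequency tables, and emits a ChemLog document in
  which repeated geometries become id-tag references. A seeded synthetic
  log generator makes the whole pipeline testable offline.
- **Query language** — `mass>17.5 and mass<19`, `name~water`,
  `formula=C2H6O`, with AND/OR (AND binds tighter), parentheses, numeric
  comparisons over mass / atomCount / heavyAtomCount and case-insensitive
  string matching over name / inchi / inchikey / formula. A bare word is a
  substring match on the name.
- **REST service** — a WSGI app under `/api/v1` exposing molecules
  (existence queries, per-format retrieval, InChIKey lookup, search),
  calculations (summaries by parent molecule, per-calculation Chemical
  JSON / vibrations / Gaussian-cube resources), conversions, and ChemLog
  upload. Molecular graphs are unique: uploads deduplicate on the InChIKey
  when present, otherwise on a Weisfeiler–Lehman graph digest, and every
  calculation refers to its parent molecule.

## Worked example

```python
from chemstore import canonical_water, Api, Client, DataStore
from chemstore.chemlog import write_chemlog
from chemstore.fixtures import random_vibrations
from chemstore.model import Quantity
from chemstore.nwchem import LogFixtureSpec, LogTask, generate_log, parse_nwchem_log

water = canonical_water()
print(water.molecular_mass(), water.hill_formula())   # 18.015 H2O

# synthesize an SCF + frequency run, parse it back
spec = LogFixtureSpec(molecule=water, tasks=[
    LogTask(kind="scf", energy=Quantity(-74.96294030, "hartree")),
    LogTask(kind="frequency", energy=Quantity(-74.96294030, "hartree"),
            vibrations=random_vibrations(water, seed=7)),
])
doc = parse_nwchem_log(generate_log(spec))
print(len(doc.calculations))                  # 2
print(doc.raw["calculations"][1]["molecule"]) # 'Molecule.1' (id-tag reference)

# upload to the service and search
client = Client(Api(DataStore(seed=1)))
up = client.post("/api/v1/calculations", write_chemlog(doc)).json()
print(up["calculationIds"])   # two calculation ids, one molecule id
hits = client.get("/api/v1/molecules/search", "q=mass>17.5 and mass<19").json()
print(hits[0]["id"] == up["moleculeId"])      # True
```

The two tasks share one geometry, so the parser emits the molecule once and
the second calculation holds the reference string `"Molecule.1"`; the upload
returns two calculation ids bound to a single deduplicated molecule record,
and the mass-window search finds it (water: 18.015 amu).

The same functionality is on the command line:

```sh
chemstore fixtures make-log --molecule water --tasks scf,freq --seed 7 > water.log
chemstore ingest water.log -o water.chemlog.json
chemstore validate --format chemlog water.chemlog.json   # ok
chemstore convert -i water.chemlog.json --from chemlog --to xyz
chemstore serve --port 8080 --store ./store
```

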