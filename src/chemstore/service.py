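"""REST data service: molecules, calculations, and conversion endpoints.

A pure-WSGI application (no third-party web framework) over an in-memory
store with an optional newline-delimited JSON journal for persistence.
Routes live under ``/api/v1``:

==========================================================  =======
``GET  /api/v1``                                            route listing
``GET  /api/v1/molecules?name=|inchi=|inchikey=``           existence query
``GET  /api/v1/molecules/search?q=...``                     query language
``GET  /api/v1/molecules/inchikey/{key}``                   lookup by InChIKey
``GET  /api/v1/molecules/{id}/{xyz|cml|cjson}``             formatted retrieval
``POST /api/v1/molecules/conversions/{format}``             file conversion
``GET  /api/v1/calculations?moleculeId=...``                calculation summaries
``GET  /api/v1/calculations/{id}/{cjson|vibrations}``       calculation resources
``GET  /api/v1/calculations/{id}/cube/{n}``                 volumetric data
``POST /api/v1/calculations``                               ChemLog upload
==========================================================  =======

Molecules are deduplicated on upload by a uniqueness index — the InChIKey
when supplied, otherwise the structure key — so a molecular graph is stored
once and calculations refer to their parent molecule by id. All endpoints
are public; authentication is out of scope.
"""

from __future__ import annotations

import hashlib
import io
import json
import os
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable
from urllib.parse import parse_qs

from . import chemlog as chemlog_mod
from . import cjson as cjson_mod
from . import converters as convert_mod
from . import query as query_mod
from .model import Calculation, Molecule, Quantity, ValidationError, VolumetricData

API_PREFIX = "/api/v1"

_CONTENT_TYPES = {
    "xyz": "text/plain",
    "cml": "chemical/x-cml",
    "cjson": "application/json",
}


class _IdGenerator:
    """Opaque, stable, 24-hex-character ids from a seeded counter+hash."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        self.counter = 0

    def next(self, namespace: str) -> str:
        self.counter += 1
        raw = f"{self.seed}:{namespace}:{self.counter}".encode()
        return hashlib.sha1(raw).hexdigest()[:24]


@dataclass
class CalculationRecord:
    calculation: Calculation
    document: chemlog_mod.ChemLogDocument | None = None
    calc_index: int = 0


@dataclass
class DataStore:
    """In-memory molecule/calculation store with optional journal replay.

    The journal is newline-delimited JSON under ``store_dir``; every upload
    is appended and replayed at startup, so a file-backed store survives
    restarts without any database.
    """

    store_dir: str | None = None
    seed: int = 0
    molecules: dict[str, Molecule] = field(default_factory=dict)
    molecule_order: list[str] = field(default_factory=list)
    unique_index: dict[str, str] = field(default_factory=dict)
    calculations: dict[str, CalculationRecord] = field(default_factory=dict)
    calc_order: list[str] = field(default_factory=list)
    by_molecule: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._ids = _IdGenerator(self.seed)
        if self.store_dir:
            os.makedirs(self.store_dir, exist_ok=True)
            self._replay()

    # -- journal ----------------------------------------------------------

    @property
    def _journal_path(self) -> str:
        assert self.store_dir
        return os.path.join(self.store_dir, "journal.ndjson")

    def _append_journal(self, entry: dict[str, Any]) -> None:
        if self.store_dir:
            with open(self._journal_path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")

    def _replay(self) -> None:
        if not os.path.exists(self._journal_path):
            return
        with open(self._journal_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                entry = json.loads(line)
                if "chemlog" in entry:
                    self._ingest_chemlog_text(entry["chemlog"], journal=False)
                elif "molecule" in entry:
                    mol, _, _ = cjson_mod.parse_cjson(entry["molecule"])
                    self._add_molecule(mol, journal=False)

    # -- molecules --------------------------------------------------------

    def add_molecule(self, mol: Molecule) -> str:
        return self._add_molecule(mol, journal=True)

    def _add_molecule(self, mol: Molecule, journal: bool) -> str:
        key = mol.inchikey or mol.structure_key()
        existing = self.unique_index.get(key)
        if existing is not None:
            return existing
        mol_id = self._ids.next("molecule")
        mol.id = mol_id
        self.molecules[mol_id] = mol
        self.molecule_order.append(mol_id)
        self.unique_index[key] = mol_id
        if journal:
            self._append_journal({"molecule": cjson_mod.write_cjson(mol, indent=None)})
        return mol_id

    def molecule_summaries(self) -> Iterable[tuple[str, Molecule]]:
        return ((mid, self.molecules[mid]) for mid in self.molecule_order)

    # -- calculations ------------------------------------------------------

    def ingest_chemlog(self, text: str) -> dict[str, Any]:
        """Upload a ChemLog document: dedup molecules, store calculations."""
        return self._ingest_chemlog_text(text, journal=True)

    def _ingest_chemlog_text(self, text: str, journal: bool) -> dict[str, Any]:
        doc = chemlog_mod.parse_chemlog(text)
        file_id = self._ids.next("file")
        calc_ids: list[str] = []
        mol_ids: list[str] = []
        for index, calc in enumerate(doc.calculations):
            mol = chemlog_mod.extract_molecule(doc, index)
            mol_id = self._add_molecule(mol, journal=False)
            mol_ids.append(mol_id)
            types = [t for t in (calc.task,) if t]
            vib = convert_mod.vibrations_from_results(calc.results, mol.atom_count)
            if vib is not None and "vibrational" not in types:
                types.append("vibrational")
            properties: dict[str, Quantity] = {}
            energy = calc.results.get("totalEnergy")
            if isinstance(energy, dict) and "value" in energy:
                properties["totalEnergy"] = Quantity(
                    float(energy["value"]), str(energy.get("units", "hartree"))
                )
            calc_id = self._ids.next("calculation")
            record = CalculationRecord(
                calculation=Calculation(
                    id=calc_id,
                    molecule_id=mol_id,
                    code=str(doc.simulation.get("code", "")),
                    theory=calc.theory,
                    calculation_types=types or ["unknown"],
                    file_id=file_id,
                    properties=properties,
                    vibrations=vib,
                ),
                document=doc,
                calc_index=index,
            )
            self.calculations[calc_id] = record
            self.calc_order.append(calc_id)
            self.by_molecule.setdefault(mol_id, []).append(calc_id)
            calc_ids.append(calc_id)
        if journal:
            self._append_journal({"chemlog": text})
        return {
            "moleculeId": mol_ids[0] if mol_ids else None,
            "moleculeIds": mol_ids,
            "calculationIds": calc_ids,
        }

    def attach_volume(self, calc_id: str, vol: VolumetricData) -> None:
        """Attach volumetric data (e.g. an orbital cube) to a calculation."""
        self.calculations[calc_id].calculation.volumes.append(vol)

    def check_referential_integrity(self) -> bool:
        return all(
            rec.calculation.molecule_id in self.molecules
            for rec in self.calculations.values()
        )


# -- WSGI application ------------------------------------------------------


class HttpError(Exception):
    def __init__(self, status: int, message: str, **extra: Any):
        super().__init__(message)
        self.status = status
        self.payload = {"message": message, **extra}


_STATUS_TEXT = {
    200: "200 OK",
    400: "400 Bad Request",
    404: "404 Not Found",
    405: "405 Method Not Allowed",
    422: "422 Unprocessable Entity",
}

ROUTES = [
    ("GET", f"{API_PREFIX}"),
    ("GET", f"{API_PREFIX}/molecules?name=|inchi=|inchikey="),
    ("GET", f"{API_PREFIX}/molecules/search?q="),
    ("GET", f"{API_PREFIX}/molecules/inchikey/{{key}}"),
    ("GET", f"{API_PREFIX}/molecules/{{id}}/{{xyz|cml|cjson}}"),
    ("POST", f"{API_PREFIX}/molecules/conversions/{{output_format}}"),
    ("GET", f"{API_PREFIX}/calculations?moleculeId="),
    ("GET", f"{API_PREFIX}/calculations/{{id}}/{{cjson|vibrations}}"),
    ("GET", f"{API_PREFIX}/calculations/{{id}}/cube/{{n}}"),
    ("POST", f"{API_PREFIX}/calculations"),
]


class Api:
    """The WSGI application over a :class:`DataStore`."""

    def __init__(self, store: DataStore | None = None):
        self.store = store if store is not None else DataStore()

    # WSGI entry point
    def __call__(self, environ: dict[str, Any], start_response: Callable) -> list[bytes]:
        try:
            status, content_type, body = self.dispatch(environ)
        except HttpError as exc:
            status = exc.status
            content_type = "application/json"
            body = json.dumps(exc.payload).encode()
        except (ValidationError, ValueError) as exc:
            status = 422
            content_type = "application/json"
            body = json.dumps({"message": str(exc)}).encode()
        start_response(
            _STATUS_TEXT.get(status, f"{status} Error"),
            [("Content-Type", content_type), ("Content-Length", str(len(body)))],
        )
        return [body]

    def dispatch(self, environ: dict[str, Any]) -> tuple[int, str, bytes]:
        method = environ["REQUEST_METHOD"].upper()
        path = environ.get("PATH_INFO", "")
        params = {
            k: v[0] for k, v in parse_qs(environ.get("QUERY_STRING", "")).items()
        }
        if not path.startswith(API_PREFIX):
            raise HttpError(404, f"not found: {path}")
        parts = [p for p in path[len(API_PREFIX):].split("/") if p]

        if not parts:
            return _json(200, {"routes": [f"{m} {r}" for m, r in ROUTES]})
        if parts[0] == "molecules":
            return self._molecules(method, parts[1:], params, environ)
        if parts[0] == "calculations":
            return self._calculations(method, parts[1:], params, environ)
        raise HttpError(404, f"not found: {path}")

    # -- molecules endpoints ----------------------------------------------

    def _molecules(
        self,
        method: str,
        parts: list[str],
        params: dict[str, str],
        environ: dict[str, Any],
    ) -> tuple[int, str, bytes]:
        store = self.store
        if not parts:
            if method != "GET":
                raise HttpError(405, "method not allowed")
            keys = [k for k in ("name", "inchi", "inchikey") if k in params]
            if len(keys) != 1:
                raise HttpError(
                    400, "exactly one of name=, inchi=, inchikey= is required"
                )
            key = keys[0]
            needle = params[key]
            matches = [
                _summary(mid, mol)
                for mid, mol in store.molecule_summaries()
                if (getattr(mol, key) or "") == needle
                or (key == "name" and (mol.name or "").lower() == needle.lower())
            ]
            return _json(200, matches)

        if parts[0] == "search":
            if "q" not in params:
                raise HttpError(400, "missing query parameter q=")
            try:
                results = query_mod.search(store.molecule_summaries(), params["q"])
            except query_mod.QuerySyntaxError as exc:
                raise HttpError(400, f"query syntax error: {exc}") from None
            return _json(200, results)

        if parts[0] == "conversions":
            if method != "POST" or len(parts) != 2:
                raise HttpError(405, "POST /molecules/conversions/{format}")
            return self._convert(parts[1], environ)

        if parts[0] == "inchikey":
            if len(parts) != 2:
                raise HttpError(400, "expected /molecules/inchikey/{key}")
            for mid, mol in store.molecule_summaries():
                if mol.inchikey == parts[1]:  # canonical keys are case-sensitive
                    return _json(200, _record(mid, mol))
            raise HttpError(404, f"no molecule with inchikey {parts[1]!r}")

        mol_id = parts[0]
        mol = store.molecules.get(mol_id)
        if mol is None:
            raise HttpError(404, f"no molecule with id {mol_id!r}")
        if len(parts) == 1:
            return _json(200, _record(mol_id, mol))
        fmt = parts[1].lower()
        if fmt not in _CONTENT_TYPES:
            raise HttpError(400, f"unknown format {parts[1]!r}; expected xyz, cml, cjson")
        body = convert_mod.write_molecule(mol, fmt)
        return 200, _CONTENT_TYPES[fmt], body.encode()

    def _convert(self, out_format: str, environ: dict[str, Any]) -> tuple[int, str, bytes]:
        payload = _read_json_body(environ)
        text = payload.get("input")
        in_format = payload.get("inputFormat")
        if not isinstance(text, str) or not isinstance(in_format, str):
            raise HttpError(400, "body must contain 'input' text and 'inputFormat'")
        try:
            fmt_in = convert_mod.normalize_format(in_format)
            fmt_out = convert_mod.normalize_format(out_format)
        except ValueError as exc:
            raise HttpError(400, str(exc)) from None
        try:
            result = convert_mod.convert(text, fmt_in, fmt_out)
        except convert_mod.UnsupportedConversionError as exc:
            raise HttpError(400, str(exc)) from None
        except (ValidationError, ValueError, json.JSONDecodeError) as exc:
            raise HttpError(422, f"could not parse input: {exc}") from None
        return _json(
            200, {"output": result.text, "lossy": result.lossy, "warnings": result.warnings}
        )

    # -- calculations endpoints -------------------------------------------

    def _calculations(
        self,
        method: str,
        parts: list[str],
        params: dict[str, str],
        environ: dict[str, Any],
    ) -> tuple[int, str, bytes]:
        store = self.store
        if not parts:
            if method == "POST":
                text = _read_body(environ)
                try:
                    result = store.ingest_chemlog(text)
                except (ValidationError, json.JSONDecodeError) as exc:
                    raise HttpError(422, f"invalid ChemLog document: {exc}") from None
                return _json(200, result)
            if "moleculeId" not in params:
                raise HttpError(400, "missing query parameter moleculeId=")
            summaries = [
                _calc_summary(store.calculations[cid])
                for cid in store.by_molecule.get(params["moleculeId"], [])
            ]
            return _json(200, summaries)

        record = store.calculations.get(parts[0])
        if record is None:
            raise HttpError(404, f"no calculation with id {parts[0]!r}")
        if len(parts) < 2:
            return _json(200, _calc_summary(record))
        resource = parts[1]
        calc = record.calculation
        if resource == "cjson":
            if record.document is None:
                raise HttpError(404, "calculation has no source document")
            doc = convert_mod.chemlog_to_cjson(record.document, record.calc_index)
            return _json(200, doc)
        if resource == "vibrations":
            vib = calc.vibrations
            if vib is None:
                raise HttpError(404, "calculation has no vibrational data")
            payload: dict[str, Any] = {
                "frequencies": vib.frequencies,
                "modes": vib.modes,
            }
            if vib.intensities is not None:
                payload["intensities"] = vib.intensities
            return _json(200, payload)
        if resource == "cube":
            if len(parts) != 3 or not parts[2].isdigit():
                raise HttpError(400, "expected /calculations/{id}/cube/{n}")
            n = int(parts[2])
            if n >= len(calc.volumes):
                raise HttpError(404, f"no cube with index {n}")
            mol = store.molecules[calc.molecule_id]
            return 200, "text/plain", convert_mod.write_cube(mol, calc.volumes[n]).encode()
        raise HttpError(404, f"unknown calculation resource {resource!r}")


def _summary(mol_id: str, mol: Molecule) -> dict[str, Any]:
    return {"id": mol_id, "inchikey": mol.inchikey, "name": mol.name}


def _record(mol_id: str, mol: Molecule) -> dict[str, Any]:
    rec = _summary(mol_id, mol)
    rec["cjson"] = cjson_mod.build_cjson(mol)
    rec["formula"] = mol.hill_formula()
    rec["mass"] = mol.molecular_mass()
    return rec


def _calc_summary(record: CalculationRecord) -> dict[str, Any]:
    calc = record.calculation
    return {
        "_id": calc.id,
        "moleculeId": calc.molecule_id,
        "code": calc.code,
        "theory": calc.theory,
        "calculationTypes": list(calc.calculation_types),
        "fileId": calc.file_id,
    }


def _json(status: int, payload: Any) -> tuple[int, str, bytes]:
    return status, "application/json", json.dumps(payload).encode()


def _read_body(environ: dict[str, Any]) -> str:
    try:
        length = int(environ.get("CONTENT_LENGTH") or 0)
    except ValueError:
        length = 0
    stream = environ.get("wsgi.input")
    data = stream.read(length) if stream is not None and length else b""
    return data.decode()


def _read_json_body(environ: dict[str, Any]) -> dict[str, Any]:
    text = _read_body(environ)
    try:
        payload = json.loads(text) if text else {}
    except json.JSONDecodeError as exc:
        raise HttpError(400, f"body is not valid JSON: {exc}") from None
    if not isinstance(payload, dict):
        raise HttpError(400, "body must be a JSON object")
    return payload


# -- in-process test client ------------------------------------------------


@dataclass
class Response:
    status: int
    headers: dict[str, str]
    body: bytes

    @property
    def text(self) -> str:
        return self.body.decode()

    def json(self) -> Any:
        return json.loads(self.body)


class Client:
    """Minimal in-process WSGI client (no sockets)."""

    def __init__(self, app: Api):
        self.app = app

    def request(
        self,
        method: str,
        path: str,
        query: str = "",
        body: bytes | str | None = None,
    ) -> Response:
        if "?" in path and not query:
            path, query = path.split("?", 1)
        raw = body.encode() if isinstance(body, str) else (body or b"")
        environ = {
            "REQUEST_METHOD": method,
            "PATH_INFO": path,
            "QUERY_STRING": query,
            "CONTENT_LENGTH": str(len(raw)),
            "wsgi.input": io.BytesIO(raw),
        }
        captured: dict[str, Any] = {}

        def start_response(status: str, headers: list[tuple[str, str]]) -> None:
            captured["status"] = int(status.split()[0])
            captured["headers"] = dict(headers)

        chunks = self.app(environ, start_response)
        return Response(
            status=captured["status"],
            headers=captured["headers"],
            body=b"".join(chunks),
        )

    def get(self, path: str, query: str = "") -> Response:
        return self.request("GET", path, query)

    def post(self, path: str, body: bytes | str) -> Response:
        return self.request("POST", path, body=body)


def serve(port: int = 8080, store_dir: str | None = None) -> None:  # pragma: no cover
    """Run the service with the standard library's WSGI server."""
    from wsgiref.simple_server import make_server

    app = Api(DataStore(store_dir=store_dir))
    with make_server("", port, app) as server:
        print(f"chemstore service listening on port {port} (prefix {API_PREFIX})")
        server.serve_forever()
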