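"""Service contract suite: endpoint shapes, dedup, referential integrity."""

import json

import pytest

from chemstore.chemlog import write_chemlog
from chemstore.cjson import parse_cjson
from chemstore.fixtures import canonical_water, random_log_spec, random_vibrations
from chemstore.model import Quantity, VolumetricData
from chemstore.nwchem import LogFixtureSpec, LogTask, generate_log, parse_nwchem_log
from chemstore.service import Api, Client, DataStore
from chemstore.xyz import read_xyz, write_xyz


@pytest.fixture
def api():
    return Api(DataStore(seed=7))


@pytest.fixture
def client(api):
    return Client(api)


def water_chemlog(tasks=None) -> str:
    water = canonical_water()
    tasks = tasks or [LogTask(kind="scf", energy=Quantity(-74.962, "hartree"))]
    doc = parse_nwchem_log(generate_log(LogFixtureSpec(molecule=water, tasks=tasks)))
    return write_chemlog(doc)


class TestMoleculesEndpoint:
    def test_query_by_name(self, api, client):
        api.store.add_molecule(canonical_water())
        res = client.get("/api/v1/molecules", "name=water")
        assert res.status == 200
        (record,) = res.json()
        assert set(record) == {"id", "inchikey", "name"}
        assert record["name"] == "water"

    def test_miss_returns_empty_array(self, client):
        res = client.get("/api/v1/molecules", "name=unobtainium")
        assert res.status == 200
        assert res.json() == []

    def test_no_parameters_rejected(self, client):
        assert client.get("/api/v1/molecules").status == 400

    def test_multiple_parameters_rejected(self, client):
        assert client.get("/api/v1/molecules", "name=a&inchi=b").status == 400

    def test_formatted_retrieval_reparses(self, api, client):
        mol_id = api.store.ingest_chemlog(water_chemlog())["moleculeId"]
        xyz_res = client.get(f"/api/v1/molecules/{mol_id}/xyz")
        assert xyz_res.status == 200
        assert xyz_res.text.startswith("3")
        assert xyz_res.headers["Content-Type"] == "text/plain"
        assert read_xyz(xyz_res.text).atomic_numbers == [8, 1, 1]

        cjson_res = client.get(f"/api/v1/molecules/{mol_id}/cjson")
        assert cjson_res.headers["Content-Type"] == "application/json"
        mol, _, _ = parse_cjson(cjson_res.text)
        assert mol.atom_count == 3

        cml_res = client.get(f"/api/v1/molecules/{mol_id}/cml")
        assert cml_res.headers["Content-Type"] == "chemical/x-cml"

    def test_unknown_id_404(self, client):
        assert client.get("/api/v1/molecules/000000000000000000000000/xyz").status == 404

    def test_unknown_format_400(self, api, client):
        mol_id = api.store.ingest_chemlog(water_chemlog())["moleculeId"]
        assert client.get(f"/api/v1/molecules/{mol_id}/sdf").status == 400

    def test_inchikey_lookup(self, api, client):
        water = canonical_water()
        water.inchikey = "XLYOFNOQVPJJNP-UHFFFAOYSA-N"
        api.store.add_molecule(water)
        hit = client.get("/api/v1/molecules/inchikey/XLYOFNOQVPJJNP-UHFFFAOYSA-N")
        assert hit.status == 200
        assert hit.json()["inchikey"] == "XLYOFNOQVPJJNP-UHFFFAOYSA-N"
        # canonical keys are case-sensitive
        assert client.get(
            "/api/v1/molecules/inchikey/xlyofnoqvpjjnp-uhfffaoysa-n"
        ).status == 404

    def test_search_endpoint_matches_engine(self, api, client):
        api.store.add_molecule(canonical_water())
        res = client.get("/api/v1/molecules/search", "q=mass>17 and mass<19")
        assert [r["name"] for r in res.json()] == ["water"]
        assert client.get("/api/v1/molecules/search", "q=mass>1e9").json() == []
        assert client.get("/api/v1/molecules/search", "q=mass>>2").status == 400


class TestConversionsEndpoint:
    def test_xyz_to_cjson(self, client):
        body = json.dumps(
            {"input": write_xyz(canonical_water()), "inputFormat": "xyz"}
        )
        res = client.post("/api/v1/molecules/conversions/cjson", body)
        assert res.status == 200
        mol, _, _ = parse_cjson(res.json()["output"])
        assert mol.atom_count == 3

    def test_unsupported_pair_lists_supported(self, client):
        body = json.dumps(
            {"input": write_xyz(canonical_water()), "inputFormat": "xyz"}
        )
        res = client.post("/api/v1/molecules/conversions/chemlog", body)
        assert res.status == 400
        assert "supported pairs" in res.json()["message"]

    def test_malformed_input_422(self, client):
        body = json.dumps({"input": "3\nbroken\nO 0 0", "inputFormat": "xyz"})
        res = client.post("/api/v1/molecules/conversions/cjson", body)
        assert res.status == 422
        assert "parse" in res.json()["message"].lower() or "atom" in res.json()["message"]


class TestCalculationsEndpoint:
    def test_summaries_have_contract_fields(self, api, client):
        tasks = [
            LogTask(kind="scf", energy=Quantity(-74.9, "hartree")),
            LogTask(kind="dft", energy=Quantity(-75.3, "hartree")),
        ]
        mol_id = api.store.ingest_chemlog(water_chemlog(tasks))["moleculeId"]
        res = client.get("/api/v1/calculations", f"moleculeId={mol_id}")
        summaries = res.json()
        assert len(summaries) == 2
        for summary in summaries:
            assert {"_id", "code", "theory", "calculationTypes", "fileId"} <= set(summary)
            assert summary["code"] == "NWChem"
            assert summary["calculationTypes"]

    def test_no_calculations_empty_array(self, api, client):
        mol_id = api.store.add_molecule(canonical_water())
        assert client.get("/api/v1/calculations", f"moleculeId={mol_id}").json() == []

    def test_missing_parameter_400(self, client):
        assert client.get("/api/v1/calculations").status == 400

    def test_cjson_resource(self, api, client):
        ids = api.store.ingest_chemlog(water_chemlog())
        res = client.get(f"/api/v1/calculations/{ids['calculationIds'][0]}/cjson")
        assert res.status == 200
        doc = res.json()
        assert doc["atoms"]["elements"]["number"] == [8, 1, 1]

    def test_vibrations_resource(self, api, client):
        water = canonical_water()
        vib = random_vibrations(water, seed=3)
        tasks = [
            LogTask(kind="frequency", energy=Quantity(-74.9, "hartree"), vibrations=vib)
        ]
        ids = api.store.ingest_chemlog(water_chemlog(tasks))
        res = client.get(f"/api/v1/calculations/{ids['calculationIds'][0]}/vibrations")
        payload = res.json()
        assert len(payload["frequencies"]) == len(payload["modes"])

    def test_vibrations_404_for_scf_only(self, api, client):
        ids = api.store.ingest_chemlog(water_chemlog())
        res = client.get(f"/api/v1/calculations/{ids['calculationIds'][0]}/vibrations")
        assert res.status == 404

    def test_cube_resource(self, api, client):
        ids = api.store.ingest_chemlog(water_chemlog())
        calc_id = ids["calculationIds"][0]
        assert client.get(f"/api/v1/calculations/{calc_id}/cube/0").status == 404
        vol = VolumetricData(
            origin=(0.0, 0.0, 0.0),
            spacing=(0.5, 0.5, 0.5),
            dims=(2, 2, 2),
            values=[0.0] * 8,
            label="homo",
        )
        api.store.attach_volume(calc_id, vol)
        res = client.get(f"/api/v1/calculations/{calc_id}/cube/0")
        assert res.status == 200
        assert res.text.splitlines()[0] == "homo"
        assert client.get(f"/api/v1/calculations/{calc_id}/cube/5").status == 404


class TestUploadAndDedup:
    def test_reupload_reuses_molecule_id(self, client):
        text = water_chemlog()
        first = client.post("/api/v1/calculations", text).json()
        second = client.post("/api/v1/calculations", text).json()
        assert first["moleculeId"] == second["moleculeId"]
        assert first["calculationIds"] != second["calculationIds"]

    def test_two_task_document_one_molecule(self, client):
        tasks = [
            LogTask(kind="scf", energy=Quantity(-74.9, "hartree")),
            LogTask(kind="dft", energy=Quantity(-75.3, "hartree")),
        ]
        result = client.post("/api/v1/calculations", water_chemlog(tasks)).json()
        assert len(result["calculationIds"]) == 2
        assert len(set(result["moleculeIds"])) == 1

    def test_dangling_reference_422(self, client):
        data = json.loads(water_chemlog())
        data["calculations"][0]["molecule"] = "Molecule.9"
        res = client.post("/api/v1/calculations", json.dumps(data))
        assert res.status == 422

    def test_dedup_conservation_over_n_uploads(self, api, client):
        text = water_chemlog()
        for _ in range(5):
            client.post("/api/v1/calculations", text)
        assert len(api.store.molecules) == 1
        assert len(api.store.calculations) == 5

    def test_referential_integrity_after_upload_sequence(self, api, client):
        for seed in range(8):
            spec = random_log_spec(seed)
            doc = parse_nwchem_log(generate_log(spec))
            res = client.post("/api/v1/calculations", write_chemlog(doc))
            assert res.status == 200
        assert api.store.check_referential_integrity()
        for rec in api.store.calculations.values():
            summary = client.get(f"/api/v1/calculations/{rec.calculation.id}")
            assert summary.json()["moleculeId"] in api.store.molecules


class TestPersistence:
    def test_journal_replay(self, tmp_path):
        store_dir = str(tmp_path / "store")
        store = DataStore(store_dir=store_dir, seed=7)
        ids = store.ingest_chemlog(water_chemlog())
        reloaded = DataStore(store_dir=store_dir, seed=7)
        assert set(reloaded.molecules) == set(store.molecules)
        assert set(reloaded.calculations) == set(store.calculations)
        assert reloaded.calculations[ids["calculationIds"][0]].calculation.theory == "scf"


class TestRouteListing:
    def test_api_root_lists_routes(self, client):
        res = client.get("/api/v1")
        assert res.status == 200
        assert any("molecules/search" in r for r in res.json()["routes"])
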