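"""The fixture generator: planted truth, feasibility, determinism, and
end-to-end recovery through the file formats."""

import json

import numpy as np
import pytest

from afscreen.aggregation import aggregate
from afscreen.contacts import find_contacts
from afscreen.structure_io import read_prediction
from afscreen.synthetic import (EnsembleSpec, FixtureSpec,
                                InfeasibleGeometryError, PlantedContact,
                                build_ensemble_predictions, build_prediction,
                                ensemble_manifest, fixture_manifest,
                                generate_ensemble, generate_fixture,
                                random_ensemble_spec, random_fixture_spec)


def planted(ra, rb, dist=5.0, plddt=(90.0, 80.0), pae=(5.0, 6.0)):
    return PlantedContact(ra, rb, dist, plddt[0], plddt[1], pae[0], pae[1])


class TestGenerateFixture:
    def test_detection_recovers_planted_contacts(self, tmp_path):
        spec = FixtureSpec(chains=[("A", 6), ("B", 6)], planted_contacts=[
            planted(("A", 1), ("B", 2)), planted(("A", 3), ("B", 5), dist=7.0),
            planted(("A", 6), ("B", 1), dist=3.5)])
        paths = generate_fixture(spec, tmp_path)
        pred = read_prediction(paths.structure, paths.pae)
        cs = find_contacts(pred, ("A", "B"))
        manifest = json.loads(paths.manifest.read_text())
        expected = {tuple(map(tuple, pair))
                    for pair in manifest["expected_contacts"]}
        got = {((a[0], a[1]), (b[0], b[1])) for (a, b) in
               ((c.key[0][:2], c.key[1][:2]) for c in cs)}
        assert len(cs) == 3
        assert got == expected

    def test_planted_distances_realized_to_hundredth(self, tmp_path):
        spec = FixtureSpec(chains=[("A", 4), ("B", 4)], planted_contacts=[
            planted(("A", 2), ("B", 3), dist=6.789)])
        paths = generate_fixture(spec, tmp_path)
        pred = read_prediction(paths.structure, paths.pae)
        cs = find_contacts(pred, ("A", "B"))
        assert cs.contacts[0].min_heavy_dist == pytest.approx(6.789, abs=0.01)

    def test_no_planted_contacts_yields_empty_interface(self, tmp_path):
        paths = generate_fixture(FixtureSpec(chains=[("A", 5), ("B", 5)]),
                                 tmp_path)
        pred = read_prediction(paths.structure, paths.pae)
        assert len(find_contacts(pred, ("A", "B"))) == 0

    def test_single_filter_knockout_recorded_not_detected(self, tmp_path):
        """A planted pair at 7.9 Å whose pAE is 16 both ways fails the pAE
        filter: absent from detection, listed as planted-but-filtered."""
        spec = FixtureSpec(chains=[("A", 3), ("B", 3)], planted_contacts=[
            planted(("A", 1), ("B", 1), dist=7.9, pae=(16.0, 16.0))])
        paths = generate_fixture(spec, tmp_path)
        pred = read_prediction(paths.structure, paths.pae)
        assert len(find_contacts(pred, ("A", "B"))) == 0
        manifest = json.loads(paths.manifest.read_text())
        assert manifest["expected_contacts"] == []
        assert len(manifest["planted_but_filtered"]) == 1
        assert manifest["planted"][0]["failed_filters"] == ["pae"]

    def test_conflicting_placements_rejected_before_writing(self, tmp_path):
        with pytest.raises(InfeasibleGeometryError):
            FixtureSpec(chains=[("A", 3), ("B", 3)], planted_contacts=[
                planted(("A", 1), ("B", 1), dist=4.0),
                planted(("A", 2), ("B", 1), dist=6.0)])
        assert list(tmp_path.iterdir()) == []

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="out of range"):
            FixtureSpec(chains=[("A", 3), ("B", 3)],
                        planted_contacts=[planted(("A", 9), ("B", 1))])
        with pytest.raises(ValueError, match="background_min_dist"):
            FixtureSpec(chains=[("A", 3), ("B", 3)], background_min_dist=5.0)
        with pytest.raises(ValueError, match="heavy_dist"):
            FixtureSpec(chains=[("A", 3), ("B", 3)],
                        planted_contacts=[planted(("A", 1), ("B", 1),
                                                  dist=8.5)])
        with pytest.raises(ValueError, match="background_plddt"):
            FixtureSpec(chains=[("A", 3), ("B", 3)], background_plddt=60.0)

    def test_identical_spec_gives_byte_identical_files(self, tmp_path):
        spec = random_fixture_spec(42)
        p1 = generate_fixture(spec, tmp_path / "run1")
        p2 = generate_fixture(spec, tmp_path / "run2")
        assert p1.structure.read_bytes() == p2.structure.read_bytes()
        assert p1.pae.read_bytes() == p2.pae.read_bytes()
        assert p1.manifest.read_bytes() == p2.manifest.read_bytes()

    def test_three_atom_residues_keep_planted_minimum(self, tmp_path):
        """With N/CA/C residues, the minimum over heavy-atom pairs is still
        the planted CA-CA distance."""
        spec = FixtureSpec(chains=[("A", 3), ("B", 3)], atoms_per_residue=3,
                           planted_contacts=[planted(("A", 1), ("B", 2),
                                                     dist=5.5)])
        paths = generate_fixture(spec, tmp_path)
        pred = read_prediction(paths.structure, paths.pae)
        cs = find_contacts(pred, ("A", "B"))
        assert len(cs) == 1
        assert cs.contacts[0].min_heavy_dist == pytest.approx(5.5, abs=0.01)
        assert all(len(r.heavy_atoms()) == 3
                   for r in pred.model.iter_residues())


class TestEnsembles:
    def test_membership_controls_per_model_detection(self):
        c1, c2 = planted(("A", 1), ("B", 1)), planted(("A", 2), ("B", 2))
        base = FixtureSpec(chains=[("A", 3), ("B", 3)],
                           planted_contacts=[c1, c2])
        spec = EnsembleSpec(M=3, base=base,
                            membership={c1.key: {1, 2, 3}, c2.key: {2}})
        preds = build_ensemble_predictions(spec)
        counts = [len(find_contacts(p, ("A", "B"))) for p in preds]
        assert counts == [1, 2, 1]

    def test_manifest_mean_and_max_of_membership_sizes(self):
        """Memberships {1..5} and {2} give counts {5, 1}: avg 3.0, max 5."""
        c1, c2 = planted(("A", 1), ("B", 1)), planted(("A", 2), ("B", 2))
        base = FixtureSpec(chains=[("A", 3), ("B", 3)],
                           planted_contacts=[c1, c2])
        spec = EnsembleSpec(M=5, base=base,
                            membership={c1.key: {1, 2, 3, 4, 5},
                                        c2.key: {2}})
        manifest = ensemble_manifest(spec)
        assert manifest["avg_n_models"] == pytest.approx(3.0)
        assert manifest["max_n_models"] == 5

    @pytest.mark.parametrize("membership_mode,expected", [
        ("all", (3.0, 3)),       # full agreement: avg = max = M
        ("disjoint", (1.0, 1)),  # every contact in exactly one model
    ])
    def test_degenerate_memberships(self, membership_mode, expected):
        cs = [planted(("A", i), ("B", i)) for i in (1, 2, 3)]
        base = FixtureSpec(chains=[("A", 3), ("B", 3)], planted_contacts=cs)
        if membership_mode == "all":
            membership = {c.key: {1, 2, 3} for c in cs}
        else:
            membership = {c.key: {i + 1} for i, c in enumerate(cs)}
        manifest = ensemble_manifest(EnsembleSpec(M=3, base=base,
                                                  membership=membership))
        assert (manifest["avg_n_models"], manifest["max_n_models"]) == expected

    def test_invalid_membership_rejected(self):
        c1 = planted(("A", 1), ("B", 1))
        base = FixtureSpec(chains=[("A", 3), ("B", 3)], planted_contacts=[c1])
        with pytest.raises(ValueError, match="non-empty subset"):
            EnsembleSpec(M=3, base=base, membership={c1.key: set()})
        with pytest.raises(ValueError, match="non-empty subset"):
            EnsembleSpec(M=3, base=base, membership={c1.key: {4}})

    @pytest.mark.parametrize("seed", range(25))
    def test_end_to_end_recovery_through_files(self, seed, tmp_path):
        """pipeline(generate_ensemble(spec)) reproduces the manifest's
        contact keys, avg_n_models and max_n_models exactly."""
        spec = random_ensemble_spec(seed, M=5)
        paths = generate_ensemble(spec, tmp_path)
        manifest = json.loads(paths.manifest.read_text())
        sets = [find_contacts(read_prediction(fp.structure, fp.pae),
                              ("A", "B")) for fp in paths.models]
        agg = aggregate(sets, pair_id=f"seed{seed}")
        assert agg.n_unique_contacts == manifest["n_unique_contacts"]
        if manifest["avg_n_models"] is None:
            assert agg.avg_n_models is None
        else:
            assert agg.avg_n_models == pytest.approx(manifest["avg_n_models"])
            assert agg.max_n_models == manifest["max_n_models"]
            expected_keys = {(tuple(c["res_a"]), tuple(c["res_b"]))
                             for c in manifest["contacts"]}
            got_keys = {(k[0][:2], k[1][:2]) for k in agg.contact_counts}
            assert got_keys == expected_keys
            counts_by_key = {(tuple(c["res_a"]), tuple(c["res_b"])): c["n_models"]
                             for c in manifest["contacts"]}
            for key, n in agg.contact_counts.items():
                assert counts_by_key[(key[0][:2], key[1][:2])] == n


class TestRandomSpecs:
    def test_random_fixture_reproducible(self):
        a, b = random_fixture_spec(7), random_fixture_spec(7)
        assert a == b

    def test_random_fixture_manifest_consistent_in_memory(self):
        for seed in range(10):
            spec = random_fixture_spec(seed)
            manifest = fixture_manifest(spec)
            cs = find_contacts(build_prediction(spec), ("A", "B"))
            assert len(cs) == manifest["n_expected_contacts"]
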