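"""Consensus waters, TP/FP evaluation, random baseline and propensity profiles."""

import numpy as np
import pytest

from waterplace import (Atom, Box, FixtureSpec, Structure, error_distribution,
                        error_quartiles, evaluate, find_consensus,
                        make_pocket, make_replicates, propensity_profile,
                        random_baseline)


def waters_structure(positions, sid="s"):
    atoms = [Atom(i + 1, "O", "O", p, record_kind="water", resname="HOH",
                  resseq=i + 1) for i, p in enumerate(np.atleast_2d(positions))]
    return Structure(atoms=atoms, id=sid)


class TestFindConsensus:
    def test_water_in_two_structures_is_consensus(self):
        s1 = waters_structure([[0, 0, 0]], "a")
        s2 = waters_structure([[0.5, 0, 0]], "b")
        cs = find_consensus([s1, s2])
        assert len(cs.consensus) == 1 and len(cs.singletons) == 0
        np.testing.assert_allclose(cs.consensus[0], [0.25, 0, 0])
        assert cs.support[0] == 2

    def test_water_in_one_structure_is_singleton(self):
        s1 = waters_structure([[0, 0, 0]], "a")
        s2 = waters_structure([[5.0, 0, 0]], "b")
        cs = find_consensus([s1, s2])
        assert len(cs.consensus) == 0 and len(cs.singletons) == 2

    def test_requires_two_structures(self):
        with pytest.raises(ValueError, match="2 replicate"):
            find_consensus([waters_structure([[0, 0, 0]])])

    def test_recovers_planted_counts_from_replicates(self):
        spec = FixtureSpec(n_sites=5, n_singletons=2, seed=17)
        cs = find_consensus(make_replicates(spec))
        assert len(cs.consensus) == 5
        assert len(cs.singletons) == 2

    def test_zero_jitter_consensus_at_planted_positions(self):
        spec = FixtureSpec(n_sites=4, replicate_jitter=0.0, n_singletons=0, seed=1)
        cs = find_consensus(make_replicates(spec))
        got = sorted(map(tuple, np.round(cs.consensus, 6)))
        want = sorted(map(tuple, spec.resolved_sites()))
        assert got == want

    def test_support_invariant_to_structure_order(self):
        spec = FixtureSpec(n_sites=4, n_singletons=3, seed=23)
        reps = make_replicates(spec)
        a = find_consensus(reps)
        b = find_consensus(reps[::-1])
        assert sorted(a.support.tolist()) == sorted(b.support.tolist())
        assert len(a.singletons) == len(b.singletons)

    def test_box_filters_out_of_region_waters(self):
        s1 = waters_structure([[0, 0, 0], [30, 0, 0]], "a")
        s2 = waters_structure([[0.4, 0, 0], [30.2, 0, 0]], "b")
        cs = find_consensus([s1, s2], box=Box(center=[0, 0, 0], side=15.0))
        assert len(cs.consensus) == 1


class TestEvaluate:
    def consensus_of(self, positions, singles=()):
        from waterplace.evaluation import ConsensusSet
        positions = np.atleast_2d(positions) if len(positions) else np.empty((0, 3))
        singles = np.atleast_2d(singles) if len(singles) else np.empty((0, 3))
        return ConsensusSet(consensus=positions,
                            support=np.full(len(positions), 2, dtype=int),
                            singletons=singles)

    def test_exact_predictions_give_full_recovery(self):
        cons = self.consensus_of([[0, 0, 0], [5, 0, 0]])
        report = evaluate(np.array([[0, 0, 0], [5, 0, 0]]), cons)
        assert report.n_predicted_consensus == 2
        assert report.n_false_positives == 0
        assert report.mean_error == pytest.approx(0.0)
        assert report.tp_rate == 1.0

    def test_distant_prediction_is_false_positive(self):
        cons = self.consensus_of([[0, 0, 0]])
        report = evaluate(np.array([[0, 0, 0], [50, 0, 0]]), cons)
        assert report.n_false_positives == 1

    def test_water_between_two_predictions_yields_tp_plus_fp(self):
        cons = self.consensus_of([[0, 0, 0]])
        report = evaluate(np.array([[-1.0, 0, 0], [1.0, 0, 0]]), cons, max_error=2.0)
        assert report.n_predicted_consensus == 1
        assert report.n_false_positives == 1

    def test_singleton_match_is_not_fp_and_not_tp(self):
        cons = self.consensus_of([[0, 0, 0]], singles=[[6.0, 0, 0]])
        report = evaluate(np.array([[0.1, 0, 0], [6.1, 0, 0]]), cons)
        assert report.n_predicted_consensus == 1
        assert report.n_false_positives == 0

    def test_tp_plus_unmatched_equals_n_consensus(self):
        rng = np.random.default_rng(2)
        cons = self.consensus_of(rng.uniform(0, 20, size=(8, 3)))
        preds = rng.uniform(0, 20, size=(6, 3))
        report = evaluate(preds, cons)
        unmatched = report.n_consensus - report.n_predicted_consensus
        assert report.n_predicted_consensus + unmatched == report.n_consensus
        assert report.n_predicted_consensus <= report.n_consensus

    def test_symmetric_under_prediction_relabeling(self):
        rng = np.random.default_rng(3)
        cons = self.consensus_of(rng.uniform(0, 15, size=(6, 3)))
        preds = rng.uniform(0, 15, size=(7, 3))
        a = evaluate(preds, cons)
        b = evaluate(preds[::-1], cons)
        assert a.n_predicted_consensus == b.n_predicted_consensus
        assert a.n_false_positives == b.n_false_positives
        assert a.mean_error == pytest.approx(b.mean_error, abs=1e-12)

    def test_protein_distance_filter_prunes_consensus(self):
        pocket = make_pocket(FixtureSpec(n_sites=1, seed=0))
        near = pocket.atoms[0].coords + np.array([2.0, 0, 0])
        cons = self.consensus_of([near, [100.0, 100, 100]])
        report = evaluate(np.array([near]), cons, protein_dist_filter=3.3,
                          structure=pocket)
        assert report.n_consensus == 1


class TestRandomBaseline:
    def test_reproducible_given_seed(self):
        s = Structure(atoms=[], id="empty")
        box = Box(center=[0, 0, 0], side=10.0)
        a = random_baseline(s, box, n=50, seed=4)
        b = random_baseline(s, box, n=50, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_empty_structure_returns_n_points(self):
        s = Structure(atoms=[], id="empty")
        pts = random_baseline(s, Box(center=[0, 0, 0], side=10.0), n=100, seed=5)
        assert len(pts) == 100
        assert Box(center=[0, 0, 0], side=10.0).contains(pts).all()

    def test_points_clear_of_clash_distance(self):
        pocket = make_pocket(FixtureSpec(n_sites=2, seed=6))
        box = Box(center=pocket.coords().mean(axis=0), side=12.0)
        pts = random_baseline(pocket, box, n=100, seed=7)
        from waterplace.water_scoring import VDW_RADII, WATER_OXYGEN_RADIUS
        for a in pocket.atoms:
            d = np.linalg.norm(pts - a.coords, axis=1)
            assert (d >= VDW_RADII[a.element.upper()] + WATER_OXYGEN_RADIUS - 1e-9).all()

    def test_fully_buried_box_warns_and_truncates(self):
        atoms = [Atom(i + 1, "CA", "C", p, resname="GLY", resseq=i + 1)
                 for i, p in enumerate(np.random.default_rng(8).uniform(-2, 2, (60, 3)))]
        s = Structure(atoms=atoms, id="core")
        with pytest.warns(UserWarning, match="clash-free"):
            pts = random_baseline(s, Box(center=[0, 0, 0], side=4.0), n=500, seed=9)
        assert len(pts) < 500


class TestErrorDistribution:
    def test_coincident_point_has_zero_error(self):
        d = error_distribution([[1, 2, 3]], [[1, 2, 3]])
        assert d[0] == 0.0

    def test_hand_computed_three_point_case(self):
        ref = [[0, 0, 0], [10, 0, 0]]
        pts = [[1, 0, 0], [10, 2, 0], [4, 3, 0]]
        np.testing.assert_allclose(error_distribution(pts, ref), [1.0, 2.0, 5.0])

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError, match="empty"):
            error_distribution([[0, 0, 0]], [])

    def test_predictions_beat_random_baseline_on_fixture(self):
        from waterplace import (ClusterParams, filter_poses, make_poses,
                                predict_sites)
        spec = FixtureSpec(seed=13)
        pocket = make_pocket(spec)
        sites = predict_sites(filter_poses(
            [p for run in make_poses(spec) for p in run]), ClusterParams())
        ref = spec.resolved_sites()
        pred_err = error_distribution([s.position for s in sites], ref)
        box = Box(center=ref.mean(axis=0), side=15.0)
        rand_err = error_distribution(random_baseline(pocket, box, n=200, seed=14), ref)
        assert np.median(pred_err) < np.median(rand_err)
        q = error_quartiles(rand_err)
        assert q["q1"] <= q["median"] <= q["q3"]


class TestPropensityProfile:
    def ligand(self):
        return Structure(atoms=[
            Atom(1, "O1", "O", [0.0, 0, 0], record_kind="ligand", resname="LIG",
                 roles={"hbond_acceptor"}),
            Atom(2, "C1", "C", [3.0, 0, 0], record_kind="ligand", resname="LIG",
                 roles={"carbon"}),
        ], id="lig")

    def test_on_site_oxygen_vs_distant_carbon(self):
        profile = propensity_profile([np.zeros(3)], self.ligand())
        assert profile["acceptor"][0.5] == 1.0
        assert profile["carbon_nonaromatic"][0.5] == 0.0
        assert profile["O"][0.5] == 1.0

    def test_cumulative_in_distance_and_bounded(self):
        rng = np.random.default_rng(15)
        atoms = [Atom(i + 1, f"C{i}", "C", p, record_kind="ligand", resname="LIG",
                      roles={"carbon"} | ({"aromatic"} if i % 2 else set()))
                 for i, p in enumerate(rng.uniform(0, 6, size=(12, 3)))]
        profile = propensity_profile(rng.uniform(0, 6, size=(4, 3)),
                                     Structure(atoms=atoms, id="lig"))
        for cls, curve in profile.items():
            if cls == "_counts":
                continue
            vals = [curve[b] for b in sorted(curve)]
            assert all(0.0 <= v <= 1.0 for v in vals)
            assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_empty_class_omitted(self):
        profile = propensity_profile([np.zeros(3)], self.ligand())
        assert "N" not in profile
        assert "donor" not in profile

    def test_planted_polar_ratio_recovered(self):
        # 9 polar atoms on sites, 1 carbon on a site, rest of carbons far away
        rng = np.random.default_rng(16)
        sites = rng.uniform(0, 40, size=(10, 3))
        atoms = [Atom(i + 1, f"O{i}", "O", sites[i], record_kind="ligand",
                      resname="LIG", roles={"hbond_acceptor"}) for i in range(9)]
        atoms.append(Atom(10, "C0", "C", sites[9], record_kind="ligand",
                          resname="LIG", roles={"carbon"}))
        atoms += [Atom(11 + i, f"C{i + 1}", "C", sites.mean(axis=0) + 100 + i,
                       record_kind="ligand", resname="LIG", roles={"carbon"})
                  for i in range(8)]
        profile = propensity_profile(sites, Structure(atoms=atoms, id="lig"))
        ratio = profile["acceptor"][0.5] / profile["C"][0.5]
        assert ratio == pytest.approx(9.0)
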