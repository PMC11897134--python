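"""Structural metrics: SASA, contact clustering, hydrogen bonds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phasekit.errors import ArgumentError, DataError
from phasekit.structure import (
    AtomRecord,
    Configuration,
    ClusterAssignment,
    Trajectory,
    aggregation_propensity,
    clustering_degree,
    compute_sasa,
    detect_hbonds,
    find_clusters,
    hbond_species_partition,
    phase_metrics,
)
from phasekit.synthetic import gen_configuration, gen_trajectory

from oracles import (
    exhaustive_hbonds,
    labels_to_signature,
    naive_clusters,
    partition_signature,
    random_contactable_config,
    two_sphere_sasa,
)


def single_atom(element="N", r=0.152, pos=(0, 0, 0), pid=0):
    return AtomRecord(element=element, position=np.array(pos, float), vdw_radius=r,
                      peptide_id=pid, species="FFM")


class TestSasa:
    def test_isolated_sphere_matches_analytic_area(self):
        config = Configuration.from_atoms([single_atom(r=0.152)])
        res = compute_sasa(config, probe_radius=0.14)
        exact = 4 * math.pi * (0.152 + 0.14) ** 2
        assert res.total_area == pytest.approx(exact, rel=0.02)
        assert res.per_atom_area.sum() == pytest.approx(res.total_area)

    def test_fully_buried_atom_has_zero_area(self):
        atoms = [single_atom(element="C", r=0.3), single_atom(element="O", r=0.05)]
        config = Configuration.from_atoms(atoms)
        res = compute_sasa(config, probe_radius=0.14)
        assert res.per_atom_area[1] == 0.0

    def test_two_overlapping_spheres_match_cap_formula(self):
        atoms = [
            single_atom(element="N", r=0.15, pos=(0, 0, 0)),
            single_atom(element="N", r=0.15, pos=(0.29, 0, 0), pid=1),
        ]
        config = Configuration.from_atoms(atoms)
        res = compute_sasa(config, probe_radius=0.14)
        exact = two_sphere_sasa(0.15, 0.14, 0.29)
        assert exact == pytest.approx(1.585, abs=5e-3)  # sanity on the oracle itself
        assert res.total_area == pytest.approx(exact, rel=0.02)

    def test_monotone_under_approach(self):
        # moving two atoms closer never increases total SASA
        totals = []
        for d in np.linspace(0.7, 0.1, 13):
            atoms = [
                single_atom(pos=(0, 0, 0)),
                single_atom(pos=(d, 0, 0), pid=1),
            ]
            totals.append(compute_sasa(Configuration.from_atoms(atoms)).total_area)
        diffs = np.diff(totals)
        assert (diffs <= 1e-12).all()

    def test_rigid_motion_invariance(self, rng):
        config = random_contactable_config(6, rng)
        base = compute_sasa(config).total_area
        from phasekit.synthetic import _random_rotation

        # translation leaves the point sampling unchanged (exact);
        # rotation re-samples the spheres, so agreement is to the 2%
        # sampling tolerance
        shifted = config.transformed(None, translation=(1.5, -2.0, 0.3))
        assert compute_sasa(shifted).total_area == pytest.approx(base, rel=1e-9)
        rotated = config.transformed(_random_rotation(rng), translation=(1.5, -2.0, 0.3))
        assert compute_sasa(rotated).total_area == pytest.approx(base, rel=0.02)

    def test_rejects_too_few_points_and_bad_coords(self):
        config = Configuration.from_atoms([single_atom()])
        with pytest.raises(ArgumentError):
            compute_sasa(config, n_sphere_points=8)
        with pytest.raises(DataError):
            Configuration.from_atoms([single_atom(pos=(np.nan, 0, 0))])


class TestAggregationPropensity:
    @pytest.mark.parametrize(
        "initial,final,ap",
        [(2.0, 2.0, 1.0), (1.0, 0.85, 1.0 / 0.85), (1.0, 0.5, 2.0)],
    )
    def test_reciprocal_mapping(self, initial, final, ap):
        got_ap, rel = aggregation_propensity(initial, final)
        assert got_ap == pytest.approx(ap)
        assert got_ap * rel == pytest.approx(1.0, abs=1e-12)

    def test_condensate_bound_at_one_decimal(self):
        ap, _ = aggregation_propensity(1.0, 0.85)
        assert round(ap, 1) == 1.2

    def test_rejects_nonpositive_area(self):
        with pytest.raises(ArgumentError):
            aggregation_propensity(0.0, 1.0)


class TestClustering:
    def test_chain_connectivity(self):
        # five peptides, consecutive pairs within the cutoff, others far away
        atoms = []
        for p in range(5):
            atoms.append(single_atom(pos=(0.4 * p, 0, 0), pid=p))
        config = Configuration.from_atoms(atoms)
        a = find_clusters(config, contact_cutoff=0.5)
        assert clustering_degree(a, 5) == 1.0

    def test_dispersed_generator_yields_singletons(self):
        config = gen_configuration("dispersed", 64, seed=1)
        a = find_clusters(config)
        assert a.n_clusters == 64
        assert clustering_degree(a, 64) == pytest.approx(1 / 64)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        config = random_contactable_config(12, rng)
        a = find_clusters(config, contact_cutoff=0.5)
        oracle = partition_signature(naive_clusters(config, 0.5))
        assert labels_to_signature(a.labels) == oracle

    def test_cluster_sizes_sum_to_n(self, rng):
        config = random_contactable_config(15, rng)
        a = find_clusters(config)
        assert a.cluster_sizes.sum() == 15

    @pytest.mark.parametrize(
        "sizes,n,cd", [([9, 1], 10, 0.9), ([1] * 20, 20, 0.05), ([7], 7, 1.0)]
    )
    def test_clustering_degree_values(self, sizes, n, cd):
        a = ClusterAssignment(
            labels=np.repeat(np.arange(len(sizes)), sizes),
            cluster_sizes=np.sort(np.array(sizes))[::-1],
            contact_cutoff=0.5,
        )
        assert clustering_degree(a, n) == pytest.approx(cd)


def _hbond_triple(d_da=0.30, angle_deg=10.0):
    """Donor at origin with H along +x; acceptor at distance d_da and the
    requested donor-side angle, in a second peptide."""
    theta = math.radians(angle_deg)
    donor = AtomRecord("N", np.zeros(3), 0.155, 0, "FFM",
                       is_donor_heavy=True, bonded_hydrogen_index=1)
    hydrogen = AtomRecord("H", np.array([0.1, 0, 0]), 0.11, 0, "FFM")
    acceptor = AtomRecord(
        "O", np.array([d_da * math.cos(theta), d_da * math.sin(theta), 0.0]),
        0.152, 1, "MFF", is_acceptor=True,
    )
    return Configuration.from_atoms([donor, hydrogen, acceptor])


class TestHbonds:
    def test_geometry_inside_both_cutoffs(self):
        bonds = detect_hbonds(_hbond_triple(0.30, 10.0))
        assert len(bonds) == 1
        b = bonds[0]
        assert b.distance_da == pytest.approx(0.30)
        assert b.angle_deg == pytest.approx(10.0, abs=1e-9)
        assert b.species_pair == ("FFM", "MFF")

    @pytest.mark.parametrize("d,angle", [(0.36, 10.0), (0.30, 35.0), (0.35, 10.0), (0.30, 30.0)])
    def test_geometry_outside_either_cutoff(self, d, angle):
        # the last two cases sit exactly on a boundary: strict inequalities exclude them
        assert detect_hbonds(_hbond_triple(d, angle)) == []

    def test_intramolecular_excluded_by_default(self):
        config = _hbond_triple(0.30, 10.0)
        config.peptide_ids[:] = 0
        assert detect_hbonds(config) == []
        assert len(detect_hbonds(config, intermolecular_only=False)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        config = random_contactable_config(10, rng)
        got = {(b.donor_index, b.hydrogen_index, b.acceptor_index)
               for b in detect_hbonds(config)}
        assert got == exhaustive_hbonds(config, 0.35, 30.0)

    def test_rigid_motion_invariance(self, rng):
        config = random_contactable_config(8, rng)
        from phasekit.synthetic import _random_rotation

        moved = config.transformed(_random_rotation(rng), translation=(0.5, 0.1, -3.0))
        assert len(detect_hbonds(moved)) == len(detect_hbonds(config))

    def test_species_partition_conservation(self, rng):
        config = gen_configuration("droplet", 32, seed=5)
        bonds = detect_hbonds(config)
        part = hbond_species_partition(bonds)
        assert sum(part.values()) == len(bonds)

    def test_all_same_species_single_bucket(self):
        config = gen_configuration("fibril", 8, seed=0)
        config.species[:] = "FFM"
        part = hbond_species_partition(detect_hbonds(config))
        assert set(part) == {("FFM", "FFM")}


class TestPhaseMetrics:
    def test_fibril_trajectory_compacts_and_clusters(self, end_state_metrics):
        m = end_state_metrics["fibril"]
        assert m.cd == 1.0
        assert m.ap > 1.0
        assert sum(m.n_hbonds_by_pair.values()) == pytest.approx(m.n_hbonds_total)

    def test_dispersed_trajectory_stays_dilute(self, end_state_metrics):
        m = end_state_metrics["dispersed"]
        assert m.ap == pytest.approx(1.0, rel=0.05)
        assert m.cd == pytest.approx(1 / 64)

    def test_tail_of_one_equals_last_frame(self):
        traj = gen_trajectory("fibril", 3, 8, seed=2)
        m = phase_metrics(traj, tail_frames=1)
        last = traj.frames[-1]
        a = find_clusters(last)
        assert m.cd == pytest.approx(clustering_degree(a, last.n_peptides))
        assert m.n_hbonds_total == len(detect_hbonds(last))

    def test_requires_two_frames(self):
        traj = gen_trajectory("fibril", 2, 4, seed=2)
        with pytest.raises(ArgumentError):
            phase_metrics(Trajectory(frames=[traj.frames[0]], times=[0.0]))


@settings(derandomize=True, max_examples=50)
@given(
    initial=st.floats(0.01, 1e3, allow_nan=False),
    relative=st.floats(0.01, 10.0, allow_nan=False),
)
def test_ap_relative_sasa_product_is_one(initial, relative):
    ap, rel = aggregation_propensity(initial, initial * relative)
    assert ap * rel == pytest.approx(1.0, rel=1e-12)
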