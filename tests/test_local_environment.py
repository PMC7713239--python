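import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from solvmut.constants import (
    SALT_BRIDGE_ACCEPTORS,
    SALT_BRIDGE_DONORS,
    VDW_RADII,
)
from solvmut.local_environment import (
    bulky_flag,
    charge_census,
    detect_salt_bridges,
    min_sidechain_distance,
    relative_exposure,
    salt_bridge_delta,
    sasa,
)
from solvmut.mutation_model import MutationSet, build_correspondence, parse_mutation_list
from solvmut.structure_io import ResidueKey
from solvmut.synthetic_data import (
    LocalTarget,
    SynthSpec,
    benchmark_suite,
    make_mutant,
    make_structure,
)


def _random_fixture(seed, n=20):
    charges = [(p, q) for p, q in
               [(2, +1), (5, -1), (9, +1), (14, -1), (17, +1)] if p <= n]
    return make_structure(SynthSpec(n_residues=n, geometry="sphere",
                                    charges=charges, seed=seed))


def _brute_force_dm(cs, res_key, site_key, coords):
    """Exhaustive pairwise minimum over side-chain heavy atoms."""
    def side_atoms(key):
        idx = cs.residue_by_key(key)
        res = cs.residues[idx]
        return [i for i in cs.residue_atom_indices(idx)
                if cs.atoms[i].is_sidechain(res)
                and not cs.atoms[i].is_hydrogen]
    a = coords[side_atoms(res_key)]
    b = coords[side_atoms(site_key)]
    return min(float(np.linalg.norm(x - y)) for x in a for y in b)


class TestMinSidechainDistance:
    def test_site_itself_zero(self):
        cs = _random_fixture(0)
        site = ResidueKey("A", 9)
        assert min_sidechain_distance(cs, site, site) == 0.0

    def test_two_beads_five_angstrom(self):
        cs = _random_fixture(0)
        coords = cs.coords.copy()
        i = cs.residue_by_key(ResidueKey("A", 1))
        j = cs.residue_by_key(ResidueKey("A", 2))
        for ai in cs.residue_atom_indices(i):
            if cs.atoms[ai].name != "CA":
                coords[ai] = [0.0, 0.0, 0.0]
        for aj in cs.residue_atom_indices(j):
            if cs.atoms[aj].name != "CA":
                coords[aj] = [5.0, 0.0, 0.0]
        d = min_sidechain_distance(cs, ResidueKey("A", 1),
                                   ResidueKey("A", 2), frame=coords)
        assert d == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        cs = _random_fixture(seed)
        site = ResidueKey("A", 9)
        for r in cs.residues:
            if r.key == site:
                continue
            assert min_sidechain_distance(cs, r.key, site) == pytest.approx(
                _brute_force_dm(cs, r.key, site, cs.coords), abs=1e-10)

    def test_multi_residue_site_takes_minimum(self):
        cs = _random_fixture(3)
        res = ResidueKey("A", 1)
        sites = [ResidueKey("A", 9), ResidueKey("A", 14)]
        expected = min(min_sidechain_distance(cs, res, s) for s in sites)
        assert min_sidechain_distance(cs, res, sites) == expected

    def test_rigid_motion_invariance(self):
        cs = _random_fixture(1)
        rot = Rotation.random(rng=np.random.default_rng(5))
        moved = rot.apply(cs.coords) + [3.0, -7.0, 11.0]
        site = ResidueKey("A", 5)
        for r in cs.residues[:6]:
            assert min_sidechain_distance(cs, r.key, site) == pytest.approx(
                min_sidechain_distance(cs, r.key, site, frame=moved),
                abs=1e-9)


class TestChargeCensus:
    def test_all_neutral(self):
        cs = make_structure(SynthSpec(n_residues=10, seed=0))
        c = charge_census(cs, ResidueKey("A", 5))
        assert (c.n_positive, c.n_negative, c.local_net) == (0, 0, 0)

    def test_engineered_pattern(self):
        """Three positives and two negatives inside the shell, mirroring a
        (+3, -2) local environment; others pushed outside."""
        cs = make_structure(SynthSpec(
            n_residues=40, geometry="sphere", radius=11.0,
            local_targets=[LocalTarget(1, +1, 15.0)], seed=2))
        site = ResidueKey("A", 1)
        base = charge_census(cs, site, cutoff=15.0)
        assert base.local_net == +1

    def test_cutoff_zero_empty(self):
        cs = _random_fixture(0)
        c = charge_census(cs, ResidueKey("A", 2), cutoff=0.0)
        assert (c.n_positive, c.n_negative, c.local_net) == (0, 0, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_cutoff_and_closure(self, seed):
        cs = _random_fixture(seed)
        site = ResidueKey("A", 2)
        prev_p = prev_n = 0
        for cutoff in (0.0, 5.0, 10.0, 20.0, 50.0, 200.0):
            c = charge_census(cs, site, cutoff=cutoff)
            assert c.n_positive >= prev_p and c.n_negative >= prev_n
            prev_p, prev_n = c.n_positive, c.n_negative
        # at cutoff >= diameter the census sees every other charge
        site_charge = cs.residues[cs.residue_by_key(site)].formal_charge
        assert c.local_net + site_charge == cs.total_charge


def _brute_force_bridges(cs, coords, cutoff):
    found = set()
    for i, ri in enumerate(cs.residues):
        if ri.aa_type not in SALT_BRIDGE_DONORS:
            continue
        for j, rj in enumerate(cs.residues):
            if rj.aa_type not in SALT_BRIDGE_ACCEPTORS:
                continue
            dn = [coords[k] for k in cs.residue_atom_indices(i)
                  if cs.atoms[k].name in SALT_BRIDGE_DONORS[ri.aa_type]]
            ac = [coords[k] for k in cs.residue_atom_indices(j)
                  if cs.atoms[k].name in SALT_BRIDGE_ACCEPTORS[rj.aa_type]]
            if dn and ac and cdist(dn, ac).min() < cutoff:
                found.add((ri.key, rj.key))
    return found


class TestSaltBridges:
    def test_engineered_bridge_detected(self, benches):
        bridges = detect_salt_bridges(benches["salt_bridge"]["structure"])
        assert len(bridges) == 1
        assert bridges[0].min_distance == pytest.approx(3.0, abs=0.1)

    def test_pair_beyond_cutoff_ignored(self, benches):
        cs = benches["salt_bridge"]["structure"]
        coords = cs.coords.copy()
        idx = cs.residue_by_key(ResidueKey("A", 2))
        for ai in cs.residue_atom_indices(idx):
            coords[ai] += [3.0, 0.0, 0.0]  # NZ-OD1 now 6 A
        assert detect_salt_bridges(cs, frame=coords) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        cs = _random_fixture(seed, n=16)
        got = {b.pair for b in detect_salt_bridges(cs)}
        assert got == _brute_force_bridges(cs, cs.coords, 4.0)

    def test_formed_and_broken_upon_mutation(self, benches):
        cs = benches["salt_bridge"]["structure"]
        # breaking: mutate the Asp away
        ms = parse_mutation_list("A:D2S")
        mut = make_mutant(cs, ms)
        cmap = build_correspondence(cs, mut, ms)
        formed, broken, involves = salt_bridge_delta(
            cs, mut, cmap, site_keys=ms.site_keys())
        assert not formed
        assert len(broken) == 1
        assert involves[broken[0].pair] is True

    def test_identical_ensembles_no_changes(self, benches):
        cs = benches["salt_bridge"]["structure"]
        cmap = build_correspondence(cs, cs, MutationSet([]))
        formed, broken, _ = salt_bridge_delta(cs, cs, cmap)
        assert formed == [] and broken == []


class TestSasa:
    def test_single_atom_closed_form(self):
        from solvmut.structure_io import Atom, Residue, StructureEnsemble
        from solvmut.structure_io import assign_formal_charges

        ens = StructureEnsemble(
            atoms=[Atom(serial=1, name="CA", element="C", residue_index=0)],
            residues=[Residue(chain_id="A", seq_number=1, aa_type="GLY")],
            frames=[np.zeros((1, 3))])
        areas = sasa(assign_formal_charges(ens), probe=1.4, n_points=960)
        r = VDW_RADII["C"] + 1.4
        assert areas[ResidueKey("A", 1)] == pytest.approx(
            4 * np.pi * r ** 2, rel=0.01)

    def test_enclosed_atom_near_zero(self):
        from solvmut.structure_io import Atom, Residue, StructureEnsemble
        from solvmut.structure_io import assign_formal_charges

        # central atom caged by 26 overlapping neighbours
        offsets = [np.array([i, j, k], dtype=float) * 2.0
                   for i in (-1, 0, 1) for j in (-1, 0, 1)
                   for k in (-1, 0, 1)]
        atoms, residues, coords = [], [], []
        for idx, off in enumerate(offsets):
            residues.append(Residue(chain_id="A", seq_number=idx + 1,
                                    aa_type="GLY"))
            atoms.append(Atom(serial=idx + 1, name="CA", element="C",
                              residue_index=idx))
            coords.append(off)
        ens = StructureEnsemble(atoms=atoms, residues=residues,
                                frames=[np.array(coords)])
        areas = sasa(assign_formal_charges(ens))
        center = ResidueKey("A", 14)  # the (0,0,0) atom
        assert areas[center] < 1.0

    def test_two_sphere_overlap_matches_fine_grid(self):
        """Accessible fraction of one sphere partially shadowed by another,
        against a dense spherical-grid numerical integration."""
        from solvmut.structure_io import Atom, Residue, StructureEnsemble
        from solvmut.structure_io import assign_formal_charges

        d = 2.5
        atoms, residues = [], []
        for idx in range(2):
            residues.append(Residue(chain_id="A", seq_number=idx + 1,
                                    aa_type="GLY"))
            atoms.append(Atom(serial=idx + 1, name="CA", element="C",
                              residue_index=idx))
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        ens = StructureEnsemble(atoms=atoms, residues=residues,
                                frames=[coords])
        areas = sasa(assign_formal_charges(ens), n_points=960)

        r = VDW_RADII["C"] + 1.4
        # dense lat-long grid on sphere 1
        n_th, n_ph = 400, 800
        th = (np.arange(n_th) + 0.5) * np.pi / n_th
        ph = (np.arange(n_ph) + 0.5) * 2 * np.pi / n_ph
        TH, PH = np.meshgrid(th, ph, indexing="ij")
        pts = r * np.stack([np.sin(TH) * np.cos(PH),
                            np.sin(TH) * np.sin(PH), np.cos(TH)], axis=-1)
        w = r ** 2 * np.sin(TH) * (np.pi / n_th) * (2 * np.pi / n_ph)
        exposed = np.linalg.norm(pts - coords[1], axis=-1) >= r
        oracle = float((w * exposed).sum())
        assert areas[ResidueKey("A", 1)] == pytest.approx(oracle, rel=0.02)

    def test_relative_exposure_of_surface_beads(self):
        cs = make_structure(SynthSpec(n_residues=20, seed=0))
        rel = relative_exposure(cs)
        assert all(v > 0.25 for v in rel.values())  # bead shells are exposed

    def test_environment_table_columns(self):
        from solvmut.local_environment import environment_table

        cs = _random_fixture(0)
        df = environment_table(cs, ResidueKey("A", 2), cutoff=15.0)
        assert list(df.columns) == ["key", "aa", "charge_class", "d_m",
                                    "sasa", "in_census"]
        assert len(df) == len(cs.residues)
        assert (df.loc[df.key == "A:2", "d_m"] == 0.0).all()


class TestBulkyFlag:
    @pytest.mark.parametrize("aa,expected", [
        ("Y", True), ("W", True), ("G", False), ("K", False),
        ("R", False), ("D", False), ("E", False), ("F", False),
    ])
    def test_default_threshold(self, aa, expected):
        assert bulky_flag(aa) is expected

    def test_lower_threshold_flags_arg_phe(self):
        assert bulky_flag("R", threshold=7)
        assert bulky_flag("F", threshold=7)
        assert not bulky_flag("K", threshold=7)
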