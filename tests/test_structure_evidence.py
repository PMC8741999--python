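import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from hlcur.io_core import AtomRecord, DdgReplicateSet, StructureModel
from hlcur.structure_evidence import (
    GeometryError,
    Mechanism,
    MechanismConfig,
    ResidueAnnotation,
    ResidueSelector,
    assign_mechanism,
    avg_shell_distance,
    burial_proxy,
    charge_delta,
    ddg_classify,
    detect_motile_regions,
    interface_residues,
    kabsch,
    kabsch_superpose,
    neighbor_shell,
    pp3_from_structure,
    sidechain_min_distance,
    template_screen,
)
from hlcur.synthetic_data import HingeHelixSpec, generate_helix_pair
from hlcur.variant_domain import Consequence, VariantRecord


# ---------------------------------------------------------------------------
# brute-force rotation oracle (grid + simplex refinement over Euler
# angles; written independently of the SVD implementation)
# ---------------------------------------------------------------------------

_GRID = Rotation.from_euler(
    "zyx",
    [(a, b, c)
     for a in np.arange(0, 360, 24)
     for b in np.arange(-90, 91, 18)
     for c in np.arange(0, 360, 24)],
    degrees=True,
).as_matrix()


def brute_force_min_rmsd(x, y):
    x0 = x - x.mean(axis=0)
    y0 = y - y.mean(axis=0)

    def rmsd_for(mat):
        return np.sqrt(np.mean(np.sum((x0 @ mat.T - y0) ** 2, axis=1)))

    def objective(euler):
        return rmsd_for(Rotation.from_euler("zyx", euler).as_matrix())

    scores = np.array([rmsd_for(m) for m in _GRID])
    best = np.inf
    # refine from several grid starts: a single simplex can stall in a
    # local minimum of the Euler parameterization
    for idx in np.argsort(scores)[:8]:
        start = Rotation.from_matrix(_GRID[idx]).as_euler("zyx")
        result = minimize(objective, start, method="Nelder-Mead",
                          options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, float(result.fun))
    return best


def make_model(points, atom_name="CA", chain="A"):
    atoms = [
        AtomRecord(i + 1, atom_name, "ALA", chain, i + 1, "", np.asarray(p), "C")
        for i, p in enumerate(points)
    ]
    return StructureModel(atoms)


def residue(chain, seq, atoms_spec):
    """atoms_spec: list of (name, xyz, element)."""
    return [
        AtomRecord(0, name, "XXX", chain, seq, "", np.asarray(xyz), el)
        for name, xyz, el in atoms_spec
    ]


class TestKabsch:
    def test_exact_copy_gives_zero_rmsd(self, helix_pair):
        ref, _ = helix_pair
        result = kabsch_superpose(ref, ref)
        assert result.global_rmsd == pytest.approx(0.0, abs=1e-9)
        assert all(v == pytest.approx(0.0, abs=1e-9)
                   for v in result.per_residue_rmsd.values())

    def test_rigid_motion_invariance(self, helix_pair):
        ref, _ = helix_pair
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = StructureModel([
            AtomRecord(a.serial, a.atom_name, a.residue_name, a.chain_id,
                       a.residue_seq, a.icode, rot @ a.coords + np.array([5.0, 5.0, 5.0]),
                       a.element)
            for a in ref.atoms
        ])
        result = kabsch_superpose(moved, ref)
        assert result.global_rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_grid_oracle_on_random_small_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(4, 7))
            x = rng.normal(size=(n, 3)) * 3.0
            y = x + rng.normal(size=(n, 3)) * 0.5
            rot, t = kabsch(x, y)
            ours = float(np.sqrt(np.mean(np.sum((x @ rot.T + t - y) ** 2, axis=1))))
            assert ours == pytest.approx(brute_force_min_rmsd(x, y), abs=1e-3)

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(GeometryError, match=">= 3"):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_rejected(self):
        x = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(GeometryError, match="collinear"):
            kabsch(x, x)

    def test_no_reflection_even_for_mirrored_input(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 3))
        y = x * np.array([1.0, 1.0, -1.0])  # mirror image
        rot, _ = kabsch(x, y)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)


class TestMotileRegions:
    def test_flat_profile_has_no_regions(self):
        profile = {i: 0.5 for i in range(1, 41)}
        assert detect_motile_regions(profile, threshold=1.0) == []

    def test_hinge_recovered_from_generated_pair(self, helix_pair):
        ref, mob = helix_pair
        result = kabsch_superpose(mob, ref)
        regions = detect_motile_regions(result.per_residue_rmsd, min_len=5)
        assert len(regions) == 1
        start, end = regions[0]
        assert start <= 20 and end >= 30

    def test_two_separated_peaks_give_two_ascending_ranges(self):
        profile = {i: 0.1 for i in range(1, 61)}
        profile.update({i: 3.0 for i in range(10, 18)})
        profile.update({i: 3.0 for i in range(40, 50)})
        assert detect_motile_regions(profile, threshold=1.0) == [(10, 17), (40, 49)]

    def test_short_runs_below_min_len_dropped(self):
        profile = {i: 0.1 for i in range(1, 31)}
        profile.update({i: 3.0 for i in range(10, 13)})
        assert detect_motile_regions(profile, min_len=5, threshold=1.0) == []

    def test_empty_profile_rejected(self):
        with pytest.raises(GeometryError):
            detect_motile_regions({})


class TestDistances:
    def two_ala(self, separation):
        atoms = residue("A", 1, [("N", (0, 0, 0), "N"), ("CA", (1.5, 0, 0), "C"),
                                 ("C", (3, 0, 0), "C"), ("O", (3, 1, 0), "O"),
                                 ("CB", (1.5, 1.5, 0), "C")])
        atoms += residue("A", 5, [("N", (0, 0, separation), "N"),
                                  ("CA", (1.5, 0, separation), "C"),
                                  ("C", (3, 0, separation), "C"),
                                  ("O", (3, 1, separation), "O"),
                                  ("CB", (1.5, 1.5, separation), "C")])
        return StructureModel(atoms)

    def test_cb_to_cb_distance(self):
        model = self.two_ala(4.0)
        d = sidechain_min_distance(model, ResidueSelector("A", 1), ResidueSelector("A", 5))
        assert d == pytest.approx(4.0)

    def test_self_distance_is_zero(self):
        model = self.two_ala(4.0)
        sel = ResidueSelector("A", 1)
        assert sidechain_min_distance(model, sel, sel) == 0.0

    def test_glycine_falls_back_to_ca(self):
        atoms = residue("A", 1, [("N", (0, 0, 0), "N"), ("CA", (0, 0, 0), "C"),
                                 ("C", (1, 0, 0), "C"), ("O", (1, 1, 0), "O")])
        atoms += residue("A", 5, [("CA", (0, 0, 3.0), "C"), ("CB", (0, 0, 2.0), "C")])
        model = StructureModel(atoms)
        d = sidechain_min_distance(model, ResidueSelector("A", 1), ResidueSelector("A", 5))
        assert d == pytest.approx(2.0)  # GLY CA at origin vs partner CB

    def test_unresolvable_selector_errors(self):
        model = self.two_ala(4.0)
        with pytest.raises(GeometryError):
            sidechain_min_distance(model, ResidueSelector("A", 1), ResidueSelector("B", 9))


class TestNeighborShell:
    def cluster(self):
        atoms = residue("A", 10, [("CA", (0, 0, 0), "C"), ("CB", (0, 0, 1), "C")])
        atoms += residue("A", 20, [("CA", (4, 0, 1), "C"), ("CB", (4, 0, 1), "C")])
        atoms += residue("A", 30, [("CA", (7, 0, 1), "C"), ("CB", (7, 0, 1), "C")])
        return StructureModel(atoms)

    def test_cutoff_selects_near_residue_only(self):
        shell = neighbor_shell(self.cluster(), ResidueSelector("A", 10), cutoff=5.0)
        assert [(s.residue_seq, pytest.approx(d)) for s, d in shell] == [(20, 4.0)]

    def test_zero_cutoff_empty(self):
        assert neighbor_shell(self.cluster(), ResidueSelector("A", 10), cutoff=0.0) == []

    def test_huge_cutoff_includes_all_but_sequence_neighbors(self):
        atoms = residue("A", 1, [("CB", (0, 0, 0), "C")])
        atoms += residue("A", 2, [("CB", (1, 0, 0), "C")])
        atoms += residue("A", 3, [("CB", (2, 0, 0), "C")])
        model = StructureModel(atoms)
        shell = neighbor_shell(model, ResidueSelector("A", 2), cutoff=1e6)
        assert shell == []  # only i±1 present, both excluded
        shell = neighbor_shell(model, ResidueSelector("A", 1), cutoff=1e6)
        assert [s.residue_seq for s, _ in shell] == [3]

    def test_membership_monotone_in_cutoff(self):
        model = self.cluster()
        small = neighbor_shell(model, ResidueSelector("A", 10), cutoff=5.0)
        large = neighbor_shell(model, ResidueSelector("A", 10), cutoff=10.0)
        assert {s for s, _ in small} <= {s for s, _ in large}

    def test_avg_shell_distance_is_mean_of_minima(self):
        atoms = residue("A", 1, [("CB", (0, 0, 0), "C")])
        for seq, d in ((10, 3.0), (20, 4.0), (30, 5.0)):
            atoms += residue("A", seq, [("CB", (d, 0, 0), "C")])
        model = StructureModel(atoms)
        partners = [ResidueSelector("A", s) for s in (10, 20, 30)]
        assert avg_shell_distance(model, ResidueSelector("A", 1), partners) == pytest.approx(4.0)
        assert avg_shell_distance(model, ResidueSelector("A", 1), partners[:1]) == pytest.approx(3.0)

    def test_avg_shell_distance_requires_partners(self):
        with pytest.raises(GeometryError):
            avg_shell_distance(self.cluster(), ResidueSelector("A", 10), [])


class TestInterface:
    def protein_plus_ligand(self, ligand_offset):
        atoms = []
        for i in range(1, 11):
            atoms += residue("A", i, [("CA", (i * 3.0, 0, 0), "C"),
                                      ("CB", (i * 3.0, 1.5, 0), "C")])
        for j in range(1, 4):
            atoms += residue("B", j, [("P", (15.0 + j * 0.5, 1.5 + ligand_offset, 0), "P")])
        return StructureModel(atoms)

    def test_only_contacting_residue_detected(self):
        model = self.protein_plus_ligand(4.0)
        iface = interface_residues(model, "B", cutoff=5.0)
        assert {s.residue_seq for s in iface} == {5, 6}

    def test_distant_ligand_gives_empty_set(self):
        model = self.protein_plus_ligand(20.0)
        assert interface_residues(model, "B", cutoff=5.0) == set()

    def test_infinite_cutoff_selects_every_protein_residue(self):
        model = self.protein_plus_ligand(4.0)
        iface = interface_residues(model, "B", cutoff=1e6)
        assert {s.residue_seq for s in iface} == set(range(1, 11))

    def test_absent_ligand_chain_errors(self):
        with pytest.raises(GeometryError):
            interface_residues(self.protein_plus_ligand(4.0), "Z")


class TestBurialProxy:
    def globule_with_tail(self, rng_seed=7):
        rng = np.random.default_rng(rng_seed)
        atoms = []
        for i in range(1, 21):  # compact core
            center = rng.normal(scale=3.0, size=3)
            atoms += residue("A", i, [("CA", center, "C"), ("CB", center + [0.5, 0, 0], "C")])
        atoms += residue("A", 40, [("CA", (40.0, 0, 0), "C"), ("CB", (40.5, 0, 0), "C")])
        return StructureModel(atoms)

    def test_core_residue_more_buried_than_peripheral(self):
        model = self.globule_with_tail()
        core = burial_proxy(model, ResidueSelector("A", 1))
        peripheral = burial_proxy(model, ResidueSelector("A", 40))
        assert core > peripheral
        assert peripheral == 0

    def test_isolated_residue_count_zero(self):
        model = StructureModel(residue("A", 1, [("CB", (0, 0, 0), "C")]))
        assert burial_proxy(model, ResidueSelector("A", 1)) == 0


class TestDdgAndCharge:
    @pytest.mark.parametrize("mean,expected", [
        (4.11, True), (0.41, False), (1.6, False), (1.6001, True), (-0.44, False),
    ])
    def test_destabilizing_strictly_above_threshold(self, mean, expected):
        assert ddg_classify(DdgReplicateSet("v", summary_mean=mean, summary_sd=0.1)) is expected

    @pytest.mark.parametrize("a,b,delta", [
        ("E", "K", 2), ("T", "M", 0), ("R", "H", -1), ("R", "Q", -1),
        ("P", "R", 1), ("D", "E", 0), ("K", "R", 0),
    ])
    def test_formal_charge_delta(self, a, b, delta):
        assert charge_delta(a, b) == delta

    def test_nonstandard_code_rejected(self):
        with pytest.raises(GeometryError):
            charge_delta("X", "K")


def missense(protein, consequence=Consequence.MISSENSE):
    return VariantRecord(patient_id="x", gene="LARS2", transcript="NM_015340.3",
                         cdna_change=f"c.0_{protein}", protein_change=protein,
                         consequence=consequence)


class TestMechanismAssignment:
    def test_interface_takes_precedence_over_charge(self):
        v = missense("p.(Glu638Lys)")
        annotation = ResidueAnnotation(interface={638}, exposed={638})
        verdict = assign_mechanism(v, annotation=annotation)
        assert verdict.label is Mechanism.INTERFACE_INTERACTION

    def test_destabilizing_ddg_gives_stability(self):
        v = missense("p.Thr629Met")
        ddg = DdgReplicateSet("p.Thr629Met", summary_mean=2.56, summary_sd=0.19)
        assert assign_mechanism(v, ddg=ddg).label is Mechanism.STABILITY

    def test_neutral_non_interface_low_ddg_is_nonconclusive(self):
        v = missense("p.(Asn124Ile)")
        ddg = DdgReplicateSet("p.(Asn124Ile)", summary_mean=0.41, summary_sd=0.66)
        assert assign_mechanism(v, ddg=ddg).label is Mechanism.NONCONCLUSIVE

    def test_charge_change_needs_surface_exposure(self):
        v = missense("p.(Arg453Gln)")
        ddg = DdgReplicateSet("x", summary_mean=1.42, summary_sd=0.3)
        buried = ResidueAnnotation(buried={453})
        assert assign_mechanism(v, ddg=ddg, annotation=buried).label is Mechanism.NONCONCLUSIVE
        exposed = ResidueAnnotation(exposed={453})
        assert assign_mechanism(v, ddg=ddg, annotation=exposed).label \
            is Mechanism.ELECTROSTATIC_SURFACE

    def test_proline_in_helix_counts_as_stability_below_threshold(self):
        v = missense("p.(Gln147Pro)")
        ddg = DdgReplicateSet("x", summary_mean=1.49, summary_sd=0.12)
        annotation = ResidueAnnotation(helix={147})
        assert assign_mechanism(v, ddg=ddg, annotation=annotation).label is Mechanism.STABILITY
        # same ΔΔG outside a helix: nonconclusive
        assert assign_mechanism(v, ddg=ddg).label is Mechanism.NONCONCLUSIVE

    def test_truncating_consequences_are_lof(self):
        v = missense("p.(Ser372*)", consequence=Consequence.NONSENSE)
        assert assign_mechanism(v).label is Mechanism.LOF

    def test_unparseable_protein_change_errors(self):
        v = missense(None)
        v.protein_change = "p.?"
        with pytest.raises(Exception):
            assign_mechanism(v)

    def test_table3_effect_column_reproduced(self, table3):
        for row in table3.variants.rows:
            verdict = assign_mechanism(row, ddg=table3.ddg.get(row.protein_change),
                                       annotation=table3.annotation)
            assert verdict.label.value == row.extra["mechanism_label"], row.protein_change


class TestPp3Derivation:
    @pytest.mark.parametrize("label,expected", [
        (Mechanism.STABILITY, "PP3"),
        (Mechanism.ELECTROSTATIC_SURFACE, "PP3"),
        (Mechanism.INTERFACE_INTERACTION, "PP3"),
        (Mechanism.NONCONCLUSIVE, None),
        (Mechanism.LOF, None),
    ])
    def test_only_conclusive_missense_mechanisms_yield_pp3(self, label, expected):
        from hlcur.structure_evidence import MechanismVerdict

        result = pp3_from_structure(MechanismVerdict(label))
        assert (result.base if result else None) == expected


class TestTemplateScreen:
    def test_cutoffs_and_ranking(self):
        candidates = [
            ("good", 0.40, 2.0),
            ("boundary_identity", 0.36, 2.0),
            ("bad_resolution", 0.50, 2.6),
            ("better", 0.55, 2.4),
            ("tie_identity", 0.40, 1.8),
        ]
        accepted = template_screen(candidates)
        assert [c[0] for c in accepted] == ["better", "tie_identity", "good"]

    def test_stricter_resolution_config(self):
        accepted = template_screen([("x", 0.5, 2.45)], max_resolution=2.4)
        assert accepted == []

    def test_invalid_inputs_rejected(self):
        with pytest.raises(GeometryError):
            template_screen([("x", 1.2, 2.0)])
        with pytest.raises(GeometryError):
            template_screen([("x", 0.5, 0.0)])
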