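import numpy as np
import pytest

from rndcensus.io_model import (
    AtomRecord,
    ChainModel,
    ResidueModel,
    RunConfig,
    StructureModel,
    UNASSIGNED,
    ValidationError,
)
from rndcensus.states import (
    ReferenceStateLibrary,
    StateAssigner,
    SubdomainScheme,
    assign_state,
    detect_O_star,
    sidechain_orientation_feature,
    subdomain_displacements,
)
from rndcensus.synthetic import TEMPLATE_RANGES

from conftest import random_rotation


def _shift_residues(model: StructureModel, ranges, delta) -> StructureModel:
    out = model.copy()
    for chain in out.chains:
        for res in chain.residues:
            if any(a <= res.number <= b for a, b in ranges):
                for atom in res.atoms:
                    atom.position = atom.position + np.asarray(delta, float)
    return out


def _rotate_residues_about_centroid(model, ranges, R):
    out = model.copy()
    for chain in out.chains:
        sel = [
            r for r in chain.residues
            if any(a <= r.number <= b for a, b in ranges)
        ]
        centroid = np.mean([r.atoms[0].position for r in sel], axis=0)
        for res in sel:
            for atom in res.atoms:
                atom.position = R @ (atom.position - centroid) + centroid
    return out


class TestAssignState:
    def test_reference_assigns_to_itself(self, default_library):
        a = assign_state(default_library.references["T"], default_library)
        assert a.state_label == "T"
        assert a.rmsd_by_state["T"] == pytest.approx(0.0, abs=1e-9)
        assert a.margin > 0

    def test_noisy_reference_always_recovered(self, default_library):
        """50 seeded σ=0.2 Å draws of the T template all classify as T."""
        ref = default_library.references["T"]
        for seed in range(50):
            rng = np.random.default_rng(seed)
            noisy = ref.copy()
            for _, _, atom in noisy.iter_atoms():
                atom.position = atom.position + rng.normal(0, 0.2, 3)
            a = assign_state(noisy, default_library)
            assert a.state_label == "T"

    def test_equidistant_tie_breaks_by_precedence(self, default_library):
        """A monomer exactly between L and T labels L with the tie flag."""
        base = default_library.references["L"]
        pn1 = TEMPLATE_RANGES["PN1"]
        ref_l = _shift_residues(base, pn1, (4.0, 0, 0))
        ref_t = _shift_residues(base, pn1, (-4.0, 0, 0))
        lib = ReferenceStateLibrary(
            {"L": ref_l, "T": ref_t}, default_library.scheme
        )
        a = assign_state(base, lib)
        assert a.state_label == "L"
        assert "tie" in a.flags
        assert a.rmsd_by_state["L"] == pytest.approx(a.rmsd_by_state["T"], abs=1e-9)

    def test_rigid_invariance(self, default_library):
        mono = default_library.references["O"]
        R = random_rotation(8)
        t = np.array([12.0, -7.0, 3.0])
        a0 = assign_state(mono, default_library)
        a1 = assign_state(mono.transformed(R, t), default_library)
        assert a1.state_label == a0.state_label
        for s in a0.rmsd_by_state:
            assert a1.rmsd_by_state[s] == pytest.approx(
                a0.rmsd_by_state[s], abs=1e-6
            )

    def test_low_coverage_unassigned(self, default_library):
        mono = default_library.references["T"].copy()
        chain = mono.chains[0]
        # drop most core residues
        chain.residues = [r for r in chain.residues if r.number > 25]
        a = assign_state(mono, default_library)
        assert a.state_label == UNASSIGNED
        assert any("coverage" in f for f in a.flags)

    def test_library_needs_two_states(self, default_library):
        with pytest.raises(ValidationError):
            ReferenceStateLibrary(
                {"T": default_library.references["T"]}, default_library.scheme
            )

    def test_separability_error_rate_under_noise(self, default_library):
        """Inter-reference porter RMSD ≥ 2 Å and σ·√6 < Δ/4 ⇒ error < 1%."""
        sigma = 0.2  # σ·√6 ≈ 0.49 < 2/4
        assigner = StateAssigner(default_library)
        wrong = total = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            for state in ("L", "T", "O"):
                ref = default_library.references[state]
                noisy = ref.copy()
                for _, _, atom in noisy.iter_atoms():
                    atom.position = atom.position + rng.normal(0, sigma, 3)
                total += 1
                wrong += assigner.assign(noisy).state_label != state
        assert wrong / total < 0.01


class TestSubdomainDisplacements:
    def test_self_comparison_is_zero(self, default_library):
        ref = default_library.references["T"]
        d = subdomain_displacements(ref, ref, default_library.scheme)
        for name, disp in d.items():
            assert disp.translation == pytest.approx(0.0, abs=1e-9)
            assert disp.rotation_angle == pytest.approx(0.0, abs=1e-6)

    def test_pure_translation_recovered(self, default_library):
        ref = default_library.references["L"]
        moved = _shift_residues(ref, TEMPLATE_RANGES["PN1"], (0, 0, 2.0))
        d = subdomain_displacements(moved, ref, default_library.scheme)
        assert d["PN1"].translation == pytest.approx(2.0, abs=1e-6)
        for other in ("PN2", "PC1", "PC2", "TM2"):
            assert d[other].translation == pytest.approx(0.0, abs=1e-6)

    def test_pure_rotation_recovered(self, default_library):
        ref = default_library.references["L"]
        th = np.deg2rad(10.0)
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        moved = _rotate_residues_about_centroid(ref, TEMPLATE_RANGES["PN2"], R)
        d = subdomain_displacements(moved, ref, default_library.scheme)
        assert d["PN2"].rotation_angle == pytest.approx(10.0, abs=1e-6)
        assert d["PN2"].translation == pytest.approx(0.0, abs=1e-6)

    def test_missing_subdomain_flagged_others_reported(self, default_library):
        ref = default_library.references["L"]
        truncated = ref.copy()
        chain = truncated.chains[0]
        chain.residues = [
            r for r in chain.residues
            if not (41 <= r.number <= 52)  # remove PN1
        ]
        d = subdomain_displacements(truncated, ref, default_library.scheme)
        assert d["PN1"].missing
        assert not d["PN2"].missing


class TestDetectOStar:
    def test_open_pore_is_o(self, o_star_library):
        is_star, bn = detect_O_star(
            o_star_library.references["O"], o_star_library.scheme, RunConfig()
        )
        assert not is_star
        assert bn == pytest.approx(2.5, abs=0.8)  # within one grid spacing

    def test_constricted_pore_is_o_star(self, o_star_library):
        is_star, bn = detect_O_star(
            o_star_library.references["O*"], o_star_library.scheme, RunConfig()
        )
        assert is_star
        assert bn < 1.5

    def test_missing_seed_residues_named(self, o_star_library):
        mono = o_star_library.references["O"].copy()
        chain = mono.chains[0]
        chain.residues = [r for r in chain.residues if r.number not in (89, 90)]
        with pytest.raises(ValidationError, match="89"):
            detect_O_star(mono, o_star_library.scheme, RunConfig())

    def test_assigner_relabels_o_star(self, o_star_library):
        assigner = StateAssigner(o_star_library)
        assert assigner.check_o_star
        a = assigner.assign(o_star_library.references["O*"])
        assert a.state_label == "O*"
        assert "o_star_checked" in a.flags
        b = assigner.assign(o_star_library.references["O"])
        assert b.state_label == "O"

    def test_no_o_star_check_without_reference(self, default_library):
        assigner = StateAssigner(default_library)
        assert not assigner.check_o_star
        a = assigner.assign(default_library.references["O"])
        assert a.state_label == "O"
        assert a.bottleneck is None


def _triad_monomer(d_asn=3.0, d_asp=6.0, truncate_lysine=False):
    def residue(num, name, atoms):
        return ResidueModel(
            num, name,
            [AtomRecord(n, e, p) for n, e, p in atoms],
        )

    lys_atoms = [("CB", "C", (0.0, 0.0, -1.5))]
    if not truncate_lysine:
        lys_atoms.append(("NZ", "N", (0.0, 0.0, 0.0)))
    chain = ChainModel(
        "A",
        [
            residue(946, "LYS", lys_atoms),
            residue(947, "ASN", [("OD1", "O", (d_asn, 0.0, 0.0)),
                                 ("ND2", "N", (d_asn + 1.0, 0.0, 0.0))]),
            residue(410, "ASP", [("OD1", "O", (0.0, d_asp, 0.0)),
                                 ("OD2", "O", (0.0, d_asp + 0.5, 0.0))]),
            residue(411, "ASP", [("OD1", "O", (0.0, -d_asp, 0.0)),
                                 ("OD2", "O", (0.0, -d_asp - 0.5, 0.0))]),
        ],
    )
    return StructureModel("triad", [chain])


class TestSidechainOrientation:
    def test_flipped_towards_asparagine(self):
        f = sidechain_orientation_feature(_triad_monomer(3.0, 6.0), 946, 947, (410, 411))
        assert f.flipped is True
        assert f.d_to_asn == pytest.approx(3.0)
        assert f.d_to_asp_min == pytest.approx(6.0)

    def test_equidistant_is_not_flipped(self):
        f = sidechain_orientation_feature(_triad_monomer(5.0, 5.0), 946, 947, (410, 411))
        assert f.flipped is False  # strict inequality

    def test_truncated_side_chain_reports_missing(self):
        f = sidechain_orientation_feature(
            _triad_monomer(truncate_lysine=True), 946, 947, (410, 411)
        )
        assert f.missing
        assert f.flipped is None


class TestSubdomainScheme:
    def test_core_porter_overlap_rejected(self):
        with pytest.raises(ValidationError):
            SubdomainScheme(
                subdomains={"PN1": ((10, 20),)}, core=((15, 30),)
            )

    def test_shipped_schemes_parse(self):
        from importlib.resources import files

        for name in ("acrb_scheme.yaml", "oqxb_scheme.yaml"):
            path = files("rndcensus.data").joinpath(name)
            scheme = SubdomainScheme.from_yaml(str(path))
            assert set(scheme.subdomains) >= {"PN1", "PN2", "PC1", "PC2", "TM2"}
            assert scheme.proton_lysine is not None
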