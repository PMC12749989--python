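"""Conformational-state assignment of extracted protomers.

A monomer is classified L, T, O or O* by superposing it onto each reference
protomer over a core anchor (the transmembrane domain) and ranking the
states by porter-domain Cα RMSD — the porter subdomains (PN1, PN2, PC1,
PC2) are what move between states, so whole-chain RMSD would dilute the
signal.  An O-architecture winner is optionally re-examined with the
channel module: if its exit channel is constricted below a threshold
(default 1.5 Å) it is relabelled O*, the open-architecture/closed-exit
state.  Side-chain features of the proton-translocation network (the
lysine flip towards the neighbouring asparagine and away from the
titratable aspartates) are reported as an auxiliary descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .channels import build_clearance_grid, find_channel
from .io_model import (
    STATE_PRECEDENCE,
    STATES,
    UNASSIGNED,
    ChainModel,
    RunConfig,
    StructureModel,
    ValidationError,
)
from .symmetry import CorrespondenceError, kabsch

PORTER_SUBDOMAINS = ("PN1", "PN2", "PC1", "PC2")

Ranges = tuple[tuple[int, int], ...]


def _normalize_ranges(ranges) -> Ranges:
    return tuple((int(a), int(b)) for a, b in ranges)


def residues_in(ranges: Ranges, numbers) -> list[int]:
    """Residue numbers (sorted) falling inside any of the inclusive ranges."""
    out = [
        n for n in numbers if any(a <= n <= b for a, b in ranges)
    ]
    return sorted(out)


@dataclass
class SubdomainScheme:
    """Residue-range curation of the subdomain architecture.

    ``subdomains`` holds the porter subdomains (PN1, PN2, PC1, PC2) and TM2;
    ``core`` is the superposition anchor (disjoint from the porter
    subdomains).  Shipped AcrB/OqxB schemes are curated approximations, not
    ground truth, and are meant to be edited for a given numbering.
    """

    subdomains: dict[str, Ranges]
    core: Ranges
    exit_seed_residues: tuple[int, ...] = ()
    proton_lysine: int | None = None
    proton_asparagine: int | None = None
    proton_aspartates: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.subdomains = {
            k: _normalize_ranges(v) for k, v in self.subdomains.items()
        }
        self.core = _normalize_ranges(self.core)
        self.exit_seed_residues = tuple(int(r) for r in self.exit_seed_residues)
        self.proton_aspartates = tuple(int(r) for r in self.proton_aspartates)
        for name in PORTER_SUBDOMAINS:
            ranges = self.subdomains.get(name, ())
            for a, b in ranges:
                for ca, cb in self.core:
                    if a <= cb and ca <= b:
                        raise ValidationError(
                            f"core range ({ca},{cb}) overlaps porter "
                            f"subdomain {name} range ({a},{b})"
                        )

    @property
    def porter_ranges(self) -> Ranges:
        out: list[tuple[int, int]] = []
        for name in PORTER_SUBDOMAINS:
            out.extend(self.subdomains.get(name, ()))
        return tuple(out)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SubdomainScheme":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        subs = {k: v for k, v in data.get("subdomains", {}).items()}
        return cls(
            subdomains=subs,
            core=data["core"],
            exit_seed_residues=tuple(data.get("exit_seed_residues", ())),
            proton_lysine=data.get("proton_lysine"),
            proton_asparagine=data.get("proton_asparagine"),
            proton_aspartates=tuple(data.get("proton_aspartates", ())),
        )


@dataclass
class ReferenceStateLibrary:
    """state label → (monomer reference model, source accession text)."""

    references: dict[str, StructureModel]
    scheme: SubdomainScheme
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.references) < 2:
            raise ValidationError("a reference library needs ≥2 distinct states")
        bad = [s for s in self.references if s not in STATES]
        if bad:
            raise ValidationError(f"unknown reference states {bad}")

    @property
    def states(self) -> list[str]:
        return sorted(self.references, key=STATE_PRECEDENCE.__getitem__)


@dataclass
class ParticleAssignment:
    """State call for one extracted monomer."""

    particle_id: str
    copy_index: int
    state_label: str
    rmsd_by_state: dict[str, float] = field(default_factory=dict)
    margin: float = 0.0
    flags: list[str] = field(default_factory=list)
    bottleneck: float | None = None


@dataclass
class SubdomainDisplacement:
    translation: float        # Å, centroid motion
    rotation_angle: float     # degrees
    n_atoms: int
    missing: bool = False


@dataclass
class SidechainFeature:
    d_to_asn: float | None
    d_to_asp_min: float | None
    flipped: bool | None
    missing: bool = False
    reason: str = ""


def _single_chain(monomer: StructureModel) -> ChainModel:
    if len(monomer.chains) != 1:
        raise ValidationError(
            f"expected a single-chain monomer, got {len(monomer.chains)} chains"
        )
    return monomer.chains[0]


def _coords_for(
    ca_map: Mapping[int, np.ndarray], resnums: Sequence[int]
) -> np.ndarray:
    return np.array([ca_map[n] for n in resnums])


def _shared_in_ranges(
    a: Mapping[int, np.ndarray], b: Mapping[int, np.ndarray], ranges: Ranges
) -> list[int]:
    return residues_in(ranges, set(a) & set(b))


def subdomain_displacements(
    monomer: StructureModel,
    reference: StructureModel,
    scheme: SubdomainScheme,
) -> dict[str, SubdomainDisplacement]:
    """Per-subdomain rigid-body displacement of a monomer vs a reference.

    After core superposition onto the reference, each subdomain's Cα set is
    fitted with its own Kabsch transform; the reported translation is the
    centroid motion and the rotation angle comes from the trace formula
    (clamped).  A subdomain absent from either model is flagged missing;
    the others are still reported.
    """
    mon = _single_chain(monomer).ca_map()
    ref = _single_chain(reference).ca_map()
    core_shared = _shared_in_ranges(mon, ref, scheme.core)
    if len(core_shared) < 3:
        raise CorrespondenceError(
            f"only {len(core_shared)} shared core residues; need ≥3"
        )
    tf, _ = kabsch(_coords_for(mon, core_shared), _coords_for(ref, core_shared))
    out: dict[str, SubdomainDisplacement] = {}
    names = [n for n in (*PORTER_SUBDOMAINS, "TM2") if n in scheme.subdomains]
    for name in names:
        shared = _shared_in_ranges(mon, ref, scheme.subdomains[name])
        if len(shared) < 3:
            out[name] = SubdomainDisplacement(np.nan, np.nan, len(shared), missing=True)
            continue
        P = tf.apply(_coords_for(mon, shared))
        Q = _coords_for(ref, shared)
        translation = float(np.linalg.norm(P.mean(axis=0) - Q.mean(axis=0)))
        sub_tf, _ = kabsch(P, Q)
        R = sub_tf.rotation
        cos_th = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
        # sine from the antisymmetric part: exact near 0°, unlike arccos
        v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        sin_th = np.linalg.norm(v) / 2.0
        angle = float(np.degrees(np.arctan2(sin_th, cos_th)))
        out[name] = SubdomainDisplacement(translation, angle, len(shared))
    return out


def detect_O_star(
    monomer: StructureModel,
    scheme: SubdomainScheme,
    config: RunConfig | None = None,
) -> tuple[bool, float]:
    """Closed-exit-channel check distinguishing O* from O.

    Runs the maximin channel search from the centroid of the exit-channel
    seed residues to the exterior; the monomer is O* when the bottleneck
    radius is below ``config.o_star_threshold`` (default 1.5 Å, motivated
    by the 1.1–1.5 Å closed-channel range) or when no path exists.
    """
    config = config or RunConfig()
    chain = _single_chain(monomer)
    ca = chain.ca_map()
    missing = [r for r in scheme.exit_seed_residues if r not in ca]
    if not scheme.exit_seed_residues:
        raise ValidationError("scheme has no exit-channel seed residues")
    if missing:
        raise ValidationError(
            f"exit-channel seed residues missing from monomer: {missing}"
        )
    seed = np.mean([ca[r] for r in scheme.exit_seed_residues], axis=0)
    grid = build_clearance_grid(
        monomer,
        spacing=config.grid_spacing,
        padding=config.grid_padding,
        probe_radius=config.probe_radius,
    )
    result = find_channel(grid, seed, snap_radius=2.0)
    if not result.reached_exterior:
        return True, result.bottleneck_radius
    return result.bottleneck_radius < config.o_star_threshold, result.bottleneck_radius


def sidechain_orientation_feature(
    monomer: StructureModel,
    lysine: int,
    asparagine: int,
    aspartates: Sequence[int],
) -> SidechainFeature:
    """Proton-network lysine orientation: flipped towards the asparagine?

    Measures the lysine terminal nitrogen (NZ) distance to (i) the
    asparagine side-chain amide atoms (min of OD1/ND2) and (ii) the nearest
    aspartate carboxylate oxygen (OD1/OD2).  ``flipped`` is the strict
    inequality d_to_asn < d_to_asp_min.  Truncated side chains yield a
    missing-feature result, not an exception.
    """
    chain = _single_chain(monomer)
    lys = chain.residue(lysine)
    asn = chain.residue(asparagine)
    if lys is None or asn is None:
        return SidechainFeature(None, None, None, True, "residue absent")
    nz = lys.atom("NZ")
    if nz is None:
        return SidechainFeature(None, None, None, True, "lysine NZ absent")
    asn_atoms = [a for n in ("OD1", "ND2") if (a := asn.atom(n)) is not None]
    if not asn_atoms:
        return SidechainFeature(None, None, None, True, "asparagine amide absent")
    d_asn = min(float(np.linalg.norm(nz.position - a.position)) for a in asn_atoms)
    asp_dists = []
    for resnum in aspartates:
        asp = chain.residue(resnum)
        if asp is None:
            continue
        for name in ("OD1", "OD2"):
            a = asp.atom(name)
            if a is not None:
                asp_dists.append(float(np.linalg.norm(nz.position - a.position)))
    if not asp_dists:
        return SidechainFeature(d_asn, None, None, True, "aspartate carboxylates absent")
    d_asp = min(asp_dists)
    return SidechainFeature(d_asn, d_asp, d_asn < d_asp)


class StateAssigner:
    """Classifier holding a reference library, scheme and configuration.

    Precomputes the reference coordinate sets so that assigning many
    monomers (symmetry-expanded particle stacks) is cheap.
    """

    def __init__(
        self,
        library: ReferenceStateLibrary,
        config: RunConfig | None = None,
        check_o_star: bool | None = None,
        classification: str = "porter_ca",
    ) -> None:
        if classification not in ("porter_ca", "whole_chain"):
            raise ValidationError(
                "classification must be 'porter_ca' or 'whole_chain'"
            )
        self.library = library
        self.config = config or RunConfig()
        self.classification = classification
        scheme = library.scheme
        # O* is an override of O only, and needs an O* reference to be
        # meaningful: default to checking only when the library contains one.
        if check_o_star is None:
            check_o_star = "O*" in library.references and bool(
                scheme.exit_seed_residues
            )
        self.check_o_star = check_o_star
        self._refs: dict[str, dict] = {}
        for state, ref in library.references.items():
            ca = _single_chain(ref).ca_map()
            core_nums = residues_in(scheme.core, ca)
            porter_nums = residues_in(scheme.porter_ranges, ca)
            self._refs[state] = {
                "ca": ca,
                "core": core_nums,
                "porter": porter_nums,
                "all": sorted(ca),
            }

    def assign(
        self, monomer: StructureModel, particle_id: str = "", copy_index: int = 0
    ) -> ParticleAssignment:
        """Classify one extracted monomer; see module docstring for the rule."""
        scheme = self.library.scheme
        mon_ca = _single_chain(monomer).ca_map()
        rmsds: dict[str, float] = {}
        flags: list[str] = []
        for state in self.library.states:
            ref = self._refs[state]
            core_shared = [n for n in ref["core"] if n in mon_ca]
            if len(ref["core"]) == 0 or (
                len(core_shared) / max(len(ref["core"]), 1)
                < self.config.min_coverage
            ):
                return ParticleAssignment(
                    particle_id,
                    copy_index,
                    UNASSIGNED,
                    {},
                    0.0,
                    [
                        f"coverage below {self.config.min_coverage:.0%} of the "
                        f"{state} reference core"
                    ],
                )
            if len(core_shared) < 3:
                return ParticleAssignment(
                    particle_id, copy_index, UNASSIGNED, {}, 0.0,
                    ["fewer than 3 shared core residues"],
                )
            tf, _ = kabsch(
                _coords_for(mon_ca, core_shared),
                _coords_for(ref["ca"], core_shared),
            )
            target_nums = (
                ref["porter"] if self.classification == "porter_ca" else ref["all"]
            )
            shared = [n for n in target_nums if n in mon_ca]
            if len(shared) < 3:
                return ParticleAssignment(
                    particle_id, copy_index, UNASSIGNED, {}, 0.0,
                    ["fewer than 3 shared classification residues"],
                )
            P = tf.apply(_coords_for(mon_ca, shared))
            Q = _coords_for(ref["ca"], shared)
            rmsds[state] = float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))
        # exact numerical ties (within 1e-9 Å) break by state precedence
        rmin = min(rmsds.values())
        exact_ties = sorted(
            (s for s in rmsds if rmsds[s] - rmin <= 1e-9),
            key=STATE_PRECEDENCE.__getitem__,
        )
        winner = exact_ties[0]
        others = sorted(r for s, r in rmsds.items() if s != winner)
        margin = (others[0] - rmsds[winner]) if others else np.inf
        if margin < self.config.tie_margin:
            flags.append("tie")
        bottleneck = None
        if winner in ("O", "O*") and self.check_o_star:
            is_o_star, bottleneck = detect_O_star(monomer, scheme, self.config)
            flags.append("o_star_checked")
            winner = "O*" if is_o_star else "O"
        return ParticleAssignment(
            particle_id, copy_index, winner, rmsds, float(margin), flags, bottleneck
        )


def assign_state(
    monomer: StructureModel,
    library: ReferenceStateLibrary,
    config: RunConfig | None = None,
    particle_id: str = "",
    copy_index: int = 0,
    **kwargs,
) -> ParticleAssignment:
    """Functional wrapper over :class:`StateAssigner` for one monomer."""
    return StateAssigner(library, config, **kwargs).assign(
        monomer, particle_id, copy_index
    )
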