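"""Synthetic data: reference-state template libraries, trimer particle sets
with known composition distributions, label corruption, and channel fixtures.

The generator stands in for raw cryo-EM particle stacks.  Templates are
abstract labelled point clouds (one Cα pseudo-atom per residue) with the
features that matter for the pipeline: a shared core anchor, porter
subdomains displaced rigidly between states (magnitudes 3–6 Å so that
inter-state porter RMSD is ≥ 2 Å), and — when the O*/O distinction is in
play — an engineered exit-pore assembly whose clear radius is wide (open O)
or constricted below 1.5 Å (closed O*).  Everything is a pure function of
(spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .census import canonicalize_name, parse_composition
from .io_model import (
    STATES,
    LabelTable,
    StructureModel,
    ValidationError,
    chain_from_arrays,
)
from .states import ReferenceStateLibrary, SubdomainScheme

logger = logging.getLogger("rndcensus")

# Template residue layout (one Cα per residue).  Core = TMD stand-in,
# disjoint from the porter subdomains; pore pseudo-atoms (when present)
# are numbered from 200.
TEMPLATE_RANGES: dict[str, tuple[tuple[int, int], ...]] = {
    "core": ((1, 30),),
    "TM2": ((31, 40),),
    "PN1": ((41, 52),),
    "PN2": ((53, 64),),
    "PC1": ((65, 76),),
    "PC2": ((77, 88),),
}
EXIT_SEED_RESIDUES = (89, 90)

#: Rigid subdomain translations (Å) defining each state relative to the base
#: cloud.  L is the base; T packs PN2 down and PC2 sideways; O shifts PN1,
#: moves PC2 towards PC1 and TM2 upward.  O* shares O's architecture exactly.
STATE_SHIFTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "L": {},
    "T": {"PN2": (0.0, 0.0, -4.0), "PC2": (0.0, 3.0, 0.0)},
    "O": {
        "PN1": (3.0, 3.0, 0.0),
        "PC2": (0.0, -3.0, 0.0),
        "TM2": (0.0, 0.0, 3.0),
    },
}
STATE_SHIFTS["O*"] = STATE_SHIFTS["O"]

_SUBDOMAIN_CENTERS = {
    "core": (25.0, 0.0, -8.0),
    "TM2": (22.0, 4.0, -4.0),
    "PN1": (25.0, 5.0, 8.0),
    "PN2": (28.0, -4.0, 8.0),
    "PC1": (21.0, -5.0, 12.0),
    "PC2": (29.0, 3.0, 13.0),
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    ``composition_distribution`` maps composition names (aliases accepted)
    to probabilities summing to 1; ``label_confusion`` is a row-stochastic
    matrix over the states of ``confusion_states``.
    """

    composition_distribution: dict[str, float] = field(
        default_factory=lambda: {"LTO": 1.0}
    )
    n_particles: int = 100
    coord_noise_sd: float = 0.0          # Å, i.i.d. per coordinate
    label_confusion: np.ndarray | None = None
    confusion_states: tuple[str, ...] = ("L", "T", "O")
    seed: int = 0
    subdomain_scatter: float = 2.5       # Å, cloud width per subdomain
    pore_clear_radius: float = 2.5       # Å, open exit pore (O)
    o_star_clear_radius: float = 1.2     # Å, constricted pore (O*)
    with_exit_pore: bool | None = None   # default: only when O* is in play

    def __post_init__(self) -> None:
        canon: dict[str, float] = {}
        for k, v in self.composition_distribution.items():
            name = canonicalize_name(k)
            canon[name] = canon.get(name, 0.0) + float(v)
        self.composition_distribution = canon
        total = sum(self.composition_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"composition probabilities sum to {total}, not 1"
            )
        if self.n_particles < 1:
            raise ValidationError("n_particles must be ≥ 1")
        if self.coord_noise_sd < 0:
            raise ValidationError("coord_noise_sd must be ≥ 0")
        if self.label_confusion is not None:
            M = np.asarray(self.label_confusion, float)
            k = len(self.confusion_states)
            if M.shape != (k, k):
                raise ValidationError(
                    f"confusion matrix must be {k}×{k} for states "
                    f"{self.confusion_states}"
                )
            if not np.allclose(M.sum(axis=1), 1.0, atol=1e-9):
                raise ValidationError("confusion rows must sum to 1")
            self.label_confusion = M

    @property
    def required_states(self) -> list[str]:
        states: set[str] = set()
        for name in self.composition_distribution:
            states.update(parse_composition(name))
        return sorted(states, key=STATES.index)


def template_scheme() -> SubdomainScheme:
    """The subdomain scheme matching the synthetic template layout."""
    return SubdomainScheme(
        subdomains={k: v for k, v in TEMPLATE_RANGES.items() if k != "core"},
        core=TEMPLATE_RANGES["core"],
        exit_seed_residues=EXIT_SEED_RESIDUES,
    )


def _pore_assembly(clear_radius: float, rng: np.random.Generator) -> np.ndarray:
    """Sealed spherical shell around the exit seed with one tubular exit.

    Returns pseudo-atom positions (carbon radii assumed, r = 1.7 Å).  The
    tube points along +z with wall atoms at ρ = clear_radius + 1.7, so the
    clearance on the tube axis is the requested clear radius.
    """
    r_c = 1.7
    center = np.array(_SUBDOMAIN_CENTERS["PN1"]) + np.array([0.0, 0.0, 14.0])
    shell_r = 6.0
    pts = []
    # shell: quasi-uniform points, drop a cap around +z where the tube exits
    n_shell = 360
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for i in range(n_shell):
        z = 1.0 - 2.0 * (i + 0.5) / n_shell
        rho = np.sqrt(max(0.0, 1.0 - z * z))
        th = golden * i
        p = shell_r * np.array([rho * np.cos(th), rho * np.sin(th), z])
        # leave the exit aperture open
        if z > 0 and np.hypot(p[0], p[1]) < clear_radius + r_c + 1.0:
            continue
        pts.append(center + p)
    # tube: rings from the shell surface outward
    wall_rho = clear_radius + r_c
    n_ring = max(10, int(np.ceil(2 * np.pi * wall_rho / 1.0)))
    ring_angles = 2 * np.pi * np.arange(n_ring) / n_ring
    z0 = np.sqrt(max(shell_r**2 - wall_rho**2, 1.0))
    for dz in np.arange(z0 - 1.0, z0 + 7.0, 1.0):
        for th in ring_angles:
            pts.append(
                center
                + np.array([wall_rho * np.cos(th), wall_rho * np.sin(th), dz])
            )
    return np.array(pts)


def make_reference_library(spec: SyntheticSpec) -> ReferenceStateLibrary:
    """Build the synthetic L/T/O(/O*) reference templates.

    The base cloud is drawn once (seeded); each state applies its rigid
    subdomain shifts, so the core is identical across states and O/O*
    differ only by the pore constriction atoms.  Deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    base: dict[int, np.ndarray] = {}
    for name, ranges in TEMPLATE_RANGES.items():
        center = np.array(_SUBDOMAIN_CENTERS[name])
        for a, b in ranges:
            for n in range(a, b + 1):
                base[n] = center + rng.normal(0, spec.subdomain_scatter, 3)
    # exit seed residues flank the pore-assembly cavity diametrically so
    # their centroid falls in open space inside it
    seed_center = np.array(_SUBDOMAIN_CENTERS["PN1"]) + np.array([0.0, 0.0, 14.0])
    base[EXIT_SEED_RESIDUES[0]] = seed_center + np.array([6.0, 0.0, -2.0])
    base[EXIT_SEED_RESIDUES[1]] = seed_center + np.array([-6.0, 0.0, -2.0])

    states = set(spec.required_states) | {"L", "T", "O"}
    with_pore = spec.with_exit_pore
    if with_pore is None:
        with_pore = "O*" in states
    refs: dict[str, StructureModel] = {}
    for state in sorted(states, key=STATES.index):
        coords = dict(base)
        for sub, shift in STATE_SHIFTS[state].items():
            for a, b in TEMPLATE_RANGES[sub]:
                for n in range(a, b + 1):
                    coords[n] = coords[n] + np.array(shift)
        resnums = sorted(coords)
        positions = np.array([coords[n] for n in resnums])
        chain = chain_from_arrays("A", resnums, positions)
        if with_pore and state in ("O", "O*"):
            radius = (
                spec.o_star_clear_radius if state == "O*" else spec.pore_clear_radius
            )
            pore = _pore_assembly(radius, rng)
            pore_chain = chain_from_arrays(
                "A", range(200, 200 + len(pore)), pore, residue_name="PSE"
            )
            chain.residues.extend(pore_chain.residues)
        refs[state] = StructureModel(f"template_{state}", [chain])
    lib = ReferenceStateLibrary(
        refs, template_scheme(), {s: "synthetic template" for s in refs}
    )
    _check_separability(lib, spec)
    return lib


def _check_separability(lib: ReferenceStateLibrary, spec: SyntheticSpec) -> None:
    porter = lib.scheme.porter_ranges
    expected_noise_rmsd = spec.coord_noise_sd * np.sqrt(3.0)
    states = lib.states
    for i, a in enumerate(states):
        for b in states[i + 1 :]:
            if {a, b} == {"O", "O*"}:
                continue  # identical porter architecture by construction
            ca_a = lib.references[a].chains[0].ca_map()
            ca_b = lib.references[b].chains[0].ca_map()
            from .states import residues_in

            shared = residues_in(porter, set(ca_a) & set(ca_b))
            d = np.array([ca_a[n] for n in shared]) - np.array(
                [ca_b[n] for n in shared]
            )
            rmsd = float(np.sqrt(np.mean(np.sum(d**2, axis=1))))
            if rmsd < 4.0 * expected_noise_rmsd:
                logger.warning(
                    "states %s/%s porter RMSD %.2f Å < 4× expected noise RMSD "
                    "%.2f Å: not separable at this noise",
                    a,
                    b,
                    rmsd,
                    expected_noise_rmsd,
                )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _rot_z(angle_deg: float) -> np.ndarray:
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def iter_simulated_particles(
    spec: SyntheticSpec, library: ReferenceStateLibrary
) -> Iterator[tuple[StructureModel, list[tuple[str, int, str]]]]:
    """Stream (trimer, truth rows) pairs; memory-light for large n.

    Per particle: a composition is drawn from the distribution, its three
    states are dealt to copy indices in random order, each state template is
    placed at 0°/120°/240° about a common z-axis, a random global rigid
    transform is applied, and i.i.d. Gaussian coordinate noise is added.
    """
    comps = sorted(spec.composition_distribution)
    probs = np.array([spec.composition_distribution[c] for c in comps])
    for name in comps:
        for s in parse_composition(name):
            if s not in library.references:
                raise ValidationError(
                    f"composition {name!r} references state {s!r} absent "
                    f"from the library"
                )
    # template coordinate arrays per state (file order)
    tmpl: dict[str, tuple[np.ndarray, list[int], list[str]]] = {}
    for state, ref in library.references.items():
        chain = ref.chains[0]
        nums = [r.number for r in chain.residues]
        names = [r.name for r in chain.residues]
        coords = np.array([r.atoms[0].position for r in chain.residues])
        tmpl[state] = (coords, nums, names)

    rng = np.random.default_rng(spec.seed)
    n_digits = len(str(spec.n_particles))
    for i in range(spec.n_particles):
        comp = comps[rng.choice(len(comps), p=probs)]
        labels = list(parse_composition(comp))
        rng.shuffle(labels)
        R_g = _random_rotation(rng)
        t_g = rng.uniform(-20.0, 20.0, 3)
        chains = []
        pid = f"p{i:0{n_digits}d}"
        truth = []
        for k, (chain_id, state) in enumerate(zip("ABC", labels)):
            coords, nums, res_names = tmpl[state]
            placed = coords @ _rot_z(120.0 * k).T
            placed = placed @ R_g.T + t_g
            if spec.coord_noise_sd > 0:
                placed = placed + rng.normal(0, spec.coord_noise_sd, placed.shape)
            ch = chain_from_arrays(chain_id, nums, placed)
            for res, name in zip(ch.residues, res_names):
                res.name = name
            chains.append(ch)
            truth.append((pid, k, state))
        yield StructureModel(pid, chains), truth


def simulate_particles(
    spec: SyntheticSpec, library: ReferenceStateLibrary
) -> tuple[list[StructureModel], LabelTable]:
    """Materialise the particle set and its ground-truth label table."""
    structures = []
    rows: list[tuple[str, int, str]] = []
    for st, truth in iter_simulated_particles(spec, library):
        structures.append(st)
        rows.extend(truth)
    return structures, LabelTable.from_rows(rows)


def corrupt_labels(
    truth: LabelTable,
    confusion: np.ndarray,
    states: tuple[str, ...] = ("L", "T", "O"),
    seed: int = 0,
) -> LabelTable:
    """Resample each label independently by its confusion-matrix row."""
    M = np.asarray(confusion, float)
    if M.shape != (len(states), len(states)):
        raise ValidationError("confusion shape must match the state tuple")
    if not np.allclose(M.sum(axis=1), 1.0, atol=1e-9):
        raise ValidationError("confusion rows must sum to 1")
    idx = {s: i for i, s in enumerate(states)}
    rng = np.random.default_rng(seed)
    df = truth.df.copy()
    new_labels = []
    for lab in df["state_label"]:
        if lab not in idx:
            new_labels.append(lab)  # UNASSIGNED or out-of-matrix states pass through
            continue
        new_labels.append(states[rng.choice(len(states), p=M[idx[lab]])])
    df["state_label"] = new_labels
    return LabelTable(df)


def sample_labels(
    spec: SyntheticSpec,
) -> LabelTable:
    """Draw a truth label table directly (no coordinates) — census-level tests."""
    comps = sorted(spec.composition_distribution)
    probs = np.array([spec.composition_distribution[c] for c in comps])
    rng = np.random.default_rng(spec.seed)
    rows = []
    n_digits = len(str(spec.n_particles))
    for i in range(spec.n_particles):
        comp = comps[rng.choice(len(comps), p=probs)]
        labels = list(parse_composition(comp))
        rng.shuffle(labels)
        pid = f"p{i:0{n_digits}d}"
        rows.extend((pid, k, s) for k, s in enumerate(labels))
    return LabelTable.from_rows(rows)


# ---------------------------------------------------------------------------
# Channel fixtures
# ---------------------------------------------------------------------------

def make_channel_fixture(
    kind: str,
    radius: float = 3.0,
    radius_end: float | None = None,
    spacing_warn: float = 0.8,
) -> tuple[StructureModel, np.ndarray]:
    """Atom slab with an engineered pore of known clear radius.

    Returns (structure, seed point).  ``cylinder``: straight pore of clear
    radius ``radius`` along z.  ``cone``: radius varies linearly from
    ``radius`` (bottom) to ``radius_end`` (top); the bottleneck is the
    analytic minimum.  ``sealed``: interior cavity with no exit.  Atoms are
    carbon pseudo-atoms (r_vdw = 1.7 Å).
    """
    r_c = 1.7
    if kind not in ("cylinder", "cone", "sealed"):
        raise ValidationError(f"unknown fixture kind {kind!r}")
    if kind != "sealed":
        if radius <= 0:
            raise ValidationError("pore radius must be > 0 for open fixtures")
        if radius < spacing_warn:
            logger.warning(
                "pore radius %.2f Å below grid spacing %.2f Å: poorly resolvable",
                radius,
                spacing_warn,
            )
    half = 9.0
    lattice = np.arange(-half, half + 1e-9, 1.2)
    zs = np.arange(-5.0, 5.0 + 1e-9, 1.2)
    pts = []
    if kind == "cone":
        # seal the wide (bottom) end so the only exit is the narrow top
        for z in (-7.4, -6.2):
            for x in lattice:
                for y in lattice:
                    pts.append((x, y, z))

    def wall_radius(z: float) -> float:
        if kind == "cylinder":
            return radius + r_c
        if kind == "cone":
            r2 = radius_end if radius_end is not None else radius
            frac = (z + 5.0) / 10.0
            return (radius + frac * (r2 - radius)) + r_c
        return 0.0

    for z in zs:
        wr = wall_radius(z)
        for x in lattice:
            for y in lattice:
                rho = np.hypot(x, y)
                if kind == "sealed":
                    if np.sqrt(x * x + y * y + z * z) < 3.5:
                        continue  # interior cavity
                    pts.append((x, y, z))
                elif rho >= wr + 0.3:
                    pts.append((x, y, z))
        if kind != "sealed":
            # explicit wall ring at the exact design radius
            n_ring = max(12, int(np.ceil(2 * np.pi * wr / 0.9)))
            for th in 2 * np.pi * np.arange(n_ring) / n_ring:
                pts.append((wr * np.cos(th), wr * np.sin(th), z))
    coords = np.array(pts)
    chain = chain_from_arrays("A", range(1, len(coords) + 1), coords)
    # cone seed sits in the wide lower section, clear of the sealing plates
    seed = np.array([0.0, 0.0, -2.0]) if kind == "cone" else np.zeros(3)
    return StructureModel(f"fixture_{kind}", [chain]), seed
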