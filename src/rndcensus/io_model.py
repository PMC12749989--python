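"""Domain types and readers/writers for structures, label tables and run configuration.

Atomic models are held in a light hierarchical container (``StructureModel`` →
``ChainModel`` → ``ResidueModel`` → ``AtomRecord``) with coordinates in Å.
PDB and mmCIF parsing/writing is delegated to :mod:`gemmi`; this module owns
the conversion into the pipeline's containers, altloc resolution, and the
validation rules for per-monomer label tables.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("rndcensus")

#: The fixed conformational-state vocabulary.  ``O*`` is the open-architecture/
#: closed-exit-channel state and is spelled with a literal asterisk in files.
STATES: tuple[str, ...] = ("L", "T", "O", "O*")
UNASSIGNED = "UNASSIGNED"
ALLOWED_LABELS: tuple[str, ...] = STATES + (UNASSIGNED,)

#: Precedence used for deterministic tie-breaking and canonical composition
#: names: L < T < O < O*.
STATE_PRECEDENCE: dict[str, int] = {s: i for i, s in enumerate(STATES)}

LABEL_COLUMNS = ("particle_id", "copy_index", "state_label")


class FormatError(ValueError):
    """A file does not parse under the named standard."""


class EmptyStructureError(ValueError):
    """A coordinate file contains no atoms."""


class ValidationError(ValueError):
    """A table or configuration violates an invariant."""


# ---------------------------------------------------------------------------
# Structure containers
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    name: str
    element: str
    position: np.ndarray  # (3,) float64, Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValidationError(
                f"atom {self.name!r}: position must be a finite 3-vector"
            )


@dataclass
class ResidueModel:
    number: int            # author numbering, 1-based, gaps allowed
    name: str              # 3-letter code
    atoms: list[AtomRecord] = field(default_factory=list)
    insertion_code: str = ""

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ChainModel:
    chain_id: str
    residues: list[ResidueModel] = field(default_factory=list)

    def residue(self, number: int) -> ResidueModel | None:
        for r in self.residues:
            if r.number == number:
                return r
        return None

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def atom_map(self, heavy_only: bool = True) -> dict[tuple[int, str], np.ndarray]:
        """(residue_number, atom_name) → position; hydrogens skipped by default."""
        out: dict[tuple[int, str], np.ndarray] = {}
        for res in self.residues:
            for a in res.atoms:
                if heavy_only and a.element.upper() in ("H", "D"):
                    continue
                out[(res.number, a.name)] = a.position
        return out

    def ca_map(self) -> dict[int, np.ndarray]:
        """residue_number → Cα position."""
        out: dict[int, np.ndarray] = {}
        for res in self.residues:
            a = res.atom("CA")
            if a is not None:
                out[res.number] = a.position
        return out


@dataclass
class StructureModel:
    """Hierarchical atomic model (chains → residues → atoms), coordinates in Å."""

    model_id: str
    chains: list[ChainModel] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chains:
            return  # empty shells allowed transiently during construction

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in {self.model_id!r}")

    @property
    def n_atoms(self) -> int:
        return sum(c.n_atoms for c in self.chains)

    def iter_atoms(self) -> Iterator[tuple[ChainModel, ResidueModel, AtomRecord]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        """All atom positions as an (N, 3) array, file order."""
        pts = [
            a.position
            for _, _, a in self.iter_atoms()
            if not (heavy_only and a.element.upper() in ("H", "D"))
        ]
        if not pts:
            return np.empty((0, 3))
        return np.array(pts)

    def elements(self, heavy_only: bool = True) -> list[str]:
        return [
            a.element
            for _, _, a in self.iter_atoms()
            if not (heavy_only and a.element.upper() in ("H", "D"))
        ]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with every atom position mapped to R·x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new_chains = []
        for c in self.chains:
            new_res = []
            for r in c.residues:
                new_atoms = [
                    dataclasses.replace(a, position=R @ a.position + t)
                    for a in r.atoms
                ]
                new_res.append(dataclasses.replace(r, atoms=new_atoms))
            new_chains.append(dataclasses.replace(c, residues=new_res))
        return StructureModel(self.model_id, new_chains, dict(self.metadata))

    def copy(self) -> "StructureModel":
        return self.transformed(np.eye(3), np.zeros(3))


def chain_from_arrays(
    chain_id: str,
    residue_numbers: Sequence[int],
    positions: np.ndarray,
    residue_name: str = "ALA",
    atom_name: str = "CA",
    element: str = "C",
) -> ChainModel:
    """Build a one-atom-per-residue chain from parallel arrays (synthetic models)."""
    positions = np.asarray(positions, float)
    residues = [
        ResidueModel(int(n), residue_name, [AtomRecord(atom_name, element, p)])
        for n, p in zip(residue_numbers, positions)
    ]
    return ChainModel(chain_id, residues)


# ---------------------------------------------------------------------------
# Structure IO (gemmi-backed)
# ---------------------------------------------------------------------------

def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc order."""
    by_name: dict[str, list[AtomRecord]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc))
        out.append(dataclasses.replace(best, altloc=""))
    return out


def read_structure(
    path: str | Path,
    format: str = "auto",
    keep_waters: bool = False,
) -> StructureModel:
    """Read a PDB or mmCIF coordinate file into a :class:`StructureModel`.

    Altlocs are resolved to a single conformer (highest occupancy, ties by
    altloc identifier).  Insertion codes are preserved.  Waters are dropped
    unless ``keep_waters``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if format not in fmt_map:
        raise ValidationError(f"unknown format {format!r}; use pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    chains: list[ChainModel] = []
    for ch in model:
        residues: list[ResidueModel] = []
        for res in ch:
            if not keep_waters and res.is_water():
                continue
            atoms = [
                AtomRecord(
                    name=at.name,
                    element=at.element.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    b_factor=at.b_iso,
                    altloc=at.altloc or "",
                )
                for at in res
            ]
            if not atoms:
                continue
            residues.append(
                ResidueModel(
                    number=res.seqid.num,
                    name=res.name,
                    atoms=_resolve_altlocs(atoms),
                    insertion_code=(res.seqid.icode or "").strip(),
                )
            )
        if residues:
            chains.append(ChainModel(ch.name, residues))
    if not chains or all(c.n_atoms == 0 for c in chains):
        raise EmptyStructureError(f"{path}: empty coordinate set")
    return StructureModel(model_id=path.stem, chains=chains)


def write_structure(model: StructureModel, path: str | Path, format: str = "auto") -> None:
    """Write a :class:`StructureModel` as PDB or mmCIF (by extension if auto)."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = gemmi.Structure()
    st.name = model.model_id
    md = gemmi.Model("1")
    for c in model.chains:
        ch = gemmi.Chain(c.chain_id)
        for r in c.residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.number, r.insertion_code or " ")
            for a in r.atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.position)
                at.occ = a.occupancy
                at.b_iso = a.b_factor
                res.add_atom(at)
            ch.add_residue(res)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    elif format == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValidationError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Label tables
# ---------------------------------------------------------------------------

@dataclass
class LabelTable:
    """Per-monomer state labels: one row per (particle_id, copy_index).

    ``copy_index`` runs 0–2 (the three protomers of a trimer);
    ``state_label`` is one of L, T, O, O* or UNASSIGNED.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in LABEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"label table missing columns: {missing}")
        df = df.copy()
        df["particle_id"] = df["particle_id"].astype(str)
        df["copy_index"] = df["copy_index"].astype(int)
        bad_copy = ~df["copy_index"].isin((0, 1, 2))
        if bad_copy.any():
            raise ValidationError(
                f"copy_index must be in 0–2; offending values: "
                f"{sorted(df.loc[bad_copy, 'copy_index'].unique().tolist())}"
            )
        bad_label = ~df["state_label"].isin(ALLOWED_LABELS)
        if bad_label.any():
            raise ValidationError(
                f"unknown state labels {sorted(df.loc[bad_label, 'state_label'].unique().tolist())}; "
                f"allowed: {list(ALLOWED_LABELS)}"
            )
        dup = df.duplicated(subset=["particle_id", "copy_index"])
        if dup.any():
            keys = df.loc[dup, ["particle_id", "copy_index"]].itertuples(index=False)
            raise ValidationError(
                "duplicate (particle_id, copy_index) keys: "
                + ", ".join(f"({p}, {c})" for p, c in list(keys)[:5])
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelTable):
            return NotImplemented
        a = self.df.sort_values(["particle_id", "copy_index"]).reset_index(drop=True)
        b = other.df.sort_values(["particle_id", "copy_index"]).reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            if col == "score":
                if not np.allclose(
                    a[col].astype(float), b[col].astype(float), equal_nan=True
                ):
                    return False
            elif not (a[col] == b[col]).all():
                return False
        return True

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[str, int, str] | tuple[str, int, str, float]]
    ) -> "LabelTable":
        recs = []
        for row in rows:
            rec = {"particle_id": row[0], "copy_index": row[1], "state_label": row[2]}
            if len(row) > 3:
                rec["score"] = row[3]
            recs.append(rec)
        return cls(pd.DataFrame(recs))


def read_label_table(path: str | Path) -> LabelTable:
    """Read a tab-separated label table (header required)."""
    df = pd.read_csv(path, sep="\t", dtype={"particle_id": str})
    return LabelTable(df)


def write_label_table(table: LabelTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline configuration with validated defaults.

    ``o_star_threshold`` (Å) is the exit-channel bottleneck below which an
    O-architecture monomer is relabelled O*; the default 1.5 Å reflects the
    upper end of the closed-channel bottleneck range reported for OqxB.
    """

    atom_selection: str = "ca"            # "ca" or "all_atom"
    core_ranges: tuple[tuple[int, int], ...] = ()
    grid_spacing: float = 0.8             # Å
    grid_padding: float = 6.0             # Å
    probe_radius: float = 3.0             # Å, exterior connectivity
    vdw_table: str = "default"
    o_star_threshold: float = 1.5         # Å
    state_precedence: tuple[str, ...] = STATES
    pseudo_symmetry_tolerance: float = 15.0  # degrees
    tie_margin: float = 0.05              # Å
    min_coverage: float = 0.5
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValidationError("grid spacing must be > 0")
        if self.o_star_threshold <= 0:
            raise ValidationError("O* bottleneck threshold must be > 0")
        if sorted(self.state_precedence) != sorted(STATES):
            raise ValidationError(
                f"state precedence must be a permutation of {STATES}"
            )
        if self.atom_selection not in ("ca", "all_atom"):
            raise ValidationError("atom_selection must be 'ca' or 'all_atom'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "core_ranges" in data:
            data["core_ranges"] = tuple(tuple(r) for r in data["core_ranges"])
        if "state_precedence" in data:
            data["state_precedence"] = tuple(data["state_precedence"])
        return cls(**data)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


def stage_summary(stage: str, n_in: int, n_out: int, **extra) -> None:
    """Machine-parseable one-line summary per pipeline stage."""
    kv = " ".join(f"{k}={v}" for k, v in extra.items())
    logger.info("stage=%s n_in=%d n_out=%d %s", stage, n_in, n_out, kv)
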