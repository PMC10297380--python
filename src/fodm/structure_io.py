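"""Structure input/output: residue clouds, effective atoms, hydrophobicity scales.

Each amino-acid residue of a structure is reduced to a single *effective atom*
at the unweighted mean of its heavy (non-hydrogen) atom coordinates, carrying
one intrinsic hydrophobicity value in [0, 1] looked up from a named scale.
All downstream profile computations operate on this reduced representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np

STANDARD_AA = frozenset([
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
])

#: Common chemically-modified residues mapped onto their standard parent.
DEFAULT_ALIASES: Mapping[str, str] = {
    "MSE": "MET",   # selenomethionine
    "SEC": "CYS",   # selenocysteine (closest standard parent for scoring)
    "PYL": "LYS",
    "HYP": "PRO",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "CSO": "CYS",
    "MLY": "LYS",
}

DEFAULT_SCALE = "kd-unit"

ResidueKey = tuple  # (chain_id, seq_number, insertion_code)


@dataclass(frozen=True)
class ResidueRecord:
    """One amino-acid residue reduced to an effective atom.

    ``intrinsic_hydrophobicity`` is NaN until a scale has been applied
    (see :func:`assign_hydrophobicity`).
    """

    chain_id: str
    seq_number: int
    insertion_code: str
    residue_name: str
    effective_position: np.ndarray
    intrinsic_hydrophobicity: float = float("nan")

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def label(self) -> str:
        icode = self.insertion_code.strip()
        return f"{self.chain_id}:{self.seq_number}{icode}"


@dataclass
class ResidueCloud:
    """Ordered effective-atom point cloud for one structure selection."""

    records: list[ResidueRecord]
    source_id: str = ""
    selection: str = ""

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError(
                f"a residue cloud needs at least 2 residues, got {len(self.records)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def positions(self) -> np.ndarray:
        return np.array([r.effective_position for r in self.records], dtype=float)

    @property
    def hydrophobicities(self) -> np.ndarray:
        return np.array([r.intrinsic_hydrophobicity for r in self.records], dtype=float)

    @property
    def keys(self) -> list[ResidueKey]:
        return [r.key for r in self.records]

    def without(self, keys: Iterable[ResidueKey]) -> "ResidueCloud":
        """Return a copy with the named residues removed (order preserved)."""
        drop = {_normalize_key(k) for k in keys}
        present = {r.key for r in self.records}
        unknown = drop - present
        if unknown:
            raise KeyError(f"residues not present in cloud: {sorted(unknown)}")
        kept = [r for r in self.records if r.key not in drop]
        if len(kept) < 2:
            raise ValueError("fewer than 2 residues remain after exclusion")
        sel = self.selection + f" minus {len(drop)} excluded" if drop else self.selection
        return ResidueCloud(kept, source_id=self.source_id, selection=sel)


def _normalize_key(key) -> ResidueKey:
    """Accept (chain, num) or (chain, num, icode); icode defaults to ''."""
    if len(key) == 2:
        return (str(key[0]), int(key[1]), "")
    chain, num, icode = key
    return (str(chain), int(num), str(icode).strip())


@dataclass(frozen=True)
class HydroScale:
    """A named intrinsic-hydrophobicity table over the 20 standard amino acids."""

    name: str
    values: Mapping[str, float]
    aliases: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_ALIASES))

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.values)
        if missing:
            raise ValueError(f"scale '{self.name}' is missing residues: {sorted(missing)}")
        bad = {k: v for k, v in self.values.items() if not (0.0 <= v <= 1.0)}
        if bad:
            raise ValueError(f"scale '{self.name}' has values outside [0,1]: {bad}")

    def lookup(self, residue_name: str) -> float:
        name = residue_name.upper()
        if name in self.values:
            return float(self.values[name])
        if name in self.aliases:
            return float(self.values[self.aliases[name]])
        raise KeyError(residue_name)


def load_scale(path: str | Path, name: Optional[str] = None,
               aliases: Optional[Mapping[str, str]] = None) -> HydroScale:
    """Load a two-column (3-letter code, value) scale file; '#' starts a comment."""
    path = Path(path)
    values: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
        values[parts[0].upper()] = float(parts[1])
    return HydroScale(
        name=name or path.stem,
        values=values,
        aliases=dict(aliases) if aliases is not None else dict(DEFAULT_ALIASES),
    )


def bundled_scale(name: str = DEFAULT_SCALE) -> HydroScale:
    """Load one of the scales shipped with the package ('kd-unit', 'eisenberg-unit')."""
    ref = resources.files("fodm.data").joinpath(f"{name}.txt")
    if not ref.is_file():
        available = sorted(
            p.name[:-4] for p in resources.files("fodm.data").iterdir()
            if p.name.endswith(".txt")
        )
        raise KeyError(f"no bundled scale '{name}'; available: {available}")
    with resources.as_file(ref) as path:
        return load_scale(path, name=name)


# ---------------------------------------------------------------------------
# parsing

def parse_structure(path: str | Path, chain: Optional[str] = None,
                    model: Optional[int] = None,
                    aliases: Optional[Mapping[str, str]] = None) -> ResidueCloud:
    """Read a PDB/mmCIF file into a ResidueCloud of effective atoms.

    Keeps polymer amino-acid residues only (waters, ligands and nucleic acids
    are dropped); for alternate locations the highest-occupancy atom wins
    (tie -> first in file).  ``model`` selects an NMR/ensemble model by its
    1-based number (default: first model in the file).

    A residue recorded as a polymer ATOM whose name is neither standard nor
    aliased is an error rather than being silently skipped.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(str(path))
    alias_map = dict(aliases) if aliases is not None else dict(DEFAULT_ALIASES)

    structure = gemmi.read_structure(str(path))
    structure.setup_entities()

    if model is None:
        mod = structure[0]
    else:
        matches = [m for m in structure if m.num == model]
        if not matches:
            raise KeyError(f"model {model} not found in {path.name}")
        mod = matches[0]

    chain_ids = [c.name for c in mod]
    if chain is not None and chain not in chain_ids:
        raise KeyError(f"chain '{chain}' not found in {path.name}; has {chain_ids}")

    records: list[ResidueRecord] = []
    for ch in mod:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            name = res.name.upper()
            known = name in STANDARD_AA or name in alias_map
            if not known:
                if res.het_flag == "A":
                    raise ValueError(
                        f"unknown polymer residue '{res.name}' at "
                        f"{ch.name}:{res.seqid.num} (add an alias to map it)"
                    )
                continue  # water / ligand / nucleic acid
            pos = _effective_position(res)
            records.append(ResidueRecord(
                chain_id=ch.name,
                seq_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                residue_name=name,
                effective_position=pos,
            ))
    if not records:
        raise ValueError(f"zero amino-acid residues after filtering in {path.name}")
    sel = f"chain {chain}" if chain else "all chains"
    if model is not None:
        sel += f", model {model}"
    return ResidueCloud(records, source_id=path.name, selection=sel)


def _effective_position(res: gemmi.Residue) -> np.ndarray:
    """Unweighted mean of heavy-atom coordinates, altlocs resolved by occupancy."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in res:
        if atom.is_hydrogen():
            continue
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            chosen[atom.name] = atom
    if not chosen:
        raise ValueError(
            f"residue {res.name} {res.seqid.num} has no heavy atoms"
        )
    coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in chosen.values()])
    return coords.mean(axis=0)


def assign_hydrophobicity(cloud: ResidueCloud, scale: HydroScale) -> ResidueCloud:
    """Return a copy of the cloud with intrinsic hydrophobicities set from ``scale``."""
    records = []
    for i, rec in enumerate(cloud.records):
        try:
            h = scale.lookup(rec.residue_name)
        except KeyError:
            raise KeyError(
                f"scale '{scale.name}' has no entry for residue "
                f"'{rec.residue_name}' at position {i} ({rec.label()})"
            ) from None
        records.append(replace(rec, intrinsic_hydrophobicity=h))
    return ResidueCloud(records, source_id=cloud.source_id, selection=cloud.selection)


# ---------------------------------------------------------------------------
# writing

def write_effective_pdb(cloud: ResidueCloud, path: str | Path) -> None:
    """Write the cloud as a one-pseudo-atom-per-residue PDB file.

    Each residue becomes a single CA pseudo-atom at its effective position;
    the B-factor column carries the intrinsic hydrophobicity when assigned.
    Re-parsing the file reproduces the effective positions (a single heavy
    atom is its own mean).
    """
    st = gemmi.Structure()
    st.name = cloud.source_id or "effective"
    mod = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    for rec in cloud.records:
        ch = chains.get(rec.chain_id)
        if ch is None:
            ch = gemmi.Chain(rec.chain_id)
            chains[rec.chain_id] = ch
        res = gemmi.Residue()
        res.name = rec.residue_name
        res.seqid = gemmi.SeqId(rec.seq_number, rec.insertion_code or " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        x, y, z = map(float, rec.effective_position)
        atom.pos = gemmi.Position(x, y, z)
        atom.occ = 1.0
        h = rec.intrinsic_hydrophobicity
        atom.b_iso = float(h) if np.isfinite(h) else 0.0
        res.add_atom(atom)
        ch.add_residue(res)
    for ch in chains.values():
        mod.add_chain(ch)
    st.add_model(mod)
    st.setup_entities()
    st.write_pdb(str(path))


def parse_residue_spec(spec: str) -> list[ResidueKey]:
    """Parse 'A:35,A:53,A:128' (author numbering, optional icode suffix) to keys."""
    keys = []
    for item in spec.split(","):
        item = item.strip()
        if not item:
            continue
        try:
            chain, resnum = item.split(":")
        except ValueError:
            raise ValueError(f"bad residue spec '{item}'; expected CHAIN:RESNUM[ICODE]")
        num = resnum.strip()
        icode = ""
        if num and num[-1].isalpha():
            num, icode = num[:-1], num[-1]
        keys.append((chain.strip(), int(num), icode))
    return keys
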