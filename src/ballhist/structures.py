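"""Protein structures as typed alpha-carbon point clouds.

The ball-histogram method consumes nothing but alpha-carbon coordinates and
residue identities, so a structure here is an ordered list of
(type, CA position) records pooled across all chains of the first model.
Residue types are described through a :class:`PropertyTable` of Boolean
amino-acid properties: the 20 identity properties plus charge classes
(Positive / Negative / Neutral) and a Polar class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .exceptions import DataError, EmptyStructureError, StructureParseError

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, three-letter codes, alphabetical.
CANONICAL_RESIDUES: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: Common non-canonical / modified residues mapped to their canonical parent.
NONCANONICAL_MAP: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine
    "PYL": "LYS",  # pyrrolysine
    "SEP": "SER",  # phosphoserine
    "TPO": "THR",  # phosphothreonine
    "PTR": "TYR",  # phosphotyrosine
    "CSO": "CYS",  # S-hydroxycysteine
    "MLY": "LYS",  # N-dimethyl-lysine
    "KCX": "LYS",  # carboxylysine
    "FME": "MET",  # N-formylmethionine
    "HYP": "PRO",  # hydroxyproline
    "HSD": "HIS", "HSE": "HIS", "HSP": "HIS",  # protonation-state variants
}

POSITIVE_RESIDUES = frozenset({"ARG", "LYS"})
NEGATIVE_RESIDUES = frozenset({"ASP", "GLU"})
#: Default polar class (uncharged polar side chains plus His and Cys); membership
#: conventions vary across the literature, so the table is user-overridable.
DEFAULT_POLAR_RESIDUES = frozenset({"SER", "THR", "ASN", "GLN", "TYR", "CYS", "HIS"})


def _identity_name(code: str) -> str:
    """Property name of an identity property, e.g. ``ARG`` -> ``Arg``."""
    return code.capitalize()


@dataclass(frozen=True)
class Residue:
    """One amino acid, represented by its alpha-carbon.

    Attributes
    ----------
    res_type : str
        Canonical three-letter code (upper case).
    ca_position : tuple of float
        Alpha-carbon coordinates in Angstroms.
    chain_id : str
        Chain identifier.
    seq_index : int
        Residue sequence number within the chain.
    insertion_code : str
        PDB insertion code, part of the residue's identity.
    """

    res_type: str
    ca_position: tuple[float, float, float]
    chain_id: str = "A"
    seq_index: int = 0
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if self.res_type not in CANONICAL_RESIDUES:
            raise DataError(f"unknown residue type {self.res_type!r}")
        if not all(np.isfinite(self.ca_position)):
            raise DataError(f"non-finite CA coordinates for {self.res_type}")


class ProteinStructure:
    """Ordered, non-empty collection of residues with an identifier."""

    def __init__(self, id: str, residues: Iterable[Residue]):
        self.id = str(id)
        self.residues: tuple[Residue, ...] = tuple(residues)
        if not self.residues:
            raise EmptyStructureError(f"structure {self.id!r} has no residues")
        seen: set[tuple[str, int, str]] = set()
        for r in self.residues:
            key = (r.chain_id, r.seq_index, r.insertion_code)
            if key in seen:
                raise DataError(f"duplicate residue identity {key} in {self.id!r}")
            seen.add(key)
        self._coords = np.array([r.ca_position for r in self.residues], dtype=float)
        self._coords.setflags(write=False)

    def __len__(self) -> int:
        return len(self.residues)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ProteinStructure)
            and self.id == other.id
            and self.residues == other.residues
        )

    def __repr__(self) -> str:
        return f"ProteinStructure(id={self.id!r}, n_residues={len(self)})"

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of alpha-carbon coordinates in Angstroms."""
        return self._coords

    @property
    def res_types(self) -> tuple[str, ...]:
        return tuple(r.res_type for r in self.residues)


class PropertyTable:
    """Boolean amino-acid properties: name -> set of residue types satisfying it.

    Always contains the 20 identity properties (singletons) and a charge
    partition Positive / Negative / Neutral covering every type exactly once.
    Additional class properties (Polar by default) may overlap freely.
    """

    def __init__(self, properties: Mapping[str, Iterable[str]]):
        self._properties: dict[str, frozenset[str]] = {
            name: frozenset(str(c).upper() for c in codes)
            for name, codes in properties.items()
        }
        self._validate()

    def _validate(self) -> None:
        for name, codes in self._properties.items():
            unknown = codes - set(CANONICAL_RESIDUES)
            if unknown:
                raise DataError(f"property {name!r} lists unknown residues {sorted(unknown)}")
        for code in CANONICAL_RESIDUES:
            name = _identity_name(code)
            if self._properties.get(name) != frozenset({code}):
                raise DataError(f"identity property {name!r} must be the singleton {{{code}}}")
        for cls in ("Positive", "Negative", "Neutral"):
            if cls not in self._properties:
                raise DataError(f"charge class {cls!r} missing from property table")
        for code in CANONICAL_RESIDUES:
            n_classes = sum(
                code in self._properties[cls] for cls in ("Positive", "Negative", "Neutral")
            )
            if n_classes != 1:
                raise DataError(
                    f"residue {code} belongs to {n_classes} charge classes (expected exactly 1)"
                )

    @classmethod
    def default(cls, polar: Iterable[str] | None = None) -> "PropertyTable":
        polar_set = frozenset(polar) if polar is not None else DEFAULT_POLAR_RESIDUES
        props: dict[str, frozenset[str]] = {
            _identity_name(c): frozenset({c}) for c in CANONICAL_RESIDUES
        }
        props["Positive"] = POSITIVE_RESIDUES
        props["Negative"] = NEGATIVE_RESIDUES
        props["Neutral"] = frozenset(
            set(CANONICAL_RESIDUES) - POSITIVE_RESIDUES - NEGATIVE_RESIDUES
        )
        props["Polar"] = frozenset(str(c).upper() for c in polar_set)
        return cls(props)

    @classmethod
    def with_overrides(cls, overrides: Mapping[str, Iterable[str]]) -> "PropertyTable":
        """Default table with named properties replaced or added."""
        base = cls.default()
        props = dict(base._properties)
        for name, codes in overrides.items():
            props[name] = frozenset(str(c).upper() for c in codes)
        return cls(props)

    @property
    def property_names(self) -> tuple[str, ...]:
        return tuple(self._properties)

    def members(self, property_name: str) -> frozenset[str]:
        try:
            return self._properties[property_name]
        except KeyError:
            raise DataError(f"unknown property {property_name!r}") from None

    def __contains__(self, property_name: str) -> bool:
        return property_name in self._properties

    def membership_matrix(
        self, res_types: Iterable[str], properties: Iterable[str]
    ) -> np.ndarray:
        """(n_residues, n_properties) 0/1 matrix of property satisfaction."""
        props = [self.members(p) for p in properties]
        return np.array(
            [[1.0 if t in p else 0.0 for p in props] for t in res_types], dtype=float
        )

    def to_dict(self) -> dict[str, list[str]]:
        return {name: sorted(codes) for name, codes in self._properties.items()}


def satisfies(res_type: str, property_name: str, table: PropertyTable | None = None) -> bool:
    """Whether an amino-acid type complies with a Boolean property."""
    table = table if table is not None else PropertyTable.default()
    return str(res_type).upper() in table.members(property_name)


def geometric_center(structure: ProteinStructure) -> np.ndarray:
    """Unweighted arithmetic mean of all alpha-carbon coordinates."""
    return structure.coords.mean(axis=0)


def read_structure(path: str, format: str = "pdb") -> ProteinStructure:
    """Read a structure file into a :class:`ProteinStructure`.

    Only the first model is used; all chains are pooled. One residue is kept
    per standard amino acid bearing an alpha-carbon (first altLoc conformer);
    waters and unmappable hetero residues are skipped. Non-canonical residues
    with a standard parent (e.g. selenomethionine) are mapped to it.
    """
    if format != "pdb":
        raise DataError(f"unsupported structure format {format!r}")
    from Bio.PDB import PDBParser
    from Bio.PDB.Atom import DisorderedAtom

    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pdb_structure = parser.get_structure("s", path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # Bio.PDB raises assorted types on malformed input
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    models = list(pdb_structure)
    if not models:
        raise StructureParseError(f"{path} contains no models")
    model = models[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetflag, seq_index, icode = res.id
            resname = res.get_resname().strip().upper()
            if hetflag == "W":
                continue
            if resname not in CANONICAL_RESIDUES:
                mapped = NONCANONICAL_MAP.get(resname)
                if mapped is None:
                    if hetflag == " ":
                        logger.warning(
                            "skipping unmappable residue %s %s%d in %s",
                            resname, chain.id, seq_index, path,
                        )
                    continue
                resname = mapped
            if "CA" not in res:
                logger.warning(
                    "skipping residue %s %s%d in %s: no alpha-carbon",
                    resname, chain.id, seq_index, path,
                )
                continue
            atom = res["CA"]
            if isinstance(atom, DisorderedAtom):
                atom = atom.disordered_get_list()[0]  # first conformer in file order
            # PDB coordinates carry exactly 3 decimals; rounding undoes the
            # float32 truncation of the parser and restores the printed value.
            x, y, z = (round(float(v), 3) for v in atom.get_coord())
            residues.append(
                Residue(
                    res_type=resname,
                    ca_position=(x, y, z),
                    chain_id=str(chain.id),
                    seq_index=int(seq_index),
                    insertion_code=str(icode).strip(),
                )
            )
    if not residues:
        raise EmptyStructureError(f"{path} contains no alpha-carbon-bearing residues")
    import os

    return ProteinStructure(id=os.path.splitext(os.path.basename(path))[0], residues=residues)
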