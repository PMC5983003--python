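"""Read C-alpha traces from PDB files and flatten multi-chain structures.

The toolkit works on a residue-level coarse-grained representation of a
protein: one point per residue, located at its C-alpha atom.  This module
extracts that trace from PDB-format text, resolves alternate locations,
maps common modified residues to their parent amino acid, and renumbers
multi-chain selections into a single continuous (flat) index so that a
homodimer can be tessellated as one point set.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser

log = logging.getLogger(__name__)

#: Canonical one-letter amino-acid alphabet, alphabetical order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Modified residues mapped to their parent amino acid.  Anything not listed
# here (and not canonical) is skipped with a warning.
MODIFIED_RESIDUES = {
    "MSE": "M",  # selenomethionine
    "CSE": "C", "SEC": "C", "CSO": "C", "CSD": "C", "CME": "C", "OCS": "C",
    "SEP": "S", "TPO": "T", "PTR": "Y",
    "MLY": "K", "KCX": "K", "LLP": "K",
    "HYP": "P", "PCA": "E", "FME": "M", "MEN": "N",
}


class StructureError(ValueError):
    """Raised for malformed or inconsistent structure input."""


@dataclass(frozen=True)
class ResidueSite:
    """One residue of the coarse-grained trace.

    ``author_resnum`` keeps the PDB (author) numbering for reporting;
    ``flat_index`` is the 0-based continuous index across the selected
    chains and is what the tessellation operates on.
    """

    chain_id: str
    author_resnum: int
    flat_index: int
    res_type: str
    coord: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.res_type not in AMINO_ACIDS:
            raise StructureError(f"unknown residue type {self.res_type!r}")
        if not all(np.isfinite(self.coord)):
            raise StructureError(f"non-finite coordinate for site {self}")


@dataclass
class CoarseStructure:
    """Ordered C-alpha point set with residue identities."""

    sites: list[ResidueSite]
    source_id: str = ""
    chain_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, s in enumerate(self.sites):
            if s.flat_index != i:
                raise StructureError(
                    f"flat_index must be consecutive from 0; site {i} has {s.flat_index}"
                )
        if not self.chain_order:
            seen: list[str] = []
            for s in self.sites:
                if s.chain_id not in seen:
                    seen.append(s.chain_id)
            self.chain_order = seen

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of C-alpha coordinates in Å."""
        return np.asarray([s.coord for s in self.sites], dtype=float)

    @property
    def sequence(self) -> str:
        return "".join(s.res_type for s in self.sites)

    def chain(self, chain_id: str) -> list[ResidueSite]:
        return [s for s in self.sites if s.chain_id == chain_id]

    def sites_at_label(self, author_resnum: int) -> list[ResidueSite]:
        """All chain copies of an author-numbered position (multimer aware)."""
        return [s for s in self.sites if s.author_resnum == author_resnum]

    def label(self, flat_index: int) -> str:
        s = self.sites[flat_index]
        return f"{s.chain_id}:{s.res_type}{s.author_resnum}"


def _as_handle(source) -> io.TextIOBase:
    if hasattr(source, "read"):
        return source
    text = str(source)
    if "\n" in text or text[:6].rstrip() in ("ATOM", "HETATM", "HEADER", "MODEL"):
        return io.StringIO(text)
    if not os.path.exists(text):
        raise FileNotFoundError(f"PDB source not found: {text}")
    return open(text)


def _resolve_ca(residue):
    """Pick the single CA atom, resolving altlocs to ' '/'A' (highest occupancy)."""
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if atom.is_disordered():
        children = sorted(
            atom.disordered_get_list(),
            key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
        )
        preferred = [a for a in children if a.get_altloc() in (" ", "A")]
        atom = (preferred or children)[0]
    return atom


def _check_duplicate_residues(text: str) -> None:
    """Reject a residue number claimed by two different residue types.

    Bio.PDB would otherwise fold such records into a disordered
    ("point mutation") residue silently.
    """
    seen: dict[tuple[str, int, str], str] = {}
    for line in text.splitlines():
        if not (line.startswith("ATOM") or line.startswith("HETATM")):
            continue
        if line[12:16].strip() != "CA" or line[16] not in (" ", "A"):
            continue
        try:
            key = (line[21], int(line[22:26]), line[26])
        except ValueError:
            continue
        resname = line[17:20].strip()
        if key in seen and seen[key] != resname:
            raise StructureError(
                f"duplicate residue number {key[1]} in chain {key[0]} "
                f"({seen[key]} vs {resname})"
            )
        seen[key] = resname


def load_calpha_structure(pdb_source, chains: Sequence[str] | None = None,
                          source_id: str = "") -> CoarseStructure:
    """Extract a C-alpha trace for the requested chains of a PDB file.

    Parameters
    ----------
    pdb_source
        Path to a PDB file, an open text handle, or PDB text itself.
    chains
        Chain identifiers to keep, in the order they should be flattened.
        ``None`` keeps every chain in file order.

    Residues without a CA atom are skipped with a warning; modified
    residues in :data:`MODIFIED_RESIDUES` are mapped to their parent type;
    other non-standard residues are skipped.  A duplicated author residue
    number within a chain is an error.
    """
    handle = _as_handle(pdb_source)
    text = handle.read()
    _check_duplicate_residues(text)
    parser = PDBParser(QUIET=True)
    model = parser.get_structure(source_id or "structure", io.StringIO(text))[0]
    available = [c.id for c in model]
    if chains is None:
        chains = available
    sites: list[ResidueSite] = []
    for chain_id in chains:
        if chain_id not in available:
            raise StructureError(
                f"chain {chain_id!r} not present in structure "
                f"(available: {','.join(available) or 'none'})"
            )
        seen_resnums: set[int] = set()
        prev_resnum: int | None = None
        for residue in model[chain_id]:
            hetflag, resnum, icode = residue.id
            resname = residue.get_resname().strip()
            if resname in _THREE_TO_ONE:
                one = _THREE_TO_ONE[resname]
            elif resname in MODIFIED_RESIDUES:
                one = MODIFIED_RESIDUES[resname]
            elif hetflag != " ":
                continue  # waters, ligands
            else:
                log.warning("skipping unknown residue %s %s%d", resname, chain_id, resnum)
                continue
            atom = _resolve_ca(residue)
            if atom is None:
                log.warning("residue %s%d has no CA atom; skipped", chain_id, resnum)
                continue
            if resnum in seen_resnums:
                raise StructureError(
                    f"duplicate residue number {resnum} in chain {chain_id}"
                )
            seen_resnums.add(resnum)
            if prev_resnum is not None and resnum < prev_resnum:
                raise StructureError(
                    f"residue numbers not increasing in chain {chain_id} at {resnum}"
                )
            prev_resnum = resnum
            x, y, z = map(float, atom.get_coord())
            sites.append(ResidueSite(chain_id, resnum, len(sites), one, (x, y, z)))
    if not sites:
        raise StructureError("no CA atoms found for the requested chains")
    return CoarseStructure(sites, source_id=source_id or "structure",
                           chain_order=list(chains))


def concatenate_chains(structures: Iterable[CoarseStructure],
                       source_id: str = "") -> CoarseStructure:
    """Flatten per-chain structures into one continuously indexed structure.

    Chain B's first residue follows chain A's last in the flat index; the
    original (chain, author number) labels are preserved for reporting.
    """
    structures = list(structures)
    if not structures:
        raise StructureError("concatenate_chains requires at least one structure")
    sites: list[ResidueSite] = []
    chain_order: list[str] = []
    for struct in structures:
        for cid in struct.chain_order:
            if cid not in chain_order:
                chain_order.append(cid)
        for s in struct.sites:
            sites.append(ResidueSite(s.chain_id, s.author_resnum, len(sites),
                                     s.res_type, s.coord))
    return CoarseStructure(sites, source_id=source_id or structures[0].source_id,
                           chain_order=chain_order)


def parse_training_list(text: str) -> list[tuple[str, str | None]]:
    """Parse a potential-training-set list.

    Each line is a 4-character PDB code followed by ``@`` (use the single
    chain in the file) or one capital chain letter (use that chain of a
    multimer).  Returns ``(pdb_code, chain or None)`` pairs.
    """
    entries: list[tuple[str, str | None]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if len(line) != 5:
            raise ValueError(f"line {lineno}: expected 5 characters, got {line!r}")
        code, tag = line[:4].lower(), line[4]
        if tag == "@":
            entries.append((code, None))
        elif tag.isalpha() and tag.isupper():
            entries.append((code, tag))
        else:
            raise ValueError(f"line {lineno}: bad chain tag {tag!r} in {line!r}")
    return entries


def secondary_structure_map(pdb_source) -> dict[tuple[str, int], str]:
    """Three-state secondary structure from PDB HELIX/SHEET header records.

    Returns a mapping ``(chain_id, author_resnum) -> 'H' | 'E'``; positions
    absent from the map are coil (``'C'``).  Structures written without
    header records (e.g. synthetic traces) therefore come out all-coil.
    """
    handle = _as_handle(pdb_source)
    ss: dict[tuple[str, int], str] = {}
    for line in handle:
        rec = line[:6]
        try:
            if rec == "HELIX ":
                chain = line[19].strip()
                start, end = int(line[21:25]), int(line[33:37])
                state = "H"
            elif rec == "SHEET ":
                chain = line[21].strip()
                start, end = int(line[22:26]), int(line[33:37])
                state = "E"
            else:
                continue
        except (ValueError, IndexError):
            log.warning("unparseable secondary-structure record: %s", line.rstrip())
            continue
        for resnum in range(start, end + 1):
            ss[(chain, resnum)] = state
    return ss


def write_calpha_pdb(structure: CoarseStructure) -> str:
    """Render a CoarseStructure as minimal CA-only PDB text."""
    lines = []
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items()}
    serial = 1
    for s in structure.sites:
        x, y, z = s.coord
        lines.append(
            f"ATOM  {serial:5d}  CA  {one_to_three[s.res_type]} {s.chain_id}"
            f"{s.author_resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"           C"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
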