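"""Structure file I/O and biological-assembly expansion.

Crystallographers deposit the asymmetric unit — the smallest portion of the
crystal from which the rest follows by symmetry — together with operator
lists describing how to build the biologically functional assembly. This
module parses mmCIF and legacy PDB files (via gemmi), keeps protein polymer
chains as Cα traces, and expands the stored operators into explicit
multi-chain :class:`Assembly` objects, the unit of all downstream symmetry
analysis.
"""

from __future__ import annotations

import logging
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .superpose import RigidTransform

logger = logging.getLogger(__name__)

_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


@dataclass
class Chain:
    """One polypeptide as a Cα trace.

    ``sequence`` holds one letter per coordinate-bearing residue, aligned
    1:1 with ``ca_coords`` and ``residue_numbers``. Modified residues carry
    their parent one-letter code (MSE → M); unknowns are 'X'.
    """

    chain_id: str
    sequence: str
    ca_coords: np.ndarray
    residue_numbers: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)
        if not self.residue_numbers:
            self.residue_numbers = list(range(1, len(self.ca_coords) + 1))
        if len(self.sequence) != len(self.ca_coords):
            raise ValueError("sequence and ca_coords must be aligned 1:1")
        if len(self.residue_numbers) != len(self.ca_coords):
            raise ValueError("residue_numbers and ca_coords must be aligned 1:1")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.ca_coords)

    @property
    def centroid(self) -> np.ndarray:
        return self.ca_coords.mean(axis=0)

    def transformed(self, transform: RigidTransform, chain_id: str | None = None) -> "Chain":
        return Chain(
            chain_id if chain_id is not None else self.chain_id,
            self.sequence,
            transform.apply(self.ca_coords),
            list(self.residue_numbers),
        )


@dataclass
class AssemblyDef:
    """One biological-assembly recipe: operator lists applied to chain subsets."""

    assembly_id: str
    # each generator: (chain ids it applies to, ordered rigid transforms)
    generators: list[tuple[list[str], list[RigidTransform]]]


@dataclass
class StructureModel:
    """Asymmetric-unit protein content of one entry plus assembly recipes."""

    entry_id: str
    chains: list[Chain]
    assembly_defs: list[AssemblyDef] = field(default_factory=list)

    def __post_init__(self):
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate chain identifiers in model")

    def assembly_ids(self) -> list[str]:
        return [a.assembly_id for a in self.assembly_defs]


@dataclass
class Assembly:
    """An expanded biological assembly: subunit Chain copies with unique ids."""

    entry_id: str
    assembly_id: str
    subunits: list[Chain]

    def __post_init__(self):
        if not self.subunits:
            raise ValueError("assembly must contain at least one subunit")
        ids = [s.chain_id for s in self.subunits]
        if len(set(ids)) != len(ids):
            raise ValueError("subunit instance ids must be unique")

    def subunit_map(self) -> dict[str, Chain]:
        return {s.chain_id: s for s in self.subunits}


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def _is_protein_residue(resname: str) -> bool:
    info = gemmi.find_tabulated_residue(resname)
    if info is None:
        # unknown residue: admitted as 'X' when it carries a carbon CA
        return True
    return info.is_amino_acid()


def _best_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy CA alternate; ties go to the first encountered."""
    best = None
    for atom in residue:
        if atom.name != "CA" or atom.element != gemmi.Element("C"):
            continue
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def _transform_from_gemmi(tr: gemmi.Transform) -> RigidTransform:
    return RigidTransform(np.array(tr.mat.tolist()), np.array(tr.vec.tolist()))


def read_structure(path, fmt: str = "auto") -> StructureModel:
    """Parse an mmCIF or legacy PDB file into a :class:`StructureModel`.

    Keeps protein polymer chains that have Cα coordinates; nucleic acids,
    ligands and waters are excluded. The first model wins for multi-model
    (NMR) files. Biological-assembly operator definitions (mmCIF
    ``_pdbx_struct_assembly_gen``/``_pdbx_struct_oper_list`` or PDB
    REMARK 350 BIOMT) are captured when present.
    """
    path = str(path)
    if fmt == "mmcif":
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
    elif fmt == "pdb":
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    elif fmt == "auto":
        st = gemmi.read_structure(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    st.setup_entities()

    chains: list[Chain] = []
    subchain_owner: dict[str, str] = {}
    if len(st) == 0:
        return StructureModel(st.name or Path(path).stem, [])
    model = st[0]
    for ch in model:
        seq, coords, numbers = [], [], []
        for res in ch:
            if not _is_protein_residue(res.name):
                continue
            ca = _best_ca(res)
            if ca is None:
                continue
            seq.append(_one_letter(res.name))
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            numbers.append(res.seqid.num)
            if res.subchain:
                subchain_owner[res.subchain] = ch.name
        if not coords:
            if len(ch) > 0:
                logger.warning("chain %s has no Cα-bearing protein residues; dropped", ch.name)
            continue
        chains.append(Chain(ch.name, "".join(seq), np.array(coords), numbers))

    chain_ids = {c.chain_id for c in chains}
    assembly_defs = []
    for asm in st.assemblies:
        generators = []
        for gen in asm.generators:
            referenced = [c for c in gen.chains if c in chain_ids]
            for sub in gen.subchains:
                owner = subchain_owner.get(sub)
                if owner in chain_ids and owner not in referenced:
                    referenced.append(owner)
            ops = [_transform_from_gemmi(op.transform) for op in gen.operators]
            if referenced and ops:
                generators.append((referenced, ops))
        if generators:
            assembly_defs.append(AssemblyDef(asm.name, generators))

    entry_id = st.name or Path(path).stem
    return StructureModel(entry_id, chains, assembly_defs)


def build_assembly(model: StructureModel, assembly_id: str = "asu") -> Assembly:
    """Expand one stored assembly recipe into explicit subunit copies.

    ``assembly_id="asu"`` uses the asymmetric-unit chains as-is (identity
    operator). Each operator applied to each referenced chain yields one
    subunit; instance ids are ``<chain>_<k>`` with a per-chain counter.
    """
    chain_map = {c.chain_id: c for c in model.chains}
    counters: dict[str, int] = {}

    def _instance(chain: Chain, transform: RigidTransform) -> Chain:
        k = counters.get(chain.chain_id, 0)
        counters[chain.chain_id] = k + 1
        return chain.transformed(transform, f"{chain.chain_id}_{k}")

    if assembly_id == "asu":
        subunits = [_instance(c, RigidTransform.identity()) for c in model.chains]
        if not subunits:
            raise ValueError("model has no protein chains")
        return Assembly(model.entry_id, "asu", subunits)

    for adef in model.assembly_defs:
        if adef.assembly_id == assembly_id:
            subunits = []
            for chain_ids, ops in adef.generators:
                for cid in chain_ids:
                    chain = chain_map[cid]
                    for op in ops:
                        subunits.append(_instance(chain, op))
            return Assembly(model.entry_id, assembly_id, subunits)
    raise KeyError(
        f"assembly {assembly_id!r} not found; available: "
        f"{['asu'] + model.assembly_ids()}"
    )


def write_assembly(assembly: Assembly, path) -> None:
    """Write an assembly as a minimal Cα-only mmCIF file.

    One model; each subunit becomes one chain named by its instance id.
    ``read_structure`` round-trips the file to format precision (1e-3 Å).
    """
    st = gemmi.Structure()
    st.name = assembly.entry_id
    model = gemmi.Model(1)
    for sub in assembly.subunits:
        ch = gemmi.Chain(sub.chain_id)
        for i, (letter, xyz, num) in enumerate(
            zip(sub.sequence, sub.ca_coords, sub.residue_numbers)
        ):
            res = gemmi.Residue()
            res.name = _THREE_LETTER.get(letter, "UNK")
            res.seqid = gemmi.SeqId(int(num), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.b_iso = 0.0
            atom.pos = gemmi.Position(*map(float, xyz))
            res.add_atom(atom)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_mmcif_document()
    doc.write_file(str(path))


def write_fasta(chains: list[Chain], path) -> None:
    """Export chain sequences as FASTA."""
    with open(path, "w") as fh:
        for c in chains:
            fh.write(f">{c.chain_id}\n{c.sequence}\n")


def fetch_structure(pdb_id: str, cache_dir=None, timeout: float = 15.0) -> Path:
    """Download an mmCIF entry from the RCSB PDB; returns the local path.

    Requires network access; cached downloads are reused.
    """
    pdb_id = pdb_id.lower()
    cache = Path(cache_dir) if cache_dir else Path.cwd() / "pdb_cache"
    cache.mkdir(parents=True, exist_ok=True)
    dest = cache / f"{pdb_id}.cif"
    if dest.exists():
        return dest
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.cif"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    dest.write_bytes(data)
    return dest
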