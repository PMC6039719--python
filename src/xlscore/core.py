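"""Structure and crosslink data model.

The package represents a protein complex as an ordered collection of
subunits (one per chain), each an ordered collection of residues with an
``atom name -> coordinate`` map in Angstroms.  Crosslinking restraints are
residue pairs with a linker identity, a maximum-bound distance and an
inter/intra-subunit classification.

PDB reading and writing goes through :mod:`gemmi`; only ATOM records of
polymer chains are kept (HETATM and waters are dropped, alternate locations
are resolved to the highest-occupancy conformer).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "Subunit",
    "ComplexStructure",
    "Crosslink",
    "DistanceResult",
    "StructureError",
    "CrosslinkTableError",
    "load_complex",
    "write_pdb",
    "read_crosslinks",
    "write_crosslinks",
    "DEFAULT_LINKER_ARM",
    "DEFAULT_MAX_BOUND_SASD",
    "DEFAULT_MAX_BOUND_ED",
    "CROSSLINKABLE_RESIDUES",
]

#: BS3/DSS linker arm length in Angstroms.
DEFAULT_LINKER_ARM = 11.4
#: Crosslinker maximum bound on the solvent-accessible surface distance.
DEFAULT_MAX_BOUND_SASD = 32.0
#: Crosslinker maximum bound on the Euclidean distance.
DEFAULT_MAX_BOUND_ED = 30.0

#: Residue types whose side chains react with amine-specific crosslinkers.
#: Serine/threonine chemistry exists but is rare; the default set is lysine
#: only.  Protein N-termini are not modelled as crosslinkable.
CROSSLINKABLE_RESIDUES = frozenset({"LYS"})

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureError(ValueError):
    """Raised when a structure violates a structural precondition."""


class CrosslinkTableError(ValueError):
    """Raised when a crosslink table cannot be parsed."""


@dataclass
class Residue:
    """A single residue: author numbering, 3-letter type, atom coordinates."""

    seq_number: int
    res_type: str
    atoms: dict[str, np.ndarray]
    insertion_code: str = ""

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_number, self.insertion_code)

    def anchor_atom(self) -> tuple[str, np.ndarray]:
        """Return the distance-anchor atom ``(name, xyz)``.

        The crosslinker reacts with the lysine side-chain amine, so the
        anchor is N-zeta when present, falling back to C-beta and finally
        C-alpha for truncated side chains or coarse models.
        """
        for name in ("NZ", "CB", "CA"):
            if name in self.atoms:
                return name, self.atoms[name]
        raise StructureError(
            f"residue {self.res_type}{self.seq_number} has no NZ/CB/CA anchor atom"
        )

    @property
    def is_crosslinkable(self) -> bool:
        return self.res_type in CROSSLINKABLE_RESIDUES


@dataclass
class Subunit:
    """One chain of a complex; ``copy_index`` disambiguates identical chains."""

    chain_id: str
    residues: list[Residue]
    copy_index: int = 0

    def __post_init__(self) -> None:
        self._index = {r.key: r for r in self.residues}

    def get_residue(self, seq_number: int, insertion_code: str = "") -> Residue | None:
        return self._index.get((seq_number, insertion_code))

    def sequence_signature(self) -> tuple[tuple[int, str], ...]:
        """Identity used to recognise copies of the same protein."""
        return tuple((r.seq_number, r.res_type) for r in self.residues)

    def ca_coordinates(self) -> np.ndarray:
        return np.array([r.atoms["CA"] for r in self.residues if "CA" in r.atoms])

    def all_atoms(self):
        """Yield ``(residue, atom_name, xyz)`` triples."""
        for res in self.residues:
            for name, xyz in res.atoms.items():
                yield res, name, xyz


@dataclass
class ComplexStructure:
    """A multi-subunit protein complex with coordinates in Angstroms."""

    subunits: list[Subunit]
    name: str = ""

    def __post_init__(self) -> None:
        ids = [(s.chain_id, s.copy_index) for s in self.subunits]
        if len(set(ids)) != len(ids):
            raise StructureError("duplicate (chain_id, copy_index) in complex")
        self._by_chain = {s.chain_id: s for s in self.subunits}

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)

    def get_subunit(self, chain_id: str) -> Subunit:
        try:
            return self._by_chain[chain_id]
        except KeyError:
            raise StructureError(f"no chain {chain_id!r} in complex {self.name!r}")

    def get_residue(self, chain_id: str, seq_number: int, insertion_code: str = "") -> Residue:
        res = self.get_subunit(chain_id).get_residue(seq_number, insertion_code)
        if res is None:
            raise StructureError(
                f"residue {chain_id}/{seq_number}{insertion_code} not in complex"
            )
        return res

    def atom_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All atoms as ``(coords (N,3), element codes, subunit indices)``.

        The element code is the first character of the inferred element
        symbol, used to look up van der Waals radii.
        """
        coords, elements, sub_idx = [], [], []
        for i, sub in enumerate(self.subunits):
            for _res, name, xyz in sub.all_atoms():
                coords.append(xyz)
                elements.append(element_of(name))
                sub_idx.append(i)
        return (
            np.asarray(coords, dtype=float),
            np.asarray(elements),
            np.asarray(sub_idx, dtype=int),
        )

    def crosslinkable_residues(self) -> list[tuple[str, Residue]]:
        out = []
        for sub in self.subunits:
            for res in sub.residues:
                if res.is_crosslinkable:
                    out.append((sub.chain_id, res))
        return out

    def transformed(self, transforms: dict[str, tuple[np.ndarray, np.ndarray]]) -> "ComplexStructure":
        """Return a copy with per-chain rigid transforms ``x -> R x + t``."""
        new_subs = []
        for sub in self.subunits:
            if sub.chain_id in transforms:
                R, t = transforms[sub.chain_id]
                new_res = [
                    replace(r, atoms={n: R @ xyz + t for n, xyz in r.atoms.items()})
                    for r in sub.residues
                ]
            else:
                new_res = [replace(r, atoms=dict(r.atoms)) for r in sub.residues]
            new_subs.append(Subunit(sub.chain_id, new_res, sub.copy_index))
        return ComplexStructure(new_subs, name=self.name)


def element_of(atom_name: str) -> str:
    """Infer the element symbol (single letter) from a PDB atom name."""
    for ch in atom_name:
        if ch.isalpha():
            return "S" if ch.upper() == "S" else ch.upper()
    return "C"


@dataclass
class Crosslink:
    """A residue-pair restraint from a crosslinking-MS experiment.

    ``classification`` is ``inter`` for crosslinks joining different
    subunits, ``intra`` within one subunit, and ``unresolved`` for rows of
    homo-oligomeric complexes whose chain assignment is ambiguous.
    """

    end_a: tuple[str, int]
    end_b: tuple[str, int]
    linker_arm: float = DEFAULT_LINKER_ARM
    max_bound_sasd: float = DEFAULT_MAX_BOUND_SASD
    max_bound_ed: float = DEFAULT_MAX_BOUND_ED
    classification: str = "unresolved"

    def __post_init__(self) -> None:
        if self.end_a == self.end_b:
            raise ValueError("crosslink endpoints must differ")
        if min(self.linker_arm, self.max_bound_sasd, self.max_bound_ed) <= 0:
            raise ValueError("crosslink bounds must be strictly positive")
        if self.classification not in ("inter", "intra", "unresolved"):
            raise ValueError(f"bad classification {self.classification!r}")

    @staticmethod
    def classify(chain_a: str, chain_b: str, ambiguous: bool = False) -> str:
        if ambiguous:
            return "unresolved"
        return "intra" if chain_a == chain_b else "inter"


@dataclass
class DistanceResult:
    """Outcome of a surface-distance computation for one residue pair.

    ``status`` is ``ok`` (SASD found), ``non_accessible`` (at least one
    endpoint buried, no SASD defined) or ``no_path`` (both endpoints
    accessible but no solvent path under the search cap).  The Euclidean
    distance is always defined.
    """

    status: str
    ed: float
    sasd: float | None = None
    path: list | None = None

    def __post_init__(self) -> None:
        if self.status not in ("ok", "non_accessible", "no_path"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "ok" and self.sasd is None:
            raise ValueError("status ok requires a SASD value")
        if self.status == "non_accessible" and self.sasd is not None:
            raise ValueError("non_accessible results carry no SASD")


# ---------------------------------------------------------------------------
# PDB I/O


def load_complex(pdb_source, name: str | None = None) -> ComplexStructure:
    """Read a multi-chain PDB file, path or text into a :class:`ComplexStructure`.

    HETATM records and waters are dropped; alternate locations are resolved
    to the highest-occupancy conformer (first wins on a tie).  Requires at
    least two chains, each with at least one C-alpha.
    """
    text, label = _read_text(pdb_source)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise CrosslinkTableError(f"cannot parse PDB input: {exc}") from exc
    if len(st) == 0:
        raise StructureError("PDB input contains no model")
    model = st[0]

    subunits = []
    for chain in model:
        residues = []
        for res in chain:
            if res.het_flag == "H" or res.name in _WATER_NAMES:
                continue
            atoms: dict[str, np.ndarray] = {}
            best_occ: dict[str, float] = {}
            for atom in res:
                if atom.element == gemmi.Element("H"):
                    continue
                occ = atom.occ
                if atom.name not in atoms or occ > best_occ[atom.name]:
                    atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                    )
                    best_occ[atom.name] = occ
            if atoms:
                icode = res.seqid.icode.strip()
                residues.append(Residue(res.seqid.num, res.name, atoms, icode))
        if residues:
            subunits.append(Subunit(chain.name, residues))

    subunits = [s for s in subunits if any("CA" in r.atoms for r in s.residues)]
    if len(subunits) < 2:
        raise StructureError(
            f"complex requires >=2 chains with C-alpha atoms, got {len(subunits)}"
        )
    return ComplexStructure(subunits, name=name or label or st.name)


def write_pdb(complex_: ComplexStructure, target=None) -> str | None:
    """Write a complex as PDB text to ``target`` (path or stream) or return it."""
    st = gemmi.Structure()
    st.name = complex_.name or "complex"
    model = gemmi.Model("1")
    for sub in complex_.subunits:
        chain = gemmi.Chain(sub.chain_id)
        for res in sub.residues:
            g = gemmi.Residue()
            g.name = res.res_type
            g.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            for aname, xyz in res.atoms.items():
                a = gemmi.Atom()
                a.name = aname
                a.element = gemmi.Element(element_of(aname))
                a.pos = gemmi.Position(*map(float, xyz))
                a.occ = 1.0
                g.add_atom(a)
            chain.add_residue(g)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string()
    if target is None:
        return text
    if hasattr(target, "write"):
        target.write(text)
        return None
    with open(target, "w") as fh:
        fh.write(text)
    return None


def _read_text(source) -> tuple[str, str]:
    """Return (text, label) from a path, stream or raw text."""
    if hasattr(source, "read"):
        return source.read(), getattr(source, "name", "")
    s = str(source)
    if "\n" in s:
        return s, ""
    with open(s) as fh:
        return fh.read(), s


# ---------------------------------------------------------------------------
# Crosslink table I/O
#
# Tab-separated with header: chain_a res_a chain_b res_b [linker]
# '#' starts a comment; '?' in a chain column marks a chain-ambiguous row
# of a homo-oligomeric complex.


class CrosslinkList(list):
    """A list of :class:`Crosslink` carrying a row-exclusion report."""

    def __init__(self, links=(), excluded=None):
        super().__init__(links)
        self.excluded: list[str] = list(excluded or [])


def read_crosslinks(table_source, complex_: ComplexStructure) -> CrosslinkList:
    """Parse a crosslink table and classify each row against ``complex_``.

    Rows referencing residues absent from the complex are excluded with a
    warning and recorded in the returned list's ``excluded`` attribute.
    """
    text, _ = _read_text(table_source)
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        return CrosslinkList()
    header = lines[0].split()
    expected = ["chain_a", "res_a", "chain_b", "res_b"]
    if [h.lower() for h in header[:4]] != expected:
        raise CrosslinkTableError(
            f"crosslink table must start with columns {expected}, got {header[:4]}"
        )

    links = CrosslinkList()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split()
        if len(fields) < 4:
            raise CrosslinkTableError(f"line {lineno}: expected >=4 columns")
        ca, ra, cb, rb = fields[0], int(fields[1]), fields[2], int(fields[3])
        linker = float(fields[4]) if len(fields) > 4 else DEFAULT_LINKER_ARM
        ambiguous = "?" in (ca, cb)
        ok = True
        for chain, seq in (((ca, ra)), ((cb, rb))):
            if chain == "?":
                if not any(s.get_residue(seq) for s in complex_.subunits):
                    ok = False
            else:
                sub = complex_._by_chain.get(chain)
                if sub is None or sub.get_residue(seq) is None:
                    ok = False
        if not ok:
            warnings.warn(f"crosslink row {lineno} references a missing residue; excluded")
            links.excluded.append(line)
            continue
        links.append(
            Crosslink(
                end_a=(ca, ra),
                end_b=(cb, rb),
                linker_arm=linker,
                classification=Crosslink.classify(ca, cb, ambiguous),
            )
        )
    return links


def write_crosslinks(links, target=None) -> str | None:
    """Write crosslinks as the tab-separated table dialect."""
    out = io.StringIO()
    out.write("chain_a\tres_a\tchain_b\tres_b\tlinker\n")
    for xl in links:
        out.write(
            f"{xl.end_a[0]}\t{xl.end_a[1]}\t{xl.end_b[0]}\t{xl.end_b[1]}\t{xl.linker_arm:g}\n"
        )
    text = out.getvalue()
    if target is None:
        return text
    if hasattr(target, "write"):
        target.write(text)
        return None
    with open(target, "w") as fh:
        fh.write(text)
    return None
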