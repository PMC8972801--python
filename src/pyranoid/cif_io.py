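"""Reading and writing monomer-library restraint dictionary entries.

A restraint dictionary entry describes one chemical component (e.g. the
pyranose sugar NAG) in terms of ideal bond lengths, bond angles, torsion
angles, chiral centres and planar groups, each with an uncertainty (sigma)
used as a weight during macromolecular refinement.  The dialect handled
here is the CCP4 monomer-library one: a ``data_comp_list`` block holding a
``_chem_comp`` loop (component id, name and group, where the group is
``pyranose`` for aldopyranoses and ``ketopyranose`` for ketopyranoses),
followed by a ``data_comp_<ID>`` block with ``_chem_comp_atom``,
``_chem_comp_bond``, ``_chem_comp_angle``, ``_chem_comp_tor``,
``_chem_comp_chir`` and ``_chem_comp_plane_atom`` loops.  Model
coordinates, when present, travel in the x/y/z columns of the atom loop.

Unknown loops and pairs are preserved verbatim and re-emitted on write, so
patching a dictionary never destroys information.

Column names follow the monomer-library convention as found in released
CCP4 entries::

    _chem_comp_tor.comp_id / id / atom_id_1..4 / value_angle /
        value_angle_esd / period

Parsing is done with :mod:`gemmi`; this module only interprets the
category semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from gemmi import cif


class CifParseError(ValueError):
    """A loop or value in the CIF source could not be interpreted."""


class DictionaryIntegrityError(ValueError):
    """A restraint references an atom that does not exist in the entry."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TorsionRestraint:
    """One torsion restraint row.

    ``id`` is ``ring_<k>`` for the six endocyclic (unimodal) torsions and
    ``tors_<k>`` (or a legacy name) for everything else.  ``period`` is the
    number of symmetry-equivalent minima per 360 degrees; period 1 encodes
    a unimodal restraint.
    """

    id: str
    atoms: tuple[str, str, str, str]
    value_deg: float
    sigma_deg: float
    period: int = 1

    def __post_init__(self) -> None:
        if self.sigma_deg <= 0:
            raise ValueError(f"torsion {self.id}: sigma must be > 0")
        if self.period < 1:
            raise ValueError(f"torsion {self.id}: period must be >= 1")
        if len(self.atoms) != 4:
            raise ValueError(f"torsion {self.id}: needs 4 atoms")

    @property
    def is_ring(self) -> bool:
        return self.id.startswith("ring_")


@dataclass(frozen=True)
class ChiralRestraint:
    """Chiral-volume sign restraint at one stereocentre."""

    id: str
    centre: str
    neighbours: tuple[str, str, str]
    sign: str  # "positive" | "negative" | "both"

    def __post_init__(self) -> None:
        if self.centre in self.neighbours:
            raise ValueError(f"chirality {self.id}: centre among neighbours")
        if len(set(self.neighbours)) != 3:
            raise ValueError(f"chirality {self.id}: neighbours not distinct")
        if self.sign not in ("positive", "negative", "both"):
            raise ValueError(f"chirality {self.id}: bad sign {self.sign!r}")


@dataclass(frozen=True)
class Bond:
    atom1: str
    atom2: str
    order: str
    length: float
    sigma: float


@dataclass(frozen=True)
class Angle:
    atom1: str
    atom2: str
    atom3: str
    value_deg: float
    sigma_deg: float

    @property
    def atoms(self) -> tuple[str, str, str]:
        return (self.atom1, self.atom2, self.atom3)


@dataclass(frozen=True)
class Plane:
    id: str
    atoms: tuple[str, ...]
    sigma: float


@dataclass(eq=False)
class MonomerCoordinates:
    """Named-atom Cartesian coordinates (Angstrom) for one residue.

    Behaves like a mapping from atom name to a length-3 numpy array.
    ``chain``/``seqnum`` identify the residue instance when read from a
    structure file; ``occupancies`` are kept when present.
    """

    coords: dict[str, np.ndarray]
    occupancies: dict[str, float] | None = None
    comp_id: str = ""
    chain: str = ""
    seqnum: int | None = None

    def __post_init__(self) -> None:
        self.coords = {k: np.asarray(v, dtype=float) for k, v in self.coords.items()}
        for name, xyz in self.coords.items():
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise ValueError(f"atom {name}: coordinates must be 3 finite numbers")

    def __eq__(self, other) -> bool:
        if not isinstance(other, MonomerCoordinates):
            return NotImplemented
        return set(self.coords) == set(other.coords) and all(
            np.array_equal(v, other.coords[k]) for k, v in self.coords.items()
        )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.coords[name]

    def __contains__(self, name: str) -> bool:
        return name in self.coords

    def __len__(self) -> int:
        return len(self.coords)

    def __iter__(self):
        return iter(self.coords)

    def atoms(self) -> list[str]:
        return list(self.coords)

    def array(self, names: Sequence[str]) -> np.ndarray:
        """Stack the coordinates of ``names`` into an (n, 3) array."""
        missing = [n for n in names if n not in self.coords]
        if missing:
            raise KeyError(f"missing atoms: {', '.join(missing)}")
        return np.stack([self.coords[n] for n in names])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MonomerCoordinates":
        rot = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return replace(
            self,
            coords={k: rot @ v + t for k, v in self.coords.items()},
        )


@dataclass
class RestraintDictionary:
    """One component's full restraint set plus optional model coordinates."""

    comp_id: str
    comp_name: str = ""
    comp_type: str = "pyranose"
    atoms: list[tuple[str, str, float]] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    angles: list[Angle] = field(default_factory=list)
    torsions: list[TorsionRestraint] = field(default_factory=list)
    chiralities: list[ChiralRestraint] = field(default_factory=list)
    planes: list[Plane] = field(default_factory=list)
    model_coords: MonomerCoordinates | None = None
    # unknown loops/pairs preserved verbatim: ("loop", tags, rows) or ("pair", tag, value)
    extra_items: list[tuple] = field(default_factory=list)

    def atom_names(self) -> list[str]:
        return [a[0] for a in self.atoms]

    def element_of(self, name: str) -> str:
        for a_name, element, _ in self.atoms:
            if a_name == name:
                return element
        raise KeyError(name)

    def heavy_atoms(self) -> list[str]:
        return [a[0] for a in self.atoms if a[1].upper() not in ("H", "D")]

    def validate(self) -> None:
        """Enforce the entry invariants; raise DictionaryIntegrityError."""
        names = self.atom_names()
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DictionaryIntegrityError(
                f"{self.comp_id}: duplicate atom names: {', '.join(dupes)}"
            )
        known = set(names)

        def check(kind: str, referenced: Iterable[str]) -> None:
            missing = [n for n in referenced if n not in known]
            if missing:
                raise DictionaryIntegrityError(
                    f"{self.comp_id}: {kind} references unknown atoms: "
                    + ", ".join(missing)
                )

        for b in self.bonds:
            check(f"bond {b.atom1}-{b.atom2}", (b.atom1, b.atom2))
        for a in self.angles:
            check(f"angle {'-'.join(a.atoms)}", a.atoms)
        for t in self.torsions:
            check(f"torsion {t.id}", t.atoms)
        for ch in self.chiralities:
            check(f"chirality {ch.id}", (ch.centre, *ch.neighbours))
        for p in self.planes:
            check(f"plane {p.id}", p.atoms)


# ---------------------------------------------------------------------------
# reading

_KNOWN_PREFIXES = (
    "_chem_comp_atom.",
    "_chem_comp_bond.",
    "_chem_comp_angle.",
    "_chem_comp_tor.",
    "_chem_comp_chir.",
    "_chem_comp_plane_atom.",
)


def _loop_rows(loop) -> list[list[str]]:
    n = loop.length()
    w = loop.width()
    vals = list(loop.values)
    return [vals[i * w : (i + 1) * w] for i in range(n)]


def _col(tags: list[str], rows: list[list[str]], name: str, loopname: str,
         required: bool = True) -> list[str] | None:
    short = [t.split(".", 1)[-1] for t in tags]
    if name not in short:
        if required:
            raise CifParseError(f"loop {loopname}: missing column {name!r}")
        return None
    i = short.index(name)
    return [r[i] for r in rows]


def _floats(values: list[str], loopname: str) -> list[float]:
    out = []
    for v in values:
        try:
            out.append(float(v))
        except ValueError as exc:
            raise CifParseError(f"loop {loopname}: bad numeric value {v!r}") from exc
    return out


def read_dictionary(source: str | Path) -> RestraintDictionary:
    """Parse one monomer-library restraint dictionary entry.

    ``source`` is CIF text or a path to a CIF file containing exactly one
    component entry (a ``data_comp_<ID>`` block, optionally preceded by a
    ``data_comp_list`` block).  All restraint loops are parsed; missing
    optional loops give empty lists; unknown loops are kept verbatim.
    """
    text = _slurp(source)
    try:
        doc = cif.read_string(text)
    except Exception as exc:
        raise CifParseError(f"not valid CIF: {exc}") from exc

    comp_name = ""
    comp_type = "pyranose"
    comp_block = None
    list_id = None
    for block in doc:
        tbl = block.find("_chem_comp.", ["id", "name", "group"])
        if tbl and len(tbl) > 0:
            row = tbl[0]
            list_id = cif.as_string(row[0])
            comp_name = cif.as_string(row[1])
            comp_type = cif.as_string(row[2])
        if block.find_loop("_chem_comp_atom.atom_id"):
            if comp_block is not None:
                raise CifParseError("more than one component entry in source")
            comp_block = block
    if comp_block is None:
        raise CifParseError("no component block with a _chem_comp_atom loop found")

    comp_id = comp_block.name.removeprefix("comp_") or (list_id or "UNK")

    d = RestraintDictionary(comp_id=comp_id, comp_name=comp_name, comp_type=comp_type)

    xyz: dict[str, np.ndarray] = {}
    for item in comp_block:
        if item.loop is None:
            if item.pair is not None:
                d.extra_items.append(("pair", item.pair[0], item.pair[1]))
            continue
        tags = list(item.loop.tags)
        rows = _loop_rows(item.loop)
        prefix = tags[0].split(".", 1)[0] + "."
        if prefix == "_chem_comp_atom.":
            names = _col(tags, rows, "atom_id", prefix)
            elements = _col(tags, rows, "type_symbol", prefix)
            charges = _col(tags, rows, "charge", prefix, required=False)
            xs = _col(tags, rows, "x", prefix, required=False)
            ys = _col(tags, rows, "y", prefix, required=False)
            zs = _col(tags, rows, "z", prefix, required=False)
            for i, name in enumerate(names):
                name = name.strip()
                q = float(charges[i]) if charges else 0.0
                d.atoms.append((name, elements[i].strip(), q))
                if xs and ys and zs and xs[i] not in (".", "?"):
                    xyz[name] = np.array(
                        _floats([xs[i], ys[i], zs[i]], prefix), dtype=float
                    )
        elif prefix == "_chem_comp_bond.":
            a1 = _col(tags, rows, "atom_id_1", prefix)
            a2 = _col(tags, rows, "atom_id_2", prefix)
            order = _col(tags, rows, "type", prefix, required=False)
            val = _floats(_col(tags, rows, "value_dist", prefix), prefix)
            esd = _floats(_col(tags, rows, "value_dist_esd", prefix), prefix)
            for i in range(len(rows)):
                d.bonds.append(
                    Bond(a1[i].strip(), a2[i].strip(),
                         order[i] if order else "single", val[i], esd[i])
                )
        elif prefix == "_chem_comp_angle.":
            a1 = _col(tags, rows, "atom_id_1", prefix)
            a2 = _col(tags, rows, "atom_id_2", prefix)
            a3 = _col(tags, rows, "atom_id_3", prefix)
            val = _floats(_col(tags, rows, "value_angle", prefix), prefix)
            esd = _floats(_col(tags, rows, "value_angle_esd", prefix), prefix)
            for i in range(len(rows)):
                d.angles.append(
                    Angle(a1[i].strip(), a2[i].strip(), a3[i].strip(), val[i], esd[i])
                )
        elif prefix == "_chem_comp_tor.":
            tid = _col(tags, rows, "id", prefix)
            ats = [
                _col(tags, rows, f"atom_id_{k}", prefix) for k in (1, 2, 3, 4)
            ]
            val = _floats(_col(tags, rows, "value_angle", prefix), prefix)
            esd = _floats(_col(tags, rows, "value_angle_esd", prefix), prefix)
            per = _col(tags, rows, "period", prefix)
            for i in range(len(rows)):
                try:
                    period = int(per[i])
                except ValueError as exc:
                    raise CifParseError(
                        f"loop {prefix}: bad period {per[i]!r}"
                    ) from exc
                d.torsions.append(
                    TorsionRestraint(
                        id=tid[i].strip(),
                        atoms=tuple(a[i].strip() for a in ats),
                        value_deg=val[i],
                        sigma_deg=esd[i],
                        period=period,
                    )
                )
        elif prefix == "_chem_comp_chir.":
            cid = _col(tags, rows, "id", prefix)
            centre = _col(tags, rows, "atom_id_centre", prefix)
            n1 = _col(tags, rows, "atom_id_1", prefix)
            n2 = _col(tags, rows, "atom_id_2", prefix)
            n3 = _col(tags, rows, "atom_id_3", prefix)
            sign = _col(tags, rows, "volume_sign", prefix)
            for i in range(len(rows)):
                d.chiralities.append(
                    ChiralRestraint(
                        id=cid[i].strip(),
                        centre=centre[i].strip(),
                        neighbours=(n1[i].strip(), n2[i].strip(), n3[i].strip()),
                        sign=sign[i].strip(),
                    )
                )
        elif prefix == "_chem_comp_plane_atom.":
            pid = _col(tags, rows, "plane_id", prefix)
            aname = _col(tags, rows, "atom_id", prefix)
            esd = _floats(_col(tags, rows, "dist_esd", prefix), prefix)
            groups: dict[str, list[tuple[str, float]]] = {}
            order = []
            for i in range(len(rows)):
                if pid[i] not in groups:
                    groups[pid[i]] = []
                    order.append(pid[i])
                groups[pid[i]].append((aname[i].strip(), esd[i]))
            for p in order:
                members = groups[p]
                d.planes.append(
                    Plane(p, tuple(a for a, _ in members), members[0][1])
                )
        else:
            d.extra_items.append(("loop", tags, rows))

    if xyz:
        d.model_coords = MonomerCoordinates(coords=xyz, comp_id=comp_id)

    d.validate()
    return d


# ---------------------------------------------------------------------------
# writing

_F3 = "{:.3f}"  # Angstrom quantities
_DEG = "{:.3f}"  # degrees; three decimals round-trips printed two-decimal values


def write_dictionary(d: RestraintDictionary, dest: str | Path | None = None) -> str:
    """Serialize a restraint dictionary entry to monomer-library CIF text.

    Ring torsions are emitted first (in ring order) followed by the other
    torsions; numeric fields use fixed decimal places so re-reading
    reproduces every value exactly, and writing the re-read entry again is
    byte-identical.
    """
    d.validate()
    doc = cif.Document()

    lst = doc.add_new_block("comp_list")
    loop = lst.init_loop("_chem_comp.", ["id", "three_letter_code", "name", "group"])
    loop.add_row([d.comp_id, d.comp_id, cif.quote(d.comp_name or d.comp_id),
                  cif.quote(d.comp_type)])

    blk = doc.add_new_block(f"comp_{d.comp_id}")
    have_xyz = d.model_coords is not None and all(
        name in d.model_coords for name in d.atom_names()
    )
    atom_tags = ["comp_id", "atom_id", "type_symbol", "charge"]
    if have_xyz:
        atom_tags += ["x", "y", "z"]
    loop = blk.init_loop("_chem_comp_atom.", atom_tags)
    for name, element, charge in d.atoms:
        row = [d.comp_id, name, element, "{:.3f}".format(charge)]
        if have_xyz:
            row += [_F3.format(v) for v in d.model_coords[name]]
        loop.add_row(row)

    if d.bonds:
        loop = blk.init_loop(
            "_chem_comp_bond.",
            ["comp_id", "atom_id_1", "atom_id_2", "type", "value_dist", "value_dist_esd"],
        )
        for b in d.bonds:
            loop.add_row([d.comp_id, b.atom1, b.atom2, b.order,
                          _F3.format(b.length), _F3.format(b.sigma)])

    if d.angles:
        loop = blk.init_loop(
            "_chem_comp_angle.",
            ["comp_id", "atom_id_1", "atom_id_2", "atom_id_3",
             "value_angle", "value_angle_esd"],
        )
        for a in d.angles:
            loop.add_row([d.comp_id, a.atom1, a.atom2, a.atom3,
                          _DEG.format(a.value_deg), _DEG.format(a.sigma_deg)])

    if d.torsions:
        ring = [t for t in d.torsions if t.is_ring]
        ring.sort(key=lambda t: t.id)
        other = [t for t in d.torsions if not t.is_ring]
        loop = blk.init_loop(
            "_chem_comp_tor.",
            ["comp_id", "id", "atom_id_1", "atom_id_2", "atom_id_3", "atom_id_4",
             "value_angle", "value_angle_esd", "period"],
        )
        for t in ring + other:
            loop.add_row([d.comp_id, t.id, *t.atoms,
                          _DEG.format(t.value_deg), _DEG.format(t.sigma_deg),
                          str(t.period)])

    if d.chiralities:
        loop = blk.init_loop(
            "_chem_comp_chir.",
            ["comp_id", "id", "atom_id_centre", "atom_id_1", "atom_id_2",
             "atom_id_3", "volume_sign"],
        )
        for ch in d.chiralities:
            loop.add_row([d.comp_id, ch.id, ch.centre, *ch.neighbours, ch.sign])

    if d.planes:
        loop = blk.init_loop(
            "_chem_comp_plane_atom.",
            ["comp_id", "plane_id", "atom_id", "dist_esd"],
        )
        for p in d.planes:
            for name in p.atoms:
                loop.add_row([d.comp_id, p.id, name, _F3.format(p.sigma)])

    for extra in d.extra_items:
        if extra[0] == "loop":
            _, tags, rows = extra
            prefix = tags[0].split(".", 1)[0] + "."
            loop = blk.init_loop(prefix, [t.split(".", 1)[-1] for t in tags])
            for row in rows:
                loop.add_row([cif.quote(v) for v in row])
        else:
            _, tag, value = extra
            blk.set_pair(tag, value)

    text = doc.as_string()
    if dest is not None:
        Path(dest).write_text(text)
    return text


# ---------------------------------------------------------------------------
# coordinate readers


def _slurp(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    s = str(source)
    if "\n" not in s and Path(s).is_file():
        return Path(s).read_text()
    return s


def _looks_like_cif(text: str) -> bool:
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        return line.startswith("data_") or line.startswith("loop_")
    return False


def read_monomer_coords(source: str | Path, comp_id: str) -> list[MonomerCoordinates]:
    """Extract coordinates for every residue instance of ``comp_id``.

    ``source`` may be PDB-format text (or a path to it) or a CCD-style
    component CIF block.  Atom names are whitespace-normalized.  When an
    atom has alternate locations, the highest-occupancy one is kept (ties
    broken by first occurrence).  An absent ``comp_id`` gives an empty
    list.
    """
    text = _slurp(source)
    if _looks_like_cif(text):
        return _coords_from_ccd(text, comp_id)
    return _coords_from_pdb(text, comp_id)


def write_pdb(
    coords: MonomerCoordinates | Sequence[MonomerCoordinates],
    path: str | Path,
    elements: Mapping[str, str] | None = None,
) -> None:
    """Write residues as a PDB file (HETATM records, one residue each).

    Elements default to the first letter of each atom name, which is
    correct for conventional sugar names (O5, C1, N2...).
    """
    import gemmi

    if isinstance(coords, MonomerCoordinates):
        coords = [coords]
    st = gemmi.Structure()
    model = gemmi.Model("1")
    chain_names = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    for i, c in enumerate(coords):
        chain = gemmi.Chain(c.chain or next(chain_names))
        res = gemmi.Residue()
        res.name = c.comp_id or "UNK"
        res.seqid.num = c.seqnum if c.seqnum is not None else i + 1
        res.het_flag = "H"
        for name in c.atoms():
            atom = gemmi.Atom()
            atom.name = name
            el = elements.get(name) if elements else None
            atom.element = gemmi.Element(el or name[0])
            x, y, z = c[name]
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = (c.occupancies or {}).get(name, 1.0)
            res.add_atom(atom)
        chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _coords_from_pdb(text: str, comp_id: str) -> list[MonomerCoordinates]:
    import gemmi

    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise CifParseError(f"unparseable PDB input: {exc}") from exc
    out: list[MonomerCoordinates] = []
    if len(st) == 0:
        return out
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name.strip() != comp_id:
                continue
            best: dict[str, tuple[float, np.ndarray]] = {}
            occ: dict[str, float] = {}
            for atom in res:
                name = atom.name.strip()
                xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if name not in best or atom.occ > best[name][0]:
                    best[name] = (atom.occ, xyz)
                    occ[name] = atom.occ
            out.append(
                MonomerCoordinates(
                    coords={k: v for k, (_, v) in best.items()},
                    occupancies=occ,
                    comp_id=comp_id,
                    chain=chain.name,
                    seqnum=res.seqid.num,
                )
            )
    return out


def _coords_from_ccd(text: str, comp_id: str) -> list[MonomerCoordinates]:
    try:
        doc = cif.read_string(text)
    except Exception as exc:
        raise CifParseError(f"not valid CIF: {exc}") from exc
    out: list[MonomerCoordinates] = []
    for block in doc:
        for cols in (
            ["comp_id", "atom_id", "model_Cartn_x", "model_Cartn_y", "model_Cartn_z"],
            ["comp_id", "atom_id", "pdbx_model_Cartn_x_ideal",
             "pdbx_model_Cartn_y_ideal", "pdbx_model_Cartn_z_ideal"],
            ["comp_id", "atom_id", "x", "y", "z"],
        ):
            tbl = block.find("_chem_comp_atom.", cols)
            if tbl and len(tbl) > 0:
                coords: dict[str, np.ndarray] = {}
                for row in tbl:
                    if cif.as_string(row[0]).strip() != comp_id:
                        continue
                    if row[2] in (".", "?"):
                        continue
                    coords[cif.as_string(row[1]).strip()] = np.array(
                        [float(row[2]), float(row[3]), float(row[4])]
                    )
                if coords:
                    out.append(MonomerCoordinates(coords=coords, comp_id=comp_id))
                break
    return out
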