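"""MDL SDF V2000 reading and writing (transparent gzip).

Records are parsed into :class:`~moltk.graph.MoleculeGraph` objects with the
MDL data block captured verbatim and in order.  Bond order 4 is interpreted as
aromatic and re-kekulized on load; ring membership and aromaticity are
perceived for every record.  Output is kekulized by default; aromatic bonds
can be written as order 4 with ``explicit_aromaticity=True``.
"""

from __future__ import annotations

import gzip
import io
import warnings
from pathlib import Path

import numpy as np

from .graph import Bond, MoleculeGraph, kekulize, perceive_rings_and_aromaticity

__all__ = ["read_sdf", "write_sdf", "read_sdf_string", "write_sdf_string",
           "SdfParseError"]

GZIP_MAGIC = b"\x1f\x8b"

# MDL charge column code -> formal charge
_MDL_CHARGE = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}
_MDL_CHARGE_INV = {v: k for k, v in _MDL_CHARGE.items()}


class SdfParseError(ValueError):
    def __init__(self, message, record_index=None):
        self.record_index = record_index
        if record_index is not None:
            message = f"record {record_index}: {message}"
        super().__init__(message)


def _open_text(source) -> io.TextIOBase:
    if isinstance(source, (str, Path)):
        raw = Path(source).read_bytes()
    elif isinstance(source, bytes):
        raw = source
    else:  # file-like
        raw = source.read()
        if isinstance(raw, str):
            raw = raw.encode()
    if raw[:2] == GZIP_MAGIC:
        raw = gzip.decompress(raw)
    return io.StringIO(raw.decode("utf-8", errors="replace"))


def _parse_record(lines: list[str], record_index: int) -> MoleculeGraph:
    if len(lines) < 4:
        raise SdfParseError("truncated record", record_index)
    name = lines[0].strip()
    counts = lines[3]
    if "V3000" in counts:
        raise SdfParseError("V3000 records are not supported", record_index)
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError) as exc:
        raise SdfParseError(f"malformed counts line {counts!r}", record_index) from exc
    if len(lines) < 4 + n_atoms + n_bonds:
        raise SdfParseError("atom/bond block shorter than counts line", record_index)
    mol = MoleculeGraph(name=name)
    for i in range(n_atoms):
        ln = lines[4 + i]
        try:
            x, y, z = float(ln[0:10]), float(ln[10:20]), float(ln[20:30])
            element = ln[31:34].strip()
            charge_code = int(ln[36:39]) if ln[36:39].strip() else 0
        except (ValueError, IndexError) as exc:
            raise SdfParseError(f"malformed atom line {i + 1}", record_index) from exc
        mol.add_atom(element, _MDL_CHARGE.get(charge_code, 0), (x, y, z))
    aromatic_input = False
    for i in range(n_bonds):
        ln = lines[4 + n_atoms + i]
        try:
            a1 = int(ln[0:3]) - 1
            a2 = int(ln[3:6]) - 1
            order = int(ln[6:9])
        except (ValueError, IndexError) as exc:
            raise SdfParseError(f"malformed bond line {i + 1}", record_index) from exc
        if not (0 <= a1 < n_atoms and 0 <= a2 < n_atoms):
            raise SdfParseError(f"bond {i + 1} references missing atom", record_index)
        if order == 4:
            aromatic_input = True
            mol.add_bond(a1, a2, 1, aromatic=True)
        else:
            mol.add_bond(a1, a2, order)
    # M  CHG lines override the atom-block charge column
    pos = 4 + n_atoms + n_bonds
    while pos < len(lines) and not lines[pos].startswith("M  END"):
        ln = lines[pos]
        if ln.startswith("M  CHG"):
            fields = ln.split()
            for j in range(4, len(fields), 2):
                mol.atoms[int(fields[j - 1]) - 1].formal_charge = int(fields[j])
        pos += 1
    # data block
    key = None
    buf: list[str] = []
    for ln in lines[pos:]:
        if ln.startswith("> "):
            if key is not None:
                mol.properties[key] = "\n".join(buf).rstrip("\n")
            lt, gt = ln.find("<"), ln.rfind(">")
            key = ln[lt + 1:gt] if 0 <= lt < gt else ln[2:].strip()
            buf = []
        elif key is not None:
            if ln.strip() == "" and buf:
                mol.properties[key] = "\n".join(buf)
                key = None
            elif ln.strip() != "" or buf:
                buf.append(ln.rstrip("\n"))
    if key is not None:
        mol.properties[key] = "\n".join(buf).rstrip("\n")
    if aromatic_input:
        for idx in {i for b in mol.bonds if b.aromatic for i in (b.a1, b.a2)}:
            mol.atoms[idx].aromatic = True
        mol = kekulize(mol, provisional=True)
    perceive_rings_and_aromaticity(mol)
    return mol


def read_sdf(source, strict: bool = False) -> list[MoleculeGraph]:
    """Read every ``$$$$``-terminated record of a V2000 SDF.

    Lenient by default: an unparseable record is skipped with a warning so a
    bad molecule can be filtered rather than abort a whole file.  ``strict``
    raises :class:`SdfParseError` instead.
    """
    text = _open_text(source).read()
    mols: list[MoleculeGraph] = []
    record: list[str] = []
    index = 0
    for raw in text.splitlines():
        if raw.strip() == "$$$$":
            try:
                mols.append(_parse_record(record, index))
            except SdfParseError:
                if strict:
                    raise
                warnings.warn(f"skipping unparseable SDF record {index}",
                              stacklevel=2)
            record = []
            index += 1
        else:
            record.append(raw)
    if any(ln.strip() for ln in record):
        try:
            mols.append(_parse_record(record, index))
        except SdfParseError:
            if strict:
                raise
            warnings.warn(f"skipping unparseable SDF record {index}",
                          stacklevel=2)
    return mols


def _format_record(mol: MoleculeGraph, explicit_aromaticity: bool) -> str:
    if explicit_aromaticity:
        out = mol
    else:
        out = mol  # bond orders are stored kekulized already
        bad = [b for b in out.bonds if b.order not in (1, 2, 3)]
        if bad:
            raise ValueError(
                f"molecule {mol.name!r}: non-kekulizable bonds at atoms "
                f"{sorted({i for b in bad for i in (b.a1, b.a2)})}")
    lines = [mol.name, "  moltk", "", f"{out.n_atoms:3d}{len(out.bonds):3d}"
             "  0  0  0  0  0  0  0  0999 V2000"]
    for a in out.atoms:
        x, y, z = (float(c) for c in a.coords)
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3s} 0"
                     f"{_MDL_CHARGE_INV.get(a.formal_charge, 0):3d}"
                     "  0  0  0  0  0  0  0  0  0  0")
    for b in out.bonds:
        order = 4 if (explicit_aromaticity and b.aromatic) else b.order
        lines.append(f"{b.a1 + 1:3d}{b.a2 + 1:3d}{order:3d}  0  0  0  0")
    charged = [(a.index + 1, a.formal_charge) for a in out.atoms
               if a.formal_charge != 0]
    for i in range(0, len(charged), 8):
        chunk = charged[i:i + 8]
        lines.append("M  CHG" + f"{len(chunk):3d}" +
                     "".join(f"{idx:4d}{q:4d}" for idx, q in chunk))
    lines.append("M  END")
    for k, v in mol.properties.items():
        lines.append(f"> <{k}>")
        lines.append(str(v))
        lines.append("")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


def write_sdf_string(mols, explicit_aromaticity: bool = False) -> str:
    if isinstance(mols, MoleculeGraph):
        mols = [mols]
    return "".join(_format_record(m, explicit_aromaticity) for m in mols)


def write_sdf(mols, target, explicit_aromaticity: bool = False) -> bytes:
    """Write molecules as V2000 SDF; ``target=None`` returns bytes.

    A ``.gz`` path suffix triggers gzip compression.
    """
    data = write_sdf_string(mols, explicit_aromaticity).encode()
    if target is None:
        return data
    path = Path(target)
    if path.suffix == ".gz":
        path.write_bytes(gzip.compress(data))
    else:
        path.write_bytes(data)
    return data


def read_sdf_string(text: str, strict: bool = False) -> list[MoleculeGraph]:
    return read_sdf(text.encode(), strict=strict)
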