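"""PDB-format I/O: REMARK 3 TLS records, ANISOU records, ensembles.

TLS groups are deposited in PDB headers in two dialects: the REFMAC layout
("RESIDUE RANGE :" selections, T/L/S element tags spread over numbered
lines) and the PHENIX layout (free-form "SELECTION:" strings).  Both are
parsed by a single tolerant scanner that never raises on arbitrary text:
malformed groups come back flagged as wrong content rather than dropped,
which is what a whole-archive survey needs.

Deposition units differ from the internal ones: ``L`` is deposited in deg^2
and ``S`` in A.deg, while internally everything is rad-based.  Conversion
happens here and only here.

Coordinate records (ATOM/ANISOU, multi-MODEL ensembles) go through gemmi.
ANISOU integers are U x 10^4 A^2 in element order U11 U22 U33 U12 U13 U23.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import gemmi
import numpy as np

from .ensemble import Ensemble
from .model import ADPSet, Atom, AtomGroup, InvalidInputError, TLSMatrices

__all__ = [
    "TLSRecord",
    "ResidueRange",
    "parse_tls_records",
    "write_tls_records",
    "to_internal_units",
    "from_internal_units",
    "parse_selection",
    "read_group_atoms",
    "read_anisou",
    "write_anisou",
    "write_ensemble",
]

DEG2RAD = math.pi / 180.0

_T_KEYS = ("T11", "T22", "T33", "T12", "T13", "T23")
_L_KEYS = ("L11", "L22", "L33", "L12", "L13", "L23")
_S_KEYS = ("S11", "S12", "S13", "S21", "S22", "S23", "S31", "S32", "S33")


@dataclass
class ResidueRange:
    """Inclusive residue range on one chain (PDB convention)."""

    chain: str
    begin: int
    end: int

    def contains(self, chain: str, resseq: int) -> bool:
        return chain == self.chain and self.begin <= resseq <= self.end


Selection = Union[str, ResidueRange, Sequence[ResidueRange]]


@dataclass
class TLSRecord:
    """One deposited TLS group, still in deposition units."""

    group_id: int
    ranges: List[ResidueRange] = field(default_factory=list)
    selection_string: Optional[str] = None
    origin: Optional[np.ndarray] = None
    T: Optional[np.ndarray] = None  # A^2
    L: Optional[np.ndarray] = None  # deg^2
    S: Optional[np.ndarray] = None  # A.deg
    dialect: str = "refmac"
    flags: List[str] = field(default_factory=list)

    @property
    def wrong_content(self) -> bool:
        return bool(self.flags)

    @property
    def complete(self) -> bool:
        return (self.origin is not None and self.T is not None
                and self.L is not None and self.S is not None
                and (self.ranges or self.selection_string))


def _sym_from_six(vals: dict, keys) -> Optional[np.ndarray]:
    if any(k not in vals for k in keys):
        return None
    a11, a22, a33, a12, a13, a23 = (vals[k] for k in keys)
    return np.array([[a11, a12, a13], [a12, a22, a23], [a13, a23, a33]])


def _s_from_nine(vals: dict) -> Optional[np.ndarray]:
    if any(k not in vals for k in _S_KEYS):
        return None
    return np.array([vals[k] for k in _S_KEYS]).reshape(3, 3)


_GROUP_RE = re.compile(r"REMARK\s+3\s+TLS GROUP\s*:\s*(\S+)")
_RANGE_RE = re.compile(
    r"REMARK\s+3\s+RESIDUE RANGE\s*:\s*(\S+)\s+(-?\d+)\S*\s+(\S+)\s+(-?\d+)")
_SELECTION_RE = re.compile(r"REMARK\s+3\s+SELECTION\s*:\s*(.+?)\s*$")
_ORIGIN_RE = re.compile(
    r"REMARK\s+3\s+ORIGIN FOR THE GROUP \(A\)\s*:?\s*(.*)$")
_ELEMENT_RE = re.compile(r"([TLS][123][123])\s*:\s*(-?[\d.]+(?:[eE][+-]?\d+)?)")


def parse_tls_records(text: str) -> List[TLSRecord]:
    """Extract every TLS group from the REMARK 3 block of PDB text.

    Total over arbitrary text: unparseable numbers, missing origins or
    incomplete tensors flag the record instead of raising.  An empty list
    simply means no TLS groups were found.
    """
    records: List[TLSRecord] = []
    current: Optional[TLSRecord] = None
    elements: dict = {}

    def close(rec: Optional[TLSRecord]) -> None:
        if rec is None:
            return
        rec.T = _sym_from_six(elements, _T_KEYS)
        rec.L = _sym_from_six(elements, _L_KEYS)
        rec.S = _s_from_nine(elements)
        if rec.origin is None:
            rec.flags.append("missing origin")
        for name, m in (("T", rec.T), ("L", rec.L), ("S", rec.S)):
            if m is None:
                rec.flags.append(f"incomplete {name} tensor")
        if not rec.ranges and not rec.selection_string:
            rec.flags.append("missing selection")
        records.append(rec)

    for line in text.splitlines():
        if not line.startswith("REMARK   3"):
            continue
        gm = _GROUP_RE.search(line)
        if gm:
            close(current)
            elements = {}
            try:
                gid = int(gm.group(1))
            except ValueError:
                gid = len(records) + 1
            current = TLSRecord(group_id=gid)
            continue
        if current is None:
            continue
        rm = _RANGE_RE.search(line)
        if rm:
            try:
                current.ranges.append(ResidueRange(
                    rm.group(1), int(rm.group(2)), int(rm.group(4))))
            except ValueError:
                current.flags.append("unreadable residue range")
            continue
        sm = _SELECTION_RE.search(line)
        if sm:
            current.selection_string = sm.group(1)
            current.dialect = "phenix"
            continue
        om = _ORIGIN_RE.search(line)
        if om:
            tail = om.group(1)
            nums = re.findall(r"-?\d+\.?\d*(?:[eE][+-]?\d+)?", tail)
            if len(nums) >= 3:
                try:
                    current.origin = np.array([float(x) for x in nums[:3]])
                except ValueError:
                    current.flags.append("unreadable origin")
            else:
                current.flags.append("unreadable origin")
            continue
        for key, val in _ELEMENT_RE.findall(line):
            try:
                elements[key] = float(val)
            except ValueError:
                current.flags.append(f"unreadable element {key}")
    close(current)
    return records


def write_tls_records(records: Sequence[TLSRecord]) -> str:
    """REFMAC-style REMARK 3 text for the given records (deposition units)."""
    lines = ["REMARK   3  TLS DETAILS",
             f"REMARK   3   NUMBER OF TLS GROUPS  : {len(records):4d}"]
    for rec in records:
        lines.append(f"REMARK   3   TLS GROUP : {rec.group_id}")
        for rr in rec.ranges:
            lines.append("REMARK   3    RESIDUE RANGE :   "
                         f"{rr.chain:<4s}{rr.begin:5d}     {rr.chain:>4s}{rr.end:6d}")
        if rec.selection_string:
            lines.append(f"REMARK   3    SELECTION: {rec.selection_string}")
        if rec.origin is not None:
            ox, oy, oz = rec.origin
            lines.append("REMARK   3    ORIGIN FOR THE GROUP (A): "
                         f"{ox:9.4f} {oy:9.4f} {oz:9.4f}")
        if rec.T is not None:
            tm = rec.T
            lines.append("REMARK   3    T TENSOR")
            lines.append(f"REMARK   3      T11: {tm[0,0]:9.4f} T22: {tm[1,1]:9.4f}")
            lines.append(f"REMARK   3      T33: {tm[2,2]:9.4f} T12: {tm[0,1]:9.4f}")
            lines.append(f"REMARK   3      T13: {tm[0,2]:9.4f} T23: {tm[1,2]:9.4f}")
        if rec.L is not None:
            lm = rec.L
            lines.append("REMARK   3    L TENSOR")
            lines.append(f"REMARK   3      L11: {lm[0,0]:9.4f} L22: {lm[1,1]:9.4f}")
            lines.append(f"REMARK   3      L33: {lm[2,2]:9.4f} L12: {lm[0,1]:9.4f}")
            lines.append(f"REMARK   3      L13: {lm[0,2]:9.4f} L23: {lm[1,2]:9.4f}")
        if rec.S is not None:
            sm = rec.S
            lines.append("REMARK   3    S TENSOR")
            lines.append(f"REMARK   3      S11: {sm[0,0]:9.4f} S12: {sm[0,1]:9.4f} "
                         f"S13: {sm[0,2]:9.4f}")
            lines.append(f"REMARK   3      S21: {sm[1,0]:9.4f} S22: {sm[1,1]:9.4f} "
                         f"S23: {sm[1,2]:9.4f}")
            lines.append(f"REMARK   3      S31: {sm[2,0]:9.4f} S32: {sm[2,1]:9.4f} "
                         f"S33: {sm[2,2]:9.4f}")
    return "\n".join(lines) + "\n"


def to_internal_units(rec: TLSRecord) -> TLSMatrices:
    """Deposition units -> internal units (L: deg^2 -> rad^2, S: A.deg -> A.rad)."""
    if not rec.complete:
        raise InvalidInputError(
            f"TLS group {rec.group_id} is incomplete: {rec.flags or 'no data'}")
    return TLSMatrices(
        T=rec.T.copy(),
        L=rec.L * DEG2RAD**2,
        S=rec.S * DEG2RAD,
        origin=rec.origin.copy(),
    )


def from_internal_units(tls: TLSMatrices, group_id: int = 1,
                        ranges: Optional[Sequence[ResidueRange]] = None,
                        selection_string: Optional[str] = None) -> TLSRecord:
    """Internal units -> a deposition-unit record (inverse of the above)."""
    return TLSRecord(
        group_id=group_id,
        ranges=list(ranges or []),
        selection_string=selection_string,
        origin=tls.origin.copy(),
        T=tls.T.copy(),
        L=tls.L / DEG2RAD**2,
        S=tls.S / DEG2RAD,
    )


_PHENIX_SEL_RE = re.compile(
    r"^\(?\s*chain\s+'?(\w+)'?\s+and\s+resseq\s+(-?\d+)\s*[:\-]\s*(-?\d+)\s*\)?$",
    re.IGNORECASE)


def parse_selection(selection: Selection) -> List[ResidueRange]:
    """Normalize a selection to residue ranges.

    Accepts ResidueRange objects, sequences of them, or the minimal PHENIX
    grammar ``chain X and resseq i:j`` (several clauses joined by ``or``).
    Anything richer is rejected with a clear message.
    """
    if isinstance(selection, ResidueRange):
        return [selection]
    if isinstance(selection, str):
        ranges = []
        for clause in re.split(r"\s+or\s+", selection.strip(), flags=re.IGNORECASE):
            m = _PHENIX_SEL_RE.match(clause.strip())
            if not m:
                raise InvalidInputError(
                    f"unsupported selection syntax: {clause!r} (supported: "
                    "\"chain X and resseq i:j\", clauses joined by 'or')")
            ranges.append(ResidueRange(m.group(1), int(m.group(2)), int(m.group(3))))
        return ranges
    return list(selection)


def _read_structure(pdb_text: str) -> gemmi.Structure:
    st = gemmi.read_pdb_string(pdb_text)
    st.setup_entities()
    return st


def _iter_selected(model: gemmi.Model, ranges: List[ResidueRange]):
    for chain in model:
        for res in chain:
            for atom in res:
                if any(r.contains(chain.name, res.seqid.num) for r in ranges):
                    yield chain, res, atom


def read_group_atoms(pdb_text: str, selection: Selection) -> AtomGroup:
    """Atoms matched by ``selection`` from the first model, in file order.

    If ANISOU records accompany the selected atoms they are attached as the
    observed ADPs (``u_obs``); a partial set of ANISOU records is flagged by
    leaving ``u_obs`` unset.
    """
    ranges = parse_selection(selection)
    st = _read_structure(pdb_text)
    if len(st) == 0:
        raise InvalidInputError("no models in PDB input")
    atoms: List[Atom] = []
    u_list: List[np.ndarray] = []
    n_aniso = 0
    for chain, res, atom in _iter_selected(st[0], ranges):
        atoms.append(Atom(
            serial=atom.serial, element=atom.element.name, chain=chain.name,
            resseq=res.seqid.num, name=atom.name,
            xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
        a = atom.aniso
        u = np.array([[a.u11, a.u12, a.u13],
                      [a.u12, a.u22, a.u23],
                      [a.u13, a.u23, a.u33]], dtype=float)
        if a.nonzero():
            n_aniso += 1
        u_list.append(u)
    if not atoms:
        raise InvalidInputError(f"selection matched no atoms: {ranges}")
    u_obs = None
    if n_aniso == len(atoms):
        u_obs = ADPSet(np.stack(u_list))
    return AtomGroup(atoms, u_obs=u_obs)


def read_anisou(pdb_text: str, selection: Selection) -> ADPSet:
    """Observed ADPs for the selection; error if any atom lacks ANISOU."""
    group = read_group_atoms(pdb_text, selection)
    if group.u_obs is None:
        raise InvalidInputError(
            "selection has atoms without ANISOU records")
    return group.u_obs


def _group_to_gemmi(group: AtomGroup, coord_sets: np.ndarray,
                    adps: Optional[ADPSet] = None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(1, 1, 1, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    # gemmi's add_chain/add_residue copy their argument, so each container
    # is filled completely before being added to its parent
    for i_model in range(coord_sets.shape[0]):
        model = gemmi.Model(i_model + 1)
        chain_order: List[str] = []
        chain_residues: dict = {}
        for j, atom in enumerate(group.atoms):
            if atom.chain not in chain_residues:
                chain_order.append(atom.chain)
                chain_residues[atom.chain] = []
            residues = chain_residues[atom.chain]
            if not residues or residues[-1].seqid.num != atom.resseq:
                res = gemmi.Residue()
                res.name = "ALA"
                res.seqid = gemmi.SeqId(atom.resseq, " ")
                res.het_flag = "A"
                residues.append(res)
            at = gemmi.Atom()
            at.name = atom.name
            at.element = gemmi.Element(atom.element)
            x, y, z = coord_sets[i_model, j]
            at.pos = gemmi.Position(x, y, z)
            at.occ = 1.0
            if adps is not None:
                u = adps.as_array()[j]
                at.b_iso = float(8.0 * math.pi**2 * np.trace(u) / 3.0)
                at.aniso = gemmi.SMat33f(u[0, 0], u[1, 1], u[2, 2],
                                         u[0, 1], u[0, 2], u[1, 2])
            else:
                at.b_iso = 10.0
            residues[-1].add_atom(at)
        for name in chain_order:
            chain = gemmi.Chain(name)
            for res in chain_residues[name]:
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_ensemble(e: Ensemble) -> str:
    """Multi-MODEL PDB text (MODEL/ENDMDL blocks, identical atom order)."""
    st = _group_to_gemmi(e.template, e.coords)
    return st.make_pdb_string()


def write_anisou(group: AtomGroup, adps: ADPSet) -> str:
    """Single-model PDB text with ATOM + ANISOU records for ``adps``.

    ANISOU integers are U x 10^4 rounded to the nearest integer (ties away
    from zero, the printf convention gemmi inherits).
    """
    if len(adps) != len(group):
        raise InvalidInputError("one ADP per atom required")
    st = _group_to_gemmi(group, group.coords[None, :, :], adps=adps)
    return st.make_pdb_string()
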