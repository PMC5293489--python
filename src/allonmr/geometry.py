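"""Structural measurements for the four-site kinase autoinhibition model.

A receptor-tyrosine-kinase domain is held inactive by four cooperating
structural elements, and released by activation-loop phosphorylation:

1. *molecular brake* — a hydrogen-bond triad (Asn/Glu/Lys equivalents) at
   the kinase hinge;
2. *DFG latch* — hydrophobic packing of the DFG-motif phenylalanine
   against two isoleucines and a leucine from αC/αE;
3. *αC tether* — van der Waals contacts between an A-loop aspartate and
   two αC-helix methionines, formed only in the active state;
4. *A-loop plug* — a salt bridge between an invariant A-loop arginine and
   the catalytic-base aspartate that occludes the substrate site.

This module measures those descriptors on a PDB structure — atom
distances, the DFG-Phe χ1 dihedral, donor–acceptor contacts, the β9-strand
backbone-pairing fingerprint — and classifies the conformation as
autoinhibited-like, activated-like, or mixed.

Hydrogen bonds are judged by heavy-atom (N/O) distance alone, matching how
such contacts are reported in crystal-structure figures; no hydrogens are
placed and no angle term is applied.
"""

from __future__ import annotations

import math
import urllib.request
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "HBOND_CUTOFF",
    "SALT_BRIDGE_CUTOFF",
    "StructureModel",
    "Classification",
    "SiteGeometryReport",
    "load_structure",
    "fetch_structure",
    "atom_distance",
    "chi1",
    "polar_contact",
    "four_site_report",
]

HBOND_CUTOFF = 3.5  # Å, heavy-atom donor-acceptor
SALT_BRIDGE_CUTOFF = 4.0  # Å
TETHER_CONTACT_CUTOFF = 4.5  # Å, van der Waals contact of the αC tether

#: Standard gamma atom defining χ1 per residue type.
_GAMMA_ATOM = {
    "VAL": "CG1", "ILE": "CG1", "THR": "OG1", "SER": "OG", "CYS": "SG",
    "ALA": None, "GLY": None,
}

_WATERS = {"HOH", "WAT", "DOD"}


@dataclass
class StructureModel:
    """One chain of one model, altloc-filtered, with hetero atoms flagged."""

    structure: gemmi.Structure
    chain: str

    @property
    def _chain(self) -> gemmi.Chain:
        return self.structure[0][self.chain]

    def residue(self, resnum: int) -> gemmi.Residue:
        for res in self._chain:
            if res.seqid.num == resnum:
                return res
        raise KeyError(f"residue {resnum} not in chain {self.chain}")

    def has_residue(self, resnum: int) -> bool:
        try:
            self.residue(resnum)
            return True
        except KeyError:
            return False

    def atom(self, resnum: int, atom_name: str) -> gemmi.Atom:
        res = self.residue(resnum)
        for atom in res:
            if atom.name == atom_name:
                return atom
        raise KeyError(
            f"atom {atom_name} not in residue {res.name}{resnum} "
            f"(has {[a.name for a in res]})"
        )

    def residue_numbers(self) -> list[int]:
        return [r.seqid.num for r in self._chain]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body copy; used to assert invariance of measurements."""
        st = self.structure.clone()
        for model in st:
            for ch in model:
                for res in ch:
                    for atom in res:
                        p = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                        q = rotation @ p + translation
                        atom.pos = gemmi.Position(*q)
        return StructureModel(structure=st, chain=self.chain)


def load_structure(path, chain: str | None = None) -> StructureModel:
    """Read a PDB file: first model, one altloc per atom, one chain.

    Altloc 'A' (or blank) is retained.  Waters and heteroatoms stay in the
    model (flagged by their residue het flag); ``chain=None`` picks the
    only chain and errors if the file has several.
    """
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    while len(st) > 1:
        del st[1]
    available = [ch.name for ch in st[0]]
    if chain is None:
        if len(available) != 1:
            raise ValueError(f"multiple chains {available}; specify one")
        chain = available[0]
    if chain not in available:
        raise ValueError(f"chain {chain!r} not in structure; available: {available}")
    for model in st:
        for ch in model:
            for res in ch:
                to_del = [i for i, a in enumerate(res) if a.altloc not in ("\0", "", "A")]
                for i in reversed(to_del):
                    del res[i]
                for a in res:
                    a.altloc = "\0"
    return StructureModel(structure=st, chain=chain)


def fetch_structure(accession: str, cache_dir=None, chain: str | None = None) -> StructureModel:
    """Download a PDB entry from the wwPDB (or reuse a cached copy).

    Requires network access; analyses that must run offline should pass
    local files to :func:`load_structure` instead.
    """
    accession = accession.upper()
    cache_dir = Path(cache_dir) if cache_dir else Path.cwd() / "pdb_cache"
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"{accession.lower()}.pdb"
    if not path.exists():
        url = f"https://files.rcsb.org/download/{accession}.pdb"
        with urllib.request.urlopen(url, timeout=60) as resp:
            path.write_bytes(resp.read())
    return load_structure(path, chain=chain)


def _pos(atom: gemmi.Atom) -> np.ndarray:
    return np.array([atom.pos.x, atom.pos.y, atom.pos.z])


def atom_distance(s: StructureModel, sel1: tuple[int, str], sel2: tuple[int, str]) -> float:
    """Euclidean distance (Å) between two (residue_number, atom_name) picks."""
    a = s.atom(*sel1)
    b = s.atom(*sel2)
    return float(np.linalg.norm(_pos(a) - _pos(b)))


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def chi1(s: StructureModel, resnum: int) -> float:
    """Signed N–CA–CB–γ dihedral in degrees, in (−180, 180]."""
    res = s.residue(resnum)
    gamma = _GAMMA_ATOM.get(res.name, "CG")
    if gamma is None:
        raise ValueError(f"residue {res.name}{resnum} has no chi1 (no gamma atom)")
    pts = [_pos(s.atom(resnum, name)) for name in ("N", "CA", "CB", gamma)]
    ang = _dihedral(*pts)
    return 180.0 if ang == -180.0 else ang


def _polar_atoms(s: StructureModel, sel) -> list[gemmi.Atom]:
    """Resolve a selection to N/O(/S for Met-free generality stays out) atoms.

    ``sel`` is (residue_number, atom_names) where atom_names may be a
    single name, an iterable of names, or None for all side-chain N/O.
    """
    resnum, names = sel
    res = s.residue(resnum)
    if names is None:
        atoms = [a for a in res if a.element.name in ("N", "O")
                 and a.name not in ("N", "O", "C", "CA")]
    else:
        if isinstance(names, str):
            names = [names]
        atoms = [s.atom(resnum, n) for n in names]
        atoms = [a for a in atoms if a.element.name in ("N", "O")]
    if not atoms:
        raise ValueError(f"selection {sel!r} resolves to no N/O atoms")
    return atoms


def polar_contact(
    s: StructureModel, donor_sel, acceptor_sel, cutoff: float = HBOND_CUTOFF
) -> tuple[float, bool]:
    """Minimal N/O–N/O distance between two selections and an engaged flag."""
    donors = _polar_atoms(s, donor_sel)
    acceptors = _polar_atoms(s, acceptor_sel)
    dmin = min(
        float(np.linalg.norm(_pos(a) - _pos(b))) for a in donors for b in acceptors
    )
    return dmin, dmin <= cutoff


class Classification(str, Enum):
    autoinhibited_like = "autoinhibited_like"
    activated_like = "activated_like"
    mixed = "mixed"


#: Marker names the residue map must provide (values: residue numbers in
#: the structure's own numbering).
MARKER_NAMES = (
    "brake_n", "brake_e", "brake_k",          # molecular brake triad N/E/K
    "dfg_phe",                                 # DFG-motif phenylalanine
    "latch_i1", "latch_i2", "latch_l",         # DFG latch I/I/L partners
    "tether_m1", "tether_m2", "aloop_d",       # αC methionines + A-loop Asp
    "plug_r", "plug_d",                        # A-loop Arg + catalytic Asp
)

_SIDECHAIN_CARBONS = {
    "ILE": ("CG1", "CG2", "CD1"),
    "LEU": ("CG", "CD1", "CD2"),
    "VAL": ("CG1", "CG2"),
    "MET": ("CG", "SD", "CE"),
}


@dataclass
class SiteGeometryReport:
    brake: dict[str, tuple[float, bool]] = field(default_factory=dict)
    brake_engaged: bool | None = None
    dfg_latch: dict[str, float] = field(default_factory=dict)
    ac_tether: dict[str, float] = field(default_factory=dict)
    a_loop_plug: float | None = None
    plug_engaged: bool | None = None
    chi1_dfg_phe: float | None = None
    beta9_present: bool | None = None
    classification: Classification | None = None
    missing: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, (d, e) in self.brake.items():
            rows.append({"site": "brake", "measure": name, "value": d, "engaged": e})
        for name, d in self.dfg_latch.items():
            rows.append({"site": "dfg_latch", "measure": name, "value": d, "engaged": None})
        for name, d in self.ac_tether.items():
            rows.append({"site": "ac_tether", "measure": name, "value": d,
                         "engaged": d <= TETHER_CONTACT_CUTOFF})
        rows.append({"site": "a_loop_plug", "measure": "min_Neta_Odelta",
                     "value": self.a_loop_plug, "engaged": self.plug_engaged})
        rows.append({"site": "dfg", "measure": "chi1_phe", "value": self.chi1_dfg_phe,
                     "engaged": None})
        rows.append({"site": "beta9", "measure": "strand_present",
                     "value": float(self.beta9_present) if self.beta9_present is not None
                     else None, "engaged": self.beta9_present})
        rows.append({"site": "classification", "measure": "overall",
                     "value": None, "engaged": None})
        df = pd.DataFrame(rows)
        df.attrs["classification"] = (
            self.classification.value if self.classification else None
        )
        return df


def _min_sidechain_distance(s: StructureModel, from_atom, resnum: int) -> float:
    res = s.residue(resnum)
    names = _SIDECHAIN_CARBONS.get(res.name)
    if names is None:
        names = [a.name for a in res if a.name not in ("N", "CA", "C", "O", "CB")]
    dists = []
    for n in names:
        try:
            dists.append(float(np.linalg.norm(_pos(from_atom) - _pos(s.atom(resnum, n)))))
        except KeyError:
            continue
    if not dists:
        raise KeyError(f"no side-chain atoms found for residue {resnum}")
    return min(dists)


def classify(report: SiteGeometryReport) -> Classification:
    """Classification as a pure function of the report's distance fields.

    activated_like: brake disengaged AND plug broken AND the closer of the
    two tether contacts ≤ 4.5 Å.  autoinhibited_like: brake engaged AND
    plug engaged.  Anything else: mixed.
    """
    if report.brake_engaged is None or report.plug_engaged is None:
        return Classification.mixed
    tether_ok = bool(report.ac_tether) and min(report.ac_tether.values()) <= TETHER_CONTACT_CUTOFF
    if not report.brake_engaged and not report.plug_engaged and tether_ok:
        return Classification.activated_like
    if report.brake_engaged and report.plug_engaged:
        return Classification.autoinhibited_like
    return Classification.mixed


def four_site_report(
    s: StructureModel,
    residue_map: dict[str, int],
    hbond_cutoff: float = HBOND_CUTOFF,
    salt_bridge_cutoff: float = SALT_BRIDGE_CUTOFF,
) -> SiteGeometryReport:
    """Measure all four sites and classify the conformation.

    ``residue_map`` maps the marker names in :data:`MARKER_NAMES` to the
    structure's residue numbers.  Missing markers leave their fields unset
    and are listed in ``report.missing``; classification then degrades to
    ``mixed`` unless the deciding sites are all measurable.
    """
    rep = SiteGeometryReport()
    rm = dict(residue_map)
    for name in MARKER_NAMES:
        if name not in rm or not s.has_residue(rm[name]):
            rep.missing.append(name)

    def have(*names: str) -> bool:
        return all(n not in rep.missing for n in names)

    # 1. molecular brake: side-chain polar contacts among the N/E/K triad
    if have("brake_n", "brake_e", "brake_k"):
        pairs = [("n_e", rm["brake_n"], rm["brake_e"]),
                 ("e_k", rm["brake_e"], rm["brake_k"]),
                 ("n_k", rm["brake_n"], rm["brake_k"])]
        for name, r1, r2 in pairs:
            d, eng = polar_contact(s, (r1, None), (r2, None), cutoff=hbond_cutoff)
            rep.brake[name] = (d, eng)
        # the triad is a chained network; call it engaged when at least
        # two of the three pairs are H-bonded
        rep.brake_engaged = sum(e for _, e in rep.brake.values()) >= 2

    # 2. DFG latch: Phe ring tip (CZ) to nearest side-chain carbon of I/I/L
    if have("dfg_phe"):
        try:
            cz = s.atom(rm["dfg_phe"], "CZ")
            for partner in ("latch_i1", "latch_i2", "latch_l"):
                if have(partner):
                    rep.dfg_latch[partner] = _min_sidechain_distance(s, cz, rm[partner])
        except KeyError:
            rep.missing.append("dfg_phe_cz")

    # 3. αC tether: A-loop Asp side chain to the Met Sδ/Cε atoms
    if have("aloop_d"):
        d_res = s.residue(rm["aloop_d"])
        d_atoms = [a for a in d_res if a.name not in ("N", "CA", "C", "O")]
        for mname in ("tether_m1", "tether_m2"):
            if not have(mname):
                continue
            dists = []
            for met_atom in ("SD", "CE"):
                try:
                    m = s.atom(rm[mname], met_atom)
                except KeyError:
                    continue
                dists.extend(float(np.linalg.norm(_pos(a) - _pos(m))) for a in d_atoms)
            if dists:
                rep.ac_tether[mname] = min(dists)

    # 4. A-loop plug: minimal guanidinium Nη – carboxylate Oδ distance
    if have("plug_r", "plug_d"):
        d, eng = polar_contact(
            s,
            (rm["plug_r"], ["NH1", "NH2", "NE"]),
            (rm["plug_d"], ["OD1", "OD2"]),
            cutoff=salt_bridge_cutoff,
        )
        rep.a_loop_plug = d
        rep.plug_engaged = eng

    if have("dfg_phe"):
        try:
            rep.chi1_dfg_phe = chi1(s, rm["dfg_phe"])
        except (KeyError, ValueError):
            rep.missing.append("dfg_phe_chi1")

    # β9 strand: >= 2 backbone N–O pairs <= hbond cutoff between the
    # A-loop strand (DFG+2 .. DFG+7) and the catalytic-loop strand
    if have("dfg_phe", "plug_d"):
        aloop = range(rm["dfg_phe"] + 2, rm["dfg_phe"] + 8)
        cat = range(rm["plug_d"] - 3, rm["plug_d"] + 4)
        n_pairs = 0
        for ra in aloop:
            for rb in cat:
                if not (s.has_residue(ra) and s.has_residue(rb)):
                    continue
                for a_name, b_name in (("N", "O"), ("O", "N")):
                    try:
                        d = atom_distance(s, (ra, a_name), (rb, b_name))
                    except KeyError:
                        continue
                    if d <= hbond_cutoff:
                        n_pairs += 1
        rep.beta9_present = n_pairs >= 2

    rep.classification = classify(rep)
    return rep
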