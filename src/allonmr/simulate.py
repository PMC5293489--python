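"""Ground-truth generators for every analysis stage.

The kinase domain is modelled as toggling between an autoinhibited and an
active conformer in fast exchange, so each observed shift is the
population-weighted average

    δ_obs = (1 − p_active)·δ_inhibited + p_active·δ_active .

A panel of states (wild type, graded gain-of-function mutants, the
phosphorylated protein) then differs only in p_active, which is exactly
the statistical structure CSP mapping and covariance clustering assume.
Dispersion curves are drawn from the fast-exchange Luz–Meiboom profile,
PRE tables from the Battiste–Wagner forward relation, and structure
fixtures are minimal PDB files whose marker atoms sit at exactly known
coordinates.  All generators are bit-reproducible under a fixed seed.

Noise models: additive Gaussian on chemical shifts and on R2,eff;
multiplicative log-normal on peak heights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .cpmg import (
    DEFAULT_CONSTANT_TIME,
    DEFAULT_NU_GRID,
    REFERENCE_FIELD_MHZ,
    DispersionCurve,
    DispersionPoint,
    ExchangeModel,
    Experiment,
    luz_meiboom,
)
from .peaklist import (
    AtomGroup,
    NucleusClass,
    PeakEntry,
    PeakList,
    ResonanceKey,
    StateSet,
)
from .pre import PREParameters, distance_to_gamma2, gamma2_to_retention

__all__ = [
    "TwoStateSpec",
    "CpmgSimSpec",
    "PreSimSpec",
    "simulate_states",
    "simulate_cpmg",
    "simulate_pre",
    "make_structure_fixture",
    "DEFAULT_STATE_POPULATIONS",
    "DEFAULT_CPMG_PHI",
    "FIXTURE_RESIDUE_MAP",
]

# Seven-state default panel: unphosphorylated WT, five activation-loop
# mutants with graded active-state populations, and phosphorylated WT.
DEFAULT_STATE_POPULATIONS = {
    "WT_unphos": 0.0,
    "K659T": 0.15,
    "K659N": 0.30,
    "K659Q": 0.45,
    "K659M": 0.60,
    "K659E": 0.75,
    "WT_phos": 1.0,
}

_AMIDE_TYPES = "ACDEFGHIKLMNQRSTVWY"  # no proline: prolines have no amide


@dataclass
class TwoStateSpec:
    """Two-state fast-exchange shift model over a panel of states.

    The construct spans ``n_residues`` starting at ``first_residue``; the
    ``n_network`` residues of the allosteric network are spread evenly
    through the sequence and are the only ones whose shifts differ between
    the two conformers.
    """

    n_residues: int = 300
    first_residue: int = 459
    n_network: int = 18
    populations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_POPULATIONS))
    delta_omega_h_range: tuple[float, float] = (0.05, 0.12)  # ppm, 1H
    delta_omega_n_range: tuple[float, float] = (0.5, 1.2)  # ppm, 15N
    noise_sd_h: float = 0.002  # ppm
    noise_sd_n: float = 0.02  # ppm
    spectrometer_h_mhz: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.populations.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("populations must lie in [0, 1]")
        if self.n_network > self.n_residues:
            raise ValueError("network larger than the protein")

    def network_residue_numbers(self) -> list[int]:
        idx = np.linspace(0, self.n_residues - 1, self.n_network).round().astype(int)
        return [self.first_residue + int(i) for i in idx]


def simulate_states(spec: TwoStateSpec) -> StateSet:
    """Generate the peak lists of the state panel (backbone amides).

    Returns a StateSet in the order of ``spec.populations``.  With zero
    noise and two states of p_active 0 and 1, the CSP of each network
    residue equals its combined Δω exactly; with graded populations the
    CCS profiles of all network residues are exactly collinear.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    resnums = np.arange(spec.first_residue, spec.first_residue + n)
    restypes = rng.choice(list(_AMIDE_TYPES), size=n)
    base_h = rng.normal(8.3, 0.45, size=n)
    base_n = rng.normal(119.0, 4.0, size=n)

    network = set(spec.network_residue_numbers())
    in_net = np.array([r in network for r in resnums])
    sign = rng.choice([-1.0, 1.0], size=n)
    dw_h = np.where(
        in_net, sign * rng.uniform(*spec.delta_omega_h_range, size=n), 0.0)
    dw_n = np.where(
        in_net, sign * rng.uniform(*spec.delta_omega_n_range, size=n), 0.0)

    states = []
    for state_id, p in spec.populations.items():
        obs_h = base_h + p * dw_h + rng.normal(0.0, spec.noise_sd_h, size=n)
        obs_n = base_n + p * dw_n + rng.normal(0.0, spec.noise_sd_n, size=n)
        heights = 1e5 * rng.lognormal(0.0, 0.1, size=n)
        pl = PeakList(state_id=state_id, nucleus_class=NucleusClass.HN_N)
        for i in range(n):
            key = ResonanceKey(int(resnums[i]), str(restypes[i]),
                               AtomGroup.backbone_amide)
            pl.add(key, PeakEntry(shift_h=float(obs_h[i]), shift_x=float(obs_n[i]),
                                  height=float(heights[i])))
        states.append(pl)
    return StateSet(states=states, spectrometer_h_mhz=spec.spectrometer_h_mhz)


# Default six-residue methyl panel for dispersion simulation: Φ at the
# reference field (s⁻²), chosen so ΔR2,eff at 600 MHz spans ~3–8 s⁻¹.
DEFAULT_CPMG_PHI = {
    ResonanceKey(548, "I", AtomGroup.ile_methyl): 17100.0,
    ResonanceKey(623, "I", AtomGroup.ile_methyl): 12000.0,
    ResonanceKey(627, "L", AtomGroup.leu_methyl): 9000.0,
    ResonanceKey(647, "L", AtomGroup.leu_methyl): 14000.0,
    ResonanceKey(707, "I", AtomGroup.ile_methyl): 11000.0,
    ResonanceKey(709, "V", AtomGroup.val_methyl): 8000.0,
}


@dataclass
class CpmgSimSpec:
    k_ex: float = 2000.0
    phi: dict = field(default_factory=lambda: dict(DEFAULT_CPMG_PHI))
    r2_0: float = 20.0
    fields_mhz: tuple[float, ...] = (600.0, 800.0)
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID
    n_replicates: int = 2
    T: float = DEFAULT_CONSTANT_TIME
    experiment: Experiment = Experiment.c13_mq
    noise_sd: float = 0.3  # s^-1
    seed: int = 0


def simulate_cpmg(spec: CpmgSimSpec) -> list[DispersionCurve]:
    """Forward-simulate dispersion curves, Φ scaled by the squared field ratio."""
    rng = np.random.default_rng(spec.seed)
    curves = []
    for key in sorted(spec.phi):
        for field_mhz in spec.fields_mhz:
            phi = spec.phi[key] * (field_mhz / REFERENCE_FIELD_MHZ) ** 2
            model = ExchangeModel(k_ex=spec.k_ex, phi=phi, r2_0=spec.r2_0)
            points = []
            for rep in range(spec.n_replicates):
                clean = luz_meiboom(np.array(spec.nu_grid), model)
                noisy = clean + rng.normal(0.0, spec.noise_sd, size=len(spec.nu_grid))
                points.extend(
                    DispersionPoint(nu_cpmg=float(nu), r2eff=float(r2), replicate_id=rep)
                    for nu, r2 in zip(spec.nu_grid, noisy)
                )
            curves.append(
                DispersionCurve(key=key, field_mhz=field_mhz,
                                experiment=spec.experiment, T=spec.T, points=points)
            )
    return curves


@dataclass
class PreSimSpec:
    true_distances: dict  # ResonanceKey -> Å
    params: PREParameters = field(default_factory=PREParameters)
    noise_sd: float = 0.02  # log-normal sigma on heights
    base_height: float = 1e5
    detection_limit: float = 0.005  # oxidized peaks below this fraction vanish
    seed: int = 0


def simulate_pre(spec: PreSimSpec) -> pd.DataFrame:
    """Oxidized/reduced height table from known spin-label distances.

    Each distance runs through the forward dipolar and ratio relations to
    a retention; heights get multiplicative log-normal noise.  Oxidized
    peaks whose retention falls below the detection limit are reported as
    zero — the short-distance bound the classifier expects.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for key in sorted(spec.true_distances):
        dist = spec.true_distances[key]
        gamma2 = distance_to_gamma2(dist, spec.params)
        retention = gamma2_to_retention(gamma2, spec.params)
        i_red = spec.base_height * rng.lognormal(0.0, spec.noise_sd)
        i_ox = retention * spec.base_height * rng.lognormal(0.0, spec.noise_sd)
        if retention < spec.detection_limit:
            i_ox = 0.0
        rows.append(
            {
                "residue_number": key.residue_number,
                "residue_type": key.residue_type,
                "i_ox": i_ox,
                "i_red": i_red,
                "true_distance": dist,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Structure fixtures
# ---------------------------------------------------------------------------

#: Marker numbering used by all structure fixtures (FGFR2-kinase style).
FIXTURE_RESIDUE_MAP = {
    "brake_n": 549, "brake_e": 565, "brake_k": 641,
    "dfg_phe": 645,
    "latch_i1": 541, "latch_i2": 547, "latch_l": 617,
    "tether_m1": 537, "tether_m2": 540, "aloop_d": 650,
    "plug_r": 664, "plug_d": 626,
}


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """Internal-coordinate (NeRF) placement of atom d bonded to c.

    |cd| = bond, angle(b, c, d) = angle_deg, dihedral(a, b, c, d) =
    dihedral_deg with the standard signed convention.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(theta), -bond * math.sin(theta) * math.cos(chi),
         -bond * math.sin(theta) * math.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _element_of(atom_name: str) -> str:
    return atom_name[0]  # all fixture atoms are C/N/O/S named conventionally


def _add_residue(chain: gemmi.Chain, resnum: int, resname: str, atoms: dict) -> None:
    res = gemmi.Residue()
    res.name = resname
    res.seqid = gemmi.SeqId(resnum, " ")
    for name, xyz in atoms.items():
        at = gemmi.Atom()
        at.name = name
        at.pos = gemmi.Position(*[float(v) for v in xyz])
        at.element = gemmi.Element(_element_of(name))
        at.occ = 1.0
        at.b_iso = 0.0
        res.add_atom(at)
    chain.add_residue(res)


def _backbone(origin) -> dict:
    o = np.asarray(origin, dtype=float)
    return {
        "N": o + (0.0, 0.0, 0.0),
        "CA": o + (1.458, 0.0, 0.0),
        "C": o + (2.01, 1.42, 0.0),
        "O": o + (3.23, 1.55, 0.0),
    }


def _phe_atoms(origin, chi1_deg: float) -> dict:
    """Phenylalanine with an exactly prescribed χ1; ring tip (CZ) colinear
    with the CB→CG direction at the canonical CG–CZ span."""
    o = np.asarray(origin, dtype=float)
    n = o + np.array([0.0, 0.0, 0.0])
    ca = o + np.array([1.458, 0.0, 0.0])
    u = np.array([math.cos(math.radians(69.5)), math.sin(math.radians(69.5)), 0.0])
    cb = ca + 1.53 * u
    cg = _place_atom(n, ca, cb, 1.50, 113.8, chi1_deg)
    cz = cg + 2.87 * (cg - cb) / np.linalg.norm(cg - cb)
    c = ca + 1.52 * np.array([0.35, -0.94, 0.0])
    oxy = c + np.array([1.1, -0.55, 0.0])
    return {"N": n, "CA": ca, "CB": cb, "CG": cg, "CZ": cz, "C": c, "O": oxy}


def _fixture_structure(name: str) -> tuple[gemmi.Structure, gemmi.Chain]:
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")
    model.add_chain(chain)
    st.add_model(model)
    return st, st[0]["A"]


def make_structure_fixture(kind: str, seed: int = 0) -> str:
    """PDB text with marker residues at exactly known coordinates.

    kind="active_like"     four-site geometry of an activated kinase
                           (brake open, plug broken, tether formed, β9 on)
    kind="inhibited_like"  the autoinhibited counterpart
    kind="chi1_pair"       chains A and B holding one phenylalanine each,
                           χ1 = −60° and +60° (a 120° rotamer change)
    kind="arbitrary"       seeded random backbone-only structure
    """
    if kind == "chi1_pair":
        st = gemmi.Structure()
        st.name = "chi1_pair"
        model = gemmi.Model(1)
        for chain_name, chi in (("A", -60.0), ("B", 60.0)):
            ch = gemmi.Chain(chain_name)
            model.add_chain(ch)
        st.add_model(model)
        for chain_name, chi in (("A", -60.0), ("B", 60.0)):
            _add_residue(st[0][chain_name], 645, "PHE", _phe_atoms((0, 0, 0), chi))
        return st.make_pdb_string()

    if kind == "arbitrary":
        rng = np.random.default_rng(seed)
        st, chain = _fixture_structure("arbitrary")
        for i in range(10):
            _add_residue(chain, 100 + i, "ALA",
                         _backbone(rng.uniform(-20.0, 20.0, size=3)))
        return st.make_pdb_string()

    if kind not in ("active_like", "inhibited_like"):
        raise ValueError(f"unknown fixture kind {kind!r}")
    active = kind == "active_like"
    st, chain = _fixture_structure(kind)
    rm = FIXTURE_RESIDUE_MAP

    residues: dict[int, tuple[str, dict]] = {}

    def put(resnum: int, resname: str, atoms: dict) -> None:
        residues[resnum] = (resname, atoms)

    # --- brake island at the origin: N...E...K chained hydrogen bonds
    gap = 6.5 if active else 2.8
    b0 = np.array([0.0, 0.0, 0.0])
    put(rm["brake_n"], "ASN", {**_backbone(b0 + (-6, -4, 0)),
        "CB": b0 + (-2.5, 0, 0), "CG": b0 + (-1.4, 0.6, 0),
        "OD1": b0 + (-1.4, 1.8, 0), "ND2": b0})
    put(rm["brake_e"], "GLU", {**_backbone(b0 + (gap + 4, -5, 0)),
        "CB": b0 + (gap + 2.0, -1.5, 0), "CG": b0 + (gap + 1.2, -0.8, 0),
        "CD": b0 + (gap + 0.6, 0.4, 0),
        "OE1": b0 + (gap, 0, 0), "OE2": b0 + (gap + 1.1, 1.3, 0)})
    put(rm["brake_k"], "LYS", {**_backbone(b0 + (2 * gap + 5, -5, 0)),
        "CE": b0 + (2 * gap + 1.3, -0.8, 0), "NZ": b0 + (2 * gap, 0, 0)})

    # --- latch island at x = 50: Phe ring tip vs I/I/L side-chain carbons
    latch_o = np.array([50.0, 0.0, 0.0])
    phe = _phe_atoms(latch_o, 180.0 if not active else -60.0)
    put(rm["dfg_phe"], "PHE", phe)
    cz = phe["CZ"]
    latch_gap = 6.5 if active else 4.0
    for i, partner in enumerate(("latch_i1", "latch_i2", "latch_l")):
        direction = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)[i]
        contact = cz + latch_gap * direction
        resname = "ILE" if partner.startswith("latch_i") else "LEU"
        near = "CD1"
        atoms = {**_backbone(contact + 6 * direction), near: contact,
                 ("CG1" if resname == "ILE" else "CG"): contact + 1.5 * direction,
                 "CG2" if resname == "ILE" else "CD2": contact + 2.5 * direction}
        put(rm[partner], resname, atoms)

    # --- tether island at x = 100: Asp side chain vs Met SD/CE
    tet_o = np.array([100.0, 0.0, 0.0])
    tether_gap = 4.0 if active else 8.0
    put(rm["aloop_d"], "ASP", {**_backbone(tet_o + (-5, -4, 0)),
        "CB": tet_o + (-1.3, -0.8, 0), "CG": tet_o + (0, 0, 0),
        "OD1": tet_o + (0.4, 1.2, 0), "OD2": tet_o + (0.9, -0.9, 0)})
    for j, mname in enumerate(("tether_m1", "tether_m2")):
        direction = np.array([1.0, 0.0, 0.0]) if j == 0 else np.array([0.0, 0.0, 1.0])
        sd = tet_o + tether_gap * direction
        put(rm[mname], "MET", {**_backbone(sd + 5 * direction),
            "CG": sd + 2.8 * direction, "SD": sd, "CE": sd + 1.8 * direction})

    # --- plug island at x = 150: Arg guanidinium vs Asp carboxylate
    plug_o = np.array([150.0, 0.0, 0.0])
    plug_gap = 8.0 if active else 2.9
    put(rm["plug_r"], "ARG", {**_backbone(plug_o + (-6, -4, 0)),
        "NE": plug_o + (-1.3, -1.1, 0), "CZ": plug_o + (-0.7, 0, 0),
        "NH1": plug_o + (0, 0, 0), "NH2": plug_o + (-1.3, 1.1, 0)})
    put(rm["plug_d"], "ASP", {**_backbone(plug_o + (plug_gap + 4, -5, 0)),
        "CB": plug_o + (plug_gap + 2.4, -0.6, 0), "CG": plug_o + (plug_gap + 1.2, 0, 0),
        "OD1": plug_o + (plug_gap, 0, 0), "OD2": plug_o + (plug_gap + 1.6, 1.2, 0)})

    # --- β9 strand island at x = 200: A-loop (DFG+2..+4) backbone paired
    # with the catalytic-loop strand (plugD−3..−1) when active
    strand_o = np.array([200.0, 0.0, 0.0])
    pair_gap = 2.9 if active else 9.0
    for k in range(3):
        a_res = rm["dfg_phe"] + 2 + k  # 647..649
        c_res = rm["plug_d"] - 3 + k  # 623..625
        bb_a = _backbone(strand_o + (3.6 * k, 0, 0))
        bb_c = _backbone(strand_o + (3.6 * k, -pair_gap, 0))
        # align N of one strand over O of the other at the pairing gap
        bb_c["O"] = bb_a["N"] + np.array([0.0, -pair_gap, 0.0])
        put(a_res, "GLY", bb_a)
        put(c_res, "GLY", bb_c)

    for resnum in sorted(residues):
        resname, atoms = residues[resnum]
        _add_residue(chain, resnum, resname, atoms)
    return st.make_pdb_string()
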