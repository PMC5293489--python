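"""Resonance tables for multi-state NMR comparisons.

A *peak list* tabulates, for one protein state and one nucleus class
(backbone amide ¹H/¹⁵N or ILV-methyl ¹H/¹³C), the assigned chemical shifts
and peak heights per residue.  Everything downstream — chemical-shift
perturbations, intensity retentions, covariance analysis — consumes these
tables, so this module is the single home of residue/atom identity
conventions.

Residue numbering is the author numbering of each construct, used verbatim.
Cross-construct equivalences (e.g. between kinase isoforms) are never
inferred; they are supplied explicitly as mapping tables by the caller.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomGroup",
    "NucleusClass",
    "ResonanceKey",
    "PeakEntry",
    "PeakList",
    "StateSet",
    "AlignedStates",
    "GYRO_RATIO",
    "ppm_to_hz",
    "hz_to_ppm",
    "read_peaklist",
    "write_peaklist",
    "read_sparky",
    "align_states",
]

# Gyromagnetic ratios relative to 1H.  Used for every Hz <-> ppm conversion;
# conversions always require the 1H spectrometer frequency explicitly.
GYRO_RATIO = {"H1": 1.0, "N15": 0.10136919, "C13": 0.25145020}

_METHYL_RESIDUES = {"I", "L", "V"}
_ONE_LETTER = set("ACDEFGHIKLMNPQRSTVWY")


class AtomGroup(str, Enum):
    backbone_amide = "backbone_amide"
    ile_methyl = "ile_methyl"
    leu_methyl = "leu_methyl"
    val_methyl = "val_methyl"


class NucleusClass(str, Enum):
    #: ¹H/¹⁵N heteronuclear correlation (backbone amide)
    HN_N = "HN_N"
    #: ¹H/¹³C heteronuclear correlation (ILV methyl)
    H_C = "H_C"

    @property
    def x_nucleus(self) -> str:
        return "N15" if self is NucleusClass.HN_N else "C13"


@dataclass(frozen=True, order=True)
class ResonanceKey:
    """Identity of one observed resonance: residue plus atom group."""

    residue_number: int
    residue_type: str
    atom_group: AtomGroup = AtomGroup.backbone_amide

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")
        if self.residue_type not in _ONE_LETTER:
            raise ValueError(f"unknown residue type {self.residue_type!r}")
        if self.atom_group is not AtomGroup.backbone_amide:
            if self.residue_type not in _METHYL_RESIDUES:
                raise ValueError(
                    f"methyl atom group {self.atom_group.value} invalid for "
                    f"residue type {self.residue_type!r} (only I, L, V)"
                )

    def label(self) -> str:
        """Human-readable label, e.g. ``I548`` or ``I548-CH3``."""
        base = f"{self.residue_type}{self.residue_number}"
        if self.atom_group is AtomGroup.backbone_amide:
            return base
        return base + "-CH3"


@dataclass
class PeakEntry:
    shift_h: float
    shift_x: float
    height: float
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing:
            if not (np.isfinite(self.shift_h) and np.isfinite(self.shift_x)):
                raise ValueError("shifts must be finite unless the entry is flagged missing")
        if np.isfinite(self.height) and self.height < 0:
            raise ValueError("peak heights must be >= 0")


@dataclass
class PeakList:
    """Resonance table for one protein state, one nucleus class."""

    state_id: str
    nucleus_class: NucleusClass
    entries: dict[ResonanceKey, PeakEntry] = field(default_factory=dict)

    def add(self, key: ResonanceKey, entry: PeakEntry) -> None:
        if key in self.entries:
            raise ValueError(f"duplicate resonance {key.label()} in state {self.state_id}")
        self.entries[key] = entry

    def keys_present(self) -> set[ResonanceKey]:
        """Keys that are assigned and not flagged missing."""
        return {k for k, e in self.entries.items() if not e.missing}

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class StateSet:
    """An ordered collection of peak lists sharing one nucleus class.

    ``spectrometer_h_mhz`` is the ¹H frequency at which all states were
    recorded; it is required for any Hz-threshold filtering.
    """

    states: list[PeakList]
    spectrometer_h_mhz: float

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError("a StateSet needs at least two states")
        classes = {s.nucleus_class for s in self.states}
        if len(classes) > 1:
            raise ValueError(f"states mix nucleus classes: {sorted(c.value for c in classes)}")
        ids = [s.state_id for s in self.states]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate state_id in StateSet")

    @property
    def nucleus_class(self) -> NucleusClass:
        return self.states[0].nucleus_class

    @property
    def state_ids(self) -> list[str]:
        return [s.state_id for s in self.states]

    def get(self, state_id: str) -> PeakList:
        for s in self.states:
            if s.state_id == state_id:
                return s
        raise KeyError(f"state {state_id!r} not in StateSet (have {self.state_ids})")


@dataclass
class AlignedStates:
    """Residue intersection across states, in a fixed residue order.

    ``shift_h``, ``shift_x`` and ``height`` are (n_residues, n_states)
    arrays following the StateSet's state order and the sorted key order.
    """

    keys: list[ResonanceKey]
    state_ids: list[str]
    shift_h: np.ndarray
    shift_x: np.ndarray
    height: np.ndarray


def ppm_to_hz(ppm: float, h_freq_mhz: float, nucleus: str = "H1") -> float:
    """Convert a shift difference in ppm to Hz at the given ¹H field."""
    return ppm * h_freq_mhz * GYRO_RATIO[nucleus]


def hz_to_ppm(hz: float, h_freq_mhz: float, nucleus: str = "H1") -> float:
    return hz / (h_freq_mhz * GYRO_RATIO[nucleus])


_COLUMNS = ["residue_number", "residue_type", "atom_group", "shift_h", "shift_x", "height"]


def read_peaklist(path, state_id: str, nucleus_class: NucleusClass | str) -> PeakList:
    """Read a tab-separated peak list.

    Expected header columns: ``residue_number``, ``residue_type``,
    ``atom_group``, ``shift_h``, ``shift_x``, ``height``.  Rows with empty
    shift cells become entries flagged missing.  Duplicate resonance keys
    and malformed rows raise ``ValueError`` naming the offending line.
    """
    nucleus_class = NucleusClass(nucleus_class)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    pl = PeakList(state_id=state_id, nucleus_class=nucleus_class)
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        try:
            key = ResonanceKey(
                residue_number=int(row.residue_number),
                residue_type=row.residue_type.strip(),
                atom_group=AtomGroup(row.atom_group.strip()),
            )
            h_txt, x_txt = row.shift_h.strip(), row.shift_x.strip()
            missing = h_txt == "" or x_txt == ""
            entry = PeakEntry(
                shift_h=float(h_txt) if h_txt else np.nan,
                shift_x=float(x_txt) if x_txt else np.nan,
                height=float(row.height) if row.height.strip() else np.nan,
                missing=missing,
            )
        except (ValueError, TypeError) as exc:
            if "duplicate resonance" in str(exc):
                raise
            raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
        try:
            pl.add(key, entry)
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return pl


def write_peaklist(pl: PeakList, path) -> None:
    """Write the tab-separated dialect read by :func:`read_peaklist`.

    Shifts are written with 4 decimal places (ppm); a write → read → write
    cycle reproduces the file byte for byte.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for key in sorted(pl.entries):
            e = pl.entries[key]
            sh = "" if not np.isfinite(e.shift_h) else f"{e.shift_h:.4f}"
            sx = "" if not np.isfinite(e.shift_x) else f"{e.shift_x:.4f}"
            ht = "" if not np.isfinite(e.height) else f"{e.height:.6g}"
            fh.write(
                f"{key.residue_number}\t{key.residue_type}\t{key.atom_group.value}"
                f"\t{sh}\t{sx}\t{ht}\n"
            )


_SPARKY_RE = re.compile(r"^([A-Z])(\d+)([A-Z0-9']+)-([A-Z0-9']+)$")

# Sparky atom name -> atom group, for methyl lists.  Stereo pair members
# (δ1/δ2, γ1/γ2) map to the same group and are collapsed on read by keeping
# the member with the larger height: perturbations are reported per residue.
_SPARKY_METHYL = {
    ("I", "CD1"): AtomGroup.ile_methyl,
    ("L", "CD1"): AtomGroup.leu_methyl,
    ("L", "CD2"): AtomGroup.leu_methyl,
    ("V", "CG1"): AtomGroup.val_methyl,
    ("V", "CG2"): AtomGroup.val_methyl,
}


def read_sparky(path, state_id: str, nucleus_class: NucleusClass | str) -> PeakList:
    """Read a three-column Sparky-style list: ``assignment w1 w2 height``.

    ``w1`` is the heteronucleus (¹⁵N or ¹³C) shift and ``w2`` the ¹H shift,
    the customary Sparky column order.  Lines starting with ``Assignment``
    or blank lines are skipped.
    """
    nucleus_class = NucleusClass(nucleus_class)
    pl = PeakList(state_id=state_id, nucleus_class=nucleus_class)
    best_height: dict[ResonanceKey, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.lower().startswith("assignment"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns, got {len(parts)}")
            m = _SPARKY_RE.match(parts[0])
            if m is None:
                raise ValueError(f"{path}: line {lineno}: cannot parse assignment {parts[0]!r}")
            rtype, rnum, atom_x, _atom_h = m.group(1), int(m.group(2)), m.group(3), m.group(4)
            if nucleus_class is NucleusClass.HN_N:
                group = AtomGroup.backbone_amide
            else:
                try:
                    group = _SPARKY_METHYL[(rtype, atom_x)]
                except KeyError:
                    raise ValueError(
                        f"{path}: line {lineno}: unsupported methyl assignment {parts[0]!r}"
                    ) from None
            key = ResonanceKey(rnum, rtype, group)
            shift_x, shift_h, height = float(parts[1]), float(parts[2]), float(parts[3])
            entry = PeakEntry(shift_h=shift_h, shift_x=shift_x, height=height)
            if key in pl.entries:
                if height > best_height[key]:
                    pl.entries[key] = entry
                    best_height[key] = height
            else:
                pl.entries[key] = entry
                best_height[key] = height
    return pl


def align_states(states: StateSet) -> AlignedStates:
    """Intersect residues across all states and stack shifts into matrices.

    Only keys that are present *and not flagged missing* in every state are
    kept.  The residue order is the sorted key order, so the result does not
    depend on state insertion order (beyond the documented state ordering of
    the columns).
    """
    common: set[ResonanceKey] | None = None
    for s in states.states:
        present = s.keys_present()
        common = present if common is None else (common & present)
    assert common is not None
    if not common:
        raise ValueError("no residue is present in all states; empty intersection")
    keys = sorted(common)
    n, m = len(keys), len(states.states)
    shift_h = np.empty((n, m))
    shift_x = np.empty((n, m))
    height = np.empty((n, m))
    for j, s in enumerate(states.states):
        for i, k in enumerate(keys):
            e = s.entries[k]
            shift_h[i, j] = e.shift_h
            shift_x[i, j] = e.shift_x
            height[i, j] = e.height
    return AlignedStates(
        keys=keys,
        state_ids=states.state_ids,
        shift_h=shift_h,
        shift_x=shift_x,
        height=height,
    )
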