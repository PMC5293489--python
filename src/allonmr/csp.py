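"""Chemical-shift perturbations and intensity retentions between two states.

The combined CSP between a reference and a perturbed state is

    Δδ = sqrt((α·Δδ_X)² + Δδ_H²)

with α = 0.154 for ¹⁵N (amide ¹H/¹⁵N correlations) and α = 0.25 for ¹³C
(ILV-methyl ¹H/¹³C correlations).  Perturbations greater than 0.02 ppm are
treated as significant by default; peaks present in the reference but
missing in the perturbed state are reported as *disappeared* — a category
of its own, since exchange broadening beyond detection is itself evidence
of a conformational process.

Intensity retention is the perturbed/reference height ratio; retentions
below 0.8 flag residues whose signal is attenuated in the perturbed state.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peaklist import NucleusClass, PeakList, ResonanceKey

__all__ = [
    "N15_SCALING",
    "C13_SCALING",
    "CSPResult",
    "RetentionResult",
    "combined_csp",
    "filter_significant",
    "intensity_retention",
    "map_to_structure",
    "csp_table",
    "retention_table",
]

#: Heteronucleus scaling factors in the combined-shift formula.
N15_SCALING = 0.154
C13_SCALING = 0.25


@dataclass
class CSPResult:
    key: ResonanceKey
    delta_h: float  # signed Δδ_H, ppm
    delta_x: float  # signed Δδ_N or Δδ_C, ppm
    combined: float  # Δδ, ppm; NaN when disappeared
    significant: bool = False
    disappeared: bool = False


@dataclass
class RetentionResult:
    key: ResonanceKey
    retention: float  # NaN when undefined (zero reference height)
    attenuated: bool = False
    undefined: bool = False


def _scaling(nucleus_class: NucleusClass) -> float:
    return N15_SCALING if nucleus_class is NucleusClass.HN_N else C13_SCALING


def combined_csp(reference: PeakList, perturbed: PeakList) -> list[CSPResult]:
    """Per-residue combined shift perturbation, perturbed minus reference.

    Keys assigned in the reference but missing from the perturbed list come
    back with ``disappeared=True`` and no numeric Δδ.  Keys absent from the
    reference are ignored: with no reference position there is no
    perturbation to report.
    """
    if reference.nucleus_class is not perturbed.nucleus_class:
        raise ValueError(
            f"nucleus class mismatch: {reference.nucleus_class.value} vs "
            f"{perturbed.nucleus_class.value}"
        )
    alpha = _scaling(reference.nucleus_class)
    out: list[CSPResult] = []
    for key in sorted(reference.entries):
        ref = reference.entries[key]
        if ref.missing:
            continue
        pert = perturbed.entries.get(key)
        if pert is None or pert.missing:
            out.append(
                CSPResult(key=key, delta_h=math.nan, delta_x=math.nan,
                          combined=math.nan, disappeared=True)
            )
            continue
        dh = pert.shift_h - ref.shift_h
        dx = pert.shift_x - ref.shift_x
        combined = math.hypot(alpha * dx, dh)
        out.append(CSPResult(key=key, delta_h=dh, delta_x=dx, combined=combined))
    return out


def filter_significant(results: list[CSPResult], cutoff: float = 0.02) -> list[CSPResult]:
    """Flag perturbations strictly greater than ``cutoff`` ppm.

    All entries are returned; ``significant`` is set in place on each.
    Disappeared entries are always retained (flagged, not numeric).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    for r in results:
        r.significant = bool(not r.disappeared and r.combined > cutoff)
    return results


def intensity_retention(
    reference: PeakList, perturbed: PeakList, threshold: float = 0.8
) -> list[RetentionResult]:
    """Perturbed/reference peak-height ratio per shared residue.

    A zero (or non-finite) reference height makes the ratio undefined;
    such entries are flagged rather than raising.
    """
    out: list[RetentionResult] = []
    shared = sorted(set(reference.entries) & set(perturbed.entries))
    for key in shared:
        h_ref = reference.entries[key].height
        h_pert = perturbed.entries[key].height
        if not np.isfinite(h_ref) or not np.isfinite(h_pert) or h_ref == 0:
            out.append(RetentionResult(key=key, retention=math.nan, undefined=True))
            continue
        ratio = h_pert / h_ref
        out.append(RetentionResult(key=key, retention=ratio, attenuated=ratio < threshold))
    return out


def map_to_structure(
    results: list,
    structure,
    residue_map: dict[int, int] | None = None,
    sentinel: float = -1.0,
    chain: str | None = None,
):
    """Write per-residue scalars into the B-factor column of a structure copy.

    ``results`` may be CSPResults (value = combined Δδ) or RetentionResults
    (value = retention).  ``residue_map`` translates construct numbering to
    structure numbering (identity when omitted).  Residues absent from the
    structure are logged to stderr and skipped; unmapped residues carry the
    sentinel value.  Returns a ``gemmi.Structure`` clone.
    """
    residue_map = residue_map or {}
    values: dict[int, float] = {}
    for r in results:
        val = getattr(r, "combined", None)
        if val is None:
            val = r.retention
        if not np.isfinite(val):
            continue
        resnum = residue_map.get(r.key.residue_number, r.key.residue_number)
        values[resnum] = float(val)

    st = structure.clone()
    seen: set[int] = set()
    for model in st:
        for ch in model:
            if chain is not None and ch.name != chain:
                continue
            for res in ch:
                val = values.get(res.seqid.num, sentinel)
                if res.seqid.num in values:
                    seen.add(res.seqid.num)
                for atom in res:
                    atom.b_iso = val
    for resnum in sorted(set(values) - seen):
        print(f"map_to_structure: residue {resnum} not in structure; skipped",
              file=sys.stderr)
    return st


def csp_table(results: list[CSPResult]) -> pd.DataFrame:
    """Tabular (TSV-ready) view of CSP results."""
    return pd.DataFrame(
        {
            "residue_number": [r.key.residue_number for r in results],
            "residue_type": [r.key.residue_type for r in results],
            "atom_group": [r.key.atom_group.value for r in results],
            "delta_h": [r.delta_h for r in results],
            "delta_x": [r.delta_x for r in results],
            "combined": [r.combined for r in results],
            "significant": [r.significant for r in results],
            "disappeared": [r.disappeared for r in results],
        }
    )


def retention_table(results: list[RetentionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue_number": [r.key.residue_number for r in results],
            "residue_type": [r.key.residue_type for r in results],
            "atom_group": [r.key.atom_group.value for r in results],
            "retention": [r.retention for r in results],
            "attenuated": [r.attenuated for r in results],
            "undefined": [r.undefined for r in results],
        }
    )
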