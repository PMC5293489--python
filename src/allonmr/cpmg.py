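"""Constant-time CPMG relaxation dispersion and fast-exchange fitting.

In a constant-time CPMG experiment the effective transverse relaxation
rate at refocusing frequency ν_CPMG is obtained from peak intensities as

    R2,eff(ν) = −ln(I_ν / I₀) / T

with T the constant-time relaxation delay (40 ms throughout) and I₀ the
reference intensity without the delay.  For two-site exchange much faster
than the shift difference (k_ex ≫ Δω), dispersion follows the Luz–Meiboom
expression

    R2,eff(ν) = R2⁰ + (Φ/k_ex)·(1 − (4ν/k_ex)·tanh(k_ex/4ν))

where Φ = p_A·p_B·Δω² lumps the populations and the shift difference (in
rad/s), and R2⁰ is the exchange-free baseline.  Δω scales linearly with
the static field, so Φ scales with the squared field ratio — the handle
that lets curves recorded at two spectrometers share one k_ex.

The amount of dispersion is summarized as ΔR2,eff = R2,eff(50 Hz) −
R2,eff(1000 Hz); curves with ΔR2,eff > 2 s⁻¹ count as significant and are
the ones entered into global exchange fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .peaklist import ResonanceKey

__all__ = [
    "DEFAULT_NU_GRID",
    "DEFAULT_CONSTANT_TIME",
    "SIGNIFICANT_DISPERSION",
    "Experiment",
    "DispersionPoint",
    "DispersionCurve",
    "ExchangeModel",
    "ExchangeFitResult",
    "r2eff_from_intensities",
    "luz_meiboom",
    "delta_r2eff",
    "select_significant",
    "fit_exchange",
]

#: Refocusing-frequency grid (Hz), acquired in duplicate.
DEFAULT_NU_GRID = (50.0, 100.0, 150.0, 200.0, 250.0, 400.0, 600.0, 800.0, 1000.0)
#: Constant-time relaxation delay (s).
DEFAULT_CONSTANT_TIME = 0.040
#: ΔR2,eff significance threshold (s⁻¹), strict inequality.
SIGNIFICANT_DISPERSION = 2.0

REFERENCE_FIELD_MHZ = 600.0
_KEX_STARTS = (500.0, 1000.0, 2000.0, 4000.0, 8000.0)


class Experiment(str, Enum):
    n15_sq = "n15_sq"  # backbone 15N TROSY single quantum
    c13_mq = "c13_mq"  # ILV methyl 13C multiple quantum


@dataclass
class DispersionPoint:
    nu_cpmg: float  # Hz
    r2eff: float  # s^-1
    replicate_id: int = 0


@dataclass
class DispersionCurve:
    key: ResonanceKey
    field_mhz: float
    experiment: Experiment = Experiment.c13_mq
    T: float = DEFAULT_CONSTANT_TIME
    i0: float = 1.0
    points: list[DispersionPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("constant-time delay T must be positive")
        if self.points and len({p.nu_cpmg for p in self.points}) < 4:
            raise ValueError("a dispersion curve needs >= 4 distinct frequencies")

    @property
    def curve_id(self) -> tuple:
        return (self.key, self.field_mhz, self.experiment)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        nu = np.array([p.nu_cpmg for p in self.points])
        r2 = np.array([p.r2eff for p in self.points])
        ok = np.isfinite(r2)
        return nu[ok], r2[ok]


@dataclass
class ExchangeModel:
    """Parameters of the fast-exchange dispersion for one curve."""

    k_ex: float  # s^-1
    phi: float  # s^-2, p_A * p_B * Δω²
    r2_0: float  # s^-1 exchange-free baseline

    def __post_init__(self) -> None:
        if self.k_ex <= 0:
            raise ValueError("k_ex must be positive")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")


@dataclass
class ExchangeFitResult:
    mode: str
    k_ex_global: float  # nan in individual mode
    k_ex_uncertainty: float  # SD of individual-fit k_ex values
    k_ex_individual: dict  # ResonanceKey -> k_ex
    phi: dict  # ResonanceKey -> Φ at the reference field
    r2_0: dict  # curve_id -> baseline
    residuals: np.ndarray
    cost: float

    @property
    def k_ex_individual_range(self) -> tuple[float, float]:
        vals = list(self.k_ex_individual.values())
        return (min(vals), max(vals))


def r2eff_from_intensities(i: float, i0: float, T: float) -> float:
    """Eq-of-the-experiment: R2,eff = −ln(I/I₀)/T.

    Non-positive intensities have no defined rate and come back as NaN
    (a flagged missing point, not an exception).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if i <= 0 or i0 <= 0 or not (np.isfinite(i) and np.isfinite(i0)):
        return math.nan
    return -math.log(i / i0) / T


def luz_meiboom(nu_cpmg, model: ExchangeModel):
    """Fast-exchange dispersion profile; accepts scalar or array ν (Hz)."""
    nu = np.asarray(nu_cpmg, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("nu_cpmg must be positive")
    x = model.k_ex / (4.0 * nu)
    out = model.r2_0 + (model.phi / model.k_ex) * (1.0 - np.tanh(x) / x)
    return float(out) if np.isscalar(nu_cpmg) else out


@dataclass
class DispersionSummary:
    key: ResonanceKey
    field_mhz: float
    delta_r2eff: float
    significant: bool


def delta_r2eff(
    curve: DispersionCurve,
    low_hz: float = 50.0,
    high_hz: float = 1000.0,
    threshold: float = SIGNIFICANT_DISPERSION,
) -> DispersionSummary:
    """ΔR2,eff = mean R2,eff(50 Hz) − mean R2,eff(1000 Hz); replicates averaged."""
    nu, r2 = curve.arrays()
    low = r2[nu == low_hz]
    high = r2[nu == high_hz]
    if low.size == 0 or high.size == 0:
        raise ValueError(
            f"{curve.key.label()} at {curve.field_mhz} MHz: endpoint frequency "
            f"({low_hz} or {high_hz} Hz) missing from the curve"
        )
    value = float(low.mean() - high.mean())
    return DispersionSummary(
        key=curve.key, field_mhz=curve.field_mhz,
        delta_r2eff=value, significant=value > threshold,
    )


def select_significant(
    curves: Sequence[DispersionCurve], threshold: float = SIGNIFICANT_DISPERSION
) -> list[DispersionCurve]:
    """Keep residues whose dispersion is significant at *every* field present.

    This mirrors the selection for global fitting: a residue enters the
    global set only if it disperses above the threshold in each of its
    recorded curves.
    """
    by_key: dict[ResonanceKey, list[DispersionCurve]] = {}
    for c in curves:
        by_key.setdefault(c.key, []).append(c)
    keep: list[DispersionCurve] = []
    for key, cs in by_key.items():
        if all(delta_r2eff(c, threshold=threshold).significant for c in cs):
            keep.extend(cs)
    return keep


def _pooled_sigma(curves: Sequence[DispersionCurve]) -> float:
    """Estimate the per-point noise from duplicate differences, pooled.

    For a duplicate pair (x1, x2) of the same frequency, (x1 − x2)²/2 is an
    unbiased estimate of the point variance.  Falls back to unit weights
    when no duplicates exist.
    """
    sq = []
    for c in curves:
        by_nu: dict[float, list[float]] = {}
        for p in c.points:
            if np.isfinite(p.r2eff):
                by_nu.setdefault(p.nu_cpmg, []).append(p.r2eff)
        for vals in by_nu.values():
            if len(vals) == 2:
                sq.append((vals[0] - vals[1]) ** 2 / 2.0)
            elif len(vals) > 2:
                sq.append(np.var(vals, ddof=1))
    if not sq:
        return 1.0
    sigma = math.sqrt(float(np.mean(sq)))
    return sigma if sigma > 0 else 1.0


def _fit_linked(
    curves: list[DispersionCurve], sigma: float
) -> tuple[float, dict, dict, np.ndarray, float]:
    """Fit one shared k_ex over ``curves``; Φ per residue (scaled by the
    squared field ratio), baseline per curve.  Multi-start over k_ex with
    ties broken toward the smaller k_ex."""
    keys = sorted({c.key for c in curves})
    key_index = {k: i for i, k in enumerate(keys)}
    nus, r2s, kidx, cidx, scale = [], [], [], [], []
    for ci, c in enumerate(curves):
        nu, r2 = c.arrays()
        if nu.size < 5:
            raise ValueError(f"{c.key.label()}: needs >= 5 usable points, has {nu.size}")
        nus.append(nu)
        r2s.append(r2)
        kidx.append(np.full(nu.size, key_index[c.key]))
        cidx.append(np.full(nu.size, ci))
        scale.append(np.full(nu.size, (c.field_mhz / REFERENCE_FIELD_MHZ) ** 2))
    nu = np.concatenate(nus)
    obs = np.concatenate(r2s)
    kidx = np.concatenate(kidx).astype(int)
    cidx = np.concatenate(cidx).astype(int)
    scale = np.concatenate(scale)
    n_keys, n_curves = len(keys), len(curves)

    def residuals(theta: np.ndarray) -> np.ndarray:
        kex = theta[0]
        phi = theta[1 : 1 + n_keys][kidx] * scale
        r2_0 = theta[1 + n_keys :][cidx]
        x = kex / (4.0 * nu)
        model = r2_0 + (phi / kex) * (1.0 - np.tanh(x) / x)
        return (model - obs) / sigma

    # initial Φ from the plateau Φ/kex ≈ ΔR2,eff; baseline from the fast limit
    dr2 = np.zeros(n_keys)
    base = np.zeros(n_curves)
    for ci, c in enumerate(curves):
        s = delta_r2eff(c)
        dr2[key_index[c.key]] = max(dr2[key_index[c.key]],
                                    s.delta_r2eff / (c.field_mhz / REFERENCE_FIELD_MHZ) ** 2)
        nu_c, r2_c = c.arrays()
        base[ci] = r2_c[nu_c >= nu_c.max()].mean()
    dr2 = np.maximum(dr2, 0.1)

    lo = np.concatenate(([10.0], np.zeros(n_keys), np.zeros(n_curves)))
    hi = np.concatenate(([1e6], np.full(n_keys, 1e9), np.full(n_curves, 1e4)))
    best = None
    for kex0 in _KEX_STARTS:
        theta0 = np.concatenate(([kex0], dr2 * kex0, np.maximum(base, 0.1)))
        sol = least_squares(residuals, theta0, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost * (1 - 1e-9) or (
            abs(sol.cost - best.cost) <= 1e-9 * max(best.cost, 1.0)
            and sol.x[0] < best.x[0]
        ):
            best = sol
    if best is None or not best.success:
        norm = math.nan if best is None else float(np.linalg.norm(best.fun))
        raise RuntimeError(f"exchange fit did not converge (residual norm {norm:.3g})")
    kex = float(best.x[0])
    phi = {k: float(best.x[1 + i]) for k, i in key_index.items()}
    r2_0 = {c.curve_id: float(best.x[1 + n_keys + ci]) for ci, c in enumerate(curves)}
    return kex, phi, r2_0, best.fun * sigma, float(best.cost)


def fit_exchange(
    curves: Sequence[DispersionCurve], mode: str = "global"
) -> ExchangeFitResult:
    """Fit the Luz–Meiboom model per residue ("individual") or with one
    shared exchange rate over all residues and fields ("global").

    In both modes each residue first gets its own fit (k_ex shared over
    that residue's fields only); the global mode then adds the linked fit
    over everything and quotes the spread of the individual k_ex values as
    the uncertainty of the global one — duplicates stay separate residuals,
    weighted by the pooled duplicate noise.
    """
    curves = list(curves)
    if mode not in ("individual", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    if not curves:
        raise ValueError("no curves to fit")
    if mode == "global" and len(curves) < 2:
        raise ValueError("global mode needs at least 2 curves")
    sigma = _pooled_sigma(curves)

    by_key: dict[ResonanceKey, list[DispersionCurve]] = {}
    for c in curves:
        by_key.setdefault(c.key, []).append(c)
    k_ind: dict[ResonanceKey, float] = {}
    phi_ind: dict[ResonanceKey, float] = {}
    r2_ind: dict = {}
    res_chunks = []
    cost_ind = 0.0
    for key in sorted(by_key):
        kex, phi, r2_0, res, cost = _fit_linked(by_key[key], sigma)
        k_ind[key] = kex
        phi_ind[key] = phi[key]
        r2_ind.update(r2_0)
        res_chunks.append(res)
        cost_ind += cost
    k_sd = float(np.std(list(k_ind.values()), ddof=1)) if len(k_ind) > 1 else math.nan

    if mode == "individual":
        return ExchangeFitResult(
            mode=mode, k_ex_global=math.nan, k_ex_uncertainty=k_sd,
            k_ex_individual=k_ind, phi=phi_ind, r2_0=r2_ind,
            residuals=np.concatenate(res_chunks), cost=cost_ind,
        )

    kex_g, phi_g, r2_g, res_g, cost_g = _fit_linked(curves, sigma)
    return ExchangeFitResult(
        mode=mode, k_ex_global=kex_g, k_ex_uncertainty=k_sd,
        k_ex_individual=k_ind, phi=phi_g, r2_0=r2_g,
        residuals=res_g, cost=cost_g,
    )


def curves_from_table(df: pd.DataFrame) -> list[DispersionCurve]:
    """Build curves from a long-format table.

    Columns: residue_number, residue_type, atom_group, field_mhz,
    experiment, T, nu_cpmg, replicate_id and either r2eff or
    (intensity, i0).
    """
    from .peaklist import AtomGroup

    curves: dict[tuple, DispersionCurve] = {}
    for row in df.itertuples(index=False):
        key = ResonanceKey(int(row.residue_number), str(row.residue_type),
                           AtomGroup(str(row.atom_group)))
        T = float(row.T)
        cid = (key, float(row.field_mhz), Experiment(str(row.experiment)))
        if cid not in curves:
            curves[cid] = DispersionCurve(
                key=key, field_mhz=float(row.field_mhz),
                experiment=Experiment(str(row.experiment)), T=T,
                i0=float(getattr(row, "i0", 1.0)),
            )
        if hasattr(row, "r2eff"):
            r2 = float(row.r2eff)
        else:
            r2 = r2eff_from_intensities(float(row.intensity), float(row.i0), T)
        curves[cid].points.append(
            DispersionPoint(nu_cpmg=float(row.nu_cpmg), r2eff=r2,
                            replicate_id=int(getattr(row, "replicate_id", 0)))
        )
    return [curves[c] for c in sorted(curves, key=lambda t: (t[0], t[1], t[2].value))]


def curves_to_table(curves: Sequence[DispersionCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for p in c.points:
            rows.append(
                {
                    "residue_number": c.key.residue_number,
                    "residue_type": c.key.residue_type,
                    "atom_group": c.key.atom_group.value,
                    "field_mhz": c.field_mhz,
                    "experiment": c.experiment.value,
                    "T": c.T,
                    "i0": c.i0,
                    "nu_cpmg": p.nu_cpmg,
                    "replicate_id": p.replicate_id,
                    "r2eff": p.r2eff,
                }
            )
    return pd.DataFrame(rows)
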