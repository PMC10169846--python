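"""Ion-transport physics of nanotube and biological nanopores.

Implements the electrolyte-cylinder conductance model, the volume-exclusion
model for the conductance drop during analyte translocation, the inference
of ion-mobility enhancement from conductance drops, the Nernst /
Goldman-Hodgkin-Katz selectivity chain, and the PEG-exclusion estimate of
pore diameter.

Unit conventions: pore dimensions nm, concentrations mol L^-1, mobilities
m^2 V^-1 s^-1, potentials mV, currents pA, conductances nS, temperature K.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import (
    DEFAULT_TEMPERATURE_K,
    ELEMENTARY_CHARGE,
    FARADAY,
    GAS_CONSTANT,
    IONS_PER_M3_PER_MOLAR,
    KCL_ACTIVITY_COEFFICIENTS,
    MU_CL_BULK,
    MU_K_BULK,
)

_NM_TO_M = 1e-9
_S_TO_NS = 1e9


@dataclass(frozen=True)
class PoreGeometry:
    """Cylindrical pore geometry.

    diameter_nm / length_nm are the lumen diameter and pore length in nm;
    pore_kind is a free label ("SWCNT", "MspA", "aHL").
    """

    diameter_nm: float
    length_nm: float
    pore_kind: str = "SWCNT"

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0 or self.length_nm <= 0:
            raise ValueError("pore diameter and length must be positive")


@dataclass(frozen=True)
class ElectrolyteState:
    """KCl electrolyte: concentration, ion mobilities and temperature."""

    c_kcl_molar: float = 1.0
    mu_k: float = MU_K_BULK
    mu_cl: float = MU_CL_BULK
    temperature_k: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if min(self.c_kcl_molar, self.mu_k, self.mu_cl, self.temperature_k) <= 0:
            raise ValueError("electrolyte parameters must be positive")


@dataclass(frozen=True)
class ExclusionModel:
    """Analyte parameters of the volume-exclusion conductance-drop model.

    d_analyte_nm is the effective analyte diameter. The optional second
    term describes counterion transport along the analyte: mu_k_star is
    the effective K+ mobility along the molecule and q_star_c_per_m its
    effective charge per unit length. When either is None the term is
    dropped (pure volume exclusion).
    """

    d_analyte_nm: float
    mu_k_star: float | None = None
    q_star_c_per_m: float | None = None

    def __post_init__(self) -> None:
        if self.d_analyte_nm <= 0:
            raise ValueError("analyte diameter must be positive")


@dataclass
class SelectivityMeasurement:
    """One reversal-potential experiment under an activity gradient."""

    a_cis: float
    a_trans: float
    reversal_potential_mv: float
    temperature_k: float = DEFAULT_TEMPERATURE_K
    transference_k: float | None = None
    selectivity: float | None = None


@dataclass(frozen=True)
class PegCalibration:
    """PEG blockade calibration table for pore-diameter estimation.

    Rows are (molecular weight Da, hydrodynamic diameter nm, fractional
    blockade); molecular weights must be strictly increasing and blockades
    in [0, 1].
    """

    mw_da: tuple[float, ...]
    dh_nm: tuple[float, ...]
    blockade_frac: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.mw_da)
        if not (len(self.dh_nm) == len(self.blockade_frac) == n):
            raise ValueError("calibration columns must have equal length")
        if any(b < 0 or b > 1 for b in self.blockade_frac):
            raise ValueError("blockade fractions must lie in [0, 1]")
        if any(a >= b for a, b in zip(self.mw_da, self.mw_da[1:])):
            raise ValueError("molecular weights must be strictly increasing")


def tube_conductance(geom: PoreGeometry, elec: ElectrolyteState) -> float:
    """Open-pore conductance (nS) of a cylinder of electrolyte.

    G = 6.02e26 (mu_K + mu_Cl) c_KCl e pi D^2 / (4 L), with D and L in
    metres internally; assumes bulk-like transport and no free-energy
    barrier or access resistance.
    """
    d_m = geom.diameter_nm * _NM_TO_M
    l_m = geom.length_nm * _NM_TO_M
    g_siemens = (
        IONS_PER_M3_PER_MOLAR
        * (elec.mu_k + elec.mu_cl)
        * elec.c_kcl_molar
        * ELEMENTARY_CHARGE
        * math.pi
        * d_m**2
        / (4.0 * l_m)
    )
    return g_siemens * _S_TO_NS


def exclusion_delta_g(
    geom: PoreGeometry, elec: ElectrolyteState, model: ExclusionModel
) -> float:
    """Conductance drop (nS) while an analyte resides in the pore.

    Volume-exclusion term: the analyte displaces a cylinder of electrolyte
    of its own diameter over the pore length. The optional counterion term
    mu_K* q* adds conductance back. Sign convention: the returned value is
    the *drop*, positive when the pore conducts less with the analyte
    inside; exact cancellation of the two terms returns 0.
    """
    if model.d_analyte_nm > geom.diameter_nm:
        raise ValueError("analyte diameter exceeds pore diameter; cannot enter")
    d_m = model.d_analyte_nm * _NM_TO_M
    l_m = geom.length_nm * _NM_TO_M
    exclusion = (
        math.pi / 4.0
        * d_m**2
        * (elec.mu_k + elec.mu_cl)
        * elec.c_kcl_molar
        * ELEMENTARY_CHARGE
    )
    counterion = 0.0
    if model.mu_k_star is not None and model.q_star_c_per_m is not None:
        counterion = model.mu_k_star * model.q_star_c_per_m
    drop_siemens = IONS_PER_M3_PER_MOLAR / l_m * (exclusion - counterion)
    return drop_siemens * _S_TO_NS


def delta_g_from_blockade(
    blockade_frac: float, open_current_pa: float, potential_mv: float
) -> float:
    """Conductance drop (nS) from a fractional blockade of a measured pore.

    dG = blockade * I0 / V; pA / mV gives nS directly.
    """
    if potential_mv == 0:
        raise ValueError("potential must be nonzero")
    return blockade_frac * open_current_pa / potential_mv


def infer_mobility_factor(
    dg_test_ns: float,
    l_test_nm: float | tuple[float, float],
    dg_ref_ns: float,
    l_ref_nm: float,
) -> float | tuple[float, float]:
    """Ion-mobility enhancement of a test pore relative to a reference pore.

    In the volume-exclusion picture dG_pore ∝ (mu_K + mu_Cl) / L_pore, so
    (mu_K + mu_Cl) ∝ dG_pore * L_pore and the enhancement factor is
    (dG_test L_test) / (dG_ref L_ref). If the test pore length is only
    known as an interval (lo, hi), the interval of factors is returned.
    """
    if dg_ref_ns <= 0 or l_ref_nm <= 0 or dg_test_ns <= 0:
        raise ValueError("conductance drops and lengths must be positive")
    ref = dg_ref_ns * l_ref_nm
    if isinstance(l_test_nm, tuple):
        lo, hi = sorted(l_test_nm)
        if lo <= 0:
            raise ValueError("test pore length must be positive")
        return (dg_test_ns * lo / ref, dg_test_ns * hi / ref)
    if l_test_nm <= 0:
        raise ValueError("test pore length must be positive")
    return dg_test_ns * l_test_nm / ref


def kcl_activity_coefficient(c_molar: float) -> float:
    """Mean activity coefficient of KCl at 25 degC.

    Table lookup (log-linear interpolation) inside the tabulated range,
    Davies equation outside it.
    """
    if c_molar <= 0:
        raise ValueError("concentration must be positive")
    table = KCL_ACTIVITY_COEFFICIENTS
    if c_molar in table:
        return table[c_molar]
    cs = sorted(table)
    if cs[0] <= c_molar <= cs[-1]:
        logc = np.log10(c_molar)
        return float(np.interp(logc, np.log10(cs), [table[c] for c in cs]))
    # Davies equation, 1:1 electrolyte at 25 degC
    sqrt_i = math.sqrt(c_molar)
    log_gamma = -0.509 * (sqrt_i / (1.0 + sqrt_i) - 0.3 * c_molar)
    return 10.0**log_gamma


def kcl_activity(c_molar: float) -> float:
    """Ionic activity a = gamma(c) * c of KCl at 25 degC."""
    return kcl_activity_coefficient(c_molar) * c_molar


def nernst_potential(
    a_cis: float, a_trans: float, temperature_k: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Nernst potential dE = (RT/F) ln(a_cis / a_trans), in mV."""
    if a_cis <= 0 or a_trans <= 0:
        raise ValueError("activities must be positive")
    return GAS_CONSTANT * temperature_k / FARADAY * math.log(a_cis / a_trans) * 1e3


def reversal_from_transference(
    t_k: float,
    a_cis: float,
    a_trans: float,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Goldman-Hodgkin-Katz reversal potential (mV) for transference t_k.

    V_R = (2 T_K - 1) (RT/F) ln(a_cis / a_trans).
    """
    return (2.0 * t_k - 1.0) * nernst_potential(a_cis, a_trans, temperature_k)


def transference_from_reversal(meas: SelectivityMeasurement) -> float:
    """Cation transference number from a measured reversal potential.

    Inverts the GHK relation; the result is clipped to the open interval
    (0, 1) with a warning if the measurement lies outside the Nernst limit.
    """
    if meas.a_cis == meas.a_trans:
        raise ValueError(
            "equal cis/trans activities: reversal potential is identically 0 "
            "and the transference number is not identifiable"
        )
    de = nernst_potential(meas.a_cis, meas.a_trans, meas.temperature_k)
    t_k = 0.5 * (meas.reversal_potential_mv / de + 1.0)
    if not 0.0 < t_k < 1.0:
        warnings.warn(
            f"transference number {t_k:.4f} outside (0, 1); clipping "
            "(reversal potential beyond the Nernst limit)",
            stacklevel=2,
        )
        eps = 1e-12
        t_k = min(max(t_k, eps), 1.0 - eps)
    meas.transference_k = t_k
    return t_k


def selectivity_ratio(t_k: float) -> float:
    """Cation/anion selectivity ratio SR = T_K / (1 - T_K).

    T_K at the boundaries 0 or 1 means exclusively anion- or
    cation-conducting; that is a boundary condition, not a finite ratio,
    and is raised as an error naming the boundary.
    """
    if t_k <= 0.0 or t_k >= 1.0:
        raise ValueError(
            f"transference number {t_k} at or beyond a selectivity boundary: "
            "the cation/anion ratio is not a finite number"
        )
    return t_k / (1.0 - t_k)


def transference_from_selectivity(sr: float) -> float:
    """Inverse of selectivity_ratio: T_K = SR / (1 + SR)."""
    if sr <= 0:
        raise ValueError("selectivity ratio must be positive")
    return sr / (1.0 + sr)


def estimate_diameter_from_peg(
    cal: PegCalibration, jump_threshold: float | None = None
) -> tuple[float, float]:
    """Pore-diameter interval (nm) from a PEG exclusion calibration.

    PEG molecules with hydrodynamic diameter below the pore diameter
    translocate and block strongly; larger ones are excluded and barely
    perturb the current. The pore diameter is therefore bracketed by the
    adjacent pair of calibration points with the largest (or first
    super-threshold) change in fractional blockade.

    With jump_threshold None the single largest step is used; otherwise the
    first adjacent step exceeding the threshold. If no step exceeds the
    threshold a warning is issued and the widest bracket (full dh range) is
    returned.
    """
    if len(cal.mw_da) < 3:
        raise ValueError("need at least 3 calibration points")
    steps = np.abs(np.diff(cal.blockade_frac))
    if jump_threshold is None:
        if np.all(steps == steps[0]):
            # perfectly flat (or uniform) profile: no exclusion transition
            if steps[0] == 0:
                warnings.warn(
                    "no exclusion transition in calibration table; "
                    "returning widest bracket",
                    stacklevel=2,
                )
                return (cal.dh_nm[0], cal.dh_nm[-1])
        i = int(np.argmax(steps))
    else:
        above = np.flatnonzero(steps > jump_threshold)
        if above.size == 0:
            warnings.warn(
                "no blockade step exceeds the jump threshold; "
                "returning widest bracket",
                stacklevel=2,
            )
            return (cal.dh_nm[0], cal.dh_nm[-1])
        i = int(above[0])
    return (cal.dh_nm[i], cal.dh_nm[i + 1])


def peg_hydrodynamic_diameter(mw_da: float | Sequence[float]) -> np.ndarray | float:
    """Hydrodynamic diameter (nm) of PEG from molecular weight.

    Empirical power law d_H = 0.0444 * MW^0.55 nm, a literature convention
    for PEG in water (gives ~1.2 nm for PEG 400 and ~1.5 nm for PEG 600);
    a convenience for building calibration tables, not a fitted result of
    this package.
    """
    mw = np.asarray(mw_da, dtype=float)
    if np.any(mw <= 0):
        raise ValueError("molecular weight must be positive")
    d = 0.0444 * mw**0.55
    return float(d) if d.ndim == 0 else d
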