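"""Hybrid ventricular bio-pacemaker ionic model.

The cell is a ten Tusscher-Panfilov (2006) human ventricular myocyte
(epicardial parameter set by default) whose inward-rectifier current
``I_K1`` carries a knock-down scaling factor ``S_K1`` and which is
augmented with two engineered currents:

* a sinoatrial-type "funny" current ``I_f`` (HCN), split into Na+ and K+
  components, scaled by ``S_f``;
* optionally a low-voltage-activated T-type Ca2+ current ``I_CaT``.

Current densities are expressed in pA/pF throughout, voltages in mV,
time in ms and concentrations in mM.  The two engineered conductances are
anchored so that the model's I-V curves reproduce the conventional
"density at -80 mV" parameterisation used to describe expression levels:
``S_K1 = 1`` gives an I_K1 density of 0.99 pA/pF at -80 mV and ``S_f = 1``
gives an I_f density of -0.63 pA/pF at -80 mV (steady-state activation),
both under the reference ionic conditions of :data:`REFERENCE_CONDITIONS`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict

import numpy as np
from numba import njit

__all__ = [
    "ModelParameters",
    "CellState",
    "CurrentSet",
    "AuxiliaryQuantities",
    "InvalidStateError",
    "compute_currents",
    "derivatives",
    "i_k1_density",
    "i_f_density",
    "iv_curve",
    "density_to_scale",
    "gate_steady_states",
    "resting_state",
    "IK1_ANCHOR_DENSITY",
    "IF_ANCHOR_DENSITY",
    "REFERENCE_CONDITIONS",
]


class InvalidStateError(ValueError):
    """Raised when a cell state contains non-finite or out-of-range entries."""


# ---------------------------------------------------------------------------
# Physical constants and cell geometry (ten Tusscher-Panfilov 2006)
# ---------------------------------------------------------------------------

R_GAS = 8314.472       # mJ/(mol*K)
TEMPERATURE = 310.0    # K
FARADAY = 96485.3415   # C/mol
RTONF = R_GAS * TEMPERATURE / FARADAY  # mV

V_CYTO = 0.016404      # cytoplasmic volume (um^3 scale factor)
V_SR = 0.001094        # sarcoplasmic-reticulum volume
V_SS = 0.00005468      # dyadic subspace volume
CM_REF = 0.185         # membrane capacitance (uF) used in flux conversions

# Base (unscaled) maximal conductances, nS/pF
G_NA = 14.838
G_K1_TP06 = 5.405
G_TO_EPI = 0.294
G_TO_ENDO = 0.073
G_KR = 0.153
G_KS_EPI = 0.392
G_KS_M = 0.098
G_CAL = 3.98e-5
P_NAK = 2.724
K_NACA = 1000.0
G_PCA = 0.1238
G_PK = 0.0146
G_BNA = 0.00029
G_BCA = 0.000592

E_CAT_REV = 45.0       # fixed T-type Ca reversal potential, mV

# I_f conductance split: the Na:K maximal-conductance ratio of the human
# sinoatrial formulation (chosen there to place the I_f reversal potential
# near -22 mV); the absolute magnitude is re-anchored below.
IF_NA_TO_K_RATIO = 0.5927

# Printed I-V anchors at -80 mV defining the density<->scale mapping.
IK1_ANCHOR_DENSITY = 0.99    # pA/pF at S_K1 = 1
IF_ANCHOR_DENSITY = -0.63    # pA/pF at S_f = 1

#: Ionic conditions under which the -80 mV anchors are evaluated.
REFERENCE_CONDITIONS = {
    "K_o": 5.4,     # mM
    "Na_o": 140.0,  # mM
    "Ca_o": 2.0,    # mM
    "K_i": 140.0,   # mM (the value consistent with the printed 0.99 anchor)
    "Na_i": 7.67,   # mM (ventricular resting value)
    "Ca_i": 7e-5,   # mM
}


def _xk1_inf(v: float, e_k: float) -> float:
    a = 0.1 / (1.0 + math.exp(0.06 * (v - e_k - 200.0)))
    b = (3.0 * math.exp(0.0002 * (v - e_k + 100.0))
         + math.exp(0.1 * (v - e_k - 10.0))) / (1.0 + math.exp(-0.5 * (v - e_k)))
    return a / (a + b)


def _y_inf(v: float, vhalf: float = -52.5, slope: float = 9.0) -> float:
    # HCN activation steady state (Boltzmann)
    return 1.0 / (1.0 + math.exp((v - vhalf) / slope))


def _ik1_raw_density(v: float, g_k1: float, k_o: float, k_i: float) -> float:
    e_k = RTONF * math.log(k_o / k_i)
    return g_k1 * math.sqrt(k_o / 5.4) * _xk1_inf(v, e_k) * (v - e_k)


def _calibrated_g_k1() -> float:
    """TP06 G_K1 rescaled so the -80 mV anchor is exactly 0.99 pA/pF."""
    raw = _ik1_raw_density(-80.0, G_K1_TP06,
                           REFERENCE_CONDITIONS["K_o"], REFERENCE_CONDITIONS["K_i"])
    return G_K1_TP06 * IK1_ANCHOR_DENSITY / raw


def _calibrated_g_f(vhalf: float = -52.5, slope: float = 9.0) -> tuple[float, float]:
    """(G_f_Na, G_f_K) such that S_f = 1 gives -0.63 pA/pF at -80 mV.

    The Na:K split follows :data:`IF_NA_TO_K_RATIO`; only the joint
    magnitude is fitted to the anchor, making the model independent of the
    source SAN model's absolute conductances.
    """
    c = REFERENCE_CONDITIONS
    e_na = RTONF * math.log(c["Na_o"] / c["Na_i"])
    e_k = RTONF * math.log(c["K_o"] / c["K_i"])
    f_na = IF_NA_TO_K_RATIO / (1.0 + IF_NA_TO_K_RATIO)
    per_unit = _y_inf(-80.0, vhalf, slope) * (
        f_na * (-80.0 - e_na) + (1.0 - f_na) * (-80.0 - e_k))
    g_total = IF_ANCHOR_DENSITY / per_unit
    return g_total * f_na, g_total * (1.0 - f_na)


G_K1_CAL = _calibrated_g_k1()
G_F_NA_CAL, G_F_K_CAL = _calibrated_g_f()

# T-type Ca2+ maximal conductance (nS/pF).  The source SAN-type formulation
# fixes the gating kinetics and the +45 mV reversal; the conductance is a
# free parameter calibrated on the documented behaviour of the stable
# (0.099, -0.63) pA/pF pacemaker, whose cycle length lengthens from
# ~853 ms to ~950 ms upon I_CaT incorporation (see docs/methods.md).
G_CAT_DEFAULT = 0.1832


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

_VARIANTS = ("epicardial", "endocardial", "mid-myocardial")


@dataclass
class ModelParameters:
    """Complete parameter set of the hybrid bio-pacemaker cell.

    ``S_K1`` scales I_K1 (1 = full ventricular expression, 0 = complete
    knock-out); ``S_f`` scales the incorporated funny current (0 = none).
    Both multiply anchored maximal conductances, so the current density at
    -80 mV under reference conditions is ``0.99 * S_K1`` pA/pF for I_K1 and
    ``-0.63 * S_f`` pA/pF for I_f.
    """

    S_K1: float = 1.0
    S_f: float = 0.0
    include_I_CaT: bool = False
    cell_variant: str = "epicardial"
    #: treat the funny-current activation y as an instantaneous function of
    #: voltage (y = y_inf(V)); by default y follows first-order kinetics
    #: with the human-SAN voltage-dependent time constant.
    instantaneous_y: bool = False
    #: half-activation voltage (mV) and slope factor (mV) of y_inf
    y_vhalf: float = -52.5
    y_slope: float = 9.0
    #: multiplier on the y-gate time constant (sensitivity analyses)
    tau_y_scale: float = 1.0
    #: compartment receiving the I_CaT Ca2+ flux: "subspace" (default, the
    #: I_CaL convention, coupling into SR release) or "cytosol"
    i_cat_compartment: str = "subspace"

    G_K1: float = G_K1_CAL
    G_f_Na: float | None = None   # None -> anchored to -0.63 pA/pF at -80 mV
    G_f_K: float | None = None
    G_CaT: float = G_CAT_DEFAULT
    C_m: float = CM_REF

    K_o: float = 5.4
    Na_o: float = 140.0
    Ca_o: float = 2.0

    G_Na: float = G_NA
    G_to: float | None = None   # None -> variant default
    G_Kr: float = G_KR
    G_Ks: float | None = None   # None -> variant default
    G_CaL: float = G_CAL
    P_NaK: float = P_NAK
    k_NaCa: float = K_NACA
    G_pCa: float = G_PCA
    G_pK: float = G_PK
    G_bNa: float = G_BNA
    G_bCa: float = G_BCA

    def __post_init__(self) -> None:
        if not 0.0 <= self.S_K1 <= 1.0:
            raise ValueError(f"S_K1 must lie in [0, 1], got {self.S_K1}")
        if self.S_f < 0.0:
            raise ValueError(f"S_f must be >= 0, got {self.S_f}")
        if self.cell_variant not in _VARIANTS:
            raise ValueError(f"cell_variant must be one of {_VARIANTS}")
        if self.i_cat_compartment not in ("cytosol", "subspace"):
            raise ValueError("i_cat_compartment must be 'cytosol' or 'subspace'")
        if min(self.K_o, self.Na_o, self.Ca_o) <= 0.0:
            raise ValueError("extracellular concentrations must be positive")
        if self.G_to is None:
            self.G_to = G_TO_ENDO if self.cell_variant == "endocardial" else G_TO_EPI
        if self.G_Ks is None:
            self.G_Ks = G_KS_M if self.cell_variant == "mid-myocardial" else G_KS_EPI
        if self.G_f_Na is None or self.G_f_K is None:
            g_na_f, g_k_f = _calibrated_g_f(self.y_vhalf, self.y_slope)
            if self.G_f_Na is None:
                self.G_f_Na = g_na_f
            if self.G_f_K is None:
                self.G_f_K = g_k_f

    # -- density parameterisation ------------------------------------------

    @classmethod
    def from_densities(cls, ik1_density: float, if_density: float = 0.0,
                       **kwargs) -> "ModelParameters":
        """Build parameters from current densities at -80 mV (pA/pF)."""
        return cls(S_K1=density_to_scale("I_K1", ik1_density),
                   S_f=density_to_scale("I_f", if_density), **kwargs)

    @property
    def ik1_density(self) -> float:
        return self.S_K1 * IK1_ANCHOR_DENSITY

    @property
    def if_density(self) -> float:
        return self.S_f * IF_ANCHOR_DENSITY

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def pvec(self) -> np.ndarray:
        """Flat parameter vector consumed by the compiled kernels."""
        return np.array([
            self.G_Na,
            self.S_K1 * self.G_K1,
            self.G_to,
            self.G_Kr,
            self.G_Ks,
            self.G_CaL,
            self.S_f * self.G_f_Na,
            self.S_f * self.G_f_K,
            self.G_CaT if self.include_I_CaT else 0.0,
            self.P_NaK,
            self.k_NaCa,
            self.G_pCa,
            self.G_pK,
            self.G_bNa,
            self.G_bCa,
            self.K_o,
            self.Na_o,
            self.Ca_o,
            self.C_m,
            1.0 if self.cell_variant == "endocardial" else 0.0,
            1.0 if self.instantaneous_y else 0.0,
            self.y_vhalf,
            self.y_slope,
            self.tau_y_scale,
            1.0 if self.i_cat_compartment == "subspace" else 0.0,
        ], dtype=np.float64)


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

STATE_FIELDS = (
    "V", "m", "h", "j", "d", "f", "f2", "fCass", "r", "s",
    "xr1", "xr2", "xs", "y", "dT", "fT",
    "Na_i", "K_i", "Ca_i", "Ca_SR", "Ca_ss", "R_bar",
)

N_STATE = len(STATE_FIELDS)
GATE_SLICE = slice(1, 16)   # 15 first-order gates
N_GATES = 15

# Published TP06 resting initial condition (epicardial), extended with the
# engineered gates at their steady state for V = -86.2 mV.
_TP06_REST = {
    "V": -86.2, "m": 0.0, "h": 0.75, "j": 0.75, "d": 0.0, "f": 1.0,
    "f2": 1.0, "fCass": 1.0, "r": 0.0, "s": 1.0, "xr1": 0.0, "xr2": 1.0,
    "xs": 0.0, "Na_i": 7.67, "K_i": 138.3, "Ca_i": 7e-5, "Ca_SR": 1.3,
    "Ca_ss": 7e-5, "R_bar": 1.0,
}


@dataclass
class CellState:
    """Full ODE state: membrane potential, gates and concentrations."""

    V: float
    m: float
    h: float
    j: float
    d: float
    f: float
    f2: float
    fCass: float
    r: float
    s: float
    xr1: float
    xr2: float
    xs: float
    y: float
    dT: float
    fT: float
    Na_i: float
    K_i: float
    Ca_i: float
    Ca_SR: float
    Ca_ss: float
    R_bar: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=np.float64)

    @classmethod
    def from_array(cls, a: np.ndarray) -> "CellState":
        a = np.asarray(a, dtype=float)
        if a.shape != (N_STATE,):
            raise ValueError(f"state array must have shape ({N_STATE},)")
        return cls(**dict(zip(STATE_FIELDS, a)))

    def validate(self) -> None:
        a = self.as_array()
        if not np.all(np.isfinite(a)):
            raise InvalidStateError("state contains non-finite entries")
        gates = a[GATE_SLICE]
        if np.any(gates < -1e-9) or np.any(gates > 1.0 + 1e-9):
            raise InvalidStateError("gating variables must lie in [0, 1]")
        if np.any(a[16:22] <= 0.0):
            raise InvalidStateError("concentrations must be positive")


def resting_state(params: "ModelParameters | None" = None) -> CellState:
    """The published ventricular resting state, engineered gates at steady state."""
    v = _TP06_REST["V"]
    d = dict(_TP06_REST)
    if params is not None:
        d["y"] = _y_inf(v, params.y_vhalf, params.y_slope)
    else:
        d["y"] = _y_inf(v)
    d["dT"] = 1.0 / (1.0 + math.exp(-(v + 37.0) / 6.8))
    d["fT"] = 1.0 / (1.0 + math.exp((v + 71.0) / 9.0))
    return CellState(**{f: d[f] for f in STATE_FIELDS})


# ---------------------------------------------------------------------------
# Currents / auxiliary containers
# ---------------------------------------------------------------------------

CURRENT_NAMES = (
    "I_Na", "I_K1", "I_to", "I_Kr", "I_Ks", "I_CaL", "I_CaT",
    "I_NaCa", "I_NaK", "I_pCa", "I_pK", "I_bCa", "I_bNa", "I_f_Na", "I_f_K",
)
N_CURRENTS = len(CURRENT_NAMES)


@dataclass
class CurrentSet:
    """All transmembrane current densities (pA/pF) at one instant."""

    I_Na: float
    I_K1: float
    I_to: float
    I_Kr: float
    I_Ks: float
    I_CaL: float
    I_CaT: float
    I_NaCa: float
    I_NaK: float
    I_pCa: float
    I_pK: float
    I_bCa: float
    I_bNa: float
    I_f_Na: float
    I_f_K: float

    @property
    def I_f(self) -> float:
        return self.I_f_Na + self.I_f_K

    @property
    def I_total(self) -> float:
        return float(sum(getattr(self, n) for n in CURRENT_NAMES))

    def as_dict(self) -> dict:
        d = {n: getattr(self, n) for n in CURRENT_NAMES}
        d["I_f"] = self.I_f
        d["I_total"] = self.I_total
        return d


@dataclass
class AuxiliaryQuantities:
    """Reversal potentials and the instantaneous I_K1 rectification factor."""

    E_K: float
    E_Na: float
    E_Ca: float
    E_Ks: float
    x_k1_inf: float


# ---------------------------------------------------------------------------
# Compiled physics kernel (single source of truth for the right-hand side)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _eval(s, p, cur, gi, gt, ds):  # pragma: no cover - exercised via wrappers
    """Fill currents, gate steady states/time constants, and state derivatives.

    ``s`` is the 22-entry state vector, ``p`` the 20-entry parameter vector
    (see ``ModelParameters.pvec``).  Returns the total ionic current I_ion.
    """
    v = s[0]
    m = s[1]; h = s[2]; j = s[3]; d = s[4]; f = s[5]; f2 = s[6]; fcass = s[7]
    r = s[8]; sg = s[9]; xr1 = s[10]; xr2 = s[11]; xs = s[12]
    y = s[13]; dcat = s[14]; fcat = s[15]
    nai = s[16]; ki = s[17]; cai = s[18]; casr = s[19]; cass = s[20]; rbar = s[21]

    ko = p[15]; nao = p[16]; cao = p[17]; cm = p[18]; endo = p[19]

    e_k = RTONF * math.log(ko / ki)
    e_na = RTONF * math.log(nao / nai)
    e_ks = RTONF * math.log((ko + 0.03 * nao) / (ki + 0.03 * nai))
    e_ca = 0.5 * RTONF * math.log(cao / cai)

    # --- membrane currents (pA/pF) ---
    i_na = p[0] * m * m * m * h * j * (v - e_na)

    ak1 = 0.1 / (1.0 + math.exp(0.06 * (v - e_k - 200.0)))
    bk1 = (3.0 * math.exp(0.0002 * (v - e_k + 100.0))
           + math.exp(0.1 * (v - e_k - 10.0))) / (1.0 + math.exp(-0.5 * (v - e_k)))
    i_k1 = p[1] * math.sqrt(ko / 5.4) * (ak1 / (ak1 + bk1)) * (v - e_k)

    i_to = p[2] * r * sg * (v - e_k)
    i_kr = p[3] * math.sqrt(ko / 5.4) * xr1 * xr2 * (v - e_k)
    i_ks = p[4] * xs * xs * (v - e_ks)

    vm15 = v - 15.0
    if abs(vm15) < 1e-6:
        vm15 = 1e-6
    ex = math.exp(2.0 * vm15 / RTONF)
    i_cal = (p[5] * d * f * f2 * fcass * 4.0 * vm15 * (FARADAY / RTONF)
             * (0.25 * cass * ex - cao) / (ex - 1.0))

    i_cat = p[8] * dcat * fcat * (v - E_CAT_REV)

    eg = math.exp(0.35 * v / RTONF)
    eg1 = math.exp(-0.65 * v / RTONF)
    i_naca = (p[10] * (eg * nai * nai * nai * cao - eg1 * nao * nao * nao * cai * 2.5)
              / ((87.5 ** 3 + nao ** 3) * (1.38 + cao) * (1.0 + 0.1 * eg1)))

    i_nak = (p[9] * ko * nai
             / ((ko + 1.0) * (nai + 40.0)
                * (1.0 + 0.1245 * math.exp(-0.1 * v / RTONF)
                   + 0.0353 * math.exp(-v / RTONF))))

    i_pca = p[11] * cai / (0.0005 + cai)
    i_pk = p[12] * (v - e_k) / (1.0 + math.exp((25.0 - v) / 5.98))
    i_bna = p[13] * (v - e_na)
    i_bca = p[14] * (v - e_ca)

    i_fna = p[6] * y * (v - e_na)
    i_fk = p[7] * y * (v - e_k)

    cur[0] = i_na; cur[1] = i_k1; cur[2] = i_to; cur[3] = i_kr; cur[4] = i_ks
    cur[5] = i_cal; cur[6] = i_cat; cur[7] = i_naca; cur[8] = i_nak
    cur[9] = i_pca; cur[10] = i_pk; cur[11] = i_bca; cur[12] = i_bna
    cur[13] = i_fna; cur[14] = i_fk

    i_tot = (i_na + i_k1 + i_to + i_kr + i_ks + i_cal + i_cat + i_naca
             + i_nak + i_pca + i_pk + i_bca + i_bna + i_fna + i_fk)

    # --- gate kinetics: steady state gi[], time constant gt[] (ms) ---
    # m
    gi[0] = 1.0 / ((1.0 + math.exp((-56.86 - v) / 9.03)) ** 2)
    am = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + math.exp((v - 50.0) / 200.0))
    gt[0] = am * bm
    # h
    gi[1] = 1.0 / ((1.0 + math.exp((v + 71.55) / 7.43)) ** 2)
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
    gt[1] = 1.0 / (ah + bh)
    # j
    gi[2] = gi[1]
    if v >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        aj = ((-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
              * (v + 37.78) / (1.0 + math.exp(0.311 * (v + 79.23))))
        bj = 0.02424 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    gt[2] = 1.0 / (aj + bj)
    # d
    gi[3] = 1.0 / (1.0 + math.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    gt[3] = ad * bd + gd
    # f
    gi[4] = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    gt[4] = (1102.5 * math.exp(-(v + 27.0) ** 2 / 225.0)
             + 200.0 / (1.0 + math.exp((13.0 - v) / 10.0))
             + 180.0 / (1.0 + math.exp((v + 30.0) / 10.0)) + 20.0)
    # f2
    gi[5] = 0.67 / (1.0 + math.exp((v + 35.0) / 7.0)) + 0.33
    gt[5] = (562.0 * math.exp(-(v + 27.0) ** 2 / 240.0)
             + 31.0 / (1.0 + math.exp((25.0 - v) / 10.0))
             + 80.0 / (1.0 + math.exp((v + 30.0) / 10.0)))
    # fCass (Ca-dependent)
    fc = 1.0 / (1.0 + (cass / 0.05) ** 2)
    gi[6] = 0.6 * fc + 0.4
    gt[6] = 80.0 * fc + 2.0
    # r
    gi[7] = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
    gt[7] = 9.5 * math.exp(-(v + 40.0) ** 2 / 1800.0) + 0.8
    # s (transmural variant)
    if endo > 0.5:
        gi[8] = 1.0 / (1.0 + math.exp((v + 28.0) / 5.0))
        gt[8] = 1000.0 * math.exp(-(v + 67.0) ** 2 / 1000.0) + 8.0
    else:
        gi[8] = 1.0 / (1.0 + math.exp((v + 20.0) / 5.0))
        gt[8] = (85.0 * math.exp(-(v + 45.0) ** 2 / 320.0)
                 + 5.0 / (1.0 + math.exp((v - 20.0) / 5.0)) + 3.0)
    # xr1
    gi[9] = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
    gt[9] = axr1 * bxr1
    # xr2
    gi[10] = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
    gt[10] = axr2 * bxr2
    # xs
    gi[11] = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((v - 35.0) / 15.0))
    gt[11] = axs * bxs + 80.0
    # y (funny-current activation; human SAN voltage dependence).  With the
    # instantaneous option the gate collapses onto its steady state within a
    # single step (vanishing time constant).
    gi[12] = 1.0 / (1.0 + math.exp((v - p[21]) / p[22]))
    if p[20] > 0.5:
        gt[12] = 1e-4
    else:
        gt[12] = p[23] * 1000.0 * 0.7166529 / (0.0708 * math.exp(-(v + 5.0) / 20.2791)
                                               + 10.6 * math.exp(v / 18.0))
    # dT (T-type activation)
    gi[13] = 1.0 / (1.0 + math.exp(-(v + 37.0) / 6.8))
    gt[13] = 1.0 / (1.068 * math.exp((v + 26.3) / 30.0)
                    + 1.068 * math.exp(-(v + 26.3) / 30.0))
    # fT (T-type inactivation)
    gi[14] = 1.0 / (1.0 + math.exp((v + 71.0) / 9.0))
    gt[14] = 1.0 / (0.0153 * math.exp(-(v + 61.7) / 83.3)
                    + 0.015 * math.exp((v + 61.7) / 15.38))

    # --- SR calcium fluxes (mM/ms) ---
    kcasr = 2.5 - 1.5 / (1.0 + (1.5 / casr) ** 2)
    k1 = 0.15 / kcasr
    k2 = 0.045 * kcasr
    o_rel = k1 * cass * cass * rbar / (0.06 + k1 * cass * cass)
    i_rel = 0.102 * o_rel * (casr - cass)
    i_leak = 0.00036 * (casr - cai)
    i_up = 0.006375 / (1.0 + (0.00025 / cai) ** 2)
    i_xfer = 0.0038 * (cass - cai)

    # --- derivatives ---
    cm_rel = cm / CM_REF
    ds[0] = -i_tot / cm_rel
    for g in range(15):
        ds[1 + g] = (gi[g] - s[1 + g]) / gt[g]

    conv = cm / (V_CYTO * FARADAY)
    ds[16] = -(i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca + i_fna) * conv
    ds[17] = -(i_k1 + i_to + i_kr + i_ks - 2.0 * i_nak + i_pk + i_fk) * conv

    if p[24] > 0.5:
        i_cat_ss = i_cat
        i_cat_cyto = 0.0
    else:
        i_cat_ss = 0.0
        i_cat_cyto = i_cat
    bufc = 1.0 / (1.0 + 0.2 * 0.001 / ((cai + 0.001) ** 2))
    ds[18] = bufc * ((i_leak - i_up) * V_SR / V_CYTO + i_xfer
                     - (i_bca + i_pca + i_cat_cyto - 2.0 * i_naca)
                     * cm / (2.0 * V_CYTO * FARADAY))
    bufsr = 1.0 / (1.0 + 10.0 * 0.3 / ((casr + 0.3) ** 2))
    ds[19] = bufsr * (i_up - i_rel - i_leak)
    bufss = 1.0 / (1.0 + 0.4 * 0.00025 / ((cass + 0.00025) ** 2))
    ds[20] = bufss * (-(i_cal + i_cat_ss) * cm / (2.0 * V_SS * FARADAY)
                      + i_rel * V_SR / V_SS - i_xfer * V_CYTO / V_SS)
    ds[21] = -k2 * cass * rbar + 0.005 * (1.0 - rbar)

    return i_tot


def _eval_state(state: CellState, params: ModelParameters):
    state.validate()
    s = state.as_array()
    p = params.pvec()
    cur = np.empty(N_CURRENTS)
    gi = np.empty(N_GATES)
    gt = np.empty(N_GATES)
    ds = np.empty(N_STATE)
    _eval(s, p, cur, gi, gt, ds)
    return cur, gi, gt, ds


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def compute_currents(state: CellState, params: ModelParameters) -> CurrentSet:
    """All membrane current densities for a given state (pA/pF)."""
    cur, _, _, _ = _eval_state(state, params)
    return CurrentSet(*cur)


def derivatives(state: CellState, params: ModelParameters) -> CellState:
    """Time derivatives of every state variable (per ms)."""
    _, _, _, ds = _eval_state(state, params)
    return CellState(**dict(zip(STATE_FIELDS, ds)))


def auxiliaries(state: CellState, params: ModelParameters) -> AuxiliaryQuantities:
    """Reversal potentials and the I_K1 rectification factor."""
    state.validate()
    e_k = RTONF * math.log(params.K_o / state.K_i)
    e_na = RTONF * math.log(params.Na_o / state.Na_i)
    e_ks = RTONF * math.log((params.K_o + 0.03 * params.Na_o)
                            / (state.K_i + 0.03 * state.Na_i))
    e_ca = 0.5 * RTONF * math.log(params.Ca_o / state.Ca_i)
    return AuxiliaryQuantities(E_K=e_k, E_Na=e_na, E_Ca=e_ca, E_Ks=e_ks,
                               x_k1_inf=_xk1_inf(state.V, e_k))


def gate_steady_states(v: float, ca_ss: float = 7e-5,
                       cell_variant: str = "epicardial") -> dict:
    """Steady-state value of every gate at a clamped voltage."""
    s = resting_state().as_array()
    s[0] = v
    s[20] = ca_ss
    p = ModelParameters(cell_variant=cell_variant, S_f=1.0,
                        include_I_CaT=True).pvec()
    cur = np.empty(N_CURRENTS)
    gi = np.empty(N_GATES)
    gt = np.empty(N_GATES)
    ds = np.empty(N_STATE)
    _eval(s, p, cur, gi, gt, ds)
    names = STATE_FIELDS[GATE_SLICE]
    return dict(zip(names, gi))


def i_k1_density(v: float, params: ModelParameters,
                 k_i: float = REFERENCE_CONDITIONS["K_i"]) -> float:
    """Scaled inward-rectifier current density at a voltage (pA/pF)."""
    if params.K_o <= 0 or k_i <= 0:
        raise ValueError("K_o and K_i must be positive")
    return params.S_K1 * _ik1_raw_density(v, params.G_K1, params.K_o, k_i)


def i_f_density(v: float, y: float, params: ModelParameters,
                na_i: float = REFERENCE_CONDITIONS["Na_i"],
                k_i: float = REFERENCE_CONDITIONS["K_i"]) -> tuple[float, float, float]:
    """(I_f_Na, I_f_K, I_f) densities for a given activation level (pA/pF)."""
    if not 0.0 <= y <= 1.0:
        raise ValueError("y must lie in [0, 1]")
    e_na = RTONF * math.log(params.Na_o / na_i)
    e_k = RTONF * math.log(params.K_o / k_i)
    i_na = params.S_f * params.G_f_Na * y * (v - e_na)
    i_k = params.S_f * params.G_f_K * y * (v - e_k)
    return i_na, i_k, i_na + i_k


def iv_curve(current_id: str, scale: float,
             v_grid=None) -> np.ndarray:
    """Steady-state I-V relation of I_K1 or I_f under reference conditions.

    Returns an (n, 2) array of (V in mV, density in pA/pF).
    """
    if v_grid is None:
        v_grid = np.arange(-120.0, 20.1, 1.0)
    v_grid = np.asarray(v_grid, dtype=float)
    out = np.empty((v_grid.size, 2))
    out[:, 0] = v_grid
    if current_id == "I_K1":
        p = ModelParameters(S_K1=1.0)
        out[:, 1] = [scale * _ik1_raw_density(v, p.G_K1, p.K_o,
                                              REFERENCE_CONDITIONS["K_i"])
                     for v in v_grid]
    elif current_id == "I_f":
        p = ModelParameters(S_f=1.0)
        out[:, 1] = [scale * i_f_density(v, _y_inf(v, p.y_vhalf, p.y_slope), p)[2]
                     for v in v_grid]
    else:
        raise ValueError(f"unknown current_id {current_id!r}; expected 'I_K1' or 'I_f'")
    return out


def density_to_scale(current_id: str, density_at_minus80: float) -> float:
    """Map a current density at -80 mV (pA/pF) onto its scaling factor."""
    d = float(density_at_minus80)
    if current_id == "I_K1":
        if d < 0:
            raise ValueError("I_K1 density at -80 mV must be >= 0")
        return d / IK1_ANCHOR_DENSITY
    if current_id == "I_f":
        if d > 0:
            raise ValueError("I_f density at -80 mV must be <= 0")
        return d / IF_ANCHOR_DENSITY
    raise ValueError(f"unknown current_id {current_id!r}; expected 'I_K1' or 'I_f'")
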