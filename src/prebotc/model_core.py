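"""Single-cell model of an embryonic preBötzinger-complex inspiratory pacemaker neuron.

The model couples a Hodgkin–Huxley-style spiking membrane carrying a
persistent sodium current (I_NaP) and a calcium-activated nonspecific
cation current (I_CAN) to a two-pool (cytosol / endoplasmic reticulum)
calcium subsystem with IP3-receptor, SERCA, voltage-gated Ca entry and
PMCA fluxes.  Bursting can arise from either of two slow processes:
slow inactivation of I_NaP (favoring short "oscillatory" bursts) or
slow ER-driven calcium oscillations acting through I_CAN (favoring
long "plateau" bursts); intermediate conductance balances yield mixed
discharge.

Electrical units are mV / ms / nS / pF / pA (so nS·mV = pA and
pA/pF = mV/ms); calcium concentrations are in µM.  Membrane currents
are positive outward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Mapping

__all__ = [
    "ModelParameters",
    "StateVector",
    "CurrentBreakdown",
    "FluxBreakdown",
    "gate_steady_state",
    "gate_time_constant",
    "compute_currents",
    "calcium_fluxes",
    "rhs",
    "make_rhs",
]


class InvalidParameterError(ValueError):
    """A model parameter violates its constraint."""


class InvalidStateError(ValueError):
    """A state vector violates its physical constraints."""


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set for the single-cell model.

    Defaults are the published values for the embryonic inspiratory
    pacemaker model; the two burst-generating conductances ``gNaP`` and
    ``gCAN`` default to the plateau-bursting reference point (2.5 nS
    each) inside their stated ranges (gNaP 0–3 nS, gCAN 0–4.5 nS).

    Attributes
    ----------
    Cm : membrane capacitance, pF.
    gNaP, gNa, gK, gL, gCAN, gCa, gh : maximal conductances, nS.
    VNaP, VNa, VK, VL, VCa, Vh : reversal potentials, mV.  I_CAN
        reverses at ``VNaP`` (as defined for this model).
    vm, sm : activation midpoint / slope of the slow persistent-sodium
        activation, shared by I_NaP and I_Ca, mV.  The fast spike-
        generating sodium current uses its own ``vm_na, sm_na``
        (antecedent-model values −34 / −5 mV by default: sharing the
        I_NaP activation with the fast Na current produces an
        unphysiological stable depolarized state instead of spiking).
        ``vm_ca, sm_ca`` decouple the Ca activation (equal to vm/sm
        by default).
    vh, sh, tau_h_bar : I_NaP inactivation midpoint, slope (mV) and
        maximal time constant (ms).
    vn, sn, tau_n_bar : delayed-rectifier gating midpoint, slope (mV)
        and (voltage-independent) time constant (ms).  Midpoint and
        slope follow the antecedent respiratory-neuron spiking model.
    KCAN : calcium half-activation of I_CAN, µM.
    lam : ER-to-plasma-membrane surface ratio λ (dimensionless).
    fi : bound-to-free calcium ratio (dimensionless).
    Vi : effective cytosolic volume scale.
    sigma : cytosol-to-ER volume ratio σ.
    IP3 : IP3 concentration, µM.
    A : IP3-receptor gate rate constant, 1/(µM·ms).
    Kd, KI, Ka : IP3R inactivation / activation dissociation
        constants, µM.
    LIP3R, PIP3R : ER leak and maximal IP3R permeabilities.
    VSERCA, KSERCA : SERCA pump maximal rate and half-activation (µM).
    alpha : conversion factor from I_Ca (pA) to calcium flux.
    VPMCA, KPMCA : PMCA pump maximal rate and half-activation (µM).
    flux_scale : single global factor converting the calcium fluxes of
        the printed rate constants to µM/ms; calibrated once so that
        the plateau / mixed / oscillatory regimes appear at the
        published conductance values.
    spiking_mode : ``"reconciled"`` (default) uses the full spiking
        membrane (fast Na, n^4 delayed rectifier, ohmic leak);
        ``"as_printed"`` uses the reduced membrane equation with an
        ohmic K-dominated leak and no fast Na / separate leak term.
    """

    Cm: float = 21.0

    gNaP: float = 2.5
    gNa: float = 28.0
    gK: float = 11.2
    gL: float = 2.7
    gCAN: float = 2.5
    gCa: float = 0.05
    gh: float = 0.0

    VNaP: float = 50.0
    VNa: float = 50.0
    VK: float = -65.0
    VL: float = -60.0
    VCa: float = 150.0
    Vh: float = -30.0

    vm: float = -40.0
    sm: float = -6.0
    vm_na: float = -34.0
    sm_na: float = -5.0
    vm_ca: float = -40.0
    sm_ca: float = -6.0

    vh: float = -48.0
    sh: float = 5.0
    tau_h_bar: float = 10000.0

    vn: float = -29.0
    sn: float = -4.0
    tau_n_bar: float = 10.0

    KCAN: float = 0.74

    lam: float = 0.03
    fi: float = 1.0e-4
    Vi: float = 4.0
    sigma: float = 0.185

    IP3: float = 1.0
    A: float = 5.0e-4
    Kd: float = 0.4
    KI: float = 1.0
    Ka: float = 0.4
    LIP3R: float = 0.37
    PIP3R: float = 31000.0
    VSERCA: float = 400.0
    KSERCA: float = 0.2
    alpha: float = 0.055
    VPMCA: float = 2.0
    KPMCA: float = 0.3

    flux_scale: float = 0.6

    spiking_mode: str = "reconciled"
    n_tau_voltage_dependent: bool = True

    def __post_init__(self) -> None:
        for name in ("gNaP", "gNa", "gK", "gL", "gCAN", "gCa", "gh"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.Cm <= 0:
            raise InvalidParameterError("Cm must be > 0")
        for name in ("tau_h_bar", "tau_n_bar"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        for name in ("KCAN", "Kd", "KI", "Ka", "KSERCA", "KPMCA"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not 0 < self.fi <= 1:
            raise InvalidParameterError("fi must be in (0, 1]")
        if self.lam <= 0:
            raise InvalidParameterError("lam must be > 0")
        if self.sigma <= 0:
            raise InvalidParameterError("sigma must be > 0")
        for name in ("sm", "sh", "sn"):
            if getattr(self, name) == 0:
                raise InvalidParameterError(f"{name} must be nonzero")
        if self.spiking_mode not in ("reconciled", "as_printed"):
            raise InvalidParameterError(
                f"spiking_mode must be 'reconciled' or 'as_printed', "
                f"got {self.spiking_mode!r}"
            )

    # -- per-current activation aliases --------------------------------
    @property
    def vmNa(self) -> float:
        return self.vm_na

    @property
    def smNa(self) -> float:
        return self.sm_na

    @property
    def vmCa(self) -> float:
        return self.vm_ca

    @property
    def smCa(self) -> float:
        return self.sm_ca

    def with_updates(self, **kwargs: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter keys: {sorted(unknown)}"
            )
        return cls(**{k: d[k] for k in d})


@dataclass
class StateVector:
    """The ODE state.

    V : membrane potential, mV.
    h : I_NaP inactivation gate in [0, 1].
    n : delayed-rectifier gating variable in [0, 1].
    Ca_i : cytosolic calcium, µM.
    Ca_tot : total (cytosol + ER, cytosol-referred) calcium, µM.
    l : IP3-receptor inactivation gate in [0, 1].
    """

    V: float
    h: float
    n: float
    Ca_i: float
    Ca_tot: float
    l: float

    def validate(self, sigma: float = 0.185) -> None:
        for name in ("h", "n", "l"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise InvalidStateError(f"gate {name}={x} outside [0, 1]")
        if self.Ca_i < 0:
            raise InvalidStateError(f"Ca_i={self.Ca_i} negative")
        if self.ca_er(sigma) < 0:
            raise InvalidStateError(
                f"Ca_ER=({self.Ca_tot}-{self.Ca_i})/{sigma} negative"
            )
        for name in ("V", "h", "n", "Ca_i", "Ca_tot", "l"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidStateError(f"non-finite state component {name}")

    def ca_er(self, sigma: float) -> float:
        """ER calcium concentration, (Ca_tot − Ca_i)/σ, µM."""
        return (self.Ca_tot - self.Ca_i) / sigma

    def as_array(self) -> list:
        return [self.V, self.h, self.n, self.Ca_i, self.Ca_tot, self.l]

    @classmethod
    def from_array(cls, y) -> "StateVector":
        return cls(*(float(x) for x in y))

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_array())


@dataclass(frozen=True)
class CurrentBreakdown:
    """Membrane currents in pA, positive outward."""

    INaP: float
    INa: float
    IK: float
    IL: float
    ICa: float
    ICAN: float
    Ih: float

    @property
    def total(self) -> float:
        return (self.INaP + self.INa + self.IK + self.IL
                + self.ICa + self.ICAN + self.Ih)


@dataclass(frozen=True)
class FluxBreakdown:
    """Calcium fluxes in the model's internal flux units.

    The right-hand side converts these to µM/ms through ``fi/Vi`` and
    the global ``flux_scale``.
    """

    J_ER_in: float
    J_ER_out: float
    J_PM_in: float
    J_PM_out: float


def gate_steady_state(V: float, Vx: float, sx: float) -> float:
    """Sigmoid steady-state gating curve x∞(V) = 1/(1+exp((V−Vx)/sx)).

    A negative slope ``sx`` gives an activation curve (increasing with
    V), a positive slope an inactivation curve.
    """
    if sx == 0:
        raise InvalidParameterError("gating slope sx must be nonzero")
    z = (V - Vx) / sx
    # guard exp overflow; the sigmoid saturates anyway
    if z > 500.0:
        return 0.0
    if z < -500.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(z))


def gate_time_constant(V: float, tau_bar: float, Vx: float, sx: float) -> float:
    """Bell-shaped voltage-dependent time constant τ(V) = τ̄/cosh((V−Vx)/(2 sx)).

    Maximal (equal to ``tau_bar``) at V = Vx and symmetric about it.
    """
    if sx == 0:
        raise InvalidParameterError("gating slope sx must be nonzero")
    if tau_bar <= 0:
        raise InvalidParameterError("tau_bar must be > 0")
    z = (V - Vx) / (2.0 * sx)
    if abs(z) > 500.0:
        return 0.0
    return tau_bar / math.cosh(z)


def compute_currents(s: StateVector, p: ModelParameters) -> CurrentBreakdown:
    """Evaluate every membrane current (pA, outward positive) at a state.

    In the default (``reconciled``) mode the membrane carries fast
    sodium gNa·m∞³·(1−n)·(V−VNa) and delayed-rectifier gK·n⁴·(V−VK)
    spiking currents plus an ohmic leak; in ``as_printed`` mode the
    spike-generating pair is absent and I_K is the ohmic K-dominated
    leak gK·(V−VK).
    """
    V = s.V
    minf = gate_steady_state(V, p.vm, p.sm)
    INaP = p.gNaP * minf * s.h * (V - p.VNaP)
    ICa = p.gCa * gate_steady_state(V, p.vmCa, p.smCa) * (V - p.VCa)
    ICAN = p.gCAN * (s.Ca_i / (s.Ca_i + p.KCAN)) * (V - p.VNaP)
    Ih = p.gh * gate_steady_state(V, p.vn, p.sn) * (V - p.Vh)
    if p.spiking_mode == "reconciled":
        mNa = gate_steady_state(V, p.vmNa, p.smNa)
        INa = p.gNa * mNa ** 3 * (1.0 - s.n) * (V - p.VNa)
        IK = p.gK * s.n ** 4 * (V - p.VK)
        IL = p.gL * (V - p.VL)
    else:
        INa = 0.0
        IK = p.gK * (V - p.VK)
        IL = 0.0
    return CurrentBreakdown(INaP=INaP, INa=INa, IK=IK, IL=IL,
                            ICa=ICa, ICAN=ICAN, Ih=Ih)


def calcium_fluxes(s: StateVector, p: ModelParameters,
                   ICa: float) -> FluxBreakdown:
    """Evaluate the four calcium fluxes at a state.

    J_ER_in : IP3R-gated + leak flux from ER to cytosol, proportional
        to the ER–cytosol gradient.
    J_ER_out : SERCA pump uptake into the ER (Hill coefficient 2).
    J_PM_in : influx through voltage-gated Ca channels, −α·I_Ca.
    J_PM_out : PMCA pump extrusion (Hill coefficient 2).
    """
    Ca = s.Ca_i
    Ca_ER = s.ca_er(p.sigma)
    if Ca_ER < 0:
        raise InvalidStateError(f"negative ER calcium: {Ca_ER}")
    po = (p.IP3 * Ca * s.l) / ((p.IP3 + p.KI) * (Ca + p.Ka))
    J_ER_in = (p.LIP3R + p.PIP3R * po ** 3) * (Ca_ER - Ca)
    J_ER_out = p.VSERCA * Ca * Ca / (p.KSERCA ** 2 + Ca * Ca)
    J_PM_in = -p.alpha * ICa
    J_PM_out = p.VPMCA * Ca * Ca / (p.KPMCA ** 2 + Ca * Ca)
    return FluxBreakdown(J_ER_in=J_ER_in, J_ER_out=J_ER_out,
                         J_PM_in=J_PM_in, J_PM_out=J_PM_out)


def rhs(t: float, s: StateVector, p: ModelParameters,
        I_app: float = 0.0) -> StateVector:
    """Time derivative of the full state (structured reference path).

    Membrane:  Cm dV/dt = −ΣI_membrane + I_app.
    Gates:     dh/dt = (h∞(V)−h)/τ_h(V);  dn/dt = (n∞(V)−n)/τ̄_n.
    Calcium:   dCa_i/dt  = s·(fi/Vi)·((1/λ)(J_PM_in−J_PM_out)
                                       + (J_ER_in−J_ER_out))
               dCa_tot/dt = s·(fi/Vi)·(1/λ)(J_PM_in−J_PM_out)
               dl/dt = A·(Kd − l·(Ca_i+Kd))
    where s is the global flux scale.  J_ER_in is a release flux
    (ER→cytosol) and J_ER_out SERCA uptake, so net ER release raises
    cytosolic calcium and drains the ER (Ca_ER = (Ca_tot−Ca_i)/σ).
    """
    for name in ("V", "h", "n", "Ca_i", "Ca_tot", "l"):
        if not math.isfinite(getattr(s, name)):
            raise InvalidStateError(f"non-finite state component {name}")
    cur = compute_currents(s, p)
    flux = calcium_fluxes(s, p, cur.ICa)
    dV = (-cur.total + I_app) / p.Cm
    hinf = gate_steady_state(s.V, p.vh, p.sh)
    tauh = gate_time_constant(s.V, p.tau_h_bar, p.vh, p.sh)
    dh = (hinf - s.h) / tauh
    ninf = gate_steady_state(s.V, p.vn, p.sn)
    if p.n_tau_voltage_dependent:
        taun = gate_time_constant(s.V, p.tau_n_bar, p.vn, p.sn)
    else:
        taun = p.tau_n_bar
    dn = (ninf - s.n) / taun
    scale = p.flux_scale * p.fi / p.Vi
    j_pm = (flux.J_PM_in - flux.J_PM_out) / p.lam
    j_er = flux.J_ER_in - flux.J_ER_out
    dCa_i = scale * (j_pm + j_er)
    dCa_tot = scale * j_pm
    dl = p.A * (p.Kd - s.l * (s.Ca_i + p.Kd))
    return StateVector(V=dV, h=dh, n=dn, Ca_i=dCa_i, Ca_tot=dCa_tot, l=dl)


def make_rhs(p: ModelParameters, I_app: float = 0.0):
    """Build a flat-array RHS ``f(t, y) -> dy`` for the ODE solver.

    Functionally identical to :func:`rhs` but operating on plain float
    arrays with all parameters bound into the closure; this is the path
    the simulator integrates (the structured path is kept as the
    readable reference and the two are tested for agreement).
    """
    Cm = p.Cm
    gNaP, gNa, gK, gL = p.gNaP, p.gNa, p.gK, p.gL
    gCAN, gCa, gh = p.gCAN, p.gCa, p.gh
    VNaP, VNa, VK, VL, VCa, Vh = p.VNaP, p.VNa, p.VK, p.VL, p.VCa, p.Vh
    vm, sm = p.vm, p.sm
    vmNa, smNa, vmCa, smCa = p.vmNa, p.smNa, p.vmCa, p.smCa
    vh, sh, tau_h_bar = p.vh, p.sh, p.tau_h_bar
    vn, sn, tau_n_bar = p.vn, p.sn, p.tau_n_bar
    KCAN = p.KCAN
    IP3, KI, Ka, Kd, A = p.IP3, p.KI, p.Ka, p.Kd, p.A
    LIP3R, PIP3R = p.LIP3R, p.PIP3R
    VSERCA, KSERCA2 = p.VSERCA, p.KSERCA ** 2
    VPMCA, KPMCA2 = p.VPMCA, p.KPMCA ** 2
    alpha, lam, sigma = p.alpha, p.lam, p.sigma
    scale = p.flux_scale * p.fi / p.Vi
    reconciled = p.spiking_mode == "reconciled"
    n_tau_vdep = p.n_tau_voltage_dependent
    exp, cosh = math.exp, math.cosh

    def f(t, y):
        V, h, n, Ca, Ca_tot, l = y
        minf = 1.0 / (1.0 + exp((V - vm) / sm))
        INaP = gNaP * minf * h * (V - VNaP)
        mCa = 1.0 / (1.0 + exp((V - vmCa) / smCa))
        ICa = gCa * mCa * (V - VCa)
        ICAN = gCAN * (Ca / (Ca + KCAN)) * (V - VNaP)
        ninf = 1.0 / (1.0 + exp((V - vn) / sn))
        Ih = gh * ninf * (V - Vh)
        if reconciled:
            mNa = 1.0 / (1.0 + exp((V - vmNa) / smNa))
            INa = gNa * mNa * mNa * mNa * (1.0 - n) * (V - VNa)
            IK = gK * n * n * n * n * (V - VK)
            IL = gL * (V - VL)
        else:
            INa = 0.0
            IK = gK * (V - VK)
            IL = 0.0
        dV = (-(INaP + INa + IK + IL + ICa + ICAN + Ih) + I_app) / Cm
        hinf = 1.0 / (1.0 + exp((V - vh) / sh))
        tauh = tau_h_bar / cosh((V - vh) / (2.0 * sh))
        dh = (hinf - h) / tauh
        if n_tau_vdep:
            dn = (ninf - n) * cosh((V - vn) / (2.0 * sn)) / tau_n_bar
        else:
            dn = (ninf - n) / tau_n_bar
        Ca_ER = (Ca_tot - Ca) / sigma
        po = (IP3 * Ca * l) / ((IP3 + KI) * (Ca + Ka))
        J_ER = (LIP3R + PIP3R * po * po * po) * (Ca_ER - Ca) \
            - VSERCA * Ca * Ca / (KSERCA2 + Ca * Ca)
        J_PM = (-alpha * ICa - VPMCA * Ca * Ca / (KPMCA2 + Ca * Ca)) / lam
        dCa = scale * (J_PM + J_ER)
        dCa_tot = scale * J_PM
        dl = A * (Kd - l * (Ca + Kd))
        return (dV, dh, dn, dCa, dCa_tot, dl)

    return f
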