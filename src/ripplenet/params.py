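"""Model parameter sets and the physical <-> dimensionless conversion.

The spiking network is a fully connected population of N leaky
integrate-and-fire (LIF) interneurons with membrane time constant
``tau_m``, capacitance ``C``, resting potential ``E_leak``, spike
threshold ``V_thr``, reset potential ``V_reset``, delayed inhibitory
pulse coupling of strength ``J`` (delay ``delta``) and independent
Gaussian white voltage noise of long-time standard deviation
``sigma_V``.

For the mean-field analysis all voltages are shifted and rescaled so
that rest sits at 0 and the spike threshold at ``V_T = 1`` (voltage
measured in units of the rest-to-threshold distance).  In these units
the model is fully characterised by the dimensionless threshold
``V_T = 1``, reset ``V_R``, coupling ``K``, noise variance ``D``, and
the time scales ``tau_m`` and ``delta`` (kept in ms).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict, replace
from pathlib import Path


@dataclass(frozen=True)
class PhysicalParams:
    """Spiking-network parameters in physical units.

    Units: ``tau_m``/``delta`` ms, ``C`` pF, voltages mV, ``J`` mV
    (peak IPSP amplitude before the 1/N scaling), ``sigma_V`` mV.
    """

    N: int = 10_000
    tau_m: float = 10.0
    C: float = 100.0
    E_leak: float = -65.0
    V_thr: float = -52.0
    V_reset: float = -65.0
    J: float = 65.0
    delta: float = 1.2
    sigma_V: float = 2.62

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.tau_m <= 0 or self.delta <= 0:
            raise ValueError("tau_m and delta must be positive")
        if self.sigma_V < 0:
            raise ValueError("sigma_V must be non-negative")
        if self.V_reset > self.V_thr:
            raise ValueError("V_reset must not exceed V_thr")


@dataclass(frozen=True)
class DimensionlessParams:
    """Rescaled parameter set (threshold at 1, rest at 0).

    ``D`` is the stationary variance of the free membrane potential,
    ``K`` the recurrent coupling strength.  ``tau_ref`` (ms) is only
    used by the stationary f-I curve; the network itself has no
    absolute refractory period.
    """

    V_T: float = 1.0
    V_R: float = 0.0
    K: float = 5.0
    D: float = 0.04
    tau_m: float = 10.0
    delta: float = 1.2
    N: int = 10_000
    tau_ref: float = 0.0

    def __post_init__(self) -> None:
        if self.V_T != 1.0:
            raise ValueError("V_T is 1 by construction of the rescaling")
        if self.V_R >= self.V_T:
            raise ValueError("V_R must be below V_T")
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.tau_m <= 0 or self.delta <= 0:
            raise ValueError("tau_m and delta must be positive")


#: Defaults in the dimensionless representation, as conventionally quoted
#: (D rounded to 0.04); the exact conversion of sigma_V = 2.62 mV gives
#: D = (2.62/13)^2 ~ 0.0406.
DEFAULT_DIMENSIONLESS = DimensionlessParams()
DEFAULT_PHYSICAL = PhysicalParams()


def voltage_scale(p: PhysicalParams) -> float:
    """Rest-to-threshold distance ``V_thr - E_leak`` in mV."""
    scale = p.V_thr - p.E_leak
    if scale <= 0:
        raise ValueError("V_thr must exceed E_leak (degenerate voltage scale)")
    return scale


def to_dimensionless(p: PhysicalParams) -> DimensionlessParams:
    """Map a physical parameter set onto the rescaled one.

    ``V_R = (V_reset - E_leak)/(V_thr - E_leak)``, ``K = J/(V_thr - E_leak)``,
    ``D = (sigma_V/(V_thr - E_leak))**2``; time constants are unchanged.
    """
    s = voltage_scale(p)
    return DimensionlessParams(
        V_T=1.0,
        V_R=(p.V_reset - p.E_leak) / s,
        K=p.J / s,
        D=(p.sigma_V / s) ** 2 if p.sigma_V > 0 else 1e-300,
        tau_m=p.tau_m,
        delta=p.delta,
        N=p.N,
    )


def to_physical(d: DimensionlessParams, template: PhysicalParams | None = None) -> PhysicalParams:
    """Inverse of :func:`to_dimensionless`, using ``template`` for the
    voltage scale and capacitance (defaults to the package defaults)."""
    t = template or DEFAULT_PHYSICAL
    s = voltage_scale(t)
    return PhysicalParams(
        N=d.N,
        tau_m=d.tau_m,
        C=t.C,
        E_leak=t.E_leak,
        V_thr=t.E_leak + s,
        V_reset=t.E_leak + d.V_R * s,
        J=d.K * s,
        delta=d.delta,
        sigma_V=(d.D ** 0.5) * s,
    )


def drive_to_dimensionless(I_ext_nA: float, p: PhysicalParams | None = None) -> float:
    """External current (nA) -> dimensionless drive ``I_E``.

    ``I_E = tau_m/(C (V_thr - E_leak)) * I_ext`` with tau_m in ms, C in pF,
    voltages in mV and the current in nA (all factors of 10^-3 cancel).
    """
    p = p or DEFAULT_PHYSICAL
    return p.tau_m / (p.C * voltage_scale(p)) * I_ext_nA * 1e3


def drive_to_physical(I_E: float, p: PhysicalParams | None = None) -> float:
    """Dimensionless drive -> external current in nA (inverse map)."""
    p = p or DEFAULT_PHYSICAL
    return I_E * p.C * voltage_scale(p) / p.tau_m * 1e-3


def as_dimensionless(params) -> DimensionlessParams:
    """Accept either parameter flavour and return the dimensionless one."""
    if isinstance(params, DimensionlessParams):
        return params
    if isinstance(params, PhysicalParams):
        return to_dimensionless(params)
    raise TypeError(f"unsupported parameter type {type(params)!r}")


_UNITS = {
    "N": "count", "tau_m": "ms", "C": "pF", "E_leak": "mV", "V_thr": "mV",
    "V_reset": "mV", "J": "mV", "delta": "ms", "sigma_V": "mV",
    "V_T": "dimensionless", "V_R": "dimensionless", "K": "dimensionless",
    "D": "dimensionless", "tau_ref": "ms",
}


def save_params(params, path) -> None:
    """Write a parameter set as a flat key-value file (one key per row,
    units in comments)."""
    kind = "physical" if isinstance(params, PhysicalParams) else "dimensionless"
    buf = io.StringIO()
    buf.write(f"# ripplenet parameter set ({kind})\n")
    for key, val in asdict(params).items():
        buf.write(f"{key} = {val!r}  # {_UNITS.get(key, '')}\n")
    Path(path).write_text(buf.getvalue())


def load_params(path):
    """Read a parameter set written by :func:`save_params`."""
    text = Path(path).read_text()
    kind = "physical" if "(physical)" in text.splitlines()[0] else "dimensionless"
    fields = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip() if not line.lstrip().startswith("#") else ""
        if not line:
            continue
        key, val = (s.strip() for s in line.split("=", 1))
        fields[key] = int(val) if key == "N" else float(val)
    cls = PhysicalParams if kind == "physical" else DimensionlessParams
    return cls(**fields)


__all__ = [
    "PhysicalParams", "DimensionlessParams", "DEFAULT_PHYSICAL",
    "DEFAULT_DIMENSIONLESS", "to_dimensionless", "to_physical",
    "drive_to_dimensionless", "drive_to_physical", "as_dimensionless",
    "save_params", "load_params", "replace",
]
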