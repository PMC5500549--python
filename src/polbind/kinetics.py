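"""Single-nucleotide insertion kinetics: Michaelis–Menten fits and the
derived comparisons used to characterize polymerase variants.

Reaction rates v (nM·min⁻¹) at varying dNTP concentrations are fit to

    v = V_max · [dNTP] / (K_m + [dNTP])

by unweighted nonlinear least squares after averaging duplicate
measurements.  Catalytic efficiency is V_max/K_m with K_m expressed in mM,
the convention that reproduces the published efficiency columns (e.g.
V_max = 1.0 nM·min⁻¹, K_m = 88.2 µM → 1.0/0.0882 ≈ 11); values are shown at
two significant figures but kept at full precision internally.

Misinsertion fidelity is the efficiency ratio of incorrect over correct
insertion opposite the same template base (dATP vs dCTP opposite G or
8-oxoG); fold-changes compare the same quantity between two variants under
matched conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor, log10

import numpy as np
from scipy.optimize import curve_fit

from .errors import ComparisonError, ContractError, DegenerateDataError


@dataclass(frozen=True)
class AssayCondition:
    variant: str = ""
    template_base: str = "G"    # "G" or "8-oxoG"
    dntp: str = "dCTP"          # "dCTP" (correct) or "dATP" (incorrect)


@dataclass
class VelocityDataset:
    concentrations: np.ndarray      # µM
    rates: np.ndarray               # nM/min, aligned with concentrations
    condition: AssayCondition = field(default_factory=AssayCondition)
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.concentrations < 0) or np.any(self.rates < 0):
            raise ContractError("concentrations and rates must be non-negative")
        if len(self.rates) != len(self.concentrations):
            raise ContractError("rates length mismatch")

    def averaged(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean rate per distinct concentration (duplicates averaged)."""
        conc = np.unique(self.concentrations)
        v = np.array([
            self.rates[self.concentrations == c].mean() for c in conc
        ])
        return conc, v


@dataclass
class MMFit:
    km: float                   # µM
    vmax: float                 # nM/min
    km_sd: float
    vmax_sd: float
    condition: AssayCondition
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def efficiency(self) -> float:
        """V_max / K_m with K_m in mM (full precision)."""
        return self.vmax / (self.km / 1000.0)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0 or not np.isfinite(x):
        return x
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def _mm(c, vmax, km):
    return vmax * c / (km + c)


def fit_michaelis_menten(data: VelocityDataset) -> MMFit:
    """Fit (K_m, V_max) on duplicate-averaged rates.

    Initialization: V_max from the max rate, K_m from the concentration at
    half-max.  SDs come from the fit covariance.  Saturation-only data
    (all rates equal) leave K_m unidentifiable and yield a flagged fit.
    """
    conc, v = data.averaged()
    positive = conc > 0
    if np.unique(conc[positive]).size < 3:
        raise ContractError("need at least 3 distinct positive concentrations")
    if np.allclose(v, 0.0):
        raise DegenerateDataError("all-zero rates")
    if np.ptp(v) < 1e-9 * max(v.max(), 1.0):
        return MMFit(
            km=float("nan"), vmax=float(v.mean()), km_sd=float("nan"),
            vmax_sd=float("nan"), condition=data.condition, converged=False,
            flags=["K_m unidentifiable: rates show no concentration dependence"],
        )
    vmax0 = float(v.max())
    km0 = float(conc[np.argmin(np.abs(v - vmax0 / 2.0))])
    km0 = max(km0, float(conc[positive].min()) * 0.1)
    try:
        popt, pcov = curve_fit(
            _mm, conc, v, p0=[vmax0, km0],
            bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        return MMFit(
            km=float("nan"), vmax=float("nan"), km_sd=float("nan"),
            vmax_sd=float("nan"), condition=data.condition, converged=False,
            flags=[f"fit did not converge: {exc}"],
        )
    vmax, km = popt
    sd = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
    flags = []
    if km <= 0 or vmax <= 0:
        flags.append("non-positive fitted parameter")
    return MMFit(
        km=float(km), vmax=float(vmax), km_sd=float(sd[1]), vmax_sd=float(sd[0]),
        condition=data.condition, converged=not flags, flags=flags,
    )


def catalytic_efficiency(fit: MMFit, sig: int | None = 2) -> float:
    """V_max/K_m in the published units (K_m converted to mM).

    ``sig`` applies display rounding (2 significant figures by default);
    pass None for full precision.
    """
    if not (fit.km > 0 and fit.vmax > 0):
        raise ContractError("efficiency requires positive fitted parameters")
    eff = fit.efficiency
    return eff if sig is None else round_sig(eff, sig)


def fold_change(a: MMFit, b: MMFit, quantity: str = "vmax",
                override: bool = False) -> float:
    """quantity(a) / quantity(b) for matched assay conditions.

    Conditions must share template base and dNTP unless ``override``.
    """
    if not override and (
        a.condition.template_base != b.condition.template_base
        or a.condition.dntp != b.condition.dntp
    ):
        raise ComparisonError(
            f"conditions differ: {a.condition} vs {b.condition}; "
            "pass override=True to compare anyway"
        )
    getters = {
        "vmax": lambda f: f.vmax,
        "km": lambda f: f.km,
        "efficiency": lambda f: f.efficiency,
    }
    if quantity not in getters:
        raise ContractError(f"unknown quantity {quantity!r}")
    return getters[quantity](a) / getters[quantity](b)


def misinsertion_ratio(correct: MMFit, incorrect: MMFit) -> float:
    """efficiency(incorrect)/efficiency(correct) opposite the same template base.

    The correct insertion is dCTP opposite G or 8-oxoG; smaller ratios mean
    higher fidelity.
    """
    if correct.condition.template_base != incorrect.condition.template_base:
        raise ComparisonError(
            f"template bases differ: {correct.condition.template_base} vs "
            f"{incorrect.condition.template_base}"
        )
    if correct.condition.dntp != "dCTP":
        raise ComparisonError("the 'correct' fit must be a dCTP insertion")
    if incorrect.efficiency == 0:
        return 0.0
    return incorrect.efficiency / correct.efficiency
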