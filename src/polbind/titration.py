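"""Equilibrium K_d from 2-aminopurine fluorescence titrations.

A fixed amount of 2AP-labeled primer/template (100 nM) is titrated with
increasing polymerase, the protein-only background measured in a matched
control is subtracted pointwise, and the corrected signal is fit to the
hyperbola

    F = F_max · [pol] / (K_d + [pol]).

[pol] is the total added polymerase (no ligand-depletion correction), which
matches how such titrations are usually reported even when the probe
concentration is comparable to K_d; a depletion-corrected quadratic model
is available behind ``model="quadratic"`` for users who want it.

The fit is unweighted nonlinear least squares on replicate-averaged data.
Whether binding enhances or quenches the 2AP signal is inferred from the
data: a decreasing signal is fit with its sign flipped and reported as
quenching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import ContractError, DegenerateDataError


@dataclass
class TitrationDataset:
    """Polymerase titration points with an optional matched control series."""

    concentrations: np.ndarray   # nM, strictly increasing
    fluorescence: np.ndarray
    control: np.ndarray | None = None
    probe_concentration: float = 100.0  # nM

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.control is not None:
            self.control = np.asarray(self.control, dtype=float)
        if np.any(self.concentrations < 0):
            raise ContractError("negative concentration")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ContractError("concentrations must be strictly increasing")
        if len(self.fluorescence) != len(self.concentrations):
            raise ContractError("fluorescence length mismatch")
        if self.control is not None and len(self.control) != len(self.concentrations):
            raise ContractError(
                "control series not matched 1:1 on concentration"
            )


@dataclass
class TitrationFit:
    kd: float                 # nM
    fmax: float
    kd_se: float
    fmax_se: float
    rss: float
    converged: bool
    quenching: bool = False   # True when the raw signal decreases with [pol]
    message: str = ""


def correct_fluorescence(data: TitrationDataset) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the matched protein-background control pointwise."""
    if data.control is None:
        raise ContractError("no control series to subtract")
    return data.concentrations.copy(), data.fluorescence - data.control


def _hyperbola(c, fmax, kd):
    return fmax * c / (kd + c)


def _quadratic_bound(c, fmax, kd, probe):
    # fraction bound from the exact 1:1 binding quadratic (ligand depletion)
    s = probe
    term = c + s + kd
    frac = (term - np.sqrt(term ** 2 - 4.0 * c * s)) / (2.0 * s)
    return fmax * frac


def fit_kd(
    concentrations: np.ndarray,
    fluorescence: np.ndarray,
    model: str = "hyperbolic",
    probe_concentration: float = 100.0,
) -> TitrationFit:
    """Fit (K_d, F_max) by unweighted nonlinear least squares.

    Initialization: F_max from the max signal, K_d from the concentration at
    half-max.  Standard errors come from the fit covariance.
    """
    c = np.asarray(concentrations, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    positive = c > 0
    if np.unique(c[positive]).size < 3:
        raise ContractError("need at least 3 distinct positive concentrations")
    if np.allclose(f, 0.0):
        raise DegenerateDataError("all-zero signal: nothing to fit")

    # sign of the response: fit on -f if fluorescence is quenched
    slope = np.polyfit(c, f, 1)[0]
    quenching = bool(slope < 0)
    y = -f if quenching else f

    fmax0 = float(np.max(y))
    if fmax0 <= 0:
        raise DegenerateDataError("non-positive signal after sign inference")
    half = fmax0 / 2.0
    kd0 = float(c[np.argmin(np.abs(y - half))])
    kd0 = max(kd0, float(np.min(c[positive])) * 0.1)

    if model == "hyperbolic":
        fun = _hyperbola
        p0 = [fmax0, kd0]
    elif model == "quadratic":
        def fun(cc, fmax, kd):
            return _quadratic_bound(cc, fmax, kd, probe_concentration)
        p0 = [fmax0, kd0]
    else:
        raise ContractError(f"unknown binding model {model!r}")

    try:
        popt, pcov = curve_fit(
            fun, c, y, p0=p0,
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        return TitrationFit(
            kd=float("nan"), fmax=float("nan"), kd_se=float("nan"),
            fmax_se=float("nan"), rss=float("nan"), converged=False,
            quenching=quenching, message=f"fit did not converge: {exc}",
        )
    fmax, kd = popt
    resid = y - fun(c, *popt)
    rss = float(resid @ resid)
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
    return TitrationFit(
        kd=float(kd), fmax=float(fmax),
        kd_se=float(perr[1]), fmax_se=float(perr[0]),
        rss=rss, converged=True, quenching=quenching,
    )


def fit_titration(data: TitrationDataset, model: str = "hyperbolic") -> TitrationFit:
    """Control-subtract (when a control is present) and fit."""
    if data.control is not None:
        c, f = correct_fluorescence(data)
    else:
        c, f = data.concentrations, data.fluorescence
    return fit_kd(c, f, model=model, probe_concentration=data.probe_concentration)
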