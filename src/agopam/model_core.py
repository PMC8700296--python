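"""Equilibrium two-state model of receptor activation with state-selective binding.

The receptor exists in an inactive conformation ``R`` and an active
conformation ``R*``, in equilibrium even without ligand.  The constitutive
activity of a construct is summarised by the unitless ratio

    alpha = [R] / [R*]   (at rest)

so that large ``alpha`` means a mostly-inactive receptor (low basal
signalling) and ``alpha = 0`` a fully active one.  An allosteric ligand ``A``
binds the single modulator site with dissociation constant ``k_inact`` on the
inactive state and ``k_act = k_inact / beta`` on the active state.  ``beta``
is therefore the state-selectivity ratio: ``beta > 1`` means the ligand
prefers the active conformation and pulls the equilibrium toward it
(an ago-PAM); ``beta = 1`` is a neutral ligand; ``beta < 1`` an inverse
agonist.

With free ligand concentration ``conc`` (ligand in excess, so free ~= total)
and ``c = conc / k_inact``, mass action over the four species
``R, R*, AR, AR*`` gives the closed-form active fraction

    f(c) = (1 + beta*c) / (1 + alpha + c*(beta + alpha))

which interpolates between the basal fraction ``1/(1+alpha)`` at ``c = 0``
and the saturating fraction ``beta/(alpha+beta)``.  The model-level
"intrinsic agonist activity" of a ligand is the window between those two
plateaus; it vanishes exactly for a neutral ligand and collapses toward zero
when constitutive activity is very low (``alpha`` large), which is the
mechanistic explanation for ago-PAMs losing agonism on
constitutive-activity-suppressing mutants.

The measured readout is an affine map of the active fraction:
``signal_floor + signal_span * f``.  Receptor-number scaling and signal
amplification are deliberately outside the model (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from agopam.exceptions import UsageError

__all__ = [
    "TwoStateParameters",
    "ConcentrationSeries",
    "basal_fraction",
    "active_fraction",
    "max_fraction",
    "agonism_window",
    "half_max_concentration",
    "response_curve",
    "agonism_vs_alpha_profile",
]

# Beyond this many multiples of k_inact the closed form is replaced by its
# saturating limit to avoid needless loss of precision at extreme ratios.
_SATURATION_RATIO = 1e9


@dataclass(frozen=True)
class TwoStateParameters:
    """Complete parameter set of the two-state activation model.

    Parameters
    ----------
    alpha : float
        Inactive:active equilibrium ratio at rest (unitless, >= 0).  The
        basal active fraction is exactly ``1 / (1 + alpha)``.
    k_inact : float
        Dissociation constant of the ligand for the inactive state (molar,
        > 0).
    beta : float
        State-selectivity ratio ``k_inact / k_act`` (unitless, > 0).
        ``beta > 1`` means the ligand binds the active state more tightly.
    signal_floor : float
        Readout value at zero active fraction (assay units).
    signal_span : float
        Readout increment from zero to full active fraction (assay units,
        >= 0).
    """

    alpha: float
    k_inact: float
    beta: float
    signal_floor: float = 0.0
    signal_span: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha}")
        if not np.isfinite(self.k_inact) or self.k_inact <= 0:
            raise ValueError(f"k_inact must be finite and > 0, got {self.k_inact}")
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise ValueError(f"beta must be finite and > 0, got {self.beta}")
        if not np.isfinite(self.signal_span) or self.signal_span < 0:
            raise ValueError(f"signal_span must be finite and >= 0, got {self.signal_span}")

    @property
    def k_act(self) -> float:
        """Dissociation constant for the active state (molar)."""
        return self.k_inact / self.beta

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "TwoStateParameters":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class ConcentrationSeries:
    """Ordered ligand concentrations in molar units."""

    values: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", tuple(arr.tolist()))
        if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr < 0)):
            raise ValueError("concentrations must be finite and >= 0")

    @classmethod
    def log_spaced(cls, low: float, high: float, n: int) -> "ConcentrationSeries":
        """``n`` log-spaced concentrations from ``low`` to ``high`` molar."""
        if low <= 0 or high <= low or n < 2:
            raise ValueError("need 0 < low < high and n >= 2")
        return cls(tuple(np.logspace(np.log10(low), np.log10(high), n)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def require_increasing(self) -> None:
        arr = self.as_array()
        if arr.size >= 2 and not np.all(np.diff(arr) > 0):
            raise ValueError("concentration series must be strictly increasing")


def basal_fraction(params: TwoStateParameters) -> float:
    """Active fraction in the absence of ligand: ``1 / (1 + alpha)``."""
    return 1.0 / (1.0 + params.alpha)


def max_fraction(params: TwoStateParameters) -> float:
    """Saturating active fraction at infinite ligand: ``beta / (alpha + beta)``."""
    return params.beta / (params.alpha + params.beta)


def active_fraction(params: TwoStateParameters, conc):
    """Fraction of receptors in the active conformation at ligand ``conc``.

    Accepts a scalar or array of molar concentrations; returns the same
    shape.  Negative concentrations raise ``ValueError``.
    """
    conc_arr = np.asarray(conc, dtype=float)
    if np.any(conc_arr < 0) or not np.all(np.isfinite(conc_arr)):
        raise ValueError("concentrations must be finite and >= 0")
    c = conc_arr / params.k_inact
    a, b = params.alpha, params.beta
    with np.errstate(over="ignore"):
        f = (1.0 + b * c) / (1.0 + a + c * (b + a))
    f = np.where(c > _SATURATION_RATIO, max_fraction(params), f)
    return float(f) if np.isscalar(conc) else f


def agonism_window(params: TwoStateParameters) -> float:
    """Intrinsic agonist activity: saturating minus basal active fraction.

    Zero exactly for a neutral ligand (``beta = 1``) and tends to zero as
    ``alpha`` grows with ``beta`` fixed — a very-low-constitutive-activity
    receptor cannot be activated by state-selective binding alone.
    """
    return max_fraction(params) - basal_fraction(params)


def half_max_concentration(params: TwoStateParameters) -> float:
    """Concentration at the midpoint of the active-fraction curve (molar).

    Analytically ``(1 + alpha) * k_inact / (beta + alpha)``.
    """
    return (1.0 + params.alpha) * params.k_inact / (params.beta + params.alpha)


def response_curve(params: TwoStateParameters, series: ConcentrationSeries) -> np.ndarray:
    """Readout-space responses along a concentration series.

    Affine transform ``signal_floor + signal_span * active_fraction``.
    """
    series.require_increasing()
    f = active_fraction(params, series.as_array())
    return params.signal_floor + params.signal_span * np.asarray(f)


def agonism_vs_alpha_profile(beta: float, k_inact: float, alphas) -> pd.DataFrame:
    """Model-level agonism profile across constitutive-activity levels.

    One row per ``alpha`` with columns ``alpha``, ``basal_fraction``,
    ``max_fraction`` and ``agonism_window``.  This is the forward computation
    behind the basal-activity-vs-PAM-agonism relationship seen across mutant
    panels: mutants with suppressed constitutive activity (large ``alpha``)
    show both low basal signalling and a small agonism window.
    """
    alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
    if alphas.size == 0:
        raise UsageError("alphas must be non-empty")
    if np.any(alphas < 0) or not np.all(np.isfinite(alphas)):
        raise UsageError("alphas must be finite and >= 0")
    rows = []
    for a in alphas:
        p = TwoStateParameters(alpha=float(a), k_inact=k_inact, beta=beta)
        rows.append(
            {
                "alpha": float(a),
                "basal_fraction": basal_fraction(p),
                "max_fraction": max_fraction(p),
                "agonism_window": agonism_window(p),
            }
        )
    return pd.DataFrame(rows)
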