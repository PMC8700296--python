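"""Concentration-response fitting and summary statistics.

Curves are fitted with the four-parameter logistic (4PL) model in the
log-concentration domain,

    Y = Bottom + (Top - Bottom) / (1 + 10**((LogEC50 - X) * Hill))

with all four parameters free.  ``Top`` doubles as the maximal efficacy
(Emax) of a ligand.  Derived quantities: the concentration producing a given
fraction ``p`` of the fitted span (EC50 at ``p = 0.5``, EC20 at ``p = 0.2``),
percent normalization to a designated reference condition, fold potentiation
between paired fits, and fixed-delay endpoints on kinetic traces.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from agopam.exceptions import DegenerateFitError, NormalizationError, UsageError

__all__ = [
    "REQUIRED_COLUMNS",
    "FourPLFit",
    "KineticTrace",
    "four_pl",
    "fit_4pl",
    "ec_fraction",
    "normalize_to_reference",
    "delta_at_time",
    "potentiation_summary",
    "validate_table",
]

#: Tidy dose-response table schema: one row per replicate measurement.
REQUIRED_COLUMNS = ("construct_id", "ligand_id", "log10_conc", "replicate", "response")


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy dose-response schema and finiteness of responses."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise UsageError(f"dose-response table missing columns: {missing}")
    if not np.all(np.isfinite(table["response"].to_numpy(dtype=float))):
        raise UsageError("responses must be finite")
    return table


def four_pl(x, bottom: float, top: float, log_ec50: float, hill: float):
    """Evaluate the 4PL curve at log10 concentration(s) ``x``."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - x) * hill))


@dataclass(frozen=True)
class FourPLFit:
    """Result of a free 4PL least-squares fit.

    ``top`` is reported as the ligand's Emax.  Standard errors come from the
    Gauss-Newton covariance at the optimum; they are NaN when the Jacobian is
    rank-deficient.  ``converged`` additionally requires ``log_ec50`` to fall
    within the fitted concentration range extended by 2 log units — a fit
    whose midpoint escapes the data is reported but not trusted.
    """

    bottom: float
    top: float
    log_ec50: float
    hill: float
    se_bottom: float
    se_top: float
    se_log_ec50: float
    se_hill: float
    rss: float
    converged: bool
    n_points: int

    @property
    def ec50(self) -> float:
        """EC50 in molar units."""
        return 10.0 ** self.log_ec50

    @property
    def emax(self) -> float:
        """Maximal fitted response; by convention the Top plateau."""
        return self.top

    def predict(self, x):
        return four_pl(x, self.bottom, self.top, self.log_ec50, self.hill)

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _start_grid(x: np.ndarray, y: np.ndarray):
    """Deterministic 3x3 multi-start grid over (log_ec50, hill)."""
    lo, hi = float(x.min()), float(x.max())
    for le in (lo, 0.5 * (lo + hi), hi):
        for h in (-1.0, 1.0, 2.0):
            yield np.array([float(y.min()), float(y.max()), le, h])


def fit_4pl(group, *, x_col: str = "log10_conc", y_col: str = "response") -> FourPLFit:
    """Fit the 4PL equation to one (construct, ligand) group.

    Parameters
    ----------
    group : DataFrame or (x, y) pair
        Either a tidy table slice with ``x_col``/``y_col`` columns or a pair
        of arrays (log10 molar concentration, response).  Replicates are
        fitted pointwise, not averaged.

    Fitting is plain least squares started from a deterministic 3x3 grid
    over (log_ec50, hill) with plateau seeds at the response extremes; the
    best start wins by lowest residual sum of squares, ties broken by lowest
    ``|hill|``.  Rows with non-finite ``x`` (e.g. log10 of a zero dose) are
    excluded.
    """
    if isinstance(group, pd.DataFrame):
        x = group[x_col].to_numpy(dtype=float)
        y = group[y_col].to_numpy(dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in group)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n_conc = np.unique(x).size
    if n_conc < 2:
        raise DegenerateFitError(f"need >= 2 distinct concentrations, got {n_conc}")
    y_scale = max(1.0, float(np.abs(y).max()))
    if float(np.std(y)) < 1e-12 * y_scale:
        raise DegenerateFitError("response variance ~ 0: nothing to fit")

    def residuals(theta):
        return four_pl(x, *theta) - y

    best = None
    for theta0 in _start_grid(x, y):
        try:
            sol = least_squares(residuals, theta0, method="lm", max_nfev=5000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        key = (round(rss, 12), abs(float(sol.x[3])))
        if best is None or key < best[0]:
            best = (key, sol, rss)
    if best is None:
        raise DegenerateFitError("no start of the 4PL grid converged")
    _, sol, rss = best

    dof = max(x.size - 4, 1)
    try:
        jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.clip(np.diag(jtj_inv) * rss / dof, 0, None))
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)

    bottom, top, log_ec50, hill = (float(v) for v in sol.x)
    se = list(se)
    if top < bottom:
        # the 4PL is invariant under (bottom, top, hill) -> (top, bottom,
        # -hill); report the canonical form with Top as the upper plateau
        bottom, top, hill = top, bottom, -hill
        se[0], se[1] = se[1], se[0]
    in_range = (x.min() - 2.0) <= log_ec50 <= (x.max() + 2.0)
    return FourPLFit(
        bottom=bottom,
        top=top,
        log_ec50=log_ec50,
        hill=hill,
        se_bottom=float(se[0]),
        se_top=float(se[1]),
        se_log_ec50=float(se[2]),
        se_hill=float(se[3]),
        rss=rss,
        converged=bool(sol.success and np.all(np.isfinite(sol.x)) and in_range),
        n_points=int(x.size),
    )


def fit_groups(table: pd.DataFrame, by=("construct_id", "ligand_id")) -> dict:
    """Fit each (construct, ligand, ...) group of a tidy table; returns
    ``{group_key: FourPLFit}``."""
    validate_table(table)
    return {key: fit_4pl(sub) for key, sub in table.groupby(list(by), sort=True)}


def ec_fraction(fit: FourPLFit, p: float) -> float:
    """Concentration (molar) where the fitted curve reaches
    ``bottom + p * (top - bottom)``.

    Closed form ``10**(log_ec50 + log10(p / (1 - p)) / hill)``; for
    ``p = 0.2`` and ``hill = 1`` this is EC50/4, and the expression is valid
    for negative Hill slopes as well (the curve then reaches the fraction
    from above).
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie in (0, 1), got {p}")
    if not fit.converged:
        raise DegenerateFitError("refusing to extrapolate from a non-converged fit")
    if fit.hill == 0:
        raise DegenerateFitError("hill = 0: curve is flat, EC fraction undefined")
    return 10.0 ** (fit.log_ec50 + np.log10(p / (1.0 - p)) / fit.hill)


def normalize_to_reference(table: pd.DataFrame, reference: dict) -> pd.DataFrame:
    """Express responses as percent of a reference condition.

    ``reference`` maps column names to values selecting the reference rows
    (e.g. ``{"ligand_id": "GABA", "log10_conc": -3.0}`` for a 1 mM GABA
    anchor).  Every response is divided by the mean reference response and
    multiplied by 100, so the reference maps to 100 on average.
    """
    validate_table(table)
    mask = np.ones(len(table), dtype=bool)
    for col, val in reference.items():
        if col not in table.columns:
            raise UsageError(f"reference column {col!r} not in table")
        if isinstance(val, float):
            mask &= np.isclose(table[col].to_numpy(dtype=float), val)
        else:
            mask &= (table[col] == val).to_numpy()
    if not mask.any():
        raise NormalizationError(f"no rows match reference {reference!r}")
    ref_mean = float(table.loc[mask, "response"].mean())
    if abs(ref_mean) < 1e-12:
        raise NormalizationError("reference mean ~ 0: cannot normalize")
    out = table.copy()
    out["response"] = out["response"] * (100.0 / ref_mean)
    return out


@dataclass(frozen=True)
class KineticTrace:
    """A single time-resolved readout (e.g. a BRET ratio trace).

    ``stimulus_time`` marks drug application; samples strictly before it
    form the baseline window.
    """

    time: tuple
    signal: tuple
    stimulus_time: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", tuple(t.tolist()))
        object.__setattr__(self, "signal", tuple(s.tolist()))
        if t.size != s.size or t.size < 2:
            raise ValueError("time and signal must be equal-length, size >= 2")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (t[0] <= self.stimulus_time <= t[-1]):
            raise ValueError("stimulus_time must lie within the trace")

    def arrays(self):
        return np.asarray(self.time), np.asarray(self.signal)


def delta_at_time(trace: KineticTrace, delay: float) -> float:
    """Signal change a fixed ``delay`` after stimulus, relative to baseline.

    The baseline is the mean of all samples strictly before
    ``stimulus_time``; the post-stimulus value is linearly interpolated.
    This is the convention behind endpoint readouts such as a BRET change
    measured 150 s after drug application.
    """
    t, s = trace.arrays()
    t_eval = trace.stimulus_time + delay
    if not (t[0] <= t_eval <= t[-1]):
        raise ValueError(f"stimulus_time + delay = {t_eval} outside trace range")
    pre = s[t < trace.stimulus_time]
    if pre.size == 0:
        raise ValueError("no samples before stimulus_time: baseline undefined")
    return float(np.interp(t_eval, t, s) - pre.mean())


def potentiation_summary(fit_without: FourPLFit, fit_with: FourPLFit):
    """Potency shift and efficacy change caused by a modulator.

    Returns ``(ec50_fold_shift, emax_ratio)`` where the fold shift is
    ``EC50(without) / EC50(with)`` (> 1 means a left shift, i.e.
    potentiation) and the Emax ratio is ``Top(with) / Top(without)``.
    """
    for name, fit in (("without", fit_without), ("with", fit_with)):
        if not fit.converged:
            raise DegenerateFitError(f"fit '{name}' did not converge")
    fold = 10.0 ** (fit_without.log_ec50 - fit_with.log_ec50)
    return float(fold), float(fit_with.top / fit_without.top)
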