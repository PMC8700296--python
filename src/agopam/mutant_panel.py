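"""Panel-level analysis across receptor constructs.

Each construct (wild type or mutant heterodimer) contributes replicate-level
endpoints: basal signalling (constitutive activity), PAM-evoked intrinsic
agonist responses, surface expression, and orthosteric-agonist efficacy.
This module normalizes endpoints to the wild-type mean (= 100), correlates
basal activity with PAM agonism across the panel, and runs the study-style
many-to-one comparison: one-way ANOVA followed by Dunnett's test against the
wild-type group, with significance tiers 0.05 / 0.005 / 0.0005 / 0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from agopam.exceptions import NormalizationError, UsageError

__all__ = [
    "ConstructRecord",
    "PanelSummary",
    "CorrelationResult",
    "SIGNIFICANCE_TIERS",
    "summarize_construct",
    "summarize_panel",
    "correlate_basal_vs_agonism",
    "compare_to_wildtype",
    "classify_pam_profile",
    "flag_low_expression",
]

#: Adjusted-p thresholds and their star labels, strictest first.
SIGNIFICANCE_TIERS = (
    (0.0001, "****"),
    (0.0005, "***"),
    (0.005, "**"),
    (0.05, "*"),
)

#: Constructs expressed below this percent of wild type are flagged (not
#: dropped) in panel summaries.
DEFAULT_EXPRESSION_FLOOR = 20.0


def significance_tier(p: float) -> str:
    for threshold, stars in SIGNIFICANCE_TIERS:
        if p < threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class ConstructRecord:
    """Replicate-level endpoints for one receptor construct."""

    construct_id: str
    subunit_mutations: tuple = ()
    surface_expression: float = 100.0  # percent of WT
    basal_signal: tuple = ()  # assay units, one entry per replicate
    pam_agonist_response: dict = field(default_factory=dict)  # pam_id -> replicates
    gaba_emax: float = np.nan  # percent of WT

    def __post_init__(self) -> None:
        if len(self.basal_signal) == 0:
            raise ValueError("basal_signal needs at least one replicate")
        if self.surface_expression < 0:
            raise ValueError("surface_expression must be >= 0")
        for pam, reps in self.pam_agonist_response.items():
            if len(reps) == 0:
                raise ValueError(f"no replicates for PAM {pam!r}")


def _mean_sem(values) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return float(v.mean()), sem


def summarize_construct(record: ConstructRecord, wt: ConstructRecord, pam_id=None) -> dict:
    """Normalized summary row for one construct: WT mean maps to 100.

    Basal activity and (if ``pam_id`` is given or the record holds exactly
    one PAM) the PAM agonist response are scaled by ``100 / WT mean`` of the
    matching endpoint; SEMs scale identically.
    """
    wt_basal_mean, _ = _mean_sem(wt.basal_signal)
    if abs(wt_basal_mean) < 1e-12:
        raise NormalizationError("wild-type basal mean ~ 0: cannot normalize")
    m, s = _mean_sem(record.basal_signal)
    row = {
        "construct_id": record.construct_id,
        "surface_expression": record.surface_expression,
        "basal_norm": 100.0 * m / wt_basal_mean,
        "basal_sem": 100.0 * s / wt_basal_mean,
    }
    if pam_id is None and len(record.pam_agonist_response) == 1:
        pam_id = next(iter(record.pam_agonist_response))
    if pam_id is not None:
        if pam_id not in record.pam_agonist_response or pam_id not in wt.pam_agonist_response:
            raise UsageError(f"PAM {pam_id!r} missing from record or wild type")
        wt_pam_mean, _ = _mean_sem(wt.pam_agonist_response[pam_id])
        if abs(wt_pam_mean) < 1e-12:
            raise NormalizationError(f"wild-type mean for PAM {pam_id!r} ~ 0")
        m, s = _mean_sem(record.pam_agonist_response[pam_id])
        row["agonism_norm"] = 100.0 * m / wt_pam_mean
        row["agonism_sem"] = 100.0 * s / wt_pam_mean
    return row


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class PanelSummary:
    """Normalized per-construct table plus the basal-vs-agonism correlation."""

    table: pd.DataFrame
    correlation: CorrelationResult
    low_expression: tuple


def summarize_panel(
    records,
    wt_id: str = "WT",
    pam_id=None,
    expression_floor: float = DEFAULT_EXPRESSION_FLOOR,
) -> PanelSummary:
    """Normalize a whole panel against its wild-type construct."""
    by_id = {r.construct_id: r for r in records}
    if wt_id not in by_id:
        raise UsageError(f"wild-type construct {wt_id!r} not in panel")
    wt = by_id[wt_id]
    rows = [summarize_construct(r, wt, pam_id=pam_id) for r in records]
    table = pd.DataFrame(rows)
    corr = correlate_basal_vs_agonism(table)
    low = tuple(flag_low_expression(records, floor=expression_floor))
    return PanelSummary(table=table, correlation=corr, low_expression=low)


def correlate_basal_vs_agonism(panel) -> CorrelationResult:
    """Pearson correlation between normalized basal activity and PAM agonism.

    ``panel`` is either a DataFrame with ``basal_norm`` / ``agonism_norm``
    columns or a pair of arrays.  The 95% CI uses the Fisher z-transform.
    A panel where either axis has zero variance has no defined correlation.
    """
    if isinstance(panel, pd.DataFrame):
        x = panel["basal_norm"].to_numpy(dtype=float)
        y = panel["agonism_norm"].to_numpy(dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in panel)
    if x.size < 3:
        raise UsageError(f"need >= 3 constructs for a correlation, got {x.size}")
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        raise UsageError("zero variance on an axis: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    n = int(x.size)
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    else:  # degenerate CI at |r| = 1 or n = 3
        lo = hi = r
    return CorrelationResult(r=r, ci_low=float(lo), ci_high=float(hi), n=n)


def compare_to_wildtype(
    groups: dict,
    wt_id: str = "WT",
    endpoint: str = "basal",
    alternative: str = "two-sided",
    random_state: int = 0,
) -> pd.DataFrame:
    """Many-to-one comparison of every construct against wild type.

    ``groups`` maps construct ids to replicate arrays.  A one-way ANOVA is
    computed across all groups, then Dunnett's test compares each mutant to
    the wild-type reference; adjusted p-values are mapped onto the star
    tiers.  Returns one row per non-reference construct with columns
    ``construct_id, endpoint, estimate, adj_p, tier`` plus the ANOVA F/p as
    DataFrame attrs.
    """
    if wt_id not in groups:
        raise UsageError(f"reference group {wt_id!r} missing")
    others = [k for k in groups if k != wt_id]
    if not others:
        raise UsageError("need at least one non-reference group")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise UsageError(f"group {k!r} needs >= 2 replicates")
    f_stat, f_p = stats.f_oneway(*arrays.values())
    res = stats.dunnett(
        *(arrays[k] for k in others),
        control=arrays[wt_id],
        alternative=alternative,
        rng=np.random.default_rng(random_state),
    )
    wt_mean = arrays[wt_id].mean()
    out = pd.DataFrame(
        {
            "construct_id": others,
            "endpoint": endpoint,
            "estimate": [arrays[k].mean() - wt_mean for k in others],
            "adj_p": res.pvalue,
            "tier": [significance_tier(p) for p in res.pvalue],
        }
    )
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(f_p)
    return out


def classify_pam_profile(assays: dict, alpha: float = 0.05, random_state: int = 0) -> str:
    """Classify a modulator's intrinsic-agonism profile across assays.

    ``assays`` maps an assay name to a dict with keys ``response`` (replicate
    responses to the PAM alone), ``vehicle`` (replicate baseline responses)
    and ``equilibrium`` (bool: an accumulating readout such as IP1, as
    opposed to a transient one such as a calcium peak).

    Returns ``"ago-PAM"`` if the PAM response significantly exceeds vehicle
    in every supplied assay, ``"pure-PAM-like"`` if it does so only in the
    equilibrium assays (weak intrinsic efficacy that accumulating readouts
    amplify), and ``"inactive"`` otherwise.  "Significantly exceeds" is a
    one-sided Dunnett-adjusted p < ``alpha`` against vehicle.
    """
    if not assays:
        raise UsageError("need at least one assay")
    hits = {}
    for name, data in assays.items():
        resp = np.asarray(data["response"], dtype=float)
        veh = np.asarray(data["vehicle"], dtype=float)
        res = stats.dunnett(
            resp, control=veh, alternative="greater", rng=np.random.default_rng(random_state)
        )
        hits[name] = float(res.pvalue[0]) < alpha
    equilibrium = {name for name, data in assays.items() if data.get("equilibrium", False)}
    if all(hits.values()):
        return "ago-PAM"
    if equilibrium and all(hits[n] for n in equilibrium) and not any(
        hits[n] for n in hits if n not in equilibrium
    ):
        return "pure-PAM-like"
    return "inactive"


def flag_low_expression(records, floor: float = DEFAULT_EXPRESSION_FLOOR):
    """Constructs whose surface expression falls below ``floor`` percent of WT."""
    return [r.construct_id for r in records if r.surface_expression < floor]
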