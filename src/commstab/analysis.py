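"""Site aggregation, diversity regressions, and slope-additivity checks.

Every decomposition quantity is log10-transformed before aggregation and
regression, so the multiplicative identities S_com = Phi * S_pop and
Phi = SAE * CPE become additive:

    log10(S_com) = log10(Phi) + log10(S_pop)
    log10(Phi)   = log10(SAE) + log10(CPE)

Because ordinary least squares is linear in the response, the fitted slopes
(and intercepts) inherit the same additivity exactly, which
:func:`check_slope_additivity` verifies.

Two analysis modes mirror the two kinds of study design: ``site`` mode
averages plot-level log10 quantities within each site and regresses site
means (observational surveys with replicate plots), and ``plot`` mode
regresses individual plots (experiments that manipulate richness at the
plot level, excluding single-species plots by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .community import CommunityMatrix
from .decomposition import decompose, COMPONENT_FIELDS
from .diversity import diversity_indices
from .exceptions import InputError
from .surrogate import SecondaryComponents

logger = logging.getLogger(__name__)

#: components regressed against diversity (log10 scale)
DEFAULT_RESPONSES = ("s_com", "s_pop", "phi", "sae", "cpe")

#: valid diversity predictors; Shannon enters untransformed (it already
#: embeds a log), richness and inverse Simpson are log10-transformed
PREDICTORS = {
    "richness": "log10_richness",
    "shannon": "shannon",
    "invsimpson": "log10_inv_simpson",
}


@dataclass
class ComponentRecord:
    """Log10 components plus diversity predictors for one plot or one site."""

    unit_id: str
    site_id: str | None
    n_plots: int
    log10_richness: float
    shannon: float
    log10_inv_simpson: float
    log10: dict[str, float]
    se: dict[str, float] | None = None
    raw: dict[str, float] = field(default_factory=dict)


def plot_record(X: CommunityMatrix, secondary: SecondaryComponents | None = None,
                ddof: int = 1) -> ComponentRecord:
    """Decompose one plot and package it for aggregation/regression."""
    comp = decompose(X, ddof=ddof)
    div = diversity_indices(X)
    raw = comp.as_dict()
    log10 = {k: float(np.log10(raw[k])) for k in COMPONENT_FIELDS}
    if secondary is not None:
        for k in ("cpe_env", "cpe_int"):
            raw[k] = getattr(secondary, k)
            log10[k] = float(np.log10(raw[k]))
    return ComponentRecord(
        unit_id=X.plot_id, site_id=X.site_id, n_plots=1,
        log10_richness=float(np.log10(div.richness)),
        shannon=div.shannon,
        log10_inv_simpson=float(np.log10(div.inv_simpson)),
        log10=log10, raw=raw,
    )


def plot_records(plots: Iterable[CommunityMatrix], min_richness: int = 2,
                 ddof: int = 1) -> list[ComponentRecord]:
    """Per-plot records, excluding plots below the richness threshold."""
    records = []
    for X in plots:
        if X.n_species < min_richness:
            logger.info("excluding plot %s: richness %d < %d",
                        X.plot_id, X.n_species, min_richness)
            continue
        records.append(plot_record(X, ddof=ddof))
    return records


def site_summaries(records: Sequence[ComponentRecord]) -> list[ComponentRecord]:
    """Average plot records within sites; SE of each log10 quantity across plots."""
    if not records:
        raise InputError("no plot records to summarise")
    out = []
    by_site: dict[str, list[ComponentRecord]] = {}
    for r in records:
        by_site.setdefault(r.site_id, []).append(r)
    for site_id, rs in by_site.items():
        n = len(rs)
        keys = rs[0].log10.keys()
        mean = {k: float(np.mean([r.log10[k] for r in rs])) for k in keys}
        if n > 1:
            se = {k: float(np.std([r.log10[k] for r in rs], ddof=1) / np.sqrt(n))
                  for k in keys}
        else:
            se = None
            logger.warning("site %s has a single plot; no standard error", site_id)
        out.append(ComponentRecord(
            unit_id=site_id, site_id=site_id, n_plots=n,
            log10_richness=float(np.mean([r.log10_richness for r in rs])),
            shannon=float(np.mean([r.shannon for r in rs])),
            log10_inv_simpson=float(np.mean([r.log10_inv_simpson for r in rs])),
            log10=mean, se=se,
        ))
    return out


def records_frame(records: Sequence[ComponentRecord]) -> pd.DataFrame:
    """Tidy table of records (one row per unit)."""
    rows = []
    for r in records:
        row = {
            "unit": r.unit_id, "site": r.site_id, "n_plots": r.n_plots,
            "log10_richness": r.log10_richness, "shannon": r.shannon,
            "log10_inv_simpson": r.log10_inv_simpson,
        }
        for k, v in r.raw.items():
            row[k] = v
        for k, v in r.log10.items():
            row["log10_" + k] = v
        if r.se:
            for k, v in r.se.items():
                row["se_log10_" + k] = v
        rows.append(row)
    return pd.DataFrame(rows)


def fit_component_regressions(
    records: Sequence[ComponentRecord],
    diversity_index: str = "richness",
    responses: Sequence[str] = DEFAULT_RESPONSES,
) -> pd.DataFrame:
    """OLS of each log10 component on a diversity predictor.

    Returns a table indexed by response with columns slope, intercept,
    p_value (two-sided t-test on the slope) and n.  Units (sites or plots)
    enter unweighted.
    """
    if diversity_index not in PREDICTORS:
        raise InputError(
            f"unknown diversity index {diversity_index!r}; "
            f"choose from {sorted(PREDICTORS)}")
    if len(records) < 3:
        raise InputError("need at least 3 units for regression")
    x = np.array([getattr(r, PREDICTORS[diversity_index]) for r in records])
    if np.ptp(x) == 0:
        raise InputError("degenerate predictor: no variation in diversity")
    design = sm.add_constant(x)
    rows = {}
    for resp in responses:
        y = np.array([r.log10[resp] for r in records])
        fit = sm.OLS(y, design).fit()
        rows[resp] = {
            "slope": float(fit.params[1]),
            "intercept": float(fit.params[0]),
            "p_value": float(fit.pvalues[1]),
            "n": int(len(records)),
        }
    table = pd.DataFrame(rows).T
    table["n"] = table["n"].astype(int)
    table.index.name = "response"
    table.attrs["diversity_index"] = diversity_index
    return table


def check_slope_additivity(table: pd.DataFrame, tol: float = 1e-8) -> dict:
    """Verify slope(log Phi) = slope(log SAE) + slope(log CPE) and
    slope(log S_com) = slope(log Phi) + slope(log S_pop)."""
    s = table["slope"]
    res_phi = float(s["phi"] - s["sae"] - s["cpe"])
    res_com = float(s["s_com"] - s["phi"] - s["s_pop"])
    return {
        "residual_phi": res_phi,
        "residual_s_com": res_com,
        "tol": tol,
        "passed": abs(res_phi) < tol and abs(res_com) < tol,
    }


def significance_stars(p: float) -> str:
    """Conventional star coding for report formatting."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
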