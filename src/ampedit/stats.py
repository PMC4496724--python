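"""Treatment-group tabulations and statistics.

Integer rate percentages (half away from zero), two-sided Fisher's exact test
by hypergeometric enumeration, and a binomial logit-link GLM on per-embryo
(edited, not-edited) read counts with nucleic-acid and enzyme main effects
plus their interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import hypergeom


@dataclass(frozen=True)
class GroupCounts:
    """Per-treatment-group tallies (Table-1 style)."""

    nucleic_acid: str  # DNA | RNA
    enzyme: str  # ZFN | TALEN
    time: str  # 8h | 18h
    odn: str = ""
    n_injected: int = 0
    n_blastocysts: int = 0
    n_analyzed: int = 0
    n_edited: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_edited <= self.n_analyzed):
            raise ValueError("need 0 <= n_edited <= n_analyzed")
        if self.n_blastocysts > self.n_injected:
            warnings.warn("more blastocysts than injected zygotes", stacklevel=2)
        if self.n_analyzed > self.n_blastocysts:
            # morulae may be analyzed in addition to blastocysts
            warnings.warn("more embryos analyzed than developed blastocysts", stacklevel=2)


@dataclass(frozen=True)
class EmbryoReadCounts:
    embryo_id: str
    reads_edited: int
    reads_not_edited: int
    nucleic_acid: str
    enzyme: str
    time: str = "18h"

    def __post_init__(self) -> None:
        if self.reads_edited < 0 or self.reads_not_edited < 0:
            raise ValueError("read counts must be >= 0")
        if self.reads_edited + self.reads_not_edited == 0:
            raise ValueError("embryo has zero reads")


def rate_percent(k: int, n: int) -> int:
    """100*k/n rounded half away from zero to an integer percent."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    return (200 * k + n) // (2 * n)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the table [[a, b], [c, d]].

    Sums the probabilities of all tables (with the observed margins) whose
    hypergeometric probability does not exceed the observed table's.
    Degenerate margins give p = 1 by convention (with a warning).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        warnings.warn("degenerate margin in 2x2 table; p = 1 by convention", stacklevel=2)
        return 1.0
    dist = hypergeom(n, row1, col1)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    ks = np.arange(lo, hi + 1)
    pmf = dist.pmf(ks)
    p_obs = dist.pmf(a)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class GlmFit:
    params: Dict[str, float]
    bse: Dict[str, float]
    pvalues: Dict[str, float]
    deviance: float
    converged: bool
    reference_levels: Dict[str, str]
    n_obs: int


def fit_binomial_logit(
    data: Sequence[EmbryoReadCounts],
    reference_nucleic_acid: str = "DNA",
    reference_enzyme: str = "TALEN",
    drop_time: Optional[str] = "8h",
) -> GlmFit:
    """Binomial logit GLM of (edited, not edited) on nucleic acid x enzyme.

    Treatment coding with the given reference levels; records at ``drop_time``
    are excluded before fitting. Terms whose factor has a single level are
    dropped, so a one-group fit reduces to the intercept (log odds).
    """
    rows = [r for r in data if drop_time is None or r.time != drop_time]
    if not rows:
        raise ValueError("no records left to fit")
    df = pd.DataFrame(
        {
            "edited": [r.reads_edited for r in rows],
            "not_edited": [r.reads_not_edited for r in rows],
            "nucleic_acid": [r.nucleic_acid for r in rows],
            "enzyme": [r.enzyme for r in rows],
        }
    )
    exog = pd.DataFrame({"Intercept": np.ones(len(df))})
    na_levels = [l for l in sorted(df["nucleic_acid"].unique()) if l != reference_nucleic_acid]
    enz_levels = [l for l in sorted(df["enzyme"].unique()) if l != reference_enzyme]
    if df["nucleic_acid"].nunique() > 1:
        for lvl in na_levels:
            exog[f"nucleic_acid[{lvl}]"] = (df["nucleic_acid"] == lvl).astype(float)
    if df["enzyme"].nunique() > 1:
        for lvl in enz_levels:
            exog[f"enzyme[{lvl}]"] = (df["enzyme"] == lvl).astype(float)
    if df["nucleic_acid"].nunique() > 1 and df["enzyme"].nunique() > 1:
        for na in na_levels:
            for enz in enz_levels:
                exog[f"nucleic_acid[{na}]:enzyme[{enz}]"] = (
                    exog[f"nucleic_acid[{na}]"] * exog[f"enzyme[{enz}]"]
                )
    endog = df[["edited", "not_edited"]].to_numpy(dtype=float)
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    with warnings.catch_warnings():
        # saturated fits (df_resid == 0) trigger a harmless scale division warning
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit(maxiter=100, tol=1e-8)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        raise RuntimeError("binomial GLM did not converge (possible separation)")
    if np.max(np.abs(res.params.to_numpy())) > 20:
        warnings.warn("extreme coefficient magnitude suggests separation", stacklevel=2)
    return GlmFit(
        params=dict(res.params),
        bse=dict(res.bse),
        pvalues=dict(res.pvalues),
        deviance=float(res.deviance),
        converged=converged,
        reference_levels={"nucleic_acid": reference_nucleic_acid, "enzyme": reference_enzyme},
        n_obs=len(rows),
    )


def group_rate_table(groups: Sequence[GroupCounts]) -> pd.DataFrame:
    """Tidy table of development and editing rates per treatment group."""
    records = []
    for g in groups:
        records.append(
            {
                "nucleic_acid": g.nucleic_acid,
                "enzyme": g.enzyme,
                "time": g.time,
                "odn": g.odn,
                "n_injected": g.n_injected,
                "n_blastocysts": g.n_blastocysts,
                "pct_developed": rate_percent(g.n_blastocysts, g.n_injected)
                if g.n_injected
                else None,
                "n_analyzed": g.n_analyzed,
                "n_edited": g.n_edited,
                "pct_edited": rate_percent(g.n_edited, g.n_analyzed) if g.n_analyzed else None,
            }
        )
    return pd.DataFrame.from_records(records)
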