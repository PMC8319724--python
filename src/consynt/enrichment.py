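"""Observed-vs-expected chi-square enrichment of a gene-set category fraction
against a fixed genome background.

The background proportion K/N (e.g. the genome-wide ortholog rate) is treated
as a fixed expectation, and the risk set's k-of-n split is tested with a
Pearson goodness-of-fit over the two cells (with / without the category),
df = 1.  No continuity correction is applied by default and p-values are
two-sided; the direction (enriched/depleted) is reported separately from the
sign of k - expected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    risk_k: int
    risk_n: int
    background_K: int
    background_N: int
    expected_k: float
    chi2: float
    df: int
    p_value: float
    significant_at: float
    direction: str  # enriched | depleted | none


def chi_square_gof(
    risk_k: int,
    risk_n: int,
    background_K: int,
    background_N: int,
    category: str = "",
    alpha: float = 0.01,
    continuity_correction: bool = False,
) -> EnrichmentResult:
    """Two-cell Pearson goodness-of-fit of k/n against the background K/N.

    Expected counts are ``n*K/N`` and ``n*(1-K/N)``.  An expected cell below 1
    is refused (the chi-square approximation is meaningless there); below 5 a
    warning is emitted.
    """
    if risk_n <= 0 or background_N <= 0:
        raise ValueError("risk_n and background_N must be positive")
    if not (0 <= risk_k <= risk_n):
        raise ValueError(f"risk_k {risk_k} outside [0, {risk_n}]")
    if not (0 < background_K < background_N):
        raise ValueError("background_K must satisfy 0 < K < N")

    p0 = background_K / background_N
    expected = [risk_n * p0, risk_n * (1.0 - p0)]
    observed = [risk_k, risk_n - risk_k]
    if min(expected) < 1.0:
        raise ValueError(
            f"expected cell count {min(expected):.3g} < 1; "
            "chi-square approximation invalid for these counts"
        )
    if min(expected) < 5.0:
        warnings.warn(
            f"expected cell count {min(expected):.3g} < 5; "
            "chi-square approximation may be poor",
            stacklevel=2,
        )
    if continuity_correction:
        chi2 = sum(
            (abs(o - e) - 0.5) ** 2 / e for o, e in zip(observed, expected)
        )
        p_value = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p_value = stats.chisquare(observed, f_exp=expected)
        chi2, p_value = float(chi2), float(p_value)

    delta = risk_k - expected[0]
    if abs(delta) < 1e-12:
        direction = "none"
    else:
        direction = "enriched" if delta > 0 else "depleted"
    return EnrichmentResult(
        category=category,
        risk_k=risk_k,
        risk_n=risk_n,
        background_K=background_K,
        background_N=background_N,
        expected_k=expected[0],
        chi2=chi2,
        df=1,
        p_value=p_value,
        significant_at=alpha,
        direction=direction,
    )


REPORT_COLUMNS = [
    "category",
    "risk_k",
    "risk_n",
    "background_K",
    "background_N",
    "expected_k",
    "chi2",
    "df",
    "p_value",
    "significant_at",
    "significant",
    "direction",
]


def enrichment_report(
    results: list[EnrichmentResult], path: str | Path | None = None
) -> pd.DataFrame:
    """One row per category, stable column order; duplicate labels suffixed."""
    if not results:
        raise ValueError("enrichment_report needs at least one result")
    labels: list[str] = []
    seen: dict[str, int] = {}
    for r in results:
        if r.category in seen:
            seen[r.category] += 1
            labels.append(f"{r.category}_{seen[r.category]}")
            logger.warning("duplicate category label %r suffixed", r.category)
        else:
            seen[r.category] = 0
            labels.append(r.category)
    frame = pd.DataFrame(
        {
            "category": labels,
            "risk_k": [r.risk_k for r in results],
            "risk_n": [r.risk_n for r in results],
            "background_K": [r.background_K for r in results],
            "background_N": [r.background_N for r in results],
            "expected_k": [r.expected_k for r in results],
            "chi2": [r.chi2 for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "significant_at": [r.significant_at for r in results],
            "significant": [r.p_value < r.significant_at for r in results],
            "direction": [r.direction for r in results],
        },
        columns=REPORT_COLUMNS,
    )
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
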