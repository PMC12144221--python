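"""Nonparametric group comparisons with Bonferroni correction.

Label measures (and reader quality ratings) are compared between lesions
or between reconstruction methods with the two-sided Mann-Whitney U test.
The unit of analysis is the per-cell mean across repeated acquisitions
(one value per dose), so repeats never enter a test as independent
observations. Families of pairwise comparisons are Bonferroni-adjusted:
adjusted p = min(1, m * p) with m the family size.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

ALPHA = 0.05

MODES = ("auto", "exact", "asymptotic")

#: largest pooled sample size for which "auto" picks the exact test
EXACT_LIMIT = 20


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise comparison within a Bonferroni family."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_raw: float
    p_adjusted: float
    m: int
    significant: bool
    measure: str | None = None
    family: str | None = None


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    ``exact`` enumerates the permutation distribution and is the default
    (via ``auto``) when n_x + n_y <= 20 and the pooled sample has no
    ties. With ties, exact enumeration is not valid; the test falls back
    to the normal approximation with mid-ranks, tie-corrected variance
    and continuity correction (a warning notes the fallback when exact
    was requested explicitly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")

    ties = _has_ties(np.concatenate([x, y]))
    if mode == "exact" and ties:
        warnings.warn(
            "ties present: exact Mann-Whitney enumeration is not valid, "
            "falling back to the tie-corrected normal approximation",
            stacklevel=2,
        )
        method = "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "asymptotic":
        method = "asymptotic"
    else:  # auto
        method = "exact" if (x.size + y.size <= EXACT_LIMIT and not ties) else "asymptotic"

    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) for each p.

    ``m`` defaults to the number of p-values and may be larger (a family
    can include comparisons reported elsewhere), never smaller.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValidationError("m must be >= number of p-values")
    return np.minimum(1.0, m * p)


def cell_means(detections: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Per-cell (dose-level) means of a measure, the unit of analysis.

    Averages ``value_col`` across matched repeats within each lesion x
    reconstruction x dose cell; cells with no contributing repeat are
    dropped (absent, not zero).
    """
    df = detections
    if "matched" in df.columns:
        df = df[df["matched"]]
    keys = ["lesion_id", "reconstruction", "dose_mGy"]
    out = df.groupby(keys, as_index=False)[value_col].mean()
    return out.dropna(subset=[value_col])


def compare_family(
    table: pd.DataFrame,
    value_col: str,
    group_col: str,
    within_col: str | None = None,
    mode: str = "auto",
    alpha: float = ALPHA,
    family_label: str | None = None,
) -> list[ComparisonResult]:
    """All pairwise Mann-Whitney comparisons of ``group_col`` levels.

    When ``within_col`` is given, each of its levels forms a separate
    Bonferroni family (e.g. lesion-pairwise within each reconstruction).
    ``table`` must already be at the unit of analysis (see
    :func:`cell_means`). Groups with no observations raise.
    """
    results: list[ComparisonResult] = []
    strata = (
        [(lvl, sub) for lvl, sub in table.groupby(within_col)]
        if within_col
        else [(None, table)]
    )
    for level, sub in strata:
        groups = sorted(sub[group_col].unique())
        pairs = list(itertools.combinations(groups, 2))
        m = len(pairs)
        fam = family_label or ""
        fam_name = f"{fam}[{within_col}={level}]" if level is not None else fam
        raw = []
        for a, b in pairs:
            xa = sub.loc[sub[group_col] == a, value_col].to_numpy()
            xb = sub.loc[sub[group_col] == b, value_col].to_numpy()
            if xa.size == 0 or xb.size == 0:
                raise ValidationError(
                    f"empty group in family {fam_name!r}: {a!r} vs {b!r}"
                )
            u, p = mann_whitney_u(xa, xb, mode=mode)
            raw.append((a, b, xa.size, xb.size, u, p))
        adj = bonferroni([r[5] for r in raw], m=m) if raw else []
        for (a, b, na, nb, u, p), pa in zip(raw, adj):
            results.append(
                ComparisonResult(
                    group_a=str(a), group_b=str(b), n_a=na, n_b=nb,
                    u_statistic=u, p_raw=p, p_adjusted=float(pa), m=m,
                    significant=bool(pa < alpha),
                    measure=value_col, family=fam_name,
                )
            )
    return results


def comparisons_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tidy CSV-ready view of a list of comparison results."""
    return pd.DataFrame([r.__dict__ for r in results])
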