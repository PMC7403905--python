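"""Selection probabilities and z-score profiles of prescribed acupoints.

The analysis restricts attention to the K most frequently prescribed
acupoints overall (K = 30 by default). Within each case, an acupoint's
selection probability P is its count divided by the case's total count over
that top-K set, so each case's K probabilities sum to one and their mean is
exactly the chance level 1/K. Z-scores then standardise each case's
probability profile (sample standard deviation, denominator K-1); an
acupoint with Z above 1.96 is flagged as prescribed for that case far more
often than the case's average acupoint.

The standardisation axis is configurable: ``axis="case"`` (the default)
standardises each case's profile across the K acupoints; ``axis="acupoint"``
standardises each acupoint's profile across the cases, which asks the
complementary question — is this point used unusually often *in this case*
relative to how it is used elsewhere.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateCaseError, ParameterError

__all__ = [
    "select_top_k",
    "compute_probabilities",
    "compute_zscores",
    "zscore_flags",
    "chance_level",
    "significant_acupoints",
]

Z_THRESHOLD_DEFAULT = 1.96


def select_top_k(counts: pd.DataFrame, k: int = 30) -> list[str]:
    """The k acupoints with the largest total count over all cases.

    Ordered by descending total; ties broken lexicographically by code. If
    fewer than k distinct acupoints exist, all are returned (with a warning).
    """
    if k <= 0:
        raise ParameterError(f"k must be a positive integer, got {k}")
    totals = counts.sum(axis=0)
    if len(totals) < k:
        import warnings

        warnings.warn(
            f"only {len(totals)} distinct acupoints available; returning all "
            f"(requested top {k})",
            stacklevel=2,
        )
        k = len(totals)
    order = sorted(totals.items(), key=lambda item: (-item[1], item[0]))
    return [code for code, _ in order[:k]]


def compute_probabilities(counts: pd.DataFrame,
                          top: Sequence[str]) -> pd.DataFrame:
    """Per-case selection probabilities over the top-K acupoint set.

    ``P[c, a] = counts[c, a] / sum_{b in top} counts[c, b]``; acupoints
    outside ``top`` enter neither numerator nor denominator. Each row sums
    to 1.

    Raises
    ------
    DegenerateCaseError
        If some case has zero total count over the top-K set.
    """
    top = list(top)
    missing = [a for a in top if a not in counts.columns]
    if missing:
        raise ParameterError(f"top-K acupoints absent from count matrix: {missing}")
    sub = counts[top].astype(float)
    denom = sub.sum(axis=1)
    zero = denom[denom <= 0]
    if len(zero):
        raise DegenerateCaseError(
            str(zero.index[0]), "zero total count over the top-K acupoint set"
        )
    return sub.div(denom, axis=0)


def chance_level(k: int) -> float:
    """Per-case mean selection probability under the top-K sum-to-one constraint."""
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    return 1.0 / k


def compute_zscores(P: pd.DataFrame, *, axis: str = "case",
                    ddof: int = 1) -> pd.DataFrame:
    """Standardise selection probabilities into z-scores.

    With ``axis="case"`` each case (row) is standardised across its K
    acupoints: ``Z[c, a] = (P[c, a] - mean_c) / sd_c`` using the sample
    standard deviation (denominator K - ddof). With ``axis="acupoint"`` each
    acupoint (column) is standardised across cases instead.

    Raises
    ------
    ParameterError
        If fewer than 2 values are available along the standardisation axis.
    DegenerateCaseError
        If a case (or acupoint) has zero standard deviation — all its
        probabilities equal, so no point stands out.
    """
    if axis not in ("case", "acupoint"):
        raise ParameterError(f"axis must be 'case' or 'acupoint', got {axis!r}")
    values = P.to_numpy(dtype=float)
    ax = 1 if axis == "case" else 0
    if values.shape[ax] < 2:
        raise ParameterError(
            f"need at least 2 values along the {axis} axis to standardise"
        )
    mean = values.mean(axis=ax, keepdims=True)
    sd = values.std(axis=ax, ddof=ddof, keepdims=True)
    flat = np.nonzero(sd.ravel() == 0)[0]
    if flat.size:
        name = (P.index[flat[0]] if axis == "case" else P.columns[flat[0]])
        raise DegenerateCaseError(
            str(name), "zero standard deviation (all selection probabilities equal)"
        )
    return pd.DataFrame((values - mean) / sd, index=P.index, columns=P.columns)


def zscore_flags(Z: pd.DataFrame,
                 threshold: float = Z_THRESHOLD_DEFAULT) -> pd.DataFrame:
    """Boolean matrix, true exactly where Z is strictly above ``threshold``."""
    return Z > threshold


def significant_acupoints(Z: pd.DataFrame,
                          threshold: float = Z_THRESHOLD_DEFAULT,
                          ) -> dict[str, list[tuple[str, float]]]:
    """Per case, the acupoints with Z strictly above ``threshold``.

    Returns ``{case_id: [(code, z), ...]}`` sorted by descending z within
    each case; a case may map to an empty list.
    """
    out: dict[str, list[tuple[str, float]]] = {}
    for case_id, row in Z.iterrows():
        hits = [(code, float(z)) for code, z in row.items() if z > threshold]
        hits.sort(key=lambda item: (-item[1], item[0]))
        out[str(case_id)] = hits
    return out
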