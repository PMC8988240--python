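"""Scoring engine: DD scores, composite score and empowerment status.

Each respondent's DD score is the proportion of that DD's indicators on
which they are empowered; the composite score is the unweighted mean of the
DD scores; a respondent is empowered when the composite reaches the
threshold (>= inclusive, default 0.5).  Because every DD is weighted
equally and indicators are averaged within DDs, the composite is also an
exact linear function of the indicators on complete rows — see
:func:`linear_weights`.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import IndexSchema, SchemaError

__all__ = [
    "MISSING_POLICIES",
    "compute_scores",
    "linear_weights",
    "read_survey",
    "METADATA_COLUMNS",
]

log = logging.getLogger(__name__)

#: How missing indicator values are handled.
#: ``renormalize``  — drop the missing indicator from its DD denominator;
#:                    a respondent with a whole DD missing is flagged and
#:                    excluded from the result.
#: ``complete-case`` — drop any respondent with at least one missing value.
MISSING_POLICIES = ("renormalize", "complete-case")

#: Non-indicator columns of a survey table.
METADATA_COLUMNS = (
    "respondent_id",
    "site",
    "group",
    "age",
    "pregnant",
    "bmi",
    "food_groups",
)


def compute_scores(
    data: pd.DataFrame,
    schema: IndexSchema,
    threshold: float | None = None,
    missing_policy: str = "renormalize",
) -> pd.DataFrame:
    """Score every respondent of ``data`` under ``schema``.

    Parameters
    ----------
    data
        Survey table with one row per respondent; must contain every schema
        indicator as a column with values in {0, 1, NaN}.
    schema
        The index schema defining indicators and their DDs.
    threshold
        Empowerment cutoff on the composite; defaults to ``schema.threshold``.
    missing_policy
        One of :data:`MISSING_POLICIES`.

    Returns
    -------
    DataFrame indexed like ``data`` (minus excluded respondents) with one
    column per DD, plus ``composite`` and ``status``.  ``attrs`` records
    ``n_excluded``, ``threshold`` and ``missing_policy``.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(
            f"missing_policy {missing_policy!r} not one of {MISSING_POLICIES}"
        )
    thr = schema.threshold if threshold is None else float(threshold)

    missing_cols = [n for n in schema.names if n not in data.columns]
    if missing_cols:
        raise SchemaError(f"data lacks indicator column(s): {missing_cols}")

    X = data.loc[:, list(schema.names)].astype(float)
    bad = ~(X.isna() | X.isin([0.0, 1.0]))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"indicator {X.columns[c]!r} has non-binary value "
            f"{X.iloc[r, c]!r} at row {X.index[r]!r}"
        )

    if missing_policy == "complete-case":
        keep = X.notna().all(axis=1)
        n_excluded = int((~keep).sum())
        X = X.loc[keep]
    else:
        n_excluded = 0  # resolved per-DD below

    by_dd = schema.indicators_by_dd()
    dd_scores = {}
    whole_dd_missing = pd.Series(False, index=X.index)
    for dd, names in by_dd.items():
        block = X.loc[:, list(names)]
        n_obs = block.notna().sum(axis=1)
        whole_dd_missing |= n_obs == 0
        with np.errstate(invalid="ignore"):
            dd_scores[dd] = block.sum(axis=1, min_count=1) / n_obs

    if missing_policy == "renormalize" and whole_dd_missing.any():
        n_excluded = int(whole_dd_missing.sum())
        log.warning(
            "%d respondent(s) excluded: an entire DD is missing under the "
            "renormalize policy",
            n_excluded,
        )
    scores = pd.DataFrame(dd_scores).loc[~whole_dd_missing]

    scores["composite"] = scores[list(by_dd)].mean(axis=1)
    scores["status"] = (scores["composite"] >= thr).astype(int)
    scores.attrs.update(
        n_excluded=n_excluded, threshold=thr, missing_policy=missing_policy
    )
    return scores


def linear_weights(schema: IndexSchema) -> pd.Series:
    """Per-indicator weights making the composite a weighted indicator sum.

    Indicator j in DD d receives weight 1 / (D * n_d) where D is the number
    of DDs and n_d the size of d.  Weights sum to 1, and on rows with no
    missing values ``composite == (X * w).sum(axis=1)`` exactly.
    """
    sizes = schema.dd_sizes()
    n_dd = len(sizes)
    w = {ind.name: 1.0 / (n_dd * sizes[ind.dd]) for ind in schema.indicators}
    return pd.Series(w, name="weight")


def read_survey(path, indicator_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a survey table from delimited text (empty cell = missing).

    Indicator columns (if named) are coerced to float {0, 1, NaN};
    ``pregnant`` to boolean.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "pregnant" in df.columns:
        df["pregnant"] = (
            df["pregnant"].map(
                {True: True, False: False, 1: True, 0: False, "1": True, "0": False}
            )
        ).astype(bool)
    if indicator_names is not None:
        for name in indicator_names:
            if name in df.columns:
                df[name] = pd.to_numeric(df[name], errors="raise")
    return df
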