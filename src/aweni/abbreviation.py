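"""End-to-end index abbreviation.

The pipeline: compute the composite score (or binary status) from the full
schema on a training region, tune each penalized-regression approach so
that exactly k indicators stay active, audit in-sample (training) and
out-of-sample (validation) RMSE of each approach's linear predictor, check
the >=50% per-DD theme-coverage rule against the full schema, and choose
the approach with the lowest out-of-sample RMSE among those that pass
coverage (ties prefer cross-validation, then the subset earliest in schema
order).  Sensitivity sweeps over the empowerment threshold, the target
number of indicators k, and the training-site partition are provided.

RMSE is reported for the penalized fit's own linear predictor, with an
unpenalized least-squares refit on the selected subset reported alongside
(``refit_*`` columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .index_core import compute_scores
from .lasso import APPROACHES, LassoConfig, LassoFit, exact_k_select, fit_lasso
from .schema import CoverageReport, IndexSchema, theme_coverage

__all__ = [
    "ApproachResult",
    "AbbreviationReport",
    "split_by_site",
    "run_abbreviation",
    "sensitivity_sweep",
]

log = logging.getLogger(__name__)


def split_by_site(data: pd.DataFrame, train_sites: Sequence[str]):
    """Partition a survey table into (train, validation) by site label."""
    train_sites = list(train_sites)
    if not train_sites:
        raise ValueError("train_sites must be non-empty")
    observed = set(data["site"].unique())
    unknown = set(train_sites) - observed
    if unknown:
        raise ValueError(f"unknown site label(s): {sorted(unknown)}")
    if observed == set(train_sites):
        raise ValueError("train_sites covers every site: validation set is empty")
    mask = data["site"].isin(train_sites)
    train, val = data.loc[mask], data.loc[~mask]
    log.info("site split: %d training rows, %d validation rows", len(train), len(val))
    return train, val


@dataclass
class ApproachResult:
    """One approach's k-indicator selection and its audit quantities."""

    approach: str
    selected: tuple[str, ...]
    n_selected: int
    n_dropped: int
    in_rmse: float
    out_rmse: float
    refit_in_rmse: float
    refit_out_rmse: float
    coverage: CoverageReport
    fit: LassoFit


@dataclass
class AbbreviationReport:
    """Comparison surface across approaches plus the final choice."""

    k: int
    response: str
    threshold: float
    n_train: int
    n_val: int
    approaches: "dict[str, ApproachResult]"
    chosen_approach: str | None
    chosen: tuple[str, ...] | None
    coverage_cutoff: float
    no_approach_passed: bool = False
    config_echo: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, res in self.approaches.items():
            rows.append(
                {
                    "approach": name,
                    "n_selected": res.n_selected,
                    "n_dropped": res.n_dropped,
                    "in_rmse": res.in_rmse,
                    "out_rmse": res.out_rmse,
                    "refit_in_rmse": res.refit_in_rmse,
                    "refit_out_rmse": res.refit_out_rmse,
                    "min_theme_coverage": res.coverage.min_coverage,
                    "coverage_passes": res.coverage.passes,
                    "chosen": name == self.chosen_approach,
                    "selected": " ".join(res.selected),
                }
            )
        return pd.DataFrame(rows).set_index("approach")


def _response_vector(
    data: pd.DataFrame, schema: IndexSchema, response: str, threshold: float,
    missing_policy: str,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Complete-row indicator matrix and the full-schema response on it."""
    X = data.loc[:, list(schema.names)].astype(float)
    complete = X.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.warning("%d row(s) with missing indicators dropped before fitting", n_dropped)
    X = X.loc[complete]
    scores = compute_scores(X, schema, threshold=threshold, missing_policy=missing_policy)
    if response == "score":
        y = scores["composite"].to_numpy()
    elif response == "status":
        y = scores["status"].to_numpy(float)
    else:
        raise ValueError(f"response must be 'score' or 'status', got {response!r}")
    return X, y


def _ols_refit(Xtr, ytr, subset):
    if not subset:
        return None
    return fit_lasso(Xtr.loc[:, list(subset)], ytr, lam=0.0)


def run_abbreviation(
    data: pd.DataFrame,
    schema: IndexSchema,
    k: int = 20,
    approaches: Sequence[str] = APPROACHES,
    response: str = "score",
    config: LassoConfig | None = None,
    *,
    train_sites: Sequence[str] | None = None,
    split: tuple[pd.DataFrame, pd.DataFrame] | None = None,
    threshold: float | None = None,
    coverage_cutoff: float = 50.0,
    missing_policy: str = "renormalize",
) -> AbbreviationReport:
    """Select k indicators per approach, audit RMSE/coverage, pick a winner.

    Either ``train_sites`` (labels defining the training region of
    ``data``) or a pre-made ``split`` must be supplied.
    """
    config = config or LassoConfig()
    thr = schema.threshold if threshold is None else float(threshold)
    if split is None:
        if train_sites is None:
            raise ValueError("supply train_sites or an explicit split")
        split = split_by_site(data, train_sites)
    train, val = split

    unknown = [a for a in approaches if a not in APPROACHES]
    if unknown:
        raise ValueError(f"unknown approach(es) {unknown}; expected among {APPROACHES}")

    Xtr, ytr = _response_vector(train, schema, response, thr, missing_policy)
    Xva, yva = _response_vector(val, schema, response, thr, missing_policy)

    results: dict[str, ApproachResult] = {}
    for approach in approaches:
        subset, fit = exact_k_select(Xtr, ytr, k, approach=approach, config=config)
        cov = theme_coverage(schema, subset, cutoff=coverage_cutoff)
        refit = _ols_refit(Xtr, ytr, subset)
        results[approach] = ApproachResult(
            approach=approach,
            selected=subset,
            n_selected=len(subset),
            n_dropped=schema.n_indicators - len(subset),
            in_rmse=fit.rmse(Xtr, ytr),
            out_rmse=fit.rmse(Xva, yva),
            refit_in_rmse=refit.rmse(Xtr.loc[:, list(subset)], ytr) if refit else float("nan"),
            refit_out_rmse=refit.rmse(Xva.loc[:, list(subset)], yva) if refit else float("nan"),
            coverage=cov,
            fit=fit,
        )

    order = {name: i for i, name in enumerate(schema.names)}
    passing = [r for r in results.values() if r.coverage.passes]
    chosen_approach = chosen = None
    if passing:
        best_rmse = min(r.out_rmse for r in passing)
        tied = [r for r in passing if r.out_rmse <= best_rmse + 1e-10]
        tied.sort(
            key=lambda r: (
                0 if r.approach == "cv" else 1,
                tuple(order[n] for n in r.selected),
                r.approach,
            )
        )
        chosen_approach, chosen = tied[0].approach, tied[0].selected
    else:
        log.warning("no approach satisfied the %.0f%% theme-coverage rule", coverage_cutoff)

    return AbbreviationReport(
        k=k,
        response=response,
        threshold=thr,
        n_train=len(Xtr),
        n_val=len(Xva),
        approaches=results,
        chosen_approach=chosen_approach,
        chosen=chosen,
        coverage_cutoff=coverage_cutoff,
        no_approach_passed=not passing,
        config_echo={
            "cv_folds": config.cv_folds,
            "cv_seed": config.cv_seed,
            "n_lambda": config.n_lambda,
            "lambda_min_ratio": config.lambda_min_ratio,
            "standardize": config.standardize,
            "ebic_xi": config.ebic_xi,
            "rigorous_c": config.rigorous_c,
            "rigorous_gamma": config.rigorous_gamma,
            "tol": config.tol,
        },
    )


def sensitivity_sweep(
    data: pd.DataFrame,
    schema: IndexSchema,
    mode: str,
    grid: Sequence,
    config: LassoConfig | None = None,
    *,
    train_sites: Sequence[str] | None = None,
    k: int = 20,
    response: str = "score",
    approaches: Sequence[str] = ("cv",),
    coverage_cutoff: float = 50.0,
) -> pd.DataFrame:
    """Robustness sweeps: one report row per grid point.

    ``mode='threshold'`` re-scores at each empowerment cutoff (the response
    switches to binary status so the cutoff matters) and reports prevalence
    alongside the re-run selection; ``mode='k'`` re-runs the selection at
    each target size; ``mode='site-swap'`` re-runs under alternative
    training partitions and reports the symmetric difference between each
    run's chosen subset and the first (baseline) partition's.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("sweep grid must be non-empty")
    config = config or LassoConfig()
    rows = []

    if mode == "threshold":
        if train_sites is None:
            raise ValueError("threshold sweep needs train_sites")
        for thr in grid:
            thr = float(thr)
            if not (0.0 < thr < 1.0):
                raise ValueError(f"threshold {thr} outside (0, 1)")
            scores = compute_scores(data, schema, threshold=thr)
            rep = run_abbreviation(
                data, schema, k=k, approaches=approaches, response="status",
                config=config, train_sites=train_sites, threshold=thr,
                coverage_cutoff=coverage_cutoff,
            )
            rows.append(
                {
                    "threshold": thr,
                    "prevalence": float(scores["status"].mean()),
                    "chosen_approach": rep.chosen_approach,
                    "n_selected": len(rep.chosen) if rep.chosen else 0,
                    "out_rmse": (
                        rep.approaches[rep.chosen_approach].out_rmse
                        if rep.chosen_approach else float("nan")
                    ),
                    "selected": " ".join(rep.chosen) if rep.chosen else "",
                }
            )
        return pd.DataFrame(rows)

    if mode == "k":
        if train_sites is None:
            raise ValueError("k sweep needs train_sites")
        for kk in grid:
            kk = int(kk)
            rep = run_abbreviation(
                data, schema, k=kk, approaches=approaches, response=response,
                config=config, train_sites=train_sites,
                coverage_cutoff=coverage_cutoff,
            )
            best = rep.approaches[rep.chosen_approach] if rep.chosen_approach else None
            rows.append(
                {
                    "k": kk,
                    "n_selected": best.n_selected if best else 0,
                    "chosen_approach": rep.chosen_approach,
                    "in_rmse": best.in_rmse if best else float("nan"),
                    "out_rmse": best.out_rmse if best else float("nan"),
                    "min_theme_coverage": best.coverage.min_coverage if best else float("nan"),
                    "selected": " ".join(rep.chosen) if rep.chosen else "",
                }
            )
        return pd.DataFrame(rows)

    if mode == "site-swap":
        baseline: set[str] | None = None
        for sites in grid:
            rep = run_abbreviation(
                data, schema, k=k, approaches=approaches, response=response,
                config=config, train_sites=list(sites),
                coverage_cutoff=coverage_cutoff,
            )
            subset = set(rep.chosen) if rep.chosen else set()
            if baseline is None:
                baseline = subset
            rows.append(
                {
                    "train_sites": ",".join(sites),
                    "chosen_approach": rep.chosen_approach,
                    "n_selected": len(subset),
                    "out_rmse": (
                        rep.approaches[rep.chosen_approach].out_rmse
                        if rep.chosen_approach else float("nan")
                    ),
                    "symmetric_difference": len(subset ^ baseline),
                    "selected": " ".join(sorted(subset)),
                }
            )
        return pd.DataFrame(rows)

    raise ValueError(f"unknown sweep mode {mode!r}")
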