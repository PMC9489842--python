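"""Mixed-effects comparison of FC variables between diagnostic groups.

The response (an FC variable or the power-law scaling exponent) is modeled as

    y ~ beta_dx * diagnosis [+ beta_n * n_neurons_c + beta_n2 * n_neurons_c^2]
        + (1 | cell_line_id)

with a random intercept per cell line; diagnosis is coded 1 for the case
group (SZ) and 0 for controls (HC), the group effect is tested with a Wald Z,
and deviance statistics under maximum likelihood decide whether the centered
neuron-count covariates are kept.  The final reported fit uses REML.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import FitFailureError, InvalidArgumentError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("network_id", "cell_line_id", "diagnosis", "n_neurons", "y")


@dataclass
class MixedModelResult:
    beta_diagnosis: float
    beta_nneurons: float | None
    beta_nneurons_sq: float | None
    random_intercept_variance: float
    z_diagnosis: float
    p_diagnosis: float
    deviance: float
    covariates_included: tuple[str, ...]
    n_rows: int
    n_groups: int

    def __post_init__(self):
        if not (0.0 <= self.p_diagnosis <= 1.0):
            raise InvalidArgumentError("p-value must lie in [0, 1]")
        if self.random_intercept_variance < 0:
            raise InvalidArgumentError("variance must be nonnegative")


@dataclass
class DevianceSelection:
    """Outcome of the covariate-necessity check via deviance statistics."""

    unadjusted: MixedModelResult
    adjusted: MixedModelResult
    deviance_difference: float  # unadjusted minus adjusted (ML deviances)
    p_value: float
    use_covariates: bool


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidArgumentError(f"variable table lacks columns: {missing}")
    if table["y"].isna().any():
        raise InvalidArgumentError("variable table has missing responses")
    if not set(np.unique(table["diagnosis"])) <= {0, 1}:
        raise InvalidArgumentError("diagnosis must be coded 0 (control) / 1 (case)")
    for dx in (0, 1):
        lines = table.loc[table["diagnosis"] == dx, "cell_line_id"].nunique()
        if 0 < lines < 2:
            logger.warning("diagnosis %d has a single cell line; effects are confounded", dx)
    return table


def center_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Add mean-centered neuron-count covariates.

    ``n_neurons_c`` is the count minus its mean; ``n_neurons_sq_c`` is the
    square of the centered count, itself re-centered.  The response is never
    touched.
    """
    if len(table) == 0:
        raise InvalidArgumentError("empty variable table")
    out = table.copy()
    centered = out["n_neurons"] - out["n_neurons"].mean()
    squared = centered**2
    out["n_neurons_c"] = centered
    out["n_neurons_sq_c"] = squared - squared.mean()
    return out


def _fit(
    table: pd.DataFrame, include_covariates: bool, reml: bool
) -> tuple[MixedModelResult, object]:
    table = validate_table(table)
    if len(table) < 10:
        raise InvalidArgumentError("need at least 10 rows to fit the mixed model")
    if table["cell_line_id"].nunique() < 2:
        raise InvalidArgumentError("need at least 2 cell lines (grouping levels)")
    table = center_covariates(table)

    covariates = ("n_neurons_c", "n_neurons_sq_c") if include_covariates else ()
    exog = pd.DataFrame({"const": 1.0, "diagnosis": table["diagnosis"].astype(float)})
    for c in covariates:
        exog[c] = table[c].astype(float)

    model = sm.MixedLM(
        endog=table["y"].astype(float),
        exog=exog,
        groups=table["cell_line_id"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary/singular warnings handled below
        try:
            fit = model.fit(reml=reml, method=["bfgs", "powell"])
        except Exception as exc:  # noqa: BLE001 - solver failure surfaces as fit failure
            raise FitFailureError("mixed model failed to fit", {"message": str(exc)}) from exc
    if not fit.converged:
        raise FitFailureError("mixed model optimizer did not converge", {"reml": reml})

    re_var = float(np.asarray(fit.cov_re)[0, 0])
    if re_var < 0 or not np.isfinite(re_var):
        logger.warning("singular random-effects variance; falling back to 0")
        re_var = 0.0
    z = float(fit.params["diagnosis"] / fit.bse["diagnosis"])
    p = float(2.0 * stats.norm.sf(abs(z)))
    result = MixedModelResult(
        beta_diagnosis=float(fit.params["diagnosis"]),
        beta_nneurons=float(fit.params["n_neurons_c"]) if include_covariates else None,
        beta_nneurons_sq=float(fit.params["n_neurons_sq_c"]) if include_covariates else None,
        random_intercept_variance=re_var,
        z_diagnosis=z,
        p_diagnosis=p,
        deviance=float(-2.0 * fit.llf),
        covariates_included=covariates,
        n_rows=len(table),
        n_groups=int(table["cell_line_id"].nunique()),
    )
    return result, fit


def fit_mixed_model(
    table: pd.DataFrame, include_covariates: bool = True, reml: bool = True
) -> MixedModelResult:
    """REML fit of the random-intercept model; Wald Z test on the group effect."""
    result, _ = _fit(table, include_covariates=include_covariates, reml=reml)
    return result


def deviance_select(table: pd.DataFrame, alpha: float = 0.05) -> DevianceSelection:
    """Decide between covariate-free and covariate-adjusted models by deviance.

    Both candidates are fitted under maximum likelihood (fixed effects differ,
    so REML deviances are not comparable); the difference is referred to a
    chi-squared with 2 degrees of freedom at the configurable ``alpha``.
    """
    unadjusted, _ = _fit(table, include_covariates=False, reml=False)
    adjusted, _ = _fit(table, include_covariates=True, reml=False)
    diff = unadjusted.deviance - adjusted.deviance
    p = float(stats.chi2.sf(max(diff, 0.0), df=2))
    return DevianceSelection(
        unadjusted=unadjusted,
        adjusted=adjusted,
        deviance_difference=float(diff),
        p_value=p,
        use_covariates=bool(p < alpha),
    )


def simulate_variable_table(
    n_cell_lines: int,
    networks_per_line: int,
    beta_diagnosis: float = 0.0,
    random_intercept_sd: float = 0.5,
    noise_sd: float = 1.0,
    beta_nneurons: float = 0.0,
    beta_nneurons_sq: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic variable table for calibration and power simulations.

    Cell lines are split evenly between diagnoses (cases first when odd);
    neuron counts are uniform on [15, 250] as in typical recordings.
    """
    if n_cell_lines < 2:
        raise InvalidArgumentError("need at least 2 cell lines")
    rng = np.random.default_rng(seed)
    rows = []
    intercepts = rng.normal(0.0, random_intercept_sd, n_cell_lines)
    for line in range(n_cell_lines):
        dx = 1 if line < (n_cell_lines + 1) // 2 else 0
        for net in range(networks_per_line):
            n_neurons = int(rng.integers(15, 251))
            rows.append(
                {
                    "network_id": f"line{line}_net{net}",
                    "cell_line_id": f"line{line}",
                    "diagnosis": dx,
                    "n_neurons": n_neurons,
                }
            )
    table = pd.DataFrame(rows)
    centered = table["n_neurons"] - table["n_neurons"].mean()
    sq = centered**2 - (centered**2).mean()
    table["y"] = (
        beta_diagnosis * table["diagnosis"]
        + beta_nneurons * centered
        + beta_nneurons_sq * sq
        + intercepts[[int(c[4:].split("_")[0]) for c in table["network_id"]]]
        + rng.normal(0.0, noise_sd, len(table))
    )
    return table
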