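"""Score-trajectory statistics across training sessions.

Three pieces: the chance floor for a K-motion vocabulary (100/K percent),
a one-sample t-test of observed scores against that floor, and a
random-intercept linear mixed model of accuracy over sessions,

    y_ij = b0 + b1 * session_ij + u_i + e_ij,
    u_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma^2),

fitted by maximum likelihood with a Wald test on the shared slope b1
(percentage points per additional session).  The random intercept absorbs
stable between-subject differences in baseline proficiency, which makes
the model robust to unbalanced session counts and irregular measurement
intervals.  A REML flag is available; session index is the default time
variable, with calendar day offset as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .core import SessionScore

__all__ = [
    "TrendFit",
    "chance_level",
    "one_sample_t",
    "scores_to_frame",
    "fit_random_intercept",
]


@dataclass
class TrendFit:
    """Random-intercept trend model estimates."""

    beta_slope: float
    beta_intercept: float
    random_intercept_variance: float
    residual_variance: float
    slope_se: float
    p_value: float
    n_subjects: int
    n_observations: int
    method: str = "ML"
    time_variable: str = "session_index"

    def __post_init__(self) -> None:
        if self.random_intercept_variance < 0 or self.residual_variance < 0:
            raise ValueError("variance components must be >= 0")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for the slope."""
        z = spstats.norm.ppf(0.5 + level / 2.0)
        return (self.beta_slope - z * self.slope_se, self.beta_slope + z * self.slope_se)

    def report(self) -> str:
        lo, hi = self.slope_ci()
        return (
            f"Random-intercept trend fit ({self.method}, time={self.time_variable})\n"
            f"  observations: {self.n_observations} from {self.n_subjects} subjects\n"
            f"  slope:     {self.beta_slope:+.4f} %/session "
            f"(SE {self.slope_se:.4f}, 95% CI [{lo:.4f}, {hi:.4f}], p={self.p_value:.4g})\n"
            f"  intercept: {self.beta_intercept:.3f} %\n"
            f"  variance:  subject {self.random_intercept_variance:.4f}, "
            f"residual {self.residual_variance:.4f}"
        )


def chance_level(n_classes: int) -> float:
    """Expected accuracy (percent) of uniform guessing over K classes.

    For the 11-motion passive vocabulary this is 100/11 = 9.09%, the floor
    against which engagement is judged.
    """
    if n_classes < 1:
        raise ValueError("need at least one class")
    return 100.0 / n_classes


def one_sample_t(scores: Sequence[float], mu0: float) -> tuple[float, float]:
    """Two-tailed one-sample t-test of the scores' mean against ``mu0``.

    Returns ``(t, p)`` with ``t = (mean - mu0) / (sd / sqrt(n))`` on
    ``n - 1`` degrees of freedom.
    """
    x = np.asarray(list(scores), dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 scores")
    if np.std(x, ddof=1) == 0:
        raise ValueError("scores have zero variance; t-statistic undefined")
    res = spstats.ttest_1samp(x, mu0)
    return float(res.statistic), float(res.pvalue)


def scores_to_frame(scores: Iterable[SessionScore]) -> pd.DataFrame:
    """Session-score records as a tidy DataFrame."""
    rows = [
        {
            "subject_id": s.subject_id,
            "limb_id": s.limb_id,
            "session_index": s.session_index,
            "day_offset": s.day_offset,
            "motion_set": s.motion_set,
            "mean_accuracy": s.mean_accuracy,
        }
        for s in scores
    ]
    return pd.DataFrame(rows)


def fit_random_intercept(
    scores: Iterable[SessionScore] | pd.DataFrame,
    time_variable: Literal["session_index", "day_offset"] = "session_index",
    group_variable: str = "limb_id",
    reml: bool = False,
) -> TrendFit:
    """Fit the random-intercept trend model to session scores.

    Maximum likelihood by default (REML optional), with a Wald p-value for
    the slope.  Groups are limbs (each limb contributes its own baseline);
    the time variable is the session index unless ``day_offset`` is chosen.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = scores if isinstance(scores, pd.DataFrame) else scores_to_frame(scores)
    required = {group_variable, time_variable, "mean_accuracy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"score table is missing columns: {sorted(missing)}")
    if df[group_variable].nunique() < 2:
        raise ValueError("need at least 2 subjects/limbs to fit a random intercept")
    per_group = df.groupby(group_variable)[time_variable].count()
    if (per_group < 2).any():
        bad = per_group[per_group < 2].index.tolist()
        raise ValueError(
            f"groups {bad} have a single session; a random intercept is not "
            "identifiable — fit ordinary least squares on the pooled scores instead"
        )

    endog = df["mean_accuracy"].to_numpy(dtype=np.float64)
    if np.ptp(endog) == 0:
        raise ValueError(
            "all scores are identical; the trend model is degenerate "
            "(no variance to decompose)"
        )
    exog = sm.add_constant(df[time_variable].to_numpy(dtype=np.float64))
    model = sm.MixedLM(endog, exog, groups=df[group_variable].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        # statsmodels warns (UserWarning) whenever an optimizer step visits a
        # boundary sigma_b^2 = 0; harmless for a scalar random intercept.
        warnings.simplefilter("ignore", UserWarning)
        fit = None
        for meth in (["lbfgs", "bfgs"], "powell"):
            try:
                fit = model.fit(reml=reml, method=meth)
                break
            except np.linalg.LinAlgError:
                # Hessian inversion fails when sigma_b^2 sits on the zero
                # boundary; retry with a derivative-free optimizer, else
                # fall through to the boundary (OLS) solution below.
                continue

    def _ols_solution() -> TrendFit:
        # On the sigma_b^2 = 0 boundary the mixed model is exactly pooled
        # OLS (and the GLS fixed-effect estimates from a boundary iterate
        # are unreliable), so take the OLS solution there.
        ols = sm.OLS(endog, exog).fit()
        n = len(endog)
        return TrendFit(
            beta_slope=float(ols.params[1]),
            beta_intercept=float(ols.params[0]),
            random_intercept_variance=0.0,
            residual_variance=float(ols.scale) if reml else float(ols.ssr / n),
            slope_se=float(ols.bse[1]),
            p_value=float(ols.pvalues[1]),
            n_subjects=int(df[group_variable].nunique()),
            n_observations=n,
            method="REML" if reml else "ML",
            time_variable=time_variable,
        )

    if fit is None:
        return _ols_solution()
    var_re = float(np.asarray(fit.cov_re)[0, 0])
    if var_re <= 1e-8 * float(fit.scale) or not np.isfinite(fit.pvalues[1]):
        return _ols_solution()

    return TrendFit(
        beta_slope=float(fit.fe_params[1]),
        beta_intercept=float(fit.fe_params[0]),
        random_intercept_variance=var_re,
        residual_variance=float(fit.scale),
        slope_se=float(fit.bse_fe[1]),
        p_value=float(fit.pvalues[1]),
        n_subjects=int(df[group_variable].nunique()),
        n_observations=int(len(df)),
        method="REML" if reml else "ML",
        time_variable=time_variable,
    )
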