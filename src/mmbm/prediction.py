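"""Posterior predicted activity probabilities for covariate profiles.

Turns a fitted model into draw-wise category probabilities for a specified
child profile (e.g. a girl in middle childhood in a low-risk society), with
equal-tailed credible intervals — the machinery behind predicted-probability
figures.  Two random-effect conventions are offered:

* ``median_unit`` (default): random effects set to zero — a typical child in
  a typical society;
* ``marginal``: probabilities averaged over fresh random-effect draws from
  the fitted covariance matrices (population-averaged).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CATEGORIES, ModelSpec, category_probs
from .inference import FitResult

DEFAULT_PREDICTION_LEVEL = 0.89  # used for prediction plots; 0.95 for tables


def profile_to_x(spec: ModelSpec, profile: dict[str, float]) -> np.ndarray:
    """Covariate vector for one profile; interaction terms are derived.

    The profile must give a value for every non-derived term of the spec
    (gender/age indicators, society covariates); reference levels are
    explicit zeros.
    """
    x = np.empty(spec.n_terms)
    missing = []
    for m, term in enumerate(spec.fixed_effects):
        if term == "intercept":
            x[m] = 1.0
        elif ":" in term:
            a, b = term.split(":")
            try:
                x[m] = _term_value(profile, a) * _term_value(profile, b)
            except KeyError as exc:
                missing.append(str(exc.args[0]))
        else:
            try:
                x[m] = _term_value(profile, term)
            except KeyError as exc:
                missing.append(str(exc.args[0]))
    if missing:
        raise ValueError(f"profile is missing terms: {sorted(set(missing))}")
    return x


def _term_value(profile: dict[str, float], term: str) -> float:
    if term in profile:
        return float(profile[term])
    raise KeyError(term)


def predict_probability(
    fit: FitResult,
    spec: ModelSpec,
    profile: dict[str, float],
    re_mode: str = "median_unit",
    n_mc: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Draw-wise category probabilities, shape (n_draws, 5).

    ``median_unit`` evaluates the linear predictor with random effects at
    zero; ``marginal`` averages the softmax over ``n_mc`` fresh random-effect
    draws from each posterior draw's covariance matrices.
    """
    x = profile_to_x(spec, profile)
    beta = fit.stacked("beta")  # (S, 4, M)
    eta = beta @ x  # (S, 4)
    if re_mode == "median_unit":
        return category_probs(eta)
    if re_mode != "marginal":
        raise ValueError("re_mode must be 'median_unit' or 'marginal'")
    if "sigma_individual" not in fit.draws:
        return category_probs(eta)
    rng = np.random.default_rng(seed)
    sig_i = fit.stacked("sigma_individual")
    sig_s = fit.stacked("sigma_society")
    corr_i = fit.stacked("corr_individual")
    corr_s = fit.stacked("corr_society")
    S = eta.shape[0]
    out = np.empty((S, len(CATEGORIES)))
    z = rng.standard_normal((n_mc, 4))
    z2 = rng.standard_normal((n_mc, 4))
    for s in range(S):
        L_i = np.linalg.cholesky(corr_i[s])
        L_s = np.linalg.cholesky(corr_s[s])
        nu = z @ (sig_i[s][:, None] * L_i).T + z2 @ (sig_s[s][:, None] * L_s).T
        out[s] = category_probs(eta[s] + nu).mean(axis=0)
    return out


def credible_interval(samples: np.ndarray, level: float) -> tuple[float, float]:
    """Equal-tailed interval by linear-interpolation percentiles."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    samples = np.asarray(samples, dtype=float)
    if samples.size < 20:
        raise ValueError("need at least 20 samples for a credible interval")
    lo = float(np.quantile(samples, (1 - level) / 2, method="linear"))
    hi = float(np.quantile(samples, 1 - (1 - level) / 2, method="linear"))
    return lo, hi


def prediction_table(
    fit: FitResult,
    spec: ModelSpec,
    profiles: dict[str, dict[str, float]],
    level: float = DEFAULT_PREDICTION_LEVEL,
    re_mode: str = "median_unit",
) -> pd.DataFrame:
    """Long table (profile, category, mean, low, high) across profiles."""
    rows = []
    for name, profile in profiles.items():
        pi = predict_probability(fit, spec, profile, re_mode=re_mode)
        for k, cat in enumerate(CATEGORIES):
            lo, hi = credible_interval(pi[:, k], level)
            rows.append(
                {
                    "profile": name,
                    "category": cat,
                    "mean": float(pi[:, k].mean()),
                    f"low{int(level * 100)}": lo,
                    f"high{int(level * 100)}": hi,
                }
            )
    return pd.DataFrame(rows)
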