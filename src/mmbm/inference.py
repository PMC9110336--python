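"""Model fitting, convergence checking, WAIC comparison, and summaries.

``fit`` runs the in-package NUTS sampler on the exact log posterior defined
in :mod:`mmbm.core` (default plan: 3 chains of 2000 iterations, first half
warmup).  Convergence is declared only when every split R-hat is below 1.01
and no post-warmup iteration diverged.  Candidate models are compared by
WAIC on the deviance scale with Akaike-style weights.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import nuts
from .core import (
    CATEGORIES,
    N_CATEGORIES,
    N_CONTRASTS,
    ModelSpec,
    MultinomialLogitPosterior,
    PriorConfig,
)

logger = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.01


@dataclass(frozen=True)
class McmcConfig:
    """Sampling plan; defaults follow the published estimation setup."""

    chains: int = 3
    iterations: int = 2000  # per chain, including warmup
    warmup: int | None = None  # default: half the iterations
    seed: int = 1
    target_accept: float = 0.9
    max_treedepth: int = 10

    @property
    def n_warmup(self) -> int:
        return self.iterations // 2 if self.warmup is None else self.warmup

    @property
    def n_keep(self) -> int:
        return self.iterations - self.n_warmup


@dataclass
class Dataset:
    """Design and outcome data for one model fit.

    ``counts`` collapses the categorical observations of each child into
    per-category counts; ``obs_child`` / ``obs_category`` retain the
    observation-level mapping needed for pointwise log-likelihoods.
    """

    counts: np.ndarray  # (n_children, 5)
    design: np.ndarray  # (n_children, n_terms)
    society_index: np.ndarray  # (n_children,)
    child_ids: list[str]
    society_ids: list[str]
    obs_child: np.ndarray  # (n_obs,) child row index per observation
    obs_category: np.ndarray  # (n_obs,) category index per observation

    @property
    def n_children(self) -> int:
        return self.counts.shape[0]

    @property
    def n_societies(self) -> int:
        return len(self.society_ids)

    @property
    def n_obs(self) -> int:
        return self.obs_child.size


def design_matrix(child_rows: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Fixed-effect design matrix from merged child + society covariates."""
    n = len(child_rows)
    cols = []
    for term in spec.fixed_effects:
        if term == "intercept":
            cols.append(np.ones(n))
        elif term == "boy":
            cols.append((child_rows["gender"] == "boy").to_numpy(float))
        elif term in ("middle", "adolescent"):
            cols.append((child_rows["age_class"] == term).to_numpy(float))
        elif term in ("boy:middle", "boy:adolescent"):
            age = term.split(":")[1]
            cols.append(
                (child_rows["gender"] == "boy").to_numpy(float)
                * (child_rows["age_class"] == age).to_numpy(float)
            )
        elif term == "mammal_density_high":
            cols.append((child_rows["mammal_density_class"] == "high").to_numpy(float))
        elif term == "water_rating":
            cols.append(child_rows["water_rating"].to_numpy(float))
        elif term == "division":
            cols.append(child_rows["gendered_division"].to_numpy(float))
        elif term == "division:boy":
            cols.append(
                child_rows["gendered_division"].to_numpy(float)
                * (child_rows["gender"] == "boy").to_numpy(float)
            )
        else:  # z-scored continuous society covariates
            if term not in child_rows.columns:
                raise ValueError(f"covariate column {term!r} missing from input")
            cols.append(child_rows[term].to_numpy(float))
    return np.column_stack(cols)


def build_dataset(
    records: pd.DataFrame,
    children: pd.DataFrame,
    societies: pd.DataFrame,
    spec: ModelSpec,
) -> Dataset:
    """Assemble counts, design matrix and index maps for one fit."""
    if len(records) == 0:
        raise ValueError("empty dataset: no observation records")
    children = children.copy()
    merged = children.merge(societies, on="society_id", how="left", validate="m:1")
    if merged[
        [c for c in ["prop_non_foraged_z"] if c in merged.columns]
    ].isna().any().any():
        raise ValueError("children reference societies missing from profiles")
    child_ids = merged["child_id"].tolist()
    child_pos = {c: i for i, c in enumerate(child_ids)}
    society_ids = sorted(merged["society_id"].unique().tolist())
    soc_pos = {s: i for i, s in enumerate(society_ids)}
    society_index = merged["society_id"].map(soc_pos).to_numpy(int)

    unknown = set(records["child_id"]) - set(child_pos)
    if unknown:
        raise ValueError(f"records reference unknown children: {sorted(unknown)[:5]}")
    obs_child = records["child_id"].map(child_pos).to_numpy(int)
    cat_pos = {c: i for i, c in enumerate(CATEGORIES)}
    obs_category = records["category"].map(cat_pos).to_numpy()
    if np.isnan(obs_category.astype(float)).any():
        raise ValueError("records contain unknown categories")
    obs_category = obs_category.astype(int)

    counts = np.zeros((len(child_ids), N_CATEGORIES))
    np.add.at(counts, (obs_child, obs_category), 1.0)

    X = design_matrix(merged, spec)
    return Dataset(
        counts=counts,
        design=X,
        society_index=society_index,
        child_ids=child_ids,
        society_ids=society_ids,
        obs_child=obs_child,
        obs_category=obs_category,
    )


@dataclass
class FitResult:
    """Posterior draws, pointwise log-likelihoods and diagnostics."""

    spec: ModelSpec
    draws: dict[str, np.ndarray]  # each (chains, n_keep, ...)
    pointwise_loglik: np.ndarray | None  # (chains * n_keep, n_obs)
    diagnostics: dict
    meta: dict
    child_ids: list[str] = field(default_factory=list)
    society_ids: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def stacked(self, name: str) -> np.ndarray:
        """Draws for ``name`` with chains flattened into the first axis."""
        a = self.draws[name]
        return a.reshape((-1,) + a.shape[2:])

    # ---- persistence ------------------------------------------------------

    def scalar_draws(self) -> pd.DataFrame:
        """Long-format table (chain, iteration, parameter, value)."""
        rows = {}
        for name, labels, arr in _iter_scalar_params(self):
            rows[_format_name(name, labels)] = arr
        chains, n = next(iter(self.draws.values())).shape[:2]
        frames = []
        for pname, arr in rows.items():
            for c in range(chains):
                frames.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(n),
                            "parameter": pname,
                            "value": arr[c],
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.scalar_draws().to_csv(path / "draws.csv", index=False)
        sidecar = {
            "model_id": self.spec.model_id,
            "fixed_effects": list(self.spec.fixed_effects),
            "diagnostics": _jsonable(self.diagnostics),
            "meta": _jsonable(self.meta),
            "child_ids": self.child_ids,
            "society_ids": self.society_ids,
        }
        (path / "fit.json").write_text(json.dumps(sidecar, indent=1))
        if self.pointwise_loglik is not None:
            np.savetxt(
                path / "pointwise_loglik.csv", self.pointwise_loglik, fmt="%.9e"
            )

    @classmethod
    def from_dir(cls, path: str | Path) -> "FitResult":
        path = Path(path)
        sidecar = json.loads((path / "fit.json").read_text())
        spec = ModelSpec(
            model_id=sidecar["model_id"],
            fixed_effects=tuple(sidecar["fixed_effects"]),
        )
        long = pd.read_csv(path / "draws.csv")
        chains = int(long["chain"].max()) + 1
        n = int(long["iteration"].max()) + 1
        draws = _draws_from_long(long, spec, sidecar, chains, n)
        pw = None
        if (path / "pointwise_loglik.csv").exists():
            pw = np.loadtxt(path / "pointwise_loglik.csv")
            pw = np.atleast_2d(pw)
        return cls(
            spec=spec,
            draws=draws,
            pointwise_loglik=pw,
            diagnostics=sidecar["diagnostics"],
            meta=sidecar["meta"],
            child_ids=sidecar["child_ids"],
            society_ids=sidecar["society_ids"],
        )


def _format_name(name: str, labels: tuple) -> str:
    if not labels:
        return name
    return f"{name}[{','.join(str(x) for x in labels)}]"


def _iter_scalar_params(fit: FitResult):
    """Yield (name, labels, (chains, n) array) for every scalar parameter."""
    spec = fit.spec
    for name, arr in fit.draws.items():
        if name == "beta":
            for k in range(N_CONTRASTS):
                for m, term in enumerate(spec.fixed_effects):
                    yield "beta", (CATEGORIES[k], term), arr[:, :, k, m]
        elif name.startswith("sigma"):
            for k in range(N_CONTRASTS):
                yield name, (CATEGORIES[k],), arr[:, :, k]
        elif name.startswith("corr"):
            for k in range(N_CONTRASTS):
                for l in range(k + 1, N_CONTRASTS):
                    yield name, (CATEGORIES[k], CATEGORIES[l]), arr[:, :, k, l]
        elif name.startswith("nu_individual"):
            for i, cid in enumerate(fit.child_ids):
                for k in range(N_CONTRASTS):
                    yield name, (cid, CATEGORIES[k]), arr[:, :, i, k]
        elif name.startswith("nu_society"):
            for j, sid in enumerate(fit.society_ids):
                for k in range(N_CONTRASTS):
                    yield name, (sid, CATEGORIES[k]), arr[:, :, j, k]
        elif arr.ndim == 2:
            yield name, (), arr


def _draws_from_long(long, spec, sidecar, chains, n):
    table = {
        p: g.sort_values(["chain", "iteration"])["value"].to_numpy().reshape(chains, n)
        for p, g in long.groupby("parameter")
    }
    M = spec.n_terms
    draws: dict[str, np.ndarray] = {}
    beta = np.empty((chains, n, N_CONTRASTS, M))
    for k in range(N_CONTRASTS):
        for m, term in enumerate(spec.fixed_effects):
            beta[:, :, k, m] = table[f"beta[{CATEGORIES[k]},{term}]"]
    draws["beta"] = beta
    if f"sigma_individual[{CATEGORIES[0]}]" in table:
        for lvl in ("individual", "society"):
            sig = np.empty((chains, n, N_CONTRASTS))
            for k in range(N_CONTRASTS):
                sig[:, :, k] = table[f"sigma_{lvl}[{CATEGORIES[k]}]"]
            draws[f"sigma_{lvl}"] = sig
            corr = np.tile(np.eye(N_CONTRASTS), (chains, n, 1, 1))
            for k in range(N_CONTRASTS):
                for l in range(k + 1, N_CONTRASTS):
                    v = table[f"corr_{lvl}[{CATEGORIES[k]},{CATEGORIES[l]}]"]
                    corr[:, :, k, l] = v
                    corr[:, :, l, k] = v
            draws[f"corr_{lvl}"] = corr
        ids = {"individual": sidecar["child_ids"], "society": sidecar["society_ids"]}
        for lvl, id_list in ids.items():
            key = f"nu_{lvl}[{id_list[0]},{CATEGORIES[0]}]" if id_list else None
            if key and key in table:
                nu = np.empty((chains, n, len(id_list), N_CONTRASTS))
                for i, ident in enumerate(id_list):
                    for k in range(N_CONTRASTS):
                        nu[:, :, i, k] = table[f"nu_{lvl}[{ident},{CATEGORIES[k]}]"]
                draws[f"nu_{lvl}"] = nu
    if "lp__" in table:
        draws["lp__"] = table["lp__"]
    return draws


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------


def fit(
    spec: ModelSpec,
    dataset: Dataset,
    config: McmcConfig = McmcConfig(),
    prior: PriorConfig = PriorConfig(),
    random_effects: bool = True,
    store_pointwise: bool = True,
    monitor: str = "fixed_effects",
) -> FitResult:
    """Fit one MMBM by NUTS; deterministic given (config.seed, config).

    ``monitor`` chooses the parameter set whose split R-hats gate the
    convergence declaration: ``"fixed_effects"`` (default; the coefficients
    the analysis reports and interprets) or ``"structural"`` (additionally
    the random-effect scales, correlations and society effects).  R-hats for
    the whole structural set are always computed and reported.
    """
    posterior = MultinomialLogitPosterior(
        counts=dataset.counts,
        design=dataset.design,
        society_index=dataset.society_index,
        n_societies=dataset.n_societies,
        prior=prior,
        random_effects=random_effects,
    )
    n_keep = config.n_keep
    chains = config.chains
    seeds = np.random.SeedSequence(config.seed).spawn(chains)
    raw = np.empty((chains, n_keep, posterior.n_params))
    lp = np.empty((chains, n_keep))
    divergences = 0
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        q0 = posterior.initial_position(rng)
        out = nuts.sample(
            posterior.logp_and_grad,
            q0,
            n_warmup=config.n_warmup,
            n_draws=n_keep,
            rng=rng,
            target_accept=config.target_accept,
            max_treedepth=config.max_treedepth,
            dense_size=posterior.dense_block_size,
            interleave=posterior.interweave_update if random_effects else None,
        )
        raw[c] = out["draws"]
        lp[c] = out["logp"]
        divergences += out["divergences"]
        logger.info(
            "chain %d/%d: accept=%.2f step=%.3g divergences=%d",
            c + 1,
            chains,
            out["accept_stat"],
            out["step_size"],
            out["divergences"],
        )

    draws = _unpack_draws(posterior, spec, raw)
    draws["lp__"] = lp
    pointwise = (
        _pointwise_loglik(posterior, dataset, raw) if store_pointwise else None
    )

    result = FitResult(
        spec=spec,
        draws=draws,
        pointwise_loglik=pointwise,
        diagnostics={},
        meta={
            "chains": chains,
            "iterations": config.iterations,
            "warmup": config.n_warmup,
            "seed": config.seed,
            "random_effects": random_effects,
            "n_children": dataset.n_children,
            "n_societies": dataset.n_societies,
            "n_obs": dataset.n_obs,
        },
        child_ids=dataset.child_ids,
        society_ids=dataset.society_ids,
    )
    # R-hats are computed for every structural parameter.  The convergence
    # gate applies to the monitored subset; the child-level latent effects
    # never gate it (with a few hundred retained draws the maximum R-hat
    # over hundreds of coordinates exceeds the threshold by chance even for
    # independent draws) but their maximum is reported.
    if monitor not in ("fixed_effects", "structural"):
        raise ValueError("monitor must be 'fixed_effects' or 'structural'")
    rhats = {
        _format_name(name, labels): rhat(arr)
        for name, labels, arr in _iter_scalar_params(result)
        if not name.startswith("nu_individual") and name != "lp__"
    }
    nu_rhats = [
        rhat(arr)
        for name, labels, arr in _iter_scalar_params(result)
        if name.startswith("nu_individual")
    ]
    if monitor == "fixed_effects":
        monitored = [v for k, v in rhats.items() if k.startswith("beta[")]
    else:
        monitored = list(rhats.values())
    finite = [r for r in monitored if np.isfinite(r)]
    max_rhat = max(monitored) if monitored else np.nan
    converged = (
        len(finite) == len(monitored)
        and (not monitored or max_rhat < RHAT_THRESHOLD)
        and divergences == 0
    )
    worst = sorted(rhats.items(), key=lambda kv: -kv[1])[:5]
    result.diagnostics = {
        "rhat": rhats,
        "monitor": monitor,
        "max_rhat": float(max_rhat),
        "max_rhat_structural": float(max(rhats.values())) if rhats else float("nan"),
        "max_rhat_individual": float(max(nu_rhats)) if nu_rhats else float("nan"),
        "divergences": int(divergences),
        "converged": bool(converged),
        "worst_rhat": [[k, float(v)] for k, v in worst],
    }
    if not converged:
        warnings.warn(
            f"fit did not converge: max R-hat {max_rhat:.4f}, "
            f"{divergences} divergent iterations; summaries are unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("worst R-hat offenders: %s", worst)
    return result


def _unpack_draws(posterior, spec, raw):
    chains, n, _ = raw.shape
    M = spec.n_terms
    draws = {"beta": np.empty((chains, n, N_CONTRASTS, M))}
    if posterior.random_effects:
        draws["sigma_individual"] = np.empty((chains, n, N_CONTRASTS))
        draws["sigma_society"] = np.empty((chains, n, N_CONTRASTS))
        draws["corr_individual"] = np.empty((chains, n, N_CONTRASTS, N_CONTRASTS))
        draws["corr_society"] = np.empty((chains, n, N_CONTRASTS, N_CONTRASTS))
        draws["nu_individual"] = np.empty(
            (chains, n, posterior.n_children, N_CONTRASTS)
        )
        draws["nu_society"] = np.empty((chains, n, posterior.n_societies, N_CONTRASTS))
    for c in range(chains):
        for t in range(n):
            p = posterior.unpack(raw[c, t])
            draws["beta"][c, t] = p.beta
            if posterior.random_effects:
                draws["sigma_individual"][c, t] = p.sigma_individual
                draws["sigma_society"][c, t] = p.sigma_society
                draws["corr_individual"][c, t] = p.corr_individual
                draws["corr_society"][c, t] = p.corr_society
                draws["nu_individual"][c, t] = p.nu_individual
                draws["nu_society"][c, t] = p.nu_society
    return draws


def _pointwise_loglik(posterior, dataset, raw):
    chains, n, _ = raw.shape
    out = np.empty((chains * n, dataset.n_obs))
    idx = 0
    for c in range(chains):
        for t in range(n):
            p = posterior.unpack(raw[c, t])
            eta = dataset.design @ p.beta.T
            if posterior.random_effects:
                eta = eta + p.nu_individual + p.nu_society[dataset.society_index]
            m = np.maximum(eta.max(axis=1), 0.0)
            lse = m + np.log(np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1))
            logpi = np.concatenate([eta - lse[:, None], -lse[:, None]], axis=1)
            out[idx] = logpi[dataset.obs_child, dataset.obs_category]
            idx += 1
    return out


# --------------------------------------------------------------------------
# Diagnostics and comparison
# --------------------------------------------------------------------------


def _split_rhat(x: np.ndarray) -> float:
    """Classic split R-hat on (chains, draws): between- vs within-half-chain
    variance."""
    m, n = x.shape
    half = n // 2
    halves = np.concatenate([x[:, :half], x[:, n - half :]], axis=0)
    n = half
    means = halves.mean(axis=1)
    W = float(halves.var(axis=1, ddof=1).mean())
    B = n * float(means.var(ddof=1))
    if W == 0.0:
        return float("nan")
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    from scipy.stats import norm, rankdata

    r = rankdata(x, axis=None).reshape(x.shape)
    return norm.ppf((r - 0.375) / (x.size + 0.25))


def rhat(chain_draws: np.ndarray, method: str = "split") -> float:
    """R-hat of one scalar parameter from (chains, draws).

    ``method="split"`` (default) is the classic split R-hat — the
    Gelman-Rubin diagnostic as reported by the Stan ecosystem at the time the
    modelling tradition this package follows was established.
    ``method="rank"`` is the stricter rank-normalized variant (maximum of
    the bulk and folded statistics).  Zero within-chain variance yields NaN,
    which callers must treat as failing.
    """
    x = np.asarray(chain_draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("need (chains, draws)")
    m, n = x.shape
    if m < 2 and n < 8:
        raise ValueError("need at least 2 chains or enough draws to split")
    if n // 2 < 2:
        raise ValueError("need at least 4 draws per chain")
    if np.all(x == x.flat[0]):
        return float("nan")
    if method == "split":
        return _split_rhat(x)
    bulk = _split_rhat(_rank_normalize(x))
    folded = _split_rhat(_rank_normalize(np.abs(x - np.median(x))))
    return float(max(bulk, folded))


def waic(pointwise_loglik_draws: np.ndarray) -> tuple[float, float, float]:
    """WAIC on the deviance scale: (waic, p_waic, se).

    lppd_i = log mean_s exp(ll_si); p_i = var_s(ll_si);
    waic = -2 * sum_i (lppd_i - p_i); se from the pointwise contributions.
    """
    ll = np.asarray(pointwise_loglik_draws, dtype=float)
    if ll.ndim != 2:
        raise ValueError("need (draws, observations)")
    if np.any(np.all(np.isneginf(ll), axis=0)):
        raise ValueError("an observation has zero likelihood under all draws")
    S = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    waic_i = -2.0 * elpd_i
    n = ll.shape[1]
    se = float(np.sqrt(n * np.var(waic_i, ddof=1))) if n > 1 else 0.0
    return float(waic_i.sum()), float(p_i.sum()), se


def model_weights(waics: list[float] | np.ndarray) -> np.ndarray:
    """Akaike-style weights: exp(-0.5 * delta WAIC), normalized."""
    w = np.asarray(waics, dtype=float)
    if w.size == 0 or not np.any(np.isfinite(w)):
        raise ValueError("need at least one finite WAIC")
    rel = np.exp(-0.5 * (w - np.nanmin(w)))
    return rel / np.nansum(rel)


def compare(fits: dict[str, FitResult] | list[FitResult]) -> pd.DataFrame:
    """WAIC comparison table across fitted models, with weights."""
    if isinstance(fits, list):
        fits = {f"model_{f.spec.model_id}": f for f in fits}
    rows = []
    for name, f in fits.items():
        if f.pointwise_loglik is None:
            raise ValueError(f"{name}: fit lacks stored pointwise log-likelihoods")
        w, p, se = waic(f.pointwise_loglik)
        rows.append({"model": name, "waic": w, "p_waic": p, "se": se})
    out = pd.DataFrame(rows)
    out["weight"] = model_weights(out["waic"].to_numpy())
    return out.sort_values("waic").reset_index(drop=True)


def summarize_fixed_effects(
    fit_result: FitResult, ci_level: float = 0.95
) -> pd.DataFrame:
    """Posterior mean, SD, equal-tailed CI and a zero-exclusion flag per
    fixed-effect coefficient, ordered category x term."""
    if not fit_result.converged:
        warnings.warn(
            "summarizing a non-converged fit", RuntimeWarning, stacklevel=2
        )
    beta = fit_result.stacked("beta")  # (draws, 4, M)
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    rows = []
    for k in range(N_CONTRASTS):
        for m, term in enumerate(fit_result.spec.fixed_effects):
            d = beta[:, k, m]
            lo, hi = float(np.quantile(d, lo_q)), float(np.quantile(d, hi_q))
            rows.append(
                {
                    "category": CATEGORIES[k],
                    "term": term,
                    "mean": float(d.mean()),
                    "sd": float(d.std(ddof=1)),
                    f"ci{int(ci_level * 100)}_low": lo,
                    f"ci{int(ci_level * 100)}_high": hi,
                    "excludes_zero": not (lo <= 0.0 <= hi),
                }
            )
    return pd.DataFrame(rows)


def random_effect_summary(fit_result: FitResult, ci_level: float = 0.95) -> pd.DataFrame:
    """Posterior summaries of the 4 scales and 6 correlations per level."""
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    rows = []
    for level in ("individual", "society"):
        sig = fit_result.stacked(f"sigma_{level}")
        for k in range(N_CONTRASTS):
            d = sig[:, k]
            rows.append(
                {
                    "level": level,
                    "parameter": f"sigma[{CATEGORIES[k]}]",
                    "mean": float(d.mean()),
                    "sd": float(d.std(ddof=1)),
                    "ci_low": float(np.quantile(d, lo_q)),
                    "ci_high": float(np.quantile(d, hi_q)),
                }
            )
        corr = fit_result.stacked(f"corr_{level}")
        for k in range(N_CONTRASTS):
            for l in range(k + 1, N_CONTRASTS):
                d = corr[:, k, l]
                rows.append(
                    {
                        "level": level,
                        "parameter": f"rho[{CATEGORIES[k]},{CATEGORIES[l]}]",
                        "mean": float(d.mean()),
                        "sd": float(d.std(ddof=1)),
                        "ci_low": float(np.quantile(d, lo_q)),
                        "ci_high": float(np.quantile(d, hi_q)),
                    }
                )
    return pd.DataFrame(rows)
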