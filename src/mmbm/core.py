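"""Core definition of the multilevel multinomial behavioural model (MMBM).

The model is a baseline-category multinomial logistic regression for a
five-category activity outcome (childcare, food production, domestic work,
play, other), with "other" pinned as the reference category.  For child ``i``
in society ``j`` the log-odds of activity ``k`` against the reference are

    log(pi_kij / pi_5ij) = beta_k + nu_individual_ki + nu_society_kj
                           + sum_m beta_km * x_im ,   k in {1..4}

where the individual- and society-level random effects are each multivariate
normal across the four contrast categories with full 4x4 covariance
``Omega = diag(sigma) @ corr @ diag(sigma)``.  Random effects are handled in
the non-centered parameterization: standard-normal draws ``z`` are mapped
through ``diag(sigma) @ cholesky(corr)``.

This module owns:

* category / term vocabulary and the five model specifications,
* the deterministic maps (linear predictor, softmax link, non-centered
  reconstruction, pointwise log-likelihood),
* weakly informative priors (Normal on fixed effects, Exponential on the
  random-effect scales, LKJ on the correlation matrices),
* :class:`MultinomialLogitPosterior`, the unconstrained log posterior with
  analytic gradient that the sampler consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import betaln

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is an optional accelerator
    njit = None

# --------------------------------------------------------------------------
# Outcome vocabulary
# --------------------------------------------------------------------------

#: Fixed category order; the last entry is the reference category whose
#: log-odds are identically zero.
CATEGORIES = ("childcare", "food_production", "domestic_work", "play", "other")
N_CATEGORIES = 5
REFERENCE_CATEGORY = "other"
REFERENCE_INDEX = 4
N_CONTRASTS = 4  # categories contrasted against the reference

#: Recognised fixed-effect term names, in canonical order.
TERMS = (
    "intercept",
    "boy",
    "middle",
    "adolescent",
    "boy:middle",
    "boy:adolescent",
    "prop_non_foraged_z",
    "npp_z",
    "annual_precip_z",
    "annual_mean_temp_z",
    "mammal_density_high",
    "water_rating",
    "division",
    "division:boy",
)

_INDIVIDUAL_TERMS = (
    "boy",
    "middle",
    "adolescent",
    "boy:middle",
    "boy:adolescent",
    "prop_non_foraged_z",
)

#: Fixed-effect blocks of the five candidate models.
MODEL_TERMS = {
    1: ("intercept",),
    2: ("intercept",) + _INDIVIDUAL_TERMS,
    3: ("intercept",)
    + _INDIVIDUAL_TERMS
    + ("npp_z", "annual_precip_z", "annual_mean_temp_z"),
    4: ("intercept",) + _INDIVIDUAL_TERMS + ("mammal_density_high", "water_rating"),
    5: ("intercept",) + _INDIVIDUAL_TERMS + ("division", "division:boy"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed effects enter the linear predictor.

    ``model_id`` 1-5 selects the published candidate-model blocks: 1 is
    intercept only; 2 adds age, gender, their interaction and the proportion
    of non-foraged food; 3-5 add the environmental, ecological-risk and
    gendered-division blocks respectively on top of model 2.
    """

    model_id: int
    fixed_effects: tuple[str, ...]
    n_categories: int = N_CATEGORIES
    reference_index: int = REFERENCE_INDEX

    def __post_init__(self) -> None:
        unknown = [t for t in self.fixed_effects if t not in TERMS]
        if unknown:
            raise ValueError(f"unknown fixed-effect terms: {unknown}")
        if not self.fixed_effects or self.fixed_effects[0] != "intercept":
            raise ValueError("fixed_effects must start with 'intercept'")

    @classmethod
    def for_model(cls, model_id: int) -> "ModelSpec":
        if model_id not in MODEL_TERMS:
            raise ValueError(f"model_id must be in 1..5, got {model_id}")
        return cls(model_id=model_id, fixed_effects=MODEL_TERMS[model_id])

    @property
    def n_terms(self) -> int:
        return len(self.fixed_effects)


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative priors for a logit-scale hierarchical model.

    beta ~ Normal(0, beta_sd); sigma ~ Exponential(sigma_rate);
    correlation matrices ~ LKJ(lkj_eta).
    """

    beta_sd: float = 2.5
    sigma_rate: float = 1.0
    lkj_eta: float = 2.0


@dataclass
class Parameters:
    """One realization of all model parameters.

    ``beta`` has shape (4, M): one row per contrast category in the order of
    :data:`CATEGORIES`, one column per term of the model spec.  ``z_*`` hold
    the standard-normal innovations of the non-centered parameterization;
    the random effects themselves are reconstructed on demand.
    """

    beta: np.ndarray
    sigma_individual: np.ndarray = field(
        default_factory=lambda: np.zeros(N_CONTRASTS)
    )
    sigma_society: np.ndarray = field(default_factory=lambda: np.zeros(N_CONTRASTS))
    corr_individual: np.ndarray = field(default_factory=lambda: np.eye(N_CONTRASTS))
    corr_society: np.ndarray = field(default_factory=lambda: np.eye(N_CONTRASTS))
    z_individual: np.ndarray = field(default_factory=lambda: np.zeros((0, N_CONTRASTS)))
    z_society: np.ndarray = field(default_factory=lambda: np.zeros((0, N_CONTRASTS)))

    @property
    def nu_individual(self) -> np.ndarray:
        return noncentered_reconstruct(
            self.z_individual, self.sigma_individual, self.corr_individual
        )

    @property
    def nu_society(self) -> np.ndarray:
        return noncentered_reconstruct(
            self.z_society, self.sigma_society, self.corr_society
        )


# --------------------------------------------------------------------------
# Deterministic maps
# --------------------------------------------------------------------------


def category_probs(eta: np.ndarray) -> np.ndarray:
    """Map 4 contrast log-odds to 5 category probabilities.

    The implicit reference logit is 0; probabilities are computed with
    max-subtraction so large ``|eta|`` cannot overflow.
    """
    eta = np.asarray(eta, dtype=float)
    if np.isnan(eta).any():
        raise ValueError("eta contains NaN")
    if eta.shape[-1] != N_CONTRASTS:
        raise ValueError(f"expected {N_CONTRASTS} log-odds, got {eta.shape[-1]}")
    m = np.maximum(eta.max(axis=-1, keepdims=True), 0.0)
    ex = np.exp(eta - m)
    ref = np.exp(-m)
    denom = ref + ex.sum(axis=-1, keepdims=True)
    probs = np.concatenate([ex, ref], axis=-1) / denom
    return probs


def linear_predictor(
    spec: ModelSpec,
    params: Parameters,
    child_covariates: np.ndarray,
    child_index: int,
    society_index: int,
) -> np.ndarray:
    """Contrast log-odds eta_k for one child: beta x + nu_ind + nu_soc."""
    x = np.asarray(child_covariates, dtype=float)
    if x.shape[-1] != spec.n_terms:
        raise ValueError(
            f"covariate vector has {x.shape[-1]} entries, spec has {spec.n_terms} terms"
        )
    eta = params.beta @ x
    if params.z_individual.shape[0]:
        eta = eta + params.nu_individual[child_index]
    if params.z_society.shape[0]:
        eta = eta + params.nu_society[society_index]
    return eta


def noncentered_reconstruct(
    z: np.ndarray, sigma: np.ndarray, corr: np.ndarray
) -> np.ndarray:
    """Map standard-normal innovations to correlated random effects.

    nu = z @ (diag(sigma) @ chol(corr)).T, so that cov(nu) =
    diag(sigma) @ corr @ diag(sigma).
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    sigma = np.asarray(sigma, dtype=float)
    corr = np.asarray(corr, dtype=float)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc
    return z @ (sigma[:, None] * chol).T


def pointwise_loglik(
    spec: ModelSpec,
    params: Parameters,
    child_covariates: np.ndarray,
    child_index: int,
    society_index: int,
    category: int | str,
) -> float:
    """Log probability of one coded observation under the model."""
    if isinstance(category, str):
        category = CATEGORIES.index(category)
    eta = linear_predictor(spec, params, child_covariates, child_index, society_index)
    return float(np.log(category_probs(eta)[category]))


# --------------------------------------------------------------------------
# Correlation-matrix transform (canonical partial correlations)
# --------------------------------------------------------------------------
# A d x d correlation matrix is parameterized by the d(d-1)/2 canonical
# partial correlations c_ij = tanh(y_ij) of its Cholesky factor:
#   L[0,0] = 1
#   L[i,j] = c_ij * prod_{m<j} sqrt(1 - c_im^2)    (j < i)
#   L[i,i] = prod_{m<i} sqrt(1 - c_im^2)
# Under an LKJ(eta) prior the c_ij are independent with a shifted-Beta
# density on (-1, 1) whose shape depends only on the column:
#   alpha_m = (d + 2*eta - 1 - (m+1)) / 2       (m 0-based)
#   p(c_im) = (1 - c^2)^(alpha_m - 1) / (2^(2*alpha_m - 1) B(alpha_m, alpha_m))


def _tril_indices(d: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(1, d) for j in range(i)]


def corr_chol_from_unconstrained(y: np.ndarray, d: int = N_CONTRASTS) -> np.ndarray:
    """Build the Cholesky factor of a correlation matrix from R^(d(d-1)/2)."""
    y = np.asarray(y, dtype=float)
    if y.size != d * (d - 1) // 2:
        raise ValueError(f"expected {d * (d - 1) // 2} values, got {y.size}")
    c = np.tanh(y)
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    k = 0
    for i in range(1, d):
        pref = 1.0
        for j in range(i):
            L[i, j] = c[k] * pref
            pref *= math.sqrt(1.0 - c[k] ** 2)
            k += 1
        L[i, i] = pref
    return L


def unconstrained_from_corr(corr: np.ndarray) -> np.ndarray:
    """Inverse of :func:`corr_chol_from_unconstrained` (corr -> y)."""
    corr = np.asarray(corr, dtype=float)
    d = corr.shape[0]
    L = np.linalg.cholesky(corr)
    y = np.zeros(d * (d - 1) // 2)
    k = 0
    for i in range(1, d):
        pref = 1.0
        for j in range(i):
            c = L[i, j] / pref
            c = float(np.clip(c, -1 + 1e-12, 1 - 1e-12))
            y[k] = math.atanh(c)
            pref *= math.sqrt(1.0 - c**2)
            k += 1
    return y


def _lkj_alpha(d: int, eta: float) -> np.ndarray:
    """Shifted-Beta shape per lower-triangular entry (ordered as _tril_indices)."""
    return np.array(
        [(d + 2.0 * eta - 1.0 - (j + 1)) / 2.0 for i, j in _tril_indices(d)]
    )


def lkj_logpdf_canonical(c: np.ndarray, d: int, eta: float) -> float:
    """Normalized LKJ(eta) log density in canonical-partial-correlation
    coordinates: independent shifted Betas on (-1, 1)."""
    c = np.asarray(c, dtype=float)
    alpha = _lkj_alpha(d, eta)
    if np.any(np.abs(c) >= 1.0):
        return -np.inf
    lognorm = (2.0 * alpha - 1.0) * math.log(2.0) + betaln(alpha, alpha)
    return float(np.sum((alpha - 1.0) * np.log1p(-(c**2)) - lognorm))


def log_prior(params: Parameters, prior: PriorConfig = PriorConfig()) -> float:
    """Joint log prior density of a :class:`Parameters` realization.

    Fixed effects are Normal(0, beta_sd); random-effect scales are
    Exponential(sigma_rate); correlation matrices follow LKJ(lkj_eta),
    evaluated in the canonical-partial-correlation parameterization; the
    non-centered innovations ``z`` are standard normal.
    """
    beta = np.asarray(params.beta, dtype=float)
    lp = float(
        -0.5 * np.sum(beta**2) / prior.beta_sd**2
        - beta.size * (math.log(prior.beta_sd) + 0.5 * math.log(2 * math.pi))
    )
    for sigma in (params.sigma_individual, params.sigma_society):
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0):
            return -np.inf
        lp += float(
            np.sum(math.log(prior.sigma_rate) - prior.sigma_rate * sigma)
        )
    for corr in (params.corr_individual, params.corr_society):
        d = corr.shape[0]
        c = np.tanh(unconstrained_from_corr(corr))
        lp += lkj_logpdf_canonical(c, d, prior.lkj_eta)
    for z in (params.z_individual, params.z_society):
        z = np.asarray(z, dtype=float)
        lp += float(-0.5 * np.sum(z**2) - z.size * 0.5 * math.log(2 * math.pi))
    return lp


# --------------------------------------------------------------------------
# Unconstrained posterior with analytic gradient
# --------------------------------------------------------------------------


class MultinomialLogitPosterior:
    """Log posterior of the MMBM on the unconstrained scale.

    The likelihood is collapsed to per-child category counts (observations of
    one child share a linear predictor, so the categorical likelihood is a
    multinomial in the counts).  Parameter vector layout::

        beta (4*M) | log sigma_I (4) | log sigma_S (4) | y_I (6) | y_S (6)
        | z_S (S*4) | z_I (C*4)

    The blocks before ``z_I`` are the "structural" coordinates; samplers may
    give them a dense mass matrix (see :attr:`dense_block_size`).

    With ``random_effects=False`` only the beta block is present, giving a
    plain fixed-effects multinomial regression.
    """

    def __init__(
        self,
        counts: np.ndarray,
        design: np.ndarray,
        society_index: np.ndarray,
        n_societies: int,
        prior: PriorConfig = PriorConfig(),
        random_effects: bool = True,
    ) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != N_CATEGORIES:
            raise ValueError("counts must be (n_children, 5)")
        if counts.sum() == 0:
            raise ValueError("dataset is empty: no observations")
        self.counts = counts
        self.design = np.asarray(design, dtype=float)
        self.society_index = np.asarray(society_index, dtype=int)
        self.n_children = counts.shape[0]
        self.n_societies = int(n_societies)
        self.n_terms = self.design.shape[1]
        self.prior = prior
        self.random_effects = bool(random_effects)
        self.d = N_CONTRASTS
        self._n_corr = self.d * (self.d - 1) // 2
        self._tril = _tril_indices(self.d)
        self._alpha = _lkj_alpha(self.d, prior.lkj_eta)
        self._row_totals = counts.sum(axis=1)
        self._counts4 = counts[:, :N_CONTRASTS]
        # Orthogonal rotation of the individual-innovation block whose leading
        # directions span the design columns.  The standard-normal prior is
        # rotation-invariant, so sampling v with z = Q v is the same model,
        # but the design-aligned components (which ride a posterior ridge
        # with beta) become leading coordinates that join the dense metric
        # block.
        if self.random_effects:
            self._Q = np.ascontiguousarray(np.linalg.qr(self.design, mode="complete")[0])
        else:
            self._Q = None
        self._soc_idx64 = np.ascontiguousarray(self.society_index, dtype=np.int64)
        self.design = np.ascontiguousarray(self.design)
        self._counts4 = np.ascontiguousarray(self._counts4)
        self._row_totals = np.ascontiguousarray(self._row_totals)

    # ---- layout -----------------------------------------------------------

    @property
    def n_params(self) -> int:
        n = self.d * self.n_terms
        if self.random_effects:
            n += 2 * self.d + 2 * self._n_corr
            n += self.d * (self.n_children + self.n_societies)
        return n

    @property
    def dense_block_size(self) -> int:
        """Leading coordinates (beta, scales, correlations, society effects,
        design-aligned individual components) whose posterior correlations
        warrant a dense mass matrix."""
        if not self.random_effects:
            return self.d * self.n_terms
        return (
            self.d * self.n_terms
            + 2 * self.d
            + 2 * self._n_corr
            + self.d * self.n_societies
            + self.d * self.n_terms
        )

    def _split(self, q: np.ndarray):
        d, M = self.d, self.n_terms
        beta = q[: d * M].reshape(d, M)
        if not self.random_effects:
            return beta, None, None, None, None, None, None
        k = d * M
        ls_i = q[k : k + d]
        ls_s = q[k + d : k + 2 * d]
        k += 2 * d
        y_i = q[k : k + self._n_corr]
        y_s = q[k + self._n_corr : k + 2 * self._n_corr]
        k += 2 * self._n_corr
        z_s = q[k : k + self.n_societies * d].reshape(self.n_societies, d)
        v_i = q[k + self.n_societies * d :].reshape(self.n_children, d)
        z_i = self._Q @ v_i
        return beta, ls_i, ls_s, y_i, y_s, z_i, z_s

    def unpack(self, q: np.ndarray) -> Parameters:
        """Constrained :class:`Parameters` from an unconstrained vector."""
        beta, ls_i, ls_s, y_i, y_s, z_i, z_s = self._split(np.asarray(q, float))
        if not self.random_effects:
            return Parameters(beta=beta.copy())
        L_i = corr_chol_from_unconstrained(y_i, self.d)
        L_s = corr_chol_from_unconstrained(y_s, self.d)
        return Parameters(
            beta=beta.copy(),
            sigma_individual=np.exp(ls_i),
            sigma_society=np.exp(ls_s),
            corr_individual=L_i @ L_i.T,
            corr_society=L_s @ L_s.T,
            z_individual=z_i.copy(),
            z_society=z_s.copy(),
        )

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        q = 0.5 * rng.uniform(-1.0, 1.0, size=self.n_params)
        return q

    # ---- density ----------------------------------------------------------

    def _chol_and_cache(self, y: np.ndarray):
        c = np.tanh(y)
        s2 = 1.0 - c**2
        d = self.d
        L = np.zeros((d, d))
        L[0, 0] = 1.0
        k = 0
        for i in range(1, d):
            pref = 1.0
            for j in range(i):
                L[i, j] = c[k] * pref
                pref *= math.sqrt(s2[k])
                k += 1
            L[i, i] = pref
        return L, c, s2

    def logp_and_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        """Log posterior density and its gradient at ``q``.

        Dispatches to a compiled kernel for the random-effects model; the
        pure-numpy reference path (`logp_and_grad_reference`) computes the
        same quantities and is cross-checked in the test suite.
        """
        if self.random_effects:
            return _logp_grad_re_fast(
                np.asarray(q, dtype=float),
                self._counts4,
                self._row_totals,
                self.design,
                self._soc_idx64,
                self.n_societies,
                self._Q,
                self._alpha,
                self.prior.beta_sd,
                self.prior.sigma_rate,
            )
        return self.logp_and_grad_reference(q)

    def logp_and_grad_reference(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        """Pure-numpy log posterior and gradient (reference path)."""
        q = np.asarray(q, dtype=float)
        beta, ls_i, ls_s, y_i, y_s, z_i, z_s = self._split(q)
        prior = self.prior
        d, M = self.d, self.n_terms

        eta = self.design @ beta.T
        if self.random_effects:
            sig_i = np.exp(ls_i)
            sig_s = np.exp(ls_s)
            L_i, c_i, s2_i = self._chol_and_cache(y_i)
            L_s, c_s, s2_s = self._chol_and_cache(y_s)
            A_i = sig_i[:, None] * L_i
            A_s = sig_s[:, None] * L_s
            nu_i = z_i @ A_i.T
            nu_s = z_s @ A_s.T
            eta = eta + nu_i + nu_s[self.society_index]

        # multinomial log-likelihood collapsed over children
        m = np.maximum(eta.max(axis=1), 0.0)
        lse = m + np.log(
            np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1)
        )
        loglik = float(np.sum(self._counts4 * eta) - self._row_totals @ lse)

        pi4 = np.exp(eta - lse[:, None])
        G = self._counts4 - self._row_totals[:, None] * pi4  # dloglik/deta

        grad = np.empty_like(q)
        # beta block: likelihood + Normal prior
        g_beta = G.T @ self.design - beta / prior.beta_sd**2
        grad[: d * M] = g_beta.ravel()
        logp = loglik - 0.5 * float(np.sum(beta**2)) / prior.beta_sd**2

        if not self.random_effects:
            return logp, grad

        # aggregate dloglik/deta by society
        G_soc = np.zeros((self.n_societies, d))
        np.add.at(G_soc, self.society_index, G)

        # priors on z
        logp += -0.5 * float(np.sum(z_i**2) + np.sum(z_s**2))
        # Exponential prior on sigma in log coordinates (incl. Jacobian)
        logp += float(np.sum(-prior.sigma_rate * sig_i + ls_i))
        logp += float(np.sum(-prior.sigma_rate * sig_s + ls_s))
        # LKJ prior in canonical coordinates incl. tanh Jacobian:
        # alpha*log(1-c^2) per entry
        logp += float(self._alpha @ np.log(s2_i) + self._alpha @ np.log(s2_s))

        k = d * M
        for (G_lvl, z, sig, L, c, s2, ls) in (
            (G, z_i, sig_i, L_i, c_i, s2_i, ls_i),
            (G_soc, z_s, sig_s, L_s, c_s, s2_s, ls_s),
        ):
            MM = G_lvl.T @ z  # d x d, dloglik/dA
            # sigma block (log coordinates): chain rule + Exponential prior
            g_sig = np.sum(MM * L, axis=1) * sig - prior.sigma_rate * sig + 1.0
            if G_lvl is G:
                grad[k : k + d] = g_sig
            else:
                grad[k + d : k + 2 * d] = g_sig
            _ = (z, ls)  # layout bookkeeping only

        # correlation blocks
        kc = d * M + 2 * d
        for idx, (G_lvl, z, sig, L, c, s2) in enumerate(
            ((G, z_i, sig_i, L_i, c_i, s2_i), (G_soc, z_s, sig_s, L_s, c_s, s2_s))
        ):
            MM = G_lvl.T @ z
            dL = MM * sig[:, None]  # dloglik/dL (lower triangle used)
            g_y = np.zeros(self._n_corr)
            pos = 0
            for i in range(1, d):
                row_start = pos
                # prefix products of s for this row
                pref = 1.0
                for j in range(i):
                    kk = row_start + j
                    gc = dL[i, j] * pref
                    # downstream entries in this row carry a factor s_ij
                    tail = 0.0
                    for j2 in range(j + 1, i):
                        tail += dL[i, j2] * L[i, j2]
                    tail += dL[i, i] * L[i, i]
                    gc += tail * (-c[kk] / s2[kk])
                    # LKJ + Jacobian term: alpha * log(1 - c^2)
                    gc += self._alpha[kk] * (-2.0 * c[kk] / s2[kk])
                    g_y[kk] = gc * s2[kk]  # dc/dy = 1 - c^2
                    pref *= math.sqrt(s2[kk])
                pos += i
            g_slice = slice(kc + idx * self._n_corr, kc + (idx + 1) * self._n_corr)
            grad[g_slice] = g_y

        # z blocks (society first: structural side of the layout)
        kz = d * M + 2 * d + 2 * self._n_corr
        g_vi = self._Q.T @ (G @ A_i - z_i)  # chain rule through z = Q v
        g_zs = G_soc @ A_s - z_s
        grad[kz : kz + self.n_societies * d] = g_zs.ravel()
        grad[kz + self.n_societies * d :] = g_vi.ravel()

        return logp, grad


    # ---- interweaving (ancillarity-sufficiency) update ---------------------

    def _level_cond_logp(self, ls, y, S, n_g):
        """log p(sigma, corr | nu) up to a constant, where nu are the
        realized random effects of one level with scatter S = nu.T @ nu.

        Given nu the likelihood is flat in (sigma, corr); the conditional is
        the multivariate-normal density of the n_g group effects times the
        priors (in unconstrained coordinates).
        """
        return float(
            _level_cond_logp_fast(
                np.ascontiguousarray(ls),
                np.ascontiguousarray(y),
                S,
                float(n_g),
                self._alpha,
                self.prior.sigma_rate,
            )
        )

    def _slice_update(self, x0, logp_fn, rng, w=0.5, max_steps=8):
        """Coordinate-wise univariate slice sampling (stepping out)."""
        x = x0.copy()
        lp = logp_fn(x)
        for i in rng.permutation(x.size):
            log_y = lp + np.log(rng.uniform())
            lo = x[i] - w * rng.uniform()
            hi = lo + w
            xi0 = x[i]
            for _ in range(max_steps):
                x[i] = lo
                if logp_fn(x) <= log_y:
                    break
                lo -= w
            for _ in range(max_steps):
                x[i] = hi
                if logp_fn(x) <= log_y:
                    break
                hi += w
            while True:
                x[i] = rng.uniform(lo, hi)
                lp_new = logp_fn(x)
                if lp_new > log_y:
                    lp = lp_new
                    break
                if x[i] < xi0:
                    lo = x[i]
                else:
                    hi = x[i]
                if hi - lo < 1e-12:
                    x[i] = xi0
                    lp = logp_fn(x)
                    break
        return x

    def interweave_update(self, q: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Resample (sigma, corr) from their conditional given the realized
        random effects, holding nu fixed, then back out the innovations.

        This ancillarity-sufficiency interweaving move breaks the slow ridge
        between the covariance parameters and the non-centered innovations:
        given nu the conditional of (sigma, corr) is sharp and cheap (no
        likelihood term), while the HMC step handles everything else.
        """
        if not self.random_effects:
            return q
        q = q.copy()
        d, M = self.d, self.n_terms
        k = d * M
        nc = self._n_corr
        slices = {
            "ls_i": slice(k, k + d),
            "ls_s": slice(k + d, k + 2 * d),
            "y_i": slice(k + 2 * d, k + 2 * d + nc),
            "y_s": slice(k + 2 * d + nc, k + 2 * d + 2 * nc),
        }
        kz = k + 2 * d + 2 * nc
        z_s = q[kz : kz + self.n_societies * d].reshape(self.n_societies, d)
        z_i = self._Q @ q[kz + self.n_societies * d :].reshape(self.n_children, d)
        for level, z, ls_key, y_key in (
            ("society", z_s, "ls_s", "y_s"),
            ("individual", z_i, "ls_i", "y_i"),
        ):
            ls = q[slices[ls_key]].copy()
            y = q[slices[y_key]].copy()
            sigma = np.exp(ls)
            L = corr_chol_from_unconstrained(y, d)
            A = sigma[:, None] * L
            nu = z @ A.T
            S = nu.T @ nu
            n_g = z.shape[0]
            x0 = np.concatenate([ls, y])

            def cond(x, S=S, n_g=n_g):
                return self._level_cond_logp(x[:d], x[d:], S, n_g)

            x1 = self._slice_update(x0, cond, rng)
            ls1, y1 = x1[:d], x1[d:]
            A1 = np.exp(ls1)[:, None] * corr_chol_from_unconstrained(y1, d)
            z_new = solve_triangular(A1, nu.T, lower=True).T
            q[slices[ls_key]] = ls1
            q[slices[y_key]] = y1
            if level == "society":
                q[kz : kz + self.n_societies * d] = z_new.ravel()
            else:
                q[kz + self.n_societies * d :] = (self._Q.T @ z_new).ravel()
        return q



# --------------------------------------------------------------------------
# Accelerated kernel (numba) for the random-effects log posterior + gradient
# --------------------------------------------------------------------------

def _logp_grad_re_py(q, counts4, row_tot, X, soc_idx, S, Q, alpha,
                     beta_sd, sigma_rate):
    """Random-effects log posterior and gradient; loop-oriented so the same
    source compiles under numba.  Must agree with the numpy reference path
    (checked by tests)."""
    C, M = X.shape
    d = 4
    ncorr = 6
    k = d * M
    beta = np.ascontiguousarray(q[:k]).reshape(d, M)
    ls_i = q[k : k + d]
    ls_s = q[k + d : k + 2 * d]
    y_i = q[k + 2 * d : k + 2 * d + ncorr]
    y_s = q[k + 2 * d + ncorr : k + 2 * d + 2 * ncorr]
    # out-of-support guard: extreme scales or correlations underflow the
    # transform; report -inf so the sampler rejects the point
    for kk in range(d):
        if abs(ls_i[kk]) > 40.0 or abs(ls_s[kk]) > 40.0:
            return -np.inf, np.zeros(q.shape[0])
    for m2 in range(ncorr):
        if abs(y_i[m2]) > 18.0 or abs(y_s[m2]) > 18.0:
            return -np.inf, np.zeros(q.shape[0])
    kz = k + 2 * d + 2 * ncorr
    z_s = np.ascontiguousarray(q[kz : kz + S * d]).reshape(S, d)
    v_i = np.ascontiguousarray(q[kz + S * d :]).reshape(C, d)
    z_i = Q @ v_i

    sig_i = np.exp(ls_i)
    sig_s = np.exp(ls_s)
    c_i = np.tanh(y_i)
    c_s = np.tanh(y_s)
    s2_i = 1.0 - c_i**2
    s2_s = 1.0 - c_s**2

    L_i = np.zeros((d, d))
    L_s = np.zeros((d, d))
    for (L, c) in ((L_i, c_i), (L_s, c_s)):
        L[0, 0] = 1.0
        kk = 0
        for i in range(1, d):
            pref = 1.0
            for j in range(i):
                L[i, j] = c[kk] * pref
                pref *= math.sqrt(1.0 - c[kk] ** 2)
                kk += 1
            L[i, i] = pref
    A_i = np.empty((d, d))
    A_s = np.empty((d, d))
    for i in range(d):
        for j in range(d):
            A_i[i, j] = sig_i[i] * L_i[i, j]
            A_s[i, j] = sig_s[i] * L_s[i, j]

    eta = X @ np.ascontiguousarray(beta.T)
    nu_i = z_i @ np.ascontiguousarray(A_i.T)
    nu_s = z_s @ np.ascontiguousarray(A_s.T)
    for i in range(C):
        j = soc_idx[i]
        for kk in range(d):
            eta[i, kk] += nu_i[i, kk] + nu_s[j, kk]

    loglik = 0.0
    G = np.empty((C, d))
    for i in range(C):
        m = 0.0
        for kk in range(d):
            if eta[i, kk] > m:
                m = eta[i, kk]
        ssum = math.exp(-m)
        for kk in range(d):
            ssum += math.exp(eta[i, kk] - m)
        lse = m + math.log(ssum)
        for kk in range(d):
            pi = math.exp(eta[i, kk] - lse)
            G[i, kk] = counts4[i, kk] - row_tot[i] * pi
            loglik += counts4[i, kk] * eta[i, kk]
        loglik -= row_tot[i] * lse

    grad = np.zeros(q.shape[0])
    # beta block
    gb = G.T @ X
    sbeta2 = 0.0
    for i in range(d):
        for j in range(M):
            grad[i * M + j] = gb[i, j] - beta[i, j] / beta_sd**2
            sbeta2 += beta[i, j] ** 2
    logp = loglik - 0.5 * sbeta2 / beta_sd**2

    # z priors (v has the same norm as z under the orthogonal rotation)
    sz = 0.0
    for i in range(C):
        for kk in range(d):
            sz += v_i[i, kk] ** 2
    for j in range(S):
        for kk in range(d):
            sz += z_s[j, kk] ** 2
    logp -= 0.5 * sz
    # sigma priors in log coordinates
    for kk in range(d):
        logp += -sigma_rate * sig_i[kk] + ls_i[kk]
        logp += -sigma_rate * sig_s[kk] + ls_s[kk]
    # LKJ + tanh Jacobian in canonical coordinates
    for m2 in range(ncorr):
        logp += alpha[m2] * math.log(s2_i[m2]) + alpha[m2] * math.log(s2_s[m2])

    G_soc = np.zeros((S, d))
    for i in range(C):
        j = soc_idx[i]
        for kk in range(d):
            G_soc[j, kk] += G[i, kk]

    M_i = G.T @ z_i
    M_s = G_soc.T @ z_s
    # sigma gradients
    for kk in range(d):
        dsig = 0.0
        for l in range(d):
            dsig += M_i[kk, l] * L_i[kk, l]
        grad[k + kk] = dsig * sig_i[kk] - sigma_rate * sig_i[kk] + 1.0
        dsig = 0.0
        for l in range(d):
            dsig += M_s[kk, l] * L_s[kk, l]
        grad[k + d + kk] = dsig * sig_s[kk] - sigma_rate * sig_s[kk] + 1.0
    # correlation gradients
    for lev in range(2):
        if lev == 0:
            MM, sig, L, c, s2 = M_i, sig_i, L_i, c_i, s2_i
            off = k + 2 * d
        else:
            MM, sig, L, c, s2 = M_s, sig_s, L_s, c_s, s2_s
            off = k + 2 * d + ncorr
        pos = 0
        for i in range(1, d):
            pref = 1.0
            for j in range(i):
                kk = pos + j
                gc = MM[i, j] * sig[i] * pref
                tail = 0.0
                for j2 in range(j + 1, i):
                    tail += MM[i, j2] * sig[i] * L[i, j2]
                tail += MM[i, i] * sig[i] * L[i, i]
                gc += tail * (-c[kk] / s2[kk])
                gc += alpha[kk] * (-2.0 * c[kk] / s2[kk])
                grad[off + kk] = gc * s2[kk]
                pref *= math.sqrt(s2[kk])
            pos += i
    # z blocks
    g_zi = G @ A_i
    for i in range(C):
        for kk in range(d):
            g_zi[i, kk] -= z_i[i, kk]
    g_vi = Q.T @ g_zi
    for j in range(S):
        for kk in range(d):
            grad[kz + j * d + kk] = 0.0
            gz = -z_s[j, kk]
            for l in range(d):
                gz += G_soc[j, l] * A_s[l, kk]
            grad[kz + j * d + kk] = gz
    base = kz + S * d
    for i in range(C):
        for kk in range(d):
            grad[base + i * d + kk] = g_vi[i, kk]
    return logp, grad


def _level_cond_logp_py(ls, y, S, n_g, alpha, sigma_rate):
    """log p(sigma, corr | nu) up to a constant for one random-effect level
    (scatter S = nu.T @ nu); loop-oriented so the same source compiles under
    numba."""
    d = 4
    for kk in range(d):
        if abs(ls[kk]) > 20.0:
            return -np.inf
    for m2 in range(6):
        if abs(y[m2]) > 20.0:
            return -np.inf
    sigma = np.exp(ls)
    c = np.tanh(y)
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    kk = 0
    for i in range(1, d):
        pref = 1.0
        for j in range(i):
            L[i, j] = c[kk] * pref
            pref *= math.sqrt(1.0 - c[kk] ** 2)
            kk += 1
        L[i, i] = pref
    A = np.empty((d, d))
    for i in range(d):
        for j in range(d):
            A[i, j] = sigma[i] * L[i, j]
    # forward-substitute B = A^{-1} (lower triangular)
    B = np.zeros((d, d))
    for i in range(d):
        B[i, i] = 1.0 / A[i, i]
        for j in range(i):
            acc = 0.0
            for l in range(j, i):
                acc += A[i, l] * B[l, j]
            B[i, j] = -acc / A[i, i]
    quad = 0.0
    BS = B @ S
    for i in range(d):
        for j in range(d):
            quad += BS[i, j] * B[i, j]
    logdet_half = 0.0
    for i in range(d):
        logdet_half += math.log(A[i, i])
    lp = -n_g * logdet_half - 0.5 * quad
    for kk in range(d):
        lp += -sigma_rate * sigma[kk] + ls[kk]
    for m2 in range(6):
        lp += alpha[m2] * math.log(1.0 - c[m2] ** 2)
    return lp


if njit is not None:
    _logp_grad_re_fast = njit(cache=True)(_logp_grad_re_py)
    _level_cond_logp_fast = njit(cache=True)(_level_cond_logp_py)
else:  # pragma: no cover
    _logp_grad_re_fast = _logp_grad_re_py
    _level_cond_logp_fast = _level_cond_logp_py


def make_spec_with_terms(fixed_effects: tuple[str, ...], model_id: int = 0) -> ModelSpec:
    """Convenience constructor for ad-hoc term lists (e.g. sensitivity runs)."""
    return ModelSpec(model_id=model_id, fixed_effects=tuple(fixed_effects))
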