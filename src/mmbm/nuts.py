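"""No-U-Turn sampler with a block mass matrix (dense head, diagonal tail).

A self-contained dynamic Hamiltonian Monte Carlo implementation in the style
of Stan's default sampler: multinomial sampling over trajectories grown by
iterative doubling, a u-turn termination criterion, dual-averaging step-size
adaptation towards a target acceptance statistic, and windowed estimation of
the metric during warmup.

Hierarchical regression posteriors concentrate their awkward correlations in
a modest number of structural coordinates (fixed effects, scales,
correlation parameters, group effects) while the many latent innovations are
nearly independent; the metric therefore supports a dense block over the
leading ``dense_size`` coordinates and a diagonal for the rest.

The sampler consumes any callable ``logp_and_grad(q) -> (float, ndarray)``;
it knows nothing about the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_DIVERGENCE_THRESHOLD = 1000.0  # energy error that flags a divergence


class Metric:
    """Inverse mass matrix: dense over the first ``dense_size`` coordinates,
    diagonal over the remainder."""

    def __init__(self, dim: int, dense_size: int = 0):
        self.dim = dim
        self.dense_size = min(dense_size, dim)
        self.diag = np.ones(dim - self.dense_size)
        if self.dense_size:
            self.set_dense(np.eye(self.dense_size))
        else:
            self._sigma = None
            self._chol = None

    def set_dense(self, sigma: np.ndarray) -> None:
        """Set the dense block of the *inverse* metric (a covariance)."""
        self._sigma = sigma
        self._chol = np.linalg.cholesky(sigma)

    def apply(self, p: np.ndarray) -> np.ndarray:
        """M^{-1} p."""
        out = np.empty_like(p)
        k = self.dense_size
        if k:
            out[:k] = self._sigma @ p[:k]
        out[k:] = self.diag * p[k:]
        return out

    def draw_momentum(self, rng: np.random.Generator) -> np.ndarray:
        """p ~ Normal(0, M)."""
        xi = rng.standard_normal(self.dim)
        p = np.empty(self.dim)
        k = self.dense_size
        if k:
            # cov(p) = L^{-T} L^{-1} = Sigma^{-1} = M_dense
            p[:k] = np.linalg.solve(self._chol.T, xi[:k])
        p[k:] = xi[k:] / np.sqrt(self.diag)
        return p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ self.apply(p))


@dataclass
class _Tree:
    q_minus: np.ndarray
    p_minus: np.ndarray
    g_minus: np.ndarray
    q_plus: np.ndarray
    p_plus: np.ndarray
    g_plus: np.ndarray
    q_prop: np.ndarray
    logp_prop: float
    g_prop: np.ndarray
    log_weight: float
    sum_metro: float
    n_steps: int
    divergent: bool
    turning: bool


def _leapfrog(logp_and_grad, q, p, g, eps, metric):
    p = p + 0.5 * eps * g
    q = q + eps * metric.apply(p)
    logp, g = logp_and_grad(q)
    p = p + 0.5 * eps * g
    return q, p, g, logp


def _is_turning(q_minus, q_plus, p_minus, p_plus, metric, sign=1.0):
    # dq must be the chronological displacement; for subtrees grown backwards
    # in time (eps < 0) the build order is reversed, hence the sign.
    dq = sign * (q_plus - q_minus)
    return (dq @ metric.apply(p_minus) < 0.0) or (dq @ metric.apply(p_plus) < 0.0)


def _build_tree(logp_and_grad, q, p, g, depth, eps, metric, h0, rng):
    if depth == 0:
        q1, p1, g1, logp1 = _leapfrog(logp_and_grad, q, p, g, eps, metric)
        if not np.isfinite(logp1):
            h1 = np.inf
        else:
            h1 = -logp1 + metric.kinetic(p1)
        err = h1 - h0
        divergent = (not np.isfinite(err)) or err > _DIVERGENCE_THRESHOLD
        log_weight = -np.inf if divergent else -err
        metro = 0.0 if divergent else min(1.0, float(np.exp(-err)))
        return _Tree(
            q1, p1, g1, q1, p1, g1, q1, logp1, g1, log_weight, metro, 1,
            divergent, False,
        )
    left = _build_tree(logp_and_grad, q, p, g, depth - 1, eps, metric, h0, rng)
    if left.divergent or left.turning:
        return left
    right = _build_tree(
        logp_and_grad,
        left.q_plus,
        left.p_plus,
        left.g_plus,
        depth - 1,
        eps,
        metric,
        h0,
        rng,
    )
    sum_metro = left.sum_metro + right.sum_metro
    n_steps = left.n_steps + right.n_steps
    if right.divergent or right.turning:
        left.sum_metro, left.n_steps = sum_metro, n_steps
        left.divergent = right.divergent
        left.turning = right.turning
        return left
    total = np.logaddexp(left.log_weight, right.log_weight)
    take_right = np.log(rng.uniform()) < right.log_weight - total
    winner = right if take_right else left
    turning = _is_turning(
        left.q_minus,
        right.q_plus,
        left.p_minus,
        right.p_plus,
        metric,
        sign=1.0 if eps > 0 else -1.0,
    )
    return _Tree(
        left.q_minus,
        left.p_minus,
        left.g_minus,
        right.q_plus,
        right.p_plus,
        right.g_plus,
        winner.q_prop,
        winner.logp_prop,
        winner.g_prop,
        total,
        sum_metro,
        n_steps,
        False,
        turning,
    )


def _nuts_step(logp_and_grad, q, logp, g, eps, metric, rng, max_treedepth):
    p = metric.draw_momentum(rng)
    h0 = -logp + metric.kinetic(p)
    q_minus = q_plus = q
    p_minus = p_plus = p
    g_minus = g_plus = g
    q_cur, logp_cur, g_cur = q, logp, g
    log_weight = 0.0  # weight of the initial point relative to itself
    sum_metro = 0.0
    n_steps = 0
    divergent = False
    for _depth in range(max_treedepth):
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(
                logp_and_grad, q_plus, p_plus, g_plus, _depth, eps, metric, h0, rng
            )
            if not (sub.divergent or sub.turning):
                q_plus, p_plus, g_plus = sub.q_plus, sub.p_plus, sub.g_plus
        else:
            sub = _build_tree(
                logp_and_grad,
                q_minus,
                p_minus,
                g_minus,
                _depth,
                -eps,
                metric,
                h0,
                rng,
            )
            if not (sub.divergent or sub.turning):
                q_minus, p_minus, g_minus = sub.q_plus, sub.p_plus, sub.g_plus
        sum_metro += sub.sum_metro
        n_steps += sub.n_steps
        if sub.divergent:
            divergent = True
            break
        if sub.turning:
            break
        # biased progressive sampling towards the new subtree
        if np.log(rng.uniform()) < sub.log_weight - log_weight:
            q_cur, logp_cur, g_cur = sub.q_prop, sub.logp_prop, sub.g_prop
        log_weight = np.logaddexp(log_weight, sub.log_weight)
        if _is_turning(q_minus, q_plus, p_minus, p_plus, metric):
            break
    accept_stat = sum_metro / max(n_steps, 1)
    return q_cur, logp_cur, g_cur, accept_stat, divergent, n_steps


def _find_reasonable_step_size(logp_and_grad, q, logp, g, metric, rng):
    eps = 1.0
    p = metric.draw_momentum(rng)
    h0 = -logp + metric.kinetic(p)

    def _h_after(eps):
        _, p1, _, logp1 = _leapfrog(logp_and_grad, q, p, g, eps, metric)
        return -logp1 + metric.kinetic(p1) if np.isfinite(logp1) else np.inf

    direction = 1 if (h0 - _h_after(eps)) > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        crossed = (h0 - _h_after(eps)) > np.log(0.5)
        if (direction == 1 and not crossed) or (direction == -1 and crossed):
            break
    return eps


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    def __init__(self, eps0, target=0.8, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_stat):
        self.count += 1
        frac = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return np.exp(self.log_eps)

    def restart(self, eps0):
        self.__init__(eps0, self.target, self.gamma, self.t0, self.kappa)


class _Welford:
    """Running mean/covariance: dense over the leading block, marginal
    variances over the rest."""

    def __init__(self, dim, dense_size):
        self.n = 0
        self.dense_size = dense_size
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)
        self.m2_dense = np.zeros((dense_size, dense_size))

    def update(self, x):
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        delta2 = x - self.mean
        self.m2 += delta * delta2
        k = self.dense_size
        if k:
            self.m2_dense += np.outer(delta[:k], delta2[:k])

    def variance(self):
        return self.m2 / max(self.n - 1, 1)

    def dense_covariance(self):
        return self.m2_dense / max(self.n - 1, 1)


def _adaptation_schedule(n_warmup, init_buffer=75, term_buffer=50, base_window=25):
    """Stan-style warmup schedule: returns (init_buffer, metric-window close
    iterations)."""
    if n_warmup < init_buffer + term_buffer + base_window:
        init_buffer = max(int(0.15 * n_warmup), 1)
        term_buffer = max(int(0.10 * n_warmup), 1)
        base_window = max(n_warmup - init_buffer - term_buffer, 1)
    boundaries = []
    start = init_buffer
    window = base_window
    while start + window <= n_warmup - term_buffer:
        end = start + window
        if end + 2 * window > n_warmup - term_buffer:
            end = n_warmup - term_buffer
        boundaries.append(end)
        start = end
        window *= 2
    if not boundaries:
        boundaries = [max(n_warmup - term_buffer, 1)]
    return init_buffer, boundaries


def _update_metric(metric, welford, dense_pool=None):
    n = welford.n
    if n < 5:
        return
    shrink = n / (n + 5.0)
    var = welford.variance()
    k = metric.dense_size
    metric.diag = shrink * var[k:] + 1e-3 * (1 - shrink)
    if not k:
        return
    if dense_pool is None or len(dense_pool) < k // 2:
        # intermediate windows: diagonal scaling in the dense slot
        metric.set_dense(np.diag(shrink * var[:k] + 1e-3 * (1 - shrink)))
        return
    # final window: shrunk (Ledoit-Wolf) covariance from pooled warmup draws
    from sklearn.covariance import LedoitWolf

    cov = LedoitWolf().fit(np.asarray(dense_pool)[:, :k]).covariance_
    try:
        metric.set_dense(cov + 1e-6 * np.eye(k))
    except np.linalg.LinAlgError:
        metric.set_dense(np.diag(shrink * var[:k] + 1e-3 * (1 - shrink)))


def sample(
    logp_and_grad,
    q0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    dense_size: int = 0,
    interleave=None,
    interleave_every: int = 1,
) -> dict:
    """Run one NUTS chain; returns post-warmup draws and diagnostics.

    Returned dict keys: ``draws`` (n_draws, dim), ``logp`` (n_draws,),
    ``divergences`` (count, post-warmup only), ``accept_stat`` (mean,
    post-warmup), ``step_size``, ``metric``, ``treedepth_steps``.

    ``interleave``, if given, is a callable ``(q, rng) -> q`` applied after
    every ``interleave_every``-th iteration; it must leave the target
    invariant (e.g. a Gibbs or interweaving move).
    """
    q = np.array(q0, dtype=float)
    logp, g = logp_and_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial position has non-finite log probability")
    metric = Metric(q.size, dense_size)
    eps = _find_reasonable_step_size(logp_and_grad, q, logp, g, metric, rng)
    da = _DualAveraging(eps, target=target_accept)
    init_buffer, boundaries = _adaptation_schedule(n_warmup)
    welford = _Welford(q.size, metric.dense_size)
    boundary_set = set(boundaries)
    last_boundary = max(boundaries)
    dense_pool: list[np.ndarray] = []

    for it in range(n_warmup):
        q, logp, g, astat, _div, _ = _nuts_step(
            logp_and_grad, q, logp, g, eps, metric, rng, max_treedepth
        )
        if interleave is not None and it % interleave_every == 0:
            q = interleave(q, rng)
            logp, g = logp_and_grad(q)
        eps = da.update(astat)
        if it >= init_buffer:
            welford.update(q)
            if metric.dense_size:
                dense_pool.append(q.copy())
        if (it + 1) in boundary_set:
            _update_metric(
                metric,
                welford,
                dense_pool if (it + 1) == last_boundary else None,
            )
            welford = _Welford(q.size, metric.dense_size)
            eps = _find_reasonable_step_size(logp_and_grad, q, logp, g, metric, rng)
            da.restart(eps)
    if n_warmup > 0:
        eps = float(np.exp(da.log_eps_bar))

    draws = np.empty((n_draws, q.size))
    logps = np.empty(n_draws)
    divergences = 0
    accept_sum = 0.0
    steps_total = 0
    for it in range(n_draws):
        q, logp, g, astat, div, nsteps = _nuts_step(
            logp_and_grad, q, logp, g, eps, metric, rng, max_treedepth
        )
        if interleave is not None and it % interleave_every == 0:
            q = interleave(q, rng)
            logp, g = logp_and_grad(q)
        draws[it] = q
        logps[it] = logp
        divergences += int(div)
        accept_sum += astat
        steps_total += nsteps
    return {
        "draws": draws,
        "logp": logps,
        "divergences": divergences,
        "accept_stat": accept_sum / max(n_draws, 1),
        "step_size": eps,
        "metric": metric,
        "treedepth_steps": steps_total,
    }
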