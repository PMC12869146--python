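"""BYM Poisson spatial regression fitted by Metropolis-within-Gibbs MCMC.

The model is the Besag-York-Mollié convolution model for small-area counts:

    Y_i ~ Poisson(E_i * exp(eta_i)),   eta_i = beta0 + x_i' beta + u_i + v_i

where ``E_i`` is the area population entering as a log offset, ``u`` is a
spatially structured random effect with an intrinsic conditional
autoregressive (ICAR) prior over the queen-contiguity graph, and ``v`` is an
unstructured iid normal effect.  The ICAR prior is improper; identifiability
is restored by constraining ``u`` to sum to zero within every connected
component of the graph.  Precisions tau_u, tau_v carry Gamma hyperpriors and
are updated by conjugate Gibbs steps; ``beta0, beta`` by a random-walk block
update; each ``u_i``/``v_i`` by single-site random-walk Metropolis steps
(vectorised over colour classes of the graph so sites updated together are
conditionally independent).

A brute-force grid-integration oracle over toy panels (<= 4 free parameters)
serves as the correctness reference for the sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import gammaln

from .geo_adjacency import AdjacencyMatrix, ComponentLabels, connected_components

RURALITY_CLASSES = ("city", "suburban_town", "rural")


# ---------------------------------------------------------------------------
# Data containers

@dataclass
class AreaYearPanel:
    """Per-area outcome counts, offsets and covariates for one study year.

    ``y`` is the outcome count (unique telehealth patients by default),
    ``offset`` the area population (the exposure E_i), ``X`` the n x p matrix
    of standardized covariates.  ``truth`` optionally stores the simulation
    parameters that generated the panel, for parameter-recovery tests.
    """

    area_ids: list[str]
    y: np.ndarray
    offset: np.ndarray
    X: np.ndarray
    covariate_names: tuple[str, ...]
    year: int | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.offset = np.asarray(self.offset, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.size == 0:
            self.X = self.X.reshape(len(self.area_ids), 0)
        n = len(self.area_ids)
        if self.y.shape != (n,) or self.offset.shape != (n,):
            raise ValueError("y and offset must have one entry per area")
        if np.any(self.y < 0) or not np.issubdtype(self.y.dtype, np.integer):
            raise ValueError("y must be nonnegative integer counts")
        if np.any(self.offset < 1):
            raise ValueError("offset (population) must be >= 1 everywhere")
        if self.X.shape != (n, len(self.covariate_names)):
            raise ValueError(
                f"X has shape {self.X.shape}, expected ({n}, {len(self.covariate_names)})"
            )

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def subset_covariates(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.covariate_names.index(nm) for nm in names]
        return self.X[:, idx]


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates and random-effect components a model includes.

    The study's comparison ladder: a crude model (density only, unstructured
    effect), a crude spatial model (density only, both effects) and a fully
    adjusted spatial model (all covariates, both effects).
    """

    covariate_names: tuple[str, ...] = ()
    include_structured: bool = True
    include_unstructured: bool = True
    name: str = "model"


@dataclass(frozen=True)
class Priors:
    """Prior hyperparameters.

    ``beta_prec``: precision of the independent normal priors on beta0 and
    beta (default 1e-4, effectively vague on standardized covariates).
    ``tau_shape``/``tau_rate``: Gamma(shape, rate) hyperprior on each of
    tau_u and tau_v (default Gamma(1, 0.0005), a common convolution-model
    default).
    """

    beta_prec: float = 1e-4
    tau_shape: float = 1.0
    tau_rate: float = 5e-4

    def __post_init__(self) -> None:
        if min(self.beta_prec, self.tau_shape, self.tau_rate) <= 0:
            raise ValueError("all prior hyperparameters must be strictly positive")


@dataclass(frozen=True)
class McmcConfig:
    n_iterations: int = 6000
    n_burnin: int = 2000
    thin: int = 1
    seed: int = 0
    proposal_scales: Mapping[str, float] = field(
        default_factory=lambda: {"beta": 0.1, "u": 0.5, "v": 0.5}
    )
    adapt_during_burnin: bool = True

    def __post_init__(self) -> None:
        if not (self.n_iterations > self.n_burnin >= 0):
            raise ValueError("need n_iterations > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if any(s <= 0 for s in self.proposal_scales.values()):
            raise ValueError("proposal scales must be positive")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus bookkeeping.

    Arrays are indexed (draw,) or (draw, dimension); ``tau_u``/``tau_v`` are
    NaN when the corresponding random-effect component is excluded from the
    model.
    """

    beta0: np.ndarray
    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    tau_u: np.ndarray
    tau_v: np.ndarray
    log_likelihood: np.ndarray
    covariate_names: tuple[str, ...]
    component_labels: np.ndarray
    acceptance_rates: dict[str, float]
    proposal_scales: dict[str, float]
    spec: ModelSpec | None = None

    @property
    def n_draws(self) -> int:
        return len(self.beta0)

    def to_long_frame(self):
        """Long-format (iteration, parameter, value) pandas DataFrame."""
        import pandas as pd

        rows = {"beta0": self.beta0}
        for k, nm in enumerate(self.covariate_names):
            rows[f"beta[{nm}]"] = self.beta[:, k]
        rows["tau_u"] = self.tau_u
        rows["tau_v"] = self.tau_v
        rows["log_likelihood"] = self.log_likelihood
        frames = []
        for name, vals in rows.items():
            frames.append(
                pd.DataFrame(
                    {"iteration": np.arange(self.n_draws), "parameter": name, "value": vals}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> dict:
        def _stats(x):
            x = x[np.isfinite(x)]
            if x.size == 0:
                return None
            return {
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                "q2.5": float(np.quantile(x, 0.025)),
                "q97.5": float(np.quantile(x, 0.975)),
            }

        out = {"beta0": _stats(self.beta0)}
        for k, nm in enumerate(self.covariate_names):
            out[f"beta[{nm}]"] = _stats(self.beta[:, k])
        out["tau_u"] = _stats(self.tau_u)
        out["tau_v"] = _stats(self.tau_v)
        out["acceptance_rates"] = self.acceptance_rates
        return out


# ---------------------------------------------------------------------------
# Log densities

def log_likelihood(
    panel: AreaYearPanel,
    beta0: float,
    beta: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    X: np.ndarray | None = None,
) -> float:
    """Poisson log likelihood with log-population offset.

    sum_i [ Y_i eta_i + Y_i log E_i - E_i exp(eta_i) - log(Y_i!) ],
    eta_i = beta0 + x_i' beta + u_i + v_i.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (np.isfinite(beta0) and np.all(np.isfinite(beta))
            and np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite parameter passed to log_likelihood")
    Xm = panel.X if X is None else X
    eta = beta0 + (Xm @ beta if Xm.shape[1] else 0.0) + u + v
    E = panel.offset
    y = panel.y
    return float(np.sum(y * eta + y * np.log(E) - E * np.exp(eta) - gammaln(y + 1)))


def pairwise_difference_sum(u: np.ndarray, adjacency: AdjacencyMatrix) -> float:
    """sum over unordered neighbour pairs of (u_i - u_j)^2."""
    ei, ej = adjacency.edge_arrays()
    if ei.size == 0:
        return 0.0
    d = u[ei] - u[ej]
    return float(d @ d)


def log_icar_prior(
    u,
    tau_u: float,
    adjacency: AdjacencyMatrix,
    components: ComponentLabels | None = None,
    constraint_tol: float = 1e-6,
) -> float:
    """ICAR log density up to an additive constant.

    ((n - c)/2) log(tau_u) - (tau_u/2) * sum_{i~j} (u_i - u_j)^2, with c the
    number of graph components; requires ``u`` to sum to zero within each
    component (the identifiability constraint).
    """
    vals = np.asarray(getattr(u, "values", u), dtype=float)
    if tau_u <= 0:
        raise ValueError("tau_u must be positive")
    comps = components or connected_components(adjacency)
    for c in range(comps.n_components):
        s = vals[comps.members(c)].sum()
        if abs(s) > constraint_tol:
            raise ValueError(
                f"sum-to-zero constraint violated in component {c}: sum={s:.3g}"
            )
    n, c = adjacency.n_areas, comps.n_components
    return ((n - c) / 2.0) * np.log(tau_u) - (tau_u / 2.0) * pairwise_difference_sum(
        vals, adjacency
    )


def tau_u_full_conditional(
    u: np.ndarray, adjacency: AdjacencyMatrix, priors: Priors, n_components: int
) -> tuple[float, float]:
    """(shape, rate) of the conjugate Gamma full conditional of tau_u:
    shape + (n - c)/2, rate + sum_{i~j}(u_i - u_j)^2 / 2."""
    n = adjacency.n_areas
    return (
        priors.tau_shape + (n - n_components) / 2.0,
        priors.tau_rate + pairwise_difference_sum(u, adjacency) / 2.0,
    )


def tau_v_full_conditional(v: np.ndarray, priors: Priors) -> tuple[float, float]:
    """(shape, rate) of the conjugate Gamma full conditional of tau_v:
    shape + n/2, rate + sum v^2 / 2."""
    v = np.asarray(v, dtype=float)
    return (priors.tau_shape + len(v) / 2.0, priors.tau_rate + float(v @ v) / 2.0)


# ---------------------------------------------------------------------------
# The sampler

def _graph_coloring(adjacency: AdjacencyMatrix) -> list[np.ndarray]:
    """Partition areas into independent sets (no edge inside a set).

    Sites in the same colour class are conditionally independent under the
    ICAR prior, so their single-site Metropolis updates can be carried out
    simultaneously with vectorised accept/reject.
    """
    g = nx.Graph()
    g.add_nodes_from(range(adjacency.n_areas))
    g.add_edges_from(adjacency.pairs)
    coloring = nx.greedy_color(g, strategy="largest_first")
    n_colors = 1 + max(coloring.values()) if coloring else 1
    return [
        np.array(sorted(i for i, c in coloring.items() if c == col), dtype=int)
        for col in range(n_colors)
    ]


def _recenter(u: np.ndarray, comps: ComponentLabels) -> float:
    """Subtract the per-component mean from u in place; return the overall
    (area-averaged) shift so the intercept can absorb it."""
    total = 0.0
    for c in range(comps.n_components):
        idx = comps.members(c)
        m = u[idx].mean()
        u[idx] -= m
        total += m * idx.size
    return total / len(u)


def fit_bym_poisson(
    panel: AreaYearPanel,
    adjacency: AdjacencyMatrix,
    spec: ModelSpec,
    priors: Priors = Priors(),
    mcmc: McmcConfig = McmcConfig(),
) -> PosteriorSamples:
    """Fit the BYM Poisson model by Metropolis-within-Gibbs.

    Update cycle per iteration: random-walk block update of (beta0, beta);
    single-site random-walk updates of every u_i (vectorised per graph
    colour) and v_i; conjugate Gibbs draws of tau_u ~ Gamma(shape +
    (n-c)/2, rate + S_u/2) with S_u the pairwise-difference sum, and tau_v ~
    Gamma(shape + n/2, rate + sum v^2 / 2); finally ``u`` is recentred to
    sum to zero per component, with beta0 absorbing the overall shift.

    Proposal scales adapt during burn-in toward ~0.44 acceptance for scalar
    sites (0.234 for the multivariate beta block) and are frozen afterwards.
    Fixed seeds give bit-identical output.
    """
    if panel.n_areas != adjacency.n_areas:
        raise ValueError(
            f"panel has {panel.n_areas} areas but adjacency has {adjacency.n_areas}"
        )
    X = panel.subset_covariates(spec.covariate_names)
    p = X.shape[1]
    if np.all(panel.y == 0) and p == 0:
        warnings.warn("all outcome counts are zero and no covariates requested; "
                      "the fit is prior-driven", UserWarning, stacklevel=2)

    comps = connected_components(adjacency)
    colors = _graph_coloring(adjacency) if spec.include_structured else []
    degrees = adjacency.degrees.astype(float)
    W = adjacency.to_sparse()
    ei, ej = adjacency.edge_arrays()
    n = panel.n_areas
    y = panel.y.astype(float)
    E = panel.offset
    logE = np.log(E)
    n_free_u = n - comps.n_components  # rank of the ICAR precision
    # degree-0 areas keep u_i = 0 (their singleton component forces it)
    active_u = degrees > 0
    # per-colour active sites and their rows of W, precomputed once
    color_blocks = [
        (idx, W[idx])
        for idx in (c[active_u[c]] for c in colors)
        if idx.size
    ]

    rng = np.random.default_rng(mcmc.seed)

    # initial state
    beta0 = float(np.log((y.sum() + 0.5) / E.sum()))
    beta = np.zeros(p)
    u = np.zeros(n)
    v = np.zeros(n)
    tau_u = 1.0
    tau_v = 1.0

    scales = {
        "beta": float(mcmc.proposal_scales.get("beta", 0.1)),
        "u": float(mcmc.proposal_scales.get("u", 0.5)),
        "v": float(mcmc.proposal_scales.get("v", 0.5)),
        "u_scale": float(mcmc.proposal_scales.get("u_scale", 0.3)),
        "shift": float(mcmc.proposal_scales.get("shift", 0.05)),
        "shift_u": float(mcmc.proposal_scales.get("shift_u", 0.05)),
    }
    ones_n = np.ones(n)
    xj_ss = [float(n)] + [float(X[:, k] @ X[:, k]) for k in range(p)]
    # component-centred covariates and their Laplacian quadratic forms,
    # used by the u-interweaving move
    centered_X = X.copy()
    for c in range(comps.n_components):
        idx = comps.members(c)
        if p:
            centered_X[idx] -= centered_X[idx].mean(axis=0)
    cLc = [
        float(np.sum((centered_X[ei, k] - centered_X[ej, k]) ** 2)) if ei.size else 0.0
        for k in range(p)
    ]
    mean_shift_X = [
        bool(np.max(np.abs(X[:, k] - centered_X[:, k])) > 1e-12) for k in range(p)
    ]
    target_beta = 0.44 if p == 0 else 0.234
    target_site = 0.44

    n_keep = (mcmc.n_iterations - mcmc.n_burnin) // mcmc.thin
    out_beta0 = np.empty(n_keep)
    out_beta = np.empty((n_keep, p))
    out_u = np.empty((n_keep, n))
    out_v = np.empty((n_keep, n))
    out_tau_u = np.full(n_keep, np.nan)
    out_tau_v = np.full(n_keep, np.nan)
    out_ll = np.empty(n_keep)

    acc_counts = {"beta": 0, "u": 0, "v": 0, "u_scale": 0, "shift": 0, "shift_u": 0}
    try_counts = {"beta": 0, "u": 0, "v": 0, "u_scale": 0, "shift": 0, "shift_u": 0}

    xb = X @ beta if p else np.zeros(n)
    # log-likelihood core: sum y*eta - E*exp(eta); the data-only constant
    # sum(y log E - log y!) is added back when draws are stored
    ll_const = float(np.sum(y * logE - gammaln(panel.y + 1)))

    def _ll_core(eta: np.ndarray) -> float:
        return float(y @ eta - E @ np.exp(eta))

    cur_ll = _ll_core(beta0 + xb + u + v)

    keep_idx = 0
    for it in range(mcmc.n_iterations):
        in_burnin = it < mcmc.n_burnin
        adapt_step = 1.0 / (1 + it) ** 0.6 if (in_burnin and mcmc.adapt_during_burnin) else 0.0

        # --- (beta0, beta) block random walk ---
        prop = rng.standard_normal(p + 1) * scales["beta"]
        b0_new = beta0 + prop[0]
        b_new = beta + prop[1:]
        xb_new = X @ b_new if p else xb
        ll_new = _ll_core(b0_new + xb_new + u + v)
        dprior = -0.5 * priors.beta_prec * (
            (b0_new ** 2 - beta0 ** 2) + float(b_new @ b_new - beta @ beta)
        )
        log_alpha = ll_new - cur_ll + dprior
        accepted = np.log(rng.random()) < log_alpha
        if accepted:
            beta0, beta, xb, cur_ll = b0_new, b_new, xb_new, ll_new
        if not in_burnin:
            acc_counts["beta"] += int(accepted)
            try_counts["beta"] += 1
        if adapt_step:
            scales["beta"] *= np.exp(adapt_step * (float(accepted) - target_beta))

        # --- structured effects u, one colour class at a time ---
        if spec.include_structured:
            acc_frac_sum = 0.0
            for idx, Wc in color_blocks:
                S = Wc.dot(u)  # neighbour sums; neighbours are other colours
                du = rng.standard_normal(idx.size) * scales["u"]
                u_old = u[idx]
                u_new = u_old + du
                base = np.exp(beta0 + xb[idx] + v[idx])
                dll = y[idx] * du - E[idx] * base * (np.exp(u_new) - np.exp(u_old))
                dpr = -0.5 * tau_u * (
                    degrees[idx] * (u_new ** 2 - u_old ** 2) - 2.0 * du * S
                )
                acc = np.log(rng.random(idx.size)) < (dll + dpr)
                u[idx[acc]] = u_new[acc]
                acc_frac_sum += acc.mean() * idx.size
                if not in_burnin:
                    acc_counts["u"] += int(acc.sum())
                    try_counts["u"] += idx.size
            n_active = int(active_u.sum())
            if adapt_step and n_active:
                scales["u"] *= np.exp(adapt_step * (acc_frac_sum / n_active - target_site))

        # --- translation moves: beta_j -> beta_j + delta with v -> v - delta*x_j
        # leaves eta (hence the likelihood) exactly invariant; only the v and
        # beta priors vote.  The conditional posterior of beta given (u, v) is
        # far narrower than its marginal, so the plain random walk above mixes
        # beta extremely slowly; these moves travel along the weakly
        # identified direction directly (an ASIS-style interweaving step). ---
        if spec.include_unstructured:
            n_shift_acc = 0
            for j in range(p + 1):
                xj = ones_n if j == 0 else X[:, j - 1]
                delta = rng.standard_normal() * scales["shift"]
                bj = beta0 if j == 0 else beta[j - 1]
                dpr = (
                    -0.5 * tau_v * (delta * delta * xj_ss[j] - 2.0 * delta * float(xj @ v))
                    - 0.5 * priors.beta_prec * ((bj + delta) ** 2 - bj ** 2)
                )
                if np.log(rng.random()) < dpr:
                    v -= delta * xj
                    if j == 0:
                        beta0 += delta
                    else:
                        beta[j - 1] += delta
                    n_shift_acc += 1
            # eta is unchanged by construction; refresh xb and cur_ll to keep
            # float bookkeeping exact
            if n_shift_acc:
                xb = X @ beta if p else xb
                cur_ll = _ll_core(beta0 + xb + u + v)
            if not in_burnin:
                acc_counts["shift"] += n_shift_acc
                try_counts["shift"] += p + 1
            if adapt_step:
                scales["shift"] *= np.exp(
                    adapt_step * (n_shift_acc / (p + 1) - target_site))

        # --- the same interweaving against u: beta_j -> beta_j + delta with
        # u -> u - delta*c_j, c_j the component-centred covariate (so the
        # sum-to-zero constraint is preserved); eta changes only by the
        # per-component means delta*(x_j - c_j), which is zero for
        # component-centred covariates ---
        if spec.include_structured and p:
            n_ushift_acc = 0
            for j in range(p):
                cj = centered_X[:, j]
                delta = rng.standard_normal() * scales["shift_u"]
                u_new = u - delta * cj
                if mean_shift_X[j]:  # eta shifts by per-component constants
                    ll_new = _ll_core(beta0 + xb + delta * X[:, j] + u_new + v)
                    dll = ll_new - cur_ll
                else:  # component-centred covariate: eta exactly invariant
                    dll = 0.0
                # ICAR prior change: -tau_u/2 (delta^2 c'Lc - 2 delta c'Lu)
                cLu = float(cj[ei] @ (u[ei] - u[ej]) - cj[ej] @ (u[ei] - u[ej])) \
                    if ei.size else 0.0
                dpr = -0.5 * tau_u * (delta * delta * cLc[j] - 2.0 * delta * cLu)
                bj = beta[j]
                dpr += -0.5 * priors.beta_prec * ((bj + delta) ** 2 - bj ** 2)
                if np.log(rng.random()) < (dll + dpr):
                    u = u_new
                    beta[j] += delta
                    n_ushift_acc += 1
            if n_ushift_acc:
                xb = X @ beta
                if any(mean_shift_X):
                    cur_ll = _ll_core(beta0 + xb + u + v)
            if not in_burnin:
                acc_counts["shift_u"] += n_ushift_acc
                try_counts["shift_u"] += p
            if adapt_step:
                scales["shift_u"] *= np.exp(
                    adapt_step * (n_ushift_acc / p - target_site))

        # --- joint rescaling of u: single-site moves change the field's
        # overall roughness only diffusively, which makes tau_u mix very
        # slowly; a multiplicative scale move u -> a*u (with Jacobian
        # (n-c) log a on the constrained subspace) fixes that ---
        if spec.include_structured and n_free_u > 0:
            log_a = rng.standard_normal() * scales["u_scale"]
            a = np.exp(log_a)
            eta_base = beta0 + xb + v
            s_u_cur = pairwise_difference_sum(u, adjacency)
            dll = float(y @ (a * u - u) - E @ (np.exp(eta_base + a * u)
                                               - np.exp(eta_base + u)))
            dpr = -0.5 * tau_u * (a * a - 1.0) * s_u_cur + n_free_u * log_a
            acc_scale = np.log(rng.random()) < (dll + dpr)
            if acc_scale:
                u *= a
            if not in_burnin:
                acc_counts["u_scale"] += int(acc_scale)
                try_counts["u_scale"] += 1
            if adapt_step:
                scales["u_scale"] *= np.exp(adapt_step * (float(acc_scale) - target_site))

        # --- unstructured effects v, all sites at once ---
        if spec.include_unstructured:
            dv = rng.standard_normal(n) * scales["v"]
            v_new = v + dv
            base = np.exp(beta0 + xb + u)
            dll = y * dv - E * base * (np.exp(v_new) - np.exp(v))
            dpr = -0.5 * tau_v * (v_new ** 2 - v ** 2)
            acc = np.log(rng.random(n)) < (dll + dpr)
            v[acc] = v_new[acc]
            if not in_burnin:
                acc_counts["v"] += int(acc.sum())
                try_counts["v"] += n
            if adapt_step:
                scales["v"] *= np.exp(adapt_step * (acc.mean() - target_site))

        # --- conjugate Gibbs updates of the precisions ---
        if spec.include_structured:
            shape_u, rate_u = tau_u_full_conditional(u, adjacency, priors,
                                                     comps.n_components)
            tau_u = rng.gamma(shape_u, 1.0 / rate_u)
        if spec.include_unstructured:
            shape_v, rate_v = tau_v_full_conditional(v, priors)
            tau_v = rng.gamma(shape_v, 1.0 / rate_v)

        # --- identifiability: recenter u, intercept absorbs the shift ---
        if spec.include_structured:
            shift = _recenter(u, comps)
            beta0 += shift

        cur_ll = _ll_core(beta0 + xb + u + v)

        if not in_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0 and keep_idx < n_keep:
            out_beta0[keep_idx] = beta0
            out_beta[keep_idx] = beta
            out_u[keep_idx] = u
            out_v[keep_idx] = v
            if spec.include_structured:
                out_tau_u[keep_idx] = tau_u
            if spec.include_unstructured:
                out_tau_v[keep_idx] = tau_v
            out_ll[keep_idx] = cur_ll + ll_const
            keep_idx += 1

    rates = {
        k: (acc_counts[k] / try_counts[k] if try_counts[k] else float("nan"))
        for k in acc_counts
    }
    return PosteriorSamples(
        beta0=out_beta0,
        beta=out_beta,
        u=out_u,
        v=out_v,
        tau_u=out_tau_u,
        tau_v=out_tau_v,
        log_likelihood=out_ll,
        covariate_names=tuple(spec.covariate_names),
        component_labels=comps.labels,
        acceptance_rates=rates,
        proposal_scales={k: float(s) for k, s in scales.items()},
        spec=spec,
    )


def convergence_diagnostics(samples: PosteriorSamples) -> dict[str, dict[str, float]]:
    """Split-chain potential scale reduction (R-hat) and effective sample size
    for the scalar parameters; intended for logging, not hard gating."""
    import arviz as az

    out: dict[str, dict[str, float]] = {}
    traces = {"beta0": samples.beta0}
    for k, nm in enumerate(samples.covariate_names):
        traces[f"beta[{nm}]"] = samples.beta[:, k]
    if np.all(np.isfinite(samples.tau_u)):
        traces["tau_u"] = samples.tau_u
    if np.all(np.isfinite(samples.tau_v)):
        traces["tau_v"] = samples.tau_v
    for name, x in traces.items():
        arr = x[np.newaxis, :]
        out[name] = {
            "rhat": float(az.rhat(arr)),
            "ess_bulk": float(az.ess(arr)),
        }
    return out


# ---------------------------------------------------------------------------
# Grid-integration oracle

@dataclass(frozen=True)
class GridSpec:
    """Regular evaluation grid: per-parameter (lower, upper, n_points)."""

    axes: Mapping[str, tuple[float, float, int]]

    def linspaces(self, names: Sequence[str]) -> list[np.ndarray]:
        out = []
        for nm in names:
            lo, hi, k = self.axes[nm]
            if not (hi > lo and k >= 3):
                raise ValueError(f"bad grid axis for {nm!r}")
            out.append(np.linspace(lo, hi, int(k)))
        return out


@dataclass
class GridPosterior:
    param_names: tuple[str, ...]
    means: dict[str, float]
    variances: dict[str, float]
    u_mean: np.ndarray | None
    boundary_mass: dict[str, float]


def _sum_to_zero_basis(adjacency: AdjacencyMatrix, comps: ComponentLabels) -> np.ndarray:
    """Orthonormal basis (n x (n-c)) of the per-component sum-to-zero
    subspace, from Laplacian eigenvectors with positive eigenvalue."""
    n = adjacency.n_areas
    L = np.diag(adjacency.degrees.astype(float)) - adjacency.to_sparse().toarray()
    lam, vec = np.linalg.eigh(L)
    keep = lam > 1e-9 * max(1.0, lam.max())
    return vec[:, keep]


def grid_posterior_oracle(
    panel: AreaYearPanel,
    adjacency: AdjacencyMatrix,
    spec: ModelSpec,
    priors: Priors,
    grid: GridSpec,
    mass_tol: float = 1e-6,
    chunk: int = 200_000,
) -> GridPosterior:
    """Brute-force posterior summaries by numerical integration on a grid.

    Free parameters, in order: ``beta0``; one ``beta[<name>]`` per covariate
    in the spec; if the structured effect is included, coordinates
    ``w0..w{n-c-1}`` of u in an orthonormal sum-to-zero basis plus ``tau_u``;
    if the unstructured effect is included, ``v0..v{n-1}`` plus ``tau_v``.
    The total must stay small (intended for panels of <= 3 areas and <= 4
    free parameters).  Normalisation uses the trapezoid rule; if any axis
    carries more than ``mass_tol`` of posterior mass in its two boundary
    slabs a warning is emitted.
    """
    if panel.n_areas > 3:
        raise ValueError("the grid oracle is restricted to panels of <= 3 areas")
    comps = connected_components(adjacency)
    X = panel.subset_covariates(spec.covariate_names)
    p = X.shape[1]
    names: list[str] = ["beta0"] + [f"beta[{nm}]" for nm in spec.covariate_names]
    B = None
    if spec.include_structured:
        B = _sum_to_zero_basis(adjacency, comps)
        names += [f"w{k}" for k in range(B.shape[1])]
        names += ["tau_u"]
    if spec.include_unstructured:
        names += [f"v{k}" for k in range(panel.n_areas)]
        names += ["tau_v"]
    if len(names) > 4:
        raise ValueError(f"{len(names)} free parameters; the oracle supports at most 4")

    axes = grid.linspaces(names)
    shapes = [len(a) for a in axes]
    mesh = np.meshgrid(*axes, indexing="ij")
    theta = np.stack([m.ravel() for m in mesh], axis=1)  # (N, d)
    # trapezoid weights: product over axes of (h, with halved endpoints)
    w_axes = []
    for a in axes:
        h = a[1] - a[0]
        w = np.full(len(a), h)
        w[0] = w[-1] = h / 2
        w_axes.append(w)
    wmesh = np.meshgrid(*w_axes, indexing="ij")
    weights = np.ones(theta.shape[0])
    for wm in wmesh:
        weights *= wm.ravel()

    y = panel.y.astype(float)
    E = panel.offset
    lgamma_y = float(np.sum(gammaln(panel.y + 1) - y * np.log(E)))
    n, c = adjacency.n_areas, comps.n_components
    ei, ej = adjacency.edge_arrays()

    col = {nm: k for k, nm in enumerate(names)}
    logpost = np.empty(theta.shape[0])
    for start in range(0, theta.shape[0], chunk):
        t = theta[start:start + chunk]
        beta0 = t[:, col["beta0"]]
        eta = np.repeat(beta0[:, None], n, axis=1)
        lp = -0.5 * priors.beta_prec * beta0 ** 2
        for k, nm in enumerate(spec.covariate_names):
            b = t[:, col[f"beta[{nm}]"]]
            eta += b[:, None] * X[:, k][None, :]
            lp += -0.5 * priors.beta_prec * b ** 2
        if spec.include_structured:
            wcoord = np.stack(
                [t[:, col[f"w{k}"]] for k in range(B.shape[1])], axis=1
            )
            u = wcoord @ B.T  # (m, n)
            eta += u
            tau_u = t[:, col["tau_u"]]
            pair = np.sum((u[:, ei] - u[:, ej]) ** 2, axis=1) if ei.size else 0.0
            lp += ((n - c) / 2.0) * np.log(tau_u) - 0.5 * tau_u * pair
            lp += (priors.tau_shape - 1) * np.log(tau_u) - priors.tau_rate * tau_u
        if spec.include_unstructured:
            vmat = np.stack([t[:, col[f"v{k}"]] for k in range(n)], axis=1)
            eta += vmat
            tau_v = t[:, col["tau_v"]]
            lp += (n / 2.0) * np.log(tau_v) - 0.5 * tau_v * np.sum(vmat ** 2, axis=1)
            lp += (priors.tau_shape - 1) * np.log(tau_v) - priors.tau_rate * tau_v
        lp += np.sum(y[None, :] * eta - E[None, :] * np.exp(eta), axis=1) - lgamma_y
        logpost[start:start + chunk] = lp

    m = logpost.max()
    dens = np.exp(logpost - m) * weights
    Z = dens.sum()
    prob = dens / Z

    # boundary-mass check per axis
    grid_idx = np.unravel_index(np.arange(theta.shape[0]), shapes)
    boundary_mass = {}
    for k, nm in enumerate(names):
        edge = (grid_idx[k] == 0) | (grid_idx[k] == shapes[k] - 1)
        bm = float(prob[edge].sum())
        boundary_mass[nm] = bm
        if bm > mass_tol:
            warnings.warn(
                f"grid axis {nm!r} holds {bm:.2e} posterior mass on its boundary; "
                "widen the bounds", UserWarning, stacklevel=2)

    means = {nm: float(theta[:, k] @ prob) for k, nm in enumerate(names)}
    variances = {
        nm: float(((theta[:, k] - means[nm]) ** 2) @ prob) for k, nm in enumerate(names)
    }
    u_mean = None
    if spec.include_structured:
        w_mean = np.array([means[f"w{k}"] for k in range(B.shape[1])])
        u_mean = B @ w_mean
    return GridPosterior(
        param_names=tuple(names),
        means=means,
        variances=variances,
        u_mean=u_mean,
        boundary_mass=boundary_mass,
    )
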