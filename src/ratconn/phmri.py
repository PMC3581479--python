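"""Pharmacological-MRI response modelling.

The drug-induced BOLD response is a three-parameter gamma-variate

    f(t) = lam * g(t; alpha, beta),   g = gamma density (shape alpha, rate beta)

so total activation (area under the curve) equals the scale ``lam``
exactly and the peak occurs at ``(alpha - 1) / beta`` (alpha > 1).
Module contents:

* subject-level nonlinear least-squares fits (:func:`fit_subject_gamma`);
* a hierarchical Bayesian model with group-level distributions over
  log-parameters, sampled with ensemble MCMC (:func:`fit_hierarchical`);
* seed-wise generalized least squares with a continuous-time AR(1)
  error structure and physiological covariates (:func:`gls_ar1`);
* the voxel-level design matrix (representative response + motion + SVD
  components) and group t-maps (:func:`build_design_matrix`,
  :func:`voxel_glm_group`);
* a linear mixed model over per-ROI summaries with subject random
  intercepts (:func:`mixed_model_group_test`).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

from .stats import impute_group_mean

COVARIATE_NAMES = ("PaCO2_before", "MABP_before", "MABP_peak")


@dataclass
class GammaParams:
    """Gamma-variate response parameters.

    alpha : shape (dimensionless, > 0)
    beta : rate (1/min)
    lam : scale (%BOLD * min); equals the area under the response curve
    """

    alpha: float
    beta: float
    lam: float

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")

    @property
    def peak_time(self) -> float:
        """Time of maximum response, (alpha - 1) / beta; alpha > 1 only."""
        if self.alpha <= 1:
            raise ValueError("peak time defined only for alpha > 1")
        return (self.alpha - 1) / self.beta

    @property
    def peak_amplitude(self) -> float:
        """Maximum of f: lam * beta * (alpha-1)^(alpha-1) e^(1-alpha) / Gamma(alpha)."""
        return peak_amplitude(self.alpha, self.beta, self.lam)

    @property
    def auc(self) -> float:
        """Total activation; the density normalization makes it lam exactly."""
        return self.lam


def peak_amplitude(alpha, beta, lam):
    a1 = np.asarray(alpha, dtype=float) - 1
    if np.any(a1 <= 0):
        raise ValueError("peak defined only for alpha > 1")
    log_peak = (np.log(beta) + a1 * np.log(a1) - a1
                - special.gammaln(np.asarray(alpha, dtype=float)))
    return lam * np.exp(log_peak)


def gamma_response(t, p: GammaParams):
    """Evaluate f(t) = lam * g(t; alpha, beta); zero for t < 0."""
    return _gamma_response_arr(np.asarray(t, dtype=float), p.alpha, p.beta, p.lam)


def _gamma_response_arr(t, alpha, beta, lam):
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast_shapes(t.shape, np.shape(alpha)), dtype=float)
    pos = np.broadcast_to(t > 0, out.shape)
    tt = np.broadcast_to(t, out.shape)[pos]
    a = np.broadcast_to(alpha, out.shape)[pos]
    b = np.broadcast_to(beta, out.shape)[pos]
    s = np.broadcast_to(lam, out.shape)[pos]
    log_g = a * np.log(b) + (a - 1) * np.log(tt) - b * tt - special.gammaln(a)
    out[pos] = s * np.exp(log_g)
    return out


# ---------------------------------------------------------------------------
# subject-level fits
# ---------------------------------------------------------------------------

def fit_subject_gamma(session: dict) -> pd.DataFrame:
    """Nonlinear least-squares gamma-variate fit per ROI of one session.

    Model: offset + lam * g(t - t_inj; alpha, beta). Start values come
    from curve moments (peak location/width); on non-convergence a
    method-of-moments fallback is returned and flagged.

    Parameters
    ----------
    session : dict
        As produced by :func:`ratconn.simulate.sim_phmri`: keys
        ``series`` (n_roi, n_frames), ``frame_times_min``,
        ``injection_time_min``.

    Returns
    -------
    pandas.DataFrame
        Columns ``roi, alpha, beta, lam, offset, converged, resid_sd``.
    """
    t = np.asarray(session["frame_times_min"], dtype=float)
    t_post = t - float(session["injection_time_min"])
    series = np.atleast_2d(session["series"])
    if np.count_nonzero(t_post > 0) < 10:
        raise ValueError("need >= 10 post-injection frames")

    def model(tp, offset, log_a, log_b, log_l):
        return offset + _gamma_response_arr(tp, np.exp(log_a), np.exp(log_b),
                                            np.exp(log_l))

    rows = []
    for r, y in enumerate(series):
        start = _moment_start(t_post, y)
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    model, t_post, y, p0=start, maxfev=20000,
                )
            if not np.all(np.isfinite(popt)):
                raise RuntimeError("non-finite fit")
        except (RuntimeError, optimize.OptimizeWarning):
            popt, converged = start, False
        offset, a, b, lam = popt[0], *np.exp(popt[1:])
        resid = y - model(t_post, *popt)
        rows.append((r, a, b, lam, offset, converged, resid.std(ddof=1)))
    return pd.DataFrame(
        rows, columns=["roi", "alpha", "beta", "lam", "offset", "converged",
                       "resid_sd"]
    )


def _moment_start(t_post, y):
    """Method-of-moments start values (log-parameterized)."""
    pos = t_post > 0
    tp, yp = t_post[pos], y[pos]
    w = np.clip(yp - np.median(y[~pos] if (~pos).any() else yp), 0, None)
    if w.sum() <= 0:
        return np.array([float(np.mean(y)), np.log(2.0), np.log(0.3), np.log(1e-3)])
    m1 = (w * tp).sum() / w.sum()
    m2 = (w * (tp - m1) ** 2).sum() / w.sum()
    m2 = max(m2, 1e-3)
    beta0 = m1 / m2
    alpha0 = max(m1 * beta0, 1.05)
    dt = np.median(np.diff(tp))
    lam0 = max(w.sum() * dt, 1e-3)
    return np.array([float(np.median(y[~pos])) if (~pos).any() else 0.0,
                     np.log(alpha0), np.log(beta0), np.log(lam0)])


# ---------------------------------------------------------------------------
# hierarchical Bayesian model
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Posterior draws and summaries of the hierarchical gamma model.

    ``group_mean_draws[param]`` maps group name -> draws of the
    group-level mean (natural scale, exp of the group-level log-mean);
    ``diff_ci95`` holds central 95% credible intervals of between-group
    differences per parameter. ``rhat`` carries split-R-hat per
    group-level parameter; ``converged`` is False when any exceeds 1.1.
    """

    group_names: tuple
    roi_summaries: pd.DataFrame
    group_mean_draws: dict
    diff_mean: dict
    diff_ci95: dict
    rhat: dict
    converged: bool
    subject_summaries: pd.DataFrame = field(default=None)
    #: draws of the across-ROI average of the group-level mean,
    #: param -> group -> 1-D array (per-draw average over ROI chains)
    group_roi_avg_draws: dict = field(default_factory=dict)


def _log_prob_roi(theta, t_post, y, group_of, prior_mu, prior_sd, sigma_scale):
    """Vectorized log-posterior for one ROI (non-centered hierarchy).

    theta : (W, ndim) walker block. Layout per walker:
    [3 * n_sub standardized subject offsets z][3 x 2 group log-means]
    [3 log group SDs][logit phi_noise][log sigma_noise]. Subject log-
    parameters are mu[group] + tau * z (non-centered parameterization:
    decorrelates subject offsets from the group scale, which mixes far
    better on the alpha/beta/lambda ridge). Noise is stationary AR(1) on
    the frame grid with marginal SD sigma and lag-1 correlation phi,
    matching the GLS analysis model.
    """
    W = theta.shape[0]
    S, T = y.shape
    zsub = theta[:, : 3 * S].reshape(W, S, 3)
    mu = theta[:, 3 * S: 3 * S + 6].reshape(W, 2, 3)
    log_tau = theta[:, 3 * S + 6: 3 * S + 9]
    x_phi = theta[:, -2]
    log_sig = theta[:, -1]

    bad = (np.abs(zsub) > 10).any(axis=(1, 2)) | (np.abs(log_tau) > 10).any(axis=1) \
        | (np.abs(log_sig) > 10) | (np.abs(mu) > 20).any(axis=(1, 2)) \
        | (np.abs(x_phi) > 15)

    tau_nc = np.exp(np.clip(log_tau, -10, 10))  # (W, 3)
    sub = mu[:, group_of, :] + tau_nc[:, None, :] * zsub  # (W, S, 3)
    bad |= (np.abs(sub) > 20).any(axis=(1, 2))
    sub = np.clip(sub, -20, 20)  # bad walkers get -inf below; avoid overflow
    log_a, log_b, log_l = sub[..., 0], sub[..., 1], sub[..., 2]

    a, b, lam = np.exp(log_a), np.exp(log_b), np.exp(log_l)
    model = _gamma_model_grid(t_post, a, b, lam)  # (W, S, T)
    sig = np.exp(log_sig)[:, None, None]
    phi = 1.0 / (1.0 + np.exp(-np.clip(x_phi, -15, 15)))[:, None, None]
    resid = y[None] - model
    # stationary AR(1) innovations: r_1 ~ N(0, s^2),
    # r_t | r_{t-1} ~ N(phi r_{t-1}, s^2 (1 - phi^2))
    innov = resid[..., 1:] - phi * resid[..., :-1]
    one_m = 1.0 - phi[..., 0] ** 2  # (W, S)-broadcastable
    loglik = (
        -0.5 * (resid[..., 0] / sig[..., 0]) ** 2
        - np.log(sig[..., 0])
        - 0.5 * (innov**2).sum(axis=-1) / (sig[..., 0] ** 2 * one_m)
        - (T - 1) * (np.log(sig[..., 0]) + 0.5 * np.log(one_m))
    ).sum(axis=1) - 0.5 * S * T * math.log(2 * math.pi)

    # non-centered: z ~ N(0, 1); the tau Jacobian is absorbed analytically
    logp_sub = (-0.5 * zsub**2).sum(axis=(1, 2))
    tau = tau_nc
    logp_mu = (-0.5 * ((mu - prior_mu[None, None, :]) / prior_sd[None, None, :]) ** 2
               ).sum(axis=(1, 2))
    # half-normal(1) on group SDs and half-normal(sigma_scale) on noise,
    # with the log-scale Jacobian
    logp_tau = (-0.5 * tau**2 + log_tau).sum(axis=1)
    sig_flat = np.exp(log_sig)
    logp_sig = -0.5 * (sig_flat / sigma_scale) ** 2 + log_sig
    logp_phi = -0.5 * (x_phi / 1.5) ** 2  # logit-normal, centered at phi=0.5

    out = loglik + logp_sub + logp_mu + logp_tau + logp_sig + logp_phi
    out[bad] = -np.inf
    return out


def _gamma_model_grid(t_post, a, b, lam):
    """lam * gamma density over a frame grid; (W, S) params x (T,) times."""
    pos = t_post > 0
    tt = t_post[pos]
    log_g = (a[..., None] * np.log(b[..., None])
             + (a[..., None] - 1) * np.log(tt)
             - b[..., None] * tt
             - special.gammaln(a[..., None]))
    out = np.zeros((*a.shape, t_post.size))
    out[..., pos] = lam[..., None] * np.exp(log_g)
    return out


def fit_hierarchical(
    sessions: list,
    n_walkers: int = None,
    n_steps: int = 1200,
    seed: int | None = None,
    rois=None,
    progress: bool = False,
) -> PosteriorSummary:
    """Hierarchical Bayesian gamma-variate fit with ensemble MCMC.

    Subject x ROI log-parameters (log alpha, log beta, log lam) are drawn
    from group-level normal distributions (per-group means, shared SDs).
    Priors on the group-level means are centered on the median of
    subject-level least-squares fits with SD = 10 x their interquartile
    range; group-level SDs and the noise SD get half-normal priors. ROIs
    share no parameters, so the model factorizes and is sampled per ROI;
    group-difference summaries pool draws across ROIs.

    Burn-in discards the first half of each chain. Split-R-hat over
    walker subgroups gates convergence at 1.1.

    Returns
    -------
    PosteriorSummary
    """
    import emcee

    groups = list(dict.fromkeys(s["group"] for s in sessions))
    if len(groups) != 2:
        raise ValueError("exactly two groups expected")
    counts = {g: sum(1 for s in sessions if s["group"] == g) for g in groups}
    if min(counts.values()) < 2:
        raise ValueError("need >= 2 subjects per group")
    group_of = np.array([groups.index(s["group"]) for s in sessions])
    t = np.asarray(sessions[0]["frame_times_min"], dtype=float)
    t_post = t - float(sessions[0]["injection_time_min"])
    n_roi = sessions[0]["series"].shape[0]
    rois = range(n_roi) if rois is None else rois
    S = len(sessions)
    ndim = 3 * S + 11
    n_walkers = n_walkers or max(2 * ndim + 2, 64)
    rng = np.random.default_rng(seed)

    # subject-level seeds for priors and walker initialization
    init_fits = [fit_subject_gamma(s) for s in sessions]

    roi_rows, subj_rows = [], []
    pooled = {p: {g: [] for g in groups} for p in ("alpha", "beta", "lam")}
    rhat_all = {}
    for r in rois:
        logs = np.array([
            [math.log(max(f.loc[r, "alpha"], 1e-6)),
             math.log(max(f.loc[r, "beta"], 1e-6)),
             math.log(max(f.loc[r, "lam"], 1e-6))]
            for f in init_fits
        ])
        logs = np.clip(logs, -8, 8)
        prior_mu = np.median(logs, axis=0)
        iqr = np.subtract(*np.percentile(logs, [75, 25], axis=0))
        prior_sd = np.clip(10 * iqr, 1.0, 50.0)
        resid_scale = float(np.median([f.loc[r, "resid_sd"] for f in init_fits]))
        sigma_scale = max(2 * resid_scale, 1e-3)

        y = np.stack([s["series"][r] - s["series"][r][t_post <= 0].mean()
                      for s in sessions])

        p0 = np.empty((n_walkers, ndim))
        mu_init = np.stack([logs[group_of == gi].mean(axis=0) for gi in (0, 1)])
        tau_init = np.log(np.clip(logs.std(axis=0), 0.05, 2.0))
        z_init = (logs - mu_init[group_of]) / np.exp(tau_init)
        p0[:, :3 * S] = z_init.reshape(-1)[None] + 0.1 * rng.standard_normal(
            (n_walkers, 3 * S))
        p0[:, 3 * S:3 * S + 6] = mu_init.reshape(-1)[None] + 0.05 * \
            rng.standard_normal((n_walkers, 6))
        p0[:, 3 * S + 6:3 * S + 9] = tau_init[None] + 0.05 * rng.standard_normal(
            (n_walkers, 3))
        p0[:, -2] = -0.85 + 0.3 * rng.standard_normal(n_walkers)  # phi ~ 0.3
        p0[:, -1] = math.log(max(resid_scale, 1e-3)) + 0.05 * rng.standard_normal(
            n_walkers)

        sampler = emcee.EnsembleSampler(
            n_walkers, ndim, _log_prob_roi,
            args=(t_post, y, group_of, prior_mu, prior_sd, sigma_scale),
            vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
        )
        # seed the sampler's internal RNG so runs are bit-reproducible
        sampler.random_state = np.random.RandomState(
            rng.integers(0, 2**31 - 1)).get_state()
        state = sampler.run_mcmc(p0, n_steps, progress=progress,
                                 skip_initial_state_check=True)
        del state
        burn = n_steps // 2
        chain = sampler.get_chain(discard=burn)  # (steps, walkers, ndim)

        # group-level draws (natural scale via exp of the log-mean)
        mu_draws = chain[:, :, 3 * S:3 * S + 6].reshape(-1, 2, 3)
        rhat = _split_rhat(chain[:, :, 3 * S:3 * S + 6]).reshape(2, 3)
        for k, pname in enumerate(("alpha", "beta", "lam")):
            rhat_all[f"roi{r}_mu_{pname}"] = max(rhat[0, k], rhat[1, k])
            for gi, g in enumerate(groups):
                pooled[pname][g].append(np.exp(mu_draws[:, gi, k]))

        z_draws = chain[:, :, :3 * S].reshape(-1, S, 3)
        mu_flat = chain[:, :, 3 * S:3 * S + 6].reshape(-1, 2, 3)
        tau_flat = np.exp(chain[:, :, 3 * S + 6:3 * S + 9].reshape(-1, 3))
        sub_draws = mu_flat[:, group_of, :] + tau_flat[:, None, :] * z_draws
        a_d, b_d, l_d = (np.exp(sub_draws[..., k]) for k in range(3))
        peak_d = peak_amplitude(np.clip(a_d, 1 + 1e-6, None), b_d, l_d)
        auc_d = l_d
        for s_i, sess in enumerate(sessions):
            subj_rows.append({
                "subject": sess["subject"], "group": sess["group"], "roi": r,
                "alpha": a_d[:, s_i].mean(), "beta": b_d[:, s_i].mean(),
                "lam": l_d[:, s_i].mean(),
                "auc": auc_d[:, s_i].mean(), "peak": peak_d[:, s_i].mean(),
            })
        for gi, g in enumerate(groups):
            roi_rows.append({
                "roi": r, "group": g,
                **{p: np.exp(mu_draws[:, gi, k]).mean()
                   for k, p in enumerate(("alpha", "beta", "lam"))},
                **{f"{p}_sd": np.exp(mu_draws[:, gi, k]).std()
                   for k, p in enumerate(("alpha", "beta", "lam"))},
            })

    group_mean_draws, diff_mean, diff_ci95, roi_avg = {}, {}, {}, {}
    for pname in ("alpha", "beta", "lam"):
        per_group = {g: np.concatenate(pooled[pname][g]) for g in groups}
        group_mean_draws[pname] = per_group
        roi_avg[pname] = {g: np.mean(np.stack(pooled[pname][g]), axis=0)
                          for g in groups}
        # per-ROI paired differences pooled across ROIs
        diffs = np.concatenate([
            pooled[pname][groups[0]][i] - pooled[pname][groups[1]][i]
            for i in range(len(pooled[pname][groups[0]]))
        ])
        diff_mean[pname] = float(diffs.mean())
        diff_ci95[pname] = (float(np.percentile(diffs, 2.5)),
                            float(np.percentile(diffs, 97.5)))

    converged = all(v <= 1.1 for v in rhat_all.values())
    if not converged:
        warnings.warn("hierarchical fit: some group-level R-hat > 1.1; "
                      "result flagged unconverged")
    return PosteriorSummary(
        group_names=tuple(groups),
        roi_summaries=pd.DataFrame(roi_rows),
        group_mean_draws=group_mean_draws,
        diff_mean=diff_mean,
        diff_ci95=diff_ci95,
        rhat=rhat_all,
        converged=converged,
        subject_summaries=pd.DataFrame(subj_rows),
        group_roi_avg_draws=roi_avg,
    )


def _split_rhat(chain):
    """Split-R-hat treating walker subgroups as chains.

    chain : (steps, walkers, ...) -> R-hat with the leading two axes
    reduced; walkers are split into 4 groups and each group's chain is
    halved (8 pseudo-chains).
    """
    steps, walkers = chain.shape[:2]
    half = steps // 2
    walkers -= walkers % 4  # equal-size walker groups
    parts = []
    for w in np.array_split(np.arange(walkers), 4):
        sub = chain[:, w]  # (steps, n_w, ...) pooled draws of the group
        parts.append(sub[:half].reshape(half * len(w), *chain.shape[2:]))
        parts.append(sub[half:2 * half].reshape(half * len(w), *chain.shape[2:]))
    parts = np.stack(parts)  # (8, n_draws, ...)
    n = parts.shape[1]
    means = parts.mean(axis=1)
    vars_ = parts.var(axis=1, ddof=1)
    W = vars_.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(var_hat / W)


# ---------------------------------------------------------------------------
# generalized least squares with continuous-time AR(1)
# ---------------------------------------------------------------------------

def _ar1_whiten(y, X, times, phi):
    """Exact GLS whitening for Corr(e_i, e_j) = phi^|t_i - t_j|."""
    if phi == 0:
        return y.copy(), X.copy(), 0.0
    rho = phi ** np.diff(times)
    scale = np.sqrt(1 - rho**2)
    r_y = rho.reshape(-1, *([1] * (y.ndim - 1)))
    s_y = scale.reshape(-1, *([1] * (y.ndim - 1)))
    yw = np.empty_like(y)
    Xw = np.empty_like(X)
    yw[0], Xw[0] = y[0], X[0]
    yw[1:] = (y[1:] - r_y * y[:-1]) / s_y
    Xw[1:] = (X[1:] - rho[:, None] * X[:-1]) / scale[:, None]
    logdet = np.sum(np.log(1 - rho**2))
    return yw, Xw, logdet


def gls_ar1(y, X, frame_times, normalize: bool = False, column_names=None):
    """Feasible GLS with continuous-time AR(1) errors.

    The error correlation is ``phi^|t_i - t_j|``; phi in [0, 1) is
    estimated by profile (maximum) likelihood, the regression solved on
    the whitened system. With ``normalize`` the response and non-constant
    predictors are z-scored before fitting (coefficients then are on the
    normalized scale).

    Returns
    -------
    dict
        ``coef, se, t, p`` (arrays over columns), ``phi``, ``df``,
        ``sigma2`` and the column names.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    times = np.asarray(frame_times, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, k) matching y")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    if normalize:
        y = (y - y.mean()) / y.std()
        X = X.copy()
        for j in range(X.shape[1]):
            col = X[:, j]
            if col.std() > 0 and not np.allclose(col, col[0]):
                X[:, j] = (col - col.mean()) / col.std()
    n, k = X.shape

    def nll(phi):
        yw, Xw, logdet = _ar1_whiten(y, X, times, phi)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        rss = np.sum((yw - Xw @ beta) ** 2)
        return n * math.log(max(rss, 1e-300) / n) + logdet

    res = optimize.minimize_scalar(nll, bounds=(0.0, 1 - 1e-6), method="bounded")
    phi = float(res.x)
    if phi >= 1 - 1e-5:
        warnings.warn("AR(1) coefficient near unit root")
    yw, Xw, _ = _ar1_whiten(y, X, times, phi)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    df = n - k
    sigma2 = float(resid @ resid / df)
    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * sps.t.sf(np.abs(tvals), df)
    return {
        "coef": beta, "se": se, "t": tvals, "p": pvals, "phi": phi,
        "df": df, "sigma2": sigma2,
        "columns": list(column_names) if column_names is not None
        else [f"x{j}" for j in range(k)],
    }


# ---------------------------------------------------------------------------
# voxel-level design and group maps
# ---------------------------------------------------------------------------

def build_design_matrix(mean_series, motion, frame_times_min, injection_time_min,
                        n_svd: int = 3):
    """Voxel-GLM design: representative response + motion + SVD components.

    Parameters
    ----------
    mean_series : (n_subjects, n_frames) array
        Per-subject mean (e.g. whole-brain) time courses in %BOLD.
    motion : (n_frames, 6) array
        Motion parameter traces.
    n_svd : int
        Number of left singular vectors of the residual matrix
        (per-subject mean responses minus the representative curve);
        reduced with a warning when fewer subjects are available.

    Returns
    -------
    (ndarray, list of str)
        Design matrix (n_frames, 1 + 6 + n_svd) and column names. The
        SVD columns are mutually orthonormal.
    """
    mean_series = np.atleast_2d(np.asarray(mean_series, dtype=float))
    motion = np.asarray(motion, dtype=float)
    n_sub, n_frames = mean_series.shape
    if motion.shape != (n_frames, 6):
        raise ValueError("motion must be (n_frames, 6)")
    if n_svd > n_sub:
        warnings.warn(f"n_svd reduced from {n_svd} to {n_sub} (subject count)")
        n_svd = n_sub
    grand = mean_series.mean(axis=0)
    degenerate = np.allclose(mean_series - grand[None], 0, atol=1e-10)
    fit = fit_subject_gamma({
        "series": grand[None], "frame_times_min": frame_times_min,
        "injection_time_min": injection_time_min,
    }).iloc[0]
    t_post = np.asarray(frame_times_min, dtype=float) - float(injection_time_min)
    rep = _gamma_response_arr(t_post, fit["alpha"], fit["beta"], fit["lam"])
    resid = (mean_series - rep[None]).T  # (n_frames, n_subjects)
    if degenerate:
        warnings.warn("identical subjects: SVD components are degenerate")
        svd_cols = np.zeros((n_frames, n_svd))
    else:
        u, s, _ = np.linalg.svd(resid, full_matrices=False)
        svd_cols = u[:, :n_svd]
    design = np.column_stack([rep, motion, svd_cols])
    names = (["response"] + [f"motion_{i}" for i in range(6)]
             + [f"svd_{i}" for i in range(n_svd)])
    return design, names


def voxel_glm_group(voxel_series, design, frame_times_min, groups,
                    covariates: pd.DataFrame | None = None):
    """Two-level voxelwise analysis of the drug response.

    First level: per-subject GLS/AR(1) fit of each voxel series on the
    design; phi is estimated once per subject from its mean voxel series
    and reused across voxels (shared acquisition noise process). Second
    level: per voxel, the response-column coefficients are regressed on
    group membership plus the physiological covariates (missing values
    group-mean imputed); the group-contrast t-map is returned.

    Parameters
    ----------
    voxel_series : list of (n_voxels, n_frames) arrays
        One per subject, voxel-aligned across subjects.
    groups : sequence
        Group label per subject (two levels).

    Returns
    -------
    dict
        ``coef_maps`` (n_subjects, n_voxels), ``group_t`` (n_voxels),
        ``group_p``, ``df``.
    """
    times = np.asarray(frame_times_min, dtype=float)
    X = np.asarray(design, dtype=float)
    n_sub = len(voxel_series)
    coef_maps = []
    Xfull = np.column_stack([np.ones(len(times)), X])
    for vs in voxel_series:
        vs = np.asarray(vs, dtype=float)
        mean_ts = vs.mean(axis=0)
        first = gls_ar1(mean_ts, Xfull, times)
        phi = first["phi"]
        yw, Xw, _ = _ar1_whiten(vs.T, Xfull, times, phi)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        coef_maps.append(beta[1])  # response column (after intercept)
    coef_maps = np.asarray(coef_maps)  # (n_subjects, n_voxels)

    glabels = pd.Series(list(groups))
    gvec = (glabels == glabels.unique()[0]).astype(float).to_numpy()
    Z = [np.ones(n_sub), gvec]
    if covariates is not None and len(covariates.columns):
        cov = impute_group_mean(covariates, glabels.to_numpy())
        Z.extend(cov[c].to_numpy(dtype=float) for c in cov.columns)
    Z = np.column_stack(Z)
    df = n_sub - Z.shape[1]
    beta2, *_ = np.linalg.lstsq(Z, coef_maps, rcond=None)
    resid = coef_maps - Z @ beta2
    sigma2 = (resid**2).sum(axis=0) / df
    gram_inv = np.linalg.inv(Z.T @ Z)
    se = np.sqrt(np.clip(sigma2 * gram_inv[1, 1], 1e-300, None))
    tmap = beta2[1] / se
    pmap = 2 * sps.t.sf(np.abs(tmap), df)
    return {"coef_maps": coef_maps, "group_t": tmap, "group_p": pmap, "df": df}


# ---------------------------------------------------------------------------
# mixed model over ROI summaries
# ---------------------------------------------------------------------------

def mixed_model_group_test(summaries: pd.DataFrame, value: str = "auc",
                           covariate_names=COVARIATE_NAMES):
    """Linear mixed model of per-ROI summaries with subject random intercepts.

    ``summaries`` must hold columns ``subject, group, roi`` plus the
    ``value`` column and any covariates present. The model is
    ``value ~ group + covariates`` with a random intercept per subject
    (the ROIs of a subject are the repeated measures). Missing covariates
    are group-mean imputed. When the estimated random-effect variance is
    (numerically) zero the fit collapses to ordinary least squares, which
    is noted in the result.

    Returns
    -------
    dict
        ``estimate, se, t, p`` for the group fixed effect, plus
        ``random_effect_sd`` and ``collapsed_to_ols``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = summaries.copy()
    if df.groupby("subject")["roi"].nunique().min() < 2:
        raise ValueError("need >= 2 ROIs per subject")
    covs = [c for c in covariate_names if c in df.columns]
    if covs:
        df[covs] = impute_group_mean(df[covs], df["group"].to_numpy())
    formula = f"{value} ~ C(group)" + "".join(f" + {c}" for c in covs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["subject"])
        fit = model.fit(reml=True, method="lbfgs")
    term = [n for n in fit.params.index if n.startswith("C(group)")][0]
    re_sd = float(np.sqrt(fit.cov_re.iloc[0, 0]))
    collapsed = re_sd < 1e-6
    if collapsed:
        ols = smf.ols(formula, df).fit()
        return {
            "estimate": float(ols.params[term]), "se": float(ols.bse[term]),
            "t": float(ols.tvalues[term]), "p": float(ols.pvalues[term]),
            "random_effect_sd": re_sd, "collapsed_to_ols": True,
        }
    return {
        "estimate": float(fit.params[term]), "se": float(fit.bse[term]),
        "t": float(fit.tvalues[term]), "p": float(fit.pvalues[term]),
        "random_effect_sd": re_sd, "collapsed_to_ols": False,
    }
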