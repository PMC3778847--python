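"""Metropolis-within-Gibbs sampler for the BYM Poisson model.

Update scheme per iteration:

* fixed effects: single-site Gaussian random-walk Metropolis, with
  per-site scales adapted during burn-in toward 0.44 acceptance;
* heterogeneity upsilon: simultaneous elementwise random-walk updates —
  valid because the full conditionals of the upsilon_i are mutually
  independent given everything else;
* spatial field S: elementwise random-walk updates swept over a greedy
  colouring of the adjacency graph (sites within a colour class have no
  common edges, so their conditionals are independent given the rest);
  after each sweep S is recentred and, for a connected graph, the mean is
  absorbed into the intercept so the likelihood is untouched;
* precisions: exact conjugate Gamma draws,
  tau_v | . ~ Gamma(a + n/2, b + sum u^2 / 2) and
  tau_S | . ~ Gamma(a + rank(Q)/2, b + S'QS/2).

Streaming accumulators collect everything the DIC/CPO evaluation needs
(per-draw deviance, mean linear predictor, harmonic-mean CPO terms and
posterior-predictive mass for masked tracts) so no latent-field draws
need storing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
import scipy.sparse as sp
from scipy.special import gammaln

from .bym import Design, FitError, PosteriorResult, Priors
from .graph import ICARStructure

_TARGET_ACC = 0.44
_LOGPMF_FLOOR = -690.7  # ln(1e-300)


def split_rhat(x: np.ndarray, n_splits: int = 4) -> float:
    """Potential scale reduction over segments of a single chain."""
    m = len(x) // n_splits
    if m < 2:
        return np.nan
    segs = x[: m * n_splits].reshape(n_splits, m)
    W = segs.var(axis=1, ddof=1).mean()
    B = m * segs.mean(axis=1).var(ddof=1)
    if W <= 0:
        return np.nan
    var_plus = (m - 1) / m * W + B / m
    return float(np.sqrt(var_plus / W))


def ess_autocorr(x: np.ndarray, max_lag: int | None = None) -> float:
    """Effective sample size via the initial positive sequence estimator."""
    n = len(x)
    if n < 10 or x.std() == 0:
        return float(n)
    xc = x - x.mean()
    if max_lag is None:
        max_lag = min(n - 2, 5000)  # sigma ridges carry long memory
    f = np.fft.rfft(np.concatenate([xc, np.zeros(n)]))
    acov = np.fft.irfft(f * np.conj(f))[: max_lag + 1] / n
    rho = acov / acov[0]
    s = 0.0
    for t in range(1, max_lag, 2):
        pair = rho[t] + rho[t + 1] if t + 1 <= max_lag else rho[t]
        if pair < 0:
            break
        s += pair
    return float(min(n, n / (1.0 + 2.0 * s)))


def _color_classes(W, degree: np.ndarray) -> list[np.ndarray]:
    g = nx.from_scipy_sparse_array(W)
    coloring = nx.greedy_color(g, strategy="largest_first")
    k = max(coloring.values()) + 1 if coloring else 1
    classes = [[] for _ in range(k)]
    for node, c in coloring.items():
        if degree[node] > 0:  # isolated tracts keep S = 0
            classes[c].append(node)
    return [np.array(sorted(c), dtype=int) for c in classes if c]


def run_mcmc(design: Design, structure: ICARStructure, priors: Priors,
             n_iter: int = 20000, n_burn: int = 5000, seed: int = 0,
             thin_store: int | None = None) -> PosteriorResult:
    if n_iter < 1 or n_burn < 0:
        raise ValueError("need n_iter >= 1 and n_burn >= 0")
    rng = np.random.default_rng(seed)
    X, O, logoff, wt = design.X, design.O, design.log_offset, design.weight
    n, p = design.n, design.p
    Q = structure.Q
    deg = np.asarray(Q.diagonal(), dtype=float)
    W = (sp.diags(deg) - Q).tocsr()  # 0/1 adjacency back from Q = D - W
    comps = structure.components
    rank = structure.rank
    marg_scale = structure.scale
    classes = _color_classes(W, deg)
    connected = structure.n_components == 1

    a_v, b_v = priors.logprec_het
    a_s, b_s = priors.logprec_spat
    tau_beta = 1.0 / priors.beta_sd**2
    gl = gammaln(O + 1)

    # per-column sparse access for fixed-effect updates
    col_idx = [np.nonzero(X[:, j])[0] for j in range(p)]
    col_val = [X[col_idx[j], j] for j in range(p)]
    col_ox = [float(np.sum(wt[col_idx[j]] * O[col_idx[j]] * col_val[j]))
              for j in range(p)]

    gamma = np.zeros(p)
    # crude initial intercept from the pooled rate
    tot_O = float((wt * O).sum())
    tot_E = float((wt * np.exp(logoff)).sum())
    gamma[0] = np.log(max(tot_O, 0.5) / tot_E) if tot_E > 0 else 0.0
    # Start the fields on the crude log-rate residuals, split evenly
    # between u and S.  Starting at u = S = 0 is a trap: the first
    # conjugate draw then sets tau ~ shape/rate (huge), which pins the
    # fields at zero for a long stretch of the run.
    resid = np.where(
        wt > 0,
        np.log((O + 0.5) / np.exp(logoff)) - gamma[0],
        0.0,
    )
    resid = np.clip(resid, -2.0, 2.0)
    u = 0.5 * resid
    S = 0.5 * resid
    for comp in comps:
        S[comp] -= S[comp].mean()
    S[deg == 0] = 0.0
    tau_v = float(np.clip(1.0 / max(np.var(u), 1e-3), 0.1, 1e3))
    tau_s = float(np.clip(1.0 / max(np.var(S), 1e-3), 0.1, 1e3))
    lin = X @ gamma + u + S
    mu = np.exp(logoff + lin)

    ls_gamma = np.full(p, np.log(0.1))
    ls_u = np.full(n, np.log(0.5))
    ls_S = np.full(n, np.log(0.5))
    ls_swap = np.full(n, np.log(0.5))
    ls_tr = np.full(p, np.log(0.1))
    ls_scu = np.log(0.1)
    ls_scs = np.log(0.1)
    acc_scu = acc_scs = 0.0
    acc_gamma = np.zeros(p)
    acc_u = np.zeros(n)
    acc_S = np.zeros(n)
    acc_swap = np.zeros(n)
    acc_tr = np.zeros(p)
    sum_x2 = [float(v @ v) for v in col_val]
    # precomputations for the gamma/S translations (S' = S - d*(x_j - xbar))
    ls_trs = np.full(p, np.log(0.1))
    acc_trs = np.zeros(p)
    mean_x = X.mean(axis=0)
    cent_x = [X[:, j] - mean_x[j] for j in range(p)]
    Qx = [np.asarray(Q @ cent_x[j]).ravel() for j in range(p)]
    xQx = [float(cent_x[j] @ Qx[j]) for j in range(p)]
    batch = 0
    batch_size = 100

    total = n_burn + n_iter
    # fixed-effect/hyper chains are cheap to keep nearly unthinned, and
    # the ESS estimate needs the long-lag autocorrelation they carry
    thin = thin_store or max(1, n_iter // 20000)
    n_store = n_iter // thin
    store_gamma = np.empty((n_store, p))
    store_sv = np.empty(n_store)
    store_ss = np.empty(n_store)
    k_store = 0

    gamma_sum = np.zeros(p); gamma2_sum = np.zeros(p)
    u_sum = np.zeros(n); u2_sum = np.zeros(n)
    S_sum = np.zeros(n); S2_sum = np.zeros(n)
    sv_sum = sv2_sum = ss_sum = ss2_sum = 0.0
    lin_sum = np.zeros(n)
    D_sum = 0.0
    invp_sum = np.zeros(n)
    invp_max = np.zeros(n)
    pred_sum = np.zeros(n)
    n_kept = 0
    masked = wt == 0.0

    for it in range(total):
        burnin = it < n_burn

        # --- fixed effects, single site ---
        for j in range(p):
            idx, val = col_idx[j], col_val[j]
            delta = np.exp(ls_gamma[j]) * rng.standard_normal()
            d_lin = delta * val
            mu_new = mu[idx] * np.exp(np.minimum(d_lin, 500))
            dll = delta * col_ox[j] - float(np.sum(wt[idx] * (mu_new - mu[idx])))
            dlp = dll - tau_beta * (delta * gamma[j] + 0.5 * delta * delta)
            if np.log(rng.uniform()) < dlp:
                gamma[j] += delta
                lin[idx] += d_lin
                mu[idx] = mu_new
                acc_gamma[j] += 1

        # --- heterogeneity: independent conditionals, joint elementwise ---
        delta = np.exp(ls_u) * rng.standard_normal(n)
        mu_new = mu * np.exp(np.minimum(delta, 500))
        dll = wt * (O * delta - (mu_new - mu))
        dlp = dll - tau_v * (delta * u + 0.5 * delta * delta)
        acc = np.log(rng.uniform(size=n)) < dlp
        u = np.where(acc, u + delta, u)
        lin = np.where(acc, lin + delta, lin)
        mu = np.where(acc, mu_new, mu)
        acc_u += acc

        # --- spatial field, by colour class ---
        for cls in classes:
            nbr = np.asarray(W[cls] @ S).ravel()
            delta = np.exp(ls_S[cls]) * rng.standard_normal(len(cls))
            mu_new = mu[cls] * np.exp(np.minimum(delta, 500))
            dll = wt[cls] * (O[cls] * delta - (mu_new - mu[cls]))
            dpr = -tau_s * (deg[cls] * (delta * S[cls] + 0.5 * delta * delta)
                            - delta * nbr)
            acc = np.log(rng.uniform(size=len(cls))) < dll + dpr
            S[cls] = np.where(acc, S[cls] + delta, S[cls])
            lin[cls] = np.where(acc, lin[cls] + delta, lin[cls])
            mu[cls] = np.where(acc, mu_new, mu[cls])
            acc_S[cls] += acc

        # --- fixed-effect/upsilon translation moves (likelihood-invariant) ---
        # eta is unchanged under (gamma_j + d, u - d * x_j), so the move is
        # judged on the priors alone; it breaks the ridge between each
        # coefficient and the mean of u over that covariate's support.
        for j in range(p):
            idx, val = col_idx[j], col_val[j]
            delta = np.exp(ls_tr[j]) * rng.standard_normal()
            dlp = (-tau_beta * (delta * gamma[j] + 0.5 * delta * delta)
                   - tau_v * (0.5 * delta * delta * sum_x2[j]
                              - delta * float(val @ u[idx])))
            if np.log(rng.uniform()) < dlp:
                gamma[j] += delta
                u[idx] -= delta * val
                acc_tr[j] += 1

        # --- fixed-effect/S translation moves (likelihood-invariant) ---
        # (gamma_j + d, S - d*(x_j - mean x_j), gamma_0 - d*mean x_j) keeps
        # eta and the sum-to-zero constraint; judged on the ICAR quadratic
        # form and the coefficient priors.  Needed because spatially
        # structured covariates ride a ridge against S (concurvity).
        if connected:
            for j in range(1, p):
                delta = np.exp(ls_trs[j]) * rng.standard_normal()
                xt = cent_x[j]
                dlp = (-tau_beta * (delta * gamma[j] + 0.5 * delta * delta)
                       - tau_beta * (-delta * mean_x[j] * gamma[0]
                                     + 0.5 * (delta * mean_x[j]) ** 2)
                       - tau_s * (0.5 * delta * delta * xQx[j]
                                  - delta * float(Qx[j] @ S)))
                if np.log(rng.uniform()) < dlp:
                    gamma[j] += delta
                    gamma[0] -= delta * mean_x[j]
                    S -= delta * xt
                    acc_trs[j] += 1

        # --- upsilon/S swap moves (likelihood-invariant) ---
        # eta depends on u + S only, so proposals (u_i + d, S_i - d) are
        # judged on the priors alone; they mix the weakly identified
        # decomposition between heterogeneity and spatial structure.
        for cls in classes:
            nbr = np.asarray(W[cls] @ S).ravel()
            delta = np.exp(ls_swap[cls]) * rng.standard_normal(len(cls))
            dlp = (-tau_v * (delta * u[cls] + 0.5 * delta * delta)
                   - tau_s * (deg[cls] * (0.5 * delta * delta - delta * S[cls])
                              + delta * nbr))
            acc = np.log(rng.uniform(size=len(cls))) < dlp
            u[cls] = np.where(acc, u[cls] + delta, u[cls])
            S[cls] = np.where(acc, S[cls] - delta, S[cls])
            acc_swap[cls] += acc

        # --- global field-rescale moves ---
        # u' = c u (resp. S' = c S) with log c Gaussian: travels the
        # ridge between field amplitude and its precision, which site
        # updates cross extremely slowly when the data barely identify
        # the variance split.  Jacobian: n log c (rank(Q) log c for S,
        # which lives on the sum-to-zero subspace).
        eps = np.exp(ls_scu) * rng.standard_normal()
        c_ = np.exp(eps)
        mu_new = mu * np.exp(np.minimum((c_ - 1.0) * u, 500))
        dlp = (float(np.sum(wt * (O * (c_ - 1.0) * u - (mu_new - mu))))
               - 0.5 * tau_v * (c_ * c_ - 1.0) * float(u @ u) + n * eps)
        if np.log(rng.uniform()) < dlp:
            lin += (c_ - 1.0) * u
            u *= c_
            mu = mu_new
            acc_scu += 1
        eps = np.exp(ls_scs) * rng.standard_normal()
        c_ = np.exp(eps)
        mu_new = mu * np.exp(np.minimum((c_ - 1.0) * S, 500))
        sqs_cur = float(S @ (Q @ S))
        dlp = (float(np.sum(wt * (O * (c_ - 1.0) * S - (mu_new - mu))))
               - 0.5 * tau_s * (c_ * c_ - 1.0) * sqs_cur + rank * eps)
        if np.log(rng.uniform()) < dlp:
            lin += (c_ - 1.0) * S
            S *= c_
            mu = mu_new
            acc_scs += 1

        # --- identifiability: recentre S ---
        if connected:
            m = S.mean()
            S -= m
            gamma[0] += m  # likelihood untouched (intercept column is 1s)
        else:
            for comp in comps:
                m = S[comp].mean()
                if m != 0.0:
                    S[comp] -= m
                    lin[comp] -= m
                    mu[comp] *= np.exp(-m)

        # --- conjugate precision updates ---
        tau_v = rng.gamma(a_v + 0.5 * n, 1.0 / (b_v + 0.5 * float(u @ u)))
        sqs = float(S @ (Q @ S))
        tau_s = rng.gamma(a_s + 0.5 * rank, 1.0 / (b_s + 0.5 * sqs))
        if not (np.isfinite(tau_v) and np.isfinite(tau_s)):
            raise FitError(f"non-finite precision at iteration {it}")

        # --- adaptation (burn-in only) ---
        if burnin and (it + 1) % batch_size == 0:
            batch += 1
            step = min(0.1, 1.0 / np.sqrt(batch)) * 2.0
            ls_gamma += step * (acc_gamma / batch_size - _TARGET_ACC)
            ls_u += step * (acc_u / batch_size - _TARGET_ACC)
            ls_S += step * (acc_S / batch_size - _TARGET_ACC)
            ls_swap += step * (acc_swap / batch_size - _TARGET_ACC)
            ls_tr += step * (acc_tr / batch_size - _TARGET_ACC)
            ls_trs += step * (acc_trs / batch_size - _TARGET_ACC)
            np.clip(ls_trs, -12, 3, out=ls_trs)
            acc_trs[:] = 0
            ls_scu = float(np.clip(
                ls_scu + step * (acc_scu / batch_size - _TARGET_ACC), -12, 1))
            ls_scs = float(np.clip(
                ls_scs + step * (acc_scs / batch_size - _TARGET_ACC), -12, 1))
            acc_scu = acc_scs = 0.0
            np.clip(ls_gamma, -12, 3, out=ls_gamma)
            np.clip(ls_u, -12, 3, out=ls_u)
            np.clip(ls_S, -12, 3, out=ls_S)
            np.clip(ls_swap, -12, 3, out=ls_swap)
            np.clip(ls_tr, -12, 3, out=ls_tr)
            acc_gamma[:] = 0; acc_u[:] = 0; acc_S[:] = 0; acc_swap[:] = 0
            acc_tr[:] = 0

        if burnin:
            continue

        # --- accumulation ---
        n_kept += 1
        gamma_sum += gamma; gamma2_sum += gamma**2
        u_sum += u; u2_sum += u**2
        S_sum += S; S2_sum += S**2
        sv = 1.0 / np.sqrt(tau_v)
        ss = np.sqrt(marg_scale / tau_s)
        sv_sum += sv; sv2_sum += sv * sv
        ss_sum += ss; ss2_sum += ss * ss
        lin_sum += lin
        logpmf = O * (logoff + lin) - mu - gl
        ll = float(np.sum(wt * (O * (logoff + lin) - mu) - wt * gl))
        D_sum += -2.0 * ll
        lp = np.maximum(logpmf, _LOGPMF_FLOOR)
        inv = np.exp(np.minimum(-lp, 700.0))
        invp_sum += inv
        np.maximum(invp_max, inv, out=invp_max)
        if masked.any():
            pred_sum[masked] += np.exp(logpmf[masked])
        kk = n_kept - 1
        if kk % thin == 0 and k_store < n_store:
            store_gamma[k_store] = gamma
            store_sv[k_store] = sv
            store_ss[k_store] = ss
            k_store += 1

    store_gamma = store_gamma[:k_store]
    store_sv = store_sv[:k_store]
    store_ss = store_ss[:k_store]

    gm = gamma_sum / n_kept
    gsd = np.sqrt(np.maximum(gamma2_sum / n_kept - gm**2, 0.0))
    qs = np.percentile(store_gamma, [2.5, 50.0, 97.5], axis=0)
    # ESS from the thinned series, not rescaled to the full run: thinning
    # discards little information here and the conservative MCSE is safer
    ess_full = np.array([ess_autocorr(store_gamma[:, j]) for j in range(p)])
    rhat = np.array([split_rhat(store_gamma[:, j]) for j in range(p)])
    fixed = pd.DataFrame(
        {
            "mean": gm,
            "sd": gsd,
            "q2.5": qs[0],
            "q50": qs[1],
            "q97.5": qs[2],
            "mcse": gsd / np.sqrt(np.maximum(ess_full, 1.0)),
            "ess": ess_full,
            "rhat": rhat,
        },
        index=design.names,
    )
    hyper = pd.DataFrame(
        {
            "mean": [ss_sum / n_kept, sv_sum / n_kept],
            "sd": [
                np.sqrt(max(ss2_sum / n_kept - (ss_sum / n_kept) ** 2, 0.0)),
                np.sqrt(max(sv2_sum / n_kept - (sv_sum / n_kept) ** 2, 0.0)),
            ],
            "q2.5": [np.percentile(store_ss, 2.5), np.percentile(store_sv, 2.5)],
            "q50": [np.percentile(store_ss, 50), np.percentile(store_sv, 50)],
            "q97.5": [np.percentile(store_ss, 97.5), np.percentile(store_sv, 97.5)],
        },
        index=["sigma_S", "sigma_v"],
    )
    latent = pd.DataFrame(
        {
            "u_mean": u_sum / n_kept,
            "u_sd": np.sqrt(np.maximum(u2_sum / n_kept - (u_sum / n_kept) ** 2, 0)),
            "S_mean": S_sum / n_kept,
            "S_sd": np.sqrt(np.maximum(S2_sum / n_kept - (S_sum / n_kept) ** 2, 0)),
        }
    )
    accum = {
        "n_kept": n_kept,
        "D_sum": D_sum,
        "lin_mean": lin_sum / n_kept,
        "invp_mean": invp_sum / n_kept,
        "invp_max": invp_max,
        "pred_mean": np.where(masked, pred_sum / n_kept, np.nan),
        "gl": gl,
    }
    meta = {
        "engine": "mcmc",
        "seed": seed,
        "n_iter": n_iter,
        "n_burn": n_burn,
        "thin_store": thin,
        "n_components": structure.n_components,
        "marginal_scale": marg_scale,
        "rank_Q": rank,
    }
    return PosteriorResult(
        engine="mcmc", fixed=fixed, hyper=hyper, latent=latent, design=design,
        meta=meta,
        samples={"gamma": store_gamma, "sigma_v": store_sv, "sigma_S": store_ss},
        accum=accum,
    )


def tau_conditionals(u: np.ndarray, S: np.ndarray, structure: ICARStructure,
                     priors: Priors) -> dict:
    """Analytic Gibbs conditionals for the two precisions (test oracle)."""
    a_v, b_v = priors.logprec_het
    a_s, b_s = priors.logprec_spat
    n = len(u)
    return {
        "tau_v": (a_v + n / 2.0, b_v + 0.5 * float(u @ u)),
        "tau_S": (a_s + structure.rank / 2.0,
                  b_s + 0.5 * float(S @ (structure.Q @ S))),
    }
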