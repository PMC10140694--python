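"""Independent reference implementations used only by the tests.

Each oracle is written from the defining formulas with a different code
path (and, for the factor model, a different parameterization and
optimizer) than the package, so agreement is evidence of correctness
rather than repetition.
"""

import itertools

import numpy as np
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# fractional ranks: brute force over tie-breaking permutations


def brute_force_ranks(values, weights):
    """Average the no-ties midpoint ranks over every permutation of the
    input order (ties then receive their group's average automatically)."""
    values = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(values)
    total = w.sum()
    acc = np.zeros(n)
    count = 0
    for perm in itertools.permutations(range(n)):
        perm = list(perm)
        order = sorted(perm, key=lambda i: values[i])
        # skip permutations that are not stable sorts of some tie-breaking:
        # every permutation of tied elements appears; untied order is forced
        cum = 0.0
        r = np.empty(n)
        for i in order:
            r[i] = (cum + w[i] / 2.0) / total
            cum += w[i]
        acc += r
        count += 1
    return acc / count


# ---------------------------------------------------------------------------
# concentration index: direct summation formula


def direct_concentration(y, r, w=None):
    """C = (2 / mu) * sum(w y r) / sum(w) - 1, valid when the weighted mean
    rank is one half."""
    y = np.asarray(y, dtype=float)
    r = np.asarray(r, dtype=float)
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=float)
    mu = np.sum(w * y) / np.sum(w)
    return 2.0 * np.sum(w * y * r) / (mu * np.sum(w)) - 1.0


# ---------------------------------------------------------------------------
# decomposition: plain-numpy Wagstaff pipeline (lstsq, midpoint ranks)


def numpy_decomposition(X, y, rank_values, names):
    """Returns (total C, {name: contribution}, residual term) from scratch:
    least squares by lstsq, ranks by average midpoint, index by direct
    covariance sums.  X must already include an intercept column first."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    order = stats.rankdata(rank_values, method="average")
    r = (order - 0.5) / n
    mu = y.mean()
    cov = lambda a: np.mean(a * r) - a.mean() * r.mean()
    total = 2.0 * cov(y) / mu
    contribs = []  # (label, contribution); labels may repeat across levels
    for j, name in enumerate(names):
        if j == 0:
            continue  # intercept
        contribs.append((name, 2.0 * beta[j] * cov(X[:, j]) / mu))
    residual = 2.0 * cov(resid) / mu
    return total, contribs, residual


def numpy_early_life_shares(cohort, outcome, covariate_specs, mediators, early):
    """Direct and total early-life percent shares computed entirely with
    numpy/scipy primitives (no package calls).  ``covariate_specs`` is a
    list of (name, levels, reference) triples."""

    def design(names):
        cols = [np.ones(len(cohort))]
        labels = ["const"]
        for name, levels, ref in covariate_specs:
            if name not in names:
                continue
            for lvl in levels:
                if lvl == ref:
                    continue
                cols.append((cohort[name] == lvl).to_numpy(dtype=float))
                labels.append(name)
        return np.column_stack(cols), labels

    y = cohort[outcome].to_numpy(dtype=float)
    y = (y - y.min()) / (y.max() - y.min())
    rank_values = cohort["wealth"].to_numpy(dtype=float)
    all_names = [s[0] for s in covariate_specs]
    shares = {}
    for tag, names in (
        ("direct", all_names),
        ("total", [n for n in all_names if n not in mediators]),
    ):
        X, labels = design(names)
        total, contribs, _ = numpy_decomposition(X, y, rank_values, labels)
        early_sum = sum(v for k, v in contribs if k in early)
        shares[tag] = 100.0 * early_sum / total
    return shares["direct"], shares["total"]


# ---------------------------------------------------------------------------
# Holm and Rubin by definition


def brute_force_holm(p, alpha=0.05):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if adj[idx] <= alpha:
            reject[idx] = True
        else:
            break
    return adj, reject


def brute_force_rubin(q, v):
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    m = len(q)
    qbar = q.sum() / m
    wbar = v.sum() / m
    b = ((q - qbar) ** 2).sum() / (m - 1)
    t = wbar + (1.0 + 1.0 / m) * b
    return qbar, wbar, b, t


# ---------------------------------------------------------------------------
# second-order CFA: RAM-style implied covariance, Nelder-Mead optimizer


def _ram_sigma(structure, load, lam, phi, psi, theta):
    """Implied covariance via the structural (RAM) representation
    f = A f + zeta over the six factors (overall first)."""
    subs = list(structure.subdomains)
    inds = list(structure.indicators)
    d, p = len(subs), len(inds)
    A = np.zeros((d + 1, d + 1))
    A[1:, 0] = lam
    zeta_var = np.concatenate(([phi], psi))
    inv = np.linalg.inv(np.eye(d + 1) - A)
    cov_f = inv @ np.diag(zeta_var) @ inv.T
    L_full = np.zeros((p, d + 1))
    for j, ind in enumerate(inds):
        L_full[j, 1 + subs.index(structure.subdomain_of(ind))] = load[j]
    return L_full @ cov_f @ L_full.T + np.diag(theta), L_full, cov_f


def ml_discrepancy(S, Sigma):
    p = S.shape[0]
    sign, ld = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return 1e10
    _, ld_s = np.linalg.slogdet(S)
    return ld + np.trace(np.linalg.solve(Sigma, S)) - ld_s - p


def fit_oracle_cfa(data, structure, true_params, maxiter=40000):
    """Nelder-Mead fit of the second-order model, started at the
    data-generating truth; variances enter through their square roots so
    the search is unconstrained.  Returns (F_min, params dict)."""
    inds = list(structure.indicators)
    subs = list(structure.subdomains)
    markers = {structure.marker(s) for s in subs}
    free_idx = [j for j, ind in enumerate(inds) if ind not in markers]
    x = data[inds].to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    S = xc.T @ xc / len(x)

    t_load, t_lam, t_phi, t_psi, t_theta = true_params

    def pack():
        return np.concatenate(
            [
                [t_load[j] for j in free_idx],
                t_lam[1:],
                [np.sqrt(t_phi)],
                np.sqrt(t_psi),
                np.sqrt(t_theta),
            ]
        )

    def unpack(v):
        k = len(free_idx)
        load = np.array(t_load, dtype=float)
        for i, j in enumerate(free_idx):
            load[j] = v[i]
        for j, ind in enumerate(inds):
            if ind in markers:
                load[j] = 1.0
        lam = np.concatenate(([1.0], v[k : k + len(subs) - 1]))
        k += len(subs) - 1
        phi = v[k] ** 2
        k += 1
        psi = v[k : k + len(subs)] ** 2
        k += len(subs)
        theta = v[k:] ** 2
        return load, lam, phi, psi, theta

    def objective(v):
        Sigma, _, _ = _ram_sigma(structure, *unpack(v))
        return ml_discrepancy(S, Sigma)

    res = optimize.minimize(
        objective,
        pack(),
        method="Nelder-Mead",
        options={"maxiter": maxiter, "fatol": 1e-12, "xatol": 1e-8, "adaptive": True},
    )
    load, lam, phi, psi, theta = unpack(res.x)
    return float(res.fun), {
        "load": load, "lam": lam, "phi": phi, "psi": psi, "theta": theta, "S": S,
    }


def oracle_overall_score(data, structure, params):
    """Regression factor score for the overall factor at oracle parameter
    values, computed through the RAM covariance algebra."""
    Sigma, L_full, cov_f = _ram_sigma(
        structure, params["load"], params["lam"], params["phi"],
        params["psi"], params["theta"],
    )
    x = data[list(structure.indicators)].to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    cov_x_overall = L_full @ cov_f[:, 0]
    return xc @ np.linalg.solve(Sigma, cov_x_overall)
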