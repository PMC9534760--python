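"""Independent oracle implementations used only by the test suite.

Each is coded from the defining formulas with plain loops / dense matrix
algebra, deliberately sharing no code with the production paths it checks.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy.optimize import minimize_scalar


def wc_components_bruteforce(genotypes_by_pop: list[list[tuple[int, int]]]):
    """Weir–Cockerham per-locus components (a, b, c) summed over alleles.

    ``genotypes_by_pop``: per population, the list of non-missing diploid
    genotypes at one locus.
    """
    pops = [g for g in genotypes_by_pop if len(g) > 0]
    r = len(pops)
    n_i = [len(g) for g in pops]
    nbar = sum(n_i) / r
    nc = (sum(n_i) - sum(n**2 for n in n_i) / sum(n_i)) / (r - 1)

    alleles = sorted({a for g in pops for pair in g for a in pair})
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = []
        h_i = []
        for g in pops:
            copies = sum(
                int(pair[0] == allele) + int(pair[1] == allele) for pair in g
            )
            hets = sum(
                1 for pair in g if pair[0] != pair[1] and allele in pair
            )
            p_i.append(copies / (2 * len(g)))
            h_i.append(hets / len(g))
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / sum(n_i)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / sum(n_i)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def dataset_components_bruteforce(dataset):
    """Brute-force (a, b, c) for every locus of a GenotypeDataset."""
    out = {}
    for li, locus in enumerate(dataset.loci):
        by_pop = []
        for p in range(dataset.n_populations):
            rows = dataset.calls[dataset.pop_index == p, li, :]
            by_pop.append([(int(r[0]), int(r[1])) for r in rows if r[0] != 0])
        present = {a for g in by_pop for pair in g for a in pair}
        if len(present) <= 1:
            out[locus] = (0.0, 0.0, 0.0)
        else:
            out[locus] = wc_components_bruteforce(by_pop)
    return out


def reml_matrix_oracle(values: np.ndarray, codes: np.ndarray) -> tuple[float, float]:
    """One-way REML via dense-matrix profiling of the restricted likelihood.

    Builds V0 = I + lam Z Z^T explicitly and evaluates the restricted
    criterion with slogdet/solve; no grouped-statistics shortcuts.
    """
    values = np.asarray(values, float)
    codes = np.asarray(codes)
    groups = np.unique(codes)
    Z = (codes[:, None] == groups[None, :]).astype(float)
    N = len(values)
    X = np.ones((N, 1))

    def crit(log_lam):
        lam = np.exp(log_lam)
        V0 = np.eye(N) + lam * Z @ Z.T
        sign, logdet = np.linalg.slogdet(V0)
        Vi_y = np.linalg.solve(V0, values)
        Vi_X = np.linalg.solve(V0, X)
        xtvx = (X.T @ Vi_X).item()
        mu = (X.T @ Vi_y).item() / xtvx
        resid = values - mu
        q = float(resid @ np.linalg.solve(V0, resid))
        sw2 = q / (N - 1)
        return (N - 1) * np.log(sw2) + logdet + np.log(xtvx)

    res = minimize_scalar(crit, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-12})
    log_lam = float(res.x)
    if crit(-12.0) < res.fun:
        log_lam = -12.0
    lam = np.exp(log_lam)
    if log_lam <= -12.0 + 1e-8:
        lam = 0.0
    V0 = np.eye(N) + lam * Z @ Z.T
    Vi_y = np.linalg.solve(V0, values)
    Vi_X = np.linalg.solve(V0, X)
    mu = (X.T @ Vi_y).item() / (X.T @ Vi_X).item()
    resid = values - mu
    q = float(resid @ np.linalg.solve(V0, resid))
    sw2 = q / (N - 1)
    return lam * sw2, sw2


def mantel_exhaustive_oracle(A: np.ndarray, B: np.ndarray) -> tuple[float, float]:
    """Exact one-sided Mantel p over all n! joint label permutations of B."""
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    x = A[iu]

    def corr(mat):
        y = mat[iu]
        xc, yc = x - x.mean(), y - y.mean()
        return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))

    r_obs = corr(B)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        p = list(perm)
        r_p = corr(B[np.ix_(p, p)])
        count += r_p >= r_obs - 1e-12
        total += 1
    return r_obs, count / total
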