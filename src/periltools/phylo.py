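"""Phylogenetic signal of exploitation across families.

Three statistics on the time-scaled family tree: the D statistic for the
binary trait "family contains exploited species" (scaled so D = 1 matches a
random scatter of the trait over the tips and D = 0 matches a
threshold-Brownian expectation), and Pagel's lambda and Blomberg's K for the
continuous trait "proportion of exploited species in a family".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .treeutils import FamilyTree, TreeArrays
from .types import PhyloDResult, SignalResult, SpeciesRecord

__all__ = [
    "phylo_d",
    "pagel_lambda",
    "blomberg_k",
    "family_exploitation_summary",
]


def _align_trait(tree: FamilyTree, trait: dict[str, float]) -> np.ndarray:
    labels = tree.tip_labels
    missing = [l for l in labels if l not in trait]
    extra = [k for k in trait if k not in set(labels)]
    if missing or extra:
        raise ValueError(
            f"trait/tip mismatch; tips without trait: {missing[:5]}, "
            f"trait keys not on tree: {extra[:5]}"
        )
    return np.array([float(trait[l]) for l in labels])


def phylo_d(
    tree: FamilyTree,
    trait: dict[str, int],
    n_sim: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PhyloDResult:
    """D statistic for a binary tip trait with permutation and Brownian nulls.

    The observed statistic ``d_obs`` sums, over internal nodes, the absolute
    differences between daughter nodal values obtained by a weighted-average
    downpass of the 0/1 trait. ``D = (d_obs - mean_d_brownian) /
    (mean_d_random - mean_d_brownian)``: the random null shuffles the trait
    across tips; the Brownian null simulates a continuous trait on the tree
    and thresholds it at the observed prevalence. ``p_random`` is the
    fraction of random-null d values <= d_obs (small d = phylogenetically
    clumped); ``p_brownian`` the fraction of Brownian-null d values >= d_obs.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    x = _align_trait(tree, trait)
    states = set(np.unique(x))
    if not states <= {0.0, 1.0}:
        raise ValueError("trait must be binary 0/1")
    if len(states) < 2:
        raise ValueError("trait is monomorphic; D undefined")
    arrays = tree.arrays()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = int(x.sum())
    n = arrays.n_tips

    _, d_obs_arr = arrays.nodal_downpass(x)
    d_obs = float(d_obs_arr[0])

    # random null: permute the 0/1 labels over tips
    perm = np.empty((n, n_sim))
    for j in range(n_sim):
        perm[:, j] = rng.permutation(x)
    _, d_rand = arrays.nodal_downpass(perm)

    # Brownian null: continuous simulation, rank-thresholded to prevalence k
    bm = arrays.simulate_brownian(n_sim, rng)
    order = np.argsort(-bm, axis=0)
    thresh = np.zeros_like(bm)
    np.put_along_axis(thresh, order[:k], 1.0, axis=0)
    _, d_brown = arrays.nodal_downpass(thresh)

    mean_rand = float(d_rand.mean())
    mean_brown = float(d_brown.mean())
    denom = mean_rand - mean_brown
    D = float("nan") if denom == 0 else (d_obs - mean_brown) / denom
    return PhyloDResult(
        D=D,
        p_random=float(np.mean(d_rand <= d_obs)),
        p_brownian=float(np.mean(d_brown >= d_obs)),
        d_obs=d_obs,
        mean_d_random=mean_rand,
        mean_d_brownian=mean_brown,
        n_sim=n_sim,
    )


def _chol(V: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor with a tiny ridge retry for near-duplicate tips."""
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        ridge = 1e-8 * float(np.mean(np.diag(V)))
        try:
            return linalg.cholesky(V + ridge * np.eye(len(V)), lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError(
                "singular phylogenetic covariance; jitter zero-length branches"
            ) from exc


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _mvn_profile_loglik(x: np.ndarray, V: np.ndarray) -> float:
    """Log-likelihood with the mean and Brownian rate profiled out."""
    n = len(x)
    L = _chol(V)
    one = np.ones(n)
    iV_x = linalg.cho_solve((L, True), x)
    iV_1 = linalg.cho_solve((L, True), one)
    mu = (one @ iV_x) / (one @ iV_1)
    r = x - mu
    iV_r = linalg.cho_solve((L, True), r)
    s2 = (r @ iV_r) / n
    if s2 <= 0:
        raise ValueError("zero trait variance; signal undefined")
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def pagel_lambda(tree: FamilyTree, trait: dict[str, float]) -> SignalResult:
    """Maximum-likelihood Pagel's lambda on [0, 1] for a continuous tip trait.

    Lambda multiplies the off-diagonal entries of the Brownian covariance
    matrix; 1 keeps full phylogenetic covariance, 0 collapses to a star.
    """
    x = _align_trait(tree, trait)
    if len(x) < 4:
        raise ValueError("at least 4 tips required")
    if np.ptp(x) == 0:
        raise ValueError("trait has zero variance; lambda undefined")
    C = tree.arrays().vcv()

    def nll(lam: float) -> float:
        return -_mvn_profile_loglik(x, _lambda_cov(C, lam))

    res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-6})
    # the bounded optimizer can miss a boundary optimum by its tolerance
    candidates = [(nll(0.0), 0.0), (nll(1.0), 1.0), (res.fun, float(res.x))]
    best_nll, best_lam = min(candidates)
    return SignalResult(lam=best_lam, logL_lambda=-best_nll)


def blomberg_k(
    tree: FamilyTree,
    trait: dict[str, float],
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> SignalResult:
    """Blomberg's K with a tip-permutation p-value.

    K compares the observed ratio of non-phylogenetic to phylogenetic mean
    squared error against its Brownian expectation on the given tree; K = 1
    under Brownian motion, K < 1 for weaker-than-Brownian signal. ``p_K`` is
    the fraction of tip permutations with K at least as large as observed.
    """
    x = _align_trait(tree, trait)
    if len(x) < 4:
        raise ValueError("at least 4 tips required")
    if np.ptp(x) == 0:
        raise ValueError("trait has zero variance; K undefined")
    arrays = tree.arrays()
    if len(arrays.children) == 1 and len(arrays.children[0]) == arrays.n_tips:
        raise ValueError("star phylogeny: K is degenerate (no internal structure)")
    C = arrays.vcv()
    n = len(x)
    L = _chol(C)
    one = np.ones(n)
    iC_1 = linalg.cho_solve((L, True), one)
    denom_11 = one @ iC_1
    expected = (np.trace(C) - n / denom_11) / (n - 1)

    def observed_ratio(v: np.ndarray) -> np.ndarray:
        """(MSE0 / MSE) for each column of v."""
        v2 = np.atleast_2d(v.T).T
        iC_v = linalg.cho_solve((L, True), v2)
        mu = (one @ iC_v) / denom_11
        r = v2 - mu
        mse0 = (r * r).sum(axis=0)
        iC_r = linalg.cho_solve((L, True), r)
        mse = (r * iC_r).sum(axis=0)
        return mse0 / mse

    K_obs = float(observed_ratio(x)[0] / expected)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.column_stack([rng.permutation(x) for _ in range(n_perm)])
    K_perm = observed_ratio(perms) / expected
    p = float((np.sum(K_perm >= K_obs) + 1) / (n_perm + 1))
    return SignalResult(K=K_obs, p_K=p)


def family_exploitation_summary(records: list[SpeciesRecord]) -> pd.DataFrame:
    """Per-family exploitation tallies.

    Columns: family, n_species, n_exploited, proportion, any_exploited."""
    if not records:
        raise ValueError("no species records")
    df = pd.DataFrame(
        {
            "family": [r.family for r in records],
            "exploited": [bool(r.exploited) for r in records],
        }
    )
    g = df.groupby("family", sort=True)["exploited"].agg(["size", "sum"])
    out = pd.DataFrame(
        {
            "family": g.index,
            "n_species": g["size"].astype(int).to_numpy(),
            "n_exploited": g["sum"].astype(int).to_numpy(),
        }
    )
    out["proportion"] = out["n_exploited"] / out["n_species"]
    out["any_exploited"] = out["n_exploited"] > 0
    return out.reset_index(drop=True)
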