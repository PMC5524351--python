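"""Mutation-drift-equilibrium bottleneck tests and factorial correspondence analysis.

Bottleneck detection follows the heterozygosity-excess principle: after a
recent crash, rare alleles are lost faster than gene diversity, so the
observed H_E at a locus exceeds the equilibrium expectation H_eq for the
*observed* number of alleles.  H_eq is obtained by single-locus coalescent
simulation under a stepwise (SMM) or two-phase (TPM) microsatellite
mutation model, conditioned on the observed allele count by adjusting θ
and rejection sampling — the Cornuet–Luikart construction.  Departure is
assessed with a one-tailed Wilcoxon signed-rank test across loci.

Factorial correspondence analysis (FCA) embeds individuals by their
allele-count profiles (0/1/2 copies per allele column); it is used to
screen for substructure and candidate immigrants without reference
populations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from fragpop.core_data import GenotypeTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Coalescent simulation of equilibrium heterozygosity
# ---------------------------------------------------------------------------


def _geometric_q_for_variance(variance: float) -> float:
    """Success probability of a geometric step-size law with given variance."""
    # var = (1-q)/q^2  ->  q = (-1 + sqrt(1 + 4 var)) / (2 var)
    if variance <= 0:
        return 1.0
    return (-1.0 + math.sqrt(1.0 + 4.0 * variance)) / (2.0 * variance)


def _simulate_locus(
    n_genes: int,
    theta: float,
    p_multistep: float,
    geom_q: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One coalescent replicate; returns the n_genes sampled allele states.

    Time is scaled in 2N generations; mutations fall on branches at rate
    θ/2 per unit time.  Each mutation is ±1 step (SMM) or, with
    probability ``p_multistep``, ±Geometric(q) steps (TPM).
    """
    n = n_genes
    # parent-pointer tree built by Kingman merging
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    blen = np.zeros(n_nodes)
    node_time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(2.0 / (j * (j - 1)))
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = active[i1], active[i2]
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        blen[a] = t - node_time[a]
        blen[b] = t - node_time[b]
        active = [x for k, x in enumerate(active) if k not in (i1, i2)]
        active.append(nxt)
        nxt += 1

    # mutations per branch, propagated root -> leaves
    n_mut = rng.poisson(theta / 2.0 * blen[: n_nodes - 1])
    total_mut = int(n_mut.sum())
    if total_mut:
        signs = rng.choice([-1, 1], size=total_mut)
        if p_multistep > 0:
            multi = rng.random(total_mut) < p_multistep
            sizes = np.ones(total_mut, dtype=int)
            if multi.any():
                sizes[multi] = rng.geometric(geom_q, size=int(multi.sum()))
        else:
            sizes = np.ones(total_mut, dtype=int)
        steps = signs * sizes
    else:
        steps = np.empty(0, dtype=int)

    branch_step = np.zeros(n_nodes, dtype=int)
    pos = 0
    for node in range(n_nodes - 1):
        m = n_mut[node]
        if m:
            branch_step[node] = steps[pos : pos + m].sum()
            pos += m
    # state = cumulative steps from the root; process nodes in decreasing
    # creation order so parents are resolved first
    state = np.zeros(n_nodes, dtype=int)
    for node in range(n_nodes - 2, -1, -1):
        state[node] = state[parent[node]] + branch_step[node]
    return state[:n]


def _mean_k(
    n_genes: int, theta: float, p_multistep: float, geom_q: float,
    rng: np.random.Generator, batch: int,
) -> float:
    ks = [
        len(np.unique(_simulate_locus(n_genes, theta, p_multistep, geom_q, rng)))
        for _ in range(batch)
    ]
    return float(np.mean(ks))


@lru_cache(maxsize=512)
def _calibrate_theta(
    k: int, n_genes: int, p_multistep: float, geom_q: float, batch: int
) -> float:
    """θ with E[#alleles] ≈ k, by bisection on a log grid (deterministic)."""
    rng = np.random.default_rng(abs(hash((k, n_genes, p_multistep))) % 2**31)
    lo, hi = 1e-3, 0.5
    while _mean_k(n_genes, hi, p_multistep, geom_q, rng, batch) < k:
        hi *= 2.0
        if hi > 1e4:
            break
    for _ in range(18):
        mid = math.sqrt(lo * hi)
        if _mean_k(n_genes, mid, p_multistep, geom_q, rng, batch) < k:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def heq_distribution(
    k: int,
    n_genes: int,
    model: str = "TPM",
    p_multistep: float = 0.30,
    reps: int = 1000,
    seed: int | None = None,
    step_variance: float = 12.0,
    calibration_batch: int = 60,
    max_attempts_factor: int = 400,
) -> np.ndarray:
    """Equilibrium-heterozygosity sample conditioned on ``k`` observed alleles.

    θ is tuned by bisection so the expected simulated allele count matches
    ``k``, then replicates are accepted only when exactly ``k`` alleles
    appear among the ``n_genes`` sampled gene copies; each accepted
    replicate contributes its unbiased gene diversity H_eq.
    """
    if k < 2:
        raise ValueError("monomorphic loci (k=1) are untestable")
    if n_genes < k:
        raise ValueError("n_genes must be at least k")
    model = model.upper()
    if model == "SMM":
        p_multistep = 0.0
    elif model != "TPM":
        raise ValueError("model must be 'SMM' or 'TPM'")
    geom_q = _geometric_q_for_variance(step_variance)
    rng = np.random.default_rng(seed)
    theta = _calibrate_theta(k, n_genes, p_multistep, geom_q, calibration_batch)

    out = np.empty(reps)
    got = 0
    attempts = 0
    max_attempts = max_attempts_factor * reps
    while got < reps and attempts < max_attempts:
        attempts += 1
        states = _simulate_locus(n_genes, theta, p_multistep, geom_q, rng)
        alleles, counts = np.unique(states, return_counts=True)
        if len(alleles) != k:
            continue
        p = counts / n_genes
        # plain gene diversity (no small-sample correction), so that the
        # 2-allele bound H <= 0.5 holds and the observed/simulated
        # comparison in bottleneck_test is on the same footing
        out[got] = 1.0 - float((p**2).sum())
        got += 1
    if got < reps:
        logger.warning(
            "heq_distribution: accepted %d/%d replicates (k=%d, n=%d)",
            got, reps, k, n_genes,
        )
        out = out[:got]
    return out


@dataclass
class BottleneckResult:
    model: str
    p_multistep: float
    reps: int
    per_locus: pd.DataFrame = field(repr=False)
    wilcoxon_p_excess: float = float("nan")
    wilcoxon_p_two_sided: float = float("nan")


def bottleneck_test(
    gt: GenotypeTable,
    model: str = "TPM",
    p_multistep: float = 0.30,
    reps: int = 10000,
    seed: int | None = None,
    step_variance: float = 12.0,
) -> BottleneckResult:
    """Heterozygosity-excess bottleneck test across loci.

    For each polymorphic locus the observed unbiased H_E is compared with
    the simulated H_eq distribution for its allele count; the one-tailed
    Wilcoxon signed-rank test over per-locus differences (H_E − mean H_eq)
    gives the bottleneck (excess) p-value.
    """
    usable = gt.usable()
    rows = []
    diffs = []
    for j, locus in enumerate(gt.loci):
        m = usable[:, j]
        calls = gt.calls[m, j, :]
        n_genes = 2 * int(m.sum())
        alleles, counts = np.unique(calls.ravel(), return_counts=True)
        k = len(alleles)
        if k < 2:
            logger.info("bottleneck_test: locus %s monomorphic, excluded", locus)
            continue
        p = counts / n_genes
        he = 1.0 - float((p**2).sum())
        heq = heq_distribution(
            k, n_genes, model=model, p_multistep=p_multistep, reps=reps,
            seed=None if seed is None else seed + 7919 * j,
            step_variance=step_variance,
        )
        mu, sd = float(heq.mean()), float(heq.std(ddof=1))
        rows.append(
            {"locus": locus, "k": k, "n_genes": n_genes, "H_E": he,
             "Heq_mean": mu, "Heq_sd": sd,
             "std_diff": (he - mu) / sd if sd > 0 else float("nan")}
        )
        diffs.append(he - mu)
    per_locus = pd.DataFrame(rows)
    if len(diffs) < 4:
        logger.warning("bottleneck_test: only %d testable loci", len(diffs))
    if len(diffs) >= 2 and np.any(np.asarray(diffs) != 0):
        p_exc = float(stats.wilcoxon(diffs, alternative="greater").pvalue)
        p_two = float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)
    else:
        p_exc = p_two = float("nan")
    return BottleneckResult(
        model=model.upper(),
        p_multistep=0.0 if model.upper() == "SMM" else p_multistep,
        reps=reps,
        per_locus=per_locus,
        wilcoxon_p_excess=p_exc,
        wilcoxon_p_two_sided=p_two,
    )


# ---------------------------------------------------------------------------
# Factorial correspondence analysis
# ---------------------------------------------------------------------------


@dataclass
class FCAResult:
    coords: np.ndarray  # (n_individuals, n_axes) row principal coordinates
    eigenvalues: np.ndarray
    total_inertia: float
    axis_shares: np.ndarray
    individual_id: list[str]
    outlier_flags: np.ndarray | None = None


def _allele_indicator_matrix(gt: GenotypeTable) -> tuple[np.ndarray, list[str]]:
    cols = []
    names = []
    usable = gt.usable()
    for j, locus in enumerate(gt.loci):
        m = usable[:, j]
        alleles = np.unique(gt.calls[m, j, :]) if m.any() else np.empty(0, int)
        for a in alleles:
            col = ((gt.calls[:, j, :] == a).sum(axis=1)).astype(float)
            col[~m] = 0.0
            cols.append(col)
            names.append(f"{locus}.{a}")
    if not cols:
        return np.zeros((gt.n_individuals, 0)), []
    return np.column_stack(cols), names


def fca(gt: GenotypeTable, n_axes: int = 2) -> FCAResult:
    """Correspondence analysis of the individuals × allele-count matrix.

    Row principal coordinates come from the SVD of the doubly
    standardized frequency matrix; eigenvalues are squared singular
    values, total inertia their sum.
    """
    if gt.n_individuals < 2:
        raise ValueError("FCA needs at least 2 individuals")
    X, names = _allele_indicator_matrix(gt)
    X = X[:, X.sum(axis=0) > 0]
    total = X.sum()
    if total == 0 or X.shape[1] < 2:
        return FCAResult(
            np.zeros((gt.n_individuals, 0)), np.empty(0), 0.0, np.empty(0),
            list(gt.individual_id),
        )
    N = X / total
    r = N.sum(axis=1)
    c = N.sum(axis=0)
    S = (N - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    eig = sv**2
    keep = eig > 1e-12
    eig = eig[keep]
    U = U[:, keep]
    sv = sv[keep]
    if eig.size == 0:
        return FCAResult(
            np.zeros((gt.n_individuals, 0)), np.empty(0), 0.0, np.empty(0),
            list(gt.individual_id),
        )
    total_inertia = float(eig.sum())
    coords = (U * sv) / np.sqrt(r)[:, None]
    n_axes = min(n_axes, coords.shape[1])
    return FCAResult(
        coords[:, :n_axes],
        eig,
        total_inertia,
        eig / total_inertia,
        list(gt.individual_id),
    )


def flag_outliers(result: FCAResult, z_threshold: float = 3.0) -> list[str]:
    """Candidate immigrants: Mahalanobis distance on the first two axes.

    One re-weighting pass (centroid and covariance recomputed without the
    initially flagged points) makes the rule resistant to the outliers
    it is meant to find.
    """
    n = len(result.individual_id)
    if n < 5:
        raise ValueError("outlier flagging needs >= 5 individuals")
    if result.coords.shape[1] == 0:
        return []
    Z = result.coords[:, : min(2, result.coords.shape[1])]

    def mahal(sub_mask: np.ndarray) -> np.ndarray:
        mu = Z[sub_mask].mean(axis=0)
        cov = np.cov(Z[sub_mask].T)
        cov = np.atleast_2d(cov) + 1e-12 * np.eye(Z.shape[1])
        inv = np.linalg.inv(cov)
        d = Z - mu
        return np.sqrt(np.einsum("ij,jk,ik->i", d, inv, d))

    dist = mahal(np.ones(n, bool))
    flagged = dist > z_threshold
    if flagged.any() and (~flagged).sum() >= 5:
        dist = mahal(~flagged)
        flagged = dist > z_threshold
    return [result.individual_id[i] for i in np.flatnonzero(flagged)]


def fca_report(
    gt: GenotypeTable, n_axes: int = 2, z_threshold: float = 3.0
) -> tuple[FCAResult, pd.DataFrame]:
    """FCA plus a tidy coordinate/flag table."""
    res = fca(gt, n_axes=n_axes)
    try:
        out = set(flag_outliers(res, z_threshold))
    except ValueError:
        out = set()
    res.outlier_flags = np.array([i in out for i in res.individual_id])
    df = pd.DataFrame(
        {
            "individual_id": res.individual_id,
            **{
                f"axis{k + 1}": (
                    res.coords[:, k] if k < res.coords.shape[1] else np.nan
                )
                for k in range(n_axes)
            },
            "outlier": res.outlier_flags,
        }
    )
    return res, df


def plot_fca(result: FCAResult, path) -> None:
    """2-D FCA scatter with outliers marked (vector output, e.g. SVG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    xy = result.coords
    if xy.shape[1] >= 2:
        flags = (
            result.outlier_flags
            if result.outlier_flags is not None
            else np.zeros(len(xy), bool)
        )
        ax.scatter(xy[~flags, 0], xy[~flags, 1], s=18, c="k", label="resident")
        if flags.any():
            ax.scatter(
                xy[flags, 0], xy[flags, 1], s=40, marker="*", c="r",
                label="candidate immigrant",
            )
        shares = result.axis_shares
        ax.set_xlabel(f"Axis 1 ({100 * shares[0]:.1f}%)")
        if len(shares) > 1:
            ax.set_ylabel(f"Axis 2 ({100 * shares[1]:.1f}%)")
        ax.legend(frameon=False)
    ax.set_title("Factorial correspondence analysis")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
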