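"""Microsatellite diversity, identity, and equilibrium statistics.

Implements the per-period summary statistics reported for small bear
populations monitored by noninvasive genetic sampling: rarefied allelic
richness, observed and Nei's unbiased expected heterozygosity, the
Weir & Cockerham within-population inbreeding coefficient, locus-bootstrap
confidence intervals, probabilities of identity (unrelated and sibling),
Hardy–Weinberg and pairwise linkage-disequilibrium permutation tests, and
a homozygote-excess null-allele screen with the Brookfield-1 estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from fragpop.core_data import MISSING, GenotypeTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class LocusFrequencies:
    locus: str
    alleles: np.ndarray  # allele codes
    counts: np.ndarray  # gene-copy counts
    n_genes: int  # 2 x usable individuals

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.n_genes

    @property
    def monomorphic(self) -> bool:
        return len(self.alleles) < 2


@dataclass
class AlleleFrequencyTable:
    loci: dict[str, LocusFrequencies] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.loci.values())

    def __getitem__(self, locus: str) -> LocusFrequencies:
        return self.loci[locus]


def allele_frequencies(gt: GenotypeTable) -> AlleleFrequencyTable:
    """Per-locus allele counts and frequencies over usable individuals.

    Loci with zero usable individuals are excluded with a warning.
    """
    out = AlleleFrequencyTable()
    usable = gt.usable()
    for j, locus in enumerate(gt.loci):
        rows = usable[:, j]
        if not rows.any():
            logger.warning("locus %s has no usable individuals; excluded", locus)
            continue
        genes = gt.calls[rows, j, :].ravel()
        alleles, counts = np.unique(genes, return_counts=True)
        lf = LocusFrequencies(locus, alleles, counts, int(rows.sum()) * 2)
        if lf.monomorphic:
            logger.info("locus %s is monomorphic", locus)
        out.loci[locus] = lf
    return out


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------


def heterozygosity(
    gt: GenotypeTable, *, unbiased: bool = True
) -> tuple[pd.DataFrame, float, float]:
    """Observed and expected heterozygosity per locus, plus multilocus means.

    H_O is the fraction of usable individuals heterozygous at the locus;
    H_E is Nei's gene diversity 1 − Σp², with the unbiased small-sample
    correction 2n/(2n−1) by default.  Multilocus values are unweighted
    locus means.
    """
    usable = gt.usable()
    rows = []
    for j, locus in enumerate(gt.loci):
        m = usable[:, j]
        n = int(m.sum())
        if n < 1:
            continue
        calls = gt.calls[m, j, :]
        ho = float((calls[:, 0] != calls[:, 1]).mean())
        _, counts = np.unique(calls.ravel(), return_counts=True)
        p = counts / (2 * n)
        he = 1.0 - float((p**2).sum())
        if unbiased and n > 0:
            he *= (2 * n) / (2 * n - 1) if 2 * n > 1 else 1.0
        rows.append({"locus": locus, "n": n, "H_O": ho, "H_E": he})
    df = pd.DataFrame(rows)
    return df, float(df["H_O"].mean()), float(df["H_E"].mean())


# ---------------------------------------------------------------------------
# Allelic richness (hypergeometric rarefaction)
# ---------------------------------------------------------------------------


def _log_comb(n: np.ndarray, k: int) -> np.ndarray:
    n = np.asarray(n, float)
    out = np.full(n.shape, -np.inf)
    ok = n >= k
    out[ok] = gammaln(n[ok] + 1) - gammaln(k + 1) - gammaln(n[ok] - k + 1)
    return out


def rarefied_richness(counts: np.ndarray, n_genes: int, g: int) -> float:
    """Expected allele count in a random subsample of g gene copies."""
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    if g > n_genes:
        raise ValueError(f"g={g} exceeds n_genes={n_genes}")
    counts = np.asarray(counts)
    # 1 - C(n_genes - c, g)/C(n_genes, g) per allele
    log_denom = _log_comb(np.array([n_genes]), g)[0]
    log_num = _log_comb(n_genes - counts, g)
    return float(np.sum(1.0 - np.exp(log_num - log_denom)))


def allelic_richness(
    gt: GenotypeTable, g: int | None = None
) -> tuple[pd.DataFrame, float, int]:
    """Rarefied allelic richness A_R per locus and its unweighted mean.

    ``g`` defaults to the minimum gene-copy count over loci so that the
    rarefaction size is attainable at every locus; pass the common
    minimum across datasets to compare periods with unequal sample size.
    """
    freqs = allele_frequencies(gt)
    n_genes_min = min(lf.n_genes for lf in freqs)
    if g is None:
        g = n_genes_min
    if g > n_genes_min:
        raise ValueError(f"g={g} exceeds the minimum gene-copy count {n_genes_min}")
    rows = [
        {
            "locus": lf.locus,
            "n_genes": lf.n_genes,
            "A_obs": len(lf.alleles),
            "A_R": rarefied_richness(lf.counts, lf.n_genes, g),
        }
        for lf in freqs
    ]
    df = pd.DataFrame(rows)
    return df, float(df["A_R"].mean()), g


# ---------------------------------------------------------------------------
# F_IS (Weir & Cockerham 1984, single population)
# ---------------------------------------------------------------------------


def _wc_components(gt: GenotypeTable) -> tuple[float, float]:
    """Summed (b, c) variance components over loci and alleles.

    For a single population the W&C f (= F_IS) estimator reduces to
    f = 1 − Σc / Σ(b + c), where, per locus and allele with sample size
    n, allele frequency p and heterozygote frequency h (share of
    individuals heterozygous for that allele):

        b = n/(n−1) · [p(1−p) − (2n−1)/(4n) · h... ]

    using the standard one-population forms
        b = n/(n-1) * (p(1-p) - h*(2n-1)/(4n))
        c = h/2
    """
    usable = gt.usable()
    sum_b = 0.0
    sum_c = 0.0
    for j in range(gt.n_loci):
        m = usable[:, j]
        n = int(m.sum())
        if n < 2:
            continue
        calls = gt.calls[m, j, :]
        alleles = np.unique(calls)
        if len(alleles) < 2:
            continue
        for a in alleles:
            x = (calls == a).sum(axis=1)  # copies of allele a per individual
            p = x.sum() / (2 * n)
            h = float((x == 1).mean())
            b = n / (n - 1) * (p * (1 - p) - h * (2 * n - 1) / (4 * n))
            c = h / 2.0
            sum_b += b
            sum_c += c
    return sum_b, sum_c


def inbreeding_fis(gt: GenotypeTable) -> float:
    """Multilocus Weir & Cockerham F_IS (ratio of summed components).

    Returns NaN when every locus is monomorphic.
    """
    b, c = _wc_components(gt)
    denom = b + c
    if denom == 0:
        return float("nan")
    return 1.0 - c / denom


# ---------------------------------------------------------------------------
# Locus bootstrap CIs
# ---------------------------------------------------------------------------

_STATS: dict[str, Callable[[GenotypeTable], float]] = {
    "H_O": lambda gt: heterozygosity(gt)[1],
    "H_E": lambda gt: heterozygosity(gt)[2],
    "F_IS": inbreeding_fis,
}


def bootstrap_ci(
    gt: GenotypeTable,
    statistic: str,
    n_boot: int = 1000,
    seed: int | None = None,
    g: int | None = None,
) -> tuple[float, float]:
    """Percentile CI (2.5/97.5%) by resampling loci with replacement.

    ``statistic`` is one of ``A_R``, ``H_O``, ``H_E``, ``F_IS``.  For
    ``A_R`` the rarefaction size ``g`` is held fixed across resamples.
    """
    if statistic == "A_R":
        _, _, g_used = allelic_richness(gt, g)
        func = lambda t: allelic_richness(t, g_used)[1]  # noqa: E731
    elif statistic in _STATS:
        func = _STATS[statistic]
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if gt.n_loci < 3:
        logger.warning("bootstrap over %d loci: CI unreliable", gt.n_loci)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    L = gt.n_loci
    for b in range(n_boot):
        idx = rng.integers(0, L, size=L)
        resampled = GenotypeTable(
            list(gt.individual_id),
            list(gt.sex),
            list(gt.period),
            [f"{gt.loci[i]}#{k}" for k, i in enumerate(idx)],
            gt.calls[:, idx, :],
        )
        vals[b] = func(resampled)
    lower, upper = np.nanpercentile(vals, [2.5, 97.5])
    return float(lower), float(upper)


# ---------------------------------------------------------------------------
# Probability of identity
# ---------------------------------------------------------------------------


def probability_identity(freqs: AlleleFrequencyTable) -> tuple[float, float, pd.DataFrame]:
    """Multilocus PI and PI_sibs (product over loci).

    Per locus: PI = Σp_i⁴ + ΣΣ_{i<j}(2 p_i p_j)²;
    PI_sibs = 0.25 + 0.5·Σp_i² + 0.5·(Σp_i²)² − 0.25·Σp_i⁴.
    """
    rows = []
    for lf in freqs:
        p = lf.freqs
        s2 = float((p**2).sum())
        s4 = float((p**4).sum())
        pi = s4 + 2 * (s2**2 - s4)  # Σp⁴ + Σ_{i≠j}(p_i p_j)·2... see below
        # Σ_{i<j}(2 p_i p_j)² = 2 Σ_{i<j} 2 p_i²p_j² = 2(s2² − s4)
        pi_sibs = 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4
        rows.append({"locus": lf.locus, "PI": pi, "PI_sibs": pi_sibs})
    df = pd.DataFrame(rows)
    return float(df["PI"].prod()), float(df["PI_sibs"].prod()), df


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact (Monte-Carlo permutation) test
# ---------------------------------------------------------------------------


def _locus_hwe_p(calls: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    """One-locus HWE test: permute gene copies, compare heterozygote deficit
    /excess via the |H_O − H_E| statistic (two-sided)."""
    n = len(calls)
    obs_het = float((calls[:, 0] != calls[:, 1]).mean())
    genes = calls.ravel().copy()
    p = np.unique(genes, return_counts=True)[1] / (2 * n)
    exp_het = 1.0 - float((p**2).sum())
    obs_stat = abs(obs_het - exp_het)
    hits = 1
    for _ in range(n_perm):
        rng.shuffle(genes)
        pairs = genes.reshape(n, 2)
        het = float((pairs[:, 0] != pairs[:, 1]).mean())
        if abs(het - exp_het) >= obs_stat - 1e-12:
            hits += 1
    return hits / (n_perm + 1)


def hwe_test(
    gt: GenotypeTable,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-locus Hardy–Weinberg permutation tests plus Fisher's combination.

    Monomorphic loci are excluded.  The returned frame carries one row
    per testable locus (columns ``locus, p, significant_bonferroni``)
    and the attributes ``chi2``, ``df``, ``global_p`` for the Fisher
    combination over testable loci (χ² with 2·L df).
    """
    rng = np.random.default_rng(seed)
    usable = gt.usable()
    rows = []
    for j, locus in enumerate(gt.loci):
        m = usable[:, j]
        calls = gt.calls[m, j, :]
        if len(np.unique(calls)) < 2 or m.sum() < 2:
            continue
        p = _locus_hwe_p(calls, n_perm, rng)
        rows.append({"locus": locus, "p": p})
    df = pd.DataFrame(rows)
    L = len(df)
    if L:
        bonf = alpha / L
        df["significant_bonferroni"] = df["p"] < bonf
        chi2 = float(-2.0 * np.log(df["p"].clip(lower=1e-300)).sum())
        global_p = float(stats.chi2.sf(chi2, 2 * L))
    else:
        chi2, global_p = 0.0, 1.0
    df.attrs["chi2"] = chi2
    df.attrs["df"] = 2 * L
    df.attrs["global_p"] = global_p
    return df


def fisher_combined(p_values: np.ndarray) -> tuple[float, int, float]:
    """Fisher's method: χ² = −2Σln p on 2L df."""
    p = np.asarray(p_values, float)
    chi2 = float(-2.0 * np.log(np.clip(p, 1e-300, None)).sum())
    df = 2 * len(p)
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Pairwise linkage disequilibrium test
# ---------------------------------------------------------------------------


def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio statistic of a 2-way contingency table."""
    t = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    n = t.sum()
    if n == 0:
        return 0.0
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * np.log(t / exp), 0.0)
    return float(2.0 * terms.sum())


def ld_pairwise_test(
    gt: GenotypeTable,
    n_perm: int = 200,
    seed: int | None = None,
    alpha: float = 0.05,
    min_complete: int = 5,
) -> pd.DataFrame:
    """Genotypic LD permutation test for every locus pair.

    For each pair, the G (log-likelihood-ratio) statistic of the joint
    genotype contingency table is compared with its permutation null
    obtained by shuffling one locus's genotypes across individuals.
    Pairs with fewer than ``min_complete`` individuals typed at both
    loci are flagged untestable.  Bonferroni threshold = alpha / n_pairs.
    """
    rng = np.random.default_rng(seed)
    usable = gt.usable()
    # genotype codes per locus: unordered pair -> integer
    codes = []
    for j in range(gt.n_loci):
        pairs = np.sort(gt.calls[:, j, :], axis=1)
        _, inv = np.unique(pairs, axis=0, return_inverse=True)
        codes.append(inv)
    rows = []
    L = gt.n_loci
    n_pairs = L * (L - 1) // 2
    for a in range(L):
        for b in range(a + 1, L):
            m = usable[:, a] & usable[:, b]
            if m.sum() < min_complete:
                rows.append(
                    {"locus1": gt.loci[a], "locus2": gt.loci[b],
                     "p": np.nan, "testable": False}
                )
                continue
            ga = codes[a][m]
            gb = codes[b][m].copy()
            ka, kb = ga.max() + 1, gb.max() + 1
            obs = _g_statistic(np.histogram2d(ga, gb, bins=(ka, kb))[0])
            hits = 1
            for _ in range(n_perm):
                rng.shuffle(gb)
                stat = _g_statistic(np.histogram2d(ga, gb, bins=(ka, kb))[0])
                if stat >= obs - 1e-12:
                    hits += 1
            rows.append(
                {"locus1": gt.loci[a], "locus2": gt.loci[b],
                 "p": hits / (n_perm + 1), "testable": True}
            )
    df = pd.DataFrame(rows)
    if n_pairs:
        df["significant_bonferroni"] = df["p"] < (alpha / n_pairs)
    df.attrs["n_pairs"] = n_pairs
    return df


# ---------------------------------------------------------------------------
# Null-allele screen
# ---------------------------------------------------------------------------


def null_allele_screen(
    gt: GenotypeTable,
    alpha: float = 0.05,
    n_perm: int = 500,
    seed: int | None = None,
) -> pd.DataFrame:
    """Homozygote-excess null-allele screen per locus.

    Flags loci with a one-tailed homozygote excess (H_O < H_E) at
    ``alpha`` using a permutation test of gene copies, and reports the
    Brookfield-1 null frequency estimate r̂ = (H_E − H_O)/(1 + H_E).
    """
    rng = np.random.default_rng(seed)
    usable = gt.usable()
    rows = []
    for j, locus in enumerate(gt.loci):
        m = usable[:, j]
        calls = gt.calls[m, j, :]
        n = int(m.sum())
        if n < 2 or len(np.unique(calls)) < 2:
            continue
        ho = float((calls[:, 0] != calls[:, 1]).mean())
        p = np.unique(calls.ravel(), return_counts=True)[1] / (2 * n)
        he = (1.0 - float((p**2).sum())) * (2 * n) / (2 * n - 1)
        r_hat = max(0.0, (he - ho) / (1 + he))
        # one-tailed permutation: how often is permuted H_O <= observed?
        genes = calls.ravel().copy()
        hits = 1
        for _ in range(n_perm):
            rng.shuffle(genes)
            het = float((genes.reshape(n, 2)[:, 0] != genes.reshape(n, 2)[:, 1]).mean())
            if het <= ho + 1e-12:
                hits += 1
        pval = hits / (n_perm + 1)
        rows.append(
            {"locus": locus, "H_O": ho, "H_E": he, "null_freq": r_hat,
             "p_homozygote_excess": pval, "flagged": pval < alpha and he > ho}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table-1-shaped report
# ---------------------------------------------------------------------------


def diversity_report(
    gt: GenotypeTable,
    n_boot: int = 1000,
    seed: int | None = None,
    g: int | None = None,
) -> pd.DataFrame:
    """Per-period genetics summary (A_R, H_O, H_E, F_IS with locus-bootstrap
    CIs), one row per sampling period.

    ``g`` defaults to the minimum gene-copy count across *all* periods
    and loci so that rarefied richness is comparable between periods.
    """
    if g is None:
        g = min(
            min(lf.n_genes for lf in allele_frequencies(gt.for_period(p)))
            for p in gt.periods()
        )
    rows = []
    for k, per in enumerate(gt.periods()):
        sub = gt.for_period(per)
        _, ar, _ = allelic_richness(sub, g)
        _, ho, he = heterozygosity(sub)
        fis = inbreeding_fis(sub)
        row = {"period": per, "n": sub.n_individuals, "A_R": ar, "H_O": ho,
               "H_E": he, "F_IS": fis, "g": g}
        for si, stat in enumerate(["A_R", "H_O", "H_E", "F_IS"]):
            lo, hi = bootstrap_ci(
                sub, stat, n_boot=n_boot,
                seed=None if seed is None else seed + 1000 * k + si, g=g,
            )
            row[f"{stat}_lo"], row[f"{stat}_hi"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)
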