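"""Diversity and differentiation statistics for diploid biallelic panels.

Implements the classical estimators used in SNP-panel hybrid-zone studies:

* allele frequencies per locus within populations;
* observed heterozygosity and Nei's unbiased expected heterozygosity;
* rarefied allelic richness;
* Weir & Cockerham (1984) variance-component estimators of Fis and
  pairwise Fst (theta), aggregated over loci as ratios of summed
  components, never averages of per-locus ratios;
* genotype-permutation significance for pairwise differentiation (a
  log-likelihood-ratio G statistic over genotype contingency tables — the
  "not assuming Hardy–Weinberg within samples" variant, permuting whole
  multilocus genotypes between the two populations) with Bonferroni
  control across pairs;
* the linkage-disequilibrium (Burrows composite r²) effective population
  size estimator with the random-mating small-sample correction and a
  jackknife-over-locus-pairs confidence interval;
* DAPC: PCA reduction of the (mean-imputed) genotype matrix followed by
  linear discriminant analysis on group labels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "allele_frequencies",
    "heterozygosities",
    "allelic_richness",
    "weir_cockerham_components",
    "fis_weir_cockerham",
    "pairwise_fst",
    "fst_significance",
    "bonferroni_threshold",
    "round_sig",
    "ld_ne",
    "NeEstimate",
    "dapc",
    "DapcResult",
    "diversity_table",
    "FstResult",
]


# ---------------------------------------------------------------------------
# Frequencies and heterozygosity
# ---------------------------------------------------------------------------

def _pop_arrays(G: GenotypeMatrix, pops: list[str] | None = None):
    """Per-population (n, p, h) arrays of shape (n_pops, n_loci).

    n = non-missing individuals, p = alternate-allele frequency, h =
    observed heterozygote fraction; p and h are NaN where n == 0.
    """
    pops = pops if pops is not None else G.populations
    n = np.zeros((len(pops), G.n_loci))
    p = np.full((len(pops), G.n_loci), np.nan)
    h = np.full((len(pops), G.n_loci), np.nan)
    for k, pop in enumerate(pops):
        sub = G.calls[G.population_mask(pop)]
        obs = sub != MISSING
        cnt = obs.sum(axis=0)
        n[k] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(cnt > 0, np.where(obs, sub, 0).sum(axis=0) / (2.0 * cnt), np.nan)
            h[k] = np.where(cnt > 0, ((sub == 1) & obs).sum(axis=0) / cnt, np.nan)
    return pops, n, p, h


def allele_frequencies(G: GenotypeMatrix, by_population: bool = True) -> pd.DataFrame:
    """Alternate-allele frequency per locus (per population if requested).

    Missing calls are excluded from numerator and denominator; an
    all-missing (locus, population) cell is NaN, not 0.
    """
    if by_population:
        pops, n, p, _ = _pop_arrays(G)
        return pd.DataFrame(p.T, index=G.locus_ids, columns=pops)
    obs = G.calls != MISSING
    cnt = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(cnt > 0, np.where(obs, G.calls, 0).sum(axis=0) / (2.0 * cnt), np.nan)
    return pd.DataFrame({"frequency": freq}, index=G.locus_ids)


def heterozygosities(G: GenotypeMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-population summary, per (locus, population) detail).

    Ho is the heterozygote fraction among non-missing calls; He is Nei's
    unbiased expected heterozygosity 2p(1−p)·2n/(2n−1), averaged over loci
    with data.
    """
    pops, n, p, h = _pop_arrays(G)
    with np.errstate(invalid="ignore", divide="ignore"):
        he = 2.0 * p * (1.0 - p) * (2.0 * n) / (2.0 * n - 1.0)
    he = np.where(n > 0, np.where(n > 0.5, he, np.nan), np.nan)
    detail = pd.DataFrame({
        "population": np.repeat(pops, G.n_loci),
        "locus": np.tile(G.locus_ids, len(pops)),
        "n": n.ravel(),
        "Ho": h.ravel(),
        "He": he.ravel(),
    })
    summary = pd.DataFrame({
        "population": pops,
        "N": [int(G.population_mask(pop).sum()) for pop in pops],
        "Ho": np.nanmean(h, axis=1),
        "He": np.nanmean(he, axis=1),
    })
    return summary, detail


def allelic_richness(G: GenotypeMatrix, g: int | None = None) -> pd.DataFrame:
    """Rarefied allelic richness per population (mean over loci).

    Per locus, Ar = Σ_alleles [1 − C(2N−N_a, g) / C(2N, g)]: the expected
    number of distinct alleles in a random subsample of ``g`` allele
    copies.  The default ``g`` is, per locus, the smallest non-missing
    allele-copy count across populations; a user-supplied ``g`` must not
    exceed that minimum at any locus.
    """
    pops, n, p, _ = _pop_arrays(G)
    copies = (2 * n).astype(int)
    with_data = copies > 0
    ar = np.full_like(p, np.nan)
    for j in range(G.n_loci):
        ks = np.flatnonzero(with_data[:, j])
        if ks.size == 0:
            continue
        g_j = int(copies[ks, j].min()) if g is None else int(g)
        if g_j < 1:
            continue
        if g_j > copies[ks, j].min():
            raise ValueError(
                f"g={g_j} exceeds the minimum allele-copy count at locus {G.locus_ids[j]}"
            )
        for k in ks:
            two_n = int(copies[k, j])
            n_alt = int(round(p[k, j] * two_n))
            denom = math.comb(two_n, g_j)
            total = 0.0
            for n_a in (n_alt, two_n - n_alt):
                if n_a > 0:
                    total += 1.0 - math.comb(two_n - n_a, g_j) / denom
            ar[k, j] = total
    return pd.DataFrame({"population": pops, "Ar": np.nanmean(ar, axis=1)})


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components
# ---------------------------------------------------------------------------

def weir_cockerham_components(G: GenotypeMatrix, pops: list[str] | None = None
                              ) -> pd.DataFrame:
    """Per-locus W&C (1984) a/b/c variance components across populations.

    Rows where fewer than two populations have data carry NaN (the locus is
    undefined for that comparison).  Columns: a, b, c, n_pops.
    """
    pops, n, p, h = _pop_arrays(G, pops)
    a = np.full(G.n_loci, np.nan)
    b = np.full(G.n_loci, np.nan)
    c = np.full(G.n_loci, np.nan)
    r_used = np.zeros(G.n_loci, int)
    for j in range(G.n_loci):
        ok = n[:, j] > 0
        r = int(ok.sum())
        r_used[j] = r
        if r < 2:
            continue
        nj, pj, hj = n[ok, j], p[ok, j], h[ok, j]
        nbar = nj.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (nj**2).sum() / (r * nbar)) / (r - 1)
        pbar = (nj * pj).sum() / (r * nbar)
        s2 = (nj * (pj - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (nj * hj).sum() / (r * nbar)
        if nc <= 0:
            continue
        a[j] = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b[j] = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c[j] = hbar / 2.0
    return pd.DataFrame({"a": a, "b": b, "c": c, "n_pops": r_used}, index=G.locus_ids)


def _single_pop_bc(G: GenotypeMatrix, pop: str) -> pd.DataFrame:
    """Within-sample b/c components (r = 1; the s² term vanishes)."""
    _, n, p, h = _pop_arrays(G, [pop])
    nj, pj, hj = n[0], p[0], h[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        b = (nj / (nj - 1)) * (pj * (1 - pj) - (2 * nj - 1) / (4 * nj) * hj)
    b = np.where(nj > 1, b, np.nan)
    c = np.where(nj > 0, hj / 2.0, np.nan)
    return pd.DataFrame({"b": b, "c": c}, index=G.locus_ids)


def fis_weir_cockerham(G: GenotypeMatrix, scope: str = "per_population",
                       pops: list[str] | None = None):
    """W&C inbreeding coefficient f = 1 − Σc / Σ(b+c) at three scopes.

    ``scope``:
      * ``'locus_across_populations'`` — per locus, components summed over
        populations (from the multi-population a/b/c decomposition);
      * ``'locus_within_population'`` — per (locus, population) single-sample
        estimate;
      * ``'per_population'`` — per population across loci (component sums).
    """
    pops = pops if pops is not None else G.populations
    if scope == "locus_across_populations":
        comp = weir_cockerham_components(G, pops)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = 1.0 - comp["c"] / (comp["b"] + comp["c"])
        return pd.DataFrame({"Fis": f}, index=G.locus_ids)
    if scope == "locus_within_population":
        frames = []
        for pop in pops:
            bc = _single_pop_bc(G, pop)
            with np.errstate(invalid="ignore", divide="ignore"):
                f = 1.0 - bc["c"] / (bc["b"] + bc["c"])
            frames.append(pd.DataFrame({"population": pop, "locus": G.locus_ids,
                                        "Fis": f.to_numpy()}))
        return pd.concat(frames, ignore_index=True)
    if scope == "per_population":
        recs = []
        for pop in pops:
            bc = _single_pop_bc(G, pop).dropna()
            denom = (bc["b"] + bc["c"]).sum()
            recs.append(dict(population=pop,
                             Fis=1.0 - bc["c"].sum() / denom if denom > 0 else np.nan))
        return pd.DataFrame(recs)
    raise ValueError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# Pairwise Fst and permutation significance
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Pairwise theta matrix with permutation p-values."""

    theta: pd.DataFrame
    p_values: pd.DataFrame | None = None
    n_permutations: int = 0
    alpha: float = 0.05
    metadata: dict = field(default_factory=dict)

    @property
    def bonferroni_level(self) -> float:
        return bonferroni_threshold(len(self.theta), self.alpha)

    def significant(self) -> pd.DataFrame:
        if self.p_values is None:
            raise ValueError("no permutation p-values computed")
        return self.p_values < self.bonferroni_level

    def to_long(self) -> pd.DataFrame:
        codes = list(self.theta.index)
        recs = []
        for a, b in itertools.combinations(codes, 2):
            rec = dict(site_a=a, site_b=b, theta=self.theta.loc[a, b])
            if self.p_values is not None:
                rec["p_value"] = self.p_values.loc[a, b]
                rec["significant"] = rec["p_value"] < self.bonferroni_level
            recs.append(rec)
        return pd.DataFrame(recs)


def _pair_theta(G: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    comp = weir_cockerham_components(G.subset_populations([pop_a, pop_b]),
                                     [pop_a, pop_b]).dropna()
    denom = (comp["a"] + comp["b"] + comp["c"]).sum()
    if denom == 0 or not len(comp):
        return np.nan
    return float(comp["a"].sum() / denom)


def pairwise_fst(G: GenotypeMatrix) -> FstResult:
    """Weir–Cockerham theta for every population pair (ratio of sums).

    Loci with undefined variance components for a pair (no data in one of
    the two populations) are excluded pair-by-pair; negative estimates are
    reported as computed.
    """
    pops = G.populations
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for a, b in itertools.combinations(pops, 2):
        t = _pair_theta(G, a, b)
        mat.loc[a, b] = mat.loc[b, a] = t
    return FstResult(mat)


def _g_from_group_counts(a: np.ndarray, col_tot: np.ndarray) -> float:
    """G statistic summed over loci from per-locus genotype counts.

    ``a``: counts (3, L) of genotypes {0,1,2} in group A; ``col_tot`` the
    pooled counts (3, L).  Uses the log-likelihood identity
    G = 2 [Σ O logO − Σ R logR − Σ C logC + N logN] per locus.
    """
    from scipy.special import xlogy

    b = col_tot - a
    na = a.sum(axis=0)
    nb = b.sum(axis=0)
    n = na + nb
    term = (xlogy(a, a).sum(axis=0) + xlogy(b, b).sum(axis=0)
            - xlogy(na, na) - xlogy(nb, nb)
            - xlogy(col_tot, col_tot).sum(axis=0) + xlogy(n, n))
    return float(2.0 * term.sum())


def _g_statistic(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Genotype-table log-likelihood G statistic summed over loci."""
    a = np.stack([(calls_a == g).sum(axis=0) for g in (0, 1, 2)]).astype(float)
    b = np.stack([(calls_b == g).sum(axis=0) for g in (0, 1, 2)]).astype(float)
    return _g_from_group_counts(a, a + b)


def fst_significance(G: GenotypeMatrix, n_permutations: int = 1000,
                     seed: int = 0, alpha: float = 0.05) -> FstResult:
    """Pairwise theta plus genotype-permutation p-values.

    For each pair, whole multilocus genotypes are shuffled between the two
    populations (the test does not assume Hardy–Weinberg within samples);
    the statistic is the genotype-contingency G summed over loci, and
    p = (1 + #{permuted ≥ observed}) / (1 + n_permutations).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    res = pairwise_fst(G)
    pops = G.populations
    pmat = pd.DataFrame(1.0, index=pops, columns=pops)
    for a, b in itertools.combinations(pops, 2):
        ia = np.flatnonzero(G.population_mask(a))
        ib = np.flatnonzero(G.population_mask(b))
        pool = np.concatenate([ia, ib])
        calls = G.calls[pool]
        na = len(ia)
        onehot = np.stack([(calls == g) for g in (0, 1, 2)]).astype(float)  # (3,n,L)
        col_tot = onehot.sum(axis=1)
        obs = _g_from_group_counts(onehot[:, :na, :].sum(axis=1), col_tot)
        count = 0
        for _ in range(n_permutations):
            sel = rng.permutation(len(pool))[:na]
            if _g_from_group_counts(onehot[:, sel, :].sum(axis=1), col_tot) >= obs - 1e-9:
                count += 1
        p = (1.0 + count) / (1.0 + n_permutations)
        pmat.loc[a, b] = pmat.loc[b, a] = p
    np.fill_diagonal(pmat.values, np.nan)
    res.p_values = pmat
    res.n_permutations = n_permutations
    res.alpha = alpha
    res.metadata = dict(seed=seed, statistic="genotype G log-likelihood")
    return res


def bonferroni_threshold(n_populations: int, alpha: float = 0.05) -> float:
    """Adjusted nominal level alpha / C(n_populations, 2)."""
    if n_populations < 2:
        raise ValueError("need at least two populations")
    return alpha / math.comb(n_populations, 2)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (report-layer convention)."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(f"{x:.{sig}g}")


# ---------------------------------------------------------------------------
# LD effective population size
# ---------------------------------------------------------------------------

@dataclass
class NeEstimate:
    """LD-based Ne with jackknife CI; np.inf encodes the infinite estimate."""

    population: str
    ne: float
    ci_low: float
    ci_high: float
    r2_mean: float
    r2_drift: float
    n_pairs: int
    n_loci_used: int
    sample_size: float
    pcrit: float

    def ne_for_log10(self, infinite_substitute: float = 1000.0) -> float:
        """Report-layer value: infinite estimates become the substitute
        (used only for log10-scale plotting, never in inference)."""
        return infinite_substitute if np.isinf(self.ne) else self.ne


def _expected_r2(s: np.ndarray) -> np.ndarray:
    """Sampling expectation of r² under random mating (Waples 2006)."""
    s = np.asarray(s, float)
    large = 1.0 / s + 3.19 / s**2
    small = 0.0018 + 0.907 / s + 4.44 / s**2
    return np.where(s >= 30, large, small)


def _ne_from_r2drift(r2d: float, s_harmonic: float) -> float:
    if r2d <= 0:
        return np.inf
    if s_harmonic >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2d
        if disc < 0:
            return max((1.0 / 3.0) / (2.0 * r2d), 0.0)
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2d)
    disc = 0.308**2 - 2.08 * r2d
    if disc < 0:
        return max(0.308 / (2.0 * r2d), 0.0)
    return (0.308 + math.sqrt(disc)) / (2.0 * r2d)


def _weighted_mean_r2(X: np.ndarray) -> tuple[float, float, int]:
    """Weighted mean of squared pairwise-complete dosage correlations.

    Weights are the per-pair complete sample sizes.  Returns
    (mean r², harmonic-mean S, number of informative pairs).
    """
    L = X.shape[1]
    O = (~np.isnan(X)).astype(float)
    Z = np.where(np.isnan(X), 0.0, X)
    n_jk = O.T @ O
    sx = Z.T @ O
    sxy = Z.T @ Z
    sxx = (Z * Z).T @ O
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = sx / n_jk
        cov = sxy / n_jk - mx * mx.T
        var_x = sxx / n_jk - mx**2
        r2m = cov**2 / (var_x * var_x.T)
    iu = np.triu_indices(L, k=1)
    r2s, w = r2m[iu], n_jk[iu]
    ok = np.isfinite(r2s) & (w >= 3)
    r2s, w = r2s[ok], w[ok]
    if r2s.size < 2:
        raise ValueError("not enough informative locus pairs")
    s_harm = r2s.size / (1.0 / w).sum()
    return float((w * r2s).sum() / w.sum()), float(s_harm), int(r2s.size)


def ld_ne(G: GenotypeMatrix, pcrit: float = 0.02, mating: str = "random",
          population: str | None = None, correction: str = "simulated",
          n_null: int = 12, seed: int = 0) -> list[NeEstimate]:
    """Linkage-disequilibrium Ne per population.

    The squared correlation of genotype dosages (the Burrows composite
    measure) is averaged over all pairs of loci passing the ``pcrit``
    minor-allele-frequency screen, weighted by the number of individuals
    complete for the pair; the expected sampling contribution E[r²|S] is
    subtracted, and Ne follows the standard random-mating drift formula.
    A non-positive drift signal yields the INFINITE estimate.

    ``correction='simulated'`` (default) computes E[r²|S] by a seeded
    Monte-Carlo null calibration: ``n_null`` replicates of independent
    Hardy–Weinberg loci at the observed allele frequencies and sample
    geometry.  ``correction='asymptotic'`` uses the classical closed-form
    approximation (1/S + 3.19/S² for S ≥ 30), which over-corrects when
    the sample approaches the whole population.

    The CI is a delete-one-individual jackknife on the mean r² with a
    t(S−1) quantile, transformed to the Ne scale.
    """
    if mating != "random":
        raise NotImplementedError("only the random-mating correction is implemented")
    if correction not in ("simulated", "asymptotic"):
        raise ValueError("correction must be 'simulated' or 'asymptotic'")
    from scipy import stats as _st

    pops = [population] if population else G.populations
    rng = np.random.default_rng(seed)
    out = []
    for pop in pops:
        sub = G.calls[G.population_mask(pop)].astype(float)
        sub[sub == MISSING] = np.nan
        cnt = np.sum(~np.isnan(sub), axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.nansum(sub, axis=0) / (2.0 * cnt)
        usable = (cnt > 1) & (np.minimum(freq, 1 - freq) >= pcrit)
        X = sub[:, usable]
        L = X.shape[1]
        if L < 2:
            raise ValueError(f"population {pop}: fewer than 2 usable loci")
        try:
            r2_mean, s_harm, n_pairs = _weighted_mean_r2(X)
        except ValueError as exc:
            raise ValueError(f"population {pop}: {exc}") from exc

        if correction == "simulated":
            S = X.shape[0]
            miss = np.isnan(X)
            nulls = []
            for _ in range(n_null):
                Xn = rng.binomial(2, freq[usable], size=(S, L)).astype(float)
                Xn[miss] = np.nan
                nulls.append(_weighted_mean_r2(Xn)[0])
            e_r2 = float(np.mean(nulls))
        else:
            e_r2 = float(_expected_r2(np.asarray(s_harm)))
        r2_drift = r2_mean - e_r2
        ne = _ne_from_r2drift(r2_drift, s_harm)

        # delete-one-individual jackknife on the mean r²
        S = X.shape[0]
        loo = np.empty(S)
        for i in range(S):
            loo[i] = _weighted_mean_r2(np.delete(X, i, axis=0))[0]
        var_j = (S - 1) / S * ((loo - loo.mean()) ** 2).sum()
        q = float(_st.t.ppf(0.975, S - 1))
        se = math.sqrt(var_j)
        ci_low = _ne_from_r2drift(r2_drift + q * se, s_harm)
        ci_high = _ne_from_r2drift(r2_drift - q * se, s_harm)
        out.append(NeEstimate(pop, ne, ci_low, ci_high, r2_mean,
                              float(r2_drift), n_pairs, L, float(s_harm), pcrit))
    return out


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

@dataclass
class DapcResult:
    coords: pd.DataFrame            # individuals x retained discriminant axes
    var_pct: np.ndarray             # % of between-group (discriminant) variance
    centroids: pd.DataFrame         # group x axes
    n_pcs: int


def dapc(G: GenotypeMatrix, group_labels: np.ndarray | None = None,
         n_pcs: int | None = None, n_axes: int | None = None) -> DapcResult:
    """Discriminant analysis of principal components.

    Missing calls are mean-imputed per locus, the matrix centred and
    projected on the leading ``n_pcs`` principal components, then a linear
    discriminant analysis is run on the group labels.  ``var_pct`` is the
    percentage of discriminant (between-group) variance per retained axis.
    """
    from sklearn.decomposition import PCA
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    labels = np.asarray(group_labels if group_labels is not None
                        else G.population_labels).astype(str)
    groups = pd.unique(labels)
    n = G.n_individuals
    if n_pcs is None:
        n_pcs = min(n - 1, G.n_loci, 50)
    if n_pcs >= n:
        raise ValueError("n_pcs must be smaller than the number of individuals")
    max_axes = len(groups) - 1
    if n_axes is None:
        n_axes = max_axes
    if n_axes > max_axes:
        raise ValueError(f"n_axes cannot exceed groups-1 = {max_axes}")

    X = G.calls.astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X -= X.mean(axis=0)

    scores = PCA(n_components=n_pcs, svd_solver="full").fit_transform(X)
    lda = LinearDiscriminantAnalysis(solver="eigen", n_components=n_axes)
    ld_coords = lda.fit_transform(scores, labels)
    var_pct = 100.0 * lda.explained_variance_ratio_[:n_axes]
    axes = [f"LD{k + 1}" for k in range(ld_coords.shape[1])]
    coords = pd.DataFrame(ld_coords, index=G.individual_ids, columns=axes)
    coords["group"] = labels
    centroids = coords.groupby("group", sort=False)[axes].mean()
    return DapcResult(coords, var_pct, centroids, n_pcs)


# ---------------------------------------------------------------------------
# Assembled diversity table
# ---------------------------------------------------------------------------

def diversity_table(G: GenotypeMatrix, rarefaction_g: int | None = None,
                    include_ne: bool = True, pcrit: float = 0.02) -> pd.DataFrame:
    """Per-population N, Ar, Ho, He, Fis and (optionally) LD-Ne with CI."""
    summary, _ = heterozygosities(G)
    ar = allelic_richness(G, rarefaction_g)
    fis = fis_weir_cockerham(G, "per_population")
    tbl = summary.merge(ar, on="population").merge(fis, on="population")
    if include_ne:
        ne_rows = {e.population: e for e in ld_ne(G, pcrit=pcrit)}
        tbl["Ne"] = [ne_rows[p].ne for p in tbl["population"]]
        tbl["Ne_ci_low"] = [ne_rows[p].ci_low for p in tbl["population"]]
        tbl["Ne_ci_high"] = [ne_rows[p].ci_high for p in tbl["population"]]
    return tbl
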