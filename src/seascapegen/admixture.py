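"""Maximum-likelihood admixture inference, replicate alignment, Evanno K.

The model is the classical admixture likelihood for unlinked biallelic
loci: individual i carries ancestry proportions q_i (a point on the
K-simplex) and cluster k has allele frequency f_kl at locus l, so the
genotype dosage g_il is Binomial(2, Σ_k q_ik f_kl).  The log-likelihood

    ℓ(Q, F) = Σ_il [ log C(2, g) + g log μ_il + (2−g) log(1−μ_il) ],
    μ_il = Σ_k q_ik f_kl,

is maximised by an expectation–maximisation block relaxation whose updates
are the standard multiplicative (EM) steps for Q and F; each update is
guaranteed not to decrease ℓ.  Missing calls contribute nothing.  This is
a deterministic, likelihood-based stand-in for MCMC clustering programs:
the downstream quantities — the Q matrix, a per-run likelihood for the
Evanno ΔK criterion, and the population classification — depend only on
those outputs.  Replicate runs from independent seeds play the role of
independent chains; their label switching is undone by exhaustive
permutation alignment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "AdmixtureModel",
    "AdmixtureResults",
    "fit_admixture",
    "align_replicates",
    "evanno_best_k",
    "EvannoTable",
    "classify_populations",
    "PopulationClassification",
]

_F_CLAMP = 1e-6


class AdmixtureModel:
    """Admixture likelihood model for a genotype matrix and fixed K.

    Parameters
    ----------
    genotypes
        A :class:`~seascapegen.genotypes.GenotypeMatrix` (or a raw dosage
        array with entries in {0, 1, 2, MISSING}).
    K
        Number of ancestral clusters (K >= 1).
    """

    def __init__(self, genotypes: GenotypeMatrix | np.ndarray, K: int):
        if K < 1:
            raise ValueError("K must be >= 1")
        if isinstance(genotypes, GenotypeMatrix):
            self.data = genotypes
            calls = genotypes.calls
        else:
            self.data = None
            calls = np.asarray(genotypes, dtype=np.int16)
        self.K = int(K)
        self._g = calls.astype(float)
        self._obs = calls != MISSING
        self._g[~self._obs] = 0.0
        self._g2 = np.where(self._obs, 2.0 - self._g, 0.0)
        self._n, self._L = calls.shape
        self._L_obs = self._obs.sum(axis=1).astype(float)
        if (self._L_obs == 0).any():
            raise ValueError("some individual has no observed calls")
        # binomial coefficient constant: log C(2, g) = log 2 for heterozygotes
        self._const = float(np.log(2.0) * np.count_nonzero(calls == 1))
        n_distinct = len({tuple(row) for row in calls.tolist()})
        self.degenerate = self.K > n_distinct

    # -- likelihood -------------------------------------------------------
    def loglike(self, Q: np.ndarray, F: np.ndarray) -> float:
        mu = np.clip(Q @ F, _F_CLAMP, 1.0 - _F_CLAMP)
        return float(
            np.sum(self._g * np.log(mu) + self._g2 * np.log1p(-mu)) + self._const
        )

    # -- fitting ----------------------------------------------------------
    def fit(self, seed: int = 0, max_iter: int = 2000, tol: float = 1e-6
            ) -> "AdmixtureResults":
        """EM block relaxation from a random Dirichlet/Uniform start."""
        rng = np.random.default_rng(seed)
        K = self.K
        Q = rng.dirichlet(np.ones(K), size=self._n)
        F = rng.uniform(0.05, 0.95, size=(K, self._L))
        ll_prev = -np.inf
        ll = self.loglike(Q, F)
        history = [ll]
        converged = False
        for it in range(1, max_iter + 1):
            F = np.clip(F, _F_CLAMP, 1.0 - _F_CLAMP)
            mu = np.clip(Q @ F, _F_CLAMP, 1.0 - _F_CLAMP)
            R1 = self._g / mu          # zero where missing
            R0 = self._g2 / (1.0 - mu)
            # E-step responsibilities folded into multiplicative updates
            num1 = Q * (R1 @ F.T)      # (n, K): expected alt-allele count by cluster
            num0 = Q * (R0 @ (1.0 - F).T)
            Q_new = (num1 + num0) / (2.0 * self._L_obs[:, None])
            Q_new /= Q_new.sum(axis=1, keepdims=True)
            A = F * (Q.T @ R1)         # (K, L)
            B = (1.0 - F) * (Q.T @ R0)
            with np.errstate(invalid="ignore"):
                F_new = A / (A + B)
            F_new = np.where(np.isfinite(F_new), F_new, F)
            Q, F = Q_new, np.clip(F_new, _F_CLAMP, 1.0 - _F_CLAMP)
            ll_prev, ll = ll, self.loglike(Q, F)
            history.append(ll)
            if abs(ll - ll_prev) < tol:
                converged = True
                break
        return AdmixtureResults(self, Q, F, ll, K, seed, len(history) - 1,
                                converged, np.asarray(history))

    def fit_replicates(self, n_replicates: int = 5, seed: int = 0,
                       **kwargs) -> list["AdmixtureResults"]:
        """Independent EM runs from seeds spawned off ``seed``."""
        ss = np.random.SeedSequence(seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]
        return [self.fit(seed=s, **kwargs) for s in seeds]


@dataclass
class AdmixtureResults:
    """Fitted ancestry proportions and cluster frequencies."""

    model: AdmixtureModel
    Q: np.ndarray             # (n, K), rows on the simplex
    F: np.ndarray             # (K, L)
    log_likelihood: float
    K: int
    seed: int
    iterations: int
    converged: bool
    loglik_history: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("Q rows must sum to 1")

    def q_frame(self) -> pd.DataFrame:
        cols = [f"Q{k + 1}" for k in range(self.K)]
        df = pd.DataFrame(self.Q, columns=cols)
        if self.model.data is not None:
            df.insert(0, "individual", self.model.data.individual_ids)
            df.insert(1, "population", self.model.data.population_labels.astype(str))
        return df

    def relabel(self, perm: tuple[int, ...]) -> "AdmixtureResults":
        """Return a copy with clusters permuted (loglik is invariant)."""
        perm = tuple(perm)
        return AdmixtureResults(self.model, self.Q[:, perm], self.F[list(perm), :],
                                self.log_likelihood, self.K, self.seed,
                                self.iterations, self.converged, self.loglik_history)

    def summary(self) -> str:
        lines = [
            "Admixture maximum-likelihood fit",
            f"  K = {self.K}, n = {self.Q.shape[0]}, loci = {self.F.shape[1]}",
            f"  log-likelihood = {self.log_likelihood:.4f}",
            f"  iterations = {self.iterations} (converged: {self.converged})",
            f"  seed = {self.seed}",
        ]
        if self.model.degenerate:
            lines.append("  WARNING: K exceeds the number of distinct multilocus "
                         "genotypes (degenerate fit)")
        if self.model.data is not None:
            means = self.q_frame().groupby("population", sort=False)[
                [f"Q{k + 1}" for k in range(self.K)]
            ].mean()
            lines.append("  population mean Q:")
            lines.extend("    " + s for s in means.round(3).to_string().splitlines())
        return "\n".join(lines)


def fit_admixture(G: GenotypeMatrix, K: int, seed: int = 0, max_iter: int = 2000,
                  tol: float = 1e-6) -> AdmixtureResults:
    """Functional wrapper over :class:`AdmixtureModel`."""
    import warnings

    model = AdmixtureModel(G, K)
    if model.degenerate:
        warnings.warn(f"K={K} exceeds the number of distinct multilocus genotypes",
                      stacklevel=2)
    return model.fit(seed=seed, max_iter=max_iter, tol=tol)


# ---------------------------------------------------------------------------
# Replicate alignment and Evanno
# ---------------------------------------------------------------------------

def align_replicates(fits: list[AdmixtureResults]
                     ) -> tuple[list[AdmixtureResults], np.ndarray]:
    """Undo label switching across replicate runs of equal K.

    Each replicate's cluster labels are permuted to minimise the Frobenius
    distance of its Q matrix to the highest-likelihood replicate
    (exhaustive over the K! permutations; K <= 6).  Returns the aligned
    fits and the consensus Q (mean of aligned Q matrices).
    """
    if not fits:
        raise ValueError("no fits supplied")
    K = fits[0].K
    if any(f.K != K for f in fits):
        raise ValueError("all fits must share K")
    if K > 6:
        raise ValueError("exhaustive alignment supported only for K <= 6")
    ref = max(fits, key=lambda f: f.log_likelihood)
    aligned = []
    for f in fits:
        best_perm = min(
            itertools.permutations(range(K)),
            key=lambda perm: float(np.linalg.norm(f.Q[:, perm] - ref.Q)),
        )
        aligned.append(f.relabel(best_perm))
    consensus = np.mean([f.Q for f in aligned], axis=0)
    return aligned, consensus


@dataclass
class EvannoTable:
    table: pd.DataFrame   # per K: mean_loglik, sd_loglik, n_replicates, delta_k
    best_k: int | None
    flags: list[str] = field(default_factory=list)


def evanno_best_k(fits_by_k: dict[int, list[AdmixtureResults]]) -> EvannoTable:
    """ΔK = |L(K+1) − 2 L(K) + L(K−1)| / SD(K), maximised over interior K.

    Needs at least three replicates per K and three consecutive K values.
    A K with zero between-replicate SD has undefined ΔK and is skipped
    (flagged); if no interior K has a defined ΔK the best K is None.
    """
    ks = sorted(fits_by_k)
    for k in ks:
        if len(fits_by_k[k]) < 3:
            raise ValueError(f"K={k}: Evanno needs at least 3 replicates")
    mean = {k: float(np.mean([f.log_likelihood for f in fits_by_k[k]])) for k in ks}
    sd = {k: float(np.std([f.log_likelihood for f in fits_by_k[k]], ddof=1)) for k in ks}
    flags: list[str] = []
    rows = []
    for k in ks:
        delta = np.nan
        if k - 1 in mean and k + 1 in mean:
            if sd[k] == 0.0:
                flags.append(f"K={k}: zero replicate SD, delta-K undefined")
            else:
                delta = abs(mean[k + 1] - 2.0 * mean[k] + mean[k - 1]) / sd[k]
        rows.append(dict(K=k, mean_loglik=mean[k], sd_loglik=sd[k],
                         n_replicates=len(fits_by_k[k]), delta_k=delta))
    table = pd.DataFrame(rows).set_index("K")
    valid = table["delta_k"].dropna()
    best = int(valid.idxmax()) if len(valid) else None
    if best is None:
        flags.append("no interior K with defined delta-K; best K undetermined")
    elif len(valid) > 1:
        ordered = valid.sort_values(ascending=False)
        if ordered.iloc[0] < 2.0 * ordered.iloc[1]:
            flags.append("weak support: top delta-K less than twice the runner-up")
    return EvannoTable(table, best, flags)


# ---------------------------------------------------------------------------
# Population classification
# ---------------------------------------------------------------------------

@dataclass
class PopulationClassification:
    """Per-population ancestry means and the admixture category."""

    table: pd.DataFrame   # population, mean Q per cluster, category
    threshold: float
    mode: str
    cluster_names: list[str]

    @property
    def admixed_populations(self) -> list[str]:
        return self.table.loc[self.table["category"] == "admixed",
                              "population"].tolist()

    def category_of(self, population: str) -> str:
        row = self.table.loc[self.table["population"] == population]
        if not len(row):
            raise KeyError(population)
        return str(row["category"].iloc[0])


def classify_populations(consensus_q: np.ndarray, population_labels,
                         threshold: float = 0.2, mode: str = "population_mean",
                         cluster_names: tuple[str, str] = ("lineage_A", "lineage_B"),
                         ) -> PopulationClassification:
    """Categorise populations as pure or admixed by the Q > threshold rule.

    ``mode='population_mean'``: a population is admixed iff its mean
    minority-cluster ancestry exceeds ``threshold`` (strict >), else pure
    with the dominant cluster's label.  ``mode='individual_strict'``: a
    population is pure only if *every* individual's minority ancestry is
    below the threshold (the stricter of the two pure-lineage dataset
    designs); any individual above it makes the population admixed.
    """
    if not (0.0 < threshold < 0.5):
        raise ValueError("threshold must be in (0, 0.5)")
    if mode not in ("population_mean", "individual_strict"):
        raise ValueError("mode must be 'population_mean' or 'individual_strict'")
    Q = np.asarray(consensus_q, float)
    if Q.ndim != 2 or Q.shape[1] != 2:
        raise ValueError("classification is defined for K = 2 ancestry matrices")
    labels = np.asarray(population_labels).astype(str)
    recs = []
    for pop in pd.unique(labels):
        qp = Q[labels == pop]
        means = qp.mean(axis=0)
        dominant = int(np.argmax(means))
        if means[0] == means[1]:
            dominant = 0  # tie broken by cluster index, flagged below
        minority_mean = float(means.min())
        if mode == "population_mean":
            admixed = minority_mean > threshold
        else:
            admixed = bool((qp.min(axis=1) > threshold).any())
        category = "admixed" if admixed else f"pure_{cluster_names[dominant]}"
        recs.append(dict(population=pop, mean_Q1=float(means[0]),
                         mean_Q2=float(means[1]), minority_mean=minority_mean,
                         category=category, dominant_tie=bool(means[0] == means[1])))
    return PopulationClassification(pd.DataFrame(recs), threshold, mode,
                                    list(cluster_names))
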