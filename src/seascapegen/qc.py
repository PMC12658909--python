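"""Locus and sample quality-control filters with an auditable report.

The filter ledger applied to a SNP panel, in its canonical order:

1. missingness — loci failing in more than 15% of samples are dropped,
   then samples missing more than 15% of the retained loci;
2. monomorphic / minor-allele-frequency — monomorphic loci and loci with
   overall MAF < 0.01 (strict ``<``) are dropped;
3. Fis two-pass — loci whose global Weir–Cockerham Fis lies outside
   ±0.3 are candidates; a candidate is dropped only if its per-population
   Fis exceeds the bound in more than 50% of the NON-admixed populations
   (an extreme Fis explained by admixture is kept);
4. Fst pruning (only ahead of pairwise-Fst estimation) — loci with
   elevated missingness that leave some pairwise variance-component term
   undefined (zero complete genotypes in a population) are removed
   iteratively, highest missingness first.

All thresholds are parameters; every discard carries exactly one primary
reason, and ``retained + discarded`` equals the input count on both axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotypes import MISSING, GenotypeMatrix
from . import popgen

__all__ = [
    "LocusFilterReport",
    "filter_missingness",
    "filter_monomorphic_and_maf",
    "fis_two_pass_filter",
    "prune_loci_for_fst",
    "apply_qc",
]

LOCUS_REASONS = ("retained", "monomorphic", "maf_below_threshold",
                 "locus_missingness", "fis_out_of_bounds", "fst_pruned")
SAMPLE_REASONS = ("retained", "sample_missingness")


@dataclass
class LocusFilterReport:
    """Per-locus and per-sample filter outcome for one filtering pass."""

    stage: str
    locus_status: dict[str, str] = field(default_factory=dict)
    sample_status: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for status in self.locus_status.values():
            if status not in LOCUS_REASONS:
                raise ValueError(f"unknown locus status {status!r}")
        for status in self.sample_status.values():
            if status not in SAMPLE_REASONS:
                raise ValueError(f"unknown sample status {status!r}")

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for status in list(self.locus_status.values()) + list(self.sample_status.values()):
            out[status] = out.get(status, 0) + 1
        return out

    def discarded_loci(self) -> list[str]:
        return [k for k, v in self.locus_status.items() if v != "retained"]

    def discarded_samples(self) -> list[str]:
        return [k for k, v in self.sample_status.items() if v != "retained"]

    def to_json(self, path: str | Path | None = None) -> str:
        obj = dict(stage=self.stage, params=self.params, counts=self.counts,
                   locus_status=self.locus_status, sample_status=self.sample_status,
                   detail=self.detail)
        text = json.dumps(obj, indent=1, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        lines = [f"filter stage: {self.stage}", f"parameters: {self.params}"]
        for reason, cnt in sorted(self.counts.items()):
            lines.append(f"  {reason}: {cnt}")
        discards = self.discarded_loci()
        if discards:
            lines.append("discarded loci: " + ", ".join(discards))
        discards = self.discarded_samples()
        if discards:
            lines.append("discarded samples: " + ", ".join(discards))
        return "\n".join(lines)


def _report(stage: str, G: GenotypeMatrix, drop_loci: dict[str, str],
            drop_samples: dict[str, str] | None = None, params: dict | None = None,
            detail: dict | None = None) -> LocusFilterReport:
    locus_status = {l: drop_loci.get(l, "retained") for l in G.locus_ids}
    sample_status = {
        i: (drop_samples or {}).get(i, "retained") for i in G.individual_ids
    }
    return LocusFilterReport(stage, locus_status, sample_status,
                             params or {}, detail or {})


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_missingness(G: GenotypeMatrix, locus_threshold: float = 0.15,
                       sample_threshold: float = 0.15
                       ) -> tuple[GenotypeMatrix, LocusFilterReport]:
    """Drop high-missingness loci first, then samples on the retained loci."""
    for t in (locus_threshold, sample_threshold):
        if not (0.0 < t <= 1.0):
            raise ValueError("thresholds must be in (0, 1]")
    locus_miss = G.missing_fraction("locus")
    drop_l = {G.locus_ids[j]: "locus_missingness"
              for j in np.flatnonzero(locus_miss > locus_threshold)}
    G1 = G.subset_loci(locus_miss <= locus_threshold)
    if G1.n_loci == 0:
        raise ValueError("all loci filtered by missingness")
    sample_miss = G1.missing_fraction("individual")
    drop_s = {G1.individual_ids[i]: "sample_missingness"
              for i in np.flatnonzero(sample_miss > sample_threshold)}
    G2 = G1.subset_individuals(sample_miss <= sample_threshold)
    if G2.n_individuals == 0:
        raise ValueError("all samples filtered by missingness")
    report = _report("missingness", G, drop_l, drop_s,
                     dict(locus_threshold=locus_threshold,
                          sample_threshold=sample_threshold),
                     dict(order="loci first, then samples on retained loci"))
    return G2, report


def filter_monomorphic_and_maf(G: GenotypeMatrix, maf_threshold: float = 0.01
                               ) -> tuple[GenotypeMatrix, LocusFilterReport]:
    """Drop monomorphic loci and polymorphic loci with overall MAF < threshold."""
    freq = popgen.allele_frequencies(G, by_population=False)["frequency"].to_numpy()
    drop: dict[str, str] = {}
    for j, locus in enumerate(G.locus_ids):
        f = freq[j]
        if np.isnan(f):
            continue  # all-missing locus: not assessable here
        maf = min(f, 1.0 - f)
        if maf == 0.0:
            drop[locus] = "monomorphic"
        elif maf < maf_threshold:
            drop[locus] = "maf_below_threshold"
    keep = np.asarray([l not in drop for l in G.locus_ids])
    G1 = G.subset_loci(keep)
    if G1.n_loci == 0:
        raise ValueError("all loci filtered as monomorphic/low MAF")
    report = _report("monomorphic_maf", G, drop, None,
                     dict(maf_threshold=maf_threshold))
    return G1, report


def fis_two_pass_filter(G: GenotypeMatrix, classification,
                        fis_bound: float = 0.3, population_fraction: float = 0.5
                        ) -> tuple[GenotypeMatrix, LocusFilterReport]:
    """Two-pass |Fis| filter that spares admixture-driven outliers.

    ``classification`` is either an object with an ``admixed_populations``
    attribute (see the admixture module) or an iterable of admixed
    population codes.  Pass 1 flags loci with global |Fis| > ``fis_bound``
    across all populations; pass 2 re-examines each candidate within the
    non-admixed populations only and discards it iff the per-population
    |Fis| exceeds the bound in more than ``population_fraction`` of them.
    """
    if not (0.0 < abs(fis_bound) < 1.0):
        raise ValueError("|fis_bound| must be in (0,1)")
    admixed = set(getattr(classification, "admixed_populations", classification))
    non_admixed = [p for p in G.populations if p not in admixed]
    if not non_admixed:
        raise ValueError(
            "no non-admixed populations: the two-pass Fis filter is undefined; "
            "revisit the classification threshold"
        )

    global_fis = popgen.fis_weir_cockerham(G, "locus_across_populations")["Fis"]
    candidates = [l for l in G.locus_ids
                  if np.isfinite(global_fis[l]) and abs(global_fis[l]) > fis_bound]

    per_pop = popgen.fis_weir_cockerham(G, "locus_within_population",
                                        pops=non_admixed)
    per_pop = per_pop.pivot(index="locus", columns="population", values="Fis")
    drop: dict[str, str] = {}
    flags: dict[str, dict] = {}
    for locus in candidates:
        vals = per_pop.loc[locus].dropna() if locus in per_pop.index else per_pop.iloc[0:0, 0]
        n_def = int(len(vals))
        n_out = int((vals.abs() > fis_bound).sum())
        flags[locus] = dict(global_fis=float(global_fis[locus]),
                            n_nonadmixed_defined=n_def, n_out_of_bounds=n_out)
        if n_def > 0 and n_out / n_def > population_fraction:
            drop[locus] = "fis_out_of_bounds"
    keep = np.asarray([l not in drop for l in G.locus_ids])
    report = _report("fis_two_pass", G, drop, None,
                     dict(fis_bound=fis_bound, population_fraction=population_fraction,
                          admixed_populations=sorted(admixed)),
                     dict(candidates=candidates, per_candidate=flags))
    return G.subset_loci(keep), report


def _interfering_loci(G: GenotypeMatrix) -> list[int]:
    """Locus indices for which some population has zero non-missing calls
    (undefined variance-component terms for every pair involving it)."""
    out = []
    masks = [G.population_mask(p) for p in G.populations]
    nonmiss = G.calls != MISSING
    for j in range(G.n_loci):
        if any(not nonmiss[m, j].any() for m in masks):
            out.append(j)
    return out


def prune_loci_for_fst(G: GenotypeMatrix,
                       per_pop_missing_bounds: tuple[float, float] = (0.02, 0.08)
                       ) -> tuple[GenotypeMatrix, LocusFilterReport]:
    """Iteratively drop loci that leave pairwise Fst terms undefined.

    At each step the interfering locus with the highest overall missingness
    is removed (preferring loci whose missing fraction lies inside the
    stated band; ties broken by locus id); iteration stops when every
    pairwise variance-component term is defined.
    """
    lo, hi = per_pop_missing_bounds
    current = G
    trace: list[dict] = []
    drop: dict[str, str] = {}
    while True:
        interfering = _interfering_loci(current)
        if not interfering:
            break
        miss = current.missing_fraction("locus")
        in_band = [j for j in interfering if lo <= miss[j] <= hi]
        pool = in_band if in_band else interfering
        # highest missingness first; ties by locus id
        pool.sort(key=lambda j: (-miss[j], current.locus_ids[j]))
        j = pool[0]
        locus = current.locus_ids[j]
        drop[locus] = "fst_pruned"
        trace.append(dict(locus=locus, missing_fraction=float(miss[j]),
                          in_band=bool(lo <= miss[j] <= hi)))
        keep = np.ones(current.n_loci, bool)
        keep[j] = False
        current = current.subset_loci(keep)
    report = _report("fst_prune", G, drop, None,
                     dict(per_pop_missing_bounds=per_pop_missing_bounds),
                     dict(removal_trace=trace))
    return current, report


def apply_qc(G: GenotypeMatrix, classification=None, *,
             locus_missing_threshold: float = 0.15,
             sample_missing_threshold: float = 0.15,
             maf_threshold: float = 0.01,
             fis_bound: float = 0.3,
             population_fraction: float = 0.5
             ) -> tuple[GenotypeMatrix, list[LocusFilterReport]]:
    """Run the canonical filter sequence; the Fis pass needs a classification."""
    reports = []
    G, rep = filter_missingness(G, locus_missing_threshold, sample_missing_threshold)
    reports.append(rep)
    G, rep = filter_monomorphic_and_maf(G, maf_threshold)
    reports.append(rep)
    if classification is not None:
        G, rep = fis_two_pass_filter(G, classification, fis_bound, population_fraction)
        reports.append(rep)
    return G, reports
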