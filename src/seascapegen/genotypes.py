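"""Diploid biallelic genotype container and file I/O.

The central data structure is :class:`GenotypeMatrix`: an individuals × loci
matrix of alternate-allele dosages (0, 1, 2) with ``MISSING = -1`` for failed
calls, one population (site) label per individual, and locus identifiers.
Every genetic statistic in the package operates on this container.

Supported on-disk formats:

* Genepop (2- or 3-digit allele codes, auto-detected on read).  The writer
  emits individual ids ``<POP>_<i>``; the reader recovers the population
  label as the id prefix before the last underscore (the whole id if there
  is none).  Missing calls are ``0000`` / ``000000``.
* A long CSV table with columns ``individual, population, locus, call``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "SiteTable",
    "read_genepop",
    "write_genepop",
    "read_long_csv",
    "write_long_csv",
    "GenepopFormatError",
]


class GenepopFormatError(ValueError):
    """Raised when a genepop file is malformed or a locus is not biallelic."""


@dataclass
class GenotypeMatrix:
    """Individuals × loci diploid biallelic calls with population labels.

    Parameters
    ----------
    calls
        Integer array of shape ``(n_individuals, n_loci)`` with entries in
        ``{0, 1, 2, MISSING}`` counting copies of the alternate allele.
    individual_ids, population_labels, locus_ids
        Row / row / column annotations; ``population_labels[i]`` is the site
        code of individual ``i``.
    """

    calls: np.ndarray
    individual_ids: list[str]
    population_labels: np.ndarray
    locus_ids: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        self.population_labels = np.asarray(self.population_labels, dtype=object)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x loci)")
        n, L = self.calls.shape
        if len(self.individual_ids) != n or len(self.population_labels) != n:
            raise ValueError("individual annotation length mismatch")
        if len(self.locus_ids) != L:
            raise ValueError("locus annotation length mismatch")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid call codes at {np.argwhere(bad)[:5].tolist()}")

    # -- basic geometry ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population codes in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.population_labels:
            seen.setdefault(str(p), None)
        return list(seen)

    def population_mask(self, pop: str) -> np.ndarray:
        return np.asarray([str(p) == pop for p in self.population_labels])

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def missing_fraction(self, axis: str) -> np.ndarray:
        """Missing fraction per ``'locus'`` or per ``'individual'``."""
        m = self.missing_mask
        if axis == "locus":
            return m.mean(axis=0)
        if axis == "individual":
            return m.mean(axis=1)
        raise ValueError("axis must be 'locus' or 'individual'")

    # -- subsetting -------------------------------------------------------
    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.calls[:, keep],
            list(self.individual_ids),
            self.population_labels.copy(),
            [self.locus_ids[j] for j in keep],
        )

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.calls[keep, :],
            [self.individual_ids[i] for i in keep],
            self.population_labels[keep],
            list(self.locus_ids),
        )

    def subset_populations(self, pops: list[str]) -> "GenotypeMatrix":
        keep = np.asarray([str(p) in set(pops) for p in self.population_labels])
        return self.subset_individuals(keep)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.calls, other.calls)
            and self.individual_ids == other.individual_ids
            and list(self.population_labels) == list(other.population_labels)
            and self.locus_ids == other.locus_ids
        )


@dataclass
class SiteTable:
    """Per-site metadata: coordinates, region, and environmental summaries."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("site_code", "latitude", "longitude")

    def __post_init__(self) -> None:
        if len(self.table):
            for col in self.REQUIRED:
                if col not in self.table.columns:
                    raise ValueError(f"site table missing column {col!r}")
            if self.table["site_code"].duplicated().any():
                raise ValueError("site codes must be unique")
            coords = self.table[["latitude", "longitude"]].to_numpy(float)
            if not np.isfinite(coords).all():
                raise ValueError("coordinates must be finite")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SiteTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def site_codes(self) -> list[str]:
        return self.table["site_code"].astype(str).tolist()


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def _pop_label(individual_id: str) -> str:
    return individual_id.rsplit("_", 1)[0] if "_" in individual_id else individual_id


def read_genepop(path: str | Path) -> tuple[GenotypeMatrix, SiteTable]:
    """Parse a genepop file; returns the matrix and a site-table stub.

    Allele codes of width 2 or 3 are auto-detected; an all-zero pair is a
    missing call.  Loci with more than two observed alleles raise
    :class:`GenepopFormatError` naming the locus.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenepopFormatError("file too short to be genepop")
    # locus names: one per line, or a single comma-separated line
    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        part = lines[i].strip()
        if part:
            locus_ids.extend(s.strip() for s in part.split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenepopFormatError("no POP line found")

    ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    width: int | None = None
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            continue
        if "," not in line:
            raise GenepopFormatError(f"line {lineno}: missing ',' separator")
        name, geno = line.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(locus_ids):
            raise GenepopFormatError(
                f"line {lineno}: expected {len(locus_ids)} loci, got {len(tokens)}"
            )
        genos = []
        for locus, tok in zip(locus_ids, tokens):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenepopFormatError(f"line {lineno}, locus {locus}: bad token {tok!r}")
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise GenepopFormatError(f"line {lineno}: inconsistent allele-code width")
            genos.append((int(tok[:w]), int(tok[w:])))
        ids.append(name.strip())
        rows.append(genos)

    if not rows:
        raise GenepopFormatError("no individuals found")

    n, L = len(rows), len(locus_ids)
    calls = np.full((n, L), MISSING, dtype=np.int16)
    for j, locus in enumerate(locus_ids):
        alleles = sorted(
            {a for row in rows for a in row[j] if a != 0}
        )
        if len(alleles) > 2:
            raise GenepopFormatError(f"locus {locus}: more than two alleles {alleles}")
        # smaller code -> reference, larger -> alternate; a lone observed
        # allele counts as reference only if it is code 1
        if len(alleles) == 2:
            alt = alleles[-1]
        elif len(alleles) == 1 and alleles[0] != 1:
            alt = alleles[0]
        else:
            alt = None
        for i_, row in enumerate(rows):
            a, b = row[j]
            if a == 0 or b == 0:
                continue  # any zero half-call treated as missing
            calls[i_, j] = (alt is not None) * ((a == alt) + (b == alt))

    labels = np.asarray([_pop_label(x) for x in ids], dtype=object)
    G = GenotypeMatrix(calls, ids, labels, list(locus_ids))
    stub = SiteTable(pd.DataFrame())
    stub.table = pd.DataFrame({"site_code": G.populations})
    return G, stub


def write_genepop(G: GenotypeMatrix, path: str | Path, *, digits: int = 2,
                  title: str = "seascapegen export") -> None:
    """Write genepop with allele codes 01/02 (or 001/002); missing = zeros."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    fmt = f"0{digits}d"
    out = [title]
    out.extend(G.locus_ids)
    counters: dict[str, int] = {}
    last_pop = None
    body: list[str] = []
    for i, pop in enumerate(G.population_labels):
        pop = str(pop)
        if pop != last_pop:
            body.append("POP")
            last_pop = pop
        counters[pop] = counters.get(pop, 0) + 1
        toks = []
        for g in G.calls[i]:
            if g == MISSING:
                toks.append("0" * (2 * digits))
            else:
                a = format(2 if g >= 1 else 1, fmt)
                b = format(2 if g == 2 else 1, fmt)
                toks.append(a + b)
        body.append(f"{pop}_{counters[pop]} ,  " + " ".join(toks))
    Path(path).write_text("\n".join(out + body) + "\n")


# ---------------------------------------------------------------------------
# Long CSV
# ---------------------------------------------------------------------------

def write_long_csv(G: GenotypeMatrix, path: str | Path) -> None:
    n, L = G.calls.shape
    df = pd.DataFrame(
        {
            "individual": np.repeat(G.individual_ids, L),
            "population": np.repeat(G.population_labels.astype(str), L),
            "locus": np.tile(G.locus_ids, n),
            "call": G.calls.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_long_csv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype={"individual": str, "population": str, "locus": str})
    ind = df["individual"].drop_duplicates().tolist()
    loci = df["locus"].drop_duplicates().tolist()
    pop_of = dict(zip(df["individual"], df["population"]))
    wide = df.pivot(index="individual", columns="locus", values="call")
    wide = wide.loc[ind, loci]
    calls = wide.to_numpy()
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int16)
    labels = np.asarray([pop_of[i] for i in ind], dtype=object)
    return GenotypeMatrix(calls, ind, labels, loci)
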