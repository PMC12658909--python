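"""Anisotropic seascape connectivity from ocean-current rasters.

The workflow mirrors the resistance-surface tradition of seascape genetics:

1. gridded eastward (u) and northward (v) surface-current velocities on a
   regular lon/lat grid with a land mask (:class:`CurrentRaster`, stored as
   ESRI ASCII grids on disk, one file per component, NODATA = land);
2. a directed conductance graph over 8-neighbouring water cells in which
   moving with the current is cheap and moving against it is expensive
   (:func:`build_transition_graph`); conductances are geo-corrected by the
   great-circle distance between cell centres so that step costs are
   comparable across latitudes and rook/diagonal moves;
3. least-cost distances between sites snapped to their nearest water cells
   (:func:`least_cost_distances`), in both directions for each pair;
4. the pairwise minimum, split into resistance categories (cat0 = no
   current-borne route at all, cat1 = moderate, cat2 = light resistance),
   and a sink–source network built from the light-resistance pairs.

The conductance scheme for an ordered step i→j with unit direction d̂ is

    c_ij = max(eps, s0 + w̄·d̂)          (w̄ = mean current vector at i, j)

which is strictly positive, anisotropic whenever currents are non-zero and
reduces to an isotropic surface when they vanish.  ``s0`` defaults to the
maximum current speed on the grid and ``eps`` to ``1e-3 * s0``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .genotypes import SiteTable

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "CurrentRaster",
    "TransitionGraph",
    "read_esri_ascii",
    "write_esri_ascii",
    "haversine_km",
    "merge_current_rasters",
    "snap_sites_to_grid",
    "build_transition_graph",
    "least_cost_distances",
    "symmetrize_and_categorize",
    "sink_source_network",
]


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class CurrentRaster:
    """u/v current components on a regular lon/lat grid; NaN marks land.

    Arrays are stored in ESRI ASCII row order: row 0 is the northernmost
    row.  ``xll``/``yll`` are the lower-left *corner* coordinates in decimal
    degrees and ``cellsize`` the cell edge in degrees.
    """

    u: np.ndarray
    v: np.ndarray
    xll: float
    yll: float
    cellsize: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape or self.u.ndim != 2:
            raise ValueError("u and v must be 2-D arrays of equal shape")
        if np.isnan(self.u).all():
            raise ValueError("raster is all land (no water cells)")

    @property
    def n_rows(self) -> int:
        return self.u.shape[0]

    @property
    def n_cols(self) -> int:
        return self.u.shape[1]

    @property
    def water_mask(self) -> np.ndarray:
        return np.isfinite(self.u) & np.isfinite(self.v)

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) of cell centres; row 0 is the top (north) row."""
        row = np.asarray(row)
        col = np.asarray(col)
        lat = self.yll + (self.n_rows - 1 - row + 0.5) * self.cellsize
        lon = self.xll + (col + 0.5) * self.cellsize
        return lat, lon

    # -- disk -------------------------------------------------------------
    @classmethod
    def from_ascii(cls, u_path: str | Path, v_path: str | Path) -> "CurrentRaster":
        u, hdr = read_esri_ascii(u_path)
        v, hdr2 = read_esri_ascii(v_path)
        for k in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if not np.isclose(hdr[k], hdr2[k]):
                raise ValueError(f"u/v rasters disagree on {k}")
        return cls(u, v, hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"])

    def to_ascii(self, u_path: str | Path, v_path: str | Path) -> None:
        hdr = dict(ncols=self.n_cols, nrows=self.n_rows, xllcorner=self.xll,
                   yllcorner=self.yll, cellsize=self.cellsize)
        write_esri_ascii(u_path, self.u, **hdr)
        write_esri_ascii(v_path, self.v, **hdr)


def read_esri_ascii(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a single-band ESRI ASCII grid; NODATA cells become NaN."""
    lines = Path(path).read_text().splitlines()
    hdr: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            hdr[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    for k in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if k not in hdr:
            raise ValueError(f"ESRI ASCII header missing {k}")
    nodata = hdr.get("nodata_value", -9999.0)
    data = np.loadtxt(lines[body_start:], dtype=float, ndmin=2)
    if data.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
        raise ValueError("grid body does not match header dimensions")
    data = np.where(np.isclose(data, nodata), np.nan, data)
    return data, hdr


def write_esri_ascii(path: str | Path, grid: np.ndarray, *, ncols: int, nrows: int,
                     xllcorner: float, yllcorner: float, cellsize: float,
                     nodata: float = -9999.0) -> None:
    out = [
        f"ncols {ncols}",
        f"nrows {nrows}",
        f"xllcorner {xllcorner!r}",
        f"yllcorner {yllcorner!r}",
        f"cellsize {cellsize!r}",
        f"NODATA_value {nodata!r}",
    ]
    body = np.where(np.isnan(grid), nodata, grid)
    for row in body:
        out.append(" ".join(repr(float(x)) for x in row))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Raster merging
# ---------------------------------------------------------------------------

def merge_current_rasters(fine: CurrentRaster, coarse: CurrentRaster) -> CurrentRaster:
    """Combine two rasters, keeping the fine resolution.

    The coarse raster is disaggregated by value replication to the fine cell
    size; wherever the fine raster defines a water value it wins.  The output
    extent is the union of the two extents on the fine grid.
    """
    ratio = coarse.cellsize / fine.cellsize
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("coarse cell size must be an integer multiple of fine")
    ratio = int(round(ratio))
    cs = fine.cellsize
    for off in ((coarse.xll - fine.xll) / cs, (coarse.yll - fine.yll) / cs):
        if abs(off - round(off)) > 1e-6:
            raise ValueError("raster origins are not aligned on the fine grid")

    xll = min(fine.xll, coarse.xll)
    yll = min(fine.yll, coarse.yll)
    xmax = max(fine.xll + fine.n_cols * cs, coarse.xll + coarse.n_cols * coarse.cellsize)
    ymax = max(fine.yll + fine.n_rows * cs, coarse.yll + coarse.n_rows * coarse.cellsize)
    n_cols = int(round((xmax - xll) / cs))
    n_rows = int(round((ymax - yll) / cs))

    u = np.full((n_rows, n_cols), np.nan)
    v = np.full((n_rows, n_cols), np.nan)

    def paste(r: CurrentRaster, rep: int) -> None:
        uu = np.repeat(np.repeat(r.u, rep, axis=0), rep, axis=1)
        vv = np.repeat(np.repeat(r.v, rep, axis=0), rep, axis=1)
        c0 = int(round((r.xll - xll) / cs))
        r_bottom = int(round((r.yll - yll) / cs))  # rows up from the bottom
        r0 = n_rows - r_bottom - uu.shape[0]
        sl = (slice(r0, r0 + uu.shape[0]), slice(c0, c0 + uu.shape[1]))
        keep = np.isfinite(uu)
        u[sl] = np.where(keep, uu, u[sl])
        v[sl] = np.where(keep, vv, v[sl])

    paste(coarse, ratio)
    paste(fine, 1)
    return CurrentRaster(u, v, xll, yll, cs)


# ---------------------------------------------------------------------------
# Site snapping
# ---------------------------------------------------------------------------

def snap_sites_to_grid(sites: SiteTable, raster: CurrentRaster,
                       max_radius_km: float = 100.0) -> pd.DataFrame:
    """Map each site to its nearest water cell by great-circle distance.

    Returns a frame with ``site_code, row, col, snap_km, tie`` where ``tie``
    flags sites equidistant (to 1e-9 km) from several water cells; ties are
    broken by (row, col) order.
    """
    water = np.argwhere(raster.water_mask)
    if water.size == 0:
        raise ValueError("raster has no water cells")
    lat_c, lon_c = raster.cell_center(water[:, 0], water[:, 1])
    recs = []
    for _, s in sites.table.iterrows():
        d = haversine_km(s["latitude"], s["longitude"], lat_c, lon_c)
        j = int(np.argmin(d))  # argmin takes first occurrence = (row, col) order
        if d[j] > max_radius_km:
            raise ValueError(
                f"site {s['site_code']}: no water cell within {max_radius_km} km"
            )
        tie = bool((np.isclose(d, d[j], rtol=0, atol=1e-9)).sum() > 1)
        recs.append(
            dict(site_code=s["site_code"], row=int(water[j, 0]), col=int(water[j, 1]),
                 snap_km=float(d[j]), tie=tie)
        )
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Transition graph & least-cost distances
# ---------------------------------------------------------------------------

@dataclass
class TransitionGraph:
    """Directed geo-corrected cost graph over water cells."""

    costs: csr_matrix
    node_of_cell: dict[tuple[int, int], int]
    geo_corrected: bool = True
    params: dict = field(default_factory=dict)


_NEIGHBOURS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def build_transition_graph(raster: CurrentRaster, s0: float | None = None,
                           epsilon: float | None = None) -> TransitionGraph:
    """Directed conductance graph over 8-neighbouring water cells.

    Edge cost i→j = dist_ij / max(eps, s0 + w̄·d̂_ij) with w̄ the mean of the
    current vectors at i and j, d̂ the unit step direction in local
    east/north coordinates and dist the great-circle distance (km) between
    the cell centres (the geo-correction).
    """
    speed = np.hypot(raster.u, raster.v)
    max_speed = np.nanmax(speed)
    if s0 is None:
        s0 = float(max_speed) if max_speed > 0 else 1.0
    if epsilon is None:
        epsilon = 1e-3 * s0
    if s0 <= 0 or epsilon <= 0:
        raise ValueError("s0 and epsilon must be positive")

    water = raster.water_mask
    cells = [tuple(rc) for rc in np.argwhere(water)]
    node_of = {rc: k for k, rc in enumerate(cells)}
    rows_idx, cols_idx, costs = [], [], []
    for (r, c), i in node_of.items():
        lat_i, lon_i = raster.cell_center(r, c)
        for dr, dc in _NEIGHBOURS:
            rc2 = (r + dr, c + dc)
            j = node_of.get(rc2)
            if j is None:
                continue
            lat_j, lon_j = raster.cell_center(*rc2)
            dist = float(haversine_km(lat_i, lon_i, lat_j, lon_j))
            # unit step direction in local east/north components
            de = (lon_j - lon_i) * np.cos(np.radians(0.5 * (lat_i + lat_j)))
            dn = lat_j - lat_i
            norm = float(np.hypot(de, dn))
            ue = 0.5 * (raster.u[r, c] + raster.u[rc2])
            vn = 0.5 * (raster.v[r, c] + raster.v[rc2])
            cond = max(epsilon, s0 + (ue * de + vn * dn) / norm)
            rows_idx.append(i)
            cols_idx.append(j)
            costs.append(dist / cond)
    mat = csr_matrix((costs, (rows_idx, cols_idx)), shape=(len(cells), len(cells)))
    return TransitionGraph(mat, node_of, True, dict(s0=s0, epsilon=epsilon))


def least_cost_distances(graph: TransitionGraph, site_cells: pd.DataFrame) -> pd.DataFrame:
    """Directed least-cost distance between every ordered pair of sites.

    ``site_cells`` is the frame from :func:`snap_sites_to_grid`.  Unreachable
    pairs get ``inf``.  Returns a square frame indexed by site code.
    """
    codes = site_cells["site_code"].astype(str).tolist()
    idx = []
    for _, s in site_cells.iterrows():
        key = (int(s["row"]), int(s["col"]))
        if key not in graph.node_of_cell:
            raise ValueError(f"site {s['site_code']} snapped to a non-water cell {key}")
        idx.append(graph.node_of_cell[key])
    dmat = dijkstra(graph.costs, directed=True, indices=idx)
    out = dmat[:, idx]
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=codes, columns=codes)


def symmetrize_and_categorize(directed: pd.DataFrame,
                              cat1_threshold: float = 3_000_000.0,
                              cat2_threshold: float = 1_100_000.0) -> pd.DataFrame:
    """Collapse directed costs to pairwise minima and assign categories.

    cat0: both directions unreachable (infinite); cat2: minimum below
    ``cat2_threshold``; cat1 otherwise.  Values falling in the formally
    unassigned middle band (cat2_threshold, cat1_threshold] are placed in
    cat1 and flagged ``middle_band``.
    """
    codes = list(directed.index)
    recs = []
    for a, b in itertools.combinations(codes, 2):
        ab = float(directed.loc[a, b])
        ba = float(directed.loc[b, a])
        value = min(ab, ba)
        if np.isinf(value):
            cat, mid = "cat0", False
        elif value < cat2_threshold:
            cat, mid = "cat2", False
        else:
            cat, mid = "cat1", value <= cat1_threshold
        recs.append(dict(site_a=a, site_b=b, cost_ab=ab, cost_ba=ba,
                         value=value, category=cat, middle_band=mid))
    return pd.DataFrame(recs)


def sink_source_network(symmetrized: pd.DataFrame) -> pd.DataFrame:
    """Edge list for the light-resistance (cat2) pairs.

    Weight is the inverse of the pairwise least-cost value; the direction is
    taken from the cheaper of the two directed costs (source = origin of the
    cheaper direction).
    """
    rows = []
    for _, r in symmetrized.iterrows():
        if r["category"] != "cat2":
            continue
        if r["cost_ab"] <= r["cost_ba"]:
            src, snk = r["site_a"], r["site_b"]
        else:
            src, snk = r["site_b"], r["site_a"]
        rows.append(dict(source=src, sink=snk, weight=1.0 / r["value"],
                         category=r["category"]))
    return pd.DataFrame(rows, columns=["source", "sink", "weight", "category"])
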