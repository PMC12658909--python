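"""End-to-end orchestration: simulate/ingest → QC → admixture → statistics
→ connectivity → regressions, from one structured config.

The admixture-dependent Fis filter creates a circular dependency (the
filter needs to know which populations are admixed, but the final
admixture run should see the filtered panel).  It is resolved by an
explicit two-phase schedule, recorded in the report: a preliminary
admixture pass on the MAF-filtered panel supplies the classification for
the Fis two-pass filter, and the final admixture (replicates across K,
Evanno ΔK) runs on the retained panel.

Every random stage draws its seed deterministically from the master seed,
so an identical config yields an identical report (hash-checked).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture as adm
from . import betareg as br
from . import connectivity as conn
from . import popgen, qc
from .genotypes import GenotypeMatrix, SiteTable, read_genepop, write_genepop, write_long_csv
from .simulate import PopSpec, RasterSpec, SimConfig, simulate_study

__all__ = ["PipelineConfig", "PipelineReport", "PipelineStageError",
           "run_pipeline", "default_synthetic_config"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: Exception, partial_report=None):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original
        self.partial_report = partial_report


@dataclass
class PipelineConfig:
    """All pipeline parameters; either ``simulation`` or input paths."""

    simulation: SimConfig | None = None
    genotypes_path: str | None = None
    sites_path: str | None = None
    raster_u_path: str | None = None
    raster_v_path: str | None = None
    outdir: str = "pipeline_out"
    seed: int = 0
    # QC
    locus_missing_threshold: float = 0.15
    sample_missing_threshold: float = 0.15
    maf_threshold: float = 0.01
    fis_bound: float = 0.3
    population_fraction: float = 0.5
    # admixture
    kmax: int = 4
    replicates: int = 5
    classification_threshold: float = 0.2
    classification_mode: str = "population_mean"
    # stats
    n_permutations: int = 200
    pcrit: float = 0.02
    # connectivity (cost units follow the raster/velocity scale in use)
    cat1_threshold: float = 3_000_000.0
    cat2_threshold: float = 1_100_000.0
    snap_max_radius_km: float = 500.0
    # regressions
    q_response_unit: str = "individual"  # or 'site'
    env_exclusion_groups: list = field(default_factory=list)

    def validate(self) -> None:
        if self.simulation is None and self.genotypes_path is None:
            raise ValueError("config needs a simulation block or a genotypes path")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (list, tuple)):
                return [enc(x) for x in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return enc(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if sim is not None:
            sim = dict(sim)
            sim["pop_specs"] = [PopSpec(**p) for p in sim.get("pop_specs", [])]
            rs = sim.get("raster_spec")
            if rs is not None:
                rs = dict(rs)
                if rs.get("land_mask") is not None:
                    rs["land_mask"] = np.asarray(rs["land_mask"], bool)
                sim["raster_spec"] = RasterSpec(**rs)
            cfg.simulation = SimConfig(**sim)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineReport:
    """Headline tables plus per-stage parameter records."""

    stages: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, pd.DataFrame):
                return json.loads(o.to_json(orient="split", double_precision=12))
            return str(o)

        text = json.dumps({"stages": self.stages, "tables": self.tables},
                          indent=1, sort_keys=True, default=default)
        if path is not None:
            Path(path).write_text(text)
        return text

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _default_land_mask(nr: int, nc: int) -> np.ndarray:
    """Default synthetic coastline: an enclosed lagoon in the north-west
    corner (source of unreachable, cat0 pairs) and a partial mid-grid
    wall that forces detours."""
    land = np.zeros((nr, nc), bool)
    land[4, 0:5] = True
    land[0:5, 4] = True
    wall_col = nc // 2
    land[nr // 3: nr, wall_col] = True
    return land


def default_synthetic_config(seed: int = 42) -> PipelineConfig:
    """The default synthetic study: 26 sites shaped like the Irish
    campaign (sample sizes from the packaged site table; three pure
    lineage-A sites, an admixed west/south group, lineage-B elsewhere),
    91 loci at divergence F = 0.3, 2% dropout, a 20×20 gyre raster with a
    lagoon so that every resistance category occurs."""
    from .datasets import irish_sites

    sites = irish_sites()
    pure_a = {"AI": 0.97, "NI12": 0.97, "SCBB": 0.87}
    admixed = {"CB": 0.30, "KF": 0.32, "KLM": 0.28, "RWB": 0.35, "SBB": 0.25,
               "MB": 0.22, "CKH": 0.30, "WF": 0.24, "MH": 0.26, "DH": 0.30}
    specs = []
    for _, row in sites.iterrows():
        code = str(row["site_code"])
        if code in pure_a:
            q, disp = pure_a[code], 0.002
        elif code in admixed:
            q, disp = admixed[code], 0.01
        else:
            q, disp = 0.05, 0.002
        specs.append(PopSpec(code, int(row["n"]), q, disp))
    raster = RasterSpec(n_cols=20, n_rows=20, cell_size=0.1, origin_lon=-10.5,
                        origin_lat=51.0, pattern="gyre", gyre_speed=0.3,
                        land_mask=_default_land_mask(20, 20))
    sim = SimConfig(n_loci=91, divergence_F=0.3, pop_specs=specs,
                    missing_rate=0.02, seed=seed)
    sim.raster_spec = raster
    return PipelineConfig(simulation=sim, seed=seed,
                          # category cut-offs on the synthetic cost scale
                          # (km per m/s on a 0.1-degree grid)
                          cat1_threshold=400.0, cat2_threshold=150.0,
                          n_permutations=100, kmax=3, replicates=3)


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> PipelineReport:
    config.validate()
    report = PipelineReport()
    outdir = Path(config.outdir)
    stage = "setup"
    try:
        if write_outputs:
            for sub in ("qc", "stats", "admix", "connect", "regress"):
                (outdir / sub).mkdir(parents=True, exist_ok=True)

        ss = np.random.SeedSequence(config.seed)
        seeds = {name: int(s.generate_state(1)[0] % (2**31)) for name, s in zip(
            ("prelim_admix", "final_admix", "perms", "pipeline"), ss.spawn(4))}

        # ---- stage: input -------------------------------------------------
        stage = "input"
        if config.simulation is not None:
            study = simulate_study(config.simulation)
            G: GenotypeMatrix = study["genotypes"]
            sites: SiteTable = study["sites"]
            raster = study["raster"]
            if write_outputs:
                write_genepop(G, outdir / "qc" / "genotypes_raw.gen")
                write_long_csv(G, outdir / "qc" / "genotypes_raw.csv")
                sites.to_csv(outdir / "connect" / "sites.csv")
                raster.to_ascii(outdir / "connect" / "current_u.asc",
                                outdir / "connect" / "current_v.asc")
                study["truth"].to_json(outdir / "qc" / "sim_truth.json")
        else:
            G, _ = read_genepop(config.genotypes_path)
            sites = SiteTable.from_csv(config.sites_path) if config.sites_path else None
            raster = (conn.CurrentRaster.from_ascii(config.raster_u_path,
                                                    config.raster_v_path)
                      if config.raster_u_path else None)
        report.stages["input"] = dict(
            n_individuals=G.n_individuals, n_loci=G.n_loci,
            n_populations=len(G.populations),
            source="simulation" if config.simulation else "files")

        # ---- stage: qc ----------------------------------------------------
        stage = "qc"
        G1, rep_miss = qc.filter_missingness(
            G, config.locus_missing_threshold, config.sample_missing_threshold)
        G2, rep_maf = qc.filter_monomorphic_and_maf(G1, config.maf_threshold)
        report.tables["filter_missingness"] = rep_miss.counts
        report.tables["filter_maf"] = rep_maf.counts

        # ---- stage: preliminary admixture --------------------------------
        stage = "preliminary_admixture"
        model2 = adm.AdmixtureModel(G2, K=2)
        prelim_fits = model2.fit_replicates(3, seed=seeds["prelim_admix"])
        _, prelim_q = adm.align_replicates(prelim_fits)
        prelim_cls = adm.classify_populations(
            prelim_q, G2.population_labels, config.classification_threshold,
            config.classification_mode)
        report.tables["preliminary_classification"] = prelim_cls.table

        # ---- stage: fis filter -------------------------------------------
        stage = "fis_filter"
        G3, rep_fis = qc.fis_two_pass_filter(
            G2, prelim_cls, config.fis_bound, config.population_fraction)
        report.tables["filter_fis"] = rep_fis.counts
        if write_outputs:
            for rep in (rep_miss, rep_maf, rep_fis):
                rep.to_json(outdir / "qc" / f"filter_{rep.stage}.json")
            write_genepop(G3, outdir / "qc" / "genotypes_qc.gen")

        # ---- stage: final admixture + Evanno -----------------------------
        stage = "final_admixture"
        fits_by_k: dict[int, list] = {}
        ss_k = np.random.SeedSequence(seeds["final_admix"]).spawn(config.kmax)
        for k in range(1, config.kmax + 1):
            model = adm.AdmixtureModel(G3, K=k)
            fits_by_k[k] = model.fit_replicates(
                config.replicates,
                seed=int(ss_k[k - 1].generate_state(1)[0] % (2**31)))
        evanno = adm.evanno_best_k(fits_by_k)
        best_k = evanno.best_k or 2
        aligned, consensus_q = adm.align_replicates(fits_by_k[best_k])
        report.tables["evanno"] = evanno.table.reset_index()
        report.stages["final_admixture"] = dict(best_k=best_k, flags=evanno.flags,
                                                replicates=config.replicates)
        if best_k == 2:
            final_cls = adm.classify_populations(
                consensus_q, G3.population_labels, config.classification_threshold,
                config.classification_mode)
        else:
            final_cls = prelim_cls
        qf = pd.DataFrame(consensus_q,
                          columns=[f"Q{k + 1}" for k in range(best_k)])
        qf.insert(0, "individual", G3.individual_ids)
        qf.insert(1, "population", G3.population_labels.astype(str))
        report.tables["consensus_q"] = qf
        report.tables["classification"] = final_cls.table
        if write_outputs:
            qf.to_csv(outdir / "admix" / "consensus_q.csv", index=False)
            evanno.table.to_csv(outdir / "admix" / "evanno.csv")
            final_cls.table.to_csv(outdir / "admix" / "classification.csv", index=False)

        # ---- stage: popgen statistics ------------------------------------
        stage = "popgen_stats"
        div = popgen.diversity_table(G3, include_ne=True, pcrit=config.pcrit)
        report.tables["diversity"] = div
        G4, rep_prune = qc.prune_loci_for_fst(G3)
        report.tables["filter_fst_prune"] = rep_prune.counts
        fst = popgen.fst_significance(G4, config.n_permutations, seed=seeds["perms"])
        report.tables["fst"] = fst.to_long()
        report.stages["popgen_stats"] = dict(
            n_loci_fst=G4.n_loci, bonferroni_level=fst.bonferroni_level,
            n_permutations=config.n_permutations)
        dapc_res = popgen.dapc(G3)
        report.stages["dapc"] = dict(
            var_pct=[float(x) for x in dapc_res.var_pct], n_pcs=dapc_res.n_pcs)
        if write_outputs:
            div.to_csv(outdir / "stats" / "diversity.csv", index=False)
            fst.theta.to_csv(outdir / "stats" / "fst_matrix.csv")
            fst.to_long().to_csv(outdir / "stats" / "fst_long.csv", index=False)

        # ---- stage: connectivity -----------------------------------------
        stage = "connectivity"
        categories = None
        if raster is not None and sites is not None:
            snapped = conn.snap_sites_to_grid(sites, raster, config.snap_max_radius_km)
            graph = conn.build_transition_graph(raster)
            directed = conn.least_cost_distances(graph, snapped)
            categories = conn.symmetrize_and_categorize(
                directed, config.cat1_threshold, config.cat2_threshold)
            network = conn.sink_source_network(categories)
            report.tables["connectivity"] = categories
            report.tables["sink_source_network"] = network
            report.stages["connectivity"] = dict(
                category_counts=categories["category"].value_counts().to_dict(),
                s0=graph.params["s0"], epsilon=graph.params["epsilon"])
            if write_outputs:
                directed.to_csv(outdir / "connect" / "least_cost_directed.csv")
                categories.to_csv(outdir / "connect" / "categories.csv", index=False)
                network.to_csv(outdir / "connect" / "network.csv", index=False)

        # ---- stage: regressions ------------------------------------------
        stage = "regressions"
        regress: dict = {}
        if sites is not None and best_k == 2 and len(sites.table.columns) > 3:
            env_cols = [c for c in sites.table.columns
                        if c.endswith(("_m", "_c", "_psu"))]
            if env_cols:
                # genotype-composition model: cluster-1 ancestry vs environment
                site_env = sites.table.set_index("site_code")
                if config.q_response_unit == "individual":
                    dfq = qf.copy()
                    dfq["response"] = br.squeeze_unit_interval(
                        dfq["Q1"].to_numpy(), "proportion")
                    for c in env_cols:
                        dfq[c] = dfq["population"].map(site_env[c])
                    frame_q = dfq.dropna(subset=env_cols)
                else:
                    mq = qf.groupby("population")["Q1"].mean()
                    frame_q = site_env.copy()
                    frame_q["response"] = br.squeeze_unit_interval(
                        mq.reindex(frame_q.index).to_numpy(), "proportion")
                    frame_q = frame_q.dropna(subset=["response"])
                sel = br.dredge_aicc(frame_q, "response", env_cols,
                                     config.env_exclusion_groups)
                null_fit = br.BetaRegression.from_dataframe(
                    frame_q, "response", []).fit()
                chi2, dfree, p = br.likelihood_ratio_test(sel.best, null_fit)
                regress["q_environment"] = dict(
                    best_predictors=list(sel.best.model.exog_names[1:]),
                    coefficients=sel.best.params.to_dict(),
                    pseudo_r2=sel.best.pseudo_r2,
                    lrt=dict(chi2=chi2, df=dfree, p=p),
                    vif=br.vif(frame_q[env_cols]).to_dict("records"),
                    unit=config.q_response_unit)
        if categories is not None:
            fst_long = fst.to_long().rename(columns={"theta": "fst"})
            merged = fst_long.merge(categories[["site_a", "site_b", "category"]],
                                    on=["site_a", "site_b"])
            merged["response"] = br.squeeze_unit_interval(
                merged["fst"].to_numpy(), "fst")
            if merged["category"].nunique() >= 2 and len(merged) >= 8:
                fit_c = br.BetaRegression.from_dataframe(
                    merged, "response", [], factor="category").fit()
                null_c = br.BetaRegression.from_dataframe(
                    merged, "response", []).fit()
                chi2, dfree, p = br.likelihood_ratio_test(fit_c, null_c)
                emm = br.emmeans_categories(fit_c, "category")
                regress["fst_connectivity"] = dict(
                    coefficients=fit_c.params.to_dict(),
                    pseudo_r2=fit_c.pseudo_r2,
                    lrt=dict(chi2=chi2, df=dfree, p=p),
                    marginal_means=emm.means.to_dict("records"),
                    contrasts=emm.contrasts.to_dict("records"))
                if sites is not None and "max_wave_height_m" in sites.table.columns:
                    wave = sites.table.set_index("site_code")["max_wave_height_m"]
                    merged["delta_wave"] = (
                        merged["site_a"].map(wave) - merged["site_b"].map(wave)
                    ).abs()
                    fit_w = br.BetaRegression.from_dataframe(
                        merged.dropna(subset=["delta_wave"]), "response",
                        ["delta_wave"], factor="category").fit()
                    regress["fst_connectivity_wave"] = dict(
                        coefficients=fit_w.params.to_dict(),
                        pseudo_r2=fit_w.pseudo_r2)
        report.tables["regressions"] = regress
        if write_outputs and regress:
            Path(outdir / "regress" / "summaries.json").write_text(
                json.dumps(regress, indent=1, default=float))

        # ---- finish -------------------------------------------------------
        stage = "report"
        report.stages["parameters"] = config.to_dict()
        if write_outputs:
            report.to_json(outdir / "report.json")
        return report
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, exc, partial_report=report) from exc
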