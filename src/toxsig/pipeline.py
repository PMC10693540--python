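"""End-to-end orchestration of the analysis stages.

Stage order: simulate (or ingest) → qc → per-treatment differential
expression → class-level analysis (reference concentrations, merged
batch-aware designs, set intersections, concordance) → ORA → upstream
regulators → benchmark-dose modelling → OCR normalization and the
mitotoxic subset. Every stage reads and writes plain TSV in the output
directory, so stages are independently re-runnable; a JSON manifest
records seeds, thresholds, package version and warning counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

import toxsig
from toxsig import classes as classmod
from toxsig import doseresponse as dr
from toxsig import io as tio
from toxsig import simulate as sim
from toxsig.containers import CountMatrix, SampleMeta, ProbeAnnotation
from toxsig.diffexp import DEModel, pairwise_de
from toxsig.enrichment import read_gmt, run_ora, run_upstream
from toxsig.errors import ConfigurationError, StageError

logger = logging.getLogger(__name__)


class Thresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")

    padj: float = 0.05
    lfc: float = 0.585
    basemean: float = 10.0
    library_size: int = 200_000
    ora_z: float = 2.0
    ora_p: float = 0.05
    williams_p: float = 0.05
    williams_fc: float = 1.5
    mito_ocr_drop: float = 40.0
    viability_ic: float = 25.0

    @field_validator("*")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("thresholds must be positive")
        return v


class PipelineConfig(BaseModel):
    """Declarative run configuration (YAML). Unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    outdir: str
    counts: str | None = None
    meta: str | None = None
    probes: str | None = None
    genesets: str | None = None
    network: str | None = None
    ocr: str | None = None
    viability: str | None = None
    simulate: dict | None = None
    thresholds: Thresholds = Field(default_factory=Thresholds)
    n_perm_ora: int = 1000
    n_perm_williams: int = 1000
    n_decoy_sets: int = 20
    regulator_targets: int = 15
    bmr: float = 0.10
    seed: int = 0

    def check_paths(self) -> None:
        if self.simulate is None and self.counts is None:
            raise ConfigurationError(
                "either a 'simulate' section or a 'counts' path is required"
            )
        for key in ("counts", "meta", "probes", "genesets", "network", "ocr", "viability"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"path for {key!r} does not exist: {p}")


def validate_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        cfg = PipelineConfig(**raw)
    except Exception as e:  # pydantic error lists unknown/missing keys
        raise ConfigurationError(str(e)) from e
    cfg.check_paths()
    return cfg


class Pipeline:
    """Stateful runner; each stage method is callable on its own."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.warnings = 0
        self.manifest: dict = {
            "package": "toxsig",
            "version": toxsig.__version__,
            "seed": config.seed,
            "thresholds": config.thresholds.model_dump(),
            "stages": [],
        }

    # -- helpers ------------------------------------------------------------

    def _run(self, name, fn):
        try:
            fn()
        except Exception as e:
            (self.out / f"FAILED_{name}").write_text(str(e))
            raise StageError(name, e) from e
        self.manifest["stages"].append(name)
        self._write_manifest()

    def _write_manifest(self):
        self.manifest["warnings"] = self.warnings
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)

    def _counts_meta(self, qc=True):
        cdir = self.out / ("counts_qc.tsv" if qc else "counts.tsv")
        cm, _ = tio.read_counts(cdir)
        meta = tio.read_sample_meta(self.out / "meta.tsv")
        meta = meta.subset(cm.sample_ids)
        return cm, meta

    def _annot(self) -> ProbeAnnotation:
        return ProbeAnnotation(pd.read_csv(self.out / "probes.tsv", sep="\t"))

    def _class_map(self) -> dict[str, str]:
        meta = tio.read_sample_meta(self.out / "meta.tsv")
        cpds = meta.table.loc[~meta.table["is_vehicle"], "compound"].unique()
        return {c: c.split("_")[0] for c in cpds}

    # -- stages -------------------------------------------------------------

    def stage_simulate(self):
        cfg = self.cfg
        if cfg.simulate is not None:
            simcfg = sim.SimConfig(**{**cfg.simulate, "seed": cfg.seed})
            cm, meta, annot, truth = sim.generate_experiment(simcfg)
            cm.to_tsv(self.out / "counts.tsv")
            meta.to_tsv(self.out / "meta.tsv")
            annot.to_tsv(self.out / "probes.tsv")
            truth.to_tsv(self.out / "truth.tsv")
            db = sim.generate_genesets(truth, cfg.n_decoy_sets, seed=cfg.seed + 1)
            db.to_gmt(self.out / "genesets.gmt")
            net = sim.generate_regulator_network(
                truth, cfg.regulator_targets, frac_consistent=1.0, seed=cfg.seed + 2
            )
            net.to_csv(self.out / "network.tsv", sep="\t", index=False)
            ocr = sim.generate_ocr_table(simcfg, seed=cfg.seed + 3)
            ocr.to_csv(self.out / "ocr_raw.tsv", sep="\t", index=False)
            via = sim.generate_viability_table(simcfg, seed=cfg.seed + 4)
            via.to_csv(self.out / "viability.tsv", sep="\t", index=False)
            self.manifest["simulate"] = {**cfg.simulate, "seed": cfg.seed}
        else:
            for key, dest in [
                ("counts", "counts.tsv"), ("meta", "meta.tsv"), ("probes", "probes.tsv"),
                ("genesets", "genesets.gmt"), ("network", "network.tsv"),
                ("ocr", "ocr_raw.tsv"), ("viability", "viability.tsv"),
            ]:
                src = getattr(cfg, key)
                if src is not None:
                    (self.out / dest).write_text(Path(src).read_text())

    def stage_qc(self):
        cm, _ = tio.read_counts(self.out / "counts.tsv")
        before = cm.shape[1]
        cm = tio.filter_library_size(cm, self.cfg.thresholds.library_size)
        dropped = before - cm.shape[1]
        if dropped:
            self.warnings += dropped
        cm.to_tsv(self.out / "counts_qc.tsv")
        self.manifest["qc"] = {"samples_in": before, "samples_dropped": dropped}

    def stage_de(self):
        cm, meta = self._counts_meta()
        th = self.cfg.thresholds
        dedir = self.out / "de"
        dedir.mkdir(exist_ok=True)
        rows = []
        treated = meta.table[~meta.table["is_vehicle"]]
        for (cpd, conc), _ in treated.groupby(["compound", "concentration"]):
            res = pairwise_de(cm, meta, cpd, conc)
            res.to_tsv(dedir / f"{cpd}_{conc:.6g}.tsv")
            n_deg = len(res.significant(th.padj, th.lfc, th.basemean))
            rows.append((cpd, conc, n_deg))
        pd.DataFrame(rows, columns=["compound", "concentration", "n_deg"]).to_csv(
            self.out / "deg_counts.tsv", sep="\t", index=False
        )

    def _cytotox_loel(self) -> dict[str, float | None]:
        """Lowest concentration with viability below the sub-IC window."""
        via = pd.read_csv(self.out / "viability.tsv", sep="\t")
        cutoff = 100.0 - self.cfg.thresholds.viability_ic
        out: dict[str, float | None] = {}
        for cpd, grp in via.groupby("compound"):
            m = grp.groupby("concentration")["viability_pct"].mean()
            toxic = m[m < cutoff]
            out[cpd] = float(toxic.index.min()) if not toxic.empty else None
        return out

    def stage_class(self):
        cm, meta = self._counts_meta()
        th = self.cfg.thresholds
        deg = pd.read_csv(self.out / "deg_counts.tsv", sep="\t")
        loel = self._cytotox_loel()
        selections = {}
        for cpd, grp in deg.groupby("compound"):
            counts = dict(zip(grp["concentration"], grp["n_deg"]))
            selections[cpd] = classmod.select_reference_concentration(
                counts, loel.get(cpd)
            )
        pd.DataFrame(
            sorted(selections.items()), columns=["compound", "reference_concentration"]
        ).to_csv(self.out / "reference_concentrations.tsv", sep="\t", index=False)

        class_map = self._class_map()
        batch = meta.table.set_index("sample_id")["experiment_id"]
        sig_sets: dict[str, set] = {}
        lfc_frames = {}
        for cls in sorted(set(class_map.values())):
            sub_cm, sub_meta = classmod.build_class_dataset(
                cm, meta, selections, class_map, cls
            )
            treated = list(sub_meta.table.loc[~sub_meta.table["is_vehicle"], "sample_id"])
            control = list(sub_meta.table.loc[sub_meta.table["is_vehicle"], "sample_id"])
            b = batch.reindex(sub_cm.sample_ids)
            model = DEModel(
                sub_cm, sub_meta, treated, control,
                batch=b if b.nunique() > 1 else None,
            )
            res = model.fit()
            res.to_tsv(self.out / f"class_{cls}.tsv")
            sig = res.significant(th.padj, th.lfc, th.basemean)
            sig_sets[cls] = set(sig.index)
            lfc_frames[cls] = res.table["log2FoldChange"]

        summary = classmod.intersect_sets(sig_sets)
        lfc = pd.DataFrame(lfc_frames)
        if len(summary.intersect) >= 3:
            summary.concordance_r2 = classmod.concordance(summary.intersect, lfc)
        summary.to_frame().to_csv(self.out / "class_sets.tsv", sep="\t", index=False)
        self.manifest["class"] = {
            "region_counts": summary.counts(),
            "concordance_r2": summary.concordance_r2,
        }
        lfc.loc[sorted(set().union(*sig_sets.values()))].to_csv(
            self.out / "class_lfc.tsv", sep="\t", index_label="gene_id"
        )

    def _class_results(self):
        for p in sorted(self.out.glob("class_*.tsv")):
            if p.stem.startswith("class_") and p.stem != "class_sets" and p.stem != "class_lfc":
                yield p.stem.removeprefix("class_"), pd.read_csv(p, sep="\t", index_col=0)

    def _to_gene_level(self, table: pd.DataFrame) -> pd.DataFrame:
        """Collapse probe-level rows to gene symbols (most significant probe)."""
        gene_of = self._annot().gene_of()
        t = table.copy()
        t["gene_symbol"] = gene_of.reindex(t.index).fillna(pd.Series(t.index, index=t.index))
        return t.sort_values("pvalue").groupby("gene_symbol", sort=False).head(1).set_index("gene_symbol")

    def stage_ora(self):
        th = self.cfg.thresholds
        db = read_gmt(self.out / "genesets.gmt")
        for cls, table in self._class_results():
            t = self._to_gene_level(table)
            universe = list(t.index[t["baseMean"] > th.basemean])
            sig = t.loc[
                (t["baseMean"] > th.basemean)
                & (t["padj"] < th.padj)
                & (t["log2FoldChange"].abs() > th.lfc)
            ]
            res = run_ora(
                list(sig.index), universe, db,
                z_min=th.ora_z, p_max=th.ora_p,
                n_perm=self.cfg.n_perm_ora, seed=self.cfg.seed + 10,
            )
            res.to_csv(self.out / f"ora_{cls}.tsv", sep="\t", index=False)

    def stage_upstream(self):
        th = self.cfg.thresholds
        net = pd.read_csv(self.out / "network.tsv", sep="\t")
        for cls, table in self._class_results():
            t = self._to_gene_level(table)
            universe = list(t.index[t["baseMean"] > th.basemean])
            sig = t.loc[
                (t["baseMean"] > th.basemean)
                & (t["padj"] < th.padj)
                & (t["log2FoldChange"].abs() > th.lfc)
            ]
            observed = np.sign(sig["log2FoldChange"]).astype(int)
            res = run_upstream(net, observed, universe)
            res.to_csv(self.out / f"upstream_{cls}.tsv", sep="\t", index=False)

    def stage_bmd(self):
        cm, meta = self._counts_meta()
        th = self.cfg.thresholds
        from toxsig.diffexp import size_factors as _sf

        sf = _sf(cm)
        norm = cm.counts.div(sf, axis=1)
        rng = np.random.default_rng(self.cfg.seed + 20)
        rows = []
        treated = meta.table[~meta.table["is_vehicle"]]
        for cpd, grp in treated.groupby("compound"):
            exps = grp["experiment_id"].unique()
            veh = [s for e in exps for s in meta.vehicles(e) if s in norm.columns]
            doses = sorted(grp["concentration"].unique())
            col_by_dose = {0.0: veh}
            for d in doses:
                ids = [s for s in meta.samples_for(cpd, d) if s in norm.columns]
                if ids:
                    col_by_dose[d] = ids
            if len(col_by_dose) < 5:
                logger.warning("compound %s: too few dose groups for Exp5; skipped", cpd)
                self.warnings += 1
                continue
            dvec = np.concatenate(
                [[d] * len(ids) for d, ids in col_by_dose.items()]
            )
            cols = [s for ids in col_by_dose.values() for s in ids]
            sub = norm[cols]
            ctrl_mean = sub[col_by_dose[0.0]].mean(axis=1)
            # cheap fold-change screen before the permutation trend test
            fcmax = pd.Series(0.0, index=sub.index)
            for d, ids in col_by_dose.items():
                if d == 0.0:
                    continue
                ratio = sub[ids].mean(axis=1) / ctrl_mean.replace(0, np.nan)
                fcmax = np.maximum(fcmax, np.maximum(ratio, 1 / ratio).fillna(0))
            candidates = sub.index[fcmax > th.williams_fc]
            for gene in candidates:
                responses = {
                    d: sub.loc[gene, ids].to_numpy() for d, ids in col_by_dose.items()
                }
                tt = dr.williams_trend_test(
                    responses,
                    n_perm=self.cfg.n_perm_williams,
                    seed=rng,
                    fc_threshold=th.williams_fc,
                    p_threshold=th.williams_p,
                    gene_id=str(gene),
                )
                if not tt.passes_prefilter:
                    continue
                fit = dr.Exp5Model(dvec, sub.loc[gene, cols].to_numpy()).fit(
                    bmr=("relative", self.cfg.bmr)
                )
                rows.append(
                    (cpd, gene, tt.statistic, tt.pvalue, tt.max_fold_change,
                     fit.a, fit.b, fit.c, fit.g, fit.rss, fit.converged, fit.bmd)
                )
        bmds = pd.DataFrame(
            rows,
            columns=["compound", "gene_id", "trend_T", "trend_p", "max_fc",
                     "a", "b", "c", "g", "rss", "converged", "bmd"],
        )
        bmds.to_csv(self.out / "bmd.tsv", sep="\t", index=False)
        acc = []
        for cpd, grp in bmds.groupby("compound"):
            curve = dr.accumulation_curve(grp["bmd"].to_numpy())
            curve.insert(0, "compound", cpd)
            acc.append(curve)
        if acc:
            pd.concat(acc).to_csv(self.out / "bmd_accumulation.tsv", sep="\t", index=False)
        else:
            pd.DataFrame(columns=["compound", "concentration", "cumulative_count"]).to_csv(
                self.out / "bmd_accumulation.tsv", sep="\t", index=False
            )

    def stage_ocr(self):
        raw = pd.read_csv(self.out / "ocr_raw.tsv", sep="\t")
        pos = raw.loc[raw["compound"] == "POS_CTRL", "raw_ocr"]
        veh_basal = raw.loc[
            (raw["compound"] == "DMSO") & (raw["phase"] == "basal"), "raw_ocr"
        ]
        out = raw[~raw["compound"].isin(["POS_CTRL"])].copy()
        out["percent_of_control"] = dr.ocr_percent_of_control(
            out["raw_ocr"].to_numpy(), pos.to_numpy(), veh_basal.to_numpy()
        )
        out.to_csv(self.out / "ocr_percent.tsv", sep="\t", index=False)

        rows = []
        for (cpd, phase), grp in out[out["compound"] != "DMSO"].groupby(["compound", "phase"]):
            veh = out[(out["compound"] == "DMSO") & (out["phase"] == phase)]
            responses = {0.0: veh["percent_of_control"].to_numpy()}
            for d, g in grp.groupby("concentration"):
                if d > 0:
                    responses[d] = g["percent_of_control"].to_numpy()
            loel, _ = dr.anova_dunnett_loel(responses)
            rows.append((cpd, phase, loel))
        pd.DataFrame(rows, columns=["compound", "phase", "loel"]).to_csv(
            self.out / "ocr_loel.tsv", sep="\t", index=False
        )

        via = pd.read_csv(self.out / "viability.tsv", sep="\t")
        th = self.cfg.thresholds
        mito = classmod.mitotoxic_subset(
            out[out["compound"] != "DMSO"], via,
            threshold_drop=th.mito_ocr_drop, max_viability_ic=th.viability_ic,
        )
        mito.to_csv(self.out / "mitotoxic_subset.tsv", sep="\t", index=False)

    # -- entry point ---------------------------------------------------------

    STAGES = ["simulate", "qc", "de", "class", "ora", "upstream", "bmd", "ocr"]

    def run(self, stages: list[str] | None = None) -> dict:
        for name in stages or self.STAGES:
            if name not in self.STAGES:
                raise ConfigurationError(f"unknown stage {name!r}")
            self._run(name, getattr(self, f"stage_{name}"))
        self._write_manifest()
        return self.manifest


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    return Pipeline(config).run(stages)
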