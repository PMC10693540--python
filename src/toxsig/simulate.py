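"""Synthetic targeted-count experiments with known ground truth.

Emulates the structure of a two-experiment (two-batch) targeted RNA-seq
dose–response study of three toxicant classes: negative-binomial counts
over a probe panel, log-spaced concentration series per compound, a common
transcriptional signature shared by all classes plus class-unique genes —
each responsive gene following an Exp5-shaped fold-change curve — gene-wise
multiplicative batch effects, log-normal library sizes (with optional
low-depth samples to exercise the QC filter), matched gene sets and signed
regulator networks, and respirometry/viability endpoint tables.

Everything is drawn from a single seeded generator per call, so identical
configurations with identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from toxsig.containers import CountMatrix, ProbeAnnotation, SampleMeta
from toxsig.enrichment import GeneSetDB
from toxsig.errors import ConfigurationError

CLASSES = ("CI", "CII", "CIII")


def _default_concentrations() -> list[float]:
    return list(np.geomspace(1e-3, 10.0, 7))


@dataclass
class SimConfig:
    """Study-design parameters of a synthetic experiment.

    Defaults mirror the design the analysis assumes: a ~3,000-gene panel,
    two batches, three classes of compounds with log-spaced concentration
    series in µM, three replicates, NB counts with constant gene-level
    dispersion, and a peak effect of 1.5 log2 units on responsive genes.
    """

    n_genes: int = 3000
    n_probes_per_gene: int = 1
    n_compounds_per_class: int = 2
    concentrations: list[float] = field(default_factory=_default_concentrations)
    n_replicates: int = 3
    n_batches: int = 2
    frac_common_signature: float = 0.10
    frac_class_unique: float = 0.02
    effect_log2fc: float = 1.5
    exp5_g_range: tuple[float, float] = (0.8, 2.0)
    dispersion: float = 0.05
    library_size_mean: float = 2e6
    library_size_cv: float = 0.3
    batch_effect_sd: float = 0.1
    n_low_depth: int = 1
    n_vehicle_replicates: int = 6
    # respirometry generator
    ocr_span: float = 100.0
    ocr_nonmito: float = 30.0
    ocr_noise_cv: float = 0.05
    n_ocr_wells: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 2 or self.n_batches < 1:
            raise ConfigurationError("n_genes >= 1, n_replicates >= 2, n_batches >= 1")
        if not 1 <= self.n_probes_per_gene <= 2:
            raise ConfigurationError("n_probes_per_gene must be 1 or 2")
        if not self.concentrations:
            raise ConfigurationError("concentration list is empty")
        c = np.asarray(self.concentrations, dtype=float)
        if (c <= 0).any() or not (np.diff(c) > 0).all():
            raise ConfigurationError("concentrations must be positive and strictly increasing")
        fracs = [self.frac_common_signature, self.frac_class_unique]
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigurationError("fractions must lie in [0, 1]")
        if self.frac_common_signature + len(CLASSES) * self.frac_class_unique > 1:
            raise ConfigurationError("signature fractions sum above 1")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.library_size_mean <= 0 or self.library_size_cv <= 0:
            raise ConfigurationError("library size parameters must be > 0")

    def compounds(self) -> dict[str, str]:
        """compound name -> class label."""
        return {
            f"{cls}_cpd{i + 1}": cls
            for cls in CLASSES
            for i in range(self.n_compounds_per_class)
        }


def _exp5_fc(d, b, c, g):
    d = np.asarray(d, dtype=float)
    return c - (c - 1.0) * np.exp(-np.power(b * d, g))


@dataclass
class GroundTruth:
    """What was planted: responsive genes, their curves, BMDs, regulators."""

    responsive: dict[str, list[str]]          # class -> gene ids
    category: dict[str, str]                  # gene -> common | unique:<class>
    curve_params: pd.DataFrame                # gene x (sign, b, c, g)
    all_genes: list[str]
    regulator_signs: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cats = set(self.category.values())
        allowed = {"common"} | {f"unique:{c}" for c in CLASSES}
        if not cats <= allowed:
            raise ConfigurationError(f"unknown signature categories: {cats - allowed}")

    def responsive_in(self, cls: str) -> list[str]:
        return self.responsive[cls]

    def true_log2fc(self, concentration: float) -> pd.Series:
        """Per responsive gene, log2 fold change at one concentration."""
        p = self.curve_params
        fc = _exp5_fc(concentration, p["b"].values, p["c"].values, p["g"].values)
        return pd.Series(np.log2(fc), index=p.index, name="log2fc")

    def true_bmd(self, bmr: float = 0.10) -> pd.Series:
        """Closed-form BMD of each planted fold-change curve (relative BMR)."""
        p = self.curve_params
        c = p["c"].values
        target = np.where(c > 1.0, 1.0 + bmr, 1.0 - bmr)
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.where(c != 1.0, (c - target) / np.where(c != 1.0, c - 1.0, 1.0), np.nan)
        bmd = np.where(
            (x > 0) & (x < 1),
            np.power(-np.log(np.clip(x, 1e-300, None)), 1.0 / p["g"].values) / p["b"].values,
            np.nan,
        )
        return pd.Series(bmd, index=p.index, name="bmd")

    def direction_of(self) -> pd.Series:
        return self.curve_params["sign"].astype(int)

    def to_tsv(self, path) -> None:
        t = self.curve_params.copy()
        t["category"] = [self.category[g] for g in t.index]
        t["bmd"] = self.true_bmd()
        t.to_csv(path, sep="\t", index_label="gene_id")


def generate_experiment(
    config: SimConfig,
) -> tuple[CountMatrix, SampleMeta, ProbeAnnotation, GroundTruth]:
    """Draw one full synthetic experiment.

    Counts are NB with mean = library size x relative abundance x
    Exp5 fold change (responsive genes under the sample's compound class) x
    gene-wise batch factor. Every batch carries a vehicle group (0.1 % DMSO
    analogue, concentration 0).
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    conc = np.asarray(config.concentrations, dtype=float)

    # --- signature assignment ------------------------------------------------
    n_common = round(config.frac_common_signature * config.n_genes)
    n_unique = round(config.frac_class_unique * config.n_genes)
    perm = rng.permutation(config.n_genes)
    category: dict[str, str] = {}
    common = [genes[i] for i in perm[:n_common]]
    for g in common:
        category[g] = "common"
    pos = n_common
    uniques: dict[str, list[str]] = {}
    for cls in CLASSES:
        uniques[cls] = [genes[i] for i in perm[pos : pos + n_unique]]
        for g in uniques[cls]:
            category[g] = f"unique:{cls}"
        pos += n_unique
    responsive = {cls: sorted(common + uniques[cls]) for cls in CLASSES}

    # --- planted dose-response curves ---------------------------------------
    resp_genes = sorted(category)
    n_resp = len(resp_genes)
    signs = rng.choice([-1, 1], size=n_resp)
    c_par = np.power(2.0, signs * config.effect_log2fc)
    lo, hi = conc[0], conc[-1]
    d_mid = np.exp(rng.uniform(np.log(lo * 3), np.log(hi / 3), size=n_resp))
    b_par = 1.0 / d_mid
    g_par = rng.uniform(*config.exp5_g_range, size=n_resp)
    curve_params = pd.DataFrame(
        {"sign": signs, "b": b_par, "c": c_par, "g": g_par},
        index=pd.Index(resp_genes, name="gene_id"),
    )
    truth = GroundTruth(
        responsive=responsive,
        category=category,
        curve_params=curve_params,
        all_genes=genes,
    )

    # --- samples -------------------------------------------------------------
    compounds = config.compounds()
    rows = []
    for j, (cpd, cls) in enumerate(compounds.items()):
        batch = j % config.n_batches + 1
        for d in conc:
            for r in range(1, config.n_replicates + 1):
                rows.append((f"{cpd}_c{d:.3g}_r{r}", cpd, d, f"exp{batch}", r, False))
    for batch in range(1, config.n_batches + 1):
        for r in range(1, config.n_vehicle_replicates + 1):
            rows.append((f"DMSO_exp{batch}_r{r}", "DMSO", 0.0, f"exp{batch}", r, True))
    meta = pd.DataFrame(
        rows,
        columns=["sample_id", "compound", "concentration", "experiment_id", "replicate", "is_vehicle"],
    )
    n_samples = len(meta)

    # --- probe panel ---------------------------------------------------------
    probes, probe_gene = [], []
    for g in genes:
        for k in range(1, config.n_probes_per_gene + 1):
            probes.append(f"{g}_P{k}")
            probe_gene.append(g)
    annot = ProbeAnnotation(
        pd.DataFrame(
            {"probe_id": probes, "gene_symbol": probe_gene, "panel_version": "v2.0"}
        )
    )

    # --- mean model ----------------------------------------------------------
    n_probes = len(probes)
    abundance = rng.lognormal(mean=0.0, sigma=1.5, size=n_probes)
    abundance /= abundance.sum()

    sigma_lib = math.sqrt(math.log(1.0 + config.library_size_cv**2))
    lib = rng.lognormal(
        mean=math.log(config.library_size_mean) - 0.5 * sigma_lib**2,
        sigma=sigma_lib,
        size=n_samples,
    )
    if config.n_low_depth > 0:
        treated_idx = meta.index[~meta["is_vehicle"]].to_numpy()
        low = rng.choice(treated_idx, size=min(config.n_low_depth, len(treated_idx)), replace=False)
        lib[low] = rng.uniform(0.8e5, 1.5e5, size=len(low))

    batch_fac = np.ones((n_probes, config.n_batches))
    for bt in range(1, config.n_batches):
        batch_fac[:, bt] = rng.lognormal(0.0, config.batch_effect_sd, size=n_probes)

    gene_index = {g: i for i, g in enumerate(resp_genes)}
    probe_resp = np.array([gene_index.get(g, -1) for g in probe_gene])
    hit = probe_resp >= 0
    which = probe_resp[hit]
    in_class = {
        cls: np.array(
            [category[resp_genes[i]] in ("common", f"unique:{cls}") for i in which]
        )
        for cls in CLASSES
    }
    mu = np.empty((n_probes, n_samples))
    batch_idx = meta["experiment_id"].str.removeprefix("exp").astype(int).to_numpy() - 1
    for s in range(n_samples):
        fc = np.ones(n_probes)
        d = meta.at[s, "concentration"]
        if not meta.at[s, "is_vehicle"] and d > 0:
            cls = compounds[meta.at[s, "compound"]]
            fc_vals = _exp5_fc(d, b_par[which], c_par[which], g_par[which])
            fc[hit] = np.where(in_class[cls], fc_vals, 1.0)
        mu[:, s] = lib[s] * abundance * fc * batch_fac[:, batch_idx[s]]

    alpha = config.dispersion
    if alpha < 1e-10:
        counts = rng.poisson(mu)
    else:
        counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(probes, name="probe_id"), columns=meta["sample_id"])
    )
    return cm, SampleMeta(meta), annot, truth


def generate_genesets(
    truth: GroundTruth,
    n_decoy_sets: int,
    seed: int = 0,
    universe: list[str] | None = None,
) -> GeneSetDB:
    """One signature set (the common responsive genes) plus size-matched
    decoy sets drawn uniformly from the universe."""
    if n_decoy_sets < 0:
        raise ConfigurationError("n_decoy_sets must be >= 0")
    if not truth.all_genes:
        raise ConfigurationError("ground truth has no genes")
    rng = np.random.default_rng(seed)
    universe = list(universe) if universe is not None else list(truth.all_genes)
    signature = sorted(g for g, cat in truth.category.items() if cat == "common")
    sets: dict[str, list[str]] = {}
    size = len(signature)
    if signature:
        sets["signature"] = signature
    else:
        size = max(10, len(universe) // 20)
    for i in range(n_decoy_sets):
        sets[f"decoy_{i + 1:03d}"] = sorted(
            rng.choice(universe, size=min(size, len(universe)), replace=False)
        )
    return GeneSetDB(sets=sets, source="synthetic")


def generate_regulator_network(
    truth: GroundTruth,
    targets_per_regulator: int,
    frac_consistent: float = 1.0,
    seed: int = 0,
    n_regulators_per_class: int = 2,
) -> pd.DataFrame:
    """Signed regulator->target edge lists over the planted genes.

    For each class, ``n_regulators_per_class`` regulators alternate between
    true activity +1 (activated) and -1 (inhibited); their targets are drawn
    from the class's responsive genes. A ``frac_consistent`` share of edges
    has expected direction ``s_R = activity * s_D_true`` (agreeing with the
    simulated change given the regulator's activity); the rest are flipped.
    True activity signs are recorded on ``truth.regulator_signs``.
    """
    if targets_per_regulator < 1:
        raise ConfigurationError("targets_per_regulator must be >= 1")
    rng = np.random.default_rng(seed)
    direction = truth.direction_of()
    rows = []
    for cls in CLASSES:
        pool = truth.responsive_in(cls)
        if not pool:
            continue
        for k in range(n_regulators_per_class):
            reg = f"REG_{cls}_{k + 1}"
            activity = 1 if k % 2 == 0 else -1
            truth.regulator_signs[reg] = activity
            targets = rng.choice(pool, size=min(targets_per_regulator, len(pool)), replace=False)
            consistent = rng.random(len(targets)) < frac_consistent
            for t, cons in zip(targets, consistent):
                s_true = int(direction[t])
                s_r = activity * s_true if cons else -activity * s_true
                rows.append((reg, t, s_r, 1.0))
    return pd.DataFrame(rows, columns=["regulator", "target", "sign", "weight"])


def generate_ocr_table(config: SimConfig, seed: int = 0) -> pd.DataFrame:
    """Per-well basal/maximal oxygen consumption rates.

    Compounds of classes CI and CIII are mitotoxic: their mitochondrial
    OCR declines sigmoidally with concentration (Hill slope 1.5, midpoint
    mid-range); CII compounds are inert. Raw OCR = non-mitochondrial floor
    + span x remaining activity, with multiplicative noise. Vehicle wells
    (concentration 0) and positive-control wells (full ETC inhibition,
    ``POS_CTRL``) are included.
    """
    rng = np.random.default_rng(seed)
    conc = np.asarray(config.concentrations, dtype=float)
    ic50 = math.sqrt(conc[0] * conc[-1])
    span = {"basal": config.ocr_span, "maximal": 1.6 * config.ocr_span}
    rows = []

    def noisy(x):
        return x * (1.0 + config.ocr_noise_cv * rng.standard_normal()) if config.ocr_noise_cv > 0 else x

    for cpd, cls in config.compounds().items():
        mitotoxic = cls in ("CI", "CIII")
        for d in conc:
            frac = 1.0 / (1.0 + (d / ic50) ** 1.5) if mitotoxic else 1.0
            for phase, sp in span.items():
                for w in range(1, config.n_ocr_wells + 1):
                    raw = config.ocr_nonmito + sp * frac
                    rows.append((cpd, d, phase, w, noisy(raw)))
    for phase, sp in span.items():
        for w in range(1, config.n_ocr_wells + 1):
            rows.append(("DMSO", 0.0, phase, w, noisy(config.ocr_nonmito + sp)))
            rows.append(("POS_CTRL", 0.0, phase, w, noisy(config.ocr_nonmito)))
    return pd.DataFrame(
        rows, columns=["compound", "concentration", "phase", "well", "raw_ocr"]
    )


def generate_viability_table(config: SimConfig, seed: int = 0) -> pd.DataFrame:
    """Percent-of-control viability per compound/concentration.

    Cytotoxicity sets in one order of magnitude above the OCR midpoint, so
    mitotoxic concentrations exist in the subtoxic window; CII compounds
    are cytotoxic only at the top of their range.
    """
    rng = np.random.default_rng(seed)
    conc = np.asarray(config.concentrations, dtype=float)
    mid = math.sqrt(conc[0] * conc[-1])
    rows = []
    for cpd, cls in config.compounds().items():
        tc50 = 10.0 * mid if cls in ("CI", "CIII") else 3.0 * conc[-1]
        for d in conc:
            via = 100.0 / (1.0 + (d / tc50) ** 2.0)
            via *= 1.0 + 0.03 * rng.standard_normal()
            rows.append((cpd, d, via))
    return pd.DataFrame(rows, columns=["compound", "concentration", "viability_pct"])
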