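"""Class-level analysis: reference concentrations, merged datasets,
intersection of significant gene sets, fold-change concordance, and the
mitotoxic compound-concentration subset.

A class (e.g. inhibitors of one respiratory-chain complex) is analysed by
merging, across experiments, the samples of each member compound at its
reference concentration — the concentration with the most differentially
expressed genes below the cytotoxicity threshold — together with the
matching vehicle groups, and testing class-vs-control with the experiment
id as a batch covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from toxsig.containers import CountMatrix, SampleMeta
from toxsig.errors import DesignError, ToxsigError


def select_reference_concentration(
    deg_counts: dict[float, int],
    cytotox_loel: float | None = None,
) -> float:
    """Concentration with the most DEGs strictly below the cytotoxic LOEL.

    Ties break toward the lower concentration. Raises when every tested
    concentration is at or above the LOEL.
    """
    if not deg_counts:
        raise ToxsigError("no DEG counts supplied")
    eligible = sorted(
        d for d in deg_counts if cytotox_loel is None or d < cytotox_loel
    )
    if not eligible:
        raise ToxsigError(
            f"all concentrations at or above the cytotoxic LOEL {cytotox_loel}"
        )
    return max(eligible, key=lambda d: (deg_counts[d], -d))


def build_class_dataset(
    cm: CountMatrix,
    meta: SampleMeta,
    selections: dict[str, float],
    class_map: dict[str, str],
    target_class: str,
    harmonized_probes: list[str] | None = None,
) -> tuple[CountMatrix, SampleMeta]:
    """Merge one reference concentration per class member with its controls.

    Returns counts and metadata for the ``target_class`` members' samples
    at their reference concentrations plus the vehicle groups of every
    experiment involved, preserving ``experiment_id`` so the batch-aware
    class-vs-control design can be fit. Probes are restricted to
    ``harmonized_probes`` when given.
    """
    members = [c for c, cls in class_map.items() if cls == target_class]
    if not members:
        raise DesignError(f"no compounds mapped to class {target_class!r}")
    missing = [c for c in members if c not in selections]
    if missing:
        raise DesignError(f"no reference concentration for: {missing}")
    present = set(cm.sample_ids)
    treated: list[str] = []
    for cpd in members:
        ids = [s for s in meta.samples_for(cpd, selections[cpd]) if s in present]
        if not ids:
            raise DesignError(
                f"no samples for {cpd} at reference concentration {selections[cpd]}"
            )
        treated.extend(ids)
    exps = sorted(
        meta.table.set_index("sample_id").loc[treated, "experiment_id"].unique()
    )
    controls: list[str] = []
    for e in exps:
        veh = [s for s in meta.vehicles(e) if s in present]
        if not veh:
            raise DesignError(f"experiment {e!r} contributes treated samples but no vehicle")
        controls.extend(veh)
    samples = controls + treated
    sub = cm.subset_samples(samples)
    if harmonized_probes is not None:
        sub = sub.subset_probes(harmonized_probes)
    return sub, meta.subset(samples)


@dataclass
class ClassSetSummary:
    """Three-set intersection structure of per-class significant genes.

    ``regions`` holds the seven disjoint Venn regions keyed by frozenset of
    class names; ``intersect`` is the triple-overlap list, ``unique`` the
    genes significant in exactly one class.
    """

    classes: tuple[str, str, str]
    regions: dict[frozenset, list[str]]
    concordance_r2: float | None = field(default=None)

    @property
    def intersect(self) -> list[str]:
        return self.regions[frozenset(self.classes)]

    def unique(self, cls: str) -> list[str]:
        return self.regions[frozenset([cls])]

    def pairwise(self, a: str, b: str) -> list[str]:
        return self.regions[frozenset([a, b])]

    def counts(self) -> dict[str, int]:
        return {
            "+".join(sorted(k)): len(v) for k, v in self.regions.items()
        }

    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("+".join(sorted(k)), len(v), ";".join(sorted(v)))
            for k, v in sorted(self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
        return pd.DataFrame(rows, columns=["region", "n_genes", "genes"])


def intersect_sets(sets_by_class: dict[str, set]) -> ClassSetSummary:
    """Exact seven-region decomposition of three per-class gene sets."""
    if len(sets_by_class) != 3:
        raise ToxsigError("exactly three classes expected")
    names = tuple(sets_by_class)
    sets = {k: set(v) for k, v in sets_by_class.items()}
    regions: dict[frozenset, list[str]] = {}
    a, b, c = names
    regions[frozenset([a, b, c])] = sorted(sets[a] & sets[b] & sets[c])
    for x, y in [(a, b), (a, c), (b, c)]:
        z = ({a, b, c} - {x, y}).pop()
        regions[frozenset([x, y])] = sorted((sets[x] & sets[y]) - sets[z])
    for x in names:
        others = [sets[y] for y in names if y != x]
        regions[frozenset([x])] = sorted(sets[x] - others[0] - others[1])
    return ClassSetSummary(classes=names, regions=regions)


def concordance(
    intersect_genes,
    lfc_by_class: pd.DataFrame,
    mode: str = "pooled",
):
    """R² of the between-class agreement of log2 fold changes.

    ``lfc_by_class`` is genes x classes. In ``pooled`` mode (default) the
    three pairwise class comparisons are stacked into one ordinary
    least-squares regression — each pair entering in both orientations so
    the result is symmetric in class order — and a single R² returned;
    ``per_pair`` returns the R² of each pair.
    """
    genes = list(intersect_genes)
    if len(genes) < 3:
        raise ToxsigError("need >= 3 intersect genes for a concordance R²")
    t = lfc_by_class.loc[genes]
    cols = list(t.columns)
    if len(cols) != 3:
        raise ToxsigError("expected exactly three class columns")
    pairs = [(cols[0], cols[1]), (cols[0], cols[2]), (cols[1], cols[2])]
    if mode == "pooled":
        x = np.concatenate(
            [t[p[0]].to_numpy() for p in pairs] + [t[p[1]].to_numpy() for p in pairs]
        )
        y = np.concatenate(
            [t[p[1]].to_numpy() for p in pairs] + [t[p[0]].to_numpy() for p in pairs]
        )
        r = stats.pearsonr(x, y).statistic
        return float(r**2)
    if mode == "per_pair":
        return {
            f"{p[0]}~{p[1]}": float(stats.pearsonr(t[p[0]], t[p[1]]).statistic ** 2)
            for p in pairs
        }
    raise ValueError(f"unknown mode {mode!r}")


def mitotoxic_subset(
    ocr_table: pd.DataFrame,
    viability_table: pd.DataFrame,
    threshold_drop: float = 40.0,
    max_viability_ic: float = 25.0,
    phase: str = "basal",
) -> pd.DataFrame:
    """Compound-concentration pairs with mitochondrial but not cytotoxic injury.

    Keeps pairs whose mean OCR percent-of-control is down by at least
    ``threshold_drop`` percent (i.e. <= 100 - drop) while viability remains
    at or above ``100 - max_viability_ic`` percent of control (the sub-IC25
    window by default).

    ``ocr_table`` needs columns compound, concentration, phase,
    percent_of_control; ``viability_table`` compound, concentration,
    viability_pct.
    """
    need = {"compound", "concentration", "phase", "percent_of_control"}
    if not need <= set(ocr_table.columns):
        raise ToxsigError(f"ocr_table needs columns {sorted(need)}")
    ocr = (
        ocr_table[ocr_table["phase"] == phase]
        .groupby(["compound", "concentration"], as_index=False)["percent_of_control"]
        .mean()
    )
    via = viability_table.groupby(["compound", "concentration"], as_index=False)[
        "viability_pct"
    ].mean()
    merged = ocr.merge(via, on=["compound", "concentration"], how="inner")
    keep = (merged["percent_of_control"] <= 100.0 - threshold_drop) & (
        merged["viability_pct"] >= 100.0 - max_viability_ic
    )
    return merged[keep].reset_index(drop=True)
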