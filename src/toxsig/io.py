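"""Reading and QC of count tables, metadata and probe panels.

Covers the front end of the analysis: delimited-text ingestion with strict
format checking, the library-size quality filter (samples under 200,000
total reads are dropped before any statistics), and harmonization of probes
across two panel versions via the log2-fold-change similarity criterion
(per-gene SD of paired responses, SDp < 0.1).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from toxsig.containers import CountMatrix, ProbeAnnotation, SampleMeta
from toxsig.errors import FormatError

logger = logging.getLogger(__name__)

#: Minimum library size (total reads per sample) retained by QC.
LIBRARY_SIZE_MIN = 200_000

#: Similarity threshold on the per-gene SD of paired log2 fold changes.
SDP_MAX = 0.1


def _sniff_sep(path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_counts(path, annotation_path=None):
    """Read a probe x sample count table, optionally with a probe panel.

    The first column must hold probe ids; remaining columns are integer
    read counts per sample. Delimiter (tab/comma/semicolon) is sniffed.

    Returns
    -------
    (CountMatrix, ProbeAnnotation | None)
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if df.shape[0] == 0:
        logger.warning("count table %s has a header only (no probes)", path)
        cm = CountMatrix(df.astype(np.int64))
    else:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[coerced.isna()][0]
                raise FormatError(
                    f"non-numeric count at probe {row!r}, sample {col!r}"
                )
            df[col] = coerced
        cm = CountMatrix(df)
    annot = None
    if annotation_path is not None:
        asep = _sniff_sep(annotation_path)
        annot = ProbeAnnotation(pd.read_csv(annotation_path, sep=asep))
    return cm, annot


def read_sample_meta(path) -> SampleMeta:
    sep = _sniff_sep(path)
    return SampleMeta(pd.read_csv(path, sep=sep))


def filter_library_size(cm: CountMatrix, min_reads: int = LIBRARY_SIZE_MIN) -> CountMatrix:
    """Drop samples whose total read count is strictly below ``min_reads``.

    Idempotent; removals are logged. Raises if nothing survives.
    """
    sizes = cm.library_sizes()
    keep = sizes[sizes >= min_reads].index
    dropped = [s for s in cm.sample_ids if s not in set(keep)]
    for s in dropped:
        logger.info("library-size filter: dropping %s (%d reads)", s, sizes[s])
    if len(keep) == 0:
        raise FormatError(
            f"library-size filter removed all {cm.shape[1]} samples "
            f"(min_reads={min_reads})"
        )
    return cm.subset_samples(list(keep))


@dataclass
class HarmonizationResult:
    """Outcome of cross-panel probe harmonization.

    ``table`` has one row per probe of either panel with columns
    ``probe_id, gene_symbol, panel, rule, sdp`` where ``rule`` is one of
    ``shared`` (identical probe in both panels), ``concordant`` (gene's
    differing probes respond alike, SDp below threshold) or ``excluded``.
    """

    kept_probes: list
    table: pd.DataFrame
    sdp_threshold: float = SDP_MAX

    @property
    def kept_genes(self) -> list:
        t = self.table
        return sorted(t.loc[t["rule"] != "excluded", "gene_symbol"].unique())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def harmonize_panels(
    log2fc_a: pd.Series,
    log2fc_b: pd.Series,
    annot_a: ProbeAnnotation,
    annot_b: ProbeAnnotation,
    sdp_max: float = SDP_MAX,
) -> HarmonizationResult:
    """Merge two probe panels on a shared reference response.

    ``log2fc_a``/``log2fc_b`` are per-probe log2 fold changes of the *same*
    reference treatment measured on each panel. Probes with identical ids
    in both panels are kept outright. For a gene whose probes differ
    between panels, the probes are kept iff the sample standard deviation
    of the gene's paired log2 fold changes (for a single pair, |Δ|/√2) is
    below ``sdp_max``. Genes measured on one panel only are excluded.

    The decision is symmetric in the two panels.
    """
    gene_a = annot_a.gene_of()
    gene_b = annot_b.gene_of()
    genes_a = set(gene_a.values)
    genes_b = set(gene_b.values)
    common_genes = genes_a & genes_b
    if not common_genes:
        raise FormatError("panels share no gene symbols; cannot harmonize")

    shared_probes = set(gene_a.index) & set(gene_b.index)
    rows = []
    kept: list = []
    for gene in sorted(common_genes):
        pa = list(gene_a.index[gene_a.values == gene])
        pb = list(gene_b.index[gene_b.values == gene])
        if set(pa) == set(pb) and set(pa) <= shared_probes:
            for p in pa:
                rows.append((p, gene, "both", "shared", 0.0))
            kept.extend(pa)
            continue
        vals = np.concatenate(
            [log2fc_a.reindex(pa).dropna().to_numpy(),
             log2fc_b.reindex(pb).dropna().to_numpy()]
        )
        if len(vals) < 2:
            sdp = np.nan
            rule = "excluded"
        else:
            sdp = float(np.std(vals, ddof=1))
            rule = "concordant" if sdp < sdp_max else "excluded"
        for p, panel in [(p, "a") for p in pa] + [(p, "b") for p in pb]:
            rows.append((p, gene, panel, rule, sdp))
        if rule == "concordant":
            kept.extend(pa)
            kept.extend(p for p in pb if p not in pa)
    for gene in sorted((genes_a | genes_b) - common_genes):
        src = gene_a if gene in genes_a else gene_b
        panel = "a" if gene in genes_a else "b"
        for p in src.index[src.values == gene]:
            rows.append((p, gene, panel, "excluded", np.nan))

    table = pd.DataFrame(
        rows, columns=["probe_id", "gene_symbol", "panel", "rule", "sdp"]
    )
    return HarmonizationResult(kept_probes=kept, table=table, sdp_threshold=sdp_max)
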