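"""Core in-memory containers: count matrix, sample metadata, probe annotation.

Thin validated wrappers around :class:`pandas.DataFrame`, mirroring the
objects a targeted-sequencing provider delivers: an integer probe x sample
count table and a sample annotation sheet (compound, concentration in µM,
experiment/batch, replicate, vehicle flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from toxsig.errors import FormatError

META_COLUMNS = [
    "sample_id",
    "compound",
    "concentration",
    "experiment_id",
    "replicate",
    "is_vehicle",
]


@dataclass
class CountMatrix:
    """Raw integer read counts, probes as rows, samples as columns."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate probe id: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        arr = df.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr), atol=0):
                    bad = np.argwhere(arr != np.round(arr))[0]
                    raise FormatError(
                        f"non-integer count at probe {df.index[bad[0]]!r}, "
                        f"sample {df.columns[bad[1]]!r}"
                    )
                self.counts = df.astype(np.int64)
                arr = self.counts.to_numpy()
            if (arr < 0).any():
                bad = np.argwhere(arr < 0)[0]
                raise FormatError(
                    f"negative count at probe {df.index[bad[0]]!r}, "
                    f"sample {df.columns[bad[1]]!r}"
                )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def library_sizes(self) -> pd.Series:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)])

    def subset_probes(self, probe_ids) -> "CountMatrix":
        keep = [p for p in probe_ids if p in self.counts.index]
        return CountMatrix(self.counts.loc[keep])

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="probe_id")


@dataclass
class SampleMeta:
    """Per-sample annotation; one row per sample of the count matrix."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample metadata missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id in metadata: {dup!r}")
        self.table = self.table.reset_index(drop=True)
        self.table["is_vehicle"] = self.table["is_vehicle"].astype(bool)
        self.table["concentration"] = self.table["concentration"].astype(float)
        if (self.table["concentration"] < 0).any():
            raise FormatError("negative concentration in sample metadata")

    def validate_against(self, cm: CountMatrix) -> None:
        """Check the one-row-per-sample and matched-vehicle invariants."""
        meta_ids = set(self.table["sample_id"])
        cm_ids = set(cm.sample_ids)
        if meta_ids != cm_ids:
            raise FormatError(
                f"sample id mismatch: {sorted(cm_ids - meta_ids)[:3]} in counts "
                f"but not metadata; {sorted(meta_ids - cm_ids)[:3]} vice versa"
            )
        treated = self.table[~self.table["is_vehicle"]]
        for exp_id, grp in treated.groupby("experiment_id"):
            veh = self.table[
                self.table["is_vehicle"] & (self.table["experiment_id"] == exp_id)
            ]
            if veh.empty:
                raise FormatError(
                    f"experiment {exp_id!r} has treated samples but no vehicle group"
                )

    def subset(self, sample_ids) -> "SampleMeta":
        ids = list(sample_ids)
        sub = self.table[self.table["sample_id"].isin(ids)].copy()
        sub["sample_id"] = pd.Categorical(sub["sample_id"], categories=ids, ordered=True)
        sub = sub.sort_values("sample_id").reset_index(drop=True)
        sub["sample_id"] = sub["sample_id"].astype(str)
        return SampleMeta(sub)

    def samples_for(self, compound: str, concentration: float) -> list[str]:
        t = self.table
        m = (t["compound"] == compound) & np.isclose(
            t["concentration"], concentration
        )
        return list(t.loc[m, "sample_id"])

    def vehicles(self, experiment_id=None) -> list[str]:
        t = self.table
        m = t["is_vehicle"]
        if experiment_id is not None:
            m = m & (t["experiment_id"] == experiment_id)
        return list(t.loc[m, "sample_id"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class ProbeAnnotation:
    """Probe to gene-symbol mapping for one panel version."""

    table: pd.DataFrame  # columns: probe_id, gene_symbol, panel_version
    panel_version: str = field(default="")

    def __post_init__(self) -> None:
        need = {"probe_id", "gene_symbol"}
        if not need.issubset(self.table.columns):
            raise FormatError(
                f"probe annotation needs columns {sorted(need)}, "
                f"got {list(self.table.columns)}"
            )
        if self.table["probe_id"].duplicated().any():
            dup = self.table.loc[self.table["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise FormatError(f"duplicate probe id in annotation: {dup!r}")
        # symbols matched case-sensitively after whitespace trimming
        self.table = self.table.assign(
            gene_symbol=self.table["gene_symbol"].astype(str).str.strip()
        ).reset_index(drop=True)
        if not self.panel_version and "panel_version" in self.table.columns:
            vals = self.table["panel_version"].unique()
            if len(vals) == 1:
                self.panel_version = str(vals[0])

    def gene_of(self) -> pd.Series:
        return self.table.set_index("probe_id")["gene_symbol"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
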