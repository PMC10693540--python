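"""Gene-set over-representation and upstream-regulator statistics.

Two independent analyses on a selected-gene list:

* ORA with the hypergeometric Z-score
  ``Z = (r - nR/N) / sqrt(n (R/N)(1 - R/N)(1 - (n-1)/(N-1)))``
  where ``N`` is the measured universe, ``R`` the selected genes, ``n`` the
  measured members of a set and ``r`` the selected members — the numerator
  and denominator are the mean and finite-population standard deviation of
  the hypergeometric distribution of ``r``. Significance by a one-sided
  label-permutation p-value.

* Upstream-regulator activation z-scores on an explicit signed network:
  ``z = sum_v w(v) s_R(v) s_D(v) / sqrt(sum_v w(v)^2)`` over targets ``v``
  that are differentially expressed, with ``s_R`` the expected regulation
  direction and ``s_D`` the observed direction; |z| >= 2 predicts an
  activation state. Overlap significance by a right-tailed Fisher exact
  test, BH-corrected across regulators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from toxsig.diffexp import bh_adjust
from toxsig.errors import FormatError, ToxsigError

logger = logging.getLogger(__name__)

NETWORK_COLUMNS = ["regulator", "target", "sign", "weight"]


@dataclass
class GeneSetDB:
    """Named gene sets (members de-duplicated, order preserved)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for name, members in self.sets.items():
            uniq = list(dict.fromkeys(members))
            if not uniq:
                raise ToxsigError(f"gene set {name!r} has no members")
            clean[name] = uniq
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, self.source or "na", *members]) + "\n")


def read_gmt(path) -> GeneSetDB:
    """Parse a GMT file (name, description, members...); empty sets are
    dropped with a warning, a line with fewer than two columns is an error."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: expected >= 2 tab-separated columns")
            name, _desc, *members = parts
            members = [m.strip() for m in members if m.strip()]
            if not members:
                logger.warning("%s: line %d: set %r has no members, dropped", path, lineno, name)
                continue
            sets[name] = list(dict.fromkeys(members))
    return GeneSetDB(sets=sets, source=str(path))


# ---------------------------------------------------------------------------
# ORA

def ora_zscore(N: int, R: int, n: int, r: int) -> float:
    """Hypergeometric Z-score for over-representation.

    ``N`` measured genes, ``R`` selected, ``n`` measured set members, ``r``
    selected set members. The statistic standardizes ``r`` by the
    hypergeometric mean ``nR/N`` and finite-population variance.
    """
    if not (1 <= n <= N):
        raise ValueError(f"need 1 <= n <= N, got n={n}, N={N}")
    if n == N:
        raise ZeroDivisionError(
            "set spans the whole universe (n == N); Z-score undefined"
        )
    if not (0 <= R <= N):
        raise ValueError(f"need 0 <= R <= N, got R={R}")
    if not (0 <= r <= min(n, R)):
        raise ValueError(f"need 0 <= r <= min(n, R), got r={r}")
    p = R / N
    var = n * p * (1.0 - p) * (1.0 - (n - 1) / (N - 1))
    if var == 0.0:
        return 0.0 if r == n * p else math.copysign(math.inf, r - n * p)
    return (r - n * p) / math.sqrt(var)


def permutation_pvalue(
    selected: np.ndarray,
    set_mask: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """One-sided label-permutation p for one set.

    ``selected`` and ``set_mask`` are boolean arrays over the measured
    universe. Selection labels are permuted uniformly ``n_perm`` times and
    the Z-score recomputed; the p-value uses the add-one correction
    ``(1 + #{Z_perm >= Z_obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    selected = np.asarray(selected, dtype=bool)
    set_mask = np.asarray(set_mask, dtype=bool)
    N = selected.size
    R = int(selected.sum())
    n = int(set_mask.sum())
    z_obs = ora_zscore(N, R, n, int((selected & set_mask).sum()))
    labels = selected.copy()
    exceed = 0
    for _ in range(n_perm):
        rng.shuffle(labels)
        r_perm = int((labels & set_mask).sum())
        if ora_zscore(N, R, n, r_perm) >= z_obs:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def run_ora(
    selected_genes,
    universe,
    db: GeneSetDB,
    z_min: float = 2.0,
    p_max: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """ORA of every set in ``db`` against the measured universe.

    ``universe`` is the analyzed gene list (e.g. genes passing the
    baseMean filter); ``selected_genes`` the significant subset. Sets are
    restricted to measured members; sets with no measured member are
    skipped with a warning. A set is flagged significant when |Z| > z_min
    and the permuted p < p_max. One shared stream of permutations is used
    for all sets (single seeded generator).
    """
    universe = list(dict.fromkeys(universe))
    idx = {g: i for i, g in enumerate(universe)}
    N = len(universe)
    selected = np.zeros(N, dtype=bool)
    for g in selected_genes:
        if g in idx:
            selected[idx[g]] = True
    R = int(selected.sum())
    rng = np.random.default_rng(seed)

    # membership matrix for joint permutation of all sets
    names, masks = [], []
    rows = []
    for name, members in db.sets.items():
        mask = np.zeros(N, dtype=bool)
        for g in members:
            if g in idx:
                mask[idx[g]] = True
        n = int(mask.sum())
        if n == 0:
            logger.warning("set %r has no measured members; skipped", name)
            continue
        if n == N:
            logger.warning("set %r spans the whole universe; skipped", name)
            continue
        names.append(name)
        masks.append(mask)
    if not names:
        return pd.DataFrame(
            columns=["set", "N", "R", "n", "r", "Z", "perm_p", "significant"]
        )
    M = np.array(masks).astype(np.int64)  # (sets, N)
    n_arr = M.sum(axis=1)
    r_obs = M @ selected.astype(np.int64)
    z_obs = np.array(
        [ora_zscore(N, R, int(n), int(r)) for n, r in zip(n_arr, r_obs)]
    )
    exceed = np.zeros(len(names), dtype=int)
    labels = selected.copy()
    p = R / N
    var = n_arr * p * (1 - p) * (1 - (n_arr - 1) / (N - 1))
    sd = np.sqrt(var)
    labels = labels.astype(np.int64)
    for _ in range(n_perm):
        rng.shuffle(labels)
        r_perm = M @ labels
        z_perm = np.where(sd > 0, (r_perm - n_arr * p) / np.where(sd > 0, sd, 1.0), 0.0)
        exceed += z_perm >= z_obs
    perm_p = (1 + exceed) / (1 + n_perm)
    out = pd.DataFrame(
        {
            "set": names,
            "N": N,
            "R": R,
            "n": n_arr.astype(int),
            "r": r_obs.astype(int),
            "Z": z_obs,
            "perm_p": perm_p,
        }
    )
    out["significant"] = (out["Z"].abs() > z_min) & (out["perm_p"] < p_max)
    return out.sort_values("Z", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# upstream regulators

@dataclass
class UpstreamResult:
    regulator: str
    activation_z: float
    overlap_p: float
    n_overlap: int
    predicted_state: str
    overlap_padj: float = field(default=np.nan)


def activation_zscore(
    edges: pd.DataFrame,
    observed: pd.Series,
    z_threshold: float = 2.0,
) -> UpstreamResult:
    """Activation z-score of one regulator.

    ``edges`` holds columns ``regulator, target, sign, weight`` for a
    single regulator (sign ∈ {+1, −1} expected regulation direction,
    weight >= 0). ``observed`` maps differentially expressed genes to
    their direction of change (±1); targets not in ``observed`` are
    excluded from both sums.
    """
    if edges.empty:
        raise ValueError("no edges supplied")
    regs = edges["regulator"].unique()
    if len(regs) != 1:
        raise ValueError(f"edges for exactly one regulator expected, got {list(regs)}")
    if edges.duplicated(subset=["regulator", "target"]).any():
        raise FormatError(f"duplicate (regulator, target) edges for {regs[0]!r}")
    hit = edges[edges["target"].isin(observed.index)]
    reg = str(regs[0])
    if hit.empty:
        return UpstreamResult(reg, np.nan, np.nan, 0, "none")
    w = hit["weight"].to_numpy(dtype=float)
    s_r = hit["sign"].to_numpy(dtype=float)
    s_d = observed.reindex(hit["target"]).to_numpy(dtype=float)
    denom = math.sqrt(float((w**2).sum()))
    z = float((w * s_r * s_d).sum()) / denom if denom > 0 else np.nan
    if np.isnan(z):
        state = "none"
    elif z >= z_threshold:
        state = "activated"
    elif z <= -z_threshold:
        state = "inhibited"
    else:
        state = "none"
    return UpstreamResult(reg, z, np.nan, len(hit), state)


def overlap_pvalue(regulator_targets, selected_genes, universe) -> float:
    """Right-tailed Fisher exact p for the regulator-target overlap."""
    universe = set(universe)
    targets = set(regulator_targets) & universe
    selected = set(selected_genes) & universe
    if not targets <= universe:
        raise ValueError("targets must be a subset of the universe")
    if not targets:
        return 1.0
    k = len(targets & selected)
    table = [
        [k, len(targets) - k],
        [len(selected) - k, len(universe) - len(targets) - len(selected) + k],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def run_upstream(
    network: pd.DataFrame,
    observed: pd.Series,
    universe,
    z_threshold: float = 2.0,
    overlap_alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every regulator of a signed network.

    ``network`` has columns ``regulator, target, sign, weight``;
    ``observed`` maps DE genes to ±1 direction. Overlap p-values are
    BH-corrected across regulators, and a state is predicted only for
    regulators whose corrected overlap p is below ``overlap_alpha``.
    """
    missing = [c for c in NETWORK_COLUMNS if c not in network.columns]
    if missing:
        raise FormatError(f"network missing columns: {missing}")
    selected = set(observed.index)
    rows = []
    for reg, edges in network.groupby("regulator", sort=True):
        res = activation_zscore(edges, observed, z_threshold)
        res.overlap_p = overlap_pvalue(edges["target"], selected, universe)
        rows.append(res)
    out = pd.DataFrame(
        {
            "regulator": [r.regulator for r in rows],
            "activation_z": [r.activation_z for r in rows],
            "overlap_p": [r.overlap_p for r in rows],
            "n_overlap": [r.n_overlap for r in rows],
            "predicted_state": [r.predicted_state for r in rows],
        }
    )
    out["overlap_padj"] = bh_adjust(out["overlap_p"])
    out.loc[out["overlap_padj"] >= overlap_alpha, "predicted_state"] = "none"
    return out.sort_values("activation_z", ascending=False).reset_index(drop=True)
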