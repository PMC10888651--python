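"""Local connectivity engine: KS enrichment, WTCS/NCS, tau percentile scoring.

Given a query signature (up/down tag lists) and a reference compendium of
level-5-style z-score profiles, every profile is scored with the classic
unweighted Kolmogorov-Smirnov connectivity statistic:

* ``es_score`` — running-sum extreme for one tag set against one ranked
  profile; positive when the set concentrates at the top of the ranking.
* ``wtcs`` — two-sided combination (es_up - es_down)/2 when the two enrichment
  scores disagree in sign, else 0 (incoherent up/down behaviour is a null).
* ``ncs`` — WTCS rescaled by the mean |WTCS| of same-sign records within the
  same cell line, harmonizing scales across cell lines.
* ``tau`` — signed percentile of |NCS| against a reference bank of NCS values
  for the same cell line, scaled to [-100, 100]. |tau| > 90 flags a
  connection worth following up.

The reference bank ("touchstone") can be built once per compendium from random
probe signatures (:func:`build_touchstone`); when absent, the query's own
profile-level NCS values within each cell line serve as the bank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import QueryError, ValidationError
from .formats_io import (
    DenseMatrixFile,
    read_gct,
    read_metadata_table,
    write_gct,
    write_metadata_table,
)
from .signature import GeneSignature

logger = logging.getLogger(__name__)

SIG_INFO_COLUMNS = ["sig_id", "pert_id", "pert_iname", "pert_type", "cell_id"]
GENE_INFO_COLUMNS = ["pr_gene_id", "pr_gene_symbol", "pr_is_lm", "pr_is_bing"]

RECORD_COLUMNS = [
    "query_id", "pert_id", "pert_iname", "cell_id", "sig_id",
    "es_up", "es_down", "wtcs", "ncs", "tau", "connected",
]


@dataclass
class ReferenceCompendium:
    """Z-score profiles plus sig_info/gene_info metadata (GSE92742 layout).

    ``zscores`` rows are genes keyed by ``gene_info.pr_gene_id``; columns are
    profiles keyed by ``sig_info.sig_id``. ``touchstone`` optionally maps each
    cell line to the NCS reference bank used for tau percentiles.
    """

    zscores: DenseMatrixFile
    sig_info: pd.DataFrame
    gene_info: pd.DataFrame
    touchstone: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        for col in SIG_INFO_COLUMNS:
            if col not in self.sig_info.columns:
                raise ValidationError(f"sig_info missing column '{col}'")
        for col in ("pr_gene_id", "pr_is_lm"):
            if col not in self.gene_info.columns:
                raise ValidationError(f"gene_info missing column '{col}'")
        sig_ids = set(self.sig_info["sig_id"])
        missing = [c for c in self.zscores.col_ids if c not in sig_ids]
        if missing:
            raise ValidationError(f"profiles without sig_info rows: {missing[:5]}")
        gene_ids = set(self.gene_info["pr_gene_id"])
        missing = [r for r in self.zscores.row_ids if r not in gene_ids]
        if missing:
            raise ValidationError(f"genes without gene_info rows: {missing[:5]}")
        self._positions: np.ndarray | None = None

    @property
    def landmark_ids(self) -> list[str]:
        lm = self.gene_info[self.gene_info["pr_is_lm"].astype(bool)]
        return [g for g in self.zscores.row_ids if g in set(lm["pr_gene_id"])]

    def profile_meta(self) -> pd.DataFrame:
        """sig_info rows aligned to the z-score columns."""
        meta = self.sig_info.set_index("sig_id", drop=False)
        return meta.loc[self.zscores.col_ids]

    def rank_positions(self) -> np.ndarray:
        """1-based rank of every gene in every profile, descending z.

        Ties in z are broken by lexicographic gene id. Cached.
        """
        if self._positions is None:
            z = self.zscores.values
            gene_ids = np.array(self.zscores.row_ids)
            n = z.shape[0]
            pos = np.empty_like(z, dtype=np.int64)
            ranks = np.arange(1, n + 1)
            for j in range(z.shape[1]):
                order = np.lexsort((gene_ids, -z[:, j]))
                pos[order, j] = ranks
            self._positions = pos
        return self._positions

    def save(self, directory, dialect: str = "gct1.2") -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_gct(self.zscores, directory / "zscores.gct", dialect=dialect)
        write_metadata_table(self.sig_info, directory / "sig_info.tsv")
        write_metadata_table(self.gene_info, directory / "gene_info.tsv")
        if self.touchstone is not None:
            rows = [
                {"cell_id": cell, "ncs": v}
                for cell, values in sorted(self.touchstone.items())
                for v in values
            ]
            pd.DataFrame(rows, columns=["cell_id", "ncs"]).to_csv(
                directory / "touchstone.tsv", sep="\t", index=False
            )
        return directory

    @classmethod
    def load(cls, directory) -> "ReferenceCompendium":
        directory = Path(directory)
        zscores = read_gct(directory / "zscores.gct")
        sig_info = read_metadata_table(directory / "sig_info.tsv", SIG_INFO_COLUMNS)
        gene_info = read_metadata_table(
            directory / "gene_info.tsv", ("pr_gene_id", "pr_is_lm")
        )
        touchstone = None
        ts_path = directory / "touchstone.tsv"
        if ts_path.exists():
            ts = pd.read_csv(ts_path, sep="\t", dtype={"cell_id": str})
            touchstone = {
                cell: grp["ncs"].to_numpy(dtype=float)
                for cell, grp in ts.groupby("cell_id")
            }
        return cls(zscores, sig_info, gene_info, touchstone=touchstone)


@dataclass
class ConnectivityConfig:
    tau_cutoff: float = 90.0
    k: int = 10
    aggregator: str = "max_abs"  # or "median"
    compounds_only: bool = True

    def __post_init__(self):
        if self.aggregator not in {"max_abs", "median"}:
            raise ValidationError(f"unknown aggregator {self.aggregator!r}")


# ---------------------------------------------------------------------------
# Scoring primitives
# ---------------------------------------------------------------------------


def _es_from_ranks(ranks: np.ndarray, n: int) -> float:
    """KS running-sum extreme from the 1-based ranks of a tag set."""
    v = np.sort(np.asarray(ranks, dtype=float))
    t = v.size
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return a if a > b else -b


def es_score(gene_set: Sequence[str], profile_ranking: Sequence[str]) -> float:
    """Enrichment score of ``gene_set`` in a profile ranked by descending z.

    With V(j) the ascending ranks of the set's genes among n ranked genes,
    ES = a if a > b else -b where a = max_j [j/t - V(j)/n] and
    b = max_j [V(j)/n - (j-1)/t]. Empty sets are an error (callers skip the
    direction instead).
    """
    if len(gene_set) == 0:
        raise ValidationError("es_score: empty gene set")
    index = {g: i + 1 for i, g in enumerate(profile_ranking)}
    try:
        ranks = np.array([index[g] for g in gene_set])
    except KeyError as exc:
        raise ValidationError(f"gene {exc.args[0]!r} absent from ranking") from exc
    return _es_from_ranks(ranks, len(profile_ranking))


def wtcs(es_up: float, es_down: float) -> float:
    """Two-sided combined score: (es_up - es_down)/2 on sign disagreement, else 0."""
    if np.sign(es_up) != np.sign(es_down):
        return (es_up - es_down) / 2.0
    return 0.0


def normalize_ncs(records: pd.DataFrame) -> pd.DataFrame:
    """Add an ``ncs`` column: wtcs / mean |wtcs| of same-sign records per cell line.

    Zero WTCS maps to zero NCS; a cell-line group whose records are all zero
    stays at zero.
    """
    out = records.copy()
    ncs = np.zeros(len(out), dtype=float)
    w = out["wtcs"].to_numpy(dtype=float)
    for _, idx in out.groupby("cell_id").indices.items():
        for mask in (w[idx] > 0, w[idx] < 0):
            if mask.any():
                denom = np.abs(w[idx][mask]).mean()
                ncs[idx[mask]] = w[idx][mask] / denom
    out["ncs"] = ncs
    return out


def tau_score(ncs: float, compendium_ncs: np.ndarray) -> float:
    """Signed percentile of |ncs| within a reference NCS bank, in [-100, 100].

    tau = sign(ncs) * 100 * fraction of bank values with |value| strictly below
    |ncs|; stronger connections land nearer +/-100.
    """
    reference = np.asarray(compendium_ncs, dtype=float)
    if reference.size == 0:
        raise ValidationError("tau_score: empty reference bank")
    frac = float(np.mean(np.abs(reference) < abs(ncs)))
    return float(np.sign(ncs)) * 100.0 * frac


# ---------------------------------------------------------------------------
# Query execution
# ---------------------------------------------------------------------------


def _tag_indices(tags: Sequence[str], gene_index: Mapping[str, int], label: str, query_id: str) -> np.ndarray:
    idx = [gene_index[t] for t in tags if t in gene_index]
    dropped = len(tags) - len(idx)
    if dropped:
        logger.info(
            "query %s: %d of %d %s tags absent from reference", query_id, dropped, len(tags), label
        )
    return np.array(idx, dtype=np.int64)


def _profile_records(sig: GeneSignature, ref: ReferenceCompendium, cfg: ConnectivityConfig) -> pd.DataFrame:
    """Per-profile ES/WTCS/NCS records for one query (pre-aggregation)."""
    meta = ref.profile_meta()
    keep = np.ones(len(meta), dtype=bool)
    if cfg.compounds_only and (meta["pert_type"] == "trt_cp").any():
        keep = (meta["pert_type"] == "trt_cp").to_numpy()
    gene_index = {g: i for i, g in enumerate(ref.zscores.row_ids)}
    up_idx = _tag_indices(sig.up_tags, gene_index, "up", sig.signature_id)
    down_idx = _tag_indices(sig.down_tags, gene_index, "down", sig.signature_id)
    if up_idx.size == 0 and down_idx.size == 0:
        raise QueryError(
            f"query {sig.signature_id}: no signature tags overlap the reference genes"
        )
    pos = ref.rank_positions()
    n = pos.shape[0]
    cols = np.flatnonzero(keep)
    rows = []
    for j in cols:
        es_up = _es_from_ranks(pos[up_idx, j], n) if up_idx.size else 0.0
        es_down = _es_from_ranks(pos[down_idx, j], n) if down_idx.size else 0.0
        if up_idx.size and down_idx.size:
            w = wtcs(es_up, es_down)
        else:  # one-sided query: half the available ES, sign preserved
            w = es_up / 2.0 if up_idx.size else -es_down / 2.0
        rows.append(
            {
                "query_id": sig.signature_id,
                "sig_id": meta["sig_id"].iloc[j],
                "pert_id": meta["pert_id"].iloc[j],
                "pert_iname": meta["pert_iname"].iloc[j],
                "cell_id": meta["cell_id"].iloc[j],
                "es_up": es_up if up_idx.size else np.nan,
                "es_down": es_down if down_idx.size else np.nan,
                "wtcs": w,
            }
        )
    return normalize_ncs(pd.DataFrame(rows))


def _aggregate(records: pd.DataFrame, aggregator: str) -> pd.DataFrame:
    """Collapse replicate profiles of one (pert_id, cell_id) to a representative."""
    picked = []
    for _, grp in records.groupby(["pert_id", "cell_id"], sort=True):
        grp = grp.sort_values("sig_id", kind="stable")
        abs_ncs = grp["ncs"].abs().to_numpy()
        if aggregator == "max_abs":
            picked.append(grp.iloc[int(np.argmax(abs_ncs))])
        else:  # median: representative closest to the median magnitude
            med = np.median(abs_ncs)
            picked.append(grp.iloc[int(np.argmin(np.abs(abs_ncs - med)))])
    return pd.DataFrame(picked).reset_index(drop=True)


def query_compendium(
    sig: GeneSignature, ref: ReferenceCompendium, cfg: ConnectivityConfig | None = None
) -> pd.DataFrame:
    """Score one query signature against every reference profile.

    Returns one record per (pert_id, cell_id) pair — replicate profiles are
    collapsed by the configured aggregator — sorted from the most to the least
    expression-correlated result by tau. The ``connected`` flag marks
    |tau| > tau_cutoff (default 90).
    """
    cfg = cfg or ConnectivityConfig()
    records = _profile_records(sig, ref, cfg)
    bank = ref.touchstone
    if bank is None:
        bank = {
            cell: grp["ncs"].to_numpy(dtype=float)
            for cell, grp in records.groupby("cell_id")
        }
    table = _aggregate(records, cfg.aggregator)
    taus = []
    for _, row in table.iterrows():
        if row["cell_id"] not in bank:
            raise QueryError(f"no touchstone bank for cell line {row['cell_id']!r}")
        taus.append(tau_score(row["ncs"], bank[row["cell_id"]]))
    table["tau"] = taus
    table["connected"] = table["tau"].abs() > cfg.tau_cutoff
    table["_abs_ncs"] = table["ncs"].abs()
    table = table.sort_values(
        ["tau", "_abs_ncs", "pert_id"], ascending=[False, False, True], kind="stable"
    ).drop(columns="_abs_ncs")
    return table[RECORD_COLUMNS].reset_index(drop=True)


def top_k(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """First ``k`` rows by descending tau (ties: |ncs| descending, then pert_id)."""
    if k <= 0:
        raise ValidationError("k must be positive")
    out = table.copy()
    out["_abs_ncs"] = out["ncs"].abs()
    out = out.sort_values(
        ["tau", "_abs_ncs", "pert_id"], ascending=[False, False, True], kind="stable"
    ).drop(columns="_abs_ncs")
    return out.head(k).reset_index(drop=True)


def build_touchstone(
    ref: ReferenceCompendium,
    n_probes: int = 50,
    tags_per_direction: int = 50,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Build the tau reference bank from random probe signatures.

    Each probe draws disjoint up/down tag sets uniformly from the reference
    genes; the per-profile NCS values of all probes are pooled per cell line.
    """
    rng = np.random.default_rng(seed)
    genes = np.array(ref.zscores.row_ids)
    t = min(tags_per_direction, len(genes) // 2)
    cfg = ConnectivityConfig()
    pooled: dict[str, list[np.ndarray]] = {}
    for i in range(n_probes):
        draw = rng.choice(len(genes), size=2 * t, replace=False)
        probe = GeneSignature(f"probe_{i}", tuple(genes[draw[:t]]), tuple(genes[draw[t:]]))
        records = _profile_records(probe, ref, cfg)
        for cell, grp in records.groupby("cell_id"):
            pooled.setdefault(cell, []).append(grp["ncs"].to_numpy(dtype=float))
    return {cell: np.concatenate(parts) for cell, parts in pooled.items()}


def heatmap_matrix(
    tables: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame], k: int = 10
) -> DenseMatrixFile:
    """Tau matrix of top-k compounds (rows) x query-cell pairs (columns).

    Rows are the union of each query's top-k pert_ids; entries are tau values
    from the full tables, NA where a pair was never scored. Column metadata
    carries the signature and cell-line labels.
    """
    if not isinstance(tables, Mapping):
        tables = {str(t["query_id"].iloc[0]): t for t in tables}
    if len(tables) == 0:
        raise ValidationError("heatmap_matrix: no connectivity tables")
    top_perts: list[str] = []
    iname: dict[str, str] = {}
    for table in tables.values():
        for _, row in top_k(table, k).iterrows():
            if row["pert_id"] not in top_perts:
                top_perts.append(row["pert_id"])
            iname[row["pert_id"]] = row["pert_iname"]
    col_ids, signatures, cell_lines = [], [], []
    data = {}
    for query_id, table in tables.items():
        for cell in sorted(table["cell_id"].unique()):
            col = f"{query_id}|{cell}"
            col_ids.append(col)
            signatures.append(query_id)
            cell_lines.append(cell)
            sub = table[table["cell_id"] == cell].set_index("pert_id")["tau"]
            data[col] = [sub.get(p, np.nan) for p in top_perts]
    values = np.array([data[c] for c in col_ids], dtype=float).T
    row_meta = pd.DataFrame({"pert_iname": [iname[p] for p in top_perts]}, index=top_perts)
    col_meta = pd.DataFrame(
        {"signature": signatures, "cell_line": cell_lines}, index=col_ids
    )
    return DenseMatrixFile(top_perts, col_ids, values, row_meta=row_meta, col_meta=col_meta)


def write_connectivity_table(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", index=False)
    return path


def read_connectivity_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={c: str for c in ("query_id", "pert_id", "pert_iname", "cell_id", "sig_id")})
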