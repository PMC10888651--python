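"""Consensus gene selection: signature genes coherently modulated by a compound.

After the connectivity step picks candidate compounds, the compendium is
subset to those compounds, the cell lines of interest, and (by default) the
978 directly measured landmark genes. A signature gene is retained for a
compound when its direction of modulation (sign of the z-score) agrees with
the signature in at least 70% of the compound's selected profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .connectivity import ReferenceCompendium
from .errors import SelectionError, ValidationError
from .signature import GeneSignature

logger = logging.getLogger(__name__)

CONSENSUS_COLUMNS = ["query_id", "pert_id", "gene_id", "direction", "support_fraction"]


@dataclass
class ConsensusConfig:
    min_direction_fraction: float = 0.70
    pert_ids: list[str] | None = None
    pert_inames: list[str] | None = None
    cell_ids: list[str] | None = None
    landmark_only: bool = True
    mode: str = "per_compound"  # or "pooled"

    def __post_init__(self):
        if not (0 < self.min_direction_fraction <= 1):
            raise ValidationError("min_direction_fraction must lie in (0, 1]")
        if self.mode not in {"per_compound", "pooled"}:
            raise ValidationError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class ConsensusGeneSet:
    query_id: str
    pert_id: str
    genes: tuple[tuple[str, str, float], ...]  # (gene_id, direction, support)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g for g, _, _ in self.genes)


def _check_axis(requested, available, axis: str) -> None:
    if requested is None:
        return
    missing = sorted(set(requested) - set(available))
    if missing:
        raise SelectionError(f"{axis} not present in compendium: {missing}")


def subset_compendium(ref: ReferenceCompendium, cfg: ConsensusConfig) -> ReferenceCompendium:
    """Restrict profiles by pert_id/pert_iname/cell_id and rows to landmarks.

    Every id in a provided selection list must exist; an empty result names
    the empty axis.
    """
    meta = ref.profile_meta()
    _check_axis(cfg.pert_ids, meta["pert_id"], "pert_id")
    _check_axis(cfg.pert_inames, meta["pert_iname"], "pert_iname")
    _check_axis(cfg.cell_ids, meta["cell_id"], "cell_id")
    mask = pd.Series(True, index=meta.index)
    if cfg.pert_ids is not None:
        mask &= meta["pert_id"].isin(cfg.pert_ids)
    if cfg.pert_inames is not None:
        mask &= meta["pert_iname"].isin(cfg.pert_inames)
    if cfg.cell_ids is not None:
        mask &= meta["cell_id"].isin(cfg.cell_ids)
    cols = [c for c, m in zip(ref.zscores.col_ids, mask) if m]
    if not cols:
        raise SelectionError("profile selection is empty (pert/cell filters)")
    rows = ref.landmark_ids if cfg.landmark_only else ref.zscores.row_ids
    if not rows:
        raise SelectionError("gene selection is empty (landmark filter)")
    zscores = ref.zscores.subset(rows=rows, cols=cols)
    sig_info = ref.sig_info[ref.sig_info["sig_id"].isin(cols)].reset_index(drop=True)
    gene_info = ref.gene_info[ref.gene_info["pr_gene_id"].isin(rows)].reset_index(drop=True)
    return ReferenceCompendium(zscores, sig_info, gene_info, touchstone=ref.touchstone)


def _direction_support(
    z: pd.DataFrame, sig: GeneSignature, min_fraction: float, query_id: str, pert_id: str
) -> ConsensusGeneSet:
    """Support fractions for one group of profiles (columns of ``z``)."""
    genes = []
    n = z.shape[1]
    for tags, direction, positive in ((sig.up_tags, "up", True), (sig.down_tags, "down", False)):
        present = [t for t in tags if t in z.index]
        skipped = len(tags) - len(present)
        if skipped:
            logger.info(
                "consensus %s/%s: %d %s tags absent from subset rows",
                query_id, pert_id, skipped, direction,
            )
        for g in present:
            row = z.loc[g].to_numpy(dtype=float)
            support = float(np.mean(row > 0)) if positive else float(np.mean(row < 0))
            if support >= min_fraction:
                genes.append((g, direction, support))
    return ConsensusGeneSet(query_id, pert_id, tuple(genes))


def consensus_select(
    sig: GeneSignature, ref_subset: ReferenceCompendium, cfg: ConsensusConfig | None = None
) -> list[ConsensusGeneSet]:
    """Per-compound consensus gene sets for one query signature.

    An up tag is supported by a profile when its z-score is strictly positive
    (z = 0 supports neither direction); retained iff the supporting fraction is
    at least ``min_direction_fraction`` of the compound's profiles. The
    ``pooled`` mode computes support across all selected profiles at once.
    """
    cfg = cfg or ConsensusConfig()
    if not ref_subset.zscores.col_ids:
        raise SelectionError("consensus_select: empty compendium subset")
    frame = ref_subset.zscores.to_frame()
    meta = ref_subset.profile_meta()
    if cfg.mode == "pooled":
        return [
            _direction_support(frame, sig, cfg.min_direction_fraction, sig.signature_id, "*")
        ]
    out = []
    for pert_id, grp in meta.groupby("pert_id", sort=True):
        z = frame[list(grp["sig_id"])]
        out.append(
            _direction_support(z, sig, cfg.min_direction_fraction, sig.signature_id, pert_id)
        )
    return out


def consensus_table(sets: list[ConsensusGeneSet]) -> pd.DataFrame:
    rows = [
        {
            "query_id": s.query_id,
            "pert_id": s.pert_id,
            "gene_id": g,
            "direction": d,
            "support_fraction": f,
        }
        for s in sets
        for g, d, f in s.genes
    ]
    return pd.DataFrame(rows, columns=CONSENSUS_COLUMNS)
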