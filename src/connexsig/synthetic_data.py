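"""Synthetic experiments, reference compendia and pathway collections.

Every downstream stage of the pipeline is exercised against data with planted
ground truth:

* :func:`simulate_experiment` — a log2 expression matrix with two groups
  (>=3 samples each) and planted differentially expressed genes shifted by a
  fixed effect size on the treated side.
* :func:`simulate_compendium` — a CMap-style z-score compendium whose
  background profiles are i.i.d. standard normal; a planted "connected"
  compound adds +s*delta to a query signature's up genes and -s*delta to its
  down genes. Metadata emulates the GSE92742 layout (978 landmark genes
  flagged pr_is_lm within a 12,328-gene gene_info by default, at desk scale
  in the profile dimension).
* :func:`simulate_pathways` — random gene sets over a universe, optionally
  with one planted set so enrichment has a known positive.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import ReferenceCompendium
from .diffexpr import ExpressionExperiment
from .errors import SpecError
from .formats_io import DenseMatrixFile, GeneSet, GeneSetCollection
from .signature import GeneSignature

#: the nine reference cell lines used for compendium subsetting by default
DEFAULT_CELL_IDS = (
    "A375", "A549", "HA1E", "HCC515", "HEPG2", "HT29", "MCF7", "PC3", "VCAP",
)

N_LANDMARK = 978
N_GENES_TOTAL = 12328


def gene_id(i: int) -> str:
    return f"G{i + 1:05d}"


@dataclass
class ExperimentSpec:
    n_genes: int = 5000
    n_per_group: int = 3
    n_up: int = 400
    n_down: int = 400
    effect_size: float = 2.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_up + self.n_down > self.n_genes:
            raise SpecError("n_up + n_down exceeds n_genes")
        if self.n_per_group < 3:
            raise SpecError("need at least 3 samples per group")
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be positive")


def simulate_experiment(spec: ExperimentSpec) -> tuple[ExpressionExperiment, pd.DataFrame]:
    """Two-group log2 expression experiment with planted DE genes.

    Control columns are baseline + noise; treated columns additionally shift
    the planted genes by +/- effect_size. The truth table lists the planted
    gene ids, their direction, and the applied shift.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [gene_id(i) for i in range(spec.n_genes)]
    baseline = rng.normal(7.0, 1.5, size=spec.n_genes)
    n_samples = 2 * spec.n_per_group
    values = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))
    planted = rng.choice(spec.n_genes, size=spec.n_up + spec.n_down, replace=False)
    up_idx, down_idx = planted[: spec.n_up], planted[spec.n_up :]
    treated_cols = slice(spec.n_per_group, n_samples)
    values[up_idx, treated_cols] += spec.effect_size
    values[down_idx, treated_cols] -= spec.effect_size
    samples = [f"ctrl_{i + 1}" for i in range(spec.n_per_group)] + [
        f"trt_{i + 1}" for i in range(spec.n_per_group)
    ]
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    groups = pd.Series(
        ["control"] * spec.n_per_group + ["treated"] * spec.n_per_group, index=samples
    )
    truth = pd.DataFrame(
        {
            "gene_id": [genes[i] for i in np.concatenate([up_idx, down_idx])],
            "direction": ["up"] * spec.n_up + ["down"] * spec.n_down,
            "shift": [spec.effect_size] * spec.n_up + [-spec.effect_size] * spec.n_down,
        }
    )
    return ExpressionExperiment(matrix, groups), truth


@dataclass
class CompendiumSpec:
    n_landmark: int = N_LANDMARK
    n_nonlandmark: int = N_GENES_TOTAL - N_LANDMARK
    compounds: list[tuple[str, str]] | None = None  # (pert_id, pert_iname)
    cell_ids: Sequence[str] = DEFAULT_CELL_IDS
    profiles_per_pair: int = 3
    planted_connections: Sequence[tuple[str, str, float]] = ()  # (query_id, pert_id, strength)
    delta: float = 3.0
    bing_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.compounds is None:
            self.compounds = [(f"BRD-S{i:04d}", f"cpd-{i}") for i in range(10)]
        pert_ids = [p for p, _ in self.compounds]
        if len(set(pert_ids)) != len(pert_ids):
            raise SpecError("duplicate pert_ids")
        for _, pert_id, strength in self.planted_connections:
            if pert_id not in pert_ids:
                raise SpecError(f"planted connection references unknown pert_id {pert_id!r}")
            if not (0 <= strength <= 1):
                raise SpecError("planted connection strength must lie in [0, 1]")
        if self.n_landmark < 1 or self.profiles_per_pair < 1:
            raise SpecError("n_landmark and profiles_per_pair must be positive")


def simulate_compendium(
    spec: CompendiumSpec, query_signatures: Sequence[GeneSignature] = ()
) -> tuple[ReferenceCompendium, pd.DataFrame]:
    """CMap-style z-score compendium with optionally planted connections.

    Background z-scores are i.i.d. standard normal. For a planted connection
    (query_id, pert_id, strength), every profile of that compound adds
    +strength*delta on the query's up tags and -strength*delta on its down
    tags. The first ``n_landmark`` genes carry pr_is_lm = 1.
    """
    by_id = {s.signature_id: s for s in query_signatures}
    for query_id, _, _ in spec.planted_connections:
        if query_id not in by_id:
            raise SpecError(f"planted connection references unknown query_id {query_id!r}")
    rng = np.random.default_rng(spec.seed)
    n_genes = spec.n_landmark + spec.n_nonlandmark
    genes = [gene_id(i) for i in range(n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}

    sig_rows = []
    for pert_id, pert_iname in spec.compounds:
        for cell in spec.cell_ids:
            for rep in range(spec.profiles_per_pair):
                sig_rows.append(
                    {
                        "sig_id": f"{pert_id}:{cell}:{rep + 1}",
                        "pert_id": pert_id,
                        "pert_iname": pert_iname,
                        "pert_type": "trt_cp",
                        "cell_id": cell,
                    }
                )
    sig_info = pd.DataFrame(sig_rows)
    values = rng.standard_normal((n_genes, len(sig_info)))

    truth_rows = []
    cols_of = sig_info.groupby("pert_id").indices
    for query_id, pert_id, strength in spec.planted_connections:
        sig = by_id[query_id]
        cols = cols_of[pert_id]
        up = [gene_index[g] for g in sig.up_tags if g in gene_index]
        down = [gene_index[g] for g in sig.down_tags if g in gene_index]
        values[np.ix_(up, cols)] += strength * spec.delta
        values[np.ix_(down, cols)] -= strength * spec.delta
        truth_rows.append({"query_id": query_id, "pert_id": pert_id, "strength": strength})

    n_bing_extra = int(round(spec.bing_fraction * spec.n_nonlandmark))
    gene_info = pd.DataFrame(
        {
            "pr_gene_id": genes,
            "pr_gene_symbol": genes,
            "pr_is_lm": [i < spec.n_landmark for i in range(n_genes)],
            "pr_is_bing": [i < spec.n_landmark + n_bing_extra for i in range(n_genes)],
        }
    )
    zscores = DenseMatrixFile(genes, list(sig_info["sig_id"]), values)
    ref = ReferenceCompendium(zscores, sig_info, gene_info)
    truth = pd.DataFrame(truth_rows, columns=["query_id", "pert_id", "strength"])
    return ref, truth


def simulate_pathways(
    n_sets: int,
    set_size_range: tuple[int, int],
    universe: Sequence[str],
    planted: tuple[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets over ``universe``, optionally with one planted set."""
    universe = list(universe)
    if not universe:
        raise SpecError("empty universe")
    lo, hi = set_size_range
    if hi > len(universe) or lo < 1 or lo > hi:
        raise SpecError("set sizes must fit the universe")
    rng = np.random.default_rng(seed)
    sets: dict[str, GeneSet] = {}
    if planted is not None:
        set_id, genes = planted
        members = tuple(dict.fromkeys(genes))
        if not set(members) <= set(universe):
            raise SpecError("planted set members must lie in the universe")
        sets[set_id] = GeneSet(set_id, "planted set", members)
    for i in range(n_sets - (1 if planted is not None else 0)):
        size = int(rng.integers(lo, hi + 1))
        members = tuple(np.array(universe)[rng.choice(len(universe), size=size, replace=False)])
        sets[f"SET{i + 1:04d}"] = GeneSet(f"SET{i + 1:04d}", f"random set {i + 1}", members)
    return GeneSetCollection(sets)
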