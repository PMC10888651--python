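"""Differential expression for two-group (treated vs control) experiments.

The analysis mirrors the standard microarray pipeline: quantile normalization
of log2 intensities, a per-gene two-sample comparison with an empirical-Bayes
moderated t-statistic (per-gene variances shrunk toward a common prior fitted
by method-of-moments on log sample variances), and Benjamini-Hochberg control
of the false discovery rate. DEGs are called at q < 0.05 by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

CONTROL = "control"
TREATED = "treated"

DEG_COLUMNS = ["gene_id", "logFC", "t", "p", "q"]


@dataclass
class ExpressionExperiment:
    """A log2 expression matrix (genes x samples) with a two-group labelling.

    ``groups`` maps each sample to ``control`` or ``treated``; each group must
    contain at least three samples.
    """

    matrix: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        self.groups = pd.Series(self.groups)
        if list(self.groups.index) != list(self.matrix.columns):
            self.groups = self.groups.reindex(self.matrix.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValidationError(f"samples without group label: {missing}")
        bad = set(self.groups) - {CONTROL, TREATED}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        counts = self.groups.value_counts()
        for label in (CONTROL, TREATED):
            if counts.get(label, 0) < 3:
                raise ValidationError(f"group '{label}' has fewer than 3 samples")
        if self.matrix.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    def group_matrix(self, label: str) -> np.ndarray:
        cols = self.groups.index[self.groups == label]
        return self.matrix[cols].to_numpy(dtype=float)


def quantile_normalize(matrix):
    """Force every column onto the same value distribution.

    The reference distribution is the vector of row-wise means of the
    column-sorted values. Within-column rank order is preserved; tied values
    receive the mean of the reference values over their rank span (the
    conventional microarray tie rule).
    """
    frame = isinstance(matrix, pd.DataFrame)
    values = matrix.to_numpy(dtype=float) if frame else np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValidationError("quantile_normalize requires a non-empty 2-D matrix")
    if np.isnan(values).all(axis=0).any():
        raise ValidationError("quantile_normalize: all-NA column")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # ties take the mean of the reference values across their sorted span
        sorted_col = col[order]
        start = 0
        for end in range(1, len(col) + 1):
            if end == len(col) or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    assigned[order[start:end]] = reference[start:end].mean()
                start = end
        out[:, j] = assigned
    if frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def benjamini_hochberg(p) -> np.ndarray:
    """BH step-up adjusted p-values (q-values); order-preserving, in [0, 1]."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the (d0, s0^2) variance prior on log variances.

    Under the scaled chi-square hierarchy, log(s_g^2) has expectation
    log(s0^2) + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2) and variance
    psi'(df/2) + psi'(d0/2); matching the sample mean and variance of the
    observed log variances gives closed-form estimates.
    """
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValueError("too few positive variances to fit the prior")
    e = np.log(positive) - digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess dispersion: variances look identical -> infinite prior df
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
    return d0, s0_sq


def fit_differential(expr: ExpressionExperiment, method: str = "moderated_t") -> pd.DataFrame:
    """Per-gene treated-vs-control test; returns the DEG table.

    ``logFC`` is mean(treated) - mean(control) on the log2 scale. With
    ``ordinary_t`` the pooled-variance two-sample t on n1+n2-2 df is used;
    ``moderated_t`` shrinks each gene's pooled variance toward the fitted prior
    s0^2 with weight d0 and tests on d0 + dg degrees of freedom.
    """
    if method not in {"moderated_t", "ordinary_t"}:
        raise ValidationError(f"unknown method {method!r}")
    treated = expr.group_matrix(TREATED)
    control = expr.group_matrix(CONTROL)
    n1, n2 = treated.shape[1], control.shape[1]
    logfc = treated.mean(axis=1) - control.mean(axis=1)
    dg = n1 + n2 - 2
    ss = treated.var(axis=1, ddof=1) * (n1 - 1) + control.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / dg
    scale = np.sqrt(1.0 / n1 + 1.0 / n2)

    d0 = 0.0
    if method == "moderated_t":
        try:
            d0, s0_sq = _fit_variance_prior(s2, dg)
        except ValueError:
            warnings.warn(
                "variance prior could not be estimated; falling back to ordinary_t",
                RuntimeWarning,
            )
            method = "ordinary_t"

    if method == "moderated_t":
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0_sq)
            df = np.inf
        else:
            s2_tilde = (d0 * s0_sq + dg * s2) / (d0 + dg)
            df = dg + d0
    else:
        s2_tilde = s2
        df = dg

    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / (np.sqrt(s2_tilde) * scale)
    t = np.where(logfc == 0, 0.0, t)
    bad = np.isnan(t) | np.isinf(t)  # zero variance with nonzero shift
    if bad.any():
        t = t.copy()
        t[bad] = np.sign(logfc[bad]) * np.inf
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(np.where(t == 0, 1.0, p), 0.0, 1.0)
    q = benjamini_hochberg(p)
    return pd.DataFrame(
        {"gene_id": expr.gene_ids, "logFC": logfc, "t": t, "p": p, "q": q}
    )


def filter_degs(table: pd.DataFrame, q_cutoff: float = 0.05) -> pd.DataFrame:
    """Retain rows with q < ``q_cutoff`` (strict), sorted by logFC descending.

    Ties in logFC are broken by ascending q, then lexicographic gene_id.
    """
    if "q" not in table.columns:
        raise ValidationError("DEG table lacks a 'q' column")
    kept = table[table["q"] < q_cutoff]
    kept = kept.sort_values(
        ["logFC", "q", "gene_id"], ascending=[False, True, True], kind="stable"
    )
    return kept.reset_index(drop=True)


def read_deg_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in DEG_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"DEG table missing columns {missing}")
    return table


def write_deg_table(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", index=False)
    return path
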