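"""Covariate-adjusted cross-block rank correlation with FDR control.

The screen tests every variable pair spanning two of the three blocks
(metabolites, clinical scores, brain metrics) and never pairs within a
block.  Each test is a partial Spearman correlation controlling for
age and sex: both variables and the covariates are average-rank
transformed on the pairwise-complete subjects, the ranked variables
are residualized on an intercept plus the ranked covariates by least
squares, and r is the Pearson correlation of the residuals.  The
two-sided p-value uses t = r * sqrt(df / (1 - r^2)) with
df = n - 2 - k (k covariates); the sample-size convention df = n - 1
is emitted alongside as ``df_printed``.

Benjamini-Hochberg q-values are attached within configurable families;
the default family key is (block pair x brain modality), with pooled
and per-block-pair alternatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FAMILY_KEYS = ("block_pair_modality", "block_pair", "pooled")

DISPLAY_NAMES = {
    "indole": "Indole", "skatole": "Skatole", "iaa": "IAA",
    "bmi": "BMI", "yfas": "YFAS", "had_anxiety": "ANX",
}


class PartialCorrResult(NamedTuple):
    r: float
    p: float
    n: int
    df: int


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def _residualize(ranked: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, ranked, rcond=None)
    return ranked - design @ beta


def partial_spearman(x, y, covariates=None) -> PartialCorrResult:
    """Partial Spearman correlation of x and y given covariates.

    Pairwise-complete cases are selected (x, y and every covariate
    non-missing).  With no covariates (or constant ones) this reduces
    to the plain Spearman correlation.

    Returns (r, p, n, df); r is NaN (with a log entry) when x or y has
    zero variance after ranking on the complete cases.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        Z = np.empty((x.shape[0], 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    k = Z.shape[1]
    mask = np.isfinite(x) & np.isfinite(y)
    if k:
        mask &= np.isfinite(Z).all(axis=1)
    n = int(mask.sum())
    if n < 4:
        raise ValueError(f"need at least 4 complete cases, got {n}")
    design = np.column_stack(
        [np.ones(n)] + [_rank(Z[mask, j]) for j in range(k)])
    # constant/collinear covariates do not consume degrees of freedom
    k = int(np.linalg.matrix_rank(design)) - 1
    if n < k + 4:
        raise ValueError(
            f"need at least k + 4 = {k + 4} complete cases, got {n}")
    rx, ry = _rank(x[mask]), _rank(y[mask])
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        logger.warning("zero variance after ranking; correlation undefined")
        return PartialCorrResult(np.nan, np.nan, n, n - 2 - k)
    ex = _residualize(rx, design)
    ey = _residualize(ry, design)
    denom = np.sqrt((ex @ ex) * (ey @ ey))
    if denom == 0:
        logger.warning("residual variance is zero; correlation undefined")
        return PartialCorrResult(np.nan, np.nan, n, n - 2 - k)
    r = float(np.clip((ex @ ey) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrResult(r, p, n, df)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("family of p-values is empty")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class VariableBlock:
    """One data block: subjects x named variables (+ block label)."""

    label: str                      # "metabolite" | "clinical" | "brain"
    data: pd.DataFrame              # indexed by subject_id

    def __post_init__(self) -> None:
        if self.label not in ("metabolite", "clinical", "brain"):
            raise ValueError(f"unknown block label {self.label!r}")

    def modality_of(self, var: str) -> str:
        if self.label != "brain":
            return ""
        if ":" in var:
            prefix = var.split(":", 1)[0]
            return {"func": "functional", "anat": "anatomical"}.get(
                prefix, prefix)
        return ""


def _family_id(key: str, block_a: str, block_b: str, modality: str) -> str:
    if key == "pooled":
        return "all"
    base = f"{block_a}~{block_b}"
    if key == "block_pair":
        return base
    return f"{base}~{modality}" if modality else base


def block_correlations(blocks: list[VariableBlock],
                       covariates: pd.DataFrame,
                       family_key: str = "block_pair_modality"
                       ) -> pd.DataFrame:
    """All cross-block partial Spearman tests, with BH q-values.

    Blocks must share a subject index with ``covariates`` (columns =
    covariate variables, e.g. age and sex).  Pairwise-complete case
    selection reproduces sample-size variation from missing scores or
    excluded scans.  Records whose correlation is undefined (zero rank
    variance) are flagged ``excluded`` and kept out of the FDR family.
    """
    if family_key not in FAMILY_KEYS:
        raise ValueError(f"family_key must be one of {FAMILY_KEYS}")
    if len(blocks) < 2:
        raise ValueError("need at least two blocks")
    index = blocks[0].data.index
    if len(index) == 0:
        raise ValueError("blocks share no subjects")
    for b in blocks[1:]:
        if not b.data.index.equals(index):
            raise ValueError("block subject indices are not aligned")
    if not covariates.index.equals(index):
        raise ValueError("covariate subject index is not aligned")
    Zfull = covariates.to_numpy(dtype=float)
    zvalid = np.isfinite(Zfull).all(axis=1)
    k = Zfull.shape[1]

    # residualized-rank cache keyed by (block, var, case mask)
    cache: dict[tuple, np.ndarray | None] = {}

    def resid(block: VariableBlock, var: str, mask: np.ndarray):
        key = (block.label, var, mask.tobytes())
        if key not in cache:
            vals = block.data[var].to_numpy(dtype=float)[mask]
            rv = _rank(vals)
            if np.ptp(rv) == 0:
                cache[key] = None
            else:
                design = np.column_stack(
                    [np.ones(mask.sum())] +
                    [_rank(Zfull[mask, j]) for j in range(k)])
                e = _residualize(rv, design)
                norm = np.sqrt(e @ e)
                cache[key] = None if norm == 0 else e / norm
        return cache[key]

    valid_cols = {
        (b.label, v): np.isfinite(b.data[v].to_numpy(dtype=float))
        for b in blocks for v in b.data.columns}

    rows = []
    for ia in range(len(blocks)):
        for ib in range(ia + 1, len(blocks)):
            A, B = blocks[ia], blocks[ib]
            for va in A.data.columns:
                for vb in B.data.columns:
                    mask = (valid_cols[(A.label, va)] &
                            valid_cols[(B.label, vb)] & zvalid)
                    n = int(mask.sum())
                    modality = A.modality_of(va) or B.modality_of(vb)
                    fam = _family_id(family_key, A.label, B.label, modality)
                    if n < k + 4:
                        rows.append({
                            "family": fam, "block_a": A.label,
                            "block_b": B.label, "variable_a": va,
                            "variable_b": vb, "modality": modality,
                            "r": np.nan, "p": np.nan, "n": n,
                            "df_test": n - 2 - k, "df_printed": n - 1,
                            "excluded": True})
                        logger.warning(
                            "pair (%s, %s) excluded: only %d complete "
                            "cases (need %d)", va, vb, n, k + 4)
                        continue
                    ea = resid(A, va, mask)
                    eb = resid(B, vb, mask)
                    if ea is None or eb is None:
                        r = p = np.nan
                        excluded = True
                        logger.warning(
                            "pair (%s, %s) excluded: zero rank variance",
                            va, vb)
                    else:
                        r = float(np.clip(ea @ eb, -1.0, 1.0))
                        df = n - 2 - k
                        if abs(r) == 1.0:
                            p = 0.0
                        else:
                            t = r * np.sqrt(df / (1.0 - r * r))
                            p = float(2.0 * stats.t.sf(abs(t), df))
                        excluded = False
                    rows.append({
                        "family": fam, "block_a": A.label,
                        "block_b": B.label, "variable_a": va,
                        "variable_b": vb, "modality": modality,
                        "r": r, "p": p, "n": n, "df_test": n - 2 - k,
                        "df_printed": n - 1, "excluded": excluded})
    records = pd.DataFrame(rows)
    records["q"] = np.nan
    ok = ~records["excluded"]
    for fam, grp in records[ok].groupby("family"):
        records.loc[grp.index, "q"] = bh_fdr(grp["p"].to_numpy())
    return records


def assemble_results_table(records: pd.DataFrame) -> pd.DataFrame:
    """Readable per-family results table.

    Sorted by (family, q, p), ties broken by |r| descending; variable
    names mapped to the conventional abbreviations; significance flags
    at q < 0.05 (primary) and p < 0.05 (secondary).
    """
    t = records.copy()
    if len(t) == 0:
        cols = list(records.columns) + ["sig_q05", "sig_p05"]
        return pd.DataFrame(columns=cols)
    for col in ("variable_a", "variable_b"):
        t[col] = t[col].map(lambda v: DISPLAY_NAMES.get(v, v))
    t["sig_q05"] = t["q"] < 0.05
    t["sig_p05"] = t["p"] < 0.05
    t["_absr"] = -t["r"].abs()
    t = t.sort_values(["family", "q", "p", "_absr"],
                      kind="mergesort").drop(columns="_absr")
    return t.reset_index(drop=True)


class CrossBlockSpearman(BaseEstimator):
    """Estimator form of the cross-block association screen.

    ``fit`` consumes the three blocks plus covariates and exposes
    ``records_`` (the association table with q-values) and
    ``results_table_``.
    """

    def __init__(self, family_key: str = "block_pair_modality"):
        self.family_key = family_key

    def fit(self, blocks: list[VariableBlock], covariates: pd.DataFrame):
        self.records_ = block_correlations(blocks, covariates,
                                           self.family_key)
        self.results_table_ = assemble_results_table(self.records_)
        return self
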