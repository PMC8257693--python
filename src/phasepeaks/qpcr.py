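"""ddCt qPCR quantification, ChIP-qPCR fold enrichment, and the DEG filter.

Relative expression uses the classical ddCt model with amplification
efficiency fixed at 2: fold = 2^-(dCt_sample - dCt_calibrator), where
dCt is the target-minus-reference cycle-threshold difference within a
condition. ChIP enrichment normalizes each immunoprecipitate to a
non-bound control locus (Sfi3 by default) and then to the empty-vector
IP. Differential expression keeps genes at BH q < 0.001 with at least a
twofold change in either direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

CT_COLUMNS = ("sample_id", "condition", "gene", "ct", "replicate")


class MissingCellError(KeyError):
    """A (condition, gene) mean Ct needed by a computation is absent."""


def load_ct_table(path) -> pd.DataFrame:
    """Read a long-format Ct table (CSV with condition, gene, ct columns)."""
    df = pd.read_csv(path)
    missing = {"condition", "gene", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if not np.isfinite(df["ct"]).all():
        raise ValueError("non-finite Ct values")
    return df


def _mean_ct(ct: pd.DataFrame, condition: str, gene: str) -> float:
    """Replicates are averaged on the Ct (cycle) scale before any delta."""
    rows = ct[(ct["condition"] == condition) & (ct["gene"] == gene)]
    if rows.empty:
        raise MissingCellError(f"no Ct values for condition={condition!r}, gene={gene!r}")
    return float(rows["ct"].mean())


def ddct_fold_change(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    sample_condition: str,
    calibrator_condition: str,
) -> float:
    """Linear fold change of target in sample vs calibrator, ddCt method."""
    dct_s = _mean_ct(ct, sample_condition, target_gene) - _mean_ct(
        ct, sample_condition, reference_gene
    )
    dct_c = _mean_ct(ct, calibrator_condition, target_gene) - _mean_ct(
        ct, calibrator_condition, reference_gene
    )
    return float(2.0 ** -(dct_s - dct_c))


def chip_fold_enrichment(
    ct: pd.DataFrame,
    target_locus: str,
    chip_condition: str,
    empty_vector_condition: str,
    normalizer_locus: str = "Sfi3",
) -> float:
    """ChIP-qPCR fold enrichment at a locus.

    Each IP's target Ct is first expressed relative to the normalizer
    locus (input-amount control), then the ChIP IP is expressed relative
    to the empty-vector IP (antibody background control).
    """
    rel = {}
    for cond in (chip_condition, empty_vector_condition):
        d = _mean_ct(ct, cond, target_locus) - _mean_ct(ct, cond, normalizer_locus)
        rel[cond] = 2.0 ** -d
    return float(rel[chip_condition] / rel[empty_vector_condition])


def load_expression_table(path) -> pd.DataFrame:
    """Read a gene/log2_fold_change/p_value table and attach BH q-values."""
    df = pd.read_csv(path)
    missing = {"gene", "log2_fold_change", "p_value"} - set(df.columns)
    if missing:
        raise ValueError(f"expression table lacks columns: {sorted(missing)}")
    return attach_qvalues(df)


def attach_qvalues(table: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg adjust p_value into a q column."""
    df = table.copy()
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene identifiers")
    p = df["p_value"].to_numpy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    df["q"] = multipletests(p, method="fdr_bh")[1]
    return df


def filter_degs(
    table: pd.DataFrame, q_max: float = 0.001, min_abs_log2fc: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split significant differentially expressed genes into (up, down) lists.

    Keeps genes with q < q_max and |log2FC| >= min_abs_log2fc (a twofold
    linear change by default, in either direction). Row order of the
    input does not affect membership.
    """
    df = table if "q" in table.columns else attach_qvalues(table)
    kept = df[(df["q"] < q_max) & (df["log2_fold_change"].abs() >= min_abs_log2fc)]
    up = kept[kept["log2_fold_change"] > 0].reset_index(drop=True)
    down = kept[kept["log2_fold_change"] < 0].reset_index(drop=True)
    return up, down
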