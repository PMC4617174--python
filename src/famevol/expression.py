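"""Relative qPCR quantification by the comparative Ct (2^-ddCt) method.

dCt = Ct_target - Ct_reference per sample; ddCt = mean dCt of the treated
sample minus mean dCt of the time-matched untreated control; relative
expression (fold change) = 2^-ddCt.  Replicates are averaged on the dCt
scale (cycle scale), where measurement error is approximately additive, and
dispersion is reported as the standard deviation of replicate-wise ddCt.
No amplification-efficiency correction is applied: the model assumes exact
doubling per cycle.

If a treatment lacks a time-matched control at some timepoint, the 0 h
sample of the same treatment is used as the calibrator instead (with a
logged warning); this reproduces the common "relative to time zero" design.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MissingReferenceError",
    "MissingControlError",
    "ddct_fold_change",
    "expression_profiles",
    "classify_response",
]

logger = logging.getLogger(__name__)

CT_COLUMNS = ("gene", "treatment", "timepoint_h", "replicate", "sample_class", "ct")


class MissingReferenceError(ValueError):
    """Reference-gene Ct missing for a sample where the target was measured."""


class MissingControlError(ValueError):
    """No untreated calibrator available for a (treatment, timepoint) cell."""


def _validate_ct_table(table: pd.DataFrame) -> None:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle numbers")
    bad = set(table["sample_class"]) - {"treated", "control"}
    if bad:
        raise ValueError(f"unknown sample_class value(s): {sorted(bad)}")


def _delta_ct(table: pd.DataFrame, gene: str, reference_gene: str) -> pd.DataFrame:
    """Per-sample dCt = Ct_gene - Ct_reference, joined on sample identity."""
    keys = ["treatment", "timepoint_h", "replicate", "sample_class"]
    tgt = table[table["gene"] == gene]
    ref = table[table["gene"] == reference_gene]
    if tgt.empty:
        raise ValueError(f"gene {gene!r} absent from Ct table")
    if ref.empty:
        raise MissingReferenceError(
            f"reference gene {reference_gene!r} absent from Ct table"
        )
    merged = tgt.merge(
        ref[keys + ["ct"]], on=keys, how="left", suffixes=("", "_ref")
    )
    if merged["ct_ref"].isna().any():
        cell = merged[merged["ct_ref"].isna()].iloc[0]
        raise MissingReferenceError(
            f"reference gene {reference_gene!r} not measured for sample "
            f"({cell['treatment']}, {cell['timepoint_h']} h, replicate "
            f"{cell['replicate']}, {cell['sample_class']})"
        )
    merged["dct"] = merged["ct"] - merged["ct_ref"]
    return merged[keys + ["dct"]]


def ddct_fold_change(
    table: pd.DataFrame,
    gene: str,
    reference_gene: str = "BcGAPDH",
    baseline_fallback: bool = True,
) -> pd.DataFrame:
    """Fold change 2^-ddCt per (treatment, timepoint) for one gene.

    Returns columns treatment, timepoint_h, ddct, fold_change, log2fc, sd,
    n_replicates.  ``sd`` is the standard deviation of replicate-wise ddCt
    (treated replicate paired with the control replicate of the same index
    when replicate sets match, otherwise against the control mean).
    """
    _validate_ct_table(table)
    dct = _delta_ct(table, gene, reference_gene)
    rows = []
    for (tr, tp), cell in dct.groupby(["treatment", "timepoint_h"], sort=True):
        treated = cell[cell["sample_class"] == "treated"]
        control = cell[cell["sample_class"] == "control"]
        if treated.empty:
            continue
        if control.empty:
            if not baseline_fallback:
                raise MissingControlError(
                    f"no control sample for ({tr}, {tp} h)"
                )
            base = dct[
                (dct["treatment"] == tr)
                & (dct["timepoint_h"] == dct["timepoint_h"].min())
                & (dct["sample_class"] == "treated")
            ]
            if base.empty:
                raise MissingControlError(
                    f"no control and no baseline sample for ({tr}, {tp} h)"
                )
            logger.warning(
                "no time-matched control for (%s, %s h); using the %s h "
                "sample as calibrator", tr, tp, dct["timepoint_h"].min(),
            )
            control = base
        t_mean = treated["dct"].mean()
        c_mean = control["dct"].mean()
        ddct = t_mean - c_mean
        t_sorted = treated.sort_values("replicate")["dct"].to_numpy()
        c_sorted = control.sort_values("replicate")["dct"].to_numpy()
        if len(t_sorted) == len(c_sorted):
            per_rep = t_sorted - c_sorted
        else:
            per_rep = t_sorted - c_mean
        sd = float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else 0.0
        rows.append(
            (tr, tp, ddct, 2.0 ** (-ddct), -ddct, sd, len(t_sorted))
        )
    return pd.DataFrame(
        rows,
        columns=[
            "treatment", "timepoint_h", "ddct", "fold_change",
            "log2fc", "sd", "n_replicates",
        ],
    )


def expression_profiles(
    table: pd.DataFrame,
    reference_gene: str = "BcGAPDH",
    genes: Sequence[str] | None = None,
    baseline_fallback: bool = True,
) -> pd.DataFrame:
    """Long-format fold-change profiles for all target genes in a Ct table."""
    _validate_ct_table(table)
    if genes is None:
        genes = [g for g in sorted(table["gene"].unique()) if g != reference_gene]
    frames = []
    for gene in genes:
        prof = ddct_fold_change(
            table, gene, reference_gene, baseline_fallback=baseline_fallback
        )
        prof.insert(0, "gene", gene)
        frames.append(prof)
    return pd.concat(frames, ignore_index=True)


def classify_response(
    profiles: pd.DataFrame,
    up_threshold: float = 2.0,
    down_threshold: float = 2.0,
) -> pd.DataFrame:
    """Label each gene x treatment trajectory induced/reduced/stable/mixed.

    A trajectory is induced if its maximum fold change reaches
    ``up_threshold``, reduced if its minimum reaches ``1/down_threshold``;
    if both, the larger |log2| deviation wins and an exact tie is "mixed".
    """
    if up_threshold < 1 or down_threshold < 1:
        raise ValueError("fold-change thresholds must be >= 1")
    if profiles.empty:
        raise ValueError("empty expression profile")
    rows = []
    for (gene, tr), cell in profiles.groupby(["gene", "treatment"], sort=True):
        fmax = cell["fold_change"].max()
        fmin = cell["fold_change"].min()
        induced = fmax >= up_threshold
        reduced = fmin <= 1.0 / down_threshold
        if induced and reduced:
            up_mag = abs(math.log2(fmax))
            down_mag = abs(math.log2(fmin))
            if math.isclose(up_mag, down_mag, rel_tol=1e-9, abs_tol=1e-12):
                label = "mixed"
            else:
                label = "induced" if up_mag > down_mag else "reduced"
        elif induced:
            label = "induced"
        elif reduced:
            label = "reduced"
        else:
            label = "stable"
        rows.append((gene, tr, label))
    return pd.DataFrame(rows, columns=["gene", "treatment", "label"])
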