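"""Association between microsatellite instability and methylation.

Among carcinoma samples with a known microsatellite status, each gene's %M
(and optionally a panel CMI) is compared between MSI and MSS tumors with the
two-sided Mann-Whitney test.  Raw p-values are the primary output, matching
common practice for this analysis; a Bonferroni-adjusted column is emitted
alongside as an extension so the multiplicity over genes stays visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CARCINOMA,
    MSI,
    MSS,
    MethylationMatrix,
    PanelDefinition,
    ValidationError,
    compute_cmi,
)
from .stats import mann_whitney

logger = logging.getLogger("methpanel")


@dataclass(frozen=True)
class MsiResult:
    gene: str
    n_msi: int
    n_mss: int
    median_msi: float
    median_mss: float
    direction: int  # sign of (MSI median - MSS median)
    p_value: float
    p_bonferroni: float | None = None  # extension, not part of the base analysis


def _msi_groups(matrix: MethylationMatrix) -> tuple[pd.Series, pd.Series]:
    if matrix.msi_labels is None:
        raise ValidationError("matrix carries no MSI labels")
    carcinoma = matrix.class_labels == CARCINOMA
    labels = matrix.msi_labels[carcinoma]
    known = labels.isin([MSI, MSS])
    n_excluded = int((~known).sum())
    if n_excluded:
        logger.info("excluding %d carcinoma samples with unknown MSI status",
                     n_excluded)
    msi_mask = carcinoma & (matrix.msi_labels == MSI)
    mss_mask = carcinoma & (matrix.msi_labels == MSS)
    if msi_mask.sum() < 2 or mss_mask.sum() < 2:
        raise ValidationError(
            f"need >= 2 samples per MSI group, got MSI={int(msi_mask.sum())}, "
            f"MSS={int(mss_mask.sum())}"
        )
    return msi_mask, mss_mask


def _one_test(scores: pd.Series, msi_mask, mss_mask, name: str,
              mw_mode: str) -> MsiResult:
    msi_vals = scores[msi_mask].to_numpy()
    mss_vals = scores[mss_mask].to_numpy()
    test = mann_whitney(msi_vals, mss_vals, mode=mw_mode)
    med_msi = float(np.median(msi_vals))
    med_mss = float(np.median(mss_vals))
    return MsiResult(
        gene=name,
        n_msi=msi_vals.size,
        n_mss=mss_vals.size,
        median_msi=med_msi,
        median_mss=med_mss,
        direction=int(np.sign(med_msi - med_mss)),
        p_value=test.p_value,
    )


def msi_differential(
    matrix: MethylationMatrix,
    genes: Sequence[str] | None = None,
    mw_mode: str = "normal_approx",
) -> list[MsiResult]:
    """Per-gene MSI-vs-MSS Mann-Whitney tests on carcinoma samples.

    Unknown-MSI samples are excluded internally (with a logged count), so
    results are identical whether or not the caller pre-filters them.
    """
    msi_mask, mss_mask = _msi_groups(matrix)
    genes = list(genes) if genes is not None else matrix.gene_ids
    results = [
        _one_test(matrix.values[g], msi_mask, mss_mask, g, mw_mode) for g in genes
    ]
    m = len(results)
    return [
        MsiResult(**{**r.__dict__, "p_bonferroni": min(1.0, r.p_value * m)})
        for r in results
    ]


def msi_cmi_test(
    matrix: MethylationMatrix,
    panel: PanelDefinition,
    mw_mode: str = "normal_approx",
) -> MsiResult:
    """MSI-vs-MSS Mann-Whitney test on the per-sample panel CMI."""
    msi_mask, mss_mask = _msi_groups(matrix)
    cmi = compute_cmi(matrix, panel)
    return _one_test(cmi, msi_mask, mss_mask, f"CMI[{panel.name}]", mw_mode)


def msi_table(results: Sequence[MsiResult]) -> pd.DataFrame:
    """Results as a tidy table (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "n_msi": r.n_msi,
                "n_mss": r.n_mss,
                "median_msi": r.median_msi,
                "median_mss": r.median_mss,
                "direction": r.direction,
                "p_raw": r.p_value,
                "p_bonferroni": r.p_bonferroni,
            }
            for r in results
        ]
    )
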