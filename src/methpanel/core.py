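"""Percent-methylation quantification and cumulative methylation index (CMI).

QM-MSP assigns each gene in each sample a percent methylation

    %M = 100 * (methylated copies) / (methylated + unmethylated copies)

and a panel of markers is scored per sample by the CMI, the sum of %M over
the panel's genes.  The :class:`MethylationMatrix` (samples x genes, %M in
[0, 100], with per-sample class labels) is the central container of the
package; everything downstream (marker selection, ROC evaluation, MSI
association) consumes it.

%M is stored as a percent in [0, 100].  Array-style beta values in [0, 1]
are a distinct type (:class:`methpanel.clustering.BetaMatrix`) to prevent
unit confusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("methpanel")

# Class labels ----------------------------------------------------------------

CARCINOMA = "carcinoma"
NORMAL = "normal"
CLASS_LABELS = (CARCINOMA, NORMAL)

MSI = "MSI"
MSS = "MSS"
MSI_UNKNOWN = "unknown"
MSI_LABELS = (MSI, MSS, MSI_UNKNOWN)


# Errors ----------------------------------------------------------------------


class MethPanelError(Exception):
    """Base class for all package errors."""


class ValidationError(MethPanelError):
    """Malformed or out-of-contract input data."""


class AssayDropoutError(ValidationError):
    """Zero total copies: %M is undefined, not zero.

    A sample/gene with no amplifiable copies signals assay dropout; recording
    it as 0 %M would silently convert a failed measurement into evidence of
    absent methylation.
    """


class MissingGeneError(ValidationError):
    """A panel gene is absent from the matrix."""


class MissingValueError(ValidationError):
    """A required %M value is missing (NaN); values are never imputed."""


class GuardError(MethPanelError):
    """Violation of the train-lock-test discipline (e.g. evaluate before lock)."""


# Copy counts -----------------------------------------------------------------


@dataclass(frozen=True)
class CopyCounts:
    """Methylated/unmethylated copy numbers for one gene in one sample."""

    gene: str
    methylated_copies: float
    unmethylated_copies: float

    def __post_init__(self) -> None:
        if self.methylated_copies < 0 or self.unmethylated_copies < 0:
            raise ValidationError(
                f"{self.gene}: copy counts must be non-negative, got "
                f"({self.methylated_copies}, {self.unmethylated_copies})"
            )


def percent_methylation(counts: CopyCounts) -> float:
    """%M = 100 * methylated / (methylated + unmethylated).

    Raises
    ------
    AssayDropoutError
        If both copy counts are zero (the ratio is undefined).
    """
    total = counts.methylated_copies + counts.unmethylated_copies
    if total <= 0:
        raise AssayDropoutError(
            f"{counts.gene}: zero total copies; %M is undefined (assay dropout)"
        )
    return 100.0 * counts.methylated_copies / total


# Panels ----------------------------------------------------------------------


@dataclass(frozen=True)
class PanelDefinition:
    """A named, ordered list of gene identifiers over which CMI is summed."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if not self.genes:
            raise ValidationError(f"panel {self.name!r}: empty gene list")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"panel {self.name!r}: duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in self.genes


#: 13 candidate markers carried from the array prescreen into the tissue assay.
TISSUE_13 = PanelDefinition(
    "tissue-13",
    (
        "ZNF671", "TWIST1", "TMEFF2", "TM6SF1", "GAS7", "MAL", "HIN1",
        "COL6A2", "AKR1B1", "GPX7", "ARHGEF7", "HIST1H3C", "APC",
    ),
)

#: Minimal tissue panel: top six of the ranked shortlist.
TISSUE_6 = PanelDefinition(
    "tissue-6", ("TMEFF2", "GPX7", "MAL", "ARHGEF7", "TWIST1", "AKR1B1")
)

#: Plasma (cell-free DNA) panel; TWIST1 excluded for assay reproducibility,
#: the three high-tissue-background genes retained (their plasma background
#: is negligible).
PLASMA_8 = PanelDefinition(
    "plasma-8",
    ("TMEFF2", "COL6A2", "ZNF671", "ARHGEF7", "TM6SF1", "MAL", "GPX7", "AKR1B1"),
)

#: Minimal plasma subset.
PLASMA_5 = PanelDefinition("plasma-5", ("TMEFF2", "ZNF671", "AKR1B1", "MAL", "COL6A2"))

PANELS: Mapping[str, PanelDefinition] = {
    p.name: p for p in (TISSUE_13, TISSUE_6, PLASMA_8, PLASMA_5)
}


# Methylation matrix ----------------------------------------------------------


@dataclass
class MethylationMatrix:
    """Samples x genes table of %M values with per-sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one float column per gene, %M in
        [0, 100].  NaN marks a missing measurement and is rejected by any
        computation that would need it (never imputed).
    class_labels
        Per-sample label, ``"carcinoma"`` or ``"normal"``.
    ages
        Optional per-sample age in years.
    msi_labels
        Optional per-sample microsatellite status, ``"MSI"``/``"MSS"``/
        ``"unknown"``.
    """

    values: pd.DataFrame
    class_labels: pd.Series
    ages: pd.Series | None = None
    msi_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if v.columns.has_duplicates:
            raise ValidationError("duplicate gene ids")
        v = v.astype(float)
        finite = v.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (finite < 0) | (finite > 100)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"%M out of [0, 100] at sample {v.index[i]!r}, gene "
                f"{v.columns[j]!r}: {finite[i, j]}"
            )
        v.index.name = "sample_id"
        v.columns.name = None
        self.values = v
        labels = self.class_labels.reindex(v.index)
        if labels.isna().any():
            missing = labels.index[labels.isna()][0]
            raise ValidationError(f"sample {missing!r} has no class label")
        unknown = set(labels.unique()) - set(CLASS_LABELS)
        if unknown:
            raise ValidationError(f"unknown class labels: {sorted(unknown)}")
        self.class_labels = labels
        if self.ages is not None:
            self.ages = self.ages.reindex(v.index).astype(float)
        if self.msi_labels is not None:
            msi = self.msi_labels.reindex(v.index).fillna(MSI_UNKNOWN)
            bad_msi = set(msi.unique()) - set(MSI_LABELS)
            if bad_msi:
                raise ValidationError(f"unknown MSI labels: {sorted(bad_msi)}")
            self.msi_labels = msi

    # -- basic accessors ------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def class_mask(self, label: str) -> pd.Series:
        return self.class_labels == label

    def gene_values(self, gene: str, class_label: str | None = None) -> np.ndarray:
        """%M values for one gene, optionally restricted to one class."""
        if gene not in self.values.columns:
            raise MissingGeneError(f"gene {gene!r} not in matrix")
        col = self.values[gene]
        if class_label is not None:
            col = col[self.class_mask(class_label)]
        return col.to_numpy()

    def select_samples(self, mask: Sequence[bool] | pd.Series) -> "MethylationMatrix":
        return MethylationMatrix(
            self.values.loc[mask],
            self.class_labels.loc[mask],
            None if self.ages is None else self.ages.loc[mask],
            None if self.msi_labels is None else self.msi_labels.loc[mask],
        )


def subset_panel(matrix: MethylationMatrix, panel: PanelDefinition) -> MethylationMatrix:
    """Restrict a matrix to a panel's genes (labels and sample order kept)."""
    missing = [g for g in panel if g not in matrix.values.columns]
    if missing:
        raise MissingGeneError(f"panel {panel.name!r}: genes not in matrix: {missing}")
    return MethylationMatrix(
        matrix.values[list(panel.genes)],
        matrix.class_labels,
        matrix.ages,
        matrix.msi_labels,
    )


def compute_cmi(matrix: MethylationMatrix, panel: PanelDefinition) -> pd.Series:
    """Per-sample cumulative methylation index: sum of %M over panel genes.

    Returns a float Series indexed by sample id, in CMI units
    (0 <= CMI <= 100 * |panel|).  Missing measurements raise
    :class:`MissingValueError` rather than being imputed.
    """
    sub = subset_panel(matrix, panel).values
    na = sub.isna()
    if na.to_numpy().any():
        i, j = np.argwhere(na.to_numpy())[0]
        sample, gene = sub.index[i], sub.columns[j]
        raise MissingValueError(
            f"missing %M for sample {sample!r}, gene {gene!r}; "
            "drop the sample or supply the measurement"
        )
    return sub.sum(axis=1)
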