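"""Packaged reference summaries for the 13 tissue candidate markers.

The package ships the published per-gene five-number summaries (%M) for a
colon tissue training cohort (30 carcinomas, 23 adjacent normals) together
with the per-gene two-sided Mann-Whitney p-values.  These summaries are the
worked example for the marker-selection procedure and parameterize the
synthetic tissue cohort generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .core import CARCINOMA, NORMAL
from .stats import FiveNumberSummary

_DATA_PACKAGE = "methpanel.data"
_REFERENCE_FILE = "colon_tissue_reference.yaml"


@dataclass(frozen=True)
class ReferenceMarker:
    """One gene's reference summaries and carcinoma-vs-normal p-value."""

    gene: str
    carcinoma: FiveNumberSummary
    normal: FiveNumberSummary
    p_value: float
    p_censored: bool  # True when only an upper bound on p is published
    parse_ambiguous: bool = False


def load_reference_markers() -> dict[str, ReferenceMarker]:
    """Load the packaged tissue reference, keyed by gene id (insertion order)."""
    text = (
        resources.files(_DATA_PACKAGE).joinpath(_REFERENCE_FILE).read_text("utf-8")
    )
    raw = yaml.safe_load(text)
    markers: dict[str, ReferenceMarker] = {}
    for gene, entry in raw["genes"].items():
        markers[gene] = ReferenceMarker(
            gene=gene,
            carcinoma=FiveNumberSummary(
                **{k: float(v) for k, v in entry["carcinoma"].items()},
                gene=gene, class_label=CARCINOMA,
            ),
            normal=FiveNumberSummary(
                **{k: float(v) for k, v in entry["normal"].items()},
                gene=gene, class_label=NORMAL,
            ),
            p_value=float(entry["p_value"]),
            p_censored=bool(entry.get("p_censored", False)),
            parse_ambiguous=bool(entry.get("parse_ambiguous", False)),
        )
    return markers


def reference_cohort_sizes() -> tuple[int, int]:
    """(n_carcinoma, n_normal) of the reference training cohort."""
    text = (
        resources.files(_DATA_PACKAGE).joinpath(_REFERENCE_FILE).read_text("utf-8")
    )
    raw = yaml.safe_load(text)
    return int(raw["cohort"]["n_carcinoma"]), int(raw["cohort"]["n_normal"])
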