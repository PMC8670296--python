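"""Three-stage minimal-panel marker selection.

Candidate markers are reduced to a minimal panel in three fixed stages:

1. **Significance** — keep genes whose %M is significantly *higher* in
   carcinoma than normal tissue (two-sided Mann-Whitney p < alpha, and
   carcinoma median >= normal median so a significant shift in the wrong
   direction never qualifies).
2. **Background** — discard genes whose *normal*-class 75th percentile is at
   or above the background cutoff (default 10 %M, inclusive): high baseline
   methylation in normal tissue risks false positives.
3. **Rank** — sort survivors by descending carcinoma-class 75th percentile
   and keep the top k (default 6).

Stage order and the inclusive background boundary are fixed; a gene with a
normal q75 of exactly 10 %M is eliminated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import CARCINOMA, NORMAL, MethylationMatrix, PanelDefinition, ValidationError
from .reference import ReferenceMarker
from .stats import (
    DEFAULT_PERCENTILE_METHOD,
    FiveNumberSummary,
    five_number_summary,
    mann_whitney,
)

logger = logging.getLogger("methpanel")


@dataclass(frozen=True)
class SelectionCriteria:
    """Tunable knobs of the selection procedure (defaults as used in tissue)."""

    alpha: float = 0.05
    background_cutoff: float = 10.0  # normal q75 >= cutoff eliminates (inclusive)
    top_k: int = 6
    percentile_method: str = DEFAULT_PERCENTILE_METHOD
    mw_mode: str = "auto"
    panel_name: str = "selected-panel"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.background_cutoff < 0:
            raise ValidationError("background_cutoff must be >= 0")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")


@dataclass(frozen=True)
class MarkerSummary:
    """Per-gene class summaries plus the carcinoma-vs-normal p-value."""

    gene: str
    carcinoma: FiveNumberSummary
    normal: FiveNumberSummary
    p_value: float


@dataclass(frozen=True)
class SelectionResult:
    discarded_nonsignificant: tuple[str, ...]
    discarded_background: tuple[str, ...]
    shortlist_ranked: tuple[str, ...]
    panel: PanelDefinition
    audit: dict[str, str] = field(default_factory=dict)


def marker_summary_from_reference(ref: ReferenceMarker) -> MarkerSummary:
    """Adapt a packaged reference entry for direct injection into selection."""
    return MarkerSummary(ref.gene, ref.carcinoma, ref.normal, ref.p_value)


def summarize_markers(
    matrix: MethylationMatrix,
    criteria: SelectionCriteria = SelectionCriteria(),
) -> list[MarkerSummary]:
    """One MarkerSummary per gene of the matrix (both classes required)."""
    classes = set(matrix.class_labels.unique())
    if classes != {CARCINOMA, NORMAL}:
        raise ValidationError(
            f"summarize_markers needs both classes present, got {sorted(classes)}"
        )
    out = []
    for gene in matrix.gene_ids:
        ca = matrix.gene_values(gene, CARCINOMA)
        no = matrix.gene_values(gene, NORMAL)
        test = mann_whitney(ca, no, mode=criteria.mw_mode)
        out.append(
            MarkerSummary(
                gene=gene,
                carcinoma=five_number_summary(
                    ca, criteria.percentile_method, gene=gene, class_label=CARCINOMA
                ),
                normal=five_number_summary(
                    no, criteria.percentile_method, gene=gene, class_label=NORMAL
                ),
                p_value=test.p_value,
            )
        )
    return out


def filter_significant(
    summaries: list[MarkerSummary],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> tuple[list[MarkerSummary], list[MarkerSummary]]:
    """Stage 1: keep genes significantly *more* methylated in carcinoma."""
    kept, discarded = [], []
    for s in summaries:
        if s.p_value < criteria.alpha and s.carcinoma.median >= s.normal.median:
            kept.append(s)
        else:
            discarded.append(s)
    return kept, discarded


def filter_background(
    summaries: list[MarkerSummary],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> tuple[list[MarkerSummary], list[MarkerSummary]]:
    """Stage 2: discard genes with normal-class q75 >= cutoff (inclusive)."""
    kept, discarded = [], []
    for s in summaries:
        if s.normal.q75 >= criteria.background_cutoff:
            discarded.append(s)
        else:
            kept.append(s)
    return kept, discarded


def _rank_key(s: MarkerSummary) -> tuple[float, float, str]:
    # descending carcinoma q75, then descending carcinoma median, then gene id
    return (-s.carcinoma.q75, -s.carcinoma.median, s.gene)


def rank_and_select(
    kept: list[MarkerSummary],
    criteria: SelectionCriteria = SelectionCriteria(),
    discarded_nonsignificant: list[MarkerSummary] | None = None,
    discarded_background: list[MarkerSummary] | None = None,
) -> SelectionResult:
    """Stage 3: rank survivors on carcinoma q75 and take the top k."""
    if not kept:
        raise ValidationError("rank_and_select: no markers survived filtering")
    ranked = sorted(kept, key=_rank_key)
    # log rank-statistic ties (resolved by median, then lexical gene id)
    by_q75: dict[float, list[str]] = {}
    for s in ranked:
        by_q75.setdefault(s.carcinoma.q75, []).append(s.gene)
    audit: dict[str, str] = {}
    for q75, genes in by_q75.items():
        if len(genes) > 1:
            logger.info(
                "rank tie at carcinoma q75=%s among %s; broken by median then "
                "gene id", q75, genes,
            )
            for g in genes:
                audit[g] = f"rank tie at carcinoma q75={q75}"
    for s in discarded_nonsignificant or []:
        audit[s.gene] = (
            f"discarded: not significantly higher in carcinoma (p={s.p_value:.4g}, "
            f"carcinoma median {s.carcinoma.median}, normal median {s.normal.median})"
        )
    for s in discarded_background or []:
        audit[s.gene] = (
            f"discarded: normal-tissue background q75={s.normal.q75} >= "
            f"{criteria.background_cutoff} %M"
        )
    shortlist = tuple(s.gene for s in ranked)
    panel_genes = shortlist[: criteria.top_k]
    for i, g in enumerate(shortlist):
        note = f"shortlist rank {i + 1}"
        if i < criteria.top_k:
            note += "; selected for panel"
        audit[g] = (audit.get(g, "") + "; " + note).lstrip("; ")
    return SelectionResult(
        discarded_nonsignificant=tuple(
            s.gene for s in (discarded_nonsignificant or [])
        ),
        discarded_background=tuple(s.gene for s in (discarded_background or [])),
        shortlist_ranked=shortlist,
        panel=PanelDefinition(criteria.panel_name, panel_genes),
        audit=audit,
    )


def select_from_summaries(
    summaries: list[MarkerSummary],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> SelectionResult:
    """Run stages 1-3 on pre-computed summaries (the worked-example entry point)."""
    sig, non_sig = filter_significant(summaries, criteria)
    low_bg, high_bg = filter_background(sig, criteria)
    return rank_and_select(low_bg, criteria, non_sig, high_bg)


def select_panel(
    matrix: MethylationMatrix,
    criteria: SelectionCriteria = SelectionCriteria(),
) -> SelectionResult:
    """Full procedure from a raw %M matrix: summarize, filter, filter, rank."""
    return select_from_summaries(summarize_markers(matrix, criteria), criteria)
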