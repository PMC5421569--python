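"""Panel-level summary statistics, tissue specificity and threshold sweeps.

Given a :class:`~mixcall.calling.CallSet`, this module computes:

- panel-wide counts/percentages (genes expressed anywhere, samples
  expressing any / exactly one panel gene, effector co-expression);
- per-gene tissue specificity as a 2×2 contingency of positive calls
  against a focal tissue label, tested with the two-tailed Fisher exact
  test (minimum-likelihood two-sided convention);
- the threshold-sweep robustness curve: positive-sample counts in the
  focal and non-focal tissues across a ladder of posterior cutoffs,
  re-thresholding cached posteriors so the curve is exactly consistent
  with single-threshold calls.

Percentages are reported at full precision alongside a formatted string
rounded half-away-from-zero to one decimal (zero decimals available where
integer percentages are conventional).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

from .calling import CallSet, ExpressionCaller
from .io import ExpressionMatrix
from .mixture import EMConfig

__all__ = [
    "DEFAULT_THRESHOLDS",
    "PanelSummary",
    "SpecificityResult",
    "SweepCurve",
    "FisherResult",
    "percentage",
    "round_half_away",
    "format_percentage",
    "fisher_exact_two_tailed",
    "summarize_panel",
    "tissue_specificity",
    "panel_specificity",
    "threshold_sweep",
    "sweep_from_callset",
]

logger = logging.getLogger(__name__)

#: Posterior-probability ladder for the robustness sweep.
DEFAULT_THRESHOLDS = (0.125, 0.25, 0.5, 0.75, 0.90, 0.95, 0.99)


def percentage(numerator: float, denominator: float) -> float:
    """``100 · numerator / denominator`` at full precision (NaN if the
    denominator is zero)."""
    if denominator == 0:
        return float("nan")
    return 100.0 * numerator / denominator


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero at the given number of decimals.

    Operates on the shortest decimal representation of ``x`` (``repr``),
    so 15.384615… → 15.4 and 2.9535… → 3.0 at the respective precisions.
    """
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percentage(numerator: float, denominator: float, decimals: int = 1) -> str:
    """Percentage formatted under the documented rounding convention."""
    pct = percentage(numerator, denominator)
    if not math.isfinite(pct):
        return "undefined"
    return f"{round_half_away(pct, decimals):.{decimals}f}"


class FisherResult(NamedTuple):
    p_two_tailed: float
    odds_ratio: float


def fisher_exact_two_tailed(table) -> FisherResult:
    """Two-tailed Fisher exact test on a 2×2 table of nonnegative integers.

    The two-sided p-value follows the minimum-likelihood convention: the
    sum, over all tables with the observed margins, of hypergeometric
    probabilities no greater than that of the observed table (tables tied
    at exact equality are included). The odds ratio is ``(a·d)/(b·c)``,
    ``inf`` when ``b·c = 0`` and ``a·d > 0``, NaN when both products are 0.
    A zero row or column margin yields ``p = 1`` by convention (logged).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be integers")
        t = np.round(t).astype(np.int64)
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    if t.sum() == 0:
        raise ValueError("table grand total must be positive")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if a * d > 0 and b * c == 0:
        odds = math.inf
    elif b * c == 0:
        odds = math.nan
    else:
        odds = (a * d) / (b * c)
    if 0 in (a + b, c + d, a + c, b + d):
        logger.info("zero margin in 2x2 table %s; p = 1 by convention", t.tolist())
        return FisherResult(1.0, odds)
    p = float(_scipy_fisher(t).pvalue)
    return FisherResult(min(p, 1.0), odds)


@dataclasses.dataclass
class PanelSummary:
    """Panel-wide counts with full-precision and formatted percentages.

    Percentages conditional on expressing samples (``pct_exactly_one``,
    ``effector_coexpression_pct``) are NaN — formatted "undefined" — when
    no sample expresses any panel gene.
    """

    n_panel_genes_tested: int
    n_genes_expressed_anywhere: int
    n_samples_total: int
    n_samples_expressing_any: int
    n_samples_expressing_exactly_one: int
    n_expressing_with_effector: int
    n_no_call_samples: int
    threshold_used: float

    @property
    def pct_genes_expressed_anywhere(self) -> float:
        return percentage(self.n_genes_expressed_anywhere, self.n_panel_genes_tested)

    @property
    def pct_samples_expressing_any(self) -> float:
        return percentage(self.n_samples_expressing_any, self.n_samples_total)

    @property
    def pct_exactly_one_of_expressing(self) -> float:
        return percentage(
            self.n_samples_expressing_exactly_one, self.n_samples_expressing_any
        )

    @property
    def effector_coexpression_pct(self) -> float:
        return percentage(
            self.n_expressing_with_effector, self.n_samples_expressing_any
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.update(
            pct_genes_expressed_anywhere=self.pct_genes_expressed_anywhere,
            pct_samples_expressing_any=self.pct_samples_expressing_any,
            pct_exactly_one_of_expressing=self.pct_exactly_one_of_expressing,
            effector_coexpression_pct=self.effector_coexpression_pct,
            fmt_genes_expressed_anywhere=format_percentage(
                self.n_genes_expressed_anywhere, self.n_panel_genes_tested
            ),
            fmt_samples_expressing_any=format_percentage(
                self.n_samples_expressing_any, self.n_samples_total
            ),
            fmt_exactly_one_of_expressing=format_percentage(
                self.n_samples_expressing_exactly_one, self.n_samples_expressing_any
            ),
            fmt_effector_coexpression=format_percentage(
                self.n_expressing_with_effector, self.n_samples_expressing_any, 2
            ),
        )
        return d


def summarize_panel(calls: CallSet) -> PanelSummary:
    """Panel-wide summary of a CallSet.

    Counts: panel genes expressed in at least one sample; samples
    expressing at least one / exactly one panel gene; and, among
    panel-expressing samples, those with at least one effector gene also
    called expressed. No-call samples are excluded from every denominator.
    """
    expressed = calls.expressed
    per_sample = expressed.sum(axis=0)
    expressing = per_sample > 0
    with_effector = expressing & calls.effector_expressed
    return PanelSummary(
        n_panel_genes_tested=int(expressed.shape[0]),
        n_genes_expressed_anywhere=int((expressed.sum(axis=1) > 0).sum()),
        n_samples_total=int(expressed.shape[1]),
        n_samples_expressing_any=int(expressing.sum()),
        n_samples_expressing_exactly_one=int((per_sample == 1).sum()),
        n_expressing_with_effector=int(with_effector.sum()),
        n_no_call_samples=len(calls.no_call_samples),
        threshold_used=calls.threshold_used,
    )


@dataclasses.dataclass
class SpecificityResult:
    """Tissue specificity of one gene's positive calls.

    ``table`` rows are (focal, other) tissues, columns (positive,
    negative) calls; no-call samples are excluded before tabulation.
    """

    gene: str
    focal_tissue: str
    table: np.ndarray
    p_two_tailed: float
    odds_ratio: float

    @property
    def positives_in_focal(self) -> int:
        return int(self.table[0, 0])

    @property
    def positives_elsewhere(self) -> int:
        return int(self.table[1, 0])

    @property
    def n_focal(self) -> int:
        return int(self.table[0].sum())

    @property
    def n_other(self) -> int:
        return int(self.table[1].sum())

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "focal_tissue": self.focal_tissue,
            "focal_positive": self.positives_in_focal,
            "focal_negative": int(self.table[0, 1]),
            "other_positive": self.positives_elsewhere,
            "other_negative": int(self.table[1, 1]),
            "odds_ratio": self.odds_ratio,
            "p_two_tailed": self.p_two_tailed,
        }


def tissue_specificity(calls: CallSet, gene: str, focal_tissue: str) -> SpecificityResult:
    """2×2 Fisher test of one gene's calls against a focal tissue label."""
    if gene not in calls.panel_genes:
        raise KeyError(f"gene {gene!r} not in call set")
    labels = calls.tissue_labels
    if focal_tissue not in set(labels):
        raise KeyError(f"tissue {focal_tissue!r} not among sample labels")
    positive = calls.expressed.loc[gene]
    focal = labels == focal_tissue
    table = np.array(
        [
            [int((positive & focal).sum()), int((~positive & focal).sum())],
            [int((positive & ~focal).sum()), int((~positive & ~focal).sum())],
        ]
    )
    p, odds = fisher_exact_two_tailed(table)
    return SpecificityResult(
        gene=gene,
        focal_tissue=focal_tissue,
        table=table,
        p_two_tailed=p,
        odds_ratio=odds,
    )


def panel_specificity(
    calls: CallSet, focal_tissue: str, bonferroni: bool = False
) -> pd.DataFrame:
    """Per-gene specificity table for the whole panel (raw p-values;
    an optional Bonferroni-adjusted column can be added, off by default
    to mirror uncorrected single-gene reporting)."""
    rows = [
        tissue_specificity(calls, g, focal_tissue).to_dict()
        for g in calls.panel_genes
    ]
    df = pd.DataFrame(rows)
    if bonferroni and len(df):
        df["p_bonferroni"] = np.minimum(df["p_two_tailed"] * len(df), 1.0)
    return df


@dataclasses.dataclass
class SweepCurve:
    """Positive-sample counts for one gene across a threshold ladder."""

    gene: str
    focal_tissue: str
    thresholds: tuple[float, ...]
    focal_counts: np.ndarray
    other_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "focal_count": self.focal_counts,
                "other_count": self.other_counts,
            }
        )


def _validate_thresholds(thresholds: Sequence[float]) -> tuple[float, ...]:
    ts = tuple(float(t) for t in thresholds)
    if not ts:
        raise ValueError("thresholds must be non-empty")
    if any(not 0.0 < t < 1.0 for t in ts):
        raise ValueError(f"thresholds must lie in (0, 1), got {ts}")
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError(f"thresholds must be strictly increasing, got {ts}")
    return ts


def sweep_from_callset(
    calls: CallSet,
    gene: str,
    focal_tissue: str,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> SweepCurve:
    """Re-threshold cached posteriors across the ladder (no refitting)."""
    ts = _validate_thresholds(thresholds)
    focal_counts = []
    other_counts = []
    for t in ts:
        res = tissue_specificity(calls.at_threshold(t), gene, focal_tissue)
        focal_counts.append(res.positives_in_focal)
        other_counts.append(res.positives_elsewhere)
    return SweepCurve(
        gene=gene,
        focal_tissue=focal_tissue,
        thresholds=ts,
        focal_counts=np.asarray(focal_counts),
        other_counts=np.asarray(other_counts),
    )


def threshold_sweep(
    matrix: ExpressionMatrix,
    panel: Sequence[str],
    effectors: Sequence[str],
    gene: str,
    focal_tissue: str,
    em: EMConfig | None = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> SweepCurve:
    """Fit once per sample, then count focal/non-focal positive samples for
    one gene at each threshold of the ladder."""
    ts = _validate_thresholds(thresholds)
    em = em or EMConfig()
    caller = ExpressionCaller(
        tol=em.tol,
        max_iter=em.max_iter,
        n_restarts=em.n_restarts,
        var_floor=em.var_floor,
        init_method=em.init_method,
        random_state=em.seed,
    )
    calls = caller.fit_call(matrix, panel, effectors)
    return sweep_from_callset(calls, gene, focal_tissue, ts)
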