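"""Binary expressed/not-expressed calls for panel genes.

One two-component mixture is fitted per sample over the whole
transcriptome; panel-gene posteriors of the high component are then
thresholded (default: posterior > 0.95) into presence/absence calls. Also
provides the ln(RSEM+1)+1 preprocessing transform for RNA-seq abundance
matrices and a diagnostic expression histogram.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import ExpressionMatrix, read_annotation, write_annotation
from .mixture import EMConfig, MixtureFit, fit_two_component_mixture, posterior_high_at

__all__ = [
    "CallConfig",
    "CallSet",
    "ExpressionCaller",
    "call_expression",
    "transform_rsem",
    "bin_histogram",
    "save_callset",
    "load_callset",
]

logger = logging.getLogger(__name__)


def transform_rsem(raw):
    """Map nonnegative RSEM abundance to the log scale used for fitting:
    ``ln(raw + 1) + 1``, elementwise.

    Raises ``ValueError`` on any negative input.
    """
    if isinstance(raw, pd.DataFrame):
        if (raw.to_numpy() < 0).any():
            raise ValueError("RSEM values must be nonnegative")
        return np.log(raw + 1.0) + 1.0
    arr = np.asarray(raw, dtype=float)
    if (arr < 0).any():
        raise ValueError("RSEM values must be nonnegative")
    out = np.log(arr + 1.0) + 1.0
    if np.isscalar(raw) or arr.ndim == 0:
        return float(out)
    return out


def bin_histogram(values, bin_width: float) -> pd.Series:
    """Bin counts of expression values over half-open bins
    ``[k·w, (k+1)·w)``.

    Diagnostic only (for eyeballing bimodality); the mixture fit always
    operates on the raw values. Non-finite values are ignored; the counts
    sum to the number of finite values. Empty input yields an empty series.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return pd.Series(dtype=int, name="count")
    k = np.floor(arr / bin_width).astype(int)
    counts = pd.Series(k).value_counts().sort_index()
    index = pd.IntervalIndex.from_arrays(
        counts.index * bin_width, (counts.index + 1) * bin_width, closed="left"
    )
    return pd.Series(counts.to_numpy(), index=index, name="count")


@dataclasses.dataclass(frozen=True)
class CallConfig:
    """Probability threshold for presence calls.

    ``strict=True`` calls a gene expressed iff its posterior is strictly
    greater than the threshold; ``strict=False`` uses >=. The two differ
    only on exact ties but must be deterministic.
    """

    threshold: float = 0.95
    strict: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")


@dataclasses.dataclass
class CallSet:
    """Presence/absence calls for panel genes across samples at one threshold.

    Samples whose mixture fit was degenerate ("no-call") are excluded from
    all matrices and listed in ``no_call_samples``; they never enter
    downstream denominators. ``expressed[g, s] ⇔ posterior[g, s] > threshold``
    (``>=`` under non-strict mode).
    """

    posterior: pd.DataFrame  # panel genes x called samples
    effector_posterior: pd.DataFrame  # effector genes x called samples
    tissue_labels: pd.Series  # per called sample
    threshold_used: float
    strict: bool = True
    skipped_genes: tuple[str, ...] = ()
    no_call_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.posterior.columns.equals(self.effector_posterior.columns):
            raise ValueError("panel and effector posterior sample sets differ")
        self.tissue_labels = self.tissue_labels.reindex(self.posterior.columns)

    @property
    def samples(self) -> pd.Index:
        return self.posterior.columns

    @property
    def panel_genes(self) -> pd.Index:
        return self.posterior.index

    def _threshold(self, post: pd.DataFrame) -> pd.DataFrame:
        if self.strict:
            return post > self.threshold_used
        return post >= self.threshold_used

    @property
    def expressed(self) -> pd.DataFrame:
        """Boolean panel genes × samples call matrix."""
        return self._threshold(self.posterior)

    @property
    def effector_expressed_matrix(self) -> pd.DataFrame:
        return self._threshold(self.effector_posterior)

    @property
    def effector_expressed(self) -> pd.Series:
        """Per-sample: at least one effector gene called expressed."""
        return self.effector_expressed_matrix.any(axis=0)

    def at_threshold(self, threshold: float, strict: bool | None = None) -> "CallSet":
        """Re-threshold the cached posteriors without refitting."""
        CallConfig(threshold=threshold)  # validate
        return dataclasses.replace(
            self,
            threshold_used=threshold,
            strict=self.strict if strict is None else strict,
        )


class ExpressionCaller(BaseEstimator):
    """Per-sample mixture fitting over a gene × sample matrix, sklearn-style.

    ``fit`` takes an :class:`~mixcall.io.ExpressionMatrix` (or a plain
    genes × samples DataFrame) and fits one two-component Gaussian mixture
    per sample column over all genes; ``call`` extracts panel/effector
    posteriors and thresholds them into a :class:`CallSet`. Per-sample EM
    restart seeds are spawned deterministically from ``random_state``.

    Parameters
    ----------
    threshold, strict
        Default calling rule (see :class:`CallConfig`).
    tol, max_iter, n_restarts, var_floor, init_method
        EM settings (see :class:`~mixcall.mixture.EMConfig`).
    exclude_genes
        Optional gene IDs withheld from the fit (the calls for them are
        still computed from their posteriors under the fitted mixture).
        Off by default: the decomposition uses all detected genes,
        panel included.
    random_state
        Global seed.

    Attributes
    ----------
    fits_ : dict[str, MixtureFit]
        Per-sample fit (all fitted samples, including degenerate ones).
    posterior_ : DataFrame
        All-gene × sample posterior of the high component.
    fit_summary_ : DataFrame
        One row per sample: weights, means, SDs, n_iter, converged,
        degenerate_flag.
    no_call_samples_ : tuple[str, ...]
        Samples with a degenerate fit, excluded from call sets.
    tissue_labels_ : Series
    """

    def __init__(
        self,
        threshold: float = 0.95,
        strict: bool = True,
        tol: float = 1e-8,
        max_iter: int = 1000,
        n_restarts: int = 3,
        var_floor: float = 1e-6,
        init_method: str = "quantile_split",
        exclude_genes: Sequence[str] | None = None,
        random_state: int = 0,
    ):
        self.threshold = threshold
        self.strict = strict
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.var_floor = var_floor
        self.init_method = init_method
        self.exclude_genes = exclude_genes
        self.random_state = random_state

    def fit(self, X: ExpressionMatrix | pd.DataFrame, y=None):
        if isinstance(X, ExpressionMatrix):
            matrix = X
        else:
            matrix = ExpressionMatrix(values=pd.DataFrame(X))
        CallConfig(threshold=self.threshold, strict=self.strict)  # validate early
        values = matrix.values
        fit_genes = values.index
        if self.exclude_genes:
            fit_genes = fit_genes.difference(self.exclude_genes, sort=False)
        seeds = np.random.SeedSequence(self.random_state).generate_state(
            matrix.n_samples
        )
        fits: dict[str, MixtureFit] = {}
        posteriors = np.empty((matrix.n_genes, matrix.n_samples))
        for j, sample in enumerate(values.columns):
            cfg = EMConfig(
                tol=self.tol,
                max_iter=self.max_iter,
                n_restarts=self.n_restarts,
                var_floor=self.var_floor,
                init_method=self.init_method,
                seed=int(seeds[j] & 0x7FFFFFFF),
            )
            col = values[sample].to_numpy()
            fit = fit_two_component_mixture(col[values.index.isin(fit_genes)], cfg)
            fits[sample] = fit
            if self.exclude_genes:
                posteriors[:, j] = posterior_high_at(col, fit)
            else:
                posteriors[:, j] = fit.posterior_high
        self.fits_ = fits
        self.posterior_ = pd.DataFrame(
            posteriors, index=values.index, columns=values.columns
        )
        self.fit_summary_ = pd.DataFrame(
            {s: f.summary_row() for s, f in fits.items()}
        ).T.rename_axis("sample_id")
        self.no_call_samples_ = tuple(
            s for s, f in fits.items() if f.degenerate_flag
        )
        if self.no_call_samples_:
            logger.info(
                "%d samples had degenerate fits (no-call)", len(self.no_call_samples_)
            )
        self.tissue_labels_ = matrix.tissue_labels
        return self

    def call(
        self,
        panel: Sequence[str],
        effectors: Sequence[str] = (),
        threshold: float | None = None,
        strict: bool | None = None,
    ) -> CallSet:
        """Threshold fitted posteriors for the given panel into a CallSet.

        Panel/effector genes absent from the fitted matrix are skipped with
        a logged count and reported in ``CallSet.skipped_genes``.
        """
        if not hasattr(self, "posterior_"):
            raise AttributeError(
                "This ExpressionCaller instance is not fitted yet; call 'fit' first."
            )
        threshold = self.threshold if threshold is None else threshold
        strict = self.strict if strict is None else strict
        CallConfig(threshold=threshold, strict=strict)
        present = self.posterior_.index
        skipped = tuple(
            g for g in list(panel) + list(effectors) if g not in present
        )
        if skipped:
            logger.info("%d panel/effector genes absent from matrix: %s",
                        len(skipped), ", ".join(skipped))
        panel_kept = [g for g in panel if g in present]
        eff_kept = [g for g in effectors if g in present]
        called = self.posterior_.columns.difference(
            self.no_call_samples_, sort=False
        )
        return CallSet(
            posterior=self.posterior_.loc[panel_kept, called],
            effector_posterior=self.posterior_.loc[eff_kept, called],
            tissue_labels=self.tissue_labels_.loc[called],
            threshold_used=threshold,
            strict=strict,
            skipped_genes=skipped,
            no_call_samples=self.no_call_samples_,
        )

    def fit_call(
        self,
        X: ExpressionMatrix | pd.DataFrame,
        panel: Sequence[str],
        effectors: Sequence[str] = (),
    ) -> CallSet:
        return self.fit(X).call(panel, effectors)


def call_expression(
    matrix: ExpressionMatrix,
    panel: Sequence[str],
    effectors: Sequence[str] = (),
    em: EMConfig | None = None,
    call: CallConfig | None = None,
) -> CallSet:
    """One mixture fit per sample, then presence calls for a gene panel.

    Functional wrapper over :class:`ExpressionCaller`.
    """
    em = em or EMConfig()
    call = call or CallConfig()
    caller = ExpressionCaller(
        threshold=call.threshold,
        strict=call.strict,
        tol=em.tol,
        max_iter=em.max_iter,
        n_restarts=em.n_restarts,
        var_floor=em.var_floor,
        init_method=em.init_method,
        random_state=em.seed,
    )
    return caller.fit_call(matrix, panel, effectors)


# ---------------------------------------------------------------------------
# CallSet (de)serialisation — TSV/JSON file set under one directory


def save_callset(calls: CallSet, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "posteriors": out / "posteriors.tsv",
        "calls": out / "calls.tsv",
        "effector_posteriors": out / "effector_posteriors.tsv",
        "effector_calls": out / "effector_calls.tsv",
        "annotation": out / "annotation.tsv",
        "meta": out / "callset_meta.json",
    }
    fmt = "%.10g"  # posteriors near 1 need more digits than expression values
    calls.posterior.to_csv(paths["posteriors"], sep="\t", index_label="gene_id",
                           float_format=fmt)
    calls.expressed.astype(int).to_csv(paths["calls"], sep="\t",
                                       index_label="gene_id")
    calls.effector_posterior.to_csv(paths["effector_posteriors"], sep="\t",
                                    index_label="gene_id", float_format=fmt)
    calls.effector_expressed_matrix.astype(int).to_csv(
        paths["effector_calls"], sep="\t", index_label="gene_id"
    )
    write_annotation(calls.tissue_labels, paths["annotation"])
    with open(paths["meta"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "threshold_used": calls.threshold_used,
                "strict": calls.strict,
                "skipped_genes": list(calls.skipped_genes),
                "no_call_samples": list(calls.no_call_samples),
            },
            fh,
            indent=2,
        )
    return paths


def load_callset(in_dir: str | Path) -> CallSet:
    src = Path(in_dir)
    with open(src / "callset_meta.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    posterior = pd.read_csv(src / "posteriors.tsv", sep="\t", index_col=0).rename_axis(None)
    effector = pd.read_csv(src / "effector_posteriors.tsv", sep="\t", index_col=0).rename_axis(None)
    labels = read_annotation(src / "annotation.tsv")
    return CallSet(
        posterior=posterior,
        effector_posterior=effector,
        tissue_labels=labels,
        threshold_used=meta["threshold_used"],
        strict=meta["strict"],
        skipped_genes=tuple(meta["skipped_genes"]),
        no_call_samples=tuple(meta["no_call_samples"]),
    )
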