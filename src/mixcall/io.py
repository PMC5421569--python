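"""Readers/writers for the tab-delimited interchange formats.

All matrices are genes-as-rows, samples-as-columns TSV (first column gene
ID, header row of sample IDs), matching the orientation of the expression
repositories this pipeline emulates. Encoding is UTF-8 and the decimal
point is always ".". Floats serialise at %.6g by default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "read_panel",
    "write_panel",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

UNLABELLED = "unlabelled"
FLOAT_FORMAT = "%.6g"
SCALE_TAGS = ("log2_microarray", "ln_rsem_transformed", "unknown")


@dataclasses.dataclass
class ExpressionMatrix:
    """Log-scale gene-by-sample expression matrix with tissue labels.

    ``values`` is a genes × samples float DataFrame; ``tissue_labels`` is a
    Series indexed by sample ID (samples without a label get
    ``"unlabelled"``). ``scale_tag`` records the provenance of the log
    scale: RMA-style log2 microarray values, ln(RSEM+1)+1 transformed
    RNA-seq values, or unknown.
    """

    values: pd.DataFrame
    tissue_labels: pd.Series | None = None
    scale_tag: str = "unknown"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(
                f"scale_tag must be one of {SCALE_TAGS}, got {self.scale_tag!r}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if self.tissue_labels is None:
            self.tissue_labels = pd.Series(
                UNLABELLED, index=self.values.columns, name="tissue_label"
            )
        else:
            missing = self.values.columns.difference(self.tissue_labels.index)
            if len(missing):
                logger.info(
                    "%d samples missing from annotation; labelled %r",
                    len(missing),
                    UNLABELLED,
                )
            self.tissue_labels = self.tissue_labels.reindex(
                self.values.columns, fill_value=UNLABELLED
            )
            self.tissue_labels.name = "tissue_label"

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def read_matrix(
    path: str | Path,
    annotation_path: str | Path | None = None,
    scale_tag: str = "unknown",
) -> ExpressionMatrix:
    """Read a gene × sample TSV matrix, joining tissue labels by sample ID.

    Samples present in the annotation but absent from the matrix are
    ignored with a logged count; matrix samples missing from the annotation
    are labelled ``"unlabelled"``. Duplicate gene IDs and non-numeric cells
    raise ``ValueError`` (the latter with row/column coordinates). Empty
    cells and literal NA markers are read as missing values.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in {path}: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    labels = None
    if annotation_path is not None:
        ann = read_annotation(annotation_path)
        unknown = ann.index.difference(numeric.columns)
        if len(unknown):
            logger.info(
                "%d annotation samples absent from matrix; ignored", len(unknown)
            )
        labels = ann.loc[ann.index.intersection(numeric.columns)]
    return ExpressionMatrix(values=numeric, tissue_labels=labels, scale_tag=scale_tag)


def write_matrix(
    matrix: ExpressionMatrix | pd.DataFrame,
    path: str | Path,
    float_format: str = FLOAT_FORMAT,
) -> None:
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    df.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)


def read_annotation(path: str | Path) -> pd.Series:
    """Read a two-column ``sample_id<TAB>tissue_label`` table."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "tissue_label"}
    if not required.issubset(ann.columns):
        raise ValueError(
            f"annotation {path} must have columns {sorted(required)}, "
            f"got {list(ann.columns)}"
        )
    return ann.set_index("sample_id")["tissue_label"]


def write_annotation(labels: pd.Series, path: str | Path) -> None:
    out = labels.rename("tissue_label").rename_axis("sample_id").reset_index()
    out.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a gene-panel file; returns ``(panel_genes, effector_genes)``.

    Accepts either a two-column ``gene_id<TAB>role`` TSV with roles
    ``panel``/``effector`` (header optional), or a plain list with one gene
    ID per line (all genes treated as panel members).
    """
    panel: list[str] = []
    effectors: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                panel.append(parts[0])
            else:
                gene, role = parts[0], parts[1].lower()
                if (gene, role) == ("gene_id", "role"):
                    continue  # header
                if role == "panel":
                    panel.append(gene)
                elif role == "effector":
                    effectors.append(gene)
                else:
                    raise ValueError(
                        f"unknown role {role!r} at {path}:{lineno + 1}"
                    )
    return panel, effectors


def write_panel(
    panel: Sequence[str], effectors: Sequence[str], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\trole\n")
        for g in panel:
            fh.write(f"{g}\tpanel\n")
        for g in effectors:
            fh.write(f"{g}\teffector\n")


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> int:
    """Run simulate/load → call → summarize → specificity (→ sweep).

    ``config`` keys (all optional unless noted):

    - ``matrix``, ``annotation``, ``panel``: input paths; if ``matrix`` is
      absent a synthetic fixture is generated (``simulate`` sub-dict holds
      :class:`~mixcall.simulate.SimulationConfig` overrides).
    - ``rsem``: apply the ln(RSEM+1)+1 transform before fitting.
    - ``threshold`` (default 0.95), ``strict`` (default True).
    - ``gene``, ``tissue``: focal gene/tissue for the specificity test and
      sweep; default to the simulated planted gene/tissue when simulating.
    - ``sweep``: run the threshold sweep; ``thresholds``: custom ladder.
    - ``seed``: global seed (default 0).
    - ``out_dir`` (required here or as argument): output directory.

    Writes calls, posteriors, fit summary, panel summary, specificity and
    sweep tables plus ``manifest.json`` recording the config hash, seed and
    library versions. Returns 0 on success; on a stage error the manifest
    records the failure point, partial outputs are preserved, and 1 is
    returned.
    """
    from . import __version__
    from .calling import CallConfig, call_expression, save_callset, transform_rsem
    from .mixture import EMConfig
    from .panel import (
        DEFAULT_THRESHOLDS,
        panel_specificity,
        summarize_panel,
        sweep_from_callset,
        tissue_specificity,
    )
    from .simulate import SimulationConfig, generate_matrix, write_fixture

    out = Path(out_dir if out_dir is not None else config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "versions": {
            "mixcall": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": [],
    }
    stage = "setup"
    try:
        stage = "input"
        if "matrix" in config:
            matrix = read_matrix(config["matrix"], config.get("annotation"))
            panel, effectors = read_panel(config["panel"])
            gene = config.get("gene")
            tissue = config.get("tissue")
        else:
            sim_overrides = dict(config.get("simulate", {}))
            sim_overrides.setdefault("seed", seed)
            sim = SimulationConfig(**sim_overrides)
            matrix, truth = generate_matrix(sim)
            write_fixture(matrix, truth, out / "fixture")
            panel = list(sim.panel_gene_ids())
            effectors = list(sim.effector_gene_ids)
            gene = config.get("gene", sim.planted_gene_id)
            tissue = config.get("tissue", sim.planted_tissue)
        if config.get("rsem"):
            matrix = ExpressionMatrix(
                values=transform_rsem(matrix.values),
                tissue_labels=matrix.tissue_labels,
                scale_tag="ln_rsem_transformed",
            )
        manifest["stages"].append("input")

        stage = "call"
        em = EMConfig(seed=seed)
        call_cfg = CallConfig(
            threshold=float(config.get("threshold", 0.95)),
            strict=bool(config.get("strict", True)),
        )
        calls = call_expression(matrix, panel, effectors, em=em, call=call_cfg)
        save_callset(calls, out / "calls")
        logger.info(
            "call: %d genes, %d samples fitted, %d no-call, %d positives",
            len(calls.panel_genes),
            len(calls.samples),
            len(calls.no_call_samples),
            int(calls.expressed.to_numpy().sum()),
        )
        manifest["stages"].append("call")

        stage = "summarize"
        summary = summarize_panel(calls)
        pd.DataFrame([summary.to_dict()]).to_csv(
            out / "panel_summary.tsv", sep="\t", index=False
        )
        manifest["stages"].append("summarize")

        stage = "specificity"
        if tissue is not None:
            spec_table = panel_specificity(calls, tissue)
            spec_table.to_csv(out / "specificity.tsv", sep="\t", index=False)
            if gene is not None:
                res = tissue_specificity(calls, gene, tissue)
                with open(out / "specificity_focal.json", "w") as fh:
                    json.dump(res.to_dict(), fh, indent=2)
            manifest["stages"].append("specificity")

        if config.get("sweep") and gene is not None and tissue is not None:
            stage = "sweep"
            thresholds = tuple(config.get("thresholds", DEFAULT_THRESHOLDS))
            curve = sweep_from_callset(calls, gene, tissue, thresholds)
            curve.to_frame().to_csv(out / "sweep.tsv", sep="\t", index=False)
            manifest["stages"].append("sweep")

        manifest["status"] = "ok"
        return 0
    except Exception as exc:  # record failure point, keep partial outputs
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        return 1
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
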