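"""File formats, run configuration and the end-to-end pipeline driver.

Canonical on-disk formats are UTF-8 TSV with a header row (CSV accepted
on read); missing values are encoded as empty strings.  Lines starting
with ``#`` are metadata comments: every file written by the pipeline
carries the run's config hash and seed, and the abundance/metadata
tables embed their own schema (feature kind tags as a ``_kind`` row,
covariate types as a ``#types:`` comment) so a fixture set is fully
self-describing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import (
    COMPARISONS,
    CohortMatrix,
    SubjectMetadata,
    ValidationError,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("cardstage")

_KIND_ROW = "_kind"


def _delim(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    if isinstance(v, (float, np.floating)):
        return format(float(v), ".12g")
    return str(v)


def _write_table(
    df: pd.DataFrame, path: Path, comments: list[str], delim: str
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write(df.index.name or "id")
        for col in df.columns:
            fh.write(delim + str(col))
        fh.write("\n")
        for idx, row in zip(df.index, df.itertuples(index=False)):
            fh.write(str(idx))
            for v in row:
                fh.write(delim + _fmt(v))
            fh.write("\n")


def write_matrix(
    matrix: CohortMatrix, path: str | Path, comments: list[str] | None = None
) -> None:
    """Write an abundance matrix as TSV; the first data row (subject ID
    ``_kind``) carries the per-feature kind tags."""
    path = Path(path)
    delim = _delim(path)
    body = matrix.values.copy()
    body.index.name = "subject_id"
    kinds = pd.DataFrame(
        [matrix.kinds.values], columns=body.columns, index=pd.Index([_KIND_ROW])
    )
    out = pd.concat([kinds, body])
    out.index.name = "subject_id"
    _write_table(out, path, comments or [], delim)


def read_matrix(path: str | Path) -> CohortMatrix:
    """Read an abundance matrix written by :func:`write_matrix`."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValidationError(f"matrix file missing or empty: {path}")
    df = pd.read_csv(path, sep=_delim(path), comment="#", index_col=0)
    if df.empty and len(df.columns) == 0:
        raise ValidationError(f"matrix file has no data rows: {path}")
    if _KIND_ROW not in df.index:
        raise ValidationError(
            f"matrix file lacks the '{_KIND_ROW}' kind-tag row: {path}"
        )
    kinds = df.loc[_KIND_ROW].astype(str)
    values = df.drop(index=_KIND_ROW).astype(float)
    values.index.name = "subject_id"
    return CohortMatrix(values=values, kinds=kinds)


def write_metadata(
    metadata: SubjectMetadata, path: str | Path, comments: list[str] | None = None
) -> None:
    """Write subject metadata as TSV with a ``#types:`` schema comment."""
    path = Path(path)
    types_line = "types: " + ";".join(
        f"{c}={t}" for c, t in sorted(metadata.covariate_types.items())
    )
    table = metadata.table.copy()
    table.index.name = "subject_id"
    _write_table(table, path, (comments or []) + [types_line], _delim(path))


def read_metadata(path: str | Path) -> SubjectMetadata:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValidationError(f"metadata file missing or empty: {path}")
    cov_types: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            stripped = line.lstrip("# ").strip()
            if stripped.startswith("types:"):
                for item in stripped[len("types:") :].strip().split(";"):
                    if "=" in item:
                        c, t = item.split("=", 1)
                        cov_types[c.strip()] = t.strip()
    table = pd.read_csv(path, sep=_delim(path), comment="#", index_col=0)
    if "subtype" in table.columns:
        table["subtype"] = table["subtype"].fillna("")
    return SubjectMetadata(table=table, covariate_types=cov_types)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Thresholds: BH FDR ``fdr_threshold`` (default 0.1) for significance,
    ``lrt_alpha`` (default 0.05) for the nested-model tests, and the
    display-only ``display_effect_threshold`` (default 0.1) applied when
    rendering reports — never during categorization.
    """

    matrix_path: str = ""
    metadata_path: str = ""
    out_dir: str = "results"
    comparisons: list[str] = field(default_factory=lambda: list(COMPARISONS))
    covariates: list[str] | None = None
    fdr_threshold: float = 0.1
    lrt_alpha: float = 0.05
    eligible_statuses: list[str] = field(default_factory=lambda: ["NC", "CD"])
    display_effect_threshold: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("fdr_threshold", "lrt_alpha", "display_effect_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name}={v} not in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
        }

    def config_hash(self) -> str:
        # hash the analytic parameters only: where outputs are written
        # must not change the scientific fingerprint of a run
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def comparison_slug(comparison: str) -> str:
    return comparison.replace(":", "_")


def write_results_table(df: pd.DataFrame, path: Path, comments: list[str]) -> None:
    _write_table(df, path, comments, _delim(path))


def run_pipeline(
    config: RunConfig,
    matrix: CohortMatrix | None = None,
    metadata: SubjectMetadata | None = None,
) -> dict:
    """Run test -> deconfound -> categorize end to end and write the
    report bundle under ``config.out_dir``.

    Returns a dict with the in-memory tables (``results``, ``verdicts``,
    ``categories``, ``summary``) and the output paths.  Deterministic:
    identical inputs and config produce byte-identical outputs.
    """
    from .categorize import build_profiles, categorize_all
    from .deconfound import run_deconfounding
    from .stats import compare_groups

    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = [
        f"cardstage {__version__}",
        f"config_hash: {config.config_hash()}",
        f"seed: {config.seed}",
    ]

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("cardstage %s, python %s", __version__, sys.version.split()[0])
        logger.info("config hash %s, seed %s", config.config_hash(), config.seed)

        def stage(name):
            logger.info("stage: %s", name)

        try:
            stage("load")
            if matrix is None:
                matrix = read_matrix(config.matrix_path)
            if metadata is None:
                metadata = read_metadata(config.metadata_path)
        except Exception as exc:
            raise RuntimeError(f"stage 'load' failed: {exc}") from exc

        try:
            stage("test")
            results = {}
            for comp in config.comparisons:
                a, b = comp.split(":")
                res = compare_groups(
                    matrix, metadata, a, b, fdr_threshold=config.fdr_threshold
                )
                results[comp] = res
                write_results_table(
                    res, out_dir / f"results_{comparison_slug(comp)}.tsv", stamp
                )
        except (ValidationError, RuntimeError):
            raise
        except Exception as exc:
            raise RuntimeError(f"stage 'test' failed: {exc}") from exc

        try:
            stage("deconfound")
            covs = (
                config.covariates
                if config.covariates is not None
                else metadata.covariates
            )
            if covs:
                verdicts = run_deconfounding(
                    matrix,
                    metadata,
                    config.comparisons,
                    covariates=covs,
                    fdr=config.fdr_threshold,
                    lrt_alpha=config.lrt_alpha,
                )
            else:
                verdicts = None
                logger.info("no covariates declared; all verdicts NC")
            if verdicts is not None:
                vt = verdicts.set_index("feature_id")
                write_results_table(vt, out_dir / "verdicts.tsv", stamp)
        except Exception as exc:
            raise RuntimeError(f"stage 'deconfound' failed: {exc}") from exc

        try:
            stage("categorize")
            profiles = build_profiles(
                results,
                verdicts,
                eligible_statuses=tuple(config.eligible_statuses),
                fdr_threshold=config.fdr_threshold,
            )
            categories, summary = categorize_all(profiles)
            write_results_table(categories, out_dir / "categories.tsv", stamp)
            summary_full = {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                **summary,
            }
            with open(out_dir / "summary.json", "w") as fh:
                json.dump(summary_full, fh, indent=2, sort_keys=True)
                fh.write("\n")
        except Exception as exc:
            raise RuntimeError(f"stage 'categorize' failed: {exc}") from exc

        logger.info(
            "done: %s features, counts %s", summary["n_features"], summary["counts"]
        )
    finally:
        logger.removeHandler(handler)
        handler.close()
    return {
        "results": results,
        "verdicts": verdicts,
        "categories": categories,
        "summary": summary_full,
        "paths": {
            "out_dir": out_dir,
            "categories": out_dir / "categories.tsv",
            "summary": out_dir / "summary.json",
            "log": log_path,
        },
    }
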