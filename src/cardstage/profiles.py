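"""Quantitative microbiome profiling utilities.

Covers the cell-count side of quantitative microbiome profiling (QMP):
rescaling relative/rarefied abundances by flow-cytometry microbial load,
rarefaction of read counts without replacement, gene richness, marker
gene based species (MGS) abundance, and KO-based metabolic module
coverage/abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ValidationError

__all__ = [
    "ModuleDefinition",
    "load_correct",
    "rarefy_counts",
    "gene_richness",
    "mgs_abundance",
    "module_profile",
    "read_module_definitions",
]

#: module presence requires coverage strictly greater than 66%; the
#: common 2/3 (0.667) coverage therefore counts as present
DETECTION_THRESHOLD = 0.66


class RarefactionError(ValidationError):
    """Sample has fewer reads than the requested rarefaction depth."""


@dataclass
class ModuleDefinition:
    """A metabolic module: alternative variants, each an ordered list of
    steps, each step a set of alternative orthologous-group IDs."""

    module_id: str
    variants: list[list[frozenset[str]]]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValidationError(f"module {self.module_id}: needs >= 1 variant")
        for v in self.variants:
            if not v:
                raise ValidationError(f"module {self.module_id}: empty variant")
            if any(len(step) == 0 for step in v):
                raise ValidationError(f"module {self.module_id}: empty step")


def load_correct(
    matrix: pd.DataFrame, loads: pd.Series, on_missing: str = "drop"
) -> pd.DataFrame:
    """Rescale each subject's abundances by its microbial-load index factor.

    The index factor of subject *i* is ``load_i / mean(load)`` over the
    dataset, so the factors average to 1 and the grand scale of the
    matrix is preserved while between-subject cell-count differences are
    reintroduced into the otherwise compositional profile.

    ``on_missing``: ``"drop"`` excludes subjects without a load (with a
    warning); ``"error"`` raises.
    """
    loads = pd.Series(loads).dropna()
    if (loads <= 0).any():
        bad = list(loads.index[loads <= 0][:5])
        raise ValidationError(f"non-positive microbial loads for subjects: {bad}")
    missing = matrix.index.difference(loads.index)
    if len(missing):
        if on_missing == "error":
            raise ValidationError(
                f"{len(missing)} subjects missing a microbial load: "
                f"{list(missing[:5])}"
            )
        warnings.warn(
            f"excluding {len(missing)} subjects without microbial load",
            stacklevel=2,
        )
        matrix = matrix.drop(index=missing)
    loads = loads.loc[matrix.index]
    factors = loads / loads.mean()
    return matrix.mul(factors, axis=0)


def rarefy_counts(counts, depth: int, seed=None) -> np.ndarray:
    """Subsample integer counts to ``depth`` reads without replacement
    (one multivariate hypergeometric draw).

    Raises :class:`RarefactionError` when the sample holds fewer reads
    than ``depth`` so callers can flag and exclude it.
    """
    arr = np.asarray(counts)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("rarefy_counts: counts must be integers")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValidationError("rarefy_counts: negative counts")
    total = int(arr.sum())
    if total < depth:
        raise RarefactionError(
            f"sample has {total} reads, fewer than rarefaction depth {depth}"
        )
    if total == depth:
        return arr.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(arr, depth)


def gene_richness(counts, depth: int, n_reps: int = 10, seed=None) -> float:
    """Gene richness: average, over ``n_reps`` independent rarefactions
    to ``depth``, of the number of genes detected at least once."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    richness = [
        int((rarefy_counts(counts, depth, rng) > 0).sum()) for _ in range(n_reps)
    ]
    return float(np.mean(richness))


def mgs_abundance(gene_abundances) -> float:
    """Marker-gene species abundance: the mean abundance of the marker
    genes (the 50 genes defining the cluster's robust centroid), provided
    strictly more than 10% of them give a positive signal; otherwise 0.
    """
    vals = np.asarray(gene_abundances, dtype=float)
    if vals.size == 0:
        raise ValidationError("mgs_abundance: empty marker set")
    positive_frac = float((vals > 0).mean())
    if positive_frac > 0.10:
        return float(vals.mean())
    return 0.0


def module_profile(
    ko_abundances,
    module: ModuleDefinition,
    detection: float = DETECTION_THRESHOLD,
    step_aggregation: str = "sum",
) -> tuple[float, bool, float]:
    """Coverage, presence and abundance of one metabolic module.

    Variant coverage = fraction of its steps with at least one detected
    ortholog (abundance > 0); module coverage = the maximum over
    variants.  The module is present iff coverage strictly exceeds
    ``detection``.  Abundance is the median over the steps of the
    maximum-coverage variant of the per-step abundance (sum of the
    detected alternative orthologs by default, ``step_aggregation="max"``
    for the largest single ortholog; undetected steps contribute 0); an
    absent module has abundance 0.
    """
    if step_aggregation not in ("sum", "max"):
        raise ValidationError(f"unknown step_aggregation {step_aggregation!r}")
    getter = (
        ko_abundances.get
        if hasattr(ko_abundances, "get")
        else lambda k, d=0.0: ko_abundances[k]
    )

    best_cov, best_variant = -1.0, None
    for variant in module.variants:
        detected = sum(
            1 for step in variant if any(float(getter(ko, 0.0) or 0.0) > 0 for ko in step)
        )
        cov = detected / len(variant)
        if cov > best_cov:
            best_cov, best_variant = cov, variant
    present = best_cov > detection
    if not present:
        return best_cov, False, 0.0
    step_abunds = []
    for step in best_variant:
        vals = [float(getter(ko, 0.0) or 0.0) for ko in step]
        vals = [v for v in vals if v > 0]
        if not vals:
            step_abunds.append(0.0)
        elif step_aggregation == "sum":
            step_abunds.append(sum(vals))
        else:
            step_abunds.append(max(vals))
    return best_cov, True, float(np.median(step_abunds))


def read_module_definitions(path: str | Path) -> list[ModuleDefinition]:
    """Parse module definitions from the plain-text dialect.

    One module per block, blocks separated by blank lines.  The first
    line of a block is ``MODULE <tab> module_id [<tab> name]``; each
    subsequent line is one variant, its steps tab-separated, each step a
    comma-separated list of alternative KO IDs::

        MODULE	M0001	butyrate production
        K00001,K00002	K00003
        K00004	K00003

    defines a two-variant module with two steps each.
    """
    modules: list[ModuleDefinition] = []
    block: list[str] = []

    def flush(block: list[str]) -> None:
        if not block:
            return
        head = block[0].split("\t")
        if head[0].strip().upper() != "MODULE" or len(head) < 2:
            raise ValidationError(
                f"module block must start with 'MODULE\\t<id>', got {block[0]!r}"
            )
        module_id = head[1].strip()
        name = head[2].strip() if len(head) > 2 else ""
        variants = []
        for line in block[1:]:
            steps = [
                frozenset(ko.strip() for ko in cell.split(",") if ko.strip())
                for cell in line.split("\t")
                if cell.strip()
            ]
            if steps:
                variants.append(steps)
        modules.append(ModuleDefinition(module_id=module_id, variants=variants, name=name))

    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#"):
                continue
            if not line.strip():
                flush(block)
                block = []
            else:
                block.append(line)
        flush(block)
    return modules
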