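"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure the staging analysis assumes: four
disease-stage groups (HC, UMMC, MMC, IHD; IHD optionally split into
ACS/CIHD/HF subtypes), group-conditional drug prescription, host
covariates (age, BMI, smoking), group-dependent fecal microbial load,
and two feature classes — zero-inflated negative-binomial counts for
taxon-like features and log-normal intensities for metabolite-like
features.

Each non-null feature carries a planted effect archetype along the
HC -> dysmetabolism -> IHD trajectory:

==============  ====================================================
archetype       log-mean shift multiplier per group (HC/UMMC/MMC/IHD)
==============  ====================================================
null            0 / 0 / 0 / 0
dmf             0 / 1 / 1 / 1   (dysmetabolism feature)
ihdf            0 / 0 / 0 / 1   (disease-specific feature)
escf            0 / 1 / 1 / 2   (escalates through both stages)
dscf            0 / 1 / 1 / 0   (reverses at the disease stage)
drug_driven     shift follows the drug indicator, not the group
==============  ====================================================

The per-stage shift is calibrated numerically so that the Cliff's delta
between the shifted and unshifted populations equals the requested
effect size: closed form for log-normal intensities, exact pmf
integration with bisection for the zero-inflated counts.  These
distributional choices are stand-ins for real multi-omics data — the
source study provides no generative model — and are documented as such
in the package docs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .containers import GROUPS, SUBTYPES, CohortMatrix, SubjectMetadata, ValidationError

__all__ = ["SyntheticSpec", "GroundTruth", "generate_cohort", "emit_fixture"]

ARCHETYPES = ("null", "dmf", "ihdf", "escf", "dscf", "drug_driven")

#: per-group multiplier applied to the calibrated per-stage shift
_STAGE_MULT = {
    "null": {"HC": 0, "UMMC": 0, "MMC": 0, "IHD": 0},
    "dmf": {"HC": 0, "UMMC": 1, "MMC": 1, "IHD": 1},
    "ihdf": {"HC": 0, "UMMC": 0, "MMC": 0, "IHD": 1},
    "escf": {"HC": 0, "UMMC": 1, "MMC": 1, "IHD": 2},
    "dscf": {"HC": 0, "UMMC": 1, "MMC": 1, "IHD": 0},
    "drug_driven": {"HC": 0, "UMMC": 0, "MMC": 0, "IHD": 0},
}

# cohort sizes of the cross-sectional study design this generator mirrors
DEFAULT_GROUP_SIZES = {"HC": 275, "UMMC": 222, "MMC": 372, "IHD": 372}
DEFAULT_SUBTYPE_SIZES = {"ACS": 112, "CIHD": 158, "HF": 102}

DEFAULT_DRUG_MODEL = {
    "statin": {"HC": 0.0, "UMMC": 0.0, "MMC": 0.60, "IHD": 0.90},
    "beta_blocker": {"HC": 0.0, "UMMC": 0.0, "MMC": 0.30, "IHD": 0.80},
    "metformin": {"HC": 0.0, "UMMC": 0.0, "MMC": 0.45, "IHD": 0.50},
    "aspirin": {"HC": 0.02, "UMMC": 0.05, "MMC": 0.15, "IHD": 0.90},
    "ppi": {"HC": 0.10, "UMMC": 0.15, "MMC": 0.30, "IHD": 0.40},
}

#: lognormal microbial load (cells per gram of feces): depleted in the
#: dysmetabolic groups (most in the untreated one), partly restored in
#: treated disease.
DEFAULT_LOAD_MODEL = {
    "HC": (1.1e11, 0.45),
    "UMMC": (5.0e10, 0.45),
    "MMC": (6.5e10, 0.45),
    "IHD": (8.5e10, 0.45),
}

DEFAULT_NOISE_MODEL = {
    "sigma_log": 1.0,  # log-scale s.d. of metabolite intensities
    "zero_inflation": 0.25,  # structural-zero probability, taxon-like
    "nb_dispersion": 1.0,  # negative-binomial size parameter r
    "taxon_mean_log": 4.6,  # mean of per-feature log base count (~100 reads)
    "taxon_mean_sd": 1.0,
}

DEFAULT_ARCHETYPE_MIX = {
    "null": 0.50,
    "dmf": 0.15,
    "ihdf": 0.10,
    "escf": 0.075,
    "dscf": 0.075,
    "drug_driven": 0.10,
}

_COVARIATE_PARAMS = {
    # group -> (age mean, age sd, bmi mean, bmi sd, smoking probs 0/1/2)
    "HC": (58.0, 8.0, 25.5, 3.5, (0.60, 0.30, 0.10)),
    "UMMC": (60.0, 8.0, 31.0, 5.0, (0.50, 0.30, 0.20)),
    "MMC": (62.0, 8.0, 30.0, 5.0, (0.50, 0.30, 0.20)),
    "IHD": (63.0, 8.0, 29.5, 4.5, (0.35, 0.35, 0.30)),
}


def _archetype_key(name: str) -> tuple[str, str | None]:
    """Split an archetype-mix key into (base archetype, IHD subtype)."""
    if "_" in name:
        base, _, suffix = name.partition("_")
        if base == "ihdf" and suffix in SUBTYPES:
            return "ihdf", suffix
        if name == "drug_driven":
            return "drug_driven", None
    if name not in ARCHETYPES:
        raise ValidationError(f"archetype_mix: unknown archetype {name!r}")
    return name, None


@dataclass
class SyntheticSpec:
    """Full parameterization of a synthetic cohort.

    ``effect_size`` is the target |Cliff's delta| between the shifted and
    unshifted populations of each planted archetype (per-stage for
    escalation/de-escalation features); give a float or a per-archetype
    dict.  ``archetype_mix`` may include subtype-specific keys such as
    ``ihdf_ACS`` (shift only in that IHD subtype).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_features: dict[str, int] = field(
        default_factory=lambda: {"taxon": 120, "metabolite": 120}
    )
    archetype_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_MIX)
    )
    effect_size: float | dict[str, float] = 0.3
    drug_model: dict[str, dict[str, float]] = field(
        default_factory=lambda: {d: dict(p) for d, p in DEFAULT_DRUG_MODEL.items()}
    )
    load_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LOAD_MODEL)
    )
    noise_model: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_MODEL)
    )
    subtypes: bool = True
    seed: int = 0

    def effect_for(self, archetype: str) -> float:
        if isinstance(self.effect_size, dict):
            return float(self.effect_size.get(archetype, 0.3))
        return float(self.effect_size)

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValidationError(f"group_sizes: unknown group {g!r}")
            if n < 2:
                raise ValidationError(f"group_sizes[{g!r}]: need >= 2 subjects, got {n}")
        for kind, n in self.n_features.items():
            if kind not in ("taxon", "module", "metabolite"):
                raise ValidationError(f"n_features: unknown feature kind {kind!r}")
            if n < 0:
                raise ValidationError(f"n_features[{kind!r}]: negative count")
        total = 0.0
        for name, prop in self.archetype_mix.items():
            _archetype_key(name)
            if not 0.0 <= prop <= 1.0:
                raise ValidationError(f"archetype_mix[{name!r}]: {prop} not in [0, 1]")
            total += prop
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"archetype_mix sums to {total}, expected 1")
        effs = (
            self.effect_size.values()
            if isinstance(self.effect_size, dict)
            else [self.effect_size]
        )
        for e in effs:
            if not 0.0 <= e < 1.0:
                raise ValidationError(f"effect_size: {e} not in [0, 1)")
        for drug, probs in self.drug_model.items():
            for g, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(
                        f"drug_model[{drug!r}][{g!r}]: {p} not in [0, 1]"
                    )

    def to_dict(self) -> dict:
        return {
            "group_sizes": dict(self.group_sizes),
            "n_features": dict(self.n_features),
            "archetype_mix": dict(self.archetype_mix),
            "effect_size": self.effect_size,
            "drug_model": {d: dict(p) for d, p in self.drug_model.items()},
            "load_model": {g: list(v) for g, v in self.load_model.items()},
            "noise_model": dict(self.noise_model),
            "subtypes": self.subtypes,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "load_model" in d:
            d["load_model"] = {g: tuple(v) for g, v in d["load_model"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted truth per feature: archetype, direction along the
    trajectory (+1 up with disease, -1 down), and — for drug-driven
    features — the single confounding drug."""

    table: pd.DataFrame  # index feature_id: archetype, subtype, direction, confounder

    def archetype_of(self, feature_id: str) -> str:
        return str(self.table.loc[feature_id, "archetype"])

    def features_with(self, archetype: str) -> pd.Index:
        return self.table.index[self.table["archetype"] == archetype]


# ---------------------------------------------------------------------------
# effect-size calibration


def shift_for_lognormal(target_delta: float, sigma: float) -> float:
    """Log-mean shift giving Cliff's delta ``target_delta`` between two
    log-normal populations with common log-scale s.d. ``sigma``.

    For X ~ N(0, s^2), Y ~ N(d, s^2) on the log scale (delta is invariant
    under the monotone exp), delta = 2 Phi(d / (s sqrt(2))) - 1.
    """
    if abs(target_delta) >= 1.0:
        raise ValidationError("target delta must lie in (-1, 1)")
    return float(np.sqrt(2.0) * sigma * sps.norm.ppf((target_delta + 1.0) / 2.0))


def zinb_delta(mu0: float, mu1: float, r: float, pi: float) -> float:
    """Exact Cliff's delta between ZINB(mu0) and ZINB(mu1) populations
    (shared dispersion ``r`` and structural-zero probability ``pi``),
    by direct integration of the probability mass functions."""
    # integrate over the support of X = ZINB(mu0) and evaluate the cdf of
    # Y = ZINB(mu1) pointwise, so an arbitrarily large shifted mean never
    # truncates the sum: delta = sum_k P(X=k) [P(Y>k) - P(Y<k)]
    hi = int(sps.nbinom.ppf(1 - 1e-10, r, r / (r + mu0)))
    k = np.arange(0, hi + 1)
    pmf0 = (1 - pi) * sps.nbinom.pmf(k, r, r / (r + mu0))
    pmf0[0] += pi
    cdf1 = pi + (1 - pi) * sps.nbinom.cdf(k, r, r / (r + mu1))  # P(Y <= k)
    below1 = np.concatenate([[0.0], cdf1[:-1]])  # P(Y < k)
    return float(np.sum(pmf0 * ((1.0 - cdf1) - below1)))


def shift_for_zinb(
    target_delta: float, mu: float, r: float, pi: float, tol: float = 5e-4
) -> float:
    """Log-mean shift giving (signed) Cliff's delta ``target_delta``
    between ZINB(mu e^d) and ZINB(mu), solved by bisection on the exact
    delta.  Returns the boundary shift if the target is unreachable
    (zero inflation caps the attainable |delta| at (1 - pi)(1 + pi))."""
    if target_delta == 0.0:
        return 0.0
    lo, hi = (0.0, 8.0) if target_delta > 0 else (-8.0, 0.0)
    f = lambda d: zinb_delta(mu, mu * np.exp(d), r, pi) - target_delta
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:  # unreachable within bounds; use the extreme
        return hi if target_delta > 0 else lo
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) < tol:
            return mid
        if f_lo * fm <= 0:
            hi = mid
        else:
            lo, f_lo = mid, fm
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# generation


def _allocate_counts(n: int, mix: dict[str, float], rng: np.random.Generator) -> list[str]:
    """Largest-remainder allocation of n features across archetypes,
    returned in shuffled order."""
    names = sorted(mix)
    raw = np.array([mix[a] * n for a in names])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(rem):
        base[order[i % len(names)]] += 1
    labels = [a for a, c in zip(names, base) for _ in range(int(c))]
    return [labels[i] for i in rng.permutation(n)]


def _make_metadata(spec: SyntheticSpec, rng: np.random.Generator) -> SubjectMetadata:
    rows = []
    sid = 0
    for g in [g for g in GROUPS if g in spec.group_sizes]:
        n = spec.group_sizes[g]
        age_m, age_s, bmi_m, bmi_s, smoke_p = _COVARIATE_PARAMS[g]
        load_mean, load_sig = spec.load_model.get(g, (8e10, 0.45))
        for _ in range(n):
            rows.append(
                {
                    "subject_id": f"S{sid:05d}",
                    "group": g,
                    "age": round(float(rng.normal(age_m, age_s)), 1),
                    "bmi": round(float(rng.normal(bmi_m, bmi_s)), 1),
                    "smoking": int(rng.choice(3, p=smoke_p)),
                    "microbial_load": float(
                        np.exp(rng.normal(np.log(load_mean), load_sig))
                    ),
                }
            )
            sid += 1
    table = pd.DataFrame(rows).set_index("subject_id")

    # IHD subtype assignment, proportional to the reference subtype sizes
    table["subtype"] = ""
    if spec.subtypes and "IHD" in spec.group_sizes:
        ihd_ids = table.index[table["group"] == "IHD"].to_numpy()
        props = np.array([DEFAULT_SUBTYPE_SIZES[s] for s in SUBTYPES], dtype=float)
        props /= props.sum()
        counts = np.floor(props * len(ihd_ids)).astype(int)
        for i in np.argsort(-(props * len(ihd_ids) - counts)):
            if counts.sum() >= len(ihd_ids):
                break
            counts[i] += 1
        labels = np.repeat(list(SUBTYPES), counts)
        table.loc[ihd_ids, "subtype"] = labels[rng.permutation(len(ihd_ids))]

    cov_types = {"age": "continuous", "bmi": "continuous", "smoking": "ordinal"}
    for drug, probs in spec.drug_model.items():
        p = table["group"].map(lambda g: probs.get(g, 0.0)).to_numpy(dtype=float)
        table[drug] = (rng.random(len(table)) < p).astype(int)
        cov_types[drug] = "binary"
    return SubjectMetadata(table=table, covariate_types=cov_types)


def generate_cohort(
    spec: SyntheticSpec, subject_seed: int | None = None
) -> tuple[CohortMatrix, SubjectMetadata, GroundTruth]:
    """Generate one synthetic cohort with planted ground truth.

    Deterministic under ``spec.seed``: the same spec always yields the
    same matrices.  Feature-level structure (archetype assignment,
    planted directions, base abundances) is governed by ``spec.seed``
    alone; pass ``subject_seed`` to resample a fresh cohort of subjects
    from the *same* underlying population, e.g. an external validation
    cohort sharing every feature's data-generating process.
    """
    spec.validate()
    subj = spec.seed if subject_seed is None else subject_seed
    # independent substreams: feature structure vs subject-level sampling
    rng_feat = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1, subj]))
    metadata = _make_metadata(spec, rng)
    groups = metadata.groups
    n_subj = len(metadata.subjects)

    active_drugs = [
        d
        for d, probs in spec.drug_model.items()
        if len({round(p, 6) for p in probs.values()}) > 1 or max(probs.values()) > 0
    ]
    if any(_archetype_key(a)[0] == "drug_driven" for a in spec.archetype_mix) and not (
        active_drugs
    ):
        raise ValidationError("drug_driven archetype requested but drug_model is empty")

    kind_map = {"taxon": "taxon", "module": "module", "metabolite": None}
    prefix = {"taxon": "tax", "module": "mod", "metabolite": "met"}
    sigma = float(spec.noise_model.get("sigma_log", 1.0))
    pi = float(spec.noise_model.get("zero_inflation", 0.25))
    r = float(spec.noise_model.get("nb_dispersion", 1.0))
    mu_log = float(spec.noise_model.get("taxon_mean_log", 4.6))
    mu_sd = float(spec.noise_model.get("taxon_mean_sd", 1.0))

    cols: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    truth_rows = []
    group_arr = groups.to_numpy()

    for kind in ("taxon", "module", "metabolite"):
        n_feat = int(spec.n_features.get(kind, 0))
        if n_feat == 0:
            continue
        arch_labels = _allocate_counts(n_feat, spec.archetype_mix, rng_feat)
        for j, arch_name in enumerate(arch_labels):
            base_arch, subtype = _archetype_key(arch_name)
            fid = f"{prefix[kind]}_{j:04d}"
            direction = int(rng_feat.choice([-1, 1]))
            effect = spec.effect_for(arch_name) if base_arch != "null" else 0.0
            confounder = ""
            if base_arch == "drug_driven":
                confounder = active_drugs[int(rng_feat.integers(len(active_drugs)))]

            is_count = kind in ("taxon", "module")
            if is_count:
                base_mu = float(np.exp(rng_feat.normal(mu_log, mu_sd)))
                d = (
                    shift_for_zinb(direction * effect, base_mu, r, pi)
                    if effect > 0
                    else 0.0
                )
            else:
                d = shift_for_lognormal(direction * effect, sigma) if effect > 0 else 0.0

            shift = np.zeros(n_subj)
            if base_arch == "drug_driven":
                shift = d * metadata.table[confounder].to_numpy(dtype=float)
            elif base_arch == "ihdf" and subtype is not None:
                in_sub = (metadata.table["subtype"] == subtype).to_numpy()
                shift = d * in_sub.astype(float)
            elif base_arch != "null":
                mult = np.array([_STAGE_MULT[base_arch][g] for g in group_arr], float)
                shift = d * mult

            if is_count:
                mu_i = base_mu * np.exp(shift)
                counts = rng.negative_binomial(r, r / (r + mu_i))
                zeros = rng.random(n_subj) < pi
                counts = np.where(zeros, 0, counts)
                cols[fid] = counts.astype(float)
            else:
                logint = rng.normal(np.log(100.0) + shift, sigma)
                cols[fid] = np.exp(logint)
            kinds[fid] = (
                kind_map[kind]
                if kind_map[kind]
                else ("metabolite_serum" if j % 2 == 0 else "metabolite_urine")
            )
            truth_rows.append(
                {
                    "feature_id": fid,
                    "archetype": arch_name,
                    "direction": direction,
                    "confounder": confounder,
                    "kind": kinds[fid],
                    "planted_shift": d,
                }
            )

    values = pd.DataFrame(cols, index=metadata.subjects)
    matrix = CohortMatrix(values=values, kinds=pd.Series(kinds))
    truth = GroundTruth(pd.DataFrame(truth_rows).set_index("feature_id"))
    return matrix, metadata, truth


def emit_fixture(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate a cohort and serialize it as a TSV/YAML fixture set.

    Writes ``abundance.tsv``, ``metadata.tsv``, ``truth.tsv`` and
    ``spec.yaml``; files round-trip losslessly through the package
    readers and are byte-identical across runs with the same seed.
    """
    from . import io as cio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, metadata, truth = generate_cohort(spec)
    paths = {
        "abundance": out / "abundance.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.tsv",
        "spec": out / "spec.yaml",
    }
    cio.write_matrix(matrix, paths["abundance"])
    cio.write_metadata(metadata, paths["metadata"])
    tt = truth.table.copy()
    tt["planted_shift"] = tt["planted_shift"].map(lambda v: f"{v:.12g}")
    tt.to_csv(paths["truth"], sep="\t")
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=True)
    return paths


def fixture_checksum(paths: dict[str, Path]) -> str:
    """SHA-256 over the emitted fixture files, for determinism checks."""
    h = hashlib.sha256()
    for key in sorted(paths):
        h.update(Path(paths[key]).read_bytes())
    return h.hexdigest()
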