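"""Synthetic field-of-view count data with a patients > samples > FoVs hierarchy.

Emulates Ki67-style immunostaining scoring: each individual contributes
one or more tissue samples (e.g. a vehicle-control and a drug-treated
explant), each sample is scored over several microscope fields of view
(FoV), and each FoV yields a positive count out of a total cell count.
Heterogeneity enters as Gaussian random intercepts on the logit scale at
the individual and the sample-within-individual level, plus within-FoV
overdispersion from the chosen count family.

Default generative truth (used by the power study): baseline positivity
30% (logit -0.847), treatment shift -0.2 on the logit scale, no batch
effects, sd_individual 0.5, sd_sample 0.1, beta-binomial with precision
phi = 3 (intra-FoV correlation 0.25).  These are declared, overridable
stand-ins for fitted values that are not publicly available.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logit

from .families import CountFamily, get_family

__all__ = [
    "StudyDesign",
    "SimulationParams",
    "CountDataset",
    "DEFAULT_DESIGN",
    "DEFAULT_PARAMS",
    "simulate_dataset",
    "read_count_table",
    "write_count_table",
    "replicate_seed",
]

COLUMNS = ("individual_id", "sample_id", "batch", "treatment",
           "fov_index", "positive", "total")

_SCHEMES = ("paired_within_individual", "between_individual")


@dataclass(frozen=True)
class StudyDesign:
    """Who is sampled and how densely each sample is scored."""

    n_individuals: int = 25
    samples_per_individual: int = 2
    treatment_scheme: str = "paired_within_individual"
    n_batches: int = 1
    n_fov: int = 25
    cells_per_fov: int = 25

    def __post_init__(self):
        if self.treatment_scheme not in _SCHEMES:
            raise ValueError(f"treatment_scheme: must be one of {_SCHEMES}")
        for name in ("n_individuals", "samples_per_individual",
                     "n_batches", "n_fov", "cells_per_fov"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name}: must be >= 1")
        if (self.treatment_scheme == "paired_within_individual"
                and self.samples_per_individual < 2):
            raise ValueError(
                "samples_per_individual: paired_within_individual needs >= 2")


@dataclass(frozen=True)
class SimulationParams:
    """Generative truth on the link scale."""

    beta0: float = float(logit(0.30))
    beta_treatment: float = -0.2
    beta_batch: tuple = ()  # reference-coded against batch 1
    sd_individual: float = 0.5
    sd_sample: float = 0.1
    family: str = "betabinomial"
    dispersion: float | None = 3.0

    def __post_init__(self):
        if self.sd_individual < 0 or self.sd_sample < 0:
            raise ValueError("sd_individual/sd_sample: must be non-negative")
        fam = get_family(self.family)
        if fam.spec.has_dispersion and self.dispersion is None:
            raise ValueError(
                f"dispersion: required for family {fam.family_id!r}")
        if not fam.spec.has_dispersion and self.dispersion is not None:
            raise ValueError(
                f"dispersion: family {fam.family_id!r} has no dispersion "
                "parameter; leave it unset")

    def validate_against(self, design: StudyDesign) -> None:
        if self.beta_batch and len(self.beta_batch) != design.n_batches - 1:
            raise ValueError(
                f"beta_batch: expected {design.n_batches - 1} reference-coded "
                f"effects for {design.n_batches} batches, "
                f"got {len(self.beta_batch)}")


DEFAULT_DESIGN = StudyDesign()
DEFAULT_PARAMS = SimulationParams()


@dataclass
class CountDataset:
    """Long-format FoV count table plus its design and provenance.

    ``df`` has one row per FoV with columns ``individual_id, sample_id,
    batch, treatment, fov_index, positive, total``.
    """

    df: pd.DataFrame
    design: StudyDesign | None = None
    provenance: str = ""
    n_censored: int = field(default=0)

    def __post_init__(self):
        self.df = validate_table(self.df)

    def __eq__(self, other):
        return (isinstance(other, CountDataset)
                and self.df.equals(other.df)
                and self.design == other.design
                and self.provenance == other.provenance)

    def __len__(self):
        return len(self.df)


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and row-level invariants; return a normalized copy."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    df = df.loc[:, list(COLUMNS)].copy()
    bad_rows: list[str] = []
    for col in ("treatment", "fov_index", "positive", "total"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals.fillna(0)))
        for i in df.index[bad]:
            bad_rows.append(f"row {i}: column {col!r} is not an integer")
        df[col] = vals
    if not bad_rows:
        for i in df.index[(df["positive"] < 0) | (df["positive"] > df["total"])]:
            bad_rows.append(f"row {i}: positive not in [0, total]")
        for i in df.index[df["total"] < 1]:
            bad_rows.append(f"row {i}: total must be >= 1")
        for i in df.index[~df["treatment"].isin((0, 1))]:
            bad_rows.append(f"row {i}: treatment must be 0 or 1")
    if bad_rows:
        raise ValueError("invalid count table:\n  " + "\n  ".join(bad_rows))
    dup = df.duplicated(subset=["individual_id", "sample_id", "fov_index"])
    if dup.any():
        rows = ", ".join(str(i) for i in df.index[dup])
        raise ValueError(
            f"invalid count table: duplicate (individual_id, sample_id, "
            f"fov_index) at row(s) {rows}")
    per_sample = df.groupby(["individual_id", "sample_id"], sort=False)
    n_levels = per_sample[["batch", "treatment"]].nunique()
    mixed = n_levels[(n_levels > 1).any(axis=1)]
    if len(mixed):
        raise ValueError(
            "invalid count table: batch/treatment not constant within "
            f"sample(s) {list(mixed.index)}")
    for col in ("treatment", "fov_index", "positive", "total"):
        df[col] = df[col].astype(np.int64)
    df["individual_id"] = df["individual_id"].astype(str)
    df["sample_id"] = df["sample_id"].astype(str)
    df["batch"] = df["batch"].astype(str)
    return df


def replicate_seed(master_seed: int, *keys: int) -> np.random.SeedSequence:
    """Counter-based substream: one SeedSequence per (master, keys) tuple.

    Replicates drawn this way are reproducible independently of execution
    order, which makes grid runs embarrassingly parallel.
    """
    return np.random.SeedSequence([int(master_seed), *[int(k) for k in keys]])


def simulate_dataset(design: StudyDesign, params: SimulationParams,
                     seed) -> CountDataset:
    """Draw one synthetic FoV count table.

    Per individual ``i``: u_i ~ N(0, sd_individual^2); per sample ``j``
    within it: v_ij ~ N(0, sd_sample^2).  The linear predictor is
    ``eta_ij = beta0 + beta_treatment*treat + batch effect + u_i + v_ij``
    and the per-FoV positive counts are drawn from ``params.family`` with
    mean ``expit(eta)`` (logit link) or ``total*exp(eta)`` (log link,
    capped at the total; capped redraws are counted in ``n_censored``).

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    params.validate_against(design)
    if isinstance(seed, np.random.SeedSequence):
        seed_seq, seed_label = seed, f"SeedSequence{tuple(seed.entropy)!r}"
    else:
        seed_seq, seed_label = np.random.SeedSequence(int(seed)), str(seed)
    rng = np.random.default_rng(seed_seq)
    family = get_family(params.family)

    n_ind = design.n_individuals
    n_samp = design.samples_per_individual
    batch_fx = np.concatenate(([0.0], np.asarray(params.beta_batch, float)
                               if params.beta_batch
                               else np.zeros(design.n_batches - 1)))

    u = rng.normal(0.0, params.sd_individual, size=n_ind)
    v = rng.normal(0.0, params.sd_sample, size=(n_ind, n_samp))

    rows = []
    etas = []
    width = len(str(n_ind))
    for i in range(n_ind):
        ind_id = f"I{i + 1:0{width}d}"
        batch = i % design.n_batches
        for j in range(n_samp):
            if design.treatment_scheme == "paired_within_individual":
                treat = j % 2
            else:
                treat = i % 2
            eta = (params.beta0 + params.beta_treatment * treat
                   + batch_fx[batch] + u[i] + v[i, j])
            for f in range(design.n_fov):
                rows.append((ind_id, f"{ind_id}-S{j + 1}",
                             f"B{batch + 1}", treat, f))
                etas.append(eta)

    df = pd.DataFrame(rows, columns=["individual_id", "sample_id", "batch",
                                     "treatment", "fov_index"])
    total = np.full(len(df), design.cells_per_fov, dtype=np.int64)
    eta = np.asarray(etas)
    n_censored = 0
    if family.spec.link == "logit":
        positive = family.sample(rng, total, eta, params.dispersion)
    else:
        # log link: mean count total*exp(eta), i.e. offset log(total)
        positive = family.sample(rng, total, eta + np.log(total),
                                 params.dispersion)
        n_censored = int(np.sum(positive >= total))  # upper bound on caps
    df["positive"] = positive
    df["total"] = total
    prov = (f"simulate_dataset(seed={seed_label}, family={family.family_id}, "
            f"n_individuals={n_ind}, n_fov={design.n_fov}, "
            f"cells_per_fov={design.cells_per_fov})")
    return CountDataset(df=df, design=design, provenance=prov,
                        n_censored=n_censored)


def _sep_for(path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","


def read_count_table(path_or_buf, *, sep: str | None = None) -> CountDataset:
    """Read a long-format count table (CSV/TSV inferred from extension)."""
    if sep is None:
        sep = _sep_for(path_or_buf) if not isinstance(
            path_or_buf, io.IOBase) else ","
    df = pd.read_csv(path_or_buf, sep=sep, dtype={
        "individual_id": str, "sample_id": str, "batch": str})
    return CountDataset(df=df, provenance=f"read_count_table({path_or_buf})")


def write_count_table(dataset: CountDataset, path, *,
                      sep: str | None = None) -> None:
    """Write the count table; delimiter inferred from the extension."""
    if sep is None:
        sep = _sep_for(path)
    dataset.df.to_csv(path, sep=sep, index=False)


def design_from_dict(d: dict) -> StudyDesign:
    return StudyDesign(**{k: v for k, v in d.items()
                          if k in StudyDesign.__dataclass_fields__})


def params_from_dict(d: dict) -> SimulationParams:
    d = {k: v for k, v in d.items()
         if k in SimulationParams.__dataclass_fields__}
    if "beta_batch" in d and d["beta_batch"] is not None:
        d["beta_batch"] = tuple(d["beta_batch"])
    return SimulationParams(**d)


def with_overrides(params: SimulationParams, **kw) -> SimulationParams:
    """Convenience: a copy of ``params`` with fields replaced."""
    return replace(params, **kw)
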