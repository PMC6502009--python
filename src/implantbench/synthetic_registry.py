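"""Synthetic arthroplasty registries with known ground truth.

The generator emulates the statistical structure a national joint registry
presents to the benchmarking analysis: thousands of constructs with heavily
right-skewed usage counts, staggered enrollment over a roughly 14-year
window, construct-specific revision hazards that differ by age band and
gender, death as independent within-stratum censoring, and administrative
censoring at a fixed extract date.

Revision times are Weibull: flexible enough for both early-failure
(shape < 1) and wear-driven late-failure (shape > 1) constructs.  Stratum
effects multiply the cumulative hazard, so for a procedure in cell
(gender g, age band b) of a construct with shape k and scale lambda

    F*(t) = 1 - exp(-c_gb (t / lambda)^k),      c_gb = c_g * c_b,

which is the closed-form net failure the 1-Kaplan-Meier estimator targets
when death censors independently.  Death times are exponential with a
per-year rate that depends on the same cell; within a cell death is
independent of the revision time by construction.

Reproducibility: one ``numpy`` seed sequence per registry, spawned from
``config.seed``; construct-level parameters and each construct's records
use deterministic child streams, so identical configs give byte-identical
registries.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .registry_io import (AGE_BANDS, Bearing, ConstructKey, ProcedureRecord,
                          Stratum, YEAR_DAYS)


@dataclass(frozen=True)
class SizeLaw:
    """Truncated discrete power law for construct usage counts:
    P(size = k) proportional to k^-exponent on [min_size, max_size]."""

    pareto_exponent: float = 2.0
    min_size: int = 2
    max_size: int = 25_000


@dataclass(frozen=True)
class RevisionModel:
    """Sampling distribution of per-construct Weibull revision hazards.

    Shapes are uniform on ``shape_range``.  Rather than drawing the scale
    directly, each construct draws a baseline 10-year net failure
    log-uniformly from ``failure10_range`` and the Weibull scale is solved
    from it, which pins the clinically meaningful quantity (most commonly
    used constructs fail in well under 10% of procedures by 10 years).
    """

    shape_range: tuple[float, float] = (0.8, 1.4)
    failure10_range: tuple[float, float] = (0.01, 0.10)


@dataclass(frozen=True)
class ConstructSpec:
    """Explicit construct override for fixtures with controlled truth."""

    stem: str
    cup: str
    bearing: str
    shape: float
    scale: float
    size: int


@dataclass(frozen=True)
class StratumEffects:
    """Multiplicative cumulative-hazard factors for revision.  Younger
    patients revise more; the gender contrast is mild."""

    gender: Mapping[str, float] = field(
        default_factory=lambda: {"M": 1.15, "F": 1.0})
    age_band: Mapping[str, float] = field(
        default_factory=lambda: {"<55": 1.6, "55-75": 1.0, ">75": 0.75})

    def factor(self, gender: str, band: str) -> float:
        return self.gender[gender] * self.age_band[band]


@dataclass(frozen=True)
class DeathModel:
    """Exponential per-year death rates by age band, scaled by gender."""

    rate_by_band: Mapping[str, float] = field(
        default_factory=lambda: {"<55": 0.004, "55-75": 0.015, ">75": 0.06})
    gender_factor: Mapping[str, float] = field(
        default_factory=lambda: {"M": 1.25, "F": 1.0})

    def rate(self, gender: str, band: str) -> float:
        return self.rate_by_band[band] * self.gender_factor[gender]


@dataclass(frozen=True)
class AgeMix:
    """Categorical age-band mix and uniform integer ages within bands."""

    band_probs: Mapping[str, float] = field(
        default_factory=lambda: {"<55": 0.12, "55-75": 0.63, ">75": 0.25})
    band_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"<55": (30, 54), "55-75": (55, 75),
                                 ">75": (76, 94)})


@dataclass(frozen=True)
class SyntheticRegistryConfig:
    n_constructs: int = 1000
    size_law: SizeLaw = field(default_factory=SizeLaw)
    revision_model: RevisionModel = field(default_factory=RevisionModel)
    stratum_effects: StratumEffects = field(default_factory=StratumEffects)
    death_model: DeathModel = field(default_factory=DeathModel)
    age_mix: AgeMix = field(default_factory=AgeMix)
    p_female: float = 0.60
    enrollment_start: dt.date = dt.date(2003, 4, 1)
    enrollment_end: dt.date = dt.date(2016, 12, 31)
    admin_censor_date: dt.date = dt.date(2016, 12, 31)
    seed: int = 0
    #: bearing mix for sampled constructs
    bearing_probs: Mapping[str, float] = field(
        default_factory=lambda: {"MoP": 0.50, "CoP": 0.32, "CoC": 0.18})
    #: explicit constructs (overrides n_constructs / size law / revision model)
    constructs: Optional[Sequence[ConstructSpec]] = None

    def validate(self) -> None:
        sl = self.size_law
        if sl.min_size > sl.max_size:
            raise ValueError("size_law: min_size > max_size")
        if sl.min_size < 1 or sl.pareto_exponent <= 1.0:
            raise ValueError("size_law: need min_size >= 1 and exponent > 1")
        if self.enrollment_end > self.admin_censor_date:
            raise ValueError("enrollment must end by the admin censor date")
        if self.enrollment_start >= self.enrollment_end:
            raise ValueError("empty enrollment window")
        if not 0.0 < self.p_female < 1.0:
            raise ValueError("p_female must be in (0, 1)")
        for probs in (self.age_mix.band_probs, self.bearing_probs):
            if any(p <= 0 for p in probs.values()):
                raise ValueError("probabilities must be strictly positive")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("probabilities must sum to 1")
        for v in list(self.stratum_effects.gender.values()) + \
                list(self.stratum_effects.age_band.values()):
            if v <= 0:
                raise ValueError("hazard factors must be strictly positive")
        for v in self.death_model.rate_by_band.values():
            if v < 0:
                raise ValueError("death rates must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form net failure for every generated construct.

    ``params`` maps each construct to its (shape, scale); the config's
    demographic mix supplies mixture weights for marginal strata.
    """

    params: Mapping[ConstructKey, tuple[float, float]]
    stratum_effects: StratumEffects
    age_mix: AgeMix
    p_female: float


def _cell_weights(truth: GroundTruth, stratum: Stratum) -> list[tuple[str, str, float]]:
    genders = ("M", "F") if stratum.gender == "all" else (stratum.gender,)
    bands = AGE_BANDS if stratum.age_band == "all" else (stratum.age_band,)
    cells = []
    for g in genders:
        pg = truth.p_female if g == "F" else 1.0 - truth.p_female
        for b in bands:
            cells.append((g, b, pg * truth.age_mix.band_probs[b]))
    total = sum(w for _, _, w in cells)
    return [(g, b, w / total) for g, b, w in cells]


def true_net_failure(truth: GroundTruth, construct: ConstructKey,
                     stratum: Stratum, t: float) -> float:
    """Ground-truth net failure F*(t) of a construct in a stratum.

    Within a single gender x age-band cell this is the Weibull CDF with the
    cell's hazard factor; marginal strata are the demographic-mix average
    of the cell values (the estimand a pooled 1-KM analysis of that
    stratum targets when censoring is non-informative within it).
    """
    if construct not in truth.params:
        raise KeyError(f"unknown construct {construct}")
    shape, scale = truth.params[construct]
    if t <= 0:
        return 0.0
    lam = (t / scale) ** shape
    return float(sum(
        w * (1.0 - math.exp(-truth.stratum_effects.factor(g, b) * lam))
        for g, b, w in _cell_weights(truth, stratum)))


def _sample_sizes(rng: np.random.Generator, law: SizeLaw, n: int) -> np.ndarray:
    ks = np.arange(law.min_size, law.max_size + 1, dtype=float)
    pmf = ks ** (-law.pareto_exponent)
    pmf /= pmf.sum()
    return rng.choice(ks.astype(np.int64), size=n, p=pmf)


def _scale_from_failure10(shape: float, f10: float) -> float:
    # solve 1 - exp(-(10/scale)^shape) = f10 for scale
    return 10.0 / (-math.log1p(-f10)) ** (1.0 / shape)


def generate_registry(config: SyntheticRegistryConfig
                      ) -> tuple[list[ProcedureRecord], GroundTruth]:
    """Generate one registry and its ground truth.

    Per record: demographics from the configured mix, primary date uniform
    on the enrollment window (at least one day before the extract date, so
    every record has positive follow-up), revision time from the
    construct's stratum-adjusted Weibull, death time exponential by cell.
    The revision date is recorded only when the revision precedes both
    death and administrative censoring; the death date is recorded whenever
    death precedes the extract date.  Times convert to dates at day
    resolution (365.25 days/year, minimum one day).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    n_constructs = (len(config.constructs) if config.constructs is not None
                    else config.n_constructs)
    children = ss.spawn(n_constructs + 1)
    param_rng = np.random.default_rng(children[0])

    if config.constructs is not None:
        specs = list(config.constructs)
    else:
        sizes = _sample_sizes(param_rng, config.size_law, n_constructs)
        shapes = param_rng.uniform(*config.revision_model.shape_range,
                                   size=n_constructs)
        lo, hi = config.revision_model.failure10_range
        f10 = np.exp(param_rng.uniform(math.log(lo), math.log(hi),
                                       size=n_constructs))
        bearings = param_rng.choice(list(config.bearing_probs),
                                    size=n_constructs,
                                    p=list(config.bearing_probs.values()))
        specs = [ConstructSpec(stem=f"stem-{i:04d}", cup=f"cup-{i:04d}",
                               bearing=str(bearings[i]),
                               shape=float(shapes[i]),
                               scale=_scale_from_failure10(float(shapes[i]),
                                                           float(f10[i])),
                               size=int(sizes[i]))
                 for i in range(n_constructs)]

    bands = list(AGE_BANDS)
    band_p = np.array([config.age_mix.band_probs[b] for b in bands])
    enroll_days = (config.enrollment_end - config.enrollment_start).days
    admin_offset = (config.admin_censor_date - config.enrollment_start).days

    records: list[ProcedureRecord] = []
    params: dict[ConstructKey, tuple[float, float]] = {}
    for ci, spec in enumerate(specs):
        key = ConstructKey.of(spec.stem, spec.cup, spec.bearing)
        params[key] = (spec.shape, spec.scale)
        n = spec.size
        rng = np.random.default_rng(children[ci + 1])
        female = rng.random(n) < config.p_female
        band_idx = rng.choice(len(bands), size=n, p=band_p)
        ages = np.empty(n, dtype=np.int64)
        for bi, b in enumerate(bands):
            lo_a, hi_a = config.age_mix.band_ranges[b]
            m = band_idx == bi
            ages[m] = rng.integers(lo_a, hi_a + 1, size=int(m.sum()))

        g_fac = np.where(female, config.stratum_effects.gender["F"],
                         config.stratum_effects.gender["M"])
        b_fac = np.array([config.stratum_effects.age_band[bands[i]]
                          for i in band_idx])
        haz = g_fac * b_fac
        # T | hazard factor c: scale * (E / c)^(1/shape), E ~ Exp(1)
        t_rev = spec.scale * (rng.exponential(size=n) / haz) ** (1.0 / spec.shape)

        g_dth = np.where(female, config.death_model.gender_factor["F"],
                         config.death_model.gender_factor["M"])
        rate = np.array([config.death_model.rate_by_band[bands[i]]
                         for i in band_idx]) * g_dth
        with np.errstate(divide="ignore"):
            t_death = np.where(rate > 0,
                               rng.exponential(size=n) / np.maximum(rate, 1e-300),
                               np.inf)

        # primary at least one day before the extract date
        primary_off = rng.integers(0, max(min(enroll_days, admin_offset - 1), 0) + 1,
                                   size=n)
        admin_days = admin_offset - primary_off
        rev_days = np.maximum(
            np.rint(np.minimum(t_rev, 1e6) * YEAR_DAYS), 1).astype(np.int64)
        # deaths later than the extract date are never recorded, so the day
        # count can be capped just beyond it (also avoids overflow at rate 0)
        death_days = np.maximum(
            np.rint(np.minimum(t_death * YEAR_DAYS, admin_offset + 1.0)), 1
        ).astype(np.int64)
        effective_end = np.minimum(death_days, admin_days)
        has_revision = rev_days <= effective_end
        has_death = death_days <= admin_days

        start = config.enrollment_start
        for j in range(n):
            primary = start + dt.timedelta(days=int(primary_off[j]))
            records.append(ProcedureRecord(
                procedure_id=f"C{ci:04d}-{j:05d}",
                gender="F" if female[j] else "M",
                age_at_primary=int(ages[j]),
                stem_brand=spec.stem,
                cup_brand=spec.cup,
                bearing=Bearing(spec.bearing),
                primary_date=primary,
                revision_date=primary + dt.timedelta(days=int(rev_days[j]))
                if has_revision[j] else None,
                death_date=primary + dt.timedelta(days=int(death_days[j]))
                if has_death[j] else None,
                mortality_traceable=True,
            ))
    truth = GroundTruth(params=params,
                        stratum_effects=config.stratum_effects,
                        age_mix=config.age_mix,
                        p_female=config.p_female)
    return records, truth


def write_ground_truth_csv(truth: GroundTruth, path: str | Path,
                           horizons: Sequence[float] = (3, 5, 7, 10)) -> None:
    """Sidecar CSV with each construct's Weibull parameters, per-stratum
    hazard factor and true net failure at the requested horizons."""
    strata = [Stratum(g, b) for g in ("M", "F") for b in AGE_BANDS]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["stem", "cup", "bearing", "gender", "age_band",
                    "shape", "scale", "factor"]
                   + [f"true_failure_{h}y" for h in horizons])
        for key in sorted(truth.params):
            shape, scale = truth.params[key]
            for s in strata:
                fac = truth.stratum_effects.factor(s.gender, s.age_band)
                w.writerow([key.stem, key.cup, key.bearing,
                            s.gender, s.age_band,
                            f"{shape:.6g}", f"{scale:.6g}", f"{fac:.6g}"]
                           + [f"{true_net_failure(truth, key, s, h):.6g}"
                              for h in horizons])
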