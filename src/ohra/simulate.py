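"""Synthetic workplace-exposure generator.

Published exposure tables typically print, per job/location, only the number
of measurements, the mean concentration, and the min–max range.  This module
turns such a summary row into a reproducible sample: workplace concentrations
are canonically lognormal, so a clipped lognormal is fitted to each row by

* treating the printed range as the expected extreme span of ``n`` draws:
  with z the standard-normal quantile at (n − 0.5)/n,
  ``sigma = ln(max/min) / (2 z)``;
* matching the mean: the plain moment condition is ``mu = ln(mean) −
  sigma²/2`` (:func:`fit_lognormal`); generation then recalibrates mu so the
  *clipped* distribution's mean equals the printed mean
  (:func:`calibrate_mu`), because the printed mean describes data bounded by
  the printed range.

Draws are quantile-stratified (one jittered draw per probability stratum, in
shuffled order) and clipped to [min, max]; a degenerate row (min = max) is a
point mass.  This is an emulation of the published summary structure, not a
reconstruction of any real dataset.

Per-row random streams are derived by stable hashing of the global seed with
(industry, location, hazard), so adding a row never perturbs the others.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.stats import norm

from .errors import ParameterError
from .exposure import DEFAULT_ED, DEFAULT_EF, DEFAULT_ET, ExposureRecord, write_exposure

log = logging.getLogger(__name__)


class SyntheticSpec(BaseModel):
    """One generation recipe: a summary row of an exposure table."""

    industry: str
    location: str
    hazard: str
    n: int = Field(ge=1)
    mean: float = Field(gt=0)
    min: float = Field(gt=0)
    max: float = Field(gt=0)
    distribution: Literal["lognormal-clipped", "uniform", "point"] = "lognormal-clipped"

    @model_validator(mode="after")
    def _ordered(self) -> "SyntheticSpec":
        if not (self.min <= self.mean <= self.max):
            raise ValueError(
                f"{self.industry}/{self.location}/{self.hazard}: "
                f"need min <= mean <= max, got {self.min}, {self.mean}, {self.max}"
            )
        return self


def fit_lognormal(mean: float, min_: float, max_: float, n: int) -> tuple[float, float]:
    """(mu, sigma) of the lognormal matching a printed (mean, range, n) row.

    The range is read as the expected extreme span of ``n`` draws; the
    implied (unclipped) mean equals ``mean`` exactly by construction.
    """
    if not (0 < min_ <= mean <= max_):
        raise ParameterError(f"need 0 < min <= mean <= max, got {min_}, {mean}, {max_}")
    if min_ == max_:
        return float(np.log(mean)), 0.0
    z = norm.ppf((n - 0.5) / n)
    sigma = float(np.log(max_ / min_) / (2.0 * z))
    mu = float(np.log(mean) - sigma**2 / 2.0)
    return mu, sigma


def clipped_lognormal_mean(mu: float, sigma: float, lo: float, hi: float) -> float:
    """Analytic mean of a lognormal clipped (not truncated) to [lo, hi]."""
    if sigma == 0.0:
        return float(np.exp(mu))
    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    core = np.exp(mu + sigma**2 / 2.0) * (norm.cdf(b - sigma) - norm.cdf(a - sigma))
    return float(lo * norm.cdf(a) + hi * norm.sf(b) + core)


def calibrate_mu(sigma: float, lo: float, hi: float, target_mean: float) -> float:
    """Location mu whose *clipped* lognormal mean equals ``target_mean``.

    A printed summary mean describes data that lie within the printed range,
    so generation matches the clipped distribution's mean, not the unclipped
    one: for wide ranges (sigma ≈ 2) the two differ by tens of percent.
    Falls back to the plain moment fit when the target sits on a range edge.
    """
    from scipy.optimize import brentq

    if not (lo < target_mean < hi):
        return float(np.log(target_mean) - sigma**2 / 2.0)
    a = float(np.log(lo)) - 40.0 * max(sigma, 1.0)
    b = float(np.log(hi)) + 40.0 * max(sigma, 1.0)
    return float(brentq(lambda mu: clipped_lognormal_mean(mu, sigma, lo, hi) - target_mean, a, b))


def _spec_seed(global_seed: int, spec: SyntheticSpec) -> int:
    key = f"{global_seed}|{spec.industry}|{spec.location}|{spec.hazard}"
    return int(hashlib.sha256(key.encode()).hexdigest()[:8], 16) % (2**31)


def _stratified_uniforms(n: int, rng: np.random.Generator) -> np.ndarray:
    """One jittered uniform per probability stratum, in shuffled order.

    Stratification pins each sample's empirical distribution to the fitted
    one, so a generated row reproduces its printed mean and range tightly
    even at n ≈ 15 — the point of emulating a summary table — while the
    jitter and shuffle keep draws random and seeded.
    """
    u = (np.arange(n) + rng.uniform(0.0, 1.0, n)) / n
    rng.shuffle(u)
    return u


def draw_concentrations(spec: SyntheticSpec, seed: int) -> np.ndarray:
    """``spec.n`` seeded concentration draws, clipped to [min, max]."""
    rng = np.random.default_rng(_spec_seed(seed, spec))
    if spec.distribution == "point" or spec.min == spec.max:
        return np.full(spec.n, spec.mean)
    u = _stratified_uniforms(spec.n, rng)
    if spec.distribution == "uniform":
        return spec.min + (spec.max - spec.min) * u
    _, sigma = fit_lognormal(spec.mean, spec.min, spec.max, spec.n)
    mu = calibrate_mu(sigma, spec.min, spec.max, spec.mean)
    with np.errstate(over="ignore"):
        draws = np.exp(mu + sigma * norm.ppf(u))
    return np.clip(draws, spec.min, spec.max)


def generate(
    specs: Iterable[SyntheticSpec],
    seed: int = 0,
    et: float = DEFAULT_ET,
    ef: float = DEFAULT_EF,
    ed: float = DEFAULT_ED,
) -> list[ExposureRecord]:
    """Exposure records for every spec, carrying full-shift defaults."""
    records = []
    for spec in specs:
        for ca in draw_concentrations(spec, seed):
            records.append(
                ExposureRecord(
                    industry=spec.industry, location=spec.location, hazard=spec.hazard,
                    ca=float(ca), et=et, ef=ef, ed=ed, n_workers=1,
                )
            )
    return records


_SPEC_COLUMNS = ["industry", "location", "hazard", "n", "mean", "min", "max"]


def load_specs(path: str | Path) -> list[SyntheticSpec]:
    """Read generation specs from a comma-separated summary table."""
    frame = pd.read_csv(path, comment="#")
    missing = set(_SPEC_COLUMNS) - set(frame.columns)
    if missing:
        raise ParameterError(f"spec file {path} lacks columns: {sorted(missing)}")
    specs = []
    for row in frame.to_dict("records"):
        data = {k: row[k] for k in _SPEC_COLUMNS}
        if "distribution" in frame.columns and isinstance(row.get("distribution"), str):
            data["distribution"] = row["distribution"]
        elif data["min"] == data["max"]:
            data["distribution"] = "point"
        specs.append(SyntheticSpec(**data))
    return specs


def default_specs_path() -> Path:
    return Path(__file__).parent / "data" / "five_industry_specs.csv"


def default_specs() -> list[SyntheticSpec]:
    """The shipped five-industry study structure (1,519 records in total)."""
    return load_specs(default_specs_path())


def ship_fixture(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the default registry, method config and a seeded exposure file.

    Returns the paths keyed as ``registry``, ``method_config``, ``exposure``,
    ``specs``.  Everything downstream of the pipeline can run from these.
    """
    import shutil

    from .config import default_config_path
    from .registry import default_registry_path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "registry": outdir / "registry.csv",
        "method_config": outdir / "method_config.yaml",
        "specs": outdir / "five_industry_specs.csv",
        "exposure": outdir / "exposure.csv",
    }
    shutil.copyfile(default_registry_path(), paths["registry"])
    shutil.copyfile(default_config_path(), paths["method_config"])
    shutil.copyfile(default_specs_path(), paths["specs"])
    records = generate(default_specs(), seed=seed)
    write_exposure(records, paths["exposure"])
    log.info("fixture written to %s (%d exposure records, seed %d)", outdir, len(records), seed)
    return paths
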