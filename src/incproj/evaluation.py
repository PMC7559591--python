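"""Rolling hold-out benchmarking: coverage, bias, precision, PIT.

The design mimics prospective use of a registry: for each projection
horizon ``n`` the models are trained on the ``L`` years ending ``n``
years before the most recent observed year ``T`` and asked to predict
the counts observed in year ``T``.  Three metrics summarise each
model x horizon combination, aggregated over age groups by arithmetic
mean:

coverage
    fraction of observed counts inside the equal-tailed 95% predictive
    band (inclusive bounds; a degenerate band covers only an exact hit);
bias
    ``100 * (observed - predicted) / observed`` per cell, 0 when they
    are equal; negative values mean overestimation.  Cells with an
    observed zero and a nonzero prediction are undefined and excluded,
    with the exclusion count reported;
precision
    the mean per-cell predictive standard deviation, reported raw and
    as ``log10(1 + sd)``.

Probability-integral-transform histograms use the nonrandomised PIT
for count data, ``(F(y) + F(y - 1)) / 2``: uniform under a calibrated
predictive distribution, U-shaped when dispersion is understated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ProjectionResult, make_projector
from .registry import RegistryTable

__all__ = [
    "EvaluationDesign",
    "MetricsRecord",
    "make_windows",
    "coverage",
    "bias",
    "precision",
    "evaluate",
    "pit",
    "metrics_frame",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationDesign:
    """Hold-out geometry: observation window length and horizons."""

    observation_length: int = 15
    horizons: tuple[int, ...] = (2, 5, 10, 15, 20)
    target_year: int | None = None  # defaults to the table's last year

    def resolve_target(self, t: RegistryTable) -> int:
        return int(t.years[-1]) if self.target_year is None else self.target_year


@dataclass
class MetricsRecord:
    """Aggregated metrics for one model at one horizon."""

    model: str
    horizon: int
    coverage: float
    bias: float
    precision_raw: float
    precision_transformed: float
    n_cells: int
    n_bias_undefined: int = 0
    strata: dict = field(default_factory=dict)
    error: str | None = None

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "horizon": self.horizon,
            "coverage": self.coverage,
            "bias": self.bias,
            "precision_raw": self.precision_raw,
            "precision_transformed": self.precision_transformed,
            "n_cells": self.n_cells,
            "n_bias_undefined": self.n_bias_undefined,
            "error": self.error,
        }
        d.update({f"stratum_{k}": v for k, v in self.strata.items()})
        return d


def make_windows(t: RegistryTable, d: EvaluationDesign):
    """Training/target slices per horizon.

    For horizon ``n``: training years ``[T - n - L + 1, T - n]`` (an
    L-year window ending ``n`` years before the target) and target year
    ``T``.  Horizons the table cannot support are skipped with a logged
    warning.
    """
    T = d.resolve_target(t)
    L = d.observation_length
    out = []
    for n in d.horizons:
        first = T - n - L + 1
        last = T - n
        if first < t.years[0] or T > t.years[-1]:
            log.warning("horizon %d skipped: needs years %d..%d", n, first, T)
            continue
        out.append((t.slice_years(first, last), t.slice_years(T, T), n))
    return out


def coverage(proj: ProjectionResult, observed: np.ndarray) -> float:
    """Fraction of observations inside their 95% band, bounds inclusive."""
    obs = np.asarray(observed, dtype=float).reshape(-1)
    lo = proj.lo.reshape(-1)
    hi = proj.hi.reshape(-1)
    if obs.size != lo.size:
        raise ValueError(f"{obs.size} observations for {lo.size} cells")
    return float(np.mean((lo <= obs) & (obs <= hi)))


def bias(observed, predicted):
    """Percent bias per cell: 0 on equality, else 100*(obs - pred)/obs.

    Negative values mean the model over-predicted.  Returns NaN where
    the observation is zero but the prediction is not (the ratio is
    undefined there; aggregation excludes and counts those cells).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    out = np.zeros(np.broadcast(obs, pred).shape)
    obs, pred = np.broadcast_arrays(obs, pred)
    neq = obs != pred
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = 100.0 * (obs - pred) / obs
    out[neq] = ratio[neq]
    out[(obs == 0) & neq] = np.nan
    return out if out.ndim else float(out)


def precision(proj: ProjectionResult) -> tuple[float, float]:
    """(mean predictive SD, log10(1 + mean predictive SD))."""
    raw = float(proj.sd.mean())
    return raw, float(np.log10(1.0 + raw))


def pit(proj: ProjectionResult, observed: np.ndarray, n_bins: int = 10):
    """Nonrandomised PIT histogram counts for count forecasts.

    Uses ``(F(y) + F(y-1))/2`` per cell, binned into ``n_bins`` equal
    bins on [0, 1]; requires the projection to carry predictive samples.
    """
    obs = np.asarray(observed, dtype=float).reshape(proj.mean.shape)
    Fy = proj.predictive_cdf(obs)
    Fy1 = proj.predictive_cdf(obs - 1)
    u = 0.5 * (Fy + Fy1)
    edges = np.linspace(0, 1, n_bins + 1)
    counts, _ = np.histogram(u.reshape(-1), bins=edges)
    return counts, edges


def _aggregate(model: str, horizon: int, proj_last: ProjectionResult,
               observed: np.ndarray, strata: dict) -> MetricsRecord:
    cov = coverage(proj_last, observed)
    b = bias(observed.reshape(-1), proj_last.mean.reshape(-1))
    undef = int(np.isnan(b).sum())
    bmean = float(np.nanmean(b)) if undef < b.size else float("nan")
    raw, trans = precision(proj_last)
    return MetricsRecord(model, horizon, cov, bmean, raw, trans,
                         n_cells=b.size - undef + undef, strata=dict(strata),
                         n_bias_undefined=undef)


def evaluate(
    t: RegistryTable,
    models: dict[str, dict] | list[str],
    design: EvaluationDesign | None = None,
    seed: int = 0,
    n_samples: int = 2000,
    keep_samples: bool = False,
    band: str = "expected",
    model_factory=make_projector,
) -> tuple[list[MetricsRecord], dict[tuple[str, int], ProjectionResult]]:
    """Fit every model on every training window and score the target year.

    ``models`` maps model names (see ``MODEL_REGISTRY``) to constructor
    options.  Future person-years handed to the models are the observed
    populations of the projection years — the benchmark isolates rate
    modelling from demographic forecasting.  Individual fit failures are
    recorded in the metrics (``error`` field) and skipped.

    ``band`` picks the interval convention the metrics score (default:
    the credible band of the projected expected count — the convention
    under which a model is rewarded for genuine uncertainty about the
    rate surface rather than for fitted dispersion).  PIT histograms,
    when requested via ``keep_samples``, always use count-scale
    predictive samples.

    Returns the metric records and the per-(model, horizon) projections
    for the target year.
    """
    if design is None:
        design = EvaluationDesign()
    if isinstance(models, list):
        models = {name: {} for name in models}
    T = design.resolve_target(t)
    records: list[MetricsRecord] = []
    projections: dict[tuple[str, int], ProjectionResult] = {}
    strata = dict(t.meta)
    for w_idx, (train, target, n) in enumerate(make_windows(t, design)):
        future = t.slice_years(T - n + 1, T)
        observed = target.incidence[0]
        for m_idx, (name, opts) in enumerate(sorted(models.items())):
            sub_seed = (seed * 1000003 + w_idx * 97 + m_idx) % (2**31 - 1)
            try:
                opts = dict(opts)
                est = model_factory(name, **_with_seed(name, opts, sub_seed))
                est.fit(train)
                proj = est.project(
                    future_N=future.population, horizon=n,
                    n_samples=n_samples, seed=sub_seed + 1,
                    keep_samples=keep_samples, band=band)
            except Exception as err:  # recorded, not fatal
                log.warning("model %s failed at horizon %d: %s", name, n, err)
                records.append(MetricsRecord(
                    name, n, float("nan"), float("nan"), float("nan"),
                    float("nan"), 0, strata=strata, error=str(err)))
                continue
            last = proj.last_year()
            rec = _aggregate(name, n, last, observed, strata)
            records.append(rec)
            projections[(name, n)] = proj
    return records, projections


def _with_seed(name: str, opts: dict, seed: int) -> dict:
    if name.startswith("constant"):
        return opts
    opts.setdefault("seed", seed)
    return opts


def metrics_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    """Tidy DataFrame of metric records (one row per model x horizon)."""
    return pd.DataFrame([r.to_dict() for r in records])
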