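"""Screening-campaign analytics: hit rates, portfolio summaries, the
hit-rate-versus-training-data regression, and scaffold-novelty distributions.

A campaign is a row of counts and rates: compounds tested, single-dose (SD)
hit rate, dose-response (DR) reconfirmation rate, and optionally an analog
round with its own rates. Portfolio summaries are unweighted means across
projects, reported to printed precision with half-up rounding; a tested-count
weighted variant is available. The packaged fixture
``internal_programs.csv`` transcribes a 22-program internal portfolio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chem import bulk_tanimoto

__all__ = [
    "ProjectRecord",
    "PortfolioSummary",
    "load_project_table",
    "packaged_internal_table",
    "hit_rate",
    "summarize_portfolio",
    "reconfirmation_rate",
    "hitrate_vs_training_regression",
    "novelty_distribution",
]

_DATA_DIR = Path(__file__).parent / "data"


def _round_half_up(value: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ProjectRecord:
    """One screening campaign's counts and rates (rates in percent)."""

    project_id: str
    n_tested: int
    sd_hit_rate: float
    dr_hit_rate: float | None = None
    n_analogs: int | None = None
    analog_sd_rate: float | None = None
    analog_dr_rate: float | None = None
    n_training_actives: int | None = None
    structure_source: str | None = None
    target_class: str | None = None
    assay_type: str | None = None

    def __post_init__(self) -> None:
        if self.n_tested < 0:
            raise ValueError(f"{self.project_id}: n_tested must be >= 0")
        for name in ("sd_hit_rate", "dr_hit_rate", "analog_sd_rate", "analog_dr_rate"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{self.project_id}: {name}={v} outside [0, 100]")


@dataclass
class PortfolioSummary:
    """Derived portfolio statistics; every field is recomputable from the records."""

    n_projects: int
    mean_sd_hit_rate: float
    mean_dr_hit_rate: float | None
    mean_analog_sd_rate: float | None
    mean_analog_dr_rate: float | None
    median_sd_hit_rate: float
    success_rate: float
    reconfirmation_rate: float | None
    mean_n_tested: float
    weighted_sd_hit_rate: float
    strata: dict[str, dict[str, float]] | None = None


def load_project_table(path: str | Path) -> list[ProjectRecord]:
    """Read campaign records from CSV (missing optional cells allowed)."""
    df = pd.read_csv(path)

    def cell(row, name, cast):
        v = row.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return cast(v)

    records = []
    for _, row in df.iterrows():
        records.append(
            ProjectRecord(
                project_id=str(row["project_id"]),
                n_tested=int(row["n_tested"]),
                sd_hit_rate=float(row["sd_hit_rate"]),
                dr_hit_rate=cell(row, "dr_hit_rate", float),
                n_analogs=cell(row, "n_analogs", int),
                analog_sd_rate=cell(row, "analog_sd_rate", float),
                analog_dr_rate=cell(row, "analog_dr_rate", float),
                n_training_actives=cell(row, "n_training_actives", int),
                structure_source=cell(row, "structure_source", str),
                target_class=cell(row, "target_class", str),
                assay_type=cell(row, "assay_type", str),
            )
        )
    return records


def packaged_internal_table() -> list[ProjectRecord]:
    """The packaged 22-program internal-portfolio transcription."""
    return load_project_table(_DATA_DIR / "internal_programs.csv")


def hit_rate(n_hits: int, n_tested: int) -> float:
    """Percentage of tested molecules that were active: 100 * hits / tested."""
    if n_tested <= 0:
        raise ValueError("n_tested must be > 0")
    if not (0 <= n_hits <= n_tested):
        raise ValueError(f"n_hits={n_hits} outside [0, {n_tested}]")
    return 100.0 * n_hits / n_tested


def _mean(values: list[float], ndigits: int = 1) -> float | None:
    if not values:
        return None
    return _round_half_up(float(np.mean(values)), ndigits)


def summarize_portfolio(
    records: Sequence[ProjectRecord],
    *,
    stratify_by: str | None = None,
) -> PortfolioSummary:
    """Unweighted means of each rate column across projects (printed to 1 dp,
    half-up), plus success and reconfirmation rates as whole percents.

    Analog means cover only projects reporting analog rates (a project with an
    analog count but no rates is excluded from those means). ``stratify_by``
    adds per-stratum SD/DR means over e.g. ``structure_source`` or
    ``target_class``.
    """
    if not records:
        raise ValueError("summarize_portfolio requires at least one record")
    sd = [r.sd_hit_rate for r in records]
    dr = [r.dr_hit_rate for r in records if r.dr_hit_rate is not None]
    asd = [r.analog_sd_rate for r in records if r.analog_sd_rate is not None]
    adr = [r.analog_dr_rate for r in records if r.analog_dr_rate is not None]
    success = 100.0 * sum(1 for r in records if r.sd_hit_rate > 0) / len(records)
    reconf = None
    if len(dr) == len(records):
        reconf = reconfirmation_rate(records)
    tested = np.array([r.n_tested for r in records], dtype=float)
    weighted = float(np.sum(np.array(sd) * tested) / tested.sum())
    strata = None
    if stratify_by is not None:
        strata = {}
        for r in records:
            key = getattr(r, stratify_by)
            if key is None:
                continue
            strata.setdefault(key, []).append(r)
        strata = {
            key: {
                "n": len(group),
                "mean_sd_hit_rate": _mean([g.sd_hit_rate for g in group]),
                "mean_dr_hit_rate": _mean(
                    [g.dr_hit_rate for g in group if g.dr_hit_rate is not None]
                ),
            }
            for key, group in sorted(strata.items())
        }
    return PortfolioSummary(
        n_projects=len(records),
        mean_sd_hit_rate=_mean(sd),
        mean_dr_hit_rate=_mean(dr),
        mean_analog_sd_rate=_mean(asd),
        mean_analog_dr_rate=_mean(adr),
        median_sd_hit_rate=_round_half_up(float(np.median(sd)), 2),
        success_rate=_round_half_up(success),
        reconfirmation_rate=reconf,
        mean_n_tested=_round_half_up(float(tested.mean()), 1),
        weighted_sd_hit_rate=_round_half_up(weighted, 1),
        strata=strata,
    )


def reconfirmation_rate(records: Sequence[ProjectRecord]) -> float:
    """Percent of projects whose SD hits reconfirmed in dose-response
    (dr_hit_rate > 0), rounded to a whole percent."""
    missing = [r.project_id for r in records if r.dr_hit_rate is None]
    if missing:
        raise ValueError(f"dr_hit_rate missing for {missing}")
    frac = sum(1 for r in records if r.dr_hit_rate > 0) / len(records)
    return _round_half_up(100.0 * frac)


def hitrate_vs_training_regression(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float, float]:
    """Ordinary least squares of hit rate on training-set size (closed form).

    Returns (slope, intercept, R^2, two-sided p-value of the slope t-test).
    Used to ask whether screening performance depends on how many known
    actives the model saw for the target: a flat fit (R^2 near 0, large p)
    indicates extrapolation beyond the training chemistry.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("zero variance in x; slope undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    dof = n - 2
    se = math.sqrt(ss_res / dof / sxx) if dof > 0 else float("nan")
    if se == 0.0:
        p_value = 0.0
    else:
        t = slope / se
        p_value = 2.0 * float(sps.t.sf(abs(t), dof))
    return slope, intercept, r_squared, p_value


def novelty_distribution(
    hits: np.ndarray,
    training_actives: np.ndarray,
    *,
    bins: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-hit maximum Tanimoto to any training active, plus a histogram.

    With an empty training set every hit scores 0 (nothing was known for the
    target). Returns (values, bin_counts, bin_edges) with edges spanning
    [0, 1].
    """
    hits = np.atleast_2d(np.asarray(hits))
    if training_actives is None or np.size(training_actives) == 0:
        values = np.zeros(hits.shape[0])
    else:
        values = bulk_tanimoto(hits, np.atleast_2d(training_actives)).max(axis=1)
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    return values, counts, edges
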