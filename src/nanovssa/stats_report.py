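"""Summary statistics for VSSA studies.

Per material: mean +/- SEM of the per-reconstruction VSSA values, a
two-sided one-sample t-test against the 60 m^2/cm^3 nanostructure
threshold, and — for spherical validation runs — Spearman rank
correlations between the measured (isosurface) totals and the totals
calculated from the projected ECD via the perfect-sphere formulas.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as _spstats

from .surface import NANOSTRUCTURE_THRESHOLD

__all__ = [
    "MaterialSummary",
    "spearman_rho",
    "one_sample_t",
    "mean_sem",
    "build_report",
]


def spearman_rho(x, y) -> float:
    """Spearman rank-order correlation: Pearson correlation of mid-ranks
    (ties get average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("spearman_rho needs two equal-length 1D arrays, n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank correlation undefined")
    rx = _spstats.rankdata(x)  # mid-ranks
    ry = _spstats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def one_sample_t(values, mu0: float) -> tuple[float, float]:
    """t = (mean - mu0) / (sd / sqrt(n)); two-sided p, n-1 df."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("one_sample_t needs n >= 2")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero sample standard deviation: t undefined")
    n = len(v)
    t = (v.mean() - mu0) / (sd / math.sqrt(n))
    p = 2.0 * _spstats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def mean_sem(values) -> tuple[float, float]:
    """Arithmetic mean and standard error (sample sd / sqrt(n))."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("mean_sem needs n >= 2")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(len(v)))


@dataclass
class MaterialSummary:
    material: str
    n: int
    vssa_values: list
    mean: float
    sem: float
    t_stat: float | None
    p_value: float | None
    classified_nano: bool
    rho_area: float | None = None
    rho_volume: float | None = None
    alpha: float = 0.05
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def build_report(records, material: str, alpha: float = 0.05) -> MaterialSummary:
    """Assemble the per-material summary from per-reconstruction records.

    ``records`` is a sequence of dicts with at least ``vssa``; records that
    additionally carry ``measured_area``/``calc_area`` and
    ``measured_volume``/``calc_volume`` feed the validation correlations.
    Statistics that cannot be computed (insufficient n, zero variance) are
    omitted with an explanatory note rather than failing the report.
    """
    vssa = [float(r["vssa"]) for r in records]
    if len(vssa) < 2:
        raise ValueError("build_report needs >= 2 reconstructions")
    mean, sem = mean_sem(vssa)
    notes: list[str] = []
    try:
        t_stat, p_value = one_sample_t(vssa, NANOSTRUCTURE_THRESHOLD)
    except ValueError as exc:
        t_stat = p_value = None
        notes.append(f"t-test omitted: {exc}")
    classified = mean > NANOSTRUCTURE_THRESHOLD and (
        p_value is not None and p_value < alpha)

    rho_area = rho_volume = None
    paired = [r for r in records
              if "measured_area" in r and "calc_area" in r
              and "measured_volume" in r and "calc_volume" in r]
    if len(paired) >= 3:
        try:
            rho_area = spearman_rho([r["measured_area"] for r in paired],
                                    [r["calc_area"] for r in paired])
            rho_volume = spearman_rho([r["measured_volume"] for r in paired],
                                      [r["calc_volume"] for r in paired])
        except ValueError as exc:
            notes.append(f"validation correlation omitted: {exc}")
    elif paired:
        notes.append("validation correlation omitted: fewer than 3 paired "
                     "reconstructions")
    return MaterialSummary(material=material, n=len(vssa), vssa_values=vssa,
                           mean=mean, sem=sem, t_stat=t_stat, p_value=p_value,
                           classified_nano=classified, rho_area=rho_area,
                           rho_volume=rho_volume, alpha=alpha, notes=notes)
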